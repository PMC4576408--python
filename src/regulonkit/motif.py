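"""Position weight matrix with a two-block core model.

Bacterial TF binding sites typically carry most of their information in two
short "core" blocks (half-sites) that are related by an intrinsic symmetry:
reverse-complement copies (palindromic), identical copies (direct repeat),
or reversed copies without complementation (inverted repeat).  The motif
model here is a plain PWM annotated with the two core block intervals and
the symmetry class inferred from them.

All dissimilarities are symmetrised Kullback-Leibler divergences in bits,
averaged over the block columns, so that a value of 0 means the transformed
blocks are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BASES

SYMMETRIES = ("palindromic", "direct_repeat", "inverted_repeat")

#: complement permutation of the A,C,G,T axis
_COMP = np.array([3, 2, 1, 0])


@dataclass
class MotifModel:
    """A PWM theta (w x 4, rows sum to 1) with core-block annotation.

    block1/block2 are half-open column intervals of equal length c >= 3,
    block1 strictly before block2.  `symmetry` is one of "palindromic",
    "direct_repeat", "inverted_repeat" or "none".
    """

    theta: np.ndarray
    block1: tuple[int, int] | None = None
    block2: tuple[int, int] | None = None
    symmetry: str = "none"
    alpha: float = 0.5
    name: str = "motif"
    nsites: int = 0
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.theta.ndim != 2 or self.theta.shape[1] != 4:
            raise ValueError("theta must be a w x 4 matrix")
        if np.any(self.theta <= 0):
            raise ValueError("theta entries must be strictly positive")
        if np.max(np.abs(self.theta.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("theta rows must sum to 1")
        if (self.block1 is None) != (self.block2 is None):
            raise ValueError("block1 and block2 must be given together")
        if self.block1 is not None:
            _check_blocks(self.width, self.block1, self.block2)

    @property
    def width(self) -> int:
        return self.theta.shape[0]

    @property
    def consensus(self) -> str:
        """Argmax base per column; ties resolved alphabetically."""
        # np.argmax takes the first maximum, and columns are in ACGT order
        return "".join(BASES[i] for i in np.argmax(self.theta, axis=1))

    def information_content(self) -> float:
        """Total information content in bits relative to uniform background."""
        return float(np.sum(2.0 + np.sum(self.theta * np.log2(self.theta), axis=1)))


def _check_blocks(width: int, block1: tuple[int, int], block2: tuple[int, int]) -> None:
    s1, e1 = block1
    s2, e2 = block2
    c1, c2 = e1 - s1, e2 - s2
    if c1 != c2:
        raise ValueError("blocks must have equal length")
    if c1 < 3:
        raise ValueError("block length must be >= 3")
    if not (0 <= s1 < e1 <= s2 < e2 <= width):
        raise ValueError("blocks must be disjoint, ordered, and inside [0, w)")


def transform_block(block: np.ndarray, symmetry: str) -> np.ndarray:
    """Apply the symmetry transform to a c x 4 block (the second core).

    palindromic: reverse columns and complement bases; direct_repeat:
    identity; inverted_repeat: reverse columns only.
    """
    if symmetry == "palindromic":
        return block[::-1][:, _COMP]
    if symmetry == "direct_repeat":
        return block
    if symmetry == "inverted_repeat":
        return block[::-1]
    raise ValueError(f"unknown symmetry {symmetry!r}")


def block_dissimilarity(
    theta: np.ndarray,
    block1: tuple[int, int],
    block2: tuple[int, int],
    symmetry: str,
) -> float:
    """Averaged symmetrised-KL distance between the two core blocks, in bits.

    D = (1/c) * sum_j [KL(p_j || q_j) + KL(q_j || p_j)] / 2 where p_j is
    the j-th column of block1 and q_j the j-th column of the symmetry-
    transformed block2.  D = 0 iff the transformed blocks are identical.
    """
    theta = np.asarray(theta, dtype=float)
    _check_blocks(theta.shape[0], block1, block2)
    if np.any(theta[block1[0] : block1[1]] <= 0) or np.any(
        theta[block2[0] : block2[1]] <= 0
    ):
        raise ValueError("theta has zero entries; apply pseudocounts first")
    p = theta[block1[0] : block1[1]]
    q = transform_block(theta[block2[0] : block2[1]], symmetry)
    # KL(p||q)+KL(q||p) collapses to sum (p-q)*log2(p/q)
    d = np.sum((p - q) * (np.log2(p) - np.log2(q)))
    c = block1[1] - block1[0]
    return float(d / (2.0 * c))


def select_symmetry(
    theta: np.ndarray,
    block1: tuple[int, int],
    block2: tuple[int, int],
    none_threshold: float = 1.0,
) -> tuple[str, float]:
    """Pick the symmetry class minimising the block dissimilarity.

    Returns ("none", D_min) when even the best class exceeds
    `none_threshold` bits.  Ties go to the first class in the fixed order
    palindromic > direct_repeat > inverted_repeat.
    """
    dists = {s: block_dissimilarity(theta, block1, block2, s) for s in SYMMETRIES}
    best = min(SYMMETRIES, key=lambda s: (dists[s], SYMMETRIES.index(s)))
    d_min = dists[best]
    if d_min > none_threshold:
        return "none", d_min
    return best, d_min


def find_blocks(
    theta: np.ndarray,
    c_min: int = 3,
    c_max: int | None = None,
    lam: float = 1.0,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Locate the two core blocks by exhaustive search.

    Scores every ordered pair of disjoint equal-length blocks with
    c in [c_min, c_max] by (total information content of both blocks)
    minus lam times the minimum-over-symmetries dissimilarity, and returns
    the maximiser.  Ties prefer smaller c, then leftmost block1, then
    leftmost block2.
    """
    theta = np.asarray(theta, dtype=float)
    w = theta.shape[0]
    if c_max is None:
        c_max = w // 2
    c_max = min(c_max, w // 2)
    if w < 2 * c_min:
        raise ValueError(f"width {w} too small for two blocks of length {c_min}")
    ic_col = 2.0 + np.sum(theta * np.log2(theta), axis=1)
    ic_cum = np.concatenate([[0.0], np.cumsum(ic_col)])
    best_key: tuple | None = None
    best_pair: tuple[tuple[int, int], tuple[int, int]] | None = None
    for c in range(c_min, c_max + 1):
        for s1 in range(0, w - 2 * c + 1):
            b1 = (s1, s1 + c)
            ic1 = ic_cum[s1 + c] - ic_cum[s1]
            for s2 in range(s1 + c, w - c + 1):
                b2 = (s2, s2 + c)
                ic2 = ic_cum[s2 + c] - ic_cum[s2]
                d_min = min(
                    block_dissimilarity(theta, b1, b2, s) for s in SYMMETRIES
                )
                score = ic1 + ic2 - lam * d_min
                # larger score wins; ties -> smaller c, then leftmost
                key = (-score, c, s1, s2)
                if best_key is None or key < best_key:
                    best_key = key
                    best_pair = (b1, b2)
    assert best_pair is not None
    return best_pair


def annotate_blocks(
    theta: np.ndarray,
    c_min: int = 3,
    c_max: int | None = None,
    lam: float = 1.0,
    none_threshold: float = 1.0,
    **model_kwargs,
) -> MotifModel:
    """Build a MotifModel with blocks and symmetry inferred from theta."""
    b1, b2 = find_blocks(theta, c_min=c_min, c_max=c_max, lam=lam)
    symmetry, _ = select_symmetry(theta, b1, b2, none_threshold=none_threshold)
    return MotifModel(theta=theta, block1=b1, block2=b2, symmetry=symmetry, **model_kwargs)
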