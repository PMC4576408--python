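"""PWM genome scanning: log-likelihood-ratio scores and exact p-values.

A candidate site of width w is scored by the log2 likelihood ratio of the
window under the PWM versus the 0-order genome background.  The p-value of
a score is the probability of reaching that score or better in a random
background word; it is computed exactly by the classic dynamic-programming
convolution of the discretised per-column score distributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import Genome, encode, revcomp
from .motif import MotifModel

logger = logging.getLogger(__name__)

BACKGROUND_FLOOR = 1e-3


@dataclass(frozen=True)
class BindingSite:
    """A scored genomic locus. `sequence` is the site in strand orientation."""

    contig: str
    start: int
    strand: str
    sequence: str
    score: float
    p_value: float


def safe_background(background: np.ndarray) -> np.ndarray:
    """Floor zero/tiny background entries at 1e-3 and renormalise."""
    bg = np.asarray(background, dtype=float)
    if np.any(bg < BACKGROUND_FLOOR):
        warnings.warn(
            "background has near-zero entries; flooring at 1e-3 and renormalising",
            stacklevel=2,
        )
        bg = np.maximum(bg, BACKGROUND_FLOOR)
        bg = bg / bg.sum()
    return bg


def llr_matrix(motif: MotifModel, background: np.ndarray) -> np.ndarray:
    """Per-position log2(theta/background) contribution table (w x 4)."""
    bg = safe_background(background)
    return np.log2(motif.theta) - np.log2(bg)[None, :]


def llr_score(motif: MotifModel, background: np.ndarray, kmer: str) -> float | None:
    """Log2 likelihood ratio of a w-mer, or None for unscorable (N) windows."""
    if len(kmer) != motif.width:
        raise ValueError(f"kmer length {len(kmer)} != motif width {motif.width}")
    codes = encode(kmer.upper())
    if np.any(codes < 0):
        return None
    mat = llr_matrix(motif, background)
    return float(mat[np.arange(motif.width), codes].sum())


class ScoreDistribution:
    """Exact distribution of the discretised LLR score under the background.

    Per-column score contributions are rounded to a common grid of step
    `eps`; the distribution of their sum is the w-fold convolution of the
    per-column distributions.  Scores are looked up on the same grid, so a
    word's p-value is exactly the background mass of words whose discretised
    score is >= the word's discretised score.
    """

    def __init__(self, motif: MotifModel, background: np.ndarray, eps: float | None = None):
        bg = safe_background(background)
        mat = llr_matrix(motif, bg)
        if eps is None:
            span = float(mat.max(axis=1).sum() - mat.min(axis=1).sum())
            eps = span / 10000.0 if span > 0 else 1e-4
        if eps <= 0:
            raise ValueError("eps must be positive")
        self.eps = float(eps)
        self.int_matrix = np.rint(mat / self.eps).astype(np.int64)
        w = motif.width
        lo = int(self.int_matrix.min(axis=1).sum())
        hi = int(self.int_matrix.max(axis=1).sum())
        # DP over columns: convolve per-column point masses
        cur = np.array([1.0])
        cur_lo = 0
        for j in range(w):
            col_lo = int(self.int_matrix[j].min())
            col_hi = int(self.int_matrix[j].max())
            col = np.zeros(col_hi - col_lo + 1)
            for b in range(4):
                col[self.int_matrix[j, b] - col_lo] += bg[b]
            cur = np.convolve(cur, col)
            cur_lo += col_lo
        assert cur_lo == lo and len(cur) == hi - lo + 1
        pmf = cur
        self.lo = lo
        self.hi = hi
        self.pmf = pmf
        # survival[i] = P(score_grid >= lo + i)
        self.survival = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])
        self.background = bg

    @property
    def total_mass(self) -> float:
        return float(self.pmf.sum())

    def int_score(self, codes: np.ndarray) -> int:
        """Discretised score of an encoded word (grid units)."""
        w = self.int_matrix.shape[0]
        return int(self.int_matrix[np.arange(w), codes].sum())

    def p_value_int(self, int_score: int) -> float:
        """P(score >= int_score) on the grid."""
        if int_score <= self.lo:
            return 1.0
        if int_score > self.hi:
            return 0.0
        return float(self.survival[int_score - self.lo])

    def p_value(self, score: float) -> float:
        """P-value of a real-valued score, rounded onto the grid."""
        return self.p_value_int(int(np.rint(score / self.eps)))


def _scan_strand(
    codes: np.ndarray, real_mat: np.ndarray, int_mat: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Score every window of one strand; returns (scores, int_scores, valid)."""
    w = real_mat.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        z = np.zeros(0)
        return z, z.astype(np.int64), np.zeros(0, dtype=bool)
    idx = np.arange(n)[:, None] + np.arange(w)[None, :]
    windows = codes[idx]
    valid = np.all(windows >= 0, axis=1)
    safe = np.where(windows >= 0, windows, 0)
    pos = np.arange(w)[None, :]
    scores = real_mat[pos, safe].sum(axis=1)
    iscores = int_mat[pos, safe].sum(axis=1)
    return scores, iscores, valid


def scan_genome(
    genome: Genome,
    motif: MotifModel,
    p_threshold: float = 0.001,
    s_threshold: float | None = None,
    max_sites: int | None = None,
    eps: float | None = None,
    background: np.ndarray | None = None,
) -> list[BindingSite]:
    """Scan both strands of every contig, keeping sites that pass both
    the p-value and the raw-score thresholds.

    A reverse-complement pair of hits covering the same window (the usual
    case for palindromic motifs) is collapsed to the higher-scoring strand,
    with ties going to +.  Output is sorted by (contig, start, strand).
    """
    if s_threshold is None:
        s_threshold = choose_score_threshold(motif, background=background)
    bg = safe_background(genome.background if background is None else background)
    w = motif.width
    dist = ScoreDistribution(motif, bg, eps=eps)
    real_mat = llr_matrix(motif, bg)
    int_mat = dist.int_matrix
    # reverse-complement score matrices: scoring the - strand of window
    # [i, i+w) equals scoring the revcomp word with the forward matrices
    rc_real = real_mat[::-1, ::-1]
    rc_int = int_mat[::-1, ::-1]
    sites: list[BindingSite] = []
    n_skipped = 0
    for contig, seq in genome.contigs.items():
        if len(seq) < w:
            continue
        codes = encode(seq)
        fwd_s, fwd_i, fwd_ok = _scan_strand(codes, real_mat, int_mat)
        rev_s, rev_i, rev_ok = _scan_strand(codes, rc_real, rc_int)
        n_skipped += int((~fwd_ok).sum())
        # collapse +/- hits on the same window: keep higher score, tie -> +
        best: dict[int, tuple[str, float, int]] = {}
        for strand, scores, iscores, ok in (
            ("+", fwd_s, fwd_i, fwd_ok),
            ("-", rev_s, rev_i, rev_ok),
        ):
            hit = ok & (scores >= s_threshold)
            for i in np.nonzero(hit)[0]:
                p = dist.p_value_int(int(iscores[i]))
                if p > p_threshold:
                    continue
                prev = best.get(int(i))
                if prev is None or float(scores[i]) > prev[1]:
                    best[int(i)] = (strand, float(scores[i]), int(iscores[i]))
        for start, (strand, score, iscore) in sorted(best.items()):
            word = seq[start : start + w]
            if strand == "-":
                word = revcomp(word)
            sites.append(
                BindingSite(
                    contig=contig,
                    start=start,
                    strand=strand,
                    sequence=word,
                    score=score,
                    p_value=dist.p_value_int(iscore),
                )
            )
    if n_skipped:
        logger.info("skipped %d N-containing windows", n_skipped)
    sites.sort(key=lambda s: (s.contig, s.start, s.strand))
    if max_sites is not None and len(sites) > max_sites:
        sites = sorted(sites, key=lambda s: -s.score)[:max_sites]
        sites.sort(key=lambda s: (s.contig, s.start, s.strand))
    return sites


def max_score(motif: MotifModel, background: np.ndarray | None = None) -> float:
    """Maximum achievable LLR score (best base per column)."""
    bg = safe_background(
        motif.background if background is None else np.asarray(background)
    )
    return float(llr_matrix(motif, bg).max(axis=1).sum())


def choose_score_threshold(
    motif: MotifModel,
    reference_sites: list[str] | None = None,
    recover_fraction: float = 0.9,
    background: np.ndarray | None = None,
) -> float:
    """Pick a raw-score threshold.

    With reference sites: the largest threshold that still recovers at
    least `recover_fraction` of them (sites with N are excluded with a
    warning).  Without: 60% of the maximum achievable score.
    """
    bg = motif.background if background is None else np.asarray(background)
    if not reference_sites:
        return 0.6 * max_score(motif, bg)
    scores = []
    n_bad = 0
    for s in reference_sites:
        sc = llr_score(motif, bg, s)
        if sc is None:
            n_bad += 1
            continue
        scores.append(sc)
    if n_bad:
        warnings.warn(f"excluded {n_bad} unscorable reference sites", stacklevel=2)
    if not scores:
        return 0.6 * max_score(motif, bg)
    scores.sort(reverse=True)
    need = int(np.ceil(recover_fraction * len(scores)))
    return scores[need - 1]
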