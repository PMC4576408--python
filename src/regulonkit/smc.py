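"""Sequential Monte Carlo motif discovery with a two-block symmetry prior.

The generative model: each upstream sequence carries at most one motif
instance (presence prior pi), placed uniformly over offsets and strands;
instance columns follow an unknown PWM theta with a Dirichlet(alpha) prior;
all other positions follow the 0-order background.  Sequences are absorbed
one at a time (in the caller-supplied feeding order): a particle is a
hypothesis of all placements so far, and each step samples the new
placement from its Dirichlet-multinomial predictive, re-weighted by a
symmetry prior exp(-lam_sym * D_min) on the tentatively-updated posterior
mean PWM, where D_min is the best two-block (half-site) dissimilarity over
the palindromic / direct-repeat / inverted-repeat transforms.

Motif width is unknown: one SMC family is run per candidate width and the
width is chosen by a penalised log marginal-likelihood estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import encode
from .motif import MotifModel, annotate_blocks

logger = logging.getLogger(__name__)

_LN2 = float(np.log(2.0))


@dataclass
class SMCParams:
    """Tunable knobs of the motif-discovery sampler."""

    n_particles: int = 1000
    pi: float = 0.8  # per-sequence presence prior
    alpha: float = 0.5  # Dirichlet pseudocount per base (Jeffreys-style)
    lam_sym: float = 1.0  # weight of the two-block symmetry prior, per bit
    resample_frac: float = 0.5  # resample when ESS < frac * n_particles
    w_min: int = 12
    w_max: int = 24
    c_min: int = 3  # minimum core-block length for final annotation
    none_threshold: float = 1.0  # bits; symmetry call above this -> "none"
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    min_sequences: int = 4
    chunk: int = 256  # particle chunk size for the vectorised candidate sweep

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)


@dataclass
class Particle:
    """A single placement hypothesis (export view of one SMC particle)."""

    placements: list[tuple[int, str] | None]
    counts: np.ndarray  # w x 4 aligned-base counts (real-valued with a prior)
    weight: float
    w: int


@dataclass
class DiscoveryResult:
    """Outcome of discover_motif."""

    status: str  # "ok" or "no motif found"
    motif: MotifModel | None
    site_calls: list[tuple[str, int | None, str | None, float]]
    width_scores: list[tuple[int, float, int]]  # (w, score, n_sites)
    ess_trace: list[float]
    selected_width: int | None = None


class SMCState:
    """Population state of one fixed-width SMC family."""

    def __init__(
        self,
        w: int,
        n_particles: int,
        params: SMCParams,
        rng: np.random.Generator,
        prior_theta: np.ndarray | None = None,
        prior_strength: float = 10.0,
    ):
        if n_particles < 1:
            raise ValueError("need at least one particle")
        self.w = w
        self.n = n_particles
        self.params = params
        self.rng = rng
        if prior_theta is not None:
            prior_theta = np.asarray(prior_theta, dtype=float)
            if prior_theta.shape != (w, 4):
                raise ValueError("prior PWM width does not match w")
            base = prior_theta * prior_strength
        else:
            base = np.zeros((w, 4))
        self.counts = np.broadcast_to(base, (n_particles, w, 4)).copy()
        self.nsites = np.full(n_particles, float(base.sum(axis=1)[0] if w else 0.0))
        self.weights = np.full(n_particles, 1.0 / n_particles)
        self.offsets: list[np.ndarray] = []  # per step, (n,) int, -1 = absent
        self.strands: list[np.ndarray] = []  # per step, (n,) int, 0=+, 1=-
        self.log_norms: list[float] = []
        self.ess_trace: list[float] = []

    # -- helpers ---------------------------------------------------------

    def ess(self) -> float:
        return float(1.0 / np.sum(self.weights**2))

    def _systematic_resample(self) -> None:
        n = self.n
        u = (self.rng.random() + np.arange(n)) / n
        idx = np.searchsorted(np.cumsum(self.weights), u, side="right")
        idx = np.minimum(idx, n - 1)
        self.counts = self.counts[idx].copy()
        self.nsites = self.nsites[idx].copy()
        self.offsets = [o[idx].copy() for o in self.offsets]
        self.strands = [s[idx].copy() for s in self.strands]
        self.weights = np.full(n, 1.0 / n)

    def _penalty_tables(self, ca: np.ndarray) -> dict | None:
        """Precompute symmetry-penalty tables for incremental evaluation.

        The two-block dissimilarity on theta-hat = N/d reduces to
        sum over paired entries of f(n1, n2) = (n1-n2)(ln n1 - ln n2)
        divided by 2*c*ln2*d.  Adding one site changes at most one entry
        per column, so per-candidate values follow from the base sum plus
        per-pair increment tables (n1+1, n2+1, or both).
        """
        w = self.w
        c = w // 2
        if c < 2:
            return None
        n1 = ca[:, :c, :]
        l1_0 = np.log(n1)
        l1_1 = np.log(n1 + 1.0)
        rev = slice(w - 1, w - c - 1, -1)
        tables = {}
        for sym, (n2,) in {
            "pal": (ca[:, rev, :][..., [3, 2, 1, 0]],),
            "dir": (ca[:, w - c :, :],),
            "inv": (ca[:, rev, :],),
        }.items():
            l2_0 = np.log(n2)
            l2_1 = np.log(n2 + 1.0)
            f0 = (n1 - n2) * (l1_0 - l2_0)
            tables[sym] = {
                "base": f0.sum(axis=(1, 2)),  # (P,)
                "g1": (n1 + 1.0 - n2) * (l1_1 - l2_0) - f0,  # n1 incremented
                "g2": (n1 - n2 - 1.0) * (l1_0 - l2_1) - f0,  # n2 incremented
                "g12": (n1 - n2) * (l1_1 - l2_1) - f0,  # both incremented
            }
        tables["c"] = c
        return tables

    def _sym_penalty(
        self,
        windows: np.ndarray | None,
        tables: dict | None,
        denom: np.ndarray,
    ) -> np.ndarray:
        """-lam_sym * D_min (in bits) for tentatively updated PWMs.

        windows: (M, w) base codes of the candidate aligned words, or None
        for the 'absent' candidate (no update).  Returns (P, M) or (P, 1).
        """
        if tables is None or self.params.lam_sym == 0.0:
            n_p = len(denom)
            n_m = 1 if windows is None else windows.shape[0]
            return np.zeros((n_p, n_m))
        w = self.w
        c = tables["c"]
        scale = 2.0 * c * _LN2
        if windows is None:
            d_raw = np.stack(
                [tables[s]["base"] for s in ("pal", "dir", "inv")]
            ).min(axis=0)
            d_min = d_raw[:, None] / (scale * denom[:, None])
            return -self.params.lam_sym * d_min
        x1 = windows[:, :c]  # (M, c) block1 bases of each candidate
        pos_c = np.arange(c)[None, :]
        # the block2-side entry touched by the candidate, per symmetry
        bx = {
            "pal": 3 - windows[:, w - 1 : w - c - 1 : -1],
            "dir": windows[:, w - c :],
            "inv": windows[:, w - 1 : w - c - 1 : -1],
        }
        d_syms = []
        for sym in ("pal", "dir", "inv"):
            t = tables[sym]
            b2 = bx[sym]
            same = x1 == b2  # both increments hit the same pair entry row
            inc1 = t["g1"][:, pos_c, x1]  # (P, M, c)
            inc2 = t["g2"][:, pos_c, b2]
            inc12 = t["g12"][:, pos_c, x1]
            delta = np.where(same[None, :, :], inc12, inc1 + inc2).sum(axis=2)
            d_syms.append(t["base"][:, None] + delta)
        d_raw = np.minimum(np.minimum(d_syms[0], d_syms[1]), d_syms[2])
        d_min = d_raw / (scale * denom[:, None])
        return -self.params.lam_sym * d_min


def smc_init(
    w: int,
    n_particles: int,
    params: SMCParams | None = None,
    prior_theta: np.ndarray | None = None,
    prior_strength: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> SMCState:
    """Fresh particle population: empty placements, uniform weights."""
    params = params or SMCParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return SMCState(
        w,
        n_particles,
        params,
        rng,
        prior_theta=prior_theta,
        prior_strength=prior_strength,
    )


def smc_step(state: SMCState, sequence: str) -> SMCState:
    """Absorb one sequence: sample a placement per particle and re-weight.

    Candidates per particle: {absent} plus every (offset, strand) window.
    Candidate weight = placement prior x Dirichlet-multinomial predictive
    likelihood ratio of the aligned w-mer x symmetry prior on the updated
    posterior-mean PWM.  The particle weight picks up the candidate
    normalising constant (the per-sequence marginal-likelihood estimate).
    """
    p = state.params
    w = state.w
    n = state.n
    codes = encode(sequence.upper())
    L = len(codes)
    m = L - w + 1
    log_bg = np.log(np.maximum(p.background, 1e-12))

    if m >= 1:
        idx = np.arange(m)[:, None] + np.arange(w)[None, :]
        win_f = codes[idx]
        valid = np.all(win_f >= 0, axis=1)
        win_f = win_f[valid]
        offs = np.nonzero(valid)[0]
        # minus-strand placement at offset o aligns the reverse complement
        win_r = 3 - win_f[:, ::-1]
    else:
        win_f = np.zeros((0, w), dtype=codes.dtype)
        win_r = win_f
        offs = np.zeros(0, dtype=int)
    mv = win_f.shape[0]  # number of valid offsets

    n_cand = 1 + 2 * mv
    log_cand = np.empty((n, n_cand))
    # placement prior: absent mass 1-pi, presence mass pi split over candidates
    if mv > 0 and p.pi > 0:
        lp_absent = float(np.log1p(-p.pi)) if p.pi < 1 else -np.inf
        lp_place = float(np.log(p.pi) - np.log(2 * mv))
    else:
        lp_absent = 0.0
        lp_place = -np.inf

    chunk = max(1, p.chunk)
    pos = np.arange(w)[None, :]
    bg_f = log_bg[win_f].sum(axis=1) if mv else np.zeros(0)
    bg_r = log_bg[win_r].sum(axis=1) if mv else np.zeros(0)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        ca = state.counts[lo:hi] + p.alpha  # (P, w, 4)
        denom0 = state.nsites[lo:hi] + 4 * p.alpha
        tables = state._penalty_tables(ca) if p.lam_sym != 0.0 else None
        # absent candidate: current-PWM symmetry penalty, no likelihood term
        pen_abs = state._sym_penalty(None, tables, denom0)[:, 0]
        log_cand[lo:hi, 0] = lp_absent + pen_abs
        if mv:
            log_ca = np.log(ca)
            denom1 = denom0 + 1.0
            for k, (win, bg_sum) in enumerate(((win_f, bg_f), (win_r, bg_r))):
                ll = log_ca[:, pos, win]  # (P, w, 4) gathered -> (P, M, w)
                loglik = ll.sum(axis=2) - w * np.log(denom0)[:, None] - bg_sum[None, :]
                pen = state._sym_penalty(win, tables, denom1)
                col = slice(1 + k * mv, 1 + (k + 1) * mv)
                log_cand[lo:hi, col] = lp_place + loglik + pen

    if p.pi <= 0 or mv == 0:
        log_cand[:, 1:] = -np.inf

    # per-particle normalising constant and categorical draw (Gumbel trick)
    mx = np.max(log_cand, axis=1, keepdims=True)
    finite = np.isfinite(mx[:, 0])
    z = np.zeros(n)
    z[finite] = (
        np.log(np.sum(np.exp(log_cand[finite] - mx[finite]), axis=1)) + mx[finite, 0]
    )
    z[~finite] = -np.inf
    gumbel = state.rng.gumbel(size=(n, n_cand))
    choice = np.argmax(log_cand + gumbel, axis=1)

    new_off = np.full(n, -1, dtype=int)
    new_str = np.zeros(n, dtype=int)
    placed = choice > 0
    which = choice[placed] - 1
    new_str[placed] = which // mv if mv else 0
    if mv:
        new_off[placed] = offs[which % mv]
        sel = which % mv
        words = np.where((which // mv)[:, None] == 0, win_f[sel], win_r[sel])
        onehot = np.zeros((words.shape[0], w, 4))
        onehot[np.arange(words.shape[0])[:, None], pos, words] = 1.0
        state.counts[placed] += onehot
        state.nsites[placed] += 1.0
    state.offsets.append(new_off)
    state.strands.append(new_str)

    # weight update and marginal-likelihood increment
    logw = np.log(np.maximum(state.weights, 1e-300)) + z
    mxw = np.max(logw)
    if not np.isfinite(mxw):
        raise FloatingPointError("all particle weights vanished")
    state.log_norms.append(float(mxw + np.log(np.sum(np.exp(logw - mxw)))))
    wts = np.exp(logw - mxw)
    state.weights = wts / wts.sum()
    state.ess_trace.append(state.ess())
    if state.ess() < p.resample_frac * n:
        state._systematic_resample()
    return state


def posterior_mean_theta(state: SMCState, particle: int, alpha: float) -> np.ndarray:
    counts = state.counts[particle]
    denom = counts.sum(axis=1, keepdims=True) + 4 * alpha
    return (counts + alpha) / denom


def max_weight_particle(state: SMCState) -> int:
    """Index of the maximum-weight particle (smallest index on ties)."""
    return int(np.argmax(state.weights))


def export_particle(state: SMCState, i: int) -> Particle:
    placements: list[tuple[int, str] | None] = []
    for off, strd in zip(state.offsets, state.strands):
        if off[i] < 0:
            placements.append(None)
        else:
            placements.append((int(off[i]), "+-"[int(strd[i])]))
    return Particle(
        placements=placements,
        counts=state.counts[i].copy(),
        weight=float(state.weights[i]),
        w=state.w,
    )


def run_family(
    sequences: list[str],
    w: int,
    params: SMCParams,
    seed: int,
    prior_theta: np.ndarray | None = None,
    prior_strength: float = 10.0,
) -> SMCState:
    """Run one fixed-width SMC family over the sequences in order."""
    prior_w = None
    if prior_theta is not None and prior_theta.shape[0] == w:
        prior_w = prior_theta
    state = smc_init(
        w,
        params.n_particles,
        params,
        prior_theta=prior_w,
        prior_strength=prior_strength,
        seed=np.random.default_rng(seed),
    )
    for seq in sequences:
        smc_step(state, seq)
    return state


def estimate_width(
    sequences: list[str],
    w_range: list[int] | None = None,
    params: SMCParams | None = None,
    seed: int = 0,
    prior_theta: np.ndarray | None = None,
    prior_strength: float = 10.0,
) -> tuple[list[tuple[int, float, int]], int, dict[int, SMCState]]:
    """Score candidate widths by penalised log marginal likelihood.

    One independent family per width (RNG stream seed + w); score = sum of
    the per-step log normalising constants minus (3w/2) * log(number of
    aligned sites) (three free parameters per PWM column).  Ties prefer the
    smaller width.
    """
    params = params or SMCParams()
    if w_range is None:
        w_range = list(range(params.w_min, params.w_max + 1))
    if not w_range:
        raise ValueError("empty width range")
    table: list[tuple[int, float, int]] = []
    states: dict[int, SMCState] = {}
    for w in sorted(w_range):
        state = run_family(
            sequences, w, params, seed + w, prior_theta=prior_theta,
            prior_strength=prior_strength,
        )
        states[w] = state
        i = max_weight_particle(state)
        n_sites = int(sum(1 for off in state.offsets if off[i] >= 0))
        loglik = float(np.sum(state.log_norms))
        if n_sites > 0:
            score = loglik - 1.5 * w * np.log(n_sites)
        else:
            score = -np.inf
        table.append((w, score, n_sites))
    best_w = min(table, key=lambda row: (-row[1], row[0]))[0]
    return table, best_w, states


def site_posteriors(state: SMCState, seq_ids: list[str]) -> list[
    tuple[str, int | None, str | None, float]
]:
    """Per-sequence posterior-mode site call from the particle population.

    Returns (seq_id, offset, strand, posterior probability); offset/strand
    are None when 'absent' carries the largest posterior mass.
    """
    calls = []
    for t, seq_id in enumerate(seq_ids):
        off = state.offsets[t]
        strd = state.strands[t]
        mass: dict[tuple[int, int], float] = {}
        for o, s, wgt in zip(off, strd, state.weights):
            key = (int(o), int(s) if o >= 0 else 0)
            mass[key] = mass.get(key, 0.0) + float(wgt)
        best_key = max(mass, key=lambda k: (mass[k], -k[0], -k[1]))
        prob = mass[best_key]
        if best_key[0] < 0:
            calls.append((seq_id, None, None, prob))
        else:
            calls.append((seq_id, best_key[0], "+-"[best_key[1]], prob))
    return calls


def discover_motif(
    sequences: list[tuple[str, str]],
    params: SMCParams | None = None,
    prior_theta: np.ndarray | None = None,
    prior_strength: float = 10.0,
    seed: int = 0,
    w_range: list[int] | None = None,
) -> DiscoveryResult:
    """Full motif discovery on ordered (id, sequence) upstream records.

    Runs width estimation, extracts the maximum-weight particle of the
    winning family, forms the posterior-mean PWM, annotates core blocks and
    symmetry, and reports per-sequence posterior site calls.
    """
    params = params or SMCParams()
    if len(sequences) < params.min_sequences:
        raise ValueError(
            f"need at least {params.min_sequences} sequences, got {len(sequences)}"
        )
    seq_ids = [sid for sid, _ in sequences]
    seqs = [s for _, s in sequences]
    table, best_w, states = estimate_width(
        seqs, w_range, params, seed=seed, prior_theta=prior_theta,
        prior_strength=prior_strength,
    )
    state = states[best_w]
    i = max_weight_particle(state)
    n_sites = int(sum(1 for off in state.offsets if off[i] >= 0))
    ess_trace = list(state.ess_trace)
    if n_sites == 0:
        return DiscoveryResult(
            status="no motif found",
            motif=None,
            site_calls=site_posteriors(state, seq_ids),
            width_scores=table,
            ess_trace=ess_trace,
            selected_width=best_w,
        )
    theta = posterior_mean_theta(state, i, params.alpha)
    motif = annotate_blocks(
        theta,
        c_min=params.c_min,
        lam=1.0,
        none_threshold=params.none_threshold,
        alpha=params.alpha,
        nsites=n_sites,
        background=params.background,
    )
    return DiscoveryResult(
        status="ok",
        motif=motif,
        site_calls=site_posteriors(state, seq_ids),
        width_scores=table,
        ess_trace=ess_trace,
        selected_width=best_w,
    )
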