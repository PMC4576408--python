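"""TF-seeded estimation of the putatively co-regulated gene set.

The working assumption is linear coherency: a gene co-regulated with the
TF satisfies x_g ~ a_g * x_TF + b_g across the conditions where the
regulatory program is active.  The bicluster estimator alternates between
a gene step (select genes whose |Pearson r| with the TF over the current
conditions clears r_init) and a condition step (fit per-gene lines against
the TF profile and discard conditions with outlying aggregate residuals)
until a fixed point or the iteration cap.

Knockout-fitness data can veto genes whose fitness profile does not track
the TF's: a systems-level guard against spurious expression correlations.

Because bacterial operon members share one promoter, only the operon head
gene carries an informative upstream region; the operon-head filter groups
adjacent same-strand co-expressed genes into runs and keeps each run's
5'-most gene before motif discovery.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AnnotationSet, Genome

logger = logging.getLogger(__name__)

MIN_SHARED_OBS = 10  # pairwise-complete observations required for any r


@dataclass
class BiclusterParams:
    r_init: float = 0.7  # |r| with the TF a member gene must clear
    residual_quantile: float = 0.9  # condition step keeps residuals <= this quantile
    min_conditions_frac: float = 0.5
    max_iter: int = 20
    r_fit_min: float = 0.5  # fitness-veto threshold on |r| with the TF fitness
    fitness_veto: bool = True
    # first-iteration seeding: admit the top-k |r| genes above a relaxed
    # floor so condition refinement can reveal a coherent subset whose
    # full-matrix correlations sit just under r_init
    seed_top_k: int = 20
    seed_floor_frac: float = 0.7


@dataclass
class Bicluster:
    tf: str
    genes: list[str]
    conditions: list[str]
    score: float  # mean |gene-TF r| over the selected conditions
    fits: pd.DataFrame = field(default_factory=pd.DataFrame)  # slope/intercept/resid
    correlations: pd.Series = field(default_factory=pd.Series)
    gene_signs: pd.Series = field(default_factory=pd.Series)  # sign of r with TF
    warnings: list[str] = field(default_factory=list)


def correlation_profile(
    expr: pd.DataFrame,
    tf: str,
    conditions: list[str] | None = None,
    min_shared: int = MIN_SHARED_OBS,
) -> pd.Series:
    """Pearson correlation of every gene with the TF gene.

    Computed pairwise over shared non-missing entries of the chosen
    condition set; genes with fewer than `min_shared` shared observations
    or zero variance get NaN (flagged, excluded from selection).
    """
    if tf not in expr.index:
        raise KeyError(f"TF gene {tf!r} not in expression matrix")
    sub = expr if conditions is None else expr.loc[:, list(conditions)]
    x = sub.loc[tf].to_numpy(dtype=float)
    mat = sub.to_numpy(dtype=float)
    ok_x = np.isfinite(x)
    out = np.full(len(sub.index), np.nan)
    for i in range(mat.shape[0]):
        y = mat[i]
        mask = ok_x & np.isfinite(y)
        if mask.sum() < min_shared:
            continue
        xv, yv = x[mask], y[mask]
        sx, sy = xv.std(), yv.std()
        if sx == 0 or sy == 0:
            continue
        out[i] = float(np.corrcoef(xv, yv)[0, 1])
    return pd.Series(out, index=sub.index, name="r")


def _condition_residuals(
    expr: pd.DataFrame, tf: str, genes: list[str]
) -> tuple[pd.Series, pd.DataFrame]:
    """Aggregate per-condition squared residuals of per-gene linear fits.

    Each member gene is fitted by least squares x_g = a*x_tf + b over the
    supplied conditions (pairwise complete); residuals are averaged over
    genes per condition.  Returns (per-condition residual, per-gene fits).
    """
    x = expr.loc[tf].to_numpy(dtype=float)
    res_sum = np.zeros(expr.shape[1])
    res_cnt = np.zeros(expr.shape[1])
    rows = []
    others = [g for g in genes if g != tf]
    for g in others:
        y = expr.loc[g].to_numpy(dtype=float)
        mask = np.isfinite(x) & np.isfinite(y)
        if mask.sum() < 2 or x[mask].std() == 0:
            rows.append((g, np.nan, np.nan, np.nan))
            continue
        a, b = np.polyfit(x[mask], y[mask], 1)
        resid = (y - (a * x + b)) ** 2
        rows.append((g, a, b, float(np.sqrt(np.nanmean(resid[mask])))))
        res_sum[mask] += resid[mask]
        res_cnt[mask] += 1
    with np.errstate(invalid="ignore"):
        per_cond = np.where(res_cnt > 0, res_sum / np.maximum(res_cnt, 1), np.nan)
    fits = pd.DataFrame(rows, columns=["gene", "slope", "intercept", "resid"]).set_index(
        "gene"
    )
    return pd.Series(per_cond, index=expr.columns), fits


def estimate_bicluster(
    expr: pd.DataFrame,
    tf: str,
    fitness: pd.DataFrame | None = None,
    params: BiclusterParams | None = None,
    fitness_conditions: list[str] | None = None,
) -> Bicluster:
    """Alternating gene/condition optimisation seeded at the TF gene.

    Gene step: over the current condition set, select (from all genes) the
    ones with |r| >= r_init against the TF.  Condition step: keep the
    conditions whose aggregate linear-fit residual is at or below the
    residual_quantile of the current condition set, never going below
    min_conditions_frac of all conditions.  Iterates to a fixed point or
    max_iter.  An optional fitness veto removes genes whose fitness profile
    is incoherent with the TF's.
    """
    params = params or BiclusterParams()
    if tf not in expr.index:
        raise KeyError(f"TF gene {tf!r} not in expression matrix")
    all_conditions = list(expr.columns)
    min_cond = max(2, int(np.ceil(params.min_conditions_frac * len(all_conditions))))
    conditions = list(all_conditions)
    genes: list[str] = [tf]
    notes: list[str] = []
    corr = pd.Series(dtype=float)

    for it in range(params.max_iter):
        prev = (tuple(genes), tuple(conditions))
        # gene step: re-select from the full gene universe
        corr = correlation_profile(expr, tf, conditions)
        selected = set(corr.index[(corr.abs() >= params.r_init) & corr.notna()])
        if it == 0 and len(selected) < params.seed_top_k:
            floor = params.seed_floor_frac * params.r_init
            ranked = corr.abs().dropna().sort_values(ascending=False)
            ranked = ranked[ranked >= floor]
            selected |= set(ranked.index[: params.seed_top_k])
        genes = sorted(selected | {tf})
        # condition step
        if len(genes) > 1:
            resid, _ = _condition_residuals(expr.loc[:, conditions], tf, genes)
            finite = resid.dropna()
            if len(finite) >= min_cond:
                tau = float(np.quantile(finite.to_numpy(), params.residual_quantile))
                keep = [c for c in conditions if np.isfinite(resid[c]) and resid[c] <= tau]
                if len(keep) < min_cond:
                    keep = list(finite.nsmallest(min_cond).index)
                    keep = [c for c in conditions if c in set(keep)]
                conditions = keep
        if (tuple(genes), tuple(conditions)) == prev:
            break

    if len(conditions) < min_cond:
        notes.append("fewer than min_conditions survived; using all conditions")
        warnings.warn(notes[-1], stacklevel=2)
        conditions = list(all_conditions)
        corr = correlation_profile(expr, tf, conditions)
        genes = sorted(
            set(corr.index[(corr.abs() >= params.r_init) & corr.notna()]) | {tf}
        )

    # fitness veto
    if fitness is not None and params.fitness_veto and tf in fitness.index:
        fit = (
            fitness if fitness_conditions is None else fitness.loc[:, fitness_conditions]
        )
        fit_r = correlation_profile(fit, tf, min_shared=min(MIN_SHARED_OBS, fit.shape[1]))
        vetoed = [
            g
            for g in genes
            if g != tf
            and g in fit_r.index
            and np.isfinite(fit_r[g])
            and abs(fit_r[g]) < params.r_fit_min
        ]
        if vetoed:
            notes.append(f"fitness veto removed: {','.join(sorted(vetoed))}")
            genes = [g for g in genes if g not in set(vetoed)]

    corr = correlation_profile(expr, tf, conditions)
    member_r = corr.loc[[g for g in genes if g in corr.index]]
    score = float(member_r.abs().mean()) if len(member_r) else 0.0
    _, fits = _condition_residuals(expr.loc[:, conditions], tf, genes)
    return Bicluster(
        tf=tf,
        genes=sorted(genes),
        conditions=conditions,
        score=min(1.0, score),
        fits=fits,
        correlations=corr,
        gene_signs=np.sign(corr) if len(corr) else pd.Series(dtype=float),
        warnings=notes,
    )


def _adjacent_runs(
    genes: list[str],
    annotations: AnnotationSet,
    expr: pd.DataFrame,
    r_adj: float,
    max_gap: int = 200,
) -> list[list[str]]:
    """Group the genes into maximal same-strand adjacent co-expressed runs.

    Two input genes are adjacent when they share contig and strand, no
    other annotated gene lies between them, and the intergenic gap is at
    most `max_gap` bp; consecutive pairs must also correlate >= r_adj.
    """
    missing = [g for g in genes if g not in annotations]
    if missing:
        raise KeyError(f"unannotated genes: {sorted(missing)}")
    gene_set = set(genes)
    runs: list[list[str]] = []
    for contig in sorted({annotations[g].contig for g in genes}):
        ordered = annotations.contig_genes(contig)
        run: list[str] = []
        for i, ann in enumerate(ordered):
            if ann.gene_id not in gene_set:
                if run:
                    runs.append(run)
                run = []
                continue
            if run:
                prev = annotations[run[-1]]
                gap = ann.start - prev.end
                ok = (
                    prev.strand == ann.strand
                    and 0 <= gap <= max_gap
                    and _pair_correlation(expr, prev.gene_id, ann.gene_id) >= r_adj
                )
                if not ok:
                    runs.append(run)
                    run = []
            run.append(ann.gene_id)
        if run:
            runs.append(run)
    return runs


def _pair_correlation(expr: pd.DataFrame, g1: str, g2: str) -> float:
    if g1 not in expr.index or g2 not in expr.index:
        return -np.inf
    x = expr.loc[g1].to_numpy(dtype=float)
    y = expr.loc[g2].to_numpy(dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < MIN_SHARED_OBS or x[mask].std() == 0 or y[mask].std() == 0:
        return -np.inf
    return float(np.corrcoef(x[mask], y[mask])[0, 1])


def filter_operon_heads(
    genes: list[str],
    annotations: AnnotationSet,
    expr: pd.DataFrame,
    tf: str,
    r_adj: float = 0.8,
    max_gap: int = 200,
) -> list[str]:
    """Keep only the head gene of each putative operon run.

    Genes whose upstream region is shared through an operon contribute no
    independent binding site, so from each run of adjacent same-strand
    genes with consecutive correlation >= r_adj only the 5'-most gene is
    retained.  Isolated genes pass through.  Idempotent.
    """
    if not (0 < r_adj < 1):
        raise ValueError("r_adj must be in (0, 1)")
    runs = _adjacent_runs(sorted(set(genes)), annotations, expr, r_adj, max_gap)
    heads = []
    for run in runs:
        anns = [annotations[g] for g in run]
        if anns[0].strand == "+":
            head = min(anns, key=lambda a: a.start)
        else:
            head = max(anns, key=lambda a: a.end)
        heads.append(head.gene_id)
    return sorted(heads)


def feeding_order(
    genes: list[str],
    expr: pd.DataFrame,
    tf: str,
    scramble_seed: int | None = None,
) -> list[str]:
    """Order genes for motif discovery by descending |r| with the TF.

    Ties break lexicographically; the TF's own gene always leads when
    present.  With `scramble_seed`, returns a seeded random permutation
    instead (for scrambled-order reruns).
    """
    genes = sorted(set(genes))
    if scramble_seed is not None:
        rng = np.random.default_rng(scramble_seed)
        out = list(genes)
        rng.shuffle(out)
        return out
    corr = correlation_profile(expr, tf)
    def key(g: str):
        r = abs(corr[g]) if g in corr.index and np.isfinite(corr[g]) else -np.inf
        return (g != tf, -r, g)
    return sorted(genes, key=key)


def extract_upstreams(
    genes: list[str],
    genome: Genome,
    annotations: AnnotationSet,
    length: int = 300,
) -> list[tuple[str, str]]:
    """The `length` bases 5' of each gene's start, in gene orientation.

    Truncated at the contig edge; genes with an empty upstream window are
    skipped with a warning.  Returns (gene id, sequence) in input order.
    """
    records = []
    for g in genes:
        ann = annotations[g]
        contig = genome.contigs[ann.contig]
        if ann.strand == "+":
            start = max(0, ann.start - length)
            seq = contig[start : ann.start]
        else:
            end = min(len(contig), ann.end + length)
            seq = genome.slice(ann.contig, ann.end, end, "-")
        if not seq:
            warnings.warn(f"gene {g} has no upstream sequence; skipped", stacklevel=2)
            continue
        if len(seq) < length:
            warnings.warn(
                f"upstream of {g} truncated to {len(seq)} bp at contig edge",
                stacklevel=2,
            )
        records.append((g, seq))
    return records
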