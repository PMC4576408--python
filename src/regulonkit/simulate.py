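"""Seeded generators for desk-scale synthetic study systems.

Everything the pipeline consumes can be generated here: a toy bacterial
genome with genes on both strands and PWM-sampled binding sites planted in
upstream windows, a log-scale expression matrix with a planted linear-
coherency bicluster and operon runs, a knockout-fitness matrix with a
coherent subset, and a ground-truth record for every planted feature.
All generators are pure functions of (parameters, seed).

The default end-to-end bundle mirrors the shape of a small bacterial
SOS-response study at reduced scale: ~50 genes, a 12-gene planted regulon
(three operons plus singleton genes plus the autoregulated TF), a 16-bp
palindromic motif, 300-bp upstream windows, and a 200-condition expression
matrix with the planted bicluster active on 120 conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import AnnotationSet, BASES, GeneAnnotation, Genome, OperonTable, revcomp
from .motif import MotifModel, transform_block

_COMP_IDX = np.array([3, 2, 1, 0])


@dataclass
class FixtureTruth:
    """Ground truth serialised alongside every fixture."""

    seed: int
    params: dict = field(default_factory=dict)
    pwm: list | None = None
    consensus: str | None = None
    symmetry: str | None = None
    blocks: list | None = None
    site_loci: list = field(default_factory=list)  # (gene, contig, start, strand, seq)
    regulon_genes: list = field(default_factory=list)
    bicluster_genes: list = field(default_factory=list)
    bicluster_conditions: list = field(default_factory=list)
    slopes: dict = field(default_factory=dict)
    operons: dict = field(default_factory=dict)
    tf: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "FixtureTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def make_pwm(
    width: int,
    symmetry: str = "palindromic",
    conservation: float = 0.85,
    seed: int = 0,
    core_frac: float = 1.0,
) -> MotifModel:
    """Random PWM whose two core blocks obey the requested symmetry exactly.

    Core columns put `conservation` probability on a random consensus base
    and split the rest evenly.  The block consensus is rejection-sampled so
    that the three symmetry transforms are pairwise distinguishable (at
    least two consensus mismatches between any pair), making the planted
    symmetry the unique minimiser.  Non-core columns (when core_frac < 1)
    are mildly non-uniform.
    """
    if not (0.25 < conservation < 1.0) and conservation != 1.0:
        raise ValueError("conservation must be in (0.25, 1]")
    rng = np.random.default_rng(seed)
    c = max(3, int(np.floor(width * core_frac / 2)))
    c = min(c, width // 2)
    block1 = (0, c)
    block2 = (width - c, width)

    def col(base: int) -> np.ndarray:
        v = np.full(4, (1.0 - conservation) / 3.0)
        v[base] = conservation
        return v

    while True:
        cons1 = rng.integers(0, 4, size=c)
        b1 = np.stack([col(b) for b in cons1])
        candidates = {
            s: transform_block(b1, s) for s in ("palindromic", "direct_repeat", "inverted_repeat")
        }
        # require the three would-be second blocks to differ pairwise at
        # two or more consensus positions, so the symmetry call is unique
        keys = list(candidates)
        consensi = {s: np.argmax(candidates[s], axis=1) for s in keys}
        ok = all(
            (consensi[a] != consensi[b]).sum() >= 2
            for i, a in enumerate(keys)
            for b in keys[i + 1 :]
        )
        if ok:
            break
    # the planted block2 equals the requested transform applied to block1
    # (each transform is an involution, so symmetry detection inverts it)
    b2 = candidates[symmetry]
    theta = np.full((width, 4), 0.25)
    mid = slice(c, width - c)
    n_mid = width - 2 * c
    if n_mid > 0:
        mild = rng.dirichlet(np.full(4, 8.0), size=n_mid)
        theta[mid] = mild
    theta[block1[0] : block1[1]] = b1
    theta[block2[0] : block2[1]] = b2
    theta = theta / theta.sum(axis=1, keepdims=True)
    return MotifModel(
        theta=theta,
        block1=block1,
        block2=block2,
        symmetry=symmetry,
        name=f"planted_{symmetry}_{width}",
    )


def sample_site(
    pwm: MotifModel, rng: np.random.Generator, identity: float | None = None
) -> str:
    """Sample one site.

    With `identity`, each position takes the consensus base with that
    probability and otherwise a uniform non-consensus base; without, the
    site is drawn from the PWM columns directly.
    """
    w = pwm.width
    cons = np.argmax(pwm.theta, axis=1)
    out = np.empty(w, dtype=int)
    for j in range(w):
        if identity is not None:
            if rng.random() < identity:
                out[j] = cons[j]
            else:
                others = [b for b in range(4) if b != cons[j]]
                out[j] = others[rng.integers(0, 3)]
        else:
            out[j] = rng.choice(4, p=pwm.theta[j])
    return "".join(BASES[b] for b in out)


def make_genome(
    n_genes: int,
    pwm: MotifModel | None = None,
    planted_genes: list[int] | None = None,
    identity: float = 0.9,
    seed: int = 0,
    gene_length: int = 600,
    spacing: int = 600,
    run_gap: int = 100,
    upstream: int = 300,
    background: np.ndarray | None = None,
    contig: str = "chr",
    operon_runs: list[list[int]] | None = None,
) -> tuple[Genome, AnnotationSet, FixtureTruth]:
    """I.i.d. background genome with transcription units on both strands.

    Genes are grouped into transcription units (operon runs given as lists
    of gene indices, everything else a singleton); units alternate strand
    along the contig with `spacing` bp between them, and genes inside a
    run sit `run_gap` bp apart on the unit strand, head gene 5'-most.

    For each planted gene index, one PWM-sampled site is written uniformly
    at random inside the gene's `upstream` window, in gene orientation.
    The truth records the exact locus and planted word of every site.
    """
    rng = np.random.default_rng(seed)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if spacing < upstream + (pwm.width if pwm else 0) + 20:
        raise ValueError("spacing too small for the upstream window")
    operon_runs = operon_runs or []
    in_run: dict[int, list[int]] = {}
    for run in operon_runs:
        for gi in run:
            if gi in in_run:
                raise ValueError("gene in more than one operon run")
            in_run[gi] = run
    units: list[list[int]] = []
    for i in range(n_genes):
        run = in_run.get(i)
        if run is None:
            units.append([i])
        elif run[0] == i:
            units.append(list(run))
    genes_by_idx: dict[int, GeneAnnotation] = {}
    cursor = spacing
    for u, unit in enumerate(units):
        strand = "+" if u % 2 == 0 else "-"
        # head gene 5'-most: leftmost on +, rightmost on -
        order = unit if strand == "+" else list(reversed(unit))
        pos = cursor
        for gi in order:
            genes_by_idx[gi] = GeneAnnotation(
                gene_id=f"g{gi:03d}",
                contig=contig,
                start=pos,
                end=pos + gene_length,
                strand=strand,
            )
            pos += gene_length + run_gap
        cursor = pos - run_gap + spacing
    length = cursor
    genes = [genes_by_idx[i] for i in range(n_genes)]
    seq = rng.choice(4, size=length, p=bg / bg.sum())
    seq_list = [BASES[b] for b in seq]
    truth = FixtureTruth(
        seed=seed,
        params={
            "n_genes": n_genes,
            "identity": identity,
            "gene_length": gene_length,
            "spacing": spacing,
            "run_gap": run_gap,
            "upstream": upstream,
        },
        operons={
            f"g{run[0]:03d}": [f"g{gi:03d}" for gi in run] for run in operon_runs
        },
    )
    if pwm is not None and planted_genes:
        truth.pwm = pwm.theta.tolist()
        truth.consensus = pwm.consensus
        truth.symmetry = pwm.symmetry
        truth.blocks = [list(pwm.block1), list(pwm.block2)] if pwm.block1 else None
        w = pwm.width
        for gi in planted_genes:
            g = genes[gi]
            word = sample_site(pwm, rng, identity=identity)
            # uniform placement within the upstream window, gene orientation
            rel = int(rng.integers(0, upstream - w + 1))
            if g.strand == "+":
                start = g.start - upstream + rel
                inserted = word
                strand = "+"
            else:
                start = g.end + upstream - rel - w
                inserted = revcomp(word)
                strand = "-"
            seq_list[start : start + w] = list(inserted)
            truth.site_loci.append([g.gene_id, contig, start, strand, word])
            truth.regulon_genes.append(g.gene_id)
    genome = Genome.from_contigs({contig: "".join(seq_list)})
    return genome, AnnotationSet(genes), truth


def make_expression(
    n_genes: int,
    n_conditions: int,
    bicluster_genes: list[str],
    bicluster_conditions: list[int] | None = None,
    tf: str = "g000",
    sigma: float = 0.3,
    sigma_background: float = 0.3,
    slope_range: tuple[float, float] = (1.0, 2.0),
    operon_runs: list[list[str]] | None = None,
    operon_sigma: float = 0.05,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, FixtureTruth]:
    """Expression matrix with a planted linear-coherency bicluster.

    The TF profile is standard normal over all conditions.  Planted genes
    follow a_g * x_TF + b_g + sigma*N(0,1) on the bicluster conditions and
    independent N(0, sigma_background) elsewhere (log-scale expression of
    unregulated conditions varies little).  Non-member genes are
    independent N(0, sigma_background) throughout.  Operon-run members copy
    their head's profile plus N(0, operon_sigma) noise.
    """
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"g{i:03d}" for i in range(n_genes)]
    conditions = [f"c{j:03d}" for j in range(n_conditions)]
    if bicluster_conditions is None:
        bicluster_conditions = list(range(int(0.6 * n_conditions)))
    if tf not in bicluster_genes:
        raise ValueError("the TF gene must be a bicluster member")
    cond_mask = np.zeros(n_conditions, dtype=bool)
    cond_mask[list(bicluster_conditions)] = True
    x_tf = rng.standard_normal(n_conditions)
    mat = rng.standard_normal((len(gene_ids), n_conditions)) * sigma_background
    index = {g: i for i, g in enumerate(gene_ids)}
    slopes: dict[str, float] = {}
    lo, hi = slope_range
    for g in bicluster_genes:
        if g == tf:
            continue
        a = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        b = rng.uniform(-1.0, 1.0)
        slopes[g] = float(a)
        row = mat[index[g]]
        row[cond_mask] = a * x_tf[cond_mask] + b + sigma * rng.standard_normal(
            cond_mask.sum()
        )
    mat[index[tf]] = x_tf
    slopes[tf] = 1.0
    if operon_runs:
        for run in operon_runs:
            head = run[0]
            for member in run[1:]:
                mat[index[member]] = mat[index[head]] + operon_sigma * rng.standard_normal(
                    n_conditions
                )
    df = pd.DataFrame(mat, index=gene_ids, columns=conditions)
    truth = FixtureTruth(
        seed=seed,
        tf=tf,
        params={
            "sigma": sigma,
            "sigma_background": sigma_background,
            "slope_range": list(slope_range),
        },
        bicluster_genes=sorted(bicluster_genes),
        bicluster_conditions=[conditions[j] for j in bicluster_conditions],
        slopes=slopes,
        operons={run[0]: run for run in (operon_runs or [])},
    )
    return df, truth


def make_fitness(
    genes: list[str],
    n_conditions: int,
    coherent: list[str],
    sigma: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, FixtureTruth]:
    """Knockout-fitness matrix: a coherent subset shares a latent response.

    Coherent genes are latent + N(0, sigma); all other genes are
    independent standard normal.  Condition ids are prefixed 'f' so they
    never collide with expression condition ids.
    """
    rng = np.random.default_rng(seed)
    conditions = [f"f{j:03d}" for j in range(n_conditions)]
    latent = rng.standard_normal(n_conditions)
    mat = rng.standard_normal((len(genes), n_conditions))
    coherent_set = set(coherent)
    for i, g in enumerate(genes):
        if g in coherent_set:
            mat[i] = latent + sigma * rng.standard_normal(n_conditions)
    df = pd.DataFrame(mat, index=list(genes), columns=conditions)
    truth = FixtureTruth(
        seed=seed, params={"sigma": sigma}, bicluster_genes=sorted(coherent)
    )
    return df, truth


@dataclass
class FixtureBundle:
    genome: Genome
    annotations: AnnotationSet
    expression: pd.DataFrame
    fitness: pd.DataFrame
    operons: OperonTable
    pwm: MotifModel
    tf: str
    truth: FixtureTruth


def make_default_bundle(seed: int = 7) -> FixtureBundle:
    """The default end-to-end study system.

    50 genes; the TF gene g000 autoregulates; planted regulon = TF + three
    operons (3+2+2 genes) + five singleton genes = 13 genes with 9 planted
    sites (operon members share the head's promoter); 16-bp palindromic
    motif planted at 0.9 per-position identity; 200-condition expression
    with the regulon coherent on the first 120 conditions; 30-condition
    fitness with the regulon genes as the coherent subset.
    """
    n_genes = 50
    tf = "g000"
    pwm = make_pwm(16, "palindromic", conservation=0.85, seed=seed + 1)
    operon_runs_idx = [[4, 5, 6], [12, 13], [23, 24]]
    singles_idx = [3, 9, 17, 31, 40]
    head_idx = [0] + [r[0] for r in operon_runs_idx] + singles_idx
    genome, annotations, truth = make_genome(
        n_genes,
        pwm=pwm,
        planted_genes=head_idx,
        identity=0.9,
        seed=seed + 2,
        operon_runs=operon_runs_idx,
    )
    operon_runs_ids = [[f"g{gi:03d}" for gi in run] for run in operon_runs_idx]
    operon_pairs = [
        (gid, f"op{k}") for k, ids in enumerate(operon_runs_ids) for gid in ids
    ]
    operons = OperonTable.from_pairs(operon_pairs, annotations)

    regulon_genes = sorted(
        {tf}
        | {g for ids in operon_runs_ids for g in ids}
        | {f"g{i:03d}" for i in singles_idx}
    )
    expression, expr_truth = make_expression(
        n_genes,
        200,
        bicluster_genes=regulon_genes,
        bicluster_conditions=list(range(120)),
        tf=tf,
        sigma=0.3,
        operon_runs=operon_runs_ids,
        seed=seed + 3,
    )
    fitness, _ = make_fitness(
        [f"g{i:03d}" for i in range(n_genes)],
        30,
        coherent=regulon_genes,
        sigma=0.1,
        seed=seed + 4,
    )
    truth.tf = tf
    truth.regulon_genes = regulon_genes
    truth.bicluster_genes = expr_truth.bicluster_genes
    truth.bicluster_conditions = expr_truth.bicluster_conditions
    truth.slopes = expr_truth.slopes
    truth.operons = {ids[0]: ids for ids in operon_runs_ids}
    return FixtureBundle(
        genome=genome,
        annotations=annotations,
        expression=expression,
        fitness=fitness,
        operons=operons,
        pwm=pwm,
        tf=tf,
        truth=truth,
    )


def make_planted_sequences(
    n_sequences: int = 20,
    length: int = 300,
    pwm: MotifModel | None = None,
    identity: float = 0.85,
    presence: float = 0.9,
    seed: int = 5,
    background: np.ndarray | None = None,
) -> tuple[list[tuple[str, str]], FixtureTruth]:
    """Upstream-like sequences with one planted site each (w.p. presence).

    Sites are planted on the forward strand at uniform offsets; truth
    records (seq id, offset, strand, word) per planted site.
    """
    rng = np.random.default_rng(seed)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    records = []
    truth = FixtureTruth(seed=seed, params={"identity": identity, "presence": presence})
    if pwm is not None:
        truth.pwm = pwm.theta.tolist()
        truth.consensus = pwm.consensus
        truth.symmetry = pwm.symmetry
    for i in range(n_sequences):
        seq = list(BASES[b] for b in rng.choice(4, size=length, p=bg / bg.sum()))
        sid = f"s{i:03d}"
        if pwm is not None and rng.random() < presence:
            word = sample_site(pwm, rng, identity=identity)
            off = int(rng.integers(0, length - pwm.width + 1))
            seq[off : off + pwm.width] = list(word)
            truth.site_loci.append([sid, "seq", off, "+", word])
        records.append((sid, "".join(seq)))
    return records, truth
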