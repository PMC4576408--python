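"""End-to-end orchestration: expression -> gene set -> motif -> regulon.

The pipeline chains the stages in the fixed order bicluster estimation,
operon-head filtering, feeding-order sorting, upstream extraction, SMC
motif discovery, genome scanning, and regulon assembly, writing every
intermediate artifact to the output directory.  All randomness flows from
the single seed, so a config plus seed reproduces outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .coexpression import (
    BiclusterParams,
    Bicluster,
    estimate_bicluster,
    extract_upstreams,
    feeding_order,
    filter_operon_heads,
)
from .core import AnnotationSet, Genome, OperonTable, revcomp
from .motif import MotifModel
from .regulon import Regulon, assemble_regulon, evaluate_regulon
from .scan import choose_score_threshold, scan_genome
from .smc import DiscoveryResult, SMCParams, discover_motif

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineParams:
    """All stage parameters in one reproducible record."""

    tf: str = ""
    seed: int = 0
    upstream_length: int = 300
    r_adj: float = 0.8
    operon_gap: int = 200
    bicluster: BiclusterParams = field(default_factory=BiclusterParams)
    smc: SMCParams = field(default_factory=SMCParams)
    p_threshold: float = 0.001
    s_threshold: float | None = None  # None -> 60% of the maximum score
    max_upstream: int = 300
    allow_intragenic: bool = True
    strand_restricted: bool = False
    extend_operons: bool = True
    scramble_seed: int | None = None
    prior_strength: float = 10.0


@dataclass
class PipelineResult:
    bicluster: Bicluster
    heads: list[str]
    order: list[str]
    upstreams: list[tuple[str, str]]
    discovery: DiscoveryResult
    motif: MotifModel
    sites: list
    regulon: Regulon
    s_threshold: float
    report: dict


def run_pipeline_objects(
    genome: Genome,
    annotations: AnnotationSet,
    expression: pd.DataFrame,
    params: PipelineParams,
    fitness: pd.DataFrame | None = None,
    operons: OperonTable | None = None,
    prior_theta: np.ndarray | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs; optionally write artifacts."""
    tf = params.tf
    if tf not in expression.index:
        raise PipelineError(f"TF gene {tf!r} absent from the expression matrix")
    annotations.validate_against(genome)
    params.smc.background = genome.background

    logger.info("stage 1: bicluster estimation seeded at %s", tf)
    bic = estimate_bicluster(expression, tf, fitness=fitness, params=params.bicluster)
    logger.info("bicluster: %d genes, %d conditions", len(bic.genes), len(bic.conditions))

    logger.info("stage 2: operon-head filtering")
    heads = filter_operon_heads(
        bic.genes, annotations, expression, tf,
        r_adj=params.r_adj, max_gap=params.operon_gap,
    )
    order = feeding_order(heads, expression, tf, scramble_seed=params.scramble_seed)
    upstreams = extract_upstreams(
        order, genome, annotations, length=params.upstream_length
    )
    if len(upstreams) < params.smc.min_sequences:
        raise PipelineError(
            f"high-confidence set too small: {len(upstreams)} upstream sequences "
            f"(need {params.smc.min_sequences}); relax r_init or check the TF id"
        )

    logger.info("stage 3: motif discovery on %d sequences", len(upstreams))
    discovery = discover_motif(
        upstreams,
        params=params.smc,
        prior_theta=prior_theta,
        prior_strength=params.prior_strength,
        seed=params.seed,
    )
    if discovery.status != "ok" or discovery.motif is None:
        raise PipelineError("no motif found in the high-confidence set")
    motif = discovery.motif

    logger.info("stage 4: genome scan (w=%d)", motif.width)
    if params.s_threshold is not None:
        s_thr = params.s_threshold
    else:
        # threshold chosen to recover the bulk of the sites the discovery
        # itself called in the high-confidence upstreams
        up_by_id = dict(upstreams)
        words = []
        for sid, off, strand, prob in discovery.site_calls:
            if off is None or prob < 0.5:
                continue
            word = up_by_id[sid][off : off + motif.width]
            if strand == "-":
                word = revcomp(word)
            if len(word) == motif.width:
                words.append(word)
        s_thr = choose_score_threshold(
            motif, reference_sites=words or None, background=genome.background
        )
        # a window scoring below 0 bits is likelier background than motif
        s_thr = max(s_thr, 0.0)
    sites = scan_genome(
        genome, motif, p_threshold=params.p_threshold, s_threshold=s_thr
    )
    logger.info("scan: %d sites pass p<=%g, score>=%.2f", len(sites), params.p_threshold, s_thr)

    logger.info("stage 5: regulon assembly")
    regulon = assemble_regulon(
        tf,
        sites,
        annotations,
        genome,
        operon_table=operons,
        max_upstream=params.max_upstream,
        allow_intragenic=params.allow_intragenic,
        strand_restricted=params.strand_restricted,
        extend=params.extend_operons,
    )
    report = {
        "tf": tf,
        "seed": params.seed,
        "n_bicluster_genes": len(bic.genes),
        "n_conditions": len(bic.conditions),
        "n_heads": len(heads),
        "motif_width": motif.width,
        "motif_consensus": motif.consensus,
        "motif_symmetry": motif.symmetry,
        "s_threshold": float(s_thr),
        "p_threshold": params.p_threshold,
        "n_sites": len(sites),
        "n_regulon_genes": len(regulon.genes),
        "n_intragenic": sum(1 for e in regulon.entries if e.intragenic),
        "n_via_operon": sum(1 for e in regulon.entries if e.via_operon),
    }
    result = PipelineResult(
        bicluster=bic,
        heads=heads,
        order=order,
        upstreams=upstreams,
        discovery=discovery,
        motif=motif,
        sites=sites,
        regulon=regulon,
        s_threshold=float(s_thr),
        report=report,
    )
    if out_dir is not None:
        write_artifacts(result, annotations, Path(out_dir))
    return result


def write_artifacts(result: PipelineResult, annotations: AnnotationSet, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bic = result.bicluster
    rows = []
    for g in sorted(bic.correlations.index):
        r = bic.correlations[g]
        kept = g in set(bic.genes)
        if not np.isfinite(r):
            reason = "undefined correlation"
        elif kept:
            reason = "member"
        else:
            reason = "below r_init"
        rows.append({"gene_id": g, "r": "" if not np.isfinite(r) else round(float(r), 6),
                     "kept": int(kept), "reason": reason})
    pd.DataFrame(rows).to_csv(out_dir / "bicluster_genes.tsv", sep="\t", index=False)
    (out_dir / "heads.txt").write_text("".join(f"{g}\n" for g in result.heads))
    rio.write_fasta(result.upstreams, out_dir / "upstreams.fasta")
    rio.write_motif(result.motif, out_dir / "motif.meme")
    pd.DataFrame(
        result.discovery.width_scores, columns=["w", "score", "n_sites"]
    ).to_csv(out_dir / "width_scores.tsv", sep="\t", index=False, float_format="%.4f")
    pd.DataFrame(
        [
            {
                "sequence": sid,
                "offset": "" if off is None else off,
                "strand": "" if strand is None else strand,
                "posterior": round(prob, 4),
            }
            for sid, off, strand, prob in result.discovery.site_calls
        ]
    ).to_csv(out_dir / "site_calls.tsv", sep="\t", index=False)
    rio.write_sites_tsv(result.sites, out_dir / "sites.tsv", motif_name=result.motif.name)
    rio.write_sites_bed(result.sites, out_dir / "sites.bed", name=result.motif.name)
    rio.write_regulon_tsv(result.regulon, out_dir / "regulon.tsv")
    rio.write_sites_gff3(result.regulon, out_dir / "sites.gff3")
    (out_dir / "report.json").write_text(
        json.dumps(result.report, indent=1, sort_keys=True) + "\n"
    )


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> PipelineResult:
    """File-based entry point: a config mapping of paths and parameters.

    Required keys: genome, annotations, expression, tf.  Optional: fitness,
    operons, prior_motif, plus any PipelineParams field and nested
    `bicluster:`/`smc:` parameter mappings.
    """
    for key in ("genome", "annotations", "expression", "tf"):
        if key not in config:
            raise PipelineError(f"config missing required key {key!r}")
    genome = rio.read_genome(config["genome"])
    annotations = rio.read_gff3(config["annotations"])
    expression = rio.read_matrix(
        config["expression"], na_token=config.get("na_token", "NA")
    )
    fitness = (
        rio.read_matrix(config["fitness"]) if config.get("fitness") else None
    )
    operons = (
        rio.read_operon_table(config["operons"], annotations)
        if config.get("operons")
        else None
    )
    prior_theta = None
    if config.get("prior_motif"):
        prior_theta = rio.read_motif(config["prior_motif"]).theta
    params = params_from_config(config)
    return run_pipeline_objects(
        genome,
        annotations,
        expression,
        params,
        fitness=fitness,
        operons=operons,
        prior_theta=prior_theta,
        out_dir=out_dir if out_dir is not None else config.get("out_dir"),
    )


def params_from_config(config: dict) -> PipelineParams:
    params = PipelineParams(tf=str(config["tf"]))
    for key in (
        "seed",
        "upstream_length",
        "r_adj",
        "operon_gap",
        "p_threshold",
        "s_threshold",
        "max_upstream",
        "allow_intragenic",
        "strand_restricted",
        "extend_operons",
        "scramble_seed",
        "prior_strength",
    ):
        if key in config and config[key] is not None:
            setattr(params, key, config[key])
    for key, value in (config.get("bicluster") or {}).items():
        setattr(params.bicluster, key, value)
    for key, value in (config.get("smc") or {}).items():
        setattr(params.smc, key, value)
    return params
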