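"""Pairing accepted binding sites with target genes and scoring regulons.

A binding site is double-stranded, so target genes are searched in both
directions: downstream along the + strand for + genes and downstream along
the - strand for - genes.  A gene pairs with a site when the site lies
within `max_upstream` bp of the gene's translation start on the gene's
side; sites inside an ORF can optionally pair with that ORF's gene as
intragenic hits.  Operon extension then appends co-operonic genes that
share the head gene's promoter.

Offsets follow the promoter convention: the position of the site's 5' end
relative to the gene's translation start, in gene orientation, so upstream
sites have negative offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core import AnnotationSet, Genome, OperonTable
from .motif import MotifModel
from .scan import BindingSite, scan_genome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegulonEntry:
    gene_id: str
    site: BindingSite
    offset: int  # site 5' end minus translation start, in gene orientation
    intragenic: bool
    via_operon: bool = False


@dataclass
class Regulon:
    tf: str
    entries: list[RegulonEntry] = field(default_factory=list)
    unassigned: list[BindingSite] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return sorted({e.gene_id for e in self.entries})

    @property
    def sites(self) -> list[BindingSite]:
        seen = []
        for e in self.entries:
            if e.site not in seen:
                seen.append(e.site)
        return seen


def _site_width(site: BindingSite) -> int:
    return len(site.sequence)


def assign_sites_to_genes(
    sites: list[BindingSite],
    annotations: AnnotationSet,
    genome: Genome,
    max_upstream: int = 300,
    allow_intragenic: bool = True,
    strand_restricted: bool = False,
) -> tuple[list[RegulonEntry], list[BindingSite]]:
    """Bidirectionally pair each site with nearby downstream genes.

    For each site, the nearest + strand gene starting downstream of the
    site (within max_upstream, not overlapping) is paired, and likewise the
    nearest - strand gene in the opposite direction.  A site inside an ORF
    pairs with that gene as intragenic when allowed.  With
    `strand_restricted`, only the direction matching the site's called
    strand is searched.  Returns (entries, unassigned sites), entries
    canonically sorted.
    """
    entries: set[RegulonEntry] = set()
    unassigned: list[BindingSite] = []
    for site in sorted(sites, key=lambda s: (s.contig, s.start, s.strand)):
        w = _site_width(site)
        s_start, s_end = site.start, site.start + w
        contig_genes = annotations.contig_genes(site.contig)
        found = False
        directions = ["+", "-"] if not strand_restricted else [site.strand]
        for direction in directions:
            best = None
            for g in contig_genes:
                if g.strand != direction:
                    continue
                if direction == "+":
                    if g.start >= s_end and g.start - s_start <= max_upstream:
                        if best is None or g.start < best.start:
                            best = g
                else:
                    if g.end <= s_start and (s_end - 1) - (g.end - 1) <= max_upstream:
                        if best is None or g.end > best.end:
                            best = g
            if best is not None:
                offset = (
                    s_start - best.start if direction == "+" else best.end - s_end
                )
                entries.add(
                    RegulonEntry(
                        gene_id=best.gene_id,
                        site=site,
                        offset=offset,
                        intragenic=False,
                    )
                )
                found = True
        if allow_intragenic:
            for g in contig_genes:
                if g.start <= s_start and s_end <= g.end:
                    offset = (
                        s_start - g.start if g.strand == "+" else g.end - s_end
                    )
                    entries.add(
                        RegulonEntry(
                            gene_id=g.gene_id,
                            site=site,
                            offset=offset,
                            intragenic=True,
                        )
                    )
                    found = True
        if not found:
            unassigned.append(site)
    ordered = sorted(
        entries,
        key=lambda e: (e.site.contig, e.site.start, e.site.strand, e.gene_id),
    )
    return ordered, unassigned


def extend_operons(
    entries: list[RegulonEntry],
    operon_table: OperonTable | None,
    annotations: AnnotationSet,
    enabled: bool = True,
) -> list[RegulonEntry]:
    """Append downstream co-operonic genes of each paired head gene.

    Added entries share the head's site and carry via_operon=True; operon
    members missing from the annotation are skipped with a warning.
    """
    if not enabled or operon_table is None:
        return list(entries)
    out = list(entries)
    seen = {(e.gene_id, e.site) for e in entries}
    for e in entries:
        for member in operon_table.downstream_of(e.gene_id):
            if member not in annotations:
                logger.warning("operon member %s not annotated; skipped", member)
                continue
            key = (member, e.site)
            if key in seen:
                continue
            seen.add(key)
            ann = annotations[member]
            w = _site_width(e.site)
            offset = (
                e.site.start - ann.start
                if ann.strand == "+"
                else ann.end - (e.site.start + w)
            )
            out.append(
                RegulonEntry(
                    gene_id=member,
                    site=e.site,
                    offset=offset,
                    intragenic=e.intragenic,
                    via_operon=True,
                )
            )
    out.sort(key=lambda e: (e.site.contig, e.site.start, e.site.strand, e.gene_id))
    return out


def evaluate_regulon(
    predicted: set[str], reference: set[str], universe: set[str]
) -> dict[str, float]:
    """Confusion counts and TPR/FPR of a predicted gene set.

    TPR = TP/(TP+FN), FPR = FP/(FP+TN), over gene ids in the universe.
    """
    predicted, reference, universe = set(predicted), set(reference), set(universe)
    if not reference <= universe:
        raise ValueError("reference genes must be a subset of the universe")
    predicted = predicted & universe
    tp = len(predicted & reference)
    fp = len(predicted - reference)
    fn = len(reference - predicted)
    tn = len(universe) - tp - fp - fn
    tpr = tp / (tp + fn) if (tp + fn) else float("nan")
    fpr = fp / (fp + tn) if (fp + tn) else float("nan")
    return {
        "TP": tp,
        "FP": fp,
        "FN": fn,
        "TN": tn,
        "TPR": tpr,
        "FPR": fpr,
    }


def assemble_regulon(
    tf: str,
    sites: list[BindingSite],
    annotations: AnnotationSet,
    genome: Genome,
    operon_table: OperonTable | None = None,
    max_upstream: int = 300,
    allow_intragenic: bool = True,
    strand_restricted: bool = False,
    extend: bool = True,
) -> Regulon:
    """Full assembly: site-gene pairing followed by operon extension."""
    entries, unassigned = assign_sites_to_genes(
        sites,
        annotations,
        genome,
        max_upstream=max_upstream,
        allow_intragenic=allow_intragenic,
        strand_restricted=strand_restricted,
    )
    entries = extend_operons(entries, operon_table, annotations, enabled=extend)
    return Regulon(tf=tf, entries=entries, unassigned=unassigned)


def roc_curve(
    motif: MotifModel,
    genome: Genome,
    annotations: AnnotationSet,
    reference: set[str],
    thresholds: list[float],
    tf: str = "tf",
    p_threshold: float = 0.001,
    operon_table: OperonTable | None = None,
    max_upstream: int = 300,
    allow_intragenic: bool = True,
) -> list[tuple[float, float, float]]:
    """Re-run scan + assembly over a descending score-threshold grid.

    Returns (s_threshold, TPR, FPR) rows; lowering the threshold can only
    add sites, so TPR is non-decreasing along the grid.
    """
    if list(thresholds) != sorted(thresholds, reverse=True):
        raise ValueError("threshold grid must be descending")
    universe = {g.gene_id for g in annotations.genes}
    rows = []
    for s_thr in thresholds:
        sites = scan_genome(genome, motif, p_threshold=p_threshold, s_threshold=s_thr)
        reg = assemble_regulon(
            tf,
            sites,
            annotations,
            genome,
            operon_table=operon_table,
            max_upstream=max_upstream,
            allow_intragenic=allow_intragenic,
        )
        m = evaluate_regulon(set(reg.genes), reference, universe)
        rows.append((float(s_thr), m["TPR"], m["FPR"]))
    return rows
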