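"""Readers and writers for the pipeline's external formats.

FASTA for genomes and upstream sequences (Biopython), GFF3 for gene
annotations and predicted sites (gffutils for parsing; GFF3 is 1-based
inclusive and converted to the internal 0-based half-open convention at
this boundary), BED6 and TSV for site lists and reports, TSV for matrices
and operon tables, and MEME minimal motif format for PWMs in and out.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AnnotationSet, BASES, GeneAnnotation, Genome, OperonTable
from .motif import MotifModel
from .regulon import Regulon
from .scan import BindingSite


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------- FASTA


def read_genome(path) -> Genome:
    """Read a (multi-)FASTA genome; background counted over A,C,G,T only."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    contigs: dict[str, str] = {}
    for rec in records:
        if rec.id in contigs:
            raise FormatError(f"{path}: duplicate contig id {rec.id!r}")
        contigs[rec.id] = str(rec.seq)
    return Genome.from_contigs(contigs)


def write_fasta(records: list[tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


# -------------------------------------------------------------- matrices


def read_matrix(path, na_token: str = "NA", transpose: bool = False) -> pd.DataFrame:
    """Genes x conditions TSV: first column gene ids, header condition ids.

    Missing cells (the NA token or empty) parse as NaN, never as zero.
    Non-numeric cells and duplicate gene ids are format errors; a matrix
    that looks condition-major must be loaded with transpose=True.
    """
    try:
        df = pd.read_csv(
            str(path),
            sep="\t",
            index_col=0,
            na_values=[na_token],
            keep_default_na=False,
        )
    except Exception as exc:  # pragma: no cover - pandas error detail varies
        raise FormatError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene ids {dupes}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path, na_token: str = "NA") -> None:
    df.to_csv(str(path), sep="\t", na_rep=na_token, float_format="%.6g")


# -------------------------------------------------------------- GFF3/BED


def read_gff3(path, feature_types: tuple[str, ...] = ("gene",)) -> AnnotationSet:
    """Parse gene features from GFF3 (1-based inclusive -> half-open)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    contig=feat.seqid,
                    start=feat.start - 1,
                    end=feat.end,
                    strand=feat.strand,
                )
            )
    if not genes:
        raise FormatError(f"{path}: no features of type {feature_types}")
    return AnnotationSet(genes)


def write_gff3(annotations: AnnotationSet, path, source: str = "regulonkit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(annotations.genes, key=lambda g: (g.contig, g.start)):
            fh.write(
                f"{g.contig}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_sites_bed(sites: list[BindingSite], path, name: str = "site") -> None:
    """BED6 (0-based half-open) with LLR score and a p-value extra column."""
    with open(path, "w") as fh:
        for s in sites:
            end = s.start + len(s.sequence)
            fh.write(
                f"{s.contig}\t{s.start}\t{end}\t{name}\t{s.score:.4f}\t{s.strand}"
                f"\t{s.p_value:.3e}\n"
            )


def write_sites_tsv(sites: list[BindingSite], path, motif_name: str = "motif") -> None:
    rows = [
        {
            "motif": motif_name,
            "contig": s.contig,
            "start": s.start,
            "end": s.start + len(s.sequence),
            "strand": s.strand,
            "sequence": s.sequence,
            "score_bits": round(s.score, 4),
            "p_value": float(f"{s.p_value:.6e}"),
        }
        for s in sites
    ]
    pd.DataFrame(
        rows,
        columns=[
            "motif",
            "contig",
            "start",
            "end",
            "strand",
            "sequence",
            "score_bits",
            "p_value",
        ],
    ).to_csv(str(path), sep="\t", index=False)


def read_sites_tsv(path) -> list[BindingSite]:
    df = pd.read_csv(str(path), sep="\t")
    return [
        BindingSite(
            contig=str(r.contig),
            start=int(r.start),
            strand=str(r.strand),
            sequence=str(r.sequence),
            score=float(r.score_bits),
            p_value=float(r.p_value),
        )
        for r in df.itertuples()
    ]


# --------------------------------------------------------------- operons


def read_operon_table(path, annotations: AnnotationSet | None = None) -> OperonTable:
    """TSV with columns gene_id, operon_id (header optional)."""
    df = pd.read_csv(str(path), sep="\t", dtype=str, comment="#")
    if list(df.columns[:2]) != ["gene_id", "operon_id"]:
        df = pd.read_csv(
            str(path), sep="\t", dtype=str, header=None, names=["gene_id", "operon_id"]
        )
    pairs = [(str(r.gene_id), str(r.operon_id)) for r in df.itertuples()]
    return OperonTable.from_pairs(pairs, annotations)


def write_operon_table(operons: OperonTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\toperon_id\n")
        for operon in sorted(operons.members):
            for gene in operons.members[operon]:
                fh.write(f"{gene}\t{operon}\n")


# ------------------------------------------------------------------ MEME


def write_motif(motif: MotifModel, path) -> None:
    """MEME minimal motif format; block spans and symmetry as comments."""
    bg = motif.background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {bg[i]:.6f}" for i, b in enumerate(BASES)) + "\n\n"
        )
        fh.write(f"MOTIF {motif.name}\n")
        if motif.block1 is not None:
            fh.write(
                f"# blocks: {motif.block1[0]}-{motif.block1[1]} "
                f"{motif.block2[0]}-{motif.block2[1]}\n"
            )
        fh.write(f"# symmetry: {motif.symmetry}\n")
        nsites = motif.nsites if motif.nsites else 20
        fh.write(
            f"letter-probability matrix: alength= 4 w= {motif.width} "
            f"nsites= {nsites} E= 0\n"
        )
        for row in motif.theta:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_motif(path, alpha: float = 0.5) -> MotifModel:
    """Read the first motif from a MEME minimal file.

    The probability matrix is parsed directly at full printed precision
    (Biopython's minimal parser re-quantises probabilities through the
    nsites count, which breaks the write->read round trip).  Probabilities
    are floored by a tiny epsilon so downstream logs never see zeros;
    block/symmetry comment lines written by `write_motif` are recovered.
    """
    lines = Path(path).read_text().splitlines()
    block1 = block2 = None
    symmetry = "none"
    name = "motif"
    nsites = 0
    bg = np.full(4, 0.25)
    rows: list[list[float]] = []
    width = None
    in_matrix = False
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("# blocks:"):
            spans = line.split(":", 1)[1].split()
            b1, b2 = spans[0].split("-"), spans[1].split("-")
            block1, block2 = (int(b1[0]), int(b1[1])), (int(b2[0]), int(b2[1]))
        elif line.startswith("# symmetry:"):
            symmetry = line.split(":", 1)[1].strip()
        elif line.startswith("Background letter frequencies"):
            i += 1
            fields = lines[i].split()
            vals = {fields[j]: float(fields[j + 1]) for j in range(0, len(fields), 2)}
            bg = np.array([vals.get(b, 0.25) for b in BASES])
            bg = bg / bg.sum()
        elif line.startswith("MOTIF"):
            if rows:
                break  # only the first motif
            name = line.split(maxsplit=2)[1] if len(line.split()) > 1 else "motif"
        elif line.startswith("letter-probability matrix"):
            if "w=" in line:
                width = int(float(line.split("w=")[1].split()[0]))
            if "nsites=" in line:
                nsites = int(float(line.split("nsites=")[1].split()[0]))
            in_matrix = True
        elif in_matrix and line and line[0] in "0123456789.":
            rows.append([float(v) for v in line.split()])
        elif in_matrix and (not line or not line[0] in "0123456789."):
            in_matrix = False
        i += 1
    if not rows:
        raise FormatError(f"{path}: no motif probability matrix found")
    theta = np.asarray(rows, dtype=float)
    if theta.shape[1] != 4 or (width is not None and theta.shape[0] != width):
        raise FormatError(f"{path}: malformed probability matrix")
    theta = np.maximum(theta, 1e-9)
    theta = theta / theta.sum(axis=1, keepdims=True)
    return MotifModel(
        theta=theta,
        block1=block1,
        block2=block2,
        symmetry=symmetry,
        alpha=alpha,
        name=name,
        nsites=nsites,
        background=bg,
    )


# ---------------------------------------------------------------- regulon


def write_regulon_tsv(regulon: Regulon, path) -> None:
    rows = []
    for e in regulon.entries:
        s = e.site
        rows.append(
            {
                "gene_id": e.gene_id,
                "contig": s.contig,
                "site_start": s.start,
                "site_strand": s.strand,
                "site_sequence": s.sequence,
                "score_bits": round(s.score, 4),
                "p_value": float(f"{s.p_value:.6e}"),
                "offset": e.offset,
                "intragenic": int(e.intragenic),
                "via_operon": int(e.via_operon),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "contig",
            "site_start",
            "site_strand",
            "site_sequence",
            "score_bits",
            "p_value",
            "offset",
            "intragenic",
            "via_operon",
        ],
    ).to_csv(str(path), sep="\t", index=False)


def write_sites_gff3(regulon: Regulon, path, source: str = "regulonkit") -> None:
    """Predicted sites as GFF3 TF_binding_site features with gene links."""
    by_site: dict[BindingSite, list[str]] = {}
    for e in regulon.entries:
        by_site.setdefault(e.site, []).append(e.gene_id)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, (s, genes) in enumerate(
            sorted(by_site.items(), key=lambda kv: (kv[0].contig, kv[0].start))
        ):
            attrs = (
                f"ID=site{i:04d};genes={','.join(sorted(set(genes)))};"
                f"pvalue={s.p_value:.3e}"
            )
            fh.write(
                f"{s.contig}\t{source}\tTF_binding_site\t{s.start + 1}\t"
                f"{s.start + len(s.sequence)}\t{s.score:.4f}\t{s.strand}\t.\t{attrs}\n"
            )


def read_gene_list(path) -> set[str]:
    """One gene id per line; '#' comments and blank lines ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line.split()[0])
    return out


# ----------------------------------------------------------------- config


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg
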