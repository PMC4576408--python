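"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; GFF3
(1-based inclusive) is converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC nucleotide codes; anything outside ACGT is degraded to N on input.
IUPAC = set("ACGTURYSWKMBDHVN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode ACGTN into int8 codes 0..3, with N (and friends) as -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out


@dataclass
class Genome:
    """A genome as a dict of contigs plus its 0-order background model.

    The background is the genome-wide nucleotide frequency over A,C,G,T
    (N excluded from the counts); it is the null model for site scoring.
    """

    contigs: dict[str, str]
    background: np.ndarray

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,):
            raise ValueError("background must be a length-4 vector")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")

    @classmethod
    def from_contigs(cls, contigs: dict[str, str]) -> "Genome":
        """Build a genome, sanitising sequences and counting the background.

        Non-ACGT IUPAC characters are replaced by N; other characters raise.
        """
        clean: dict[str, str] = {}
        counts = np.zeros(4, dtype=np.int64)
        for name, seq in contigs.items():
            seq = seq.upper()
            bad = set(seq) - IUPAC
            if bad:
                raise ValueError(
                    f"contig {name!r} contains non-IUPAC characters: {sorted(bad)}"
                )
            seq = "".join(c if c in "ACGT" else "N" for c in seq)
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            clean[name] = seq
            codes = encode(seq)
            counts += np.bincount(codes[codes >= 0], minlength=4)
        total = counts.sum()
        if total == 0:
            # all-N genome: fall back to uniform
            background = np.full(4, 0.25)
        else:
            background = counts / total
        return cls(contigs=clean, background=background)

    def slice(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Genome slice in the given orientation."""
        seq = self.contigs[contig][start:end]
        return revcomp(seq) if strand == "-" else seq


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene locus: contig, [start, end) in 0-based half-open, strand."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad coordinates for {self.gene_id}: {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand for {self.gene_id}: {self.strand!r}")

    @property
    def tss(self) -> int:
        """Genomic coordinate of the translation start (5' end in orientation)."""
        return self.start if self.strand == "+" else self.end - 1


class AnnotationSet:
    """Indexed collection of gene annotations with unique gene ids."""

    def __init__(self, genes: list[GeneAnnotation]):
        self.genes = list(genes)
        self.by_id: dict[str, GeneAnnotation] = {}
        for g in self.genes:
            if g.gene_id in self.by_id:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            self.by_id[g.gene_id] = g
        self._by_contig: dict[str, list[GeneAnnotation]] = {}
        for g in self.genes:
            self._by_contig.setdefault(g.contig, []).append(g)
        for lst in self._by_contig.values():
            lst.sort(key=lambda g: (g.start, g.end, g.gene_id))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.by_id

    def __getitem__(self, gene_id: str) -> GeneAnnotation:
        return self.by_id[gene_id]

    def contig_genes(self, contig: str) -> list[GeneAnnotation]:
        """Genes on a contig sorted by start coordinate."""
        return self._by_contig.get(contig, [])

    def validate_against(self, genome: Genome) -> None:
        for g in self.genes:
            if g.contig not in genome.contigs:
                raise ValueError(f"gene {g.gene_id} on unknown contig {g.contig!r}")
            if g.end > len(genome.contigs[g.contig]):
                raise ValueError(f"gene {g.gene_id} extends past contig end")


@dataclass
class OperonTable:
    """Predicted operons: gene -> operon id plus ordered member lists.

    Member lists are in operon orientation (head first); every gene belongs
    to at most one operon and members share contig and strand.
    """

    gene_to_operon: dict[str, str] = field(default_factory=dict)
    members: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_pairs(
        cls, pairs: list[tuple[str, str]], annotations: AnnotationSet | None = None
    ) -> "OperonTable":
        gene_to_operon: dict[str, str] = {}
        raw: dict[str, list[str]] = {}
        for gene, operon in pairs:
            if gene in gene_to_operon:
                raise ValueError(f"gene {gene!r} assigned to more than one operon")
            gene_to_operon[gene] = operon
            raw.setdefault(operon, []).append(gene)
        members: dict[str, list[str]] = {}
        for operon, genes in raw.items():
            if annotations is not None and all(g in annotations for g in genes):
                anns = [annotations[g] for g in genes]
                contigs = {a.contig for a in anns}
                strands = {a.strand for a in anns}
                if len(contigs) > 1 or len(strands) > 1:
                    raise ValueError(
                        f"operon {operon!r} members span contigs/strands"
                    )
                reverse = strands.pop() == "-"
                genes = [
                    a.gene_id
                    for a in sorted(anns, key=lambda a: a.start, reverse=reverse)
                ]
            members[operon] = genes
        return cls(gene_to_operon=gene_to_operon, members=members)

    def operon_of(self, gene_id: str) -> str | None:
        return self.gene_to_operon.get(gene_id)

    def downstream_of(self, gene_id: str) -> list[str]:
        """Co-operonic genes following `gene_id` in operon order."""
        operon = self.gene_to_operon.get(gene_id)
        if operon is None:
            return []
        genes = self.members[operon]
        idx = genes.index(gene_id)
        return genes[idx + 1 :]
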