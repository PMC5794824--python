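"""Reference genome and gene-model handling.

Loads FASTA contigs and GFF3 gene models, validates transcript structure,
and derives the strand-aware region intervals the annotation stage
queries: CDS, 5'/3' UTR, splice-site windows (the first/last two
nucleotides of each intron by default) and promoter windows (500 bp
upstream through 30 bp downstream of the transcription start site by
default).

Coordinates follow the conventions of the formats involved: GFF3 and all
``GeneModel`` fields are 1-based closed intervals; interval-tree
arithmetic internally uses 0-based half-open ranges and converts at the
boundary.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gffutils
from Bio import SeqIO
from intervaltree import IntervalTree

__all__ = [
    "GenomeSequence",
    "GeneModel",
    "AnnotationConfig",
    "RegionIndex",
    "read_fasta",
    "read_gff",
    "write_gff",
    "promoter_window",
    "splice_site_intervals",
    "utr_intervals",
    "intron_intervals",
    "build_region_index",
]

#: Region kinds, in annotation precedence order (highest first).
REGION_KINDS = ("CDS", "SPLICE", "UTR5", "UTR3", "INTRON", "PROMOTER")
_KIND_RANK = {k: i for i, k in enumerate(REGION_KINDS)}


class GffValidationError(ValueError):
    """A gene model violates a structural invariant."""


@dataclass
class GenomeSequence:
    """Reference sequence: contig id -> uppercased nucleotide string."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Sequence of the 1-based closed interval [start, end]."""
        return self.contigs[contig][start - 1 : end]


@dataclass
class GeneModel:
    """One transcript's strand-aware structure.

    ``exons`` and ``cds`` are sorted lists of 1-based closed genomic
    intervals in ascending genomic order.  ``tss`` is the transcription
    start: the 5'-most genomic coordinate of the transcript on the +
    strand, the 3'-most on the - strand.
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    tss: int = 0
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GffValidationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            # CDS-only annotations degrade to exons == cds
            self.exons = list(self.cds)
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            for (a, b) in ivs:
                if a > b:
                    raise GffValidationError(
                        f"{self.transcript_id}: inverted {name} interval ({a}, {b})"
                    )
            for (_, b1), (a2, _) in zip(ivs, ivs[1:]):
                if a2 <= b1:
                    raise GffValidationError(
                        f"{self.transcript_id}: overlapping {name} intervals"
                    )
        exon_pos: set[int] = set()
        for a, b in self.exons:
            exon_pos.update(range(a, b + 1))
        for a, b in self.cds:
            if not all(p in exon_pos for p in (a, b)):
                raise GffValidationError(
                    f"{self.transcript_id}: CDS interval ({a}, {b}) outside exons"
                )
        cds_len = sum(b - a + 1 for a, b in self.cds)
        if cds_len % 3 != 0:
            self.warnings.append(
                f"{self.transcript_id}: CDS length {cds_len} not divisible by 3"
            )
        if self.tss == 0:
            # Default: transcript extent; equals CDS start when UTRs are absent.
            self.tss = self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_start(self) -> int | None:
        return self.cds[0][0] if self.cds else None

    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)


@dataclass
class AnnotationConfig:
    """Region definitions used during annotation.

    promoter_upstream / promoter_downstream
        Promoter window extent in bp on either side of the TSS
        (defaults 500 upstream, 30 downstream).
    splice_window
        Nucleotides at each intron edge counted as splice site
        (default 2: the first or last two nucleotides of an intron).
    """

    promoter_upstream: int = 500
    promoter_downstream: int = 30
    splice_window: int = 2

    def __post_init__(self) -> None:
        if min(self.promoter_upstream, self.promoter_downstream, self.splice_window) < 0:
            raise ValueError("annotation window sizes must be >= 0")


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a (multi-record, possibly wrapped) FASTA into a GenomeSequence.

    Contigs are keyed by the first whitespace-delimited header token and
    sequences are uppercased.  Sequence data before any header is a
    parse error naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: sequence data before first FASTA header"
                )
            break
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"{path}: duplicate contig id {rec.id!r}")
        contigs[rec.id] = str(rec.seq).upper()
    return GenomeSequence(contigs)


def _tx_models_from_db(db: gffutils.FeatureDB) -> Iterator[GeneModel]:
    for tx in db.features_of_type(("mRNA", "transcript")):
        exons = [(f.start, f.end) for f in db.children(tx, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(tx, featuretype="CDS")]
        parents = list(db.parents(tx, featuretype="gene"))
        gene_id = parents[0].id if parents else tx.id
        yield GeneModel(
            gene_id=gene_id,
            transcript_id=tx.id,
            contig=tx.seqid,
            strand=tx.strand,
            exons=exons,
            cds=cds,
        )


def read_gff(path: str | Path, genome: GenomeSequence) -> list[GeneModel]:
    """Load gene models from a GFF3 file.

    One ``GeneModel`` per mRNA/transcript feature, with exons and CDS
    linked through Parent attributes.  Models on contigs absent from
    ``genome`` raise; CDS outside exons raises a validation error naming
    the transcript.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = sorted(
        _tx_models_from_db(db), key=lambda g: (g.contig, g.start, g.transcript_id)
    )
    for g in models:
        if g.contig not in genome:
            raise ValueError(
                f"{g.transcript_id}: contig {g.contig!r} not present in genome"
            )
        if g.end > genome.length(g.contig):
            raise GffValidationError(
                f"{g.transcript_id}: extends past end of contig {g.contig!r}"
            )
    return models


def write_gff(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig, g.start, g.transcript_id)):
            fh.write(
                "\t".join(
                    [g.contig, "mutscreen", "gene", str(g.start), str(g.end), ".",
                     g.strand, ".", f"ID={g.gene_id}"]
                )
                + "\n"
            )
            fh.write(
                "\t".join(
                    [g.contig, "mutscreen", "mRNA", str(g.start), str(g.end), ".",
                     g.strand, ".", f"ID={g.transcript_id};Parent={g.gene_id}"]
                )
                + "\n"
            )
            for i, (a, b) in enumerate(g.exons, 1):
                fh.write(
                    "\t".join(
                        [g.contig, "mutscreen", "exon", str(a), str(b), ".",
                         g.strand, ".",
                         f"ID={g.transcript_id}.exon{i};Parent={g.transcript_id}"]
                    )
                    + "\n"
                )
            phase = 0
            cds_iter = g.cds if g.strand == "+" else list(reversed(g.cds))
            phases = {}
            for a, b in cds_iter:
                phases[(a, b)] = phase
                phase = (3 - ((b - a + 1 - phase) % 3)) % 3
            for i, (a, b) in enumerate(g.cds, 1):
                fh.write(
                    "\t".join(
                        [g.contig, "mutscreen", "CDS", str(a), str(b), ".",
                         g.strand, str(phases[(a, b)]),
                         f"ID={g.transcript_id}.cds{i};Parent={g.transcript_id}"]
                    )
                    + "\n"
                )


def promoter_window(
    gene: GeneModel, cfg: AnnotationConfig, contig_length: int | None = None
) -> tuple[int, int]:
    """Promoter interval of a gene: upstream..downstream of the TSS.

    On the + strand this is [tss - upstream, tss + downstream]; on the -
    strand the strand-aware mirror [tss - downstream, tss + upstream].
    The interval is clipped to [1, contig_length].
    """
    if gene.strand == "+":
        lo, hi = gene.tss - cfg.promoter_upstream, gene.tss + cfg.promoter_downstream
    else:
        lo, hi = gene.tss - cfg.promoter_downstream, gene.tss + cfg.promoter_upstream
    lo = max(lo, 1)
    if contig_length is not None:
        hi = min(hi, contig_length)
    return (lo, hi)


def intron_intervals(gene: GeneModel) -> list[tuple[int, int]]:
    """Introns: gaps between consecutive exons, genomic order."""
    out = []
    for (_, b1), (a2, _) in zip(gene.exons, gene.exons[1:]):
        if a2 - b1 > 1:
            out.append((b1 + 1, a2 - 1))
    return out


def splice_site_intervals(
    gene: GeneModel, cfg: AnnotationConfig
) -> list[tuple[int, int]]:
    """Splice-site windows: the first and last ``splice_window``
    nucleotides of each intron.  Introns too short for two disjoint
    windows yield the whole intron once."""
    w = cfg.splice_window
    if w == 0:
        return []
    out = []
    for a, b in intron_intervals(gene):
        if (b - a + 1) <= 2 * w:
            out.append((a, b))
        else:
            out.append((a, a + w - 1))
            out.append((b - w + 1, b))
    return out


def utr_intervals(gene: GeneModel) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """(UTR5, UTR3) intervals: exonic sequence outside the CDS span,
    assigned by strand-aware side of the CDS."""
    if not gene.cds:
        return [], []
    cds_lo, cds_hi = gene.cds[0][0], gene.cds[-1][1]
    left, right = [], []
    for a, b in gene.exons:
        if a < cds_lo:
            left.append((a, min(b, cds_lo - 1)))
        if b > cds_hi:
            right.append((max(a, cds_hi + 1), b))
    if gene.strand == "+":
        return left, right
    return right, left


@dataclass
class RegionIndex:
    """Per-contig interval lookup: position -> [(gene, region-kind)].

    Query results are deterministic: sorted by (gene_id, transcript_id,
    precedence rank of the kind).
    """

    trees: dict[str, IntervalTree]
    genes: dict[str, GeneModel]
    cfg: AnnotationConfig

    def query(self, contig: str, start: int, end: int | None = None) -> list[tuple[GeneModel, str]]:
        """All (gene, kind) pairs overlapping the 1-based closed
        interval [start, end] (a single position if end is None)."""
        if end is None:
            end = start
        tree = self.trees.get(contig)
        if tree is None:
            return []
        hits = {(iv.data[0], iv.data[1]) for iv in tree.overlap(start - 1, end)}
        out = sorted(
            hits,
            key=lambda t: (
                self.genes[t[0]].gene_id,
                t[0],
                _KIND_RANK[t[1]],
            ),
        )
        return [(self.genes[tid], kind) for tid, kind in out]


def _gene_regions(
    gene: GeneModel, cfg: AnnotationConfig, contig_length: int | None
) -> Iterator[tuple[str, tuple[int, int]]]:
    for iv in gene.cds:
        yield "CDS", iv
    u5, u3 = utr_intervals(gene)
    for iv in u5:
        yield "UTR5", iv
    for iv in u3:
        yield "UTR3", iv
    for iv in splice_site_intervals(gene, cfg):
        yield "SPLICE", iv
    for iv in intron_intervals(gene):
        yield "INTRON", iv
    yield "PROMOTER", promoter_window(gene, cfg, contig_length)


def build_region_index(
    genes: list[GeneModel],
    cfg: AnnotationConfig | None = None,
    genome: GenomeSequence | None = None,
) -> RegionIndex:
    """Index every region interval of every gene for overlap queries.

    A position may map to multiple (gene, kind) pairs; all overlapping
    assignments are retained (overlapping genes are not collapsed).
    """
    cfg = cfg or AnnotationConfig()
    trees: dict[str, IntervalTree] = {}
    gene_map: dict[str, GeneModel] = {}
    for g in genes:
        if g.transcript_id in gene_map:
            raise ValueError(f"duplicate transcript_id {g.transcript_id!r}")
        gene_map[g.transcript_id] = g
        clen = genome.length(g.contig) if genome is not None else None
        tree = trees.setdefault(g.contig, IntervalTree())
        for kind, (a, b) in _gene_regions(g, cfg, clen):
            if a <= b:
                tree.addi(a - 1, b, (g.transcript_id, kind))
    return RegionIndex(trees=trees, genes=gene_map, cfg=cfg)
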