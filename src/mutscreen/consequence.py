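"""Variant consequence annotation.

Each retained variant is assigned, per overlapping gene, the highest-
precedence region it touches — CODING > SPLICE > UTR5/UTR3 > INTRON >
PROMOTER — so a splice-site base inside an annotated intron is reported
as SPLICE and a promoter overlap is only reported when no transcribed
region of the same gene is hit.  Variants touching no gene region get a
single INTERGENIC call.  Coding SNVs are translated in transcript
orientation with the standard nuclear genetic code; synonymous coding
changes are excluded from downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from mutscreen.genome_model import (
    AnnotationConfig,
    GeneModel,
    GenomeSequence,
    RegionIndex,
)
from mutscreen.variant_core import CallSet, VariantRecord

__all__ = [
    "ConsequenceCall",
    "AnnotatedStrain",
    "coding_effect",
    "annotate_variant",
    "annotate_strain",
    "exclude_synonymous",
]

REGIONS = ("CODING", "UTR5", "UTR3", "SPLICE", "PROMOTER", "INTRON", "INTERGENIC")
CODING_EFFECTS = (
    "SYNONYMOUS", "MISSENSE", "NONSENSE", "STOP_LOSS",
    "FRAMESHIFT", "INFRAME_INDEL", "LARGE_INSERTION", "LARGE_DELETION",
)

# kind in the region index -> reported region label
_KIND_TO_REGION = {
    "CDS": "CODING", "SPLICE": "SPLICE", "UTR5": "UTR5", "UTR3": "UTR3",
    "INTRON": "INTRON", "PROMOTER": "PROMOTER",
}
_PRECEDENCE = {"CDS": 0, "SPLICE": 1, "UTR5": 2, "UTR3": 2, "INTRON": 3, "PROMOTER": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class ConsequenceCall:
    """A variant's region category and coding effect for one gene."""

    variant: VariantRecord
    gene_id: str | None
    transcript_id: str | None
    region: str
    coding_effect: str | None = None
    aa_change: str | None = None

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if (self.coding_effect is not None) != (self.region == "CODING"):
            raise ValueError(
                "coding_effect must be present exactly when region is CODING"
            )
        if self.coding_effect is not None and self.coding_effect not in CODING_EFFECTS:
            raise ValueError(f"unknown coding effect {self.coding_effect!r}")


@dataclass
class AnnotatedStrain:
    """All consequence calls retained for one strain after exclusions."""

    strain: str
    calls: list[ConsequenceCall] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.calls)


def _cds_positions(gene: GeneModel) -> list[int]:
    """Genomic positions of CDS bases in transcript (5'->3') order."""
    pos = [p for a, b in gene.cds for p in range(a, b + 1)]
    return pos if gene.strand == "+" else pos[::-1]


def _tx_base(base: str, strand: str) -> str:
    return base if strand == "+" else base.translate(_COMPLEMENT)


def cds_sequence(gene: GeneModel, genome: GenomeSequence) -> str:
    """Spliced CDS nucleotide sequence in transcript orientation."""
    seq = "".join(genome.fetch(gene.contig, a, b) for a, b in gene.cds)
    if gene.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq


def mutant_cds_sequence(
    v: VariantRecord, gene: GeneModel, genome: GenomeSequence
) -> str:
    """Rebuild the full CDS with the variant applied (genomic edit,
    then splice and orient).  Inserted bases landing between two CDS
    bases are included; bases deleted from the CDS are removed."""
    contig = genome.contigs[gene.contig]
    edited: dict[int, str] = {}
    n = min(len(v.ref), len(v.alt))
    for i in range(len(v.ref)):
        edited[v.pos + i] = v.alt[i] if i < n else ""
    if len(v.alt) > len(v.ref):
        edited[v.pos + len(v.ref) - 1] += v.alt[len(v.ref):]
    parts = []
    for a, b in gene.cds:
        for p in range(a, b + 1):
            parts.append(edited.get(p, contig[p - 1]))
    seq = "".join(parts)
    if gene.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq


def _aa_change_string(old_aa: str, codon_number: int, new_aa: str) -> str:
    def name(a: str) -> str:
        return "Ter" if a == "*" else seq3(a)
    return f"p.{name(old_aa)}{codon_number}{name(new_aa)}"


def coding_effect(
    v: VariantRecord, gene: GeneModel, genome: GenomeSequence
) -> tuple[str, str | None]:
    """Coding effect and (for SNVs) protein-level change of a variant
    overlapping the CDS of ``gene``.

    SNVs are classified by translating the affected codon in transcript
    orientation: SYNONYMOUS, MISSENSE, NONSENSE (gain of stop) or
    STOP_LOSS.  Indels are FRAMESHIFT when the CDS-overlapping net
    length change is not a multiple of 3, else INFRAME_INDEL.  Large
    structural events map to LARGE_INSERTION / LARGE_DELETION.
    """
    if v.svtype is not None:
        if v.svtype == "large_deletion":
            return "LARGE_DELETION", None
        return "LARGE_INSERTION", None

    cds_pos = _cds_positions(gene)
    pos_index = {p: i for i, p in enumerate(cds_pos)}
    lo, hi = v.ref_span()
    overlap = [p for p in range(lo, hi + 1) if p in pos_index]
    if not overlap and not (len(v.alt) > len(v.ref) and v.pos in pos_index):
        raise ValueError(
            f"variant {v.contig}:{v.pos} does not overlap CDS of {gene.transcript_id}"
        )

    if v.is_snv:
        i = pos_index[v.pos]
        codon_idx = i // 3
        codon = [
            genome.fetch(gene.contig, p, p) for p in cds_pos[codon_idx * 3 : codon_idx * 3 + 3]
        ]
        codon = [_tx_base(b, gene.strand) for b in codon]
        old_aa = str(Seq("".join(codon)).translate())
        codon[i % 3] = _tx_base(v.alt, gene.strand)
        new_aa = str(Seq("".join(codon)).translate())
        aa = _aa_change_string(old_aa, codon_idx + 1, new_aa)
        if new_aa == old_aa:
            return "SYNONYMOUS", aa
        if new_aa == "*":
            return "NONSENSE", aa
        if old_aa == "*":
            return "STOP_LOSS", aa
        return "MISSENSE", aa

    if len(v.ref) == len(v.alt):
        # multi-nucleotide substitution: rebuild and compare translations
        old_prot = str(Seq(cds_sequence(gene, genome)).translate())
        new_prot = str(Seq(mutant_cds_sequence(v, gene, genome)).translate())
        if new_prot == old_prot:
            return "SYNONYMOUS", None
        if "*" in new_prot[:-1] and "*" not in old_prot[:-1]:
            return "NONSENSE", None
        if old_prot.endswith("*") and not new_prot.endswith("*"):
            return "STOP_LOSS", None
        return "MISSENSE", None

    # indel: net length change of the CDS-overlapping portion decides frame
    if len(v.ref) > len(v.alt):  # deletion (anchored)
        deleted = range(v.pos + len(v.alt), v.pos + len(v.ref))
        net = -sum(1 for p in deleted if p in pos_index)
    else:  # insertion at anchor; counts only if the anchor sits in the CDS
        net = (len(v.alt) - len(v.ref)) if v.pos in pos_index else 0
    if net == 0:
        return "INFRAME_INDEL", None
    return ("FRAMESHIFT", None) if net % 3 != 0 else ("INFRAME_INDEL", None)


def annotate_variant(
    v: VariantRecord, idx: RegionIndex, genome: GenomeSequence
) -> list[ConsequenceCall]:
    """All consequence calls of a variant, one per overlapping gene.

    Per gene, only the highest-precedence overlapping region is
    reported (CODING > SPLICE > UTR > INTRON > PROMOTER); a variant
    overlapping no gene region yields a single INTERGENIC call.
    Multi-gene overlaps are assigned independently per gene, so a
    variant may be CODING for one gene and PROMOTER for another.
    """
    lo, hi = v.ref_span()
    hits = idx.query(v.contig, lo, hi)
    per_gene: dict[str, tuple[GeneModel, str]] = {}
    for gene, kind in hits:
        prev = per_gene.get(gene.transcript_id)
        if prev is None or _PRECEDENCE[kind] < _PRECEDENCE[prev[1]]:
            per_gene[gene.transcript_id] = (gene, kind)
    if not per_gene:
        return [
            ConsequenceCall(variant=v, gene_id=None, transcript_id=None,
                            region="INTERGENIC")
        ]
    calls = []
    for tid in sorted(per_gene):
        gene, kind = per_gene[tid]
        region = _KIND_TO_REGION[kind]
        effect = aa = None
        if region == "CODING":
            effect, aa = coding_effect(v, gene, genome)
            if not (v.is_snv and effect in ("SYNONYMOUS", "MISSENSE", "NONSENSE", "STOP_LOSS")):
                aa = None
        calls.append(
            ConsequenceCall(
                variant=v, gene_id=gene.gene_id, transcript_id=tid,
                region=region, coding_effect=effect, aa_change=aa,
            )
        )
    return calls


def exclude_synonymous(calls: list[ConsequenceCall]) -> list[ConsequenceCall]:
    """Drop synonymous coding calls; everything else is retained."""
    return [c for c in calls if c.coding_effect != "SYNONYMOUS"]


def annotate_strain(
    cs: CallSet, idx: RegionIndex, genome: GenomeSequence,
    drop_synonymous: bool = True,
) -> AnnotatedStrain:
    """Annotate every record of a strain's (post-subtraction) call set
    and apply the synonymous-coding exclusion."""
    calls: list[ConsequenceCall] = []
    for r in cs.records:
        calls.extend(annotate_variant(r, idx, genome))
    if drop_synonymous:
        calls = exclude_synonymous(calls)
    return AnnotatedStrain(strain=cs.strain, calls=calls)


def calls_to_rows(strains: list[AnnotatedStrain]) -> list[dict]:
    """Flatten annotated strains to TSV-ready row dicts."""
    rows = []
    for s in strains:
        for c in s.calls:
            v = c.variant
            rows.append(
                {
                    "strain": s.strain, "contig": v.contig, "pos": v.pos,
                    "ref": v.ref, "alt": v.alt, "gene_id": c.gene_id or "",
                    "transcript_id": c.transcript_id or "", "region": c.region,
                    "coding_effect": c.coding_effect or "",
                    "aa_change": c.aa_change or "",
                }
            )
    return rows
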