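"""Per-strain variant call sets: I/O, normalization, filtering,
two-caller consensus, parental subtraction.

The consensus design mirrors a dual-caller resequencing workflow: each
strain is called independently by two callers; after hard filtering,
only variants reported by both (identical normalized contig/pos/ref/alt)
are retained, and variants shared with the unmutagenized parent strain
are subtracted, leaving candidate induced lesions.

Structural records (``svtype`` set) bypass left-alignment and match on
(contig, pos within ``SV_MATCH_WINDOW`` bp, svtype) instead of the exact
allele key, replacing manual inspection of large events with a stated
positional tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import pysam

from mutscreen.genome_model import GenomeSequence

__all__ = [
    "VariantRecord",
    "CallSet",
    "FilterConfig",
    "read_vcf",
    "write_vcf",
    "normalize_variant",
    "normalize_callset",
    "apply_filters",
    "intersect_callsets",
    "subtract_parent",
    "SV_MATCH_WINDOW",
]

#: Positional tolerance (bp) when matching structural records across
#: callers or against the parent.
SV_MATCH_WINDOW = 50

_SVTYPES = {"large_insertion": "INS", "large_deletion": "DEL", "duplication": "DUP"}
_SVTYPES_REV = {v: k for k, v in _SVTYPES.items()}
_NUC = set("ACGTN")


@dataclass(frozen=True)
class VariantRecord:
    """One normalized variant call.

    ``pos`` is 1-based.  ``svtype`` is None for SNVs/small indels, else
    one of {large_insertion, large_deletion, duplication} with the event
    size in ``svlen`` (bp).
    """

    contig: str
    pos: int
    ref: str
    alt: str
    qual: float
    depth: int
    strain: str
    caller: str
    svtype: str | None = None
    svlen: int | None = None

    def __post_init__(self) -> None:
        if self.svtype is None:
            if not self.ref or not self.alt:
                raise ValueError(f"{self}: empty allele")
            if self.ref == self.alt:
                raise ValueError(f"{self}: ref == alt")
            bad = (set(self.ref) | set(self.alt)) - _NUC
            if bad:
                raise ValueError(f"{self}: non-nucleotide characters {bad}")
        elif self.svtype not in _SVTYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return self.svtype is None and len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return self.svtype is None and len(self.ref) != len(self.alt)

    def indel_length(self) -> int:
        """Signed net length change (insertions positive)."""
        if self.svtype == "large_insertion":
            return self.svlen or 0
        if self.svtype == "large_deletion":
            return -(self.svlen or 0)
        return len(self.alt) - len(self.ref)

    def ref_span(self) -> tuple[int, int]:
        """1-based closed genomic interval of reference bases affected."""
        if self.svtype == "large_deletion" or self.svtype == "duplication":
            return (self.pos, self.pos + (self.svlen or 1) - 1)
        return (self.pos, self.pos + len(self.ref) - 1)


@dataclass
class CallSet:
    """All calls of one (strain, caller), unique by allele key, sorted."""

    strain: str
    caller: str
    records: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.contig, r.pos, r.ref, r.alt))
        seen: set[tuple] = set()
        for r in self.records:
            if r.key in seen:
                raise ValueError(f"duplicate record key {r.key} in call set")
            seen.add(r.key)

    def __len__(self) -> int:
        return len(self.records)

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {r.key for r in self.records if r.svtype is None}

    def sv_records(self) -> list[VariantRecord]:
        return [r for r in self.records if r.svtype is not None]


@dataclass
class FilterConfig:
    """Hard-filter thresholds applied per record before consensus.

    The published analysis applied unstated "fixed threshold filters";
    these defaults (QUAL >= 30, DP >= 10) are conventional hard cutoffs
    and are fully exposed so a reanalysis can state its thresholds.
    ``max_missing_fraction`` bounds the fraction of strains allowed to
    lack a genotype at a retained site in cohort-level filtering.
    """

    min_qual: float = 30.0
    min_depth: int = 10
    max_missing_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_qual < 0 or self.min_depth < 0 or self.max_missing_fraction < 0:
            raise ValueError("filter thresholds must be >= 0")


def read_vcf(path: str | Path, strain: str, caller: str) -> CallSet:
    """Read a VCF 4.x file into a CallSet.

    Multi-allelic sites are decomposed into one record per ALT allele.
    For multi-sample files the column named ``strain`` is used; an
    unknown name raises an error listing the available samples.  Missing
    per-sample DP yields depth 0.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        sample = None
        if samples:
            if len(samples) == 1:
                sample = samples[0]
            elif strain in samples:
                sample = strain
            else:
                raise ValueError(
                    f"strain {strain!r} not among VCF samples {samples}"
                )
        for rec in vf:
            qual = float(rec.qual) if rec.qual is not None else 0.0
            depth = 0
            if sample is not None:
                dp = rec.samples[sample].get("DP")
                if dp is not None:
                    depth = int(dp)
            if depth == 0 and "DP" in rec.info:
                depth = int(rec.info["DP"])
            # membership test first: pysam raises on .get of a key the
            # header does not declare
            svtype = rec.info["SVTYPE"] if "SVTYPE" in rec.info else None
            svlen = rec.info["SVLEN"] if "SVLEN" in rec.info else None
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            for alt in rec.alts or ():
                if svtype is not None:
                    records.append(
                        VariantRecord(
                            contig=rec.contig, pos=rec.pos, ref=rec.ref or "N",
                            alt=alt, qual=qual, depth=depth, strain=strain,
                            caller=caller,
                            svtype=_SVTYPES_REV.get(str(svtype), "large_insertion"),
                            svlen=abs(int(svlen)) if svlen is not None else None,
                        )
                    )
                else:
                    records.append(
                        VariantRecord(
                            contig=rec.contig, pos=rec.pos, ref=rec.ref,
                            alt=alt, qual=qual, depth=depth, strain=strain,
                            caller=caller,
                        )
                    )
    return CallSet(strain=strain, caller=caller, records=records)


def write_vcf(
    cs: CallSet, path: str | Path, genome: GenomeSequence | None = None
) -> None:
    """Write a CallSet as a sorted single-sample VCF 4.2 file.

    Contig header lengths come from ``genome`` when provided, otherwise
    from the maximum coordinate seen.  Structural records carry
    INFO/SVTYPE and SVLEN.  ``read_vcf(write_vcf(cs))`` is the identity
    on records.
    """
    header = pysam.VariantHeader()
    contigs: dict[str, int] = {}
    if genome is not None:
        contigs = {c: genome.length(c) for c in genome.contigs}
    for r in cs.records:
        need = r.pos + max(len(r.ref), (r.svlen or 0)) + 1
        if r.contig not in contigs or (genome is None and contigs[r.contig] < need):
            contigs[r.contig] = max(contigs.get(r.contig, 0), need)
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("SVTYPE", 1, "String", "Structural variant type")
    header.info.add("SVLEN", 1, "Integer", "Structural variant length (bp)")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.add_sample(cs.strain)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in cs.records:
            rec = out.new_record(
                contig=r.contig, start=r.pos - 1, alleles=(r.ref, r.alt),
                qual=r.qual,
            )
            rec.stop = r.pos - 1 + len(r.ref)
            if r.svtype is not None:
                rec.info["SVTYPE"] = _SVTYPES[r.svtype]
                if r.svlen is not None:
                    rec.info["SVLEN"] = r.svlen
            rec.samples[cs.strain]["GT"] = (1,)
            rec.samples[cs.strain]["DP"] = r.depth
            out.write(rec)


def normalize_variant(v: VariantRecord, genome: GenomeSequence) -> VariantRecord:
    """Left-align and trim a variant to its minimal representation.

    Shared leading/trailing bases are removed (keeping one anchor base
    for indels, per VCF convention) and indels are shifted left as far
    as the reference allows.  SNVs pass through unchanged; structural
    records bypass normalization entirely.  A REF allele that does not
    match the genome raises an error naming the position.
    """
    if v.svtype is not None:
        return v
    seq = genome.contigs[v.contig]
    if genome.fetch(v.contig, v.pos, v.pos + len(v.ref) - 1) != v.ref:
        raise ValueError(
            f"REF mismatch at {v.contig}:{v.pos}: VCF says {v.ref!r}, "
            f"genome has {genome.fetch(v.contig, v.pos, v.pos + len(v.ref) - 1)!r}"
        )
    pos, ref, alt = v.pos, v.ref, v.alt
    changed = True
    while changed:
        changed = False
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        if not ref or not alt:
            if pos == 1:
                break
            pad = seq[pos - 2]
            ref, alt, pos = pad + ref, pad + alt, pos - 1
            changed = True
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    if (pos, ref, alt) == (v.pos, v.ref, v.alt):
        return v
    return replace(v, pos=pos, ref=ref, alt=alt)


def normalize_callset(cs: CallSet, genome: GenomeSequence) -> CallSet:
    """Normalize every record; representational duplicates collapse."""
    seen: dict[tuple, VariantRecord] = {}
    for r in cs.records:
        n = normalize_variant(r, genome)
        k = n.key if n.svtype is None else (n.contig, n.pos, n.svtype, id(n))
        seen.setdefault(k, n)
    return CallSet(strain=cs.strain, caller=cs.caller, records=list(seen.values()))


def apply_filters(cs: CallSet, cfg: FilterConfig) -> CallSet:
    """Retain records with qual >= min_qual and depth >= min_depth."""
    kept = [
        r for r in cs.records
        if r.qual >= cfg.min_qual and r.depth >= cfg.min_depth
    ]
    return CallSet(strain=cs.strain, caller=cs.caller, records=kept)


def _match_sv(a: VariantRecord, bs: list[VariantRecord]) -> VariantRecord | None:
    for b in bs:
        if (
            b.contig == a.contig
            and b.svtype == a.svtype
            and abs(b.pos - a.pos) <= SV_MATCH_WINDOW
        ):
            return b
    return None


def intersect_callsets(a: CallSet, b: CallSet) -> CallSet:
    """Two-caller consensus: records called by both callers.

    Small variants match on exact normalized (contig, pos, ref, alt);
    structural records match on (contig, pos +/- 50 bp, svtype).  QUAL
    and DP of a consensus record are the minima across the two callers,
    and the caller label becomes ``consensus``.
    """
    if a.caller == b.caller:
        raise ValueError(f"cannot intersect two call sets from caller {a.caller!r}")
    if a.strain != b.strain:
        raise ValueError(f"strain mismatch: {a.strain!r} vs {b.strain!r}")
    b_by_key = {r.key: r for r in b.records if r.svtype is None}
    b_svs = b.sv_records()
    out: list[VariantRecord] = []
    for r in a.records:
        mate = (
            b_by_key.get(r.key) if r.svtype is None else _match_sv(r, b_svs)
        )
        if mate is None:
            continue
        out.append(
            replace(
                r,
                caller="consensus",
                qual=min(r.qual, mate.qual),
                depth=min(r.depth, mate.depth),
            )
        )
    return CallSet(strain=a.strain, caller="consensus", records=out)


def subtract_parent(mutant: CallSet, parent: CallSet) -> CallSet:
    """Remove variants shared with the parent strain.

    Matching rules are the same as for consensus intersection: exact
    allele key for small variants, positional window for structural
    records.  What remains are candidate induced lesions.
    """
    parent_keys = parent.keys()
    parent_svs = parent.sv_records()
    kept = [
        r for r in mutant.records
        if (r.key not in parent_keys if r.svtype is None
            else _match_sv(r, parent_svs) is None)
    ]
    return CallSet(strain=mutant.strain, caller=mutant.caller, records=kept)


def warn_heterozygous(genotypes: dict[str, tuple]) -> None:
    """Flag heterozygous calls in this haploid organism (likely mapping
    artifacts); they are retained, not dropped."""
    for strain, gt in genotypes.items():
        alleles = set(gt)
        if len(alleles - {None}) > 1:
            warnings.warn(
                f"heterozygous genotype {gt} for haploid strain {strain}; "
                "possible mapping artifact",
                stacklevel=2,
            )
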