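"""End-to-end screen analysis orchestration.

Stages: read -> normalize -> hard-filter -> two-caller consensus ->
parent subtraction -> region/consequence annotation -> synonymous
exclusion -> phenotype classification -> recurrence ranking -> report.
Every stage appends per-strain record counts to a ledger so a run can
be audited the way a resequencing analysis reports its variant counts
(caller totals, post-filter, consensus, post-subtraction).

Parent subtraction defaults to the *union* of both callers' raw parent
calls rather than the parent's filtered consensus: any variant either
caller sees in the parent is treated as background.  This is
deliberately permissive — a parental variant missed by one caller must
not resurface as a recurrent "lesion" across every mutant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from mutscreen.consequence import AnnotatedStrain, annotate_strain, calls_to_rows
from mutscreen.genome_model import (
    AnnotationConfig,
    GeneModel,
    GenomeSequence,
    build_region_index,
    read_fasta,
    read_gff,
)
from mutscreen.phenotyping import (
    AssayMeasurement,
    ClassifierThresholds,
    StrainPhenotype,
    phenotype_strains,
    read_assay_table,
    write_phenotype_table,
)
from mutscreen.prioritization import (
    CandidateReport,
    RecurrenceMatrix,
    build_matrix,
    build_report,
    render_report,
)
from mutscreen.variant_core import (
    CallSet,
    FilterConfig,
    VariantRecord,
    apply_filters,
    intersect_callsets,
    normalize_callset,
    read_vcf,
    subtract_parent,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_screen"]


@dataclass
class PipelineConfig:
    """All inputs and knobs of a file-based pipeline run."""

    genome: str | Path
    gff: str | Path
    calls_a: str | Path
    calls_b: str | Path
    assays: str | Path
    parent: str
    out: str | Path
    filters: FilterConfig = field(default_factory=FilterConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    include_ambiguous: bool = False
    coding_only: bool = False
    parent_subtraction: str = "union"  # or "consensus"

    def __post_init__(self) -> None:
        if self.parent_subtraction not in ("union", "consensus"):
            raise ValueError("parent_subtraction must be 'union' or 'consensus'")


@dataclass
class PipelineResult:
    """Everything a run produced, for inspection or serialization."""

    report: CandidateReport
    matrix: RecurrenceMatrix
    phenotypes: list[StrainPhenotype]
    annotated: list[AnnotatedStrain]
    consensus: dict[str, CallSet]
    subtracted: dict[str, CallSet]
    ledger: pd.DataFrame


def _union_callset(a: CallSet, b: CallSet) -> CallSet:
    seen: dict[tuple, VariantRecord] = {}
    sv: list[VariantRecord] = []
    for r in list(a.records) + list(b.records):
        if r.svtype is None:
            seen.setdefault(r.key, r)
        else:
            sv.append(r)
    # SVs: keep one representative per (contig, svtype) cluster key
    sv_seen: dict[tuple, VariantRecord] = {}
    for r in sv:
        sv_seen.setdefault((r.contig, r.pos, r.svtype), r)
    records = list(seen.values()) + list(sv_seen.values())
    return CallSet(strain=a.strain, caller="union", records=records)


def run_screen(
    genome: GenomeSequence,
    genes: list[GeneModel],
    callsets: dict[str, dict[str, CallSet]],
    measurements: list[AssayMeasurement],
    parent: str,
    filters: FilterConfig | None = None,
    annotation: AnnotationConfig | None = None,
    thresholds: ClassifierThresholds | None = None,
    include_ambiguous: bool = False,
    coding_only: bool = False,
    parent_subtraction: str = "union",
) -> PipelineResult:
    """Run the full analysis on in-memory call sets.

    ``callsets`` maps strain -> {"callerA": CallSet, "callerB": CallSet}
    and must include the parent strain.  Returns the candidate report
    plus all intermediates and the per-stage count ledger.
    """
    filters = filters or FilterConfig()
    annotation = annotation or AnnotationConfig()
    thresholds = thresholds or ClassifierThresholds()
    if parent not in callsets:
        raise ValueError(f"parent strain {parent!r} missing from call sets")

    ledger_rows: list[dict] = []

    def log(stage: str, strain: str, count: int) -> None:
        ledger_rows.append({"stage": stage, "strain": strain, "count": count})

    normalized: dict[str, dict[str, CallSet]] = {}
    for strain, by_caller in sorted(callsets.items()):
        normalized[strain] = {}
        for caller, cs in sorted(by_caller.items()):
            n = normalize_callset(cs, genome)
            normalized[strain][caller] = n
            log(f"{caller}_total", strain, len(n))

    filtered: dict[str, dict[str, CallSet]] = {}
    for strain, by_caller in normalized.items():
        filtered[strain] = {}
        for caller, cs in by_caller.items():
            f = apply_filters(cs, filters)
            filtered[strain][caller] = f
            log(f"{caller}_post_filter", strain, len(f))

    callers = sorted(next(iter(normalized.values())))
    if len(callers) != 2:
        raise ValueError(f"expected exactly two callers per strain, got {callers}")

    consensus: dict[str, CallSet] = {}
    for strain, by_caller in filtered.items():
        cons = intersect_callsets(by_caller[callers[0]], by_caller[callers[1]])
        consensus[strain] = cons
        log("consensus", strain, len(cons))
    pooled = len({k for s, cs in consensus.items() if s != parent for k in cs.keys()})
    log("consensus_pooled_unique", "ALL", pooled)

    if parent_subtraction == "union":
        parent_set = _union_callset(
            normalized[parent][callers[0]], normalized[parent][callers[1]]
        )
    else:
        parent_set = consensus[parent]

    subtracted: dict[str, CallSet] = {}
    for strain, cs in consensus.items():
        if strain == parent:
            continue
        sub = subtract_parent(cs, parent_set)
        subtracted[strain] = sub
        log("post_parent_subtraction", strain, len(sub))

    idx = build_region_index(genes, annotation, genome=genome)
    annotated: list[AnnotatedStrain] = []
    for strain, cs in sorted(subtracted.items()):
        ann = annotate_strain(cs, idx, genome, drop_synonymous=True)
        annotated.append(ann)
        log("post_synonymous_exclusion", strain, len(ann))

    phenotypes = phenotype_strains(measurements, parent=parent, thresholds=thresholds)
    matrix = build_matrix(annotated, phenotypes, coding_only=coding_only)
    categories: tuple[str, ...] = ("HET", "BOTH", "NAT")
    if include_ambiguous:
        categories = categories + ("AMBIGUOUS",)
    report = build_report(matrix, categories=categories)

    return PipelineResult(
        report=report, matrix=matrix, phenotypes=phenotypes,
        annotated=annotated, consensus=consensus, subtracted=subtracted,
        ledger=pd.DataFrame(ledger_rows, columns=["stage", "strain", "count"]),
    )


def _read_call_dir(path: Path, caller: str) -> dict[str, CallSet]:
    out = {}
    for vcf in sorted(path.glob("*.vcf")):
        strain = vcf.stem
        out[strain] = read_vcf(vcf, strain=strain, caller=caller)
    if not out:
        raise ValueError(f"no .vcf files found in {path}")
    return out


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """File-based entry point: read all inputs, run, write all outputs.

    Outputs under ``cfg.out``: candidates.tsv / candidates.md (ranked
    report), phenotypes.tsv, annotated.tsv, ledger.tsv.
    """
    genome = read_fasta(cfg.genome)
    genes = read_gff(cfg.gff, genome)
    a = _read_call_dir(Path(cfg.calls_a), "callerA")
    b = _read_call_dir(Path(cfg.calls_b), "callerB")
    if set(a) != set(b):
        raise ValueError(
            f"caller directories disagree on strains: "
            f"{sorted(set(a) ^ set(b))}"
        )
    callsets = {s: {"callerA": a[s], "callerB": b[s]} for s in a}
    measurements = read_assay_table(cfg.assays)
    # strain names in assay tables may contain spaces; VCF files use _
    rename = {m.strain.replace(" ", "_"): m.strain for m in measurements}
    callsets = {rename.get(s, s): cs for s, cs in callsets.items()}
    for strain, by_caller in callsets.items():
        for caller, cs in by_caller.items():
            by_caller[caller] = CallSet(
                strain=strain, caller=caller,
                records=[
                    r if r.strain == strain else replace(r, strain=strain)
                    for r in cs.records
                ],
            )

    result = run_screen(
        genome, genes, callsets, measurements, parent=cfg.parent,
        filters=cfg.filters, annotation=cfg.annotation,
        thresholds=cfg.thresholds, include_ambiguous=cfg.include_ambiguous,
        coding_only=cfg.coding_only, parent_subtraction=cfg.parent_subtraction,
    )

    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    render_report(result.report, out / "candidates.tsv", format="tsv")
    render_report(result.report, out / "candidates.md", format="markdown")
    write_phenotype_table(result.phenotypes, out / "phenotypes.tsv")
    pd.DataFrame(calls_to_rows(result.annotated)).to_csv(
        out / "annotated.tsv", sep="\t", index=False
    )
    result.ledger.to_csv(out / "ledger.tsv", sep="\t", index=False)
    return result
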