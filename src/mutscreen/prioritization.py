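"""Phenotype-stratified gene recurrence ranking.

Candidate causal loci of a forward-genetics screen are prioritized by
recurrence: a gene independently mutated in several strains of the same
phenotype category is a stronger candidate than one hit once.  The
central object is the gene x strain incidence matrix of retained
(non-synonymous or regulatory) mutations; ranking counts distinct
mutated strains per gene within a category, and loci hit in two or more
categories are reported separately as shared candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from mutscreen.consequence import AnnotatedStrain, ConsequenceCall
from mutscreen.phenotyping import StrainPhenotype

__all__ = [
    "RecurrenceMatrix",
    "CandidateRow",
    "CandidateReport",
    "build_matrix",
    "rank_candidates",
    "shared_loci",
    "render_report",
]

#: Categories included in stratified ranking by default.
RANKED_CATEGORIES = ("HET", "BOTH", "NAT")


@dataclass
class RecurrenceMatrix:
    """Gene x strain incidence of retained mutations.

    ``cells[(transcript_id, strain)]`` holds that strain's consequence
    calls in that gene (absent key = no hit); ``categories`` maps each
    strain to exactly one phenotype category.
    """

    genes: list[str]
    strains: list[str]
    categories: dict[str, str]
    cells: dict[tuple[str, str], list[ConsequenceCall]] = field(default_factory=dict)

    def strains_hit(self, gene: str, category: str | None = None) -> list[str]:
        """Strains with >= 1 call in ``gene`` (optionally restricted to
        one category), in stable sorted order."""
        out = [
            s for s in self.strains
            if (gene, s) in self.cells
            and (category is None or self.categories[s] == category)
        ]
        return sorted(out)

    def category_strains(self, category: str) -> list[str]:
        return sorted(s for s in self.strains if self.categories[s] == category)


@dataclass
class CandidateRow:
    """One ranked gene within a category."""

    transcript_id: str
    n_strains_hit: int
    effects: str
    strains: list[str]


@dataclass
class CandidateReport:
    """Ranked candidates per category plus cross-category shared loci."""

    sections: dict[str, list[CandidateRow]] = field(default_factory=dict)
    shared: list[tuple[str, list[str], dict[str, list[str]]]] = field(default_factory=list)


def build_matrix(
    annotated: list[AnnotatedStrain],
    phenotypes: list[StrainPhenotype],
    coding_only: bool = False,
) -> RecurrenceMatrix:
    """Populate the incidence matrix from annotated strains.

    Every retained call with a gene assignment (region != INTERGENIC)
    contributes; genes never hit are absent.  With ``coding_only``,
    only CODING calls count.  A strain with calls but no phenotype is
    an error.
    """
    cat = {p.strain: p.category for p in phenotypes}
    cells: dict[tuple[str, str], list[ConsequenceCall]] = {}
    strains = []
    for s in annotated:
        if s.strain not in cat:
            raise ValueError(f"strain {s.strain!r} has calls but no phenotype")
        strains.append(s.strain)
        for c in s.calls:
            if c.transcript_id is None or c.region == "INTERGENIC":
                continue
            if coding_only and c.region != "CODING":
                continue
            cells.setdefault((c.transcript_id, s.strain), []).append(c)
    genes = sorted({g for g, _ in cells})
    return RecurrenceMatrix(
        genes=genes, strains=strains,
        categories={s: cat[s] for s in strains}, cells=cells,
    )


def _effect_summary(calls: list[ConsequenceCall]) -> str:
    labels = sorted(
        {c.coding_effect if c.region == "CODING" else c.region for c in calls}
    )
    return ",".join(labels)


def rank_candidates(m: RecurrenceMatrix, category: str) -> list[CandidateRow]:
    """Rank genes by the number of distinct ``category`` strains hit.

    Two mutations in one gene in one strain count once.  Ties break
    lexicographically by transcript id; the effect summary aggregates
    the coding-effect / region labels seen across the category's hits.
    """
    members = m.category_strains(category)
    if not members:
        raise ValueError(f"no strains in category {category!r}")
    rows = []
    for gene in m.genes:
        hit = m.strains_hit(gene, category)
        if not hit:
            continue
        calls = [c for s in hit for c in m.cells[(gene, s)]]
        rows.append(
            CandidateRow(
                transcript_id=gene, n_strains_hit=len(hit),
                effects=_effect_summary(calls), strains=hit,
            )
        )
    rows.sort(key=lambda r: (-r.n_strains_hit, r.transcript_id))
    return rows


def shared_loci(
    m: RecurrenceMatrix, categories: tuple[str, ...] = RANKED_CATEGORIES
) -> list[tuple[str, list[str], dict[str, list[str]]]]:
    """Genes hit in >= 2 distinct categories: (transcript_id,
    categories, per-category strain lists)."""
    out = []
    for gene in m.genes:
        per_cat = {
            c: m.strains_hit(gene, c)
            for c in categories
            if m.strains_hit(gene, c)
        }
        if len(per_cat) >= 2:
            out.append((gene, sorted(per_cat), per_cat))
    return out


def build_report(
    m: RecurrenceMatrix,
    categories: tuple[str, ...] = RANKED_CATEGORIES,
) -> CandidateReport:
    """Rank every category with members and collect shared loci."""
    report = CandidateReport()
    for c in categories:
        if m.category_strains(c):
            report.sections[c] = rank_candidates(m, c)
    report.shared = shared_loci(m, categories)
    return report


def render_report(
    report: CandidateReport, path: str | Path, format: str = "tsv"
) -> None:
    """Write the candidate report; byte-identical for identical input.

    TSV columns: category, rank, transcript_id, n_strains_hit, strains,
    effects; shared loci appear under the pseudo-category SHARED.
    Markdown renders the same content as tables.
    """
    if format not in ("tsv", "markdown"):
        raise ValueError(f"unknown report format {format!r}")
    lines: list[str] = []
    if format == "tsv":
        lines.append("category\trank\ttranscript_id\tn_strains_hit\tstrains\teffects")
        for cat in sorted(report.sections):
            for rank, row in enumerate(report.sections[cat], 1):
                lines.append(
                    f"{cat}\t{rank}\t{row.transcript_id}\t{row.n_strains_hit}\t"
                    f"{','.join(row.strains)}\t{row.effects}"
                )
        for gene, cats, per_cat in report.shared:
            strains = ";".join(
                f"{c}:{','.join(per_cat[c])}" for c in cats
            )
            lines.append(f"SHARED\t.\t{gene}\t.\t{strains}\t{'+'.join(cats)}")
    else:
        lines.append("# Candidate loci by phenotype category")
        for cat in sorted(report.sections):
            lines.append(f"\n## {cat}\n")
            lines.append("| rank | transcript | strains hit | strains | effects |")
            lines.append("|---|---|---|---|---|")
            for rank, row in enumerate(report.sections[cat], 1):
                lines.append(
                    f"| {rank} | {row.transcript_id} | {row.n_strains_hit} | "
                    f"{', '.join(row.strains)} | {row.effects} |"
                )
        lines.append("\n## Shared across categories\n")
        lines.append("| transcript | categories | strains |")
        lines.append("|---|---|---|")
        for gene, cats, per_cat in report.shared:
            strains = "; ".join(f"{c}: {', '.join(per_cat[c])}" for c in cats)
            lines.append(f"| {gene} | {'+'.join(cats)} | {strains} |")
    Path(path).write_text("\n".join(lines) + "\n")
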