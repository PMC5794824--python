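"""Enzyme-assay phenotyping of screen isolates.

A strain secreting an ionic-liquid (IL)-tolerant heterologous
β-glucosidase can be distinguished from one over-producing the IL-
sensitive native enzyme by assaying activity with and without 10% v/v
IL: the percent reduction of activity under IL reflects the native
fraction of the secreted enzyme pool.  Strains whose biomass-normalized
activity exceeds the hyper-producer gate are classified by that
reduction — < 10% heterologous (HET), > 75% native (NAT), 30-60% both —
with the undefined gaps labeled AMBIGUOUS rather than forced into a
bin.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "AssayMeasurement",
    "ClassifierThresholds",
    "StrainPhenotype",
    "CATEGORIES",
    "normalize_measurement",
    "fold_change",
    "il_reduction",
    "classify_strain",
    "tally_categories",
    "phenotype_strains",
    "read_assay_table",
    "write_phenotype_table",
]

CATEGORIES = ("HET", "NAT", "BOTH", "AMBIGUOUS", "NOT_HYPER")

ASSAY_COLUMNS = [
    "strain", "replicate", "total_protein", "bg_activity_noIL",
    "bg_activity_IL", "biomass",
]


@dataclass(frozen=True)
class AssayMeasurement:
    """One replicate culture's secreted-enzyme assay readings.

    total_protein: µg/µL (Bradford); bg_activity_noIL / bg_activity_IL:
    β-glucosidase activity in mM-equivalents without / with 10% v/v
    ionic liquid; biomass: g dry weight of the culture.
    """

    strain: str
    replicate: int
    total_protein: float
    bg_activity_noIL: float
    bg_activity_IL: float
    biomass: float

    def __post_init__(self) -> None:
        if self.biomass <= 0:
            raise ValueError(
                f"strain {self.strain} replicate {self.replicate}: "
                f"biomass must be > 0, got {self.biomass}"
            )
        if min(self.total_protein, self.bg_activity_noIL, self.bg_activity_IL) < 0:
            raise ValueError(
                f"strain {self.strain} replicate {self.replicate}: "
                "negative assay reading"
            )


@dataclass
class ClassifierThresholds:
    """IL-reduction bands (percent) and hyper-producer gate.

    het_max_reduction: below this the strain is producing primarily the
    heterologous enzyme.  nat_min_reduction: above this, primarily the
    native enzyme.  [both_min, both_max]: producing both.  Reductions in
    the uncovered gaps (10-30, 60-75 by default) are AMBIGUOUS.
    min_fold_activity: biomass-normalized activity fold over the parent
    required to call a hyper-producer at all (default 2.0, the weakest
    accepted screen isolate).
    """

    het_max_reduction: float = 10.0
    nat_min_reduction: float = 75.0
    both_min: float = 30.0
    both_max: float = 60.0
    min_fold_activity: float = 2.0

    def __post_init__(self) -> None:
        if not (
            self.het_max_reduction < self.both_min <= self.both_max < self.nat_min_reduction
        ):
            raise ValueError(
                "thresholds must satisfy het_max < both_min <= both_max < nat_min"
            )


@dataclass
class StrainPhenotype:
    """Fold-change metrics and category for one strain."""

    strain: str
    fold_protein: float
    fold_activity: float
    il_reduction: float
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def normalize_measurement(m: AssayMeasurement) -> tuple[float, float]:
    """Biomass-normalize one replicate: (protein per g, activity per g).

    Replicates are averaged downstream, not here.
    """
    return (m.total_protein / m.biomass, m.bg_activity_noIL / m.biomass)


def fold_change(strain_mean: float, parent_mean: float) -> float:
    """Ratio of a strain's mean to the parent's mean (parent -> 1.0)."""
    if parent_mean <= 0:
        raise ValueError(f"parent mean must be > 0, got {parent_mean}")
    return strain_mean / parent_mean


def il_reduction(noIL: float, withIL: float, strain: str | None = None) -> float:
    """Percent reduction of activity under ionic liquid:
    100 * (noIL - withIL) / noIL, floored at 0.

    Apparent activation under IL (withIL > noIL) is reported as 0%
    reduction with a warning rather than a negative percentage.
    """
    if noIL <= 0:
        raise ValueError(
            f"activity without IL must be > 0"
            + (f" (strain {strain})" if strain else "")
        )
    pct = 100.0 * (noIL - withIL) / noIL
    if pct < 0:
        warnings.warn(
            f"activity increased under ionic liquid"
            + (f" for strain {strain}" if strain else "")
            + "; reporting 0% reduction",
            stacklevel=2,
        )
        return 0.0
    return pct


def classify_strain(
    fold_activity: float, reduction: float, t: ClassifierThresholds | None = None
) -> str:
    """Assign HET / NAT / BOTH / AMBIGUOUS / NOT_HYPER.

    NOT_HYPER when the activity fold over the parent is below the gate;
    otherwise the IL-reduction bands decide, with the uncovered gaps
    mapping to AMBIGUOUS.  Every (fold, reduction) pair maps to exactly
    one category.
    """
    t = t or ClassifierThresholds()
    if fold_activity < t.min_fold_activity:
        return "NOT_HYPER"
    if reduction < t.het_max_reduction:
        return "HET"
    if reduction > t.nat_min_reduction:
        return "NAT"
    if t.both_min <= reduction <= t.both_max:
        return "BOTH"
    return "AMBIGUOUS"


def tally_categories(phenotypes: list[StrainPhenotype]) -> dict[str, int]:
    """Counts per category, plus the combined ``heterologous_producing``
    tally (HET + BOTH: strains whose secreted activity includes the
    heterologous enzyme)."""
    counts = Counter(p.category for p in phenotypes)
    out = {c: counts.get(c, 0) for c in CATEGORIES}
    out["heterologous_producing"] = out["HET"] + out["BOTH"]
    return out


def phenotype_strains(
    measurements: list[AssayMeasurement],
    parent: str,
    thresholds: ClassifierThresholds | None = None,
) -> list[StrainPhenotype]:
    """Full phenotyping of a screen: biomass-normalize, average
    replicates, compute fold changes vs. the parent strain and the IL
    reduction, and classify every non-parent strain."""
    thresholds = thresholds or ClassifierThresholds()
    by_strain: dict[str, list[AssayMeasurement]] = {}
    for m in measurements:
        by_strain.setdefault(m.strain, []).append(m)
    if parent not in by_strain:
        raise ValueError(f"parent strain {parent!r} has no assay measurements")

    def strain_means(ms: list[AssayMeasurement]) -> tuple[float, float, float]:
        prot = sum(m.total_protein / m.biomass for m in ms) / len(ms)
        act = sum(m.bg_activity_noIL / m.biomass for m in ms) / len(ms)
        act_il = sum(m.bg_activity_IL / m.biomass for m in ms) / len(ms)
        return prot, act, act_il

    p_prot, p_act, _ = strain_means(by_strain[parent])
    out = []
    for strain in sorted(by_strain):
        if strain == parent:
            continue
        prot, act, act_il = strain_means(by_strain[strain])
        fp = fold_change(prot, p_prot)
        fa = fold_change(act, p_act)
        red = il_reduction(act, act_il, strain=strain)
        out.append(
            StrainPhenotype(
                strain=strain, fold_protein=fp, fold_activity=fa,
                il_reduction=red,
                category=classify_strain(fa, red, thresholds),
            )
        )
    return out


def read_assay_table(path: str | Path) -> list[AssayMeasurement]:
    """Read the assay TSV (strain, replicate, total_protein,
    bg_activity_noIL, bg_activity_IL, biomass)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(ASSAY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    return [
        AssayMeasurement(
            strain=str(r.strain), replicate=int(r.replicate),
            total_protein=float(r.total_protein),
            bg_activity_noIL=float(r.bg_activity_noIL),
            bg_activity_IL=float(r.bg_activity_IL),
            biomass=float(r.biomass),
        )
        for r in df.itertuples()
    ]


def write_phenotype_table(phenotypes: list[StrainPhenotype], path: str | Path) -> None:
    """Write phenotypes as TSV (strain, fold_protein, fold_activity,
    il_reduction, category)."""
    df = pd.DataFrame(
        [
            {
                "strain": p.strain,
                "fold_protein": round(p.fold_protein, 4),
                "fold_activity": round(p.fold_activity, 4),
                "il_reduction": round(p.il_reduction, 4),
                "category": p.category,
            }
            for p in phenotypes
        ],
        columns=["strain", "fold_protein", "fold_activity", "il_reduction", "category"],
    )
    df.to_csv(path, sep="\t", index=False)
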