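"""Synthetic forward-genetics screen generator and packaged fixtures.

The generator produces everything the pipeline consumes, from scratch
and deterministically per seed: a random genome with strand-mixed
intron-containing gene models; a parent strain carrying shared
background variants; mutant strains with Poisson-distributed induced
lesions (transition-biased SNVs plus a small indel fraction, a labeled
stand-in for a point mutagen's spectrum) and a planted nonsynonymous
causal lesion per phenotype category; two discordant noisy caller
outputs per strain; and triplicate enzyme-assay tables whose
ionic-liquid sensitivity encodes each strain's true category.

Two fixtures encode published observations for desk checks: the
phenotype table of the 12-mutant cohort (:func:`table2_fixture`) and
the text-described gene x strain mutation incidence
(:func:`fig2_fixture`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from mutscreen.consequence import AnnotatedStrain, ConsequenceCall, coding_effect
from mutscreen.genome_model import GeneModel, GenomeSequence, write_gff
from mutscreen.phenotyping import AssayMeasurement, StrainPhenotype
from mutscreen.variant_core import CallSet, VariantRecord, normalize_variant, write_vcf

__all__ = [
    "ScreenSimConfig",
    "TruthSet",
    "simulate_genome",
    "simulate_screen",
    "emit_caller_callsets",
    "write_screen",
    "table2_fixture",
    "table2_phenotypes",
    "fig2_fixture",
]

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}
_STOPS = ("TAA", "TAG", "TGA")

#: IL-reduction centers (percent) used when constructing true assay
#: means for each planted category.
CATEGORY_REDUCTION_CENTERS = {"HET": 5.0, "BOTH": 45.0, "NAT": 85.0}
#: Uniform ranges for true activity fold over the parent, per category,
#: spanning the spread observed in the published 12-mutant cohort.
CATEGORY_FOLD_RANGES = {"HET": (2.5, 6.0), "BOTH": (20.0, 120.0), "NAT": (5.0, 100.0)}


@dataclass
class ScreenSimConfig:
    """Study conditions of a simulated screen.

    The cohort (6 HET, 4 BOTH, 2 NAT mutants plus the parent) matches
    the published screen.  Lesion counts, caller error rates and assay
    noise are this package's stated stand-ins; see the methods note.
    """

    n_contigs: int = 2
    contig_length: int = 300_000
    n_genes: int = 20
    mean_introns_per_gene: float = 1.0
    n_strains_per_category: dict[str, int] = field(
        default_factory=lambda: {"HET": 6, "BOTH": 4, "NAT": 2}
    )
    lesions_per_strain: float = 8.0
    ti_tv_bias: float = 3.0
    indel_fraction: float = 0.10
    parent_background_variants: int = 40
    causal_genes: dict[str, str] | None = None
    causal_penetrance: float = 1.0
    plant_large_insertion: bool = False
    callerA_fpr: float = 0.05
    callerA_fnr: float = 0.005
    callerB_fpr: float = 0.05
    callerB_fnr: float = 0.005
    assay_noise_sigma: float = 0.1
    replicates: int = 3
    parent_strain: str = "PARENT"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.causal_penetrance <= 1:
            raise ValueError("causal_penetrance must be in [0, 1]")
        for r in (self.callerA_fpr, self.callerA_fnr, self.callerB_fpr, self.callerB_fnr):
            if not 0 <= r < 1:
                raise ValueError("caller error rates must be in [0, 1)")
        if min(self.n_contigs, self.contig_length, self.n_genes) < 0:
            raise ValueError("counts must be >= 0")

    def strain_names(self) -> dict[str, list[str]]:
        return {
            cat: [f"{cat}-{i + 1:02d}" for i in range(n)]
            for cat, n in self.n_strains_per_category.items()
        }


@dataclass
class TruthSet:
    """Ground truth of one simulated screen."""

    parent_strain: str
    parent_variants: list[VariantRecord]
    lesions: dict[str, list[VariantRecord]]
    causal: dict[str, VariantRecord | None]
    categories: dict[str, str]
    causal_genes: dict[str, str]
    measurements: list[AssayMeasurement]
    true_fold_activity: dict[str, float]
    true_il_reduction: dict[str, float]

    def strain_variants(self, strain: str) -> list[VariantRecord]:
        """All variants truly present in a strain (parent background +
        induced lesions), relabeled with the strain id."""
        if strain == self.parent_strain:
            return [replace(v, strain=strain) for v in self.parent_variants]
        return sorted(
            [replace(v, strain=strain) for v in self.parent_variants]
            + self.lesions[strain],
            key=lambda r: (r.contig, r.pos, r.ref, r.alt),
        )


def _rng(seed: int | None, cfg_seed: int, stream: int) -> np.random.Generator:
    base = cfg_seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence(entropy=(base, stream)))


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n sense codons (no internal stops)."""
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(_BASES, size=3))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def simulate_genome(
    cfg: ScreenSimConfig, seed: int | None = None
) -> tuple[GenomeSequence, list[GeneModel]]:
    """Random genome plus non-overlapping gene models on both strands.

    Every CDS starts with ATG, ends with a stop, contains no internal
    stop, and has length divisible by 3.  Genes carry UTRs and a
    Poisson number of introns and are spaced so promoter windows do not
    run off contig ends.  Deterministic per (config, seed).
    """
    rng = _rng(seed, cfg.seed, stream=1)
    contigs = {
        f"ctg{c + 1}": "".join(rng.choice(_BASES, size=cfg.contig_length))
        for c in range(cfg.n_contigs)
    }
    genes: list[GeneModel] = []
    if cfg.n_genes == 0:
        return GenomeSequence(contigs), genes
    per_contig = [
        cfg.n_genes // cfg.n_contigs + (1 if c < cfg.n_genes % cfg.n_contigs else 0)
        for c in range(cfg.n_contigs)
    ]
    margin = 1200  # promoter clearance + spacing between neighbors
    gene_no = 0
    seqs = {k: list(v) for k, v in contigs.items()}
    for c, n_here in enumerate(per_contig):
        contig = f"ctg{c + 1}"
        if n_here == 0:
            continue
        slot = cfg.contig_length // n_here
        for s in range(n_here):
            gene_no += 1
            tid = f"tx{gene_no:03d}"
            strand = "+" if gene_no % 2 else "-"
            u5 = int(rng.integers(30, 81))
            u3 = int(rng.integers(30, 81))
            n_codons = int(rng.integers(60, 181))
            cds_seq = "ATG" + _random_codons(rng, n_codons - 2) + _STOPS[
                int(rng.integers(0, 3))
            ]
            tx_len = u5 + len(cds_seq) + u3
            n_introns = int(rng.poisson(cfg.mean_introns_per_gene))
            intron_lens = [int(rng.integers(40, 81)) for _ in range(n_introns)]
            # intron insertion points strictly inside the CDS
            cuts = sorted(
                int(x) for x in rng.choice(
                    np.arange(u5 + 10, u5 + len(cds_seq) - 10),
                    size=n_introns, replace=False,
                )
            ) if n_introns else []
            span = tx_len + sum(intron_lens)
            if span + margin > slot:
                raise ValueError(
                    f"gene {tid} (span {span} bp) does not fit in a "
                    f"{slot} bp slot; increase contig_length or reduce n_genes"
                )
            start = s * slot + margin // 2 + int(
                rng.integers(0, max(1, slot - span - margin))
            ) + 1
            # walk transcript (5'->3') across genomic positions,
            # skipping introns at the cut points
            dirn = 1 if strand == "+" else -1
            gpos = start if strand == "+" else start + span - 1
            tx_positions: list[int] = []
            cut_iter = list(cuts)
            for t in range(tx_len):
                if cut_iter and t == cut_iter[0]:
                    gpos += dirn * intron_lens[len(cuts) - len(cut_iter)]
                    cut_iter.pop(0)
                tx_positions.append(gpos)
                gpos += dirn
            # write CDS bases into the contig (complemented on -)
            for i, base in enumerate(cds_seq):
                p = tx_positions[u5 + i]
                seqs[contig][p - 1] = (
                    base if strand == "+" else base.translate(_COMP)
                )
            exon_pos = sorted(tx_positions)
            exons = _runs(exon_pos)
            cds_pos = sorted(tx_positions[u5 : u5 + len(cds_seq)])
            cds = _runs(cds_pos)
            genes.append(
                GeneModel(
                    gene_id=f"gene{gene_no:03d}", transcript_id=tid,
                    contig=contig, strand=strand, exons=exons, cds=cds,
                )
            )
    genome = GenomeSequence({k: "".join(v) for k, v in seqs.items()})
    return genome, genes


_COMP = str.maketrans("ACGTN", "TGCAN")


def _runs(positions: list[int]) -> list[tuple[int, int]]:
    """Collapse a sorted position list into closed intervals."""
    out: list[tuple[int, int]] = []
    for p in positions:
        if out and p == out[-1][1] + 1:
            out[-1] = (out[-1][0], p)
        else:
            out.append((p, p))
    return out


def sample_snv(
    rng: np.random.Generator, genome: GenomeSequence, ti_tv_bias: float,
    strain: str = "truth",
) -> VariantRecord:
    """One random SNV with the configured transition:transversion bias.

    P(transition) = r / (r + 1) where r is the bias, so the expected
    count ratio of transitions to transversions equals r.
    """
    contig, pos = _random_position(rng, genome, pad=5)
    ref = genome.contigs[contig][pos - 1]
    if rng.random() < ti_tv_bias / (ti_tv_bias + 1.0):
        alt = _TRANSITION[ref]
    else:
        alt = _TRANSVERSIONS[ref][int(rng.integers(0, 2))]
    return VariantRecord(
        contig=contig, pos=pos, ref=ref, alt=alt, qual=0.0, depth=0,
        strain=strain, caller="truth",
    )


def _random_position(
    rng: np.random.Generator, genome: GenomeSequence, pad: int
) -> tuple[str, int]:
    names = sorted(genome.contigs)
    lengths = np.array([genome.length(n) for n in names], dtype=float)
    contig = names[int(rng.choice(len(names), p=lengths / lengths.sum()))]
    pos = int(rng.integers(2, genome.length(contig) - pad))
    return contig, pos


def _sample_lesion(
    rng: np.random.Generator, genome: GenomeSequence, cfg: ScreenSimConfig,
    strain: str,
) -> VariantRecord:
    if rng.random() < cfg.indel_fraction:
        contig, pos = _random_position(rng, genome, pad=10)
        size = int(rng.integers(1, 4))
        anchor = genome.contigs[contig][pos - 1]
        if rng.random() < 0.5:  # insertion
            ins = "".join(rng.choice(_BASES, size=size))
            v = VariantRecord(
                contig=contig, pos=pos, ref=anchor, alt=anchor + ins,
                qual=0.0, depth=0, strain=strain, caller="truth",
            )
        else:  # deletion
            ref = genome.contigs[contig][pos - 1 : pos + size]
            v = VariantRecord(
                contig=contig, pos=pos, ref=ref, alt=anchor,
                qual=0.0, depth=0, strain=strain, caller="truth",
            )
        return normalize_variant(v, genome)
    return sample_snv(rng, genome, cfg.ti_tv_bias, strain=strain)


def _plant_causal(
    rng: np.random.Generator, genome: GenomeSequence, gene: GeneModel,
    strain: str, large_insertion: bool, used: set[tuple] | None = None,
) -> VariantRecord:
    """A guaranteed nonsynonymous coding lesion in ``gene``, avoiding
    allele keys already present in the strain or parent."""
    used = used or set()
    if large_insertion:
        a, b = gene.cds[0]
        pos = int(rng.integers(a + 3, b))
        return VariantRecord(
            contig=gene.contig, pos=pos,
            ref=genome.contigs[gene.contig][pos - 1], alt="<INS>",
            qual=0.0, depth=0, strain=strain, caller="truth",
            svtype="large_insertion", svlen=9000,
        )
    cds_positions = [p for a, b in gene.cds for p in range(a, b + 1)]
    for _ in range(500):
        pos = int(rng.choice(cds_positions))
        ref = genome.contigs[gene.contig][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        v = VariantRecord(
            contig=gene.contig, pos=pos, ref=ref, alt=alt,
            qual=0.0, depth=0, strain=strain, caller="truth",
        )
        effect, _ = coding_effect(v, gene, genome)
        if effect in ("MISSENSE", "NONSENSE") and v.key not in used:
            return v
    raise RuntimeError(f"could not plant a nonsynonymous lesion in {gene.transcript_id}")


def default_causal_genes(genes: list[GeneModel]) -> dict[str, str]:
    """Deterministic causal-gene assignment: three genes spread across
    the (sorted) model list, one per category."""
    tids = sorted(g.transcript_id for g in genes)
    if len(tids) < 3:
        raise ValueError("need >= 3 genes to assign causal genes per category")
    picks = [tids[len(tids) // 6], tids[len(tids) // 2], tids[(5 * len(tids)) // 6]]
    return {"HET": picks[0], "BOTH": picks[1], "NAT": picks[2]}


def simulate_screen(
    genome: GenomeSequence, genes: list[GeneModel], cfg: ScreenSimConfig,
    seed: int | None = None,
) -> TruthSet:
    """Simulate the mutagenized cohort on a given genome.

    Each mutant receives Poisson(``lesions_per_strain``) background
    lesions plus, with probability ``causal_penetrance``, one
    nonsynonymous lesion in its category's causal gene.  Parent
    background variants are shared by every strain.  True assay means
    are constructed so the ionic-liquid reduction falls in the strain's
    category band.
    """
    rng = _rng(seed, cfg.seed, stream=2)
    gene_by_tid = {g.transcript_id: g for g in genes}
    causal_genes = cfg.causal_genes or default_causal_genes(genes)
    for cat, tid in causal_genes.items():
        if tid not in gene_by_tid:
            raise ValueError(f"causal gene {tid!r} for {cat} not in gene models")

    parent_keys: set[tuple] = set()
    parent_variants: list[VariantRecord] = []
    while len(parent_variants) < cfg.parent_background_variants:
        v = _sample_lesion(rng, genome, cfg, strain=cfg.parent_strain)
        if v.key not in parent_keys:
            parent_keys.add(v.key)
            parent_variants.append(v)
    parent_variants.sort(key=lambda r: (r.contig, r.pos, r.ref, r.alt))

    lesions: dict[str, list[VariantRecord]] = {}
    causal: dict[str, VariantRecord | None] = {}
    categories: dict[str, str] = {}
    measurements: list[AssayMeasurement] = []
    true_fold: dict[str, float] = {}
    true_red: dict[str, float] = {}

    def add_measurements(strain: str, fold_act: float, fold_prot: float, red: float) -> None:
        # parent per-gram means anchoring all folds
        p_act, p_prot = 2.0, 1.0
        for rep in range(1, cfg.replicates + 1):
            biomass = float(rng.uniform(0.8, 1.2))
            # biological (per-culture) noise is shared by all three
            # readings of a replicate; technical (per-reading) noise is
            # much smaller, so the IL ratio is only technically noisy
            shared = float(np.exp(rng.normal(0.0, cfg.assay_noise_sigma)))
            def noisy(x: float) -> float:
                return x * shared * float(
                    np.exp(rng.normal(0.0, cfg.assay_noise_sigma / 6))
                )
            measurements.append(
                AssayMeasurement(
                    strain=strain, replicate=rep,
                    total_protein=noisy(p_prot * fold_prot * biomass),
                    bg_activity_noIL=noisy(p_act * fold_act * biomass),
                    bg_activity_IL=noisy(p_act * fold_act * biomass * (1 - red / 100)),
                    biomass=biomass,
                )
            )

    add_measurements(cfg.parent_strain, 1.0, 1.0, CATEGORY_REDUCTION_CENTERS["HET"])

    large_ins_used = False
    for cat, names in sorted(cfg.strain_names().items()):
        for strain in names:
            categories[strain] = cat
            used = set(parent_keys)
            strain_lesions: list[VariantRecord] = []
            n_bg = int(rng.poisson(cfg.lesions_per_strain))
            while len(strain_lesions) < n_bg:
                v = _sample_lesion(rng, genome, cfg, strain=strain)
                if v.key not in used:
                    used.add(v.key)
                    strain_lesions.append(v)
            causal[strain] = None
            if rng.random() < cfg.causal_penetrance:
                want_sv = cfg.plant_large_insertion and not large_ins_used and cat == "HET"
                cv = _plant_causal(
                    rng, genome, gene_by_tid[causal_genes[cat]], strain,
                    large_insertion=want_sv, used=used,
                )
                if want_sv:
                    large_ins_used = True
                used.add(cv.key)
                strain_lesions.append(cv)
                causal[strain] = cv
            strain_lesions.sort(key=lambda r: (r.contig, r.pos, r.ref, r.alt))
            lesions[strain] = strain_lesions

            lo, hi = CATEGORY_FOLD_RANGES[cat]
            fold_act = float(rng.uniform(lo, hi))
            fold_prot = float(rng.uniform(1.0, 4.5))
            center = CATEGORY_REDUCTION_CENTERS[cat]
            spread = {"HET": (1.5, 1.0, 9.0), "BOTH": (4.0, 32.0, 58.0),
                      "NAT": (3.0, 77.0, 97.0)}[cat]
            red = float(np.clip(rng.normal(center, spread[0]), spread[1], spread[2]))
            true_fold[strain] = fold_act
            true_red[strain] = red
            add_measurements(strain, fold_act, fold_prot, red)

    return TruthSet(
        parent_strain=cfg.parent_strain, parent_variants=parent_variants,
        lesions=lesions, causal=causal, categories=categories,
        causal_genes=causal_genes, measurements=measurements,
        true_fold_activity=true_fold, true_il_reduction=true_red,
    )


def emit_caller_callsets(
    truth: TruthSet, genome: GenomeSequence, cfg: ScreenSimConfig,
    seed: int | None = None,
) -> dict[str, dict[str, CallSet]]:
    """Two noisy caller outputs per strain (parent included).

    Each caller independently misses true variants at its false-negative
    rate and adds caller-private spurious calls at its false-positive
    rate (expected count = fpr x true-call count).  QUAL/DP are drawn
    from separated distributions: true calls always pass the default
    hard filters, spurious calls only sometimes, and their caller-
    private positions make the consensus intersection remove the rest.
    """
    rng = _rng(seed, cfg.seed, stream=3)
    rates = {"callerA": (cfg.callerA_fpr, cfg.callerA_fnr),
             "callerB": (cfg.callerB_fpr, cfg.callerB_fnr)}
    out: dict[str, dict[str, CallSet]] = {}
    strains = [truth.parent_strain] + sorted(truth.lesions)
    for strain in strains:
        true_vars = truth.strain_variants(strain)
        out[strain] = {}
        for caller, (fpr, fnr) in rates.items():
            records: list[VariantRecord] = []
            used: set[tuple] = set()
            for v in true_vars:
                if rng.random() < fnr:
                    continue
                records.append(
                    replace(
                        v, strain=strain, caller=caller,
                        qual=float(rng.uniform(50, 95)),
                        depth=int(rng.integers(15, 45)),
                    )
                )
                used.add(v.key)
            n_spurious = int(rng.poisson(fpr * max(len(true_vars), 1)))
            added = 0
            while added < n_spurious:
                s = sample_snv(rng, genome, ti_tv_bias=1.0, strain=strain)
                if s.key in used:
                    continue
                used.add(s.key)
                records.append(
                    replace(
                        s, caller=caller,
                        qual=float(rng.uniform(15, 70)),
                        depth=int(rng.integers(5, 30)),
                    )
                )
                added += 1
            out[strain][caller] = CallSet(strain=strain, caller=caller, records=records)
    return out


def write_screen(
    genome: GenomeSequence, genes: list[GeneModel], truth: TruthSet,
    callsets: dict[str, dict[str, CallSet]], outdir: str | Path,
) -> dict[str, Path]:
    """Write a simulated screen to disk: FASTA, GFF3, per-strain VCFs
    (one directory per caller), assay TSV and a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for name in sorted(genome.contigs):
            fh.write(f">{name}\n")
            seq = genome.contigs[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    paths["fasta"] = fasta

    gff = outdir / "genes.gff3"
    write_gff(genes, gff)
    paths["gff"] = gff

    for caller in ("callerA", "callerB"):
        d = outdir / caller
        d.mkdir(exist_ok=True)
        for strain, by_caller in callsets.items():
            safe = strain.replace(" ", "_")
            write_vcf(by_caller[caller], d / f"{safe}.vcf", genome=genome)
        paths[caller] = d

    assay = outdir / "assays.tsv"
    pd.DataFrame(
        [
            {
                "strain": m.strain, "replicate": m.replicate,
                "total_protein": round(m.total_protein, 6),
                "bg_activity_noIL": round(m.bg_activity_noIL, 6),
                "bg_activity_IL": round(m.bg_activity_IL, 6),
                "biomass": round(m.biomass, 6),
            }
            for m in truth.measurements
        ]
    ).to_csv(assay, sep="\t", index=False)
    paths["assays"] = assay

    truth_json = outdir / "truth.json"
    truth_json.write_text(
        json.dumps(
            {
                "parent_strain": truth.parent_strain,
                "causal_genes": truth.causal_genes,
                "categories": truth.categories,
                "parent_variants": [list(v.key) for v in truth.parent_variants],
                "lesions": {
                    s: [
                        {"key": list(v.key), "svtype": v.svtype,
                         "causal": truth.causal[s] is not None
                         and v.key == truth.causal[s].key}
                        for v in vs
                    ]
                    for s, vs in truth.lesions.items()
                },
            },
            indent=1,
        )
    )
    paths["truth"] = truth_json
    return paths


# ---------------------------------------------------------------------------
# Packaged fixtures encoding published observations
# ---------------------------------------------------------------------------

#: (strain, fold secreted total protein, fold secreted BG activity,
#: phenotype label) for the parent and the 12 accepted mutants.
_TABLE2_ROWS = [
    ("J03", 1.0, 1.0, "parent"),
    ("J03 1.1", 2.4, 5.2, "Heterologous"),
    ("J03 1.2", 3.7, 63.3, "Both"),
    ("J03 1.6", 2.2, 4.6, "Heterologous"),
    ("J03 1.7", 1.5, 3.0, "Heterologous"),
    ("J03 1.10", 1.0, 2.0, "Heterologous"),
    ("J03 2.8", 3.9, 111.0, "Both"),
    ("J03 4.3", 3.4, 98.0, "Native"),
    ("J03 6.3", 2.4, 5.2, "Native"),
    ("J03 7.2", 2.4, 5.0, "Heterologous"),
    ("J03 7.4", 4.1, 95.8, "Both"),
    ("J03 8.2", 2.4, 4.3, "Heterologous"),
    ("J03 8.3", 3.4, 22.3, "Both"),
]

_LABEL_TO_CATEGORY = {"Heterologous": "HET", "Native": "NAT", "Both": "BOTH"}


def table2_fixture() -> pd.DataFrame:
    """The published cohort phenotype table: 13 rows (parent + 12
    mutants) with fold secreted total protein, fold secreted
    β-glucosidase activity, and the phenotype label."""
    return pd.DataFrame(
        _TABLE2_ROWS,
        columns=["strain", "fold_protein", "fold_activity", "phenotype"],
    )


def table2_phenotypes() -> list[StrainPhenotype]:
    """The 12 mutants as StrainPhenotype objects.

    The published table reports categories, not numeric IL reductions,
    so each strain carries its category band's representative center
    (HET 5%, BOTH 45%, NAT 85%) as a synthetic stand-in value; the
    category field itself is as published.
    """
    out = []
    for strain, fp, fa, label in _TABLE2_ROWS:
        if label == "parent":
            continue
        cat = _LABEL_TO_CATEGORY[label]
        out.append(
            StrainPhenotype(
                strain=strain, fold_protein=fp, fold_activity=fa,
                il_reduction=CATEGORY_REDUCTION_CENTERS[cat], category=cat,
            )
        )
    return out


def _fig2_call(
    strain: str, transcript: str, region: str, effect: str | None,
    pos: int,
) -> ConsequenceCall:
    svtype = None
    svlen = None
    ref, alt = "A", "G"
    if effect == "LARGE_INSERTION":
        svtype, svlen, alt = "large_insertion", 9000, "<INS>"
    if effect == "FRAMESHIFT":
        ref, alt = "AG", "A"
    v = VariantRecord(
        contig="fig2", pos=pos, ref=ref, alt=alt, qual=60.0, depth=30,
        strain=strain, caller="consensus", svtype=svtype, svlen=svlen,
    )
    return ConsequenceCall(
        variant=v, gene_id=transcript, transcript_id=transcript,
        region=region, coding_effect=effect if region == "CODING" else None,
    )


# Incidence cells described in the screen's published text.  Where the
# text gives a set of strains and a set of effects without a one-to-one
# mapping (e.g. "five missense and one insertion of ~9 kb" across five
# strains; "three independent nonsense and one frameshift" across four;
# "coding or promoter" pairs), the assignment of effect to strain below
# is an arbitrary but fixed choice; recurrence counting only uses
# which strains hit which gene.  The figure may contain further cells
# not enumerated in the text; this encoding is deliberately partial.
_FIG2_CELLS: list[tuple[str, str, str, str | None]] = [
    # low-affinity glucose transporter mstC: 5 of 6 HET strains, coding
    ("J03 1.1", "1121897", "CODING", "MISSENSE"),
    ("J03 1.1", "1121897", "CODING", "LARGE_INSERTION"),
    ("J03 1.6", "1121897", "CODING", "MISSENSE"),
    ("J03 1.7", "1121897", "CODING", "MISSENSE"),
    ("J03 7.2", "1121897", "CODING", "MISSENSE"),
    ("J03 8.2", "1121897", "CODING", "MISSENSE"),
    # predicted amino acid transporter: promoter hits in the remaining
    # HET strain and one BOTH strain (different mutations, same region)
    ("J03 1.10", "1167209", "PROMOTER", None),
    ("J03 1.2", "1167209", "PROMOTER", None),
    # carbon catabolite repressor creA: all four BOTH strains
    ("J03 1.2", "1020757", "CODING", "NONSENSE"),
    ("J03 2.8", "1020757", "CODING", "NONSENSE"),
    ("J03 7.4", "1020757", "CODING", "NONSENSE"),
    ("J03 8.3", "1020757", "CODING", "FRAMESHIFT"),
    # unstudied fungal-specific transcription factor
    ("J03 7.4", "1209131", "CODING", "MISSENSE"),
    ("J03 8.3", "1209131", "PROMOTER", None),
    # trehalose-6-phosphate synthase tpsA
    ("J03 2.8", "1156486", "CODING", "MISSENSE"),
    ("J03 7.4", "1156486", "PROMOTER", None),
    # amylase regulator amyR: both NAT strains
    ("J03 4.3", "1094021", "CODING", "MISSENSE"),
    ("J03 6.3", "1094021", "SPLICE", None),
    # Ypt/Rab GTPase-activating protein
    ("J03 4.3", "1169228", "CODING", "MISSENSE"),
    ("J03 2.8", "1169228", "UTR5", None),
]


def fig2_fixture() -> tuple[list[AnnotatedStrain], list[StrainPhenotype]]:
    """The published gene x strain mutation incidence, text-described
    cells only, with the cohort phenotypes.

    Returns one AnnotatedStrain per mutant (strains without any
    text-described cell have empty call lists) and the 12 phenotypes.
    """
    phenotypes = table2_phenotypes()
    calls_by_strain: dict[str, list[ConsequenceCall]] = {p.strain: [] for p in phenotypes}
    for i, (strain, transcript, region, effect) in enumerate(_FIG2_CELLS):
        calls_by_strain[strain].append(
            _fig2_call(strain, transcript, region, effect, pos=1000 + 100 * i)
        )
    annotated = [
        AnnotatedStrain(strain=s, calls=calls) for s, calls in calls_by_strain.items()
    ]
    return annotated, phenotypes
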