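# Methods

## The analysis model

`mutscreen` treats a resequenced mutagenesis screen as a set-algebra and
annotation problem over per-strain variant call sets. The underlying
experimental design it assumes:

- a haploid parent strain carrying an IL-tolerant heterologous
  β-glucosidase expression construct, plus background variants relative to
  the reference assembly that are shared by every derived strain;
- mutant isolates derived from that parent by a point mutagen, each with a
  modest number of induced lesions (SNVs dominated, a minority of small
  indels, occasionally a large structural event);
- two independent variant callers per strain, each with its own false
  positives and misses;
- a triplicate secreted-enzyme assay (total protein, BG activity with and
  without 10% v/v ionic liquid, dry biomass) whose IL sensitivity reads out
  which enzyme — heterologous, native, or both — a hyper-producer secretes.

The pipeline's central assumptions are that (i) true induced lesions are
called by both callers at identical normalized alleles, while caller noise
is mostly caller-private, so the consensus intersection enriches strongly
for real variants; (ii) anything present in the parent is not an induced
lesion; and (iii) causality is indicated by within-phenotype recurrence,
because independent isolates with the same phenotype are unlikely to hit
the same gene by chance when per-strain lesion counts are small relative to
genome size.

## Region definitions and annotation order

Regions are derived per transcript, strand-aware:

- **Promoter**: 500 bp upstream through 30 bp downstream of the
  transcription start site (TSS), clipped to contig bounds. The TSS is the
  transcript's 5′-most coordinate; for CDS-only annotations it degrades to
  the CDS start (and the 5′ UTR is empty).
- **Splice sites**: the first and last two nucleotides of each intron,
  introns being the gaps between consecutive exons (purely positional; no
  motif checking). Introns shorter than twice the window yield the whole
  intron once.
- **UTRs**: exonic sequence outside the CDS span, sided by strand.

A variant is assigned, per overlapping gene, only its highest-precedence
region: CODING > SPLICE > UTR5/UTR3 > INTRON > PROMOTER. The ordering
encodes two rules: a splice-site base inside an annotated intron must not
be reported as mere INTRON, and a promoter assignment is only made when no
transcribed region of the same gene is hit. Overlapping genes are annotated
independently (one call per gene; no canonical-gene collapsing), so one
variant can be CODING for gene A and PROMOTER for gene B. Intronic variants
outside splice windows are retained and reported as INTRON rather than
silently dropped. Indels spanning a CDS boundary are classified by their
CDS-overlapping net length change; stop-loss is carried as its own class
for completeness of the genetic-code case analysis.

Coding SNVs are translated in transcript orientation under the standard
nuclear code by mutating the affected codon; the test suite proves this
codon-local shortcut equivalent to rebuilding and translating the entire
mutant CDS, exhaustively over every alt at every CDS position of multiple
genes on both strands.

## Variant matching

All small-variant matching (consensus, parent subtraction) uses the exact
normalized key (contig, pos, ref, alt). Normalization trims shared
leading/trailing allele bases (keeping the VCF anchor base) and left-aligns
indels as far as the reference allows; it is idempotent and
haplotype-preserving. No fuzzy indel window matching is done — the position
of an induced lesion is deterministic once both callers' representations
are normalized. Structural records (SVTYPE set) bypass normalization and
match on (contig, position within 50 bp, type), a stated tolerance that
replaces manual inspection of large events.

**Parent subtraction uses the union of both callers' raw parent calls** by
default, not the parent's filtered consensus. The asymmetry is deliberate:
a parental variant that one caller misses in the parent but both callers
see in the mutants would otherwise survive subtraction in *every* strain
and masquerade as a maximally recurrent lesion. Subtracting anything either
caller attributes to the parent is the conservative choice for a screen
whose statistic is recurrence; the strict-consensus alternative is exposed
as `parent_subtraction="consensus"`.

Hard filters default to QUAL ≥ 30 and DP ≥ 10. These are conventional
values, exposed in `FilterConfig` and echoed to the log, because the
analysis is only auditable if thresholds are explicit.

## Phenotype classification

Readings are biomass-normalized, replicates averaged (mean; the SD is
reported, not used for gating), folds taken against the parent means, and
the IL reduction computed as `100·(noIL − withIL)/noIL`, floored at 0 with
a warning on apparent activation. The category bands are reduction < 10%
HET, > 75% NAT, 30–60% BOTH. The gaps (10–30, 60–75) are deliberately
labeled AMBIGUOUS rather than forced into a neighboring bin, and AMBIGUOUS
strains are excluded from category-stratified ranking by default. The
hyper-producer gate is fold ≥ 2.0 over the parent, anchored to the weakest
accepted isolate of the cohort the thresholds come from. The reduction is
computed on normalized activities; since biomass divides both assay
readings of a culture, the ratio is algebraically identical on raw
readings.

## Recurrence ranking

Recurrence counts **distinct strains** per gene within a category — two
lesions in one gene in one strain count once. Ties break lexicographically
by transcript id. Promoter/UTR/splice/intron hits count equally with coding
hits by default (a regulatory lesion can be a strain's candidate lesion);
`coding_only=True` restricts to coding. Genes hit in ≥ 2 categories are
reported separately as shared loci. No permutation significance is
attached: with 2–6 strains per category the honest output is the incidence
structure itself.

## The synthetic screen generator

Defaults (all overridable in `ScreenSimConfig`):

| parameter | default | rationale |
|---|---|---|
| genome | 2 contigs × 300 kb | small enough for 100-replicate runs, large enough that background recurrence is rare |
| genes | 20, both strands, Poisson(1) introns, CDS 60–180 codons | exercises every region type |
| cohort | 6 HET + 4 BOTH + 2 NAT + parent | the published screen's cohort |
| lesions/strain | Poisson(8) | see calibration below |
| SNV spectrum | Ti:Tv 3.0, 10% indels (1–3 bp) | transition-biased point mutagen stand-in; the real mutagen's spectrum is uncharacterized, only recurrence logic is under test |
| parent background | 40 shared variants | exercises subtraction |
| causal penetrance | 1.0 | every category strain carries one planted nonsynonymous lesion in its category's causal gene |
| caller noise | fpr 0.05, fnr 0.005 per caller | consensus compounds misses as (1−fnr)²; with a 2-strain NAT category, per-caller miss rates above ~1% would make loss of a planted lesion, not ranking, the dominant failure mode. Sub-percent misses are realistic for 30–100× haploid coverage |
| assay noise | lognormal σ = 0.1 per culture, σ/6 per reading, n = 3 | biological variation dominates and is shared by the three readings of a culture; the IL ratio carries only the small technical component, keeping category recovery ≥ 99% |
| large insertion | off by default | `plant_large_insertion=True` converts one HET causal lesion to a 9 kb SVTYPE record to exercise the structural path |

Calibration: with ~8 lesions per strain on a 600 kb genome of which ~40 kb
falls in counted gene regions, the chance a given gene region is hit in one
strain is ≈ 0.03, so the expected number of background genes reaching the
NAT category's planted recurrence of 2-of-2 is ≈ 20·0.03² ≈ 0.02 — the
planted gene ranks first in ≥ 95 of 100 seeded replicates, which the
acceptance suite measures rather than assumes.

Caller QUAL/DP are drawn from separated distributions: true calls always
pass the default filters (QUAL 50–95, DP 15–45); spurious calls
(caller-private random SNVs, expected count fpr × true-call count) span the
thresholds (QUAL 15–70, DP 5–30), so the filter stage removes some and the
consensus intersection removes essentially all the rest.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: read-level artifacts (mapping bias, duplicate
reads, coverage troughs), correlated caller errors (real callers miss the
same hard regions), multi-nucleotide mutation clusters, heterozygous-looking
calls from repeats, and any realistic mutagen dose-response. The generator
validates the pipeline's logic, not the callers.

Everything is deterministic per (config, seed): seeds feed
`numpy.random.SeedSequence` substreams per stage, and the writers produce
byte-identical FASTA/GFF3/VCF/TSV across runs.

## Packaged fixtures

`table2_fixture()` carries the published cohort's fold values and phenotype
labels (13 rows including the parent). Since the source prints categories
rather than numeric IL reductions, `table2_phenotypes()` attaches each
category's band center (5/45/85%) as an explicitly synthetic stand-in
value. `fig2_fixture()` encodes only the text-described gene × strain
incidence cells; where the source gives effects and strains without a
one-to-one mapping, the assignment is an arbitrary fixed choice documented
in the fixture source, and recurrence counting never depends on it.

## Numerical and degenerate-input choices

- Filters use ≥ comparisons (a record at exactly QUAL 30 passes).
- Classification band edges are inclusive for BOTH (30 and 60 classify as
  BOTH), strict for HET/NAT (<10, >75), matching the stated ranges.
- Promoter windows are clipped at contig bounds, never rejected.
- Introns shorter than 2× the splice window become a single splice
  interval.
- Zero-gene genomes, empty call sets, empty cohorts and header-only VCFs
  are all valid inputs producing empty outputs.
- CDS lengths not divisible by 3 are a validation warning, not an error.

## Known limitations

- The published raw-data counts (1727/1844 caller calls, 1694/1326
  post-filter, 962 consensus) require the original reads, reference
  assembly and external callers; the pipeline reproduces the procedure,
  and the stage-count ledger is its analogue on synthetic data.
- Joint multi-sample genotyping is reduced to per-strain presence/absence
  plus a cohort missing-fraction filter; downstream analysis consumes only
  presence/absence.
- Consensus is computed per strain; the pooled unique-key total is logged
  for comparison with cohort-level reporting.
- No statistical significance is attached to recurrence or fold changes.
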