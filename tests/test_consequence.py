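"""Coding-effect calls, region precedence, synonymous exclusion."""

import pytest
from Bio.Seq import Seq

from mutscreen.consequence import (
    ConsequenceCall,
    annotate_variant,
    cds_sequence,
    coding_effect,
    exclude_synonymous,
    mutant_cds_sequence,
)
from mutscreen.genome_model import (
    AnnotationConfig,
    GeneModel,
    GenomeSequence,
    build_region_index,
)
from mutscreen.variant_core import VariantRecord

CFG = AnnotationConfig()


def V(pos, ref, alt, contig="c1", **kw):
    return VariantRecord(contig=contig, pos=pos, ref=ref, alt=alt, qual=60.0,
                         depth=30, strain="s1", caller="consensus", **kw)


@pytest.fixture
def toy():
    """Intronless + strand gene: CDS = ATG GGA CAA TGC TAA at 11..25."""
    cds = "ATGGGACAATGCTAA"
    seq = "T" * 10 + cds + "T" * 75
    genome = GenomeSequence({"c1": seq})
    gene = GeneModel(gene_id="g1", transcript_id="t1", contig="c1", strand="+",
                     exons=[(5, 30)], cds=[(11, 25)])
    return genome, gene


class TestCodingEffectSNV:
    def test_missense_gly_to_glu(self, toy):
        genome, gene = toy
        # codon 2 GGA -> GAA: Gly -> Glu
        effect, aa = coding_effect(V(15, "G", "A"), gene, genome)
        assert effect == "MISSENSE"
        assert aa == "p.Gly2Glu"

    def test_nonsense_caa_to_taa(self, toy):
        genome, gene = toy
        effect, aa = coding_effect(V(17, "C", "T"), gene, genome)
        assert effect == "NONSENSE"
        assert aa == "p.Gln3Ter"

    def test_synonymous_third_position(self, toy):
        genome, gene = toy
        # GGA -> GGG both glycine
        effect, _ = coding_effect(V(16, "A", "G"), gene, genome)
        assert effect == "SYNONYMOUS"

    def test_stop_loss(self, toy):
        genome, gene = toy
        # TAA -> CAA at the stop codon
        effect, aa = coding_effect(V(23, "T", "C"), gene, genome)
        assert effect == "STOP_LOSS"
        assert aa == "p.Ter5Gln"

    def test_not_in_cds_is_error(self, toy):
        genome, gene = toy
        with pytest.raises(ValueError, match="does not overlap CDS"):
            coding_effect(V(5, "T", "A"), gene, genome)


class TestCodingEffectIndel:
    def test_two_bp_deletion_frameshift(self, toy):
        genome, gene = toy
        seq = genome.contigs["c1"]
        effect, _ = coding_effect(V(14, seq[13:16], seq[13]), gene, genome)
        assert effect == "FRAMESHIFT"

    def test_three_bp_deletion_inframe(self, toy):
        genome, gene = toy
        seq = genome.contigs["c1"]
        effect, _ = coding_effect(V(14, seq[13:17], seq[13]), gene, genome)
        assert effect == "INFRAME_INDEL"

    def test_insertion_frameshift(self, toy):
        genome, gene = toy
        effect, _ = coding_effect(V(14, "G", "GT"), gene, genome)
        assert effect == "FRAMESHIFT"

    def test_large_events(self, toy):
        genome, gene = toy
        v = V(14, "N", "<INS>", svtype="large_insertion", svlen=9000)
        assert coding_effect(v, gene, genome)[0] == "LARGE_INSERTION"
        v = V(14, "N", "<DEL>", svtype="large_deletion", svlen=5000)
        assert coding_effect(v, gene, genome)[0] == "LARGE_DELETION"


def translate_oracle(v, gene, genome):
    """Independent full-CDS rebuild-and-translate classification."""
    old = str(Seq(cds_sequence(gene, genome)).translate())
    new = str(Seq(mutant_cds_sequence(v, gene, genome)).translate())
    if new == old:
        return "SYNONYMOUS"
    # first differing amino acid decides
    for o, n in zip(old, new):
        if o != n:
            if n == "*":
                return "NONSENSE"
            if o == "*":
                return "STOP_LOSS"
            return "MISSENSE"
    return "MISSENSE"


class TestTranslationOracle:
    def test_exhaustive_snvs_match_full_rebuild(self, sim_genome):
        """Every alt at every CDS position of one + and one - strand
        synthetic gene agrees with rebuild-and-translate."""
        genome, genes = sim_genome
        plus = next(g for g in genes if g.strand == "+")
        minus = next(g for g in genes if g.strand == "-")
        for gene in (plus, minus):
            for a, b in gene.cds:
                for pos in range(a, b + 1):
                    ref = genome.contigs[gene.contig][pos - 1]
                    for alt in "ACGT":
                        if alt == ref:
                            continue
                        v = V(pos, ref, alt, contig=gene.contig)
                        effect, _ = coding_effect(v, gene, genome)
                        assert effect == translate_oracle(v, gene, genome), (
                            f"{gene.transcript_id} {pos} {ref}>{alt}"
                        )

    def test_strand_symmetry(self, toy):
        """Reverse-complementing genome and model leaves effects fixed."""
        genome, gene = toy
        L = len(genome.contigs["c1"])
        rc = str(Seq(genome.contigs["c1"]).reverse_complement())
        genome_rc = GenomeSequence({"c1": rc})
        flip = lambda iv: (L - iv[1] + 1, L - iv[0] + 1)
        gene_rc = GeneModel(
            gene_id="g1", transcript_id="t1", contig="c1", strand="-",
            exons=sorted(flip(e) for e in gene.exons),
            cds=sorted(flip(c) for c in gene.cds),
        )
        comp = str.maketrans("ACGT", "TGCA")
        for pos, ref, alt in [(15, "G", "A"), (17, "C", "T"), (16, "A", "G")]:
            fwd, aa_f = coding_effect(V(pos, ref, alt), gene, genome)
            rev, aa_r = coding_effect(
                V(L - pos + 1, ref.translate(comp), alt.translate(comp)),
                gene_rc, genome_rc,
            )
            assert (fwd, aa_f) == (rev, aa_r)


@pytest.fixture
def two_gene_index():
    """Gene A (+, with intron) and gene B upstream whose UTR3 overlaps
    A's promoter window."""
    seq = ("T" * 299 + "ATGGGA" + "GT" + "T" * 96 + "AG" + "CAATGCTAA" + "T" * 600)
    genome = GenomeSequence({"c1": seq + "A" * (1500 - len(seq))})
    # exon1 300-305 (ATGGGA), intron 306-405, exon2 406-414
    gene_a = GeneModel(gene_id="A", transcript_id="tA", contig="c1", strand="+",
                       exons=[(290, 305), (406, 430)], cds=[(300, 305), (406, 414)])
    gene_b = GeneModel(gene_id="B", transcript_id="tB", contig="c1", strand="+",
                       exons=[(10, 150)], cds=[(20, 100)])
    idx = build_region_index([gene_a, gene_b], CFG, genome=genome)
    return genome, gene_a, gene_b, idx


class TestAnnotateVariant:
    def test_cds_snv_single_coding_call(self, two_gene_index):
        genome, gene_a, _, idx = two_gene_index
        (call,) = [c for c in annotate_variant(V(301, "T", "A"), idx, genome)
                   if c.transcript_id == "tA"]
        assert call.region == "CODING" and call.coding_effect is not None

    def test_first_intron_base_is_splice_not_intron(self, two_gene_index):
        genome, _, _, idx = two_gene_index
        ref = genome.contigs["c1"][305]
        calls = [c for c in annotate_variant(V(306, ref, "C" if ref != "C" else "G"),
                                             idx, genome)
                 if c.transcript_id == "tA"]
        assert [c.region for c in calls] == ["SPLICE"]

    def test_mid_intron_is_intron(self, two_gene_index):
        genome, _, _, idx = two_gene_index
        ref = genome.contigs["c1"][349]
        calls = [c for c in annotate_variant(V(350, ref, "A" if ref != "A" else "C"),
                                             idx, genome)
                 if c.transcript_id == "tA"]
        assert [c.region for c in calls] == ["INTRON"]

    def test_promoter_and_neighbor_utr3_both_called(self, two_gene_index):
        genome, _, _, idx = two_gene_index
        # 100 bp upstream of A's tss (290) inside B's UTR3 (101-150)
        ref = genome.contigs["c1"][139]
        calls = annotate_variant(V(140, ref, "G" if ref != "G" else "T"), idx, genome)
        regions = {c.transcript_id: c.region for c in calls}
        assert regions == {"tA": "PROMOTER", "tB": "UTR3"}

    def test_promoter_never_when_higher_region_overlaps_same_gene(self, two_gene_index):
        genome, _, _, idx = two_gene_index
        # every position in A's transcribed span must not be PROMOTER for A
        for pos in range(290, 431):
            ref = genome.contigs["c1"][pos - 1]
            alt = "A" if ref != "A" else "G"
            for c in annotate_variant(V(pos, ref, alt), idx, genome):
                if c.transcript_id == "tA":
                    assert c.region != "PROMOTER"

    def test_intergenic(self, two_gene_index):
        genome, _, _, idx = two_gene_index
        (call,) = annotate_variant(V(1400, genome.contigs["c1"][1399], "A"
                                     if genome.contigs["c1"][1399] != "A" else "C"),
                                   idx, genome)
        assert call.region == "INTERGENIC" and call.transcript_id is None


class TestExcludeSynonymous:
    def _call(self, effect):
        return ConsequenceCall(
            variant=V(100, "A", "G"), gene_id="g", transcript_id="t",
            region="CODING", coding_effect=effect,
        )

    def test_all_synonymous_empty(self):
        calls = [self._call("SYNONYMOUS")] * 3
        assert exclude_synonymous(calls) == []

    def test_mixed_drops_exactly_synonymous(self):
        calls = [self._call("SYNONYMOUS"), self._call("MISSENSE"),
                 self._call("NONSENSE"), self._call("SYNONYMOUS")]
        kept = exclude_synonymous(calls)
        assert len(kept) == 2
        assert all(c.coding_effect != "SYNONYMOUS" for c in kept)

    def test_invariant_effect_only_with_coding(self):
        with pytest.raises(ValueError):
            ConsequenceCall(variant=V(1, "A", "G"), gene_id="g",
                            transcript_id="t", region="UTR5",
                            coding_effect="MISSENSE")
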