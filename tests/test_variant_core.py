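"""Variant normalization, filtering, consensus and parent subtraction."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutscreen.genome_model import GenomeSequence
from mutscreen.variant_core import (
    CallSet,
    FilterConfig,
    VariantRecord,
    apply_filters,
    intersect_callsets,
    normalize_callset,
    normalize_variant,
    read_vcf,
    subtract_parent,
    write_vcf,
)


def V(contig="c1", pos=100, ref="A", alt="T", qual=60.0, depth=30,
      strain="s1", caller="callerA", **kw):
    return VariantRecord(contig=contig, pos=pos, ref=ref, alt=alt, qual=qual,
                         depth=depth, strain=strain, caller=caller, **kw)


def apply_to_reference(seq, v):
    """Independent haplotype oracle: splice the ALT allele into the
    reference string."""
    return seq[: v.pos - 1] + v.alt + seq[v.pos - 1 + len(v.ref):]


class TestVcfIO:
    VCF_TEXT = "\n".join(
        [
            "##fileformat=VCFv4.2",
            "##contig=<ID=c1,length=1000>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1",
            "c1\t150\t.\tA\tT\t60\tPASS\t.\tGT:DP\t1/1:33",
            "c1\t300\t.\tA\tT,C\t50\tPASS\t.\tGT:DP\t1/2:20",
            "",
        ]
    )

    def test_single_record(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(self.VCF_TEXT)
        cs = read_vcf(p, strain="s1", caller="callerA")
        r = cs.records[0]
        assert (r.contig, r.pos, r.ref, r.alt, r.qual, r.depth) == ("c1", 150, "A", "T", 60.0, 33)

    def test_multiallelic_decomposition(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(self.VCF_TEXT)
        cs = read_vcf(p, strain="s1", caller="callerA")
        at_300 = [r for r in cs.records if r.pos == 300]
        assert sorted(r.alt for r in at_300) == ["C", "T"]

    def test_roundtrip_identity(self, tmp_path):
        records = [
            V(pos=10), V(pos=50, ref="AT", alt="A", qual=45.5, depth=12),
            V(pos=200, ref="G", alt="GCC"),
            V(pos=400, ref="N", alt="<INS>", svtype="large_insertion", svlen=9000),
        ]
        cs = CallSet(strain="s1", caller="callerA", records=records)
        path = tmp_path / "rt.vcf"
        write_vcf(cs, path)
        back = read_vcf(path, strain="s1", caller="callerA")
        assert [(r.contig, r.pos, r.ref, r.alt, r.qual, r.depth, r.svtype, r.svlen)
                for r in back.records] == \
               [(r.contig, r.pos, r.ref, r.alt, r.qual, r.depth, r.svtype, r.svlen)
                for r in cs.records]

    def test_empty_callset_header_only(self, tmp_path):
        path = tmp_path / "empty.vcf"
        write_vcf(CallSet(strain="s1", caller="callerA", records=[]), path)
        lines = path.read_text().splitlines()
        assert all(line.startswith("#") for line in lines)
        assert read_vcf(path, strain="s1", caller="callerA").records == []

    def test_sv_fields_round_trip(self, tmp_path):
        cs = CallSet(strain="s1", caller="callerA", records=[
            V(pos=400, ref="N", alt="<DEL>", svtype="large_deletion", svlen=5000)])
        path = tmp_path / "sv.vcf"
        write_vcf(cs, path)
        assert "SVTYPE=DEL" in path.read_text() and "SVLEN=5000" in path.read_text()


class TestNormalize:
    GENOME = GenomeSequence({"c1": "GGACTTTTGACGTACGTACG" + "A" * 80})

    def test_snv_unchanged(self):
        v = V(pos=4, ref="C", alt="A")
        assert normalize_variant(v, self.GENOME) is v

    def test_deletion_left_aligned(self):
        # c1: G G A C T T T T G ... deleting two Ts anywhere in the run
        # must left-align to the first representation after the C
        v = V(pos=6, ref="TTT", alt="T")
        n = normalize_variant(v, self.GENOME)
        assert (n.pos, n.ref, n.alt) == (4, "CTT", "C")

    def test_shared_prefix_trimmed(self):
        seq = self.GENOME.contigs["c1"]
        v = V(pos=10, ref=seq[9:11], alt=seq[9] + "G")
        n = normalize_variant(v, self.GENOME)
        assert (n.pos, n.ref, n.alt) == (11, seq[10], "G")

    def test_ref_mismatch_names_position(self):
        with pytest.raises(ValueError, match="c1:4"):
            normalize_variant(V(pos=4, ref="T", alt="A"), self.GENOME)

    def test_haplotype_equivalence_and_idempotence(self):
        seq = self.GENOME.contigs["c1"]
        rng = random.Random(5)
        for _ in range(300):
            pos = rng.randrange(2, 90)
            kind = rng.choice(["snv", "ins", "del"])
            if kind == "snv":
                ref = seq[pos - 1]
                alt = rng.choice([b for b in "ACGT" if b != ref])
            elif kind == "ins":
                ref = seq[pos - 1]
                alt = ref + "".join(rng.choices("ACGT", k=rng.randrange(1, 4)))
            else:
                size = rng.randrange(1, 4)
                ref = seq[pos - 1 : pos + size]
                alt = seq[pos - 1]
            v = V(pos=pos, ref=ref, alt=alt)
            n = normalize_variant(v, self.GENOME)
            assert apply_to_reference(seq, v) == apply_to_reference(seq, n)
            n2 = normalize_variant(n, self.GENOME)
            assert (n2.pos, n2.ref, n2.alt) == (n.pos, n.ref, n.alt)


class TestFilters:
    def _cs(self, records):
        return CallSet(strain="s1", caller="callerA", records=records)

    def test_all_passing_unchanged(self):
        cs = self._cs([V(pos=p) for p in (1, 2, 3)])
        assert len(apply_filters(cs, FilterConfig())) == 3

    def test_boundary_qual_removed(self):
        cs = self._cs([V(pos=1, qual=29.9), V(pos=2, qual=30.0)])
        kept = apply_filters(cs, FilterConfig())
        assert [r.pos for r in kept.records] == [2]

    def test_predicate_oracle_and_monotonicity(self):
        rng = random.Random(11)
        records = [
            V(pos=i, qual=rng.uniform(0, 100), depth=rng.randrange(0, 60))
            for i in range(1, 400)
        ]
        cs = self._cs(records)
        cfg = FilterConfig(min_qual=37.5, min_depth=13)
        kept = apply_filters(cs, cfg)
        oracle = [r for r in records if r.qual >= 37.5 and r.depth >= 13]
        assert kept.records == sorted(oracle, key=lambda r: (r.contig, r.pos, r.ref, r.alt))
        stricter = apply_filters(cs, FilterConfig(min_qual=50, min_depth=13))
        assert set(stricter.keys()) <= set(kept.keys())


def _callset_from_keys(keys, strain="s1", caller="callerA"):
    return CallSet(strain=strain, caller=caller, records=[
        V(pos=pos, ref=ref, alt=alt, strain=strain, caller=caller)
        for (pos, ref, alt) in keys
    ])


_key = st.tuples(
    st.integers(1, 60),
    st.sampled_from(["A", "C", "G", "T"]),
    st.sampled_from(["A", "C", "G", "T"]),
).filter(lambda k: k[1] != k[2])


class TestSetAlgebra:
    def test_identical_sets_all_retained(self):
        a = _callset_from_keys([(1, "A", "T"), (5, "C", "G")])
        b = _callset_from_keys([(1, "A", "T"), (5, "C", "G")], caller="callerB")
        assert intersect_callsets(a, b).keys() == a.keys()

    def test_disjoint_sets_empty(self):
        a = _callset_from_keys([(1, "A", "T")])
        b = _callset_from_keys([(2, "A", "T")], caller="callerB")
        assert len(intersect_callsets(a, b)) == 0

    def test_same_caller_is_error(self):
        a = _callset_from_keys([(1, "A", "T")])
        with pytest.raises(ValueError, match="caller"):
            intersect_callsets(a, a)

    def test_parent_superset_subtracts_to_empty(self):
        mut = _callset_from_keys([(1, "A", "T"), (5, "C", "G")])
        parent = _callset_from_keys(
            [(1, "A", "T"), (5, "C", "G"), (9, "G", "A")], strain="P")
        assert len(subtract_parent(mut, parent)) == 0

    def test_empty_parent_identity(self):
        mut = _callset_from_keys([(1, "A", "T")])
        parent = CallSet(strain="P", caller="callerA", records=[])
        assert subtract_parent(mut, parent).keys() == mut.keys()

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.sets(_key, max_size=25), st.sets(_key, max_size=25))
    def test_intersection_and_subtraction_match_set_algebra(self, ka, kb):
        a = _callset_from_keys(ka)
        b = _callset_from_keys(kb, caller="callerB")
        cons = intersect_callsets(a, b)
        assert cons.keys() == a.keys() & b.keys()
        assert len(cons) <= min(len(a), len(b))
        sub = subtract_parent(a, b)
        assert sub.keys() == a.keys() - b.keys()

    def test_consensus_takes_min_qual_depth(self):
        a = CallSet(strain="s1", caller="callerA",
                    records=[V(pos=1, qual=80, depth=40)])
        b = CallSet(strain="s1", caller="callerB",
                    records=[V(pos=1, qual=55, depth=22, caller="callerB")])
        (r,) = intersect_callsets(a, b).records
        assert (r.qual, r.depth, r.caller) == (55, 22, "consensus")

    def test_sv_positional_window_matching(self):
        a = CallSet(strain="s1", caller="callerA", records=[
            V(pos=100, ref="N", alt="<INS>", svtype="large_insertion", svlen=9000)])
        near = CallSet(strain="s1", caller="callerB", records=[
            V(pos=140, ref="N", alt="<INS>", svtype="large_insertion",
              svlen=8800, caller="callerB")])
        far = CallSet(strain="s1", caller="callerB", records=[
            V(pos=200, ref="N", alt="<INS>", svtype="large_insertion",
              svlen=8800, caller="callerB")])
        assert len(intersect_callsets(a, near)) == 1
        assert len(intersect_callsets(a, far)) == 0


class TestNormalizeCallset:
    def test_representational_duplicates_collapse(self):
        genome = GenomeSequence({"c1": "GGACTTTTGACGT" + "A" * 40})
        a = V(pos=4, ref="CTT", alt="C")
        b = V(pos=6, ref="TTT", alt="T")  # same haplotype, shifted
        cs = CallSet(strain="s1", caller="callerA", records=[a, b])
        n = normalize_callset(cs, genome)
        assert len(n) == 1 and n.records[0].pos == 4
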