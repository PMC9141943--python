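"""Pooled small-variant calling, filtering, impact annotation, VCF I/O."""

import numpy as np
import pytest

from pulascreen import align as al
from pulascreen import simcohort as sc
from pulascreen import smallvar as sv
from pulascreen.locusmodel import Locus

from .oracles import impact_oracle


def mk_read(ref_start, cigar, seq, rid="r", strand="+"):
    return al.AlignedRead(read_id=rid, seq=seq, ref_start=ref_start,
                          cigar=tuple(cigar), strand=strand, edit_distance=0,
                          mapped=True, score=100)


@pytest.fixture(scope="module")
def toy_locus():
    # 60 bp locus, CDS 16..45 (10 codons)
    rng = np.random.default_rng(0)
    flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 15))
    cds = "ATG" + "GAATGGTTCAAAGCTGGTCAG" + "TAA"  # no internal stop
    down = "".join("ACGT"[i] for i in rng.integers(0, 4, 60 - 15 - len(cds)))
    return Locus("toy", flank + cds + down, cds_start=16, cds_end=15 + len(cds))


class TestPileup:
    def test_identical_reads_give_uniform_reference_depth(self, toy_locus):
        reads = [mk_read(1, [("M", 50)], toy_locus.seq[:50], rid=f"r{i}")
                 for i in range(10)]
        pile = sv.pileup(reads, toy_locus)
        assert all(pile.depth[p] == 10 for p in range(1, 51))
        col = pile.column(20)
        ref_base = toy_locus.seq[19]
        assert col.base_counts[ref_base] == 10 and col.depth == 10

    def test_deletion_read_among_reference_reads(self, toy_locus):
        ref = toy_locus.seq
        reads = [mk_read(1, [("M", 50)], ref[:50], rid=f"r{i}") for i in range(9)]
        # one read deleting positions 25-26
        reads.append(mk_read(1, [("M", 24), ("D", 2), ("M", 24)],
                             ref[:24] + ref[26:50], rid="del"))
        pile = sv.pileup(reads, toy_locus)
        assert pile.depth[25] == 10  # deleted positions still covered
        key = sv.normalize_variant(24, ref[23:26], ref[23], ref)
        assert pile.indel_obs[key] == 1

    def test_soft_clips_contribute_nothing(self, toy_locus):
        reads = [mk_read(1, [("M", 20), ("S", 30)], toy_locus.seq[:20] + "A" * 30)]
        pile = sv.pileup(reads, toy_locus)
        assert pile.depth[20] == 1 and pile.depth[21] == 0

    def test_alignment_past_locus_end_rejected(self, toy_locus):
        with pytest.raises(ValueError):
            sv.pileup([mk_read(31, [("M", 50)], "A" * 50)], toy_locus)


class TestCoverageGate:
    def test_uniform_depth_above_minimum_included(self, toy_locus):
        reads = [mk_read(1, [("M", 60)], toy_locus.seq, rid=f"r{i}")
                 for i in range(12)]
        gate = sv.coverage_gate(sv.pileup(reads, toy_locus), toy_locus)
        assert gate.included and gate.fraction_covered == 1.0

    def test_single_shallow_cds_position_excludes_sample(self, toy_locus):
        # depth 12 everywhere except the last CDS base (42) at depth 8
        reads = [mk_read(1, [("M", 41)], toy_locus.seq[:41], rid=f"a{i}")
                 for i in range(4)]
        reads += [mk_read(1, [("M", 60)], toy_locus.seq, rid=f"b{i}")
                  for i in range(8)]
        gate = sv.coverage_gate(sv.pileup(reads, toy_locus), toy_locus)
        assert not gate.included

    def test_gate_fraction_is_configurable(self, toy_locus):
        reads = [mk_read(1, [("M", 41)], toy_locus.seq[:41], rid=f"a{i}")
                 for i in range(10)]
        pile = sv.pileup(reads, toy_locus)
        loose = sv.CallingParams(coverage_gate_fraction=0.9)
        assert not sv.coverage_gate(pile, toy_locus).included
        assert sv.coverage_gate(pile, toy_locus, loose).included


class TestCalling:
    def _pile_with_snv(self, toy_locus, depth, alt_count, pos=20):
        ref = toy_locus.seq
        alt_base = "A" if ref[pos - 1] != "A" else "C"
        reads = [mk_read(1, [("M", 60)], ref, rid=f"r{i}")
                 for i in range(depth - alt_count)]
        alt_seq = ref[: pos - 1] + alt_base + ref[pos:]
        reads += [mk_read(1, [("M", 60)], alt_seq, rid=f"a{i}")
                  for i in range(alt_count)]
        return sv.pileup(reads, toy_locus), alt_base

    def test_minimum_evidence_is_called(self, toy_locus):
        pile, alt = self._pile_with_snv(toy_locus, depth=10, alt_count=2)
        calls = sv.call_sample_variants(pile, toy_locus)
        (v,) = [c for c in calls if c.pos == 20]
        assert v.alt == alt and v.af == pytest.approx(0.2)

    def test_insufficient_depth_not_called(self, toy_locus):
        pile, _ = self._pile_with_snv(toy_locus, depth=9, alt_count=3)
        assert not [c for c in sv.call_sample_variants(pile, toy_locus)
                    if c.pos == 20]

    def test_below_alt_fraction_not_called(self, toy_locus):
        pile = sv.Pileup(toy_locus)
        pos = 20
        ref_code = "ACGT".index(toy_locus.seq[pos - 1])
        alt_code = (ref_code + 1) % 4
        pile.depth[pos] = 1000
        pile.base_counts[ref_code, pos] = 995
        pile.base_counts[alt_code, pos] = 5
        assert sv.call_sample_variants(pile, toy_locus) == []

    def test_no_false_positives_without_errors(self, locus, haplotypes):
        spec = sc.SampleSpec(id="s", mixture={"intact": 1.0}, mean_depth=15,
                             sub_error_rate=0.0, seed=21)
        reads, _ = sc.simulate_reads(spec, haplotypes, locus)
        pile = sv.pileup(al.align_reads(reads, locus), locus)
        assert sv.call_sample_variants(pile, locus) == []


class TestJointFilter:
    def _obs(self, af, depth=100, pos=20, locus=None):
        ref = locus.seq[pos - 1]
        alt = "A" if ref != "A" else "C"
        return sv.VariantObservation(pos, ref, alt, "snv",
                                     int(round(af * depth)), depth)

    def test_low_af_everywhere_removed(self, toy_locus):
        obs = {f"s{i}": [self._obs(0.04, locus=toy_locus)] for i in range(6)}
        assert sv.joint_filter(obs, toy_locus) == []

    def test_two_sample_prevalence_removed(self, toy_locus):
        obs = {f"s{i}": [self._obs(0.5, locus=toy_locus)] for i in range(2)}
        assert sv.joint_filter(obs, toy_locus) == []

    def test_five_sample_prevalence_retained_with_subthreshold_evidence(self, toy_locus):
        obs = {f"s{i}": [self._obs(0.5, locus=toy_locus)] for i in range(5)}
        obs["s_low"] = [self._obs(0.02, locus=toy_locus)]
        (v,) = sv.joint_filter(obs, toy_locus)
        assert v.prevalence == 5
        assert "s_low" in v.per_sample  # sub-threshold evidence kept

    def test_loosening_thresholds_never_removes_variants(self, toy_locus):
        obs = {f"s{i}": [self._obs(0.06 + 0.1 * i, locus=toy_locus)]
               for i in range(5)}
        strict = {v.key for v in sv.joint_filter(obs, toy_locus)}
        for params in (sv.CallingParams(report_min_af=0.03),
                       sv.CallingParams(min_prevalence_samples=2)):
            loose = {v.key for v in sv.joint_filter(obs, toy_locus, params)}
            assert strict <= loose


class TestImpact:
    def _annotate(self, locus, pos, ref, alt):
        return sv.annotate_impact(
            sv.VariantObservation(pos, ref, alt, "snv", 0, 0), locus)

    def test_archetype_classes(self, toy_locus):
        ref = toy_locus.seq
        cs = toy_locus.cds_start
        # frameshift: 2-nt deletion inside CDS
        assert self._annotate(toy_locus, cs + 3, ref[cs + 2 : cs + 5],
                              ref[cs + 2]) == sv.HIGH
        # stop gain: codon 3 TGG (positions cs+6..cs+8) -> TAG
        assert ref[cs + 5 : cs + 8] == "TGG"
        assert self._annotate(toy_locus, cs + 7, "G", "A") == sv.HIGH
        # synonymous: GAA -> GAG (codon 1 after start: positions cs+3? use GAA at 19..21)
        assert ref[cs - 1 + 3 : cs - 1 + 6] == "GAA"
        assert self._annotate(toy_locus, cs + 5, "A", "G") == sv.LOW
        # in-frame deletion: 3 nt
        assert self._annotate(toy_locus, cs + 3, ref[cs + 2 : cs + 6],
                              ref[cs + 2]) == sv.MODERATE
        # upstream SNV
        base = ref[0]
        assert self._annotate(toy_locus, 1, base,
                              "A" if base != "A" else "C") == sv.MODIFIER
        # start loss
        assert self._annotate(toy_locus, cs, "A", "G") == sv.HIGH

    def test_indel_straddling_cds_boundary_is_high(self, toy_locus):
        cs = toy_locus.cds_start
        ref = toy_locus.seq
        anchor = cs - 3
        assert self._annotate(toy_locus, anchor, ref[anchor - 1 : anchor + 5],
                              ref[anchor - 1]) == sv.HIGH

    def test_agrees_with_translate_and_compare_oracle(self, locus):
        rng = np.random.default_rng(7)
        bases = "ACGT"
        for _ in range(300):
            kind = rng.integers(0, 3)
            if kind == 0:  # SNV anywhere
                pos = int(rng.integers(1, len(locus) + 1))
                ref = locus.seq[pos - 1]
                alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
            elif kind == 1:  # deletion, anchored
                pos = int(rng.integers(1, len(locus) - 8))
                n = int(rng.integers(1, 7))
                ref = locus.seq[pos - 1 : pos + n]
                alt = locus.seq[pos - 1]
            else:  # insertion, anchored
                pos = int(rng.integers(1, len(locus)))
                ref = locus.seq[pos - 1]
                alt = ref + "".join(bases[i] for i in
                                    rng.integers(0, 4, int(rng.integers(1, 7))))
            got = self._annotate(locus, pos, ref, alt)
            assert got == impact_oracle(locus, pos, ref, alt), (pos, ref, alt)


class TestHighFrequency:
    @pytest.mark.parametrize("af,flagged", [(0.8, True), (0.7, True), (0.69, False)])
    def test_inclusive_boundary(self, toy_locus, af, flagged):
        obs = sv.VariantObservation(20, "A", "C", "snv", int(af * 100), 100,
                                    impact=sv.HIGH)
        out = sv.high_frequency_flags({"s1": [obs]})
        assert (len(out) == 1) is flagged


class TestVcfRoundTrip:
    def test_cohort_table_roundtrips_exactly(self, toy_locus, tmp_path):
        ref = toy_locus.seq
        variants = [
            sv.SmallVariant(20, ref[19], "A" if ref[19] != "A" else "C", "snv",
                            sv.MODIFIER, {"s1": (10, 50), "s2": (40, 80)}, 2),
            sv.SmallVariant(24, ref[23:26], ref[23], "deletion", sv.HIGH,
                            {"s1": (30, 40), "s3": (5, 100)}, 1),
            sv.SmallVariant(30, ref[29], ref[29] + "TT", "insertion", sv.HIGH,
                            {"s2": (12, 12)}, 1),
        ]
        path = tmp_path / "v.vcf"
        sv.write_vcf(variants, toy_locus, path)
        back = sv.read_vcf(path)
        assert back == sorted(variants, key=lambda v: v.key)

    def test_snv_and_anchored_deletion_records(self, toy_locus, tmp_path):
        ref = toy_locus.seq
        variants = [sv.SmallVariant(24, ref[23:26], ref[23], "deletion",
                                    sv.HIGH, {"s1": (30, 40)}, 1)]
        path = tmp_path / "v.vcf"
        sv.write_vcf(variants, toy_locus, path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        fields = lines[0].split("\t")
        assert fields[1] == "24" and fields[3] == ref[23:26] and fields[4] == ref[23]
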