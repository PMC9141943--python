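"""Structural variants from clipped reads; transposase clustering/classification."""

import numpy as np
import pytest

from pulascreen import align as al
from pulascreen import simcohort as sc
from pulascreen import svscan as svs


def mk_read(ref_start, cigar, seq, rid="r"):
    return al.AlignedRead(read_id=rid, seq=seq, ref_start=ref_start,
                          cigar=tuple(cigar), strand="+", edit_distance=0,
                          mapped=True, score=100)


def simulate_and_call(locus, haplotypes, genotype, depth, seed, mixture=None):
    mixture = mixture or {genotype: 1.0}
    spec = sc.SampleSpec(id="s", mixture=mixture, mean_depth=depth, seed=seed)
    reads, truth = sc.simulate_reads(spec, haplotypes, locus)
    alns = al.align_reads(reads, locus)
    clusters = svs.detect_breakpoints(alns, locus)
    return alns, clusters, svs.call_structural_variants(clusters, locus), truth


class TestDetectBreakpoints:
    def test_support_below_minimum_is_dropped(self, small_locus):
        ref = small_locus.seq
        reads = [mk_read(1, [("M", 100), ("S", 50)], ref[:100] + "T" * 50,
                         rid=f"c{i}") for i in range(9)]
        assert svs.detect_breakpoints(reads, small_locus) == []

    def test_cluster_counts_and_spanning_reads(self, small_locus):
        ref = small_locus.seq
        reads = [mk_read(801, [("M", 100), ("S", 50)], ref[800:900] + "T" * 50,
                         rid=f"c{i}") for i in range(25)]
        reads += [mk_read(850, [("M", 150)], ref[849:999], rid=f"s{i}")
                  for i in range(10)]
        (cluster,) = svs.detect_breakpoints(reads, small_locus)
        assert (cluster.pos, cluster.side) == (900, "right")
        assert cluster.clip_reads == 25 and cluster.span_reads == 10
        assert cluster.frequency == pytest.approx(25 / 35)

    def test_unedited_sample_yields_no_clusters(self, small_locus, small_haplotypes):
        _, clusters, svlist, _ = simulate_and_call(
            small_locus, small_haplotypes, "intact", depth=30, seed=3)
        assert clusters == [] and svlist == []


class TestCallStructuralVariants:
    def test_element_insertion_recovered_at_planted_breakpoint(
            self, small_locus, small_haplotypes):
        planted = small_haplotypes["element_insertion"].spec.edits[0].position
        _, _, svlist, _ = simulate_and_call(
            small_locus, small_haplotypes, "element_insertion", depth=50, seed=1)
        (svt,) = svlist
        assert svt.type == "insertion"
        assert abs(svt.start - planted) <= svs.SVParams().cluster_window
        assert svt.frequency >= 0.9 and svt.support_reads >= 10

    def test_large_deletion_recovered_with_both_breakpoints(
            self, small_locus, small_haplotypes):
        edit = small_haplotypes["large_deletion"].spec.edits[0]
        _, _, svlist, _ = simulate_and_call(
            small_locus, small_haplotypes, "large_deletion", depth=50, seed=2)
        dels = [s for s in svlist if s.type == "deletion"]
        assert len(dels) == 1
        w = svs.SVParams().cluster_window
        assert abs(dels[0].start - edit.position) <= w
        assert abs(dels[0].end - (edit.position + edit.length - 1)) <= w
        assert dels[0].frequency >= 0.9

    def test_planted_events_recovered_across_seeds(self, small_locus,
                                                   small_haplotypes):
        w = svs.SVParams().cluster_window
        for seed in range(10, 20):
            genotype = "element_insertion" if seed % 2 else "large_deletion"
            planted = small_haplotypes[genotype].spec.edits[0]
            _, _, svlist, _ = simulate_and_call(
                small_locus, small_haplotypes, genotype, depth=50, seed=seed)
            wanted = "insertion" if genotype == "element_insertion" else "deletion"
            hits = [s for s in svlist if s.type == wanted
                    and abs(s.start - planted.position) <= w]
            assert hits, (seed, genotype, svlist)

    def test_half_mixture_frequency_recovered_and_not_high(
            self, small_locus, small_haplotypes):
        _, _, svlist, _ = simulate_and_call(
            small_locus, small_haplotypes, None, depth=100, seed=5,
            mixture={"element_insertion": 0.5, "intact": 0.5})
        (svt,) = [s for s in svlist if s.type == "insertion"]
        assert abs(svt.frequency - 0.5) <= 0.1
        assert not svt.high_frequency


class TestClusterSequences:
    def test_identical_pair_collapses(self):
        db = svs.cluster_sequences({"a": "ACGT" * 100, "b": "ACGT" * 100})
        assert len(db.representatives) == 1
        assert set(db.cluster_map.values()) == {"a"}

    def test_ninety_percent_identity_stays_separate(self):
        rng = np.random.default_rng(3)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        b = list(a)
        for i in rng.choice(500, size=50, replace=False):
            b[i] = "ACGT"[(("ACGT".index(b[i])) + 1) % 4]
        db = svs.cluster_sequences({"a": a, "b": "".join(b)})
        assert len(db.representatives) == 2

    def test_simulated_families_collapse_to_one_representative_each(self, elements):
        seqs, families = elements
        db = svs.cluster_sequences(seqs)
        assert len(db.representatives) == len(set(families.values()))
        for member, rep in db.cluster_map.items():
            assert families[member] == families[rep]

    def test_clustering_representatives_is_idempotent(self, elements):
        seqs, _ = elements
        db = svs.cluster_sequences(seqs)
        again = svs.cluster_sequences(dict(db.representatives))
        assert set(again.representatives) == set(db.representatives)

    def test_members_meet_identity_threshold_to_representative(self, elements):
        seqs, _ = elements
        db = svs.cluster_sequences(seqs)
        for member, rep in db.cluster_map.items():
            assert svs.pairwise_identity(seqs[member],
                                         db.representatives[rep]) >= 0.95

    def test_empty_input_gives_empty_db(self):
        db = svs.cluster_sequences({})
        assert db.representatives == {} and db.cluster_map == {}


@pytest.fixture(scope="module")
def db(elements):
    seqs, _ = elements
    return svs.cluster_sequences(seqs)


class TestClassifyClippedReads:
    def test_boundary_is_strictly_more_than_twenty(self, db, elements):
        seqs, _ = elements
        tail = seqs["tnpfam0_copy0"][100:160]
        for n, expected in ((20, False), (21, True)):
            cls = svs.classify_clipped_reads([tail] * n, db)
            assert cls.total == n and cls.flag is expected

    def test_locus_derived_tails_do_not_count(self, db, small_locus):
        tails = [small_locus.seq[i : i + 60] for i in range(0, 600, 20)]
        cls = svs.classify_clipped_reads(tails, db)
        assert cls.total == 0 and not cls.flag

    def test_tails_attribute_to_their_own_family(self, db, elements):
        seqs, families = elements
        tails = [seqs["tnpfam1_copy2"][i : i + 80] for i in range(0, 800, 40)]
        cls = svs.classify_clipped_reads(tails, db)
        assert cls.per_element
        modal = max(cls.per_element, key=cls.per_element.get)
        assert families[modal] == "tnpfam1"

    def test_empty_db_never_flags(self, elements):
        seqs, _ = elements
        cls = svs.classify_clipped_reads([seqs["tnpfam0_copy0"][:100]] * 30,
                                         svs.cluster_sequences({}))
        assert cls.total == 0 and not cls.flag


class TestAttachEvidence:
    def test_flagged_insertion_gains_modal_element(self, small_locus,
                                                   small_haplotypes, elements):
        seqs, families = elements
        db = svs.cluster_sequences(seqs)
        alns, _, svlist, _ = simulate_and_call(
            small_locus, small_haplotypes, "element_insertion", depth=50, seed=7)
        tails = [t for a in alns if a.mapped
                 for t in (a.left_clip_seq, a.right_clip_seq) if len(t) >= 10]
        tails += [a.seq for a in alns if not a.mapped]
        cls = svs.classify_clipped_reads(tails, db)
        assert cls.flag
        out = svs.attach_transposase_evidence(svlist, cls, db)
        (ins,) = [s for s in out if s.type == "insertion"]
        assert ins.transposase is not None
        element, count = ins.transposase
        assert families[element] == "tnpfam0" and count > 20

    def test_deletion_sv_keeps_empty_transposase(self, small_locus,
                                                 small_haplotypes, elements):
        seqs, _ = elements
        db = svs.cluster_sequences(seqs)
        alns, _, svlist, _ = simulate_and_call(
            small_locus, small_haplotypes, "large_deletion", depth=50, seed=8)
        tails = [t for a in alns if a.mapped
                 for t in (a.left_clip_seq, a.right_clip_seq) if len(t) >= 10]
        cls = svs.classify_clipped_reads(tails, db)
        assert not cls.flag  # locus-derived tails match nothing
        out = svs.attach_transposase_evidence(svlist, cls, db)
        assert all(s.transposase is None for s in out)
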