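"""QC cascade: exact Hardy-Weinberg test, ordered filters, merge and
concordance behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import localpanel as lp
from localpanel.panels import MISSING
from conftest import make_genotype_matrix
from oracles import hwe_enumeration_pvalue


class TestHweExactTest:
    def test_monomorphic_has_full_mass(self):
        assert lp.hwe_exact_test(100, 0, 0) == 1.0
        assert lp.hwe_exact_test(0, 0, 57) == 1.0

    def test_all_heterozygotes_matches_enumeration(self):
        p = lp.hwe_exact_test(0, 100, 0)
        assert p == pytest.approx(hwe_enumeration_pvalue(0, 100, 0),
                                  abs=1e-12)

    def test_hwe_proportional_counts_are_modal(self):
        p = lp.hwe_exact_test(25, 50, 25)
        assert p == pytest.approx(hwe_enumeration_pvalue(25, 50, 25),
                                  abs=1e-12)
        assert p > 0.5

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            lp.hwe_exact_test(-1, 2, 3)
        with pytest.raises(ValueError):
            lp.hwe_exact_test(0, 0, 0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
    def test_agrees_with_enumeration_oracle(self, aa, ab, bb):
        if aa + ab + bb == 0:
            return
        assert lp.hwe_exact_test(aa, ab, bb) == pytest.approx(
            hwe_enumeration_pvalue(aa, ab, bb), abs=1e-12)


def planted_sequence_fixture():
    """20 sites: 3 fail site QUAL, 2 fail call rate after masking, 1 fails
    the MAF filter (monomorphic after masking); 14 retained."""
    rng = np.random.default_rng(0)
    n, l = 10, 20
    calls = rng.integers(0, 3, size=(n, l)).astype(np.int8)
    # keep genotype counts HWE-friendly: resample from HWE at p=0.5
    calls = (rng.random((n, l)) < 0.5).astype(np.int8) \
        + (rng.random((n, l)) < 0.5).astype(np.int8)
    gq = np.full((n, l), 60.0)
    qual = np.full(l, 100.0)
    qual[[0, 5, 9]] = 39.0                      # 3 sites below QUAL 40
    # sites 1, 6: mask 6 of 10 calls -> call rate 0.4
    gq[:6, 1] = 10.0
    gq[:6, 6] = 10.0
    # site 2: monomorphic after masking its only carriers
    calls[:, 2] = 0
    calls[0, 2] = 1
    gq[0, 2] = 10.0
    return make_genotype_matrix(calls, gq=gq, site_qual=qual)


class TestSequenceQc:
    def test_planted_fixture_counts_at_each_stage(self):
        gm = planted_sequence_fixture()
        out, report = lp.apply_sequence_qc(gm)
        assert report.removed_at("site_qual").n_removed_sites == 3
        assert report.removed_at("call_rate").n_removed_sites == 2
        assert report.removed_at("maf").n_removed_sites == 1
        assert report.removed_at("hwe").n_removed_sites == 0
        assert out.n_sites == 14

    def test_clean_input_is_identity(self):
        rng = np.random.default_rng(1)
        calls = ((rng.random((20, 15)) < 0.4).astype(np.int8)
                 + (rng.random((20, 15)) < 0.4).astype(np.int8))
        gm = make_genotype_matrix(calls)
        out, report = lp.apply_sequence_qc(gm)
        assert out.n_sites == gm.n_sites
        assert np.array_equal(out.calls, gm.calls)

    def test_maf_threshold_implies_two_minor_alleles(self):
        # 99 diploid subjects: 0.75% of 198 alleles = 1.485 -> need >= 2
        n = 99
        base = np.zeros((n, 3), dtype=np.int8)
        one_minor = base.copy()
        one_minor[0, 0] = 1
        two_minor = base.copy()
        two_minor[0, 1] = 1
        two_minor[1, 1] = 1
        calls = np.concatenate([one_minor[:, :1], two_minor[:, 1:2],
                                base[:, 2:]], axis=1)
        # make third site clearly polymorphic so it survives
        calls[: n // 2, 2] = 1
        gm = make_genotype_matrix(calls)
        out, report = lp.apply_sequence_qc(gm)
        kept = set(out.sites.ids.tolist())
        assert "s0" not in kept      # single minor allele: MAF 1/198 < 0.75%
        assert "s1" in kept          # two minor alleles: MAF 2/198 >= 0.75%
        assert report.removed_at("maf").n_removed_sites == 1

    def test_hwe_filter_removes_excess_heterozygosity(self):
        n = 60
        calls = np.zeros((n, 2), dtype=np.int8)
        calls[:, 0] = 1                       # all heterozygous: HWE blows up
        calls[: n // 4, 1] = 2                # site 1 ~ HWE at p=0.5
        calls[n // 4: 3 * n // 4, 1] = 1
        gm = make_genotype_matrix(calls)
        out, report = lp.apply_sequence_qc(gm)
        assert report.removed_at("hwe").n_removed_sites == 1
        assert out.sites.ids.tolist() == ["s1"]

    def test_non_snv_and_multimapping_removed(self):
        rng = np.random.default_rng(2)
        calls = ((rng.random((30, 4)) < 0.5).astype(np.int8)
                 + (rng.random((30, 4)) < 0.5).astype(np.int8))
        gm = make_genotype_matrix(
            calls, alt=np.array(["C", "CT", "C", "C"], dtype=object),
            is_multimapping=[False, False, True, False])
        out, report = lp.apply_sequence_qc(gm)
        assert report.removed_at("multimapping").n_removed_sites == 1
        assert report.removed_at("snv_only").n_removed_sites == 1
        assert out.n_sites == 2

    def test_idempotent_on_own_output(self):
        gm = planted_sequence_fixture()
        once, _ = lp.apply_sequence_qc(gm)
        twice, rep = lp.apply_sequence_qc(once)
        assert twice.n_sites == once.n_sites
        assert np.array_equal(twice.calls, once.calls)
        assert all(s.n_removed_sites == 0 for s in rep.stages)

    def test_filters_never_alter_retained_calls(self):
        gm = planted_sequence_fixture()
        out, _ = lp.apply_sequence_qc(gm)
        idx = gm.sites.key_index()
        for j, key in enumerate(out.sites.keys()):
            src = idx[key]
            masked = (gm.gq[:, src] < 20)
            same = out.calls[:, j] == gm.calls[:, src]
            assert np.all(same | masked)
            assert np.all(out.calls[masked, j] == MISSING)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            lp.apply_sequence_qc(make_genotype_matrix(np.zeros((0, 0),
                                                               dtype=np.int8)))


class TestMergeArraySequence:
    def _pair(self, n=60, l=120, seed=0):
        rng = np.random.default_rng(seed)
        calls = ((rng.random((n, l)) < 0.4).astype(np.int8)
                 + (rng.random((n, l)) < 0.4).astype(np.int8))
        seq = make_genotype_matrix(calls.copy())
        arr = make_genotype_matrix(calls.copy())
        return arr, seq

    def test_identical_calls_full_concordance(self):
        arr, seq = self._pair()
        merged, report = lp.merge_array_sequence(arr, seq)
        assert report.concordance["overall_pct"] == 100.0
        assert report.removed_at("merge_subject_mismatch").n_removed_subjects == 0
        assert report.removed_at("merge_variant_mismatch").n_removed_sites == 0
        assert merged.n_subjects == arr.n_subjects

    def test_threshold_straddling_exclusions(self):
        arr, seq = self._pair()
        flip = lambda c: ((c + 1) % 3).astype(np.int8)
        # subject 0: 51 mismatches (over threshold), subject 1: exactly 50
        arr.calls[0, :51] = flip(seq.calls[0, :51])
        arr.calls[1, 51:101] = flip(seq.calls[1, 51:101])
        # variant 110: 31 mismatches (over), variant 111: exactly 30
        arr.calls[2:33, 110] = flip(seq.calls[2:33, 110])
        arr.calls[2:32, 111] = flip(seq.calls[2:32, 111])
        merged, report = lp.merge_array_sequence(arr, seq)
        assert report.removed_at("merge_subject_mismatch").n_removed_subjects == 1
        assert "S000" not in merged.subjects.tolist()
        assert "S001" in merged.subjects.tolist()
        assert report.removed_at("merge_variant_mismatch").n_removed_sites == 1
        kept = set(merged.sites.ids.tolist())
        assert "s110" not in kept and "s111" in kept

    def test_overall_concordance_arithmetic(self):
        arr, seq = self._pair(n=50, l=120)  # 6000 overlapping calls
        flips = [(0, 3), (7, 20), (11, 40), (23, 60), (31, 80), (44, 100)]
        for i, j in flips:
            arr.calls[i, j] = (seq.calls[i, j] + 1) % 3
        _, report = lp.merge_array_sequence(arr, seq)
        assert report.concordance["n_compared_calls"] == 6000
        assert report.concordance["overall_pct"] == pytest.approx(99.9)

    def test_sequence_call_wins_at_overlap(self):
        arr, seq = self._pair(n=10, l=5)
        arr.calls[3, 2] = (seq.calls[3, 2] + 1) % 3
        merged, _ = lp.merge_array_sequence(arr, seq)
        j = merged.sites.ids.tolist().index("s2")
        assert merged.calls[3, j] == seq.calls[3, 2]

    def test_disjoint_subjects_rejected(self):
        arr, seq = self._pair(n=4, l=5)
        arr.subjects = np.array([f"X{i}" for i in range(4)], dtype=object)
        with pytest.raises(ValueError):
            lp.merge_array_sequence(arr, seq)


class TestPanelRestriction:
    def test_subset_with_matching_alleles_is_identity(self, tiny_truth):
        gm = tiny_truth.local_called_genotypes
        out, report = lp.restrict_to_global_panel(gm, tiny_truth.global_panel)
        assert out.n_sites == gm.n_sites
        assert report.removed_at("panel_absent").n_removed_sites == 0

    def test_absent_and_mismatched_sites_counted_separately(self):
        rng = np.random.default_rng(5)
        calls = ((rng.random((8, 100)) < 0.5).astype(np.int8))
        gm = make_genotype_matrix(calls)
        # panel covers sites 0..84; sites 80..84 with swapped ref/alt
        keep = gm.sites.take(np.arange(85))
        alleles = np.zeros((4, 85), dtype=np.int8)
        ref = keep.ref.copy()
        alt = keep.alt.copy()
        for j in range(80, 85):
            ref[j], alt[j] = alt[j], ref[j]
        sites = lp.SiteMap(chrom=keep.chrom, pos=keep.pos, ids=keep.ids,
                           ref=ref, alt=alt, cm=keep.cm,
                           is_exomic=keep.is_exomic, is_array=keep.is_array,
                           is_multimapping=keep.is_multimapping)
        panel = lp.HaplotypePanel(
            np.array([f"h{i}" for i in range(4)], dtype=object),
            np.array([f"P{i//2}" for i in range(4)], dtype=object),
            sites, alleles)
        out, report = lp.restrict_to_global_panel(gm, panel)
        assert out.n_sites == 80
        assert report.removed_at("panel_absent").n_removed_sites == 15
        assert report.removed_at("panel_allele_mismatch").n_removed_sites == 5


class TestSubjectCallRate:
    def test_boundary_at_eighty_percent(self):
        l = 100
        calls = np.ones((3, l), dtype=np.int8)
        calls[1, :21] = MISSING   # 79% call rate -> removed
        calls[2, :20] = MISSING   # exactly 80% -> retained
        gm = make_genotype_matrix(calls)
        out, report = lp.filter_subject_call_rate(gm)
        assert out.subjects.tolist() == ["S000", "S002"]
        assert report.removed_at("subject_call_rate").n_removed_subjects == 1

    def test_complete_subjects_untouched(self):
        calls = np.ones((4, 10), dtype=np.int8)
        gm = make_genotype_matrix(calls)
        out, _ = lp.filter_subject_call_rate(gm)
        assert out.n_subjects == 4
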