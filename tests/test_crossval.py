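"""Accuracy evaluation: leave-one-out panels, r^2, MAF binning, summary
statistics and grids."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import localpanel as lp
from localpanel.lshmm import LeaveOneOutViolation
from oracles import pearson_r2_formula


class TestLeaveOneOut:
    def test_removes_exactly_one_subject(self, tiny_truth):
        local = tiny_truth.local_truth
        s = local.subjects[3]
        loo = lp.leave_one_out_panel(local, s)
        assert loo.n_haps == local.n_haps - 2
        assert s not in loo.subjects

    def test_remove_and_readd_roundtrips(self, tiny_truth):
        local = tiny_truth.local_truth
        s = local.subjects[0]
        rows = local.haps_of(s)
        removed = lp.HaplotypePanel(local.hap_ids[rows],
                                    local.subject_ids[rows], local.sites,
                                    local.alleles[rows])
        loo = lp.leave_one_out_panel(local, s)
        rebuilt = lp.HaplotypePanel.concatenate(loo, removed)
        # order-insensitive equality
        orig = {h: local.alleles[i].tobytes()
                for i, h in enumerate(local.hap_ids)}
        new = {h: rebuilt.alleles[i].tobytes()
               for i, h in enumerate(rebuilt.hap_ids)}
        assert orig == new

    def test_unknown_subject_rejected(self, tiny_truth):
        with pytest.raises(KeyError):
            lp.leave_one_out_panel(tiny_truth.local_truth, "nobody")

    def test_panel_size_arithmetic_for_91_subjects(self):
        rng = np.random.default_rng(0)
        l = 10
        alleles = rng.integers(0, 2, size=(182, l)).astype(np.int8)
        sites = lp.SiteMap(
            chrom=np.full(l, "1", dtype=object), pos=np.arange(1, l + 1),
            ids=np.array([f"v{i}" for i in range(l)], dtype=object),
            ref=np.full(l, "A", dtype=object), alt=np.full(l, "T", dtype=object),
            cm=np.linspace(0, 0.01, l), is_exomic=np.ones(l, dtype=bool),
            is_array=np.zeros(l, dtype=bool),
            is_multimapping=np.zeros(l, dtype=bool))
        hap_ids = np.array([f"S{i//2:03d}_{'AB'[i%2]}" for i in range(182)],
                           dtype=object)
        subj = np.array([f"S{i//2:03d}" for i in range(182)], dtype=object)
        panel = lp.HaplotypePanel(hap_ids, subj, sites, alleles)
        assert lp.leave_one_out_panel(panel, "S000").n_haps == 180


class TestSnpR2:
    def test_perfect_and_anticorrelated_dosages(self):
        truth = np.array([0, 1, 2, 1, 0])
        assert lp.snp_r2(truth.astype(float), truth) == pytest.approx(1.0)
        assert lp.snp_r2(2.0 - truth, truth) == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        truth = np.array([0, 1, 2, 1])
        dosage = np.array([0.1, 0.9, 1.7, 1.3])
        assert lp.snp_r2(dosage, truth) == pytest.approx(
            pearson_r2_formula(dosage, truth), abs=1e-12)

    def test_undefined_cases(self):
        assert lp.snp_r2(np.array([1.0, 1.0]), np.array([0, 1])) is None
        assert lp.snp_r2(np.array([0.5, 1.0]), np.array([1, 1])) is None
        assert lp.snp_r2(np.array([0.5]), np.array([1])) is None

    def test_missing_truth_dropped(self):
        truth = np.array([0, 1, 2, lp.MISSING])
        dosage = np.array([0.0, 1.0, 2.0, 1.0])
        assert lp.snp_r2(dosage, truth) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lp.snp_r2(np.zeros(3), np.zeros(4))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 2), min_size=3, max_size=20),
           st.floats(0.01, 1.0), st.floats(-0.5, 0.5))
    def test_affine_invariance(self, truth, scale, shift):
        truth = np.array(truth)
        if np.ptp(truth) == 0:
            return
        dosage = scale * truth + shift
        if np.ptp(dosage) == 0:
            return
        r2 = lp.snp_r2(dosage, truth)
        assert r2 == pytest.approx(1.0, abs=1e-9)


class TestMafBins:
    @pytest.mark.parametrize("maf,label", [
        (0.05, "3.2-10%"),
        (0.01, "1-3.2%"),
        (0.5, ">32%"),
        (10 ** -1.5, "3.2-10%"),
        (0.0999, "3.2-10%"),
        (0.1, "10-32%"),
        (0.32, ">32%"),
        (0.005, "<1%"),
    ])
    def test_bin_assignment(self, maf, label):
        assert lp.assign_maf_bin(maf) == label

    @pytest.mark.parametrize("maf", [0.0, 0.51, -0.1, 1.0])
    def test_out_of_range_rejected(self, maf):
        with pytest.raises(ValueError):
            lp.assign_maf_bin(maf)


def make_table(maf_local, maf_global, r2_one, r2_two):
    n = len(r2_one)
    return pd.DataFrame({
        "site_id": [f"v{i}" for i in range(n)],
        "pos": np.arange(1, n + 1),
        "maf_local": maf_local, "maf_global": maf_global,
        "r2_one_panel": r2_one, "r2_two_panel": r2_two,
        "n_subjects_used": 90,
    })


class TestSummaries:
    def test_single_record_bin(self):
        t = make_table([0.02], [0.02], [0.5], [0.7])
        s = lp.summarize_bins(t).set_index("bin")
        row = s.loc["1-3.2%"]
        assert row["n_snps"] == 1
        assert row["mean_increase"] == pytest.approx(0.2)
        assert np.isnan(row["sd_increase"])

    def test_se_matches_bootstrap_oracle(self):
        rng = np.random.default_rng(0)
        n = 1000
        inc = rng.normal(0.1, 0.05, n)
        r1 = np.full(n, 0.5)
        t = make_table(np.full(n, 0.02), np.full(n, 0.02), r1, r1 + inc)
        s = lp.summarize_bins(t).set_index("bin")
        se = s.loc["1-3.2%", "se_increase"]
        boots = [rng.choice(inc, n).mean() for _ in range(400)]
        boot_se = np.std(boots, ddof=1)
        assert abs(se - 0.05 / np.sqrt(n)) < 3 * boot_se

    def test_published_bin_means_give_printed_increase(self):
        # the published 1-3.2% bin means for the Adriatic-isolate cohort
        t = make_table([0.02], [0.02], [0.504], [0.697])
        s = lp.summarize_bins(t).set_index("bin")
        assert s.loc["1-3.2%", "mean_increase"] == pytest.approx(0.193)

    def test_undefined_records_excluded(self):
        t = make_table([0.02, 0.02], [0.02, 0.02], [0.5, np.nan], [0.7, np.nan])
        s = lp.summarize_bins(t).set_index("bin")
        assert s.loc["1-3.2%", "n_snps"] == 1

    def test_global_band_stratification(self):
        t = make_table([0.02] * 3, [0.005, 0.02, 0.2],
                       [0.3, 0.5, 0.8], [0.8, 0.7, 0.9])
        s = lp.summarize_bins(t, bin_by="global").set_index("bin")
        assert s.loc["<1%", "mean_increase"] == pytest.approx(0.5)
        assert s.loc["1-3.2%", "mean_increase"] == pytest.approx(0.2)
        assert s.loc[">3.2%", "mean_increase"] == pytest.approx(0.1)


class TestEssIncrease:
    def test_published_cells(self):
        assert round(lp.ess_increase(0.504, 0.697)) == 38
        assert round(lp.ess_increase(0.586, 0.753)) == 28

    def test_identity_is_zero(self):
        assert lp.ess_increase(0.42, 0.42) == 0.0

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            lp.ess_increase(0.0, 0.5)


class TestCrosstab:
    def test_all_perfect(self):
        t = make_table([0.02] * 4, [0.02] * 4, [1.0] * 4, [1.0] * 4)
        frac, rescued = lp.poor_to_well_crosstab(t)
        assert frac == 0.0 and rescued is None

    def test_fixture_fractions(self):
        r1 = np.full(100, 0.5)
        r1[:10] = 0.1                 # 10 poor SNPs
        r2 = np.full(100, 0.9)
        r2[:8] = 0.5                  # 2 of the poor ones rescued above 0.8
        t = make_table(np.full(100, 0.02), np.full(100, 0.02), r1, r2)
        frac, rescued = lp.poor_to_well_crosstab(t)
        assert frac == pytest.approx(0.10)
        assert rescued == pytest.approx(0.20)

    def test_equal_thresholds_rejected(self):
        t = make_table([0.02], [0.02], [0.5], [0.7])
        with pytest.raises(ValueError):
            lp.poor_to_well_crosstab(t, poor=0.5, well=0.5)


class TestImprovementGrid:
    def test_single_cell_equals_overall_mean(self):
        t = make_table([0.02] * 5, [0.02] * 5,
                       [0.4, 0.5, 0.6, 0.3, 0.2],
                       [0.6, 0.6, 0.9, 0.5, 0.4])
        means, counts = lp.improvement_grid(t)
        assert counts.loc["1-3.16%", "1-3.16%"] == 5
        assert means.loc["1-3.16%", "1-3.16%"] == pytest.approx(
            np.mean([0.2, 0.1, 0.3, 0.2, 0.2]))
        assert counts.to_numpy().sum() == 5

    def test_planted_ordering_recovered(self):
        # cells where the variant is rarer globally than locally improve more
        maf_local = np.array([0.05] * 40)
        maf_global = np.array([0.005] * 20 + [0.2] * 20)
        inc = np.where(maf_global < maf_local, 0.4, 0.05)
        r1 = np.full(40, 0.3)
        t = make_table(maf_local, maf_global, r1, r1 + inc)
        means, counts = lp.improvement_grid(t)
        row = means.loc["3.16-10%"]
        assert row["<1%"] > row["10-50%"]

    def test_empty_cells_have_no_mean(self):
        t = make_table([0.02], [0.02], [0.5], [0.7])
        means, counts = lp.improvement_grid(t)
        assert (counts.to_numpy() == 0).sum() == counts.size - 1
        assert np.isnan(means.to_numpy()).sum() == means.size - 1


class TestRunCrossval:
    def test_records_and_guards(self, tiny_truth):
        table = lp.run_crossval(tiny_truth)
        assert len(table) > 0
        defined = table.dropna(subset=["r2_one_panel", "r2_two_panel"])
        assert ((defined["r2_one_panel"] >= 0)
                & (defined["r2_one_panel"] <= 1)).all()
        assert ((defined["r2_two_panel"] >= 0)
                & (defined["r2_two_panel"] <= 1)).all()
        assert (defined["n_subjects_used"] >= 2).all()

    def test_monomorphic_targets_flagged_undefined(self, tiny_truth):
        table = lp.run_crossval(tiny_truth)
        truth_gm = tiny_truth.local_truth.to_genotypes()
        idx = {i: j for j, i in enumerate(tiny_truth.site_map.ids)}
        mono = [row.site_id for row in table.itertuples()
                if np.ptp(truth_gm.calls[:, idx[row.site_id]]) == 0]
        if mono:
            sub = table.set_index("site_id").loc[mono]
            assert sub["r2_one_panel"].isna().all()

    def test_too_few_subjects_rejected(self, tiny_truth):
        small = tiny_truth.local_truth
        keep = np.isin(small.subject_ids, small.subjects[:2])
        panel2 = lp.HaplotypePanel(small.hap_ids[keep],
                                   small.subject_ids[keep], small.sites,
                                   small.alleles[keep])
        with pytest.raises(ValueError):
            lp.run_crossval(tiny_truth, local_panel=panel2)
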