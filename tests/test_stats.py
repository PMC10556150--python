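"""Group inference: t-tests (raw and from summaries), Levene, Pearson,
BH-FDR, block contrasts."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dfnckit import (
    NetworkPartition,
    WindowedFNCSeries,
    fdr_bh,
    levene_test,
    pearson_corr,
    run_group_analysis,
    state_block_connectivity,
    two_sample_t,
)


class TestTwoSampleT:
    def test_published_state1_dwell_summaries(self):
        # printed group summaries reproduce t(105) = 3.244
        res = two_sample_t((50, 89.040, 59.216), (57, 57.491, 40.671), "pooled")
        assert res.df == 105
        assert res.statistic == pytest.approx(3.244, abs=5e-4)
        assert res.pvalue == pytest.approx(0.002, abs=5e-4)

    def test_published_state4_dwell_summaries(self):
        res = two_sample_t((50, 31.300, 39.413), (57, 66.438, 45.734), "pooled")
        assert res.df == 105
        assert res.statistic == pytest.approx(-4.227, abs=5e-4)
        assert res.pvalue < 0.001

    def test_identical_summaries_null(self):
        res = two_sample_t((10, 5.0, 2.0), (12, 5.0, 2.0), "pooled")
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_summary_equals_raw(self, rng):
        x = rng.standard_normal(14) * 2 + 1
        y = rng.standard_normal(19) * 3
        raw = two_sample_t(x, y, "pooled")
        summ = two_sample_t(
            (x.size, x.mean(), x.std(ddof=1)), (y.size, y.mean(), y.std(ddof=1)),
            "pooled",
        )
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-9)
        assert raw.pvalue == pytest.approx(summ.pvalue, abs=1e-9)

    def test_welch_df_below_pooled_under_unequal_variance(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(30) * 5
        assert two_sample_t(x, y, "welch").df < two_sample_t(x, y, "pooled").df

    def test_degenerate_equal_constants_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            two_sample_t((5, 1.0, 0.0), (5, 1.0, 0.0))

    def test_type_one_error_calibrated(self, rng):
        # pooled t at nominal 0.05 under the Gaussian equal-variance null
        from scipy import stats as sps

        sims = 10_000
        x = rng.standard_normal((sims, 25))
        y = rng.standard_normal((sims, 25))
        _, p = sps.ttest_ind(x, y, axis=1)
        rate = float(np.mean(p < 0.05))
        assert 0.04 <= rate <= 0.06


class TestLevene:
    def test_identical_samples_zero_statistic(self, rng):
        x = rng.standard_normal(30)
        assert levene_test(x, x.copy()).statistic == pytest.approx(0.0, abs=1e-12)

    def test_scaled_group_detected(self, rng):
        x = rng.standard_normal(50)
        res = levene_test(x, 10 * rng.standard_normal(50))
        assert res.pvalue < 1e-6

    def test_null_pvalues_roughly_uniform(self, rng):
        # calibration: Kolmogorov distance of null p-values to U(0,1)
        from scipy import stats as sps

        pvals = [
            levene_test(rng.standard_normal(30), rng.standard_normal(30)).pvalue
            for _ in range(2000)
        ]
        d = sps.kstest(pvals, "uniform").statistic
        assert d < 0.05


class TestPearson:
    def test_perfect_positive_and_negative(self, rng):
        x = rng.standard_normal(20)
        assert pearson_corr(x, x).statistic == pytest.approx(1.0)
        assert pearson_corr(x, -2 * x + 3).statistic == pytest.approx(-1.0)

    def test_rowwise_deletion_of_nonfinite_pairs(self, rng):
        x = rng.standard_normal(50)
        y = 0.5 * x + 0.1 * rng.standard_normal(50)
        x_nan = x.copy()
        x_nan[::7] = np.nan
        res = pearson_corr(x_nan, y)
        keep = np.isfinite(x_nan)
        assert res.n1 == int(keep.sum())
        expected = np.corrcoef(x[keep], y[keep])[0, 1]
        assert res.statistic == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFdrBH:
    def test_exchangeable_ties(self):
        p_adj, reject = fdr_bh([0.01] * 10, q=0.05)
        np.testing.assert_allclose(p_adj, 0.01)
        assert reject.all()

    def test_hand_step_up(self):
        p_adj, reject = fdr_bh([0.01, 0.02, 0.9], q=0.05)
        np.testing.assert_allclose(p_adj, [0.03, 0.03, 0.9])
        assert reject.tolist() == [True, True, False]

    def test_single_pvalue_unchanged(self):
        p_adj, _ = fdr_bh([0.2])
        assert p_adj[0] == pytest.approx(0.2)

    def test_adjusted_monotone_in_raw_order(self, rng):
        p = rng.uniform(size=40)
        p_adj, _ = fdr_bh(p)
        order = np.argsort(p)
        assert (np.diff(p_adj[order]) >= -1e-12).all()


class TestBlockConnectivity:
    PART = NetworkPartition(sizes=(2, 2, 2))

    def make_series(self, data):
        return WindowedFNCSeries(
            subject_id="s", data=data, window_starts=np.arange(len(data)),
            lambda_used=0.1, partition=self.PART,
        )

    def test_constant_field_gives_constant_blocks(self):
        s = self.make_series(np.full((6, 15), 0.7))
        blocks = state_block_connectivity(s, np.ones(6, dtype=int), state=1)
        assert all(v == pytest.approx(0.7) for v in blocks.values())

    def test_indicator_block_structure(self):
        nets = self.PART.component_networks
        iu, ju = np.triu_indices(6, 1)
        vec = np.where((nets[iu] == "DMN") & (nets[ju] == "DMN"), 0.5, 0.0)
        s = self.make_series(np.tile(vec, (4, 1)))
        blocks = state_block_connectivity(s, np.ones(4, dtype=int), state=1)
        assert blocks["DMN-DMN"] == pytest.approx(0.5)
        assert all(
            blocks[k] == pytest.approx(0.0) for k in blocks if k != "DMN-DMN"
        )

    def test_matches_masked_average_oracle(self, rng):
        data = rng.standard_normal((10, 15))
        labels = rng.integers(1, 3, size=10)
        s = self.make_series(data)
        blocks = state_block_connectivity(s, labels, state=1)
        nets = self.PART.component_networks
        iu, ju = np.triu_indices(6, 1)
        mean_vec = data[labels == 1].mean(axis=0)
        for name, val in blocks.items():
            a, b = name.split("-")
            mask = ((nets[iu] == a) & (nets[ju] == b)) | (
                (nets[iu] == b) & (nets[ju] == a)
            )
            assert val == pytest.approx(mean_vec[mask].mean())

    def test_absent_subject_returns_none(self, rng):
        s = self.make_series(rng.standard_normal((5, 15)))
        assert state_block_connectivity(s, np.ones(5, dtype=int), state=2) is None


class TestRunGroupAnalysis:
    @staticmethod
    def build_tables(rng, shift=6.0, n_per=30):
        rows = []
        clin = []
        for i in range(2 * n_per):
            group = "CD" if i < n_per else "HC"
            dwell1 = rng.normal(10 + (shift if group == "CD" else 0), 3)
            rows.append({
                "subject_id": f"s{i}", "group": group,
                "dwell_s1": dwell1, "dwell_s2": rng.normal(8, 2),
                "frac_s1": rng.uniform(0.2, 0.8), "frac_s2": rng.uniform(0.2, 0.8),
                "n_transitions": rng.poisson(6),
            })
            clin.append({
                "subject_id": f"s{i}", "group": group,
                "moca": 26 - 0.3 * dwell1 + rng.normal(0, 1),
            })
        return pd.DataFrame(rows), pd.DataFrame(clin)

    def test_planted_effect_detected_with_positive_direction(self, rng):
        profiles, clinical = self.build_tables(rng)
        res = run_group_analysis(profiles, clinical, n_states=2,
                                 correlation_states=(1,))
        row = res[(res.analysis == "dwell_and_transitions")
                  & (res.variable == "dwell_s1")].iloc[0]
        assert row.statistic > 0 and row.reject

    def test_correlation_row_present_and_negative(self, rng):
        profiles, clinical = self.build_tables(rng)
        res = run_group_analysis(profiles, clinical, n_states=2,
                                 correlation_states=(1,))
        row = res[res.analysis == "correlation_dwell_s1"].iloc[0]
        assert row.variable == "moca" and row.statistic < 0

    def test_patient_scope_restricts_n(self, rng):
        profiles, clinical = self.build_tables(rng, n_per=25)
        res = run_group_analysis(
            profiles, clinical, n_states=2, correlation_states=(1,),
            correlation_columns={"moca": "patients"},
        )
        row = res[res.analysis == "correlation_dwell_s1"].iloc[0]
        assert row.n1 == 25

    def test_orphan_subjects_rejected(self, rng):
        profiles, clinical = self.build_tables(rng, n_per=5)
        clinical = clinical.iloc[:-1]
        with pytest.raises(ValueError, match="mismatch"):
            run_group_analysis(profiles, clinical, n_states=2)

    def test_null_cohort_family_rejection_rate_near_q(self, rng):
        # with identical groups the FDR battery should reject at ~q per family
        hits = 0
        trials = 300
        for _ in range(trials):
            profiles, clinical = self.build_tables(rng, shift=0.0, n_per=15)
            res = run_group_analysis(profiles, clinical, n_states=2,
                                     correlation_states=())
            fam = res[res.analysis == "dwell_and_transitions"]
            hits += int(fam.reject.any())
        rate = hits / trials
        assert rate < 0.12  # FDR controls family error at q = 0.05
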