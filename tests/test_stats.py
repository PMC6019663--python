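"""Correlation, ICC, exact proportion intervals and the study report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from diamotion import (
    CohortSpec,
    clopper_pearson,
    icc_oneway,
    simulate_cohort,
    spearman_ci,
    split_by_mean,
    study_report,
)


class TestSpearmanCI:
    def test_monotone_pair_gives_one(self):
        x = np.arange(10.0)
        r = spearman_ci(x, np.exp(x))
        assert r.r_s == pytest.approx(1.0)

    def test_reversed_pair_gives_minus_one(self):
        x = np.arange(10.0)
        assert spearman_ci(x, -x).r_s == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # ranks d = (-1, 1, -1, 1, 0): sum d^2 = 4 -> 1 - 24/120 = 0.8
        r = spearman_ci([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r.r_s == pytest.approx(0.8)
        # exact permutation p: share of the 120 pairings at least as extreme
        assert 0 < r.p < 1

    def test_exact_p_matches_enumeration_count(self):
        # perfect concordance at n=5: only 2 of 5! = 120 permutations reach |1|
        r = spearman_ci([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert r.p == pytest.approx(2 / 120)

    def test_ci_contains_estimate_and_stays_in_range(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        r = spearman_ci(x, y)
        assert -1 <= r.ci_low <= r.r_s <= r.ci_high <= 1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_ci([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 9999))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = spearman_ci(x, y)
        trans = spearman_ci(np.exp(x), y**3)
        assert trans.r_s == pytest.approx(base.r_s)
        assert trans.p == pytest.approx(base.p)


class TestSplitByMean:
    @staticmethod
    def _table(values, volumes):
        return pd.DataFrame(
            {"method": "area", "value": values, "units": "cm2",
             "volume_l": volumes}
        )

    def test_symmetric_data_splits_evenly(self):
        vol = np.arange(1.0, 9.0)
        sp = split_by_mean(self._table(vol * 10, vol), "area")
        assert sp.low.n == sp.high.n == 4
        assert sp.mean_cut == pytest.approx(vol.mean())

    def test_noise_free_monotone_both_strata_perfect(self):
        vol = np.linspace(0.5, 6.0, 12)
        sp = split_by_mean(self._table(vol**2, vol), "area")
        assert sp.low.r_s == pytest.approx(1.0)
        assert sp.high.r_s == pytest.approx(1.0)

    def test_small_stratum_rejected_by_name(self):
        vol = np.array([1.0, 1.1, 1.2, 1.3, 1.4, 9.0])
        with pytest.raises(ValueError, match="high stratum"):
            split_by_mean(self._table(vol, vol), "area")


class TestICCOneWay:
    def test_identical_raters_give_exactly_one(self):
        m = np.tile(np.arange(10.0)[:, None], (1, 2))
        res = icc_oneway(m)
        assert res.icc == 1.0
        assert res.p == 0.0

    @pytest.mark.parametrize("ratio", [0.5, 0.8, 0.9])
    def test_recovers_variance_ratio(self, ratio):
        """ICC(1,1) estimates σb²/(σb²+σw²) on simulated targets."""
        rng = np.random.default_rng(42)
        n, k = 2000, 2
        sigma_b = np.sqrt(ratio)
        sigma_w = np.sqrt(1 - ratio)
        targets = rng.normal(0, sigma_b, n)[:, None]
        m = targets + rng.normal(0, sigma_w, (n, k))
        assert icc_oneway(m).icc == pytest.approx(ratio, abs=0.02)

    def test_independent_raters_give_near_zero(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(3000, 2))
        assert abs(icc_oneway(m).icc) < 0.05

    def test_agrees_with_pingouin(self):
        """Independent oracle: pingouin's ICC1 on a small rating set."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        m = rng.normal(0, 3, 20)[:, None] + rng.normal(0, 1, (20, 2))
        ours = icc_oneway(m)
        long = pd.DataFrame(
            {
                "target": np.repeat(np.arange(20), 2),
                "rater": np.tile(["a", "b"], 20),
                "score": m.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="target", raters="rater", ratings="score"
        )
        icc1 = ref.loc[ref["Type"].isin(["ICC1", "ICC(1,1)"]), "ICC"].iloc[0]
        assert ours.icc == pytest.approx(icc1, abs=1e-9)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            icc_oneway(np.full((6, 2), 3.0))


class TestClopperPearson:
    @pytest.mark.parametrize(
        "k,n,lo,hi",
        [
            (2, 10, 0.03, 0.56),
            (8, 10, 0.44, 0.97),
            (10, 10, 0.69, 1.00),
            (1, 10, 0.00, 0.45),
        ],
    )
    def test_two_decimal_bounds(self, k, n, lo, hi):
        ci = clopper_pearson(k, n)
        assert round(ci.ci_low, 2) == lo
        assert round(ci.ci_high, 2) == hi

    def test_boundary_counts(self):
        assert clopper_pearson(0, 7).ci_low == 0.0
        assert clopper_pearson(7, 7).ci_high == 1.0
        # closed form for k = n: lower bound = (α/2)^(1/n)
        assert clopper_pearson(10, 10).ci_low == pytest.approx(0.025 ** 0.1)

    def test_no_trials_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(0, 0)

    def test_coverage_at_nominal_level(self):
        """Exact interval covers the true p in ≥ 95% of simulated binomials."""
        rng = np.random.default_rng(0)
        n = 10
        for p in np.arange(0.1, 0.95, 0.1):
            ks = rng.binomial(n, p, size=5000)
            covered = np.fromiter(
                (
                    clopper_pearson(int(k), n).ci_low <= p <= clopper_pearson(int(k), n).ci_high
                    for k in np.unique(ks)
                ),
                dtype=bool,
            )
            # aggregate coverage over the sampled k values
            unique, counts = np.unique(ks, return_counts=True)
            coverage = counts[covered].sum() / counts.sum()
            assert coverage >= 0.95


class TestStudyReport:
    @pytest.fixture(scope="class")
    def cohort(self):
        return simulate_cohort(CohortSpec(n_subjects=8, n_breaths=3, seed=9))

    def test_report_sections_and_files(self, cohort, tmp_path):
        report = study_report(
            cohort.table,
            cohort.ratings,
            proportions=[("mmode left", 2, 10)],
            out_dir=tmp_path,
        )
        assert set(report.summary["method"]) == {"area", "bmode", "mmode"}
        assert len(report.icc) == 3
        assert (tmp_path / "report.txt").exists()
        assert (tmp_path / "correlations.csv").exists()
        assert "Feasibility proportions" in report.text

    def test_empty_ratings_section_omitted(self, cohort):
        report = study_report(cohort.table, ratings=None)
        assert report.icc.empty
        assert "ICC" not in report.text

    def test_summary_against_streaming_oracle(self, cohort):
        """Mean/SD cross-checked against an independent Welford pass."""
        report = study_report(cohort.table)
        for _, row in report.summary.iterrows():
            values = cohort.table.loc[
                cohort.table["method"] == row["method"], "value"
            ].to_numpy()
            mean = m2 = 0.0
            for i, v in enumerate(values, 1):
                d = v - mean
                mean += d / i
                m2 += d * (v - mean)
            sd = np.sqrt(m2 / (len(values) - 1))
            assert row["mean"] == pytest.approx(mean)
            assert row["sd"] == pytest.approx(sd)

    def test_seeded_report_deterministic(self, cohort, tmp_path):
        r1 = study_report(cohort.table)
        again = simulate_cohort(CohortSpec(n_subjects=8, n_breaths=3, seed=9))
        r2 = study_report(again.table)
        assert r1.text == r2.text
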