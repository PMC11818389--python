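"""Tests of the cohort-analysis stage: exclusions, Little's MCAR test,
imputation and the paired duration comparison."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rflesion.cohort import (
    ExclusionConfig,
    apply_exclusions,
    compare_durations,
    impute_durations,
    little_mcar_test,
    summarize_cohort,
)
from rflesion.synthetic import MissingnessSpec, inject_missingness


def lesion_fixture(n=100, n_dur_bad=0, n_ild_bad=0, n_overlap=0, seed=0):
    """A lesion table with a controlled number of exclusion violations."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "duration_li_s": rng.uniform(5, 25, n),
        "duration_ai_s": rng.uniform(4, 10, n),
        "duration_lsi_s": rng.uniform(14, 28, n),
        "ild_mm": rng.uniform(2, 5.5, n),
        "cf_mean_g": rng.uniform(8, 30, n),
        "cf_start_g": rng.uniform(8, 30, n),
        "li_drop_ohm": rng.uniform(10, 35, n),
        "li_start_ohm": rng.uniform(130, 165, n),
    })
    # n_dur_bad / n_ild_bad are per-rule totals; n_overlap rows violate both
    idx = rng.permutation(n)
    dur_idx = idx[:n_dur_bad]
    ild_idx = idx[n_dur_bad - n_overlap:n_dur_bad - n_overlap + n_ild_bad]
    df.loc[dur_idx, "duration_li_s"] = 31.0
    df.loc[ild_idx, "ild_mm"] = 7.0
    return df


class TestExclusions:
    def test_all_compliant_retained(self):
        df = lesion_fixture(50)
        kept, log = apply_exclusions(df)
        assert len(kept) == 50
        assert log.n_excluded == 0

    def test_boundary_values_retained(self):
        df = lesion_fixture(5)
        df.loc[0, "duration_li_s"] = 30.0
        df.loc[1, "ild_mm"] = 6.0
        kept, log = apply_exclusions(df)
        assert len(kept) == 5  # 'over' is strict

    def test_constructed_violation_bookkeeping(self):
        df = lesion_fixture(100, n_dur_bad=8, n_ild_bad=6, n_overlap=1, seed=3)
        kept, log = apply_exclusions(df)
        assert len(kept) == 87
        assert log.n_duration_violations == 8
        assert log.n_ild_violations == 6
        assert log.n_overlap == 1
        assert log.n_excluded == 13
        assert log.fraction_excluded == pytest.approx(0.13)

    def test_idempotent_and_commutative(self):
        df = lesion_fixture(60, n_dur_bad=5, n_ild_bad=4, seed=7)
        once, _ = apply_exclusions(df)
        twice, log2 = apply_exclusions(once)
        pd.testing.assert_frame_equal(once, twice)
        assert log2.n_excluded == 0
        # filters commute: applying one rule then the other gives the same set
        only_dur, _ = apply_exclusions(df, ExclusionConfig(max_ild_mm=1e9))
        both_a, _ = apply_exclusions(only_dur, ExclusionConfig(max_duration_s=1e9))
        assert set(both_a.index) == set(once.index)

    def test_missing_ild_not_excluded(self):
        df = lesion_fixture(10)
        df.loc[0, "ild_mm"] = np.nan
        kept, _ = apply_exclusions(df)
        assert 0 in kept.index


class TestLittleMCAR:
    def test_single_pattern_undefined(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [4.0, 5, 6]})
        with pytest.raises(ValueError, match="pattern"):
            little_mcar_test(df)

    def test_null_rejection_rate_near_alpha(self):
        """Under MCAR the test rejects at about the nominal level."""
        rej, reps = 0, 200
        cov = np.array([[1, .5, .2], [.5, 1, .3], [.2, .3, 1]])
        for r in range(reps):
            rng = np.random.default_rng(r)
            df = pd.DataFrame(rng.multivariate_normal([0, 0, 0], cov, 500),
                              columns=list("abc"))
            df.loc[rng.uniform(size=500) < 0.2, "c"] = np.nan
            rej += little_mcar_test(df).p_value < 0.05
        assert 0.03 <= rej / reps <= 0.08

    def test_strong_mar_detected(self):
        rej, reps = 0, 40
        for r in range(reps):
            rng = np.random.default_rng(500 + r)
            a = rng.normal(0, 1, 500)
            df = pd.DataFrame({"a": a, "c": 2 * a + rng.normal(0, 1, 500)})
            p_del = 0.4 / (1 + np.exp(-2 * a))
            df.loc[rng.uniform(size=500) < p_del, "c"] = np.nan
            rej += little_mcar_test(df).p_value < 0.05
        assert rej / reps > 0.8


class TestImputation:
    def mar_fixture(self, n=300, seed=0, rate=0.2):
        rng = np.random.default_rng(seed)
        driver = rng.normal(18, 5, n)
        df = pd.DataFrame({
            "duration_li_s": rng.normal(12, 3, n),
            "duration_ai_s": rng.normal(7, 1.5, n),
            "cf_mean_g": driver,
            "cf_start_g": driver + rng.normal(0, 1, n),
            "li_drop_ohm": rng.normal(20, 5, n),
            "li_start_ohm": rng.normal(147, 8, n),
            "duration_lsi_s": 2.0 * driver + rng.normal(0, 2, n),
        })
        truth = df["duration_lsi_s"].copy()
        missing, mask = inject_missingness(
            df, MissingnessSpec("MAR", rate, "cf_mean_g", seed=seed + 1))
        return missing, mask, truth

    def test_no_missing_is_identity(self):
        df, _, _ = self.mar_fixture(rate=0.0)
        rep = impute_durations(df, run_mcar_test=False)
        pd.testing.assert_frame_equal(rep.table, df)
        assert rep.n_missing == 0
        assert (rep.agreement["discrepancy_mae"] == 0).all()

    def test_chained_equations_beats_mean_on_mar(self):
        df, mask, truth = self.mar_fixture(seed=5)
        rep = impute_durations(df, seed=5, run_mcar_test=False)
        cells = mask.to_numpy()
        t = truth[cells].to_numpy()
        r_mice = np.corrcoef(rep.completed["mice"].loc[cells, "duration_lsi_s"], t)[0, 1]
        r_mean = np.corrcoef(rep.completed["mean"].loc[cells, "duration_lsi_s"], t)[0, 1] \
            if rep.completed["mean"].loc[cells, "duration_lsi_s"].std() > 0 else 0.0
        assert r_mice > 0.5
        assert r_mice > r_mean

    def test_observed_cells_never_altered(self):
        df, mask, _ = self.mar_fixture(seed=2)
        rep = impute_durations(df, seed=2, run_mcar_test=False)
        kept = ~mask
        for m, completed in rep.completed.items():
            assert np.allclose(completed.loc[kept, "duration_lsi_s"],
                               df.loc[kept, "duration_lsi_s"])

    def test_iteration_count_stability(self):
        df, _, _ = self.mar_fixture(seed=9)
        meds = []
        for it in (5, 10, 15):
            rep = impute_durations(df, iterations=it, seed=9, run_mcar_test=False)
            meds.append(rep.table["duration_lsi_s"].median())
        spread = (max(meds) - min(meds)) / abs(np.mean(meds))
        assert spread < 0.05

    def test_all_missing_rejected(self):
        df, _, _ = self.mar_fixture()
        df["duration_lsi_s"] = np.nan
        with pytest.raises(ValueError, match="entirely missing"):
            impute_durations(df)


def friedman_oracle(data: np.ndarray) -> float:
    """Hand-computed Friedman chi-square (no ties): within-row ranks."""
    n, k = data.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    rbar = ranks.mean(axis=0)
    return 12 * n / (k * (k + 1)) * np.sum((rbar - (k + 1) / 2) ** 2)


def wilcoxon_oracle(d: np.ndarray) -> tuple[float, float]:
    """Exhaustive signed-rank enumeration: statistic min(W+, W-), exact
    two-sided p over all sign assignments."""
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_stat = min(w_plus, n * (n + 1) / 2 - w_plus)
    dist: dict[float, int] = {}
    for signs in itertools.product([False, True], repeat=n):
        w = ranks[np.array(signs)].sum()
        dist[w] = dist.get(w, 0) + 1
    total = 2**n
    p_le = sum(c for w, c in dist.items() if w <= w_plus) / total
    p_ge = sum(c for w, c in dist.items() if w >= w_plus) / total
    return w_stat, min(1.0, 2 * min(p_le, p_ge))


class TestCompareDurations:
    def test_identical_columns_degenerate(self):
        df = pd.DataFrame({c: [1.0, 2, 3, 4, 5] for c in
                           ("duration_ai_s", "duration_li_s", "duration_lsi_s")})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cc = compare_durations(df)
        assert cc.friedman_chi2 == 0.0
        assert cc.friedman_p == 1.0

    def test_small_table_matches_enumeration_oracles(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame({
            "duration_ai_s": rng.uniform(4, 10, 8),
            "duration_li_s": rng.uniform(8, 16, 8),
            "duration_lsi_s": rng.uniform(14, 25, 8),
        })
        cc = compare_durations(df)
        assert cc.friedman_chi2 == pytest.approx(
            friedman_oracle(df.to_numpy()), rel=1e-10)
        for pair_res in cc.pairwise:
            a, b = pair_res.pair
            w_or, p_or = wilcoxon_oracle(df[a].to_numpy() - df[b].to_numpy())
            assert pair_res.w_statistic == pytest.approx(w_or)
            assert pair_res.p_raw == pytest.approx(p_or, rel=1e-10)
            assert pair_res.p_bonferroni == pytest.approx(min(1.0, 3 * p_or))

    def test_effect_size_sign_follows_median_difference(self):
        rng = np.random.default_rng(23)
        n = 60
        ai = rng.uniform(4, 8, n)
        df = pd.DataFrame({
            "duration_ai_s": ai,
            "duration_li_s": ai + rng.uniform(1, 5, n),
            "duration_lsi_s": ai + rng.uniform(6, 14, n),
        })
        cc = compare_durations(df)
        for p in cc.pairwise:
            assert p.effect_size_r < 0  # first-listed is always the faster rule
            assert -1.0 <= p.effect_size_r <= 1.0

    def test_too_few_lesions_rejected(self):
        df = pd.DataFrame({c: [1.0, 2] for c in
                           ("duration_ai_s", "duration_li_s", "duration_lsi_s")})
        with pytest.raises(ValueError, match=">= 5"):
            compare_durations(df)


class TestSummarizeCohort:
    def test_five_point_column(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5]})
        s = summarize_cohort(df)
        assert s.loc["x", "median"] == 3
        assert s.loc["x", "q1"] == 2
        assert s.loc["x", "q3"] == 4

    def test_constant_column(self):
        df = pd.DataFrame({"x": [7.0] * 9})
        s = summarize_cohort(df)
        assert s.loc["x", "median"] == 7.0
        assert s.loc["x", "q3"] - s.loc["x", "q1"] == 0.0

    def test_deterministic_regeneration(self, midsize_lesions):
        a = summarize_cohort(midsize_lesions)
        b = summarize_cohort(midsize_lesions.copy())
        pd.testing.assert_frame_equal(a, b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort(pd.DataFrame())
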