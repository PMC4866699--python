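"""Nonparametric group-comparison pipeline."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from infodim import (
    cohens_u3,
    fdr_correct,
    fit_interaction,
    make_cohort,
    mann_whitney_two_tailed,
    read_fd_spreadsheet,
    shapiro_wilk,
    spearman_correlation,
    summarize_structures,
)


def exact_mw_two_tailed(a, b):
    """Enumeration oracle: exact two-tailed p over all label assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(b) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.asarray(us)
    return float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-9))


class TestMannWhitney:
    def test_identical_samples(self):
        with pytest.warns(UserWarning, match="identical"):
            u, p = mann_whitney_two_tailed([1.0] * 4, [1.0] * 4)
        assert u == 8.0 and p == 1.0

    def test_complete_separation_exact_p(self):
        u, p = mann_whitney_two_tailed([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)  # 2 of 6 rank assignments as extreme

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(3, 8))
        b = rng.normal(size=rng.integers(3, 8)) + 0.5
        _, p = mann_whitney_two_tailed(a, b)
        assert p == pytest.approx(exact_mw_two_tailed(a, b), abs=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_two_tailed([1.0], [2.0, 3.0])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_mann_whitney_duality(seed):
    """U(a,b) + U(b,a) = n1 * n2 exactly."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=6)
    b = rng.normal(size=9)
    u_ab, _ = mann_whitney_two_tailed(a, b)
    u_ba, _ = mann_whitney_two_tailed(b, a)
    assert u_ab + u_ba == pytest.approx(len(a) * len(b))


class TestShapiro:
    def test_calibrated_under_normality(self):
        rng = np.random.default_rng(0)
        rej = sum(
            shapiro_wilk(rng.normal(size=19))[1] < 0.05 for _ in range(500)
        )
        assert 0.02 <= rej / 500 <= 0.09

    def test_detects_lognormal(self):
        rng = np.random.default_rng(1)
        rej = sum(
            shapiro_wilk(np.exp(rng.normal(0, 1.5, size=19)))[1] < 0.05
            for _ in range(200)
        )
        assert rej / 200 > 0.5

    def test_n2_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            shapiro_wilk([2.0] * 10)


# The fifteen per-structure two-tailed p-values of the emulated study design
# (seven bilateral structures plus brainstem); the left hippocampus is
# reported as p < 0.001, entered at its printed precision.
FIFTEEN_P = {
    "L_Thal": 0.005, "R_Thal": 0.163,
    "L_Caud": 0.181, "R_Caud": 0.181,
    "L_Puta": 0.840, "R_Puta": 0.191,
    "L_Pall": 0.123, "R_Pall": 0.040,
    "L_Hipp": 0.000, "R_Hipp": 0.004,
    "L_Amyg": 0.258, "R_Amyg": 0.370,
    "L_Accu": 0.234, "R_Accu": 0.172,
    "BrStem": 0.138,
}


class TestFdr:
    def test_all_half_no_flags(self):
        flags, crit = fdr_correct([0.5] * 15)
        assert not flags.any() and math.isnan(crit)

    def test_fifteen_structure_profile(self):
        names = list(FIFTEEN_P)
        flags, crit = fdr_correct([FIFTEEN_P[n] for n in names], alpha=0.05)
        assert {n for n, f in zip(names, flags) if f} == {"L_Hipp", "R_Hipp", "L_Thal"}
        assert crit < 0.006  # realized critical p, below the 0.040 runner-up

    def test_single_test_reduces_to_uncorrected(self):
        flags, crit = fdr_correct([0.04], alpha=0.05)
        assert flags[0] and crit == 0.04

    def test_monotone_in_other_pvalues(self, rng):
        """Lowering one p-value never removes a flag from another test."""
        for _ in range(20):
            p = rng.random(10)
            flags, _ = fdr_correct(p)
            k = rng.integers(0, 10)
            p2 = p.copy()
            p2[k] = p2[k] * rng.random()
            flags2, _ = fdr_correct(p2)
            others = np.arange(10) != k
            assert (flags2[others] >= flags[others]).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([])


class TestCohensU3:
    def test_identical_distributions_near_half(self, rng):
        lower = rng.normal(size=4000)
        higher = rng.normal(size=4000)
        u3, _ = cohens_u3(lower, higher, n_boot=100, seed=0)
        assert abs(u3 - 0.5) < 0.05

    def test_hand_counted_example(self):
        u3, ci = cohens_u3([1, 2, 3, 4], [3, 4, 5, 6], n_boot=2000, seed=0)
        assert u3 == 1.0  # all four strictly below median 4.5
        assert ci[0] <= u3 <= ci[1]

    def test_equal_to_median_not_counted(self):
        u3, _ = cohens_u3([1.0, 2.0, 3.0], [3.0, 3.0, 5.0], n_boot=100, seed=0)
        assert u3 == pytest.approx(2 / 3)

    def test_monotone_transform_invariance(self, rng):
        lower = rng.normal(size=15)
        higher = rng.normal(size=15) + 1
        u3_raw, _ = cohens_u3(lower, higher, n_boot=100, seed=1)
        u3_exp, _ = cohens_u3(np.exp(lower), np.exp(higher), n_boot=100, seed=1)
        assert u3_raw == u3_exp

    def test_ci_contains_point_and_shrinks_with_n(self, rng):
        widths = []
        for n in (10, 200):
            lower = rng.normal(size=n)
            higher = rng.normal(1.0, 1.0, size=n)
            u3, (lo, hi) = cohens_u3(lower, higher, n_boot=2000, seed=2)
            assert lo - 1e-12 <= u3 <= hi + 1e-12
            assert 0 <= lo <= hi <= 1
            widths.append(hi - lo)
        assert widths[1] < widths[0]


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman_correlation([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_hand_computed_rank_formula(self):
        # no ties: rho = 1 - 6 sum(d^2) / (n (n^2 - 1)); d = (-1,1,-1,1,0)
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        d2 = sum((xi - yi) ** 2 for xi, yi in zip(x, y))
        expected = 1 - 6 * d2 / (5 * (25 - 1))
        rho, _ = spearman_correlation(x, y)
        assert rho == pytest.approx(expected)
        assert rho == pytest.approx(0.8)

    def test_cohort_volume_fd_positive(self):
        t = make_cohort(seed=11)
        rho, p = spearman_correlation(t["fd"], t["volume_mm3"])
        assert rho > 0 and p < 0.05

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            spearman_correlation([1.0] * 5, [1, 2, 3, 4, 5])


class TestInteraction:
    def test_type_i_error_near_alpha(self):
        """beta3 rejects ~alpha under the null of no group or age effect."""
        rej = 0
        n_rep = 1000
        for rep in range(n_rep):
            t = make_cohort(effect=0.0, interaction_slope=0.0, seed=50_000 + rep)
            model = fit_interaction(t["fd"], t["group"], t["age"])
            rej += model.interaction_p < 0.05
        assert 0.03 <= rej / n_rep <= 0.075

    def test_interaction_sign_recovered(self):
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            t = make_cohort(interaction_slope=0.0008, noise_sd=0.015,
                            seed=90_000 + rep)
            model = fit_interaction(t["fd"], t["group"], t["age"])
            # groups sorted: HC=0, SCZ=1; generator subtracts slope*age for SCZ
            hits += model.params[3] < 0
        assert hits / n_rep > 0.90

    def test_df_and_simple_slopes_dof(self):
        t = make_cohort(seed=1)
        model = fit_interaction(t["fd"], t["group"], t["age"])
        assert model.df_resid == 38 - 4
        for beta, tval, df, p in model.simple_slopes.values():
            assert df == 19 - 2

    def test_centering_leaves_interaction_unchanged(self):
        t = make_cohort(interaction_slope=0.0005, seed=2)
        m1 = fit_interaction(t["fd"], t["group"], t["age"])
        m2 = fit_interaction(t["fd"], t["group"], t["age"] - t["age"].mean())
        assert m2.params[3] == pytest.approx(m1.params[3])
        assert m2.tvalues[3] == pytest.approx(m1.tvalues[3])

    def test_constant_covariate_rejected(self):
        t = make_cohort(seed=3)
        with pytest.raises(ValueError, match="collinear"):
            fit_interaction(t["fd"], t["group"], np.ones(len(t)))


class TestSummarize:
    def test_single_true_effect_flagged(self):
        effects = {s: 0.0 for s in ("A", "B", "C", "D", "E")}
        effects["C"] = 0.03
        t = make_cohort(effect=effects, structures=tuple(effects), seed=4)
        comps = summarize_structures(t, n_boot=500, seed=0)
        flagged = {c.structure for c in comps if c.fdr_significant}
        assert flagged == {"C"}
        by_name = {c.structure: c for c in comps}
        assert by_name["C"].u3 > 0.7
        assert by_name["C"].group_stats["SCZ"]["median"] < by_name["C"].group_stats["HC"]["median"]

    def test_null_cohorts_rarely_flagged(self):
        # FDR at 0.05 keeps the family-wise false-positive rate near 5%,
        # so flags on null cohorts are rare but not impossible
        flagged_cohorts = 0
        for seed in range(10):
            t = make_cohort(effect=0.0, structures=("A", "B", "C"), seed=seed)
            comps = summarize_structures(t, n_boot=50, seed=0)
            flagged_cohorts += any(c.fdr_significant for c in comps)
            for c in comps:
                n1 = c.group_stats["SCZ"]["n"]
                n2 = c.group_stats["HC"]["n"]
                assert 0 <= c.u_statistic <= n1 * n2 / 2  # min-U convention
        assert flagged_cohorts <= 2

    def test_missing_group_skipped_with_warning(self):
        t = make_cohort(structures=("A", "B"), seed=6)
        t = t[~((t.structure == "B") & (t.group == "SCZ"))]
        with pytest.warns(UserWarning, match="skipped"):
            comps = summarize_structures(t, n_boot=100, seed=0)
        assert [c.structure for c in comps] == ["A"]


class TestSpreadsheetImport:
    def test_wide_to_long_roundtrip(self, tmp_path):
        wide = pd.DataFrame(
            {
                "subject_id": ["S1", "S2", "S3", "S4"],
                "group": ["SCZ", "SCZ", "HC", "HC"],
                "age": [30.0, 41.0, 35.0, 28.0],
                "L_Hipp": [2.15, 2.10, 2.17, 2.18],
                "R_Hipp": [2.14, 2.11, 2.18, 2.17],
            }
        )
        path = tmp_path / "fd.xlsx"
        wide.to_excel(path, index=False)
        long = read_fd_spreadsheet(path)
        assert len(long) == 8
        assert set(long["structure"]) == {"L_Hipp", "R_Hipp"}
        got = long[(long.subject_id == "S1") & (long.structure == "L_Hipp")]["fd"]
        assert got.iloc[0] == 2.15
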