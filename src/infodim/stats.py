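"""Nonparametric group statistics for per-subject fractal-dimension tables.

The inferential pipeline for contrasting two groups (e.g. patients vs
controls) structure by structure: Shapiro-Wilk normality screening (the gate
justifying nonparametric tests), two-tailed Mann-Whitney U tests,
Benjamini-Hochberg FDR correction across all reported structures, Cohen's U3
effect sizes with bootstrap confidence intervals, Spearman FD-volume
correlation, and group x covariate interaction regressions
(Y = b0 + b1*group + b2*cov + b3*group*cov) with per-group simple slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "InteractionModel",
    "mann_whitney_two_tailed",
    "shapiro_wilk",
    "fdr_correct",
    "cohens_u3",
    "spearman_correlation",
    "fit_interaction",
    "summarize_structures",
    "read_fd_spreadsheet",
]


@dataclass
class GroupComparison:
    """Two-group test output for one structure.

    ``u_statistic`` is reported in the min-U convention
    (min(U_ab, n1*n2 - U_ab)), the convention of common statistics packages.
    """

    structure: str
    group_stats: dict[str, dict[str, float]]  # group -> median/min/max/n
    u_statistic: float
    p_value: float
    fdr_significant: bool = False
    u3: float = float("nan")
    u3_ci: tuple[float, float] = (float("nan"), float("nan"))
    shapiro_p: dict[str, float] = field(default_factory=dict)


@dataclass
class InteractionModel:
    """OLS fit of Y = b0 + b1*group + b2*cov + b3*group*cov.

    ``simple_slopes`` maps each group label to (beta, t, df, p) from a
    within-group regression of the outcome on the covariate.
    """

    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    df_resid: int
    term_names: tuple[str, str, str, str]
    simple_slopes: dict[str, tuple[float, float, int, float]]

    @property
    def interaction_p(self) -> float:
        return float(self.pvalues[3])


def mann_whitney_two_tailed(a, b) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test; U is computed from the first sample.

    Exact p for small samples (both n <= 10) without ties; tie-corrected
    normal approximation otherwise.  Identical samples give p = 1 with a
    warning.  ``U(a,b) + U(b,a) = n1 * n2``; the complementary value (or
    ``min(U, n1*n2 - U)``) recovers the min-U convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical across groups; p set to 1", stacklevel=2)
        return len(a) * len(b) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not has_ties and len(a) <= 10 and len(b) <= 10) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p) for 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("W undefined for constant input")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def fdr_correct(p_values, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up at level ``alpha``.

    Returns per-test significance flags and the realized critical p (the
    largest p-value flagged; NaN if none).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    flags = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    crit = float(p[flags].max()) if flags.any() else float("nan")
    return flags, crit


def cohens_u3(
    lower, higher, n_boot: int = 10_000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Cohen's U3 with a percentile-bootstrap confidence interval.

    U3 is the proportion of the lower-scoring group lying strictly below the
    median of the higher-scoring group (values equal to the median do not
    count).  The CI resamples both groups with replacement ``n_boot`` times
    (seeded) and takes the 2.5/97.5 percentiles.
    """
    lower = np.asarray(lower, dtype=float)
    higher = np.asarray(higher, dtype=float)
    if len(lower) < 2 or len(higher) < 2:
        raise ValueError("each group needs at least 2 observations")
    u3 = float(np.mean(lower < np.median(higher)))
    rng = np.random.default_rng(seed)
    idx_lo = rng.integers(0, len(lower), size=(n_boot, len(lower)))
    idx_hi = rng.integers(0, len(higher), size=(n_boot, len(higher)))
    med_hi = np.median(higher[idx_hi], axis=1)
    boot = (lower[idx_lo] < med_hi[:, None]).mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return u3, (float(lo), float(hi))


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (rho, two-tailed p) with tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for constant input")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def fit_interaction(fd, group, covariate) -> InteractionModel:
    """OLS with terms (intercept, group, covariate, group x covariate).

    ``group`` may be 0/1 or two string labels (the second level in sorted
    order is coded 1).  Simple slopes are fitted within each group
    (df = n_g - 2).  A rank-deficient design raises with the collinear term
    named.
    """
    fd = np.asarray(fd, dtype=float)
    group = np.asarray(group)
    cov = np.asarray(covariate, dtype=float)
    n = len(fd)
    if n <= 4:
        raise ValueError("need n > 4 for the 4-term model")
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {levels!r}")
    g = (group == levels[1]).astype(float)
    if np.ptp(cov) == 0:
        raise ValueError("covariate is constant: 'covariate' term is collinear "
                         "with the intercept")
    X = np.column_stack([np.ones(n), g, cov, g * cov])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("rank-deficient design: 'group x covariate' term is "
                         "collinear")
    fit = sm.OLS(fd, X).fit()
    slopes: dict[str, tuple[float, float, int, float]] = {}
    for lev in levels:
        m = group == lev
        sub = sm.OLS(fd[m], sm.add_constant(cov[m])).fit()
        slopes[str(lev)] = (
            float(sub.params[1]),
            float(sub.tvalues[1]),
            int(sub.df_resid),
            float(sub.pvalues[1]),
        )
    return InteractionModel(
        params=np.asarray(fit.params),
        bse=np.asarray(fit.bse),
        tvalues=np.asarray(fit.tvalues),
        pvalues=np.asarray(fit.pvalues),
        df_resid=int(fit.df_resid),
        term_names=("intercept", "group", "covariate", "group_x_covariate"),
        simple_slopes=slopes,
    )


def summarize_structures(
    table: pd.DataFrame,
    alpha: float = 0.05,
    n_boot: int = 10_000,
    seed: int = 0,
    group_col: str = "group",
    value_col: str = "fd",
) -> list[GroupComparison]:
    """Per-structure two-group summary with FDR correction across structures.

    For each structure: group medians/ranges, Shapiro-Wilk p per group, the
    Mann-Whitney U (min-U convention) and two-tailed p; then BH-FDR flags
    across all structures and Cohen's U3 + bootstrap CI (lower-median group
    vs higher-median group) for every structure.  Structures missing one of
    the two groups are skipped with a warning.
    """
    structures = sorted(table["structure"].unique())
    if len(structures) < 1:
        raise ValueError("no structures in table")
    levels = sorted(table[group_col].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels!r}")
    results: list[GroupComparison] = []
    for struct in structures:
        sub = table[table["structure"] == struct]
        vals = {lev: sub.loc[sub[group_col] == lev, value_col].to_numpy()
                for lev in levels}
        if any(len(v) < 2 for v in vals.values()):
            warnings.warn(f"structure {struct!r} lacks a full group; skipped",
                          stacklevel=2)
            continue
        a, b = vals[levels[0]], vals[levels[1]]
        u_first, p = mann_whitney_two_tailed(a, b)
        u_min = min(u_first, len(a) * len(b) - u_first)
        gstats = {
            lev: {
                "n": float(len(v)),
                "median": float(np.median(v)),
                "min": float(v.min()),
                "max": float(v.max()),
            }
            for lev, v in vals.items()
        }
        shap = {}
        for lev, v in vals.items():
            try:
                shap[lev] = shapiro_wilk(v)[1]
            except ValueError:
                shap[lev] = float("nan")
        results.append(
            GroupComparison(
                structure=struct,
                group_stats=gstats,
                u_statistic=u_min,
                p_value=p,
                shapiro_p=shap,
            )
        )
    if not results:
        raise ValueError("no structure had both groups present")
    flags, _ = fdr_correct([r.p_value for r in results], alpha=alpha)
    for k, res in enumerate(results):
        res.fdr_significant = bool(flags[k])
        sub = table[table["structure"] == res.structure]
        vals = {lev: sub.loc[sub[group_col] == lev, value_col].to_numpy()
                for lev in levels}
        medians = {lev: np.median(v) for lev, v in vals.items()}
        lo_lev = min(medians, key=medians.get)
        hi_lev = max(medians, key=medians.get)
        if lo_lev == hi_lev:  # equal medians: order is arbitrary
            lo_lev, hi_lev = levels
        res.u3, res.u3_ci = cohens_u3(
            vals[lo_lev], vals[hi_lev], n_boot=n_boot, seed=seed + k
        )
    return results


def read_fd_spreadsheet(path, sheet: int | str = 0) -> pd.DataFrame:
    """Import a wide per-subject FD spreadsheet into the tidy cohort layout.

    Expected layout: one row per subject with columns ``subject_id``,
    ``group``, optionally ``age``/``sex``, then one column per structure
    holding FD values.  Returns the long format used by
    :func:`summarize_structures`.
    """
    wide = pd.read_excel(path, sheet_name=sheet)
    meta = [c for c in ("subject_id", "group", "age", "sex") if c in wide.columns]
    if "subject_id" not in meta or "group" not in meta:
        raise ValueError("spreadsheet must contain subject_id and group columns")
    value_cols = [c for c in wide.columns if c not in meta]
    long = wide.melt(id_vars=meta, value_vars=value_cols,
                     var_name="structure", value_name="fd")
    return long.dropna(subset=["fd"]).reset_index(drop=True)
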