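"""Group-level statistics for the DM vs non-DM comparison.

Numeric variables are compared with Welch's unequal-variance t test (the
group sizes differ substantially) or, for variables that cannot be assumed
normal, the two-sided Mann-Whitney U test; 2x2 categorical tables use
Fisher's exact test; associations use Pearson correlation.  Because
multiple 5-mm segments cluster within a patient, segment-level group
contrasts are additionally fitted as a linear mixed model with a random
intercept per patient (REML via statsmodels MixedLM).

No multiple-testing correction is applied by default; a config flag adds
Benjamini-Hochberg adjusted p-values for users who want them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import ConstantInputError, ValidationError


@dataclass
class GroupComparison:
    variable: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    test: str            # "t" | "mann_whitney" | "fisher"
    statistic: float
    p_value: float


def compare_numeric(group_a, group_b, normality: bool = True,
                    variable: str = "") -> GroupComparison:
    """Two-sided Welch t test (normality=True) or Mann-Whitney U test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("compare_numeric: each group needs n >= 2")
    if normality:
        res = sps.ttest_ind(a, b, equal_var=False)
        test, stat, p = "t", float(res.statistic), float(res.pvalue)
        if np.isnan(stat):  # identical constant groups: zero difference
            stat, p = 0.0, 1.0
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        test, stat, p = "mann_whitney", float(res.statistic), float(res.pvalue)
    return GroupComparison(
        variable=variable,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=int(a.size),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=int(b.size),
        test=test, statistic=stat, p_value=min(p, 1.0),
    )


def compare_categorical(table, variable: str = "") -> GroupComparison:
    """Two-sided Fisher exact test on a 2x2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError("compare_categorical: table must be 2x2")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.all(t == np.floor(t)):
            raise ValidationError("compare_categorical: counts must be integers")
        t = t.astype(int)
    if np.any(t < 0):
        raise ValidationError("compare_categorical: counts must be >= 0")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return GroupComparison(
        variable=variable,
        mean_a=float(t[0, 0]), sd_a=0.0, n_a=int(t[0].sum()),
        mean_b=float(t[1, 0]), sd_b=0.0, n_b=int(t[1].sum()),
        test="fisher", statistic=float(odds), p_value=float(p),
    )


def correlate(x, y) -> tuple[float, float]:
    """Pearson R with its two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("correlate: need equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlate: correlation undefined for a "
                                 "constant vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class MixedEffectResult:
    estimate: float          # fixed group effect (difference of group means)
    std_error: float
    p_value: float
    random_intercept_var: float
    method: str              # "mixedlm_reml" or "ols_fallback"
    converged: bool


def mixed_effect_group_test(df: pd.DataFrame, value_col: str = "delta",
                            group_col: str = "group",
                            patient_col: str = "patient_id") -> MixedEffectResult:
    """Random-intercept-per-patient model of ``value ~ group``.

    Returns the fixed group-effect estimate with its SE and p value plus the
    patient random-intercept variance.  A singular / non-converged fit falls
    back to the fixed-effect-only (OLS) estimate, flagged via ``method`` —
    never silently.
    """
    data = df[[value_col, group_col, patient_col]].dropna()
    groups = sorted(data[group_col].unique())
    if len(groups) != 2:
        raise ValidationError("mixed_effect_group_test: need exactly 2 groups")
    for g in groups:
        if data.loc[data[group_col] == g, patient_col].nunique() < 2:
            raise ValidationError(
                f"mixed_effect_group_test: group {g!r} needs >= 2 patients")
    x = (data[group_col] == groups[1]).astype(float).to_numpy()
    exog = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            # statsmodels reports boundary (zero-variance) fits via UserWarning
            warnings.simplefilter("ignore", UserWarning)
            fit = sm.MixedLM(data[value_col].to_numpy(), exog,
                             groups=data[patient_col].to_numpy()).fit(reml=True)
        est = float(fit.params[1])
        se = float(fit.bse[1])
        p = float(fit.pvalues[1])
        var = float(np.asarray(fit.cov_re)[0, 0])
        if np.isfinite(est) and np.isfinite(se) and np.isfinite(p):
            return MixedEffectResult(est, se, p, max(var, 0.0),
                                     "mixedlm_reml", bool(fit.converged))
    except (np.linalg.LinAlgError, ValueError):
        pass
    # Singular fit: report the fixed-effect-only estimate with zero
    # random-intercept variance, explicitly flagged.
    ols = sm.OLS(data[value_col].to_numpy(), exog).fit()
    return MixedEffectResult(float(ols.params[1]), float(ols.bse[1]),
                             float(ols.pvalues[1]), 0.0, "ols_fallback", False)


def paired_change_p(before, after, normality: bool = True) -> float:
    """Within-group baseline-vs-follow-up p value (paired t or Wilcoxon)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size != after.size or before.size < 2:
        raise ValidationError("paired_change_p: need paired vectors, n >= 2")
    diff = after - before
    if np.ptp(diff) == 0:       # constant shift: degenerate t statistic
        return 1.0 if diff[0] == 0 else 0.0
    if normality:
        return float(sps.ttest_rel(after, before).pvalue)
    return float(sps.wilcoxon(after, before).pvalue)


def add_bh_adjusted(table: pd.DataFrame, p_col: str = "p_value",
                    out_col: str = "p_bh") -> pd.DataFrame:
    """Append Benjamini-Hochberg adjusted p-values to a stats table."""
    table = table.copy()
    mask = table[p_col].notna()
    adjusted = np.full(len(table), np.nan)
    if mask.any():
        adjusted[mask.to_numpy()] = multipletests(
            table.loc[mask, p_col].to_numpy(), method="fdr_bh")[1]
    table[out_col] = adjusted
    return table
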