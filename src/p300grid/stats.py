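"""One-way ANOVA over the experiment grid: models, and pooling strides.

The grid of subject-averaged accuracies for one trial length is a 30 x 6
table (patch codes x pool strides). Two analyses ask whether accuracy
depends on the factor:

* across *models*: 30 groups (patch codes), each with the 6 per-stride
  accuracies as observations -> df (29, 150), critical F(0.05) ~ 1.54;
* across *strides*: 6 groups (strides), each with the 30 per-model
  accuracies as observations -> df (5, 174), critical F(0.05) ~ 2.26.

The F statistic comes from the classic between/within sum-of-squares
decomposition, written out here; only the F distribution's tail and
quantile are delegated to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .cnn import PATCH_CODES, POOL_STRIDES


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    F_critical: float
    alpha: float
    significant: bool

    def as_row(self) -> dict:
        return {
            "F": self.F, "p": self.p,
            "df_between": self.df_between, "df_within": self.df_within,
            "F_critical": self.F_critical, "significant": self.significant,
        }


def f_critical(alpha: float, df_between: int, df_within: int) -> float:
    """Upper-alpha quantile of the F(df_between, df_within) distribution."""
    if df_between < 1 or df_within < 1:
        raise ValueError("degrees of freedom must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return float(f_dist.ppf(1.0 - alpha, df_between, df_within))


def one_way_anova(groups: list, alpha: float = 0.05) -> AnovaResult:
    """Classic one-way fixed-effects ANOVA.

    ``groups`` is a list of >= 2 observation vectors, each with >= 2 values.
    SS_total = SS_between + SS_within; F = MS_between / MS_within; p is the
    F-distribution tail. If both SS terms are zero (all observations equal)
    F is defined as 0 with p = 1.
    """
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs at least two observations")
    k = len(arrs)
    n = sum(a.size for a in arrs)
    pooled = np.concatenate(arrs)
    grand = pooled.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_between, df_within = k - 1, n - k

    # SS terms below float round-off of the raw sum of squares are zero:
    # without this, an exactly constant grid yields F = tiny/0 = inf
    tol = 1e-12 * max(float((pooled**2).sum()), 1e-300)
    ss_between = 0.0 if ss_between <= tol else ss_between
    ss_within = 0.0 if ss_within <= tol else ss_within

    if ss_within == 0.0:
        F = 0.0 if ss_between == 0.0 else np.inf
    else:
        F = (ss_between / df_between) / (ss_within / df_within)
    p = 1.0 if (F == 0.0 and ss_between == 0.0) else float(f_dist.sf(F, df_between, df_within))
    crit = f_critical(alpha, df_between, df_within)
    return AnovaResult(
        F=float(F), p=p, df_between=df_between, df_within=df_within,
        F_critical=crit, alpha=alpha, significant=bool(F > crit),
    )


def _subject_averaged_grid(results: pd.DataFrame, trial_length_ms: float) -> pd.DataFrame:
    """30 x 6 pivot of subject-averaged accuracy; errors on missing cells."""
    sub = results[results.trial_length_ms == trial_length_ms]
    sub = sub.astype({"patch_code": str})
    pivot = (
        sub.groupby(["patch_code", "pool_stride"])["accuracy"]
        .mean()
        .unstack("pool_stride")
    )
    missing = [
        (c, s)
        for c in PATCH_CODES
        for s in POOL_STRIDES
        if c not in pivot.index or s not in pivot.columns or pd.isna(pivot.loc[c, s])
    ]
    if missing:
        shown = ", ".join(f"({c}, {s})" for c, s in missing[:8])
        more = "" if len(missing) <= 8 else f" and {len(missing) - 8} more"
        raise ValueError(
            f"incomplete grid for trial length {trial_length_ms}: "
            f"missing cells {shown}{more}"
        )
    return pivot.loc[list(PATCH_CODES), list(POOL_STRIDES)]


def anova_models(results: pd.DataFrame, trial_length_ms: float,
                 alpha: float = 0.05) -> AnovaResult:
    """Do the 30 patch-code models differ? Groups = codes, obs = 6 strides."""
    pivot = _subject_averaged_grid(results, trial_length_ms)
    return one_way_anova([pivot.loc[c].to_numpy() for c in PATCH_CODES], alpha)


def anova_strides(results: pd.DataFrame, trial_length_ms: float,
                  alpha: float = 0.05) -> AnovaResult:
    """Do the 6 pool strides differ? Groups = strides, obs = 30 models."""
    pivot = _subject_averaged_grid(results, trial_length_ms)
    return one_way_anova([pivot[s].to_numpy() for s in POOL_STRIDES], alpha)


def anova_table(results: pd.DataFrame, by: str = "models",
                alpha: float = 0.05) -> pd.DataFrame:
    """F / p / significance per trial length, in descending trial length."""
    fn = {"models": anova_models, "strides": anova_strides}[by]
    rows = []
    for tl in sorted(results.trial_length_ms.unique(), reverse=True):
        res = fn(results, tl, alpha)
        rows.append({"trial_length_ms": tl, **res.as_row()})
    return pd.DataFrame(rows)
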