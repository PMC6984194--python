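"""Bootstrap statistics for the 2 (group) x 2 (block/condition) study design.

All significance tests are resampling-based: a mixed two-way ANOVA whose
null F distribution is built by centering each subject's values on their
across-condition mean, resampling subjects with replacement and
re-randomizing group labels; a two-sided independent-samples t test with
pooled resampling; and a Pearson correlation tested by shuffling one
variable.  Default replicate count is B = 3000; p-values use the
(1 + exceedances) / (B + 1) convention so they are never exactly zero.
Family-wise error is controlled with Bonferroni-Holm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BootstrapResult",
    "mixed_anova_F",
    "bootstrap_mixed_anova",
    "bootstrap_ttest",
    "bootstrap_correlation",
    "holm_correction",
]


@dataclass
class BootstrapResult:
    """Observed statistic, its bootstrap null distribution, and the p-value."""

    observed: float
    null_distribution: np.ndarray
    p: float
    ci: tuple = None  # 2.5/97.5 percentiles of the null where reported
    B: int = 3000
    seed: int = None
    extra: dict = field(default_factory=dict)


def _as_design(data) -> pd.DataFrame:
    df = pd.DataFrame(data)
    required = {"subject", "group", "condition", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"design needs columns {sorted(required)}")
    return df


def _design_arrays(df: pd.DataFrame):
    """Pivot a long-format balanced 2x2 mixed design into arrays.

    Returns ``(values, group)``: values (N, 2) ordered by condition level,
    group a boolean array (N,) marking the second group level.
    """
    groups = sorted(df["group"].unique())
    conditions = sorted(df["condition"].unique())
    if len(groups) != 2 or len(conditions) != 2:
        raise ValueError("exactly two groups and two within-factor levels required")
    wide = df.pivot_table(index=["subject", "group"], columns="condition",
                          values="value", aggfunc="mean")
    if wide.isna().any().any() or wide.shape[1] != 2:
        raise ValueError("missing cell: every subject needs a value in both conditions")
    subj_group = wide.index.get_level_values("group")
    group = np.asarray(subj_group == groups[1])
    n0, n1 = int((~group).sum()), int(group.sum())
    if min(n0, n1) < 2:
        raise ValueError("need at least 2 subjects per group")
    return wide[conditions].to_numpy(dtype=float), group


def _mixed_F(values, group):
    """Vectorized 2x2 mixed-design F statistics.

    ``values``: (..., N, 2); ``group``: (..., N) boolean.  Returns
    ``(F_group, F_within, F_interaction)`` each of shape ``(...,)`` with
    classical sums of squares and (1, N - 2) degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group, dtype=bool)
    N = values.shape[-2]
    g1 = group[..., np.newaxis]  # broadcasting helper over conditions
    n1 = group.sum(axis=-1, keepdims=True)
    n0 = N - n1

    grand = values.mean(axis=(-2, -1))[..., np.newaxis, np.newaxis]
    subj_mean = values.mean(axis=-1)  # (..., N)
    cond_mean = values.mean(axis=-2)[..., np.newaxis, :]  # (..., 1, 2)

    sum0 = np.where(~g1, values, 0.0).sum(axis=-2)  # (..., 2) per-condition group sums
    sum1 = np.where(g1, values, 0.0).sum(axis=-2)
    cell0 = sum0 / n0
    cell1 = sum1 / n1
    gm0 = cell0.mean(axis=-1)  # (...,) group means
    gm1 = cell1.mean(axis=-1)
    grand_flat = grand[..., 0, 0]

    ss_group = 2.0 * (n0[..., 0] * (gm0 - grand_flat) ** 2 + n1[..., 0] * (gm1 - grand_flat) ** 2)
    subj_group_mean = np.where(group, gm1[..., np.newaxis], gm0[..., np.newaxis])
    ss_subj = 2.0 * ((subj_mean - subj_group_mean) ** 2).sum(axis=-1)
    ss_cond = float(N) * ((cond_mean[..., 0, :] - grand_flat[..., np.newaxis]) ** 2).sum(axis=-1)

    inter0 = cell0 - gm0[..., np.newaxis] - cond_mean[..., 0, :] + grand_flat[..., np.newaxis]
    inter1 = cell1 - gm1[..., np.newaxis] - cond_mean[..., 0, :] + grand_flat[..., np.newaxis]
    ss_inter = (n0 * inter0 ** 2 + n1 * inter1 ** 2).sum(axis=-1)

    cell = np.where(g1, cell1[..., np.newaxis, :], cell0[..., np.newaxis, :])
    resid = values - cell - subj_mean[..., np.newaxis] + subj_group_mean[..., np.newaxis]
    ss_err = (resid ** 2).sum(axis=(-2, -1))

    df_err = N - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f_group = ss_group / (ss_subj / df_err)
        f_within = ss_cond / (ss_err / df_err)
        f_inter = ss_inter / (ss_err / df_err)
    return (np.nan_to_num(f_group, nan=0.0), np.nan_to_num(f_within, nan=0.0),
            np.nan_to_num(f_inter, nan=0.0))


def mixed_anova_F(data):
    """Classical F statistics of a balanced 2x2 mixed ANOVA.

    ``data`` is long format with columns subject / group / condition /
    value.  Returns ``{"group": F, "within": F, "interaction": F}``; the
    between effect is tested against subjects-within-groups, the within and
    interaction effects against the condition-by-subject residual, all with
    (1, N - 2) degrees of freedom.
    """
    values, group = _design_arrays(_as_design(data))
    fg, fw, fi = _mixed_F(values, group)
    return {"group": float(fg), "within": float(fw), "interaction": float(fi)}


def _check_B(B):
    if B < 1:
        raise ValueError("B must be positive")
    if B < 100:
        warnings.warn(f"B={B} gives unstable bootstrap p-values")


def bootstrap_mixed_anova(data, B: int = 3000, seed: int = None) -> dict:
    """Bootstrap null distributions for the three mixed-ANOVA effects.

    Null construction: (i) center the within-subject factor by removing
    each condition's mean (so no block effect survives), (ii) resample N
    subjects with replacement, (iii) randomly reassign group labels
    preserving group sizes (so no group or interaction effect survives);
    the F statistics are recomputed per replicate and
    p = (1 + #{F_null >= F_obs}) / (B + 1).
    """
    _check_B(B)
    values, group = _design_arrays(_as_design(data))
    N = values.shape[0]
    fg, fw, fi = _mixed_F(values, group)
    observed = {"group": float(fg), "within": float(fw), "interaction": float(fi)}

    rng = np.random.default_rng(seed)
    centered = values - values.mean(axis=0, keepdims=True)
    idx = rng.integers(0, N, size=(B, N))
    boot_values = centered[idx]  # (B, N, 2)
    boot_group = rng.permuted(np.broadcast_to(group, (B, N)).copy(), axis=1)
    fg_b, fw_b, fi_b = _mixed_F(boot_values, boot_group)
    nulls = {"group": fg_b, "within": fw_b, "interaction": fi_b}

    out = {}
    for effect, null in nulls.items():
        obs = observed[effect]
        p = (1.0 + np.sum(null >= obs)) / (B + 1.0)
        out[effect] = BootstrapResult(observed=obs, null_distribution=null,
                                      p=float(p), B=B, seed=seed)
    return out


def bootstrap_ttest(x, y, B: int = 3000, seed: int = None) -> BootstrapResult:
    """Two-sided independent-samples t test with pooled resampling.

    The null t distribution is built by pooling both samples and drawing
    two resamples (with replacement) of the original sizes; the two-sided
    p is the proportion of null |t| at least as large as the observed |t|,
    and ``ci`` holds the 2.5/97.5 percentiles of the null t distribution.
    """
    _check_B(B)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled = np.concatenate([x, y])
    if np.var(pooled) == 0:
        raise ValueError("zero pooled variance: t statistic undefined")

    def tstat(a, b):
        na, nb = a.shape[-1], b.shape[-1]
        va = a.var(axis=-1, ddof=1)
        vb = b.var(axis=-1, ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (a.mean(axis=-1) - b.mean(axis=-1)) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        return np.nan_to_num(t, nan=0.0)

    t_obs = float(tstat(x, y))
    rng = np.random.default_rng(seed)
    n = len(pooled)
    xb = pooled[rng.integers(0, n, size=(B, len(x)))]
    yb = pooled[rng.integers(0, n, size=(B, len(y)))]
    t_null = tstat(xb, yb)
    p = (1.0 + np.sum(np.abs(t_null) >= abs(t_obs))) / (B + 1.0)
    ci = tuple(np.percentile(t_null, [2.5, 97.5]))
    return BootstrapResult(observed=t_obs, null_distribution=t_null, p=float(p),
                           ci=ci, B=B, seed=seed)


def bootstrap_correlation(x, y, B: int = 3000, seed: int = None) -> BootstrapResult:
    """Pearson correlation tested by shuffling one variable.

    The observed statistic is r (with t(n-2) = r sqrt(n-2) / sqrt(1-r^2)
    and R^2 reported in ``extra``); the null is built by permuting y while
    keeping x fixed, and the two-sided p compares |r|.
    """
    _check_B(B)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("paired samples of length >= 3 required")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant variable: correlation undefined")
    n = len(x)
    r_obs = float(stats.pearsonr(x, y).statistic)

    rng = np.random.default_rng(seed)
    xz = (x - x.mean()) / x.std()
    yz = (y - y.mean()) / y.std()
    y_perm = rng.permuted(np.broadcast_to(yz, (B, n)).copy(), axis=1)
    r_null = (y_perm * xz).mean(axis=1)
    p = (1.0 + np.sum(np.abs(r_null) >= abs(r_obs) - 1e-12)) / (B + 1.0)

    with np.errstate(divide="ignore", over="ignore"):
        t_obs = r_obs * np.sqrt((n - 2) / max(1.0 - r_obs ** 2, np.finfo(float).tiny))
    ci = tuple(np.percentile(r_null * np.sqrt((n - 2) / np.maximum(1 - r_null ** 2, 1e-12)),
                             [2.5, 97.5]))
    return BootstrapResult(
        observed=r_obs, null_distribution=r_null, p=float(p), ci=ci, B=B, seed=seed,
        extra={"t": float(t_obs), "r_squared": float(r_obs ** 2), "df": n - 2},
    )


def holm_correction(p_values, alpha: float = 0.05):
    """Bonferroni-Holm step-down correction.

    Returns ``(reject, p_adjusted)``: p-values are sorted ascending,
    p_(i) is compared against alpha / (m - i + 1), testing stops at the
    first failure, and adjusted p-values are the monotone running maxima
    of (m - i + 1) * p_(i), clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.maximum.accumulate(p[order] * (m - np.arange(m)))
    adj_sorted = np.minimum(adj_sorted, 1.0)

    reject_sorted = np.zeros(m, dtype=bool)
    for i in range(m):
        if p[order][i] <= alpha / (m - i):
            reject_sorted[i] = True
        else:
            break
    reject = np.empty(m, dtype=bool)
    p_adj = np.empty(m)
    reject[order] = reject_sorted
    p_adj[order] = adj_sorted
    return reject, p_adj
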