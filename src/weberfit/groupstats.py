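"""Group-level inference for two-factor mixed (split-plot) designs.

One between-subject factor (group) crossed with one within-subject factor
(intensity level, every participant measured at every level).  The
classical univariate sums-of-squares decomposition is used, with no
sphericity correction by default (integer degrees of freedom); a
Greenhouse–Geisser correction is available behind a flag.  Effect sizes
are partial eta squared, SS_effect / (SS_effect + SS_error) with the
error term taken from the effect's own stratum.

Also provided: orthogonal-polynomial linear trend contrasts for ordered
within-factors, Cousineau–Morey within-subject confidence intervals, and
pooled/Welch two-sample t tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnovaResult:
    """Effect table of a two-factor mixed ANOVA plus design metadata.

    ``table`` has one row per effect (group, within, interaction) with
    SS, df1, df2, MS, F, p and partial eta squared; error strata are in
    ``ss_error_between`` / ``ss_error_within``.  ``degenerate`` flags a
    zero error variance (F reported as inf).
    """

    table: pd.DataFrame
    ss_error_between: float
    ss_error_within: float
    ss_total: float
    group_sizes: dict
    n_levels: int
    degenerate: bool = False
    sphericity_correction: str | None = None

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


class TrendContrast(NamedTuple):
    """Polynomial trend contrast on an ordered within-subject factor."""

    weights: np.ndarray
    estimate: float       # mean per-subject contrast score
    ss_contrast: float
    ss_error: float
    F: float
    df: tuple
    p: float
    partial_eta_sq: float
    degenerate: bool


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float
    degenerate: bool


def _f_row(effect, ss_eff, df_eff, ss_err, df_err):
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    if ms_err <= 0:
        f = np.inf if ms_eff > 0 else 0.0
        p = 0.0 if ms_eff > 0 else 1.0
        degenerate = True
    else:
        f = ms_eff / ms_err
        p = float(stats.f.sf(f, df_eff, df_err))
        degenerate = False
    eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    return (
        {
            "effect": effect,
            "SS": ss_eff,
            "df1": df_eff,
            "df2": df_err,
            "MS": ms_eff,
            "F": f,
            "p": p,
            "partial_eta_sq": eta,
        },
        degenerate,
    )


def mixed_anova_arrays(y: np.ndarray, group_labels: Sequence) -> AnovaResult:
    """Mixed ANOVA on a (n_subjects, n_levels) response matrix.

    Fast array core used by :func:`mixed_anova` and by null simulations.
    The decomposition uses weighted (per-observation) marginal means, so
    SS_total = SS_between_subjects + SS_within_subjects partitions
    exactly even with unequal group sizes; the interaction and error
    strata coincide with the standard least-squares ones because the
    within factor is fully balanced.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2:
        raise ValueError("y must be (n_subjects, n_levels)")
    n_subj, n_lev = y.shape
    groups = np.asarray(group_labels)
    if groups.shape[0] != n_subj:
        raise ValueError("group_labels length must match n_subjects")
    uniq, codes = np.unique(groups, return_inverse=True)
    n_groups = uniq.size
    sizes = np.bincount(codes)
    if np.any(sizes < 2):
        raise ValueError("every group needs >= 2 participants")
    if n_lev < 2:
        raise ValueError("need >= 2 within-factor levels")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([subj_means[codes == i].mean() for i in range(n_groups)])
    level_means = y.mean(axis=0)
    cell_means = np.vstack([y[codes == i].mean(axis=0) for i in range(n_groups)])

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(n_lev * ((subj_means - grand) ** 2).sum())
    ss_group = float(n_lev * (sizes * (group_means - grand) ** 2).sum())
    ss_subj_err = ss_between_subj - ss_group
    ss_level = float(n_subj * ((level_means - grand) ** 2).sum())
    ss_cells = float((sizes[:, None] * (cell_means - grand) ** 2).sum())
    ss_inter = ss_cells - ss_group - ss_level
    ss_within_err = ss_total - ss_between_subj - ss_level - ss_inter

    df_group = n_groups - 1
    df_subj_err = n_subj - n_groups
    df_level = n_lev - 1
    df_inter = df_group * df_level
    df_within_err = df_subj_err * df_level

    rows, degen = [], False
    for args in (
        ("group", ss_group, df_group, ss_subj_err, df_subj_err),
        ("within", ss_level, df_level, ss_within_err, df_within_err),
        ("interaction", ss_inter, df_inter, ss_within_err, df_within_err),
    ):
        row, d = _f_row(*args)
        rows.append(row)
        degen = degen or d
    return AnovaResult(
        table=pd.DataFrame(rows),
        ss_error_between=ss_subj_err,
        ss_error_within=ss_within_err,
        ss_total=ss_total,
        group_sizes={str(u): int(s) for u, s in zip(uniq, sizes)},
        n_levels=n_lev,
        degenerate=degen,
    )


def pivot_balanced(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "level",
    between: str = "group",
    subject: str = "participant",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Long table -> (responses (N, L), group label per subject, level order).

    Raises if any (subject, level) cell is missing or duplicated — the
    mixed model here requires a complete repeated-measures design and
    performs no imputation.
    """
    wide = table.pivot_table(index=subject, columns=within, values=dv, aggfunc="count")
    bad = wide.isna() | (wide != 1)
    if bad.to_numpy().any():
        subj = bad.any(axis=1)
        lev = bad.any(axis=0)
        raise ValueError(
            "unbalanced design: subjects %s at levels %s have missing or "
            "duplicated cells" % (list(wide.index[subj]), list(wide.columns[lev]))
        )
    values = table.pivot(index=subject, columns=within, values=dv)
    grp = table.drop_duplicates(subject).set_index(subject)[between]
    grp = grp.loc[values.index]
    return values.to_numpy(dtype=float), grp.to_numpy(), values.columns.to_numpy()


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "level",
    between: str = "group",
    subject: str = "participant",
    sphericity_correction: bool = False,
) -> AnovaResult:
    """Two-factor mixed ANOVA on a tidy long table.

    ``sphericity_correction`` applies Greenhouse–Geisser epsilon to the
    within and interaction df (off by default: uncorrected integer df).
    """
    y, groups, _ = pivot_balanced(table, dv, within, between, subject)
    res = mixed_anova_arrays(y, groups)
    if sphericity_correction:
        eps = _greenhouse_geisser_epsilon(y)
        t = res.table.set_index("effect")
        t[["df1", "df2"]] = t[["df1", "df2"]].astype(float)
        for eff in ("within", "interaction"):
            df1, df2 = t.loc[eff, "df1"] * eps, t.loc[eff, "df2"] * eps
            t.loc[eff, ["df1", "df2"]] = df1, df2
            if np.isfinite(t.loc[eff, "F"]):
                t.loc[eff, "p"] = float(stats.f.sf(t.loc[eff, "F"], df1, df2))
        res.table = t.reset_index()
        res.sphericity_correction = "greenhouse-geisser"
    return res


def _greenhouse_geisser_epsilon(y: np.ndarray) -> float:
    # epsilon from the pooled within-subject covariance of the level scores
    yc = y - y.mean(axis=1, keepdims=True)
    S = np.cov(yc.T, ddof=1)
    L = S.shape[0]
    mean_diag = np.trace(S) / L
    num = (L * mean_diag - S.mean()) ** 2
    den = (L - 1) * (np.sum(S**2) - 2 * L * np.sum(S.mean(axis=1) ** 2) + L**2 * S.mean() ** 2)
    return float(np.clip(num / den, 1.0 / (L - 1), 1.0))


def polynomial_weights(n_levels: int, spacing: Sequence[float] | None = None) -> np.ndarray:
    """Centered linear contrast weights over equally spaced level indices,
    or over explicit physical spacing when given."""
    x = np.arange(n_levels, dtype=float) if spacing is None else np.asarray(spacing, dtype=float)
    if x.size != n_levels:
        raise ValueError("spacing length must equal n_levels")
    return x - x.mean()


def linear_trend(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "level",
    subject: str = "participant",
    level_order: Sequence | None = None,
    spacing: Sequence[float] | None = None,
) -> TrendContrast:
    """Linear trend contrast on an ordered within-subject factor (one group).

    Each subject's values are projected onto centered linear weights over
    the level *index* by default (equally spaced levels; physical spacing
    available via ``spacing``); the contrast is tested with df (1, n−1).
    ``level_order`` fixes the factor ordering when it is not sortable.
    """
    wide = table.pivot(index=subject, columns=within, values=dv)
    if level_order is not None:
        missing = set(level_order) - set(wide.columns)
        if missing:
            raise ValueError(f"levels {sorted(missing)} absent from data")
        wide = wide[list(level_order)]
    if wide.isna().to_numpy().any():
        raise ValueError("unbalanced design: missing (subject, level) cells")
    y = wide.to_numpy(dtype=float)
    n, L = y.shape
    if L < 2:
        raise ValueError("need >= 2 ordered levels")
    if n < 2:
        raise ValueError("need >= 2 subjects")
    w = polynomial_weights(L, spacing)
    scores = y @ w
    est = float(scores.mean())
    wss = float(w @ w)
    ss_contrast = n * est**2 / wss
    ss_error = float(((scores - est) ** 2).sum()) / wss
    df = (1, n - 1)
    if ss_error <= 0:
        f = np.inf if ss_contrast > 0 else 0.0
        p = 0.0 if ss_contrast > 0 else 1.0
        degenerate = True
    else:
        f = ss_contrast / (ss_error / (n - 1))
        p = float(stats.f.sf(f, *df))
        degenerate = False
    eta = ss_contrast / (ss_contrast + ss_error) if (ss_contrast + ss_error) > 0 else 0.0
    return TrendContrast(w, est, ss_contrast, ss_error, float(f), df, p, eta, degenerate)


def within_subject_ci(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "level",
    subject: str = "participant",
    level: float = 0.95,
) -> pd.Series:
    """95% (by default) within-subject CI half-widths per condition.

    Cousineau normalisation (subtract each subject's mean, add the grand
    mean) removes between-subject offsets; the Morey L/(L−1) factor
    corrects the resulting variance underestimate.  Half-width =
    t(1−α/2, n−1) · SD_normalised / √n.
    """
    wide = table.pivot(index=subject, columns=within, values=dv)
    if wide.isna().to_numpy().any():
        raise ValueError("unbalanced design: missing (subject, level) cells")
    y = wide.to_numpy(dtype=float)
    n, L = y.shape
    if n < 2:
        raise ValueError("need >= 2 subjects")
    norm_y = y - y.mean(axis=1, keepdims=True) + y.mean()
    var = norm_y.var(axis=0, ddof=1) * L / (L - 1)
    tcrit = stats.t.ppf(0.5 + level / 2.0, n - 1)
    half = tcrit * np.sqrt(var / n)
    return pd.Series(half, index=wide.columns, name="ci_half_width")


def two_sample_t(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    equal_var: bool = True,
) -> TTestResult:
    """Two-sample t test: Student's pooled-variance by default
    (df = n1 + n2 − 2), Welch with ``equal_var=False``, or paired."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per sample")
    if paired:
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    t = float(res.statistic)
    df = float(res.df)
    degenerate = not np.isfinite(t)
    if degenerate:  # zero pooled variance
        diff = float(np.mean(a) - np.mean(b)) if not paired else float(np.mean(a - b))
        t = 0.0 if diff == 0 else np.copysign(np.inf, diff)
        if paired or equal_var:
            df = float(a.size + b.size - 2) if not paired else float(a.size - 1)
        return TTestResult(t, df, 1.0 if t == 0 else 0.0, True)
    return TTestResult(t, df, float(res.pvalue), degenerate)
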