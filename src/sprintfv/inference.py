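"""Comparative statistics for the pre-post two-group sprint study.

The design is a 2 (session: pre, post; repeated) x 2 (group: combined sprint
training CST, maximal sprint training MST; between) mixed ANOVA on each
trial-aggregated sprint variable, preceded by independent t-tests at
pre-test, with within-group pre-post paired tests, pooled-SD standardized
mean differences (Cohen's d) with 95% confidence limits, per-subject percent
change, and a noncentral-F power analysis for the within-between interaction
(the G*Power 'ANOVA: Repeated measures, within-between interaction' test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateStatisticError, IncompleteDesignError, InvalidInputError

__all__ = [
    "EffectSize",
    "PowerSpec",
    "AnovaEffect",
    "independent_t",
    "mixed_anova_2x2",
    "paired_change_test",
    "cohens_d_pooled",
    "cohens_d_from_summary",
    "label_effect_size",
    "percent_change",
    "achieved_power",
    "required_sample_size",
]

# lower edges inclusive; 'extremely large' strictly above 2.00
_ES_BANDS = [
    (1.20, "large"),
    (0.60, "moderate"),
    (0.20, "small"),
    (-np.inf, "trivial"),
]


@dataclass(frozen=True)
class EffectSize:
    """Standardized mean difference with normal-approximation 95% limits."""

    d: float
    cl95: tuple[float, float]
    label: str


@dataclass(frozen=True)
class AnovaEffect:
    ss: float
    df: float
    ms: float
    f: float
    p: float


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for the repeated-measures within-between interaction.

    ``effect_size_f`` is Cohen's f; ``corr_rho`` the assumed correlation
    among repeated measures; ``nonsphericity_eps`` the Greenhouse-Geisser
    epsilon (1 = sphericity holds, exact for two measurements).
    """

    effect_size_f: float = 0.3
    alpha: float = 0.05
    n_groups: int = 2
    n_measurements: int = 2
    corr_rho: float = 0.5
    nonsphericity_eps: float = 1.0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise InvalidInputError("alpha must be in (0,1)")
        if self.n_groups < 2 or self.n_measurements < 2:
            raise InvalidInputError("need at least 2 groups and 2 measurements")
        if not 0 <= self.corr_rho < 1:
            raise InvalidInputError("corr_rho must be in [0, 1)")
        if self.effect_size_f < 0:
            raise InvalidInputError("effect size f must be non-negative")


def independent_t(group_a, group_b) -> tuple[float, float]:
    """Two-sided pooled-variance independent-samples t-test: (t, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("need n >= 2 per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            raise DegenerateStatisticError("zero variance in both groups with equal means")
        # infinite t: report a hard zero p
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def mixed_anova_2x2(
    frame: pd.DataFrame,
    value: str = "value",
    subject: str = "subject",
    group: str = "group",
    session: str = "session",
) -> pd.DataFrame:
    """Classical split-plot ANOVA: one between factor, one repeated factor.

    Expects long format with one row per subject x session; every subject
    must have all sessions and exactly one group.  Unequal group sizes are
    allowed.  Returns a table with rows ``group``, ``time``, ``interaction``
    and their error strata.

    For two sessions the interaction F equals the squared pooled-variance
    independent t on change scores (an identity used as a test oracle).
    """
    df = frame[[subject, group, session, value]].dropna()
    piv = df.pivot_table(index=[subject, group], columns=session, values=value)
    if piv.isna().any().any():
        missing = piv[piv.isna().any(axis=1)].index.tolist()
        raise IncompleteDesignError(f"subjects missing sessions: {missing}")
    subj_group = piv.index.get_level_values(group).to_numpy()
    y = piv.to_numpy()  # subjects x sessions
    n_total, m = y.shape
    groups = np.unique(subj_group)
    g = groups.size
    if g < 2 or m < 2:
        raise IncompleteDesignError("need at least 2 groups and 2 sessions")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    time_means = y.mean(axis=0)
    ss_total = np.sum((y - grand) ** 2)
    ss_subjects = m * np.sum((subj_means - grand) ** 2)

    ss_group = 0.0
    ss_inter = 0.0
    ss_err_between = 0.0
    for gi in groups:
        sel = subj_group == gi
        ni = sel.sum()
        gm = y[sel].mean()
        ss_group += m * ni * (gm - grand) ** 2
        ss_err_between += m * np.sum((subj_means[sel] - gm) ** 2)
        cell = y[sel].mean(axis=0)
        ss_inter += ni * np.sum((cell - gm - time_means + grand) ** 2)
    ss_time = n_total * np.sum((time_means - grand) ** 2)
    ss_err_within = ss_total - ss_subjects - ss_time - ss_inter

    df_group, df_eb = g - 1, n_total - g
    df_time = m - 1
    df_inter = (g - 1) * (m - 1)
    df_ew = (n_total - g) * (m - 1)

    def effect(ss, df_num, ss_err, df_err):
        ms, ms_e = ss / df_num, ss_err / df_err
        scale = max(abs(grand), 1.0)
        if ms_e <= 1e-14 * scale**2:  # error stratum exhausted
            if ms <= 1e-14 * scale**2:
                return AnovaEffect(float(ss), df_num, float(ms), 0.0, 1.0)
            return AnovaEffect(float(ss), df_num, float(ms), np.inf, 0.0)
        f = ms / ms_e
        return AnovaEffect(float(ss), df_num, float(ms), float(f),
                           float(stats.f.sf(f, df_num, df_err)))

    eff = {
        "group": effect(ss_group, df_group, ss_err_between, df_eb),
        "time": effect(ss_time, df_time, ss_err_within, df_ew),
        "interaction": effect(ss_inter, df_inter, ss_err_within, df_ew),
    }
    out = pd.DataFrame(
        {
            "effect": list(eff) + ["error_between", "error_within"],
            "ss": [e.ss for e in eff.values()] + [float(ss_err_between), float(ss_err_within)],
            "df": [e.df for e in eff.values()] + [df_eb, df_ew],
            "F": [e.f for e in eff.values()] + [np.nan, np.nan],
            "p": [e.p for e in eff.values()] + [np.nan, np.nan],
        }
    ).set_index("effect")
    return out


def paired_change_test(pre, post) -> tuple[float, EffectSize]:
    """Within-group pre-post test: paired t (2 levels) plus a within-group d.

    d = mean change / pooled SD of the pre and post scores.  With zero
    change variance the test is degenerate; the exact constant change is
    reported in the raised error.
    """
    a = np.asarray(pre, dtype=float)
    b = np.asarray(post, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise InvalidInputError("pre/post must be paired with n >= 2")
    diff = b - a
    if np.allclose(diff.var(ddof=1), 0.0):
        raise DegenerateStatisticError(
            "zero change variance: paired test undefined",
            detail={"exact_change": float(diff.mean())},
        )
    _, p = stats.ttest_rel(b, a)
    sp = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    d = float(diff.mean() / sp)
    n = a.size
    # normal-approximation SE for a paired standardized change
    se = np.sqrt(2.0 * (1.0 / n) + d**2 / (2.0 * n))
    return float(p), EffectSize(d, (d - 1.96 * se, d + 1.96 * se), label_effect_size(d))


def cohens_d_from_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> EffectSize:
    """Pooled-SD Cohen's d from summary statistics, with 95% limits.

    sd_pooled = sqrt(((nA-1)sA^2 + (nB-1)sB^2) / (nA+nB-2));
    SE(d) = sqrt((nA+nB)/(nA*nB) + d^2/(2(nA+nB))) (normal approximation).
    """
    if n_a < 2 or n_b < 2:
        raise InvalidInputError("need n >= 2 per side")
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    if sp2 <= 0:
        raise DegenerateStatisticError("zero pooled SD: d undefined")
    d = (mean_a - mean_b) / np.sqrt(sp2)
    se = np.sqrt((n_a + n_b) / (n_a * n_b) + d**2 / (2 * (n_a + n_b)))
    return EffectSize(float(d), (float(d - 1.96 * se), float(d + 1.96 * se)),
                      label_effect_size(d))


def cohens_d_pooled(a, b) -> EffectSize:
    """Pooled-SD Cohen's d between two samples (a minus b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return cohens_d_from_summary(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


def label_effect_size(d: float) -> str:
    """Magnitude band of |d|: trivial <0.20, small, moderate, large, extremely large >2.00."""
    if not np.isfinite(d):
        raise InvalidInputError("d must be finite")
    m = abs(d)
    if m > 2.00:
        return "extremely large"
    for edge, name in _ES_BANDS:
        if m >= edge:
            return name
    return "trivial"


def percent_change(pre, post, mode: str = "per-subject") -> tuple[float, float]:
    """Percent change pre -> post: (mean %, SD %).

    ``per-subject`` (default): 100*(post-pre)/pre per subject, then mean and
    SD across subjects.  ``of-means``: single percent change of the group
    means (SD reported as 0).
    """
    a = np.asarray(pre, dtype=float)
    b = np.asarray(post, dtype=float)
    if a.shape != b.shape or a.size < 1:
        raise InvalidInputError("pre/post must be paired and nonempty")
    if np.any(a == 0):
        raise InvalidInputError("zero pre value: percent change undefined")
    if mode == "per-subject":
        pc = 100.0 * (b - a) / a
        sd = float(pc.std(ddof=1)) if pc.size > 1 else 0.0
        return float(pc.mean()), sd
    if mode == "of-means":
        return float(100.0 * (b.mean() - a.mean()) / a.mean()), 0.0
    raise InvalidInputError(f"unknown mode {mode!r}")


def achieved_power(spec: PowerSpec, n_total: int) -> float:
    """Power of the within-between interaction test at total sample size N.

    Noncentral-F computation with noncentrality
    lambda = f^2 * N * m * eps / (1 - rho), numerator df (g-1)(m-1)*eps and
    denominator df (N-g)(m-1)*eps, critical value at the specified alpha.
    """
    g, m, eps = spec.n_groups, spec.n_measurements, spec.nonsphericity_eps
    if n_total < g + 1:
        raise InvalidInputError(f"N must be at least g+1 = {g + 1}")
    lam = spec.effect_size_f**2 * n_total * m * eps / (1.0 - spec.corr_rho)
    df1 = (g - 1) * (m - 1) * eps
    df2 = (n_total - g) * (m - 1) * eps
    fcrit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    if lam == 0:
        return float(spec.alpha)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def required_sample_size(spec: PowerSpec, target_power: float = 0.8, n_max: int = 100000) -> int:
    """Smallest total N whose achieved interaction power reaches the target."""
    if not 0 < target_power < 1:
        raise InvalidInputError("target power must be in (0,1)")
    if spec.effect_size_f == 0:
        raise InvalidInputError("null effect size: no finite N reaches the target")
    for n in range(spec.n_groups + 1, n_max + 1):
        if achieved_power(spec, n) >= target_power:
            return n
    raise InvalidInputError(f"no N <= {n_max} reaches power {target_power}")
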