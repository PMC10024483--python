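"""Relative and absolute reliability of repeated sprint trials.

Relative reliability is the two-way mixed-effects, consistency, single-
measure intraclass correlation ICC(3,1): trials are fixed repeats of the
same device and protocol, subjects are random.  Absolute reliability is the
standard error of measurement SEM = SD*sqrt(1-ICC), from which the minimal
detectable change at 90% confidence is MDC = 1.645*SEM*sqrt(2), and
MDC% = 100*MDC/mean.  A measured pre-post change is flagged as a 'true'
change only when it exceeds the MDC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateStatisticError, InvalidInputError

__all__ = [
    "IccResult",
    "ReliabilityReport",
    "icc_single",
    "sem_from_icc",
    "mdc",
    "mdc_percent",
    "label_icc",
    "true_change_flag",
    "reliability_report",
    "MDC_FACTOR",
]

#: MDC/SEM ratio at 90% confidence: 1.645 * sqrt(2).
MDC_FACTOR = 1.645 * np.sqrt(2.0)

#: Qualitative ICC bands; lower edge inclusive.
_ICC_BANDS = [
    (0.99, "extremely high"),
    (0.90, "very high"),
    (0.75, "high"),
    (0.50, "moderate"),
    (-np.inf, "poor"),
]


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci95: tuple[float, float]
    ms_subjects: float
    ms_error: float
    n_subjects: int
    n_trials: int


@dataclass(frozen=True)
class ReliabilityReport:
    """Per-variable reliability summary (one row of the reliability table)."""

    variable: str
    icc: float
    icc_ci95: tuple[float, float]
    sem: float
    mdc: float
    mdc_percent: float
    icc_label: str


def icc_single(measurements: np.ndarray | pd.DataFrame, alpha: float = 0.05) -> IccResult:
    """ICC(3,1) with a 95% confidence interval from F-distribution bounds.

    Parameters
    ----------
    measurements
        ``(n_subjects, k_trials)`` matrix; complete (no missing cells).

    Notes
    -----
    With MS_R the between-subject and MS_E the residual mean square of the
    two-way (subject x trial) ANOVA,

        ICC(3,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E)

    and the CI follows from F = MS_R/MS_E with (n-1, (n-1)(k-1)) df.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2:
        raise InvalidInputError("measurements must be a 2-D subjects x trials matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise InvalidInputError("need at least 2 subjects and 2 trials")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("measurements must be complete and finite")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    if np.allclose(row_means.var(), 0.0):
        raise DegenerateStatisticError("zero between-subject variance: ICC undefined")

    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    df_rows = n - 1
    df_err = (n - 1) * (k - 1)
    ms_rows = ss_rows / df_rows
    ms_err = ss_err / df_err
    if ms_err <= 0:
        # perfect consistency: all error variance removed by subject+trial effects
        return IccResult(1.0, (1.0, 1.0), ms_rows, 0.0, n, k)

    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    f_obs = ms_rows / ms_err
    f_low = f_obs / stats.f.ppf(1 - alpha / 2, df_rows, df_err)
    f_up = f_obs * stats.f.ppf(1 - alpha / 2, df_err, df_rows)
    lo = (f_low - 1) / (f_low + k - 1)
    hi = (f_up - 1) / (f_up + k - 1)
    return IccResult(float(icc), (float(lo), float(hi)), float(ms_rows), float(ms_err), n, k)


def sem_from_icc(between_subject_sd: float, icc: float) -> float:
    """SEM = SD * sqrt(1 - ICC)."""
    if between_subject_sd < 0:
        raise InvalidInputError("sd must be non-negative")
    if icc > 1:
        raise InvalidInputError("icc cannot exceed 1")
    return between_subject_sd * np.sqrt(1.0 - icc)


def mdc(sem: float) -> float:
    """Minimal detectable change at 90% confidence: 1.645 * SEM * sqrt(2)."""
    if sem < 0:
        raise InvalidInputError("sem must be non-negative")
    return MDC_FACTOR * sem


def mdc_percent(mdc_value: float, grand_mean: float) -> float:
    """MDC as a percentage of the grand mean: 100 * MDC / mean."""
    if grand_mean == 0:
        raise InvalidInputError("grand mean of zero: MDC% undefined")
    return 100.0 * mdc_value / abs(grand_mean)


def label_icc(icc: float) -> str:
    """Qualitative ICC band: poor (<0.50), moderate, high, very high, extremely high."""
    if not np.isfinite(icc):
        raise InvalidInputError("icc must be finite")
    for edge, name in _ICC_BANDS:
        if icc >= edge:
            return name
    return "poor"


def true_change_flag(pre_mean: float, post_mean: float, mdc_value: float) -> bool:
    """True iff |post - pre| strictly exceeds the minimal detectable change."""
    for v in (pre_mean, post_mean, mdc_value):
        if not np.isfinite(v):
            raise InvalidInputError("inputs must be finite")
    return abs(post_mean - pre_mean) > mdc_value


def reliability_report(trial_matrices: dict[str, np.ndarray]) -> pd.DataFrame:
    """Reliability table over variables: ICC (CI), SEM, MDC, MDC%, label.

    Parameters
    ----------
    trial_matrices
        Variable name -> ``(n_subjects, k_trials)`` matrix of raw trial
        values (one session).  SEM uses the SD of all observations; MDC%
        uses the grand mean.
    """
    rows = []
    for name, mat in trial_matrices.items():
        mat = np.asarray(mat, dtype=float)
        res = icc_single(mat)
        sd = float(mat.std(ddof=1))
        sem = sem_from_icc(sd, res.icc)
        m = mdc(sem)
        rows.append(
            ReliabilityReport(
                variable=name,
                icc=res.icc,
                icc_ci95=res.ci95,
                sem=sem,
                mdc=m,
                mdc_percent=mdc_percent(m, float(mat.mean())),
                icc_label=label_icc(res.icc),
            )
        )
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "icc": [r.icc for r in rows],
            "icc_ci95_low": [r.icc_ci95[0] for r in rows],
            "icc_ci95_high": [r.icc_ci95[1] for r in rows],
            "sem": [r.sem for r in rows],
            "mdc": [r.mdc for r in rows],
            "mdc_percent": [r.mdc_percent for r in rows],
            "icc_label": [r.icc_label for r in rows],
        }
    )
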