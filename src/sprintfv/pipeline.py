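"""End-to-end study orchestration.

``run_study`` takes either a directory of radar trace CSVs with a manifest
(``files`` mode) or a synthetic cohort configuration (``simulate`` mode),
fits every trial, derives force-velocity profiles and split times, averages
the three trials of each athlete-session at the derived-variable level, and
produces the study's two summary tables: a reliability table (ICC, SEM, MDC,
MDC% per variable, from the pre-session trials) and a pre-post comparison
table (per-group means, within-group effects, percent change, 2x2 mixed
ANOVA) plus a machine-readable JSON of every statistic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .cohort import CohortConfig, simulate_study
from .errors import DegenerateStatisticError, SprintFVError, ValidationError
from .fitting import RadarTrace, aggregate_trials, fit_sprint_model, trim_trace
from .inference import (
    cohens_d_pooled,
    independent_t,
    label_effect_size,
    mixed_anova_2x2,
    paired_change_test,
    percent_change,
)
from .io import read_manifest, read_trace
from .model import (
    Athlete,
    EnvironmentConditions,
    derive_fv_profile,
    segment_time,
    split_table,
)
from .reliability import reliability_report, true_change_flag

__all__ = ["StudyConfig", "StudyTables", "run_study", "write_tables", "read_tables",
           "analyse_trace", "PROFILE_VARIABLES"]

log = logging.getLogger(__name__)

#: Variables carried through aggregation and the statistical layer.
PROFILE_VARIABLES = [
    "F0_rel", "v0", "Pmax_rel", "S_FV_rel", "RF_max", "D_RF",
    "t_5m", "t_10m", "t_15m", "t_20m", "t_10_20m",
]


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one full study run."""

    mode: str = "simulate"  # "simulate" | "files"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    manifest_path: str | None = None
    env: EnvironmentConditions = field(default_factory=EnvironmentConditions)
    onset_threshold: float = 0.3  # m/s
    onset_sustain: int = 3
    sim_mode: str = "mono_exp"
    seed: int = 0
    groups: tuple[str, str] = ("CST", "MST")

    def __post_init__(self):
        if self.mode not in ("simulate", "files"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "files" and not self.manifest_path:
            raise ValidationError("files mode requires manifest_path")


@dataclass
class StudyTables:
    """All study outputs."""

    profiles: pd.DataFrame  # per athlete-session trial-aggregated variables
    trials: pd.DataFrame  # per-trial fitted values and diagnostics
    reliability: pd.DataFrame  # Table-2 analogue
    comparison: pd.DataFrame  # Table-3 analogue
    pretest: pd.DataFrame  # pre-test between-group t-tests
    exclusions: list[dict]
    metadata: dict


def analyse_trace(
    trace: RadarTrace,
    athlete: Athlete,
    env: EnvironmentConditions,
    onset_threshold: float = 0.3,
    onset_sustain: int = 3,
) -> dict[str, float]:
    """Trim, fit and derive all per-trial variables for one radar trace."""
    trimmed, report = trim_trace(trace, onset_threshold, onset_sustain)
    fit = fit_sprint_model(trimmed)
    profile = derive_fv_profile(fit, athlete, env, sprint_distance=trace.sprint_distance)
    splits = split_table(fit)
    p = profile.as_dict()
    row = {
        "F0_rel": p["F0_rel"], "v0": p["v0"], "Pmax_rel": p["Pmax_rel"],
        "S_FV_rel": p["S_FV_rel"], "RF_max": p["RF_max"], "D_RF": p["D_RF"],
        "F0": p["F0"], "Pmax": p["Pmax"], "S_FV": p["S_FV"],
        "fv_linearity_r2": p["fv_linearity_r2"],
        "mss": fit.mss, "tau": fit.tau, "time_shift": fit.time_shift,
        "rmse": fit.rmse, "n_samples": fit.n_samples,
        "n_leading_removed": report.n_leading_removed,
        "n_trailing_removed": report.n_trailing_removed,
    }
    row.update(splits.as_dict())
    row["t_10_20m"] = segment_time(10.0, 20.0, fit)
    return row


def _gather_trials(config: StudyConfig) -> tuple[pd.DataFrame, list[dict]]:
    """Per-trial variable table and exclusion log."""
    rows, exclusions = [], []
    if config.mode == "simulate":
        traces, cohort = simulate_study(
            config.cohort, config.seed, env=config.env, mode=config.sim_mode
        )
        lookup = {sa.athlete.athlete_id: (sa.athlete, sa.group) for sa in cohort}
        items = [(tr, *lookup[tr.athlete_id]) for tr in traces]
    else:
        manifest = read_manifest(config.manifest_path)
        base = Path(config.manifest_path).parent
        items = []
        for _, r in manifest.iterrows():
            ath = Athlete(str(r["athlete"]), float(r["mass_kg"]), float(r["stature_m"]))
            tr = read_trace(
                base / r["file"], athlete_id=str(r["athlete"]),
                session=str(r["session"]), trial_index=int(r["trial"]),
            )
            items.append((tr, ath, str(r["group"])))
    for trace, athlete, group in items:
        try:
            row = analyse_trace(trace, athlete, config.env,
                                config.onset_threshold, config.onset_sustain)
        except SprintFVError as exc:
            exclusions.append(
                {"athlete": trace.athlete_id, "session": trace.session,
                 "trial": trace.trial_index, "reason": f"{type(exc).__name__}: {exc}"}
            )
            log.warning("trial %s/%s/%s excluded: %s", trace.athlete_id,
                        trace.session, trace.trial_index, exc)
            continue
        row.update({"athlete": trace.athlete_id, "group": group,
                    "session": trace.session, "trial": trace.trial_index})
        rows.append(row)
    return pd.DataFrame(rows), exclusions


def _comparison_table(profiles: pd.DataFrame, mdc_by_var: dict[str, float],
                      groups: tuple[str, str]) -> pd.DataFrame:
    """Table-3 analogue: per variable x group stats plus mixed-ANOVA effects."""
    rows = []
    for var in PROFILE_VARIABLES:
        wide = profiles.pivot_table(index=["athlete", "group"], columns="session",
                                    values=var)[["pre", "post"]]
        frame = profiles.rename(columns={var: "value"})[
            ["athlete", "group", "session", "value"]]
        anova = mixed_anova_2x2(frame, subject="athlete")
        ga = wide.xs(groups[0], level="group")
        gb = wide.xs(groups[1], level="group")
        # marginal standardized mean differences matching the ANOVA effects

        def safe_d(a, b):
            try:
                return cohens_d_pooled(a, b).d
            except DegenerateStatisticError:
                return 0.0

        d_group = safe_d(ga.mean(axis=1), gb.mean(axis=1))
        all_pre, all_post = wide["pre"].to_numpy(), wide["post"].to_numpy()
        d_time = safe_d(all_post, all_pre)
        d_int = safe_d(ga["post"] - ga["pre"], gb["post"] - gb["pre"])
        for gname, gw in ((groups[0], ga), (groups[1], gb)):
            pre, post = gw["pre"].to_numpy(), gw["post"].to_numpy()
            try:
                p_within, es_within = paired_change_test(pre, post)
                d_w, cl_w, lab_w = es_within.d, es_within.cl95, es_within.label
            except DegenerateStatisticError as exc:
                p_within, d_w, cl_w = np.nan, 0.0, (np.nan, np.nan)
                lab_w = f"degenerate ({exc.detail.get('exact_change', 0.0):+g} exact)"
            pc_mean, pc_sd = percent_change(pre, post)
            mdc_val = mdc_by_var.get(var, np.nan)
            rows.append({
                "variable": var, "group": gname, "n": len(gw),
                "pre_mean": pre.mean(), "pre_sd": pre.std(ddof=1),
                "post_mean": post.mean(), "post_sd": post.std(ddof=1),
                "within_d": d_w, "within_cl_low": cl_w[0], "within_cl_high": cl_w[1],
                "within_label": lab_w, "within_p": p_within,
                "pct_change_mean": pc_mean, "pct_change_sd": pc_sd,
                "true_change": (true_change_flag(pre.mean(), post.mean(), mdc_val)
                                if np.isfinite(mdc_val) else False),
                "group_F": anova.loc["group", "F"], "group_p": anova.loc["group", "p"],
                "group_es": d_group,
                "time_F": anova.loc["time", "F"], "time_p": anova.loc["time", "p"],
                "time_es": d_time,
                "interaction_F": anova.loc["interaction", "F"],
                "interaction_p": anova.loc["interaction", "p"],
                "interaction_es": d_int,
            })
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> StudyTables:
    """Execute the full pipeline and return all study tables.

    Trials that fail trimming or fitting are logged and their athlete's
    affected session is dropped if fewer than two trials survive; athletes
    missing a whole session are excluded from the comparison, mirroring the
    removal of participants who could not complete post-testing.
    """
    trials, exclusions = _gather_trials(config)
    if trials.empty:
        raise ValidationError("no trial could be analysed")

    agg_rows = []
    for (ath, grp, ses), sub in trials.groupby(["athlete", "group", "session"]):
        if len(sub) < 2:
            exclusions.append({"athlete": ath, "session": ses, "trial": None,
                               "reason": "fewer than 2 usable trials"})
            continue
        means = aggregate_trials(sub[PROFILE_VARIABLES])
        means.update({"athlete": ath, "group": grp, "session": ses, "n_trials": len(sub)})
        agg_rows.append(means)
    profiles = pd.DataFrame(agg_rows)

    # keep only athletes with both sessions
    counts = profiles.groupby("athlete")["session"].nunique()
    complete = counts[counts == 2].index
    for ath in counts[counts < 2].index:
        exclusions.append({"athlete": ath, "session": None, "trial": None,
                           "reason": "missing a session after trial exclusions"})
        log.warning("athlete %s dropped: missing a session", ath)
    profiles = profiles[profiles["athlete"].isin(complete)].reset_index(drop=True)

    # reliability from pre-session per-trial values (complete-trial athletes)
    pre = trials[trials["session"] == "pre"]
    mats = {}
    for var in PROFILE_VARIABLES:
        piv = pre.pivot_table(index="athlete", columns="trial", values=var).dropna()
        if len(piv) >= 2 and piv.shape[1] >= 2:
            mats[var] = piv.to_numpy()
    reliability = reliability_report(mats)
    mdc_by_var = dict(zip(reliability["variable"], reliability["mdc"]))

    # pre-test between-group comparison
    pre_rows = []
    pre_agg = profiles[profiles["session"] == "pre"]
    for var in PROFILE_VARIABLES:
        a = pre_agg.loc[pre_agg["group"] == config.groups[0], var].to_numpy()
        b = pre_agg.loc[pre_agg["group"] == config.groups[1], var].to_numpy()
        try:
            t, p = independent_t(a, b)
        except DegenerateStatisticError:
            t, p = 0.0, 1.0
        pre_rows.append({"variable": var, "t": t, "p": p})
    pretest = pd.DataFrame(pre_rows)

    comparison = _comparison_table(profiles, mdc_by_var, config.groups)

    cfg_dict = dataclasses.asdict(config)
    cfg_json = json.dumps(cfg_dict, default=str, sort_keys=True)
    metadata = {
        "seed": config.seed,
        "mode": config.mode,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "software_version": _version,
        "n_athletes_analysed": int(profiles["athlete"].nunique()),
        "n_trials_analysed": int(len(trials)),
        "n_exclusions": len(exclusions),
    }
    return StudyTables(profiles=profiles, trials=trials, reliability=reliability,
                       comparison=comparison, pretest=pretest,
                       exclusions=exclusions, metadata=metadata)


def write_tables(tables: StudyTables, outdir: str | Path) -> dict[str, Path]:
    """Write the study tables: reliability, comparison, profiles CSVs + run JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reliability": outdir / "table2_reliability.csv",
        "comparison": outdir / "table3_comparison.csv",
        "profiles": outdir / "profiles.csv",
        "run": outdir / "run.json",
    }
    tables.reliability.to_csv(paths["reliability"], index=False)
    tables.comparison.to_csv(paths["comparison"], index=False)
    tables.profiles.to_csv(paths["profiles"], index=False)
    payload = {
        "metadata": tables.metadata,
        "exclusions": tables.exclusions,
        "reliability": tables.reliability.to_dict(orient="records"),
        "comparison": tables.comparison.to_dict(orient="records"),
        "pretest": tables.pretest.to_dict(orient="records"),
    }
    paths["run"].write_text(json.dumps(payload, indent=1, default=float))
    return paths


def read_tables(outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Read back the CSV tables written by :func:`write_tables`."""
    outdir = Path(outdir)
    return {
        "reliability": pd.read_csv(outdir / "table2_reliability.csv"),
        "comparison": pd.read_csv(outdir / "table3_comparison.csv"),
        "profiles": pd.read_csv(outdir / "profiles.csv"),
    }
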