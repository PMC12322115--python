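"""Quartile-dichotomized survival analysis with 5-year truncation.

Subjects are split on a subclone (or pathway) score into a low group
(score <= lower quartile) and a high group (score >= upper quartile);
the middle half is excluded. Follow-up is administratively censored at a
60-month horizon. Group comparison uses the two-group log-rank test and a
univariate Cox proportional-hazards model with Efron tie handling (via
lifelines), reporting the hazard ratio with a 95% Wald interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from lifelines.utils import ConvergenceWarning

from evopharm.io import ValidationError


def quartile_groups(records: pd.DataFrame) -> dict[str, list[str]]:
    """Split subjects into high/low score groups at the outer quartiles.

    Quartiles use the linear-interpolation (type-7) convention. Subjects
    tied with the quartile value are included in the corresponding group.
    """
    if len(records) < 4:
        raise ValidationError("need >= 4 subjects for quartile dichotomization")
    scores = records["score"].to_numpy(dtype=float)
    if np.all(scores == scores[0]):
        raise ValidationError("all scores equal; no quartile separation")
    q1, q3 = np.quantile(scores, [0.25, 0.75])
    ids = records["subject_id"].astype(str)
    low = list(ids[scores <= q1])
    high = list(ids[scores >= q3])
    excluded = list(ids[(scores > q1) & (scores < q3)])
    return {"high": high, "low": low, "excluded": excluded}


def truncate_followup(records: pd.DataFrame, horizon: float = 60.0) -> pd.DataFrame:
    """Administratively censor all follow-up beyond the horizon (months)."""
    if horizon <= 0:
        raise ValidationError("horizon must be positive")
    out = records.copy()
    over = out["time_months"] > horizon
    out.loc[over, "time_months"] = horizon
    out.loc[over, "event"] = 0
    return out


def _group_frames(records: pd.DataFrame, groups: dict[str, list[str]]):
    by_id = records.set_index(records["subject_id"].astype(str))
    frames = {}
    for name in ("high", "low"):
        ids = groups.get(name, [])
        if not ids:
            raise ValidationError(f"empty group {name!r}")
        frames[name] = by_id.loc[ids]
    return frames


def logrank(records: pd.DataFrame, groups: dict[str, list[str]]):
    """Two-group log-rank statistic (chi2, p), df=1."""
    frames = _group_frames(records, groups)
    if frames["high"]["event"].sum() + frames["low"]["event"].sum() == 0:
        raise ValidationError("no events in either group")
    res = logrank_test(
        frames["high"]["time_months"], frames["low"]["time_months"],
        event_observed_A=frames["high"]["event"],
        event_observed_B=frames["low"]["event"],
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    hr: float
    ci95: tuple[float, float]
    p: float
    n_high: int
    n_low: int
    converged: bool


def cox_univariate(
    records: pd.DataFrame,
    groups: dict[str, list[str]] | None = None,
) -> CoxResult:
    """Univariate Cox PH fit: high-vs-low group indicator, or the raw score.

    With `groups`, the covariate is 1 for the high group and 0 for the low
    group and excluded subjects are dropped; without, the continuous score
    is used. A monotone likelihood (complete separation) is flagged via
    `converged=False` rather than raised.
    """
    if groups is not None:
        frames = _group_frames(records, groups)
        df = pd.concat([
            frames["high"].assign(x=1.0), frames["low"].assign(x=0.0),
        ])
        n_high, n_low = len(frames["high"]), len(frames["low"])
    else:
        df = records.assign(x=records["score"].astype(float))
        n_high = n_low = 0
    if df["x"].nunique() < 2:
        raise ValidationError("covariate is constant")
    fit_df = df[["time_months", "event", "x"]].reset_index(drop=True)
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            cph.fit(fit_df, duration_col="time_months", event_col="event",
                    fit_options={"precision": 1e-10})
        except (ConvergenceWarning, ConvergenceError):
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    cph.fit(fit_df, duration_col="time_months", event_col="event",
                    fit_options={"precision": 1e-10})
                except ConvergenceError:
                    return CoxResult(float("nan"), (float("nan"), float("nan")),
                                     float("nan"), n_high, n_low, False)
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    p = float(cph.summary.loc["x", "p"])
    lo, hi = np.exp(beta - 1.959963984540054 * se), np.exp(beta + 1.959963984540054 * se)
    return CoxResult(float(np.exp(beta)), (float(lo), float(hi)), p,
                     n_high, n_low, converged)


def km_table(records: pd.DataFrame, groups: dict[str, list[str]]) -> pd.DataFrame:
    """Kaplan–Meier survival table per group (time, at risk, survival)."""
    from lifelines import KaplanMeierFitter

    frames = _group_frames(records, groups)
    rows = []
    for name, frame in frames.items():
        km = KaplanMeierFitter()
        km.fit(frame["time_months"], frame["event"], label=name)
        surv = km.survival_function_
        for t, s in surv.itertuples():
            rows.append({"group": name, "time_months": float(t), "survival": float(s)})
    return pd.DataFrame(rows)
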