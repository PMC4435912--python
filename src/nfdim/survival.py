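"""5-year disease-specific survival (DSS) machinery.

Outcome preparation restricts follow-up to 60 months: a disease-specific
death within 60 months is an event at its death time; other-cause deaths
and disease deaths after 60 months are censored (at min(time, 60)). The
restriction is applied uniformly before cut-point search, log-rank tests
and Cox fits.

Kaplan-Meier estimation, the two-group log-rank test and Cox
proportional-hazards fits (Efron tie handling, 95% Wald intervals) are
delegated to lifelines behind this module's interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .cohort import PatientRecord
from .errors import DegenerateGroupError, FitFailureError, InvalidRecordError

DSS_HORIZON_MONTHS = 60.0


@dataclass
class SurvivalRecord:
    """One patient's restricted outcome plus analysis covariates."""

    patient_id: str
    time_months: float
    event: bool
    group: str | None = None
    covariates: dict = field(default_factory=dict)


@dataclass
class CoxResult:
    """Hazard ratios with 95% Wald intervals for one proportional-hazards fit."""

    table: pd.DataFrame  # index: covariate; columns: hazard_ratio, ci_low, ci_high, p
    n: int
    n_events: int

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hazard_ratio"])


def prepare_dss(
    records: Sequence[PatientRecord],
    horizon_months: float = DSS_HORIZON_MONTHS,
) -> list[SurvivalRecord]:
    """Cap follow-up at the horizon and derive the DSS event indicator."""
    out = []
    for r in records:
        if r.time_months is None or r.time_months <= 0:
            raise InvalidRecordError(
                f"patient {r.patient_id!r}: non-positive or missing time "
                f"({r.time_months})"
            )
        event = bool(r.dss_event) and r.time_months <= horizon_months
        out.append(
            SurvivalRecord(
                patient_id=r.patient_id,
                time_months=min(float(r.time_months), horizon_months),
                event=event,
                group=r.nfd_group,
                covariates=dict(r.covariates),
            )
        )
    return out


def km_estimate(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Product-limit survival estimate as a tidy (time, survival) table."""
    if not records:
        raise InvalidRecordError("empty input")
    kmf = KaplanMeierFitter()
    kmf.fit(
        durations=[r.time_months for r in records],
        event_observed=[r.event for r in records],
    )
    df = kmf.survival_function_.reset_index()
    df.columns = ["time_months", "survival"]
    return df


def logrank(
    a: Sequence[SurvivalRecord], b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test (1 df); returns (chi_square, p_value)."""
    if not a or not b:
        raise DegenerateGroupError("both groups must be non-empty")
    if sum(r.time_months for r in a) == 0 or sum(r.time_months for r in b) == 0:
        raise DegenerateGroupError("a group contributes no at-risk time")
    res = logrank_test(
        [r.time_months for r in a],
        [r.time_months for r in b],
        event_observed_A=[r.event for r in a],
        event_observed_B=[r.event for r in b],
    )
    return float(res.test_statistic), float(res.p_value)


def logrank_scan(
    times: np.ndarray,
    events: np.ndarray,
    values: np.ndarray,
    candidates: np.ndarray,
) -> np.ndarray:
    """Two-group log-rank chi-square for every candidate dichotomization.

    For each candidate c the groups are ``values <= c`` versus
    ``values > c``. Vectorized over candidates: the at-risk matrix is
    built once per (event time, candidate) pair, using the standard
    hypergeometric variance with the multiplicity correction for tied
    event times. Agrees with the pairwise log-rank test applied per
    candidate (asserted in the test suite).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    values = np.asarray(values, float)
    candidates = np.asarray(candidates, float)

    event_times = np.unique(times[events])
    # d_j: events at t_j; n_j: at risk at t_j (whole cohort)
    d = np.array([(events & (times == t)).sum() for t in event_times], float)
    n = np.array([(times >= t).sum() for t in event_times], float)
    # group-1 membership per candidate: (n_candidates, n_patients)
    in_high = values[None, :] > candidates[:, None]
    # n1_j, d1_j per candidate: (n_candidates, n_times)
    at_risk = times[None, :] >= event_times[:, None]  # (n_times, n_patients)
    event_at = (events[None, :] & (times[None, :] == event_times[:, None]))
    n1 = in_high @ at_risk.T.astype(float)
    d1 = in_high @ event_at.T.astype(float)

    frac = n1 / n[None, :]
    expected = (d[None, :] * frac).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_terms = (
            d[None, :] * frac * (1 - frac) * (n[None, :] - d[None, :])
            / np.maximum(n[None, :] - 1, 1)
        )
    variance = var_terms.sum(axis=1)
    observed = d1.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(variance > 0, (observed - expected) ** 2 / variance, 0.0)
    return chi2


def cox_fit(
    records: Sequence[SurvivalRecord],
    covariates: Sequence[str],
    min_events: int = 10,
) -> CoxResult:
    """Cox proportional-hazards fit on the named 0/1-encodable covariates.

    Binary factors follow the reference codings of the study design: for
    ``nfd_group`` the hazard of high relative to low (high = 1); for
    ``pt_stage`` T3/T4 relative to T1/T2; for ``pn_status`` N1/N2 relative
    to N0; for ``treatment`` surgery+RT relative to surgery alone.
    """
    df = _design_matrix(records, covariates)
    n_events = int(df["event"].sum())
    if n_events < min_events:
        raise InvalidRecordError(f"need >= {min_events} events, got {n_events}")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        # near-separated bootstrap cohorts trigger advisory warnings from
        # the fitter; genuine non-convergence still raises below
        from lifelines.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.filterwarnings("ignore", message=".*variance matrix.*")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceError as exc:  # carries lifelines' iteration trace
            raise FitFailureError(str(exc)) from exc
    summary = cph.summary
    table = pd.DataFrame(
        {
            "hazard_ratio": summary["exp(coef)"],
            "ci_low": summary["exp(coef) lower 95%"],
            "ci_high": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )
    table.index.name = "covariate"
    return CoxResult(table=table, n=len(df), n_events=n_events)


_BINARY_CODING = {
    "nfd_group": {"low": 0, "high": 1},
    "li_group": {"low": 0, "high": 1},
    "ki67_group": {"low": 0, "high": 1},
    "pt_stage": {"low": 0, "high": 1},
    "pn_status": {"N0": 0, "N1/N2": 1},
    "treatment": {"surgery": 0, "surgery+RT": 1},
}


def _encode(name: str, value):
    if value is None:
        return np.nan
    coding = _BINARY_CODING.get(name)
    if coding is not None:
        if value not in coding:
            raise InvalidRecordError(f"{name}: unknown level {value!r}")
        return coding[value]
    return float(value)


def _design_matrix(
    records: Sequence[SurvivalRecord], covariates: Sequence[str]
) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"time": r.time_months, "event": int(r.event)}
        for name in covariates:
            value = r.group if name == "nfd_group" else r.covariates.get(name)
            row[name] = _encode(name, value)
        rows.append(row)
    # complete-case with respect to the requested covariates
    return pd.DataFrame(rows).dropna().reset_index(drop=True)


def percent_hazard_reduction(hazard_ratio: float) -> float:
    """Percent reduction in hazard implied by an HR below 1."""
    return 100.0 * (1.0 - hazard_ratio)
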