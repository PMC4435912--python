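"""Shared fixtures and independent oracles.

The oracle implementations here are deliberately naive (explicit loops,
closed forms, full enumeration) and independent of the library code paths
they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from nfdim.cohort import PatientRecord
from nfdim.synthetic import SyntheticCohortConfig, generate_cohort


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_box_count(bits: np.ndarray, size: int) -> int:
    """Explicit double loop over grid cells; the counting oracle."""
    h, w = bits.shape
    count = 0
    for i0 in range(0, h, size):
        for j0 in range(0, w, size):
            if bits[i0: i0 + size, j0: j0 + size].any():
                count += 1
    return count


def ols_slope_closed_form(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form least squares slope/intercept on (x, y)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xbar, ybar = x.mean(), y.mean()
    slope = float(((x - xbar) * (y - ybar)).sum() / ((x - xbar) ** 2).sum())
    return slope, float(ybar - slope * xbar)


def fisher_p_enumeration(table: np.ndarray) -> float:
    """Two-sided Fisher p by full enumeration over 2x2 tables with the
    observed margins (point-probability rule)."""
    table = np.asarray(table, int)
    r0, r1 = table.sum(axis=1)
    c0, _ = table.sum(axis=0)
    n = table.sum()

    def log_prob(a: int) -> float:
        b, c = r0 - a, c0 - a
        d = r1 - c
        if min(b, c, d) < 0:
            return -math.inf
        return (
            math.lgamma(r0 + 1) + math.lgamma(r1 + 1)
            + math.lgamma(c0 + 1) + math.lgamma(n - c0 + 1)
            - math.lgamma(n + 1) - math.lgamma(a + 1) - math.lgamma(b + 1)
            - math.lgamma(c + 1) - math.lgamma(d + 1)
        )

    lp_obs = log_prob(table[0, 0])
    total = 0.0
    for a in range(0, min(r0, c0) + 1):
        lp = log_prob(a)
        if lp > -math.inf and lp <= lp_obs + 1e-10:
            total += math.exp(lp)
    return min(total, 1.0)


def logrank_chi2_by_hand(times_a, events_a, times_b, events_b) -> float:
    """O-E tabulation of the two-group log-rank statistic, written plainly."""
    times_a, times_b = list(times_a), list(times_b)
    all_times = sorted(
        {t for t, e in zip(times_a + times_b, list(events_a) + list(events_b)) if e}
    )
    o_minus_e = 0.0
    var = 0.0
    for t in all_times:
        n_a = sum(1 for x in times_a if x >= t)
        n_b = sum(1 for x in times_b if x >= t)
        d_a = sum(1 for x, e in zip(times_a, events_a) if e and x == t)
        d_b = sum(1 for x, e in zip(times_b, events_b) if e and x == t)
        n, d = n_a + n_b, d_a + d_b
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def slow_cutpoint_scan(records, min_group_fraction=0.10):
    """Second, independently coded exhaustive cut-point scan.

    Uses the hand-written log-rank tabulation per candidate; returns
    (cut_value, chi_square)."""
    usable = [
        r for r in records
        if r.mean_nfd is not None and r.time_months is not None
        and r.dss_event is not None
    ]
    n = len(usable)
    times = [min(r.time_months, 60.0) for r in usable]
    events = [bool(r.dss_event) and r.time_months <= 60.0 for r in usable]
    nfd = [r.mean_nfd for r in usable]
    distinct = sorted(set(nfd))
    best = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        cut = 0.5 * (lo + hi)
        high = [v > cut for v in nfd]
        n_high = sum(high)
        if n_high < min_group_fraction * n or n - n_high < min_group_fraction * n:
            continue
        chi2 = logrank_chi2_by_hand(
            [t for t, h in zip(times, high) if not h],
            [e for e, h in zip(events, high) if not h],
            [t for t, h in zip(times, high) if h],
            [e for e, h in zip(events, high) if h],
        )
        if best is None or chi2 > best[1] + 1e-12:
            best = (cut, chi2)
    return best


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def recovery_cohort():
    """One seeded end-to-end cohort under the default study conditions."""
    config = SyntheticCohortConfig(n_patients=300, seed=11)
    return generate_cohort(config), config


def latent_patients(patients, cores) -> list[PatientRecord]:
    """Aggregate latent core scores into analysis-ready patient records."""
    from nfdim import cohort as C

    kept, _ = C.qc_filter(cores)
    by_patient: dict[str, list] = {}
    for c in kept:
        by_patient.setdefault(c.patient_id, []).append(c)
    records = [C.aggregate_patient(v) for v in by_patient.values()]
    outcome = {p.patient_id: (p.time_months, p.dss_event, p.covariates)
               for p in patients}
    for r in records:
        r.time_months, r.dss_event, r.covariates = outcome[r.patient_id]
    return records
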