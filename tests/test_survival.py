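"""Tests for the 5-year disease-specific survival machinery."""

import numpy as np
import pytest

from nfdim.cohort import PatientRecord
from nfdim.errors import DegenerateGroupError, InvalidRecordError
from nfdim.survival import (
    SurvivalRecord,
    cox_fit,
    km_estimate,
    logrank,
    logrank_scan,
    percent_hazard_reduction,
    prepare_dss,
)

from conftest import logrank_chi2_by_hand


def patient(pid, t, event, **kw):
    return PatientRecord(patient_id=pid, time_months=t, dss_event=event, **kw)


def srec(t, event, group=None, **cov):
    return SurvivalRecord(patient_id="x", time_months=t, event=event,
                          group=group, covariates=cov)


class TestPrepareDss:
    def test_late_disease_death_is_censored_at_horizon(self):
        [r] = prepare_dss([patient("a", 70.0, True)])
        assert (r.time_months, r.event) == (60.0, False)

    def test_early_disease_death_is_event(self):
        [r] = prepare_dss([patient("a", 12.0, True)])
        assert (r.time_months, r.event) == (12.0, True)

    def test_other_cause_death_is_censored(self):
        [r] = prepare_dss([patient("a", 30.0, False)])
        assert (r.time_months, r.event) == (30.0, False)

    def test_non_positive_time_rejected(self):
        with pytest.raises(InvalidRecordError):
            prepare_dss([patient("a", 0.0, True)])


class TestKaplanMeier:
    def test_single_event_step(self):
        df = km_estimate([srec(5.0, True)])
        s = dict(zip(df.time_months, df.survival))
        assert s[0.0] == 1.0 and s[5.0] == 0.0

    def test_two_events_halve_then_zero(self):
        df = km_estimate([srec(5.0, True), srec(10.0, True)])
        s = dict(zip(df.time_months, df.survival))
        assert s[5.0] == pytest.approx(0.5) and s[10.0] == 0.0

    def test_censoring_before_event_shrinks_risk_set(self):
        # at t=5 the risk set is a single patient, so S drops to 0
        df = km_estimate([srec(4.0, False), srec(5.0, True)])
        s = dict(zip(df.time_months, df.survival))
        assert s[5.0] == 0.0

    def test_no_censoring_equals_empirical_survival(self):
        # with every subject an event, the product-limit estimator reduces
        # to the empirical survival function S(t) = P(T > t)
        rng = np.random.default_rng(8)
        times = rng.exponential(20, 50).round(1) + 0.1
        records = [srec(float(t), True) for t in times]
        df = km_estimate(records)
        for t in sorted(set(times)):
            s_here = float(df.loc[df.time_months == t, "survival"].iloc[0])
            assert s_here == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidRecordError):
            km_estimate([])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        group = [srec(float(t), True) for t in (3, 6, 9)]
        chi2, p = logrank(group, list(group))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_oe_table(self):
        a_times, b_times = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
        a = [srec(t, True) for t in a_times]
        b = [srec(t, True) for t in b_times]
        chi2, _ = logrank(a, b)
        expected = logrank_chi2_by_hand(a_times, [True] * 3, b_times, [True] * 3)
        assert chi2 == pytest.approx(expected, abs=1e-9)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        a = [srec(float(t), bool(e)) for t, e in
             zip(rng.exponential(30, 40), rng.uniform(size=40) < 0.7)]
        b = [srec(float(t), bool(e)) for t, e in
             zip(rng.exponential(20, 35), rng.uniform(size=35) < 0.7)]
        assert logrank(a, b)[0] == pytest.approx(logrank(b, a)[0], abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateGroupError):
            logrank([], [srec(1.0, True)])

    def test_null_rejection_rate_is_nominal(self):
        """Under a true hazard ratio of 1 the test keeps its size."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.exponential(50, 1000)
            b = rng.exponential(50, 1000)
            times = np.concatenate([a, b]).clip(max=60)
            events = np.concatenate([a, b]) <= 60
            chi2 = logrank_scan(
                times, events,
                values=np.r_[np.zeros(1000), np.ones(1000)],
                candidates=np.array([0.5]),
            )[0]
            from scipy import stats
            rejections += stats.chi2.sf(chi2, 1) < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09


class TestLogrankScan:
    def test_scan_equals_pairwise_test_at_every_candidate(self):
        rng = np.random.default_rng(5)
        n = 60
        times = rng.exponential(40, n).clip(0.5, 60)
        events = rng.uniform(size=n) < 0.6
        values = rng.normal(1.5, 0.1, n)
        candidates = np.quantile(values, [0.2, 0.4, 0.6, 0.8])
        chi2 = logrank_scan(times, events, values, candidates)
        for c, x in zip(candidates, chi2):
            high = values > c
            a = [srec(float(t), bool(e)) for t, e in
                 zip(times[~high], events[~high])]
            b = [srec(float(t), bool(e)) for t, e in
                 zip(times[high], events[high])]
            assert x == pytest.approx(logrank(a, b)[0], abs=1e-9)


class TestCox:
    def test_identical_groups_have_unit_hazard_ratio(self):
        rng = np.random.default_rng(1)
        base = [(float(t), bool(e)) for t, e in
                zip(rng.exponential(30, 60), rng.uniform(size=60) < 0.8)]
        records = [srec(t, e, group="low") for t, e in base]
        records += [srec(t, e, group="high") for t, e in base]
        res = cox_fit(records, ["nfd_group"])
        assert res.hazard_ratio("nfd_group") == pytest.approx(1.0, abs=1e-6)

    def test_coding_flip_inverts_hazard_ratio(self):
        rng = np.random.default_rng(2)
        records = []
        for i in range(300):
            high = i % 2 == 0
            t = rng.exponential(1 / (0.01 * (0.4 if high else 1.0)))
            records.append(srec(float(min(t, 60)), bool(t <= 60),
                                group="high" if high else "low"))
        hr = cox_fit(records, ["nfd_group"]).hazard_ratio("nfd_group")
        flipped = [srec(r.time_months, r.event,
                        group="low" if r.group == "high" else "high")
                   for r in records]
        hr_flip = cox_fit(flipped, ["nfd_group"]).hazard_ratio("nfd_group")
        assert hr * hr_flip == pytest.approx(1.0, abs=1e-6)

    def test_score_test_at_null_equals_logrank_without_ties(self):
        # with a single binary covariate and no tied event times the Cox
        # partial-likelihood score test at beta=0 equals the log-rank
        # statistic exactly: U(0) = sum(x_i - xbar_risk), I(0) = sum of
        # risk-set variances of x
        rng = np.random.default_rng(7)
        times = rng.exponential(30, 80)  # continuous: no ties
        events = rng.uniform(size=80) < 0.7
        x = np.r_[np.zeros(40), np.ones(40)]
        u = info = 0.0
        for t in times[events]:
            risk = times >= t
            p = x[risk].mean()
            i = int(np.flatnonzero(times == t)[0])
            u += x[i] - p
            info += p * (1 - p)
        chi2_score = u**2 / info
        a = [srec(float(t), bool(e)) for t, e in zip(times[:40], events[:40])]
        b = [srec(float(t), bool(e)) for t, e in zip(times[40:], events[40:])]
        chi2_lr, _ = logrank(a, b)
        assert chi2_lr == pytest.approx(chi2_score, abs=1e-6)

    def test_binary_recovery_and_ci_coverage(self):
        """True HR 0.5 cohorts: point estimate near truth, CI covers it."""
        rng = np.random.default_rng(9)
        covered = 0
        n_rep = 60
        estimates = []
        for _ in range(n_rep):
            high = rng.uniform(size=1000) < 0.5
            hazard = 0.02 * np.where(high, 0.5, 1.0)
            t = rng.exponential(1.0 / hazard)
            censor = np.minimum(rng.exponential(120, 1000), 60.0)
            records = [
                srec(float(min(ti, ci)), bool(ti <= ci),
                     group="high" if h else "low")
                for ti, ci, h in zip(t, censor, high)
            ]
            res = cox_fit(records, ["nfd_group"])
            row = res.table.loc["nfd_group"]
            estimates.append(row["hazard_ratio"])
            covered += row["ci_low"] <= 0.5 <= row["ci_high"]
        assert 0.42 <= float(np.median(estimates)) <= 0.60
        assert covered / n_rep >= 0.90

    def test_multivariate_recovery(self):
        """Three independent binary covariates with true HRs (0.2, 2, 2)."""
        rng = np.random.default_rng(12)
        n = 1500
        x = rng.uniform(size=(n, 3)) < 0.5
        true_hr = np.array([0.2, 2.0, 2.0])
        hazard = 0.01 * np.prod(np.where(x, true_hr, 1.0), axis=1)
        t = rng.exponential(1.0 / hazard)
        censor = np.minimum(rng.exponential(200, n), 60.0)
        records = [
            SurvivalRecord(
                patient_id=str(i), time_months=float(min(t[i], censor[i])),
                event=bool(t[i] <= censor[i]),
                covariates={"a": int(x[i, 0]), "b": int(x[i, 1]),
                            "c": int(x[i, 2])},
            )
            for i in range(n)
        ]
        res = cox_fit(records, ["a", "b", "c"])
        for name, hr_true in zip("abc", true_hr):
            assert res.hazard_ratio(name) == pytest.approx(hr_true, rel=0.25)

    def test_too_few_events_rejected(self):
        records = [srec(10.0, False, group="low") for _ in range(30)]
        records += [srec(10.0, True, group="high") for _ in range(3)]
        with pytest.raises(InvalidRecordError):
            cox_fit(records, ["nfd_group"])


def test_percent_hazard_reduction():
    assert percent_hazard_reduction(0.09) == pytest.approx(91.0)
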