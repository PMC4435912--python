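"""Association tests between nFD group and clinico-pathological covariates.

Covers the contingency-table comparisons of the clinical-characteristics
table (Fisher's exact test, complete-case per covariate) and the group
comparisons of continuous nFD against proliferation (Ki67) and lymphocytic
infiltration groups (two-sided Wilcoxon rank-sum by default, Welch t as a
configurable alternative).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PatientRecord
from .errors import InvalidParameterError, UndefinedTestError

log = logging.getLogger(__name__)

#: Largest table total for which the r x c exact test enumerates all tables.
EXACT_RXC_MAX_N = 200


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise InvalidParameterError(
                f"contingency table must be at least 2x2, got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise InvalidParameterError("counts must be non-negative")

    @property
    def degenerate(self) -> bool:
        """True when a margin is zero (no valid test)."""
        return (
            self.counts.sum() == 0
            or (self.counts.sum(axis=0) == 0).any()
            or (self.counts.sum(axis=1) == 0).any()
        )


def crosstab(
    records: Sequence[PatientRecord], covariate: str
) -> ContingencyTable:
    """Covariate levels x nFD group counts, complete-case on both."""
    rows = []
    for r in records:
        if r.nfd_group is None:
            continue
        value = _covariate_value(r, covariate)
        if value is not None:
            rows.append((str(value), r.nfd_group))
    if not rows:
        raise UndefinedTestError(f"covariate {covariate!r}: no complete cases")
    df = pd.DataFrame(rows, columns=[covariate, "nfd_group"])
    table = pd.crosstab(df[covariate], df["nfd_group"])
    # fixed column order low, high; rows in sorted level order
    for col in ("low", "high"):
        if col not in table.columns:
            table[col] = 0
    table = table[["low", "high"]]
    return ContingencyTable(
        row_labels=[str(x) for x in table.index],
        col_labels=["low", "high"],
        counts=table.to_numpy(),
    )


def _covariate_value(record: PatientRecord, covariate: str):
    if covariate == "li_group":
        return record.li_group
    if covariate in record.covariates:
        return record.covariates.get(covariate)
    if covariate not in (
        "gender", "pt_stage", "pn_status", "smoking", "alcohol",
        "differentiation", "treatment", "ki67_group",
    ):
        raise InvalidParameterError(f"unknown covariate {covariate!r}")
    return None


def fishers_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Two-sidedness follows the point-probability rule: the sum of
    hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's.
    """
    if table.counts.shape != (2, 2):
        raise InvalidParameterError(
            f"fishers_exact needs a 2x2 table, got {table.counts.shape}; "
            "use exact_rxc for larger tables"
        )
    if table.degenerate:
        raise UndefinedTestError("zero margin: Fisher's exact test undefined")
    return float(stats.fisher_exact(table.counts, alternative="two-sided").pvalue)


def exact_rxc(table: ContingencyTable) -> tuple[float, str]:
    """Generalized Fisher exact test for r x c tables by full enumeration.

    Enumerates every table with the observed margins, summing the
    (multivariate hypergeometric) probabilities of tables no more probable
    than the observed one. Falls back to the chi-square test (with a logged
    warning) when the table total exceeds ``EXACT_RXC_MAX_N``; returns
    (p_value, test_name).
    """
    if table.degenerate:
        raise UndefinedTestError("zero margin: exact test undefined")
    counts = table.counts
    if counts.shape == (2, 2):
        return fishers_exact(table), "fisher_exact"
    if counts.sum() > EXACT_RXC_MAX_N:
        log.warning(
            "table total %d > %d: using chi-square approximation",
            counts.sum(), EXACT_RXC_MAX_N,
        )
        chi2 = stats.chi2_contingency(counts, correction=False)
        return float(chi2.pvalue), "chi_square"

    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    log_obs = _log_table_prob(counts, row_sums, col_sums)
    total = 0.0
    for candidate in _tables_with_margins(tuple(row_sums), tuple(col_sums)):
        lp = _log_table_prob(candidate, row_sums, col_sums)
        if lp <= log_obs + 1e-10:
            total += math.exp(lp)
    return float(min(total, 1.0)), "fisher_exact"


def _log_table_prob(counts, row_sums, col_sums) -> float:
    n = int(np.sum(row_sums))
    lp = (
        sum(math.lgamma(r + 1) for r in row_sums)
        + sum(math.lgamma(c + 1) for c in col_sums)
        - math.lgamma(n + 1)
        - float(np.vectorize(lambda x: math.lgamma(x + 1))(np.asarray(counts)).sum())
    )
    return lp


def _tables_with_margins(row_sums: tuple[int, ...], col_sums: tuple[int, ...]):
    """Yield every non-negative integer matrix with the given margins."""
    if len(row_sums) == 1:
        yield np.array([col_sums], dtype=int)
        return
    first, rest = row_sums[0], row_sums[1:]
    for row in _rows_summing_to(first, col_sums):
        remaining = tuple(c - x for c, x in zip(col_sums, row))
        for sub in _tables_with_margins(rest, remaining):
            yield np.vstack([np.array(row, dtype=int), sub])


def _rows_summing_to(total: int, caps: tuple[int, ...]):
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    for x in range(min(total, caps[0]) + 1):
        for rest in _rows_summing_to(total - x, caps[1:]):
            yield (x, *rest)


def rank_compare(
    a: Sequence[float], b: Sequence[float], method: str = "wilcoxon"
) -> tuple[float, float]:
    """Two-sided comparison of continuous nFD between two groups.

    ``method``: 'wilcoxon' (rank-sum, default) or 'welch' (unequal-variance
    t). Returns (statistic, p_value). Identical pooled values are a
    degenerate comparison with p = 1.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidParameterError("each group needs >= 2 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return (float(len(a) * len(b) / 2.0), 1.0) if method == "wilcoxon" else (0.0, 1.0)
    if method == "wilcoxon":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    raise InvalidParameterError(f"unknown method {method!r}")


def boxplot_summary(values_by_group: dict[str, Sequence[float]]) -> pd.DataFrame:
    """Five-number summary (min, Q1, median, Q3, max) per group.

    Quartiles use linear interpolation, matching standard box-plot hinges.
    """
    rows = {}
    for name, values in values_by_group.items():
        v = np.asarray(values, float)
        if v.size < 1:
            raise InvalidParameterError(f"group {name!r} is empty")
        rows[name] = dict(
            zip(
                ["min", "q1", "median", "q3", "max"],
                np.percentile(v, [0, 25, 50, 75, 100], method="linear"),
            )
        )
    return pd.DataFrame(rows).T
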