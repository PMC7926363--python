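"""Contingency tables, the chi-square/Fisher selection rule, and exact tests.

For each categorical comparison a test decides whether observed frequencies
depart from the expected frequencies of a contingency table.  When at least
80% of the cells have an expected count of five or more and no expected
count is zero, Pearson's chi-squared test (without continuity correction)
is used; otherwise Fisher's exact test.  Fisher's test is implemented for
general r x c tables by full enumeration of tables with the observed
margins, summing the probabilities of all tables no more probable than the
observed one under the multivariate hypergeometric law — the convention of
mainstream exact-test implementations.  A Monte-Carlo fallback is available
when the margins make enumeration infeasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2_contingency, random_table

from .schema import Codebook, DEFAULT_CODEBOOK, Evaluation, PatientRecord

__all__ = [
    "ContingencyTable",
    "TestResult",
    "choose_test",
    "pearson_chi2",
    "fisher_exact",
    "crosstab",
]


@dataclass
class ContingencyTable:
    row_labels: list
    col_labels: list
    counts: np.ndarray
    missing_per_column: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def expected(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("zero grand total")
        return np.outer(self.row_margins, self.col_margins) / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass
class TestResult:
    test: str                       # pearson_chi2 | fisher_exact
    p_value: float
    statistic: float | None = None
    df: int | None = None
    expected_matrix: np.ndarray | None = None


def _as_table(table) -> ContingencyTable:
    if isinstance(table, ContingencyTable):
        return table
    arr = np.asarray(table)
    return ContingencyTable(
        row_labels=list(range(arr.shape[0])),
        col_labels=list(range(arr.shape[1])),
        counts=arr,
    )


def choose_test(table) -> str:
    """Apply the expected-count selection rule.

    Returns ``"pearson_chi2"`` iff at least 80% of cells have an expected
    count of five or more and the minimum expected count is positive,
    otherwise ``"fisher_exact"``.  Degenerate tables (fewer than two rows or
    columns, or a zero margin) are rejected.
    """
    t = _as_table(table)
    if t.counts.shape[0] < 2 or t.counts.shape[1] < 2:
        raise ValueError("need at least a 2 x 2 table")
    if (t.row_margins == 0).any() or (t.col_margins == 0).any():
        raise ValueError("zero row or column margin")
    E = t.expected()
    if (E >= 5).mean() >= 0.8 and E.min() > 0:
        return "pearson_chi2"
    return "fisher_exact"


def pearson_chi2(table) -> TestResult:
    """Pearson's chi-squared test of independence, no continuity correction."""
    t = _as_table(table)
    E = t.expected()
    if (E == 0).any():
        raise ValueError("zero expected count: chi-squared statistic undefined")
    res = chi2_contingency(t.counts, correction=False)
    return TestResult(
        test="pearson_chi2",
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        df=int(res.dof),
        expected_matrix=res.expected_freq,
    )


_REL_EPS = 1e-7  # tolerance factor on the observed table's probability


def fisher_exact(
    table,
    max_tables: int = 20_000_000,
    monte_carlo: bool = False,
    n_resamples: int = 200_000,
    seed: int | None = 0,
) -> TestResult:
    """Fisher's exact test on an r x c table with fixed margins.

    The p-value sums the multivariate-hypergeometric probabilities of every
    table with the observed margins whose probability does not exceed the
    observed table's (times ``1 + 1e-7``).  Enumeration walks tables row by
    row; if the margins admit more than ``max_tables`` candidate branches,
    an error advises the ``monte_carlo`` flag, which estimates the same
    p-value by sampling tables with fixed margins.
    """
    t = _as_table(table)
    counts = t.counts.astype(int)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("Fisher's exact test needs at least a 2 x 2 table")
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    N = int(counts.sum())
    if N == 0:
        raise ValueError("zero grand total")
    const = float(gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(N + 1))

    def logprob(tab: np.ndarray) -> float:
        return const - float(gammaln(tab + 1).sum())

    lp_obs = logprob(counts)
    cutoff = lp_obs + np.log1p(_REL_EPS)

    if monte_carlo:
        rng = np.random.default_rng(seed)
        samples = random_table(rows, cols).rvs(size=n_resamples, random_state=rng)
        lps = const - gammaln(samples + 1).sum(axis=(1, 2))
        hits = int((lps <= cutoff).sum())
        return TestResult(test="fisher_exact", p_value=(hits + 1) / (n_resamples + 1))

    # crude work bound: product of per-free-cell ranges
    bound = 1.0
    for i in range(len(rows) - 1):
        for j in range(len(cols) - 1):
            bound *= min(rows[i], cols[j]) + 1
            if bound > max_tables:
                raise ValueError(
                    "margins too large for exact enumeration; "
                    "pass monte_carlo=True for a resampling p-value"
                )

    r, c = counts.shape
    total_p = 0.0

    def enumerate_rows(i: int, remaining: np.ndarray, acc: list[list[int]]) -> None:
        nonlocal total_p
        if i == r - 1:
            if (remaining >= 0).all():
                lp = logprob(np.asarray(acc + [remaining.tolist()]))
                if lp <= cutoff:
                    total_p += float(np.exp(lp))
            return

        def fill(j: int, left: int, row: list[int]) -> None:
            if j == c - 1:
                if 0 <= left <= remaining[j]:
                    enumerate_rows(i + 1, remaining - np.asarray(row + [left]), acc + [row + [left]])
                return
            for v in range(min(left, int(remaining[j])) + 1):
                fill(j + 1, left - v, row + [v])

        fill(0, int(rows[i]), [])

    enumerate_rows(0, cols.copy(), [])
    return TestResult(test="fisher_exact", p_value=min(total_p, 1.0))


_PATIENT_FIELDS = {"sex": "sex", "age": "age_years", "age_years": "age_years",
                   "exposure": "prior_exposure", "prior_exposure": "prior_exposure"}
_PATIENT_ORDERS = {"sex": ["girl", "boy"], "age_years": [3, 4, 5],
                   "prior_exposure": ["previous", "first"]}


def _values_for(record, name: str, codebook: Codebook):
    if isinstance(record, Evaluation):
        if name == "day":
            return record.day
        if name in codebook.variables:
            return record.measures.get(name)
        raise ValueError(f"unknown evaluation variable {name!r}")
    if isinstance(record, PatientRecord):
        if name not in _PATIENT_FIELDS:
            raise ValueError(f"unknown patient characteristic {name!r}")
        return getattr(record, _PATIENT_FIELDS[name])
    raise TypeError(f"cannot tabulate {type(record).__name__}")


def _level_order(name: str, codebook: Codebook, observed: list) -> list:
    if name == "day":
        return [d for d in codebook.days if d in observed]
    if name in codebook.variables:
        return [c for c in codebook.categories[name] if c in observed]
    canon = _PATIENT_ORDERS.get(_PATIENT_FIELDS.get(name, ""), None)
    if canon:
        return [c for c in canon if c in observed]
    return sorted(observed)


def crosstab(
    records: Sequence,
    variable: str,
    stratifier: str,
    codebook: Codebook = DEFAULT_CODEBOOK,
) -> ContingencyTable:
    """Cross-tabulate a variable against a stratifier.

    Works on evaluations (observational variables, or ``day``) and on
    patient records (``sex``, ``age``, ``exposure``).  Rows with a missing
    value on either axis are excluded from the counts; per-column counts of
    rows missing the *variable* are reported separately.
    """
    pairs = []
    missing: dict = {}
    for rec in records:
        v = _values_for(rec, variable, codebook)
        s = _values_for(rec, stratifier, codebook)
        if s is None:
            continue
        if v is None:
            missing[s] = missing.get(s, 0) + 1
            continue
        pairs.append((v, s))
    if not pairs:
        raise ValueError("no complete records to tabulate")
    row_labels = _level_order(variable, codebook, sorted({v for v, _ in pairs}, key=str))
    col_labels = _level_order(stratifier, codebook, sorted({s for _, s in pairs}, key=str))
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=int)
    for v, s in pairs:
        counts[row_labels.index(v), col_labels.index(s)] += 1
    return ContingencyTable(
        row_labels=row_labels,
        col_labels=col_labels,
        counts=counts,
        missing_per_column=np.asarray([missing.get(s, 0) for s in col_labels]),
    )
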