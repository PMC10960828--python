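"""Small clinical statistics: IHC composite score, maximally selected
rank-statistic cutpoints, the two-group log-rank test, and sample QC filters.

The log-rank statistic is computed directly from the risk tables (so the
maxstat scan stays cheap); :mod:`lifelines` serves as an independent
cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SampleQC",
    "ihc_composite",
    "logrank_test",
    "maxstat_cutpoint",
    "sample_filter",
]


@dataclass
class SampleQC:
    min_malignant_cells: int = 100
    max_mito_fraction: float = 0.05

    def validate(self) -> None:
        if self.min_malignant_cells < 0 or not 0 < self.max_mito_fraction <= 1:
            raise ValueError("QC thresholds must be positive")


def ihc_composite(intensity: int, area: int) -> int:
    """Staining intensity (0-3) times positive-area score (0-4), range 0-12."""
    if intensity not in range(4):
        raise ValueError("intensity must be an integer in 0..3")
    if area not in range(5):
        raise ValueError("area must be an integer in 0..4")
    return intensity * area


def _logrank_oe(time: np.ndarray, event: np.ndarray, in_a: np.ndarray) -> tuple[float, float]:
    """Observed-minus-expected events in group A and its hypergeometric variance."""
    order = np.argsort(time, kind="stable")
    time, event, in_a = time[order], event[order], in_a[order]
    n = len(time)
    o_minus_e = 0.0
    var = 0.0
    i = 0
    at_risk_a = in_a.sum()
    at_risk = n
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d = event[i:j].sum()
        if d > 0 and at_risk > 1:
            d_a = event[i:j][in_a[i:j]].sum()
            e_a = d * at_risk_a / at_risk
            o_minus_e += d_a - e_a
            var += (
                d
                * (at_risk_a / at_risk)
                * (1 - at_risk_a / at_risk)
                * (at_risk - d)
                / (at_risk - 1)
            )
        at_risk_a -= in_a[i:j].sum()
        at_risk -= j - i
        i = j
    return o_minus_e, var


def logrank_test(
    time_a: np.ndarray, event_a: np.ndarray, time_b: np.ndarray, event_b: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square with 1 df, two-sided p)."""
    time_a, event_a = np.asarray(time_a, float), np.asarray(event_a, int)
    time_b, event_b = np.asarray(time_b, float), np.asarray(event_b, int)
    if len(time_a) == 0 or len(time_b) == 0:
        raise ValueError("both groups must be non-empty")
    if event_a.sum() + event_b.sum() == 0:
        raise ValueError("no events in either group")
    time = np.concatenate([time_a, time_b])
    event = np.concatenate([event_a, event_b])
    in_a = np.zeros(len(time), dtype=bool)
    in_a[: len(time_a)] = True
    o_minus_e, var = _logrank_oe(time, event, in_a)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def maxstat_cutpoint(
    records: pd.DataFrame, min_prop: float = 0.1
) -> tuple[float, float]:
    """Covariate cutpoint maximizing the standardized log-rank statistic.

    ``records`` needs columns time, event, value.  Candidate cutpoints are
    the unique covariate values whose split leaves at least ``min_prop`` of
    the records on each side; the returned statistic is |O - E| / sqrt(V)
    at the best split (ties resolved to the smaller cutpoint).

    Note: selecting a cutpoint this way and then testing the resulting
    split with a naive log-rank p-value inflates the type-I error; the
    selection statistic needs a maximally-selected-rank-statistics
    correction before it is interpreted as a test.
    """
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    value = records["value"].to_numpy(dtype=float)
    n = len(records)
    if n < 10 or event.sum() < 1:
        raise ValueError("need at least 10 records with at least one event")
    if (time <= 0).any():
        raise ValueError("times must be positive")

    candidates = [
        v
        for v in np.unique(value)
        if min_prop <= np.mean(value <= v) <= 1 - min_prop
    ]
    if not candidates:
        raise ValueError("no admissible cutpoint under min_prop")

    best_cut, best_stat = None, -np.inf
    for cut in candidates:
        in_a = value <= cut
        o_minus_e, var = _logrank_oe(time, event, in_a)
        if var == 0:
            continue
        stat = abs(o_minus_e) / np.sqrt(var)
        if stat > best_stat:  # ties keep the earlier (smaller) cutpoint
            best_cut, best_stat = cut, stat
    if best_cut is None:
        raise ValueError("no admissible cutpoint with positive variance")
    return float(best_cut), float(best_stat)


def sample_filter(malignant_counts: pd.Series, qc: SampleQC | None = None) -> list:
    """Samples retaining at least ``min_malignant_cells`` malignant cells."""
    qc = qc or SampleQC()
    retained = [s for s, c in malignant_counts.items() if c >= qc.min_malignant_cells]
    if not retained:
        import warnings

        warnings.warn("all samples fall below the malignant-cell threshold")
    return retained
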