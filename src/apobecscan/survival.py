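"""Kaplan–Meier estimation and log-rank comparison between groups.

The product-limit estimator and the two-group log-rank test are delegated
to lifelines; this module fixes the data contract (times in months,
strictly positive; ``event`` True when death was observed, False for
censoring) and the summary quantities reported by the pipeline: per-group
KM curves, median survival (smallest event time with S(t) <= 0.5), and the
1-df log-rank chi-square.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .stats_core import DegenerateTestError, TestResult


@dataclasses.dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float  # months
    event: bool  # True = death observed, False = censored

    def __post_init__(self) -> None:
        if not math.isfinite(self.time) or self.time <= 0:
            raise ValueError(
                f"{self.sample_id}: survival time must be finite and > 0"
            )


@dataclasses.dataclass
class KMCurve:
    """Step function: S(t) with at-risk counts at each distinct time."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


def read_clinical(path: str) -> list[SurvivalRecord]:
    """Read a clinical TSV with columns sample_id, time_months, event."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing clinical columns {sorted(missing)}")
    return [
        SurvivalRecord(str(r.sample_id), float(r.time_months), bool(int(r.event)))
        for r in df.itertuples()
    ]


def km_curve(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit survival estimate over the distinct observed times."""
    if not records:
        raise ValueError("empty survival group")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    # drop the t=0 anchor row; keep observed timeline
    sf = kmf.survival_function_.iloc[1:] if len(kmf.survival_function_) > 1 else kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = np.array([(times >= ti).sum() for ti in t])
    return KMCurve(times=t, survival=s, at_risk=at_risk)


def km_median(curve: KMCurve) -> float | None:
    """Smallest observed time with S(t) <= 0.5, or None if never reached."""
    below = curve.survival <= 0.5
    if not below.any():
        return None
    return float(curve.times[below][0])


def logrank_test(
    a: Sequence[SurvivalRecord], b: Sequence[SurvivalRecord]
) -> TestResult:
    """Two-group log-rank chi-square (1 df) with p-value.

    Symmetric in group order; undefined (error) when no event is observed
    in either group.
    """
    if not a or not b:
        raise ValueError("both survival groups must be non-empty")
    if not any(r.event for r in a) and not any(r.event for r in b):
        raise DegenerateTestError("no events observed; log-rank undefined")
    res = _ll_logrank(
        np.array([r.time for r in a]),
        np.array([r.time for r in b]),
        event_observed_A=np.array([r.event for r in a], dtype=bool),
        event_observed_B=np.array([r.event for r in b], dtype=bool),
    )
    return TestResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        sidedness="two_sided",
    )


def compare_groups(
    records: Iterable[SurvivalRecord],
    labels: dict[str, str],
) -> dict:
    """KM medians and log-rank p between two labelled groups.

    ``labels`` maps sample_id to a group name; exactly two distinct group
    names must be present among the matched records.
    """
    groups: dict[str, list[SurvivalRecord]] = {}
    for r in records:
        g = labels.get(r.sample_id)
        if g is not None:
            groups.setdefault(g, []).append(r)
    if len(groups) != 2:
        raise ValueError(
            f"expected exactly 2 groups, found {sorted(groups)}"
        )
    (name_a, recs_a), (name_b, recs_b) = sorted(groups.items())
    test = logrank_test(recs_a, recs_b)
    return {
        "groups": {
            name_a: {
                "n": len(recs_a),
                "median_months": km_median(km_curve(recs_a)),
            },
            name_b: {
                "n": len(recs_b),
                "median_months": km_median(km_curve(recs_b)),
            },
        },
        "logrank_statistic": test.statistic,
        "logrank_p": test.p_value,
    }
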