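"""Shared elementary statistics.

Thin, typed wrappers over scipy/statsmodels primitives plus the small
amount of arithmetic they do not provide (Woolf odds-ratio confidence
intervals, the qPCR ΔΔCt calculator).  Every analysis stage draws its
Fisher tests, FDR correction, rank correlation and ANOVA from here so the
conventions (sidedness, zero-cell handling) are fixed in one place.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class DegenerateTestError(ValueError):
    """The requested test is undefined on the given input."""


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows = group, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError(f"negative cell in {cells}")
        if sum(cells) == 0:
            raise DegenerateTestError("all-zero 2x2 table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclasses.dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    odds_ratio: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    sidedness: str = "two_sided"


def odds_ratio(t: ContingencyTable2x2) -> float:
    """Sample odds ratio a*d / (b*c); +inf when b*c == 0 and a*d > 0."""
    num, den = t.a * t.d, t.b * t.c
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def woolf_ci(
    t: ContingencyTable2x2, alpha: float = 0.05
) -> tuple[float, float]:
    """Woolf log-OR normal-approximation CI.

    A Haldane–Anscombe 0.5 is added to every cell when any cell is zero,
    keeping the interval finite and deterministic.
    """
    cells = [t.a, t.b, t.c, t.d]
    if any(x == 0 for x in cells):
        cells = [x + 0.5 for x in cells]
    a, b, c, d = cells
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - alpha / 2)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def fisher_exact(
    t: ContingencyTable2x2, sidedness: str = "two_sided"
) -> TestResult:
    """Fisher's exact test on a 2x2 table.

    Two-sided p follows the probability-mass rule (sum of hypergeometric
    probabilities of all tables, at fixed margins, no more probable than
    the observed one); ``greater`` tests enrichment of cell ``a``.  The
    reported odds ratio is the sample OR a*d/(b*c), with a Woolf CI.
    """
    alternative = {"two_sided": "two-sided", "greater": "greater"}.get(sidedness)
    if alternative is None:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    res = sps.fisher_exact(t.as_array(), alternative=alternative)
    ci_low, ci_high = woolf_ci(t)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        odds_ratio=odds_ratio(t),
        ci_low=ci_low,
        ci_high=ci_high,
        sidedness=sidedness,
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties) and its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("spearman needs two equal-length vectors, n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateTestError("constant vector: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def oneway_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA F statistic and p-value."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("ANOVA needs >= 2 groups with n >= 2 each")
    if all(np.var(a) == 0 for a in arrays):
        raise DegenerateTestError("zero within-group variance in all groups")
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def delta_delta_ct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """qPCR relative quantification: fold change = 2**(-ΔΔCt).

    ΔΔCt = (Ct_target − Ct_reference) in the treated condition minus the
    same difference in the control condition.
    """
    for ct in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not math.isfinite(ct):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (
        ct_target_control - ct_ref_control
    )
    return 2.0 ** (-ddct)
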