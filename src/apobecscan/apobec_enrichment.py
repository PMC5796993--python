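"""Per-sample APOBEC enrichment scoring and cohort classification.

APOBEC3 cytidine deaminases mutate cytosines in single-stranded DNA with a
strong preference for the T-C-W motif (W ∈ {A, T}), producing C>T and C>G
substitutions.  The per-sample enrichment score measures how concentrated a
tumor's C>T/C>G mutations are at TCW motifs relative to how available those
motifs are around the mutated sites:

    E = (m_tcw * bg_c) / (m_c * bg_tcw)

where m_tcw is the number of C>T/C>G mutations at TCW, m_c the number of
all C>T/C>G mutations, and bg_tcw / bg_c the numbers of TCW motifs and
cytosines (both strands) in ±window-nt windows around every counted
mutation.  E = 1 means mutations hit TCW no more often than motif
availability predicts.  Each sample's departure from proportionality is
tested with a one-sided Fisher exact test on

    [[m_tcw, m_c - m_tcw], [bg_tcw, bg_c - bg_tcw]]

and the p-values are Benjamini–Hochberg corrected across the cohort.  A
sample is called APOBEC-high when E > 2 and the corrected q-value < 0.05;
everything else (including unscorable samples) is APOBEC-low.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats_core import (
    ContingencyTable2x2,
    benjamini_hochberg,
    fisher_exact,
)
from .variant_io import (
    ReferenceSequence,
    VariantRecord,
    count_backgrounds,
    extract_context,
    snv_class,
)

#: Classification thresholds from the published rule.
E_THRESHOLD = 2.0
FDR_THRESHOLD = 0.05
#: Cohort outlier cuts: hypermutator rate and minimum informative burden.
HIGH_BURDEN_CUT = 150.0  # mutations per Mb
LOW_COUNT_CUT = 5  # total mutations
#: Covered exome territory used to convert counts to mutations/Mb.
DEFAULT_EXOME_MB = 38.0

APOBEC_HIGH = "APOBEC_high"
APOBEC_LOW = "APOBEC_low"


@dataclasses.dataclass(frozen=True)
class SampleContextCounts:
    """TCW mutation and background-motif counts for one sample."""

    sample_id: str
    m_tcw: int
    m_c: int
    bg_tcw: int
    bg_c: int

    def __post_init__(self) -> None:
        if min(self.m_tcw, self.m_c, self.bg_tcw, self.bg_c) < 0:
            raise ValueError("counts must be non-negative")
        if self.m_tcw > self.m_c or self.bg_tcw > self.bg_c:
            raise ValueError(
                f"{self.sample_id}: TCW counts exceed cytosine counts"
            )

    @property
    def scorable(self) -> bool:
        return self.m_c > 0 and self.bg_tcw > 0 and self.bg_c > 0


@dataclasses.dataclass(frozen=True)
class EnrichmentResult:
    sample_id: str
    enrichment: float
    p_value: float
    q_value: float
    label: str
    scorable: bool = True


def accumulate_counts(
    variants: Iterable[VariantRecord],
    ref: ReferenceSequence,
    window: int = 20,
) -> list[SampleContextCounts]:
    """Aggregate per-sample TCW/cytosine mutation and background counts.

    Only C>T and C>G SNVs (pyrimidine-oriented) enter both numerator and
    denominator, so the score compares like with like; other substitution
    classes and indels are ignored.  Background motifs are summed over a
    ±``window`` nt window around every counted mutation.  Samples with no
    countable mutation still produce a (zero) record.
    """
    per_sample: dict[str, list[int]] = defaultdict(lambda: [0, 0, 0, 0])
    for v in variants:
        if not v.is_snv:
            continue
        # touch the sample so mutation-bearing samples always appear
        acc = per_sample[v.sample_id]
        if snv_class(v) not in ("C>T", "C>G"):
            continue
        ctx = extract_context(v, ref)
        bg_tcw, bg_c = count_backgrounds(v, ref, window=window)
        acc[0] += int(ctx.is_tcw)
        acc[1] += 1
        acc[2] += bg_tcw
        acc[3] += bg_c
    return [
        SampleContextCounts(sid, *counts)
        for sid, counts in sorted(per_sample.items())
    ]


def enrichment_score(c: SampleContextCounts) -> tuple[float, float]:
    """Fold enrichment E and one-sided Fisher p for one sample.

    Requires a scorable sample (``m_c > 0`` and non-zero backgrounds).
    ``m_tcw = 0`` gives E = 0 with p = 1 — no evidence of enrichment.
    """
    if not c.scorable:
        raise ValueError(f"{c.sample_id}: unscorable counts, no defined E")
    e = (c.m_tcw * c.bg_c) / (c.m_c * c.bg_tcw)
    if c.m_tcw == 0:
        return 0.0, 1.0
    table = ContingencyTable2x2(
        c.m_tcw, c.m_c - c.m_tcw, c.bg_tcw, c.bg_c - c.bg_tcw
    )
    res = fisher_exact(table, sidedness="greater")
    return e, res.p_value


def classify_cohort(
    counts: Sequence[SampleContextCounts],
    e_threshold: float = E_THRESHOLD,
    fdr: float = FDR_THRESHOLD,
) -> list[EnrichmentResult]:
    """Score, BH-correct across the cohort, and label every sample.

    APOBEC-high requires E > ``e_threshold`` and q < ``fdr``; all other
    samples, including unscorable ones (reported with E = 0, q = 1), are
    APOBEC-low.
    """
    if not counts:
        raise ValueError("empty cohort")
    scorable = [c for c in counts if c.scorable]
    results: dict[str, EnrichmentResult] = {}
    if scorable:
        scores = [enrichment_score(c) for c in scorable]
        qvals = benjamini_hochberg([p for _, p in scores])
        for c, (e, p), q in zip(scorable, scores, qvals):
            label = APOBEC_HIGH if (e > e_threshold and q < fdr) else APOBEC_LOW
            results[c.sample_id] = EnrichmentResult(
                c.sample_id, e, p, float(q), label, scorable=True
            )
    for c in counts:
        if c.sample_id not in results:
            results[c.sample_id] = EnrichmentResult(
                c.sample_id, 0.0, 1.0, 1.0, APOBEC_LOW, scorable=False
            )
    return [results[c.sample_id] for c in counts]


def remove_outliers(
    burdens: Mapping[str, tuple[float, int]],
    high_cut: float = HIGH_BURDEN_CUT,
    low_cut: int = LOW_COUNT_CUT,
) -> tuple[set[str], list[str]]:
    """Drop hypermutator and near-silent samples from mutational analysis.

    ``burdens`` maps sample -> (mutations/Mb, total mutation count).
    Samples with rate > ``high_cut`` or total count <= ``low_cut`` are
    excluded.  Returns (retained sample set, sorted excluded list).
    """
    excluded = sorted(
        sid
        for sid, (rate, total) in burdens.items()
        if rate > high_cut or total <= low_cut
    )
    retained = set(burdens) - set(excluded)
    return retained, excluded


def mutation_burdens(
    variants: Iterable[VariantRecord], exome_mb: float = DEFAULT_EXOME_MB
) -> dict[str, tuple[float, int]]:
    """Per-sample (mutations/Mb, total mutation count) from a variant list."""
    totals: dict[str, int] = defaultdict(int)
    for v in variants:
        totals[v.sample_id] += 1
    return {sid: (n / exome_mb, n) for sid, n in totals.items()}


def snv_class_by_burden_bins(
    variants: Sequence[VariantRecord], bin_size: int = 20
) -> pd.DataFrame:
    """Percentage of each of the 6 SNV classes in burden-ordered sample bins.

    Samples are sorted by ascending total mutation count and chunked into
    consecutive bins of ``bin_size`` samples (the last bin may be short);
    within each bin the SNV-class percentages sum to 100.  This mirrors the
    standard cohort display of mutation spectrum as a function of load.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    per_sample_total: dict[str, int] = defaultdict(int)
    per_sample_class: dict[str, dict[str, int]] = defaultdict(
        lambda: defaultdict(int)
    )
    for v in variants:
        per_sample_total[v.sample_id] += 1
        if v.is_snv:
            per_sample_class[v.sample_id][snv_class(v)] += 1
    order = sorted(per_sample_total, key=lambda s: (per_sample_total[s], s))
    classes = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
    rows = []
    for b, start in enumerate(range(0, len(order), bin_size)):
        chunk = order[start : start + bin_size]
        class_counts = {
            cls: sum(per_sample_class[s][cls] for s in chunk) for cls in classes
        }
        total_snvs = sum(class_counts.values())
        row: dict[str, object] = {
            "bin": b,
            "n_samples": len(chunk),
            "median_burden": float(
                np.median([per_sample_total[s] for s in chunk])
            ),
        }
        for cls in classes:
            row[cls] = (
                100.0 * class_counts[cls] / total_snvs if total_snvs else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows)


def results_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "enrichment": [r.enrichment for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
            "label": [r.label for r in results],
            "scorable": [r.scorable for r in results],
        }
    )


def counts_table(counts: Sequence[SampleContextCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in counts],
            "m_tcw": [c.m_tcw for c in counts],
            "m_c": [c.m_c for c in counts],
            "bg_tcw": [c.bg_tcw for c in counts],
            "bg_c": [c.bg_c for c in counts],
        }
    )
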