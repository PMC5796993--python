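"""Per-gene differential mutation, mutual exclusivity, and hotspot tables.

Given per-sample APOBEC-high/low labels, each gene's non-silent mutation
status is cross-tabulated against group membership and tested with a
two-sided Fisher exact test; odds ratios are oriented so OR > 1 means the
gene is more often mutated in the APOBEC-high group.  Benjamini–Hochberg
correction runs across all tested genes.  Mutual exclusivity between two
genes is the same Fisher machinery on the co-occurrence table (OR < 1
indicates exclusivity).  Hotspot tables aggregate a gene's variants by
protein position and flag whether each recurrent site sits in a TCW motif.
"""

from __future__ import annotations

import dataclasses
import re
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .apobec_enrichment import APOBEC_HIGH, APOBEC_LOW, EnrichmentResult
from .stats_core import (
    ContingencyTable2x2,
    TestResult,
    benjamini_hochberg,
    fisher_exact,
)
from .variant_io import ReferenceSequence, VariantRecord, extract_context

DEFAULT_MIN_SAMPLES_MUTATED = 5

_PROTEIN_CHANGE_RE = re.compile(
    r"^p?\.?([A-Z\*])(\d+)([A-Z\*]|fs\*?\d*|del|ins[A-Z]*)$"
)


@dataclasses.dataclass
class GeneMutationMatrix:
    """Binary sample × gene indicator of non-silent mutation."""

    indicator: pd.DataFrame  # index = sample_id, columns = genes, values 0/1
    dropped_genes: list[str] = dataclasses.field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.indicator.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.indicator.index)


@dataclasses.dataclass(frozen=True)
class DiffMutResult:
    gene: str
    n_high_mut: int
    n_high_wt: int
    n_low_mut: int
    n_low_wt: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    q: float


def build_gene_matrix(
    variants: Iterable[VariantRecord],
    min_samples_mutated: int = DEFAULT_MIN_SAMPLES_MUTATED,
    samples: Sequence[str] | None = None,
) -> GeneMutationMatrix:
    """Sample × gene non-silent mutation indicator matrix.

    Silent variants and variants without a gene symbol are ignored.  Genes
    mutated in fewer than ``min_samples_mutated`` samples are dropped (and
    listed in ``dropped_genes``) — genes that rare carry no power for the
    group comparison.  ``samples`` fixes the row universe (so wild-type
    samples appear even if they carry no qualifying variant).
    """
    mutated: dict[str, set[str]] = defaultdict(set)
    seen_samples: set[str] = set(samples) if samples is not None else set()
    for v in variants:
        if samples is None:
            seen_samples.add(v.sample_id)
        if not v.gene or not v.is_non_silent:
            continue
        if samples is not None and v.sample_id not in seen_samples:
            continue
        mutated[v.gene].add(v.sample_id)
    kept = sorted(
        g for g, s in mutated.items() if len(s) >= min_samples_mutated
    )
    dropped = sorted(set(mutated) - set(kept))
    sample_order = (
        list(samples) if samples is not None else sorted(seen_samples)
    )
    indicator = pd.DataFrame(
        0, index=sample_order, columns=kept, dtype=int
    )
    for g in kept:
        hit = [s for s in mutated[g] if s in indicator.index]
        indicator.loc[hit, g] = 1
    return GeneMutationMatrix(indicator=indicator, dropped_genes=dropped)


def _split_groups(
    m: GeneMutationMatrix, labels: Sequence[EnrichmentResult] | Mapping[str, str]
) -> tuple[list[str], list[str]]:
    if not isinstance(labels, Mapping):
        labels = {r.sample_id: r.label for r in labels}
    high = [s for s in m.samples if labels.get(s) == APOBEC_HIGH]
    low = [s for s in m.samples if labels.get(s) == APOBEC_LOW]
    if not high or not low:
        raise ValueError(
            f"both groups must be non-empty (high={len(high)}, low={len(low)})"
        )
    return high, low


def differential_test(
    m: GeneMutationMatrix,
    labels: Sequence[EnrichmentResult] | Mapping[str, str],
) -> list[DiffMutResult]:
    """Two-sided Fisher test of mutation frequency, per gene, high vs low.

    OR > 1 means enriched in the APOBEC-high group.  Results are BH
    corrected across all tested genes and sorted by q (ties by gene name).
    """
    high, low = _split_groups(m, labels)
    raw: list[tuple[str, ContingencyTable2x2, TestResult]] = []
    for gene in m.genes:
        col = m.indicator[gene]
        a = int(col.loc[high].sum())
        b = len(high) - a
        c = int(col.loc[low].sum())
        d = len(low) - c
        table = ContingencyTable2x2(a, b, c, d)
        raw.append((gene, table, fisher_exact(table, "two_sided")))
    qvals = benjamini_hochberg([r.p_value for _, _, r in raw])
    results = [
        DiffMutResult(
            gene=gene,
            n_high_mut=t.a,
            n_high_wt=t.b,
            n_low_mut=t.c,
            n_low_wt=t.d,
            odds_ratio=r.odds_ratio,
            ci_low=r.ci_low,
            ci_high=r.ci_high,
            p=r.p_value,
            q=float(q),
        )
        for (gene, t, r), q in zip(raw, qvals)
    ]
    return sorted(results, key=lambda r: (r.q, r.p, r.gene))


def mutual_exclusivity(
    m: GeneMutationMatrix, gene_a: str, gene_b: str
) -> tuple[TestResult, int]:
    """Fisher test of co-occurrence between two genes.

    Returns the two-sided test (OR < 1 indicates mutual exclusivity) and
    the observed co-mutated sample count.
    """
    for g in (gene_a, gene_b):
        if g not in m.indicator.columns:
            raise KeyError(f"gene {g!r} not in mutation matrix")
    a_col = m.indicator[gene_a].astype(bool)
    b_col = m.indicator[gene_b].astype(bool)
    both = int((a_col & b_col).sum())
    a_only = int((a_col & ~b_col).sum())
    b_only = int((~a_col & b_col).sum())
    neither = int((~a_col & ~b_col).sum())
    table = ContingencyTable2x2(both, a_only, b_only, neither)
    return fisher_exact(table, "two_sided"), both


def hotspot_table(
    variants: Iterable[VariantRecord],
    gene: str,
    ref: ReferenceSequence | None = None,
) -> pd.DataFrame:
    """Aggregate one gene's variants by protein position and change.

    Rows are (gene, protein_position, aa_change, count, n_tcw_context);
    variants whose ``protein_change`` cannot be parsed are tallied in a
    single ``unparsed`` row with position -1.  ``n_tcw_context`` counts how
    many of the row's variants are SNVs in a TCW motif (0 when no
    reference is supplied).
    """
    counts: dict[tuple[int, str], int] = defaultdict(int)
    tcw_counts: dict[tuple[int, str], int] = defaultdict(int)
    unparsed = 0
    for v in variants:
        if v.gene != gene:
            continue
        match = _PROTEIN_CHANGE_RE.match(v.protein_change or "")
        if not match:
            unparsed += 1
            continue
        pos = int(match.group(2))
        change = f"{match.group(1)}{pos}{match.group(3)}"
        counts[(pos, change)] += 1
        if ref is not None and v.is_snv:
            ctx = extract_context(v, ref)
            tcw_counts[(pos, change)] += int(ctx.is_tcw)
    rows = [
        {
            "gene": gene,
            "protein_position": pos,
            "aa_change": change,
            "count": n,
            "n_tcw_context": tcw_counts[(pos, change)],
            "is_tcw_context": tcw_counts[(pos, change)] == n and n > 0,
        }
        for (pos, change), n in sorted(counts.items())
    ]
    if unparsed:
        rows.append(
            {
                "gene": gene,
                "protein_position": -1,
                "aa_change": "unparsed",
                "count": unparsed,
                "n_tcw_context": 0,
                "is_tcw_context": False,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "protein_position",
            "aa_change",
            "count",
            "n_tcw_context",
            "is_tcw_context",
        ],
    )


def diffmut_table(results: Sequence[DiffMutResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])
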