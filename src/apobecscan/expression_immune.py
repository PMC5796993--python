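"""Immune gene-set scoring, enrichment correlations, subtype clustering,
and rank-based differential expression.

Expression values are RSEM-like non-negative abundances, analysed on the
log2(x + 1) scale.  A gene set's signature score for a sample is the mean
of the member genes' cross-sample z-scored log2 expression, so each
signature has mean ~0 over the cohort by construction and scores are
invariant to global rescaling of the raw matrix.

Molecular subtypes (luminal / p53-like / basal / claudin-low) come from
agglomerative hierarchical clustering (Euclidean distance, Ward linkage)
of the most-variable genes, with clusters named by the marker gene set
whose mean z-score is highest at the cluster centroid.

Differential expression between APOBEC-high and APOBEC-low groups uses a
per-gene Mann–Whitney rank test with BH correction — a deliberately
dependency-light, rank-based alternative to moderated linear-model
statistics, adequate for the two-group comparison performed here.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import AgglomerativeClustering

from .apobec_enrichment import APOBEC_HIGH, APOBEC_LOW, EnrichmentResult
from .stats_core import benjamini_hochberg, spearman

SUBTYPES = ("luminal", "p53_like", "basal", "claudin_low")


@dataclasses.dataclass
class ExpressionMatrix:
    """Genes × samples non-negative expression values."""

    values: pd.DataFrame  # index = gene symbols, columns = sample ids

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene symbols in expression matrix")

    @classmethod
    def from_tsv(cls, path: str) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path: str) -> str:
        self.values.to_csv(path, sep="\t", index_label="gene")
        return path

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def log2(self) -> pd.DataFrame:
        return np.log2(self.values + 1.0)


class GeneSetCollection(dict):
    """Named gene sets (name -> list of gene symbols)."""

    @classmethod
    def from_gmt(cls, path: str) -> "GeneSetCollection":
        sets = cls()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                name, _desc, *genes = parts
                sets[name] = [g for g in genes if g]
        return sets

    def to_gmt(self, path: str) -> str:
        with open(path, "w") as fh:
            for name, genes in self.items():
                fh.write("\t".join([name, name] + list(genes)) + "\n")
        return path


def zscore_genes(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene cross-sample z-score of log2(x+1) expression.

    Zero-variance genes are dropped (their z-score is undefined).
    """
    if len(expr.samples) < 2:
        raise ValueError("z-scoring needs >= 2 samples")
    log = expr.log2()
    mu = log.mean(axis=1)
    sd = log.std(axis=1, ddof=0)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(
            f"{dropped} zero-variance genes excluded from signature scoring"
        )
    return log.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)


def score_signatures(
    expr: ExpressionMatrix, sets: GeneSetCollection
) -> pd.DataFrame:
    """Sample × signature score matrix (mean z of member genes).

    Gene sets with no member present in the matrix are flagged with an
    all-NaN column and a warning rather than silently omitted.
    """
    z = zscore_genes(expr)
    scores = {}
    for name, genes in sets.items():
        present = [g for g in genes if g in z.index]
        if not present:
            warnings.warn(f"gene set {name!r} has no genes in the matrix")
            scores[name] = pd.Series(np.nan, index=z.columns)
            continue
        scores[name] = z.loc[present].mean(axis=0)
    out = pd.DataFrame(scores)
    out.index.name = "sample_id"
    return out


def correlate_with_enrichment(
    scores_or_expr: pd.DataFrame | ExpressionMatrix,
    enrichment: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Spearman correlation of each signature/gene with the numeric
    APOBEC enrichment score, BH-corrected across the tested set.

    ``scores_or_expr`` is either a sample × signature score frame or an
    :class:`ExpressionMatrix` (correlated on the log2 scale, rank-based so
    the transform is immaterial).  Constant vectors are skipped with a
    warning.
    """
    if isinstance(scores_or_expr, ExpressionMatrix):
        frame = scores_or_expr.log2().T  # samples × genes
    else:
        frame = scores_or_expr
    e = pd.Series(dict(enrichment) if not isinstance(enrichment, pd.Series) else enrichment)
    shared = [s for s in frame.index if s in e.index]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples for correlation")
    e = e.loc[shared].astype(float)
    rows = []
    for name in frame.columns:
        v = frame.loc[shared, name].astype(float)
        if v.isna().any() or v.nunique() <= 1 or e.nunique() <= 1:
            warnings.warn(f"skipping constant or missing vector {name!r}")
            continue
        rho, p = spearman(v.to_numpy(), e.to_numpy())
        rows.append({"name": name, "rho": rho, "p": p})
    out = pd.DataFrame(rows, columns=["name", "rho", "p"])
    if len(out):
        out["q"] = benjamini_hochberg(out["p"])
    else:
        out["q"] = []
    return out


@dataclasses.dataclass
class SubtypeAssignment:
    subtype: pd.Series  # sample -> subtype name
    cluster: pd.Series  # sample -> raw cluster index


def cluster_subtypes(
    expr: ExpressionMatrix,
    marker_sets: GeneSetCollection,
    n_clusters: int = 4,
    n_top_genes: int = 2000,
) -> SubtypeAssignment:
    """Ward-linkage hierarchical clustering into molecular subtypes.

    Samples are clustered on the z-scored log2 expression of the
    ``n_top_genes`` most variable genes (Euclidean distance, Ward
    linkage, deterministic given input order).  Each cluster is labelled
    with the marker set whose mean z-score is highest at its centroid;
    if two clusters claim the same marker set the higher-scoring cluster
    wins and the other takes its best remaining label.
    """
    if len(expr.samples) < n_clusters:
        raise ValueError("fewer samples than requested clusters")
    z = zscore_genes(expr)
    variances = expr.log2().var(axis=1, ddof=0)
    top = variances.loc[z.index].nlargest(min(n_top_genes, len(z.index))).index
    X = z.loc[top].T.to_numpy()  # samples × genes
    model = AgglomerativeClustering(
        n_clusters=n_clusters, metric="euclidean", linkage="ward"
    )
    cluster_idx = model.fit_predict(X)
    clusters = pd.Series(cluster_idx, index=expr.samples, name="cluster")

    # score each cluster centroid against each marker set
    centroid_scores: dict[int, dict[str, float]] = {}
    for k in range(n_clusters):
        members = clusters.index[clusters == k]
        centroid_scores[k] = {}
        for name, genes in marker_sets.items():
            present = [g for g in genes if g in z.index]
            centroid_scores[k][name] = (
                float(z.loc[present, members].mean().mean())
                if present
                else -math.inf
            )
    # greedy assignment: best (cluster, marker) pairs first, no reuse
    pairs = sorted(
        (
            (score, k, name)
            for k, d in centroid_scores.items()
            for name, score in d.items()
        ),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    label_of: dict[int, str] = {}
    used: set[str] = set()
    for score, k, name in pairs:
        if k in label_of or name in used:
            continue
        label_of[k] = name
        used.add(name)
    for k in range(n_clusters):  # more clusters than marker sets
        label_of.setdefault(k, f"cluster_{k}")
    subtype = clusters.map(label_of).rename("subtype")
    return SubtypeAssignment(subtype=subtype, cluster=clusters)


def rank_de_test(
    expr: ExpressionMatrix,
    labels: Sequence[EnrichmentResult] | Mapping[str, str],
) -> pd.DataFrame:
    """Per-gene Mann–Whitney test of log2 expression, high vs low group.

    Returns (gene, log2_median_fc, direction, p, q) sorted by q;
    ``log2_median_fc`` > 0 means higher in the APOBEC-high group.
    All-zero genes are skipped.
    """
    if not isinstance(labels, Mapping):
        labels = {r.sample_id: r.label for r in labels}
    high = [s for s in expr.samples if labels.get(s) == APOBEC_HIGH]
    low = [s for s in expr.samples if labels.get(s) == APOBEC_LOW]
    if len(high) < 3 or len(low) < 3:
        raise ValueError("both groups need >= 3 samples for the rank test")
    log = expr.log2()
    rows = []
    for gene in log.index:
        x = log.loc[gene, high].to_numpy()
        y = log.loc[gene, low].to_numpy()
        if (x == 0).all() and (y == 0).all():
            continue
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            p = 1.0
        else:
            _, p = sps.mannwhitneyu(x, y, alternative="two-sided")
        fc = float(np.median(x) - np.median(y))
        rows.append(
            {
                "gene": gene,
                "log2_median_fc": fc,
                "direction": "up_in_high" if fc > 0 else (
                    "down_in_high" if fc < 0 else "none"
                ),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "log2_median_fc", "direction", "p"])
    if len(out):
        out["q"] = benjamini_hochberg(out["p"])
        out = out.sort_values(["q", "p", "gene"]).reset_index(drop=True)
    else:
        out["q"] = []
    return out
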