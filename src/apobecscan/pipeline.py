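"""End-to-end cohort analysis: outlier removal, enrichment classification,
signature attribution, differential mutation, immune expression scoring,
and survival comparison, driven by one config.

Each stage writes its table into the output directory and contributes to a
single ``summary.json``; any stage failure aborts with the stage name in
the error.  Given identical inputs and config, the report is
deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from typing import Sequence

import pandas as pd

from . import (
    apobec_enrichment as enr,
    differential_mutation as dm,
    expression_immune as ei,
    signature_fit as sf,
    survival as surv,
    variant_io as vio,
)

logger = logging.getLogger("apobecscan")

DEFAULT_EXCLUSIVITY_PAIRS = (
    ("FGFR3", "KRAS"),
    ("FGFR3", "HRAS"),
    ("FGFR3", "NRAS"),
)


@dataclasses.dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    Threshold defaults are the published classification rule (E > 2,
    FDR < 0.05), the outlier cuts (>150 mutations/Mb, ≤5 total
    mutations), the ≥5-mutated-samples gene filter, and the ±20 nt
    background window.
    """

    maf: str
    reference: str
    out_dir: str
    expression: str | None = None
    clinical: str | None = None
    immune_sets: str | None = None
    marker_sets: str | None = None
    signature_file: str | None = None
    maf_dialect: str = "tcga"
    signature_names: Sequence[str] = sf.DEFAULT_SIGNATURES
    window: int = 20
    e_threshold: float = enr.E_THRESHOLD
    fdr: float = enr.FDR_THRESHOLD
    high_burden_cut: float = enr.HIGH_BURDEN_CUT
    low_count_cut: int = enr.LOW_COUNT_CUT
    exome_mb: float = enr.DEFAULT_EXOME_MB
    min_samples_mutated: int = dm.DEFAULT_MIN_SAMPLES_MUTATED
    exclusivity_pairs: Sequence[tuple[str, str]] = DEFAULT_EXCLUSIVITY_PAIRS
    hotspot_genes: Sequence[str] = ("PIK3CA",)
    seed: int = 0

    @classmethod
    def from_json(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for name in ("maf", "reference"):
            p = getattr(self, name)
            if not os.path.exists(p):
                raise FileNotFoundError(f"{name} file not found: {p}")
        for name in (
            "expression", "clinical", "immune_sets", "marker_sets",
            "signature_file",
        ):
            p = getattr(self, name)
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"{name} file not found: {p}")
        if min(self.e_threshold, self.fdr, self.high_burden_cut) <= 0:
            raise ValueError("thresholds must be positive")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write(df: pd.DataFrame, out_dir: str, name: str) -> str:
    path = os.path.join(out_dir, name)
    df.to_csv(path, sep="\t", index=False)
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every applicable stage; returns the summary dict (also written
    to ``summary.json``)."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    summary: dict = {"stages": [], "parameters": {
        "window": config.window,
        "e_threshold": config.e_threshold,
        "fdr": config.fdr,
        "high_burden_cut": config.high_burden_cut,
        "low_count_cut": config.low_count_cut,
        "exome_mb": config.exome_mb,
        "min_samples_mutated": config.min_samples_mutated,
        "signature_names": list(config.signature_names),
        "seed": config.seed,
    }}

    def stage(name):
        logger.info("stage %s", name)
        summary["stages"].append(name)

    try:
        stage("load")
        variants = vio.read_maf(config.maf, dialect=config.maf_dialect)
        ref = vio.ReferenceSequence.from_fasta(config.reference)
        logger.info("loaded %d variants", len(variants))
    except Exception as exc:
        raise StageError("load", exc) from exc

    try:
        stage("outliers")
        burdens = enr.mutation_burdens(variants, exome_mb=config.exome_mb)
        retained, excluded = enr.remove_outliers(
            burdens,
            high_cut=config.high_burden_cut,
            low_cut=config.low_count_cut,
        )
        for sid in excluded:
            logger.info(
                "excluded outlier %s (%.1f mut/Mb, %d mutations)",
                sid, burdens[sid][0], burdens[sid][1],
            )
        variants = [v for v in variants if v.sample_id in retained]
        summary["outliers_excluded"] = excluded
        summary["n_samples"] = len(retained)
    except Exception as exc:
        raise StageError("outliers", exc) from exc

    try:
        stage("enrichment")
        counts = enr.accumulate_counts(variants, ref, window=config.window)
        results = enr.classify_cohort(
            counts, e_threshold=config.e_threshold, fdr=config.fdr
        )
        labels = {r.sample_id: r.label for r in results}
        enrichment_by_sample = {r.sample_id: r.enrichment for r in results}
        table = enr.counts_table(counts).merge(
            enr.results_table(results), on="sample_id"
        )
        _write(table, config.out_dir, "enrichment.tsv")
        n_high = sum(1 for r in results if r.label == enr.APOBEC_HIGH)
        summary["enrichment"] = {
            "n_high": n_high,
            "n_low": len(results) - n_high,
        }
        bins = enr.snv_class_by_burden_bins(variants)
        _write(bins, config.out_dir, "snv_class_bins.tsv")
    except Exception as exc:
        raise StageError("enrichment", exc) from exc

    try:
        stage("signatures")
        if config.signature_file:
            sig_matrix = sf.read_signatures(config.signature_file)
        else:
            sig_matrix = sf.synthetic_cosmic_signatures()
        sig_matrix = sig_matrix.subset(config.signature_names)
        catalog = sf.build_catalog(variants, ref)
        exposures = sf.fit_exposures(catalog, sig_matrix)
        _write(sf.exposures_table(exposures), config.out_dir, "exposures.tsv")
        summary["signatures"] = {
            "mean_exposure": {
                name: float(exposures.frac[name].mean())
                for name in sig_matrix.names
            },
            "mean_cosine": float(exposures.cosine.dropna().mean()),
        }
    except Exception as exc:
        raise StageError("signatures", exc) from exc

    try:
        stage("differential_mutation")
        matrix = dm.build_gene_matrix(
            variants,
            min_samples_mutated=config.min_samples_mutated,
            samples=sorted({v.sample_id for v in variants}),
        )
        if matrix.dropped_genes:
            logger.info(
                "dropped %d genes below the %d-sample filter",
                len(matrix.dropped_genes), config.min_samples_mutated,
            )
        diff = dm.differential_test(matrix, labels)
        _write(dm.diffmut_table(diff), config.out_dir, "diffmut.tsv")
        summary["differential_mutation"] = {
            "n_genes_tested": len(diff),
            "top_genes": [
                {"gene": r.gene, "odds_ratio": r.odds_ratio, "q": r.q}
                for r in diff[:10]
            ],
        }
        excl_rows = []
        for a, b in config.exclusivity_pairs:
            if a in matrix.indicator.columns and b in matrix.indicator.columns:
                res, both = dm.mutual_exclusivity(matrix, a, b)
                excl_rows.append(
                    {
                        "gene_a": a, "gene_b": b, "co_mutated": both,
                        "odds_ratio": res.odds_ratio, "p": res.p_value,
                    }
                )
        if excl_rows:
            _write(
                pd.DataFrame(excl_rows), config.out_dir, "exclusivity.tsv"
            )
            summary["mutual_exclusivity"] = excl_rows
        hotspot_frames = [
            dm.hotspot_table(variants, gene, ref)
            for gene in config.hotspot_genes
        ]
        hotspots = pd.concat(hotspot_frames, ignore_index=True) if (
            hotspot_frames
        ) else pd.DataFrame()
        if len(hotspots):
            _write(hotspots, config.out_dir, "hotspots.tsv")
    except Exception as exc:
        raise StageError("differential_mutation", exc) from exc

    if config.expression:
        try:
            stage("expression_immune")
            expr = ei.ExpressionMatrix.from_tsv(config.expression)
            if config.immune_sets:
                sets = ei.GeneSetCollection.from_gmt(config.immune_sets)
                scores = ei.score_signatures(expr, sets)
                _write(
                    scores.reset_index(), config.out_dir,
                    "immune_scores.tsv",
                )
                corr = ei.correlate_with_enrichment(
                    scores, enrichment_by_sample
                )
                _write(corr, config.out_dir, "immune_enrichment_corr.tsv")
                summary["immune"] = {
                    "n_signatures": int(len(scores.columns)),
                    "n_significant_correlations": int(
                        (corr["q"] < 0.05).sum()
                    ) if len(corr) else 0,
                }
            apobec3 = [
                g for g in ("APOBEC3A", "APOBEC3B") if g in expr.genes
            ]
            if apobec3:
                sub = ei.ExpressionMatrix(expr.values.loc[apobec3])
                corr3 = ei.correlate_with_enrichment(
                    sub, enrichment_by_sample
                )
                _write(corr3, config.out_dir, "apobec3_corr.tsv")
                summary["apobec3_correlation"] = corr3.set_index("name")[
                    "rho"
                ].to_dict()
            if config.marker_sets:
                markers = ei.GeneSetCollection.from_gmt(config.marker_sets)
                assignment = ei.cluster_subtypes(expr, markers)
                _write(
                    pd.DataFrame(
                        {
                            "sample_id": assignment.subtype.index,
                            "subtype": assignment.subtype.values,
                            "cluster": assignment.cluster.values,
                        }
                    ),
                    config.out_dir,
                    "subtypes.tsv",
                )
                summary["subtypes"] = (
                    assignment.subtype.value_counts().to_dict()
                )
            de = ei.rank_de_test(expr, labels)
            _write(de, config.out_dir, "rank_de.tsv")
            summary["rank_de"] = {
                "n_genes": int(len(de)),
                "n_significant": int((de["q"] < 0.05).sum()) if len(de) else 0,
            }
        except Exception as exc:
            raise StageError("expression_immune", exc) from exc
    else:
        summary["expression_immune"] = "skipped (no expression input)"

    if config.clinical:
        try:
            stage("survival")
            records = surv.read_clinical(config.clinical)
            comparison = surv.compare_groups(records, labels)
            summary["survival"] = comparison
        except Exception as exc:
            raise StageError("survival", exc) from exc
    else:
        summary["survival"] = "skipped (no clinical input)"

    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
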