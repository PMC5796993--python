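"""Differential mutation testing, mutual exclusivity, hotspot tables."""

import math
from collections import defaultdict

import numpy as np
import pandas as pd
import pytest

from apobecscan import (
    APOBEC_HIGH,
    APOBEC_LOW,
    VariantRecord,
    build_gene_matrix,
    differential_test,
    hotspot_table,
    mutual_exclusivity,
)
from apobecscan.differential_mutation import GeneMutationMatrix

from conftest import toy_reference


def _matrix_from_indicator(ind: pd.DataFrame) -> GeneMutationMatrix:
    return GeneMutationMatrix(indicator=ind)


def _labels(high: list[str], low: list[str]) -> dict[str, str]:
    return {**{s: APOBEC_HIGH for s in high}, **{s: APOBEC_LOW for s in low}}


class TestBuildGeneMatrix:
    def test_rare_gene_dropped(self):
        variants = [
            VariantRecord(f"s{i}", "chr1", 10, "C", "T", "COMMON", "missense")
            for i in range(10)
        ] + [VariantRecord("s0", "chr1", 20, "C", "T", "RARE", "missense")]
        m = build_gene_matrix(variants, min_samples_mutated=5)
        assert m.genes == ["COMMON"]
        assert m.dropped_genes == ["RARE"]

    def test_silent_only_gene_absent(self):
        variants = [
            VariantRecord(f"s{i}", "chr1", 10, "C", "T", "SIL", "silent")
            for i in range(10)
        ]
        m = build_gene_matrix(variants, min_samples_mutated=1)
        assert m.genes == []

    def test_column_sums_match_brute_recount(self, bundle):
        m = build_gene_matrix(bundle.variants, min_samples_mutated=1)
        recount: dict[str, set] = defaultdict(set)
        for v in bundle.variants:
            if v.gene and v.is_non_silent:
                recount[v.gene].add(v.sample_id)
        for gene in m.genes:
            assert m.indicator[gene].sum() == len(recount[gene])


class TestDifferentialTest:
    def test_infinite_or_with_corrected_ci(self):
        ind = pd.DataFrame(
            {"G": [1] * 40 + [0] * 60 + [0] * 50},
            index=[f"h{i}" for i in range(100)] + [f"l{i}" for i in range(50)],
        )
        labels = _labels(
            [f"h{i}" for i in range(100)], [f"l{i}" for i in range(50)]
        )
        (res,) = differential_test(_matrix_from_indicator(ind), labels)
        assert res.n_high_mut == 40 and res.n_low_mut == 0
        assert math.isinf(res.odds_ratio)
        assert 0 < res.ci_low < res.ci_high < math.inf
        assert res.q < 1e-3

    def test_identical_rates_null(self):
        ind = pd.DataFrame(
            {"G": [1] * 10 + [0] * 10 + [1] * 10 + [0] * 10},
            index=[f"h{i}" for i in range(20)] + [f"l{i}" for i in range(20)],
        )
        labels = _labels(
            [f"h{i}" for i in range(20)], [f"l{i}" for i in range(20)]
        )
        (res,) = differential_test(_matrix_from_indicator(ind), labels)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_label_swap_inverts_odds_ratios(self, bundle, bundle_labels):
        m = build_gene_matrix(bundle.variants, min_samples_mutated=5)
        labels = {r.sample_id: r.label for r in bundle_labels}
        swapped = {
            s: APOBEC_LOW if l == APOBEC_HIGH else APOBEC_HIGH
            for s, l in labels.items()
        }
        res_a = {r.gene: r for r in differential_test(m, labels)}
        res_b = {r.gene: r for r in differential_test(m, swapped)}
        for gene in res_a:
            a, b = res_a[gene], res_b[gene]
            assert a.p == pytest.approx(b.p, abs=1e-12)
            if 0 < a.odds_ratio < math.inf:
                assert b.odds_ratio == pytest.approx(1 / a.odds_ratio)

    def test_driver_recovery_across_replicates(self):
        """TP53 enriched 4x in high and FGFR3 4x in low (n = 300) are both
        recovered at q < 0.05 with correctly signed OR in nearly every
        seeded replicate."""
        successes = 0
        n_rep = 25
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            n_high, n_low = 150, 150
            samples = [f"h{i}" for i in range(n_high)] + [
                f"l{i}" for i in range(n_low)
            ]
            n = n_high + n_low
            p_tp53 = [0.57] * n_high + [0.25] * n_low  # odds ratio 4
            p_fgfr3 = [0.12] * n_high + [0.35] * n_low  # odds ratio ~0.25
            ind = pd.DataFrame(
                {
                    "TP53": rng.random(n) < np.array(p_tp53),
                    "FGFR3": rng.random(n) < np.array(p_fgfr3),
                    # neutral background genes for the BH universe
                    **{
                        f"BGN{j}": rng.random(300) < 0.2
                        for j in range(8)
                    },
                },
                index=samples,
            ).astype(int)
            labels = _labels(samples[:n_high], samples[n_high:])
            res = {
                r.gene: r
                for r in differential_test(_matrix_from_indicator(ind), labels)
            }
            ok = (
                res["TP53"].q < 0.05
                and res["TP53"].odds_ratio > 1
                and res["FGFR3"].q < 0.05
                and res["FGFR3"].odds_ratio < 1
            )
            successes += ok
        assert successes / n_rep >= 0.9

    def test_empty_group_rejected(self):
        ind = pd.DataFrame({"G": [1, 0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            differential_test(
                _matrix_from_indicator(ind),
                {"a": APOBEC_HIGH, "b": APOBEC_HIGH},
            )

    def test_gene_order_invariance(self, bundle, bundle_labels):
        m = build_gene_matrix(bundle.variants, min_samples_mutated=5)
        labels = {r.sample_id: r.label for r in bundle_labels}
        reversed_m = _matrix_from_indicator(m.indicator[m.genes[::-1]])
        sig_a = {r.gene for r in differential_test(m, labels) if r.q < 0.05}
        sig_b = {
            r.gene for r in differential_test(reversed_m, labels) if r.q < 0.05
        }
        assert sig_a == sig_b


class TestPermutationCalibration:
    def test_permuted_labels_give_uniformish_p(self, bundle, bundle_labels):
        """With labels shuffled, the fraction of genes at p < 0.05 stays
        near the nominal level."""
        m = build_gene_matrix(bundle.variants, min_samples_mutated=5)
        labels = [r.label for r in bundle_labels]
        sample_order = [r.sample_id for r in bundle_labels]
        rng = np.random.default_rng(2024)
        fractions = []
        for _ in range(100):
            perm = rng.permutation(labels)
            lab = dict(zip(sample_order, perm))
            res = differential_test(m, lab)
            ps = np.array([r.p for r in res])
            fractions.append((ps < 0.05).mean())
        assert 0.01 <= np.mean(fractions) <= 0.10


class TestMutualExclusivity:
    def test_perfectly_exclusive(self):
        ind = pd.DataFrame(
            {
                "A": [1] * 20 + [0] * 20 + [0] * 60,
                "B": [0] * 20 + [1] * 20 + [0] * 60,
            },
            index=[f"s{i}" for i in range(100)],
        )
        res, both = mutual_exclusivity(_matrix_from_indicator(ind), "A", "B")
        assert both == 0
        assert res.odds_ratio < 1

    def test_independent_genes_or_near_one(self):
        rng = np.random.default_rng(5)
        ind = pd.DataFrame(
            {
                "A": (rng.random(1000) < 0.1).astype(int),
                "B": (rng.random(1000) < 0.1).astype(int),
            },
            index=[f"s{i}" for i in range(1000)],
        )
        res, _ = mutual_exclusivity(_matrix_from_indicator(ind), "A", "B")
        assert 0.4 < res.odds_ratio < 2.5
        assert res.p_value > 0.05

    def test_nested_genes_cooccur(self):
        ind = pd.DataFrame(
            {
                "A": [1] * 10 + [0] * 90,
                "B": [1] * 30 + [0] * 70,
            },
            index=[f"s{i}" for i in range(100)],
        )
        res, both = mutual_exclusivity(_matrix_from_indicator(ind), "A", "B")
        assert both == 10
        assert res.odds_ratio > 1 or math.isinf(res.odds_ratio)

    def test_absent_gene_key_error(self):
        ind = pd.DataFrame({"A": [1, 0]}, index=["a", "b"])
        with pytest.raises(KeyError):
            mutual_exclusivity(_matrix_from_indicator(ind), "A", "MISSING")


class TestHotspotTable:
    def test_tcw_hotspot_aggregation(self):
        ref = toy_reference("ATCAG")
        variants = [
            VariantRecord(
                f"s{i}", "chr1", 3, "C", "T", "PIK3CA", "missense", "E542K"
            )
            for i in range(3)
        ]
        table = hotspot_table(variants, "PIK3CA", ref)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["aa_change"] == "E542K"
        assert row["count"] == 3
        assert row["is_tcw_context"]

    def test_unparsed_bucket(self):
        variants = [
            VariantRecord("s", "chr1", 3, "C", "T", "TP53", "missense", "")
        ]
        table = hotspot_table(variants, "TP53")
        assert list(table["aa_change"]) == ["unparsed"]

    def test_counts_match_brute_group_by(self, bundle):
        table = hotspot_table(bundle.variants, "TP53", bundle.reference)
        manual = defaultdict(int)
        for v in bundle.variants:
            if v.gene == "TP53" and v.protein_change:
                manual[v.protein_change] += 1
        parsed = table[table["aa_change"] != "unparsed"]
        assert parsed["count"].sum() == sum(manual.values())
        for _, row in parsed.iterrows():
            assert manual[row["aa_change"]] == row["count"]
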