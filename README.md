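# apobecscan

Analysis toolkit for **APOBEC-mediated mutagenesis in tumor cohorts**,
built around the workflow used to characterise urothelial (bladder)
carcinoma: classify each tumor by how strongly its mutations bear the
APOBEC fingerprint, then ask what distinguishes the two classes — driver
mutations, mutational-signature composition, immune gene expression, and
survival.

It is written for computational biologists who have a somatic MAF, a
reference FASTA, and optionally an expression matrix and clinical table,
and who want the complete stratified analysis (or any single stage) as a
library or from the shell. A seeded synthetic-cohort generator with
latent ground truth makes every stage testable end to end without any
data download.

## The statistic at the core

APOBEC3 cytidine deaminases attack cytosine in single-stranded DNA at the
trinucleotide motif **TCW** (W ∈ {A, T}), producing C>T and C>G
substitutions. For each sample the **APOBEC enrichment score** compares
how often its C>T/C>G mutations hit TCW with how available the motif is
around the mutated sites:

```
E = (m_TCW / m_C) / (bg_TCW / bg_C)
```

where `m_TCW` is the number of C>T/C>G mutations at TCW, `m_C` the number
of all C>T/C>G mutations, and `bg_TCW` / `bg_C` count TCW motifs and
cytosines (both strands) within ±20 nt of every counted mutation. Each
sample gets a one-sided Fisher exact test of the same 2×2; p-values are
Benjamini–Hochberg corrected across the cohort, and a sample is called
**APOBEC-high** when `E > 2` and `q < 0.05`, otherwise **APOBEC-low**.

Around that core the package provides:

* 96-channel mutation catalogs and non-negative least-squares attribution
  to reference signatures (APOBEC signatures 2 + 13, CpG-deamination
  signature 1, flat signature 5, aristolochic-acid signature 22) with
  per-sample reconstruction cosine;
* per-gene differential mutation between the two classes (Fisher exact,
  odds ratios with Woolf CIs, BH correction), FGFR3/RAS mutual-exclusivity
  testing, and TCW-flagged protein hotspot tables (PIK3CA E542/E545);
* immune gene-set scores (mean z-scored log2 expression), Spearman
  correlation of scores and genes with the numeric enrichment score,
  Ward-linkage subtype clustering, and a rank-based differential-expression
  test;
* Kaplan–Meier curves, median survival, and the log-rank test;
* a fully deterministic synthetic-cohort generator (`simulate_cohort`)
  emulating the statistical structure of a muscle-invasive bladder-cancer
  exome cohort, with all latent truth exported.

## Worked example

```python
from apobecscan import (CohortSpec, simulate_cohort, accumulate_counts,
                        classify_cohort, build_gene_matrix,
                        differential_test, compare_groups, APOBEC_HIGH)

bundle = simulate_cohort(CohortSpec(n_samples=100, seed=11))
counts = accumulate_counts(bundle.variants, bundle.reference)
results = classify_cohort(counts)
n_high = sum(r.label == APOBEC_HIGH for r in results)
print(f"APOBEC-high: {n_high} / {len(results)} samples")

labels = {r.sample_id: r.label for r in results}
top = differential_test(build_gene_matrix(bundle.variants), labels)[0]
print(f"top gene: {top.gene}, OR = {top.odds_ratio:.2f}, q = {top.q:.2e}")
print(compare_groups(bundle.clinical, labels))
```

prints

```
APOBEC-high: 83 / 100 samples
top gene: PSG024, OR = 12.00, q = 1.74e-03
{'groups': {'APOBEC_high': {'n': 83, 'median_months': 47.4},
            'APOBEC_low': {'n': 17, 'median_months': 22.7}},
 'logrank_statistic': 4.287, 'logrank_p': 0.0384}
```

83 of 100 synthetic tumors are called APOBEC-high (the generator's latent
prevalence is ~0.84, so classification recovers the split); the top
differentially mutated gene is enriched twelve-fold in the high group;
and the high group's median overall survival is roughly twice the low
group's, with a significant log-rank test — the cohort structure the
method is designed to expose.

The same stages are available from the shell:

```bash
apobecscan simulate --out data/ --seed 11 --n-samples 100
apobecscan enrich --maf data/cohort.maf --ref data/ref.fa --out enrichment.tsv
apobecscan report --maf data/cohort.maf --ref data/ref.fa \
    --expr data/expr.tsv --clinical data/clinical.tsv \
    --immune-sets data/sets.gmt --marker-sets data/markers.gmt --out report/
```

## Notes

* The bundled reference-signature vectors are a synthetic emulation of
  the COSMIC v2 signatures' motif structure (see
  `apobecscan.signature_fit.synthetic_cosmic_signatures`); for real tumor
  data load the published catalog with `read_signatures`.
* Methodological details, parameter defaults, and known limitations are
  documented in `docs/methods.md`.
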