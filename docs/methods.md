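# Methods

## Model and procedure

### Enrichment score and classification

The unit of analysis is the pyrimidine-oriented single-nucleotide
variant: a substitution whose reference base is a purine is re-expressed
on the opposite strand, so every context has a C or T center and every
SNV falls into one of 96 channels (6 substitution classes × 16 flank
combinations).

For each sample we count `m_C`, the C>T and C>G SNVs (the two classes
APOBEC deamination produces), and `m_TCW`, the subset whose context is
T-C-W with W ∈ {A, T}. Restricting the denominator to the same two
substitution classes keeps numerator and denominator comparable; C>A
mutations, which arise mostly from other processes, enter neither count.
Motif availability is measured locally: around every counted mutation we
count TCW motifs (either strand, i.e. TCW or WGA on the given strand) and
cytosines (C or G) within ±20 nt, truncated at contig ends, N bases
skipped. The enrichment score is the ratio of ratios

    E = (m_TCW * bg_C) / (m_C * bg_TCW),

E = 1 meaning TCW is hit exactly as often as its availability predicts.
Evidence is quantified by a one-sided (greater) Fisher exact test on
[[m_TCW, m_C − m_TCW], [bg_TCW, bg_C − bg_TCW]]; the per-sample p-values
are Benjamini–Hochberg corrected across all scorable samples of the
cohort, and the classification rule is

    APOBEC-high  ⇔  E > 2  and  q < 0.05,

everything else APOBEC-low. Samples with no countable mutation or a zero
background are unscorable and default to APOBEC-low (the complement
class), reported with E = 0 and q = 1.

Before scoring, cohort outliers are removed: samples above 150
mutations/Mb (hypermutators that distort spectrum summaries) and samples
with ≤ 5 total mutations (no information for a ratio statistic). Rates
use a configurable covered-exome constant, default 38 Mb.

### Signature attribution

Per-sample catalogs are decomposed onto a fixed signature set by
non-negative least squares on the L1-normalised spectrum:
min ‖s − P e‖₂ subject to e ≥ 0, exposures reported as fractions
e / Σe with the cosine similarity between observed and reconstructed
spectra as fit quality. No de novo discovery, no sparsity penalty, no
opportunity-renormalisation (a hook exists: supply any channel × signature
TSV via `read_signatures`). The deterministic active-set NNLS solution is
taken as-is.

The distributed signature vectors are a **synthetic emulation** of COSMIC
v2 signatures 1, 2, 5, 13 and 22, constructed from each signature's
defining motif preference (1: C>T at NpCpG; 2: C>T at TpCpW with a minor
C>G component; 13: the C>G/C>T mirror of 2; 5: near-flat with mild
C>T/T>C weight; 22: T>A at CpTpG) plus a 0.002-per-channel floor. They
reproduce the qualitative geometry that matters for validation — the
2/13 pair shares the TCW motif (cosine ≈ 0.59, separable but correlated)
— but they are not the published probability vectors; analyses of real
tumors should substitute the published catalog.

### Differential mutation, exclusivity, hotspots

Gene-level mutation status is any non-silent variant (consequence filter
configurable); genes mutated in fewer than 5 samples cohort-wide are
dropped before testing — below that the 2×2 carries no power and only
inflates the BH universe. Each remaining gene is tested with a two-sided
Fisher exact test of mutation × group, odds ratios oriented so OR > 1
means enriched in APOBEC-high, Woolf log-OR confidence intervals with
Haldane–Anscombe 0.5 correction on zero cells, BH across tested genes.
Mutual exclusivity is the same machinery on the co-occurrence table
(OR < 1 ⇒ exclusive), reported with the observed co-mutated count.
Hotspot tables aggregate a gene's variants by parsed protein change
("E542K" style) and flag rows whose variants all sit in TCW contexts;
unparseable changes are tallied separately rather than dropped.

### Expression and immune scoring

Expression values are RSEM-like non-negative abundances analysed as
log2(x+1). A gene-set score is the mean over member genes of the
cross-sample z-score, so scores are centered at 0 by construction and
invariant (up to the pseudo-count) to global rescaling. Zero-variance
genes are excluded with a warning; sets with no gene in the matrix are
flagged rather than silently dropped. Association with the numeric
enrichment score uses Spearman's rho (rank-based, hence invariant to
monotone transforms of E) with BH across whatever family is tested.

Molecular subtyping is agglomerative hierarchical clustering (Euclidean
distance, Ward linkage) of the z-scored log2 expression of the 2000
most-variable genes, cut at 4 clusters. Clusters are named
luminal / p53-like / basal / claudin-low by greedily matching each
cluster centroid to the marker gene set with the highest mean z-score,
without label reuse. The marker sets ship as editable configuration; the
feature count is configurable because no canonical feature list exists.

Differential expression between the classes is a per-gene Mann–Whitney
test on log2 values with BH correction and a log2 median fold-change —
a deliberately dependency-light rank-based procedure chosen over
moderated linear-model statistics; it is less powerful for small groups
but assumption-free and adequate for the two-group screen performed here.

### Survival

Kaplan–Meier product-limit curves, median survival defined as the
smallest observed time with S(t) ≤ 0.5 (undefined if never reached), and
the standard two-group log-rank chi-square with 1 df, ties handled by the
aggregated increments. Estimation is delegated to lifelines; the tests
validate it against hand product-limit computation and a brute-force
observed-vs-expected tabulation. No Cox regression or competing risks.

### ΔΔCt calculator

For qPCR experiments the relative fold change is 2^(−ΔΔCt) with
ΔΔCt = (Ct_target − Ct_ref)_treated − (Ct_target − Ct_ref)_control.
Pure arithmetic, exposed for completeness of the analysis surface.

## Synthetic cohort generator

`simulate_cohort(CohortSpec)` emulates the statistical structure of a
muscle-invasive bladder-cancer exome cohort; the entire bundle (FASTA,
MAF, expression TSV, clinical TSV, gene sets, truth table) is a pure
function of the `CohortSpec` and its mandatory seed.

Default conditions and why:

| parameter | default | rationale |
|---|---|---|
| n_samples | 388 | the cohort size the analysis is designed around |
| p_high | 324/388 | observed APOBEC-high prevalence in that cohort |
| burden | log-normal, median 180 (high), e-fold lower (low), σ = 1 | spans ~0.1–150 mutations/Mb over a 38-Mb exome; APOBEC-driven tumors are hypermutated |
| APOBEC fraction | Beta(6,4) high / Beta(1,19) low | high tumors dominated by signatures 2+13, low tumors mostly background; Beta(0,·) pins the fraction to 0 for null cohorts |
| background split | 40% signature 1, 60% signature 5 | CpG deamination plus clock-like background |
| drivers | TP53/PIK3CA/ARID1A/ATR/BRCA2/MLL/MLL3 OR 2.5–4 in high; FGFR3/KRAS/HRAS/NRAS OR 0.25–0.3 | direction and rough magnitude of the reported group differences |
| exclusivity | FGFR3–KRAS–HRAS–NRAS group, second draw suppressed | FGFR3 and RAS mutations do not co-occur |
| PIK3CA hotspots | E542K/E545K pinned to TCW C>T sites | the helical-domain TCW hotspots under study |
| expression | baseline log2 ~ N(5, 1.5), noise σ = 1; APOBEC3A/3B +1.5·z(log burden); immune sets +1.2 in high; subtype markers +2.5 | burden-coupled APOBEC3 expression, immune elevation with APOBEC activity, four marker-defined subtypes |
| survival | exponential medians 38.2 / 18.5 months, uniform censoring on [0, 120] | the reported two-fold survival split with administrative censoring |
| reference | 100 kb i.i.d., GC 0.41 | human-like composition at desk scale |

Mutations are placed by channel-conditional sampling against a
precomputed index of every trinucleotide occurrence (both strands), so
each emitted variant's reference context reproduces its generating
channel exactly — downstream context extraction closes the loop, which is
what makes enrichment and exposure recovery testable against latent
truth. Non-hotspot driver contexts are drawn from the sample's own
signature mixture so drivers do not distort the enrichment statistic.

What the generator does **not** emulate: real chromosome structure,
regional mutation-rate covariates, copy number, subclonality, kataegis,
realistic gene lengths (passenger gene labels are uniform over a 50-gene
pool), or correlated immune-cell populations. Passing closed-loop tests
therefore demonstrates correctness of the statistics under the stated
generative model, not robustness to every property of real tumor data.
The immune and subtype marker gene lists are small synthetic stand-ins
using canonical lineage symbols, not any published signature file.

## Numerical choices

* Coordinates are 1-based inclusive everywhere; 0-based arithmetic is
  confined to `variant_io`.
* Reference-base mismatch and N-containing contexts are hard errors:
  silent context corruption would bias E invisibly.
* Two-sided Fisher uses the probability-mass rule; the Woolf CI is used
  for determinism (conditional-MLE intervals would also be defensible).
* Fisher sidedness: one-sided (greater) for the per-sample enrichment
  test, whose alternative is directional by construction; two-sided for
  gene-level comparisons, where either direction is of interest.
* BH adjustment preserves input order and caps at 1.
* NNLS ties/degeneracy resolve to the deterministic active-set solution.
* Zero-mutation samples: all-zero exposures flagged unscorable rather
  than NaN rows; unscorable enrichment defaults to the low class.
* Clustering label assignment is greedy best-score-first, deterministic
  given input order.

## Problem sizes

Tests run the generator at 80–200 samples with a 100-kb reference
(≈ 25–60 k placed mutations), 100-seed recovery loops at 500 mutations
per spectrum, and 100-replicate permutation calibrations; the acceptance
script uses the full 388-sample default cohort plus a 200-sample null
cohort. These sizes give stable stochastic checks while keeping the
whole suite inside a half-minute desk run.

## Known limitations

* The enrichment background is mutation-local (±20 nt windows), the
  standard construction for this score; whole-territory backgrounds would
  need the covered-interval BED, which the MAF does not carry.
* The rank-based expression test substitutes for moderated linear-model
  statistics; small-group power differs.
* Subtype labels are only as good as the supplied marker sets; the
  shipped defaults are illustrative.
* The synthetic signature matrix approximates published vectors'
  motif structure, not their exact channel weights; absolute exposure
  values on real data require the published catalog.
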