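"""Synthetic tumor-cohort generator with known ground truth.

Generates every input the analysis consumes — reference FASTA, somatic
MAF, expression matrix, clinical table, gene sets — from a single seeded
specification, emulating the statistical structure of a muscle-invasive
bladder-cancer exome cohort:

* per-sample mutation burdens are log-normal, spanning roughly 0.1–150
  mutations/Mb over a 38-Mb exome equivalent;
* each sample's mutation catalog is a mixture of the reference signatures
  (APOBEC signatures 2 + 13 for a latent "high" group, CpG-deamination
  signature 1 and flat signature 5 as background, optionally signature 22);
* driver genes are Bernoulli per sample with group-dependent odds (TP53,
  PIK3CA, ARID1A, ATR, BRCA2, MLL, MLL3 enriched in the high group; FGFR3
  and the RAS family in the low group, FGFR3/RAS mutually exclusive;
  PIK3CA drivers sit at E542/E545 in TCW contexts);
* APOBEC3A/3B expression is coupled to log mutation burden, immune
  gene-set expression is elevated in the high group, and subtype marker
  genes are shifted per latent subtype;
* survival is exponential per group (medians mirroring the ~38 vs ~18
  month split), with uniform administrative censoring.

Mutations are placed by channel-conditional rejection-free sampling: a
position index of every trinucleotide occurrence (both strands) is built
once, so each emitted variant's reference context reproduces its
generating channel exactly — downstream context extraction closes the
loop.  The whole cohort is a pure function of (spec, seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .apobec_enrichment import DEFAULT_EXOME_MB
from .expression_immune import ExpressionMatrix, GeneSetCollection, SUBTYPES
from .signature_fit import SignatureMatrix, synthetic_cosmic_signatures
from .survival import SurvivalRecord
from .variant_io import (
    CHANNELS,
    COMPLEMENT,
    ReferenceSequence,
    VariantRecord,
    reverse_complement,
    write_maf,
)

HIGH, LOW = "high", "low"


@dataclasses.dataclass
class DriverGene:
    """Group-dependent mutation odds for one driver gene.

    ``p_low`` is the mutation probability in the low group; the high-group
    probability is derived from ``odds_ratio`` (odds_high = OR * odds_low).
    """

    gene: str
    p_low: float
    odds_ratio: float

    @property
    def p_high(self) -> float:
        odds = self.odds_ratio * self.p_low / (1 - self.p_low)
        return odds / (1 + odds)


def default_driver_table() -> list[DriverGene]:
    return [
        DriverGene("TP53", 0.25, 4.0),
        DriverGene("PIK3CA", 0.15, 3.0),
        DriverGene("ARID1A", 0.15, 2.5),
        DriverGene("ATR", 0.05, 3.0),
        DriverGene("BRCA2", 0.05, 3.0),
        DriverGene("MLL", 0.08, 2.5),
        DriverGene("MLL3", 0.08, 2.5),
        DriverGene("FGFR3", 0.35, 0.25),
        DriverGene("KRAS", 0.20, 0.25),
        DriverGene("HRAS", 0.10, 0.3),
        DriverGene("NRAS", 0.10, 0.3),
    ]


@dataclasses.dataclass
class CohortSpec:
    """Everything the generator needs; seeded and fully deterministic."""

    n_samples: int = 388
    seed: int = 0
    #: latent fraction of APOBEC-driven tumors (cohort split 324/388)
    p_high: float = 324 / 388
    # --- mutation burden (total exonic mutations per sample) ---
    burden_log_mean: float = math.log(180.0)
    burden_log_sigma: float = 1.0
    #: APOBEC-driven tumors are hypermutated: the low group's log-burden
    #: mean sits this far below ``burden_log_mean``
    burden_group_log_shift: float = 1.0
    exome_mb: float = DEFAULT_EXOME_MB
    # --- signature mixture ---
    signature_names: tuple[str, ...] = ("COSMIC1", "COSMIC2", "COSMIC5", "COSMIC13")
    #: Beta parameters of the APOBEC (sig 2+13) fraction per group
    apobec_beta_high: tuple[float, float] = (6.0, 4.0)
    apobec_beta_low: tuple[float, float] = (1.0, 19.0)
    #: share of the non-APOBEC mass on signature 1 (rest on 5, then 22)
    sig1_share: float = 0.4
    sig22_share: float = 0.0  # of non-APOBEC mass, only if COSMIC22 present
    # --- drivers ---
    drivers: list[DriverGene] = dataclasses.field(
        default_factory=default_driver_table
    )
    exclusivity_groups: tuple[tuple[str, ...], ...] = (
        ("FGFR3", "KRAS", "HRAS", "NRAS"),
    )
    #: fraction of PIK3CA drivers at each hotspot (rest random positions)
    pik3ca_hotspots: tuple[str, ...] = ("E542K", "E545K")
    # --- passenger annotation ---
    n_passenger_genes: int = 50
    silent_fraction: float = 0.3
    # --- reference ---
    ref_length: int = 100_000
    ref_name: str = "chr1"
    gc_content: float = 0.41
    # --- expression ---
    n_background_genes: int = 150
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    noise_log2_sd: float = 1.0
    apobec3_coupling: float = 1.5  # log2 shift per SD of log burden
    immune_shift_log2: float = 1.2  # immune-set elevation in the high group
    subtype_marker_shift_log2: float = 2.5
    # --- survival ---
    median_survival_high: float = 38.2  # months
    median_survival_low: float = 18.5
    censor_horizon: float = 120.0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=list)


@dataclasses.dataclass
class CohortBundle:
    """A complete generated cohort plus its ground truth."""

    spec: CohortSpec
    reference: ReferenceSequence
    variants: list[VariantRecord]
    expression: ExpressionMatrix
    clinical: list[SurvivalRecord]
    truth: pd.DataFrame  # sample_id, group, burden, exposures, subtype
    immune_sets: GeneSetCollection
    marker_sets: GeneSetCollection
    signatures: SignatureMatrix

    def write(self, out_dir: str | os.PathLike) -> dict[str, str]:
        out = str(out_dir)
        os.makedirs(out, exist_ok=True)
        paths = {
            "reference": os.path.join(out, "ref.fa"),
            "maf": os.path.join(out, "cohort.maf"),
            "expression": os.path.join(out, "expr.tsv"),
            "clinical": os.path.join(out, "clinical.tsv"),
            "truth": os.path.join(out, "truth.tsv"),
            "immune_sets": os.path.join(out, "sets.gmt"),
            "marker_sets": os.path.join(out, "markers.gmt"),
            "spec": os.path.join(out, "spec.json"),
        }
        self.reference.write_fasta(paths["reference"])
        write_maf(self.variants, paths["maf"], dialect="tcga")
        self.expression.to_tsv(paths["expression"])
        pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.clinical],
                "time_months": [r.time for r in self.clinical],
                "event": [int(r.event) for r in self.clinical],
            }
        ).to_csv(paths["clinical"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        self.immune_sets.to_gmt(paths["immune_sets"])
        self.marker_sets.to_gmt(paths["marker_sets"])
        with open(paths["spec"], "w") as fh:
            fh.write(self.spec.to_json())
        return paths


# ---------------------------------------------------------------------------
# gene sets (synthetic stand-ins with canonical marker symbols)
# ---------------------------------------------------------------------------

def default_immune_sets() -> GeneSetCollection:
    """Immune cell, MHC-II, IFN and checkpoint gene sets.

    Set names follow the immune-cell populations commonly scored in tumor
    expression cohorts; memberships are small synthetic marker lists built
    from canonical lineage genes (the checkpoint set uses the nine HGNC
    symbols of PD-1, PD-L1, PD-L2, CTLA-4, B7-H4, TIM-3, LAG3, OX40 and
    OX40L), not a copy of any published signature file.
    """
    sets = {
        "B_cells": ["CD19", "MS4A1", "CD79A", "CD79B", "BLK"],
        "T_cells": ["CD3D", "CD3E", "CD3G", "CD2", "TRAT1"],
        "T_helper": ["CD4", "ICOS", "CD28"],
        "Tcm": ["CCR7", "SELL", "IL7R"],
        "Tem": ["GZMK", "CCL5", "EOMES"],
        "Th1": ["TBX21", "IFNG", "IL12RB2", "STAT4"],
        "Th2": ["IL4", "IL5", "IL13", "CCR4"],
        "TFH": ["CXCR5", "BCL6", "IL21"],
        "Th17": ["RORC", "IL17A", "IL23R"],
        "Treg": ["FOXP3", "IL2RA", "IKZF2"],
        "Tgd": ["TRGC1", "TRGC2", "TRDC"],
        "Cytotoxic": ["GZMA", "GZMB", "PRF1", "GNLY", "KLRK1"],
        "NK": ["NCR1", "KIR2DL1", "NCAM1", "KLRD1"],
        "NK_CD56bright": ["XCL1", "XCL2", "NCR3"],
        "NK_CD56dim": ["KIR2DL3", "KIR3DL1", "IL21R"],
        "DC": ["CD1C", "ITGAX", "HLA-DQB2"],
        "iDC": ["CD1A", "CD1B", "F13A1"],
        "aDC": ["CCL19", "CCL22", "LAMP3"],
        "pDC": ["IL3RA", "CLEC4C", "LILRA4"],
        "Eosinophils": ["IL5RA", "CCR3", "SIGLEC8"],
        "Macrophages": ["CD68", "CD163", "MSR1", "MRC1"],
        "Mast_cells": ["TPSAB1", "TPSB2", "CPA3", "MS4A2"],
        "Neutrophils": ["FCGR3B", "CSF3R", "CEACAM3"],
        "PMNs": ["S100A8", "S100A9", "FPR1"],
        "MHC_II": [
            "HLA-DRA", "HLA-DRB1", "HLA-DPA1", "HLA-DPB1",
            "HLA-DQA1", "HLA-DQB1", "HLA-DMA", "HLA-DMB", "CD74",
        ],
        "IFN": [
            "STAT1", "IRF1", "GBP1", "CXCL9", "CXCL10", "IDO1",
            "IFIT1", "IFIT3", "ISG15", "MX1", "OAS1",
        ],
        "Checkpoint": [
            "PDCD1", "CD274", "PDCD1LG2", "CTLA4", "VTCN1",
            "HAVCR2", "LAG3", "TNFRSF4", "TNFSF4",
        ],
    }
    return GeneSetCollection(sets)


def default_subtype_markers() -> GeneSetCollection:
    """Marker gene sets naming the four expression subtypes (synthetic
    stand-in marker lists built from canonical lineage genes)."""
    return GeneSetCollection(
        {
            "luminal": ["KRT20", "UPK2", "UPK1B", "PPARG", "GATA3", "FOXA1"],
            "p53_like": ["ACTG2", "CNN1", "MYH11", "PGM5", "DES"],
            "basal": ["KRT5", "KRT6A", "KRT14", "CD44", "CDH3"],
            "claudin_low": ["ZEB1", "ZEB2", "VIM", "TWIST1", "SNAI2"],
        }
    )


# ---------------------------------------------------------------------------
# reference and mutation placement
# ---------------------------------------------------------------------------

def make_reference(
    length: int, seed: int, gc_content: float = 0.41, name: str = "chr1"
) -> ReferenceSequence:
    """I.i.d. random reference of the requested length and GC content."""
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    rng = np.random.default_rng(seed)
    p_gc = gc_content / 2
    p_at = (1 - gc_content) / 2
    bases = rng.choice(
        np.array(list("ACGT")), size=length, p=[p_at, p_gc, p_gc, p_at]
    )
    return ReferenceSequence({name: "".join(bases)})


def _context_position_index(
    ref: ReferenceSequence, chrom: str
) -> dict[str, list[tuple[int, int]]]:
    """Map each pyrimidine-centered trinucleotide to its genomic sites.

    Values are (pos, strand) with strand +1 when the forward trinucleotide
    equals the motif and -1 when it equals the motif's reverse complement.
    """
    seq = ref.fetch(chrom, 1, ref.length(chrom))
    index: dict[str, list[tuple[int, int]]] = {}
    for i in range(1, len(seq) - 1):
        tri = seq[i - 1 : i + 2]
        if "N" in tri:
            continue
        pos = i + 1  # 1-based center
        if tri[1] in "CT":
            index.setdefault(tri, []).append((pos, +1))
        else:
            index.setdefault(reverse_complement(tri), []).append((pos, -1))
    return index


def _channel_parts(label: str) -> tuple[str, str, str, str]:
    # "T[C>G]A" -> (up, ref, alt, down)
    return label[0], label[2], label[4], label[6]


def _place_mutation(
    channel_label: str,
    index: Mapping[str, Sequence[tuple[int, int]]],
    rng: np.random.Generator,
) -> tuple[int, str, str]:
    """Choose a genomic site carrying the channel's trinucleotide.

    Returns (pos, ref_allele, alt_allele) on the forward strand.
    """
    up, center, alt, down = _channel_parts(channel_label)
    sites = index.get(up + center + down)
    if not sites:
        raise ValueError(
            f"reference has no site for context {up}{center}{down} "
            f"(channel {channel_label})"
        )
    pos, strand = sites[rng.integers(len(sites))]
    if strand > 0:
        return pos, center, alt
    return pos, COMPLEMENT[center], COMPLEMENT[alt]


# ---------------------------------------------------------------------------
# cohort simulation stages
# ---------------------------------------------------------------------------

def _sample_exposures(
    spec: CohortSpec, groups: Sequence[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Per-sample true signature fractions given latent group labels."""
    names = list(spec.signature_names)
    has22 = "COSMIC22" in names
    rows = []
    for g in groups:
        a, b = (
            spec.apobec_beta_high if g == HIGH else spec.apobec_beta_low
        )
        # degenerate Beta endpoints: a = 0 pins the APOBEC fraction to 0
        # (pure background cohort), b = 0 pins it to 1
        if a <= 0:
            apobec = 0.0
        elif b <= 0:
            apobec = 1.0
        else:
            apobec = rng.beta(a, b)
        split2 = rng.beta(5, 5)  # sig2 vs sig13 share of the APOBEC mass
        rest = 1 - apobec
        sig22 = rest * spec.sig22_share if has22 else 0.0
        bg = rest - sig22
        exp = {
            "COSMIC1": bg * spec.sig1_share,
            "COSMIC2": apobec * split2,
            "COSMIC5": bg * (1 - spec.sig1_share),
            "COSMIC13": apobec * (1 - split2),
        }
        if has22:
            exp["COSMIC22"] = sig22
        rows.append([exp.get(n, 0.0) for n in names])
    return pd.DataFrame(rows, columns=names)


def simulate_mutations(
    spec: CohortSpec,
    ref: ReferenceSequence,
    rng: np.random.Generator,
    signatures: SignatureMatrix | None = None,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Draw burdens, exposures, and context-consistent passenger SNVs.

    Returns the variant list and the per-sample truth table (group,
    burden, true exposures).
    """
    if signatures is None:
        signatures = synthetic_cosmic_signatures()
    sigs = signatures.subset(spec.signature_names)
    P = sigs.prob.to_numpy()  # 96 × K

    sample_ids = [f"S{i:04d}" for i in range(spec.n_samples)]
    groups = [
        HIGH if rng.random() < spec.p_high else LOW for _ in sample_ids
    ]
    log_means = np.array(
        [
            spec.burden_log_mean
            - (spec.burden_group_log_shift if g == LOW else 0.0)
            for g in groups
        ]
    )
    burdens = np.maximum(
        1,
        rng.lognormal(
            log_means, spec.burden_log_sigma, size=spec.n_samples
        ).astype(int),
    )
    exposures = _sample_exposures(spec, groups, rng)
    index = _context_position_index(ref, spec.ref_name)
    passenger_genes = [
        f"PSG{i:03d}" for i in range(spec.n_passenger_genes)
    ]

    variants: list[VariantRecord] = []
    for i, sid in enumerate(sample_ids):
        mixture = P @ exposures.iloc[i].to_numpy()
        mixture = mixture / mixture.sum()
        channel_draws = rng.choice(len(CHANNELS), size=burdens[i], p=mixture)
        for ch in channel_draws:
            pos, ref_b, alt_b = _place_mutation(CHANNELS[ch], index, rng)
            silent = rng.random() < spec.silent_fraction
            variants.append(
                VariantRecord(
                    sample_id=sid,
                    chrom=spec.ref_name,
                    pos=pos,
                    ref_allele=ref_b,
                    alt_allele=alt_b,
                    gene=passenger_genes[rng.integers(len(passenger_genes))],
                    variant_class="silent" if silent else "missense",
                )
            )
    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": groups,
            "burden": burdens,
        }
    )
    truth = pd.concat([truth, exposures.add_prefix("true_")], axis=1)
    return variants, truth


def simulate_drivers(
    spec: CohortSpec,
    truth: pd.DataFrame,
    ref: ReferenceSequence,
    rng: np.random.Generator,
    signatures: SignatureMatrix | None = None,
) -> list[VariantRecord]:
    """Group-dependent driver mutations, honouring exclusivity groups.

    Driver SNV contexts are drawn from the sample's own signature mixture
    (so they do not distort the enrichment statistic), except PIK3CA
    hotspot drivers, which are pinned to TCW-context C>T sites with
    protein changes E542K/E545K — the motif placement under study.
    """
    if signatures is None:
        signatures = synthetic_cosmic_signatures()
    sigs = signatures.subset(spec.signature_names)
    P = sigs.prob.to_numpy()
    index = _context_position_index(ref, spec.ref_name)
    exposure_cols = [f"true_{n}" for n in spec.signature_names]
    tcw_ct_channels = [
        CHANNELS.index("T[C>T]A"),
        CHANNELS.index("T[C>T]T"),
    ]

    variants: list[VariantRecord] = []
    for row in truth.itertuples():
        sid, group = row.sample_id, row.group
        mixture = P @ np.array([getattr(row, c) for c in exposure_cols])
        mixture = mixture / mixture.sum()
        suppressed: set[str] = set()
        for d in spec.drivers:
            if d.gene in suppressed:
                continue
            p = d.p_high if group == HIGH else d.p_low
            if rng.random() >= p:
                continue
            for grp in spec.exclusivity_groups:
                if d.gene in grp:
                    suppressed.update(g for g in grp if g != d.gene)
            if d.gene == "PIK3CA":
                hotspot = spec.pik3ca_hotspots[
                    rng.integers(len(spec.pik3ca_hotspots))
                ]
                ch = tcw_ct_channels[rng.integers(len(tcw_ct_channels))]
                protein = hotspot
            else:
                ch = int(rng.choice(len(CHANNELS), p=mixture))
                aa = "ACDEFGHIKLMNPQRSTVWY"
                protein = (
                    f"{aa[rng.integers(20)]}{rng.integers(30, 900)}"
                    f"{aa[rng.integers(20)]}"
                )
            pos, ref_b, alt_b = _place_mutation(CHANNELS[ch], index, rng)
            variants.append(
                VariantRecord(
                    sample_id=sid,
                    chrom=spec.ref_name,
                    pos=pos,
                    ref_allele=ref_b,
                    alt_allele=alt_b,
                    gene=d.gene,
                    variant_class="missense",
                    protein_change=protein,
                )
            )
    return variants


def simulate_expression(
    spec: CohortSpec,
    truth: pd.DataFrame,
    rng: np.random.Generator,
    immune_sets: GeneSetCollection | None = None,
    marker_sets: GeneSetCollection | None = None,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Log-normal expression with burden-coupled APOBEC3A/3B, immune
    elevation in the high group, and subtype marker shifts.

    Returns the matrix and the latent subtype per sample.
    """
    immune_sets = immune_sets or default_immune_sets()
    marker_sets = marker_sets or default_subtype_markers()
    samples = list(truth["sample_id"])
    n = len(samples)
    groups = list(truth["group"])
    subtype = pd.Series(
        [SUBTYPES[rng.integers(len(SUBTYPES))] for _ in samples],
        index=samples,
        name="subtype",
    )

    immune_genes = sorted({g for gs in immune_sets.values() for g in gs})
    marker_genes = sorted({g for gs in marker_sets.values() for g in gs})
    background = [f"BG{i:03d}" for i in range(spec.n_background_genes)]
    genes = (
        ["APOBEC3A", "APOBEC3B"]
        + immune_genes
        + marker_genes
        + background
    )
    genes = list(dict.fromkeys(genes))

    log_burden = np.log(truth["burden"].to_numpy(dtype=float))
    z_burden = (log_burden - log_burden.mean()) / max(log_burden.std(), 1e-9)

    baseline = rng.normal(
        spec.baseline_log2_mean, spec.baseline_log2_sd, size=len(genes)
    )
    log2 = (
        baseline[:, None]
        + rng.normal(0.0, spec.noise_log2_sd, size=(len(genes), n))
    )
    gene_idx = {g: i for i, g in enumerate(genes)}
    for g in ("APOBEC3A", "APOBEC3B"):
        log2[gene_idx[g]] += spec.apobec3_coupling * z_burden
    high_mask = np.array([g == HIGH for g in groups])
    for g in immune_genes:
        log2[gene_idx[g], high_mask] += spec.immune_shift_log2
    for name, markers in marker_sets.items():
        mask = np.array([subtype[s] == name for s in samples])
        for g in markers:
            log2[gene_idx[g], mask] += spec.subtype_marker_shift_log2

    values = pd.DataFrame(
        np.power(2.0, log2), index=genes, columns=samples
    )
    return ExpressionMatrix(values), subtype


def simulate_survival(
    spec: CohortSpec, truth: pd.DataFrame, rng: np.random.Generator
) -> list[SurvivalRecord]:
    """Exponential event times per group with uniform admin censoring."""
    records = []
    for row in truth.itertuples():
        median = (
            spec.median_survival_high
            if row.group == HIGH
            else spec.median_survival_low
        )
        t_event = rng.exponential(median / math.log(2))
        t_censor = rng.uniform(0.0, spec.censor_horizon)
        time = max(min(t_event, t_censor), 1e-3)
        records.append(
            SurvivalRecord(row.sample_id, time, event=t_event <= t_censor)
        )
    return records


def simulate_cohort(
    spec: CohortSpec, out_dir: str | os.PathLike | None = None
) -> CohortBundle:
    """Generate a full cohort bundle; optionally write it to ``out_dir``."""
    rng = np.random.default_rng(spec.seed)
    signatures = synthetic_cosmic_signatures()
    ref = make_reference(
        spec.ref_length, seed=spec.seed, gc_content=spec.gc_content,
        name=spec.ref_name,
    )
    variants, truth = simulate_mutations(spec, ref, rng, signatures)
    variants += simulate_drivers(spec, truth, ref, rng, signatures)
    immune_sets = default_immune_sets()
    marker_sets = default_subtype_markers()
    expression, subtype = simulate_expression(
        spec, truth, rng, immune_sets, marker_sets
    )
    truth = truth.merge(
        subtype.rename_axis("sample_id").reset_index(), on="sample_id"
    )
    clinical = simulate_survival(spec, truth, rng)
    bundle = CohortBundle(
        spec=spec,
        reference=ref,
        variants=variants,
        expression=expression,
        clinical=clinical,
        truth=truth,
        immune_sets=immune_sets,
        marker_sets=marker_sets,
        signatures=signatures,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
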