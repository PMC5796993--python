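"""96-channel mutation catalogs and signature exposure fitting.

A sample's SNVs are summarised as counts over the 96 pyrimidine-centered
trinucleotide substitution channels; the per-sample catalog row is then
decomposed as a non-negative mixture of known reference signatures by
non-negative least squares (NNLS), reporting fractional exposures and the
cosine similarity between the observed and reconstructed spectra.  No de
novo signature discovery is attempted: attribution is to a fixed,
caller-chosen signature set.

Reference signatures
--------------------
The distributed reference vectors are a *synthetic* emulation of the five
COSMIC v2 signatures this analysis uses, built parametrically from each
signature's defining motif preference (see
:func:`synthetic_cosmic_signatures`).  They are suitable for simulation
closed loops and method validation; analyses of real tumor data should
substitute the published COSMIC probability vectors via ``read_signatures``.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .variant_io import (
    BASES,
    CHANNELS,
    ReferenceSequence,
    VariantRecord,
    extract_context,
)

DEFAULT_SIGNATURES = ("COSMIC1", "COSMIC2", "COSMIC5", "COSMIC13")
EXTENDED_SIGNATURES = ("COSMIC1", "COSMIC2", "COSMIC5", "COSMIC13", "COSMIC22")


@dataclasses.dataclass
class MutationCatalog:
    """Samples × 96 channel count matrix."""

    counts: pd.DataFrame  # index = sample_id, columns = CHANNELS

    def __post_init__(self) -> None:
        if tuple(self.counts.columns) != CHANNELS:
            raise ValueError("catalog columns must be the 96 channels in order")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    def row(self, sample_id: str) -> np.ndarray:
        return self.counts.loc[sample_id].to_numpy(dtype=float)


@dataclasses.dataclass
class SignatureMatrix:
    """Channel × signature probability matrix; columns sum to 1."""

    prob: pd.DataFrame  # index = CHANNELS, columns = signature names

    def __post_init__(self) -> None:
        if tuple(self.prob.index) != CHANNELS:
            raise ValueError(
                "signature matrix rows must be the 96 channels in order"
            )
        arr = self.prob.to_numpy()
        if (arr < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        if not np.allclose(arr.sum(axis=0), 1.0, atol=1e-8):
            raise ValueError("signature columns must sum to 1")

    @property
    def names(self) -> list[str]:
        return list(self.prob.columns)

    def subset(self, names: Sequence[str]) -> "SignatureMatrix":
        missing = [n for n in names if n not in self.prob.columns]
        if missing:
            raise KeyError(f"unknown signatures {missing}")
        return SignatureMatrix(self.prob[list(names)])


@dataclasses.dataclass
class ExposureMatrix:
    """Per-sample fractional signature contributions plus fit quality."""

    frac: pd.DataFrame  # index = sample_id, columns = signature names
    cosine: pd.Series  # reconstruction cosine similarity per sample
    scorable: pd.Series  # False for zero-mutation samples


def _spread(weights: Mapping[str, float]) -> np.ndarray:
    v = np.zeros(len(CHANNELS))
    for label, w in weights.items():
        v[CHANNELS.index(label)] = w
    return v


def synthetic_cosmic_signatures() -> SignatureMatrix:
    """Synthetic stand-in for COSMIC v2 signatures 1, 2, 5, 13 and 22.

    Each column is built from the signature's defining trinucleotide
    preference rather than copied from the published catalog:

    * ``COSMIC1``  — spontaneous 5-methylcytosine deamination: C>T at
      NpCpG dinucleotides.
    * ``COSMIC2``  — APOBEC cytidine deamination: predominantly C>T at
      TpCpW (W ∈ {A, T}), with a minor C>G component at the same motif.
    * ``COSMIC5``  — flat "clock-like" background spread over all
      channels with mild C>T and T>C weight.
    * ``COSMIC13`` — APOBEC lesion bypass: predominantly C>G at TpCpW
      with a minor C>T component (sharing the TCW motif with COSMIC2 but
      differing in substitution class, so the pair is correlated yet
      separable).
    * ``COSMIC22`` — aristolochic acid exposure: T>A at CpTpG.

    A small uniform floor keeps every channel strictly positive; columns
    are normalised to sum to 1.  These vectors are for synthetic-cohort
    validation; real-data runs should load the published catalog instead.
    """
    floor = 0.002 * np.ones(len(CHANNELS))

    sig1 = _spread(
        {f"{up}[C>T]G": {"A": 1.0, "C": 1.2, "G": 0.8, "T": 1.0}[up] for up in BASES}
    )

    apobec_ct = {f"T[C>T]A": 0.55, "T[C>T]T": 0.45}
    apobec_cg = {f"T[C>G]A": 0.55, "T[C>G]T": 0.45}
    sig2 = 0.72 * _spread(apobec_ct) + 0.23 * _spread(apobec_cg)
    sig13 = 0.72 * _spread(apobec_cg) + 0.23 * _spread(apobec_ct)

    sig5 = np.ones(len(CHANNELS))
    for i, label in enumerate(CHANNELS):
        if "[C>T]" in label or "[T>C]" in label:
            sig5[i] *= 2.5

    sig22 = _spread({"C[T>A]G": 0.8, "C[T>A]A": 0.1, "C[T>A]T": 0.1})

    cols = {
        "COSMIC1": sig1,
        "COSMIC2": sig2,
        "COSMIC5": sig5,
        "COSMIC13": sig13,
        "COSMIC22": sig22,
    }
    prob = pd.DataFrame(
        {
            name: (v / v.sum() + floor) / (1 + floor.sum())
            for name, v in cols.items()
        },
        index=list(CHANNELS),
    )
    prob = prob / prob.sum(axis=0)
    return SignatureMatrix(prob)


def read_signatures(path: str) -> SignatureMatrix:
    """Read a channel × signature TSV (96 labelled rows, one column per
    signature)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.reindex(list(CHANNELS))
    if df.isna().any().any():
        raise ValueError(f"{path}: missing or mislabelled channel rows")
    return SignatureMatrix(df)


def write_signatures(sigs: SignatureMatrix, path: str) -> str:
    sigs.prob.to_csv(path, sep="\t", index_label="channel")
    return path


def build_catalog(
    variants: Iterable[VariantRecord],
    ref: ReferenceSequence,
    samples: Sequence[str] | None = None,
) -> MutationCatalog:
    """Count every SNV's pyrimidine-centered channel, per sample.

    Non-SNVs are ignored; context errors propagate.  ``samples`` may be
    given to fix row order and include mutation-free samples.
    """
    counts: dict[str, np.ndarray] = defaultdict(
        lambda: np.zeros(len(CHANNELS), dtype=np.int64)
    )
    if samples is not None:
        for s in samples:
            counts[s]
    for v in variants:
        if not v.is_snv:
            continue
        ctx = extract_context(v, ref)
        counts[v.sample_id][ctx.channel] += 1
    order = list(samples) if samples is not None else sorted(counts)
    df = pd.DataFrame(
        {s: counts[s] for s in order}, index=list(CHANNELS)
    ).T
    df.columns = list(CHANNELS)
    return MutationCatalog(df)


def cosine_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """Cosine of the angle between two non-negative spectra, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero vector")
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def fit_exposures(
    catalog: MutationCatalog, sigs: SignatureMatrix
) -> ExposureMatrix:
    """Per-sample NNLS decomposition onto the signature set.

    Each catalog row is L1-normalised and solved as
    ``min ||spectrum − P e||₂  s.t.  e ≥ 0`` with P the channel ×
    signature matrix; exposures are reported as fractions e / Σe together
    with the cosine similarity between the observed and reconstructed
    spectra.  Zero-mutation samples get all-zero exposures and are flagged
    unscorable.
    """
    P = sigs.prob.to_numpy()
    fracs, cosines, scorable = [], [], []
    for sample in catalog.samples:
        row = catalog.row(sample)
        total = row.sum()
        if total == 0:
            fracs.append(np.zeros(P.shape[1]))
            cosines.append(np.nan)
            scorable.append(False)
            continue
        spectrum = row / total
        e, _ = nnls(P, spectrum)
        s = e.sum()
        frac = e / s if s > 0 else np.zeros_like(e)
        recon = P @ e
        cos = cosine_similarity(spectrum, recon) if recon.sum() > 0 else 0.0
        fracs.append(frac)
        cosines.append(cos)
        scorable.append(True)
    frac_df = pd.DataFrame(
        np.vstack(fracs), index=catalog.samples, columns=sigs.names
    )
    return ExposureMatrix(
        frac=frac_df,
        cosine=pd.Series(cosines, index=catalog.samples, name="cosine"),
        scorable=pd.Series(scorable, index=catalog.samples, name="scorable"),
    )


def exposures_table(exp: ExposureMatrix) -> pd.DataFrame:
    out = exp.frac.copy()
    out["cosine"] = exp.cosine
    out["scorable"] = exp.scorable
    out.index.name = "sample_id"
    return out.reset_index()
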