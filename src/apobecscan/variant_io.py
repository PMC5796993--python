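"""MAF and FASTA input/output and trinucleotide-context extraction.

Somatic single-nucleotide variants (SNVs) are analysed in their
pyrimidine-centered trinucleotide context: a substitution whose reference
base is a purine is reported on the opposite strand, so the center of every
context is C or T.  The 96 mutation channels are the 6 substitution classes
(C>A, C>G, C>T, T>A, T>C, T>G) crossed with the 16 upstream/downstream
flank combinations, in the fixed lexicographic order used by mutational
signature catalogs.

All genomic coordinates in this module are 1-based inclusive (MAF
convention); any 0-based arithmetic is internal.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Iterable, Sequence

try:  # pragma: no cover - import guard only
    from pyfaidx import Fasta as _PyfaidxFasta
except ImportError:  # pragma: no cover
    _PyfaidxFasta = None

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 channel labels, e.g. "A[C>A]A", ordered by substitution class,
#: then upstream flank, then downstream flank.
CHANNELS: tuple[str, ...] = tuple(
    f"{up}[{sub}]{down}"
    for sub in SUBSTITUTION_CLASSES
    for up in BASES
    for down in BASES
)
CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS)}

#: Variant_Classification values treated as non-silent when building gene
#: mutation matrices.
NON_SILENT_CLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "splice",
        "frameshift_indel",
        "inframe_indel",
    }
)

_VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "silent",
    "splice",
    "frameshift_indel",
    "inframe_indel",
    "other",
)

# TCGA MAF Variant_Classification -> internal consequence class
_TCGA_CLASS_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Silent": "silent",
    "Splice_Site": "splice",
    "Frame_Shift_Del": "frameshift_indel",
    "Frame_Shift_Ins": "frameshift_indel",
    "In_Frame_Del": "inframe_indel",
    "In_Frame_Ins": "inframe_indel",
}
_TCGA_CLASS_INVERSE = {
    "missense": "Missense_Mutation",
    "nonsense": "Nonsense_Mutation",
    "silent": "Silent",
    "splice": "Splice_Site",
    "frameshift_indel": "Frame_Shift_Del",
    "inframe_indel": "In_Frame_Del",
    "other": "Other",
}


class MafFormatError(ValueError):
    """A MAF file violates the expected column or row structure."""


class ReferenceMismatchError(ValueError):
    """The reference base at a variant locus does not match the record."""


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """One somatic mutation call.

    ``ref_allele``/``alt_allele`` are single bases for SNVs; indels carry
    the raw allele strings and are flagged by :meth:`is_snv`.
    """

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene: str = ""
    variant_class: str = "other"
    protein_change: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.variant_class not in _VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.variant_class!r}")
        if self.is_snv and self.ref_allele == self.alt_allele:
            raise ValueError(
                f"SNV with ref == alt ({self.ref_allele}) at "
                f"{self.chrom}:{self.pos}"
            )

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in BASES
            and self.alt_allele in BASES
        )

    @property
    def is_non_silent(self) -> bool:
        return self.variant_class in NON_SILENT_CLASSES


@dataclasses.dataclass(frozen=True)
class TrinucContext:
    """Pyrimidine-oriented trinucleotide context of an SNV."""

    upstream: str
    center_ref: str
    downstream: str
    center_alt: str

    def __post_init__(self) -> None:
        if self.center_ref not in "CT":
            raise ValueError(
                "context must be pyrimidine-oriented; center "
                f"{self.center_ref!r}"
            )

    @property
    def substitution(self) -> str:
        return f"{self.center_ref}>{self.center_alt}"

    @property
    def label(self) -> str:
        return f"{self.upstream}[{self.substitution}]{self.downstream}"

    @property
    def channel(self) -> int:
        return CHANNEL_INDEX[self.label]

    @property
    def is_tcw(self) -> bool:
        """True for the APOBEC target motif T-C-W with W in {A, T}."""
        return (
            self.center_ref == "C"
            and self.upstream == "T"
            and self.downstream in "AT"
        )


class ReferenceSequence:
    """Random-access reference, backed by in-memory strings or a FASTA.

    ``fetch(chrom, start, end)`` uses 1-based inclusive coordinates and
    raises ``KeyError``/``IndexError`` for unknown contigs or out-of-bounds
    requests.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}
        for name, seq in self._seqs.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"contig {name!r} has non-ACGTN bases {bad}")

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "ReferenceSequence":
        if _PyfaidxFasta is None:  # pragma: no cover
            raise ImportError("pyfaidx is required to read FASTA files")
        fa = _PyfaidxFasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def contigs(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown contig {chrom!r}")
        seq = self._seqs[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise IndexError(
                f"lookup {chrom}:{start}-{end} outside 1..{len(seq)}"
            )
        return seq[start - 1 : end]

    def write_fasta(self, path: str | os.PathLike, width: int = 70) -> str:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
        return str(path)


# ---------------------------------------------------------------------------
# MAF reading and writing
# ---------------------------------------------------------------------------

_DIALECTS = {
    "tcga": {
        "sample": "Tumor_Sample_Barcode",
        "chrom": "Chromosome",
        "pos": "Start_position",
        "ref": "Reference_Allele",
        "alt": "Tumor_Seq_Allele2",
        "gene": "Hugo_Symbol",
        "class": "Variant_Classification",
        "protein": "Protein_Change",
    },
    "minimal": {
        "sample": "sample",
        "chrom": "chrom",
        "pos": "pos",
        "ref": "ref",
        "alt": "alt",
        "gene": "gene",
        "class": "class",
        "protein": "protein_change",
    },
}
# Columns that may legitimately be absent; they default to "".
_OPTIONAL_FIELDS = {"protein"}

# Accepted spellings per logical column, per dialect (GDAC files vary in
# the case of Start_position).
_ALIASES = {
    "tcga": {
        "pos": ("Start_position", "Start_Position"),
        "protein": ("Protein_Change", "HGVSp_Short", "amino_acid_change"),
    },
}


def normalize_tcga_barcode(barcode: str, level: int = 3) -> str:
    """Truncate a TCGA barcode to its first ``level`` dash-separated parts.

    Level 3 (``TCGA-XX-YYYY``) identifies the participant, which is the
    unit every cohort table here is keyed on.  Non-TCGA identifiers are
    returned unchanged.
    """
    if barcode.upper().startswith("TCGA-"):
        return "-".join(barcode.split("-")[:level])
    return barcode


def _tcga_class_to_internal(value: str) -> str:
    return _TCGA_CLASS_MAP.get(value, "other")


def read_maf(path: str | os.PathLike, dialect: str = "tcga") -> list[VariantRecord]:
    """Read a tab-separated MAF into :class:`VariantRecord` objects.

    Indel rows are retained (``is_snv`` False).  TCGA sample barcodes are
    truncated to the participant level.  A missing required column or an
    unparseable position is a hard :class:`MafFormatError` naming the
    column or line; rows are never silently dropped.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    colmap = _DIALECTS[dialect]
    aliases = _ALIASES.get(dialect, {})
    records: list[VariantRecord] = []
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise MafFormatError(f"{path}: empty file, no header row")
        header = header_line.rstrip("\n").split("\t")
        col_idx: dict[str, int] = {}
        for field, name in colmap.items():
            candidates = aliases.get(field, (name,))
            idx = next(
                (header.index(c) for c in candidates if c in header), None
            )
            if idx is None:
                if field in _OPTIONAL_FIELDS:
                    continue
                raise MafFormatError(
                    f"{path}: required column {name!r} not found in header"
                )
            col_idx[field] = idx
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")

            def get(field: str, default: str = "") -> str:
                idx = col_idx.get(field)
                if idx is None or idx >= len(parts):
                    return default
                return parts[idx]

            try:
                pos = int(get("pos"))
            except ValueError as exc:
                raise MafFormatError(
                    f"{path}:{lineno}: unparseable position {get('pos')!r}"
                ) from exc
            sample = get("sample")
            if dialect == "tcga":
                sample = normalize_tcga_barcode(sample)
                vclass = _tcga_class_to_internal(get("class"))
            else:
                vclass = get("class") or "other"
                if vclass not in _VARIANT_CLASSES:
                    vclass = "other"
            ref, alt = get("ref").upper(), get("alt").upper()
            if (
                len(ref) == 1
                and len(alt) == 1
                and ref in BASES
                and alt in BASES
                and ref == alt
            ):
                raise MafFormatError(
                    f"{path}:{lineno}: SNV row with ref == alt ({ref})"
                )
            records.append(
                VariantRecord(
                    sample_id=sample,
                    chrom=get("chrom"),
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    gene=get("gene"),
                    variant_class=vclass,
                    protein_change=get("protein"),
                )
            )
    return records


def write_maf(
    records: Iterable[VariantRecord],
    path: str | os.PathLike,
    dialect: str = "tcga",
) -> str:
    """Write records as a MAF; inverse of :func:`read_maf` on valid input."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    colmap = _DIALECTS[dialect]
    fields = ["gene", "chrom", "pos", "ref", "alt", "class", "sample", "protein"]
    with open(path, "w") as fh:
        fh.write("\t".join(colmap[f] for f in fields) + "\n")
        for rec in records:
            if dialect == "tcga":
                vclass = _TCGA_CLASS_INVERSE[rec.variant_class]
            else:
                vclass = rec.variant_class
            row = {
                "gene": rec.gene,
                "chrom": rec.chrom,
                "pos": str(rec.pos),
                "ref": rec.ref_allele,
                "alt": rec.alt_allele,
                "class": vclass,
                "sample": rec.sample_id,
                "protein": rec.protein_change,
            }
            fh.write("\t".join(row[f] for f in fields) + "\n")
    return str(path)


# ---------------------------------------------------------------------------
# Context extraction and background motif counting
# ---------------------------------------------------------------------------

def extract_context(v: VariantRecord, ref: ReferenceSequence) -> TrinucContext:
    """Pyrimidine-oriented trinucleotide context of an SNV.

    The reference base at ``v.pos`` must equal ``v.ref_allele``; a mismatch
    is a hard :class:`ReferenceMismatchError` (a silent mismatch would
    corrupt every downstream motif statistic).  Purine-reference variants
    are reverse-complemented, flanks included.
    """
    if not v.is_snv:
        raise ValueError(f"context requested for non-SNV at {v.chrom}:{v.pos}")
    if v.pos < 2 or v.pos > ref.length(v.chrom) - 1:
        raise IndexError(
            f"{v.chrom}:{v.pos}: context needs one flanking base on each side"
        )
    tri = ref.fetch(v.chrom, v.pos - 1, v.pos + 1)
    if tri[1] != v.ref_allele:
        raise ReferenceMismatchError(
            f"{v.chrom}:{v.pos}: expected reference base {v.ref_allele}, "
            f"found {tri[1]}"
        )
    if "N" in tri:
        raise ReferenceMismatchError(
            f"{v.chrom}:{v.pos}: N base in trinucleotide context {tri}"
        )
    alt = v.alt_allele
    if tri[1] in "AG":  # purine center: report on the opposite strand
        tri = reverse_complement(tri)
        alt = COMPLEMENT[alt]
    return TrinucContext(
        upstream=tri[0], center_ref=tri[1], downstream=tri[2], center_alt=alt
    )


def count_backgrounds(
    v: VariantRecord, ref: ReferenceSequence, window: int = 20
) -> tuple[int, int]:
    """Count (TCW motifs, cytosines) within ±``window`` nt of a variant.

    Both strands are counted: a TCW motif is a TCW trinucleotide read on
    the given strand or its reverse complement WGA; a cytosine is a C or a
    G.  The window is truncated at the sequence ends, and N bases are
    skipped.  Returns ``(tcw_contexts, c_contexts)``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    start = max(1, v.pos - window)
    end = min(ref.length(v.chrom), v.pos + window)
    seq = ref.fetch(v.chrom, start, end)
    c_contexts = sum(1 for b in seq if b in "CG")
    tcw = 0
    for i in range(len(seq) - 2):
        tri = seq[i : i + 3]
        if "N" in tri:
            continue
        if tri[1] == "C" and tri[0] == "T" and tri[2] in "AT":
            tcw += 1
        if tri[1] == "G" and tri[2] == "A" and tri[0] in "AT":
            tcw += 1
    return tcw, c_contexts


def snv_class(v: VariantRecord) -> str:
    """Pyrimidine-oriented substitution class (one of the 6) of an SNV."""
    ref_b, alt_b = v.ref_allele, v.alt_allele
    if ref_b in "AG":
        ref_b, alt_b = COMPLEMENT[ref_b], COMPLEMENT[alt_b]
    return f"{ref_b}>{alt_b}"
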