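"""MAF round-trips, trinucleotide contexts, and background motif counts."""

import pytest
from hypothesis import given, settings, strategies as st

from apobecscan import (
    ReferenceSequence,
    VariantRecord,
    count_backgrounds,
    extract_context,
    read_maf,
    write_maf,
)
from apobecscan.variant_io import (
    CHANNELS,
    MafFormatError,
    ReferenceMismatchError,
    normalize_tcga_barcode,
    reverse_complement,
    snv_class,
)

from conftest import toy_reference


def _write_lines(tmp_path, name, lines):
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return str(path)


class TestReadMaf:
    def test_minimal_three_rows_two_snvs(self, tmp_path):
        path = _write_lines(
            tmp_path,
            "m.maf",
            [
                "sample\tchrom\tpos\tref\talt\tgene\tclass",
                "s1\tchr1\t10\tC\tT\tTP53\tmissense",
                "s1\tchr1\t20\tG\tA\tKRAS\tmissense",
                "s2\tchr1\t30\tAC\tA\tFGFR3\tframeshift_indel",
            ],
        )
        records = read_maf(path, dialect="minimal")
        assert len(records) == 3
        assert sum(r.is_snv for r in records) == 2

    def test_ref_equals_alt_rejected(self, tmp_path):
        path = _write_lines(
            tmp_path,
            "bad.maf",
            [
                "sample\tchrom\tpos\tref\talt\tgene\tclass",
                "s1\tchr1\t10\tC\tC\tTP53\tmissense",
            ],
        )
        with pytest.raises(MafFormatError, match="ref == alt"):
            read_maf(path, dialect="minimal")

    def test_missing_column_names_the_column(self, tmp_path):
        path = _write_lines(
            tmp_path,
            "cols.maf",
            ["sample\tchrom\tpos\tref\talt\tgene", "s1\tchr1\t1\tC\tT\tX"],
        )
        with pytest.raises(MafFormatError, match="class"):
            read_maf(path, dialect="minimal")

    def test_unparseable_position_reports_line(self, tmp_path):
        path = _write_lines(
            tmp_path,
            "pos.maf",
            [
                "sample\tchrom\tpos\tref\talt\tgene\tclass",
                "s1\tchr1\txyz\tC\tT\tTP53\tmissense",
            ],
        )
        with pytest.raises(MafFormatError, match=":2"):
            read_maf(path, dialect="minimal")

    def test_tcga_dialect_parses_like_minimal(self, tmp_path):
        """The same variants written in either dialect read back equal."""
        records = [
            VariantRecord("s1", "chr1", 10, "C", "T", "TP53", "missense", "R175H"),
            VariantRecord("s2", "chr2", 99, "G", "A", "KRAS", "silent", ""),
        ]
        p1 = str(tmp_path / "a.maf")
        p2 = str(tmp_path / "b.maf")
        write_maf(records, p1, dialect="tcga")
        write_maf(records, p2, dialect="minimal")
        assert read_maf(p1, dialect="tcga") == read_maf(p2, dialect="minimal")

    def test_tcga_barcode_truncation(self, tmp_path):
        path = _write_lines(
            tmp_path,
            "tcga.maf",
            [
                "Hugo_Symbol\tChromosome\tStart_position\tReference_Allele\t"
                "Tumor_Seq_Allele2\tVariant_Classification\tTumor_Sample_Barcode",
                "TP53\t17\t7577120\tC\tT\tMissense_Mutation\tTCGA-DK-A6AW-01A-11D",
            ],
        )
        (rec,) = read_maf(path, dialect="tcga")
        assert rec.sample_id == "TCGA-DK-A6AW"
        assert normalize_tcga_barcode("not-a-barcode") == "not-a-barcode"


_allele_pairs = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]
record_strategy = st.builds(
    lambda sample_id, chrom, pos, alleles, gene, variant_class, protein_change: (
        VariantRecord(
            sample_id, chrom, pos, alleles[0], alleles[1], gene,
            variant_class, protein_change,
        )
    ),
    sample_id=st.text(alphabet="ABCdef123", min_size=1, max_size=8),
    chrom=st.sampled_from(["chr1", "chr2", "X"]),
    pos=st.integers(min_value=2, max_value=10_000),
    alleles=st.sampled_from(_allele_pairs),
    gene=st.sampled_from(["TP53", "KRAS", ""]),
    variant_class=st.sampled_from(
        ["missense", "nonsense", "silent", "splice", "other"]
    ),
    protein_change=st.sampled_from(["", "E542K", "R175H"]),
)


@settings(max_examples=50, deadline=None)
@given(records=st.lists(record_strategy, max_size=30),
       dialect=st.sampled_from(["tcga", "minimal"]))
def test_maf_round_trip(tmp_path_factory, records, dialect):
    """read_maf(write_maf(x)) is the identity on valid records."""
    path = str(tmp_path_factory.mktemp("rt") / "rt.maf")
    write_maf(records, path, dialect=dialect)
    assert read_maf(path, dialect=dialect) == records


def test_empty_round_trip(tmp_path):
    path = str(tmp_path / "empty.maf")
    write_maf([], path, dialect="minimal")
    assert read_maf(path, dialect="minimal") == []
    assert open(path).read().count("\n") == 1  # header only


class TestExtractContext:
    def test_forward_tcw(self):
        ref = toy_reference("ATCAG")
        ctx = extract_context(VariantRecord("s", "chr1", 3, "C", "T"), ref)
        assert ctx.label == "T[C>T]A"
        assert ctx.is_tcw

    def test_purine_center_reverse_complemented(self):
        ref = toy_reference("TTGAA")
        ctx = extract_context(VariantRecord("s", "chr1", 3, "G", "A"), ref)
        assert ctx.label == "T[C>T]A"
        assert ctx.is_tcw

    def test_non_tcw_context(self):
        ref = toy_reference("ACCGT")
        ctx = extract_context(VariantRecord("s", "chr1", 3, "C", "G"), ref)
        assert ctx.label == "C[C>G]G"
        assert not ctx.is_tcw

    def test_reference_mismatch_is_hard_error(self):
        ref = toy_reference("ATCAG")
        with pytest.raises(ReferenceMismatchError, match="expected"):
            extract_context(VariantRecord("s", "chr1", 3, "G", "A"), ref)

    def test_n_in_context_is_error(self):
        ref = toy_reference("ANCAG")
        with pytest.raises(ReferenceMismatchError):
            extract_context(VariantRecord("s", "chr1", 3, "C", "T"), ref)

    def test_strand_involution_same_channel(self, small_ref, rng):
        """A variant and its reverse-complement representation share one
        channel."""
        seq = small_ref.fetch("chr1", 1, small_ref.length("chr1"))
        rc = ReferenceSequence({"chr1": reverse_complement(seq)})
        n = len(seq)
        checked = 0
        for _ in range(200):
            pos = int(rng.integers(2, n))
            base = seq[pos - 1]
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[base]
            v_fwd = VariantRecord("s", "chr1", pos, base, alt)
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            v_rev = VariantRecord(
                "s", "chr1", n - pos + 1, comp[base], comp[alt]
            )
            assert (
                extract_context(v_fwd, small_ref).channel
                == extract_context(v_rev, rc).channel
            )
            checked += 1
        assert checked == 200


class TestCountBackgrounds:
    def test_printed_example(self):
        ref = toy_reference("TTCAA")
        tcw, c = count_backgrounds(
            VariantRecord("s", "chr1", 3, "C", "T"), ref, window=2
        )
        assert (tcw, c) == (1, 1)

    def test_no_cytosines(self):
        ref = toy_reference("A" * 50)
        tcw, c = count_backgrounds(
            VariantRecord("s", "chr1", 25, "A", "G"), ref, window=10
        )
        assert (tcw, c) == (0, 0)

    def test_locality(self, small_ref):
        """Counts ignore sequence outside the window."""
        seq = small_ref.fetch("chr1", 1, 400)
        doubled = toy_reference(seq + seq)
        single = toy_reference(seq)
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[199]]
        v = VariantRecord("s", "chr1", 200, seq[199], alt)
        assert count_backgrounds(v, single, window=20) == count_backgrounds(
            v, doubled, window=20
        )

    @pytest.mark.parametrize("window", [1, 5, 20])
    def test_brute_force_oracle(self, small_ref, rng, window):
        """Counts agree with a naive two-strand scan of the window."""
        seq = small_ref.fetch("chr1", 1, small_ref.length("chr1"))
        for _ in range(50):
            pos = int(rng.integers(1, len(seq) + 1))
            base = seq[pos - 1]
            alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
            v = VariantRecord("s", "chr1", pos, base, alt)
            lo = max(0, pos - 1 - window)
            hi = min(len(seq), pos + window)
            win = seq[lo:hi]
            exp_c = win.count("C") + win.count("G")
            exp_tcw = 0
            for i in range(len(win) - 2):
                tri = win[i : i + 3]
                if tri in ("TCA", "TCT") or reverse_complement(tri) in (
                    "TCA",
                    "TCT",
                ):
                    exp_tcw += 1
            assert count_backgrounds(v, small_ref, window=window) == (
                exp_tcw,
                exp_c,
            )


def test_snv_class_pyrimidine_orientation():
    assert snv_class(VariantRecord("s", "c", 5, "G", "A")) == "C>T"
    assert snv_class(VariantRecord("s", "c", 5, "A", "C")) == "T>G"
    assert len(CHANNELS) == 96 and len(set(CHANNELS)) == 96
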