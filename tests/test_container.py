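"""Archive round trips, header integrity, guards, and the CLI."""

import gzip

import pytest

from conftest import multisets_equal, read_fasta
from pathenc import (EncodeOptions, SimConfig, WrongReferenceError, cli,
                     decode_file, encode_file, make_reads,
                     make_transcriptome, two_bit_baseline)
from pathenc.bittree import CorruptArchiveError


def test_empty_input_roundtrip(tmp_path):
    src = tmp_path / "empty.fasta"
    src.write_text("")
    info = encode_file(src, out_path=tmp_path / "empty.pe")
    assert info.header["read_count"] == 0
    outs = decode_file(tmp_path / "empty.pe")
    assert read_fasta(outs[0]) == []


def test_roundtrip_exact_with_orientation(small_corpus):
    tmp = small_corpus["tmp"]
    opts = EncodeOptions(k=8, store_orientation=True)
    encode_file(small_corpus["fastq"], reference=small_corpus["ref"],
                out_path=tmp / "a.pe", options=opts)
    outs = decode_file(tmp / "a.pe", reference=small_corpus["ref"],
                       out_path=tmp / "dec.fasta")
    assert multisets_equal(read_fasta(outs[0]), small_corpus["reads"].reads)


def test_roundtrip_up_to_strand_without_orientation(small_corpus):
    tmp = small_corpus["tmp"]
    encode_file(small_corpus["fastq"], reference=small_corpus["ref"],
                out_path=tmp / "a.pe", options=EncodeOptions(k=8))
    outs = decode_file(tmp / "a.pe", reference=small_corpus["ref"])
    assert multisets_equal(read_fasta(outs[0]),
                           small_corpus["reads"].reads, up_to_rc=True)


def test_header_records_all_options(small_corpus):
    tmp = small_corpus["tmp"]
    opts = EncodeOptions(k=8, weight=7, dynamic=False, rc=False,
                         dedup=False, store_orientation=True)
    info = encode_file(small_corpus["fastq"], out_path=tmp / "a.pe",
                       options=opts)
    h = info.header
    assert h["k"] == 8 and h["weight"] == 7
    assert h["flags"] == {"reference": False, "dynamic": False, "rc": False,
                          "dedup": False, "orientation": True,
                          "paired": False, "pair_same_strand": False}
    assert h["uniform_length"] == 60
    # decode needs nothing beyond the archive for a no-reference encode
    outs = decode_file(tmp / "a.pe")
    assert multisets_equal(read_fasta(outs[0]), small_corpus["reads"].reads)


def test_mixed_lengths_enable_length_stream(tmp_path):
    src = tmp_path / "mixed.fasta"
    src.write_text(">a\nACGTACGTAAAT\n>b\nACGTACGTAATTCCGG\n>c\nTTTTCCCCGGG\n")
    info = encode_file(src, out_path=tmp_path / "m.pe",
                       options=EncodeOptions(k=4))
    assert "lengths.gz" in info.stream_sizes
    assert info.header["uniform_length"] is None
    outs = decode_file(tmp_path / "m.pe")
    assert multisets_equal(read_fasta(outs[0]),
                           ["ACGTACGTAAAT", "ACGTACGTAATTCCGG",
                            "TTTTCCCCGGG"])


def test_read_shorter_than_k_is_fatal_with_read_named(tmp_path):
    src = tmp_path / "short.fasta"
    src.write_text(">a\nACGTACGTACGT\n>b\nACG\n")
    with pytest.raises(ValueError, match="read 1"):
        encode_file(src, out_path=tmp_path / "s.pe",
                    options=EncodeOptions(k=8))


def test_wrong_reference_rejected_before_output(small_corpus):
    tmp = small_corpus["tmp"]
    encode_file(small_corpus["fastq"], reference=small_corpus["ref"],
                out_path=tmp / "a.pe", options=EncodeOptions(k=8))
    other_cfg = SimConfig(seed=99, n_transcripts=3,
                          transcript_len_range=(300, 400))
    make_transcriptome(other_cfg, tmp / "other.fa")
    with pytest.raises(WrongReferenceError):
        decode_file(tmp / "a.pe", reference=tmp / "other.fa",
                    out_path=tmp / "x.fasta")
    with pytest.raises(WrongReferenceError):
        decode_file(tmp / "a.pe")  # reference omitted entirely
    assert not (tmp / "x.fasta").exists()


def test_truncated_archive_detected(small_corpus):
    tmp = small_corpus["tmp"]
    encode_file(small_corpus["fastq"], out_path=tmp / "a.pe",
                options=EncodeOptions(k=8))
    blob = (tmp / "a.pe").read_bytes()
    (tmp / "bad.pe").write_bytes(blob[: len(blob) // 2])
    with pytest.raises(CorruptArchiveError):
        decode_file(tmp / "bad.pe")


def test_paired_roundtrip_restores_mates(tmp_path):
    cfg = SimConfig(seed=21, n_transcripts=4, transcript_len_range=(500, 900),
                    n_reads=150, read_len=40, paired=True,
                    fragment_len_range=(100, 160), antisense_fraction=0.5,
                    n_rate=0.002)
    tr = make_transcriptome(cfg, tmp_path / "ref.fa")
    rs = make_reads(tr, cfg)
    rs.write_fastq(tmp_path / "r1.fq", tmp_path / "r2.fq")
    opts = EncodeOptions(k=8, paired=True, store_orientation=True)
    encode_file(tmp_path / "r1.fq", reference=tmp_path / "ref.fa",
                out_path=tmp_path / "p.pe", options=opts,
                mate2_in=tmp_path / "r2.fq")
    o1, o2 = decode_file(tmp_path / "p.pe", reference=tmp_path / "ref.fa",
                         out_path=tmp_path / "out")
    pairs = sorted(zip(read_fasta(o1), read_fasta(o2)))
    assert pairs == sorted(zip(rs.reads, rs.mates2))


def test_gzipped_inputs_accepted(tmp_path):
    cfg = SimConfig(seed=5, n_transcripts=3, transcript_len_range=(300, 500),
                    n_reads=50, read_len=40)
    make_transcriptome(cfg, tmp_path / "ref.fa.gz")
    rs = make_reads(tmp_path / "ref.fa.gz", cfg)
    fq = tmp_path / "reads.fq.gz"
    with gzip.open(fq, "wt") as fh:
        for i, s in enumerate(rs.reads):
            fh.write(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n")
    encode_file(fq, reference=tmp_path / "ref.fa.gz",
                out_path=tmp_path / "g.pe", options=EncodeOptions(k=8))
    outs = decode_file(tmp_path / "g.pe", reference=tmp_path / "ref.fa.gz")
    assert multisets_equal(read_fasta(outs[0]), rs.reads)


class TestCli:
    def _corpus(self, tmp_path, **cfg_kwargs):
        cfg = SimConfig(seed=3, n_transcripts=3,
                        transcript_len_range=(300, 500), n_reads=80,
                        read_len=40, **cfg_kwargs)
        tr = make_transcriptome(cfg, tmp_path / "ref.fa")
        rs = make_reads(tr, cfg)
        rs.write_fastq(tmp_path / "reads.fq")
        return rs

    def test_no_ref_roundtrip(self, tmp_path):
        rs = self._corpus(tmp_path)
        assert cli(["encode", str(tmp_path / "reads.fq"), "--no-ref",
                    "-k", "8", "-o", str(tmp_path / "a.pe")]) == 0
        assert cli(["decode", str(tmp_path / "a.pe"),
                    "-o", str(tmp_path / "out.fasta")]) == 0
        assert multisets_equal(read_fasta(tmp_path / "out.fasta"), rs.reads)

    def test_decode_takes_k_from_header(self, tmp_path):
        rs = self._corpus(tmp_path)
        assert cli(["encode", str(tmp_path / "reads.fq"), "-k", "4",
                    "-o", str(tmp_path / "a.pe")]) == 0
        # decode passes a contradictory -k; the header wins
        assert cli(["decode", str(tmp_path / "a.pe"), "-k", "16",
                    "-o", str(tmp_path / "out.fasta")]) == 0
        assert multisets_equal(read_fasta(tmp_path / "out.fasta"), rs.reads)

    def test_report_lists_component_names(self, tmp_path, capsys):
        self._corpus(tmp_path, n_rate=0.01, antisense_fraction=0.4)
        assert cli(["encode", str(tmp_path / "reads.fq"),
                    "--ref", str(tmp_path / "ref.fa"), "-k", "8",
                    "--store-orientation", "--report",
                    "-o", str(tmp_path / "a.pe")]) == 0
        out = capsys.readouterr().out
        for name in ("Read tails", "Bit tree", "Read head counts",
                     "N locations", "Flipped bits"):
            assert name in out

    def test_unknown_flag_exits_nonzero(self):
        with pytest.raises(SystemExit) as exc:
            cli(["encode", "--frobnicate"])
        assert exc.value.code != 0

    def test_missing_input_is_an_error(self, tmp_path):
        assert cli(["encode", str(tmp_path / "nope.fq"),
                    "-o", str(tmp_path / "x.pe")]) == 1


def test_tails_dominate_with_realistic_errors(tmp_path):
    """With sequencing errors present, the arithmetic-coded tails are the
    largest archive component, mirroring observed size breakdowns."""
    cfg = SimConfig(seed=17, n_transcripts=10,
                    transcript_len_range=(2000, 3000), n_reads=4000,
                    read_len=100, substitution_error_rate=0.01)
    tr = make_transcriptome(cfg, tmp_path / "ref.fa")
    make_reads(tr, cfg).write_fastq(tmp_path / "reads.fq")
    info = encode_file(tmp_path / "reads.fq", reference=tmp_path / "ref.fa",
                       out_path=tmp_path / "a.pe")
    assert info.stream_sizes["tails.ac"] == max(info.stream_sizes.values())
    assert info.total_size < two_bit_baseline(tmp_path / "reads.fq")
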