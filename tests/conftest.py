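"""Shared helpers: canonical multiset comparison and tiny corpora."""

from __future__ import annotations

from pathlib import Path

import pytest

from pathenc import SimConfig, make_reads, make_transcriptome, \
    reverse_complement
from Bio.SeqIO.FastaIO import SimpleFastaParser


def read_fasta(path) -> list[str]:
    with open(path) as fh:
        return [seq for _t, seq in SimpleFastaParser(fh)]


def canonical(seq: str) -> str:
    """Strand-insensitive representative of a read."""
    rc = reverse_complement(seq)
    return seq if seq <= rc else rc


def multisets_equal(a, b, *, up_to_rc: bool = False) -> bool:
    if up_to_rc:
        a = map(canonical, a)
        b = map(canonical, b)
    return sorted(a) == sorted(b)


@pytest.fixture
def small_corpus(tmp_path: Path):
    """A modest single-end corpus with errors, Ns, dupes and mixed strands."""
    cfg = SimConfig(seed=11, n_transcripts=5, transcript_len_range=(400, 900),
                    n_reads=300, read_len=60, substitution_error_rate=0.01,
                    n_rate=0.003, duplicate_fraction=0.2,
                    antisense_fraction=0.5)
    transcripts = make_transcriptome(cfg, tmp_path / "ref.fa")
    reads = make_reads(transcripts, cfg)
    reads.write_fastq(tmp_path / "reads.fq")
    return {"cfg": cfg, "transcripts": transcripts, "reads": reads,
            "ref": tmp_path / "ref.fa", "fastq": tmp_path / "reads.fq",
            "tmp": tmp_path}
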