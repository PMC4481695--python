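"""Deterministic synthetic transcriptomes and read sets.

Every test and benchmark in the package runs on data from this module, so
nothing needs to be downloaded.  The generator emulates the structure of
RNA-seq sequence data that the codec cares about: reads sampled from a
shared transcriptome, substitution sequencing errors, N base calls, exact
duplicate reads (as arise from pooled technical replicates), strand mixing
from unstranded protocols, and fr-oriented mate pairs.

Transcript bases are i.i.d. uniform (not Markovian) on purpose: it keeps
the information content analytic — 2 bits per novel base, ~0 for bases
predicted by the model — so entropy oracles in tests have closed forms.
An optional shared "repeat block" can be spliced into several transcripts
to create high-multiplicity k-mers that exercise the counter-overflow path.
Abundance-weighted (expression-level) sampling and indel errors are out of
scope; the codec is substitution-agnostic and round-trips any sequence.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Knobs for one synthetic dataset; all randomness flows from ``seed``."""

    seed: int = 0
    n_transcripts: int = 20
    transcript_len_range: tuple[int, int] = (500, 3000)
    n_reads: int = 1000
    read_len: int = 100
    substitution_error_rate: float = 0.0
    n_rate: float = 0.0
    duplicate_fraction: float = 0.0
    antisense_fraction: float = 0.0
    paired: bool = False
    fragment_len_range: tuple[int, int] = (200, 400)
    repeat_blocks: int = 0
    repeat_block_len: int = 200

    def __post_init__(self) -> None:
        for name in ("substitution_error_rate", "n_rate",
                     "duplicate_fraction", "antisense_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class TruthRecord:
    """Provenance of one read (or fragment): enough to reverse the noise."""

    read_id: int
    transcript: int
    position: int
    strand: str  # '+' or '-'
    duplicate_of: int  # source read id, or -1
    error_positions: list[int] = field(default_factory=list)
    n_positions: list[int] = field(default_factory=list)
    # paired mode only: the same fields for mate 2
    error_positions2: list[int] = field(default_factory=list)
    n_positions2: list[int] = field(default_factory=list)


@dataclass
class ReadSet:
    """Generated reads plus their truth table."""

    config: SimConfig
    reads: list[str]                  # single-end, or mate-1 sequences
    mates2: list[str] | None
    truth: list[TruthRecord]

    def write_fastq(self, path, path2=None) -> None:
        _write_fastq(Path(path), self.reads)
        if self.mates2 is not None:
            if path2 is None:
                raise ValueError("paired read set needs two output paths")
            _write_fastq(Path(path2), self.mates2)

    def write_truth_tsv(self, path) -> None:
        cols = ("read_id", "transcript", "position", "strand",
                "duplicate_of", "error_positions", "n_positions",
                "error_positions2", "n_positions2")
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for t in self.truth:
                fh.write("\t".join((
                    str(t.read_id), str(t.transcript), str(t.position),
                    t.strand, str(t.duplicate_of),
                    ",".join(map(str, t.error_positions)),
                    ",".join(map(str, t.n_positions)),
                    ",".join(map(str, t.error_positions2)),
                    ",".join(map(str, t.n_positions2)))) + "\n")


def _write_fastq(path: Path, reads: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def make_transcriptome(cfg: SimConfig, path=None) -> list[tuple[str, str]]:
    """Generate ``(name, sequence)`` transcripts; optionally write FASTA.

    Deterministic under ``cfg.seed`` (a generation stream separate from the
    read sampler's, so reads can be re-drawn without regenerating).  With
    ``repeat_blocks > 0`` that many shared blocks are spliced into every
    transcript at random offsets, creating k-mers seen many times.
    """
    rng = np.random.default_rng([cfg.seed, 0x7245])
    lo, hi = cfg.transcript_len_range
    blocks = [_random_sequence(rng, cfg.repeat_block_len)
              for _ in range(cfg.repeat_blocks)]
    transcripts: list[tuple[str, str]] = []
    for i in range(cfg.n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_sequence(rng, length)
        for block in blocks:
            if len(block) < length:
                at = int(rng.integers(0, length - len(block) + 1))
                seq = seq[:at] + block + seq[at + len(block):]
        transcripts.append((f"transcript{i}", seq))
    if path is not None:
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            for name, seq in transcripts:
                fh.write(f">{name}\n{seq}\n")
    return transcripts


def make_reads(transcriptome: Sequence[tuple[str, str]] | str | Path,
               cfg: SimConfig) -> ReadSet:
    """Sample a read set from a transcriptome according to ``cfg``.

    Reads are drawn uniformly over valid start positions; a fraction is
    reverse-complemented (antisense), substitution errors and Ns are
    applied i.i.d. per position, and a fraction of the output consists of
    exact copies of earlier reads.  The final order is a deterministic
    shuffle, and every read's provenance lands in the truth table.
    """
    if isinstance(transcriptome, (str, Path)):
        from .model import read_fasta_sequences
        seqs = list(read_fasta_sequences(transcriptome))
    else:
        seqs = [s for _n, s in transcriptome]
    rng = np.random.default_rng([cfg.seed, 0x5EED])

    span = (cfg.fragment_len_range if cfg.paired
            else (cfg.read_len, cfg.read_len))
    usable = [i for i, s in enumerate(seqs) if len(s) >= span[1]]
    if not usable and cfg.n_reads > 0:
        raise ValueError("no transcript long enough for the requested reads")

    n_dup = int(round(cfg.duplicate_fraction * cfg.n_reads))
    n_unique = cfg.n_reads - n_dup

    reads1: list[str] = []
    reads2: list[str] = []
    truth: list[TruthRecord] = []
    for i in range(n_unique):
        t = usable[int(rng.integers(0, len(usable)))]
        seq = seqs[t]
        flen = int(rng.integers(span[0], span[1] + 1))
        pos = int(rng.integers(0, len(seq) - flen + 1))
        frag = seq[pos:pos + flen]
        antisense = bool(rng.random() < cfg.antisense_fraction)
        if antisense:
            frag = reverse_complement(frag)
        rec = TruthRecord(read_id=i, transcript=t, position=pos,
                          strand="-" if antisense else "+", duplicate_of=-1)
        if cfg.paired:
            m1 = _apply_noise(frag[:cfg.read_len], rng, cfg,
                              rec.error_positions, rec.n_positions)
            m2raw = reverse_complement(frag[-cfg.read_len:])
            m2 = _apply_noise(m2raw, rng, cfg,
                              rec.error_positions2, rec.n_positions2)
            reads1.append(m1)
            reads2.append(m2)
        else:
            reads1.append(_apply_noise(frag, rng, cfg,
                                       rec.error_positions,
                                       rec.n_positions))
        truth.append(rec)

    for i in range(n_unique, cfg.n_reads):
        src = int(rng.integers(0, n_unique)) if n_unique else 0
        s = truth[src]
        reads1.append(reads1[src])
        if cfg.paired:
            reads2.append(reads2[src])
        truth.append(TruthRecord(
            read_id=i, transcript=s.transcript, position=s.position,
            strand=s.strand, duplicate_of=src,
            error_positions=list(s.error_positions),
            n_positions=list(s.n_positions),
            error_positions2=list(s.error_positions2),
            n_positions2=list(s.n_positions2)))

    order = rng.permutation(cfg.n_reads)
    remap = {int(old): new for new, old in enumerate(order)}
    reads1 = [reads1[int(j)] for j in order]
    if cfg.paired:
        reads2 = [reads2[int(j)] for j in order]
    shuffled_truth = []
    for new, old in enumerate(order):
        t = truth[int(old)]
        t.read_id = new
        t.duplicate_of = remap[t.duplicate_of] if t.duplicate_of >= 0 else -1
        shuffled_truth.append(t)

    return ReadSet(config=cfg, reads=reads1,
                   mates2=reads2 if cfg.paired else None,
                   truth=shuffled_truth)


def _apply_noise(seq: str, rng: np.random.Generator, cfg: SimConfig,
                 error_positions: list[int], n_positions: list[int]) -> str:
    """Apply substitution errors then Ns; record positions in the truth."""
    buf = bytearray(seq.encode("ascii"))
    if cfg.substitution_error_rate > 0:
        mask = rng.random(len(buf)) < cfg.substitution_error_rate
        for p in np.flatnonzero(mask):
            p = int(p)
            cur = b"ACGT".index(buf[p])
            buf[p] = b"ACGT"[(cur + 1 + int(rng.integers(0, 3))) % 4]
            error_positions.append(p)
    if cfg.n_rate > 0:
        mask = rng.random(len(buf)) < cfg.n_rate
        for p in np.flatnonzero(mask):
            p = int(p)
            buf[p] = 0x4E
            if p not in n_positions:
                n_positions.append(p)
    return buf.decode("ascii")
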