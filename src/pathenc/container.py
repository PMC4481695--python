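"""Archive layout, encode/decode orchestration, and the command-line tool.

An archive is a single file bundling the streams the method produces:

========================  =====================================================
stream                    contents
========================  =====================================================
``heads.bt.gz``           bit-tree serialization of the distinct read heads
``heads.cnt.gz``          per-head read counts (negative = collapsed dupes)
``tails.ac``              arithmetic-coded read tails (raw; incompressible)
``flip.gz``               per-read orientation bits (only if requested)
``nloc.gz``               positions of Ns translated to A (only if any)
``lengths.gz``            per-read lengths (only if lengths are not uniform)
``split.gz``              per-read mate-1 lengths (paired, non-uniform only)
========================  =====================================================

A small JSON header records k, the flags, the read count, the uniform
read length (when applicable) and a checksum of the reference's (k+1)-mer
multiset, so decoding needs nothing but the archive and (when one was
used) the same reference file.  The header plus the reference fully
determine the decoder's initial model; everything else is derived on the
fly, which is what makes the format streamable.
"""

from __future__ import annotations

import argparse
import gzip
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

from . import accoder, bittree, preprocess
from .bittree import CorruptArchiveError
from .model import ContextModel, DEFAULT_K, DEFAULT_WEIGHT, \
    read_fasta_sequences, reverse_complement
from .preprocess import ReadRecord

logger = logging.getLogger("pathenc")

MAGIC = b"PTHE"
FORMAT_VERSION = 1

#: Display names for the archive components in size reports.
COMPONENT_NAMES = {
    "tails.ac": "Read tails",
    "heads.bt.gz": "Bit tree",
    "heads.cnt.gz": "Read head counts",
    "nloc.gz": "N locations",
    "flip.gz": "Flipped bits",
    "lengths.gz": "Read lengths",
    "split.gz": "Pair split points",
}


class WrongReferenceError(ValueError):
    """The reference supplied at decode time does not match the archive."""


@dataclass
class EncodeOptions:
    k: int = DEFAULT_K
    weight: int = DEFAULT_WEIGHT
    dynamic: bool = True            # False = "no dynamic updates" ablation
    rc: bool = True                 # reverse-complement heuristic
    dedup: bool = True              # collapse pure duplicate buckets
    store_orientation: bool = False
    paired: bool = False
    pair_same_strand: bool = False  # suppress mate-2 reverse complementing


@dataclass
class ArchiveInfo:
    """What :func:`encode_file` produced: header dict and stream sizes."""

    path: Path
    header: dict
    stream_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def total_size(self) -> int:
        return self.path.stat().st_size

    @property
    def payload_size(self) -> int:
        return sum(self.stream_sizes.values())

    def report(self) -> str:
        lines = ["component            bytes", "-" * 27]
        for name in COMPONENT_NAMES.values():
            size = next((s for key, s in self.stream_sizes.items()
                         if COMPONENT_NAMES[key] == name), None)
            if size is not None:
                lines.append(f"{name:<20} {size:>6}")
        lines.append("-" * 27)
        lines.append(f"{'total (with header)':<20} {self.total_size:>6}")
        return "\n".join(lines)


# -- sequence input ------------------------------------------------------

def read_sequences(path) -> list[str]:
    """Read sequences from a FASTA or FASTQ file, plain or gzipped.

    Names are dropped (they are not stored in archives); FASTQ quality
    values are discarded with a warning.
    """
    from Bio.SeqIO.FastaIO import SimpleFastaParser
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    path = Path(path)
    with open(path, "rb") as fh:
        gz = fh.read(2) == b"\x1f\x8b"
    opener = gzip.open if gz else open
    with opener(path, "rt") as handle:
        first = handle.read(1)
        handle.seek(0)
        if first == ">":
            return [seq for _t, seq in SimpleFastaParser(handle)]
        if first == "@":
            logger.warning("%s: FASTQ quality values are not stored", path)
            return [seq for _t, seq, _q in FastqGeneralIterator(handle)]
        if first == "":
            return []
        raise ValueError(f"{path}: not a FASTA or FASTQ file")


def _load_model(reference, options: EncodeOptions) -> ContextModel:
    model = ContextModel(options.k, dynamic=options.dynamic,
                         weight=options.weight)
    if reference is not None:
        model.prime(read_fasta_sequences(reference))
        logger.info("primed model: %d reference windows",
                    model.reference_edge_count)
    return model


# -- container framing ---------------------------------------------------

def _write_container(path: Path, header: dict,
                     streams: dict[str, bytes]) -> None:
    header = dict(header, streams=list(streams))
    blob = json.dumps(header, separators=(",", ":")).encode("ascii")
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(bytes([FORMAT_VERSION]))
        fh.write(len(blob).to_bytes(4, "big"))
        fh.write(blob)
        for name, payload in streams.items():
            enc = name.encode("ascii")
            fh.write(bytes([len(enc)]))
            fh.write(enc)
            fh.write(len(payload).to_bytes(8, "big"))
            fh.write(payload)


def _read_container(path: Path) -> tuple[dict, dict[str, bytes]]:
    with open(path, "rb") as fh:
        if fh.read(4) != MAGIC:
            raise CorruptArchiveError(f"{path}: not a path-encoding archive")
        version = fh.read(1)
        if not version or version[0] != FORMAT_VERSION:
            raise CorruptArchiveError(f"{path}: unsupported format version")
        hlen = int.from_bytes(fh.read(4), "big")
        try:
            header = json.loads(fh.read(hlen))
        except ValueError as exc:
            raise CorruptArchiveError(f"{path}: bad header") from exc
        streams: dict[str, bytes] = {}
        while True:
            nlen = fh.read(1)
            if not nlen:
                break
            name = fh.read(nlen[0]).decode("ascii")
            plen = int.from_bytes(fh.read(8), "big")
            payload = fh.read(plen)
            if len(payload) != plen:
                raise CorruptArchiveError(f"{path}: truncated stream {name}")
            streams[name] = payload
    missing = set(header.get("streams", [])) - set(streams)
    if missing:
        raise CorruptArchiveError(f"{path}: missing streams {missing}")
    return header, streams


# -- encoding ------------------------------------------------------------

def encode_file(reads_in, reference=None, out_path=None,
                options: EncodeOptions | None = None,
                mate2_in=None) -> ArchiveInfo:
    """Compress a read file (or a mate pair of files) into an archive.

    ``reads_in`` is a FASTA/FASTQ path; for paired-end data pass mate 2 as
    ``mate2_in`` and set ``options.paired``.  ``reference`` is an optional
    (gzipped) multi-FASTA transcriptome used to prime the model; the same
    file must be presented again at decode time.
    """
    options = options or EncodeOptions()
    out_path = Path(out_path if out_path is not None
                    else str(reads_in) + ".pe")
    k = options.k

    model = _load_model(reference, options)

    raw1 = read_sequences(reads_in)
    records: list[ReadRecord] = []
    if options.paired:
        if mate2_in is None:
            raise ValueError("paired mode needs a mate-2 file")
        raw2 = read_sequences(mate2_in)
        if len(raw1) != len(raw2):
            raise ValueError("mate files have different read counts")
        for i, (s1, s2) in enumerate(zip(raw1, raw2)):
            q1, n1 = preprocess.translate_ns(s1)
            q2, n2 = preprocess.translate_ns(s2)
            records.append(preprocess.merge_pair(
                ReadRecord(q1, original_index=i, n_positions=n1),
                ReadRecord(q2, original_index=i, n_positions=n2),
                opposite_strands=not options.pair_same_strand))
    else:
        for i, s in enumerate(raw1):
            q, npos = preprocess.translate_ns(s)
            records.append(ReadRecord(q, original_index=i, n_positions=npos))

    for rec in records:
        if len(rec.sequence) < k:
            raise ValueError(
                f"read {rec.original_index} has length "
                f"{len(rec.sequence)} < k={k}")

    if options.rc:
        for rec in records:
            preprocess.maybe_flip(rec, model)

    grouped = preprocess.group_and_dedup(records, k, dedup=options.dedup)

    tails_payload, _ = accoder.encode_tails(
        [r.sequence for r in grouped.representatives], model)

    streams: dict[str, bytes] = {
        "heads.bt.gz": bittree.pack_bittree_stream(grouped.heads, k),
        "heads.cnt.gz": bittree.encode_counts(grouped.counts),
        "tails.ac": tails_payload,
    }

    final = grouped.final_order
    lengths = [len(r.sequence) for r in final]
    uniform_length = lengths[0] if lengths and len(set(lengths)) == 1 else None
    if lengths and uniform_length is None:
        streams["lengths.gz"] = gzip.compress(
            " ".join(map(str, lengths)).encode("ascii"), mtime=0)

    uniform_split = None
    if options.paired and final:
        splits = [r.pair_split for r in final]
        if len(set(splits)) == 1:
            uniform_split = splits[0]
        else:
            streams["split.gz"] = gzip.compress(
                " ".join(map(str, splits)).encode("ascii"), mtime=0)

    if options.store_orientation:
        streams["flip.gz"] = preprocess.pack_flip_bits(
            [r.flipped for r in final])

    if any(r.n_positions for r in final):
        streams["nloc.gz"] = preprocess.pack_n_locations(
            [r.n_positions for r in final])

    header = {
        "k": k,
        "weight": options.weight,
        "flags": {
            "reference": reference is not None,
            "dynamic": options.dynamic,
            "rc": options.rc,
            "dedup": options.dedup,
            "orientation": options.store_orientation,
            "paired": options.paired,
            "pair_same_strand": options.pair_same_strand,
        },
        "read_count": len(final),
        "uniform_length": uniform_length,
        "uniform_split": uniform_split,
        "ref_checksum": model.reference_checksum,
    }
    _write_container(out_path, header, streams)
    info = ArchiveInfo(out_path, header,
                       {n: len(p) for n, p in streams.items()})
    logger.info("wrote %s (%d bytes)\n%s", out_path, info.total_size,
                info.report())
    return info


# -- decoding ------------------------------------------------------------

def decode_file(archive, reference=None, out_path=None) -> list[Path]:
    """Decompress an archive back to FASTA; returns the output path(s).

    When the archive was encoded with a reference, the same reference file
    must be supplied; a mismatch is detected via the header checksum before
    any read is emitted.  Paired archives produce two files (suffixes
    ``_1.fasta``/``_2.fasta``); reads are named by their archive ordinal
    (original names are not stored).
    """
    archive = Path(archive)
    header, streams = _read_container(archive)
    k = header["k"]
    flags = header["flags"]
    n_reads = header["read_count"]

    model = ContextModel(k, dynamic=flags["dynamic"],
                         weight=header["weight"])
    if flags["reference"]:
        if reference is None:
            raise WrongReferenceError(
                f"{archive}: encoded with a reference; pass the same file")
        model.prime(read_fasta_sequences(reference))
        if model.reference_checksum != header["ref_checksum"]:
            raise WrongReferenceError(
                f"{archive}: wrong reference (checksum mismatch)")

    heads = bittree.unpack_bittree_stream(streams["heads.bt.gz"], k)
    counts = bittree.decode_counts(streams["heads.cnt.gz"], len(heads))
    if sum(abs(c) for c in counts) != n_reads:
        raise CorruptArchiveError(
            f"{archive}: head counts disagree with read count")

    if "lengths.gz" in streams:
        lengths = _unpack_int_stream(streams["lengths.gz"], n_reads,
                                     "length")
    else:
        lengths = [header["uniform_length"]] * n_reads

    sequences = accoder.decode_tails(
        streams["tails.ac"], list(zip(heads, counts)), model, lengths)

    if "nloc.gz" in streams:
        n_positions = preprocess.unpack_n_locations(streams["nloc.gz"],
                                                    n_reads)
    else:
        n_positions = [[]] * n_reads

    if flags["orientation"]:
        flips = preprocess.unpack_flip_bits(streams["flip.gz"], n_reads)
    else:
        flips = [False] * n_reads

    if flags["paired"]:
        if "split.gz" in streams:
            splits = _unpack_int_stream(streams["split.gz"], n_reads,
                                        "split")
        else:
            splits = [header["uniform_split"]] * n_reads
    else:
        splits = None

    out_paths = _output_paths(archive, out_path, paired=flags["paired"])
    handles = [open(p, "w") for p in out_paths]
    try:
        for i, seq in enumerate(sequences):
            seq = preprocess.restore_ns(seq, n_positions[i])
            if flips[i]:
                seq = reverse_complement(seq)
            if flags["paired"]:
                m1, m2 = preprocess.unmerge_pair(
                    seq, splits[i],
                    opposite_strands=not flags["pair_same_strand"])
                handles[0].write(f">read{i}/1\n{m1}\n")
                handles[1].write(f">read{i}/2\n{m2}\n")
            else:
                handles[0].write(f">read{i}\n{seq}\n")
    finally:
        for h in handles:
            h.close()
    return out_paths


def _unpack_int_stream(blob: bytes, expected_n: int, what: str) -> list[int]:
    try:
        values = [int(t) for t in gzip.decompress(blob).split()]
    except (OSError, EOFError, ValueError) as exc:
        raise CorruptArchiveError(f"bad {what} stream: {exc}") from exc
    if len(values) != expected_n:
        raise CorruptArchiveError(
            f"{what} stream has {len(values)} entries, expected {expected_n}")
    return values


def _output_paths(archive: Path, out_path, *, paired: bool) -> list[Path]:
    if paired:
        if out_path is None:
            stem = archive.with_suffix("")
            return [Path(f"{stem}_1.fasta"), Path(f"{stem}_2.fasta")]
        stem = Path(out_path)
        if stem.suffix == ".fasta":
            stem = stem.with_suffix("")
        return [Path(f"{stem}_1.fasta"), Path(f"{stem}_2.fasta")]
    if out_path is None:
        return [archive.with_suffix(".fasta")]
    return [Path(out_path)]


def two_bit_baseline(reads_in, mate2_in=None) -> int:
    """ceil(total bases / 4): the naive 2-bits-per-base size in bytes."""
    total = sum(len(s) for s in read_sequences(reads_in))
    if mate2_in is not None:
        total += sum(len(s) for s in read_sequences(mate2_in))
    return (total + 3) // 4


# -- CLI -----------------------------------------------------------------

def _build_parser() -> argparse.ArgumentParser:
    parser = argparse.ArgumentParser(
        prog="pathenc",
        description="Lossless, reference-assisted compression of short "
                    "sequencing reads by path encoding.")
    sub = parser.add_subparsers(dest="command", required=True)

    enc = sub.add_parser("encode", help="compress a read file")
    enc.add_argument("reads", nargs="?", help="FASTA/FASTQ file (or .gz)")
    enc.add_argument("--paired", nargs=2, metavar=("R1", "R2"),
                     help="paired-end mate files")
    enc.add_argument("-o", "--output", help="archive path (default: "
                                            "READS.pe)")
    enc.add_argument("--ref", help="reference transcriptome multi-FASTA "
                                   "(plain or .gz)")
    enc.add_argument("--no-ref", action="store_true",
                     help="start from an empty model (explicit)")
    enc.add_argument("-k", type=int, default=DEFAULT_K,
                     help="context length (default %(default)s)")
    enc.add_argument("--weight", type=int, default=DEFAULT_WEIGHT,
                     help="observation weight (default %(default)s)")
    enc.add_argument("--static-model", action="store_true",
                     help="disable adaptive model updates")
    enc.add_argument("--no-rc", action="store_true",
                     help="disable the reverse-complement heuristic")
    enc.add_argument("--no-dedup", action="store_true",
                     help="disable duplicate-read collapsing")
    enc.add_argument("--store-orientation", action="store_true",
                     help="record a flip bit per read so original strands "
                          "are restored")
    enc.add_argument("--pair-same-strand", action="store_true",
                     help="do not reverse-complement mate 2 when merging")
    enc.add_argument("--report", action="store_true",
                     help="print the per-component size table")

    dec = sub.add_parser("decode", help="decompress an archive")
    dec.add_argument("archive")
    dec.add_argument("--ref", help="reference used at encode time")
    dec.add_argument("-o", "--output", help="output FASTA path (paired "
                                            "archives get _1/_2 suffixes)")
    dec.add_argument("-k", type=int, default=None,
                     help="ignored: k is read from the archive header")
    return parser


def cli(argv: Sequence[str] | None = None) -> int:
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(message)s")
    args = _build_parser().parse_args(argv)
    try:
        if args.command == "encode":
            if args.paired and args.reads:
                raise ValueError("give either READS or --paired R1 R2")
            if not args.paired and not args.reads:
                raise ValueError("no input reads given")
            if args.ref and args.no_ref:
                raise ValueError("--ref and --no-ref are mutually exclusive")
            options = EncodeOptions(
                k=args.k, weight=args.weight,
                dynamic=not args.static_model,
                rc=not args.no_rc, dedup=not args.no_dedup,
                store_orientation=args.store_orientation,
                paired=bool(args.paired),
                pair_same_strand=args.pair_same_strand)
            reads_in = args.paired[0] if args.paired else args.reads
            mate2 = args.paired[1] if args.paired else None
            out = args.output or str(reads_in) + ".pe"
            info = encode_file(reads_in, reference=args.ref, out_path=out,
                               options=options, mate2_in=mate2)
            if args.report:
                print(info.report())
        else:
            if args.k is not None:
                logger.warning("decode ignores -k; the archive header "
                               "fixes it")
            paths = decode_file(args.archive, reference=args.ref,
                                out_path=args.output)
            logger.info("wrote %s", ", ".join(map(str, paths)))
    except (ValueError, OSError) as exc:
        logger.error("%s", exc)
        return 1
    return 0


def main() -> None:  # console-script entry point
    raise SystemExit(cli())
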