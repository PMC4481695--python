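"""Read-set normalization ahead of head/tail splitting.

Order of operations on the way into the codec:

1. every N (or other non-ACGT character) becomes an A, its position kept in
   a sidecar stream so the original string is recoverable;
2. paired-end mates are merged into one longer read (mate 2 reverse-
   complemented first for the usual fr-orientation libraries) so that
   reordering cannot separate a pair;
3. each read may be reverse-complemented when its reverse complement has
   more reference-supported k-mer transitions than the forward sequence —
   the reference models the forward strand only, and in an unstranded
   protocol the recorded strand was arbitrary to begin with;
4. reads are bucketed by their first k bases (the head) and buckets are
   emitted in trie DFS order; a bucket consisting entirely of d copies of
   one sequence is collapsed to a single stored tail with count -d.

Every step is deterministic and driven only by data the decoder also has
(the reference and the archive flags), except the per-read flip bit and N
positions, which travel in their own small streams.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field

from .bittree import BitReader, BitWriter, CorruptArchiveError
from .model import ContextModel, reverse_complement, sequence_codes

_NON_ACGT = re.compile(r"[^ACGT]")


@dataclass
class ReadRecord:
    """One read (or merged mate pair) in its normalized ACGT form."""

    sequence: str
    original_index: int = 0
    flipped: bool = False
    n_positions: list[int] = field(default_factory=list)
    pair_split: int | None = None  # length of mate 1 inside a merged read

    def __post_init__(self) -> None:
        if self.pair_split is not None and not (
                0 < self.pair_split < len(self.sequence)):
            raise ValueError("pair_split must lie strictly inside the read")


def translate_ns(raw: str) -> tuple[str, list[int]]:
    """Replace every non-ACGT character (N, IUPAC codes) by A.

    Returns the translated sequence and the 0-based offsets of the
    replacements, which are restored as Ns on decode.
    """
    raw = raw.upper()
    if _NON_ACGT.search(raw) is None:
        return raw, []
    positions = [m.start() for m in _NON_ACGT.finditer(raw)]
    return _NON_ACGT.sub("A", raw), positions


def restore_ns(seq: str, n_positions: list[int]) -> str:
    if not n_positions:
        return seq
    buf = bytearray(seq.encode("ascii"))
    for p in n_positions:
        buf[p] = 0x4E  # 'N'
    return buf.decode("ascii")


def rc_score(seq: str, model: ContextModel, k: int | None = None
             ) -> tuple[int, int]:
    """Reference support for a read versus its reverse complement.

    Counts the positions j >= k whose context k-mer has the observed base
    as a known transition in the *initial* model, for the forward sequence
    and for its reverse complement.  Reads shorter than k+1 score (0, 0).
    """
    if k is None:
        k = model.k
    table = model.table

    def hits(s: str) -> int:
        codes = sequence_codes(s)
        if len(codes) <= k:
            return 0
        mask = (1 << (2 * k)) - 1
        ctx = 0
        for c in codes[:k]:
            ctx = (ctx << 2) | c
        h = 0
        for j in range(k, len(codes)):
            c = codes[j]
            entry = table.get(ctx)
            if entry is not None and ((entry[4] >> c) & 1 or entry[c] >= 1):
                h += 1
            ctx = ((ctx << 2) | c) & mask
        return h

    return hits(seq), hits(reverse_complement(seq))


def maybe_flip(read: ReadRecord, model: ContextModel) -> ReadRecord:
    """Reverse-complement the read if its RC better matches the model.

    The decision (rev_hits > fwd_hits; a tie keeps the forward orientation,
    so an unprimed model never flips) is made against the initial model for
    all reads before any coding starts.  N positions are remapped to the
    flipped coordinates.
    """
    fwd, rev = rc_score(read.sequence, model)
    if rev > fwd:
        length = len(read.sequence)
        read.sequence = reverse_complement(read.sequence)
        read.n_positions = sorted(length - 1 - p for p in read.n_positions)
        read.flipped = True
    return read


def merge_pair(mate1: ReadRecord, mate2: ReadRecord, *,
               opposite_strands: bool = True) -> ReadRecord:
    """Merge a mate pair into one read (mate 1 then mate 2).

    With ``opposite_strands`` (fr libraries) mate 2 is reverse-complemented
    first so the whole merged read comes from one strand.  ``pair_split``
    records mate 1's length for unmerging; N positions are carried along.
    """
    len1, len2 = len(mate1.sequence), len(mate2.sequence)
    seq2 = mate2.sequence
    npos2 = mate2.n_positions
    if opposite_strands:
        seq2 = reverse_complement(seq2)
        npos2 = sorted(len2 - 1 - p for p in npos2)
    return ReadRecord(
        sequence=mate1.sequence + seq2,
        original_index=mate1.original_index,
        n_positions=mate1.n_positions + [len1 + p for p in npos2],
        pair_split=len1,
    )


def unmerge_pair(seq: str, pair_split: int, *,
                 opposite_strands: bool = True) -> tuple[str, str]:
    """Inverse of :func:`merge_pair` on the (N-restored) sequence."""
    mate1 = seq[:pair_split]
    mate2 = seq[pair_split:]
    if opposite_strands:
        mate2 = reverse_complement(mate2)
    return mate1, mate2


@dataclass
class GroupedReads:
    """Reads bucketed by head, in trie-DFS (lexicographic) head order."""

    heads: list[int]                 # distinct head k-mers, ascending
    counts: list[int]                # signed: -d marks a collapsed bucket
    representatives: list[ReadRecord]  # reads whose tails are coded
    final_order: list[ReadRecord]    # all reads (duplicates included)

    @property
    def n_reads(self) -> int:
        return len(self.final_order)


def group_and_dedup(reads: list[ReadRecord], k: int, *,
                    dedup: bool = True) -> GroupedReads:
    """Bucket reads by their first k bases and collapse pure duplicates.

    Buckets are emitted in DFS order of their heads; within a bucket reads
    keep stable input order.  A bucket is collapsed (count -d, one stored
    tail) only when it has d >= 2 members that are all the identical full
    sequence — a deliberately conservative duplicate test.  Flip bits, N
    locations and lengths are later emitted in ``final_order``, which lists
    every read including collapsed duplicates.
    """
    buckets: dict[int, list[ReadRecord]] = {}
    for read in reads:
        if len(read.sequence) < k:
            raise ValueError(
                f"read {read.original_index} is shorter than k={k}")
        codes = sequence_codes(read.sequence[:k])
        head = 0
        for c in codes:
            head = (head << 2) | c
        buckets.setdefault(head, []).append(read)

    heads: list[int] = []
    counts: list[int] = []
    representatives: list[ReadRecord] = []
    final_order: list[ReadRecord] = []
    for head in sorted(buckets):
        bucket = buckets[head]
        heads.append(head)
        d = len(bucket)
        first_seq = bucket[0].sequence
        if (dedup and d >= 2
                and all(r.sequence == first_seq for r in bucket[1:])):
            counts.append(-d)
            representatives.append(bucket[0])
        else:
            counts.append(d)
            representatives.extend(bucket)
        final_order.extend(bucket)
    return GroupedReads(heads, counts, representatives, final_order)


# -- sidecar streams -----------------------------------------------------

def pack_flip_bits(flags: list[bool]) -> bytes:
    """``flip.gz``: one bit per final read, MSB-first, gzipped."""
    w = BitWriter()
    for f in flags:
        w.write(1 if f else 0)
    return gzip.compress(w.getvalue(), mtime=0)


def unpack_flip_bits(blob: bytes, n_reads: int) -> list[bool]:
    try:
        data = gzip.decompress(blob)
    except (OSError, EOFError) as exc:
        raise CorruptArchiveError(f"bad flip stream: {exc}") from exc
    if len(data) < (n_reads + 7) // 8:
        raise CorruptArchiveError("flip stream shorter than read count")
    r = BitReader(data, slack=0)
    return [bool(r.read()) for _ in range(n_reads)]


def pack_n_locations(per_read: list[list[int]]) -> bytes:
    """``nloc.gz``: per read, a count then delta-encoded offsets (ASCII)."""
    parts: list[str] = []
    for positions in per_read:
        parts.append(str(len(positions)))
        prev = 0
        for p in positions:
            parts.append(str(p - prev))
            prev = p
    return gzip.compress(" ".join(parts).encode("ascii"), mtime=0)


def unpack_n_locations(blob: bytes, n_reads: int) -> list[list[int]]:
    try:
        tokens = gzip.decompress(blob).split()
    except (OSError, EOFError) as exc:
        raise CorruptArchiveError(f"bad N-location stream: {exc}") from exc
    out: list[list[int]] = []
    i = 0
    try:
        for _ in range(n_reads):
            n = int(tokens[i])
            i += 1
            positions = []
            prev = 0
            for _ in range(n):
                prev += int(tokens[i])
                i += 1
                positions.append(prev)
            out.append(positions)
    except IndexError as exc:
        raise CorruptArchiveError("N-location stream truncated") from exc
    if i != len(tokens):
        raise CorruptArchiveError("N-location stream has trailing data")
    return out
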