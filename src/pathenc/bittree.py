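"""Succinct serialization of a k-mer set as a depth-first trie bit stream.

The first k bases of every read (the read *head*) are stored collectively:
the set of distinct heads ``K`` induces a subtree of the complete 4-ary
depth-k trie, and that subtree is written as the bit sequence produced by a
depth-first traversal that visits the four children of every node in the
fixed nucleotide order (A, C, G, T), emitting 1 when a child edge is used
by some k-mer in ``K`` (and descending) and 0 when it is not.  Nodes at
depth k are leaves, so no bits are emitted for their (nonexistent)
children.  The traversal terminates intrinsically, which makes the stream
self-delimiting: decoding replays the same traversal, pruning on 0 bits.

Neither encoder nor decoder ever materializes the trie — a sorted k-mer
list suffices to simulate the traversal.

Alongside the tree, the per-head multiplicities travel in a *count file*:
space-separated ASCII integers in DFS (= lexicographic) head order,
gzip-compressed.  A negative count ``-d`` marks a head whose d reads are
exact duplicates of one stored tail.
"""

from __future__ import annotations

import gzip
from typing import Sequence

from .model import decode_kmer, encode_kmer


class CorruptArchiveError(ValueError):
    """An archive stream is truncated or inconsistent."""


class BitWriter:
    """Accumulates single bits, packing them MSB-first into bytes."""

    __slots__ = ("_buf", "_acc", "_nbits")

    def __init__(self) -> None:
        self._buf = bytearray()
        self._acc = 0
        self._nbits = 0

    def write(self, bit: int) -> None:
        self._acc = (self._acc << 1) | bit
        self._nbits += 1
        if self._nbits == 8:
            self._buf.append(self._acc)
            self._acc = 0
            self._nbits = 0

    def getvalue(self) -> bytes:
        """Packed bytes, final partial byte zero-padded on the right."""
        out = bytes(self._buf)
        if self._nbits:
            out += bytes([self._acc << (8 - self._nbits)])
        return out

    def __len__(self) -> int:  # bits written so far
        return 8 * len(self._buf) + self._nbits


class BitReader:
    """MSB-first bit source over bytes.

    Reads past the end return 0 up to ``slack`` bits (the arithmetic coder
    legitimately reads a few bits beyond its flushed output); beyond that a
    :class:`CorruptArchiveError` is raised.
    """

    __slots__ = ("_data", "_pos", "_nbits", "_overrun", "slack")

    def __init__(self, data: bytes, slack: int = 48) -> None:
        self._data = data
        self._pos = 0
        self._nbits = 8 * len(data)
        self._overrun = 0
        self.slack = slack

    def read(self) -> int:
        pos = self._pos
        if pos >= self._nbits:
            self._overrun += 1
            if self._overrun > self.slack:
                raise CorruptArchiveError("bit stream exhausted")
            return 0
        self._pos = pos + 1
        return (self._data[pos >> 3] >> (7 - (pos & 7))) & 1


def _as_ints(kmers: Sequence, k: int) -> list[int]:
    if kmers and isinstance(kmers[0], str):
        return [encode_kmer(s) for s in kmers]
    return list(kmers)


def encode_bittree(kmers: Sequence, k: int) -> bytes:
    """Serialize a sorted set of k-mers (ints or strings) to packed bits.

    The input must be strictly increasing under the A<C<G<T encoding; this
    is exactly the DFS order of the trie, so the traversal can be simulated
    with a cursor over the list.  The empty set is valid and yields four
    zero bits (an all-absent root).
    """
    ks = _as_ints(kmers, k)
    for i in range(1, len(ks)):
        if ks[i] <= ks[i - 1]:
            raise ValueError("k-mer list must be sorted and duplicate-free")
    out = BitWriter()
    write = out.write

    # DFS over (lo, hi) slices of the sorted list: each child bit is
    # followed immediately by that child's whole subtree, mirroring the
    # recursive traversal the decoder replays.
    def walk(lo: int, hi: int, depth: int) -> None:
        shift = 2 * (k - 1 - depth)
        i = lo
        for b in range(4):
            j = i
            while j < hi and ((ks[j] >> shift) & 3) == b:
                j += 1
            if j > i:
                write(1)
                if depth + 1 < k:
                    walk(i, j, depth + 1)
            else:
                write(0)
            i = j

    walk(0, len(ks), 0)
    return out.getvalue()


def decode_bittree(data: bytes, k: int, *, as_strings: bool = False) -> list:
    """Inverse of :func:`encode_bittree`; output in DFS (sorted) order."""
    reader = BitReader(data, slack=0)
    read = reader.read
    result: list[int] = []

    def walk(depth: int, prefix: int) -> None:
        for b in range(4):
            if read():
                child = (prefix << 2) | b
                if depth + 1 == k:
                    result.append(child)
                else:
                    walk(depth + 1, child)

    try:
        walk(0, 0)
    except RecursionError:  # pragma: no cover - k is capped at 30
        raise CorruptArchiveError("trie deeper than k")
    if as_strings:
        return [decode_kmer(x, k) for x in result]
    return result


def bittree_bit_count(kmers: Sequence, k: int) -> int:
    """Exact bit length of the serialized tree: 4 bits per internal node.

    Every node at depth < k (including the root) contributes one bit per
    child slot; internal nodes correspond one-to-one with the distinct
    proper prefixes (including the empty prefix) of the k-mers in the set.
    """
    ks = _as_ints(kmers, k)
    prefixes = {(x >> (2 * (k - d)), d) for x in ks for d in range(k)}
    return 4 * (len(prefixes) if ks else 1)


# -- archive stream framing ---------------------------------------------

def pack_bittree_stream(kmers: Sequence, k: int) -> bytes:
    """``heads.bt.gz``: 4-byte big-endian cardinality + packed bits, gzipped.

    The count prefix is an integrity check: the decoder verifies it against
    the number of k-mers the traversal yields.
    """
    ks = _as_ints(kmers, k)
    payload = len(ks).to_bytes(4, "big") + encode_bittree(ks, k)
    return gzip.compress(payload, mtime=0)


def unpack_bittree_stream(blob: bytes, k: int) -> list[int]:
    try:
        payload = gzip.decompress(blob)
    except (OSError, EOFError) as exc:
        raise CorruptArchiveError(f"bad bit-tree stream: {exc}") from exc
    if len(payload) < 4:
        raise CorruptArchiveError("bit-tree stream too short")
    n = int.from_bytes(payload[:4], "big")
    kmers = decode_bittree(payload[4:], k)
    if len(kmers) != n:
        raise CorruptArchiveError(
            f"bit tree decoded {len(kmers)} k-mers, header says {n}")
    return kmers


def encode_counts(counts: Sequence[int]) -> bytes:
    """``heads.cnt.gz``: space-separated ASCII integers, gzipped.

    Counts are aligned with DFS k-mer order; a negative value ``-d`` flags a
    collapsed group of d identical reads.
    """
    return gzip.compress(" ".join(map(str, counts)).encode("ascii"), mtime=0)


def decode_counts(blob: bytes, expected_n: int) -> list[int]:
    try:
        text = gzip.decompress(blob).decode("ascii")
    except (OSError, EOFError, UnicodeDecodeError) as exc:
        raise CorruptArchiveError(f"bad count stream: {exc}") from exc
    counts = [int(t) for t in text.split()] if text else []
    if len(counts) != expected_n:
        raise CorruptArchiveError(
            f"count stream has {len(counts)} entries, expected {expected_n}")
    return counts
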