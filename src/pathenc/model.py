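"""Context model for path encoding.

A collection of reads is viewed as a set of paths through the de Bruijn
graph ``G`` whose nodes are the k-mers of the data and whose edge
``(u, v)`` exists when ``v`` follows ``u`` with a k-1 overlap.  Compressing
a read tail then amounts to arithmetic-coding each successive base ``b``
under a conditional distribution ``p_u(b)`` attached to the current context
k-mer ``u``.  This module houses that statistical model: the per-context
observation counts, the reference-primed edge set, the fallback ("default")
distribution used for never-seen contexts, and the online update protocol
that encoder and decoder replay in lockstep so that no side information is
needed to keep their models identical.

Counts follow a three-branch rule designed to be robust to sequencing
errors: an edge seen in the reference behaves as if observed twice from the
start, an edge observed at least twice in the reads gets full weight, and
everything else keeps a pseudocount of 1 so that errors (which rarely recur)
never inflate the model::

    c_u(v) = weight * (n_uv + 2)   if (u, v) occurs in the reference
           = weight * n_uv         if n_uv >= 2 and (u, v) not in reference
           = 1                     otherwise

with ``weight = 10`` by default and ``p_u(v) = c_u(v) / sum_w c_u(w)``.
"""

from __future__ import annotations

import gzip
from typing import Iterable, Iterator, Sequence

#: Archive-format constant: the fixed child/symbol order used everywhere —
#: the trie serialization, the coder's cumulative distribution and the
#: reverse-complement tables all rely on A,C,G,T (lexicographic).
NUCLEOTIDES = "ACGT"

#: Default context length.  16 is where compression is typically best for
#: short reads: longer contexts predict better but inflate the head trie
#: and make each sequencing error poison the context for longer.
DEFAULT_K = 16

#: Default relative weight of observations versus the pseudocount.
DEFAULT_WEIGHT = 10

#: Per-base observation counters live in 8-bit cells; a counter that
#: reaches this value spills into an exact side table so no information
#: is lost (the cell then only means "look aside").
CELL_MAX = 255

#: Largest total frequency the arithmetic coder accepts (14 bits, matching
#: the classic 16-bit code-value layout in :mod:`pathenc.accoder`).
MAX_TOTAL = (1 << 14) - 1

_CODE = {c: i for i, c in enumerate(NUCLEOTIDES)}
_COMP = str.maketrans("ACGTN", "TGCAN")
# byte -> 2-bit code; everything outside ACGT maps to the 0xFF sentinel
_BYTE_CODE = bytearray([0xFF]) * 256
for _i, _c in enumerate(NUCLEOTIDES):
    _BYTE_CODE[ord(_c)] = _i
_N_TO_A = str.maketrans("N", "A")


def encode_kmer(kmer: str) -> int:
    """Pack a k-mer over ACGT into an integer, 2 bits per base, A=0..T=3."""
    x = 0
    for c in kmer:
        x = (x << 2) | _CODE[c]
    return x


def decode_kmer(x: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    return "".join(NUCLEOTIDES[(x >> (2 * (k - 1 - i))) & 3] for i in range(k))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def sequence_codes(seq: str) -> bytes:
    """Translate an ACGT string to 2-bit codes (one byte per base)."""
    return seq.encode("ascii").translate(bytes(_BYTE_CODE))


def _mix64(x: int) -> int:
    """splitmix64 finalizer; used for the order-independent edge digest."""
    x = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return x ^ (x >> 31)


class ContextModel:
    """Adaptive, reference-primable transition model over k-mer contexts.

    Parameters
    ----------
    k
        Context length (number of preceding bases), 1..30.
    dynamic
        When False the model is frozen: :meth:`observe` is a no-op.  This is
        the "no dynamic updates" ablation; coding stays lossless either way.
    weight
        Multiplier applied to trusted observation counts (default 10).
    """

    __slots__ = (
        "k", "dynamic", "weight", "table", "default_counts",
        "_overflow", "_ref_digest", "_ref_edges", "cap_events",
    )

    def __init__(self, k: int = DEFAULT_K, *, dynamic: bool = True,
                 weight: int = DEFAULT_WEIGHT) -> None:
        if not 1 <= k <= 30:
            raise ValueError(f"k must be in [1, 30], got {k}")
        if weight < 1:
            raise ValueError("weight must be a positive integer")
        self.k = k
        self.dynamic = dynamic
        self.weight = weight
        # kmer -> [n_A, n_C, n_G, n_T, ref_mask]; cells saturate at CELL_MAX
        self.table: dict[int, list[int]] = {}
        # fallback counts c0(b); pseudocount floor of 1 per base
        self.default_counts: list[int] = [1, 1, 1, 1]
        # (kmer << 2 | base) -> exact count, for counters >= CELL_MAX
        self._overflow: dict[int, int] = {}
        self._ref_digest = 0
        self._ref_edges = 0
        self.cap_events = 0  # frequency-total halvings (coder bookkeeping)

    # -- queries ---------------------------------------------------------

    def count(self, u: int, b: int) -> int:
        """c_u(b) for a context present in the table (three-branch rule)."""
        entry = self.table[u]
        n = entry[b]
        if n == CELL_MAX:
            n = self._overflow[(u << 2) | b]
        if (entry[4] >> b) & 1:
            return self.weight * (n + 2)
        if n >= 2:
            return self.weight * n
        return 1

    def frequencies(self, u: int, max_total: int = MAX_TOTAL
                    ) -> tuple[list[int], int, bool]:
        """Integer coder frequencies for the base following context ``u``.

        Returns ``(freqs, total, is_default)`` where ``freqs`` are the four
        per-base counts under the fixed nucleotide order and ``total`` their
        sum, halved (flooring at 1) as needed to stay within ``max_total``
        so they can feed the coder's frequency registers directly.  Unknown
        contexts fall back to the default distribution ``c0``.
        """
        entry = self.table.get(u)
        if entry is None:
            f = self.default_counts.copy()
            is_default = True
        else:
            f = [self.count(u, 0), self.count(u, 1),
                 self.count(u, 2), self.count(u, 3)]
            is_default = False
        total = f[0] + f[1] + f[2] + f[3]
        while total > max_total:
            f = [max(1, c >> 1) for c in f]
            total = f[0] + f[1] + f[2] + f[3]
            self.cap_events += 1
        return f, total, is_default

    def next_distribution(self, u: int) -> tuple[
            tuple[float, float, float, float],
            tuple[float, float, float, float], bool]:
        """Probability and cumulative-probability vectors for context ``u``.

        ``p_u(b) = c_u(b) / sum c_u``, derived from the same capped integer
        frequencies the coder consumes, so the fixed-point cumulative totals
        match the coder's registers exactly.  ``is_default`` flags the
        fallback (unknown-context) distribution.
        """
        f, total, is_default = self.frequencies(u)
        p = tuple(c / total for c in f)
        cum = (0.0, f[0] / total, (f[0] + f[1]) / total,
               (f[0] + f[1] + f[2]) / total)
        return p, cum, is_default  # type: ignore[return-value]

    def has_transition(self, u: int, b: int) -> bool:
        """True iff edge (u, b) is in the reference or has been observed."""
        entry = self.table.get(u)
        if entry is None:
            return False
        return bool((entry[4] >> b) & 1) or entry[b] >= 1

    # -- updates ---------------------------------------------------------

    def observe(self, u: int, b: int) -> None:
        """Record one traversal of edge ``(u, b)``.

        Called by encoder and decoder immediately *after* the base is coded
        (the decoder only knows the base then), which is what keeps the two
        models synchronized.  A brand-new context is inserted with zero
        counts and the coded base is credited to the default distribution
        instead.  No-op when the model is static.
        """
        if not self.dynamic:
            return
        entry = self.table.get(u)
        if entry is None:
            self.default_counts[b] += 1
            self.table[u] = [0, 0, 0, 0, 0]
            return
        n = entry[b]
        if n < CELL_MAX:
            n += 1
            entry[b] = n
            if n == CELL_MAX:
                self._overflow[(u << 2) | b] = n
        else:
            self._overflow[(u << 2) | b] += 1

    def exact_count(self, u: int, b: int) -> int:
        """The unbounded observation count n_ub (transparent to overflow)."""
        entry = self.table.get(u)
        if entry is None:
            return 0
        n = entry[b]
        if n == CELL_MAX:
            n = self._overflow[(u << 2) | b]
        return n

    def _add_ref_edge(self, u: int, b: int) -> None:
        entry = self.table.get(u)
        if entry is None:
            entry = self.table[u] = [0, 0, 0, 0, 0]
        mask = 1 << b
        if not entry[4] & mask:
            entry[4] |= mask
        # digest accumulates the (k+1)-mer multiset, order-independently
        self._ref_digest = (
            self._ref_digest + _mix64(((u << 2) | b) ^ (self.k << 56))
        ) & 0xFFFFFFFFFFFFFFFF
        self._ref_edges += 1

    # -- reference priming ----------------------------------------------

    def prime(self, ref_sequences: Iterable[str]) -> "ContextModel":
        """Prime the model from reference sequences (forward strand only).

        Every (k+1)-mer window of every sequence marks the edge from its
        length-k prefix to its final base as present-in-reference, with the
        observation count left at zero (the "+2" of the count rule makes
        these edges start as if seen twice).  Ns are translated to A, the
        same convention applied to reads; windows containing any other
        character are skipped.  Sequences shorter than k+1 contribute
        nothing.
        """
        k = self.k
        mask = (1 << (2 * k)) - 1
        for seq in ref_sequences:
            codes = sequence_codes(seq.upper().translate(_N_TO_A))
            ctx = 0
            run = 0  # valid bases accumulated in the current window
            for c in codes:
                if c == 0xFF:
                    run = 0
                    continue
                if run >= k:
                    self._add_ref_edge(ctx & mask, c)
                ctx = ((ctx << 2) | c) & mask
                run += 1
        return self

    @property
    def reference_checksum(self) -> int:
        """Order-independent 64-bit digest of the primed (k+1)-mer multiset.

        Stored in the archive header so a decode attempted with the wrong
        reference fails immediately instead of producing garbage.
        """
        return self._ref_digest

    @property
    def reference_edge_count(self) -> int:
        return self._ref_edges


def prime_from_reference(ref_sequences: Iterable[str], k: int = DEFAULT_K, *,
                         dynamic: bool = True,
                         weight: int = DEFAULT_WEIGHT) -> ContextModel:
    """Build a :class:`ContextModel` primed from reference sequences."""
    return ContextModel(k, dynamic=dynamic, weight=weight).prime(ref_sequences)


def read_fasta_sequences(path) -> Iterator[str]:
    """Yield sequences from a multi-FASTA file, plain or gzip-compressed.

    Header lines are ignored except as record delimiters.
    """
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    opener = gzip.open if _is_gzip(path) else open
    with opener(path, "rt") as handle:
        for _title, seq in SimpleFastaParser(handle):
            yield seq


def _is_gzip(path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"
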