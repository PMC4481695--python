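"""Finite-precision arithmetic coding engine and the read-tail codec.

Conceptually the coder maintains an interval [a, b), initially [0, 1); to
code a symbol with probability p and cumulative probability p' it narrows
the interval to

    [a + (b - a) p',  a + (b - a)(p' + p))

and the final message is any number inside the last interval: high-
probability symbols shrink the interval little and therefore cost few bits.
Infinite-precision real arithmetic is of course unavailable, so this
implementation follows the classic 16-bit integer scheme (code values in
[0, 2^16), frequency totals capped at 2^14 - 1): the interval is kept as
integers ``low``/``high``, settled leading bits are emitted as soon as both
bounds agree on them, and near-convergence around the midpoint is handled
by the standard pending-bit (underflow) counter.

The tail codec at the bottom of the module drives one coder instance over
the concatenated tails of all reads, fetching each base's frequency vector
from the context model and updating the model *after* coding the base, so
the decoder — which learns the base only by decoding it — can replay the
identical model evolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .bittree import CorruptArchiveError
from .model import NUCLEOTIDES, ContextModel, decode_kmer, sequence_codes

#: Archive-format constants: classic 16-bit code-value layout.
CODE_VALUE_BITS = 16
TOP_VALUE = (1 << CODE_VALUE_BITS) - 1      # 0xFFFF
FIRST_QTR = (TOP_VALUE >> 2) + 1            # 0x4000
HALF = 2 * FIRST_QTR                        # 0x8000
THIRD_QTR = 3 * FIRST_QTR                   # 0xC000
MAX_FREQUENCY = (1 << 14) - 1               # 0x3FFF

_ASCII = NUCLEOTIDES.encode("ascii")


def subinterval(low: int, high: int, cum_lo: int, cum_hi: int,
                total: int) -> tuple[int, int]:
    """Narrow [low, high] to the symbol's sub-range (before renormalizing).

    This is the integer form of the interval update: the fractions
    ``new_low / 2^16`` and ``(new_high + 1) / 2^16`` approximate
    ``a + (b - a) p'`` and ``a + (b - a)(p' + p)``.
    """
    rng = high - low + 1
    return (low + rng * cum_lo // total,
            low + rng * cum_hi // total - 1)


class ArithmeticEncoder:
    """Streaming arithmetic encoder emitting MSB-first packed bytes."""

    __slots__ = ("low", "high", "pending", "_buf", "_acc", "_nbits",
                 "bits_written", "_finished")

    def __init__(self) -> None:
        self.low = 0
        self.high = TOP_VALUE
        self.pending = 0
        self._buf = bytearray()
        self._acc = 0
        self._nbits = 0
        self.bits_written = 0
        self._finished = False

    def encode_symbol(self, sym: int, freqs: Sequence[int],
                      total: int) -> None:
        """Code ``sym`` (0..3) under integer frequency vector ``freqs``.

        ``total`` must equal ``sum(freqs)`` and be at most
        :data:`MAX_FREQUENCY`; every frequency must be >= 1 (the model's
        pseudocounts guarantee this).
        """
        cum_lo = 0
        for i in range(sym):
            cum_lo += freqs[i]
        cum_hi = cum_lo + freqs[sym]
        if cum_hi == cum_lo:
            raise ValueError("cannot encode a zero-frequency symbol")

        low = self.low
        high = self.high
        rng = high - low + 1
        high = low + rng * cum_hi // total - 1
        low = low + rng * cum_lo // total

        pending = self.pending
        acc = self._acc
        nbits = self._nbits
        buf = self._buf
        nwritten = 0
        while True:
            if high < HALF:
                bit = 0
            elif low >= HALF:
                bit = 1
                low -= HALF
                high -= HALF
            elif low >= FIRST_QTR and high < THIRD_QTR:
                pending += 1
                low -= FIRST_QTR
                high -= FIRST_QTR
                low += low
                high += high + 1
                continue
            else:
                break
            low += low
            high += high + 1
            acc = (acc << 1) | bit
            nbits += 1
            nwritten += 1
            if nbits == 8:
                buf.append(acc)
                acc = 0
                nbits = 0
            if pending:
                opp = bit ^ 1
                nwritten += pending
                while pending:
                    acc = (acc << 1) | opp
                    nbits += 1
                    pending -= 1
                    if nbits == 8:
                        buf.append(acc)
                        acc = 0
                        nbits = 0
        self.low = low
        self.high = high
        self.pending = pending
        self._acc = acc
        self._nbits = nbits
        self.bits_written += nwritten

    def _emit(self, bit: int) -> None:
        self._acc = (self._acc << 1) | bit
        self._nbits += 1
        self.bits_written += 1
        if self._nbits == 8:
            self._buf.append(self._acc)
            self._acc = 0
            self._nbits = 0

    def finish(self) -> bytes:
        """Flush: two disambiguating bits select a number inside the final
        interval; the tail byte is zero-padded."""
        if not self._finished:
            self.pending += 1
            first = 0 if self.low < FIRST_QTR else 1
            self._emit(first)
            while self.pending:
                self._emit(first ^ 1)
                self.pending -= 1
            if self._nbits:
                self._acc <<= 8 - self._nbits
                self._buf.append(self._acc)
                self._acc = 0
                self._nbits = 0
            self._finished = True
        return bytes(self._buf)


class ArithmeticDecoder:
    """Mirror of :class:`ArithmeticEncoder` over a byte string.

    Reads up to ``CODE_VALUE_BITS`` zero bits past the end of the input (the
    encoder's flush leaves that many bits implicit); substantially deeper
    overruns raise :class:`~pathenc.bittree.CorruptArchiveError`.
    """

    __slots__ = ("low", "high", "value", "_data", "_pos", "_nbits",
                 "_overrun", "_slack")

    def __init__(self, data: bytes) -> None:
        self.low = 0
        self.high = TOP_VALUE
        self._data = data
        self._pos = 0
        self._nbits = 8 * len(data)
        self._overrun = 0
        self._slack = CODE_VALUE_BITS + 16
        value = 0
        for _ in range(CODE_VALUE_BITS):
            value = (value << 1) | self._read_bit()
        self.value = value

    def _read_bit(self) -> int:
        pos = self._pos
        if pos >= self._nbits:
            self._overrun += 1
            if self._overrun > self._slack:
                raise CorruptArchiveError("arithmetic-coded stream exhausted")
            return 0
        self._pos = pos + 1
        return (self._data[pos >> 3] >> (7 - (pos & 7))) & 1

    def decode_symbol(self, freqs: Sequence[int], total: int) -> int:
        """Return the symbol the encoder coded under the same frequencies."""
        low = self.low
        high = self.high
        rng = high - low + 1
        target = ((self.value - low + 1) * total - 1) // rng
        if target < 0 or target >= total:
            raise CorruptArchiveError("decoder desynchronized: bad target")

        cum_lo = 0
        sym = 0
        f = freqs[0]
        while cum_lo + f <= target:
            cum_lo += f
            sym += 1
            f = freqs[sym]
        cum_hi = cum_lo + f

        high = low + rng * cum_hi // total - 1
        low = low + rng * cum_lo // total

        value = self.value
        data = self._data
        nbits = self._nbits
        pos = self._pos
        while True:
            if high < HALF:
                pass
            elif low >= HALF:
                value -= HALF
                low -= HALF
                high -= HALF
            elif low >= FIRST_QTR and high < THIRD_QTR:
                value -= FIRST_QTR
                low -= FIRST_QTR
                high -= FIRST_QTR
            else:
                break
            low += low
            high += high + 1
            if pos < nbits:
                value = (value << 1) | ((data[pos >> 3] >> (7 - (pos & 7))) & 1)
                pos += 1
            else:
                self._overrun += 1
                if self._overrun > self._slack:
                    raise CorruptArchiveError(
                        "arithmetic-coded stream exhausted")
                value += value
        self.low = low
        self.high = high
        self.value = value
        self._pos = pos
        return sym


# Spec-style functional aliases over the class engine.
def ac_encode_symbol(encoder: ArithmeticEncoder, sym: int,
                     freqs: Sequence[int], total: int) -> None:
    encoder.encode_symbol(sym, freqs, total)


def ac_decode_symbol(decoder: ArithmeticDecoder, freqs: Sequence[int],
                     total: int) -> int:
    return decoder.decode_symbol(freqs, total)


# -- read-tail codec -----------------------------------------------------

@dataclass
class TailStats:
    """Bookkeeping from one tail-coding pass.

    ``cross_entropy`` is the ideal code length -sum log2 p over the coded
    symbols under the exact integer distributions the coder used; the real
    output can only exceed it by the finite-precision overhead.
    """
    symbols: int = 0
    bits_written: int = 0
    cap_events: int = 0
    cross_entropy: float = 0.0
    #: per-read ideal cost (-sum log2 p), filled when stats are collected
    per_read_cost: list[float] = field(default_factory=list)


def encode_tails(reads: Sequence[str], model: ContextModel, *,
                 collect_stats: bool = False) -> tuple[bytes, TailStats]:
    """Arithmetic-code the tails of ``reads`` (in final archive order).

    For each read, positions k..len-1 are coded left to right: the context
    is the previous k bases, the frequency vector comes from the model
    (default distribution for unknown contexts), and the model observes the
    base after it is coded.  One coder instance spans all tails; read
    boundaries are carried by length metadata, not by the stream.  Reads of
    length exactly k contribute no symbols.  Duplicate-collapsed groups
    must be represented by a single read here.
    """
    k = model.k
    mask = (1 << (2 * k)) - 1
    enc = ArithmeticEncoder()
    encode_symbol = enc.encode_symbol
    frequencies = model.frequencies
    observe = model.observe
    stats = TailStats()
    log2 = math.log2

    for seq in reads:
        if len(seq) < k:
            raise ValueError(f"read shorter than k={k}: {seq!r}")
        codes = sequence_codes(seq)
        if 0xFF in codes:
            raise ValueError("read contains non-ACGT characters; "
                             "translate Ns before encoding")
        ctx = 0
        for c in codes[:k]:
            ctx = (ctx << 2) | c
        read_start_h = stats.cross_entropy
        for j in range(k, len(codes)):
            b = codes[j]
            freqs, total, _ = frequencies(ctx)
            encode_symbol(b, freqs, total)
            observe(ctx, b)
            ctx = ((ctx << 2) | b) & mask
            if collect_stats:
                stats.cross_entropy -= log2(freqs[b] / total)
        stats.symbols += len(codes) - k
        if collect_stats:
            stats.per_read_cost.append(stats.cross_entropy - read_start_h)
    payload = enc.finish()
    stats.bits_written = enc.bits_written
    stats.cap_events = model.cap_events
    return payload, stats


def decode_tails(stream: bytes, head_groups: Sequence[tuple[int, int]],
                 model: ContextModel, lengths: Sequence[int]
                 ) -> list[str]:
    """Inverse of :func:`encode_tails`.

    ``head_groups`` is the DFS-ordered list of (head k-mer, count) pairs; a
    negative count -d means one coded tail re-expanded to d identical
    reads.  ``lengths`` gives the total read length for every final read
    (duplicates included).  The model must be in the identical initial
    state as the encoder's (same reference, flags, k, weight).
    """
    k = model.k
    mask = (1 << (2 * k)) - 1
    dec = ArithmeticDecoder(stream)
    decode_symbol = dec.decode_symbol
    frequencies = model.frequencies
    observe = model.observe
    out: list[str] = []
    li = 0

    for head, count in head_groups:
        n_copies, n_decodes = (-count, 1) if count < 0 else (1, count)
        for _ in range(n_decodes):
            length = lengths[li]
            li += n_copies
            buf = bytearray(length)
            head_str = decode_kmer(head, k)
            buf[:k] = head_str.encode("ascii")
            ctx = head
            for j in range(k, length):
                freqs, total, _ = frequencies(ctx)
                b = decode_symbol(freqs, total)
                observe(ctx, b)
                buf[j] = _ASCII[b]
                ctx = ((ctx << 2) | b) & mask
            seq = buf.decode("ascii")
            out.extend([seq] * n_copies)
    if li != len(lengths):
        raise CorruptArchiveError("length metadata does not match head counts")
    return out
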