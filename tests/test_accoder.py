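"""Arithmetic coder correctness, entropy behavior, and the tail codec."""

import math
import random

import pytest

from pathenc.accoder import (MAX_FREQUENCY, TOP_VALUE, ArithmeticDecoder,
                             ArithmeticEncoder, decode_tails, encode_tails,
                             subinterval)
from pathenc.bittree import CorruptArchiveError
from pathenc.model import ContextModel, encode_kmer, prime_from_reference


class TestInterval:
    def test_uniform_third_symbol_selects_third_quarter(self):
        # freqs (1,1,1,1), symbol index 2: conceptual interval [0.50, 0.75)
        low, high = subinterval(0, TOP_VALUE, 2, 3, 4)
        assert low / (TOP_VALUE + 1) == 0.5
        assert (high + 1) / (TOP_VALUE + 1) == 0.75

    def test_zero_frequency_symbol_rejected(self):
        enc = ArithmeticEncoder()
        with pytest.raises(ValueError):
            enc.encode_symbol(1, (2, 0, 1, 1), 4)


class TestEntropy:
    def test_uniform_symbols_cost_two_bits_each(self):
        n = 5000
        enc = ArithmeticEncoder()
        for _ in range(n):
            enc.encode_symbol(0, (1, 1, 1, 1), 4)
        enc.finish()
        assert abs(enc.bits_written - 2 * n) <= 2

    def test_skewed_frequencies_approach_entropy(self):
        enc = ArithmeticEncoder()
        for _ in range(100):
            enc.encode_symbol(0, (20, 1, 1, 1), 23)
        enc.finish()
        ideal = 100 * math.log2(23 / 20)  # ~20.16 bits
        assert abs(enc.bits_written - ideal) <= 2


class TestRoundTrip:
    def test_random_symbols_with_evolving_tables(self):
        """decode . encode = identity over 10^5 symbols whose frequency
        tables change (identically on both sides) as coding proceeds."""
        rng = random.Random(31)
        n = 100_000
        freqs = [5, 1, 7, 3]
        syms = []
        enc = ArithmeticEncoder()
        table_rng = random.Random(77)
        for _ in range(n):
            s = rng.randrange(4)
            syms.append(s)
            enc.encode_symbol(s, freqs, sum(freqs))
            freqs[table_rng.randrange(4)] += table_rng.randrange(3)
            if sum(freqs) > MAX_FREQUENCY:
                freqs = [max(1, f >> 1) for f in freqs]
        data = enc.finish()

        dec = ArithmeticDecoder(data)
        freqs = [5, 1, 7, 3]
        table_rng = random.Random(77)
        for i in range(n):
            assert dec.decode_symbol(freqs, sum(freqs)) == syms[i]
            freqs[table_rng.randrange(4)] += table_rng.randrange(3)
            if sum(freqs) > MAX_FREQUENCY:
                freqs = [max(1, f >> 1) for f in freqs]

    def test_single_symbol_message(self):
        enc = ArithmeticEncoder()
        enc.encode_symbol(3, (1, 1, 1, 5), 8)
        data = enc.finish()
        assert ArithmeticDecoder(data).decode_symbol((1, 1, 1, 5), 8) == 3

    def test_adversarial_skew_near_frequency_cap(self):
        freqs = (MAX_FREQUENCY - 3, 1, 1, 1)
        syms = [0] * 60 + [1, 2, 3] * 20 + [0] * 60
        enc = ArithmeticEncoder()
        for s in syms:
            enc.encode_symbol(s, freqs, MAX_FREQUENCY)
        data = enc.finish()
        dec = ArithmeticDecoder(data)
        assert [dec.decode_symbol(freqs, MAX_FREQUENCY)
                for _ in syms] == syms

    def test_lockstep_states_identical(self):
        """Encoder and decoder interval bounds agree after every symbol."""
        rng = random.Random(5)
        freqs = (3, 9, 1, 4)
        syms = [rng.randrange(4) for _ in range(500)]
        enc = ArithmeticEncoder()
        enc_states = []
        for s in syms:
            enc.encode_symbol(s, freqs, 17)
            enc_states.append((enc.low, enc.high))
        data = enc.finish()
        dec = ArithmeticDecoder(data)
        for i, s in enumerate(syms):
            assert dec.decode_symbol(freqs, 17) == s
            assert (dec.low, dec.high) == enc_states[i]

    def test_exhausted_stream_detected(self):
        enc = ArithmeticEncoder()
        rng = random.Random(1)
        syms = [rng.randrange(4) for _ in range(5000)]
        for s in syms:
            enc.encode_symbol(s, (1, 1, 1, 1), 4)
        data = enc.finish()
        dec = ArithmeticDecoder(data[: len(data) // 4])
        with pytest.raises(CorruptArchiveError):
            for _ in syms:
                dec.decode_symbol((1, 1, 1, 1), 4)


class TestTailCodec:
    def test_read_of_length_k_contributes_no_symbols(self):
        model = ContextModel(4)
        payload, stats = encode_tails(["ACGT"], model)
        assert stats.symbols == 0
        assert len(payload) <= 1  # just the coder flush

    def test_roundtrip_with_and_without_reference(self):
        rng = random.Random(13)
        ref = ["".join(rng.choice("ACGT") for _ in range(500))]
        reads = sorted(
            ref[0][p:p + 40] for p in rng.sample(range(450), 30))
        for primed in (True, False):
            for dynamic in (True, False):
                make = (lambda: prime_from_reference(ref, 8,
                                                     dynamic=dynamic)
                        ) if primed else (
                        lambda: ContextModel(8, dynamic=dynamic))
                payload, _ = encode_tails(reads, make())
                groups = [(encode_kmer(r[:8]), 1) for r in reads]
                decoded = decode_tails(payload, groups, make(),
                                       [len(r) for r in reads])
                assert decoded == reads

    def test_reference_reads_beat_two_bits_and_match_cross_entropy(self):
        """Error-free reads drawn from the primed reference, static model:
        cost well below 2 bits/base and close to the model cross-entropy."""
        rng = random.Random(23)
        ref = ["".join(rng.choice("ACGT") for _ in range(2000))]
        reads = sorted(ref[0][p:p + 60]
                       for p in rng.sample(range(1900), 100))
        model = prime_from_reference(ref, 10, dynamic=False)
        payload, stats = encode_tails(reads, model, collect_stats=True)
        bits_per_base = stats.bits_written / stats.symbols
        assert bits_per_base < 2.0
        assert abs(bits_per_base
                   - stats.cross_entropy / stats.symbols) < 0.2

    def test_coded_length_bounded_by_cross_entropy_oracle(self):
        rng = random.Random(41)
        ref = ["".join(rng.choice("ACGT") for _ in range(800))]
        reads = sorted({ref[0][p:p + 50] for p in
                        rng.sample(range(700), 60)})
        for model in (prime_from_reference(ref, 8), ContextModel(8)):
            payload, stats = encode_tails(reads, model, collect_stats=True)
            assert stats.bits_written <= (stats.cross_entropy + 32
                                          + 2 * stats.cap_events)

    def test_repeated_read_cost_non_increasing(self):
        """With dynamic updates on, each repetition of the same read gets
        cheaper (or equal) after the model has absorbed it twice."""
        rng = random.Random(3)
        read = "".join(rng.choice("ACGT") for _ in range(80))
        model = ContextModel(8)
        _, stats = encode_tails([read] * 100, model, collect_stats=True)
        costs = stats.per_read_cost
        for i in range(2, 99):
            assert costs[i + 1] <= costs[i] + 1e-9
        assert costs[99] < costs[0]

    def test_duplicate_groups_reexpanded(self):
        reads = ["ACGTACGTAA"]
        model = ContextModel(4)
        payload, _ = encode_tails(reads, model)
        decoded = decode_tails(payload, [(encode_kmer("ACGT"), -3)],
                               ContextModel(4), [10, 10, 10])
        assert decoded == reads * 3
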