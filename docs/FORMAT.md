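# Archive format (version 1)

All multi-byte integers are big-endian. One archive is a single file:

    magic   4 bytes   "PTHE"
    version 1 byte    0x01
    hlen    4 bytes   header length
    header  hlen      JSON (ASCII)
    then, repeated until EOF:
      nlen    1 byte    stream-name length
      name    nlen      stream name (ASCII)
      plen    8 bytes   payload length
      payload plen

## Header fields

| field | meaning |
|---|---|
| `k` | context/head length used at encode time (decode ignores CLI k) |
| `weight` | observation weight of the count rule |
| `flags.reference` | model was primed from a reference |
| `flags.dynamic` | online model updates enabled |
| `flags.rc` | reverse-complement heuristic was applied |
| `flags.dedup` | duplicate buckets collapsed |
| `flags.orientation` | flip bits stored (`flip.gz` present) |
| `flags.paired` / `flags.pair_same_strand` | pair merging convention |
| `read_count` | number of final reads (merged pairs count once) |
| `uniform_length` | read length when uniform, else null (`lengths.gz`) |
| `uniform_split` | mate-1 length when uniform, else null (`split.gz`) |
| `ref_checksum` | 64-bit digest of the reference (k+1)-mer multiset |
| `streams` | names of the payload streams that must be present |

## Streams

* `heads.bt.gz` — gzip of: 4-byte k-mer-set cardinality, then the trie
  bit stream packed MSB-first, zero-padded to a byte.
* `heads.cnt.gz` — gzip of space-separated ASCII head counts in DFS
  order; negative `-d` marks a collapsed duplicate bucket.
* `tails.ac` — raw arithmetic-coded tail bytes (not gzipped; the coder
  output is incompressible).
* `flip.gz` — gzip of per-read flip bits, MSB-first packed, final read
  order.
* `nloc.gz` — gzip of ASCII tokens, per read: count, then delta-encoded
  N offsets. Present only when any read contained a non-ACGT character.
* `lengths.gz`, `split.gz` — gzip of space-separated ASCII integers, one
  per final read.

## Bit-exact constants

* Nucleotide order everywhere (trie children, coder cumulative
  distributions, head sort): **A, C, G, T**.
* Arithmetic coder: 16-bit code values (`TOP = 0xFFFF`, quarter
  boundaries 0x4000/0x8000/0xC000), maximum frequency total `0x3FFF`,
  flush = one bit plus pending opposites, decoder primed with 16 bits.
* Frequency capping: while a context's total exceeds `0x3FFF`, halve all
  four counts with floor 1.
* Count cells: 8-bit saturating at 255 with an exact overflow side table.
* Reference checksum: sum mod 2^64 of splitmix64(edge ^ (k << 56)) over
  every (k+1)-mer window (multiset, order-independent).
* gzip streams are written with `mtime=0` for reproducible bytes.
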