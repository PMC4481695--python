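# Methods

## The generative model

A collection of reads over {A,C,G,T} is modelled by an order-k Markov
chain whose states are k-mers — equivalently, a de Bruijn graph G with a
node per k-mer and an edge (u, v) whenever v can follow u with a k−1
overlap. Compressing a read tail is then encoding a path in G: at each
position the current context u supplies a conditional distribution
p_u(·) over the next base, and the base is arithmetic-coded under it.

Counts behind p_u are deliberately error-robust. An edge contributes its
full weight only if it occurs in the reference or has been observed at
least twice in the reads coded so far:

    c_u(v) = w·(n_uv + 2)  if (u,v) occurs in the reference
           = w·n_uv        if n_uv ≥ 2 and (u,v) ∉ reference
           = 1             otherwise,          p_u(v) = c_u(v) / Σ_w c_u(w)

with weight w = 10 by default. A single observation — the typical
signature of a sequencing error — never rises above the pseudocount
floor, so errors do not distort the model, while reference edges start as
if already seen twice. Contexts absent from the table entirely (neither
reference nor previously observed) are coded under a separate default
distribution c0(b), itself adaptive: it counts how often each base has
been coded through the fallback path, starting from a uniform prior of 1.

Model updates happen immediately **after** each base is coded, on both
sides: the decoder learns the base only by decoding it, so post-symbol
update is the only schedule that keeps encoder and decoder bit-identical
with zero side information. The first time a context is seen it is
inserted with zero counts (the base it emitted is credited to c0); from
the second time on the count rule above applies. With `--static-model`
updates are disabled entirely and the model stays at its primed state —
coding remains lossless, only less effective.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 16 | context length and head length, 1–30. Larger k predicts better but grows the head trie and lets one error corrupt k subsequent contexts; 16 also packs a k-mer into 32 bits. |
| weight | 10 | multiplier of trusted observations vs the pseudocount 1. Compression is insensitive to it within a reasonable range; it is exposed as a knob. |
| dynamic | on | online model updates (the adaptivity ablation switch). |
| rc | on | reverse-complement heuristic (below). |
| dedup | on | duplicate-bucket collapsing (below). |

## Pipeline

1. **N translation.** Every non-ACGT character becomes an A; its offset is
   recorded and restored on decode. This keeps the coder's alphabet at
   exactly four symbols.
2. **Pair merging.** Paired-end mates are merged into one longer read
   (mate 2 reverse-complemented unless `--pair-same-strand`), because
   reordering by head would otherwise separate pairs. The mate-1 length is
   kept (header constant when uniform, else a sidecar stream) so decode
   re-splits exactly. Merging precedes the flip decision, so one flip bit
   covers the merged read — flipping mates independently would both
   double the orientation metadata and fight the mate-2 strand convention.
3. **Reverse-complement heuristic.** The reference primes only the forward
   strand, but unstranded protocols read either strand. For each read the
   number of context→base transitions known to the *initial* model is
   counted for the read and for its reverse complement; if the reverse
   complement scores strictly higher the read is flipped (ties keep the
   input orientation, so with no reference nothing ever flips). All
   decisions are made before any coding, so the decoder never needs to
   repeat them; original orientations are recoverable only when
   `--store-orientation` records the per-read flip bits.
4. **Grouping and duplicate collapsing.** Reads are bucketed by head and
   buckets emitted in trie DFS (= lexicographic) order; within a bucket
   input order is kept. A bucket whose d ≥ 2 members are all the identical
   sequence is stored as one tail with head count −d. The test is
   deliberately bucket-wide and exact — a cheap check that collapses
   pooled technical replicates without a general duplicate search.
5. **Head serialization.** The distinct heads go into the bit tree; the
   traversal is simulated over the sorted k-mer list, so the trie is never
   materialized. The packed stream is gzipped and carries a 4-byte
   cardinality prefix as an integrity check.
6. **Tail coding.** One arithmetic coder instance spans all tails in final
   read order; read boundaries come from the length metadata (a single
   header value for uniform-length corpora), never from the stream, and
   there is no in-band EOF symbol.

## Numerical choices

The coder is the classic 16-bit integer implementation: code values in
[0, 2^16), frequency totals capped at 2^14 − 1, midpoint-straddling
intervals handled with a pending-bit counter, flush emits the two
standard disambiguation bits. Integer counts feed the coder directly as
frequencies; when a context's total would exceed the cap, all four counts
are halved (flooring at 1) until it fits — deterministic, hence mirrored
exactly on decode. Per-base observation counters live in 8-bit cells; a
counter reaching 255 spills to an exact side table, so bounded storage
never loses information. The decoder tolerates reading a flush-word's
worth of implicit zero bits past the end of the stream; deeper overruns
raise a corrupt-archive error, as do bit-tree underruns, count-length
mismatches and head/read-count disagreements. A 64-bit order-independent
digest of the reference's (k+1)-mer multiset is stored in the header and
checked before decoding, so a wrong reference fails fast instead of
producing garbage. The nucleotide order A, C, G, T is a single
archive-format constant used by the trie, the coder's cumulative
distributions and the head sort alike.

## What the simulator does and does not emulate

`fixtures` generates transcriptomes with i.i.d. uniform bases and reads
with uniform start positions, i.i.d. substitution errors and N calls,
exact duplicates, antisense reads and fr-oriented mate pairs, all
deterministic under a seed and each read's provenance recorded in a truth
table. Uniform bases keep information content analytic (2 bits per novel
base), which the entropy tests rely on; an optional shared repeat block
creates high-count k-mers to exercise the counter-overflow path.

It does **not** emulate abundance-weighted expression, base-composition
bias, position-dependent error profiles, indels or quality strings.
Passing tests therefore demonstrate correctness (losslessness holds for
arbitrary sequences) and the *direction and rough magnitude* of each
feature's compression benefit, not the exact ratios achievable on real
RNA-seq, where repeat structure and skewed coverage change the constants.
Test and benchmark corpora are scaled to desk size (10^4–10^5 reads from
10^5-base transcriptomes) so the full suite runs in minutes on one CPU.

## Known limitations

* Read names and quality values are not stored (decode emits sequential
  numeric FASTA headers); quality streams are a separate problem with
  dedicated tools.
* No random access into an archive: arithmetic coding makes every symbol
  depend on its predecessors. Decoding is streaming, start to finish.
* Without `--store-orientation`, flipped reads decode in their flipped
  orientation — intentional for unstranded data, wrong for stranded
  libraries (use the flag there).
* The reference is primed forward-strand only; SNP- or error-model-
  augmented priming and within-bucket tail sorting are possible
  extensions, not implemented.
* Mates of unequal length are supported via the per-read split stream;
  archives of wildly mixed read lengths pay for an explicit length stream.
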