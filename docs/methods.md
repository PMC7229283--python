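# Methods

`polishnet` corrects (polishes) a noisy draft assembly of a genome using the
error-prone long reads it was assembled from, and optionally produces a phased
diploid consensus. This note records the model, the simulator it is validated
against, the numerical choices, and what a green test does and does not
establish.

## The consensus model

Reads are aligned to the draft and stacked into a pileup. Per draft position
`i` and strand, the pileup records counts of A/C/G/T and gap (read deletes the
draft base), and per inter-position slot `i` (between `i` and `i+1`) the
number of reads carrying an insertion there, the identity of the first
inserted base, and the total inserted length (a mean-length accumulator).
Keeping the two strands separate preserves strand-bias information; counts are
divided by the spanning-read depth so features are coverage-invariant, with a
capped depth scalar (`min(depth, 100)/100`) carrying absolute coverage.

Each position is encoded as the concatenation of the feature vectors of a
**3-column window** (`i-1, i, i+1`; out-of-range columns are zero). The
window is the core representational choice: evidence for an error rarely sits
in a single column — alignment wobble around indels and homopolymers spreads
it over neighbours — and a per-position encoding destroys that spatial
relationship.

The network is deliberately small: a **single bidirectional GRU layer, 64
units per direction** (~51k parameters), over the window tensors, with three
softmax heads sharing the trunk:

* **phase 1** (5 classes): the corrected base A/C/G/T at this draft position,
  or DEL — the draft base has no counterpart in the underlying genome and is
  dropped;
* **phase 2** (2 x 5 classes): up to two bases *missing* from the draft
  immediately after this position (none/A/C/G/T each). This is the
  base-recovery phase that targets the deletion-dominant error profile of
  nanopore data.

No deep-learning framework is assumed at run time; the GRU forward pass,
backpropagation through time and Adam live in `polishnet.nn` (numpy).

### Decoding

Per position, emit the phase-1 argmax unless DEL; then recover slot bases.
A recovered base is emitted when the head's posterior mass of "some base"
exceeds the mass of "no base" (P(none) < 1/2), with identity the argmax over
A..T; the second base is considered only when the first was emitted. The
existence/identity split matters: the identity of the *second* missing base
has no direct pileup feature, so a pure 5-way argmax abstains almost always.
Emitting a best-guess base costs the same as omitting it in one round
(one error either way) but converts an invisible deletion into an ordinary
mismatch column that the next polish iteration fixes from read evidence.

### Training

Labels come from an **alignment** of the draft to the truth (same aligner as
read mapping), not from the simulator's generative corruption script: the
position of an indel inside a repeat is a convention of the aligner, and
labels must share it or they are unlearnable at exactly those positions
(switching conventions moved the per-position Bayes ceiling on our benchmark
from ~0.979 to ~0.996). Truth bases falling between draft-aligned positions
become phase-2 labels on the left slot; runs longer than 2 are truncated and
counted.

Cross-entropy is summed over the three heads; Adam (lr 2e-3, gradient norm
clip 5), batches of 8 chunks of 250 positions (BPTT window). Training is
two-stage within the epoch budget: the second half of the epochs continues on
a mixture including tensors from a once-polished draft, so iteration 2+ of
the polish loop sees in-distribution inputs rather than only 88%-identity
drafts. Inference is chunked (1000 positions, 50 overlap, center-keep
stitching) so memory is bounded and seams are testable.

### Iterative polishing

`polish(draft, reads, model, k)` repeats: pileup -> window tensors -> predict
-> decode; between iterations reads are re-aligned to the new consensus
(minimap2 when on PATH, otherwise the internal banded aligner anchored
through the decode's draft-to-output coordinate map). Iteration matters for
deletions longer than the 2-base phase-2 capacity: each round recovers up to
two bases per site, so a 5-base deletion resolves over 2-3 rounds.

## Diploid mode

Heterozygous candidate sites are pileup positions where the two most frequent
symbols each reach 25% of depth (depth >= 10). Reads are partitioned by a
greedy seeded 2-coloring over SNV sites (indel sites are excluded as
indel-noise dominated): reads vote with their observed alleles against
running per-haplotype profiles, join the better-agreeing haplotype
(>= 2 informative sites, agreement >= 0.6), and otherwise stay UNASSIGNED.
UNASSIGNED reads contribute to *both* per-haplotype pileups so homozygous
regions never fall below haploid coverage. Haplotype labels are exchangeable;
every metric is computed label-swap invariantly (the consensus/truth pairing
maximizes total matches). An externally produced read->haplotype table (e.g.
from WhatsHap) can be substituted for the built-in phaser.

Accuracy statistics follow the haploid/diploid comparison convention: `Lh`,
`Ah` are the aligned length and accuracy of the haploid consensus (scored
against the closer truth haplotype); the diploid aligned length `Ld` is the
arithmetic mean of the two per-haplotype aligned lengths and `Ad` pools
matches over both. Treating aligned columns as independent Bernoulli trials,
`p_hat = (Lh*Ah + Ld*Ad)/(Lh + Ld)`,
`z = (Ad - Ah)/sqrt(p_hat(1-p_hat)(1/Lh + 1/Ld))`, with a **one-sided**
p-value in the observed direction (`Phi(-|z|)`); degenerate pooled
proportions give `z = 0, p = 0.5`. The one-sided convention was chosen
because it reproduces the published contig example (6/160 vs 7/159 ->
p ~ 0.38-0.40) far better than the two-sided tail (~0.77).

## The simulator (the stated world)

* **Reads**: at each template base an insertion event (p = 0.0248), a
  deletion event (p = 0.0574) and a substitution (p = 0.03) are drawn
  independently; indel event lengths are geometric(0.7) capped at 5; bases
  consumed by a deletion event receive no further draws. Inside homopolymer
  runs >= 3 the deletion probability is doubled. Read lengths are lognormal
  (sigma 0.5) around the requested mean (default 5 kb), rejected below 50 bp;
  raw start positions may be negative so contig edges get full coverage;
  strands are fair coins, minus reads stored reverse-complemented with the
  truth edit script on the forward template.
* **Draft**: the same error machinery with a global rate multiplier,
  calibrated by bisection on the script-implied identity and refined (<= 3
  secant steps) against the alignment identity, to hit a target identity
  (default 0.8865, the miniasm-like operating point).
* **Diploid**: phased heterozygous SNVs and short indels applied to exactly
  one of two haplotypes, rejection-resolved to a sorted non-overlapping set.

What it does **not** emulate: base-quality signal, chimeric/split reads,
coverage biases, long repeats or structural variation, and real nanopore
systematic error beyond the homopolymer deletion boost. A green benchmark
therefore establishes that the method recovers a deletion-dominant error
process at realistic rates and coverage — not performance on real flowcell
data.

## Numerical choices

* **Banded aligner**: global affine Needleman-Wunsch (match +2, mismatch -4,
  gap open -4, extend -2; default band 15% of the longer length) restricted
  to a band around the straight corner-to-corner diagonal, which absorbs the
  net length difference; the inner sweep is numba-compiled; integer scores
  make comparisons and traceback exact. A band-overflow error is raised when
  the corners cannot connect; paths pinned against the band edge are flagged
  and `evaluate.identity` doubles the band (up to 3 retries) starting from
  `max(128, 3*sqrt(n))`.
* **Identity** = matches / aligned columns (matches + mismatches + inserted
  + deleted) of the optimal in-band alignment — an internal, dependency-free
  stand-in for QUAST-style identity.
* **Ties** break deterministically everywhere (symbol order A<C<G<T<gap;
  state preference M>X>Y in the aligner).
* **Determinism**: fixed seeds make simulation, initialization, training and
  inference reproducible within a platform under single-threaded execution.
* **Degenerate inputs**: zero-depth positions pass the draft base through
  (no evidence -> no edit); empty pileups and empty sequences raise.

## Known limitations

* Phase-2 capacity is 2 bases per slot; longer deletion runs are truncated in
  the labels (counted) and need extra polish iterations.
* The identity of a second recovered base is inferred from context only;
  first-pass output can carry placeholder bases at such sites (by design —
  see Decoding).
* The greedy phaser has no likelihood model and no switch-error optimization;
  it stands in for a dedicated read-backed phaser and is the first thing to
  replace for real diploid data.
* Multi-contig assemblies are handled contig by contig with a single best
  alignment per contig; there is no chaining or misassembly detection.
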