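# Methods

This note documents the models, rules and numerical choices behind
`ypanel`, and what the synthetic-data generator does and does not emulate.

## Panel model

A Y-STR locus is described by two exact 15-bp anchor sequences, reference
prefix/suffix flanks, and an ordered list of repeat blocks.  Blocks are
variable repeats (`MOTIF[min-max:ref]`, unit length 2–6 bp, at least three
homogeneous repetitions in the reference — the standard inclusion rule for
counting a stretch as a repeat), fixed repeats (`MOTIF[k]`) or fixed
interruptions (`N[k]:SEQ`).  Only variable blocks contribute to the allele
call.  A locus carries 1, 2 or 4 copies; copies of most multi-copy loci
(chrY palindromes) are indistinguishable by flanking sequence and are
reported as sorted allele vectors.  Repeat types: *simple* (one block),
*compound* (adjacent blocks), *complex* (interrupted).

Y-SNP positions files are filtered before use: SNPs flagged as lying in
amplicon primer regions, with equal or unknown mutations (`T->N`), indels
and poly-allelic records are excluded and counted by reason; records that
share a coordinate with identical alleles are merged as aliases (the first
name is canonical).  The exclusion report's format is ours — reference
positions files run to hundreds of thousands of SNPs and publish no
per-filter tallies.

The haplogroup tree is derived from lineage-label prefixes (`R` → `R1` →
`R1a` …): a node's parent is its longest proper-prefix label present in
the set, main-letter haplogroups sit at depth 1 under an implicit root
`Y`.  An explicit parent table can override this when a machine-readable
tree exists.  Branch depth equals the number of letter/number alternations
when the label set is prefix-closed.

## STR calling

**Tabulation.** A read is assigned to a locus iff its first 15 bp match
the 5′ anchor or the reverse-complemented 3′ anchor within
`min_anchor_match` mismatches (default 1 per 15 bp — tolerant to a
realistic per-base error rate without cross-locus capture), and the far
anchor is found in the read.  Unique between-anchor sequences are counted
per read end and strand.

**Decomposition.** Greedy left-to-right block matching with variable
blocks maximal, implemented with backtracking.  Flank lengths may deviate
from the reference by at most ±3 bp (the tolerance is configurable; no
published value exists for "too long or too short"), and the flank must
agree with the reference over its overlap (mismatch fraction ≤ 0.5) so
that repeat units cannot masquerade as flank — the signature of primer
homology on another chromosome.  Among admissible parses the one with
flank lengths closest to the reference wins, then the longer leading
repeat; this makes the parse of error-free in-structure sequences unique
and round-trip exact.  Flank substitutions are reported as isoallele
variants.  Failures carry a reason (`flank_too_short`, `flank_too_long`,
`block_missing`).

**Stutter filter.** Replication slippage mostly loses one repeat unit, so
a candidate 1 (or 2) repeats below a better-supported candidate is flagged
when its depth is below `threshold × parent depth`.  Defaults by shortest
variable motif: dinucleotide 0.50, tri 0.15, tetra 0.15, penta/hexa 0.10,
halved at n−2.  The thresholds are deliberately permissive for
dinucleotides, whose stutter ladders are tallest; the top-depth candidate
is never flagged, so a genuine second allele of a multi-copy locus one or
two repeats away survives whenever its depth is comparable.  No published
stutter ratios exist for this chemistry; the values are design choices
exposed in the API.

**Calling.** Candidates are examined in descending depth; only the top
`4 × copy_count` are validated by decomposition.  No valid candidate, or
fewer than `min_reads` (default 10) total reads, yields `no_data` — a
value, not an error.  When fewer distinct sequences survive than the locus
has copies (identical alleles on two copies collapse into one sequence at
double depth), copies are apportioned to survivors proportionally to
depth.  Calls are reported sorted ascending.

**Paired-end consensus.** Equal single-end calls agree; on disagreement
the end whose repeat region starts fewer bases from its own anchor is
selected (per-cycle error accumulation), with higher depth breaking offset
ties and R1 breaking exact ties.  "Offset" is interpreted as the observed
repeat-start offset (prefix length for R1, suffix length for R2).

## SNP calling and assignment

Bases below Q20 are excluded from the pileup; a call requires depth ≥ 10
and a ≥ 90% majority among quality-passing bases, and the majority base
must be the ancestral or derived allele.  These thresholds are monotone:
raising either can only turn calls into no-calls.

The terminal haplogroup is the deepest node with ≥ 1 derived call whose
root path contains no contradicted node; a node is contradicted when its
ancestral calls outnumber its derived calls (majority-with-depth
preference — the conflict rule is ours and configurable in spirit: real
pipelines delegate it to the haplogroup caller unspecified).  Ties prefer
more supporting derived SNPs, then the smaller label.  SNPs with unknown
phylogenetic position are reported but never steer the assignment.
All-ancestral samples are reported unresolved at the root.

Because the positions file carries no sequence, each SNP's amplicon
context is a deterministic synthetic surrogate derived from its hg19
coordinate; simulator and pileup share it, standing in for the reference
genome.

## Mutation-rate estimation

Per pair and locus, calls in both samples are compared; `no_data` in
either sample removes that locus from the pair's meiosis denominator
(which is why per-locus meiosis totals fluctuate in real studies).
Multi-copy vectors are matched by the assignment minimising total repeat
steps (exhaustive over ≤ 4! assignments; ties prefer fewer events, then a
fixed order).  Compound/complex loci are compared per variable motif, so
two parallel one-step mutations that cancel in the summed allele call are
still detected — the case hidden from CE fragment sizing.

Each non-zero per-motif, per-copy difference is one event of its step
size.  The event count brackets the true mutation number: one- and
two-step events count as single mutations at both ends of the bracket,
while an event of size *s* ≥ 3 counts 1 at the lower end and *s* at the
upper (it may hide up to *s* one-step mutations).  The midpoint is the
rate numerator.  The bracket midpoint may be fractional; it is rounded
half-up to an integer for the exact CI only, never for the point rate.

Per-locus 95% CIs are Clopper–Pearson (beta quantiles).  The panel-wide
aggregate is reported with both a normal-approximation interval (the
convention for aggregate rates in the genealogy literature) and the exact
one, labeled.  Classification uses the unrounded rate: slow < 10⁻³ ≤
moderate < 5·10⁻³ ≤ fast < 10⁻² ≤ rapid, with zero-difference loci
reported separately as non-mutating; boundary values land in the higher
class.

Literature comparison is a one-degree-of-freedom chi-square
goodness-of-fit of (events, non-events) against the expectation under the
reference rate, flagged at α = 0.05; for small expected counts it is an
approximation to the exact binomial test (the tests agree in direction
and, at study-scale counts, closely in p-value).

Individualization: `P(≥1 difference) = 1 − Π (1−rᵢ)^g`, assuming
independent loci and per-meiosis, per-locus Bernoulli mutation.  Under a
uniform rate this is `1 − (1−r)^(L·g)`.  The kinship-verification
threshold `max_allowed_differences` is the smallest k with
`P(total ≤ k) ≥ quantile` under independent per-locus Binomial(g, rᵢ)
counts, evaluated exactly by PMF convolution (Poisson–binomial at g = 1).
Note the model deliberately ignores back/parallel-mutation cancellation
across generations, so for large g it slightly overstates observable
differences.

## The simulator

The generator emulates the assay the callers target: paired 2 × 300 bp
amplicon reads over anchored STR and SNP targets.

* **Pedigrees.** Chains of father-to-son transmissions; per meiosis each
  locus copy mutates with its per-meiosis rate (locus-level probability
  rate × copies).  Step sizes follow the one-step-dominated mix observed
  in genealogical data (P(1) = 0.83, P(2) = 0.11, geometric tail beyond),
  direction ± with equal probability, reflected then clamped at the
  block's allele range — biological allele ranges are bounded.  Within a
  copy the mutating block is chosen proportionally to its current repeat
  count (longer stretches slip more).  The planted-truth record is exact:
  replaying the mutation list from the founder reproduces every
  generation's genotype.
* **Reads.** Per locus copy, the amplicon
  `anchor5 + prefix + repeats + suffix + anchor3` is emitted at
  negative-binomial depth (mean 150 reads — a realistic per-locus
  average for this panel class — dispersion k = 4, matching the wide
  per-locus spread seen in practice; k = 0 selects deterministic depth
  for noise-free tests).  Stutter products at n−1 (and n−2, and
  optionally n+1) of each variable block are emitted at binomial
  fractions of the parent depth: dinucleotide 0.30, tri 0.12, tetra
  0.10, penta/hexa 0.05, decay 0.3 for n−2.  Per-base substitution errors
  (default 0.5%) apply independently per read; qualities are constant
  Phred 35 (the pipeline's only quality use is the SNP Q20 filter).  An
  optional degradation factor decays expected depth per 100 bp of
  amplicon length.  SNP amplicons (mean depth 717, the panel-class
  average for SNP targets) carry the derived base for SNPs on the
  sample's planted haplogroup path.  Female (no-chrY) mode emits only
  off-target random reads.
* **Determinism.** Every draw flows from the config seed; identical seeds
  give byte-identical FASTQ.

What the simulator does **not** model: PCR chimeras, index hopping,
contamination and mixtures, quality decay along the read, indel errors,
length-dependent stutter variation within a motif class, and inter-locus
amplification competition.  Green tests therefore demonstrate the
correctness of the calling logic under a faithful but idealized error
model, not performance on degraded casework samples.

## Validation problem sizes

The end-to-end check runs 20 samples over a 30-locus synthetic panel
(≈ 60% simple, 20% compound, 20% complex loci; 20% multi-copy) and a
24-node haplogroup tree, at the panel design depth of 150 reads per
target with error-free bases and full stutter ladders — the regime where
recovery should be near-perfect, so residual misses isolate depth
sampling (the negative-binomial low tail under the 10-read threshold)
rather than caller defects.  Parsimony matching is verified against
factorial enumeration on 1,000 random vectors, decomposition round-trips
10,000 random in-structure sequences, and Clopper–Pearson coverage of a
planted rate (900 meioses at 4.57·10⁻³ mpg, conditions where the exact
interval's conservatism is mildest) is measured over 1,000 replicates.

## Known limitations

* Distinguishable multi-copy loci are modeled as separate single-copy
  loci; the panel model carries the flag but the caller does not use
  flanking differences to split copies.
* The stutter filter is threshold-based, not a learned noise model; very
  unbalanced multi-copy allele pairs (depth ratio beyond the dinucleotide
  threshold) can lose the minor allele.
* Haplogroup conflict resolution is majority-per-node along the path;
  recurrent/homoplastic SNPs are not modeled.
* The 4-generation distinguishability expectation under this model is
  ≈ 97% for 136 loci at 6.64·10⁻³ mpg; higher published figures for the
  same inputs are not reproducible from `1 − (1−r)^(L·g)`.
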