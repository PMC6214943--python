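# Methods

## Problem setting and model

The input is a set of full-length, non-chimeric CCS reads from targeted
(primer-pair) sequencing of one gene family, with per-base Phred qualities.
Reads are assumed pre-processed (primers/barcodes removed, chimeras and
partial reads discarded). The goal is the set of distinct transcript
sequences present in the sample, at nucleotide precision, together with a
grouping of those transcripts into putative gene copies.

Two properties of the data drive the design: (i) true biological differences
between transcripts can be as small as one substitution, i.e. smaller than
the per-read error load; (ii) reads span the whole transcript, so multiple
variant positions on one transcript are physically linked within each read
and their evidence multiplies.

## Clustering and partial correction

Clusters are anchored at centers via the directed nearest-neighbor graph
under unit-cost edit distance. Center selection maximizes the number of
vertices with a path to the candidate center; ties are broken by the
multiplicity of the center's string and then the lexicographically smallest
read id (the algorithm is deterministic end to end; identical reads are
distinct vertices, which internally are condensed into one weighted node —
exact, because a duplicated string's closest neighbors are its copies at
distance 0). After a cluster is cut out, edges are not recomputed for the
residual graph.

Correction compares each cluster's reads to the per-column majority
consensus of the multi-alignment matrix. Support is state-specific
(n_j^t / n^t over the four states match/substitution/insertion/deletion)
so that the more frequent error types (indels, in CCS data) require more
coverage before a variant is protected. Per read and per round only the
⌈k/2⌉ lowest-support variant cells are corrected (ceiling, so a
single-error read is correctable), ties among a read's variant cells broken
by column index, and no correction is made where the column majority is not
unique. The majority-tie rule is the no-overcorrection guarantee: two
equally deep haplotypes differing by one substitution produce a tied column
and are never merged.

Termination: a cluster converges when its strings are identical. Three
heuristics guarantee progress — a read's correction is undone if it
increased its distance to the center relative to the previous round; a read
whose center assignment alternates cyclically (signature A,B,A over a
3-round window) is frozen; a cluster whose membership repeats with a
zero-change round (all selected cells tied) is declared converged. A global
check stops the loop when no string changes or when the multiset of working
strings repeats; a hard cap (default 20 rounds) raises an error rather than
looping. In practice all tested instances (up to 500 reads) converge well
below the cap.

## Multi-alignment construction

Pairwise global alignments of all cluster reads to the center (or, in the
test stage, to candidate d) are stacked: target columns are kept in order,
and between consecutive target positions as many insertion columns are
created as the longest insertion any row places there, insertions
left-aligned within the slot. This construction is deterministic and
order-independent given sorted read ids, and every row spells its original
string after gap removal. Alignments and distances use edlib (exact
unit-cost global alignment, internally banded); the package intentionally
uses the same cost model for graph distances and alignment rows so that the
two are mutually consistent. For the grouping stage, where gap
consolidation matters more than unit-cost optimality, an affine-gap aligner
(biopython's PairwiseAligner) with a prohibitive mismatch penalty is used
instead.

## Statistical test

For candidates c (tested) and d (closest neighbor, acting as the null
origin), reads pooled from both candidates plus c itself are aligned to d;
V is the set of columns where c's row disagrees with d. Read i supports c
(s_i = 1) iff it matches c at every column of V.

Per-position error probabilities p_ij come from the read's Phred score at
the column: substitution variants use (10^(-q/10))/3 — the error must
produce the specific base c carries; insertion/deletion variants use
10^(-q/10) undivided; where the read has a gap, q is the minimum over the
two flanking read bases. Probabilities are clamped to [1e-7, 0.5]: the
ceiling enforces the Bernoulli-mean interpretation (p < 1) and the floor
guards against over-confident qualities. The clamp is applied after the
division by 3, so a Phred-0 substitution contributes 1/3 and a Phred-0
indel the cap of 0.5. Both the division convention (`specific` vs `raw`)
and the clamp are configurable.

The statistic T = ∏_{s_i=1} 1/p_i is computed in log space throughout
(log T = Σ −s_i log p_i), so n up to 10^4 reads and p_i down to 1e-300
cause no overflow. With t′ = log t / max_k(−log p_k) and
μ = Σ p_i(−log p_i) / max_k(−log p_k), the reported significance is the
Chernoff–Hoeffding bound (e^δ/(1+δ)^{1+δ})^μ with δ = t′/μ, evaluated in
log space; when t′ ≤ μ the observation is below its error-only expectation
and the value defaults to 0.5. δ = t′/μ is used as printed even though the
theorem then bounds the tail at (1+δ)μ = t′+μ, a point above t′ — i.e. the
reported value is, if anything, slightly anti-conservative in μ; the
alternative δ = t′/μ − 1 (bound applied exactly at t′, strictly larger
p-values) is available as `delta_convention="shifted"`. The normalization
makes the bound invariant to the logarithm base; natural logs are used.

Validity assumptions (documented, never asserted at runtime): d is
error-free; where c and d agree they are not both wrong; errors at
different positions of a read are independent; reads are independent.
Candidate pairs with more than 10 variant positions are not evaluated
(their p-value would be ~0) and count as significant. Reads whose alignment
does not overlap some column of V are counted as non-supporting.

## Filtering loop

Original reads are greedily assigned: repeatedly pick the candidate that is
a closest neighbor of the most unassigned reads (ties: larger source
cluster, then lexicographically smallest sequence), bind those reads,
remove both, recompute closest sets over the reduced candidate set. Each
candidate is then tested against each of its closest-neighbor candidates
and receives its largest (least significant) pairwise p-value; each round
removes at most τ = 10 candidates with p > α = 0.01, highest first, and the
loop re-assigns and re-tests (p-values are never cached across rounds)
until all survivors are significant. τ is a configurable default — its
value only throttles how many candidates fall per round, not which ones
eventually fall. A singleton candidate set is kept (nothing to test
against).

## Simulator

The generator encodes the study conditions the pipeline is evaluated under:

* **Root gene**: random sequence split into exons (minimum 30 nt), profile
  presets 914 nt/6 exons, 2668 nt/6 exons, 5904 nt/28 exons.
* **Gene copies**: copy 1 is the root; each later copy mutates a uniformly
  chosen earlier copy with independent per-base substitutions at rate
  μ_mut (default scenarios use 0.005 ≈ 4–5 substitutions per 914 nt copy,
  mid-range between nearly identical and clearly separated copies).
* **Isoforms**: exon-skipping patterns (full inclusion, then single and
  double skips of internal exons; terminal exons always kept, as the RT-PCR
  primers sit in them). Identical sequences arising from identical copies
  are collapsed, summing abundances.
* **Abundances**: drawn from {2^i, i = 1..8}; for the 30-isoform design the
  implied relative abundances are ~0.1%–15% in expectation (individual
  draws can fall slightly outside). Equal-abundance variants set all values
  equal.
* **Reads**: origins are multinomial in the relative abundances. Per read,
  the error rate is the profile rate times a unit-mean lognormal factor
  (σ = 0.5), standing in for pass-count variability; a nominal pass count
  (lognormal around the profile's median passes: 18, 16, 2) is recorded on
  the read. Errors are substitution:insertion:deletion 1:1:1; every emitted
  base carries Phred quality −10·log10(per-base error rate used), capped at
  93. This is a deliberate simplification of real CCS behavior: qualities
  are uniform within a read, homopolymer-biased indels, base-dependent
  quality and RT-PCR artifacts are not modeled. Passing tests therefore
  demonstrate the algorithmic behavior under calibrated error loads, not
  performance on any particular instrument chemistry.

Scoring is exact-sequence recall (fraction of truth transcripts matched
exactly by ≥1 prediction) and precision (fraction of predictions exactly
matching some truth transcript); an empty prediction set scores precision 1,
recall 0. An optional end-trimming tolerance exists and defaults to 0.

## Gene-copy grouping

Two transcripts are compatible when an optimal alignment under a
prohibitive mismatch penalty (so a substitution-free co-linear alignment
wins whenever one exists; affine gaps, open −6 / extend −1) has no
mismatched column and no gap run shorter than `min_indel_length`
(default 20 nt — exon-scale; the threshold is a policy default, reported in
the output). Groups are maximal cliques; the copy-number proxy is the exact
minimum number of maximal cliques covering all transcripts, found by
exhaustive search over clique subsets in increasing size (guarded to ≤ 64
transcripts; ties prefer larger cliques, then lexicographic ids). A
transcript skipping a copy-distinguishing exon legitimately lands in
several groups.

## Problem sizes used in the test suite

Chosen so the default suite and the acceptance sweep each complete in
minutes on a single CPU:

* depth-saturation sweep: 8 equal-abundance transcripts (914 nt profile),
  depths 4–16×, 3 seeds (the acceptance script sweeps 2–24× with 5 seeds);
* precision check: 30-isoform family, 500 total reads;
* long-noisy-profile check: 4 transcripts of the 5.9 kb / 6.1% profile at
  50× each (a scaled-down version of the published high-coverage setting);
* tail-bound validation: 200 random support profiles (n ≤ 10), 10^6
  Monte-Carlo draws each;
* oracle comparisons: quadratic-DP edit distance (strings ≤ 50 nt),
  brute-force transitive closure (≤ 12 vertices), subset-enumeration
  minimum cover (≤ 10 transcripts);
* rare-variant sensitivity: 1-substitution pair at depths 300/10 and 300/1,
  1% error, Phred 30.

## Known limitations

* The statistical test is pairwise and applies no multiple-testing
  correction across candidate pairs (α is a direct threshold).
* Candidates are compared only against closest-neighbor candidates; a
  spurious candidate whose nearest neighbor is another spurious candidate
  can in principle survive a round longer.
* The simulator's per-read uniform quality model understates within-read
  quality variability; the statistical test consumes per-base qualities and
  would exploit real variability.
* Grouping cannot separate copies with identical exonic sequences, and RNA
  editing would inflate the copy-number proxy; group sizes are upper bounds
  on isoforms per copy.
* The exact minimum-cover search is exponential in the number of maximal
  cliques and intentionally guarded to small transcript sets.
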