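# Methods

## The measurement being modelled

A suppression-PCR junction library reduces whole-genome retroelement
profiling to a per-insertion signature: genomic DNA is digested with
blunt restriction enzymes (AluI + HaeIII for L1 libraries, AluI + RsaI
for Alu), suppression adapters are ligated, and nested PCR with
subfamily-diagnostic primers amplifies only those fragments that
contain the junction between an L1Hs 3'-terminus (or an AluYa5
5'-terminus) and its genomic flank. Sequencing read 1 therefore starts
inside the element, crosses the junction at a fixed offset determined
by the PCR design, and continues into unique flank sequence; mapping
the flank yields the insertion coordinate at single-base resolution.

Insertions are classified by cross-library comparison within one
individual: a call at an annotated same-family reference-RE junction is
*reference*; a non-reference call seen in every tissue library is
*germline/polymorphic*; a non-reference call seen in exactly one
library is *potentially somatic*. Calls seen in an intermediate number
of libraries are kept in an explicit `ambiguous_multi_tissue` class so
that neither extreme is silently inflated (the source protocol defines
only the two extremes).

## The simulator

`somre.simulate` generates the whole process at sequence level on a toy
genome, so every downstream stage can be validated against planted
truth. Key properties:

* **Digestion is physical.** Restriction sites are located on the
  insertion-bearing sequence, so an insertion can create or destroy a
  site; fragments are bounded by the nearest cut on each side of the
  junction. A fragment is amplifiable only if it retains all diagnostic
  primer sites and its genomic flank is ≥ `min_flank` (25 bp); with no
  cut within `max_fragment` (3 kb, an assumption exposed in the config
  — the original protocol does not state a size-selection window) the
  fragment is counted as suppression loss.
* **Somatic read support is low by construction.** Somatic events draw
  read multiplicity from the categorical distribution
  {1: 0.85, 2: 0.08, 3: 0.04, 4: 0.02, 5: 0.01} (observed somatic
  insertions are supported overwhelmingly by one read and never more
  than ~5); germline/reference events draw Poisson with mean
  `read_depth`.
* **Synthetic consensus termini.** The family termini are invented
  sequences that embed the published subfamily primer sequences
  verbatim and contain no recognition site of their own library's
  enzymes; they are stand-ins, not the biological consensus. One
  enzyme site is placed in the element body so the element-side
  fragment boundary is always well-defined.
* **Coordinates.** An insertion point is a 0-based inter-base
  coordinate; target-site duplications are not modelled because calling
  resolves a single junction side only. All intervals are half-open;
  1-based coordinates never appear in machine-readable output.

Default study conditions (chosen once as a realistic scaled-down
stand-in; the real experiment's ~1 somatic insertion/Mb over a 3.2-Gb
genome cannot be simulated at toy size):

| parameter | default | note |
|---|---|---|
| genome | 3 × 1 Mb chromosomes | ≥ 50 kb enforced per chromosome |
| gene fraction | 0.45 | steered to within one gene length |
| reference REs | 60 per family | planted into the sequence |
| germline non-reference | 30 per family | carried by all tissues |
| somatic rate | 50 events/Mb/tissue/family | ~150 events per tissue, sized so a 1.5× rate contrast is detectable by the conditional Poisson test |
| co-orientation prob. | L1 0.41, Alu 0.49 | matches the observed genic orientation fractions |
| genic multiplier | L1 1.2, Alu 1.0 | L1 shows genic enrichment |
| read length / depth | 101 bp / mean 30 pairs per germline event | |
| substitution error | 0.001 per base | no indels, constant quality |

What the simulator does **not** emulate: PCR duplicates and chimeras,
indel errors, quality-score variation, mappability structure of a real
genome (the toy genome is i.i.d. random, so flanks are almost always
unique), polyA tails, and 5'-truncation heterogeneity. Passing
recovery tests therefore demonstrate the correctness of the pipeline's
logic under its own assumptions, not expected performance on real
libraries, where repeats and mapping bias dominate the error budget.

## Calling

Read 1 is screened for the family's expected terminus prefix (fixed
length 30 bp, set by the PCR design) allowing one mismatch; adapter
read-through is trimmed by suffix overlap (≥ 3 bp, one mismatch per
8 bp); flanks shorter than `min_flank` are discarded and tallied. The
flank mapper is a deliberately small seed-and-extend scheme over a
sorted array of 2-bit-packed 20-mers: exact seeds at offsets 0/10/20 on
both strands, full-flank verification allowing ≤ 2 mismatches, and a
unique/ambiguous/unmapped trichotomy. Ambiguous flanks are discarded —
only a uniquely mapped flank establishes a coordinate at single-base
resolution. Real-data mode accepts externally produced BED/SAM
alignments through the same CallSet contract.

The element strand is inferred from the flank's mapped orientation
combined with which element end the family flanks (equal for
3'-flanked L1, flipped for 5'-flanked Alu) — the original analysis
reports orientation but not the inference rule.

Junctions within 3 bp on the same chromosome and strand collapse into
one call at the modal coordinate (ties break toward the smaller
coordinate); collapse is idempotent.

## Classification and summaries

Calls are merged across libraries within 3 bp; reference matching uses
a 100-bp tolerance around annotated same-family RE junction ends. No
read-count ceiling is imposed on the somatic class (the observed ≤ 4–5
read support is an observation, not a filter). The per-library summary
reports the normalized rate 100 × somatic reads / total reads rounded
half-up to 4 decimals and compartment percentages to 2 decimals
(printed-table convention; Python's built-in round is banker's
rounding). A zero-read library reports a missing rate, not zero.

## Annotation

Promoters are exactly the 5,000 bp upstream of each TSS on the gene's
strand, clipped at chromosome bounds. Genic takes precedence over
promoter for points in both (overlapping windows), making the
compartments a partition. Boundary membership follows the half-open
convention (start inclusive, end exclusive). Orientation (co/counter)
is defined only in genic/promoter compartments as element strand ==
gene strand.

## Statistics

* **Exact two-sample Poisson rate test.** Conditional construction:
  given T = x₁ + x₂, x₁ ~ Binomial(T, n₁/(n₁+n₂)) under equal rates.
  Two-sided p-values use the minimum-likelihood convention (sum of all
  outcome probabilities ≤ the observed one, with the customary 1+1e-7
  relative tolerance), implemented directly and cross-checked against
  brute-force enumeration and `scipy.stats.binomtest` in the tests.
  The conditional-exact choice is validated by reproducing the
  published cerebellum-vs-SVZ Alu p = 0.0506 at printed precision.
  x₁ = x₂ = 0 returns p = 1.
* **Monte-Carlo genomic distribution test.** Each of R (default 1000)
  replicates draws N coordinates uniformly over the genome (chromosome
  proportional to length) and counts hits in merged gene intervals and
  in promoter-minus-gene space (mirroring the annotation precedence).
  Empirical p-values use (1 + hits)/(R + 1) and can never be zero; the
  generator seed is recorded in every result. No mappability mask is
  applied (none is specified for the original analysis); real-data use
  can subset the sampling space upstream.
* **Overdispersion test.** D = Σ(xᵢ − nᵢp̄)²/(nᵢp̄(1−p̄)) with pooled
  p̄, referred to χ² with k−1 df (upper tail). The construction used in
  the original analysis (via the R qcc package) is not spelled out;
  this declared statistic is reported as computed.
* **Orientation test.** Exact binomial against 0.5, same two-sided
  convention.

## Fixture battery and documented discrepancies

The packaged TSVs transcribe the published per-tissue count tables and
are guarded by SHA-256 checksums. `paper-check` recomputes every
derivable printed number; 110 of 118 checks pass at printed precision.
The remaining eight are flagged `expected_discrepancy` and are
properties of the printed tables or of unspecified constructions, not
tuning targets:

* the Alu/gene/cerebellum orientation row is internally inconsistent
  (323 co + 301 counter = 624 against a printed total of 623, with the
  printed counter-% equal to 100 − co-% rather than 301/623);
* the counter-oriented genic-L1 mean ± SD does not recompute from the
  printed counts (59.04 ± 0.31 here against 59.05 ± 0.29 as printed;
  the co-oriented 40.96 ± 0.31 does recompute exactly);
* the blanket claim that genic L1 orientation is significant below
  1e-4 in every tissue fails for the frontal cortex (97/236 gives
  p = 0.0075 — still strongly significant, just above the printed
  bound);
* the overdispersion p-values (printed "> 0.98" and "0.9999") come out
  at 0.94/0.67/0.56/0.07 for the compartment fractions and 0.9978 for
  the co-oriented counts under the declared D statistic.

## Problem sizes used in the test suite

Recovery checks run 20 replicates of a 3-Mb, five-tissue, L1-only
experiment with the DG somatic rate at 1.5× (and 20 replicates at
equal rates for the type-I check); somatic precision/recall are scored
against planted truth restricted to events that emitted at least one
read pair — an event with zero reads is undetectable by any caller.
Monte-Carlo calibration uses N = 3,000 coordinates and R = 1,000
replicates; enrichment power is measured over 20 draws with the genic
multiplier set to produce a 10% genic excess. Unit tests use 0.3-Mb
genomes.

## Known limitations

* The flank mapper is adequate only for small, mostly unique genomes;
  real data should be mapped externally and imported.
* Chromosome ends within `max_fragment + 400` bp of a boundary are
  excluded from insertion placement, so telomeric insertions are out of
  scope.
* Somatic insertions are excluded from a 150-bp zone around
  reference-RE footprints: a somatic junction inside that zone would be
  indistinguishable from the reference copy at the 100-bp matching
  tolerance, and insertions into same-family repeats are not resolvable
  by this assay design anyway.
* The ambiguous (2..k−1 libraries) class is reported but not further
  interpreted; whether such events are cross-contamination, shared
  early-development clones, or coordinate collisions is not modelled.
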