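# Methods

## The forward proportion model

A pooled sample contains `n_i` specimens of taxon *i*, each contributing
one leg. Assuming DNA is liberated equally well from every leg and PCR
amplifies every template equally, the share of amplicon reads attributable
to taxon *i* is

    p_i = n_i c_i / Σ_j n_j c_j,

where `c_i` — the copy-number correction factor — collapses three
quantities that cannot be separated from read data alone: rRNA gene copies
per haploid genome, haploid genomes per cell, and cells per leg. `c` is
identified only up to a positive scale, so every reported factor vector is
normalized to minimum 1 ("fold units relative to the lowest-copy taxon").
The inverse map used for abundance estimation,
`q_i = (r_i/c_i) / Σ_j (r_j/c_j)`, is the exact algebraic inverse of the
forward model on proportions; the composition of the two is the identity,
which the test suite asserts.

Assumptions worth stating explicitly: no PCR amplification bias between
taxa, no chimera formation, equal tissue lysis across taxa, and factors
constant within a taxon. Violations load onto `c_i` (which is why it is a
"correction factor", not a copy-number measurement) or, when they vary
between samples, into residual error the model cannot absorb.

## Calibration data

Factors are trained only on *concordant* samples: samples whose set of
genera with specimen count > 0 equals the set of genera with read count
> 0 (after collapsing taxa through an optional taxon→genus map). This
sidesteps tissue-degradation dropout, which otherwise makes a specimen
count > 0 coexist with zero reads and poisons the fit. The spike-in
calibrator (two fresh beetle legs per pool) is appended to every specimen
row as a pseudo-taxon with count 2 and its reads enter the observed
proportions, anchoring the factors against a taxon of known, constant
input. Observed proportions are computed over the modelled taxon set only;
unassigned and ambiguous reads are excluded from the denominator.

## The genetic algorithm

Each "genome" is a positive factor vector over the calibration taxa
(including the calibrator). The population (default 1,000) starts at a
constant 10 for every taxon. Per iteration:

1. score every genome: SSE between model proportions and observed
   proportions, summed over samples and taxa;
2. remove the worst ⌊N/3⌋ genomes;
3. replace them with copies of the best ⌊N/3⌋; each copy mutates by adding
   a N(0, 5²) draw, clamped below at 0.01 to preserve positivity; the
   originals are kept unmutated (elitism), so the best SSE ever seen is
   non-increasing — asserted on the checkpoint trajectory;
4. the middle third is untouched.

Population size is exactly preserved for any N. Best SSE is recorded at
eight logarithmically spaced checkpoints.

**Mutation mode.** Two readings of "mutate by an amount drawn from a
normal distribution" are possible: perturb *every* coordinate of a
duplicated genome, or perturb *one* randomly chosen coordinate. Both are
implemented (`GAConfig.mutation_mode = "all" | "single"`); the default is
"single". The choice is empirical as well as textual: with factors
spanning three orders of magnitude, all-coordinate mutation couples every
accepted step across taxa, and the additive sd of 5 puts an error floor on
small-factor taxa that stalls convergence around SSE ~10⁻³ at the default
budget, whereas single-coordinate mutation turns the search into an
elitist coordinate-wise ratchet that reaches SSE ~10⁻⁹ and sub-1% factor
recovery on noiseless data in the same 100,000 iterations.

**Budget.** The package default is 100,000 iterations (about a minute at
population 1,000 with the vectorized scorer, which re-scores only the
replaced third each iteration). The configuration accepts 10,000,000 for a
full-scale run; on noiseless calibration data the extra budget changes the
recovered factors by less than the reporting precision.

**Numerical details.** Scoring is dense float64; a genome's expected
proportions are computed per sample as `n·c` row-normalized. The factor
floor of 0.01 is the only constraint; no upper bound is imposed. The
optimizer's internal scale is free to drift (the objective is
scale-invariant) and typically settles within one order of magnitude of
init; only normalized factors are comparable across runs.

## Read processing conventions

- **Expected-error filter.** E = Σ 10^(−Q/10) over the read; a read is
  discarded when E ≥ 1.0, i.e. "at least one predicted error" removes the
  read. The boundary is deliberately strict (E = 1.0 is discarded), unlike
  the common `maxee` convention that keeps it.
- **Dereplication** is exact full-length string equality — no sub-string
  containment or clustering. Replicate floors: ≥ 10 (taxa pools, used to
  validate references), ≥ 2 (community pools).
- **Identity** is global (end-to-end, Needleman–Wunsch via edlib):
  matching columns divided by total alignment columns, so gap columns count
  against identity and length variants are penalized. When several
  minimum-edit-distance alignments exist (e.g. a run of adjacent
  substitutions re-expressible as an indel pair), the aligner's returned
  path defines the column count; co-optimal paths can differ in identity
  by ~0.1% on a 507 nt read, which only matters exactly at the threshold.
- **Assignment.** Best reference with identity ≥ 0.99 takes the unique's
  whole replicate count; ties at the best identity are tallied as
  *ambiguous* and assigned to no taxon (deterministic and conservative);
  best identity < 0.99 is *unassigned*; calibrator hits are tallied
  separately. Per sample, mapped + unassigned + ambiguous + calibrator
  equals the post-filter read count exactly — an invariant the suite
  checks.

## The synthetic-data generator

What it emulates, and the defaults chosen where the emulated survey's
underlying parameters are unpublished:

- **Design**: 2 management types × 4 locations × 28 sampling dates = 224
  community pools; 20 traps per site; one taxa pool per observed taxon (56
  under the default 56-taxon community).
- **Abundance**: per-trap negative binomial (mean m, size k, variance
  m + m²/k), summed over traps. The calibration experiment uses m = 3,
  k = 0.8 per sample — overdispersed catches with ~30% zeros, so genus
  sets genuinely vary between samples while remaining concordant by
  construction. Optional per-location multipliers give each rare taxon a
  "home" location, producing communities that separate by location rather
  than management in ordination.
- **References**: random ACGT sequences of 507 nt accepted by rejection
  sampling under a pairwise Hamming floor (default 9 substitutions — a
  well-discriminating marker; 1,000 attempts per sequence before an
  infeasible-configuration error). A low-divergence mode derives each new
  sequence from an accepted one by 1–few substitutions, emulating a
  conserved locus whose taxa collapse at the 99% mapping threshold.
- **Correction factors**: five genera carry the benchmark values 1
  (Hylaeus), 14.9 (Hoplitis), 30.0 (Lasioglossum), 124.5 (Megachile),
  1,248 (Bombus); the other ten calibration genera carry fixed values
  log-spread over the same range (3.5–320); the beetle calibrator is 450,
  reflecting fresh tissue out-yielding stored specimens.
- **Reads**: multinomial draw per sample with probability ∝ (surviving
  n_i + calibrator spike) × c_i; i.i.d. substitution errors at a constant
  per-base rate; quality strings are a constant Phred score
  round(−10·log₁₀(e)) capped to [2, 40]. Note the interaction with the
  strict filter: a 507 nt read passes E < 1 only when e < 1/507 ≈ 0.002,
  so the default per-base error is 0.001 (Q30, E ≈ 0.51). Dropout is per
  specimen (binomial thinning of n_i), not per taxon, so partial loss of a
  taxon is possible; calibrator legs never drop out.

What it does **not** emulate: PCR cycle-level bias and chimera formation,
indel sequencing errors, quality variation along the read, primer
mismatch, plant/non-target amplification, and within-taxon factor
variation. Passing tests therefore demonstrate correctness of the
algorithms under the forward model's own assumptions — not robustness of
the factors to the wet-lab artifacts that dominate real surveys.

## Community analytics

- **Richness** is presence-based per sample; the calibrator is excluded.
  Pearson correlation between morphological and molecular richness
  requires ≥ 3 samples and non-constant vectors.
- **Rarefaction** treats the pooled sampling date as the sampling unit.
  Interpolation uses the exact hypergeometric expectation
  S(t) = S_obs − Σ_i C(T−T_i, t)/C(T, t) (computed with exact integer
  binomials; verified against exhaustive subset enumeration for T ≤ 8);
  extrapolation uses Chao2,
  Q̂₀ = ((T−1)/T)·Q1²/(2Q2), with the standard substitution
  Q1(Q1−1)/2 when Q2 = 0, and
  S(T+t*) = S_obs + Q̂₀[1 − (1 − Q1/(T·Q̂₀+Q1))^t*]. Point estimates
  only; bootstrap confidence bands are out of scope.
- **Ordination** is a PCA of per-sample relative abundance (rows
  normalized to sum 1; all-zero rows left at zero), columns centred, not
  scaled — scale-free and standard for composition when the transformation
  is otherwise unspecified. All components are kept so explained variances
  sum to the total column variance. Per-group minimum convex polygons are
  computed on the first two components; groups with fewer than three
  distinct or non-collinear points return their points.
- **Group summaries** report mean ± 1.96·SE per location × management as
  descriptive plumbing; mixed-model inference on abundance/richness is
  deliberately out of scope.

## Problem sizes

The test suite and the acceptance script run the calibration experiment at
15 samples × 16 taxa with population 1,000 and 100,000 iterations (~1
minute), and the smaller three-taxon recovery at population 200. Survey
simulations in tests use reduced designs (2–8 pools, hundreds to a few
thousand reads per sample); the generator's defaults produce the full
224-pool survey in seconds, with read simulation the only stage that
scales with depth.

## Known limitations

- SSE on proportions weights abundant, high-copy taxa most; factors of
  rare, low-copy taxa are the least constrained (on noisy data they are
  recovered worst — consistent with quantitation degrading for infrequent
  taxa).
- No uncertainty intervals on fitted factors; the GA returns a point
  estimate.
- The identity denominator convention (gap-inclusive, returned-path
  columns) can differ from other tools' definitions exactly at the
  threshold.
- Factors are per-genus in the calibration setting; within-genus
  copy-number variation is unmodelled.
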