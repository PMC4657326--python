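# Methods

This note documents the models implemented in `crystprop`, the choices made
where the underlying procedures are under-specified in the literature, what
the synthetic-data generator does and does not emulate, and the package's
numerical conventions.

## Distribution probability

The r residues of one amino-acid type in a protein of length L are treated
as r distinguishable balls dropped independently and uniformly into n = r
holes. The holes are realised as contiguous sequence partitions whose sizes
differ by at most one residue: with L = q·r + s, the first s partitions have
q + 1 residues and the rest q. This remainder rule ("longer partitions
first") is one of several defensible placements; it is fixed and documented
so results are deterministic, and the occupancy vector it produces is what
the probability is evaluated on. Positions are 1-based.

For an observed occupancy (r₁, …, rₙ) with multiplicities q_j (the number
of partitions holding exactly j residues), the probability of the occupancy
*pattern* (order of partitions irrelevant) is

    P = r!/(Π_j q_j!) · r!/(Π_i r_i!) · n^(−r).

Both factorial quotients are evaluated in exact integer (rational)
arithmetic with a single final conversion to float, so counts in the
hundreds neither overflow nor lose leading digits. An absent residue type
(r = 0) is assigned probability 0 by convention in the 20-vector encoding —
the value used for zero-count entries in reference tables — rather than
being left undefined.

Correctness is established two ways: an independent brute-force oracle
enumerates all n^r assignments and counts those matching the observed
pattern (tested for every occupancy multiset with r ≤ 6, agreement to
1e-12), and the probabilities over all patterns of fixed r sum to 1.

## Future composition

A 20×20 transition matrix P(a→b) is derived from the standard genetic code:
each codon of amino acid a is expanded into its 9 single-nucleotide mutants
and the translated targets tallied. Defaults, all configurable:

* **uniform codon weighting** — protein sequences carry no codon-usage
  information, so each of a's codons counts equally;
* **stop targets excluded** — mutation events producing a stop codon are
  dropped before normalisation (`stop_handling="exclude"`); the
  `"renormalize"` option tallies over all events and rescales rows
  afterwards, which coincides with `"exclude"` under uniform weighting
  (both are row-stochastic);
* **synonymous transitions included** — a→a events (e.g. third-position
  wobble) stay in the tally; excluding them is supported.

The future composition of type b is 100 · Σ_a c_a P(a→b) with c the current
composition (counts/L), in percent; with a row-stochastic matrix the twenty
percentages sum to 100 exactly. Note that published per-protein tables of
this quantity do not always sum to 100, indicating an undocumented
normalisation in some historical calculators; this implementation follows
the compositional definition above and guarantees mass conservation.

## Pair predictability

Over the L−1 overlapping adjacent pairs, the expected count of the ordered
pair (X, Y) from composition alone is r_X·r_Y/L for X ≠ Y and
r_X·(r_X−1)/L for X = Y (algebraically the sampling-without-replacement
form r_X/L · r'_Y/(L−1) · (L−1)). Expectations over the 400 ordered types
sum to exactly L−1 (verified in rational arithmetic). The predicted count is
the expectation rounded half-up (computed on exact rationals so that .5
cases never depend on float representation); rounding is consistent with the
reference worked examples, which are also consistent with flooring — the
choice is documented here because those examples cannot discriminate.

Classification rules:

* **strict** (default): all occurrences of a pair type are predictable iff
  actual == predicted; otherwise all are unpredictable. This is the literal
  reading of the verbal definition.
* **min** (optional): min(actual, predicted) occurrences count as
  predictable — a softer credit for partial agreement.

Under both rules the predictable and unpredictable portions are percentages
of L−1 and sum to 100.

## Constant-characteristic benchmark

AAIndex1 flat files are parsed natively (H/D/I record structure, two rows of
ten values in the database's A R N D C Q E G H I / L K M F P S T W Y V
order, `NA` masked). The benchmark encoding of a protein weights each
characteristic value by the residue count, x_a = value_a · count_a; the
unweighted "raw" mode (x_a = value_a, identical for every protein) is
retained only to demonstrate that an unweighted constant characteristic
carries no per-protein information. Entries with NA values for residues
present in the dataset are excluded from screens, with the exclusion list
reported.

A structural consequence worth knowing: every count-weighted constant
encoding is the count vector rescaled by a fixed diagonal matrix, so under
logistic regression all such encodings span the same model class and full-fit
screening accuracies tie across characteristics (ties are broken by
accession for determinism). Distinguishing constant characteristics
therefore requires either a model that is not reparameterization-invariant
(the neural network) or validated rather than fitted accuracy. The dynamic
encodings are not diagonal rescalings of counts and do separate from the
constant family.

## Classifiers

**Logistic regression.** P(y=1|x) = 1/(1+e^(−(b0+Σbᵢxᵢ))), fitted by
maximum likelihood (L-BFGS on internally z-scored predictors, coefficients
mapped back to the raw scale; optional L2 strength α, penalised on the
standardised scale). The variant convention with a positive exponent,
P = 1/(1+e^(+η)), is supported via `sign_convention="paper"`; the stored
coefficients absorb the sign flip and refitting under either convention
gives identical probabilities. Degenerate inputs are handled explicitly:
single-class labels or all-constant predictors yield an intercept-only
prevalence model (intercept clipped to keep coefficients finite);
numerically constant columns (relative tolerance 1e-12) get coefficient 0
with a warning; complete separation (standardised coefficient norm
diverging past 30) triggers an automatic refit at α = 1e-4 with a warning
and a `separation_fallback_` flag. Standard errors come from the observed
Fisher information on the raw scale and back the planted-recovery checks.

**Neural network.** One hidden layer of 10 tanh units over the 20
predictors, one logistic output — trained full-batch with L-BFGS on
cross-entropy (small L2, α = 1e-4, for conditioning), with seeded
initialisation, so training is deterministic: identical (X, y, seed) give
bit-identical weights, and full-batch training makes the fit invariant to
row order. Historical uses of this architecture ran proprietary trainers
whose algorithm, epochs and initialisation are unrecorded; this package's
contract with the architecture is therefore behavioral — capacity on
separable and XOR-structured data, determinism, and serialisability — not
weight-level equivalence. Inputs are z-scored internally and predictions
computed from the stored weights, so serialised models round-trip exactly.

Classification thresholds P at 0.5 with ties to the positive class.

## Evaluation

* **Fit mode** trains and evaluates on all n proteins (a first-stage
  workability check). **Jackknife mode** is delete-1: n models, each
  predicting only its held-out protein, per-fold seeds derived
  deterministically from (run seed, fold index) via `SeedSequence`. A fold
  whose training split loses one class is flagged and predicted by the
  training prevalence.
* Accuracy/sensitivity/specificity are percentages; an undefined ratio
  (empty class) is reported as missing, never as 0.
* ROC curves are computed over all distinct score thresholds; the AUC is the
  trapezoidal area in the sensitivity-vs-(1−specificity) convention and
  equals the Mann–Whitney U/(n₁n₂) identity to 1e-9 (tested). Points are
  also exported in the sensitivity-vs-specificity convention used in older
  plots.
* **Per-protein accuracy** (for the group comparison) is not well defined
  for a single deterministic fit, so it is implemented as the percentage of
  repeated model trainings (default 20 seeds; fit or jackknife mode) in
  which the protein is classified correctly. For the deterministic logistic
  model this collapses to 0/100; it is informative for the seeded network.
  This is one defensible reading of a per-protein accuracy bar; the repeat
  count is configurable.
* The group comparison splits proteins at a 90 % per-protein-accuracy
  cutoff and compares pair-predictable portions between groups with a
  two-sided Mann–Whitney U test — exact when both groups are small
  (min n ≤ 8) and tie-free, otherwise the normal approximation with tie
  correction. Group medians and interquartile ranges are reported.

## Synthetic data

The generator emulates the shape of a structural-genomics screening set:
default n = 301 proteins, lengths uniform on 50–1000 residues,
crystallization prevalence 85/301 ≈ 0.28, sequences i.i.d. from a residue
composition (uniform 1/20 by default; a "table1" preset uses the
composition of a real 122-residue plant protein, lysine-rich and
tryptophan/cysteine/arginine-poor). Labels are either pure noise at the
target prevalence or planted from a logistic model on a chosen encoding
with known coefficients, the intercept tuned to the target prevalence by
bisection on the simulated mean probability. Everything derives from one
integer seed.

What passing tests on this generator show: the estimators recover planted
structure (coefficients within 3 SE at n = 5000; a planted encoding
outranks 51 decoy characteristics), the validation machinery honours its
contracts, and null data yield null results. What they do not show: real
crystallization labels are not logistic in any single 20-vector encoding,
real sequences are not i.i.d. draws, and no claim about biological
predictive power on real screening sets follows from these fixtures.

## Problem sizes and numerical conventions

Test and demonstration runs use n in the tens to hundreds (301 for
screening fixtures, 5000 for the coefficient-recovery check) — sizes chosen
so the full suite exercises every code path at comfortable desk scale.
Probabilities are exact-rational until the final float; percentages are
printed to 2 decimals; 20-vectors are always alphabetical by one-letter
code; sequence positions are 1-based; all randomness flows from explicit
integer seeds, with derived seeds kept below 2³¹.

## Known limitations

* The partition remainder rule and the mutation-matrix conventions are
  fixed choices among several defensible ones; alternatives beyond the
  documented options are not implemented.
* The strict/min predictability rules cannot be discriminated by the
  available worked examples; strict is the default on textual grounds.
* The AAIndex NA-exclusion filter approximates, but cannot exactly
  reproduce, historical entry subsets whose exclusion lists were never
  published.
* Constant-characteristic screening ties under logistic regression are
  structural (see above), not a bug.
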