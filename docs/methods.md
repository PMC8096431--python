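# Methods

This note documents the models, rules and numerical choices behind each
pipeline, the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the known limitations.

## Compound-interaction scoring

**Model.** Each well's fluorescence `T_F` is normalized to a fractional
inhibition `FI = 1 − (T_F − MC_F)/(IC_F − MC_F)`, where `MC_F` and
`IC_F` are the mean fluorescence of the medium-sterility and inoculum
controls of the same plate. FI is 0 at the inoculum control, 1 at the
sterile background, and is **never clipped**: FI < 0 (growth
stimulation) and FI > 1 propagate into every downstream mean, because
clipping would bias the Bliss excess toward synergy. Percent inhibition
is FI × 100.

Bliss Independence treats two inhibitors as acting independently, so the
expected combined inhibition is `E_AB = FI_A + FI_B − FI_A·FI_B`. The
expectation is evaluated over the full replicate cross product (n_A × n_B
values, a-outer/b-inner order), and the Bliss excess is computed from
means, `b = mean(E_AB) − mean(FI_AB)`. Significance comes from a
two-sided Welch t-test of the cross-combination values against the
observed combination replicates. A pair is labelled

* *synergistic* when `p ≤ α` and `b ≥ θ`,
* *antagonistic* when `p ≤ α` and `b ≤ −θ`,
* *additive* when `p ≤ α` and `|b| < θ`, or when `p > α` and `|b| ≤ θ`,
* *indeterminate* when `p > α` but `|b| > θ` — a large but statistically
  unsupported excess is left uncalled rather than silently labelled
  additive.

Defaults: `θ = 0.08`, `α = 0.05`, both configurable
(`PipelineConfig.b_threshold`, `.alpha`).

**Sign convention.** `b` is defined as expected minus observed combined
inhibition, with `b ≥ θ` called synergistic — the convention of the assay
this package operationalizes, reproduced as stated. Users accustomed to
"positive excess = more inhibition than expected" should note the
orientation before comparing with other tools.

**Pseudo-replication.** Comparing n_A × n_B cross-combinations against
n_AB observations inflates the nominal sample size of the expectation.
The default mode reproduces that design faithfully; an optional
`pseudoreplication="paired"` mode pairs solo replicates by index
(n values vs n values) for a conservative alternative.

**Degenerate inputs.** Coinciding control means raise an explicit error
naming the control group. Two constant equal samples in the t-test report
`(t, p) = (0, 1)`; two constant samples differing beyond floating noise
report `p = 0`; constant samples whose means differ only within machine
epsilon are rejected as irresolvable.

## LC-MS dereplication

**Matching.** A feature matches a compound when its m/z lies within
±5 ppm (inclusive) of a theoretical adduct mass `(M + shift)/z`. The
default positive-mode adduct list is [M+H]⁺, [M+Na]⁺, [M+NH4]⁺, [M+K]⁺,
[M+2H]²⁺ (proton mass 1.007276466 Da); co-elution requires ±0.1 min
(inclusive). "At least two adducts" counts the primary ion as one of the
two; the stricter reading (two *additional* adducts) can be obtained by
raising the count thresholds.

**MS2 similarity.** Spectra are compared by cosine similarity on
square-root-scaled intensities with greedy fragment pairing inside a
0.02 Da window (highest intensity product first, each fragment used
once), normalized by the full spectral norms — symmetric, in [0, 1], and
equal to the optimal-assignment score whenever fragment matching is
unambiguous. A "match" for identification levels 1–2 requires similarity
≥ 0.7 with ≥ 4 matched fragments; an analog match (level 3) requires
≥ 0.5. These cutoffs are configurable because the original workflow used
expert judgment; they are deliberately conservative defaults.

**Identification levels.** Level 1 = RT within tolerance of a commercial
standard **and** MS2 match against that standard; level 2 = MS2 match
against a literature/library spectrum; level 3 = MS2 similarity to an
analog standard. Candidates with no usable MS2 proceed to the
environmental evidence rules or are rejected (culture extracts).

**Environmental rules.** With MS2 triggered in a sample, acceptance
requires presence in the MS/MS run and in all three LC-MS technical
replicates (a differing replicate count errors unless explicitly
overridden). Without MS2 in that sample but with MS2 somewhere among the
environmental samples, mass/RT agreement plus either ≥ 2 co-eluting
adducts or an already-accepted same-family compound in the same sample
suffices (level 2 with a reference spectrum available, else 3). No MS2 in
any environmental sample ⇒ never accepted. Family co-detection is
evaluated in a single pass in decreasing evidence order, so hits that
stand only on family evidence can never bootstrap one another.
Polyene macrolides replace the adduct criterion with a replicate
pattern: ≥ 2 distinct adducts in one technical replicate and ≥ 1 adduct
in two other replicates (accepting [2,1,1], rejecting [2,1,0] and
[1,1,1]); any accepted polyene therefore has ≥ 4 adduct observations in
total.

**Detection** means intensity > 0 by default; a per-sample detection
threshold can be supplied where blank-subtracted tables carry noise.

## Chemotype clustering and tanglegrams

Features detected in any blank sample (above the detection threshold)
are removed entirely; the survivors are binarized with a strict
`intensity > 1×10⁶` rule (an intensity of exactly 1×10⁶ is absent).
Strains are compared by Jaccard distance `1 − |A∩B|/|A∪B|`, defined as 0
(with a warning) when both profiles are empty.

UPGMA merges the closest pair of clusters, recomputing distances as
size-weighted arithmetic means. Node height equals the merging distance
`d` (not `d/2`; the d/2 convention is available via
`height_is_distance=False`), so the cophenetic matrix of the output
reproduces an ultrametric input exactly. Ties are broken by the
lexicographically smallest pair of cluster labels (a cluster is labelled
by its smallest leaf), making the dendrogram fully deterministic.

Entanglement between two leaf orderings is
`Σ_i |posL(i) − posR(i)|^L`, normalized by its value when one ordering
reverses the other; the exponent defaults to L = 1.5 (configurable).
Untangling starts from both trees ladderized (larger subtree last) and
alternates sides: one tree's leaf order is fixed and the other is rotated
to its one-sided optimum, computed exactly by dynamic programming over
(subtree, position-interval) states — child blocks occupy contiguous
intervals of fixed sizes, so flips decompose over subtrees. Because
alternating one-sided optima can still stall in a joint local optimum,
instances with ≤ 10 leaves are solved exactly by enumerating one tree's
2^(n−1) rotations against the DP on the other; beyond that the
alternating pass (run from both starting sides, best result kept) is
used. The returned entanglement never exceeds the initial ladderized
value.

## Competition statistics

Growth is summarized as the CFU fold change `final/initial` per
replicate (initial counts are verified by plating, so a zero initial
count is an error naming the row; a zero final count is a flagged
below-detection observation that enters as fold change 0). Fold changes
are analysed on the natural scale, as they are plotted; a log10 mode is
available for heavy-tailed data. Two groups: Welch two-sided t-test.
Three or more: one-way ANOVA, then Tukey's HSD with studentized-range
adjusted p-values (statsmodels).

## Synthetic-data generators

All generators derive their streams from a single root seed through
numpy seed sequences keyed by per-generator constants, so outputs are
byte-identical across reruns and adding one generator call does not
shift another's draws.

* **Plates.** A well with true inhibition f draws fluorescence
  `Normal(IC − f·(IC − MC), noise_sd·(IC − MC))` — noise proportional to
  the control dynamic range, keeping FI noise comparable across plates.
  Defaults emulate the assay design: 7 biological replicates, noise sd
  0.02 of the range, and control means 12 000 (inoculum) over 2 000
  (medium background), typical plate-reader scales that keep simulated
  fluorescence safely positive. The combination well's true FI is
  `E_AB(fi_a, fi_b) − b_true`, so the analysis inverts the generator
  exactly when noise is 0.
* **Feature tables.** Spiked compounds appear as co-eluting adduct
  series (three adducts by default) across 4 samples × 3 technical
  replicates plus an MS/MS run, with truncated-Gaussian mass error
  (sd 1 ppm, capped at 3 ppm) and RT jitter (sd 0.01 min, capped at
  0.03 min), base intensity 5×10⁶ with 20 % lognormal replicate scatter;
  MS2 is attached to the protonated ion. 500 decoys are kept ≥ 20 ppm
  from every library adduct mass and 50 blank contaminants are placed in
  the blank samples. The bundled default library spans the gallery
  compound families with approximate literature monoisotopic masses and
  deterministic pseudo-fragment reference spectra (synthetic stand-ins
  keyed by compound name — stick lists, not measured spectra).
* **Tree pairs.** The first tree is the UPGMA of a random ultrametric
  matrix (random agglomeration at sorted uniform heights); the second is
  the UPGMA of the same matrix after `round(discordance · n)` random
  label transpositions, recorded in the truth manifest.
* **CFU tables.** Counts draw lognormal noise (dispersion 0.25) around
  `initial × fold_change`, 8 replicates per treatment, emulating the
  competition design; dispersion 0 recovers fold changes exactly.

**What the generators do not emulate:** chromatographic peak shape,
ragged/missing features across samples, isotope patterns, in-source
fragmentation, correlated plate effects (edge wells, drift), and
phylogenetic signal in chemotypes. Passing tests therefore demonstrate
correctness of the computations and rules under the stated statistical
structure, not robustness to every artefact of real instrument data.

## Problem sizes used in the checks

The bundled verification runs use 1,000 simulated pairs for the
false-call rate and 500 + 500 for effect recovery; 100 random 8-leaf
matrices for the clustering oracle; 40 random ≤ 6-leaf tree pairs for
exhaustive-rotation optimality plus a 4-level × 20-seed discordance
sweep at 12 leaves; and 10,000 permutation draws for the t-test
cross-check — sizes at which the binomial noise of every rate estimate
is well inside the acceptance margins.

## Known limitations

* The interaction t-test inherits the cross-combination design's
  pseudo-replication (see above); the paired mode is a mitigation, not a
  full mixed-model treatment.
* Dereplication assumes aligned feature tables; it does no peak picking,
  isotope scoring or molecular networking.
* The entanglement optimizer guarantees global optimality only up to the
  exact-enumeration limit; larger tanglegrams get a deterministic
  alternating local optimum.
* Jaccard on very sparse profiles is noisy; empty-vs-empty pairs are
  defined as distance 0 and flagged with a warning.
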