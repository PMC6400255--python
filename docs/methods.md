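# Methods

## The problem

Modern multi-crystal experiments (mesh/serial collection on many
micro-crystals) produce pools of hundreds of *sub-data sets*: partial wedges
of typically 17–45% completeness each, which must be merged to form a
usable data set. When the goal is SAD phasing from a weak anomalous signal
(Bijvoet difference ratios of 1–2%), indiscriminate merging is dangerous:
non-isomorphism between crystals inflates merging residuals and, worse,
corrupts the tiny Friedel-pair intensity differences that carry the phasing
signal. Choosing which sub-data sets to merge is a combinatorial problem —
2^n − 1 non-empty subsets for n wedges — that exhaustive search cannot touch
beyond n ≈ 20.

## The genetic algorithm

A candidate grouping is a *chromosome*: an integer array of length n whose
i-th entry is the merging-group label of sub-data set i. The default is
three groups: in practice two potentially isomorphous groups plus a sink
for low-quality wedges. The population is initialised uniformly at random
and evolved by

* **mutation** — with per-individual probability 0.6 a chromosome has each
  position resampled uniformly over all labels at a per-position rate of
  1/n by default. (The headline probability is the chance that the mutation
  operator fires for an individual, the convention of the GA frameworks
  this design follows; a *per-position* rate of 0.6 would reduce the search
  to random sampling.)
* **crossover** — with probability 0.3, single- or double-point (equal
  odds), tails/middle swapped between two tournament-selected parents.
* **selection** — size-2 tournament on fitness, with the single best
  individual carried over unchanged (elitism), so the best-ever fitness is
  monotone.

Every fitness evaluation is appended to an archive that is never pruned;
a run of 150 generations × 50 individuals leaves 7 500 scored groupings
for post-hoc analysis.

### Fitness

Each group with at least `min_group_size` (default 3) members is scored

    score = − w_R·R_meas(inner) + w_I·⟨I/σ⟩(overall) + w_anom·CC_anom(overall)
            + w_half·CC1/2(overall) + w_comp·completeness(overall)
            + w_mult·multiplicity(overall)

and the chromosome's fitness is its best group's score (the other groups act
as sinks; a configuration switch sums the groups instead). R_meas is judged
on the inner resolution shell, all other terms on the overall column. The
default user weights are 1.0, 2.0, 0.0, 1.0, 0.2 and 0.0 respectively. A
statistic that is undefined for a group (e.g. CC_anom without Friedel
coverage) contributes a fixed penalty (default 1000) rather than a silent
zero, so degenerate groups are strongly disfavoured but do not crash the
run. Chromosomes with no qualifying group receive the maximal penalty.

### Weight balancing

The six terms live on wildly different scales (⟨I/σ⟩ in the tens,
correlations near 1). A single calibration generation is evaluated with
unit weights; the best value of each term over all qualifying groups is
collected; the automatic weight of each non-R term is set to
`r_user / best_value`, so at calibration every balanced term tops out at
exactly `r_user`, and the R_meas weight stays at 1. User multipliers are
applied on top — this is the mechanism for emphasising one statistic
(typically the anomalous correlation) without letting it dominate by scale.
Terms whose calibration best is ≤ 0 get weight 0 and are reported.
`r_user` sets the relative strength of the R_meas term against everything
else: since R values on these pools sit near 0.05–0.2, `r_user = 0.1`
weights discrimination by R_meas on a par with each balanced term; this is
the study default used in the recovery experiments.

### Random control

The control with the same evaluation budget evaluates population ×
generations *fresh uniformly random* chromosomes (operators off,
fitness-blind survival). This mirrors building the same number of randomly
merged data sets, which is the distribution the GA must beat. Re-selecting
randomly from a fixed initial population would only ever re-evaluate
population-size distinct groupings and makes no useful null.

### Exhaustive oracle

For small pools the global optimum is found by enumerating all label
assignments, quotiented by group-label permutation (restricted growth
strings), refusing when the raw space g^n exceeds 10^6. The GA is required
to match this optimum on 6–10-wedge pools in ≥ 18/20 seeds.

## Merging statistics

Computed per subset over the inner shell, outer shell (equal-count shelling,
default 10 shells, shell 1 = lowest resolution) and overall (on the
unshelled set, never averaged over shells):

* R_merge = Σ_h Σ_i |I_hi − ⟨I_h⟩| / Σ_h Σ_i I_hi over reflections measured
  ≥ 2 times; R_meas applies the per-reflection √(n/(n−1)) multiplicity
  correction, so R_meas ≥ R_merge always.
* ⟨I/σ⟩ is the inverse-variance merged intensity over its propagated sigma,
  averaged over unique reflections (the scaling-program convention; it
  grows with multiplicity under random error).
* CC1/2 correlates the mean intensities of two seeded random balanced
  half-sets of each reflection's observations; no σ-τ extrapolation.
* CC_anom forms ⟨I+⟩ − ⟨I−⟩ per half-set (requiring ≥ 2 observations per
  Friedel sign) and correlates the two half-set difference series.
* SigAno = mean |⟨I+⟩ − ⟨I−⟩| / √(σ² + σ²) with per-sign inverse-variance
  merging. It is computed on intensities; no French–Wilson conversion to
  amplitudes is performed, a documented deviation from programs that quote
  amplitude-based values.
* Completeness counts reference uniques hit at least once; the default
  reference is every unique index observed anywhere in the pool (an
  explicit reference count can be configured). Multiplicity is observations
  per observed unique.

The half-set split is defined by a per-run random priority per observation:
within each (reflection[, sign]) group the selected observations are ranked
by priority and alternate halves by rank parity. This yields balanced,
seeded, subset-stable splits, and one split seed is fixed per GA run so
fitness values are comparable across chromosomes. Undefined statistics
propagate as missing values, never zero. Symmetry handling defaults to P1
plus Friedel reduction (representative = mate whose first nonzero index is
positive); an explicit operator list extends the orbit for higher symmetry.
Everything is computed from unmerged, already-scaled observations — no
rescaling or outlier rejection is performed here.

An array engine presorts the pool once per run so each of the thousands of
per-subset evaluations reduces to linear `bincount` passes, and per-group
results are cached by group membership; results are identical whether a
subset is evaluated directly or inside a GA run.

## Synthetic data generator

The generator produces pools with known ground truth so that recovery of
anomalous signal can be measured directly (the role that model-phased
anomalous difference maps play for real data).

* **Intensities**: exponential (Wilson-like) with a single overall
  B = 20 Å² falloff, I₀ = 100, cell 50 × 60 × 70 Å orthorhombic (treated as
  P1), resolution 20–2 Å, 600 unique reflections by default.
* **Anomalous signal**: with F = √I, per-reflection amplitude differences
  ΔF ~ N(0, (r·RMS F)²) give ΔI = 2 F ΔF; Friedel mates measure I ± ΔI/2.
  The default Bijvoet ratio r = 1.5% matches the weak-signal regime of the
  experiments this method targets (estimated ratios 1.1–1.7%).
* **Non-isomorphism**: each class carries a fixed per-reflection intensity
  perturbation 2·σ_Δ·I·z (z ~ N(0,1) drawn once per class) — a linearised
  amplitude offset of σ_Δ·|F| — plus an overall scale and B offset. The
  perturbation is shared by both Friedel mates, so Bijvoet differences
  measured within one class are clean; mixing classes corrupts them through
  unbalanced sampling of the two signs across classes, which is exactly the
  mechanism that makes non-isomorphism poisonous to SAD phasing. σ_Δ = 0.15
  ("strong" non-isomorphism) is the study default; it was chosen so that
  mixed-class merges visibly inflate R_meas and depress CC_anom while pure
  classes stay clean, and is a tunable, not a fitted, quantity.
* **Sampling**: 60 wedges by default — two classes of 25 plus 10 junk
  wedges whose noise is 5× inflated. Each wedge covers a completeness drawn
  from N(0.45, 0.046), observes each covered unique 1 + Poisson(1.5) times
  with a random Friedel sign per observation, and reports honest sigmas
  σ = 0.35·√(I + 5) (per-observation I/σ ≈ 25 inner shell to ≈ 4 outer);
  z-scores of noise-only data pass a Kolmogorov–Smirnov normality check.

**Recovery proxy.** `anomalous_recovery` is the Pearson correlation between
merged observed Bijvoet differences and the planted ΔI over Friedel-paired
reflections. Only directions and ranks of this quantity are comparable with
peak-height analyses of real data; absolute map-sigma peak heights are out
of reach by construction.

**What the generator does not emulate**: radiation damage and dose-dependent
scaling, space-group symmetry beyond P1, diffraction-image artefacts,
correlated (non-Gaussian) noise, and partiality. Passing tests demonstrate
the selection machinery under the stated statistical model, not performance
on any particular real data set.

### A note on CC_anom as an optimisation target

In this generator, sufficiently strong non-isomorphism produces *spuriously
high* CC_anom in mixed groups: the class-offset corruption of the Bijvoet
differences contains a component shared between half-sets (set-level
sign-composition imbalance), which half-set correlation cannot distinguish
from signal. A GA told to maximise CC_anom directly will find and exploit
such artefact groups. The study runs therefore use the default user weights
(CC_anom weight 0) and let R_meas, CC1/2 and ⟨I/σ⟩ drive the grouping;
CC_anom and the recovery proxy are then *evaluation* quantities, on which
the selected pure-class groups beat the all-merged set. This mirrors the
practice of judging a grouping by anomalous signal while optimising robust
merging statistics, and is documented here because it is a property of the
synthetic noise model as much as of the statistic.

## Study conditions and problem sizes

Recovery experiments: default pools (60 wedges, 600 uniques), balanced
weights with r_user = 0.1 and the default user weights, population 40,
80 generations, 10 seeds — sizes chosen so a full ten-seed study with its
matched random controls runs in minutes on one core while the GA still
converges well before the generation budget. Oracle comparisons: 6–10-wedge
pools, 120 uniques, 2 groups, population 50, 150 generations, 20 seeds.
Statistic verification: 100 random merged sets of up to ~2 000 observations
against naive loop references at 1e-10.

## Numerical choices and degenerate inputs

* Equal-count shells (populations within ±1) rather than equal-volume;
  degenerate d-spacing distributions and pools with fewer uniques than
  shells are rejected.
* Resolution filtering at load uses the half-open interval (d_min, d_max];
  observations with σ ≤ 0 are dropped and counted, never silently.
* Friedel reduction is deterministic and idempotent; (0,0,0) is rejected
  at d-spacing computation and by the readers.
* Pearson correlations are clipped to [−1, 1] against rounding; zero
  variance in a half-set series makes the statistic undefined (missing).
* Inverse-variance merging uses weights 1/σ²; sigma floors of 1e-8 keep
  the noise-free limit of the generator valid.
* All randomness (population initialisation, operators, half-splits,
  generator) flows from explicit integer seeds through numpy Generators;
  identical (pool, config, seed) gives bit-identical results, including
  byte-identical archive exports.

## Known limitations

* CC1/2 has no σ-τ correction and CC_anom's multiplicity guard (≥ 2 per
  sign) is one convention among several; numerical agreement with any
  specific scaling program's printout is not guaranteed.
* SigAno on intensities is systematically different from amplitude-based
  SigAno.
* The best-group fitness (rather than a sum over groups) is a design
  choice; the alternative is available via `GAConfig.fitness_mode`.
* P1-only symmetry means statistics on real higher-symmetry files treat
  symmetry mates as distinct uniques unless operators are supplied.
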