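# Methods

## The measurement model

`clonaltrace` analyses dual ¹⁵N-labelling experiments on clonal plant
fragments: a parent ramet, an offspring ramet (the growing shoot and, at
the leafing stage, its nascent leaves), and the rhizome connecting them.
Two labelling treatments apply the same tracer dose at different entry
points — cavity injection into the parent culm (PL) or application to the
rhizosphere soil of the rhizome (RL) — alongside an unlabelled control, at
three replicate fragments per treatment, sampled at four growth stages
(ES, PS, BS, LS: early, peak, branching, leafing).

The isotope arithmetic is classical two-pool mixing. For an organ with
measured atom% ¹⁵N equal to *b*, control (background) abundance *a*, and
tracer enrichment *c*:

    Ndff (%)            = 100 · (b − a) / (c − a)
    ¹⁵N_conc (mg kg⁻¹)  = TN_conc (mg kg⁻¹) · Ndff · 10⁻²
    ¹⁵N_content (g)     = ¹⁵N_conc · biomass (kg) · 10⁻³
    recovery (%)        = 100 · Σ_organs ¹⁵N_content / applied ¹⁵N

Units are fixed (mg kg⁻¹ for N concentrations, kg for biomass, g for
contents, mg for tracer masses); loaders validate the column-name
convention rather than converting silently.

Assumptions worth stating: the tracer mixes into each organ's single
well-mixed N pool; background abundance is stationary between control and
labelled fragments; and applied ¹⁵N not found in any organ is reported as
"loss" (for rhizosphere labelling this includes label still resident in
the soil, which is not a sampled compartment).

### Background abundance

*a* is taken per (stage, organ) as the mean of the control replicates;
cells without control rows fall back to a configurable natural-abundance
constant of 0.3663 atom%. Negative Ndff values — measurement noise pushing
*b* below *a* — are retained (preserving mass-balance additivity) and
flagged with a warning; clipping at zero is an opt-in flag.

### Aggregation order

All quantities are computed per replicate first and aggregated to
mean ± SD (n = 3) second, matching how such field data are reported.

## Fate partitioning

* **Allocation shares** divide each organ's replicate-mean ¹⁵N content by
  the applied dose; shares plus unrecovered loss total 100% identically.
* **Source contributions**: with equal doses in the two treatments, the
  offspring ramet's dose-normalised recovery under PL and RL partitions
  its N supply: `parent_share = 100·PL/(PL+RL)`. Shares are computed from
  recoveries rather than raw contents so unequal doses would also be
  handled; an optional mode first divides by each treatment's
  whole-fragment recovery (excluding loss) before splitting.
* **Backflow** between consecutive stages is the net relative decline of a
  compartment's label, `100·(before − after)/before`, computed on
  replicate means (replicate-level series are available); negative values
  mean net gain.
* Organ-to-ramet assignment: leaf + culm → parent; shoot + nascent leaf →
  offspring; the rhizome is its own account.

## The fragment simulator

The simulator is stage-stepped rather than continuous-time: label moves
between seven compartments (soil source pool, leaf, culm, rhizome, shoot,
nascent leaf, loss) through one row-stochastic transfer matrix per stage
transition. Four discrete transitions match the four sampling occasions,
keep ground truth exactly computable by matrix products, and avoid
asserting kinetics the design cannot observe. After each transition the
loss column absorbs the floating-point residue, so label mass is conserved
*exactly*, not approximately.

Organ atom% is reconstructed by inverting the mixing equation:
`b = a₀ + (label / TN_pool)·(c − a₀)`, with the organ's total-N pool given
by its total-N concentration × biomass trajectory. A noise-free simulation
therefore round-trips through the analysis pipeline to the planted truth
at machine precision — the basis of the pipeline-inversion tests.

### Noise model

Measurement noise has two components, each with a distinct physical
source:

* multiplicative lognormal noise (unit mean; default CV 10%) on the
  tracer-derived atom% *excess* and on biomass — fragment-to-fragment
  biological variability in how much label an organ received and how big
  it grew;
* additive Gaussian error on atom% itself (default SD 0.002 atom%) —
  isotope-ratio instrument precision.

Putting the relative noise on the excess rather than on the whole atom%
value reflects how such data behave: isotope-ratio mass spectrometry
resolves atom% to the third decimal, while the tracer-derived excess in a
weakly labelled organ (parent culm, late-stage shoot) can be a hundredth
of the natural abundance. A 10% error on the *whole* atom% of such an
organ would exceed its entire signal many times over and produce recovery
artefacts of tens of percent that real datasets do not show. The additive
instrument term still lets measured atom% dip below background, so the
negative-Ndff path is exercised under realistic conditions.

### The bundled scenario

The default scenario is synthetic throughout; its transfer fractions were
hand-designed once so that the parent-vs-rhizome supply split to the
offspring sweeps from roughly 7:3 at ES through near-parity at PS and BS
to roughly 3:7 at LS, with part of the offspring's label withdrawn into
the parent leaf (30.4% of the offspring pool) and rhizome between BS and
LS under parent labelling. Under equal-dose normalisation this pattern
cannot coexist with a *positive* offspring backflow in the
rhizosphere-labelling arm, because the late rhizome-root dominance
requires continued soil-label uptake into LS; the scenario therefore lets
the RL offspring pool keep rising. Total-N pools are sized so organ atom%
stays well below the tracer enrichment (the soil pool is large relative to
the dose, keeping rhizosphere-treatment enrichments low). Stage
trajectories give the shoot a two-orders-of-magnitude biomass increase
with N-concentration dilution.

### Expression / trait generator

Four physiological traits (TN, NH₄⁺, NO₃⁻, soluble protein) co-vary along
one latent N-status axis with an explicit stage profile peaking at PS —
as the traits of a growing ramet do. Planted trait genes are affine in
that latent axis on the FPKM scale, with cell-level noise calibrated to a
target correlation (default r ≈ 0.95) and small replicate noise; because
the axis itself contrasts ES vs PS, planted trait genes are
simultaneously differentially expressed, so they survive the full funnel
(trait-correlated ⊆ common DEGs), mirroring how a real screen's final
candidates are a subset of the shared DEGs. Planted DEGs get a pure
log₂ shift (default 3) at PS in every organ; background genes draw
lognormal FPKM around gene-specific baselines. Truth labels are returned
for recall/false-positive accounting.

What the generator does **not** emulate: count-based sampling noise
(FPKM are drawn directly, so dispersion–mean coupling and library-size
effects are absent), correlated gene modules beyond the single latent
axis, compositional effects, or batch structure. Passing screens on this
generator therefore demonstrate the correctness of the filtering logic
and its statistical calibration — not robustness to RNA-seq artefacts.

## Statistics

* One-way ANOVA uses the classical between/within decomposition (checked
  against `scipy.stats.f_oneway`); a zero within-group variance with
  distinct means reports a machine-floor p with a warning.
* Normality gating is Shapiro–Wilk at α = 0.05 with a square-root
  fallback transform; constant vectors pass through with a warning.
* **Duncan's multiple range test**: group means are ranked; a stretch of
  p consecutive ranked means is tested against the least significant
  range `q(1−(1−α)^(p−1), p, df)·√(MSE/n_h)` (studentized-range points
  from scipy), with the step-down rule that stretches inside a
  non-significant stretch are non-significant. Unbalanced designs use the
  harmonic mean n_h — a documented convention choice. Letters are
  assembled by insert–absorb, assigned in descending-mean order
  ('a' = highest mean), matching how such figures read. The test suite
  checks both the pairwise decisions and the letter classes against an
  exhaustive brute-force oracle (maximal cliques of the
  not-different graph).
* Pearson correlations carry t-distribution p-values; the screen uses raw
  p < 0.05 as its primary decision rule and always reports
  Benjamini–Hochberg-adjusted values alongside.

## Screening funnel

DEG calling applies the thresholds p < 0.05 and |log₂FC| ≥ 1 to supplied
DE tables when present; otherwise a built-in stand-in (Welch t on
log₂(FPKM+1)) fills in — it is labelled as such and is *not* DESeq2.
Gene–trait correlations pair (organ, stage) mean expression with the
trait table (16 cells; per-replicate pairing is available behind a flag);
a gene survives when significant against all four traits (configurable).
The FPKM abundance floor is inclusive (mean FPKM ≥ 10 passes). The
¹⁵N-correlation screen pairs per-organ stage means of expression with the
organ's ¹⁵N-content trajectory and marks p < 0.05 / p < 0.01 with
star annotations; cells with under three stage pairs or constant
expression stay blank. qPCR quantification is 2^−ΔΔCt.

## Numerical and design choices

* Tracer-salt stoichiometry uses atomic masses ¹⁵N 15.0001, ¹⁴N 14.0031,
  H 1.008, O 15.999; partial enrichment linearly interpolates the mean N
  atomic mass between isotopes.
* Stage order ES < PS < BS < LS is an ordered categorical everywhere; the
  nascent leaf exists only at LS and the validator rejects it elsewhere.
* Output CSVs carry the seed and a configuration hash; identical
  configurations re-run byte-identically.
* Simulation sizes in the test suite — 500 Monte-Carlo draws for
  contribution recovery, 500 seeded expression panels of 40 genes for
  screen calibration, 100 random instances for the Duncan oracle — were
  chosen as the smallest sizes at which the checked rates are stable.

## Known limitations

* The two-source contribution split assumes the two treatments are
  comparable fragments receiving equal doses; it is not a Bayesian mixing
  model and provides no uncertainty interval beyond replicate spread.
* Backflow on stage means cannot distinguish withdrawal from dilution by
  concurrent influx; it is net, not gross.
* The simulator's discrete transitions cannot represent within-stage
  dynamics, and its loss compartment conflates soil residence with true
  system loss for rhizosphere labelling — exactly as the field
  measurement does.
* Duncan's test is implemented for the balanced and mildly unbalanced
  designs it is used for here; strongly unbalanced designs should use a
  different post hoc procedure.
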