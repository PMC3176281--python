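# Methods

## The problem

In a fully censused forest stand every woody stem ≥ 1 cm dbh has mapped
coordinates, a species identity and a diameter, but the roots beneath the
soil surface are invisible. When root fragments from soil cores can be
assigned to taxa (today usually by DNA barcoding), each core becomes a
compositional sample of the root community at a known point. `rootkern`
connects the two data layers with an inverse model: the mapped stems are
the sources, the cores are the samples, and the model parameters describe
how much root mass a stem of a given size produces and how that mass is
spread over the ground around it. The approach is the below-ground
transplant of inverse modeling of seed dispersal from seed-trap data, with
species identities playing the role of seed genotypes.

## The forward model

The relative root-mass density contributed by stem *i* (diameter *z_i* cm,
position *x_i*) at a point *u* is

    m_i(u) = z_i^β · F(‖u − x_i‖; z_i)

* **β** is the mass–diameter scaling exponent: total (sampled-size-class)
  root mass is assumed proportional to *z*^β. The proportionality constant
  is unidentifiable from compositional data and is omitted throughout —
  only proportions ever enter the likelihood, and they are invariant to a
  common rescaling of every stem's mass.
* **F** is a two-dimensional probability density *per unit ground area*:
  ∫ F(r) · 2πr dr = 1 over its support. Six families are implemented
  (`hyperbolic`, `inverse_power`, `exponential`, `gaussian`,
  `linear_threshold`, `constant_threshold`); closed forms are in the
  `rootkern.kernels` docstring. All are nonincreasing in distance.

The distance scale *s* of a family may be constant (*s = α*) or a power
function of diameter (*s = α z^θ*, the `diameter_power` scale mode). The
threshold families have a single distance parameter — their cutoff radius
— so in fitting that cutoff plays the role of α (and may scale with
diameter under `diameter_power`). The hyperbolic family is treated as
scale-free: density falls as 1/r for every stem size, truncated at a fixed
`r_max` (default 50 m) that merely makes it normalizable. That reading
follows its usual role in neighborhood-interference models; an alternative
with a fitted cutoff is one extension point.

The expected composition of a sample at *u* over a taxon list *S* is the
simplex vector

    p_s(u) = Σ_{i ∈ s} m_i(u) / ( Σ_{j ∈ S} m_j(u) + b ),

where *b* ≥ 0 is an optional background density absorbing root mass from
sources absent from the stem map (unmapped lianas, herbs, plants outside
the plot).

## The likelihood

Each sequenced fragment is treated as an independent categorical draw from
the expected composition at its core's location, so a core contributes a
multinomial log-likelihood over its fragment counts. Fragments are the
sampling unit because they are what was individually sequenced; per-fragment
masses, when present, support an alternative least-squares objective on
observed mass proportions (`objective: mass_proportion_ls`).

Taxa observed in cores but absent from the stem map are routed to the
background category when *b* > 0 (each unmatched taxon's probability is
floored at 10⁻⁶ so reference-library gaps cannot produce infinite
penalties); with the background disabled they are excluded from the fitted
taxon set, with a logged count. Unobserved mapped species still appear in
the denominator — they are legitimate zero-count categories of the
multinomial.

Only fragments from the top 20 cm of soil enter the fit by default
(`depth_cutoff`), the depth band for which observations are typically
available at every sampling point.

## Optimization and model selection

Parameters are transformed to an unconstrained scale — logistic-bounded
β ∈ [0, 4] and θ ∈ [0, 2], log-scale-bounded α ∈ [0.25, 100] m and
inverse-power tail p ∈ (2.05, 10] — and each (family, scale-mode)
combination is maximized by Nelder–Mead simplex from `n_starts` seeded
random starts (default 8, seed 20110919); the best local optimum wins and
the full run is bit-reproducible from the seed. Families are compared by
AIC = 2k − 2ℓ (AICc is also reported); ties break toward fewer parameters,
then enumeration order. Parameter counts: hyperbolic 1 (β only),
exponential/gaussian and the threshold families 2 (+1 under
`diameter_power`), inverse-power 3 (+1).

Goodness of fit is summarized as the fraction of variation in observed
proportions explained, 1 − SS_res/SS_tot over all (core, taxon) pairs with
SS_tot about the grand mean; it can be negative for models worse than the
grand mean and is undefined (reported as such) when all observed
proportions are equal.

Numerical details worth knowing:

* The hyperbolic 1/r singularity is integrable; point evaluations below
  r = 10⁻³ m return the value at 10⁻³ m, which does not measurably affect
  any integral or likelihood.
* Supplying `r_max` to a smooth family truncates and renormalizes it
  (closed-form interior masses), giving all families comparable support
  when that is wanted for selection.
* A taxon observed where the model predicts exactly zero yields a large
  finite penalty inside the optimizer (so the simplex can move away) but
  an explicit `inf` plus a report of the offending (core, taxon) pairs
  from the public likelihood function.
* Proportions at points within one cutoff radius (or three distance
  scales) of the mapped boundary are refused by default, because unmapped
  outside stems would bias them; `buffer_available` on the stem map or an
  explicit `ignore_edge` overrides this. Synthetic worlds contain no
  outside stems by construction, so fits on generated data pass
  `ignore_edge=True`.

## The synthetic generator

`rootkern.simulate` emulates the statistical structure of a censused
tropical hectare:

* **Abundances**: log-series across species, the standard model for
  tropical tree communities, calibrated so the expected stem total matches
  the target (the BCI-like preset: 160 species, ≈ 4023 stems on
  100 × 100 m). Every species has abundance ≥ 1, so the preset realizes
  all 160 species; the realized total is high-variance, as real log-series
  communities are.
* **Positions**: homogeneous Poisson. Real stands are clustered; kernel
  fitting under clustering is untested here, and a Thomas-process option
  is a documented extension.
* **Diameters**: shifted exponential above 1 cm with mean 5 cm, plus a 2 %
  log-uniform admixture up to 200 cm standing in for large canopy trees.
* **Cores**: the preset places 13 cores 2.83 m NE of the centers of
  alternate 20 × 20 m subplots; random and explicit layouts are available.
  Fragment counts are uniform on 3–22 per core (the observed range in the
  reference dataset); fragment masses are lognormal with median 0.02 g.
* **Fragment taxa** are multinomial draws from the forward model's
  expected composition at the core, with a configurable fraction (preset
  10 %) routed to an out-of-map "liana-like" taxon to exercise the
  background pathway. The parameter-recovery configuration sets that
  fraction to 0 because its truth is a pure exponential kernel.

What the generator does **not** emulate: spatial clustering of stems,
depth-stratified root profiles, identification error and PCR failure,
interspecific kernel variation, and mass-dependent sequencing success.
Passing recovery tests therefore show that the estimator is consistent and
well-identified under its own assumptions — not that those assumptions
hold in any particular forest.

## Problem sizes used in tests and the acceptance script

Parameter recovery runs 10 replicates of the BCI-like stand sampled with
200 cores × 20 fragments (4000 fragments per replicate), chosen as the
point where the exponent is estimated to ± ≈ 0.05 and family selection is
reliable while a full six-family, multi-start refit of all replicates
completes in minutes on one core. The test suite fits all six families
with 4 starts each; the acceptance script fits the exponential family with
the default 8 starts. Example scripts use smaller stands (60 cores) purely
for narrative speed.

## The reference dataset

The packaged 12-core table ships with two documented caveats (see
`rootkern.fixtures`): per-fragment depths are a convention (all flagged
`depth-unresolved`), and core coordinates are design-derived synthetic
stand-ins, because neither was published. The printed composition table
resolves 32 taxa and 120 fragments while the accompanying narrative counts
33 taxa and 117 fragments; the fixture follows the table (whose row and
column marginals are internally consistent), and the census-summary
constants follow the narrative counts.

## Known limitations

* One shared kernel and one β for all species; per-species kernels are an
  extension point, not implemented.
* No depth-resolved (3-D) forward model.
* No uncertainty intervals (bootstrap / profile likelihood) in this
  version; AIC differences are the only model-comparison currency.
* Real-stand quantities that depend on the external censuses (nearest-stem
  distance distributions, equivalent sampling areas for the real hectare,
  the real-data fit itself) cannot be recomputed from the shipped data;
  the package exposes the operations and degrades explicitly when the
  inputs are absent.
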