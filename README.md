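# rootkern

Inverse modeling of below-ground root distributions in mapped forest
stands.

## The problem

Roots are the invisible half of a forest. In a fully censused stand —
every woody stem ≥ 1 cm dbh mapped, measured and identified — DNA
barcoding can assign root fragments from soil cores to species, turning
each core into a compositional sample of the root community at a known
point. `rootkern` links those samples back to the mapped stems with an
inverse model, for ecologists asking how far trees forage laterally, how
strongly root production scales with stem size, and how many species
overlap below ground at a point.

## The model

Stem *i* with diameter *z_i* contributes relative root-mass density

&nbsp;&nbsp;&nbsp;&nbsp;*m_i(u) = z_i^β · F(‖u − x_i‖; z_i)*

at point *u*, where *F* is a two-dimensional kernel (probability per unit
area, ∫F(r)·2πr dr = 1) from one of six families — hyperbolic, inverse
power, exponential, Gaussian, linear-to-threshold, constant-to-threshold —
whose distance scale is constant (*α*) or diameter-dependent (*αz^θ*).
The expected species composition at *u* is the normalized vector of
per-species contribution sums. Treating each sequenced fragment as an
independent draw from that composition gives a multinomial likelihood;
maximizing it per family and comparing by AIC selects the kernel shape
and estimates the mass-scaling exponent *β*. Descriptive statistics
(per-core richness, species accumulation, nearest-stem distances,
equivalent above-ground sampling areas, per-species density rasters) and a
seeded synthetic-forest generator with known truth complete the toolkit.

## Worked example

```python
from rootkern import (FitConfig, KernelFamily, fit_all, gen_core_dataset,
                      gen_stem_map, make_recovery_config, select_model)

config = make_recovery_config(seed=7, n_cores=60, fragments_per_core=20)
stand = gen_stem_map(config)            # ~4200 stems, 160 species, 1 ha
cores = gen_core_dataset(stand, config) # 60 cores x 20 fragments

fit_config = FitConfig(families=(KernelFamily.EXPONENTIAL,
                                 KernelFamily.GAUSSIAN,
                                 KernelFamily.HYPERBOLIC),
                       n_starts=4, ignore_edge=True)
results = fit_all(cores, stand, fit_config)
best = select_model(results)
```

Running `python examples/03_simulate_and_fit.py` (which is exactly this)
prints:

```
simulated 4212 stems, 60 cores, 1200 fragments
truth: beta = 1.79, family = exponential, alpha = 5.0 m

  family         k      AIC    beta   alpha
  exponential    2    6623.4   1.81   5.20
  gaussian       2    6691.5   1.75   11.68
  hyperbolic     1    7216.2   1.80   -

AIC winner: exponential (beta-hat = 1.81, R^2 on proportions = 0.80)
```

The generating family wins by 68 AIC units, and both the scaling exponent
(truth 1.79) and the kernel scale (truth 5 m) are recovered from
compositional data alone. The other scripts in `examples/` walk through
the packaged 12-core reference dataset (`01`), the forward model (`02`)
and density-raster export (`04`).

A thin CLI wraps the same stages for shell pipelines:

```bash
rootkern simulate --seed 1 --out run/
rootkern fit --stems run/stems.csv --cores run/cores.csv \
             --fragments run/fragments.csv --ignore-edge --out run/fit/
rootkern stats --cores run/cores.csv --fragments run/fragments.csv --out run/stats/
```

## Reference dataset

`rootkern.load_table1_fixture()` returns a packaged 12-core dataset (120
DNA-identified root fragments, 32 taxa) from one censused tropical-forest
hectare, with per-core depth, total root mass and sequenced-mass fraction.
Its per-core richness (mean 4.67, SD 2.06, max 9) and marginals are locked
by tests. Two caveats — conventional fragment depths and synthetic
design-derived core coordinates — are documented in
`rootkern.fixtures` and `docs/methods.md`.

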