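"""The forward model: from mapped stems to expected root composition.

Builds a three-stem toy stand and shows how kernel family, stem diameter
and distance shape the expected species proportions in a soil sample.
"""

from rootkern import (KernelFamily, KernelParams, RootModelParams, Stem,
                      StemMap, expected_proportions, kernel_pdf)

# density per m^2 at 2 m from a stem, for each family at scale/cutoff 5 m
print("kernel densities at r = 2 m (per m^2):")
for family, params in [
    (KernelFamily.HYPERBOLIC, KernelParams(r_max=5.0)),
    (KernelFamily.EXPONENTIAL, KernelParams(alpha=5.0)),
    (KernelFamily.GAUSSIAN, KernelParams(alpha=5.0)),
    (KernelFamily.CONSTANT_THRESHOLD, KernelParams(r_max=5.0)),
]:
    print(f"  {family.value:20s} {kernel_pdf(family, params, 2.0):.5f}")

stems = [
    Stem("big", "quercus", 40.0, 50.0, 60.0),   # large stem, 10 m away
    Stem("near", "ficus", 52.0, 50.0, 8.0),     # small stem, 2 m away
    Stem("far", "ficus", 70.0, 50.0, 8.0),      # small stem, 20 m away
]
stand = StemMap(stems, (0.0, 0.0, 100.0, 100.0))
model = RootModelParams(beta=1.79, family=KernelFamily.EXPONENTIAL,
                        kernel=KernelParams(alpha=5.0))

p = expected_proportions(stand, (50.0, 50.0), model, ["quercus", "ficus"],
                         ignore_edge=True)
print(f"\nexpected root proportions at the sample point: "
      f"quercus {p[0]:.2f}, ficus {p[1]:.2f}")
print("the 60-cm stem dominates from 10 m away: with root mass scaling as "
      "dbh^1.79, size beats proximity.")
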