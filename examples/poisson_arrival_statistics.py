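"""Why multi-crystal indexing matters: Poisson crystal-arrival statistics.

When crystals arrive randomly in the beam, the number of diffraction
patterns per image is Poisson distributed.  This script prints the
closed-form image-class fractions, the mean that maximizes single-crystal
images, and a Monte-Carlo check of the closed forms.
"""

import numpy as np

from pyfelix import poisson_crystal_counts, poisson_expectations
from pyfelix.simulate import max_one_crystal_fraction

lam_star, best = max_one_crystal_fraction()
print(f"optimal Poisson mean: {lam_star:.4f} crystals/image")
print(f"  one-crystal fraction : {100 * best.one_crystal_fraction:.1f} %")
print(f"  hit fraction         : {100 * best.hit_fraction:.1f} %")
print(f"  multi-crystal images : {100 * best.multi_crystal_fraction:.1f} %")
# Even at the single-crystal optimum, more than a quarter of the *hits*
# contain several lattices - discarding them wastes beamtime and sample.

for lam in (0.5, 1.0, 2.0):
    one, hit, multi = poisson_expectations(lam)
    print(f"lambda={lam:3.1f}: one={100 * one:5.1f}%  hit={100 * hit:5.1f}%  "
          f"multi={100 * multi:5.1f}%  multi/hit={100 * multi / hit:5.1f}%")

rng = np.random.default_rng(7)
counts = poisson_crystal_counts(1.0, 200_000, rng)
print(f"Monte-Carlo at lambda=1: one-crystal fraction "
      f"{100 * (counts == 1).mean():.2f} % (closed form "
      f"{100 * poisson_expectations(1.0).one_crystal_fraction:.2f} %)")
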