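"""Spectral signatures of a sparse excitatory/inhibitory network.

Builds a raw Dalean matrix (200 neurons, 10% connectivity, spectral
radius 10, inhibition three times stronger than excitation) and compares
the closed-form predictions — the inhibitory outlier and the outer/inner
radii of the eigenvalue distribution — against a generic eigensolver.
"""

import numpy as np

from schurnet import (
    DaleSpec,
    base_weight,
    empirical_radii,
    init_random,
    predicted_outlier,
    predicted_radii,
)

spec = DaleSpec(N=200, p=0.1, R_outer=10.0, ie_ratio=3.0)
print(f"excitatory weight w0/sqrt(N) = {base_weight(spec) / np.sqrt(spec.N):.2f}")

net = init_random(spec, np.random.default_rng(7))
lam = net.eigenvalues()
print(f"sum of Re(lambda)            = {lam.real.sum():+.2e}  (zero trace, no autapses)")
print(f"outlier: empirical {lam.real.min():8.2f}   predicted {predicted_outlier(spec):8.2f}")

outer, inner = empirical_radii(lam)
outer_pred, inner_pred = predicted_radii(spec)
print(f"outer radius: empirical {outer:6.2f}   construction target {outer_pred:6.2f}")
print(f"inner radius (half-max density): empirical {inner:6.2f}   "
      f"closed form {inner_pred:6.2f}")

# Inhibitory dominance produces one strongly negative real eigenvalue
# (the outlier, ~ E(1 - I/E)) and concentrates the remaining eigenvalues
# towards the origin inside the outer circle of radius R_outer.
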