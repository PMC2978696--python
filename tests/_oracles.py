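"""Independent numeric oracles shared by the tests.

These recompute expected values directly from definitions (quadrature over
the ideal circular-mixture density), independent of the package's
estimators.
"""

import math

import numpy as np
from scipy.integrate import quad
from scipy.special import i0

from cgchannel.potentials import GAS_CONSTANT_KCAL


def mixture_density(theta_deg, components):
    """Circular mixture density per degree. components: (mean_deg, kappa, w)."""
    theta = math.radians(theta_deg)
    dens = 0.0
    for mean, kappa, w in components:
        mu = math.radians(mean)
        if kappa == 0.0:
            dens += w / (2 * math.pi)
        else:
            dens += w * math.exp(kappa * math.cos(theta - mu)) / (2 * math.pi * i0(kappa))
    return dens * math.pi / 180.0  # per degree


def binned_true_entropy_TS(components, bin_width=10.0, temperature=298.0):
    """T*S of the ideal binned mixture by quadrature over each bin."""
    k = int(round(360.0 / bin_width))
    edges = np.linspace(-180.0, 180.0, k + 1)
    p = np.array([quad(mixture_density, lo, hi, args=(components,), limit=200)[0]
                  for lo, hi in zip(edges[:-1], edges[1:])])
    p = p / p.sum()
    p = p[p > 1e-300]
    S = -GAS_CONSTANT_KCAL * float(np.sum(p * np.log(p)))
    return temperature * S
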