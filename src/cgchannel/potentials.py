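"""Pair potentials, forces and the Stokes–Einstein diffusion coefficient.

The nonbonded model is the soft 8–6 Lennard-Jones form

    U_vdw(r) = s * 0.5 * [ (sigma/r)^8 - 1.5 (sigma/r)^6 ],   sigma = r_i + r_j,

whose contact value is U(sigma) = -0.25 s and whose minimum sits at
r = sigma * sqrt(8/9) with depth -0.266968 s, together with a screened
Coulomb term with a distance-dependent dielectric e(r) = 4 r:

    U_elec(r) = C q_i q_j / (4 r^2),   C = 332.06 kcal Å / (mol e^2).

Energies are kcal/mol, distances Å, charges elementary charges.
"""

from __future__ import annotations

import math

import numpy as np

#: Coulomb constant in kcal·Å/(mol·e²).
COULOMB_CONSTANT = 332.06

#: Gas constant in kcal/(mol·K).
GAS_CONSTANT_KCAL = 1.9872e-3

#: Boltzmann constant (J/K) — used only inside Stokes–Einstein.
_KB_SI = 1.380649e-23


class SingularityError(ValueError):
    """Two interacting beads coincide (r_ij ~ 0)."""


def vdw_energy(r_i: float, r_j: float, r_ij, energy_scale: float = 1.0):
    """Soft 8–6 van der Waals energy between beads of radii ``r_i``/``r_j``.

    ``energy_scale`` multiplies the bare 0.5 prefactor; the default 1.0
    means the bracketed form is read directly in kcal/mol (well depth
    ~0.267 kcal/mol, a weak, mostly steric interaction).
    """
    r_ij = np.asarray(r_ij, dtype=float)
    if np.any(r_ij <= 0):
        raise SingularityError("vdw_energy undefined for r_ij <= 0")
    x = (r_i + r_j) / r_ij
    x6 = x ** 6
    return energy_scale * 0.5 * (x6 * x * x - 1.5 * x6)


def vdw_force_mag(r_i: float, r_j: float, r_ij, energy_scale: float = 1.0):
    """-dU_vdw/dr; positive = repulsive (force pushes the pair apart)."""
    r_ij = np.asarray(r_ij, dtype=float)
    if np.any(r_ij <= 0):
        raise SingularityError("vdw force undefined for r_ij <= 0")
    sigma = r_i + r_j
    x = sigma / r_ij
    x6 = x ** 6
    # dU/dr = 0.5 s [ -8 sigma^8/r^9 + 9 sigma^6/r^7 ]
    return energy_scale * 0.5 * (8.0 * x6 * x * x - 9.0 * x6) / r_ij


def coulomb_energy(q_i: float, q_j: float, r_ij):
    """Screened Coulomb energy with distance-dependent dielectric 4r:
    U = C q_i q_j / (4 r^2)."""
    r_ij = np.asarray(r_ij, dtype=float)
    if np.any(r_ij <= 0):
        raise SingularityError("coulomb_energy undefined for r_ij <= 0")
    return COULOMB_CONSTANT * q_i * q_j / (4.0 * r_ij ** 2)


def coulomb_force_mag(q_i: float, q_j: float, r_ij):
    """-dU_elec/dr for the 1/(4 r^2) screened form: C q_i q_j / (2 r^3)."""
    r_ij = np.asarray(r_ij, dtype=float)
    if np.any(r_ij <= 0):
        raise SingularityError("coulomb force undefined for r_ij <= 0")
    return COULOMB_CONSTANT * q_i * q_j / (2.0 * r_ij ** 3)


def diffusion_coefficient(radius: float, temperature: float = 293.0,
                          viscosity: float = 1.0) -> float:
    """Stokes–Einstein diffusion coefficient in Å²/ns.

    Parameters
    ----------
    radius : float, Å — hydrodynamic bead radius.
    temperature : float, K.
    viscosity : float, centipoise (1 cp = 1e-3 Pa·s, water at ~293 K).
    """
    if radius <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("radius, temperature and viscosity must be positive")
    d_si = _KB_SI * temperature / (6.0 * math.pi * viscosity * 1e-3 * radius * 1e-10)
    return d_si * 1e11  # m²/s -> Å²/ns


def switch_function(r, switch_start: float, cutoff: float):
    """Cubic switch s(r): 1 below ``switch_start``, 0 above ``cutoff``,
    C¹-smooth in between. Returns (s, ds/dr)."""
    r = np.asarray(r, dtype=float)
    t = np.clip((r - switch_start) / (cutoff - switch_start), 0.0, 1.0)
    s = 1.0 - 3.0 * t ** 2 + 2.0 * t ** 3
    ds = (-6.0 * t + 6.0 * t ** 2) / (cutoff - switch_start)
    ds = np.where((r > switch_start) & (r < cutoff), ds, 0.0)
    return s, ds


def pair_energy_force(delta: np.ndarray, r_i: float, r_j: float,
                      q_i: float, q_j: float, energy_scale: float,
                      switch_start: float, cutoff: float):
    """Switched energy and force vector on bead i for one pair.

    ``delta`` is x_i - x_j (Å). Returns (U, F_i) with the cubic switch
    applied to the summed vdW + Coulomb pair term.
    """
    r = float(np.linalg.norm(delta))
    if r >= cutoff:
        return 0.0, np.zeros(3)
    if r < 0.01:
        raise SingularityError(f"bead overlap: r_ij = {r:.4f} Å")
    u = vdw_energy(r_i, r_j, r, energy_scale) + coulomb_energy(q_i, q_j, r)
    f = vdw_force_mag(r_i, r_j, r, energy_scale) + coulomb_force_mag(q_i, q_j, r)
    s, ds = switch_function(r, switch_start, cutoff)
    # d(U s)/dr = U' s + U s'  ->  force magnitude = f s - U ds
    fmag = f * float(s) - u * float(ds)
    return u * float(s), fmag * delta / r
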