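"""Brownian dynamics propagation of the two-bead indole through a rigid
coarse-grained protein.

The propagator is the overdamped Ermak–McCammon step: per bead,

    dx = (D dt / kT) F + R,    R ~ N(0, 2 D dt) per coordinate,

followed by re-imposition of the rigid virtual bond (both beads projected
so the pair midpoint is preserved and the inter-bead distance equals the
bond length).  A trajectory terminates when indole reaches the β-site
(any bead within the reaction distance of the β-site center — tested
first), escapes (both beads farther than the escape radius from the α-site
center), or exhausts the time cap, in which case the channel is considered
blocked.

The inner loop is compiled with numba and consumes Gaussian noise generated
in chunks by a seeded numpy Generator, so a trajectory is bit-reproducible
for a given seed.  :func:`bd_step` is the plain-Python reference update used
by the unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .model import CGProtein, IndoleLigand
from .potentials import (
    GAS_CONSTANT_KCAL,
    COULOMB_CONSTANT,
    SingularityError,
    diffusion_coefficient,
    pair_energy_force,
    vdw_energy,
)

__all__ = [
    "BDParams", "TrajectoryResult", "PropagationError",
    "total_force", "bd_step", "run_trajectory", "free_single_bead_msd",
]

_NOISE_CHUNK = 200_000

OUTCOME_REACHED = "reached"
OUTCOME_ESCAPED = "escaped"
OUTCOME_BLOCKED = "blocked"
OUTCOME_INVALID = "invalid_start"


class PropagationError(RuntimeError):
    """Non-finite displacement or bead overlap during propagation."""


@dataclass(frozen=True)
class BDParams:
    """Simulation parameters.

    timestep_fs : BD time step (fs); 50 fs by default.
    temperature : K; the channeling simulations use 293 K (water, 1 cp).
    viscosity_cp : solvent viscosity in centipoise.
    max_time_us : trajectory cap in µs; a trajectory that neither reaches
        nor escapes within the cap is classified blocked.
    escape_radius : Å from the α-site center beyond which indole (both
        beads) is considered escaped.
    reaction_distance : Å from the β-site center within which indole (any
        bead) is considered to have reacted.
    nonbond_cutoff / switch_start : Å; pair interactions are smoothly
        switched to zero between switch_start and the cutoff.
    lj_energy_scale : multiplier on the 8–6 van der Waals form (kcal/mol).
    snapshot_interval : steps between recorded indole positions (0 = none).
    """

    timestep_fs: float = 50.0
    temperature: float = 293.0
    viscosity_cp: float = 1.0
    max_time_us: float = 4.0
    escape_radius: float = 40.0
    reaction_distance: float = 5.0
    nonbond_cutoff: float = 20.0
    switch_start: float = 18.0
    lj_energy_scale: float = 1.0
    dielectric_model: str = "distance_dependent_4r"
    snapshot_interval: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")
        if not self.escape_radius > self.reaction_distance > 0:
            raise ValueError("need escape_radius > reaction_distance > 0")
        if self.switch_start >= self.nonbond_cutoff:
            raise ValueError("switch_start must lie below the cutoff")
        if self.dielectric_model != "distance_dependent_4r":
            raise ValueError(f"unknown dielectric model {self.dielectric_model!r}")
        n = self.max_time_us * 1e9 / self.timestep_fs
        if abs(n - round(n)) > 1e-6:
            raise ValueError("max_time must be a whole number of steps")

    @property
    def n_steps(self) -> int:
        return int(round(self.max_time_us * 1e9 / self.timestep_fs))

    @property
    def timestep_ns(self) -> float:
        return self.timestep_fs * 1e-6

    @property
    def kT(self) -> float:
        """Thermal energy in kcal/mol."""
        return GAS_CONSTANT_KCAL * self.temperature


@dataclass
class TrajectoryResult:
    """Outcome of one BD trajectory."""

    outcome: str
    n_steps: int
    travel_time_ns: Optional[float]
    seed: int
    samples: Optional[np.ndarray] = field(default=None, repr=False)
    # samples columns: time_ns, x1, y1, z1, x2, y2, z2


def total_force(indole_positions: np.ndarray, protein: CGProtein,
                params: BDParams, indole: IndoleLigand | None = None) -> np.ndarray:
    """Analytic forces (kcal/mol/Å) on the two indole beads.

    Negative gradient of the switched vdW + Coulomb pair sum over
    protein–indole pairs within the cutoff.  Reference implementation used
    for validation; the propagation kernel computes the same quantity.
    """
    if indole is None:
        indole = IndoleLigand()
    pos = np.asarray(indole_positions, dtype=float).reshape(2, 3)
    forces = np.zeros((2, 3))
    ppos, prad, pq = protein.positions, protein.radii, protein.charges
    for i in range(2):
        for j in range(len(ppos)):
            delta = pos[i] - ppos[j]
            if np.abs(delta).max() >= params.nonbond_cutoff:
                continue
            _, f = pair_energy_force(
                delta, indole.radii[i], prad[j], indole.charges[i], pq[j],
                params.lj_energy_scale, params.switch_start, params.nonbond_cutoff,
            )
            forces[i] += f
    return forces


def _apply_bond_constraint(pos: np.ndarray, bond_length: float) -> np.ndarray:
    mid = pos.mean(axis=0)
    d = pos[1] - pos[0]
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        # Degenerate collapse: restore along z.
        d = np.array([0.0, 0.0, 1.0])
        norm = 1.0
    half = 0.5 * bond_length * d / norm
    return np.stack([mid - half, mid + half])


def bd_step(indole: IndoleLigand, forces: np.ndarray, params: BDParams,
            rng: np.random.Generator, dt_ns: float | None = None) -> np.ndarray:
    """One Ermak–McCammon step (reference path).

    Returns new (2, 3) positions; the rigid bond constraint is re-imposed by
    projecting both beads about the preserved midpoint.  ``dt_ns`` overrides
    the params time step (``dt_ns=0`` leaves positions exactly unchanged).
    """
    if indole.bond_model != "rigid_constraint":
        raise NotImplementedError("only the rigid virtual bond is propagated")
    forces = np.asarray(forces, dtype=float).reshape(2, 3)
    if not np.all(np.isfinite(forces)):
        raise PropagationError("non-finite forces entering bd_step")
    dt = params.timestep_ns if dt_ns is None else dt_ns
    D = np.array([diffusion_coefficient(r, params.temperature, params.viscosity_cp)
                  for r in indole.radii])
    drift = (D * dt / params.kT)[:, None] * forces
    noise = rng.standard_normal((2, 3)) * np.sqrt(2.0 * D * dt)[:, None]
    new = indole.positions + drift + noise
    if not np.all(np.isfinite(new)):
        raise PropagationError("non-finite displacement")
    return _apply_bond_constraint(new, indole.bond_length)


@njit(cache=True)
def _forces_kernel(pos, ppos, prad, pq, irad, iq, lj_scale, switch_start, cutoff,
                   nbr, n_nbr, out):
    out[:, :] = 0.0
    cut2 = cutoff * cutoff
    for i in range(2):
        for jj in range(n_nbr):
            j = nbr[jj]
            dx = pos[i, 0] - ppos[j, 0]
            dy = pos[i, 1] - ppos[j, 1]
            dz = pos[i, 2] - ppos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= cut2:
                continue
            r = np.sqrt(r2)
            if r < 0.01:
                return -1
            sigma = irad[i] + prad[j]
            x = sigma / r
            x6 = x ** 6
            x8 = x6 * x * x
            u = lj_scale * 0.5 * (x8 - 1.5 * x6)
            f = lj_scale * 0.5 * (8.0 * x8 - 9.0 * x6) / r
            qq = iq[i] * pq[j]
            if qq != 0.0:
                u += COULOMB_CONSTANT * qq / (4.0 * r2)
                f += COULOMB_CONSTANT * qq / (2.0 * r2 * r)
            if r > switch_start:
                t = (r - switch_start) / (cutoff - switch_start)
                s = 1.0 - 3.0 * t * t + 2.0 * t * t * t
                ds = (-6.0 * t + 6.0 * t * t) / (cutoff - switch_start)
                f = f * s - u * ds
            inv = f / r
            out[i, 0] += dx * inv
            out[i, 1] += dy * inv
            out[i, 2] += dz * inv
    return 0


@njit(cache=True)
def _run_chunk(pos, ppos, prad, pq, irad, iq, mobility, noise_scale, bond_length,
               noise, lj_scale, switch_start, cutoff,
               alpha_c, beta_c, escape_r, react_d,
               sample_interval, step0, dt_ns, samples, n_samples_in):
    """Advance up to noise.shape[0] steps; returns (status, steps_done, n_samples).

    status: 0 = cap not yet reached, 1 = reached, 2 = escaped, 3 = overlap error.
    """
    forces = np.zeros((2, 3))
    react2 = react_d * react_d
    escape2 = escape_r * escape_r
    n_samples = n_samples_in
    nsteps = noise.shape[0]
    # Verlet neighbor list about the bead midpoint, rebuilt when the
    # midpoint has moved more than half the skin since the last build
    skin = 4.0
    half_bond = 0.5 * bond_length
    list_r2 = (cutoff + half_bond + skin) ** 2
    nbr = np.empty(ppos.shape[0], dtype=np.int64)
    n_nbr = 0
    ref0 = 1e30
    ref1 = 1e30
    ref2 = 1e30
    for k in range(nsteps):
        mx0 = 0.5 * (pos[0, 0] + pos[1, 0])
        my0 = 0.5 * (pos[0, 1] + pos[1, 1])
        mz0 = 0.5 * (pos[0, 2] + pos[1, 2])
        dref = (mx0 - ref0) ** 2 + (my0 - ref1) ** 2 + (mz0 - ref2) ** 2
        if dref > (0.5 * skin) ** 2:
            n_nbr = 0
            for j in range(ppos.shape[0]):
                ddx = mx0 - ppos[j, 0]
                ddy = my0 - ppos[j, 1]
                ddz = mz0 - ppos[j, 2]
                if ddx * ddx + ddy * ddy + ddz * ddz < list_r2:
                    nbr[n_nbr] = j
                    n_nbr += 1
            ref0, ref1, ref2 = mx0, my0, mz0
        err = _forces_kernel(pos, ppos, prad, pq, irad, iq,
                             lj_scale, switch_start, cutoff, nbr, n_nbr, forces)
        if err != 0:
            return 3, k, n_samples
        for i in range(2):
            for c in range(3):
                pos[i, c] += mobility[i] * forces[i, c] + noise_scale[i] * noise[k, i, c]
        # rigid bond: project about midpoint
        mx = 0.5 * (pos[0, 0] + pos[1, 0])
        my = 0.5 * (pos[0, 1] + pos[1, 1])
        mz = 0.5 * (pos[0, 2] + pos[1, 2])
        dx = pos[1, 0] - pos[0, 0]
        dy = pos[1, 1] - pos[0, 1]
        dz = pos[1, 2] - pos[0, 2]
        norm = np.sqrt(dx * dx + dy * dy + dz * dz)
        if norm < 1e-12:
            dx, dy, dz, norm = 0.0, 0.0, 1.0, 1.0
        h = 0.5 * bond_length / norm
        pos[0, 0] = mx - dx * h
        pos[0, 1] = my - dy * h
        pos[0, 2] = mz - dz * h
        pos[1, 0] = mx + dx * h
        pos[1, 1] = my + dy * h
        pos[1, 2] = mz + dz * h

        step = step0 + k + 1
        if sample_interval > 0 and step % sample_interval == 0:
            samples[n_samples, 0] = step * dt_ns
            samples[n_samples, 1:4] = pos[0]
            samples[n_samples, 4:7] = pos[1]
            n_samples += 1

        # termination: reached tested before escaped
        reached = False
        for i in range(2):
            ddx = pos[i, 0] - beta_c[0]
            ddy = pos[i, 1] - beta_c[1]
            ddz = pos[i, 2] - beta_c[2]
            if ddx * ddx + ddy * ddy + ddz * ddz < react2:
                reached = True
        if reached:
            return 1, k + 1, n_samples
        escaped = True
        for i in range(2):
            ddx = pos[i, 0] - alpha_c[0]
            ddy = pos[i, 1] - alpha_c[1]
            ddz = pos[i, 2] - alpha_c[2]
            if ddx * ddx + ddy * ddy + ddz * ddz <= escape2:
                escaped = False
        if escaped:
            return 2, k + 1, n_samples
    return 0, nsteps, n_samples


def _resolve_initial_overlap(pos: np.ndarray, protein: CGProtein,
                             indole: IndoleLigand, params: BDParams,
                             max_iter: int = 100) -> np.ndarray | None:
    """Steepest-descent relaxation of indole only, used when superposition
    places a bead inside a protein bead.  Returns relaxed positions or None
    if the overlap cannot be resolved."""
    ppos, prad = protein.positions, protein.radii

    def overlapped(p):
        d = np.linalg.norm(p[:, None, :] - ppos[None, :, :], axis=2)
        sigma = indole.radii[:, None] + prad[None, :]
        return bool(np.any(d < 0.75 * sigma))

    pos = pos.copy()
    for _ in range(max_iter):
        if not overlapped(pos):
            return pos
        # rigid-body descent: translate the pair along the mean force (the
        # midpoint projection cancels equal-and-opposite per-bead pushes)
        direction = np.zeros(3)
        try:
            direction = total_force(pos, protein, params, indole).mean(axis=0)
        except SingularityError:
            pass
        norm = np.linalg.norm(direction)
        if norm < 1e-9:
            mid = pos.mean(axis=0)
            j = int(np.argmin(np.linalg.norm(ppos - mid, axis=1)))
            direction = mid - ppos[j]
            norm = np.linalg.norm(direction)
            if norm < 1e-9:
                direction, norm = np.array([0.0, 0.0, 1.0]), 1.0
        pos = pos + 0.15 * direction / norm
    return pos if not overlapped(pos) else None


def run_trajectory(protein: CGProtein, indole: IndoleLigand, params: BDParams,
                   seed: int) -> TrajectoryResult:
    """Run one trajectory until it reaches the β-site, escapes, or hits the
    time cap (blocked).  Bit-reproducible for a given seed."""
    if indole.bond_model != "rigid_constraint":
        raise NotImplementedError("only the rigid virtual bond is propagated")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pos = indole.positions.astype(float).copy()
    alpha_c = protein.alpha_center
    beta_c = protein.beta_center

    pos_relaxed = _resolve_initial_overlap(pos, protein, indole, params)
    if pos_relaxed is None:
        return TrajectoryResult(OUTCOME_INVALID, 0, None, seed)
    pos = np.ascontiguousarray(pos_relaxed)

    # immediate satisfaction at t = 0
    if np.min(np.linalg.norm(pos - beta_c, axis=1)) < params.reaction_distance:
        return TrajectoryResult(OUTCOME_REACHED, 0, 0.0, seed)
    if np.min(np.linalg.norm(pos - alpha_c, axis=1)) > params.escape_radius:
        return TrajectoryResult(OUTCOME_ESCAPED, 0, None, seed)

    dt = params.timestep_ns
    D = np.array([diffusion_coefficient(r, params.temperature, params.viscosity_cp)
                  for r in indole.radii])
    mobility = D * dt / params.kT
    noise_scale = np.sqrt(2.0 * D * dt)
    ppos = np.ascontiguousarray(protein.positions)
    prad = protein.radii
    pq = protein.charges

    interval = int(params.snapshot_interval)
    sample_chunks = []
    if interval > 0:
        first = np.empty((1, 7))
        first[0, 0] = 0.0
        first[0, 1:4] = pos[0]
        first[0, 4:7] = pos[1]
        sample_chunks.append(first)

    total_steps = params.n_steps
    done = 0
    status = 0
    while done < total_steps:
        chunk = min(_NOISE_CHUNK, total_steps - done)
        noise = rng.standard_normal((chunk, 2, 3))
        cap = (chunk // interval + 2) if interval > 0 else 1
        buf = np.empty((cap, 7))
        status, used, nsamp = _run_chunk(
            pos, ppos, prad, pq, indole.radii, indole.charges,
            mobility, noise_scale, indole.bond_length, noise,
            params.lj_energy_scale, params.switch_start, params.nonbond_cutoff,
            alpha_c, beta_c, params.escape_radius, params.reaction_distance,
            interval, done, dt, buf, 0,
        )
        done += used
        if interval > 0 and nsamp > 0:
            sample_chunks.append(buf[:nsamp])
        if status == 3:
            raise PropagationError(
                f"bead overlap after {done} steps (seed {seed}); positions: {pos}")
        if status != 0:
            break

    samples = np.vstack(sample_chunks) if sample_chunks else None
    if status == 1:
        return TrajectoryResult(OUTCOME_REACHED, done, done * dt, seed, samples)
    if status == 2:
        return TrajectoryResult(OUTCOME_ESCAPED, done, None, seed, samples)
    return TrajectoryResult(OUTCOME_BLOCKED, done, None, seed, samples)


def free_single_bead_msd(radius: float, n_steps: int, n_replicates: int,
                         params: BDParams, seed: int) -> tuple[float, float]:
    """Force-free diffusion diagnostic for a single unbonded bead.

    Propagates the exact Ermak–McCammon step with zero force, vectorized
    over replicates.  MSD/t is estimated the way diffusion coefficients are
    read off MD MSD curves: displacements over ten disjoint time windows
    (time-origin averaging) pooled across replicates, so every step of every
    replicate contributes an independent increment.  Returns the estimate
    extrapolated to t_final = n_steps·dt and the theoretical 6·D·t_final.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    dt = params.timestep_ns
    D = diffusion_coefficient(radius, params.temperature, params.viscosity_cp)
    scale = np.sqrt(2.0 * D * dt)
    window = max(1, n_steps // 10)
    disp = np.zeros((n_replicates, 3))
    window_msds = []
    for step in range(1, n_steps + 1):
        disp += scale * rng.standard_normal((n_replicates, 3))
        if step % window == 0:
            window_msds.append(float(np.mean(np.sum(disp ** 2, axis=1))))
            disp[:] = 0.0
    rate = float(np.mean(window_msds)) / (window * dt)
    t_final = n_steps * dt
    return rate * t_final, 6.0 * D * t_final


def free_dimer_msd(n_steps: int, n_replicates: int, params: BDParams,
                   seed: int, indole: IndoleLigand | None = None
                   ) -> tuple[float, float]:
    """Force-free diffusion of the constrained two-bead indole.

    Returns (measured midpoint MSD at t = n_steps·dt, 6·D_pair·t) where
    D_pair = (D1 + D2)/4 is the exact midpoint diffusion coefficient of the
    rigid pair: the projection preserves the midpoint, whose update is the
    mean of the two independent bead displacements.  D_pair is below either
    single-bead coefficient.
    """
    if indole is None:
        indole = IndoleLigand()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    dt = params.timestep_ns
    D = np.array([diffusion_coefficient(r, params.temperature, params.viscosity_cp)
                  for r in indole.radii])
    scale = np.sqrt(2.0 * D * dt)
    half = 0.5 * indole.bond_length
    pos = np.zeros((n_replicates, 2, 3))
    pos[:, 0, 2] = -half
    pos[:, 1, 2] = +half
    start_mid = pos.mean(axis=1).copy()
    for _ in range(n_steps):
        pos += scale[None, :, None] * rng.standard_normal((n_replicates, 2, 3))
        mid = pos.mean(axis=1, keepdims=True)
        d = pos[:, 1] - pos[:, 0]
        norm = np.linalg.norm(d, axis=1, keepdims=True)
        u = d / norm
        pos[:, 0] = mid[:, 0] - half * u
        pos[:, 1] = mid[:, 0] + half * u
    disp = pos.mean(axis=1) - start_mid
    msd = float(np.mean(np.sum(disp ** 2, axis=1)))
    d_pair = 0.25 * (D[0] + D[1])
    return msd, 6.0 * d_pair * n_steps * dt
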