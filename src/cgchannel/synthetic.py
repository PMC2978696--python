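"""Synthetic test systems with known ground truth.

Two generators live here:

* :func:`make_toy_channel` builds a rigid bead-wall "channel protein" —
  two spherical pockets joined by a cylindrical tunnel of wall beads —
  mimicking the geometry an indole intermediate crosses between the α- and
  β-active sites.  Variants with a wall aperture (leaky, escape-prone), or
  an axial plug bead (blocked) emulate open, leaking and obstructed
  channel conformations.

* :func:`sample_dihedral_series` draws dihedral-angle time series from a
  mixture of von Mises (circular normal) components with known binned
  entropy, for validating the configurational-entropy estimator.

Wall beads are laid out on staggered rings (cylinder) and Fibonacci
lattices (spheres) with centre spacing at most twice the wall-bead radius,
so adjacent bead surfaces overlap and the wall is sterically closed to the
1.6/1.9 Å indole beads unless an aperture is cut explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import CGBead, CGProtein, InvalidSpecError, SiteDefinition
from .entropy import DihedralSeries

__all__ = [
    "ToyChannelSpec", "DihedralSimSpec", "make_toy_channel",
    "sample_dihedral_series", "write_toy_pdb", "three_state_specs",
]

_GOLDEN = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class ToyChannelSpec:
    """Geometry of a toy channel (all lengths in Å).

    The tunnel runs along +z from the α-pocket center at the origin to the
    β-pocket center at ``(0, 0, tunnel_length)``.  ``leak`` is an optional
    ``(axial_position, aperture_radius)`` pair cutting a hole through the
    wall; ``constriction`` an optional ``(axial_position, plug_bead_radius)``
    pair inserting a plug bead on the axis.
    """

    tunnel_length: float = 25.0
    tunnel_inner_radius: float = 4.0
    wall_bead_radius: float = 2.0
    wall_bead_spacing: float = 3.0
    pocket_radius_alpha: float = 8.0
    pocket_radius_beta: float = 6.0
    leak: Optional[tuple[float, float]] = None
    constriction: Optional[tuple[float, float]] = None
    seed: int = 0

    def __post_init__(self):
        if self.tunnel_length <= 0:
            raise InvalidSpecError("tunnel_length must be positive")
        if self.tunnel_inner_radius <= 0:
            raise InvalidSpecError("tunnel_inner_radius must be positive")
        if self.wall_bead_spacing > 2.0 * self.wall_bead_radius:
            raise InvalidSpecError(
                "wall_bead_spacing must not exceed twice the wall bead radius "
                "(steric closure)")
        for name, rp in (("alpha", self.pocket_radius_alpha), ("beta", self.pocket_radius_beta)):
            if rp <= self.tunnel_inner_radius:
                raise InvalidSpecError(
                    f"pocket_radius_{name} must exceed tunnel_inner_radius "
                    "(otherwise no interior pocket volume remains)")
        for what in (self.leak, self.constriction):
            if what is not None:
                z, r = what
                if not (0.0 <= z <= self.tunnel_length):
                    raise InvalidSpecError("axial position must lie in [0, tunnel_length]")
                if r <= 0:
                    raise InvalidSpecError("aperture/plug radius must be positive")


@dataclass(frozen=True)
class DihedralSimSpec:
    """A circular-mixture dihedral model: components of (mean_angle deg,
    concentration kappa, weight)."""

    components: tuple[tuple[float, float, float], ...]
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self):
        comps = tuple((float(m), float(k), float(w)) for m, k, w in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise InvalidSpecError("need at least one mixture component")
        for _, kappa, w in comps:
            if kappa < 0:
                raise InvalidSpecError(f"concentration kappa must be >= 0, got {kappa}")
            if w < 0:
                raise InvalidSpecError("component weights must be non-negative")
        if abs(sum(w for _, _, w in comps) - 1.0) > 1e-8:
            raise InvalidSpecError("component weights must sum to 1")
        if self.n_frames < 1:
            raise InvalidSpecError("n_frames must be >= 1")


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = _GOLDEN * i
    return radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _pocket_beads(center_z: float, shell_radius: float, spacing: float,
                  opening_toward: float, opening_rho: float) -> np.ndarray:
    """Fibonacci shell around (0,0,center_z) with a circular opening facing
    the tunnel (direction sign ``opening_toward``).  The point density is
    set slightly above hexagonal packing at the wall spacing, so adjacent
    bead surfaces overlap (spacing <= 2 x bead radius)."""
    n = max(16, int(math.ceil(4.0 * math.pi * shell_radius ** 2 / (0.72 * spacing ** 2))))
    pts = _fibonacci_sphere(n, shell_radius)
    rho = np.hypot(pts[:, 0], pts[:, 1])
    facing = pts[:, 2] * opening_toward > 0
    keep = ~(facing & (rho < opening_rho))
    pts = pts[keep]
    pts[:, 2] += center_z
    return pts


def _equator_ring(center_z: float, ring_radius: float, n: int = 12) -> np.ndarray:
    ang = 2.0 * math.pi * np.arange(n) / n
    return np.column_stack([ring_radius * np.cos(ang),
                            ring_radius * np.sin(ang),
                            np.full(n, center_z)])


def make_toy_channel(spec: ToyChannelSpec) -> CGProtein:
    """Build the rigid toy channel as a :class:`CGProtein`.

    The α-site (β-site) is defined by a 12-bead ring placed exactly on the
    pocket equator, so the site center coincides with the pocket center by
    symmetry; the channel axis is the straight segment between the two
    pocket centers.  Construction is deterministic (the lattice layout has
    no random element; ``spec.seed`` is carried through for provenance).
    """
    s = spec.wall_bead_spacing
    rw = spec.wall_bead_radius
    L = spec.tunnel_length
    wall_c = spec.tunnel_inner_radius + rw           # cylinder of bead centers
    shell_a = spec.pocket_radius_alpha + rw
    shell_b = spec.pocket_radius_beta + rw
    if shell_a <= wall_c or shell_b <= wall_c:
        raise InvalidSpecError("pocket shell must be wider than the tunnel wall")

    # tunnel wall: staggered rings of beads, flush with the pocket shells so
    # the interior wall surface runs continuously from pocket into tunnel
    # (the ring-to-shell seam beads overlap, keeping the junction watertight)
    z_ja = math.sqrt(shell_a ** 2 - wall_c ** 2)
    z_jb = math.sqrt(shell_b ** 2 - wall_c ** 2)
    n_rows = max(2, int(math.ceil((L - z_jb - z_ja) / s)) + 1)
    ring_z = np.linspace(z_ja, L - z_jb, n_rows)
    n_ring = max(6, int(math.ceil(2.0 * math.pi * wall_c / s)))
    tunnel = []
    for k, z in enumerate(ring_z):
        ang = 2.0 * math.pi * (np.arange(n_ring) + 0.5 * (k % 2)) / n_ring
        tunnel.append(np.column_stack([wall_c * np.cos(ang),
                                       wall_c * np.sin(ang),
                                       np.full(n_ring, z)]))
    tunnel = np.vstack(tunnel)

    open_rho = wall_c + 0.3 * s
    alpha_shell = _pocket_beads(0.0, shell_a, s, +1.0, open_rho)
    beta_shell = _pocket_beads(L, shell_b, s, -1.0, open_rho)
    alpha_ring = _equator_ring(0.0, shell_a)
    beta_ring = _equator_ring(L, shell_b)

    groups = [
        ("W", "WAL", tunnel),
        ("C", "WAL", alpha_shell),
        ("D", "WAL", beta_shell),
        ("A", "SIT", alpha_ring),
        ("B", "SIT", beta_ring),
    ]
    plug = None
    if spec.constriction is not None:
        z_plug, r_plug = spec.constriction
        plug = np.array([[0.0, 0.0, z_plug]])
        groups.append(("P", "PLG", plug))

    beads: list[CGBead] = []
    for chain, resname, pts in groups:
        # site-marker rings are kept out of the aperture cut so the site
        # centers stay pinned to the pocket centers by symmetry
        if spec.leak is not None and resname == "WAL":
            z_leak, aperture = spec.leak
            rho = np.hypot(pts[:, 0], pts[:, 1])
            # arc-distance from the aperture center at azimuth 0, height z_leak
            arc = rho * np.abs(np.arctan2(pts[:, 1], pts[:, 0]))
            hole = (np.abs(pts[:, 2] - z_leak) < aperture) & (arc < aperture)
            pts = pts[~hole]
        radius = rw if resname != "PLG" else spec.constriction[1]
        for i, p in enumerate(pts, start=1):
            beads.append(CGBead(p, radius, 0.0, chain, i, resname))

    alpha_site = SiteDefinition([("A", i) for i in range(1, 13)])
    beta_site = SiteDefinition([("B", i) for i in range(1, 13)])
    axis = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, L]])
    return CGProtein(beads, alpha_site, beta_site, axis)


def three_state_specs(
    leak_axial: float = 3.0, leak_aperture: float = 12.0,
    plug_axial: float = 12.5,
) -> dict[str, ToyChannelSpec]:
    """Watertight / leaky / plugged toy variants emulating the fully closed,
    open (leak near the α end, where an open loop lets the intermediate
    slip out) and obstructed channel conformations."""
    base = ToyChannelSpec()
    return {
        "closed": base,
        "leaky": ToyChannelSpec(leak=(leak_axial, leak_aperture)),
        "plugged": ToyChannelSpec(constriction=(plug_axial, base.tunnel_inner_radius)),
    }


def sample_dihedral_series(spec: DihedralSimSpec, chain: str = "A",
                           residue_number: int = 1,
                           dihedral_type: str = "chi1") -> DihedralSeries:
    """Draw i.i.d. angles (degrees, in (-180, 180]) from the circular
    mixture; kappa = 0 components are sampled as exact circular uniforms."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    weights = np.array([w for _, _, w in spec.components])
    choices = rng.choice(len(spec.components), size=spec.n_frames, p=weights / weights.sum())
    angles = np.empty(spec.n_frames)
    for idx, (mean, kappa, _) in enumerate(spec.components):
        mask = choices == idx
        n = int(mask.sum())
        if n == 0:
            continue
        if kappa == 0.0:
            draw = rng.uniform(-math.pi, math.pi, size=n)
        else:
            draw = rng.vonmises(math.radians(mean), kappa, size=n)
        angles[mask] = np.degrees(draw)
    # normalize to (-180, 180]
    angles = ((angles + 180.0) % 360.0) - 180.0
    angles[angles == -180.0] = 180.0
    return DihedralSeries(chain=chain, residue_number=residue_number,
                          dihedral_type=dihedral_type, angles=angles)


def write_toy_pdb(protein: CGProtein, path) -> None:
    """Write the bead model as pseudo-atom PDB records plus a TSV sidecar
    (``<path>.beads.tsv``) preserving radii, charges and site membership.

    See :func:`cgchannel.structure_io.write_cg_pdb`.
    """
    from .structure_io import write_cg_pdb

    write_cg_pdb(protein, path)
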