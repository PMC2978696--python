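"""Core data model for the coarse-grained channeling simulations.

The protein is a rigid set of one-bead-per-residue particles (bead at the
Cα position, with an effective radius standing in for the side chain and an
optional formal charge).  The mobile species is a two-bead indole: one bead
for the pyrrole ring (1.6 Å) and one for the benzene ring (1.9 Å), joined by
a rigid virtual bond.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

# Effective radii admissible for a coarse-grained residue bead (Å).
RADIUS_MIN = 0.5
RADIUS_MAX = 8.0

#: Pyrrole- and benzene-ring bead radii of the two-bead indole model (Å).
INDOLE_RADII = (1.6, 1.9)

#: Centroid separation of the pyrrole and benzene rings in an idealized
#: (MMFF-minimized) planar indole geometry (Å); used as the rigid virtual
#: bond length between the two indole beads.
INDOLE_BOND_LENGTH = 2.17


class InvalidSpecError(ValueError):
    """A geometry or sampler specification violates its invariants."""


class SiteError(ValueError):
    """An active-site definition does not resolve against the bead model."""


@dataclass(frozen=True)
class CGBead:
    """One coarse-grained particle.

    Parameters
    ----------
    position : (3,) array-like, Å
    radius : float, Å — the ``r_i`` entering the van der Waals potential.
    charge : float, elementary charges — the ``q_i`` of the Coulomb term.
    chain, residue_number, residue_name : identity of the source residue.
    diffusion_coefficient : float or None, Å²/ns; only meaningful for
        mobile beads (the protein is held rigid).
    """

    position: np.ndarray
    radius: float
    charge: float = 0.0
    chain: str = ""
    residue_number: int = 0
    residue_name: str = ""
    diffusion_coefficient: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,):
            raise ValueError("bead position must be a 3-vector")
        if not self.radius > 0:
            raise ValueError(f"bead radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class SiteDefinition:
    """An active site given as a list of (chain, residue_number) selectors.

    The site center is the unweighted mean of the selected bead positions
    (every bead carries the same implicit mass in the one-bead model).
    """

    selectors: tuple[tuple[str, int], ...]

    def __init__(self, selectors: Iterable[tuple[str, int]]):
        sels = tuple((str(c), int(r)) for c, r in selectors)
        if not sels:
            raise SiteError("site definition needs at least one residue selector")
        object.__setattr__(self, "selectors", sels)

    def resolve(self, protein: "CGProtein") -> np.ndarray:
        """Indices of the protein beads selected by this site."""
        index = {(b.chain, b.residue_number): i for i, b in enumerate(protein.beads)}
        try:
            return np.array([index[s] for s in self.selectors], dtype=int)
        except KeyError as exc:
            raise SiteError(f"site selector {exc.args[0]} not present in protein") from exc


class CGProtein:
    """A rigid assembly of coarse-grained beads with two active sites.

    Attributes
    ----------
    beads : list of :class:`CGBead`
    alpha_site, beta_site : :class:`SiteDefinition`
    channel_axis : (M, 3) ndarray, Å — polyline from the α-site center to
        the β-site center (endpoints coincide with the site centers).
    """

    def __init__(
        self,
        beads: Sequence[CGBead],
        alpha_site: SiteDefinition,
        beta_site: SiteDefinition,
        channel_axis: np.ndarray | None = None,
    ):
        if len(beads) == 0:
            raise ValueError("a CGProtein needs at least one bead")
        self.beads = list(beads)
        self.alpha_site = alpha_site
        self.beta_site = beta_site
        radii = self.radii
        if np.any(radii <= 0):
            raise ValueError("all bead radii must be positive")
        # Resolve sites eagerly so bad definitions fail at construction.
        self._alpha_idx = alpha_site.resolve(self)
        self._beta_idx = beta_site.resolve(self)
        if channel_axis is None:
            channel_axis = np.stack([self.alpha_center, self.beta_center])
        channel_axis = np.asarray(channel_axis, dtype=float)
        if channel_axis.ndim != 2 or channel_axis.shape[1] != 3 or len(channel_axis) < 2:
            raise ValueError("channel_axis must be an (M>=2, 3) polyline")
        for end, center in ((channel_axis[0], self.alpha_center), (channel_axis[-1], self.beta_center)):
            if np.linalg.norm(end - center) > 0.5:
                raise ValueError("channel_axis endpoints must coincide with the site centers (0.5 Å)")
        self.channel_axis = channel_axis

    # -- array views ------------------------------------------------------
    @property
    def positions(self) -> np.ndarray:
        return np.array([b.position for b in self.beads], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([b.radius for b in self.beads], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([b.charge for b in self.beads], dtype=float)

    @property
    def alpha_center(self) -> np.ndarray:
        return self.positions[self._alpha_idx].mean(axis=0)

    @property
    def beta_center(self) -> np.ndarray:
        return self.positions[self._beta_idx].mean(axis=0)

    def __len__(self) -> int:
        return len(self.beads)

    def with_charges(self, charges: np.ndarray) -> "CGProtein":
        """A copy of this protein with per-bead charges replaced."""
        charges = np.asarray(charges, dtype=float)
        if charges.shape != (len(self),):
            raise ValueError("charge array length must match bead count")
        beads = [
            CGBead(b.position, b.radius, q, b.chain, b.residue_number, b.residue_name)
            for b, q in zip(self.beads, charges)
        ]
        return CGProtein(beads, self.alpha_site, self.beta_site, self.channel_axis)


class IndoleLigand:
    """The mobile two-bead indole: pyrrole (1.6 Å) and benzene (1.9 Å) beads
    joined by a rigid virtual bond along the ring–ring centroid axis."""

    def __init__(
        self,
        positions: np.ndarray | None = None,
        radii: Sequence[float] = INDOLE_RADII,
        charges: Sequence[float] = (0.0, 0.0),
        bond_length: float = INDOLE_BOND_LENGTH,
        bond_model: str = "rigid_constraint",
    ):
        self.radii = np.asarray(radii, dtype=float)
        self.charges = np.asarray(charges, dtype=float)
        if self.radii.shape != (2,) or self.charges.shape != (2,):
            raise ValueError("an indole ligand has exactly two beads")
        if not bond_length > 0:
            raise ValueError("bond_length must be positive")
        if bond_model not in ("rigid_constraint", "harmonic"):
            raise ValueError(f"unknown bond model {bond_model!r}")
        self.bond_length = float(bond_length)
        self.bond_model = bond_model
        if positions is None:
            positions = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, bond_length]])
        self.positions = np.asarray(positions, dtype=float)
        if self.positions.shape != (2, 3):
            raise ValueError("indole positions must be (2, 3)")

    def placed_at(self, center: np.ndarray, direction: np.ndarray | None = None) -> "IndoleLigand":
        """A copy with the bead midpoint at *center*, bond along *direction*."""
        center = np.asarray(center, dtype=float)
        if direction is None:
            direction = np.array([0.0, 0.0, 1.0])
        u = np.asarray(direction, dtype=float)
        u = u / np.linalg.norm(u)
        half = 0.5 * self.bond_length * u
        return IndoleLigand(
            np.stack([center - half, center + half]),
            self.radii, self.charges, self.bond_length, self.bond_model,
        )

    @property
    def midpoint(self) -> np.ndarray:
        return self.positions.mean(axis=0)


@dataclass
class RadiiTable:
    """Per-residue effective bead radii with per-residue-instance overrides.

    ``defaults`` maps residue names (three-letter, upper case) to radii in Å;
    ``overrides`` maps (chain, residue_number) to a measured radius, used for
    active-site and channel-lining residues whose side-chain extent is taken
    from a crystal structure.
    """

    defaults: Mapping[str, float]
    overrides: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self):
        for name, r in self.defaults.items():
            if not (RADIUS_MIN < r < RADIUS_MAX):
                raise ValueError(f"radius for {name} out of ({RADIUS_MIN}, {RADIUS_MAX}) Å: {r}")

    def lookup(self, chain: str, residue_number: int, residue_name: str,
               strict: bool = False, fallback: float = 3.0) -> float:
        key = (chain, residue_number)
        if key in self.overrides:
            return self.overrides[key]
        name = residue_name.upper()
        if name in self.defaults:
            return self.defaults[name]
        if strict:
            raise KeyError(f"no radius for residue {residue_name} and no override for {key}")
        return fallback
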