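"""Configurational entropy from dihedral-angle distributions, and Cα RMSF.

For each rotatable dihedral x the Gibbs (plug-in) entropy of its binned
circular distribution is

    S = -R * sum_b p(b) ln p(b),        p(b) = counts_b / n_frames,

reported as T*S in kcal/mol (T = 298 K by default, R the gas constant).
Empty bins contribute zero.  The entropy change on binding is the
difference of bound- and free-state values, T*dS = T*S_bound - T*S_free.
Backbone phi/psi and side-chain chi1..chi4 series are extracted from
trajectories with mdtraj; the peptide-bond omega is excluded by default
(it is stiff and contributes little conformational freedom).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .potentials import GAS_CONSTANT_KCAL

__all__ = [
    "DihedralSeries", "EntropyResult", "RegionDefinition", "RegionError",
    "gibbs_entropy", "entropy_table", "region_entropy", "entropy_change",
    "extract_dihedrals", "rmsf",
]

DIHEDRAL_TYPES = ("phi", "psi", "omega", "chi1", "chi2", "chi3", "chi4", "chi5")


class RegionError(ValueError):
    """A region definition selects no dihedrals from the results."""


@dataclass
class DihedralSeries:
    """An angle time series (degrees, in (-180, 180]) for one dihedral."""

    chain: str
    residue_number: int
    dihedral_type: str
    angles: np.ndarray

    def __post_init__(self):
        if self.dihedral_type not in DIHEDRAL_TYPES:
            raise ValueError(f"unknown dihedral type {self.dihedral_type!r}")
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 1 or self.angles.size < 1:
            raise ValueError("angles must be a non-empty 1-D array")
        if np.any(self.angles <= -180.0) or np.any(self.angles > 180.0):
            raise ValueError("angles must lie in (-180, 180] degrees")

    @property
    def n_frames(self) -> int:
        return self.angles.size


@dataclass
class EntropyResult:
    """Per-dihedral T*S values (kcal/mol) with the binning used.

    ``table`` has columns chain, residue_number, dihedral_type, TS.
    """

    table: pd.DataFrame
    bin_width: float
    temperature: float

    @property
    def total(self) -> float:
        return float(self.table["TS"].sum())

    def per_residue(self) -> pd.DataFrame:
        return (self.table.groupby(["chain", "residue_number"], as_index=False)["TS"]
                .sum())


@dataclass(frozen=True)
class RegionDefinition:
    """A named set of residue ranges per chain, e.g. the two mobile α-loops
    (L2: 53–60, L6: 179–193) or the β COMM domain (102–189)."""

    label: str
    ranges: Mapping[str, tuple[tuple[int, int], ...]]

    def __init__(self, label: str, ranges: Mapping[str, Iterable[tuple[int, int]]]):
        object.__setattr__(self, "label", label)
        norm = {str(c): tuple((int(a), int(b)) for a, b in rr) for c, rr in ranges.items()}
        if not norm or any(len(rr) == 0 for rr in norm.values()):
            raise ValueError("region needs at least one residue range")
        object.__setattr__(self, "ranges", norm)

    def contains(self, chain: str, residue_number: int) -> bool:
        for lo, hi in self.ranges.get(chain, ()):
            if lo <= residue_number <= hi:
                return True
        return False


def _bin_counts(angles: np.ndarray, bin_width: float) -> np.ndarray:
    k = 360.0 / bin_width
    if abs(k - round(k)) > 1e-9:
        raise ValueError(f"bin_width must divide 360, got {bin_width}")
    k = int(round(k))
    idx = np.floor((np.asarray(angles, dtype=float) + 180.0) / bin_width).astype(int)
    idx = np.clip(idx, 0, k - 1)  # +180 lands in the last bin (periodic range)
    return np.bincount(idx, minlength=k)


def gibbs_entropy(series, bin_width: float = 10.0, temperature: float = 298.0) -> float:
    """T*S (kcal/mol) of the binned dihedral distribution.

    ``series`` may be a :class:`DihedralSeries` or a plain angle array in
    degrees.  The estimator is the plug-in form: empty bins contribute
    nothing and no bias correction is applied.
    """
    angles = series.angles if isinstance(series, DihedralSeries) else np.asarray(series)
    counts = _bin_counts(angles, bin_width)
    n = counts.sum()
    p = counts[counts > 0] / n
    S = -GAS_CONSTANT_KCAL * float(np.sum(p * np.log(p)))
    return temperature * S


def entropy_table(series_list: Sequence[DihedralSeries], bin_width: float = 10.0,
                  temperature: float = 298.0) -> EntropyResult:
    """Compute T*S for every series and collect them in an EntropyResult."""
    rows = [{
        "chain": s.chain, "residue_number": s.residue_number,
        "dihedral_type": s.dihedral_type,
        "TS": gibbs_entropy(s, bin_width, temperature),
    } for s in series_list]
    return EntropyResult(pd.DataFrame(rows), bin_width, temperature)


def region_entropy(result: EntropyResult, region: RegionDefinition) -> float:
    """Exact sum of member-dihedral T*S values over the region."""
    t = result.table
    mask = t.apply(lambda r: region.contains(r["chain"], r["residue_number"]), axis=1)
    if not mask.any():
        raise RegionError(f"region {region.label!r} selects no dihedrals")
    return float(t.loc[mask, "TS"].sum())


def entropy_change(bound: EntropyResult, free: EntropyResult) -> pd.DataFrame:
    """Per-dihedral T*dS = T*S_bound - T*S_free.

    Both results must cover identical dihedral identities; a mismatch
    raises with the symmetric difference listed.
    """
    key = ["chain", "residue_number", "dihedral_type"]
    b = bound.table.set_index(key)["TS"]
    f = free.table.set_index(key)["TS"]
    only_b = b.index.difference(f.index)
    only_f = f.index.difference(b.index)
    if len(only_b) or len(only_f):
        raise ValueError(
            "dihedral identities differ between states; only-bound: "
            f"{list(only_b)}; only-free: {list(only_f)}")
    out = (b - f).rename("TdS").reset_index()
    return out


# ---------------------------------------------------------------------------
# trajectory-based extraction (mdtraj-backed)

def _series_from_mdtraj(traj, compute, dtype: str) -> list[DihedralSeries]:
    indices, angles = compute(traj)
    out = []
    top = traj.topology
    for col, quad in enumerate(indices):
        res = top.atom(int(quad[1])).residue
        chain = res.chain.chain_id or str(res.chain.index)
        deg = np.degrees(angles[:, col].astype(float))
        deg = ((deg + 180.0) % 360.0) - 180.0
        deg[deg == -180.0] = 180.0
        out.append(DihedralSeries(chain, res.resSeq, dtype, deg))
    return out


def extract_dihedrals(traj, include_omega: bool = False) -> list[DihedralSeries]:
    """Backbone phi/psi and side-chain chi1..chi4 series from an mdtraj
    trajectory.  Terminal residues that lack a phi or psi are simply not
    produced by the geometry scan; omega is excluded unless requested.
    """
    import mdtraj as md

    if traj.n_frames < 1:
        raise ValueError("trajectory has no frames")
    jobs = [(md.compute_phi, "phi"), (md.compute_psi, "psi"),
            (md.compute_chi1, "chi1"), (md.compute_chi2, "chi2"),
            (md.compute_chi3, "chi3"), (md.compute_chi4, "chi4")]
    if include_omega:
        jobs.append((md.compute_omega, "omega"))
    series: list[DihedralSeries] = []
    for compute, dtype in jobs:
        series.extend(_series_from_mdtraj(traj, compute, dtype))
    return series


def rmsf(traj, atom_indices=None) -> pd.DataFrame:
    """Per-residue Cα root mean square fluctuation (Å).

    Frames are superposed onto their mean structure (two refinement
    passes), then RMSF_i = sqrt(<|x_i - <x_i>|^2>) over frames.
    """
    import mdtraj as md

    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    if atom_indices is None:
        atom_indices = traj.topology.select("name CA")
    atom_indices = np.asarray(atom_indices, dtype=int)
    if atom_indices.size == 0:
        raise ValueError("no atoms selected for RMSF")

    work = traj[:]
    work.superpose(work, 0, atom_indices=atom_indices)
    for _ in range(2):
        mean_xyz = work.xyz.mean(axis=0, keepdims=True)
        ref = md.Trajectory(mean_xyz, work.topology)
        work.superpose(ref, 0, atom_indices=atom_indices)
    xyz = work.xyz[:, atom_indices, :]
    fluct = xyz - xyz.mean(axis=0, keepdims=True)
    vals = np.sqrt((fluct ** 2).sum(axis=2).mean(axis=0)) * 10.0  # nm -> Å
    top = work.topology
    rows = []
    for a, v in zip(atom_indices, vals):
        res = top.atom(int(a)).residue
        rows.append({"chain": res.chain.chain_id or str(res.chain.index),
                     "residue_number": res.resSeq,
                     "residue_name": res.name,
                     "rmsf_A": float(v)})
    return pd.DataFrame(rows)
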