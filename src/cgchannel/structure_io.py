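"""PDB input/output and coarse-grain model construction.

Parsing and rigid-body superposition are delegated to Biopython
(``Bio.PDB``); this module turns a parsed structure into the one-bead-per-
residue :class:`~cgchannel.model.CGProtein` (bead at the Cα, effective
radius from a residue table or a per-residue crystal-structure measurement,
formal charges), places the two-bead indole into a snapshot frame by
Kabsch superposition onto a reference structure, and round-trips bead
models through pseudo-atom PDB files with a TSV sidecar carrying radii,
charges and site membership.
"""

from __future__ import annotations

import importlib.resources
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.SVDSuperimposer import SVDSuperimposer

from .model import CGBead, CGProtein, IndoleLigand, RadiiTable, SiteDefinition

__all__ = [
    "FormatError", "AlignmentError", "read_structure", "default_radii_table",
    "build_cg_protein", "assign_charges", "measure_sidechain_radius",
    "superpose_and_place", "site_center", "write_cg_pdb", "read_cg_pdb",
]

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

FORMAL_CHARGES = {"ASP": -1.0, "GLU": -1.0, "LYS": 1.0, "ARG": 1.0, "HIS": 0.0}


class FormatError(ValueError):
    """The input file is not a usable PDB."""


class AlignmentError(ValueError):
    """Superposition impossible (fewer than three shared Cα atoms)."""


def read_structure(path):
    """Parse a PDB file into a Biopython model (the first MODEL).

    Alternate locations resolve to the highest-occupancy conformer
    (Biopython's default disordered-atom selection); HETATM residues are
    retained and can be recognised by their blank-less hetero flag.
    """
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("s", str(path))
    except Exception as exc:  # Bio raises bare exceptions on garbage input
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    models = list(structure)
    if not models or sum(1 for _ in models[0].get_atoms()) == 0:
        raise FormatError(f"{path} contains no atoms")
    return models[0]


def default_radii_table() -> RadiiTable:
    """The shipped per-residue effective-radius table."""
    text = (importlib.resources.files("cgchannel") / "data" / "radii.tsv").read_text()
    defaults = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, val = line.split("\t")
        defaults[name.upper()] = float(val)
    return RadiiTable(defaults)


def _residues_with_ca(model):
    for chain in model:
        for res in chain:
            if "CA" in res:
                yield chain.id, res
            elif res.id[0] == " ":
                warnings.warn(
                    f"residue {chain.id}/{res.id[1]} {res.get_resname()} has no "
                    "Cα and was skipped")


def build_cg_protein(
    model,
    radii: RadiiTable | None = None,
    alpha_site: SiteDefinition | Iterable[tuple[str, int]] | None = None,
    beta_site: SiteDefinition | Iterable[tuple[str, int]] | None = None,
    charge_scheme: str = "formal",
    strict: bool = False,
    channel_axis: np.ndarray | None = None,
) -> CGProtein:
    """One bead per residue at its Cα coordinate.

    Radii come from the override map when present, else the residue-name
    lookup (``strict=True`` turns unknown residue names into errors instead
    of a warned default).  Charges follow ``charge_scheme`` ("formal":
    Asp/Glu −1e, Lys/Arg +1e, everything else including His neutral;
    "none": all zero).
    """
    if radii is None:
        radii = default_radii_table()
    beads = []
    for chain_id, res in _residues_with_ca(model):
        resname = res.get_resname()
        resnum = res.id[1]
        try:
            r = radii.lookup(chain_id, resnum, resname, strict=strict)
        except KeyError as exc:
            raise KeyError(f"no radius entry for {resname} ({chain_id}/{resnum}); "
                           "add a table entry or an override") from exc
        if resname.upper() not in radii.defaults and (chain_id, resnum) not in radii.overrides:
            warnings.warn(f"residue {resname} not in radii table; default "
                          f"{r:.2f} Å used for {chain_id}/{resnum}")
        beads.append(CGBead(res["CA"].get_coord().astype(float), r, 0.0,
                            chain_id, resnum, resname))

    def _as_site(s, fallback_index):
        if isinstance(s, SiteDefinition):
            return s
        if s is not None:
            return SiteDefinition(s)
        b = beads[fallback_index]
        return SiteDefinition([(b.chain, b.residue_number)])

    protein = CGProtein(beads, _as_site(alpha_site, 0), _as_site(beta_site, -1),
                        channel_axis)
    return assign_charges(protein, charge_scheme)


def assign_charges(protein: CGProtein, scheme: str = "formal") -> CGProtein:
    """Return a copy with per-bead charges set by the scheme."""
    if scheme == "none":
        return protein.with_charges(np.zeros(len(protein)))
    if scheme == "formal":
        q = np.array([FORMAL_CHARGES.get(b.residue_name.upper(), 0.0)
                      for b in protein.beads])
        return protein.with_charges(q)
    raise ValueError(f"unknown charge scheme {scheme!r}")


def measure_sidechain_radius(model, chain: str, residue_number: int,
                             convention: str = "centroid",
                             default: float | None = None) -> float:
    """Cα-to-side-chain distance (Å) used as the bead radius for channel
    and active-site residues.

    ``convention`` selects the side-chain point: "centroid" (mean of the
    heavy side-chain atoms; stabler for flexible side chains) or
    "farthest" (the most distal heavy atom).  Residues without side-chain
    heavy atoms (Gly, or truncated side chains) fall back to ``default``
    with a warning.
    """
    if convention not in ("centroid", "farthest"):
        raise ValueError(f"unknown convention {convention!r}")
    res = model[chain][(" ", residue_number, " ")]
    ca = res["CA"].get_coord().astype(float)
    side = np.array([a.get_coord() for a in res
                     if a.get_name() not in _BACKBONE and a.element != "H"])
    if len(side) == 0:
        if default is None:
            raise ValueError(
                f"{chain}/{residue_number} has no side-chain heavy atoms and "
                "no default radius was given")
        warnings.warn(f"{chain}/{residue_number}: no side-chain heavy atoms; "
                      f"table value {default:.2f} Å used")
        return float(default)
    d = np.linalg.norm(side - ca, axis=1)
    if convention == "centroid":
        return float(np.linalg.norm(side.mean(axis=0) - ca))
    return float(d.max())


def _common_ca(snapshot, reference):
    def ca_map(model):
        out = {}
        for chain_id, res in _residues_with_ca(model):
            out[(chain_id, res.id[1])] = res["CA"].get_coord().astype(float)
        return out

    a, b = ca_map(snapshot), ca_map(reference)
    keys = sorted(set(a) & set(b))
    return (np.array([a[k] for k in keys]).reshape(-1, 3),
            np.array([b[k] for k in keys]).reshape(-1, 3))


def superpose_and_place(snapshot, reference, indole_reference_position,
                        indole: IndoleLigand | None = None
                        ) -> tuple[IndoleLigand, float]:
    """Least-squares (Kabsch/SVD) superposition of *snapshot* onto
    *reference* over their shared Cα atoms, then placement of the
    reference-frame indole position into the snapshot frame.

    ``indole_reference_position`` is either the indole midpoint (3,) or
    explicit bead positions (2, 3) in the reference frame.  Returns the
    positioned :class:`IndoleLigand` and the superposition RMSD (Å).
    """
    snap_ca, ref_ca = _common_ca(snapshot, reference)
    if len(snap_ca) < 3:
        raise AlignmentError(
            f"only {len(snap_ca)} shared Cα atoms; need at least 3")
    sup = SVDSuperimposer()
    # rot/tran map reference coords onto the snapshot frame
    sup.set(snap_ca, ref_ca)
    sup.run()
    rot, tran = sup.get_rotran()
    rmsd = float(sup.get_rms())
    if indole is None:
        indole = IndoleLigand()
    pos = np.asarray(indole_reference_position, dtype=float)
    if pos.shape == (2, 3):
        placed = IndoleLigand(pos @ rot + tran, indole.radii, indole.charges,
                              indole.bond_length, indole.bond_model)
    elif pos.shape == (3,):
        center = pos @ rot + tran
        direction = np.array([0.0, 0.0, 1.0]) @ rot
        placed = indole.placed_at(center, direction)
    else:
        raise ValueError("indole_reference_position must be (3,) or (2, 3)")
    return placed, rmsd


def site_center(protein: CGProtein, site: SiteDefinition) -> np.ndarray:
    """Unweighted mean position of the site's beads (Å)."""
    idx = site.resolve(protein)
    return protein.positions[idx].mean(axis=0)


# ---------------------------------------------------------------------------
# pseudo-atom PDB round trip

def write_cg_pdb(protein: CGProtein, path) -> None:
    """One ATOM record per bead plus a ``<path>.beads.tsv`` sidecar with
    bead_id, chain, resnum, resname, radius (Å), charge (e) and site
    membership; positions survive the round trip to 0.001 Å (PDB field
    precision)."""
    if len(protein) == 0:
        raise ValueError("refusing to write an empty protein")
    alpha = {s for s in protein.alpha_site.selectors}
    beta = {s for s in protein.beta_site.selectors}
    lines = []
    rows = []
    for i, b in enumerate(protein.beads, start=1):
        x, y, z = b.position
        lines.append(
            f"ATOM  {i % 100000:5d}  CA  {b.residue_name:<3s} {(b.chain or 'A')[:1]}"
            f"{b.residue_number % 10000:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"  1.00  0.00           C")
        key = (b.chain, b.residue_number)
        rows.append({
            "bead_id": i, "chain": b.chain, "resnum": b.residue_number,
            "resname": b.residue_name, "radius_A": b.radius, "charge_e": b.charge,
            "site": "alpha" if key in alpha else ("beta" if key in beta else ""),
        })
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    pd.DataFrame(rows).to_csv(f"{path}.beads.tsv", sep="\t", index=False)


def read_cg_pdb(path) -> CGProtein:
    """Rebuild a :class:`CGProtein` written by :func:`write_cg_pdb`."""
    model = read_structure(path)
    side = pd.read_csv(f"{path}.beads.tsv", sep="\t", keep_default_na=False)
    coords = {}
    for chain_id, res in _residues_with_ca(model):
        coords[(chain_id, res.id[1])] = res["CA"].get_coord().astype(float)
    beads = []
    for row in side.itertuples():
        key = (str(row.chain), int(row.resnum))
        if key not in coords:
            raise FormatError(f"sidecar bead {key} missing from {path}")
        beads.append(CGBead(coords[key], float(row.radius_A), float(row.charge_e),
                            key[0], key[1], str(row.resname)))
    alpha = [(str(r.chain), int(r.resnum)) for r in side.itertuples() if r.site == "alpha"]
    beta = [(str(r.chain), int(r.resnum)) for r in side.itertuples() if r.site == "beta"]
    if not alpha or not beta:
        raise FormatError(f"sidecar of {path} lacks site annotations")
    return CGProtein(beads, SiteDefinition(alpha), SiteDefinition(beta))
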