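"""Voxelization of protein binding sites into 8-channel occupancy grids.

A binding site is a set of heavy atoms around the ligand pose.  Each atom is
assigned up to eight pharmacophoric channels (hydrophobic, aromatic, H-bond
acceptor, H-bond donor, positive ionizable, negative ionizable, metal,
excluded volume) and smeared onto a cubic grid — by default 30 Å per edge at
1 Å resolution — using the van der Waals occupancy

    n(r) = 1 - exp(-(r_vdw / r)^12)

which is ~1 inside the vdW sphere and decays steeply outside it.  Per voxel
and channel, contributions from multiple atoms are aggregated with ``max``,
so the grid is idempotent under duplicated atoms and independent of atom
order.  The resulting (8, 30, 30, 30) array is the local-pathway input of
the interaction network.

Channel typing follows an explicit, overridable rule table (documented in
``docs/methods.md``): metals by element; hydrophobic = C/S without a polar
neighbour; aromatic = ring-aromatic atoms; acceptor = N/O with a lone pair;
donor = N/O carrying hydrogen; positive/negative ionizable by formal charge
or standard protonatable groups; excluded volume = every heavy atom.  For
PDB input the bonded context is resolved through a per-residue atom-name
table covering the 20 standard residues.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

CHANNELS: tuple[str, ...] = (
    "hydrophobic",
    "aromatic",
    "acceptor",
    "donor",
    "positive",
    "negative",
    "metal",
    "excluded_volume",
)
N_CHANNELS = len(CHANNELS)

METAL_ELEMENTS = frozenset(
    "Li Na K Rb Cs Mg Ca Sr Ba Mn Fe Co Ni Cu Zn Cd Hg Al Ga In Tl Sn Pb V Cr Ti Zr Mo W Ag Au Pt Pd".split()
)

#: Bondi-style van der Waals radii in Å (fallback 1.7 for unlisted elements).
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98, "Se": 1.90, "Si": 2.10,
    "B": 1.92, "As": 1.85, "Li": 1.82, "Na": 2.27, "K": 2.75, "Mg": 1.73,
    "Ca": 2.31, "Mn": 1.61, "Fe": 1.52, "Co": 1.52, "Ni": 1.63, "Cu": 1.40,
    "Zn": 1.39, "Cd": 1.58, "Hg": 1.55, "Al": 1.84, "Pt": 1.75, "Au": 1.66,
}
DEFAULT_VDW_RADIUS = 1.70


@dataclass(frozen=True)
class SiteAtom:
    """One binding-site atom: element, Cartesian position (Å), vdW radius
    and its 8 channel flags (boolean array ordered as :data:`CHANNELS`)."""

    element: str
    position: np.ndarray
    vdw_radius: float
    channels: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "channels", np.asarray(self.channels, dtype=bool))
        if self.vdw_radius <= 0:
            raise ValueError(f"vdw_radius must be positive, got {self.vdw_radius}")
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("position must be 3 finite coordinates")
        if self.channels.shape != (N_CHANNELS,):
            raise ValueError(f"channels must have {N_CHANNELS} flags")


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned cubic grid: ``center`` in Å, ``edge_length`` Å per side,
    ``resolution`` Å per voxel.  Voxel centers sit at half-integer offsets
    from the box corner."""

    center: np.ndarray
    edge_length: float = 30.0
    resolution: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.center.shape != (3,):
            raise ValueError("center must be a 3-vector")
        n = self.edge_length / self.resolution
        if abs(n - round(n)) > 1e-9 or n <= 0:
            raise ValueError("edge_length must be a positive multiple of resolution")

    @property
    def voxels_per_axis(self) -> int:
        return int(round(self.edge_length / self.resolution))

    def axis_coordinates(self) -> np.ndarray:
        """Voxel-center coordinates along one axis, relative offsets applied
        per axis against ``center``: shape (voxels_per_axis, 3)."""
        n = self.voxels_per_axis
        offsets = (np.arange(n) + 0.5 - n / 2.0) * self.resolution
        return self.center[None, :] + offsets[:, None]


def occupancy(r, rvdw):
    """Van der Waals occupancy ``1 - exp(-(rvdw/r)^12)``.

    ``r`` may be a scalar or array of distances (Å); ``rvdw`` the atom's vdW
    radius.  Defined as 1 at r = 0 (the continuity limit).  Raises
    ``ValueError`` for negative distances or non-positive radii.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance r must be non-negative")
    if not np.all(np.asarray(rvdw) > 0):
        raise ValueError("vdw radius must be positive")
    with np.errstate(divide="ignore", over="ignore"):
        val = 1.0 - np.exp(-((rvdw / r) ** 12))
    val = np.where(r == 0, 1.0, val)
    return float(val) if val.ndim == 0 else val


def assign_channels(
    element: str,
    *,
    aromatic: bool = False,
    n_hydrogens: int = 0,
    polar_neighbor: bool = False,
    has_lone_pair: bool = True,
    formal_charge: int = 0,
) -> np.ndarray:
    """Channel flags for one atom from element plus simple bonded context.

    Rule table (overridable by constructing :class:`SiteAtom` directly):
    metals → metal only; hydrophobic = C/S with no polar (N/O) neighbour;
    aromatic = ring-aromatic atom; acceptor = N/O with a lone pair; donor =
    N/O bonded to ≥1 H; positive/negative ionizable = formal charge sign;
    excluded volume = every heavy atom.  Unrecognized elements get the
    excluded-volume flag only, with a logged warning.
    """
    flags = np.zeros(N_CHANNELS, dtype=bool)
    el = element.capitalize()
    if el == "H":
        return flags
    flags[7] = True  # excluded volume: every heavy atom
    if el in METAL_ELEMENTS:
        flags[6] = True
        return flags
    if el not in VDW_RADII:
        logger.warning("unrecognized element %r: excluded-volume flags only", element)
        return flags
    if el in ("C", "S") and not polar_neighbor:
        flags[0] = True
    if aromatic:
        flags[1] = True
    if el in ("N", "O"):
        if has_lone_pair:
            flags[2] = True
        if n_hydrogens >= 1:
            flags[3] = True
    if formal_charge > 0:
        flags[4] = True
    elif formal_charge < 0:
        flags[5] = True
    return flags


def site_center(points) -> np.ndarray:
    """Arithmetic centroid of a non-empty list of 3-D points (Å)."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("cannot compute the center of an empty point list")
    pts = pts.reshape(-1, 3)
    return pts.mean(axis=0)


def build_grid(atoms: list[SiteAtom], spec: GridSpec) -> np.ndarray:
    """Rasterize site atoms into the (8, n, n, n) occupancy grid.

    Per channel and voxel the value is the maximum over contributing atoms of
    ``occupancy(distance(atom, voxel center), rvdw)``.  Atoms outside the box
    still contribute to voxels inside it.  An empty atom list yields an
    all-zero grid.
    """
    n = spec.voxels_per_axis
    grid = np.zeros((N_CHANNELS, n, n, n), dtype=float)
    if not atoms:
        return grid
    ax = spec.axis_coordinates()  # (n, 3)
    xs, ys, zs = ax[:, 0], ax[:, 1], ax[:, 2]
    for atom in atoms:
        if not atom.channels.any():
            continue
        dx = xs - atom.position[0]
        dy = ys - atom.position[1]
        dz = zs - atom.position[2]
        d2 = (
            dx[:, None, None] ** 2
            + dy[None, :, None] ** 2
            + dz[None, None, :] ** 2
        )
        occ = occupancy(np.sqrt(d2), atom.vdw_radius)
        for c in np.flatnonzero(atom.channels):
            np.maximum(grid[c], occ, out=grid[c])
    return grid


# ---------------------------------------------------------------------------
# Residue-context channel table for PDB input (20 standard residues).
# ---------------------------------------------------------------------------

_BACKBONE_DONOR_N = "N"
_BACKBONE_ACCEPTOR_O = ("O", "OXT")

_AROMATIC_RING: dict[str, frozenset[str]] = {
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    "HIS": frozenset({"CG", "ND1", "CD2", "CE1", "NE2"}),
}

_SIDECHAIN_DONOR: dict[str, frozenset[str]] = {
    "SER": frozenset({"OG"}), "THR": frozenset({"OG1"}), "TYR": frozenset({"OH"}),
    "ASN": frozenset({"ND2"}), "GLN": frozenset({"NE2"}),
    "LYS": frozenset({"NZ"}), "ARG": frozenset({"NE", "NH1", "NH2"}),
    "TRP": frozenset({"NE1"}), "HIS": frozenset({"ND1", "NE2"}),
}

_SIDECHAIN_ACCEPTOR: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}), "GLU": frozenset({"OE1", "OE2"}),
    "ASN": frozenset({"OD1"}), "GLN": frozenset({"OE1"}),
    "SER": frozenset({"OG"}), "THR": frozenset({"OG1"}), "TYR": frozenset({"OH"}),
    "HIS": frozenset({"ND1", "NE2"}),
}

_POSITIVE: dict[str, frozenset[str]] = {
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NE", "NH1", "NH2", "CZ"}),
    "HIS": frozenset({"ND1", "NE2"}),
}

_NEGATIVE: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
}

# Carbons bonded to N/O (hence not hydrophobic) beyond the backbone C/CA.
_POLAR_ADJACENT_C: dict[str, frozenset[str]] = {
    "SER": frozenset({"CB"}), "THR": frozenset({"CB"}), "CYS": frozenset({"CB"}),
    "ASP": frozenset({"CG"}), "GLU": frozenset({"CD"}), "ASN": frozenset({"CG"}),
    "GLN": frozenset({"CD"}), "ARG": frozenset({"CD", "CZ"}), "LYS": frozenset({"CE"}),
    "PRO": frozenset({"CD"}), "TYR": frozenset({"CZ"}),
    "TRP": frozenset({"CD1", "CE2"}),
    "HIS": frozenset({"CG", "CD2", "CE1"}),
    "MET": frozenset(),
}


def residue_channels(res_name: str, atom_name: str, element: str) -> np.ndarray:
    """Channel flags for a standard-residue atom by residue/atom-name table."""
    res, name = res_name.upper(), atom_name.upper()
    el = element.capitalize()
    flags = np.zeros(N_CHANNELS, dtype=bool)
    if el == "H":
        return flags
    if el in METAL_ELEMENTS:
        flags[6] = flags[7] = True
        return flags
    flags[7] = True
    if name in _AROMATIC_RING.get(res, ()):  # aromatic ring membership
        flags[1] = True
    if el in ("C", "S"):
        polar_adjacent = name in ("C", "CA") or name in _POLAR_ADJACENT_C.get(res, ())
        if not polar_adjacent:
            flags[0] = True
    if el in ("N", "O"):
        if name in _BACKBONE_ACCEPTOR_O or name in _SIDECHAIN_ACCEPTOR.get(res, ()):
            flags[2] = True
        if (name == _BACKBONE_DONOR_N and res != "PRO") or name in _SIDECHAIN_DONOR.get(res, ()):
            flags[3] = True
    if name in _POSITIVE.get(res, ()):
        flags[4] = True
    if name in _NEGATIVE.get(res, ()) or name == "OXT":
        flags[5] = True
    return flags


def _element_from_pdb(line: str) -> str:
    el = line[76:78].strip() if len(line) >= 78 else ""
    if not el:
        name = line[12:16]
        el = name.strip().lstrip("0123456789")[:1]
    return el.capitalize()


def parse_pdb_site(path, residue_selection=None, include_hydrogens: bool = False) -> list[SiteAtom]:
    """Read ATOM/HETATM records (PDB 3.3 fixed width) into :class:`SiteAtom`.

    ``residue_selection`` optionally restricts to a set of ``(chain_id,
    res_seq)`` pairs.  Channels come from the residue-context table for
    standard residues; HETATM metals map to the metal channel; other hetero
    atoms fall back to element-only rules.
    """
    atoms: list[SiteAtom] = []
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            altloc = line[16]
            if altloc not in (" ", "A"):
                continue
            element = _element_from_pdb(line)
            if element == "H" and not include_hydrogens:
                continue
            chain = line[21]
            res_seq = int(line[22:26])
            if residue_selection is not None and (chain, res_seq) not in residue_selection:
                continue
            res_name = line[17:20].strip()
            atom_name = line[12:16].strip()
            pos = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            if rec == "ATOM":
                flags = residue_channels(res_name, atom_name, element)
            else:
                flags = assign_channels(element)
            atoms.append(
                SiteAtom(
                    element=element,
                    position=np.array(pos),
                    vdw_radius=VDW_RADII.get(element, DEFAULT_VDW_RADIUS),
                    channels=flags,
                )
            )
    return atoms


def read_site_table(path) -> list[SiteAtom]:
    """Read a plain site-atom TSV: element, x, y, z and optionally the 8
    channel-flag columns (named as :data:`CHANNELS`); flags default to the
    element-only rule table when absent."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"element", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"site table must have columns {sorted(required)}")
    has_flags = all(c in df.columns for c in CHANNELS)
    atoms = []
    for row in df.itertuples(index=False):
        el = str(row.element)
        if has_flags:
            flags = np.array([bool(getattr(row, c)) for c in CHANNELS])
        else:
            flags = assign_channels(el)
        atoms.append(
            SiteAtom(
                element=el,
                position=np.array([row.x, row.y, row.z], dtype=float),
                vdw_radius=VDW_RADII.get(el.capitalize(), DEFAULT_VDW_RADIUS),
                channels=flags,
            )
        )
    return atoms


def write_site_table(path, atoms: list[SiteAtom]) -> None:
    import pandas as pd

    rows = []
    for a in atoms:
        row = {"element": a.element, "x": a.position[0], "y": a.position[1], "z": a.position[2]}
        row.update({c: int(f) for c, f in zip(CHANNELS, a.channels)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def save_grid(path, grid: np.ndarray, spec: GridSpec) -> None:
    """Write a grid to a chunked HDF5 container (one named dataset per
    channel) with a JSON sidecar holding the grid geometry."""
    import h5py

    with h5py.File(path, "w") as fh:
        for i, name in enumerate(CHANNELS):
            fh.create_dataset(name, data=grid[i], chunks=True, compression="gzip")
    sidecar = {
        "center": list(map(float, spec.center)),
        "edge_length": spec.edge_length,
        "resolution": spec.resolution,
        "channels": list(CHANNELS),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_grid(path) -> tuple[np.ndarray, GridSpec]:
    import h5py

    with h5py.File(path, "r") as fh:
        grid = np.stack([fh[name][()] for name in CHANNELS])
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    spec = GridSpec(
        center=np.array(meta["center"]),
        edge_length=meta["edge_length"],
        resolution=meta["resolution"],
    )
    return grid, spec
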