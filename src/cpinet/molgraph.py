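"""Molecular graphs from SMILES with one-hot atom features and normalized
graph convolution.

A molecule is the heavy-atom graph G = (V, E): one node per atom, one edge
per covalent bond.  Each node carries a 73-dimensional binary feature vector
built from five one-hot blocks — atom type (44 symbols, catch-all ``X``
last), heavy-atom degree (0–5), total hydrogen count (0–10), implicit
hydrogen count (0–10) and an aromaticity flag.  Message passing uses the
symmetrically normalized adjacency with self-loops,

    H^(l+1) = sigma( D~^{-1/2} (A + I) D~^{-1/2} H^l W^l ),

where D~ is the degree matrix of A + I.  The trainable pathway (three such
layers with pooling and a global-max readout) lives in
:mod:`cpinet.network`; this module provides the featurization and the
layer-level math.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: Atom-type vocabulary, fixed order, catch-all "X" last (44 symbols).
ATOM_TYPES: tuple[str, ...] = (
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb", "X",
)
_ATOM_TYPE_INDEX = {s: i for i, s in enumerate(ATOM_TYPES)}

MAX_DEGREE = 5
MAX_H = 10
#: feature layout: 44 atom types + 6 degrees + 11 H counts + 11 implicit H + 1 aromatic
FEATURE_DIM = len(ATOM_TYPES) + (MAX_DEGREE + 1) + (MAX_H + 1) + (MAX_H + 1) + 1


@dataclass(frozen=True)
class MolGraph:
    """Node features ``X`` (N x 73), symmetric adjacency ``A`` with zero
    diagonal, and the self-loop quantities à = A + I and D̃ = diag(Σ_j Ã_ij)."""

    features: np.ndarray
    adjacency: np.ndarray
    smiles: str = ""

    def __post_init__(self):
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")

    @property
    def n_atoms(self) -> int:
        return self.adjacency.shape[0]

    @property
    def a_tilde(self) -> np.ndarray:
        return self.adjacency + np.eye(self.n_atoms)

    @property
    def d_tilde(self) -> np.ndarray:
        return np.diag(self.a_tilde.sum(axis=1))

    @property
    def norm_adjacency(self) -> np.ndarray:
        """The propagation operator D̃^(-1/2) Ã D̃^(-1/2)."""
        d = self.a_tilde.sum(axis=1)
        inv_sqrt = 1.0 / np.sqrt(d)
        return self.a_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


def _one_hot(index: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    v[index] = 1.0
    return v


def featurize_atom(atom) -> np.ndarray:
    """73-dim one-hot feature vector for an RDKit atom.

    Degree above 5 or hydrogen counts above 10 clamp to the last bucket with
    a logged warning; elements outside the 44-symbol list map to ``X``.
    """
    symbol = atom.GetSymbol()
    type_idx = _ATOM_TYPE_INDEX.get(symbol, _ATOM_TYPE_INDEX["X"])

    degree = atom.GetDegree()
    if degree > MAX_DEGREE:
        logger.warning("degree %d clamped to %d", degree, MAX_DEGREE)
        degree = MAX_DEGREE
    n_h = atom.GetTotalNumHs()
    if n_h > MAX_H:
        logger.warning("H count %d clamped to %d", n_h, MAX_H)
        n_h = MAX_H
    n_imp = atom.GetNumImplicitHs()
    if n_imp > MAX_H:
        logger.warning("implicit H count %d clamped to %d", n_imp, MAX_H)
        n_imp = MAX_H

    return np.concatenate(
        [
            _one_hot(type_idx, len(ATOM_TYPES)),
            _one_hot(degree, MAX_DEGREE + 1),
            _one_hot(n_h, MAX_H + 1),
            _one_hot(n_imp, MAX_H + 1),
            np.array([1.0 if atom.GetIsAromatic() else 0.0]),
        ]
    )


def build_graph(smiles: str) -> MolGraph:
    """Parse a SMILES string into a heavy-atom :class:`MolGraph`.

    Raises ``ValueError`` carrying the offending string when RDKit cannot
    parse it.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    X = np.zeros((n, FEATURE_DIM))
    for atom in mol.GetAtoms():
        X[atom.GetIdx()] = featurize_atom(atom)
    A = np.zeros((n, n))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        A[i, j] = A[j, i] = 1.0
    return MolGraph(features=X, adjacency=A, smiles=smiles)


def gcn_layer(H: np.ndarray, graph: MolGraph, W: np.ndarray, activation=None) -> np.ndarray:
    """One normalized graph-convolution step sigma(D̃^(-1/2) Ã D̃^(-1/2) H W)."""
    H = np.asarray(H, dtype=float)
    W = np.asarray(W, dtype=float)
    if H.shape[0] != graph.n_atoms:
        raise ValueError("node-feature rows must match the number of atoms")
    if H.shape[1] != W.shape[0]:
        raise ValueError(f"W expects input dim {W.shape[0]}, features have {H.shape[1]}")
    out = graph.norm_adjacency @ H @ W
    return activation(out) if activation is not None else out


def readout(node_features: np.ndarray) -> np.ndarray:
    """Global max over nodes per feature dimension (size-invariant)."""
    node_features = np.asarray(node_features)
    if node_features.size == 0 or node_features.shape[0] == 0:
        raise ValueError("readout of an empty graph is undefined")
    return node_features.max(axis=0)


def read_smiles_file(path) -> dict[str, str]:
    """Read a SMILES list file: one molecule per line, ``id SMILES``."""
    mols: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'id SMILES'")
            mols[parts[0]] = parts[1].strip()
    return mols


def write_smiles_file(path, molecules: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for mol_id, smi in molecules.items():
            fh.write(f"{mol_id}\t{smi}\n")
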