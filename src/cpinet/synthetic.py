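"""Desk-scale synthetic targets and screening datasets with a planted,
learnable interaction rule.

The generator emulates the structure of a virtual-screening benchmark — one
binding-site atom cloud and one amino-acid sequence per target, per-target
active/decoy molecule sets at a controlled positive:negative ratio — without
any external download.  The label-generating process is an explicit planted
rule:

    label = ( site_predicate(target) AND molecule_predicate(molecule) )
            XOR Bernoulli(noise)

with, by default, site predicate = "a metal-channel atom is present and the
aromatic-channel fraction is at least 0.10" and molecule predicate =
"contains a nitrogen atom and at least one aromatic atom".  Targets
alternate by index between site-capable and site-incapable, so any split
contains both kinds and the site pathway carries label signal: pairs on
site-incapable targets are all negative, including molecules that satisfy
the molecule predicate.

All randomness descends from a single integer seed; per-target streams are
derived from (seed, target index), so targets are reproducible
independently of how many are generated.  Molecules come from a bundled
library of 244 parseable drug-like SMILES.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from importlib import resources

import numpy as np

from . import molgraph, seq_encoder, voxelizer
from .data_eval import SamplePair
from .voxelizer import CHANNELS, SiteAtom, VDW_RADII, assign_channels

logger = logging.getLogger(__name__)

SITE_RADIUS = 12.0      # Å, sphere holding the site atom cloud
MIN_ATOMS, MAX_ATOMS = 30, 80
MIN_SEQ, MAX_SEQ = 50, 1200


def molecule_library() -> dict[str, str]:
    """The bundled molecule library: id -> SMILES (244 molecules)."""
    text = resources.files("cpinet.data").joinpath("molecule_library.smi").read_text()
    mols = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        mol_id, smi = line.split("\t")
        mols[mol_id] = smi
    return mols


@dataclass(frozen=True)
class PlantedRule:
    """The label-generating rule.  ``noise`` is the label-flip probability."""

    require_metal: bool = True
    min_aromatic_fraction: float = 0.10
    mol_requires_nitrogen: bool = True
    mol_requires_aromatic: bool = True
    noise: float = 0.0

    def __post_init__(self):
        # noise = 0.5 makes labels independent of the features entirely
        # (the no-signal control); beyond 0.5 the rule would invert.
        if not 0.0 <= self.noise <= 0.5:
            raise ValueError("noise must lie in [0, 0.5]")

    def site_predicate(self, atoms: list[SiteAtom]) -> bool:
        if not atoms:
            return False
        flags = np.stack([a.channels for a in atoms])
        metal_idx = CHANNELS.index("metal")
        aromatic_idx = CHANNELS.index("aromatic")
        ok = True
        if self.require_metal:
            ok &= bool(flags[:, metal_idx].any())
        ok &= flags[:, aromatic_idx].mean() >= self.min_aromatic_fraction
        return ok

    def mol_predicate(self, smiles: str) -> bool:
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        ok = True
        if self.mol_requires_nitrogen:
            ok &= any(a.GetSymbol() == "N" for a in mol.GetAtoms())
        if self.mol_requires_aromatic:
            ok &= any(a.GetIsAromatic() for a in mol.GetAtoms())
        return ok


@dataclass(frozen=True)
class SyntheticTarget:
    target_id: str
    atoms: list[SiteAtom]
    sequence: str
    site_capable: bool


# -- site atom sampling -------------------------------------------------------

def _sample_position(rng: np.random.Generator) -> np.ndarray:
    """Uniform point in the site sphere."""
    while True:
        p = rng.uniform(-SITE_RADIUS, SITE_RADIUS, 3)
        if np.dot(p, p) <= SITE_RADIUS ** 2:
            return p


def _make_atom(kind: str, rng: np.random.Generator) -> SiteAtom:
    """Sample one atom of the requested channel kind from its element pool,
    with context chosen so the rule table fires that channel."""
    pos = _sample_position(rng)
    if kind == "metal":
        el = rng.choice(["Zn", "Fe", "Mg", "Ca", "Mn"])
        flags = assign_channels(el)
    elif kind == "aromatic":
        el = "C"
        flags = assign_channels(el, aromatic=True)
    elif kind == "hydrophobic":
        el = rng.choice(["C", "S"])
        flags = assign_channels(el)
    elif kind == "donor":
        el = "N"
        flags = assign_channels(el, n_hydrogens=1)
    elif kind == "acceptor":
        el = "O"
        flags = assign_channels(el)
    elif kind == "positive":
        el = "N"
        flags = assign_channels(el, n_hydrogens=3, formal_charge=1)
    elif kind == "negative":
        el = "O"
        flags = assign_channels(el, formal_charge=-1)
    else:
        raise ValueError(f"unknown atom kind {kind!r}")
    return SiteAtom(
        element=str(el),
        position=pos,
        vdw_radius=VDW_RADII[str(el)],
        channels=flags,
    )


def generate_targets(n: int, seed: int = 0) -> list[SyntheticTarget]:
    """Generate ``n`` synthetic targets, deterministic under ``seed``.

    Even-indexed targets are site-capable (carry metal atoms and an aromatic
    fraction of 0.15–0.35); odd-indexed targets have no metal and a low
    aromatic fraction, so the default planted rule's site predicate is false
    for them.  Composition and sequence length vary across targets.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    targets = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        site_capable = i % 2 == 0
        n_atoms = int(rng.integers(MIN_ATOMS, MAX_ATOMS + 1))
        if site_capable:
            n_metal = int(rng.integers(1, 4))
            aromatic_frac = rng.uniform(0.15, 0.35)
        else:
            n_metal = 0
            aromatic_frac = rng.uniform(0.0, 0.05)
        n_aromatic = int(round(aromatic_frac * n_atoms))
        kinds = ["metal"] * n_metal + ["aromatic"] * n_aromatic
        filler_kinds = ["hydrophobic", "donor", "acceptor", "positive", "negative"]
        filler_p = np.array([0.45, 0.2, 0.2, 0.075, 0.075])
        while len(kinds) < n_atoms:
            kinds.append(str(rng.choice(filler_kinds, p=filler_p)))
        atoms = [_make_atom(k, rng) for k in kinds]
        seq_len = int(rng.integers(MIN_SEQ, MAX_SEQ + 1))
        sequence = "".join(rng.choice(list(seq_encoder.AMINO_ACIDS), size=seq_len))
        targets.append(
            SyntheticTarget(
                target_id=f"T{i:03d}",
                atoms=atoms,
                sequence=sequence,
                site_capable=site_capable,
            )
        )
    return targets


def generate_pairs(
    targets: list[SyntheticTarget],
    molecules_per_target: int = 40,
    ratio: int = 1,
    rule: PlantedRule | None = None,
    seed: int = 0,
) -> tuple[list[SamplePair], dict[str, str], dict]:
    """Per-target screening pairs under the planted rule.

    For site-capable targets, ``molecules_per_target`` splits into
    ``molecules_per_target / (1 + ratio)`` predicate-true actives and
    ``ratio`` times as many predicate-false decoys; for site-incapable
    targets the same number of molecules is drawn from the whole library and
    every pair is negative under the rule.  Labels are then flipped with
    probability ``rule.noise``.  Returns (pairs, molecules used, manifest);
    the manifest fully determines regeneration.
    """
    rule = rule or PlantedRule()
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    library = molecule_library()
    mol_ids = sorted(library)
    pred = {m: rule.mol_predicate(library[m]) for m in mol_ids}
    true_pool = [m for m in mol_ids if pred[m]]
    false_pool = [m for m in mol_ids if not pred[m]]

    n_pos = molecules_per_target // (1 + ratio)
    n_neg = molecules_per_target - n_pos
    if n_pos < 1:
        raise ValueError("molecules_per_target too small for the requested ratio")
    if n_pos > len(true_pool) or n_neg > len(false_pool):
        raise ValueError(
            f"library exhausted: need {n_pos} predicate-true of {len(true_pool)} "
            f"and {n_neg} predicate-false of {len(false_pool)} molecules"
        )

    pairs: list[SamplePair] = []
    used: dict[str, str] = {}
    n_flipped = 0
    for t_i, target in enumerate(targets):
        rng = np.random.default_rng([seed, 1, t_i])
        site_ok = rule.site_predicate(target.atoms)
        if site_ok:
            chosen = [true_pool[i] for i in rng.choice(len(true_pool), n_pos, replace=False)]
            chosen += [false_pool[i] for i in rng.choice(len(false_pool), n_neg, replace=False)]
        else:
            chosen = [mol_ids[i] for i in rng.choice(len(mol_ids), molecules_per_target, replace=False)]
        for mol_id in chosen:
            label = int(site_ok and pred[mol_id])
            if rule.noise > 0 and rng.random() < rule.noise:
                label = 1 - label
                n_flipped += 1
            used[mol_id] = library[mol_id]
            pairs.append(SamplePair(target.target_id, mol_id, label))

    manifest = {
        "rule": asdict(rule),
        "seed": seed,
        "molecules_per_target": molecules_per_target,
        "ratio": ratio,
        "n_targets": len(targets),
        "n_pairs": len(pairs),
        "n_positive": int(sum(p.label for p in pairs)),
        "n_flipped": n_flipped,
        "target_ids": [t.target_id for t in targets],
    }
    return pairs, used, manifest


# -- emission in the real-path formats ----------------------------------------

def write_dataset(
    outdir,
    targets: list[SyntheticTarget],
    pairs: list[SamplePair],
    molecules: dict[str, str],
    manifest: dict,
) -> None:
    """Emit the formats the real pipeline consumes: per-target site-atom TSV,
    FASTA of sequences, a SMILES list, a pairs TSV and the JSON manifest."""
    import os

    from .data_eval import write_pairs

    os.makedirs(outdir, exist_ok=True)
    sites_dir = os.path.join(outdir, "sites")
    os.makedirs(sites_dir, exist_ok=True)
    for t in targets:
        voxelizer.write_site_table(os.path.join(sites_dir, f"{t.target_id}.tsv"), t.atoms)
    seq_encoder.write_fasta(
        os.path.join(outdir, "sequences.fasta"), {t.target_id: t.sequence for t in targets}
    )
    molgraph.write_smiles_file(os.path.join(outdir, "molecules.smi"), dict(sorted(molecules.items())))
    write_pairs(os.path.join(outdir, "pairs.tsv"), pairs)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def featurize_targets(targets: list[SyntheticTarget]) -> tuple[dict, dict]:
    """Voxel grids and token vectors for synthetic targets, keyed by id.
    The grid is centered on the site-atom centroid (no bound ligand here)."""
    grids, tokens = {}, {}
    for t in targets:
        center = voxelizer.site_center([a.position for a in t.atoms])
        spec = voxelizer.GridSpec(center=center)
        grids[t.target_id] = voxelizer.build_grid(t.atoms, spec)
        tokens[t.target_id] = seq_encoder.tokenize(t.sequence)
    return grids, tokens


def featurize_molecules(molecules: dict[str, str]) -> dict:
    """Molecular graphs keyed by molecule id."""
    return {mol_id: molgraph.build_graph(smi) for mol_id, smi in molecules.items()}


def planted_recovery_experiment(
    seed: int = 1,
    noise: float = 0.0,
    n_train_targets: int = 8,
    n_test_targets: int = 2,
    molecules_per_target: int = 40,
    ratio: int = 1,
    epochs: int = 30,
    learning_rate: float = 1e-3,
    batch_size: int = 16,
):
    """Train the desk-scale network on a planted-rule dataset and report the
    held-out (target-disjoint) ROC AUC.

    Generates ``n_train_targets + n_test_targets`` synthetic targets, builds
    pairs under the planted rule at the given flip ``noise``, trains the
    small network configuration and scores the held-out targets.  Returns a
    dict with the held-out AUC, the per-epoch history and the dataset
    manifest.  With ``noise = 0.5`` the labels carry no signal and the AUC
    should hover around one half.
    """
    from . import network
    from .data_eval import roc_auc

    n_total = n_train_targets + n_test_targets
    rule = PlantedRule(noise=noise)
    targets = generate_targets(n_total, seed=seed)
    pairs, molecules, manifest = generate_pairs(
        targets, molecules_per_target=molecules_per_target, ratio=ratio, rule=rule, seed=seed
    )
    grids, tokens = featurize_targets(targets)
    graphs = featurize_molecules(molecules)
    data = network.encode_dataset(pairs, grids, tokens, graphs)
    train_ids = sorted(t.target_id for t in targets[:n_train_targets])
    pair_targets = np.array(data.pair_target_ids())
    train_idx = np.flatnonzero(np.isin(pair_targets, train_ids))
    test_idx = np.flatnonzero(~np.isin(pair_targets, train_ids))
    model = network.CPINetwork(network.NetworkConfig.small(), seed=seed)
    train_cfg = network.TrainConfig(
        epochs=epochs, batch_size=batch_size, learning_rate=learning_rate, seed=seed
    )
    history = network.train_model(
        model, data.subset(train_idx), data.subset(test_idx), train_cfg
    )
    scores = network.predict_dataset(model, data.subset(test_idx))
    return {
        "heldout_auc": roc_auc(scores, data.labels[test_idx]),
        "best_epoch_auc": max(h["val_auc"] for h in history if h.get("val_auc") is not None),
        "history": history,
        "manifest": manifest,
        "model": model,
        "n_train_pairs": int(len(train_idx)),
        "n_test_pairs": int(len(test_idx)),
    }
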