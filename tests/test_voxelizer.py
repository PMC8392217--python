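"""Occupancy model, channel typing and grid construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpinet import voxelizer as vx
from cpinet.voxelizer import CHANNELS, GridSpec, SiteAtom


def make_atom(element="C", pos=(0.0, 0.0, 0.0), channels=None, rvdw=None):
    flags = vx.assign_channels(element) if channels is None else np.asarray(channels, bool)
    return SiteAtom(
        element=element,
        position=np.asarray(pos, float),
        vdw_radius=rvdw or vx.VDW_RADII.get(element, vx.DEFAULT_VDW_RADIUS),
        channels=flags,
    )


class TestOccupancy:
    @pytest.mark.parametrize(
        "r,rvdw,expected",
        [
            (1.7, 1.7, 1 - np.exp(-1)),           # r equals the vdW radius
            (0.0, 1.7, 1.0),                       # continuity limit at contact
            (3.4, 1.7, 1 - np.exp(-(2.0 ** -12))),  # r = 2 rvdw, ~2.4411e-4
            (2.0, 1.0, 1 - np.exp(-(2.0 ** -12))),
        ],
    )
    def test_pointwise(self, r, rvdw, expected):
        assert vx.occupancy(r, rvdw) == pytest.approx(expected, abs=1e-9)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            vx.occupancy(-0.1, 1.7)
        with pytest.raises(ValueError):
            vx.occupancy(1.0, 0.0)
        with pytest.raises(ValueError):
            vx.occupancy(1.0, -1.7)

    @settings(deadline=None, derandomize=True)
    @given(
        r=st.floats(0.0, 50.0),
        rvdw=st.floats(0.5, 3.0),
        dr=st.floats(1e-6, 5.0),
    )
    def test_monotone_and_bounded(self, r, rvdw, dr):
        v = vx.occupancy(r, rvdw)
        assert 0.0 <= v <= 1.0
        assert vx.occupancy(r + dr, rvdw) <= v + 1e-15


class TestAssignChannels:
    def test_metal(self):
        flags = vx.assign_channels("Zn")
        assert flags[CHANNELS.index("metal")]
        assert flags[CHANNELS.index("excluded_volume")]
        # a metal atom carries no hydrophobic or aromatic flags
        assert not flags[CHANNELS.index("hydrophobic")]
        assert not flags[CHANNELS.index("aromatic")]
        assert flags.sum() == 2

    def test_apolar_carbon_is_hydrophobic(self):
        flags = vx.assign_channels("C")
        assert flags[CHANNELS.index("hydrophobic")]
        assert flags[CHANNELS.index("excluded_volume")]
        assert flags.sum() == 2

    def test_polar_context_carbon_not_hydrophobic(self):
        flags = vx.assign_channels("C", polar_neighbor=True)
        assert not flags[CHANNELS.index("hydrophobic")]

    def test_carbonyl_oxygen_acceptor(self):
        flags = vx.assign_channels("O")
        assert flags[CHANNELS.index("acceptor")]
        assert not flags[CHANNELS.index("donor")]

    def test_nh_donor(self):
        flags = vx.assign_channels("N", n_hydrogens=1)
        assert flags[CHANNELS.index("donor")]

    def test_charge_flags(self):
        assert vx.assign_channels("N", formal_charge=1)[CHANNELS.index("positive")]
        assert vx.assign_channels("O", formal_charge=-1)[CHANNELS.index("negative")]

    def test_unrecognized_element_excluded_only(self, caplog):
        with caplog.at_level("WARNING"):
            flags = vx.assign_channels("Xx")
        assert flags[CHANNELS.index("excluded_volume")]
        assert flags.sum() == 1
        assert "unrecognized" in caplog.text

    def test_every_heavy_atom_has_excluded_volume(self):
        for el in ("C", "N", "O", "S", "Zn", "Fe", "Cl"):
            assert vx.assign_channels(el)[CHANNELS.index("excluded_volume")]


def naive_grid(atoms, spec):
    """Triple-loop oracle over (channel, voxel, atom)."""
    n = spec.voxels_per_axis
    ax = spec.axis_coordinates()
    grid = np.zeros((len(CHANNELS), n, n, n))
    for c in range(len(CHANNELS)):
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    center = np.array([ax[i, 0], ax[j, 1], ax[k, 2]])
                    best = 0.0
                    for a in atoms:
                        if not a.channels[c]:
                            continue
                        r = np.linalg.norm(a.position - center)
                        best = max(best, vx.occupancy(r, a.vdw_radius))
                    grid[c, i, j, k] = best
    return grid


class TestBuildGrid:
    def test_empty_atom_list_gives_zero_grid(self):
        grid = vx.build_grid([], GridSpec(center=np.zeros(3)))
        assert grid.shape == (8, 30, 30, 30)
        assert not grid.any()

    def test_metal_at_voxel_center(self):
        # default 30-voxel grid centered at origin has voxel centers at
        # half-integer coordinates; (0.5, 0.5, 0.5) is one of them
        spec = GridSpec(center=np.zeros(3))
        atom = make_atom("Zn", pos=(0.5, 0.5, 0.5))
        grid = vx.build_grid([atom], spec)
        m = CHANNELS.index("metal")
        assert grid[m, 15, 15, 15] == pytest.approx(1.0)
        # every other voxel equals the occupancy at its center distance
        ax = spec.axis_coordinates()
        d = np.sqrt(
            (ax[:, 0, None, None] - 0.5) ** 2
            + (ax[None, :, 1, None] - 0.5) ** 2
            + (ax[None, None, :, 2] - 0.5) ** 2
        )
        np.testing.assert_allclose(grid[m], vx.occupancy(d, atom.vdw_radius), atol=1e-12)
        # channels the atom is not flagged for stay empty
        assert not grid[CHANNELS.index("hydrophobic")].any()

    def test_duplicate_atoms_idempotent(self):
        spec = GridSpec(center=np.zeros(3))
        atom = make_atom("C", pos=(1.2, -0.7, 3.0))
        one = vx.build_grid([atom], spec)
        two = vx.build_grid([atom, atom], spec)
        np.testing.assert_array_equal(one, two)

    def test_matches_naive_oracle(self, rng):
        spec = GridSpec(center=rng.normal(size=3), edge_length=6.0, resolution=1.0)
        elements = ["C", "N", "O", "Zn", "S"]
        atoms = [
            make_atom(
                rng.choice(elements),
                pos=spec.center + rng.uniform(-4, 4, 3),
            )
            for _ in range(7)
        ]
        fast = vx.build_grid(atoms, spec)
        slow = naive_grid(atoms, spec)
        np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_translation_invariance(self, rng):
        shift = rng.normal(size=3) * 10
        atoms = [make_atom("C", pos=rng.uniform(-5, 5, 3)) for _ in range(5)]
        spec0 = GridSpec(center=np.zeros(3), edge_length=10.0)
        spec1 = GridSpec(center=shift, edge_length=10.0)
        moved = [make_atom("C", pos=a.position + shift) for a in atoms]
        np.testing.assert_allclose(
            vx.build_grid(atoms, spec0), vx.build_grid(moved, spec1), atol=1e-10
        )

    def test_atom_order_invariance(self, rng):
        atoms = [
            make_atom(el, pos=rng.uniform(-5, 5, 3))
            for el in ("C", "N", "O", "Zn", "S", "C")
        ]
        spec = GridSpec(center=np.zeros(3), edge_length=12.0)
        a = vx.build_grid(atoms, spec)
        b = vx.build_grid(atoms[::-1], spec)
        np.testing.assert_array_equal(a, b)

    def test_outside_atom_still_contributes(self):
        spec = GridSpec(center=np.zeros(3), edge_length=4.0)
        atom = make_atom("C", pos=(3.5, 0.0, 0.0))  # outside the 4 A box
        grid = vx.build_grid([atom], spec)
        assert grid[CHANNELS.index("hydrophobic")].max() > 0


class TestSiteCenter:
    def test_singleton(self):
        np.testing.assert_array_equal(vx.site_center([(1.0, 2.0, 3.0)]), [1, 2, 3])

    def test_midpoint(self):
        np.testing.assert_array_equal(
            vx.site_center([(0, 0, 0), (2, 0, 0)]), [1, 0, 0]
        )

    def test_four_points_mean(self):
        pts = np.array([[1, 2, 3], [4, 5, 6], [-2, 0, 2], [5, 1, 1]], float)
        np.testing.assert_allclose(vx.site_center(pts), pts.sum(axis=0) / 4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vx.site_center([])


PDB_SNIPPET = """\
ATOM      1  N   ASP A  30      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ASP A  30      12.560   6.351  -6.510  1.00  0.00           C
ATOM      3  CB  ASP A  30      13.000   7.000  -7.800  1.00  0.00           C
ATOM      4  OD1 ASP A  30      14.000   8.000  -8.000  1.00  0.00           O
ATOM      5  CG  PHE A  31      10.000   5.000  -5.000  1.00  0.00           C
ATOM      6  H   ASP A  30      11.000   6.000  -6.000  1.00  0.00           H
HETATM    7 ZN    ZN A 100      12.000   6.000  -7.000  1.00  0.00          ZN
"""


class TestPdbParsing:
    def test_records_channels_and_selection(self, tmp_path):
        path = tmp_path / "site.pdb"
        path.write_text(PDB_SNIPPET)
        atoms = vx.parse_pdb_site(path)
        assert len(atoms) == 6  # hydrogen skipped
        by = {(a.element, tuple(np.round(a.position, 1))): a for a in atoms}
        n_backbone = atoms[0]
        assert n_backbone.channels[CHANNELS.index("donor")]
        oD1 = atoms[3]
        assert oD1.channels[CHANNELS.index("acceptor")]
        assert oD1.channels[CHANNELS.index("negative")]
        phe_cg = atoms[4]
        assert phe_cg.channels[CHANNELS.index("aromatic")]
        zn = atoms[5]
        assert zn.channels[CHANNELS.index("metal")]
        # residue selection restricts atoms
        only_31 = vx.parse_pdb_site(path, residue_selection={("A", 31)})
        assert len(only_31) == 1

    def test_backbone_ca_not_hydrophobic(self, tmp_path):
        path = tmp_path / "site.pdb"
        path.write_text(PDB_SNIPPET)
        atoms = vx.parse_pdb_site(path)
        ca = atoms[1]
        assert not ca.channels[CHANNELS.index("hydrophobic")]
        cb = atoms[2]  # ASP CB is apolar-bonded? CB bonds CG (polar-adjacent via table)
        assert cb.channels[CHANNELS.index("excluded_volume")]


class TestSiteTableRoundtrip:
    def test_roundtrip_preserves_atoms(self, tmp_path, tiny_targets):
        atoms = tiny_targets[0].atoms
        path = tmp_path / "site.tsv"
        vx.write_site_table(path, atoms)
        back = vx.read_site_table(path)
        assert len(back) == len(atoms)
        for a, b in zip(atoms, back):
            assert a.element == b.element
            np.testing.assert_allclose(a.position, b.position)
            np.testing.assert_array_equal(a.channels, b.channels)

    def test_flags_default_to_rule_table(self, tmp_path):
        path = tmp_path / "bare.tsv"
        path.write_text("element\tx\ty\tz\nZn\t0\t0\t0\nC\t1\t1\t1\n")
        atoms = vx.read_site_table(path)
        assert atoms[0].channels[CHANNELS.index("metal")]
        assert atoms[1].channels[CHANNELS.index("hydrophobic")]


class TestGridContainer:
    def test_save_load_roundtrip(self, tmp_path, rng):
        grid = rng.uniform(0, 1, (8, 30, 30, 30))
        spec = GridSpec(center=np.array([1.0, 2.0, 3.0]))
        path = tmp_path / "grid.h5"
        vx.save_grid(path, grid, spec)
        back, back_spec = vx.load_grid(path)
        np.testing.assert_allclose(back, grid)
        np.testing.assert_allclose(back_spec.center, spec.center)
        assert back_spec.voxels_per_axis == 30
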