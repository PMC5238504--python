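"""Tests for per-residue RMSF and ligand-contact frequency analysis."""

import textwrap

import numpy as np
import pandas as pd
import pytest

from tandemsite.errors import NumericalError, ValidationError
from tandemsite.trajectory_metrics import (
    ContactCriteria,
    Trajectory,
    contact_frequency,
    kabsch,
    ligand_rings,
    rmsf,
)
from tests.conftest import make_static_protein


def random_rotation(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_trajectory(atoms, frames):
    return Trajectory(coords=np.array(frames), atoms=atoms)


class TestRmsf:
    def test_static_trajectory_is_zero(self, static_protein):
        atoms, xyz = static_protein
        traj = make_trajectory(atoms, [xyz] * 6)
        prof = rmsf(traj, subset="backbone")
        assert np.allclose(prof.table["rmsf_A"], 0.0, atol=1e-10)

    def test_sinusoidal_atom_approaches_inverse_sqrt2(self):
        # one atom oscillating with amplitude 1 A along x over full
        # periods: variance of a sinusoid -> RMSF = 1/sqrt(2)
        atoms, xyz = make_static_protein(n_residues=200)
        n_frames = 64
        frames = []
        mobile = atoms.index[atoms["residue_id"] == 1][0]
        for k in range(n_frames):
            f = xyz.copy()
            f[mobile, 0] += np.sin(2 * np.pi * k / n_frames)
            frames.append(f)
        prof = rmsf(make_trajectory(atoms, frames), subset="backbone")
        table = prof.table.set_index("residue_id")
        moving = table.loc[1, "rmsf_A"]
        # residue-level RMSF pools the residue's 3 atoms (2 static):
        # sqrt(mean([0.5, 0, 0])) = sqrt(1/6); superposition absorbs an
        # O(1/n_atoms) share of the motion, hence the many static anchors
        assert moving == pytest.approx(np.sqrt(0.5 / 3.0), rel=0.01)
        assert np.allclose(table.drop(index=1)["rmsf_A"], 0.0, atol=0.01)

    def test_invariant_under_rigid_motion_of_frames(self, static_protein):
        atoms, xyz = static_protein
        rng = np.random.default_rng(3)
        frames = [xyz @ random_rotation(rng).T + rng.uniform(-30, 30, 3)
                  for _ in range(8)]
        prof = rmsf(make_trajectory(atoms, frames), subset="backbone")
        assert np.allclose(prof.table["rmsf_A"], 0.0, atol=1e-8)

    def test_idempotent_under_trajectory_duplication(self):
        atoms, xyz = make_static_protein(seed=5)
        rng = np.random.default_rng(7)
        frames = [xyz + 0.3 * rng.standard_normal(xyz.shape)
                  for _ in range(10)]
        traj1 = make_trajectory(atoms, frames)
        traj2 = make_trajectory(atoms, frames + frames)
        a = rmsf(traj1).table["rmsf_A"].to_numpy()
        b = rmsf(traj2).table["rmsf_A"].to_numpy()
        assert np.allclose(a, b, rtol=1e-12)

    def test_collinear_subset_raises(self):
        atoms = pd.DataFrame({
            "atom_id": range(3), "name": ["CA"] * 3,
            "residue_id": [1, 2, 3], "residue_name": ["ALA"] * 3,
            "element": ["C"] * 3})
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(NumericalError, match="collinear"):
            rmsf(make_trajectory(atoms, [line, line + 1.0]),
                 subset="backbone")

    def test_kabsch_recovers_known_rotation(self):
        rng = np.random.default_rng(11)
        pts = rng.standard_normal((20, 3))
        rot_true = random_rotation(rng)
        moved = pts @ rot_true.T + np.array([1.0, -2.0, 3.0])
        rot, trans = kabsch(moved, pts)
        assert np.allclose(moved @ rot.T + trans, pts, atol=1e-10)

    def test_validation(self, static_protein):
        atoms, xyz = static_protein
        with pytest.raises(ValidationError):
            Trajectory(coords=xyz[None], atoms=atoms)  # single frame
        with pytest.raises(ValidationError):
            bad = np.array([xyz, xyz])
            bad[0, 0, 0] = np.nan
            Trajectory(coords=bad, atoms=atoms)


def hbond_system(n_frames=10, bound_frames=10, two_bonds=False):
    """Ligand hydroxyl donating to a serine side-chain oxygen.

    The donor geometry is satisfied in ``bound_frames`` of ``n_frames``;
    with ``two_bonds`` a second ligand O-H donates to the same residue.
    """
    rows = [
        {"atom_id": 0, "name": "OG", "residue_id": 1, "residue_name": "SER",
         "element": "O"},
        {"atom_id": 1, "name": "CB", "residue_id": 1, "residue_name": "SER",
         "element": "C"},
        {"atom_id": 2, "name": "O1", "residue_id": 99, "residue_name": "LIG",
         "element": "O"},
        {"atom_id": 3, "name": "H1", "residue_id": 99, "residue_name": "LIG",
         "element": "H"},
    ]
    if two_bonds:
        rows += [
            {"atom_id": 4, "name": "O2", "residue_id": 99,
             "residue_name": "LIG", "element": "O"},
            {"atom_id": 5, "name": "H2", "residue_id": 99,
             "residue_name": "LIG", "element": "H"},
        ]
    atoms = pd.DataFrame(rows)
    near = {
        0: [0.0, 0.0, 0.0], 1: [0.0, 1.5, 0.0],
        2: [2.9, 0.0, 0.0], 3: [1.9, 0.0, 0.0],   # linear O-H...O, DA 2.9 A
        4: [0.0, 0.0, 2.9], 5: [0.0, 0.0, 1.9],
    }
    far = {k: [v[0] + 50.0, v[1], v[2]] if k >= 2 else v
           for k, v in near.items()}
    n_atoms = len(atoms)
    frames = []
    for i in range(n_frames):
        pos = near if i < bound_frames else far
        frames.append(np.array([pos[a] for a in range(n_atoms)]))
    return Trajectory(coords=np.array(frames), atoms=atoms,
                      ligand_resnames=("LIG",))


def ring(center, radius=1.4, normal_axis=2, n=6):
    pts = []
    for k in range(n):
        ang = 2 * np.pi * k / n
        p = [0.0, 0.0, 0.0]
        p[(normal_axis + 1) % 3] = radius * np.cos(ang)
        p[(normal_axis + 2) % 3] = radius * np.sin(ang)
        pts.append(np.asarray(center) + p)
    return np.array(pts)


def stacking_system(separation=3.5, n_frames=4):
    """Ligand benzene stacked on a phenylalanine ring."""
    phe_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    rows = [{"atom_id": i, "name": nm, "residue_id": 1,
             "residue_name": "PHE", "element": "C"}
            for i, nm in enumerate(phe_names)]
    rows += [{"atom_id": 6 + i, "name": f"C{i+1}", "residue_id": 99,
              "residue_name": "LIG", "element": "C"} for i in range(6)]
    atoms = pd.DataFrame(rows)
    frame = np.vstack([ring([0.0, 0.0, 0.0]),
                       ring([0.0, 0.0, separation])])
    return Trajectory(coords=np.array([frame] * n_frames), atoms=atoms,
                      ligand_resnames=("LIG",))


class TestContacts:
    def test_partial_occupancy_gives_percent(self):
        traj = hbond_system(n_frames=10, bound_frames=5)
        prof = contact_frequency(traj)
        row = prof.table.set_index("residue_id").loc[1]
        assert row["hbond_pct"] == pytest.approx(50.0)

    def test_two_simultaneous_bonds_exceed_hundred(self):
        traj = hbond_system(n_frames=6, bound_frames=6, two_bonds=True)
        prof = contact_frequency(traj)
        row = prof.table.set_index("residue_id").loc[1]
        assert row["hbond_pct"] == pytest.approx(200.0)

    def test_zero_distance_criteria_kill_all_contacts(self):
        traj = hbond_system()
        crit = ContactCriteria(hbond_distance=0.0, stack_distance=0.0)
        prof = contact_frequency(traj, crit)
        assert (prof.table["hbond_pct"] == 0).all()
        assert (prof.table["stack_pct"] == 0).all()

    def test_ring_stacking_detected(self):
        traj = stacking_system(separation=3.5)
        assert len(ligand_rings(traj)) == 1
        prof = contact_frequency(traj)
        row = prof.table.set_index("residue_id").loc[1]
        assert row["stack_pct"] == pytest.approx(100.0)

    def test_distant_rings_not_stacked(self):
        traj = stacking_system(separation=8.0)
        prof = contact_frequency(traj)
        assert (prof.table["stack_pct"] == 0).all()

    def test_interplanar_angle_criterion(self):
        # perpendicular rings fail a 30-degree coplanarity cutoff
        phe_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        rows = [{"atom_id": i, "name": nm, "residue_id": 1,
                 "residue_name": "PHE", "element": "C"}
                for i, nm in enumerate(phe_names)]
        rows += [{"atom_id": 6 + i, "name": f"C{i+1}", "residue_id": 99,
                  "residue_name": "LIG", "element": "C"} for i in range(6)]
        atoms = pd.DataFrame(rows)
        frame = np.vstack([ring([0.0, 0.0, 0.0], normal_axis=2),
                           ring([0.0, 0.0, 3.5], normal_axis=0)])
        traj = Trajectory(coords=np.array([frame, frame]), atoms=atoms,
                          ligand_resnames=("LIG",))
        strict = contact_frequency(traj, ContactCriteria(stack_angle=30.0))
        loose = contact_frequency(traj, ContactCriteria(stack_angle=None))
        assert (strict.table["stack_pct"] == 0).all()
        assert loose.table.set_index("residue_id").loc[1, "stack_pct"] == 100.0

    def test_no_rings_warns_and_returns_zeros(self):
        traj = hbond_system()  # ligand is just O-H, no rings
        with pytest.warns(UserWarning, match="no rings"):
            prof = contact_frequency(traj)
        assert (prof.table["stack_pct"] == 0).all()

    def test_frame_permutation_invariance(self):
        traj = hbond_system(n_frames=10, bound_frames=4)
        perm = np.random.default_rng(0).permutation(10)
        shuffled = Trajectory(coords=traj.coords[perm], atoms=traj.atoms,
                              ligand_resnames=traj.ligand_resnames)
        a = contact_frequency(traj).table
        b = contact_frequency(shuffled).table
        pd.testing.assert_frame_equal(a, b)


class TestFileReading:
    def test_multi_model_pdb_roundtrip(self, tmp_path):
        pdb = textwrap.dedent("""\
            MODEL        1
            ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
            ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
            ATOM      3  C   ALA A   1       2.200   1.300   0.000  1.00  0.00           C
            ENDMDL
            MODEL        2
            ATOM      1  N   ALA A   1       0.000   0.000   1.000  1.00  0.00           N
            ATOM      2  CA  ALA A   1       1.500   0.000   1.000  1.00  0.00           C
            ATOM      3  C   ALA A   1       2.200   1.300   1.000  1.00  0.00           C
            ENDMDL
            END
            """)
        path = tmp_path / "tiny.pdb"
        path.write_text(pdb)
        traj = Trajectory.from_file(path)
        assert traj.n_frames == 2
        assert list(traj.atoms["name"]) == ["N", "CA", "C"]
        assert traj.coords[1, 0, 2] == pytest.approx(1.0)

    def test_xyz_reading(self, tmp_path):
        xyz = ("3\nframe 1\nC 0.0 0.0 0.0\nC 1.4 0.0 0.0\nO 2.0 1.0 0.0\n"
               "3\nframe 2\nC 0.0 0.0 0.5\nC 1.4 0.0 0.5\nO 2.0 1.0 0.5\n")
        path = tmp_path / "tiny.xyz"
        path.write_text(xyz)
        traj = Trajectory.from_file(path)
        assert traj.n_frames == 2
        assert traj.coords.shape == (2, 3, 3)
        assert traj.atoms["element"].tolist() == ["C", "C", "O"]

    def test_profile_csv_writing(self, tmp_path, static_protein):
        atoms, xyz = static_protein
        traj = Trajectory(coords=np.array([xyz, xyz]), atoms=atoms)
        prof = rmsf(traj)
        out = tmp_path / "rmsf.csv"
        prof.to_csv(out)
        back = pd.read_csv(out)
        assert list(back.columns) == ["residue_id", "residue_name", "rmsf_A"]
        assert len(back) == atoms["residue_id"].nunique()
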