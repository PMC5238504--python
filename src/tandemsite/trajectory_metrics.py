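"""Per-residue fluctuation and ligand-contact statistics for trajectories.

Two observables used to characterize receptor flexibility and
ligand-receptor interactions along a coordinate trajectory:

- **RMSF**: every frame is rigid-body superposed (Kabsch least-squares)
  onto a reference frame over a chosen atom subset, then the root mean
  square fluctuation of residue *i* is the RMS over frames and over the
  residue's subset atoms of the displacement from the reference
  positions.
- **Contact frequencies**: per residue, the number of hydrogen bonds and
  of ring-stacking (pi-pi) contacts with a ligand, counted per frame and
  normalized over the trajectory as ``100 * total / n_frames`` — values
  over 100 are possible because the ligand may make multiple simultaneous
  contacts with one residue.

Trajectories are read from multi-model PDB or XYZ files through
MDAnalysis.  Geometric criteria (donor-acceptor distance/angle, ring
centroid distance, interplanar angle) are configurable; the defaults are
the conventional choices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from tandemsite.errors import NumericalError, ValidationError

BACKBONE_NAMES = {"N", "CA", "C", "O"}

#: ring atom names of the standard aromatic residues
AROMATIC_RINGS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2")],
}

_HBOND_ELEMENTS = {"N", "O"}
_COVALENT_H_CUTOFF = 1.25   # A, donor-hydrogen bond detection
_BOND_CUTOFF = 1.8          # A, heavy-atom bond graph for ring perception


@dataclass
class Trajectory:
    """Frame-indexed Cartesian coordinates plus an atom table.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom; ``atoms``
    has one row per atom with columns ``atom_id``, ``name``,
    ``residue_id``, ``residue_name``, ``element``.  ``ligand_resnames``
    marks which residue names are the ligand for contact analysis.
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    ligand_resnames: tuple = ()
    dt_ps: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 2:
            raise ValidationError("trajectory needs >= 2 frames")
        if self.coords.shape[1] != len(self.atoms):
            raise ValidationError("atom table does not match coordinates")
        if not np.isfinite(self.coords).all():
            raise ValidationError("coordinates must be finite")
        required = {"atom_id", "name", "residue_id", "residue_name",
                    "element"}
        missing = required - set(self.atoms.columns)
        if missing:
            raise ValidationError(f"atom table missing columns {missing}")
        # positional row index is relied on throughout
        self.atoms = self.atoms.reset_index(drop=True)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @classmethod
    def from_file(cls, path, ligand_resnames: tuple = (),
                  **universe_kwargs) -> "Trajectory":
        """Read a multi-model PDB or XYZ trajectory via MDAnalysis."""
        import MDAnalysis as mda

        path = Path(path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), **universe_kwargs)
            coords = np.array([u.atoms.positions.copy() for _ in u.trajectory])
        n_atoms = coords.shape[1]
        try:
            names = [str(n) for n in u.atoms.names]
        except Exception:
            names = [f"X{i}" for i in range(n_atoms)]
        try:
            elements = [str(e).capitalize() for e in u.atoms.elements]
        except Exception:
            elements = [_element_from_name(n) for n in names]
        try:
            resids = np.asarray(u.atoms.resids)
            resnames = [str(r) for r in u.atoms.resnames]
        except Exception:
            # XYZ carries no residue information: single unknown residue
            resids = np.ones(n_atoms, dtype=int)
            resnames = ["UNK"] * n_atoms
        atoms = pd.DataFrame({
            "atom_id": np.arange(n_atoms),
            "name": names,
            "residue_id": resids,
            "residue_name": resnames,
            "element": elements,
        })
        return cls(coords=coords, atoms=atoms,
                   ligand_resnames=tuple(ligand_resnames))


def _element_from_name(name: str) -> str:
    stripped = name.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].capitalize() in ("Cl", "Br"):
        return stripped[:2].capitalize()
    return stripped[:1].upper()


@dataclass
class FluctuationProfile:
    """Per-residue RMSF (Angstrom) for a chosen atom subset."""

    table: pd.DataFrame          # residue_id, residue_name, rmsf_A
    subset: str
    reference_frame: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")


@dataclass
class ContactProfile:
    """Per-residue percent contact frequencies over a trajectory."""

    table: pd.DataFrame          # residue_id, residue_name, hbond_pct, stack_pct
    n_frames: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric thresholds for hydrogen bonds and ring stacking."""

    hbond_distance: float = 3.5       # donor-acceptor, A
    hbond_angle: float = 120.0        # donor-H-acceptor minimum, degrees
    stack_distance: float = 5.5       # ring centroid-centroid, A
    stack_angle: float | None = None  # max interplanar angle, degrees

    def __post_init__(self) -> None:
        if self.hbond_distance < 0 or self.stack_distance < 0:
            raise ValidationError("criteria distances must be >= 0")
        if not (0 <= self.hbond_angle <= 180):
            raise ValidationError("hbond_angle must lie in [0, 180] degrees")


# ---------------------------------------------------------------------------
# superposition


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition (rotation + translation) of point sets.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` minimizes the RMSD
    to ``reference``.  Raises :class:`NumericalError` when the points are
    collinear (rotation underdetermined).
    """
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    p = mobile - mob_c
    q = reference - ref_c
    if np.linalg.matrix_rank(p, tol=1e-8) < 2:
        raise NumericalError("superposition singular: collinear atom subset")
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = ref_c - rot @ mob_c
    return rot, trans


def _subset_mask(traj: Trajectory, subset: str) -> np.ndarray:
    if subset == "backbone":
        mask = traj.atoms["name"].isin(BACKBONE_NAMES).to_numpy()
    elif subset == "heavy":
        mask = (traj.atoms["element"] != "H").to_numpy()
    else:
        raise ValidationError("subset must be 'backbone' or 'heavy'")
    if traj.ligand_resnames:
        mask &= ~traj.atoms["residue_name"].isin(traj.ligand_resnames).to_numpy()
    if not mask.any():
        raise ValidationError(f"no atoms in subset {subset!r}")
    return mask


def rmsf(traj: Trajectory, subset: str = "backbone",
         reference_frame: int = 0) -> FluctuationProfile:
    """Per-residue RMSF after Kabsch superposition onto a reference frame.

    Each frame is superposed onto ``reference_frame`` over the chosen
    subset (``backbone`` or ``heavy``, ligand excluded); the residue RMSF
    is the RMS over frames and the residue's subset atoms of the
    displacement from the reference — not the mean of per-atom RMSFs.
    """
    mask = _subset_mask(traj, subset)
    ref = traj.coords[reference_frame]
    sq = np.zeros(mask.sum())
    idx = np.flatnonzero(mask)
    for frame in traj.coords:
        rot, trans = kabsch(frame[idx], ref[idx])
        aligned = frame[idx] @ rot.T + trans
        sq += np.sum((aligned - ref[idx]) ** 2, axis=1)
    sq /= traj.n_frames

    sub = traj.atoms.iloc[idx].copy()
    sub["sq"] = sq
    per_res = sub.groupby(["residue_id", "residue_name"], sort=True)["sq"]
    table = per_res.mean().pow(0.5).rename("rmsf_A").reset_index()
    residues_missing = [r for r in np.unique(traj.atoms["residue_id"])
                        if r not in set(table["residue_id"])]
    if residues_missing and not traj.ligand_resnames:
        raise ValidationError(
            f"residues {residues_missing} have no atoms in subset {subset!r}")
    return FluctuationProfile(table=table, subset=subset,
                              reference_frame=reference_frame)


# ---------------------------------------------------------------------------
# contacts


def _ligand_mask(traj: Trajectory) -> np.ndarray:
    if not traj.ligand_resnames:
        raise ValidationError("trajectory has no ligand selection")
    mask = traj.atoms["residue_name"].isin(traj.ligand_resnames).to_numpy()
    if not mask.any():
        raise ValidationError(
            f"no atoms match ligand residue names {traj.ligand_resnames}")
    return mask


def _donors_with_h(traj: Trajectory, mask: np.ndarray,
                   frame0: np.ndarray) -> list[tuple[int, int]]:
    """(donor, hydrogen) index pairs among masked atoms (frame-0 bonds)."""
    atoms = traj.atoms
    heavy = np.flatnonzero(mask & atoms["element"].isin(_HBOND_ELEMENTS))
    hydro = np.flatnonzero(mask & (atoms["element"] == "H").to_numpy())
    pairs = []
    for d in heavy:
        if hydro.size == 0:
            continue
        dist = np.linalg.norm(frame0[hydro] - frame0[d], axis=1)
        for h in hydro[dist <= _COVALENT_H_CUTOFF]:
            pairs.append((int(d), int(h)))
    return pairs


def _acceptors(traj: Trajectory, mask: np.ndarray) -> np.ndarray:
    return np.flatnonzero(mask & traj.atoms["element"].isin(_HBOND_ELEMENTS))


def _hbond_count(frame: np.ndarray, donors, acceptors,
                 crit: ContactCriteria) -> list[tuple[int, int]]:
    """(donor, acceptor) pairs satisfying distance + angle in one frame."""
    hits = []
    for d, h in donors:
        if acceptors.size == 0:
            continue
        da = np.linalg.norm(frame[acceptors] - frame[d], axis=1)
        close = acceptors[(da <= crit.hbond_distance) & (da > 1e-6)]
        for a in close:
            v1 = frame[d] - frame[h]
            v2 = frame[a] - frame[h]
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 < 1e-9 or n2 < 1e-9:
                continue
            cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
            if np.degrees(np.arccos(cosang)) >= crit.hbond_angle:
                hits.append((d, int(a)))
    return hits


def ligand_rings(traj: Trajectory) -> list[np.ndarray]:
    """Ring atom-index sets of the ligand, perceived from a bond graph.

    Bonds are assigned between heavy ligand atoms closer than 1.8 A in
    frame 0; rings are the 5-7-membered cycles of that graph.
    """
    lig = _ligand_mask(traj)
    heavy = np.flatnonzero(lig & (traj.atoms["element"] != "H").to_numpy())
    frame0 = traj.coords[0]
    g = nx.Graph()
    g.add_nodes_from(heavy.tolist())
    for i, a in enumerate(heavy):
        d = np.linalg.norm(frame0[heavy[i + 1:]] - frame0[a], axis=1)
        for b in heavy[i + 1:][d <= _BOND_CUTOFF]:
            g.add_edge(int(a), int(b))
    return [np.array(cycle) for cycle in nx.cycle_basis(g)
            if 5 <= len(cycle) <= 7]


def _residue_rings(traj: Trajectory) -> list[tuple[int, np.ndarray]]:
    """(residue_id, ring atom indices) for standard aromatic residues."""
    atoms = traj.atoms
    out = []
    for (rid, rname), grp in atoms.groupby(["residue_id", "residue_name"]):
        if traj.ligand_resnames and rname in traj.ligand_resnames:
            continue
        for ring_names in AROMATIC_RINGS.get(str(rname).upper(), []):
            sel = grp[grp["name"].isin(ring_names)]
            if len(sel) == len(ring_names):
                out.append((rid, sel.index.to_numpy()))
    return out


def _ring_geometry(frame: np.ndarray, idx: np.ndarray):
    pts = frame[idx]
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered)
    return centroid, vt[2]


def contact_frequency(traj: Trajectory,
                      criteria: ContactCriteria | None = None) -> ContactProfile:
    """Hydrogen-bond and ring-stacking frequencies per receptor residue.

    Per frame, every ligand-receptor pair satisfying the hydrogen-bond
    geometry (donor-acceptor distance and donor-H-acceptor angle, both
    directions) or the ring-stacking geometry (centroid distance and
    optional interplanar angle) is counted; frequencies are
    ``100 * count / n_frames`` per residue and may exceed 100.
    """
    crit = criteria or ContactCriteria()
    lig_mask = _ligand_mask(traj)
    rec_mask = ~lig_mask
    frame0 = traj.coords[0]

    lig_donors = _donors_with_h(traj, lig_mask, frame0)
    rec_donors = _donors_with_h(traj, rec_mask, frame0)
    lig_acc = _acceptors(traj, lig_mask)
    rec_acc = _acceptors(traj, rec_mask)
    lig_ring_sets = ligand_rings(traj)
    rec_ring_sets = _residue_rings(traj)
    if not lig_ring_sets:
        warnings.warn("ligand has no rings: stacking profile is empty",
                      stacklevel=2)

    resid_of = traj.atoms["residue_id"].to_numpy()
    hbond_counts: dict[int, int] = {}
    stack_counts: dict[int, int] = {}
    for frame in traj.coords:
        for d, a in _hbond_count(frame, lig_donors, rec_acc, crit):
            hbond_counts[resid_of[a]] = hbond_counts.get(resid_of[a], 0) + 1
        for d, a in _hbond_count(frame, rec_donors, lig_acc, crit):
            hbond_counts[resid_of[d]] = hbond_counts.get(resid_of[d], 0) + 1
        for lig_ring in lig_ring_sets:
            lc, ln = _ring_geometry(frame, lig_ring)
            for rid, rec_ring in rec_ring_sets:
                rc, rn = _ring_geometry(frame, rec_ring)
                if np.linalg.norm(lc - rc) > crit.stack_distance:
                    continue
                if crit.stack_angle is not None:
                    cosang = abs(float(np.clip(ln @ rn, -1.0, 1.0)))
                    if np.degrees(np.arccos(cosang)) > crit.stack_angle:
                        continue
                stack_counts[rid] = stack_counts.get(rid, 0) + 1

    residues = (traj.atoms.loc[rec_mask, ["residue_id", "residue_name"]]
                .drop_duplicates("residue_id").sort_values("residue_id"))
    n = traj.n_frames
    table = residues.assign(
        hbond_pct=[100.0 * hbond_counts.get(r, 0) / n
                   for r in residues["residue_id"]],
        stack_pct=[100.0 * stack_counts.get(r, 0) / n
                   for r in residues["residue_id"]],
    ).reset_index(drop=True)
    return ContactProfile(table=table, n_frames=n)
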