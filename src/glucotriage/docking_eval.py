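"""Docking-campaign evaluation: pose pooling, the best-pose acceptance
criterion, symmetry-aware RMSD, and residue-level interaction profiling.

Poses are ligand coordinate sets with an affinity energy E_A (kcal/mol)
as produced by a docking engine; this module never computes E_A itself.
The acceptance gate selects, among pooled poses, the lowest-energy pose
with E_A below -6.0 kcal/mol whose RMSD to a reference (typically the
co-crystallized ligand) is below 2.0 A. RMSD is computed in the receptor
frame without re-superposition, optionally minimized over the molecular
graph's automorphisms so that topologically equivalent atoms (e.g. the
two ortho carbons of a phenyl ring) cannot inflate it.

Interaction profiling reports one record per (residue, type) between a
receptor structure (a biotite AtomArray with residue annotations) and a
pose: hydrophobic carbon-carbon contacts, heavy-atom donor/acceptor
hydrogen bonds binned into strength classes, and pi-cation contacts
between a charged ligand nitrogen and an aromatic ring centroid.
"""

from __future__ import annotations

import itertools
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bst_pdb

__all__ = [
    "GridBox",
    "Pose",
    "DockingResult",
    "InteractionRecord",
    "DEFAULT_GRID_BOXES",
    "EA_CUT",
    "RMSD_CUT",
    "pose_rmsd",
    "select_best_pose",
    "classify_hbond",
    "profile_interactions",
    "gridbox_contains",
    "read_pdbqt_poses",
    "read_receptor",
]

EA_CUT = -6.0        # kcal/mol: acceptable poses lie strictly below
RMSD_CUT = 2.0       # A: protocol-validation gate (strictly below)
HYDROPHOBIC_CUT = 4.5    # A, carbon-carbon
HBOND_CUT = 4.0          # A, heavy-atom donor-acceptor
PI_CATION_CUT = 6.0      # A, cation to aromatic ring centroid
MAX_AUTOMORPHISMS = 10_000

# Strength bins for heavy-atom donor-acceptor distances (A).
HBOND_BINS = (("strong", 2.2, 2.5), ("moderate", 2.5, 3.2), ("weak", 3.2, 4.0))

# Aromatic side-chain rings used for pi-cation detection.
_AROMATIC_RINGS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [("CG", "CD1", "CD2", "NE1", "CE2"),
            ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")],
}

# Single-bond covalent radii (A) for bond inference from coordinates.
_COV_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}


@dataclass(frozen=True)
class GridBox:
    """Axis-aligned docking search box (center and dimensions in A)."""

    center: tuple[float, float, float]
    dimensions: tuple[float, float, float]
    target_id: str = ""

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dimensions):
            raise ValueError(f"dimensions must be positive, got {self.dimensions}")


#: Published search boxes for the two receptor targets: aldose reductase
#: (PDB 2IKH) and glucokinase (PDB 4IXC).
DEFAULT_GRID_BOXES = {
    "2IKH": GridBox((14.17, -0.095, 23.464), (60.0, 40.0, 56.0), "2IKH"),
    "4IXC": GridBox((63.267, 25.856, 0.231), (66.0, 72.0, 66.0), "4IXC"),
}


@dataclass
class Pose:
    """One docked ligand pose in the receptor frame."""

    coords: np.ndarray                  # (N, 3) A
    elements: tuple[str, ...]
    energy: float                       # E_A, kcal/mol
    run_index: int = 0
    pose_index: int = 0
    formal_charges: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if len(self.elements) != len(self.coords):
            raise ValueError("one element label per coordinate required")
        if not math.isfinite(self.energy):
            raise ValueError(f"affinity energy must be finite, got {self.energy}")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)


@dataclass
class InteractionRecord:
    residue: str                # e.g. "ASP43.A"
    kind: str                   # hydrophobic | hbond | pi_cation
    distance: float             # A (minimal over the pair set)
    strength: str               # strong | moderate | weak | none | n/a


@dataclass
class DockingResult:
    poses: list[Pose]
    best: Pose | None
    best_rmsd: float | None
    accepted: bool
    interactions: list[InteractionRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def _infer_graph(elements: Sequence[str], coords: np.ndarray) -> nx.Graph:
    """Bond graph from covalent radii (1.25 x sum-of-radii tolerance)."""
    g = nx.Graph()
    for i, el in enumerate(elements):
        g.add_node(i, element=el)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    for i, j in itertools.combinations(range(len(elements)), 2):
        cut = 1.25 * (_COV_RADII.get(elements[i], 0.76)
                      + _COV_RADII.get(elements[j], 0.76))
        if d[i, j] <= cut:
            g.add_edge(i, j)
    return g


def _automorphisms(g: nx.Graph, cap: int = MAX_AUTOMORPHISMS) -> list[dict[int, int]]:
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g, node_match=lambda a, b: a["element"] == b["element"]
    )
    perms: list[dict[int, int]] = []
    for perm in matcher.isomorphisms_iter():
        perms.append(perm)
        if len(perms) > cap:
            warnings.warn(
                f"more than {cap} graph automorphisms; falling back to the "
                "identity mapping", stacklevel=3,
            )
            return [{i: i for i in g.nodes}]
    return perms


def pose_rmsd(a: Pose, b: Pose, symmetry_aware: bool = True) -> float:
    """Root-mean-square deviation between two poses of the same molecule.

    Coordinates are compared in the shared receptor frame (no
    superposition). With ``symmetry_aware`` the RMSD is minimized over
    atom relabelings induced by the molecular graph's automorphisms
    (graph inferred from pose ``a``'s geometry), capped at 10^4
    permutations.
    """
    if sorted(a.elements) != sorted(b.elements):
        raise ValueError(
            f"element multisets differ: {sorted(set(a.elements))} vs "
            f"{sorted(set(b.elements))} (or counts mismatch)"
        )
    if a.n_atoms != b.n_atoms:
        raise ValueError(f"atom counts differ: {a.n_atoms} vs {b.n_atoms}")

    def rmsd_for(mapping: dict[int, int]) -> float:
        idx = [mapping[i] for i in range(a.n_atoms)]
        delta = a.coords - b.coords[idx]
        return float(np.sqrt((delta**2).sum(axis=1).mean()))

    identity = {i: i for i in range(a.n_atoms)}
    if a.elements != b.elements and not symmetry_aware:
        raise ValueError("atom orders differ; use symmetry_aware=True")
    if not symmetry_aware:
        return rmsd_for(identity)
    g = _infer_graph(a.elements, a.coords)
    best = math.inf
    for perm in _automorphisms(g):
        # permutation must respect element labels of pose b's ordering
        if any(a.elements[i] != b.elements[perm[i]] for i in range(a.n_atoms)):
            continue
        best = min(best, rmsd_for(perm))
    if math.isinf(best):
        best = rmsd_for(identity)
    return best


def select_best_pose(
    poses: Iterable[Pose],
    reference: Pose | None = None,
    ea_cut: float = EA_CUT,
    rmsd_cut: float = RMSD_CUT,
    symmetry_aware: bool = True,
) -> DockingResult:
    """Acceptance gate over a pooled docking campaign.

    Among poses with E_A strictly below ``ea_cut`` and (when a reference
    pose is given) RMSD to the reference strictly below ``rmsd_cut``,
    select the lowest-energy pose. Verdict is ``accepted=False`` when no
    pose passes both filters. Result is invariant to pose order (energy,
    then run/pose index break ties).
    """
    poses = sorted(poses, key=lambda p: (p.energy, p.run_index, p.pose_index))
    if not poses:
        raise ValueError("empty pose set")
    best, best_rmsd = None, None
    for pose in poses:
        if not pose.energy < ea_cut:
            continue
        if reference is not None:
            r = pose_rmsd(pose, reference, symmetry_aware=symmetry_aware)
            if not r < rmsd_cut:
                continue
            best, best_rmsd = pose, r
        else:
            best = pose
        break
    return DockingResult(
        poses=list(poses), best=best, best_rmsd=best_rmsd,
        accepted=best is not None,
    )


# ---------------------------------------------------------------------------
# Interactions
# ---------------------------------------------------------------------------

def classify_hbond(distance: float) -> str:
    """Strength class of a heavy-atom donor-acceptor distance (A):
    strong [2.2, 2.5), moderate [2.5, 3.2), weak [3.2, 4.0), none >= 4.0.
    """
    if not distance > 0:
        raise ValueError(f"distance must be positive, got {distance}")
    for name, lo, hi in HBOND_BINS:
        if lo <= distance < hi:
            return name
    return "none"


def _residue_label(res_name: str, res_id: int, chain: str) -> str:
    return f"{res_name}{res_id}.{chain}"


def read_receptor(path: str | Path) -> bst.AtomArray:
    """Read a receptor PDB file into a biotite AtomArray (first model)."""
    pdb = bst_pdb.PDBFile.read(str(path))
    structure = pdb.get_structure(model=1)
    return structure


def profile_interactions(
    receptor: bst.AtomArray,
    pose: Pose,
    hydrophobic_cut: float = HYDROPHOBIC_CUT,
    hbond_cut: float = HBOND_CUT,
    pi_cation_cut: float = PI_CATION_CUT,
) -> list[InteractionRecord]:
    """Residue-level interaction fingerprint of a pose.

    * hydrophobic: any ligand carbon within ``hydrophobic_cut`` of a
      residue carbon;
    * hbond: any ligand N/O within ``hbond_cut`` of a residue N/O,
      classed by :func:`classify_hbond`;
    * pi_cation: a positively charged ligand nitrogen (``formal_charges``
      must mark it) within ``pi_cation_cut`` of an aromatic side-chain
      ring centroid.

    One record per (residue, type), reporting the minimal distance.
    """
    if receptor.array_length() == 0:
        raise ValueError("empty receptor structure")
    if (getattr(receptor, "res_name", None) is None
            or len(set(receptor.res_name)) == 0):
        raise ValueError("receptor lacks residue annotations")
    rec_xyz = receptor.coord
    rec_el = np.char.upper(receptor.element.astype(str))
    lig_el = np.char.upper(np.asarray(pose.elements, dtype=str))
    d = np.linalg.norm(pose.coords[:, None, :] - rec_xyz[None, :, :], axis=2)

    records: dict[tuple[str, str], float] = {}

    def note(label: str, kind: str, dist: float) -> None:
        key = (label, kind)
        if key not in records or dist < records[key]:
            records[key] = dist

    labels = np.array([
        _residue_label(rn, ri, ch)
        for rn, ri, ch in zip(receptor.res_name, receptor.res_id,
                              receptor.chain_id)
    ])

    lig_c = lig_el == "C"
    rec_c = rec_el == "C"
    if lig_c.any() and rec_c.any():
        sub = d[np.ix_(lig_c, rec_c)]
        close = sub <= hydrophobic_cut
        for j in np.nonzero(close.any(axis=0))[0]:
            label = labels[rec_c][j]
            note(label, "hydrophobic", float(sub[:, j].min()))

    lig_polar = np.isin(lig_el, ("N", "O"))
    rec_polar = np.isin(rec_el, ("N", "O"))
    if lig_polar.any() and rec_polar.any():
        sub = d[np.ix_(lig_polar, rec_polar)]
        close = sub <= hbond_cut
        for j in np.nonzero(close.any(axis=0))[0]:
            label = labels[rec_polar][j]
            note(label, "hbond", float(sub[:, j].min()))

    if pose.formal_charges is not None:
        cations = [
            i for i, (el, q) in enumerate(zip(lig_el, pose.formal_charges))
            if el == "N" and q > 0
        ]
        if cations:
            for res_name, rings in _AROMATIC_RINGS.items():
                mask = receptor.res_name == res_name
                for res_id in np.unique(receptor.res_id[mask]):
                    rmask = mask & (receptor.res_id == res_id)
                    chain = receptor.chain_id[rmask][0]
                    atom_names = receptor.atom_name[rmask]
                    for ring in rings:
                        sel = np.isin(atom_names, ring)
                        if sel.sum() < len(ring):
                            continue
                        centroid = rec_xyz[rmask][sel].mean(axis=0)
                        for i in cations:
                            dist = float(np.linalg.norm(
                                pose.coords[i] - centroid))
                            if dist <= pi_cation_cut:
                                note(_residue_label(res_name, int(res_id),
                                                    str(chain)),
                                     "pi_cation", dist)

    out = []
    for (label, kind), dist in sorted(records.items()):
        strength = classify_hbond(dist) if kind == "hbond" else "n/a"
        out.append(InteractionRecord(residue=label, kind=kind,
                                     distance=dist, strength=strength))
    return out


def gridbox_contains(box: GridBox, pose: Pose) -> float:
    """Fraction of ligand atoms inside the half-open box
    [center - dim/2, center + dim/2)."""
    center = np.asarray(box.center)
    half = np.asarray(box.dimensions) / 2.0
    lo, hi = center - half, center + half
    inside = ((pose.coords >= lo) & (pose.coords < hi)).all(axis=1)
    return float(inside.mean())


# ---------------------------------------------------------------------------
# Pose input
# ---------------------------------------------------------------------------

_VINA_RE = re.compile(r"REMARK VINA RESULT:\s+(-?\d+\.?\d*)")


def read_pdbqt_poses(path: str | Path) -> list[Pose]:
    """Parse docked poses from a Vina-style multi-model PDBQT file.

    Affinities come from ``REMARK VINA RESULT`` lines; elements from the
    PDBQT atom-type column (AutoDock types reduced to elements).
    """
    poses: list[Pose] = []
    coords: list[list[float]] = []
    elements: list[str] = []
    energy: float | None = None
    model = 0

    def flush() -> None:
        nonlocal coords, elements, energy
        if coords:
            if energy is None:
                raise ValueError(
                    f"pose {len(poses)} in {path} has no REMARK VINA RESULT")
            poses.append(Pose(
                coords=np.array(coords), elements=tuple(elements),
                energy=energy, run_index=0, pose_index=len(poses),
            ))
        coords, elements, energy = [], [], None

    for line in Path(path).read_text().splitlines():
        if line.startswith("MODEL"):
            flush()
            model += 1
        elif m := _VINA_RE.match(line):
            energy = float(m.group(1))
        elif line.startswith(("ATOM", "HETATM")):
            coords.append([float(line[30:38]), float(line[38:46]),
                           float(line[46:54])])
            adtype = line[77:79].strip() or line[12:16].strip()[:1]
            el = adtype.rstrip("AaDdHh") or adtype  # OA->O, NA->N, HD->H
            elements.append(el[:2].capitalize() if len(el) > 1 else el.upper())
    flush()
    if not poses:
        raise ValueError(f"no poses found in {path}")
    return poses
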