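"""Seeded generators for every input the triage pipeline consumes.

Each generator is deterministic under a fixed seed and returns its
ground truth alongside the data (and writes it to a sidecar JSON when
asked), so recovery tests never re-derive the truth from the data.

What is emulated, at desk scale:

* GTT tables: a glucose-overload excursion (piecewise-linear rise to a
  15-min peak, then decay) per group of 7 animals, with treatment
  groups scaling group-mean glycemia down by per-timepoint reduction
  factors and multiplicative lognormal animal noise (glycemia is
  positive by construction);
* ITT tables: exponential glucose disappearance at a known Kitt
  (glycemia = G0 * exp(-(Kitt/100) * t)) with lognormal noise;
* descriptor/PK/toxicity panels: uniform draws within configured
  ranges, an optional planted all-attributes-inside row that must score
  the maximum desirability, and toxicity endpoints with a planted
  correlation between chosen pairs (Gaussian copula);
* toy receptor-ligand complexes: minimal residues placed so that each
  requested interaction (hydrophobic, H-bond, pi-cation) sits at its
  requested distance from the matching ligand atom.

The GTT curve shape exercises the AUC/percent-reduction code; it is not
a physiological model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure as bst
import biotite.structure.io.pdb as bst_pdb

from .docking_eval import Pose

__all__ = [
    "SimSpec",
    "Contact",
    "gen_gtt",
    "gen_itt",
    "gen_descriptor_table",
    "gen_toy_complex",
    "write_bundle",
]

GTT_TIMES = (0.0, 15.0, 30.0, 60.0, 120.0, 180.0)
ITT_TIMES = (0.0, 7.0, 14.0, 28.0)


@dataclass(frozen=True)
class SimSpec:
    """Shared simulation parameters. ``sigma`` is the multiplicative
    (lognormal) noise scale; 7 animals per group by default."""

    seed: int = 0
    n_per_group: int = 7
    sigma: float = 0.02

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_per_group < 1:
            raise ValueError("need at least one animal per group")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _lognoise(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    if sigma == 0:
        return np.ones(size)
    return np.exp(rng.normal(0.0, sigma, size=size))


# ---------------------------------------------------------------------------
# GTT
# ---------------------------------------------------------------------------

def _control_template(baseline: float, peak: float) -> dict[float, float]:
    """Rise to the 15-min peak, then exponential-ish decay to baseline."""
    decay = {30.0: 0.85, 60.0: 0.70, 120.0: 0.45, 180.0: 0.18}
    curve = {0.0: baseline, 15.0: peak}
    for t, f in decay.items():
        curve[t] = baseline + f * (peak - baseline)
    return curve


def gen_gtt(
    spec: SimSpec,
    reductions: Mapping[str, Mapping[float, float] | float] | None = None,
    baseline: float = 100.0,
    peak: float = 380.0,
    control_group: str = "hyperglycemic",
) -> tuple[pd.DataFrame, dict]:
    """Simulate a glucose tolerance test.

    ``reductions`` maps each treatment-group label to a reduction factor
    in [0, 1) applied to the control group-mean glycemia at every
    post-overload timepoint (scalar), or to a per-timepoint mapping.
    Time 0 is never reduced. Returns the tidy table and a ground-truth
    dict (template means and reduction factors).
    """
    reductions = dict(reductions or {})
    template = _control_template(baseline, peak)
    group_means: dict[str, dict[float, float]] = {control_group: dict(template)}
    for label, red in reductions.items():
        means = {}
        for t, mean in template.items():
            r = 0.0 if t == 0 else (
                red if isinstance(red, (int, float)) else red.get(t, 0.0))
            if not 0 <= r < 1:
                raise ValueError(f"reduction factor must be in [0, 1), got {r}")
            means[t] = mean * (1.0 - r)
        group_means[label] = means

    rng = spec.rng(stream=1)
    rows = []
    for label, means in group_means.items():
        for i in range(spec.n_per_group):
            animal = f"{label}-{i + 1:02d}"
            noise = _lognoise(rng, spec.sigma, len(means))
            for (t, mean), eps in zip(sorted(means.items()), noise):
                rows.append({
                    "animal": animal, "group": label, "time_min": t,
                    "glycemia_mg_dl": mean * eps,
                })
    truth = {
        "control_group": control_group,
        "group_means": {g: {str(t): v for t, v in m.items()}
                        for g, m in group_means.items()},
        "reductions": {
            g: (r if isinstance(r, (int, float))
                else {str(t): v for t, v in r.items()})
            for g, r in reductions.items()
        },
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# ITT
# ---------------------------------------------------------------------------

def gen_itt(
    spec: SimSpec,
    kitt_true: Mapping[str, float] | float = 2.31,
    g0: float = 150.0,
    times: Sequence[float] = ITT_TIMES,
) -> tuple[pd.DataFrame, dict]:
    """Simulate an insulin tolerance test at known Kitt (%/min) per group.

    The decay is defined through the half-life the Kitt formula implies,
    t_half = 0.693 * 100 / Kitt, as glycemia(t) = G0 * 2^(-t / t_half),
    so a noise-free analysis recovers the planted Kitt exactly. Kitt 0
    produces a flat series (the analyzer must flag it invalid).
    """
    groups = kitt_true if isinstance(kitt_true, Mapping) else {"treated": kitt_true}
    if any(k < 0 for k in groups.values()):
        raise ValueError("true Kitt must be non-negative")
    rng = spec.rng(stream=2)
    t = np.asarray(times, dtype=float)
    rows = []
    for label, k in groups.items():
        decay = np.ones_like(t) if k == 0 else \
            np.exp2(-t * k / (0.693 * 100.0))
        for i in range(spec.n_per_group):
            animal = f"{label}-{i + 1:02d}"
            g = g0 * decay * _lognoise(rng, spec.sigma, t.size)
            for tj, gj in zip(t, g):
                rows.append({"animal": animal, "group": label,
                             "time_min": tj, "glycemia_mg_dl": gj})
    truth = {"kitt_true": dict(groups), "g0": g0, "times": list(map(float, t))}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Descriptor / PK / toxicity panels
# ---------------------------------------------------------------------------

DESCRIPTOR_RANGES = {
    "mw": (250.0, 520.0), "tpsa": (30.0, 130.0), "hbd": (0, 4),
    "logp": (0.5, 5.5), "logd74": (0.0, 4.5), "pka_basic": (5.0, 10.5),
}
TOX_ENDPOINTS = ("dili", "ames", "roa", "fdamdd", "h_ht", "neurotoxicity")


def gen_descriptor_table(
    spec: SimSpec,
    n_compounds: int = 20,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    plant_perfect: bool = True,
    tox_rho: float = 0.0,
    tox_rho_pair: tuple[str, str] = ("dili", "h_ht"),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Random descriptor, PK and toxicity panels with planted structure.

    Returns (descriptors, pk, tox, truth). ``plant_perfect`` adds one
    compound whose six attributes sit strictly inside every
    full-desirability threshold (its id is recorded in the truth).
    ``tox_rho`` plants a correlation between one endpoint pair via a
    Gaussian copula; the remaining endpoints are independent.
    """
    ranges = {**DESCRIPTOR_RANGES, **(ranges or {})}
    for k, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValueError(f"range for {k} is reversed: {(lo, hi)}")
    if not -1.0 <= tox_rho <= 1.0:
        raise ValueError("tox_rho must be in [-1, 1]")
    rng = spec.rng(stream=3)
    ids = [f"cmpd-{i + 1:03d}" for i in range(n_compounds)]
    desc = pd.DataFrame({"compound_id": ids})
    for k, (lo, hi) in ranges.items():
        draw = rng.uniform(lo, hi, n_compounds)
        desc[k] = np.round(draw) if k == "hbd" else np.round(draw, 2)
    perfect_id = None
    if plant_perfect:
        perfect_id = "cmpd-perfect"
        desc = pd.concat([desc, pd.DataFrame([{
            "compound_id": perfect_id, "mw": 330.0, "tpsa": 65.0, "hbd": 1,
            "logp": 2.2, "logd74": 1.5, "pka_basic": 7.0,
        }])], ignore_index=True)
    desc["dg_hyd"] = np.nan

    all_ids = desc["compound_id"].tolist()
    n = len(all_ids)
    pk = pd.DataFrame({
        "compound_id": all_ids,
        "papp_caco2": 10 ** rng.uniform(-6.5, -4.5, n),
        "papp_mdck": 10 ** rng.uniform(-6.0, -4.0, n),
        "vdss": np.round(rng.uniform(0.5, 8.0, n), 2),
        "oral_f": np.round(rng.uniform(0.3, 1.0, n), 2),
        "cl_hepa_human": np.round(rng.uniform(2.0, 150.0, n), 1),
        "cl_micro": np.round(rng.uniform(1.0, 20.0, n), 1),
    })

    z = rng.standard_normal((n, len(TOX_ENDPOINTS)))
    cols = {e: i for i, e in enumerate(TOX_ENDPOINTS)}
    i, j = cols[tox_rho_pair[0]], cols[tox_rho_pair[1]]
    z[:, j] = tox_rho * z[:, i] + np.sqrt(1 - tox_rho**2) * z[:, j]
    from scipy.stats import norm
    probs = norm.cdf(z)
    tox = pd.DataFrame(probs, columns=list(TOX_ENDPOINTS))
    tox.insert(0, "compound_id", all_ids)

    truth = {
        "perfect_id": perfect_id,
        "tox_rho": tox_rho,
        "tox_rho_pair": list(tox_rho_pair),
        "ranges": {k: list(v) for k, v in ranges.items()},
    }
    return desc, pk, tox, truth


# ---------------------------------------------------------------------------
# Toy receptor-ligand complex
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contact:
    """A planted interaction: residue of ``res_name`` placed so its key
    atom (or ring centroid for pi_cation) sits ``distance`` A from the
    matching ligand atom."""

    kind: str           # hydrophobic | hbond | pi_cation
    res_name: str       # PHE/TRP/TYR for rings; any for hbond partners
    distance: float

    def __post_init__(self) -> None:
        if self.kind not in ("hydrophobic", "hbond", "pi_cation"):
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if not self.distance > 0:
            raise ValueError("contact distance must be positive")


# Ligand probe atoms: a carbon for hydrophobic contacts, a donor/acceptor
# nitrogen, and a protonatable (cationic) nitrogen, spaced far apart.
_LIG_ATOMS = (
    ("C", np.array([0.0, 0.0, 0.0]), 0),
    ("N", np.array([0.0, 0.0, 30.0]), 0),
    ("N", np.array([0.0, 0.0, 60.0]), 1),
)
_PROBE_INDEX = {"hydrophobic": 0, "hbond": 1, "pi_cation": 2}


def _hexagon(center: np.ndarray, radius: float = 1.39) -> np.ndarray:
    ang = np.arange(6) * np.pi / 3.0
    ring = np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.zeros(6)])
    return center + ring


def gen_toy_complex(
    spec: SimSpec,
    contacts: Sequence[Contact],
    energy: float = -7.5,
) -> tuple[bst.AtomArray, Pose, dict]:
    """Build a minimal receptor + pose realizing the requested contacts.

    Each contact claims its own residue, offset along +x from its probe
    ligand atom and spaced 25 A apart in y so contacts cannot cross-talk.
    A pi_cation contact requires an aromatic residue (PHE/TYR/TRP).
    Returns (receptor, pose, truth).
    """
    # benzene-ring atom names matching the profiler's ring definitions
    ring_names_by_res = {
        "PHE": ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
        "TYR": ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
        "TRP": ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    }
    atoms: list[bst.Atom] = []
    truth_contacts = []
    for idx, c in enumerate(contacts):
        _, probe_xyz, _ = _LIG_ATOMS[_PROBE_INDEX[c.kind]]
        # each contact gets its own azimuth around its probe atom
        angle = idx * 2.0 * np.pi / 9.0
        direction = np.array([np.cos(angle), np.sin(angle), 0.0])
        res_id = idx + 1
        if c.kind == "pi_cation":
            if c.res_name not in ("PHE", "TYR", "TRP"):
                raise ValueError(
                    f"pi_cation contact needs an aromatic residue, got {c.res_name}"
                )
            centroid = probe_xyz + c.distance * direction
            for name, xyz in zip(ring_names_by_res[c.res_name],
                                 _hexagon(centroid)):
                atoms.append(bst.Atom(
                    xyz, chain_id="A", res_id=res_id, res_name=c.res_name,
                    atom_name=name, element="C", hetero=False,
                ))
        else:
            key_el = "C" if c.kind == "hydrophobic" else "O"
            key_name = "CD1" if c.kind == "hydrophobic" else "OD1"
            key_xyz = probe_xyz + c.distance * direction
            atoms.append(bst.Atom(
                key_xyz, chain_id="A", res_id=res_id, res_name=c.res_name,
                atom_name=key_name, element=key_el, hetero=False,
            ))
            # a backbone carbon well away from every cutoff
            atoms.append(bst.Atom(
                key_xyz + 8.0 * direction, chain_id="A",
                res_id=res_id, res_name=c.res_name, atom_name="CA",
                element="C", hetero=False,
            ))
        truth_contacts.append({
            "residue": f"{c.res_name}{res_id}.A", "kind": c.kind,
            "distance": c.distance,
        })
    if atoms:
        receptor = bst.array(atoms)
        # residues planted for different contacts must not collide
        for i, j in ((i, j) for i in range(len(atoms))
                     for j in range(i + 1, len(atoms))):
            if (atoms[i].res_id != atoms[j].res_id
                    and np.linalg.norm(atoms[i].coord - atoms[j].coord) < 2.0):
                raise ValueError(
                    "conflicting geometry: planted residues "
                    f"{atoms[i].res_name}{atoms[i].res_id} and "
                    f"{atoms[j].res_name}{atoms[j].res_id} collide"
                )
    else:
        receptor = bst.AtomArray(0)
    pose = Pose(
        coords=np.array([xyz for _, xyz, _ in _LIG_ATOMS]),
        elements=tuple(el for el, _, _ in _LIG_ATOMS),
        energy=energy,
        formal_charges=tuple(q for _, _, q in _LIG_ATOMS),
    )
    truth = {"contacts": truth_contacts, "energy": energy}
    return receptor, pose, truth


def write_toy_complex(
    receptor: bst.AtomArray, pose: Pose, out_dir: str | Path
) -> dict[str, Path]:
    """Write the receptor as PDB and the pose as an SD file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_path = out_dir / "receptor.pdb"
    pdb = bst_pdb.PDBFile()
    pdb.set_structure(receptor)
    pdb.write(str(pdb_path))
    sdf_path = out_dir / "pose.sdf"
    lines = ["ligand", "  glucotriage", "",
             f"{pose.n_atoms:3d}  0  0  0  0  0  0  0  0  0999 V2000"]
    for (x, y, z), el in zip(pose.coords, pose.elements):
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {el:<3s} 0  0  0  0  0")
    lines += ["M  END", "> <E_A>", f"{pose.energy}", "", "$$$$", ""]
    sdf_path.write_text("\n".join(lines))
    return {"receptor": pdb_path, "pose": sdf_path}


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

def write_bundle(
    spec: SimSpec,
    out_dir: str | Path,
    gtt_reductions: Mapping[str, float] | None = None,
    kitt_true: Mapping[str, float] | float = 2.31,
    n_compounds: int = 20,
    tox_rho: float = 0.8,
) -> dict[str, Path]:
    """Generate a full synthetic input bundle with sidecar ground truth.

    Writes GTT/ITT CSVs, descriptor/PK/toxicity CSVs, a toy complex and
    ``truth.json`` under ``out_dir``; byte-identical for identical specs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gtt_reductions = dict(
        gtt_reductions or {"treated": 0.4, "sitagliptin": 0.53})
    gtt, gtt_truth = gen_gtt(spec, reductions=gtt_reductions)
    itt, itt_truth = gen_itt(spec, kitt_true=kitt_true)
    desc, pk, tox, panel_truth = gen_descriptor_table(
        spec, n_compounds=n_compounds, tox_rho=tox_rho)
    # affinity energies: random for the panel, planted lowest for the
    # planted-perfect compound so the documented ranking must select it
    rng = spec.rng(stream=4)
    ids = desc["compound_id"].tolist()
    ea = pd.DataFrame({
        "compound_id": ids,
        "target": "toy_receptor",
        "ea_kcal_mol": np.round(rng.uniform(-9.5, -6.5, len(ids)), 3),
    })
    if panel_truth["perfect_id"] is not None:
        ea.loc[ea["compound_id"] == panel_truth["perfect_id"],
               "ea_kcal_mol"] = -11.0
        panel_truth["planted_best_ea"] = -11.0
    receptor, pose, complex_truth = gen_toy_complex(spec, contacts=[
        Contact("hydrophobic", "PHE", 3.6),
        Contact("hbond", "ASP", 2.73),
        Contact("pi_cation", "TRP", 4.0),
    ])
    paths = {
        "gtt": out_dir / "gtt.csv",
        "itt": out_dir / "itt.csv",
        "descriptors": out_dir / "descriptors.csv",
        "pk": out_dir / "pk.csv",
        "tox": out_dir / "tox.csv",
        "ea": out_dir / "ea.csv",
        "truth": out_dir / "truth.json",
    }
    float_fmt = "%.6f"
    gtt.to_csv(paths["gtt"], index=False, float_format=float_fmt)
    itt.to_csv(paths["itt"], index=False, float_format=float_fmt)
    desc.to_csv(paths["descriptors"], index=False, float_format=float_fmt)
    pk.to_csv(paths["pk"], index=False, float_format="%.8e")
    tox.to_csv(paths["tox"], index=False, float_format=float_fmt)
    ea.to_csv(paths["ea"], index=False, float_format=float_fmt)
    paths.update(write_toy_complex(receptor, pose, out_dir))
    truth = {
        "spec": {"seed": spec.seed, "n_per_group": spec.n_per_group,
                 "sigma": spec.sigma},
        "gtt": gtt_truth, "itt": itt_truth, "panel": panel_truth,
        "complex": complex_truth,
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths
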