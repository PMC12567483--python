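"""Structure I/O and structure-derived physicochemical quantities.

This module owns the chemistry end of the triage pipeline:

* parsing SMILES / SDF input into sanitized RDKit molecules,
* the six multiparameter-optimization attributes (MW, TPSA, HBD, logP,
  logD7.4, pKa) gathered into a :class:`DescriptorSet` with per-field
  provenance (``computed`` from structure vs ``supplied`` by an external
  predictor),
* the logP <-> hydration-free-energy relation
  ``logP = dG_hyd / (2.303 * R * T)``,
* a molecular lipophilicity potential (MLP) field: at each evaluation
  point *k*, ``MLP_k = sum_i f_i * F(d_ik)`` over atomic lipophilicity
  contributions ``f_i`` weighted by a distance function ``F``.

TPSA uses Ertl fragment contributions and logP the Crippen/Wildman
atomic-contribution scheme, both via RDKit; the same atomic Crippen
contributions serve as the default MLP fragment constants ``f_i``.
pKa and logD7.4 are never predicted here — they are ionization-aware
quantities that must be supplied from an external predictor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Crippen, Descriptors, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "StructureParseError",
    "Molecule",
    "DescriptorSet",
    "ThermoConfig",
    "MlpField",
    "parse_structure",
    "read_structures",
    "compute_descriptors",
    "logp_dghyd",
    "mlp_field",
    "embed_3d",
    "sas_dots",
    "read_descriptor_table",
    "write_descriptor_table",
    "DESCRIPTOR_COLUMNS",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.987e-3

#: Canonical descriptor-table column order (CSV dialect).
DESCRIPTOR_COLUMNS = [
    "compound_id", "mw", "tpsa", "hbd", "logp", "logd74", "pka_basic", "dg_hyd",
]

# A molecule is simply a sanitized RDKit Mol; the alias documents intent.
Molecule = Chem.Mol


class StructureParseError(ValueError):
    """Raised when a line notation or SDF record cannot be parsed."""


def _longest_valid_prefix(smiles: str) -> int:
    """Length of the longest parseable prefix, to localize a bad token."""
    best = 0
    for i in range(1, len(smiles) + 1):
        if Chem.MolFromSmiles(smiles[:i]) is not None:
            best = i
    return best


def parse_structure(text: str, name: str | None = None) -> Molecule:
    """Parse a SMILES string or a single SDF (molblock) record.

    Returns a sanitized molecule with perceived aromaticity. ``name``
    (or the molblock title) is preserved as the molecule's ``_Name``.

    Raises
    ------
    StructureParseError
        If the input is empty or unparsable; for SMILES the message
        points at the position after the longest valid prefix.
    """
    if not text or not text.strip():
        raise StructureParseError("empty structure input")
    if "\n" in text.strip() or "V2000" in text or "V3000" in text:
        mol = Chem.MolFromMolBlock(text, sanitize=True)
        if mol is None:
            raise StructureParseError("unparsable SDF/molblock record")
    else:
        smiles = text.strip()
        mol = Chem.MolFromSmiles(smiles, sanitize=True)
        if mol is None:
            pos = _longest_valid_prefix(smiles)
            raise StructureParseError(
                f"unparsable SMILES {smiles!r}: parse fails at position {pos} "
                f"(near {smiles[max(0, pos - 1):pos + 2]!r})"
            )
    if name is not None:
        mol.SetProp("_Name", name)
    return mol


def read_structures(path: str | Path) -> dict[str, Molecule]:
    """Read a ``.smi`` file (``SMILES[\\t id]`` per line) or an SDF file."""
    path = Path(path)
    out: dict[str, Molecule] = {}
    if path.suffix.lower() == ".sdf":
        for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
            if mol is None:
                raise StructureParseError(f"unparsable SDF record #{i} in {path}")
            out[mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"] = mol
        return out
    for i, line in enumerate(path.read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        smiles = parts[0]
        name = parts[1] if len(parts) > 1 else f"mol{i}"
        out[name] = parse_structure(smiles, name=name)
    return out


@dataclass
class DescriptorSet:
    """The six MPO attributes plus optional hydration free energy.

    ``provenance`` maps each populated field to ``"computed"`` (derived
    from the structure here) or ``"supplied"`` (external predictor
    output). Supplied values are never overwritten by computed ones.
    """

    compound_id: str
    mw: float | None = None            # g/mol
    tpsa: float | None = None          # A^2
    hbd: int | None = None             # donor-group count
    logp: float | None = None
    logd74: float | None = None
    pka_basic: float | None = None
    dg_hyd: float | None = None        # kcal/mol
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mw is not None and not self.mw > 0:
            raise ValueError(f"MW must be positive, got {self.mw}")
        if self.tpsa is not None and self.tpsa < 0:
            raise ValueError(f"TPSA must be non-negative, got {self.tpsa}")
        if self.hbd is not None and (self.hbd < 0 or int(self.hbd) != self.hbd):
            raise ValueError(f"HBD must be a non-negative integer, got {self.hbd}")

    def as_dict(self) -> dict[str, float | int | str | None]:
        return {c: getattr(self, c) for c in DESCRIPTOR_COLUMNS}


def compute_descriptors(
    mol: Molecule,
    supplied: Mapping[str, float] | None = None,
    compound_id: str | None = None,
) -> DescriptorSet:
    """Compute MW, TPSA (Ertl), HBD and Crippen logP from the structure.

    ``supplied`` may carry predictor outputs (``logd74``, ``pka_basic``,
    ``logp``, ``dg_hyd``); a supplied ``logp`` suppresses the computed
    one. Provenance is recorded per field.
    """
    supplied = dict(supplied or {})
    cid = compound_id or (mol.GetProp("_Name") if mol.HasProp("_Name") else "unnamed")
    values: dict[str, float | int] = {
        "mw": round(Descriptors.MolWt(mol), 2),
        "tpsa": round(rdMolDescriptors.CalcTPSA(mol), 2),
        "hbd": rdMolDescriptors.CalcNumHBD(mol),
    }
    provenance = {k: "computed" for k in values}
    if "logp" not in supplied or supplied["logp"] is None:
        values["logp"] = round(Crippen.MolLogP(mol), 2)
        provenance["logp"] = "computed"
    for key in ("logp", "logd74", "pka_basic", "dg_hyd"):
        val = supplied.get(key)
        if val is not None and not (isinstance(val, float) and math.isnan(val)):
            values[key] = float(val)
            provenance[key] = "supplied"
    return DescriptorSet(compound_id=cid, provenance=provenance, **values)


@dataclass(frozen=True)
class ThermoConfig:
    """Thermodynamic constants for the logP <-> dG_hyd relation.

    ``negate`` flips the sign convention: the literal relation yields a
    positive dG_hyd for a positive logP, whereas hydration free energies
    of soluble drug-like molecules are conventionally negative.
    """

    temperature: float = 298.15           # K
    gas_constant: float = GAS_CONSTANT_KCAL
    negate: bool = False

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")


def logp_dghyd(
    value: float,
    cfg: ThermoConfig = ThermoConfig(),
    direction: str = "to_dghyd",
) -> float:
    """Convert between logP and hydration free energy (kcal/mol).

    ``direction="to_dghyd"`` applies ``dG = 2.303 * R * T * logP``;
    ``"to_logp"`` applies the inverse. With ``cfg.negate`` the result
    (or input) carries the opposite sign.
    """
    if not math.isfinite(value):
        raise ValueError(f"input must be finite, got {value}")
    factor = 2.303 * cfg.gas_constant * cfg.temperature
    sign = -1.0 if cfg.negate else 1.0
    if direction == "to_dghyd":
        return sign * factor * value
    if direction == "to_logp":
        return sign * value / factor
    raise ValueError(f"direction must be 'to_dghyd' or 'to_logp', got {direction!r}")


# ---------------------------------------------------------------------------
# Molecular lipophilicity potential
# ---------------------------------------------------------------------------

#: Distance weighting functions F(d), d in Angstrom.
DISTANCE_FUNCTIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "exp": lambda d: np.exp(-d / 2.0),
    "inverse": lambda d: 1.0 / (1.0 + d),
}

# Bondi-ish van der Waals radii (A) for surface dot generation.
_VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}


@dataclass
class MlpField:
    """Lipophilicity potential sampled at a set of 3-D points."""

    points: np.ndarray          # (M, 3) A
    values: np.ndarray          # (M,)
    fragment_constants: np.ndarray   # f_i per heavy atom, (N,)
    distance_fn: str
    n_fragments: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.points[:, 0], "y": self.points[:, 1],
             "z": self.points[:, 2], "mlp": self.values}
        )


def embed_3d(mol: Molecule, seed: int = 2129) -> Molecule:
    """Deterministic 3-D embedding (ETKDG, fixed seed) with added H."""
    mol3d = Chem.AddHs(Chem.Mol(mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol3d, params) != 0:
        raise RuntimeError("3-D embedding failed")
    AllChem.MMFFOptimizeMolecule(mol3d)
    return Chem.RemoveHs(mol3d)


def _sphere_dots(n: int) -> np.ndarray:
    """n near-uniform unit-sphere directions (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sas_dots(mol: Molecule, probe: float = 1.4, dots_per_atom: int = 96) -> np.ndarray:
    """Dotted solvent-accessible surface of a 3-D molecule.

    Each heavy atom contributes up to ``dots_per_atom`` dots on a sphere
    of radius vdW + probe; dots buried inside a neighbouring atom's
    solvent-expanded sphere are removed. Deterministic.
    """
    conf = mol.GetConformer()
    coords = conf.GetPositions()
    radii = np.array(
        [_VDW_RADII.get(a.GetSymbol(), 1.7) + probe for a in mol.GetAtoms()]
    )
    unit = _sphere_dots(dots_per_atom)
    kept: list[np.ndarray] = []
    for i in range(len(coords)):
        dots = coords[i] + radii[i] * unit
        d = np.linalg.norm(dots[:, None, :] - coords[None, :, :], axis=2)
        d[:, i] = np.inf
        kept.append(dots[(d >= radii[None, :] - 1e-9).all(axis=1)])
    if not kept:
        raise ValueError("molecule has no atoms")
    return np.vstack(kept)


def mlp_field(
    mol: Molecule,
    points: np.ndarray | None = None,
    constants: Sequence[float] | Mapping[str, float] | None = None,
    distance_fn: str = "exp",
    probe: float = 1.4,
    dots_per_atom: int = 96,
) -> MlpField:
    """Evaluate the MLP field ``MLP_k = sum_i f_i * F(d_ik)``.

    Fragments are heavy atoms. ``constants`` may be an explicit per-atom
    sequence, a mapping from element symbol to a constant (missing
    elements raise), or ``None`` for Crippen atomic logP contributions.
    ``points`` defaults to a dotted solvent-accessible surface.
    """
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no 3-D coordinates; embed it first")
    coords = mol.GetConformer().GetPositions()
    if constants is None:
        f = np.array([c[0] for c in rdMolDescriptors._CalcCrippenContribs(mol)])
    elif isinstance(constants, Mapping):
        missing = sorted(
            {a.GetSymbol() for a in mol.GetAtoms()} - set(constants)
        )
        if missing:
            raise KeyError(
                f"no fragment lipophilicity constant for element(s): {missing}"
            )
        f = np.array([constants[a.GetSymbol()] for a in mol.GetAtoms()])
    else:
        f = np.asarray(constants, dtype=float)
        if f.shape[0] != mol.GetNumAtoms():
            raise ValueError(
                f"{f.shape[0]} constants for {mol.GetNumAtoms()} atoms"
            )
    try:
        F = DISTANCE_FUNCTIONS[distance_fn]
    except KeyError:
        raise ValueError(
            f"unknown distance function {distance_fn!r}; "
            f"choose from {sorted(DISTANCE_FUNCTIONS)}"
        ) from None
    if points is None:
        points = sas_dots(mol, probe=probe, dots_per_atom=dots_per_atom)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.linalg.norm(points[:, None, :] - coords[None, :, :], axis=2)
    values = (f[None, :] * F(d)).sum(axis=1)
    return MlpField(
        points=points, values=values, fragment_constants=f,
        distance_fn=distance_fn, n_fragments=len(f),
    )


# ---------------------------------------------------------------------------
# Descriptor-table I/O
# ---------------------------------------------------------------------------

def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    """Read the descriptor CSV dialect (``compound_id,mw,...,dg_hyd``)."""
    df = pd.read_csv(path)
    missing = set(DESCRIPTOR_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise ValueError(f"descriptor table missing column(s): {sorted(missing)}")
    return df


def write_descriptor_table(
    rows: Iterable[DescriptorSet], path: str | Path
) -> pd.DataFrame:
    df = pd.DataFrame([r.as_dict() for r in rows], columns=DESCRIPTOR_COLUMNS)
    df.to_csv(path, index=False)
    return df
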