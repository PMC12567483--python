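"""Packaged reference data for the DPP-4 inhibitor candidate series.

The five beta-amino-N-acylhydrazone analogs (LASSBio-2123/2124/2125/
2129/2130) and the sitagliptin comparator, with:

* structures reconstructed from the published IUPAC name of
  LASSBio-2129 and the series' benzylidene-ring substitution scheme;
* supplied predictor values (logD7.4, basic pKa) — the LASSBio-2129 pair
  (2.32, 6.46) is as reported, the remainder are synthetic
  reconstructions consistent with the reported narrative (analogs below
  logD 2.5 except the dichloro analog above 2.8; a shared amine
  scaffold, hence similar pKa);
* a synthetic reconstruction of the glucose-tolerance-test group-mean
  table, built so group arithmetic reproduces the reported percent
  reductions and AUC reductions exactly (see docs/methods.md);
* docking affinity energies: reported values for LASSBio-2129 and the
  two co-crystallized inhibitors (LIT, 1JD); synthetic placeholders
  (below -8 kcal/mol, as reported for the series) for the rest.

Files carrying any reconstructed value are suffixed ``_synthetic``.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from . import chemstruct
from .chemstruct import DescriptorSet, Molecule

__all__ = [
    "reference_compounds",
    "supplied_values",
    "reference_descriptors",
    "gtt_group_means",
    "affinity_energies",
    "data_path",
]

#: Group label of the untreated (vehicle + glucose overload) animals.
GTT_CONTROL_GROUP = "hyperglycemic"


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("glucotriage.data") / name)


def reference_compounds() -> dict[str, Molecule]:
    """The six reference structures, keyed by compound id."""
    return chemstruct.read_structures(data_path("compounds.smi"))


def supplied_values() -> pd.DataFrame:
    """Predictor-supplied logD7.4 and basic pKa, indexed by compound."""
    return pd.read_csv(
        data_path("supplied_descriptors_synthetic.csv")
    ).set_index("compound_id")


def reference_descriptors() -> dict[str, DescriptorSet]:
    """Full descriptor sets: MW/TPSA/HBD/logP computed from structure,
    logD7.4 and pKa joined from the supplied table."""
    supplied = supplied_values()
    out = {}
    for cid, mol in reference_compounds().items():
        out[cid] = chemstruct.compute_descriptors(
            mol, supplied=supplied.loc[cid].to_dict(), compound_id=cid)
    return out


def gtt_group_means() -> pd.DataFrame:
    """Reconstructed GTT group-mean glycemia table (tidy dialect with a
    synthetic one-record-per-group ``animal`` column)."""
    df = pd.read_csv(data_path("gtt_group_means_synthetic.csv"))
    df.insert(0, "animal", df["group"] + "-mean")
    return df


def affinity_energies() -> pd.DataFrame:
    """Docking affinity energies (kcal/mol) per compound and target."""
    return pd.read_csv(data_path("affinity_energies_synthetic.csv"))
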