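"""Rule-based ADMET triage and lead ranking.

Pure-function rules that map predictor outputs (membrane permeability,
clearances, oral bioavailability, toxicity-endpoint probabilities) to
named flags, plus the Pearson similarity matrix over toxicity endpoints
and the final desirability-then-affinity lead ranking.

Thresholds (strict as printed unless noted):

* permeability: high iff Papp(A->B) > 20e-6 cm/s (then HIA ~ 96%),
  low iff < 1e-6 cm/s, moderate between;
* hepatocyte clearance: stable iff Cl_Hepa < 100 uL/min/1e6 cells,
  enhanced stability iff < 20; microsomal: stable iff Cl_Micro < 8.0
  uL/min/mg;
* oral-bioavailability risk iff logD7.4 > 2.8 and MW > 450 g/mol;
  high oral bioavailability iff %F >= 0.9 (inclusive);
* FDA maximum-daily-dose exceeded iff the dose bound < 0.011
  mmol/kg-bw/day.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemstruct import DescriptorSet
from .mpo import MpoResult

__all__ = [
    "PkProfile",
    "TriageReport",
    "PERMEABILITY_HIGH_CUT",
    "PERMEABILITY_LOW_CUT",
    "classify_permeability",
    "stability_flags",
    "bioavailability_and_risk",
    "tox_similarity",
    "rank_leads",
    "triage_report",
]

PERMEABILITY_HIGH_CUT = 20e-6   # cm/s
PERMEABILITY_LOW_CUT = 1e-6     # cm/s
HIA_HIGH = 0.96
CL_HEPA_STABLE = 100.0          # uL/min/1e6 cells
CL_HEPA_ENHANCED = 20.0
CL_MICRO_STABLE = 8.0           # uL/min/mg
ORAL_RISK_LOGD = 2.8
ORAL_RISK_MW = 450.0            # g/mol
HIGH_F_CUT = 0.9                # fraction, inclusive
FDAMDD_CUT = 0.011              # mmol/kg-bw/day


@dataclass
class PkProfile:
    """Pharmacokinetic predictor outputs for one compound. Units as in
    the module docstring; any field may be absent (None)."""

    compound_id: str
    papp_caco2: float | None = None     # cm/s
    papp_mdck: float | None = None      # cm/s
    vdss: float | None = None           # L/kg
    oral_f: float | None = None         # fraction in [0, 1]
    cl_hepa_human: float | None = None  # uL/min/1e6 cells
    cl_hepa_rat: float | None = None
    cl_micro: float | None = None       # uL/min/mg
    cl_int_u: float | None = None       # mL/min/kg

    def __post_init__(self) -> None:
        for name in ("papp_caco2", "papp_mdck"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.oral_f is not None and not 0.0 <= self.oral_f <= 1.0:
            raise ValueError(f"oral_f must be in [0, 1], got {self.oral_f}")


def classify_permeability(papp: float, line: str = "Caco-2") -> dict:
    """Classify an apical-to-basolateral permeability value.

    Returns class (low/moderate/high), the order-of-magnitude band of
    Papp, log10(Papp), and — for the high class only — the ~96% human
    intestinal absorption estimate associated with it.
    """
    if not papp > 0:
        raise ValueError(f"Papp must be positive, got {papp}")
    if line not in ("Caco-2", "MDCK"):
        raise ValueError(f"unknown cell line {line!r}")
    log_papp = math.log10(papp)
    if papp > PERMEABILITY_HIGH_CUT:
        cls = "high"
    elif papp < PERMEABILITY_LOW_CUT:
        cls = "low"
    else:
        cls = "moderate"
    return {
        "line": line,
        "class": cls,
        "log_papp": log_papp,
        "band": f"1e{math.floor(log_papp):d}",
        "hia": HIA_HIGH if cls == "high" else None,
        "rule": "papp_gt_20e-6_high",
    }


def stability_flags(profile: PkProfile) -> dict:
    """Metabolic-stability flags; absent inputs yield None (undetermined).

    Hepatocyte flags use the human value, falling back to rat.
    """
    cl_hepa = (profile.cl_hepa_human if profile.cl_hepa_human is not None
               else profile.cl_hepa_rat)
    out = {
        "hepatocyte_stable": None,
        "hepatocyte_enhanced_stability": None,
        "microsomal_stable": None,
        "rule": "cl_hepa_lt_100_stable; cl_hepa_lt_20_enhanced; cl_micro_lt_8_stable",
    }
    if cl_hepa is not None:
        out["hepatocyte_stable"] = bool(cl_hepa < CL_HEPA_STABLE)
        out["hepatocyte_enhanced_stability"] = bool(cl_hepa < CL_HEPA_ENHANCED)
    if profile.cl_micro is not None:
        out["microsomal_stable"] = bool(profile.cl_micro < CL_MICRO_STABLE)
    return out


def bioavailability_and_risk(
    descr: DescriptorSet | Mapping[str, float],
    profile: PkProfile | None = None,
    fdamdd_dose: float | None = None,
) -> dict:
    """Oral-bioavailability flags from lipophilicity, size, %F and the
    FDA maximum-daily-dose bound (mmol/kg-bw/day)."""
    get = (lambda k: getattr(descr, k)) if isinstance(descr, DescriptorSet) \
        else (lambda k: descr.get(k))
    logd, mw = get("logd74"), get("mw")
    if logd is None or mw is None:
        raise ValueError("logd74 and mw are required for the oral-risk rule")
    out = {
        "oral_risk": bool(logd > ORAL_RISK_LOGD and mw > ORAL_RISK_MW),
        "high_oral_bioavailability": None,
        "fdamdd_exceeded": None,
        "rule": "logd_gt_2.8_and_mw_gt_450_risk; f_ge_0.9_high; fdamdd_lt_0.011_exceeded",
    }
    if profile is not None and profile.oral_f is not None:
        out["high_oral_bioavailability"] = bool(profile.oral_f >= HIGH_F_CUT)
    if fdamdd_dose is not None:
        out["fdamdd_exceeded"] = bool(fdamdd_dose < FDAMDD_CUT)
    return out


def tox_similarity(
    profiles: pd.DataFrame, orientation: str = "endpoints"
) -> pd.DataFrame:
    """Pearson similarity matrix over toxicity-endpoint probabilities.

    ``profiles`` is compounds x endpoints with probabilities in [0, 1].
    With ``orientation="endpoints"`` (default) correlations are between
    endpoint columns across compounds; ``"compounds"`` transposes first.
    Zero-variance rows/columns yield NaN entries (off-diagonal) with a
    warning rather than a silent 0.
    """
    if orientation == "compounds":
        profiles = profiles.T
    elif orientation != "endpoints":
        raise ValueError(f"unknown orientation {orientation!r}")
    X = profiles.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 observations (rows) for correlations")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 endpoints (columns)")
    if np.nanmin(X) < 0 or np.nanmax(X) > 1:
        raise ValueError("endpoint probabilities must lie in [0, 1]")
    constant = X.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            "constant endpoint column(s) "
            f"{list(profiles.columns[constant])}: correlation undefined (NaN)",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=profiles.columns, columns=profiles.columns)


def rank_leads(
    mpo: Mapping[str, MpoResult | float],
    ea: Mapping[str, float | Sequence[float]],
) -> list[str]:
    """Rank compounds: higher MPO score first, then lower mean affinity
    energy (kcal/mol), deterministic tie-break by compound id.

    ``mpo`` maps compound id to an :class:`MpoResult` or a bare score;
    ``ea`` maps compound id to one or more affinity energies.
    """
    missing = sorted(set(mpo) - set(ea)) + sorted(set(ea) - set(mpo))
    if missing:
        raise ValueError(f"compounds without both MPO and EA: {missing}")

    def key(cid: str):
        score = mpo[cid].score if isinstance(mpo[cid], MpoResult) else float(mpo[cid])
        energies = np.atleast_1d(np.asarray(ea[cid], dtype=float))
        return (-score, float(energies.mean()), cid)

    return sorted(mpo, key=key)


@dataclass
class TriageReport:
    """Per-compound flag table plus the composite ranking."""

    flags: pd.DataFrame
    ranking: list[str] = field(default_factory=list)

    @property
    def lead(self) -> str | None:
        return self.ranking[0] if self.ranking else None


def triage_report(
    descriptors: Mapping[str, DescriptorSet | Mapping[str, float]],
    profiles: Mapping[str, PkProfile],
    mpo: Mapping[str, MpoResult | float] | None = None,
    ea: Mapping[str, float | Sequence[float]] | None = None,
    fdamdd: Mapping[str, float] | None = None,
) -> TriageReport:
    """Assemble the full rule-based report for a compound panel."""
    rows = []
    for cid, descr in descriptors.items():
        prof = profiles.get(cid)
        row: dict = {"compound_id": cid}
        if prof is not None and prof.papp_caco2 is not None:
            perm = classify_permeability(prof.papp_caco2, "Caco-2")
            row["permeability_caco2"] = perm["class"]
        if prof is not None and prof.papp_mdck is not None:
            perm = classify_permeability(prof.papp_mdck, "MDCK")
            row["permeability_mdck"] = perm["class"]
            row["hia"] = perm["hia"]
        if prof is not None:
            row.update({k: v for k, v in stability_flags(prof).items()
                        if k != "rule"})
        row.update({k: v for k, v in bioavailability_and_risk(
            descr, prof, (fdamdd or {}).get(cid)).items() if k != "rule"})
        rows.append(row)
    flags = pd.DataFrame(rows).set_index("compound_id")
    ranking = rank_leads(mpo, ea) if mpo and ea else []
    return TriageReport(flags=flags, ranking=ranking)
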