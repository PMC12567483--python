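"""End-to-end orchestration: descriptors -> MPO -> triage -> docking
evaluation -> pharmacology, with a combined lead-nomination report.

A :class:`PipelineConfig` names the input files and toggles stages; the
runner executes enabled stages in order, writes per-stage CSV/JSON under
the output directory, and emits a summary that nominates a lead via the
documented desirability-then-affinity ranking rule. Re-running with the
same config and inputs reproduces identical report content.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import chemstruct, docking_eval, mpo, pharmacology, pk_triage

logger = logging.getLogger("glucotriage")

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]

STAGES = ("descriptors", "mpo", "triage", "dock_eval", "pharmacology")


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Stage toggles and input paths for one pipeline run."""

    out_dir: str = "glucotriage-out"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    structures: str | None = None       # .smi or .sdf
    descriptors: str | None = None      # descriptor CSV (supplied values)
    pk: str | None = None               # PK predictor CSV
    tox: str | None = None              # toxicity-endpoint CSV
    ea: str | None = None               # affinity energies CSV
    receptor: str | None = None         # receptor PDB
    poses: str | None = None            # PDBQT poses
    gtt: str | None = None              # tidy GTT CSV
    itt: str | None = None              # tidy ITT CSV
    qpcr: str | None = None
    mtt: str | None = None
    gtt_control: str = "hyperglycemic"
    mpo_config: str | None = None       # YAML; default: calibrated config
    auc_window: tuple[float, float] = (0.0, 120.0)
    auc_baseline_corrected: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "auc_window" in raw:
            raw["auc_window"] = tuple(raw["auc_window"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["auc_window"] = list(self.auc_window)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def _load_descriptor_rows(cfg: PipelineConfig) -> dict[str, chemstruct.DescriptorSet]:
    supplied: dict[str, dict] = {}
    if cfg.descriptors:
        table = chemstruct.read_descriptor_table(cfg.descriptors)
        supplied = table.set_index("compound_id").to_dict("index")
    rows: dict[str, chemstruct.DescriptorSet] = {}
    if cfg.structures:
        for cid, mol in chemstruct.read_structures(cfg.structures).items():
            rows[cid] = chemstruct.compute_descriptors(
                mol, supplied=supplied.get(cid, {}), compound_id=cid)
    else:
        for cid, vals in supplied.items():
            clean = {k: v for k, v in vals.items() if pd.notna(v)}
            rows[cid] = chemstruct.DescriptorSet(
                compound_id=cid,
                provenance={k: "supplied" for k in clean}, **clean)
    if not rows:
        raise ValueError("no structures or descriptor table configured")
    return rows


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order and write the report bundle.

    Returns the summary report dict (also written as ``report.json``).
    Raises :class:`StageError` naming the first failing stage; outputs
    of completed stages are retained.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    report: dict = {"stages": {}, "config": dataclasses.asdict(config)}
    report["config"]["auc_window"] = list(config.auc_window)

    descriptor_rows: dict[str, chemstruct.DescriptorSet] = {}
    mpo_results: dict[str, mpo.MpoResult] = {}

    def run_stage(name: str, fn) -> None:
        if name not in config.stages:
            return
        t0 = time.perf_counter()
        try:
            report["stages"][name] = fn() or {}
        except Exception as exc:  # noqa: BLE001 - report and re-raise with stage
            logger.error("stage %s failed: %s", name, exc)
            (out_dir / "report.json").write_text(
                json.dumps(report, indent=2, default=str))
            raise StageError(name, exc) from exc
        dt = time.perf_counter() - t0
        logger.info(json.dumps({"stage": name, "seconds": round(dt, 3)}))

    def stage_descriptors() -> dict:
        nonlocal descriptor_rows
        descriptor_rows = _load_descriptor_rows(config)
        df = chemstruct.write_descriptor_table(
            descriptor_rows.values(), out_dir / "descriptors.csv")
        return {"n_compounds": len(df)}

    def stage_mpo() -> dict:
        if not descriptor_rows:
            stage_descriptors()
        cfg = (mpo.MpoConfig.from_yaml(config.mpo_config)
               if config.mpo_config else mpo.CALIBRATED_CONFIG)
        rows = []
        for cid, descr in descriptor_rows.items():
            res = mpo.mpo_score(descr, cfg)
            mpo_results[cid] = res
            rows.append({
                "compound_id": cid, "D": res.score,
                "D_rounded": res.rounded_score,
                **{f"T_{a}": res.desirabilities[a] for a in mpo.ATTRIBUTES},
                "violations": ";".join(res.violations),
            })
        pd.DataFrame(rows).to_csv(out_dir / "mpo.csv", index=False)
        return {"scores": {r["compound_id"]: r["D_rounded"] for r in rows}}

    def stage_triage() -> dict:
        profiles: dict[str, pk_triage.PkProfile] = {}
        if config.pk:
            pk_df = pd.read_csv(config.pk)
            for _, row in pk_df.iterrows():
                vals = {k: v for k, v in row.items() if pd.notna(v)}
                profiles[str(row["compound_id"])] = pk_triage.PkProfile(**{
                    k: vals.get(k) for k in (
                        "compound_id", "papp_caco2", "papp_mdck", "vdss",
                        "oral_f", "cl_hepa_human", "cl_hepa_rat", "cl_micro",
                        "cl_int_u") if k in vals})
        ea_map: dict[str, list[float]] = {}
        if config.ea:
            ea_df = pd.read_csv(config.ea)
            for cid, grp in ea_df.groupby("compound_id"):
                ea_map[str(cid)] = grp["ea_kcal_mol"].tolist()
        mpo_map = {c: r for c, r in mpo_results.items() if c in ea_map} \
            if ea_map else {}
        rep = pk_triage.triage_report(
            descriptors=descriptor_rows, profiles=profiles,
            mpo=mpo_map or None, ea={c: ea_map[c] for c in mpo_map} or None)
        rep.flags.to_csv(out_dir / "triage.csv")
        out: dict = {"ranking": rep.ranking, "lead": rep.lead}
        if config.tox:
            tox_df = pd.read_csv(config.tox).set_index("compound_id")
            corr = pk_triage.tox_similarity(tox_df)
            corr.to_csv(out_dir / "tox_corr.csv")
            out["tox_endpoints"] = list(corr.columns)
        return out

    def stage_dock_eval() -> dict:
        if not config.receptor or not config.poses:
            return {"skipped": "no receptor/poses configured"}
        receptor = docking_eval.read_receptor(config.receptor)
        poses = docking_eval.read_pdbqt_poses(config.poses)
        result = docking_eval.select_best_pose(poses)
        out = {"n_poses": len(poses), "accepted": result.accepted,
               "best_energy": result.best.energy if result.best else None}
        if result.best is not None:
            records = docking_eval.profile_interactions(receptor, result.best)
            pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
                out_dir / "interactions.csv", index=False)
            out["n_interactions"] = len(records)
        return out

    def stage_pharmacology() -> dict:
        out: dict = {}
        if config.gtt:
            df = pharmacology.validate_gtt(pd.read_csv(config.gtt))
            control = config.gtt_control
            treated = sorted(set(df["group"]) - {control})
            out["gtt"] = {}
            for grp in treated:
                reductions = {
                    str(t): pharmacology.percent_reduction(df, grp, control, t)
                    for t in sorted(df["time_min"].unique()) if t > 0
                }
                out["gtt"][grp] = {
                    "percent_reduction": reductions,
                    "auc_reduction": pharmacology.auc_reduction(
                        df, grp, control,
                        baseline_corrected=config.auc_baseline_corrected,
                        window=config.auc_window),
                }
        if config.itt:
            df = pd.read_csv(config.itt)
            out["kitt"] = pharmacology.kitt_by_group(df)["kitt"].to_dict()
        if config.qpcr:
            df = pharmacology.ddct(pd.read_csv(config.qpcr), "control")
            out["qpcr_fold"] = df.groupby("group")["fold"].mean().to_dict()
        if config.mtt:
            df = pharmacology.viability(pd.read_csv(config.mtt), 0.0)
            out["viability_pct"] = df["viability_pct"].to_dict()
        if out:
            (out_dir / "pharmacology.json").write_text(
                json.dumps(out, indent=2, default=float))
        return out

    run_stage("descriptors", stage_descriptors)
    run_stage("mpo", stage_mpo)
    run_stage("triage", stage_triage)
    run_stage("dock_eval", stage_dock_eval)
    run_stage("pharmacology", stage_pharmacology)

    report["nominated_lead"] = report["stages"].get("triage", {}).get("lead")
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, default=str))
    logger.removeHandler(handler)
    return report
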