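"""In-vivo glucose-homeostasis statistics.

Operations on tidy measurement tables:

* glucose tolerance test (GTT): percent reduction of group-mean
  glycemia at a timepoint, and trapezoidal area under the glycemia-time
  curve over an explicit window (default 0-120 min), raw or
  baseline-corrected (time-0 glycemia subtracted from every point, so
  dips below baseline contribute negatively);
* insulin tolerance test (ITT): the glucose disappearance constant
  Kitt = 0.693 * 100 / t_half (%/min), with t_half = ln2/|slope| from an
  ordinary least-squares fit of ln(glycemia) on time;
* glycogen fold change (treated mean / control mean);
* relative qPCR quantification 2^-ddCt against a reference gene and a
  control group;
* MTT viability as percent of control absorbance.

Expected tidy CSV dialects: ``animal,group,time_min,glycemia_mg_dl``
(GTT/ITT), ``sample,group,ct_target,ct_ref`` (qPCR),
``well,condition_uM,abs570`` (MTT). Group-comparison statistics
(ANOVA/t-test, mean +/- SEM) are delegated to scipy as plumbing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KittResult",
    "percent_reduction",
    "gtt_auc",
    "group_auc",
    "auc_reduction",
    "kitt",
    "kitt_by_group",
    "fold_change",
    "ddct",
    "viability",
    "group_summary",
    "validate_gtt",
    "validate_itt",
]

LN2 = math.log(2.0)

GTT_COLUMNS = ("animal", "group", "time_min", "glycemia_mg_dl")


def validate_gtt(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a tidy GTT table: positive glycemia, non-negative times,
    a time-0 record per animal."""
    missing = set(GTT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"GTT table missing column(s): {sorted(missing)}")
    if not (df["glycemia_mg_dl"] > 0).all():
        raise ValueError("glycemia must be positive")
    if (df["time_min"] < 0).any():
        raise ValueError("times must be non-negative")
    no_t0 = [a for a, g in df.groupby("animal") if 0 not in g["time_min"].values]
    if no_t0:
        raise ValueError(f"animal(s) without a time-0 record: {no_t0}")
    return df


def validate_itt(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a tidy ITT table: >= 3 timepoints per animal."""
    missing = set(GTT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ITT table missing column(s): {sorted(missing)}")
    if not (df["glycemia_mg_dl"] > 0).all():
        raise ValueError("glycemia must be positive")
    short = [a for a, g in df.groupby("animal") if g["time_min"].nunique() < 3]
    if short:
        raise ValueError(f"animal(s) with fewer than 3 timepoints: {short}")
    return df


def percent_reduction(
    df: pd.DataFrame, treated: str, control: str, time: float
) -> float:
    """Percent reduction of treated group-mean glycemia vs control at a
    timepoint: ``100 * (mean_control - mean_treated) / mean_control``.
    Negative when the treated mean exceeds control.
    """
    out = {}
    for label in (control, treated):
        sel = df[(df["group"] == label) & (df["time_min"] == time)]
        if sel.empty:
            raise ValueError(f"group {label!r} has no measurement at t={time}")
        out[label] = sel["glycemia_mg_dl"].mean()
    return 100.0 * (out[control] - out[treated]) / out[control]


def gtt_auc(
    times: np.ndarray,
    glycemia: np.ndarray,
    baseline_corrected: bool = True,
    window: tuple[float, float] = (0.0, 120.0),
) -> float:
    """Trapezoidal AUC of one glycemia-time curve (mg.min/dL).

    Times must be strictly increasing. The integral runs over
    ``window``; an unsampled endpoint is linearly interpolated. With
    ``baseline_corrected`` the value at the first timepoint is
    subtracted from the whole curve first, and negative segments
    contribute negatively.
    """
    t = np.asarray(times, dtype=float)
    g = np.asarray(glycemia, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 timepoints")
    if not (np.diff(t) > 0).all():
        raise ValueError("times must be strictly increasing")
    lo, hi = window
    if not (t[0] <= lo < hi <= t[-1]):
        raise ValueError(f"window {window} outside sampled range [{t[0]}, {t[-1]}]")
    if baseline_corrected:
        g = g - g[0]
    grid = np.unique(np.concatenate([t[(t >= lo) & (t <= hi)], [lo, hi]]))
    vals = np.interp(grid, t, g)
    return float(np.trapezoid(vals, grid))


def group_auc(
    df: pd.DataFrame,
    group: str,
    baseline_corrected: bool = True,
    window: tuple[float, float] = (0.0, 120.0),
) -> float:
    """AUC of a group's mean glycemia curve."""
    sel = df[df["group"] == group]
    if sel.empty:
        raise ValueError(f"no data for group {group!r}")
    means = sel.groupby("time_min")["glycemia_mg_dl"].mean().sort_index()
    return gtt_auc(means.index.to_numpy(), means.to_numpy(),
                   baseline_corrected=baseline_corrected, window=window)


def auc_reduction(
    df: pd.DataFrame,
    treated: str,
    control: str,
    baseline_corrected: bool = True,
    window: tuple[float, float] = (0.0, 120.0),
) -> float:
    """Percent reduction of the treated group's AUC vs control."""
    a_c = group_auc(df, control, baseline_corrected, window)
    a_t = group_auc(df, treated, baseline_corrected, window)
    if a_c == 0:
        raise ValueError("control AUC is zero; reduction undefined")
    return 100.0 * (a_c - a_t) / a_c


@dataclass
class KittResult:
    """Glucose-disappearance fit for one decay series.

    ``kitt`` is in %/min and equals ``0.693 * 100 / t_half`` with
    ``t_half = ln2 / |slope|`` of the ln(glycemia)-vs-time regression.
    ``valid`` is False when the slope is non-negative (no measurable
    disappearance), in which case kitt/t_half are NaN, never negative.
    """

    slope: float        # min^-1
    t_half: float       # min
    kitt: float         # %/min
    r_squared: float
    valid: bool


def kitt(times: np.ndarray, glycemia: np.ndarray) -> KittResult:
    """Fit one animal's ITT decay: OLS of ln(glycemia) on time."""
    t = np.asarray(times, dtype=float)
    g = np.asarray(glycemia, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 timepoints")
    if not (g > 0).all():
        raise ValueError("glycemia must be positive")
    fit = stats.linregress(t, np.log(g))
    slope = float(fit.slope)
    r2 = float(fit.rvalue**2) if not math.isnan(fit.rvalue) else 0.0
    if slope >= 0:
        return KittResult(slope=slope, t_half=math.nan, kitt=math.nan,
                          r_squared=r2, valid=False)
    t_half = LN2 / abs(slope)
    return KittResult(slope=slope, t_half=t_half, kitt=0.693 * 100.0 / t_half,
                      r_squared=r2, valid=True)


def kitt_by_group(df: pd.DataFrame, pooled: bool = False) -> pd.DataFrame:
    """Kitt per group: per-animal fits averaged (default), or one pooled
    regression over all of a group's points (``pooled=True``).

    Returns a frame indexed by group with columns ``kitt`` (%/min,
    mean of valid per-animal values, or the pooled estimate), ``sem``,
    ``n_valid`` and ``n_animals``.
    """
    validate_itt(df)
    rows = []
    for label, g in df.groupby("group"):
        if pooled:
            res = kitt(g["time_min"].to_numpy(), g["glycemia_mg_dl"].to_numpy())
            rows.append({"group": label, "kitt": res.kitt, "sem": math.nan,
                         "n_valid": int(res.valid),
                         "n_animals": g["animal"].nunique()})
            continue
        per_animal = [
            kitt(a["time_min"].to_numpy(), a["glycemia_mg_dl"].to_numpy())
            for _, a in g.groupby("animal")
        ]
        vals = np.array([r.kitt for r in per_animal if r.valid])
        rows.append({
            "group": label,
            "kitt": float(vals.mean()) if vals.size else math.nan,
            "sem": float(stats.sem(vals)) if vals.size > 1 else math.nan,
            "n_valid": int(vals.size),
            "n_animals": len(per_animal),
        })
    return pd.DataFrame(rows).set_index("group")


def fold_change(treated: np.ndarray, control: np.ndarray) -> float:
    """Mean(treated) / mean(control); control mean must be positive."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValueError("empty measurement set")
    c = control.mean()
    if not c > 0:
        raise ValueError(f"control mean must be positive, got {c}")
    return float(treated.mean() / c)


def ddct(records: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Relative expression 2^-ddCt per sample.

    ``records`` columns: ``sample, group, ct_target, ct_ref``. dCt =
    Ct_target - Ct_ref; ddCt subtracts the control group's mean dCt;
    fold = 2^-ddCt. Adds per-sample ``dct``, ``ddct`` and ``fold``
    columns; the control group's folds center on 1.
    """
    required = {"sample", "group", "ct_target", "ct_ref"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"qPCR table missing column(s): {sorted(missing)}")
    cts = records[["ct_target", "ct_ref"]].to_numpy(dtype=float)
    if not ((cts > 0) & (cts < 45)).all():
        raise ValueError("Ct values must lie in (0, 45)")
    out = records.copy()
    out["dct"] = out["ct_target"] - out["ct_ref"]
    control = out[out["group"] == control_group]
    if control.empty:
        raise ValueError(f"empty control group {control_group!r}")
    out["ddct"] = out["dct"] - control["dct"].mean()
    out["fold"] = 2.0 ** (-out["ddct"])
    return out


def viability(records: pd.DataFrame, control_condition: object) -> pd.DataFrame:
    """Percent MTT viability per condition vs the control condition.

    ``records`` columns: ``well, condition_uM, abs570``. Returns per
    condition the mean absorbance, percent viability
    (``100 * mean / control mean``) and percent reduction.
    """
    required = {"well", "condition_uM", "abs570"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"MTT table missing column(s): {sorted(missing)}")
    if (records["abs570"] < 0).any():
        raise ValueError("absorbance must be non-negative")
    means = records.groupby("condition_uM")["abs570"].mean()
    if control_condition not in means.index:
        raise ValueError(f"no wells for control condition {control_condition!r}")
    ctrl = means[control_condition]
    if not ctrl > 0:
        raise ValueError("control absorbance is zero; viability undefined")
    out = means.to_frame("mean_abs570")
    out["viability_pct"] = 100.0 * means / ctrl
    out["reduction_pct"] = 100.0 - out["viability_pct"]
    return out


def group_summary(df: pd.DataFrame, value: str, by: str = "group") -> pd.DataFrame:
    """Mean +/- SEM and n per group (reporting convention)."""
    g = df.groupby(by)[value]
    return pd.DataFrame({
        "mean": g.mean(),
        "sem": g.apply(lambda x: stats.sem(x) if len(x) > 1 else math.nan),
        "n": g.size(),
    })
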