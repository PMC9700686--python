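"""Per-scenario feature aggregation, saliency and time-course analyses.

Turns filtered event tables into the participant x scenario feature
rows used by the group statistics and the classifiers, attributes
fixations to scene objects, computes the normalized scanpath saliency
(NSS) index against a saliency map, bins events into 1-s windows for
the ambient/focal time-course analysis, and summarises head motion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._geometry import quat_geodesic_deg
from .gaze_io import SaliencyMap
from .simulate import SceneSpec

__all__ = [
    "aggregate_scenario",
    "scenario_feature_table",
    "feature_matrix",
    "participant_weighted_means",
    "assign_objects",
    "relevance_stats",
    "nss",
    "bin_time_course",
    "head_motion_metrics",
]

#: The three event features aggregated per scenario.
EVENT_FEATURES = ["mean_fix_dur_ms", "mean_sacc_dur_ms", "mean_sacc_amp_deg"]


def aggregate_scenario(
    events: pd.DataFrame, samples: pd.DataFrame | None = None, phase: str = "execution"
) -> dict:
    """Aggregate one participant x scenario block of filtered events.

    Means are computed over the requested phase only (default execution,
    matching the analysis convention that instruction-phase eye
    movements are excluded); empty means are missing (NaN), never zero.
    """
    if phase is not None and len(events):
        events = events[events["phase"] == phase]
    fix = events[events["kind"] == "fixation"]
    sacc = events[events["kind"] == "saccade"]
    row = {
        "mean_fix_dur_ms": float(fix["duration_ms"].mean()) if len(fix) else np.nan,
        "mean_sacc_dur_ms": float(sacc["duration_ms"].mean()) if len(sacc) else np.nan,
        "mean_sacc_amp_deg": float(sacc["amplitude_deg"].mean()) if len(sacc) else np.nan,
        "n_fix": int(len(fix)),
        "n_sacc": int(len(sacc)),
    }
    if samples is not None and len(samples):
        row["invalid_pct"] = 100.0 * (1.0 - samples["valid"].mean())
    else:
        row["invalid_pct"] = np.nan
    return row


def scenario_feature_table(
    events: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    salmap: SaliencyMap | None = None,
    phase: str = "execution",
) -> pd.DataFrame:
    """One row per participant x scenario with the aggregate features.

    Adds NSS per scenario when a saliency map is supplied.
    """
    rows = []
    sample_groups = None
    if samples is not None:
        sample_groups = dict(tuple(samples.groupby(["participant", "scenario"], sort=True)))
    for (participant, scenario), chunk in events.groupby(
        ["participant", "scenario"], sort=True
    ):
        schunk = sample_groups.get((participant, scenario)) if sample_groups else None
        row = aggregate_scenario(chunk, schunk, phase=phase)
        row["participant"] = participant
        row["scenario"] = scenario
        row["group"] = chunk["group"].iloc[0] if "group" in chunk else None
        if salmap is not None:
            fix = chunk[(chunk["kind"] == "fixation") & (chunk["phase"] == phase)]
            row["nss"] = nss(salmap, fix) if len(fix) else np.nan
        rows.append(row)
    cols = [
        "participant",
        "group",
        "scenario",
        "mean_fix_dur_ms",
        "mean_sacc_dur_ms",
        "mean_sacc_amp_deg",
        "n_fix",
        "n_sacc",
        "invalid_pct",
    ]
    if salmap is not None:
        cols.append("nss")
    return pd.DataFrame(rows)[cols]


def feature_matrix(features: pd.DataFrame, columns=EVENT_FEATURES):
    """Wide per-participant matrix: one column per feature x scenario.

    Width is len(columns) x n_scenarios (39 for the default three
    features and 13 scenarios). Returns (X DataFrame, y group labels).
    """
    wide = features.pivot(index="participant", columns="scenario", values=list(columns))
    wide.columns = [f"{feat}_s{scen}" for feat, scen in wide.columns]
    groups = features.groupby("participant")["group"].first()
    return wide, groups.loc[wide.index]


def participant_weighted_means(
    events: pd.DataFrame, phase: str = "execution"
) -> pd.DataFrame:
    """Grand means per group: mean over participants of the mean over
    that participant's scenario means (participant-weighted)."""
    feats = scenario_feature_table(events, phase=phase)
    per_participant = feats.groupby(["group", "participant"])[EVENT_FEATURES].mean()
    return per_participant.groupby("group").mean()


# ---------------------------------------------------------------------------
# object attribution


def assign_objects(fixations: pd.DataFrame, scene: SceneSpec) -> pd.DataFrame:
    """Label fixations with the AOI containing their centroid.

    Non-object surfaces (floor, walls, waypoints) keep their AOI id but
    are marked ``relevance='non-object'``; fixations outside every AOI
    get None for both. Ties between nested AOIs go to the smallest.
    """
    out = fixations.copy()
    if len(out) == 0:
        return out
    ids, rel = scene.locate(
        out["start_az_deg"].to_numpy(float), out["start_el_deg"].to_numpy(float)
    )
    out["object_id"] = ids
    out["relevance"] = rel
    return out


def relevance_stats(fixations: pd.DataFrame) -> pd.DataFrame:
    """Mean fixation duration on relevant vs irrelevant objects, per
    participant. Non-object and unassigned fixations are excluded."""
    rows = []
    for participant, chunk in fixations.groupby("participant", sort=True):
        rel = chunk[chunk["relevance"] == "relevant"]
        irr = chunk[chunk["relevance"] == "irrelevant"]
        rows.append(
            {
                "participant": participant,
                "group": chunk["group"].iloc[0] if "group" in chunk else None,
                "relevant_mean_ms": float(rel["duration_ms"].mean()) if len(rel) else np.nan,
                "irrelevant_mean_ms": float(irr["duration_ms"].mean()) if len(irr) else np.nan,
                "n_relevant": int(len(rel)),
                "n_irrelevant": int(len(irr)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# normalized scanpath saliency


def nss(salmap: SaliencyMap, fixations, mode: str = "centroid") -> float:
    """Normalized scanpath saliency of a set of fixations.

    The map is z-scored over all cells (population SD); the NSS is the
    mean bilinearly interpolated z-value at each fixation centroid
    (``mode='centroid'``). ``mode='positions'`` accepts raw (az, el)
    arrays instead of an event table. Fixations outside the map domain
    are skipped; with no usable fixation the value is NaN. A constant
    map raises ValueError (z-scoring undefined).
    """
    z = salmap.zscored()
    if isinstance(fixations, pd.DataFrame):
        az = fixations["start_az_deg"].to_numpy(float)
        el = fixations["start_el_deg"].to_numpy(float)
    else:
        az, el = (np.asarray(a, dtype=float) for a in fixations)
    inside = z.contains(az, el)
    if not inside.any():
        return float("nan")
    return float(np.mean(z.interp(az[inside], el[inside])))


# ---------------------------------------------------------------------------
# ambient vs focal time course


def bin_time_course(events: pd.DataFrame, bin_s: float = 1.0) -> pd.DataFrame:
    """Per-1-s-bin features of one execution phase.

    Events are assigned to bins by onset time relative to the start of
    the execution phase (bin 0 starts when the instruction ended). For
    each bin: mean fixation duration, number of fixations, mean saccade
    amplitude, and the proportion of saccades whose flanking fixations
    share an object — saccades flanked by non-object or unassigned
    fixations are excluded from the denominator; with an empty
    denominator the proportion is missing.
    """
    ev = events.sort_values("onset_ms").reset_index(drop=True)
    if len(ev) == 0:
        return pd.DataFrame(
            columns=[
                "bin_index",
                "mean_fix_dur_ms",
                "n_fixations",
                "mean_sacc_amp_deg",
                "prop_same_object_saccades",
            ]
        )
    t0 = float(ev["onset_ms"].iloc[0])
    bin_ms = bin_s * 1000.0
    ev["bin_index"] = ((ev["onset_ms"] - t0) / bin_ms).astype(int)

    # same-object status per saccade from its flanking fixations
    kinds = ev["kind"].to_numpy()
    obj = ev["object_id"].to_numpy(object)
    rel = ev["relevance"].to_numpy(object) if "relevance" in ev else np.full(len(ev), None)
    same = np.full(len(ev), np.nan)  # NaN = not in denominator
    for i in np.flatnonzero(kinds == "saccade"):
        if i == 0 or i == len(ev) - 1:
            continue
        if kinds[i - 1] != "fixation" or kinds[i + 1] != "fixation":
            continue
        labels = []
        for j in (i - 1, i + 1):
            if rel[j] in ("relevant", "irrelevant") and obj[j] is not None:
                labels.append(obj[j])
        if len(labels) == 2:
            same[i] = 1.0 if labels[0] == labels[1] else 0.0
    ev["_same"] = same

    rows = []
    for b, chunk in ev.groupby("bin_index", sort=True):
        fix = chunk[chunk["kind"] == "fixation"]
        sacc = chunk[chunk["kind"] == "saccade"]
        denom = sacc["_same"].notna().sum()
        rows.append(
            {
                "bin_index": int(b),
                "mean_fix_dur_ms": float(fix["duration_ms"].mean()) if len(fix) else np.nan,
                "n_fixations": int(len(fix)),
                "mean_sacc_amp_deg": float(sacc["amplitude_deg"].mean())
                if len(sacc)
                else np.nan,
                "prop_same_object_saccades": float(sacc["_same"].sum() / denom)
                if denom
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# head motion


def head_motion_metrics(quats_wxyz, t_ms):
    """(total rotation angle deg, mean rotation speed deg/s).

    The total angle is the sum of successive quaternion geodesic angles;
    the mean speed is the average of per-step angle / dt.
    """
    q = np.asarray(quats_wxyz, dtype=float)
    t = np.asarray(t_ms, dtype=float)
    if len(q) < 2:
        raise ValueError("need at least 2 samples")
    steps = quat_geodesic_deg(q[:-1], q[1:])
    dt_s = np.diff(t) / 1000.0
    if np.any(dt_s <= 0):
        raise ValueError("timestamps must be strictly increasing")
    return float(steps.sum()), float(np.mean(steps / dt_s))
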