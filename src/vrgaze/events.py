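"""Oculomotor event detection for head-free VR gaze recordings.

The detector follows the adaptive velocity-threshold approach of Engbert
& Kliegl, adapted to unconstrained head movement: head-frame gaze
directions are first mapped into world coordinates using the concurrent
head orientation, angular velocities are estimated with a moving-window
differentiator, and a sample is classified as saccadic when its velocity
exceeds a per-component threshold of lambda times a median-based robust
estimate of the velocity noise. Complementary intervals are fixations.

Detected events are then cleaned with the standard plausibility filters:
saccades must last 22-300 ms (the lower bound is two sample intervals at
90 Hz), span at least 0.75 degrees, and stay below 36,000 deg/s^2 peak
acceleration; fixations must last 100-1000 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geometry import ang_to_vec, great_circle_deg, quat_rotate, slerp_vec, vec_to_ang

__all__ = [
    "DetectionParams",
    "FilterParams",
    "DegenerateVelocityError",
    "min_saccade_duration_ms",
    "to_world_angles",
    "ek_velocity",
    "adaptive_threshold",
    "detect_events",
    "filter_events",
    "detect_cohort",
    "EVENT_COLUMNS",
]

#: Columns of an event table (detected or ground truth).
EVENT_COLUMNS = [
    "kind",
    "onset_ms",
    "offset_ms",
    "duration_ms",
    "start_az_deg",
    "start_el_deg",
    "end_az_deg",
    "end_el_deg",
    "amplitude_deg",
    "peak_accel_deg_s2",
    "object_id",
    "relevance",
    "participant",
    "group",
    "scenario",
    "phase",
]


class DegenerateVelocityError(ValueError):
    """Raised when the velocity trace has zero robust spread.

    A constant trace gives a zero adaptive threshold; add a noise floor
    or check the input.
    """


@dataclass
class DetectionParams:
    """Tunables of the adaptive velocity-threshold detector."""

    lam: float = 6.0  # threshold multiplier on the robust velocity SD
    velocity_window: int = 5  # odd moving-window length, samples
    min_saccade_samples: int = 2
    gap_interpolation_max_samples: int = 2
    min_intersaccadic_ms: float = 40.0

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.velocity_window < 3 or self.velocity_window % 2 == 0:
            raise ValueError("velocity_window must be an odd integer >= 3")
        if self.min_saccade_samples < 1:
            raise ValueError("min_saccade_samples must be >= 1")
        if self.gap_interpolation_max_samples < 0:
            raise ValueError("gap_interpolation_max_samples must be >= 0")
        if self.min_intersaccadic_ms < 0:
            raise ValueError("min_intersaccadic_ms must be >= 0")


@dataclass
class FilterParams:
    """Plausibility windows for detected events."""

    saccade_dur_ms: tuple[float, float] = (22.0, 300.0)
    saccade_min_amp_deg: float = 0.75
    saccade_max_accel_deg_s2: float = 36000.0
    fixation_dur_ms: tuple[float, float] = (100.0, 1000.0)

    def __post_init__(self):
        for lo, hi in (self.saccade_dur_ms, self.fixation_dur_ms):
            if not lo < hi:
                raise ValueError("interval lower bound must be below upper bound")


def min_saccade_duration_ms(rate_hz: float) -> float:
    """Minimum credible saccade duration: two sample intervals, floored
    to whole milliseconds (22 ms at 90 Hz)."""
    if rate_hz <= 0:
        raise ValueError("sampling rate must be positive")
    return float(math.floor(2.0 * 1000.0 / rate_hz))


# ---------------------------------------------------------------------------
# head compensation


def to_world_angles(samples: pd.DataFrame, gap_interpolation_max_samples: int = 2):
    """Map head-frame gaze samples of one scenario into world angles.

    Returns a DataFrame with columns ``t_ms``, ``az_deg``, ``el_deg``,
    ``valid``, ``segment_id``. Invalid gaps of at most
    ``gap_interpolation_max_samples`` samples are interpolated along the
    great circle between the flanking valid samples; longer gaps split
    the trace into separate segments. Samples in unsplittable positions
    (leading/trailing gaps) stay invalid with segment_id -1.
    """
    t = samples["t_ms"].to_numpy(dtype=float)
    gaze = samples[["gx", "gy", "gz"]].to_numpy(dtype=float)
    quat = samples[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float)
    valid = samples["valid"].to_numpy(dtype=bool)
    n = len(t)
    if n == 0:
        return pd.DataFrame(
            {"t_ms": [], "az_deg": [], "el_deg": [], "valid": [], "segment_id": []}
        )
    norms = np.linalg.norm(gaze, axis=1)
    if np.any(valid & (norms < 1e-9)):
        raise ValueError("zero-norm gaze vector among valid samples")

    world = np.full((n, 3), np.nan)
    if valid.any():
        world[valid] = quat_rotate(quat[valid], gaze[valid])

    # classify invalid runs: interpolate short interior gaps, split on others
    segment_id = np.full(n, -1, dtype=int)
    filled = valid.copy()
    idx = np.flatnonzero(np.diff(np.concatenate(([True], valid, [True]))))
    gaps = list(zip(idx[::2], idx[1::2]))  # [start, stop) of invalid runs
    for start, stop in gaps:
        length = stop - start
        interior = start > 0 and stop < n
        if interior and length <= gap_interpolation_max_samples:
            u = world[start - 1]
            v = world[stop]
            frac = (t[start:stop] - t[start - 1]) / (t[stop] - t[start - 1])
            world[start:stop] = slerp_vec(u, v, frac)
            filled[start:stop] = True

    # contiguous filled runs become segments
    seg = 0
    run_edges = np.flatnonzero(np.diff(np.concatenate(([False], filled, [False]))))
    for start, stop in zip(run_edges[::2], run_edges[1::2]):
        segment_id[start:stop] = seg
        seg += 1

    az = np.full(n, np.nan)
    el = np.full(n, np.nan)
    az[filled], el[filled] = vec_to_ang(world[filled])
    return pd.DataFrame(
        {"t_ms": t, "az_deg": az, "el_deg": el, "valid": filled, "segment_id": segment_id}
    )


# ---------------------------------------------------------------------------
# velocity estimation and thresholds


def _window_velocity(x: np.ndarray, dt_s: float, window: int) -> np.ndarray:
    """Moving-window derivative within one segment.

    Interior samples use the symmetric estimator; for window 5:
    v_n = (x_{n+2} + x_{n+1} - x_{n-1} - x_{n-2}) / (6 dt).
    Samples too close to the edges fall back to shorter stencils
    (central difference, then one-sided difference at the very ends).
    """
    n = len(x)
    v = np.empty(n)
    if n == 1:
        v[0] = 0.0
        return v
    half = window // 2
    # smallest stencils first; wider estimates overwrite interior values
    v[:-1] = np.diff(x) / dt_s
    v[-1] = (x[-1] - x[-2]) / dt_s
    if n >= 3:
        v[1:-1] = (x[2:] - x[:-2]) / (2.0 * dt_s)
    for h in range(2, half + 1):
        if n >= 2 * h + 1:
            denom = 2.0 * sum(range(1, h + 1)) * dt_s
            core = np.zeros(n - 2 * h)
            for k in range(1, h + 1):
                core += x[2 * h - h + k : n - h + k] - x[h - k : n - h - k]
            v[h : n - h] = core / denom
    return v


def ek_velocity(trace: pd.DataFrame, window: int = 5) -> pd.DataFrame:
    """Angular velocity (deg/s) per component within valid segments.

    Azimuth velocity is scaled by cos(elevation) so both components are
    true angular rates on the sphere. Segments shorter than ``window``
    are skipped (velocity NaN).
    """
    out = trace.copy()
    n = len(trace)
    v_az = np.full(n, np.nan)
    v_el = np.full(n, np.nan)
    seg_ids = trace["segment_id"].to_numpy()
    t = trace["t_ms"].to_numpy(dtype=float)
    az = trace["az_deg"].to_numpy(dtype=float)
    el = trace["el_deg"].to_numpy(dtype=float)
    for seg in np.unique(seg_ids[seg_ids >= 0]):
        m = seg_ids == seg
        idx = np.flatnonzero(m)
        if len(idx) < window:
            continue
        dt_s = float(np.median(np.diff(t[idx]))) / 1000.0
        az_u = np.unwrap(np.deg2rad(az[idx]))
        az_u = np.rad2deg(az_u)
        v_az[idx] = _window_velocity(az_u, dt_s, window) * np.cos(np.deg2rad(el[idx]))
        v_el[idx] = _window_velocity(el[idx], dt_s, window)
    out["v_az"] = v_az
    out["v_el"] = v_el
    return out


def adaptive_threshold(v_az: np.ndarray, v_el: np.ndarray, lam: float = 6.0):
    """Per-component detection thresholds eta = lambda * sigma.

    sigma_c is the median-based robust spread
    sqrt(median(v_c^2) - median(v_c)^2) over all finite velocity samples
    of the estimation window (one scenario).
    """
    etas = []
    for v in (np.asarray(v_az, float), np.asarray(v_el, float)):
        v = v[np.isfinite(v)]
        if len(v) < 10:
            raise ValueError("need at least 10 valid velocity samples")
        var = np.median(v**2) - np.median(v) ** 2
        if var <= 0:
            raise DegenerateVelocityError(
                "degenerate (constant) velocity trace: robust spread is zero; "
                "add a noise floor before detection"
            )
        etas.append(lam * math.sqrt(var))
    return tuple(etas)


# ---------------------------------------------------------------------------
# event detection


def _runs(mask: np.ndarray):
    """[start, stop) index pairs of True runs."""
    edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False]))))
    return list(zip(edges[::2], edges[1::2]))


def detect_events(
    trace: pd.DataFrame,
    params: DetectionParams | None = None,
    thresholds: tuple[float, float] | None = None,
    meta: dict | None = None,
) -> pd.DataFrame:
    """Detect saccades and fixations in one scenario's angular trace.

    ``trace`` must carry ``v_az``/``v_el`` columns (see
    :func:`ek_velocity`); otherwise they are computed here. A sample is
    saccadic when (v_az/eta_az)^2 + (v_el/eta_el)^2 > 1; runs of at
    least ``min_saccade_samples`` such samples are saccade candidates.
    Candidates closer than ``min_intersaccadic_ms`` are merged. Complementary intervals are fixations. Events adjacent to a
    data-loss split are discarded (their extent is censored).
    """
    params = params or DetectionParams()
    meta = meta or {}
    if len(trace) == 0:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    if "v_az" not in trace.columns:
        trace = ek_velocity(trace, params.velocity_window)
    if thresholds is None:
        thresholds = adaptive_threshold(
            trace["v_az"].to_numpy(), trace["v_el"].to_numpy(), params.lam
        )
    eta_az, eta_el = thresholds

    t = trace["t_ms"].to_numpy(dtype=float)
    az = trace["az_deg"].to_numpy(dtype=float)
    el = trace["el_deg"].to_numpy(dtype=float)
    seg_ids = trace["segment_id"].to_numpy()
    v_az = trace["v_az"].to_numpy(dtype=float)
    v_el = trace["v_el"].to_numpy(dtype=float)
    speed = np.hypot(v_az, v_el)

    seg_order = np.unique(seg_ids[seg_ids >= 0])
    n_segments = len(seg_order)
    records = []
    for seg_pos, seg in enumerate(seg_order):
        idx = np.flatnonzero(seg_ids == seg)
        if len(idx) < params.velocity_window:
            continue
        ts = t[idx]
        dt_ms = float(np.median(np.diff(ts)))
        crit = (v_az[idx] / eta_az) ** 2 + (v_el[idx] / eta_el) ** 2 > 1.0
        crit &= np.isfinite(v_az[idx])

        sacc_runs = [
            [a, b] for a, b in _runs(crit) if b - a >= params.min_saccade_samples
        ]
        # merge candidates separated by less than the intersaccadic minimum
        merged = []
        for run in sacc_runs:
            if merged and (ts[run[0]] - ts[merged[-1][1] - 1]) < params.min_intersaccadic_ms:
                merged[-1][1] = run[1]
            else:
                merged.append(run)

        vecs = ang_to_vec(az[idx], el[idx])
        n_i = len(idx)

        def add_event(kind, a, b):
            """Event spanning samples [a, b) of this segment."""
            dur = (b - a) * dt_ms
            if kind == "saccade":
                ia = max(a - 1, 0)
                ib = min(b, n_i - 1)
                amp = float(great_circle_deg(vecs[ia], vecs[ib]))
                p0, p1 = vecs[ia], vecs[ib]
                sp = speed[idx[max(a - 1, 0) : min(b + 1, n_i)]]
                sp = sp[np.isfinite(sp)]
                accel = float(np.max(np.abs(np.diff(sp))) / (dt_ms / 1000.0)) if len(sp) > 1 else 0.0
            else:
                centroid = vecs[a:b].mean(axis=0)
                centroid /= np.linalg.norm(centroid)
                amp = float(np.max(great_circle_deg(vecs[a:b], centroid)))
                p0 = p1 = centroid
                accel = 0.0
            az0, el0 = vec_to_ang(p0)
            az1, el1 = vec_to_ang(p1)
            records.append(
                {
                    "kind": kind,
                    "onset_ms": ts[a],
                    "offset_ms": ts[a] + dur,
                    "duration_ms": dur,
                    "start_az_deg": float(az0),
                    "start_el_deg": float(el0),
                    "end_az_deg": float(az1),
                    "end_el_deg": float(el1),
                    "amplitude_deg": amp,
                    "peak_accel_deg_s2": accel,
                    "object_id": None,
                    "relevance": None,
                    "_censored": _censored(a, b),
                }
            )

        def _censored(a, b):
            # events touching an interior split boundary have unknown
            # true extent; stream start/end are genuine event boundaries
            left_split = seg_pos > 0 and a == 0
            right_split = seg_pos < n_segments - 1 and b == n_i
            return left_split or right_split

        cursor = 0
        for a, b in merged:
            if a > cursor:
                add_event("fixation", cursor, a)
            add_event("saccade", a, b)
            cursor = b
        if cursor < n_i:
            add_event("fixation", cursor, n_i)

    if not records:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    ev = pd.DataFrame.from_records(records)
    ev = ev[~ev.pop("_censored")].reset_index(drop=True)
    for key, value in meta.items():
        ev[key] = value
    for col in EVENT_COLUMNS:
        if col not in ev.columns:
            ev[col] = None
    return ev[EVENT_COLUMNS]


def filter_events(events: pd.DataFrame, params: FilterParams | None = None):
    """Apply the plausibility filters; returns (kept, removal counts).

    An event survives iff every bound applicable to its kind holds.
    ``counts`` reports removals per rule (an event failing several rules
    is counted under each).
    """
    params = params or FilterParams()
    if len(events) == 0:
        return events.copy(), {}
    kind = events["kind"].to_numpy()
    dur = events["duration_ms"].to_numpy(dtype=float)
    amp = events["amplitude_deg"].to_numpy(dtype=float)
    accel = events["peak_accel_deg_s2"].to_numpy(dtype=float)

    is_sacc = kind == "saccade"
    is_fix = kind == "fixation"
    lo_s, hi_s = params.saccade_dur_ms
    lo_f, hi_f = params.fixation_dur_ms

    bad_short = is_sacc & (dur < lo_s)
    bad_long = is_sacc & (dur > hi_s)
    bad_amp = is_sacc & (amp < params.saccade_min_amp_deg)
    bad_accel = is_sacc & (accel > params.saccade_max_accel_deg_s2)
    bad_fix = is_fix & ((dur < lo_f) | (dur > hi_f))

    counts = {
        "saccade_too_short": int(bad_short.sum()),
        "saccade_too_long": int(bad_long.sum()),
        "saccade_amplitude": int(bad_amp.sum()),
        "saccade_acceleration": int(bad_accel.sum()),
        "fixation_duration": int(bad_fix.sum()),
    }
    keep = ~(bad_short | bad_long | bad_amp | bad_accel | bad_fix)
    return events[keep].reset_index(drop=True), counts


# ---------------------------------------------------------------------------
# cohort-level convenience


def detect_cohort(
    samples: pd.DataFrame,
    det_params: DetectionParams | None = None,
    filt_params: FilterParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Head-compensate, detect and filter events for a whole sample table.

    Thresholds are estimated per participant x scenario, matching the
    per-scenario analysis grain. Returns (filtered events, removal
    counts summed over scenarios).
    """
    det_params = det_params or DetectionParams()
    filt_params = filt_params or FilterParams()
    all_events = []
    totals: dict[str, int] = {}
    for (participant, scenario), chunk in samples.groupby(
        ["participant", "scenario"], sort=True
    ):
        trace = to_world_angles(chunk, det_params.gap_interpolation_max_samples)
        trace = ek_velocity(trace, det_params.velocity_window)
        try:
            thresholds = adaptive_threshold(
                trace["v_az"].to_numpy(), trace["v_el"].to_numpy(), det_params.lam
            )
        except ValueError:
            continue
        meta = {
            "participant": participant,
            "scenario": scenario,
            "group": chunk["group"].iloc[0] if "group" in chunk else None,
        }
        ev = detect_events(trace, det_params, thresholds, meta)
        if len(ev):
            # assign phase by event onset
            exec_mask = chunk["phase"] == "execution"
            if exec_mask.any():
                exec_start = float(chunk.loc[exec_mask, "t_ms"].min())
                ev["phase"] = np.where(
                    ev["onset_ms"] >= exec_start, "execution", "instruction"
                )
            else:
                ev["phase"] = "instruction"
            all_events.append(ev)
    if not all_events:
        return pd.DataFrame(columns=EVENT_COLUMNS), totals
    events = pd.concat(all_events, ignore_index=True)
    filtered, counts = filter_events(events, filt_params)
    for key, val in counts.items():
        totals[key] = totals.get(key, 0) + val
    return filtered, totals
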