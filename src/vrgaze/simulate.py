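"""Synthetic VR gaze sessions with a ground-truth event ledger.

The generator emulates a two-group study in which children perform a
series of everyday-chore scenarios in a virtual apartment while a 90 Hz
eye tracker records gaze in the head frame. Each scenario has an
instruction phase (gaze parked near the instructing character) and a
90 s execution phase (gaze scanning the scene in alternating fixations
and saccades). Per group, the generator is calibrated so that the
post-filter means of fixation duration, saccade duration and saccade
amplitude reproduce printed group summary statistics exactly as
*realized sample statistics*:

* between-participant effects are drawn standard-normal and then
  standardized to exact sample mean 0 / SD 1, so the cohort of
  participant means reproduces the target group mean and SD;
* within a participant, fixation durations and saccade amplitudes are
  drawn from truncated normals whose location is solved numerically so
  the truncated mean equals the participant's target (truncation bounds
  are the downstream plausibility filters, making the filters no-ops on
  ground truth);
* saccade durations follow an affine main sequence in amplitude
  (2.2 ms/deg) plus noise, with the intercept re-centered per
  participant onto the participant's duration target.

Every generated event is recorded in a ground-truth ledger so detection
and feature pipelines can be validated against known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from ._geometry import (
    ang_to_vec,
    great_circle_deg,
    quat_from_yaw_deg,
    quat_rotate_inv,
    slerp_vec,
    tangent_noise,
    vec_to_ang,
)
from .events import EVENT_COLUMNS, FilterParams
from .gaze_io import DEFAULT_CONFIG, GAZE_COLUMNS, SaliencyMap

__all__ = [
    "GroupParams",
    "CohortSpec",
    "AOI",
    "SceneSpec",
    "CohortData",
    "CalibrationError",
    "calibrate_truncated_mean",
    "make_saliency_map",
    "make_scene",
    "simulate_participant",
    "simulate_cohort",
    "render_gaze_trace",
    "inject_data_loss",
    "SinusoidalYawHead",
    "StaticHead",
    "ADHD_PARAMS",
    "CONTROL_PARAMS",
    "PERFORMANCE_MEASURES",
]

#: Names (and clip ranges) of the five task-performance measures.
PERFORMANCE_MEASURES = [
    "total_score_pct",
    "task_efficacy_pct",
    "navigation_efficacy",
    "controller_motion",
    "total_actions",
]
_PERFORMANCE_CLIPS = [(0.0, 100.0), (0.0, 100.0), (0.0, None), (0.0, None), (0.0, None)]

#: Main-sequence slope tying saccade duration to amplitude.
MAIN_SEQUENCE_MS_PER_DEG = 2.2

#: Upper truncation used for saccade amplitudes (physiological bound).
AMP_UPPER_DEG = 60.0

_FILT = FilterParams()


class CalibrationError(RuntimeError):
    """Truncated-mean calibration failed to converge."""


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class GroupParams:
    """Generative parameters of one diagnostic group."""

    fixation_mean_ms: float
    fixation_between_sd_ms: float
    fixation_within_sd_ms: float
    saccade_dur_mean_ms: float
    saccade_dur_between_sd_ms: float
    saccade_dur_within_sd_ms: float
    saccade_amp_mean_deg: float
    saccade_amp_between_sd_deg: float
    saccade_amp_within_sd_deg: float
    invalid_rate: float
    performance_means: tuple = ()
    performance_sds: tuple = ()
    relevant_fixation_offset_ms: float = 0.0

    def __post_init__(self):
        lo_f, hi_f = _FILT.fixation_dur_ms
        lo_s, hi_s = _FILT.saccade_dur_ms
        if not lo_f < self.fixation_mean_ms < hi_f:
            raise ValueError("fixation mean must lie inside the admissible window")
        if not lo_s < self.saccade_dur_mean_ms < hi_s:
            raise ValueError("saccade duration mean must lie inside the admissible window")
        if not self.saccade_amp_mean_deg > _FILT.saccade_min_amp_deg:
            raise ValueError("saccade amplitude mean must exceed the minimum amplitude")
        for name in (
            "fixation_between_sd_ms",
            "fixation_within_sd_ms",
            "saccade_dur_between_sd_ms",
            "saccade_dur_within_sd_ms",
            "saccade_amp_between_sd_deg",
            "saccade_amp_within_sd_deg",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.invalid_rate < 0.3:
            raise ValueError("invalid_rate must be in [0, 0.3) (30%+ loss is excluded)")
        self.performance_means = tuple(self.performance_means) or tuple(
            [70.0, 60.0, 1.3, 1200.0, 145.0]
        )
        self.performance_sds = tuple(self.performance_sds) or (14.0, 12.0, 0.4, 300.0, 35.0)
        if len(self.performance_means) != 5 or len(self.performance_sds) != 5:
            raise ValueError("performance means/sds must be 5-vectors")
        if any(sd < 0 for sd in self.performance_sds):
            raise ValueError("performance SDs must be nonnegative")


def _params_from_config(section: dict) -> GroupParams:
    return GroupParams(**section)


ADHD_PARAMS = _params_from_config(DEFAULT_CONFIG["group_adhd"])
CONTROL_PARAMS = _params_from_config(DEFAULT_CONFIG["group_control"])


@dataclass
class CohortSpec:
    """Study-level design: group sizes, scenario structure, sampling."""

    n_per_group: dict = field(default_factory=lambda: {"ADHD": 37, "control": 36})
    n_scenarios: int = 13
    scenario_duration_s: float = 90.0
    instruction_duration_s: float = 10.0
    sampling_rate_hz: float = 90.0
    seed: int = 0
    group_params: dict = field(
        default_factory=lambda: {"ADHD": ADHD_PARAMS, "control": CONTROL_PARAMS}
    )

    def __post_init__(self):
        if set(self.n_per_group) != {"ADHD", "control"}:
            raise ValueError("group labels must be exactly {'ADHD', 'control'}")
        if set(self.group_params) != {"ADHD", "control"}:
            raise ValueError("group_params labels must be exactly {'ADHD', 'control'}")
        if self.n_scenarios < 1:
            raise ValueError("n_scenarios must be >= 1")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.scenario_duration_s <= 0 or self.instruction_duration_s < 0:
            raise ValueError("durations must be nonnegative (execution positive)")


@dataclass
class AOI:
    """Angular bounding box of a scene object."""

    object_id: str
    az_min: float
    az_max: float
    el_min: float
    el_max: float
    relevance: str  # relevant | irrelevant | non-object

    def __post_init__(self):
        if self.relevance not in ("relevant", "irrelevant", "non-object"):
            raise ValueError("relevance must be relevant/irrelevant/non-object")
        if not (self.az_min < self.az_max and self.el_min < self.el_max):
            raise ValueError("degenerate AOI bounding box")

    @property
    def area(self) -> float:
        return (self.az_max - self.az_min) * (self.el_max - self.el_min)


@dataclass
class SceneSpec:
    """Scene annotation: object AOIs plus a saliency map."""

    objects: list
    saliency_map: SaliencyMap

    def __post_init__(self):
        az_lo, az_hi = self.saliency_map.az_range_deg
        el_lo, el_hi = self.saliency_map.el_range_deg
        for aoi in self.objects:
            if not (
                az_lo <= aoi.az_min
                and aoi.az_max <= az_hi
                and el_lo <= aoi.el_min
                and aoi.el_max <= el_hi
            ):
                raise ValueError(f"AOI {aoi.object_id} outside the map's angular domain")

    def locate(self, az_deg, el_deg):
        """(object_id, relevance) arrays for angular positions.

        A position inside several AOIs is assigned to the smallest one;
        outside every AOI both entries are None.
        """
        az = np.atleast_1d(np.asarray(az_deg, dtype=float))
        el = np.atleast_1d(np.asarray(el_deg, dtype=float))
        ids = np.full(az.shape, None, dtype=object)
        rel = np.full(az.shape, None, dtype=object)
        best_area = np.full(az.shape, np.inf)
        for aoi in self.objects:
            inside = (
                (az >= aoi.az_min)
                & (az <= aoi.az_max)
                & (el >= aoi.el_min)
                & (el <= aoi.el_max)
            )
            better = inside & (aoi.area < best_area)
            ids[better] = aoi.object_id
            rel[better] = aoi.relevance
            best_area[better] = aoi.area
        return ids, rel

    def aoi_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "object_id": a.object_id,
                    "az_min": a.az_min,
                    "az_max": a.az_max,
                    "el_min": a.el_min,
                    "el_max": a.el_max,
                    "relevance": a.relevance,
                }
                for a in self.objects
            ]
        )


@dataclass
class CohortData:
    """One simulated study: sample streams, ground truth, performance."""

    samples: pd.DataFrame | None
    events: pd.DataFrame
    performance: pd.DataFrame
    scene: SceneSpec
    spec: CohortSpec


# ---------------------------------------------------------------------------
# truncated-normal calibration


def calibrate_truncated_mean(
    target_mean: float, sd: float, lower: float, upper: float, rel_tol: float = 1e-3
) -> float:
    """Location of a normal(loc, sd) whose [lower, upper]-truncated mean
    equals ``target_mean``.

    Solved by bracketing + Brent root finding on the monotone map
    loc -> truncated mean. Raises :class:`CalibrationError` if no
    bracket is found within 200 doublings or the root search fails.
    """
    if not lower < target_mean < upper:
        raise ValueError("target mean must lie strictly inside the truncation bounds")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if sd < 1e-9 * (upper - lower):
        return float(target_mean)  # truncation is immaterial at this scale

    def trunc_mean(loc):
        a = (lower - loc) / sd
        b = (upper - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd)

    lo, hi = target_mean - sd, target_mean + sd
    for _ in range(200):
        if trunc_mean(lo) <= target_mean:
            break
        lo -= sd
    else:
        raise CalibrationError("no lower bracket for truncated-mean calibration")
    for _ in range(200):
        if trunc_mean(hi) >= target_mean:
            break
        hi += sd
    else:
        raise CalibrationError("no upper bracket for truncated-mean calibration")
    try:
        loc = brentq(lambda m: trunc_mean(m) - target_mean, lo, hi, maxiter=200)
    except RuntimeError as exc:  # pragma: no cover - brentq rarely fails here
        raise CalibrationError(str(exc)) from exc
    if abs(trunc_mean(loc) - target_mean) > rel_tol * abs(target_mean):
        raise CalibrationError("calibration did not reach the requested tolerance")
    return float(loc)


def _trunc_rvs(loc, sd, lower, upper, size, rng):
    a = (lower - loc) / sd
    b = (upper - loc) / sd
    return truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


# ---------------------------------------------------------------------------
# scene construction


def make_saliency_map(
    shape=(32, 64),
    hotspots=(),
    az_range=(-60.0, 60.0),
    el_range=(-30.0, 30.0),
    base: float = 0.1,
    seed=None,
) -> SaliencyMap:
    """Nonnegative saliency grid with Gaussian hotspots.

    ``hotspots`` is a sequence of (az_deg, el_deg, sd_deg[, weight])
    tuples; each must lie within the angular domain. With no hotspots
    the map is constant at ``base``.
    """
    n_el, n_az = shape
    if n_el < 2 or n_az < 2:
        raise ValueError("saliency grid must be at least 2x2")
    values = np.full((n_el, n_az), float(base))
    salmap = SaliencyMap(values, tuple(az_range), tuple(el_range))
    az_c, el_c = salmap.cell_centers()
    az_grid, el_grid = np.meshgrid(az_c, el_c)
    for spot in hotspots:
        az0, el0, sd = spot[0], spot[1], spot[2]
        weight = spot[3] if len(spot) > 3 else 1.0
        if not (az_range[0] <= az0 <= az_range[1] and el_range[0] <= el0 <= el_range[1]):
            raise ValueError(f"hotspot ({az0}, {el0}) outside the angular domain")
        values += weight * np.exp(
            -((az_grid - az0) ** 2 + (el_grid - el0) ** 2) / (2.0 * sd**2)
        )
    return SaliencyMap(values, tuple(az_range), tuple(el_range))


def make_scene(
    n_relevant: int = 4,
    n_irrelevant: int = 19,
    seed: int = 0,
    az_range=(-60.0, 60.0),
    el_range=(-30.0, 30.0),
    box_deg: float = 6.0,
) -> SceneSpec:
    """Default synthetic scene.

    Emulates one scenario's annotation: a handful of task-relevant
    objects, many task-irrelevant ones (roughly the printed 47:243 ratio
    per scenario), a floor band and teleport waypoints as non-objects,
    and a saliency map with hotspots on a few objects.
    """
    rng = np.random.default_rng(seed)
    objects = []
    centers = []
    margin = box_deg / 2 + 1.0
    for i in range(n_relevant + n_irrelevant):
        az0 = rng.uniform(az_range[0] + margin, az_range[1] - margin)
        el0 = rng.uniform(el_range[0] + margin + 4.0, el_range[1] - margin)
        size = box_deg * rng.uniform(0.7, 1.3)
        relevance = "relevant" if i < n_relevant else "irrelevant"
        objects.append(
            AOI(
                object_id=f"obj{i:02d}",
                az_min=az0 - size / 2,
                az_max=az0 + size / 2,
                el_min=el0 - size / 2,
                el_max=el0 + size / 2,
                relevance=relevance,
            )
        )
        centers.append((az0, el0))
    # non-object surfaces: floor band and two teleport waypoints
    objects.append(
        AOI("floor", az_range[0], az_range[1], el_range[0], el_range[0] + 4.0, "non-object")
    )
    for j, az0 in enumerate((-30.0, 30.0)):
        objects.append(
            AOI(f"waypoint{j}", az0 - 2.0, az0 + 2.0, el_range[0] + 4.0, el_range[0] + 8.0, "non-object")
        )
    hotspots = [(az, el, 4.0) for az, el in centers[: max(2, n_relevant // 2)]]
    salmap = make_saliency_map((32, 64), hotspots, az_range, el_range, seed=seed)
    return SceneSpec(objects=objects, saliency_map=salmap)


# ---------------------------------------------------------------------------
# head-motion profiles


class StaticHead:
    """Head fixed at the identity orientation."""

    def quaternions(self, t_ms, exec_start_ms=0.0):
        n = len(np.atleast_1d(t_ms))
        q = np.zeros((n, 4))
        q[:, 0] = 1.0
        return q


class SinusoidalYawHead:
    """Slow sinusoidal yaw during execution, static during instruction.

    Default +-20 deg at 0.1 Hz: enough head motion that head
    compensation is genuinely exercised, slow enough that the
    vestibulo-ocular gaze stays world-stationary during fixations.
    """

    def __init__(self, amplitude_deg: float = 20.0, freq_hz: float = 0.1):
        self.amplitude_deg = amplitude_deg
        self.freq_hz = freq_hz

    def quaternions(self, t_ms, exec_start_ms=0.0):
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        dt_s = (t - exec_start_ms) / 1000.0
        yaw = np.where(
            dt_s >= 0.0,
            self.amplitude_deg * np.sin(2.0 * math.pi * self.freq_hz * dt_s),
            0.0,
        )
        return quat_from_yaw_deg(yaw)


# ---------------------------------------------------------------------------
# event-level simulation


def _standardized(n: int, rng) -> np.ndarray:
    """n draws from N(0,1), standardized to exact sample mean 0 / SD 1.

    Treats printed group summaries as realized sample statistics: the
    cohort of participant means reproduces them exactly.
    """
    if n == 1:
        return np.zeros(1)
    z = rng.standard_normal(n)
    z = z - z.mean()
    sd = z.std(ddof=1)
    if sd == 0:
        return np.zeros(n)
    return z / sd


def _bounded_standardized(n, rng, mean, sd, lower, upper, max_tries=200) -> np.ndarray:
    """Standardized effects whose implied participant means stay inside
    the admissible window.

    Extreme standardized draws can push mean + sd * z outside the event
    filters' windows (the admissibility invariant of the group
    parameters); such vectors are redrawn, deterministically under the
    given generator.
    """
    if sd == 0:
        return np.zeros(n)
    for _ in range(max_tries):
        z = _standardized(n, rng)
        means = mean + sd * z
        if means.min() > lower and means.max() < upper:
            return z
    raise CalibrationError(
        "could not draw participant means inside the admissible window; "
        "the between-participant SD is too large for the filter bounds"
    )


def _accel_floor_ms(amp_deg: np.ndarray, max_accel: float) -> np.ndarray:
    """Shortest duration (ms) keeping a raised-cosine saccade of the
    given amplitude below the acceleration cap."""
    return 1000.0 * np.sqrt(amp_deg * math.pi**2 / (2.0 * max_accel))


def _peak_accel(amp_deg: np.ndarray, dur_ms: np.ndarray) -> np.ndarray:
    """Peak acceleration of a raised-cosine saccade profile."""
    return amp_deg * math.pi**2 / (2.0 * (dur_ms / 1000.0) ** 2)


_SPEAKER_AZ, _SPEAKER_EL = 0.0, -5.0
_DOMAIN_AZ, _DOMAIN_EL = 55.0, 26.0  # safe walk domain half-widths


def _random_walk(start_vec, amps_deg, rng):
    """Great-circle random walk with the given step sizes.

    Heading is uniform; steps that would leave the safe angular domain
    head toward the scene center instead. Returns (n+1, 3) vectors.
    Scalar math on purpose: the walk is inherently sequential and plain
    floats are much faster than per-step numpy calls.
    """
    n = len(amps_deg)
    pts = np.empty((n + 1, 3))
    pts[0] = start_vec
    headings = rng.uniform(0.0, 2.0 * math.pi, size=n)
    cos_h = np.cos(headings)
    sin_h = np.sin(headings)
    a_rad = np.deg2rad(np.asarray(amps_deg, dtype=float))
    cos_a = np.cos(a_rad)
    sin_a = np.sin(a_rad)
    sin_el_max = math.sin(math.radians(_DOMAIN_EL))
    tan_az_max = math.tan(math.radians(_DOMAIN_AZ))
    px, py, pz = (float(v) for v in start_vec)
    for i in range(n):
        # local east = normalize(up x p), north = p x east
        hn = math.hypot(px, py)
        ex, ey = -py / hn, px / hn
        nx, ny, nz = -pz * ey, pz * ex, px * ey - py * ex
        dx = cos_h[i] * ex + sin_h[i] * nx
        dy = cos_h[i] * ey + sin_h[i] * ny
        dz = sin_h[i] * nz
        qx = cos_a[i] * px + sin_a[i] * dx
        qy = cos_a[i] * py + sin_a[i] * dy
        qz = cos_a[i] * pz + sin_a[i] * dz
        if abs(qz) > sin_el_max or qx <= 0 or abs(qy) > tan_az_max * qx:
            # re-aim at the scene center (1, 0, 0) along the great circle
            cx = 1.0 - px * px  # center minus its projection on p
            cy = -px * py
            cz = -px * pz
            cn = math.sqrt(cx * cx + cy * cy + cz * cz)
            if cn > 1e-12:
                cx, cy, cz = cx / cn, cy / cn, cz / cn
                qx = cos_a[i] * px + sin_a[i] * cx
                qy = cos_a[i] * py + sin_a[i] * cy
                qz = cos_a[i] * pz + sin_a[i] * cz
        pts[i + 1] = (qx, qy, qz)
        px, py, pz = qx, qy, qz
    return pts


def _scenario_events(
    rng,
    duration_ms: float,
    start_vec,
    fix_loc: float,
    fix_loc_relevant: float,
    fix_sd: float,
    amp_loc: float,
    amp_sd: float,
    dur_intercept: float,
    dur_sd: float,
    scene: SceneSpec,
    start_with_saccade: bool,
):
    """Alternating saccade/fixation events filling ``duration_ms``.

    Returns a dict of column arrays (onset/offset relative to 0) and the
    final gaze vector. The event sequence starts with a saccade leaving
    ``start_vec`` (execution) or a fixation at it (instruction).
    """
    lo_f, hi_f = _FILT.fixation_dur_ms
    lo_s, hi_s = _FILT.saccade_dur_ms
    mean_cycle = max(fix_loc, lo_f) + dur_intercept + MAIN_SEQUENCE_MS_PER_DEG * amp_loc
    n_est = int(duration_ms / mean_cycle * 1.4) + 12
    for _ in range(8):  # enlarge if the cycle estimate undershoots
        amps = _trunc_rvs(
            amp_loc, amp_sd, _FILT.saccade_min_amp_deg, AMP_UPPER_DEG, n_est, rng
        )
        fix_probe = n_est * (max(fix_loc, lo_f))
        if amps.sum() * MAIN_SEQUENCE_MS_PER_DEG + n_est * dur_intercept + fix_probe > duration_ms:
            break
        n_est *= 2
    sacc_durs = dur_intercept + MAIN_SEQUENCE_MS_PER_DEG * amps + rng.normal(0.0, dur_sd, n_est)
    floor = np.maximum(
        lo_s + 0.5, _accel_floor_ms(amps, _FILT.saccade_max_accel_deg_s2) * 1.02
    )
    sacc_durs = np.clip(sacc_durs, floor, hi_s - 1.0)

    pts = _random_walk(start_vec, amps, rng)
    fix_vecs = pts[1:]  # fixation i follows saccade i
    fix_az, fix_el = vec_to_ang(fix_vecs)
    obj_ids, relevances = scene.locate(fix_az, fix_el)

    fix_durs = _trunc_rvs(fix_loc, fix_sd, lo_f, hi_f, n_est, rng)
    if fix_loc_relevant != fix_loc:
        rel_mask = relevances == "relevant"
        if rel_mask.any():
            fix_durs[rel_mask] = _trunc_rvs(
                fix_loc_relevant, fix_sd, lo_f, hi_f, int(rel_mask.sum()), rng
            )

    if start_with_saccade:
        durs = np.empty(2 * n_est)
        durs[0::2] = sacc_durs
        durs[1::2] = fix_durs
    else:
        # instruction-style: fixation first, then saccade, ...
        durs = np.empty(2 * n_est)
        durs[0::2] = fix_durs
        durs[1::2] = sacc_durs
    offsets = np.cumsum(durs)
    n_keep = int(np.searchsorted(offsets, duration_ms, side="right"))
    if n_keep == 0:
        n_keep = 1  # degenerate, extremely short phase: keep one event
    onsets = np.concatenate(([0.0], offsets[:-1]))[:n_keep]
    offsets = offsets[:n_keep]
    durs = durs[:n_keep]

    all_az, all_el = vec_to_ang(pts)
    gc_amps = great_circle_deg(pts[:-1], pts[1:])
    i = np.arange(n_keep)
    pair = i // 2
    is_sacc = (i % 2 == 0) if start_with_saccade else (i % 2 == 1)
    fix_pos = pair + (1 if start_with_saccade else 0)
    start_idx = np.where(is_sacc, pair, fix_pos)
    end_idx = np.where(is_sacc, pair + 1, fix_pos)
    obj_col = np.full(n_keep, None, dtype=object)
    rel_col = np.full(n_keep, None, dtype=object)
    fix_rows = ~is_sacc
    fix_src = fix_pos[fix_rows] - 1
    usable = fix_src >= 0
    obj_col[np.flatnonzero(fix_rows)[usable]] = obj_ids[fix_src[usable]]
    rel_col[np.flatnonzero(fix_rows)[usable]] = relevances[fix_src[usable]]
    records = {
        "kind": np.where(is_sacc, "saccade", "fixation").astype(object),
        "onset_ms": onsets,
        "offset_ms": offsets,
        "duration_ms": durs,
        "start_az_deg": all_az[start_idx],
        "start_el_deg": all_el[start_idx],
        "end_az_deg": all_az[end_idx],
        "end_el_deg": all_el[end_idx],
        "amplitude_deg": np.where(is_sacc, gc_amps[pair], 0.0),
        "peak_accel_deg_s2": np.where(is_sacc, _peak_accel(amps[pair], durs), 0.0),
        "object_id": obj_col,
        "relevance": rel_col,
    }
    last_vec_idx = (n_keep + 1) // 2 if start_with_saccade else n_keep // 2
    return records, pts[min(last_vec_idx, len(pts) - 1)]


def _instruction_events(rng, duration_ms: float, scene: SceneSpec):
    """Instruction-phase events: long fixations parked at the speaker
    with small re-fixation saccades around it."""
    speaker = ang_to_vec(_SPEAKER_AZ, _SPEAKER_EL)
    lo_f, hi_f = _FILT.fixation_dur_ms
    n_est = int(duration_ms / 450.0) + 6
    fix_durs = _trunc_rvs(480.0, 150.0, lo_f, hi_f, n_est, rng)
    amps = rng.uniform(0.3, 1.5, n_est)
    sacc_durs = 21.0 + MAIN_SEQUENCE_MS_PER_DEG * amps + rng.normal(0.0, 2.0, n_est)
    sacc_durs = np.clip(sacc_durs, 14.0, 60.0)

    # jittered positions around the speaker
    az = _SPEAKER_AZ + rng.normal(0.0, 0.8, n_est + 1)
    el = _SPEAKER_EL + rng.normal(0.0, 0.8, n_est + 1)
    pts = ang_to_vec(az, el)
    pts[0] = speaker

    durs = np.empty(2 * n_est)
    durs[0::2] = fix_durs
    durs[1::2] = sacc_durs
    offsets = np.cumsum(durs)
    n_keep = int(np.searchsorted(offsets, duration_ms, side="right"))
    # end the instruction on a fixation so the phase hand-off is a saccade
    if n_keep % 2 == 0 and n_keep > 0:
        n_keep -= 1
    if n_keep <= 0:
        return None, speaker
    onsets = np.concatenate(([0.0], offsets[:-1]))[:n_keep]
    durs = durs[:n_keep]
    all_az, all_el = vec_to_ang(pts)
    gc_amps = great_circle_deg(pts[:-1], pts[1:])
    i = np.arange(n_keep)
    pair = i // 2
    is_sacc = i % 2 == 1
    end_idx = np.where(is_sacc, pair + 1, pair)
    amplitude = np.where(is_sacc, gc_amps[np.minimum(pair, len(gc_amps) - 1)], 0.0)
    rows = {
        "kind": np.where(is_sacc, "saccade", "fixation").astype(object),
        "onset_ms": onsets,
        "offset_ms": offsets[:n_keep],
        "duration_ms": durs,
        "start_az_deg": all_az[pair],
        "start_el_deg": all_el[pair],
        "end_az_deg": all_az[end_idx],
        "end_el_deg": all_el[end_idx],
        "amplitude_deg": amplitude,
        "peak_accel_deg_s2": np.where(is_sacc, _peak_accel(amplitude, durs), 0.0),
        "object_id": np.full(n_keep, None, dtype=object),
        "relevance": np.full(n_keep, None, dtype=object),
    }
    last_fix = (n_keep - 1) // 2
    return rows, pts[last_fix]


def simulate_participant(
    group_params: GroupParams,
    cohort_spec: CohortSpec,
    scene: SceneSpec,
    participant_seed: int,
    participant: str = "p000",
    group: str = "control",
    mean_overrides: dict | None = None,
    render: bool = True,
    head_profile=None,
    noise_sd_deg: float = 0.1,
):
    """Simulate one participant's full session.

    Returns (samples, events, performance): a gaze-sample table (or
    None when ``render`` is False), the ground-truth event ledger, and
    the 5-vector of task-performance measures.

    ``mean_overrides`` may pin the participant-level targets
    (fixation_mean_ms, saccade_dur_mean_ms, saccade_amp_mean_deg,
    performance); without it they are drawn from the group's
    between-participant distributions.
    """
    ss = np.random.SeedSequence(participant_seed)
    children = ss.spawn(cohort_spec.n_scenarios + 2)
    rng0 = np.random.default_rng(children[0])

    ov = mean_overrides or {}
    fix_mean = ov.get(
        "fixation_mean_ms",
        group_params.fixation_mean_ms
        + group_params.fixation_between_sd_ms * rng0.standard_normal(),
    )
    dur_mean = ov.get(
        "saccade_dur_mean_ms",
        group_params.saccade_dur_mean_ms
        + group_params.saccade_dur_between_sd_ms * rng0.standard_normal(),
    )
    amp_mean = ov.get(
        "saccade_amp_mean_deg",
        group_params.saccade_amp_mean_deg
        + group_params.saccade_amp_between_sd_deg * rng0.standard_normal(),
    )
    lo_f, hi_f = _FILT.fixation_dur_ms
    lo_s, hi_s = _FILT.saccade_dur_ms
    if not (lo_f < fix_mean < hi_f and lo_s < dur_mean < hi_s):
        raise ValueError(
            f"participant mean outside the admissible filter window "
            f"(fixation {fix_mean:.1f} ms, saccade {dur_mean:.1f} ms)"
        )
    if not amp_mean > _FILT.saccade_min_amp_deg:
        raise ValueError(f"participant amplitude mean {amp_mean:.2f} deg below minimum")

    if "performance" in ov:
        perf = np.asarray(ov["performance"], dtype=float)
    else:
        perf = np.array(group_params.performance_means) + np.array(
            group_params.performance_sds
        ) * rng0.standard_normal(5)
    perf = np.array(
        [
            np.clip(v, lo if lo is not None else -np.inf, hi if hi is not None else np.inf)
            for v, (lo, hi) in zip(perf, _PERFORMANCE_CLIPS)
        ]
    )

    fix_sd = group_params.fixation_within_sd_ms
    amp_sd = group_params.saccade_amp_within_sd_deg
    dur_sd = group_params.saccade_dur_within_sd_ms
    fix_loc = calibrate_truncated_mean(fix_mean, fix_sd, lo_f, hi_f)
    amp_loc = calibrate_truncated_mean(
        amp_mean, amp_sd, _FILT.saccade_min_amp_deg, AMP_UPPER_DEG
    )
    offset = group_params.relevant_fixation_offset_ms
    if offset != 0.0:
        fix_loc_rel = calibrate_truncated_mean(fix_mean + offset, fix_sd, lo_f, hi_f)
    else:
        fix_loc_rel = fix_loc
    dur_intercept = dur_mean - MAIN_SEQUENCE_MS_PER_DEG * amp_mean

    exec_ms = cohort_spec.scenario_duration_s * 1000.0
    instr_ms = cohort_spec.instruction_duration_s * 1000.0

    chunks: dict[str, list] = {}
    sample_frames = []
    for s in range(cohort_spec.n_scenarios):
        rng = np.random.default_rng(children[s + 1])
        if instr_ms > 0:
            instr_rows, start_vec = _instruction_events(rng, instr_ms, scene)
        else:
            instr_rows, start_vec = None, ang_to_vec(_SPEAKER_AZ, _SPEAKER_EL)
        t_exec0 = 0.0
        scen_parts = []
        if instr_rows is not None:
            n_i = len(instr_rows["onset_ms"])
            instr_rows["phase"] = np.full(n_i, "instruction", dtype=object)
            t_exec0 = float(instr_rows["offset_ms"][-1])
            scen_parts.append(instr_rows)
        exec_rows, _ = _scenario_events(
            rng,
            exec_ms,
            start_vec,
            fix_loc,
            fix_loc_rel,
            fix_sd,
            amp_loc,
            amp_sd,
            dur_intercept,
            dur_sd,
            scene,
            start_with_saccade=True,
        )
        n_e = len(exec_rows["onset_ms"])
        exec_rows["phase"] = np.full(n_e, "execution", dtype=object)
        exec_rows["onset_ms"] = exec_rows["onset_ms"] + t_exec0
        exec_rows["offset_ms"] = exec_rows["offset_ms"] + t_exec0
        scen_parts.append(exec_rows)
        n_scen = sum(len(part["onset_ms"]) for part in scen_parts)
        for part in scen_parts:
            for key, arr in part.items():
                chunks.setdefault(key, []).append(np.asarray(arr))
        chunks.setdefault("scenario", []).append(np.full(n_scen, s))

        if render:
            scen_df = pd.DataFrame(
                {key: np.concatenate(chunks[key][-len(scen_parts):]) for key in scen_parts[0]}
            )
            profile = head_profile if head_profile is not None else SinusoidalYawHead()
            samples = render_gaze_trace(
                scen_df,
                cohort_spec.sampling_rate_hz,
                noise_sd_deg,
                profile,
                seed=children[s + 1].spawn(1)[0],
            )
            samples["scenario"] = s
            sample_frames.append(samples)

    events = pd.DataFrame(
        {key: np.concatenate(arrs) for key, arrs in chunks.items()}
    )
    events["participant"] = participant
    events["group"] = group
    events = events[EVENT_COLUMNS]

    samples = None
    if render:
        samples = pd.concat(sample_frames, ignore_index=True)
        samples["participant"] = participant
        samples["group"] = group
        samples = inject_data_loss(
            samples,
            group_params.invalid_rate,
            mean_burst_len=5,
            seed=np.random.default_rng(children[-1]).integers(2**31),
        )
        samples = samples[GAZE_COLUMNS]
    return samples, events, perf


def simulate_cohort(
    spec: CohortSpec,
    scene: SceneSpec | None = None,
    render: bool = False,
    head_profile=None,
    noise_sd_deg: float = 0.1,
) -> CohortData:
    """Simulate the full two-group study.

    Participant-level targets are standardized within each group so the
    realized cohort mean and SD of participant means equal the group
    parameters exactly (see module docstring). With ``render=False``
    only the ground-truth ledger and performance table are produced.
    """
    scene = scene or make_scene(seed=spec.seed)
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(2 * len(spec.n_per_group))

    all_samples = []
    all_events = []
    perf_rows = []
    for gi, (glabel, n) in enumerate(sorted(spec.n_per_group.items())):
        gp = spec.group_params[glabel]
        grng = np.random.default_rng(children[2 * gi])
        lo_f, hi_f = _FILT.fixation_dur_ms
        lo_s, hi_s = _FILT.saccade_dur_ms
        z_fix = _bounded_standardized(
            n, grng, gp.fixation_mean_ms, gp.fixation_between_sd_ms, lo_f + 10, hi_f - 10
        )
        z_dur = _bounded_standardized(
            n, grng, gp.saccade_dur_mean_ms, gp.saccade_dur_between_sd_ms, lo_s + 2, hi_s - 2
        )
        z_amp = _bounded_standardized(
            n,
            grng,
            gp.saccade_amp_mean_deg,
            gp.saccade_amp_between_sd_deg,
            _FILT.saccade_min_amp_deg + 0.05,
            AMP_UPPER_DEG - 1.0,
        )
        z_perf = np.column_stack([_standardized(n, grng) for _ in range(5)])
        pseeds = [
            int(s.generate_state(1)[0] % (2**31))
            for s in children[2 * gi + 1].spawn(n)
        ]
        for i in range(n):
            label = f"{glabel}_{i:03d}"
            overrides = {
                "fixation_mean_ms": gp.fixation_mean_ms
                + gp.fixation_between_sd_ms * z_fix[i],
                "saccade_dur_mean_ms": gp.saccade_dur_mean_ms
                + gp.saccade_dur_between_sd_ms * z_dur[i],
                "saccade_amp_mean_deg": gp.saccade_amp_mean_deg
                + gp.saccade_amp_between_sd_deg * z_amp[i],
                "performance": np.array(gp.performance_means)
                + np.array(gp.performance_sds) * z_perf[i],
            }
            samples, events, perf = simulate_participant(
                gp,
                spec,
                scene,
                pseeds[i],
                participant=label,
                group=glabel,
                mean_overrides=overrides,
                render=render,
                head_profile=head_profile,
                noise_sd_deg=noise_sd_deg,
            )
            all_events.append(events)
            if samples is not None:
                all_samples.append(samples)
            perf_rows.append(
                {"participant": label, "group": glabel}
                | dict(zip(PERFORMANCE_MEASURES, perf))
            )
    events = pd.concat(all_events, ignore_index=True)
    samples = pd.concat(all_samples, ignore_index=True) if all_samples else None
    performance = pd.DataFrame(perf_rows)
    return CohortData(samples, events, performance, scene, spec)


# ---------------------------------------------------------------------------
# rendering and data loss


def render_gaze_trace(
    events: pd.DataFrame,
    rate_hz: float,
    noise_sd_deg: float = 0.0,
    head_profile=None,
    seed=None,
) -> pd.DataFrame:
    """Render one scenario's event ledger to a head-frame gaze stream.

    Fixations render as a stationary world direction plus isotropic
    angular noise; saccades as raised-cosine (smooth, monotone)
    great-circle interpolation between their endpoints. The world
    direction is then re-expressed in the head frame using the head
    profile's orientation at each sample, so downstream head
    compensation is genuinely exercised. Sample count is
    floor(total duration x rate).
    """
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    ev = events.sort_values("onset_ms").reset_index(drop=True)
    onsets = ev["onset_ms"].to_numpy(dtype=float)
    offsets = ev["offset_ms"].to_numpy(dtype=float)
    if np.any(onsets[1:] < offsets[:-1] - 1e-6):
        raise ValueError("overlapping events cannot be rendered")
    p0 = ang_to_vec(ev["start_az_deg"].to_numpy(float), ev["start_el_deg"].to_numpy(float))
    p1 = ang_to_vec(ev["end_az_deg"].to_numpy(float), ev["end_el_deg"].to_numpy(float))

    t0 = onsets[0]
    total = offsets[-1] - t0
    n = int(math.floor(total * rate_hz / 1000.0))
    t = t0 + np.arange(n) * (1000.0 / rate_hz)

    idx = np.searchsorted(onsets, t, side="right") - 1
    idx = np.clip(idx, 0, len(ev) - 1)
    u = (t - onsets[idx]) / np.maximum(offsets[idx] - onsets[idx], 1e-9)
    u = np.clip(u, 0.0, 1.0)
    prog = 0.5 * (1.0 - np.cos(math.pi * u))
    is_fix = (ev["kind"].to_numpy() == "fixation")[idx]
    prog[is_fix] = 0.0
    world = slerp_vec(p0[idx], p1[idx], prog)

    rng = np.random.default_rng(seed)
    world = tangent_noise(world, noise_sd_deg, rng)

    phase = ev["phase"].to_numpy() if "phase" in ev.columns else np.array(["execution"] * len(ev))
    sample_phase = phase[idx]
    exec_onsets = onsets[phase == "execution"]
    exec_start = float(exec_onsets.min()) if len(exec_onsets) else float(t0)

    profile = head_profile if head_profile is not None else StaticHead()
    q = profile.quaternions(t, exec_start)
    gaze_head = quat_rotate_inv(q, world)

    out = pd.DataFrame(
        {
            "t_ms": t,
            "gx": gaze_head[:, 0],
            "gy": gaze_head[:, 1],
            "gz": gaze_head[:, 2],
            "qw": q[:, 0],
            "qx": q[:, 1],
            "qy": q[:, 2],
            "qz": q[:, 3],
            "valid": True,
            "phase": sample_phase,
        }
    )
    for col in ("participant", "group", "scenario"):
        if col in ev.columns:
            out[col] = ev[col].iloc[0]
    return out


def inject_data_loss(
    samples: pd.DataFrame, invalid_rate: float, mean_burst_len: int = 5, seed=None
) -> pd.DataFrame:
    """Clear validity flags in geometrically distributed bursts.

    Burst lengths are geometric with mean ``mean_burst_len``; valid runs
    geometric with the mean implied by ``invalid_rate``, so the
    long-run invalid fraction converges to ``invalid_rate``.
    """
    if not 0.0 <= invalid_rate < 1.0:
        raise ValueError("invalid_rate must be in [0, 1)")
    out = samples.copy()
    if invalid_rate == 0.0 or len(samples) == 0:
        return out
    rng = np.random.default_rng(seed)
    n = len(samples)
    mean_valid_run = mean_burst_len * (1.0 - invalid_rate) / invalid_rate
    p_valid = min(1.0, 1.0 / max(mean_valid_run, 1e-9))
    p_burst = 1.0 / mean_burst_len
    valid = out["valid"].to_numpy(bool).copy()
    pos = int(rng.geometric(p_valid))
    while pos < n:
        burst = int(rng.geometric(p_burst))
        valid[pos : pos + burst] = False
        pos += burst + int(rng.geometric(p_valid))
    out["valid"] = valid
    return out
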