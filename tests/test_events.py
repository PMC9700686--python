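"""Detector tests: head compensation, velocities, thresholds, filters."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from vrgaze._geometry import ang_to_vec, great_circle_deg, vec_to_ang
from vrgaze.events import (
    DegenerateVelocityError,
    DetectionParams,
    FilterParams,
    adaptive_threshold,
    detect_events,
    ek_velocity,
    filter_events,
    min_saccade_duration_ms,
    to_world_angles,
)
from vrgaze.simulate import StaticHead, render_gaze_trace


def _samples_from_world(az, el, quat_wxyz=None, rate=90.0, valid=None):
    """Build a gaze-sample table whose world angles are az/el under the
    given head orientation (default identity)."""
    az = np.asarray(az, dtype=float)
    n = len(az)
    t = np.arange(n) * 1000.0 / rate
    if quat_wxyz is None:
        quat_wxyz = np.tile([1.0, 0.0, 0.0, 0.0], (n, 1))
    quat_wxyz = np.asarray(quat_wxyz, dtype=float)
    world = ang_to_vec(az, el)
    rot = Rotation.from_quat(np.roll(quat_wxyz, -1, axis=-1)).inv()
    gaze_head = rot.apply(world)
    return pd.DataFrame(
        {
            "t_ms": t,
            "gx": gaze_head[:, 0],
            "gy": gaze_head[:, 1],
            "gz": gaze_head[:, 2],
            "qw": quat_wxyz[:, 0],
            "qx": quat_wxyz[:, 1],
            "qy": quat_wxyz[:, 2],
            "qz": quat_wxyz[:, 3],
            "valid": True if valid is None else valid,
            "participant": "p0",
            "group": "control",
            "scenario": 0,
            "phase": "execution",
        }
    )


# ---------------------------------------------------------------------------
# analytic minimum saccade duration


@pytest.mark.parametrize("rate,expected", [(90.0, 22.0), (1000.0, 2.0), (120.0, 16.0)])
def test_min_saccade_duration(rate, expected):
    assert min_saccade_duration_ms(rate) == expected


def test_min_saccade_duration_rejects_bad_rate():
    with pytest.raises(ValueError):
        min_saccade_duration_ms(0.0)


# ---------------------------------------------------------------------------
# head compensation


def test_identity_quaternion_world_equals_head():
    az = np.linspace(-10, 10, 30)
    el = np.linspace(5, -5, 30)
    trace = to_world_angles(_samples_from_world(az, el))
    assert np.allclose(trace["az_deg"], az, atol=1e-9)
    assert np.allclose(trace["el_deg"], el, atol=1e-9)


def test_yaw90_straight_gaze_maps_to_azimuth_90():
    n = 10
    q = np.tile(
        [math.cos(math.radians(45)), 0.0, 0.0, math.sin(math.radians(45))], (n, 1)
    )
    samples = pd.DataFrame(
        {
            "t_ms": np.arange(n) * 11.0,
            "gx": 1.0,
            "gy": 0.0,
            "gz": 0.0,
            "qw": q[:, 0],
            "qx": q[:, 1],
            "qy": q[:, 2],
            "qz": q[:, 3],
            "valid": True,
        }
    )
    trace = to_world_angles(samples)
    assert np.allclose(trace["az_deg"], 90.0, atol=1e-9)
    assert np.allclose(trace["el_deg"], 0.0, atol=1e-9)


def test_head_mapping_is_an_isometry():
    """Angular distances between gaze directions survive the mapping."""
    rng = np.random.default_rng(3)
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    for _ in range(100):
        v = rng.standard_normal((2, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        az_in, el_in = vec_to_ang(v)
        samples = pd.DataFrame(
            {
                "t_ms": [0.0, 11.0],
                "gx": v[:, 0],
                "gy": v[:, 1],
                "gz": v[:, 2],
                "qw": q[0],
                "qx": q[1],
                "qy": q[2],
                "qz": q[3],
                "valid": True,
            }
        )
        trace = to_world_angles(samples)
        out = ang_to_vec(trace["az_deg"].to_numpy(), trace["el_deg"].to_numpy())
        assert great_circle_deg(out[0], out[1]) == pytest.approx(
            great_circle_deg(v[0], v[1]), abs=1e-9
        )


def test_gap_policy_interpolates_short_and_splits_long():
    az = np.zeros(40)
    valid = np.ones(40, dtype=bool)
    valid[10:12] = False  # 2-sample gap: interpolated
    valid[25:29] = False  # 4-sample gap: split
    samples = _samples_from_world(az, np.zeros(40), valid=valid)
    trace = to_world_angles(samples, gap_interpolation_max_samples=2)
    assert trace["valid"][10:12].all()  # filled
    assert not trace["valid"][25:29].any()
    segs = trace.loc[trace["segment_id"] >= 0, "segment_id"].unique()
    assert len(segs) == 2


def test_zero_norm_gaze_rejected():
    samples = _samples_from_world(np.zeros(5), np.zeros(5))
    samples.loc[2, ["gx", "gy", "gz"]] = 0.0
    with pytest.raises(ValueError, match="zero-norm"):
        to_world_angles(samples)


# ---------------------------------------------------------------------------
# velocity estimation


def _trace(az, el=None, rate=90.0):
    az = np.asarray(az, dtype=float)
    el = np.zeros_like(az) if el is None else np.asarray(el, dtype=float)
    return pd.DataFrame(
        {
            "t_ms": np.arange(len(az)) * 1000.0 / rate,
            "az_deg": az,
            "el_deg": el,
            "valid": True,
            "segment_id": 0,
        }
    )


def test_velocity_constant_position_is_zero():
    v = ek_velocity(_trace(np.full(50, 7.0)), window=5)
    assert np.allclose(v["v_az"], 0.0, atol=1e-12)
    assert np.allclose(v["v_el"], 0.0, atol=1e-12)


def test_velocity_linear_ramp_closed_form():
    # 1 deg per sample at 90 Hz -> 90 deg/s everywhere incl. edges
    v = ek_velocity(_trace(np.arange(60, dtype=float)), window=5)
    assert np.allclose(v["v_az"], 90.0, atol=1e-9)


def test_velocity_sine_matches_analytic_derivative():
    rate = 90.0
    t = np.arange(0, 900) / rate  # 10 s
    az = 2.0 * np.sin(2 * math.pi * 1.0 * t)
    v = ek_velocity(_trace(az, rate=rate), window=5)["v_az"].to_numpy()
    truth = 2.0 * 2 * math.pi * np.cos(2 * math.pi * t)  # deg/s
    core = slice(2, -2)
    rms_err = np.sqrt(np.mean((v[core] - truth[core]) ** 2))
    rms_sig = np.sqrt(np.mean(truth[core] ** 2))
    assert rms_err / rms_sig < 0.02


# ---------------------------------------------------------------------------
# adaptive thresholds


def test_threshold_symmetric_pattern_closed_form():
    v = np.tile([-1.0, 0.0, 1.0], 30)
    eta_az, eta_el = adaptive_threshold(v, v, lam=6.0)
    # median 0, median of squares 1 -> sigma = 1
    assert eta_az == pytest.approx(6.0)
    assert eta_el == pytest.approx(6.0)


def test_threshold_scale_equivariance():
    rng = np.random.default_rng(0)
    v = rng.normal(0, 5, 500)
    e1 = adaptive_threshold(v, v, lam=6.0)[0]
    e2 = adaptive_threshold(2 * v, 2 * v, lam=6.0)[0]
    assert e2 == pytest.approx(2 * e1, rel=1e-12)


def test_threshold_median_estimator_consistency():
    """The median-based spread of N(0, sigma) converges to ~0.6745 sigma."""
    rng = np.random.default_rng(12)
    v = rng.normal(0.0, 10.0, 8100)
    sigma = adaptive_threshold(v, v, lam=1.0)[0]
    # median(|v|) of a centered normal is 0.6745 sigma
    assert sigma == pytest.approx(10.0 * 0.67449, rel=0.05)


def test_threshold_degenerate_input_raises():
    with pytest.raises(DegenerateVelocityError):
        adaptive_threshold(np.ones(100), np.ones(100))


# ---------------------------------------------------------------------------
# detection


def _three_fixation_ledger(fix_ms=400.0, sacc_ms=44.0, step_deg=5.0):
    rows = []
    t = 0.0
    az = 0.0
    for i in range(3):
        rows.append(
            dict(
                kind="fixation",
                onset_ms=t,
                offset_ms=t + fix_ms,
                duration_ms=fix_ms,
                start_az_deg=az,
                start_el_deg=0.0,
                end_az_deg=az,
                end_el_deg=0.0,
                phase="execution",
            )
        )
        t += fix_ms
        if i < 2:
            rows.append(
                dict(
                    kind="saccade",
                    onset_ms=t,
                    offset_ms=t + sacc_ms,
                    duration_ms=sacc_ms,
                    start_az_deg=az,
                    start_el_deg=0.0,
                    end_az_deg=az + step_deg,
                    end_el_deg=0.0,
                    phase="execution",
                )
            )
            az += step_deg
            t += sacc_ms
    return pd.DataFrame(rows)


def _detect_from_ledger(ledger, noise=0.05, seed=2, params=None, head=None):
    samples = render_gaze_trace(
        ledger, 90.0, noise_sd_deg=noise, head_profile=head or StaticHead(), seed=seed
    )
    trace = to_world_angles(samples)
    return detect_events(trace, params or DetectionParams())


def test_detect_recovers_constructed_events():
    ledger = _three_fixation_ledger()
    events = _detect_from_ledger(ledger)
    sacc = events[events["kind"] == "saccade"]
    fix = events[events["kind"] == "fixation"]
    assert len(sacc) == 2
    assert len(fix) == 3
    dt = 1000.0 / 90.0
    true_onsets = ledger.loc[ledger["kind"] == "saccade", "onset_ms"].to_numpy()
    for got, want in zip(np.sort(sacc["onset_ms"].to_numpy()), true_onsets):
        assert abs(got - want) <= dt + 1e-9
    assert np.allclose(sacc["amplitude_deg"], 5.0, atol=0.3)


def test_detect_empty_trace():
    empty = pd.DataFrame(
        {"t_ms": [], "az_deg": [], "el_deg": [], "valid": [], "segment_id": []}
    )
    assert len(detect_events(empty)) == 0


def test_pure_fixation_yields_no_filtered_saccades():
    """10 s of fixation with 0.1 deg noise: nothing survives the 0.75 deg
    amplitude filter at lambda = 6."""
    ledger = pd.DataFrame(
        [
            dict(
                kind="fixation",
                onset_ms=0.0,
                offset_ms=10_000.0,
                duration_ms=10_000.0,
                start_az_deg=0.0,
                start_el_deg=0.0,
                end_az_deg=0.0,
                end_el_deg=0.0,
                phase="execution",
            )
        ]
    )
    events = _detect_from_ledger(ledger, noise=0.1, seed=4)
    filtered, _ = filter_events(events)
    assert (filtered["kind"] == "fixation").all()


def test_rotation_invariance_global_yaw():
    """A global head rotation leaves event durations and amplitudes
    unchanged (the sphere is rotated rigidly)."""
    ledger = _three_fixation_ledger()
    samples = render_gaze_trace(ledger, 90.0, noise_sd_deg=0.05, seed=8)
    events_base = detect_events(to_world_angles(samples))

    extra = Rotation.from_euler("z", 25.0, degrees=True)
    q_old = samples[["qw", "qx", "qy", "qz"]].to_numpy()
    q_new = (extra * Rotation.from_quat(np.roll(q_old, -1, axis=-1))).as_quat()
    rotated = samples.copy()
    rotated[["qw", "qx", "qy", "qz"]] = np.roll(q_new, 1, axis=-1)
    events_rot = detect_events(to_world_angles(rotated))

    assert len(events_base) == len(events_rot)
    assert np.allclose(events_base["duration_ms"], events_rot["duration_ms"], atol=1e-9)
    assert np.allclose(
        events_base["amplitude_deg"], events_rot["amplitude_deg"], atol=1e-6
    )


def test_rotation_invariance_general_rotation():
    ledger = _three_fixation_ledger()
    samples = render_gaze_trace(ledger, 90.0, noise_sd_deg=0.05, seed=8)
    events_base = detect_events(to_world_angles(samples))

    extra = Rotation.from_euler("xz", [8.0, -40.0], degrees=True)
    q_old = samples[["qw", "qx", "qy", "qz"]].to_numpy()
    q_new = (extra * Rotation.from_quat(np.roll(q_old, -1, axis=-1))).as_quat()
    rotated = samples.copy()
    rotated[["qw", "qx", "qy", "qz"]] = np.roll(q_new, 1, axis=-1)
    events_rot = detect_events(to_world_angles(rotated))

    assert len(events_base) == len(events_rot)
    dt = 1000.0 / 90.0
    assert np.max(np.abs(
        events_base["duration_ms"].to_numpy() - events_rot["duration_ms"].to_numpy()
    )) <= dt + 1e-9
    sacc_b = events_base[events_base["kind"] == "saccade"]["amplitude_deg"].to_numpy()
    sacc_r = events_rot[events_rot["kind"] == "saccade"]["amplitude_deg"].to_numpy()
    assert np.allclose(sacc_b, sacc_r, rtol=0.05, atol=0.1)


def test_threshold_unit_scale_gives_identical_segmentation():
    """Criterion masks agree whether velocities are in deg/s or rad/s."""
    rng = np.random.default_rng(5)
    v_az = rng.normal(0, 3, 2000)
    v_el = rng.normal(0, 3, 2000)
    v_az[500:505] += 120.0
    eta_deg = adaptive_threshold(v_az, v_el, lam=6.0)
    k = math.pi / 180.0
    eta_rad = adaptive_threshold(v_az * k, v_el * k, lam=6.0)
    mask_deg = (v_az / eta_deg[0]) ** 2 + (v_el / eta_deg[1]) ** 2 > 1
    mask_rad = (v_az * k / eta_rad[0]) ** 2 + (v_el * k / eta_rad[1]) ** 2 > 1
    assert np.array_equal(mask_deg, mask_rad)


# ---------------------------------------------------------------------------
# plausibility filters


def _event(kind, dur, amp=5.0, accel=1000.0):
    return dict(
        kind=kind,
        onset_ms=0.0,
        offset_ms=dur,
        duration_ms=dur,
        start_az_deg=0.0,
        start_el_deg=0.0,
        end_az_deg=amp,
        end_el_deg=0.0,
        amplitude_deg=amp,
        peak_accel_deg_s2=accel,
        object_id=None,
        relevance=None,
        participant="p",
        group="g",
        scenario=0,
        phase="execution",
    )


@pytest.mark.parametrize(
    "event,kept",
    [
        (_event("saccade", 10.0, amp=5.0), False),  # below 22 ms
        (_event("saccade", 50.0, amp=0.5), False),  # below 0.75 deg
        (_event("saccade", 350.0), False),  # above 300 ms
        (_event("saccade", 50.0, accel=40_000.0), False),  # above 36,000 deg/s^2
        (_event("saccade", 50.0), True),
        (_event("fixation", 1500.0), False),  # outside 100-1000 ms
        (_event("fixation", 50.0), False),
        (_event("fixation", 500.0), True),
    ],
)
def test_filter_rules(event, kept):
    out, _ = filter_events(pd.DataFrame([event]))
    assert (len(out) == 1) == kept


def test_filter_idempotent_and_counts():
    events = pd.DataFrame(
        [
            _event("saccade", 10.0),
            _event("saccade", 50.0, amp=0.5),
            _event("saccade", 50.0),
            _event("fixation", 500.0),
            _event("fixation", 1500.0),
        ]
    )
    once, counts = filter_events(events)
    twice, counts2 = filter_events(once)
    assert once.equals(twice)
    assert counts == {
        "saccade_too_short": 1,
        "saccade_too_long": 0,
        "saccade_amplitude": 1,
        "saccade_acceleration": 0,
        "fixation_duration": 1,
    }
    assert sum(counts2.values()) == 0


def test_filter_params_validation():
    with pytest.raises(ValueError):
        FilterParams(saccade_dur_ms=(300.0, 22.0))
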