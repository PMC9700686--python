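"""Generator tests: calibration, determinism, rendering, data loss."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from vrgaze._geometry import ang_to_vec, great_circle_deg
from vrgaze.events import FilterParams, filter_events, to_world_angles
from vrgaze.features import participant_weighted_means
from vrgaze.simulate import (
    ADHD_PARAMS,
    CONTROL_PARAMS,
    CohortSpec,
    SinusoidalYawHead,
    StaticHead,
    calibrate_truncated_mean,
    inject_data_loss,
    make_saliency_map,
    render_gaze_trace,
    simulate_cohort,
    simulate_participant,
)


# ---------------------------------------------------------------------------
# truncated-mean calibration


def test_calibrate_symmetric_truncation_is_identity():
    # bounds symmetric around the target: no shift needed
    assert calibrate_truncated_mean(550.0, 50.0, 100.0, 1000.0) == pytest.approx(550.0)


def test_calibrate_degenerate_sd():
    assert calibrate_truncated_mean(317.0, 1e-6, 100.0, 1000.0) == pytest.approx(317.0)


def test_calibrate_matches_quadrature_oracle():
    """Quadrature over the truncated density recovers the target mean."""
    loc = calibrate_truncated_mean(317.0, 100.0, 100.0, 1000.0)
    assert loc < 317.0  # lower bound is closer: location shifts down

    def density(x):
        return stats.norm.pdf(x, loc=loc, scale=100.0)

    z, _ = integrate.quad(density, 100.0, 1000.0)
    m, _ = integrate.quad(lambda x: x * density(x), 100.0, 1000.0)
    assert m / z == pytest.approx(317.0, abs=0.3)


def test_calibrate_rejects_target_outside_bounds():
    with pytest.raises(ValueError):
        calibrate_truncated_mean(50.0, 10.0, 100.0, 1000.0)


# ---------------------------------------------------------------------------
# participant simulation


def _tiny_spec(**kw):
    defaults = dict(
        n_per_group={"ADHD": 1, "control": 1},
        n_scenarios=2,
        scenario_duration_s=15.0,
        instruction_duration_s=3.0,
        seed=0,
    )
    defaults.update(kw)
    return CohortSpec(**defaults)


def test_participant_determinism(scene):
    spec = _tiny_spec()
    out1 = simulate_participant(ADHD_PARAMS, spec, scene, 123, render=True)
    out2 = simulate_participant(ADHD_PARAMS, spec, scene, 123, render=True)
    assert out1[0].equals(out2[0])
    assert out1[1].equals(out2[1])
    assert np.array_equal(out1[2], out2[2])


def test_zero_invalid_rate_keeps_all_samples(scene):
    params = dataclasses.replace(ADHD_PARAMS, invalid_rate=0.0)
    samples, _, _ = simulate_participant(params, _tiny_spec(), scene, 7, render=True)
    assert samples["valid"].all()


def test_participant_mean_outside_window_rejected(scene):
    with pytest.raises(ValueError, match="filter window"):
        simulate_participant(
            ADHD_PARAMS,
            _tiny_spec(),
            scene,
            7,
            mean_overrides={"fixation_mean_ms": 60.0},
            render=False,
        )


def test_ground_truth_ledger_invariants(small_cohort):
    ev = small_cohort.events
    for (_, _), chunk in ev.groupby(["participant", "scenario"]):
        kinds = chunk["kind"].to_numpy()
        assert all(kinds[i] != kinds[i + 1] for i in range(len(kinds) - 1))
        assert (chunk["offset_ms"].to_numpy() > chunk["onset_ms"].to_numpy()).all()
        # non-overlap: next onset not before current offset
        assert (
            chunk["onset_ms"].to_numpy()[1:] >= chunk["offset_ms"].to_numpy()[:-1] - 1e-9
        ).all()
    sacc = ev[ev["kind"] == "saccade"]
    gc = great_circle_deg(
        ang_to_vec(sacc["start_az_deg"], sacc["start_el_deg"]),
        ang_to_vec(sacc["end_az_deg"], sacc["end_el_deg"]),
    )
    assert np.max(np.abs(gc - sacc["amplitude_deg"].to_numpy())) < 1e-6


def test_small_cohort_calibration(small_cohort):
    """Post-filter ground-truth grand means track the group targets."""
    ev = small_cohort.events
    filt, _ = filter_events(ev[ev["phase"] == "execution"], FilterParams())
    gm = participant_weighted_means(filt)
    for group, params in (("ADHD", ADHD_PARAMS), ("control", CONTROL_PARAMS)):
        assert gm.loc[group, "mean_fix_dur_ms"] == pytest.approx(
            params.fixation_mean_ms, rel=0.02
        )
        assert gm.loc[group, "mean_sacc_dur_ms"] == pytest.approx(
            params.saccade_dur_mean_ms, rel=0.02
        )
        assert gm.loc[group, "mean_sacc_amp_deg"] == pytest.approx(
            params.saccade_amp_mean_deg, rel=0.02
        )


def test_group_params_validation():
    with pytest.raises(ValueError):
        dataclasses.replace(ADHD_PARAMS, invalid_rate=0.5)
    with pytest.raises(ValueError):
        dataclasses.replace(ADHD_PARAMS, fixation_mean_ms=50.0)
    with pytest.raises(ValueError):
        dataclasses.replace(ADHD_PARAMS, saccade_amp_mean_deg=0.5)


def test_cohort_spec_validation():
    with pytest.raises(ValueError, match="group labels"):
        CohortSpec(n_per_group={"cases": 3, "control": 3})
    with pytest.raises(ValueError):
        CohortSpec(n_scenarios=0)


# ---------------------------------------------------------------------------
# rendering


def _single_fixation_events(duration_ms=500.0, az=3.0, el=-2.0):
    return pd.DataFrame(
        [
            {
                "kind": "fixation",
                "onset_ms": 0.0,
                "offset_ms": duration_ms,
                "duration_ms": duration_ms,
                "start_az_deg": az,
                "start_el_deg": el,
                "end_az_deg": az,
                "end_el_deg": el,
                "amplitude_deg": 0.0,
                "peak_accel_deg_s2": 0.0,
                "phase": "execution",
            }
        ]
    )


def test_render_sample_count_and_noise_radius():
    ev = _single_fixation_events(500.0)
    samples = render_gaze_trace(ev, 90.0, noise_sd_deg=0.2, seed=1)
    assert len(samples) == 45  # floor(0.5 s * 90 Hz)
    target = ang_to_vec(3.0, -2.0)
    world = samples[["gx", "gy", "gz"]].to_numpy()  # static head: world frame
    assert np.max(great_circle_deg(world, target)) < 4 * 0.2


def test_render_noiseless_identity_roundtrip(small_cohort):
    one = small_cohort.events.query("participant == 'ADHD_000' and scenario == 0")
    samples = render_gaze_trace(one, 90.0, noise_sd_deg=0.0, head_profile=StaticHead())
    samples["participant"], samples["scenario"] = "p", 0
    trace = to_world_angles(samples)
    # every sample direction must coincide with the ledger's trajectory
    onsets = one["onset_ms"].to_numpy()
    idx = np.searchsorted(onsets, trace["t_ms"].to_numpy(), side="right") - 1
    fix = one["kind"].to_numpy()[idx] == "fixation"
    expected = ang_to_vec(
        one["start_az_deg"].to_numpy()[idx], one["start_el_deg"].to_numpy()[idx]
    )
    got = ang_to_vec(trace["az_deg"].to_numpy(), trace["el_deg"].to_numpy())
    assert np.max(great_circle_deg(got[fix], expected[fix])) < 1e-9


def test_render_head_compensation_roundtrip(small_cohort):
    """A moving head changes head-frame gaze but not recovered world gaze."""
    one = small_cohort.events.query("participant == 'control_000' and scenario == 1")
    moving = render_gaze_trace(
        one, 90.0, noise_sd_deg=0.0, head_profile=SinusoidalYawHead(20.0, 0.1)
    )
    static = render_gaze_trace(one, 90.0, noise_sd_deg=0.0, head_profile=StaticHead())
    assert not np.allclose(
        moving[["gx", "gy", "gz"]].to_numpy(), static[["gx", "gy", "gz"]].to_numpy()
    )
    for df in (moving, static):
        df["participant"], df["scenario"] = "p", 0
    t_m = to_world_angles(moving)
    t_s = to_world_angles(static)
    got = ang_to_vec(t_m["az_deg"], t_m["el_deg"])
    want = ang_to_vec(t_s["az_deg"], t_s["el_deg"])
    assert np.max(great_circle_deg(got, want)) < 1e-6


def test_render_saccade_peak_speed_exceeds_mean():
    """Raised-cosine kinematics: peak speed ~ pi/2 times the mean speed."""
    ev = pd.DataFrame(
        [
            {
                "kind": "fixation",
                "onset_ms": 0.0,
                "offset_ms": 200.0,
                "duration_ms": 200.0,
                "start_az_deg": 0.0,
                "start_el_deg": 0.0,
                "end_az_deg": 0.0,
                "end_el_deg": 0.0,
                "phase": "execution",
            },
            {
                "kind": "saccade",
                "onset_ms": 200.0,
                "offset_ms": 244.0,
                "duration_ms": 44.0,
                "start_az_deg": 0.0,
                "start_el_deg": 0.0,
                "end_az_deg": 5.0,
                "end_el_deg": 0.0,
                "phase": "execution",
            },
            {
                "kind": "fixation",
                "onset_ms": 244.0,
                "offset_ms": 444.0,
                "duration_ms": 200.0,
                "start_az_deg": 5.0,
                "start_el_deg": 0.0,
                "end_az_deg": 5.0,
                "end_el_deg": 0.0,
                "phase": "execution",
            },
        ]
    )
    samples = render_gaze_trace(ev, 1000.0, noise_sd_deg=0.0)
    vecs = samples[["gx", "gy", "gz"]].to_numpy()
    step_deg = great_circle_deg(vecs[:-1], vecs[1:])
    speed = step_deg * 1000.0  # deg/s at 1 kHz
    mean_speed = 5.0 / 0.044  # ~114 deg/s
    assert speed.max() > mean_speed
    assert speed.max() == pytest.approx(mean_speed * np.pi / 2.0, rel=0.05)


def test_render_rejects_overlapping_events():
    ev = _single_fixation_events(500.0)
    bad = pd.concat([ev, ev.assign(onset_ms=300.0, offset_ms=800.0)], ignore_index=True)
    with pytest.raises(ValueError, match="overlap"):
        render_gaze_trace(bad, 90.0)


def test_ledger_matches_threshold_free_segmentation(small_cohort):
    """Event boundaries recomputed from a noiseless trace by motion
    segmentation coincide with the ledger within one sample interval."""
    one = small_cohort.events.query("participant == 'ADHD_001' and scenario == 2")
    rate = 90.0
    samples = render_gaze_trace(one, rate, noise_sd_deg=0.0, head_profile=StaticHead())
    vecs = samples[["gx", "gy", "gz"]].to_numpy()
    t = samples["t_ms"].to_numpy()
    moving = great_circle_deg(vecs[:-1], vecs[1:]) > 1e-9
    onsets_est = t[1:][np.flatnonzero(np.diff(moving.astype(int)) == 1) + 1]
    true_sacc_onsets = one.loc[one["kind"] == "saccade", "onset_ms"].to_numpy()
    dt = 1000.0 / rate
    matched = 0
    for onset in onsets_est:
        if np.min(np.abs(true_sacc_onsets - onset)) <= dt + 1e-9:
            matched += 1
    assert matched == len(onsets_est)
    # every true saccade long enough to span a sample interval is found
    spanning = (one["kind"] == "saccade") & (one["duration_ms"] > dt)
    assert len(onsets_est) >= 0.9 * spanning.sum()


# ---------------------------------------------------------------------------
# data loss


def test_inject_loss_zero_rate_unchanged(mini_rendered):
    samples = mini_rendered.samples.head(5000).copy()
    samples["valid"] = True
    out = inject_data_loss(samples, 0.0, seed=3)
    assert out["valid"].all()


@pytest.mark.parametrize("rate", [0.05, 0.16])
def test_inject_loss_realized_fraction(rate):
    n = 13 * 90 * 90  # thirteen 90-s scenarios at 90 Hz
    samples = pd.DataFrame({"valid": np.ones(n, dtype=bool)})
    out = inject_data_loss(samples, rate, mean_burst_len=5, seed=11)
    realized = 1.0 - out["valid"].mean()
    assert abs(realized - rate) < 0.01


def test_inject_loss_rejects_bad_rate():
    samples = pd.DataFrame({"valid": [True, True]})
    with pytest.raises(ValueError):
        inject_data_loss(samples, 1.5)


# ---------------------------------------------------------------------------
# saliency maps


def test_saliency_no_hotspots_constant():
    m = make_saliency_map((8, 16), hotspots=())
    assert np.ptp(m.values) == 0.0


def test_saliency_single_hotspot_argmax_at_position():
    m = make_saliency_map((32, 64), hotspots=[(10.0, 5.0, 4.0)])
    iy, ix = np.unravel_index(np.argmax(m.values), m.values.shape)
    az_c, el_c = m.cell_centers()
    d_az, d_el = m.cell_size
    assert abs(az_c[ix] - 10.0) <= d_az / 2 + 1e-9
    assert abs(el_c[iy] - 5.0) <= d_el / 2 + 1e-9


def test_saliency_two_equal_hotspots_match_gaussian_oracle():
    # positions chosen on cell centers (d_az = d_el = 1.5 deg)
    spots = [(-20.25, -9.75, 4.0), (24.75, 12.75, 4.0)]
    m = make_saliency_map((40, 80), hotspots=spots, base=0.0)
    az_c, el_c = m.cell_centers()
    az_g, el_g = np.meshgrid(az_c, el_c)
    oracle = np.zeros_like(m.values)
    for az0, el0, sd in spots:
        oracle += np.exp(-((az_g - az0) ** 2 + (el_g - el0) ** 2) / (2 * sd**2))
    assert np.allclose(m.values, oracle, atol=1e-12)
    peaks = [m.values[np.argmin(np.abs(el_c - el0)), np.argmin(np.abs(az_c - az0))]
             for az0, el0, _ in spots]
    assert abs(peaks[0] - peaks[1]) < 1e-9


def test_saliency_hotspot_outside_domain_rejected():
    with pytest.raises(ValueError, match="outside"):
        make_saliency_map((8, 16), hotspots=[(200.0, 0.0, 4.0)])


def test_cohort_determinism_by_seed():
    spec = CohortSpec(
        n_per_group={"ADHD": 2, "control": 2},
        n_scenarios=1,
        scenario_duration_s=10.0,
        instruction_duration_s=2.0,
        seed=5,
    )
    c1 = simulate_cohort(spec, render=False)
    c2 = simulate_cohort(spec, render=False)
    assert c1.events.equals(c2.events)
    assert c1.performance.equals(c2.performance)
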