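"""Readers and writers for the on-disk artifacts, plus run configuration.

All tabular formats are UTF-8 tab-separated text with a single header
line prefixed by ``#`` naming the columns. Saliency maps are plain-text
matrices preceded by a four-line angular-domain header. Everything is
diff-able and language-agnostic.
"""

from __future__ import annotations

import copy
import io
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SaliencyMap",
    "GazeParseError",
    "ConfigError",
    "GAZE_COLUMNS",
    "read_gaze",
    "write_gaze",
    "read_events",
    "write_events",
    "read_aoi",
    "write_aoi",
    "read_saliency_map",
    "write_saliency_map",
    "screen_participants",
    "load_config",
    "DEFAULT_CONFIG",
]

UNIT_TOL = 1e-6

GAZE_COLUMNS = [
    "t_ms",
    "gx",
    "gy",
    "gz",
    "qw",
    "qx",
    "qy",
    "qz",
    "valid",
    "participant",
    "group",
    "scenario",
    "phase",
]

AOI_COLUMNS = ["object_id", "az_min", "az_max", "el_min", "el_max", "relevance"]


class GazeParseError(ValueError):
    """A file violated the format contract; message names the line."""


class ConfigError(ValueError):
    """A run configuration had unknown keys or out-of-range values."""


# ---------------------------------------------------------------------------
# saliency maps


@dataclass
class SaliencyMap:
    """Dense salience over scene angular coordinates.

    ``values`` has shape (n_el, n_az); rows run from ``el_range[0]`` to
    ``el_range[1]``, columns from ``az_range[0]`` to ``az_range[1]``.
    Cells are cell-centered: the center of cell (i, j) is at
    el_range[0] + (i + 0.5) * d_el, az_range[0] + (j + 0.5) * d_az.
    """

    values: np.ndarray
    az_range_deg: tuple[float, float]
    el_range_deg: tuple[float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 2:
            raise ValueError("saliency map must be a 2-D grid of at least 2x2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("saliency map must be finite")

    @property
    def cell_size(self):
        n_el, n_az = self.values.shape
        d_az = (self.az_range_deg[1] - self.az_range_deg[0]) / n_az
        d_el = (self.el_range_deg[1] - self.el_range_deg[0]) / n_el
        return d_az, d_el

    def cell_centers(self):
        """(az_centers, el_centers) 1-D arrays."""
        n_el, n_az = self.values.shape
        d_az, d_el = self.cell_size
        az = self.az_range_deg[0] + (np.arange(n_az) + 0.5) * d_az
        el = self.el_range_deg[0] + (np.arange(n_el) + 0.5) * d_el
        return az, el

    def contains(self, az_deg, el_deg):
        az = np.asarray(az_deg, dtype=float)
        el = np.asarray(el_deg, dtype=float)
        return (
            (az >= self.az_range_deg[0])
            & (az <= self.az_range_deg[1])
            & (el >= self.el_range_deg[0])
            & (el <= self.el_range_deg[1])
        )

    def zscored(self) -> "SaliencyMap":
        sd = self.values.std()  # population SD
        scale = max(1.0, float(np.abs(self.values).max()))
        if sd <= 1e-12 * scale:
            raise ValueError("constant saliency map: z-scoring undefined")
        return SaliencyMap(
            (self.values - self.values.mean()) / sd, self.az_range_deg, self.el_range_deg
        )

    def interp(self, az_deg, el_deg):
        """Bilinear interpolation at angular positions (clamped to the
        outermost cell centers at the border)."""
        az = np.atleast_1d(np.asarray(az_deg, dtype=float))
        el = np.atleast_1d(np.asarray(el_deg, dtype=float))
        n_el, n_az = self.values.shape
        d_az, d_el = self.cell_size
        fx = (az - self.az_range_deg[0]) / d_az - 0.5
        fy = (el - self.el_range_deg[0]) / d_el - 0.5
        fx = np.clip(fx, 0.0, n_az - 1.0)
        fy = np.clip(fy, 0.0, n_el - 1.0)
        x0 = np.clip(np.floor(fx).astype(int), 0, n_az - 2)
        y0 = np.clip(np.floor(fy).astype(int), 0, n_el - 2)
        wx = fx - x0
        wy = fy - y0
        v = (
            self.values[y0, x0] * (1 - wx) * (1 - wy)
            + self.values[y0, x0 + 1] * wx * (1 - wy)
            + self.values[y0 + 1, x0] * (1 - wx) * wy
            + self.values[y0 + 1, x0 + 1] * wx * wy
        )
        return v


def write_saliency_map(path, salmap: SaliencyMap):
    n_el, n_az = salmap.values.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# az_range_deg\t{salmap.az_range_deg[0]:.12g}\t{salmap.az_range_deg[1]:.12g}\n")
        fh.write(f"# el_range_deg\t{salmap.el_range_deg[0]:.12g}\t{salmap.el_range_deg[1]:.12g}\n")
        fh.write("# registration\tcell-centered\n")
        fh.write(f"# shape\t{n_el}\t{n_az}\n")
        np.savetxt(fh, salmap.values, fmt="%.12g", delimiter="\t")


def read_saliency_map(path) -> SaliencyMap:
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    if len(lines) < 4:
        raise GazeParseError(f"{path}: truncated saliency map header")
    try:
        az = tuple(float(x) for x in lines[0].split("\t")[1:3])
        el = tuple(float(x) for x in lines[1].split("\t")[1:3])
        n_el, n_az = (int(x) for x in lines[3].split("\t")[1:3])
    except (ValueError, IndexError) as exc:
        raise GazeParseError(f"{path}: bad saliency header: {exc}") from exc
    values = np.loadtxt(io.StringIO("".join(lines[4:])), delimiter="\t", ndmin=2)
    if values.shape != (n_el, n_az):
        raise GazeParseError(
            f"{path}: shape header {(n_el, n_az)} does not match data {values.shape}"
        )
    return SaliencyMap(values, az, el)


# ---------------------------------------------------------------------------
# gaze samples


def write_gaze(path, samples: pd.DataFrame):
    _write_table(path, samples, GAZE_COLUMNS)


def read_gaze(path) -> pd.DataFrame:
    df = _read_table(path, GAZE_COLUMNS)
    df["valid"] = df["valid"].astype(bool) if df["valid"].dtype == bool else df[
        "valid"
    ].isin([True, "True", "true", 1, "1"])
    for col in ["t_ms", "gx", "gy", "gz", "qw", "qx", "qy", "qz"]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].isna()
        if bad.any():
            raise GazeParseError(
                f"{path}: non-numeric value in column {col} at line "
                f"{int(np.flatnonzero(bad)[0]) + 2}"
            )
    _validate_gaze(df, str(path))
    return df


def _validate_gaze(df: pd.DataFrame, origin: str):
    gnorm = np.linalg.norm(df[["gx", "gy", "gz"]].to_numpy(float), axis=1)
    qnorm = np.linalg.norm(df[["qw", "qx", "qy", "qz"]].to_numpy(float), axis=1)
    valid = df["valid"].to_numpy(bool)
    bad_g = valid & (np.abs(gnorm - 1.0) > UNIT_TOL)
    if bad_g.any():
        line = int(np.flatnonzero(bad_g)[0]) + 2  # 1-based incl. header
        raise GazeParseError(f"{origin}: gaze vector norm off unit at line {line}")
    bad_q = valid & (np.abs(qnorm - 1.0) > UNIT_TOL)
    if bad_q.any():
        line = int(np.flatnonzero(bad_q)[0]) + 2
        raise GazeParseError(f"{origin}: quaternion norm off unit at line {line}")
    for (p, s), chunk in df.groupby(["participant", "scenario"], sort=False):
        t = chunk["t_ms"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            line = int(chunk.index[np.argmax(np.diff(t) <= 0) + 1]) + 2
            raise GazeParseError(
                f"{origin}: non-monotone timestamps for participant {p}, "
                f"scenario {s} at line {line}"
            )


# ---------------------------------------------------------------------------
# events and AOIs


def write_events(path, events: pd.DataFrame):
    from .events import EVENT_COLUMNS

    _write_table(path, events, EVENT_COLUMNS)


def read_events(path) -> pd.DataFrame:
    from .events import EVENT_COLUMNS

    df = _read_table(path, EVENT_COLUMNS)
    num = [
        "onset_ms",
        "offset_ms",
        "duration_ms",
        "start_az_deg",
        "start_el_deg",
        "end_az_deg",
        "end_el_deg",
        "amplitude_deg",
        "peak_accel_deg_s2",
    ]
    for col in num:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("object_id", "relevance"):
        df[col] = df[col].where(df[col].notna() & (df[col] != ""), None)
    return df


def write_aoi(path, aoi: pd.DataFrame):
    _write_table(path, aoi, AOI_COLUMNS)


def read_aoi(path) -> pd.DataFrame:
    df = _read_table(path, AOI_COLUMNS)
    for col in ["az_min", "az_max", "el_min", "el_max"]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def _write_table(path, df: pd.DataFrame, columns):
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns for writing: {missing}")
    out = df[columns]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(columns) + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False, float_format="%.17g")


def _read_table(path, columns) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise GazeParseError(f"{path}: missing #-prefixed header at line 1")
        names = header[1:].strip("\n").split("\t")
        missing = [c for c in columns if c not in names]
        if missing:
            raise GazeParseError(f"{path}: missing column(s) {missing} in header")
        df = pd.read_csv(fh, sep="\t", header=None, names=names, na_values=[""])
    return df[columns] if len(df) else pd.DataFrame(columns=columns)


# ---------------------------------------------------------------------------
# participant screening


def screen_participants(samples: pd.DataFrame, max_invalid_frac: float = 0.30):
    """Exclude participants by data loss; returns (kept samples, report).

    A participant whose fraction of invalid samples reaches
    ``max_invalid_frac`` (default 30%) is excluded. The report lists
    every participant's invalid percentage and status. Idempotent.
    """
    rows = []
    keep_labels = []
    for participant, chunk in samples.groupby("participant", sort=True):
        invalid_pct = 100.0 * (1.0 - chunk["valid"].mean())
        excluded = invalid_pct >= 100.0 * max_invalid_frac
        rows.append(
            {
                "participant": participant,
                "group": chunk["group"].iloc[0] if "group" in chunk else None,
                "invalid_pct": invalid_pct,
                "excluded": bool(excluded),
            }
        )
        if not excluded:
            keep_labels.append(participant)
    report = pd.DataFrame(rows)
    kept = samples[samples["participant"].isin(keep_labels)].reset_index(drop=True)
    return kept, report


# ---------------------------------------------------------------------------
# run configuration

DEFAULT_CONFIG: dict = {
    "cohort": {
        "n_adhd": 37,
        "n_control": 36,
        "n_scenarios": 13,
        "scenario_duration_s": 90.0,
        "instruction_duration_s": 10.0,
        "sampling_rate_hz": 90.0,
        "seed": 0,
    },
    "render": {
        "noise_sd_deg": 0.1,
        "head_yaw_amplitude_deg": 20.0,
        "head_yaw_freq_hz": 0.1,
        "mean_burst_len": 5,
    },
    "detection": {
        "lambda": 6.0,
        "velocity_window": 5,
        "min_saccade_samples": 2,
        "gap_interpolation_max_samples": 2,
        "min_intersaccadic_ms": 40.0,
    },
    "filters": {
        "min_sacc_ms": 22.0,
        "max_sacc_ms": 300.0,
        "min_amp_deg": 0.75,
        "max_accel_deg_s2": 36000.0,
        "min_fix_ms": 100.0,
        "max_fix_ms": 1000.0,
    },
    "screening": {"max_invalid_frac": 0.30},
    # group-level generative parameters: means/SDs of per-participant
    # event statistics, tracker data-loss rate, and the five task
    # performance measures (total score %, task efficacy %, navigation
    # efficacy, controller motion, total actions)
    "group_adhd": {
        "fixation_mean_ms": 317.0,
        "fixation_between_sd_ms": 36.0,
        "fixation_within_sd_ms": 80.0,
        "saccade_dur_mean_ms": 57.0,
        "saccade_dur_between_sd_ms": 8.3,
        "saccade_dur_within_sd_ms": 8.0,
        "saccade_amp_mean_deg": 5.44,
        "saccade_amp_between_sd_deg": 1.4,
        "saccade_amp_within_sd_deg": 2.0,
        "invalid_rate": 0.06,
        "performance_means": [67.1, 55.8, 1.16, 1255.0, 152.25],
        "performance_sds": [14.0, 12.0, 0.40, 300.0, 35.0],
        "relevant_fixation_offset_ms": 0.0,
    },
    "group_control": {
        "fixation_mean_ms": 309.0,
        "fixation_between_sd_ms": 30.0,
        "fixation_within_sd_ms": 80.0,
        "saccade_dur_mean_ms": 67.0,
        "saccade_dur_between_sd_ms": 10.1,
        "saccade_dur_within_sd_ms": 8.0,
        "saccade_amp_mean_deg": 6.29,
        "saccade_amp_between_sd_deg": 1.7,
        "saccade_amp_within_sd_deg": 2.0,
        "invalid_rate": 0.03,
        "performance_means": [72.0, 60.0, 1.30, 1150.0, 140.0],
        "performance_sds": [14.0, 12.0, 0.40, 300.0, 35.0],
        "relevant_fixation_offset_ms": 0.0,
    },
    "features": {"nss_mode": "centroid", "bin_s": 1.0},
    "classification": {
        "outer_folds": 10,
        "inner_folds": 5,
        "bootstrap_iterations": 30,
    },
}

_RANGES = {
    ("cohort", "n_adhd"): (1, 10_000),
    ("cohort", "n_control"): (1, 10_000),
    ("cohort", "n_scenarios"): (1, 1_000),
    ("cohort", "scenario_duration_s"): (1e-3, 1e5),
    ("cohort", "instruction_duration_s"): (0.0, 1e5),
    ("cohort", "sampling_rate_hz"): (1e-3, 1e5),
    ("render", "noise_sd_deg"): (0.0, 45.0),
    ("render", "mean_burst_len"): (1, 1e6),
    ("detection", "lambda"): (1e-9, 1e6),
    ("detection", "velocity_window"): (3, 101),
    ("screening", "max_invalid_frac"): (0.0, 1.0),
    # participants above 30% loss are excluded, so a generative loss
    # rate at or above that would produce an unusable cohort
    ("group_adhd", "invalid_rate"): (0.0, 0.2999),
    ("group_control", "invalid_rate"): (0.0, 0.2999),
    ("group_adhd", "fixation_mean_ms"): (100.0, 1000.0),
    ("group_control", "fixation_mean_ms"): (100.0, 1000.0),
    ("group_adhd", "saccade_dur_mean_ms"): (22.0, 300.0),
    ("group_control", "saccade_dur_mean_ms"): (22.0, 300.0),
    ("group_adhd", "saccade_amp_mean_deg"): (0.75, 90.0),
    ("group_control", "saccade_amp_mean_deg"): (0.75, 90.0),
    ("filters", "min_fix_ms"): (0.0, 1e6),
    ("classification", "outer_folds"): (2, 1000),
    ("classification", "inner_folds"): (2, 1000),
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML run configuration, fill defaults, validate.

    Unknown keys and out-of-range values raise :class:`ConfigError`
    naming every offending key. An empty/absent file yields the full
    default set.
    """
    user: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    if overrides:
        for section, vals in overrides.items():
            user.setdefault(section, {}).update(vals)

    config = copy.deepcopy(DEFAULT_CONFIG)
    problems = []
    for section, vals in user.items():
        if section not in config:
            problems.append(f"unknown section '{section}'")
            continue
        if not isinstance(vals, dict):
            problems.append(f"section '{section}' must be a mapping")
            continue
        for key, value in vals.items():
            if key not in config[section]:
                problems.append(f"unknown key '{section}.{key}'")
                continue
            config[section][key] = value
    for (section, key), (lo, hi) in _RANGES.items():
        value = config[section][key]
        if not isinstance(value, (int, float)) or isinstance(value, bool) or not (
            lo <= value <= hi
        ):
            problems.append(f"'{section}.{key}' = {value!r} outside [{lo}, {hi}]")
    if not math.isfinite(config["cohort"]["seed"] if isinstance(config["cohort"]["seed"], (int, float)) else 0):
        problems.append("'cohort.seed' must be a finite integer")
    if problems:
        raise ConfigError("; ".join(problems))
    return config
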