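"""Spherical and quaternion geometry helpers.

Conventions used throughout the package:

* Directions are unit 3-vectors in a right-handed frame: +x forward,
  +y left, +z up.
* Azimuth is the angle of the direction's horizontal projection from +x
  toward +y (degrees, positive leftward); elevation is the angle above
  the horizontal plane (degrees).
* Head orientation quaternions are Hamilton convention, scalar first
  (w, x, y, z), and rotate head-frame vectors into the world frame.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def ang_to_vec(az_deg, el_deg):
    """Unit direction vector(s) for azimuth/elevation in degrees."""
    az = np.deg2rad(np.asarray(az_deg, dtype=float))
    el = np.deg2rad(np.asarray(el_deg, dtype=float))
    cos_el = np.cos(el)
    return np.stack([cos_el * np.cos(az), cos_el * np.sin(az), np.sin(el)], axis=-1)


def vec_to_ang(v):
    """(azimuth, elevation) in degrees for unit vector(s), shape (..., 3)."""
    v = np.asarray(v, dtype=float)
    az = np.rad2deg(np.arctan2(v[..., 1], v[..., 0]))
    el = np.rad2deg(np.arcsin(np.clip(v[..., 2], -1.0, 1.0)))
    return az, el


def great_circle_deg(u, v):
    """Great-circle angle between unit vectors, in degrees.

    Uses atan2(|u x v|, u . v), which is accurate for both small and
    near-antipodal separations.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    cross = np.cross(u, v)
    sin_a = np.linalg.norm(cross, axis=-1)
    cos_a = np.sum(u * v, axis=-1)
    return np.rad2deg(np.arctan2(sin_a, cos_a))


def slerp_vec(u, v, frac):
    """Spherical linear interpolation between unit vectors.

    ``u``, ``v`` and ``frac`` broadcast; ``frac`` = 0 gives ``u``,
    1 gives ``v``. Falls back to linear interpolation + renormalisation
    for nearly parallel endpoints.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    frac = np.asarray(frac, dtype=float)[..., None]
    dot = np.clip(np.sum(u * v, axis=-1, keepdims=True), -1.0, 1.0)
    omega = np.arccos(dot)
    sin_omega = np.sin(omega)
    small = sin_omega < 1e-9
    with np.errstate(divide="ignore", invalid="ignore"):
        w0 = np.where(small, 1.0 - frac, np.sin((1.0 - frac) * omega) / sin_omega)
        w1 = np.where(small, frac, np.sin(frac * omega) / sin_omega)
    out = w0 * u + w1 * v
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


def quat_rotate(q_wxyz, vec):
    """Apply quaternion(s) (w, x, y, z) to vector(s)."""
    q = np.asarray(q_wxyz, dtype=float)
    r = Rotation.from_quat(np.roll(np.atleast_2d(q), -1, axis=-1))
    out = r.apply(np.atleast_2d(vec))
    return out if np.asarray(vec).ndim > 1 else out[0]


def quat_rotate_inv(q_wxyz, vec):
    """Apply the inverse rotation of quaternion(s) (w, x, y, z)."""
    q = np.asarray(q_wxyz, dtype=float)
    r = Rotation.from_quat(np.roll(np.atleast_2d(q), -1, axis=-1)).inv()
    out = r.apply(np.atleast_2d(vec))
    return out if np.asarray(vec).ndim > 1 else out[0]


def quat_from_yaw_deg(yaw_deg):
    """Quaternions (w, x, y, z) for rotations about +z by ``yaw_deg``."""
    half = np.deg2rad(np.asarray(yaw_deg, dtype=float)) / 2.0
    zeros = np.zeros_like(half)
    return np.stack([np.cos(half), zeros, zeros, np.sin(half)], axis=-1)


def quat_geodesic_deg(q1_wxyz, q2_wxyz):
    """Geodesic rotation angle(s) between quaternion pairs, degrees."""
    q1 = np.asarray(q1_wxyz, dtype=float)
    q2 = np.asarray(q2_wxyz, dtype=float)
    dot = np.abs(np.sum(q1 * q2, axis=-1))
    return np.rad2deg(2.0 * np.arccos(np.clip(dot, -1.0, 1.0)))


def tangent_noise(vecs, sd_deg, rng):
    """Add isotropic angular noise (degrees) in the tangent plane."""
    if sd_deg <= 0:
        return vecs
    vecs = np.asarray(vecs, dtype=float)
    g = rng.standard_normal(vecs.shape)
    g -= np.sum(g * vecs, axis=-1, keepdims=True) * vecs
    out = vecs + np.deg2rad(sd_deg) * g
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


def spherical_step(p, heading_rad, step_deg):
    """Move ``step_deg`` along a great circle from unit vector ``p``.

    ``heading_rad`` = 0 moves toward local east (+azimuth at el = 0
    is toward +y), pi/2 toward local north (+elevation). Scalar inputs.
    """
    up = np.array([0.0, 0.0, 1.0])
    east = np.cross(up, p)
    n = np.linalg.norm(east)
    if n < 1e-12:  # at a pole: any horizontal direction works
        east = np.array([0.0, 1.0, 0.0])
    else:
        east /= n
    north = np.cross(p, east)
    a = np.deg2rad(step_deg)
    d = np.cos(heading_rad) * east + np.sin(heading_rad) * north
    return np.cos(a) * p + np.sin(a) * d
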