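"""Circular-statistics helpers shared across the package.

All angles are radians, counterclockwise from the +x axis, wrapped to
(-pi, pi].  Circular distances are unsigned, so the sign convention never
enters any statistic.
"""
from __future__ import annotations

import numpy as np


def wrap_angle(theta):
    """Wrap angle(s) to the interval (-pi, pi].

    Values already inside the interval are returned bit-identically, so
    wrapping is exactly idempotent (a requirement for lossless round trips
    through the on-disk session format).
    """
    theta = np.asarray(theta, dtype=float)
    wrapped = np.pi - np.mod(np.pi - theta, 2.0 * np.pi)
    return np.where((theta > -np.pi) & (theta <= np.pi), theta, wrapped)


def circ_dist(a, b):
    """Unsigned circular distance, d = pi - |pi - |a - b| mod 2pi|, in [0, pi]."""
    d = np.mod(np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)),
               2.0 * np.pi)
    return np.pi - np.abs(np.pi - d)


def circular_mean(angles, weights=None):
    """Mean direction of a set of angles, wrapped to (-pi, pi]."""
    angles = np.asarray(angles, dtype=float)
    if weights is None:
        c, s = np.cos(angles).mean(), np.sin(angles).mean()
    else:
        w = np.asarray(weights, dtype=float)
        c, s = np.average(np.cos(angles), weights=w), np.average(np.sin(angles), weights=w)
    return float(wrap_angle(np.arctan2(s, c)))


def resultant_length(angles):
    """Mean resultant length R in [0, 1]; R -> 1 for concentrated samples."""
    angles = np.asarray(angles, dtype=float)
    return float(np.hypot(np.cos(angles).mean(), np.sin(angles).mean()))


def circular_dispersion(angles):
    """Largest pairwise circular distance within a set of angles.

    This is the trial-level cue-uncertainty measure: the maximal unsigned
    circular distance over all pairs of cue line-segment angles.

    Parameters
    ----------
    angles : array-like of float
        At least two angles, radians.

    Returns
    -------
    float
        max_{i<j} d(theta_i, theta_j), in [0, pi].
    """
    angles = np.asarray(angles, dtype=float)
    if angles.ndim != 1 or angles.size < 2:
        raise ValueError("circular_dispersion needs at least 2 angles")
    d = circ_dist(angles[:, None], angles[None, :])
    return float(d.max())
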