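"""Circular-angle conventions and von Mises helpers.

Stimulus orientation is 180-degree periodic. Internally every angle lives on
the full circle [-pi, pi): a stimulus orientation of d degrees (0 = vertical,
d in [-90, 90)) maps to d * pi / 90 radians, so that 0 and +-pi are the two
cardinal orientations and +-pi/2 the obliques. All public I/O is in stimulus
degrees; all internal math is in circle radians.
"""

from __future__ import annotations

import numpy as np
from scipy.special import i0e, i1e

TWO_PI = 2.0 * np.pi


def wrap_circle(theta):
    """Wrap circle radians to [-pi, pi)."""
    return np.mod(np.asarray(theta, dtype=float) + np.pi, TWO_PI) - np.pi


def wrap_degrees(deg):
    """Wrap stimulus degrees to [-90, 90)."""
    return np.mod(np.asarray(deg, dtype=float) + 90.0, 180.0) - 90.0


def deg_to_circle(deg):
    """Stimulus degrees -> circle radians (d * pi / 90), wrapped."""
    return wrap_circle(np.asarray(deg, dtype=float) * (np.pi / 90.0))


def circle_to_deg(theta):
    """Circle radians -> stimulus degrees, wrapped to [-90, 90)."""
    return wrap_degrees(np.asarray(theta, dtype=float) * (90.0 / np.pi))


def vm_pdf(theta, mu, kappa):
    """von Mises density on the circle, numerically stable for large kappa.

    exp(kappa cos(x - mu)) / (2 pi I0(kappa)) computed via the exponentially
    scaled Bessel function.
    """
    theta = np.asarray(theta, dtype=float)
    return np.exp(kappa * (np.cos(theta - mu) - 1.0)) / (TWO_PI * i0e(kappa))


def vm_fisher(kappa):
    """Fisher information about the location of a von Mises sample.

    J(kappa) = kappa * I1(kappa) / I0(kappa); tends to kappa for large kappa
    and to kappa^2/2 for small kappa.
    """
    return kappa * i1e(kappa) / i0e(kappa)


def circular_grid(n: int) -> np.ndarray:
    """Uniform periodic grid of n points on [-pi, pi) (right endpoint open)."""
    return np.linspace(-np.pi, np.pi, n, endpoint=False)


def periodic_trapezoid(values: np.ndarray, n: int | None = None) -> float:
    """Trapezoidal integral over the full circle of values on circular_grid(n).

    The grid is periodic, so the trapezoid rule reduces to the mean times 2 pi.
    """
    values = np.asarray(values, dtype=float)
    if n is None:
        n = values.shape[-1]
    return float(np.mean(values, axis=-1) * TWO_PI) if values.ndim == 1 else np.mean(values, axis=-1) * TWO_PI


def periodic_cumtrapz(values: np.ndarray) -> np.ndarray:
    """Cumulative trapezoidal integral from -pi along circular_grid(n).

    Returns an array of the same length; entry i is the integral from -pi to
    grid[i] (entry 0 is 0). Uses the periodic extension for the last panel
    implicitly only when the caller closes the circle.
    """
    v = np.asarray(values, dtype=float)
    h = TWO_PI / v.size
    mids = 0.5 * (v[1:] + v[:-1]) * h
    out = np.empty_like(v)
    out[0] = 0.0
    np.cumsum(mids, out=out[1:])
    return out
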