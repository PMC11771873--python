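"""2AFC decision probabilities and simulated responses.

The observer compares the sensory measurements of the reference and test
stimuli directly: the reference is reported clockwise (CW, decreasing
stimulus degrees) when the wrapped difference m_r - m_t falls in (-pi, 0) on
the circle. Because the encoding transforms are monotone circular maps shared
by both stimuli, the comparison is evaluated in the final sensory space,
where both measurements are von Mises with the model's effective
concentration around the encoded orientations. There the CW probability
depends only on the encoded separation delta = mu_r - mu_t:

    P(delta) = integral vm(y; 0, kappa) * H(y - delta) dy,
    H(d)     = integral_{d-pi}^{d} vm(u; 0, kappa) du,

which is precomputed once per model as a lookup table over delta (a circular
cross-correlation, evaluated by FFT) and interpolated per trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._angles import TWO_PI, circular_grid, deg_to_circle, vm_pdf, wrap_circle
from .core_model import ObserverModel


@dataclass
class DecisionTable:
    """P("reference CW") as a function of encoded separation mu_r - mu_t."""

    delta: np.ndarray
    prob: np.ndarray
    kappa: float

    def __call__(self, delta) -> np.ndarray:
        d = wrap_circle(delta)
        p = np.interp(d, self.delta, self.prob, period=TWO_PI)
        # identical encoded positions: symmetric comparison, exactly 1/2
        return np.where(np.asarray(d) == 0.0, 0.5, p)


def decision_table(model_or_kappa, n_grid: int | None = None) -> DecisionTable:
    """Build the CW-probability lookup for a model (or a raw concentration)."""
    if isinstance(model_or_kappa, ObserverModel):
        kappa = model_or_kappa.kappa_eff
        n = model_or_kappa.n_grid if n_grid is None else n_grid
    else:
        kappa = float(model_or_kappa)
        n = 1024 if n_grid is None else n_grid
    if n % 2:
        n += 1
    grid = circular_grid(n)
    v = vm_pdf(grid, 0.0, kappa)
    v = v / (np.mean(v) * TWO_PI)  # unit circular integral, exactly

    # cumulative from -pi; C[i] = int_{-pi}^{grid[i]}
    h = TWO_PI / n
    c = np.empty(n)
    c[0] = 0.0
    np.cumsum(0.5 * (v[1:] + v[:-1]) * h, out=c[1:])

    # H(grid[i]) = int_{grid[i]-pi}^{grid[i]} vm: shift by half the circle
    half = n // 2
    H = np.empty(n)
    H[half:] = c[half:] - c[:half]            # delta >= 0
    H[:half] = c[:half] - c[half:] + 1.0      # delta < 0 wraps past -pi

    # P(delta_j) = (2 pi / n) * sum_i v_i H_{i-j}  (circular cross-correlation)
    P = np.fft.irfft(np.fft.rfft(H) * np.conj(np.fft.rfft(v)), n) * h
    P = np.clip(P, 0.0, 1.0)
    return DecisionTable(delta=grid, prob=P, kappa=kappa)


def prob_reference_cw(
    model: ObserverModel,
    test_deg,
    reference_deg,
    table: DecisionTable | None = None,
):
    """P("reference is CW of test" | theta_t, theta_r) for the observer.

    Accepts scalars or arrays of stimulus orientations in degrees.
    """
    if table is None:
        table = decision_table(model)
    mu_t = model.encode(deg_to_circle(test_deg))
    mu_r = model.encode(deg_to_circle(reference_deg))
    p = table(mu_r - mu_t)
    return float(p) if np.isscalar(test_deg) and np.isscalar(reference_deg) else p


def simulate_response(
    model: ObserverModel,
    test_deg,
    reference_deg,
    rng: np.random.Generator,
    n: int | None = None,
):
    """Sample the generative decision: draw both measurements, compare.

    Returns True where the reference is reported clockwise of the test.
    """
    mu_t = model.encode(deg_to_circle(test_deg))
    mu_r = model.encode(deg_to_circle(reference_deg))
    size = None if n is None else n
    m_t = rng.vonmises(mu_t, model.kappa_eff, size=size)
    m_r = rng.vonmises(mu_r, model.kappa_eff, size=size)
    diff = wrap_circle(m_r - m_t)
    cw = (diff < 0) & (diff >= -np.pi)
    return bool(cw) if (n is None and np.isscalar(test_deg)) else cw


def model_threshold(
    model: ObserverModel,
    test_deg: float,
    level: float = 0.75,
    table: DecisionTable | None = None,
) -> float:
    """Model-implied discrimination threshold D(theta_t) in stimulus degrees.

    Two-sided definition, matching how thresholds are read off symmetric
    psychometric fits: the mean of the clockwise-side and
    counter-clockwise-side offsets at which the corresponding report
    probability reaches ``level``. (A one-sided threshold would pick up the
    local gradient of the allocation; the two-sided mean cancels it.)
    """
    from scipy.optimize import brentq

    if table is None:
        table = decision_table(model)
    theta_t = float(deg_to_circle(test_deg))
    mu_t = float(model.encode(theta_t))

    def one_side(side: float) -> float:
        def p_resp(delta_rad: float) -> float:
            mu_r = float(model.encode(theta_t + side * delta_rad))
            p_cw = float(table(mu_r - mu_t))
            return 1.0 - p_cw if side > 0 else p_cw

        deltas = np.linspace(1e-6, np.pi / 2, 257)
        vals = np.array([p_resp(d) for d in deltas])
        above = np.nonzero(vals >= level)[0]
        if above.size == 0:
            return float("nan")
        i = above[0]
        if i == 0:
            return float(deltas[0])
        return brentq(lambda d: p_resp(d) - level, deltas[i - 1], deltas[i], xtol=1e-8)

    d_ccw = one_side(+1.0)
    d_cw = one_side(-1.0)
    return float(0.5 * (d_ccw + d_cw) * 90.0 / np.pi)
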