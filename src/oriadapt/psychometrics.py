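"""Model-free psychometric analysis of 2AFC orientation discrimination data.

For each test orientation, the probability of a counter-clockwise report as a
function of the signed reference offset Delta = theta_r - theta_t (wrapped,
stimulus degrees) is fit with a zero-mean cumulative Gaussian with no lapse
rate, p(CCW | Delta) = Phi(Delta / sigma); with the package's clockwise
convention (CW = decreasing degrees) this is the same as p(CW) = Phi(-Delta /
sigma). The discrimination threshold is read off at the 75% level,
D = sigma * z(0.75), and discriminability is its reciprocal. Uncertainty is
quantified by a per-trial bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from ._angles import wrap_degrees
from .errors import DegenerateDataError

Z75 = float(norm.ppf(0.75))
SIGMA_FLOOR = 1e-3
SIGMA_CEIL = 50.0


@dataclass
class PsychometricFit:
    """Zero-mean cumulative-Gaussian fit at one test orientation."""

    sigma: float                 # slope parameter, stimulus degrees
    threshold: float             # D(theta) at the 75% level, degrees
    discriminability: float      # 1 / threshold, 1/deg
    n_trials: int
    boundary: bool = False       # sigma pinned at the optimization floor
    log_likelihood: float = 0.0


@dataclass
class BootstrapInterval:
    low: float
    high: float
    n_boot: int
    n_degenerate: int = 0
    warn: bool = False           # > 10% of refits were degenerate


def signed_offset_deg(test_deg, reference_deg) -> np.ndarray:
    """Wrapped signed difference theta_r - theta_t in stimulus degrees.

    Wrapping to (-90, 90] matters at the 90-degree test orientation, where
    references sit on both sides of the periodic boundary.
    """
    d = wrap_degrees(np.asarray(reference_deg, float) - np.asarray(test_deg, float))
    return np.where(d == -90.0, 90.0, d)


def _nll_sigma(log_sigma: float, delta: np.ndarray, ccw: np.ndarray) -> float:
    sigma = np.exp(log_sigma)
    z = delta / sigma
    ll = np.where(ccw, norm.logcdf(z), norm.logcdf(-z))
    return -float(np.sum(ll))


def fit_psychometric(delta_deg, response_cw) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit.

    Parameters
    ----------
    delta_deg : array
        Signed reference offsets theta_r - theta_t (degrees, wrapped).
    response_cw : bool array
        True where the reference was reported clockwise.
    """
    delta = np.asarray(delta_deg, dtype=float)
    cw = np.asarray(response_cw, dtype=bool)
    if delta.size == 0:
        raise DegenerateDataError("no trials")
    nonzero = delta[delta != 0.0]
    if np.unique(np.abs(nonzero)).size == 0 or np.unique(delta).size < 2:
        raise DegenerateDataError("no slope information: all offsets identical")
    if cw.all() or (~cw).all():
        raise DegenerateDataError("all responses identical")

    # perfectly separable responses drive sigma to zero; clip at the floor
    nz = delta != 0.0
    if np.all(cw[nz] == (delta[nz] < 0.0)):
        return PsychometricFit(
            sigma=SIGMA_FLOOR, threshold=SIGMA_FLOOR * Z75,
            discriminability=1.0 / (SIGMA_FLOOR * Z75),
            n_trials=int(delta.size), boundary=True,
            log_likelihood=float(delta.size - nz.sum()) * np.log(0.5),
        )

    ccw = ~cw
    res = minimize_scalar(
        _nll_sigma,
        bounds=(np.log(SIGMA_FLOOR), np.log(SIGMA_CEIL)),
        args=(delta, ccw),
        method="bounded",
        options={"xatol": 1e-8},
    )
    sigma = float(np.exp(res.x))
    boundary = sigma <= SIGMA_FLOOR * 1.01
    sigma = max(sigma, SIGMA_FLOOR)
    return PsychometricFit(
        sigma=sigma,
        threshold=sigma * Z75,
        discriminability=1.0 / (sigma * Z75),
        n_trials=int(delta.size),
        boundary=bool(boundary),
        log_likelihood=-float(res.fun),
    )


def bootstrap_discriminability(
    delta_deg,
    response_cw,
    n_boot: int = 1000,
    rng_seed: int = 0,
    ci: float = 95.0,
) -> BootstrapInterval:
    """Percentile bootstrap interval for discriminability (per-trial resampling)."""
    delta = np.asarray(delta_deg, dtype=float)
    cw = np.asarray(response_cw, dtype=bool)
    fit_psychometric(delta, cw)  # precondition: full-data fit must succeed
    rng = np.random.default_rng(rng_seed)
    n = delta.size
    vals = np.empty(n_boot)
    n_bad = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            vals[b] = fit_psychometric(delta[idx], cw[idx]).discriminability
        except DegenerateDataError:
            vals[b] = np.nan
            n_bad += 1
    ok = vals[np.isfinite(vals)]
    tail = (100.0 - ci) / 2.0
    low, high = np.percentile(ok, [tail, 100.0 - tail])
    return BootstrapInterval(
        low=float(low),
        high=float(high),
        n_boot=n_boot,
        n_degenerate=n_bad,
        warn=n_bad > 0.1 * n_boot,
    )


def analyze_dataset(
    dataset,
    n_boot: int = 1000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Per-(subject, condition, adaptor, test orientation) psychometric table.

    Returns one row per cell with sigma, threshold_deg, discriminability and
    the bootstrap interval; the output matches the package's CSV schema.
    """
    df = dataset.df
    rows = []
    keys = ["subject", "condition", "adaptor_deg", "test_deg"]
    for (subject, condition, adaptor, test), sub in df.groupby(keys, dropna=False):
        delta = signed_offset_deg(sub["test_deg"].to_numpy(), sub["reference_deg"].to_numpy())
        cw = sub["response_cw"].to_numpy().astype(bool)
        try:
            fit = fit_psychometric(delta, cw)
        except DegenerateDataError:
            continue
        if n_boot > 0:
            bi = bootstrap_discriminability(delta, cw, n_boot=n_boot, rng_seed=rng_seed)
            lo, hi, warn = bi.low, bi.high, bi.warn
        else:
            lo = hi = np.nan
            warn = False
        rows.append({
            "subject": subject,
            "condition": condition,
            "adaptor_deg": adaptor,
            "test_orientation_deg": test,
            "sigma": fit.sigma,
            "threshold_deg": fit.threshold,
            "discriminability": fit.discriminability,
            "ci_low": lo,
            "ci_high": hi,
            "n_trials": fit.n_trials,
            "boundary": fit.boundary,
            "bootstrap_warn": warn,
            "bootstrap_unit": "trial",
        })
    return pd.DataFrame(rows)
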