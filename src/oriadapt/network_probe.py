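"""Fisher information of an orientation-indexed neural response matrix.

Under independent Gaussian noise of unit variance, the Fisher information a
population carries about orientation is the summed squared slope of the unit
responses, J(theta) = sum_i (dr_i / dtheta)^2. The derivative is taken with
respect to the orientation circle (stimulus degrees d map to d * pi / 90
radians, so orientation is a full circle) with periodic central finite
differences at the probe spacing. Because only the distribution of coding
resources is of interest, sqrt(J) is normalized to unit sum over the probe
grid.

``filter_bank_fixture`` provides a desk-scale response set: von Mises-tuned,
linearly rectified energy units probed with orientation-filtered noise, the
same stimulus family as the psychophysical experiment. Any response matrix
with the same layout (units x orientations at uniform spacing) can be fed to
``fisher_from_responses`` unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEG_TO_CIRCLE = np.pi / 90.0


@dataclass
class ResponseCurveSet:
    """Unit responses on a uniform orientation grid (1-degree default)."""

    theta_deg: np.ndarray        # (n,) uniform grid covering the orientation circle
    responses: np.ndarray        # (units, n)

    def __post_init__(self):
        self.theta_deg = np.asarray(self.theta_deg, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if self.responses.shape[1] != self.theta_deg.size:
            raise ValueError("responses must be (units, len(theta_deg))")
        d = np.diff(self.theta_deg)
        if d.size and not np.allclose(d, d[0]):
            raise ValueError("orientation grid must be uniform")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")

    @property
    def spacing_deg(self) -> float:
        return float(self.theta_deg[1] - self.theta_deg[0])

    @classmethod
    def from_csv(cls, path) -> "ResponseCurveSet":
        df = pd.read_csv(path)
        theta = df["orientation_deg"].to_numpy()
        resp = df.drop(columns=["orientation_deg"]).to_numpy().T
        return cls(theta_deg=theta, responses=resp)


@dataclass
class FisherCurve:
    """Normalized sqrt-Fisher allocation over the probe grid."""

    theta_deg: np.ndarray
    sqrt_j: np.ndarray           # normalized to unit sum
    j_raw: np.ndarray            # unnormalized J(theta)
    degenerate: bool = False     # all response gradients vanish

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "orientation_deg": self.theta_deg,
            "sqrt_fisher_normalized": self.sqrt_j,
        }).to_csv(path, index=False)


def fisher_from_responses(curves: ResponseCurveSet) -> FisherCurve:
    """J(theta) = sum over units of the squared response derivative.

    Central differences with periodic wrap; derivative with respect to the
    orientation circle in radians; sqrt(J) normalized to unit sum.
    """
    if curves.theta_deg.size < 3:
        raise ValueError("need at least 3 grid points for central differences")
    d_theta = curves.spacing_deg * DEG_TO_CIRCLE
    r = curves.responses
    dr = (np.roll(r, -1, axis=1) - np.roll(r, 1, axis=1)) / (2.0 * d_theta)
    j = np.sum(dr * dr, axis=0)
    sqrt_j = np.sqrt(j)
    total = sqrt_j.sum()
    degenerate = not total > 0
    if degenerate:
        norm = np.zeros_like(sqrt_j)
    else:
        norm = sqrt_j / total
    return FisherCurve(theta_deg=curves.theta_deg, sqrt_j=norm, j_raw=j,
                       degenerate=degenerate)


def _wrapped_laplace_profile(x_deg: np.ndarray, sigma_deg: float) -> np.ndarray:
    """Axial wrapped-Laplace orientation spectrum with standard deviation sigma."""
    d = np.mod(x_deg + 90.0, 180.0) - 90.0
    scale = sigma_deg / np.sqrt(2.0)
    return np.exp(-np.abs(d) / scale)


def filter_bank_fixture(
    n_units: int = 36,
    tuning_kappa: float = 4.0,
    preferred_deg: np.ndarray | None = None,
    n_stim_seeds: int = 50,
    stim_sigma_deg: float = 1.4,
    probe_spacing_deg: float = 1.0,
    rng_seed: int = 0,
    rectification_threshold: float = 0.0,
) -> ResponseCurveSet:
    """Responses of a toy oriented-filter bank to orientation-filtered noise.

    Units are von Mises-tuned (concentration ``tuning_kappa`` on the doubled
    orientation angle) energy detectors with linear rectification. Each
    stimulus seed draws one noise energy pattern which is rotated rigidly
    across probe orientations (the probe rotates the same pattern); responses
    are averaged over seeds.
    """
    if preferred_deg is None:
        preferred_deg = np.linspace(-90.0, 90.0, n_units, endpoint=False)
    preferred_deg = np.asarray(preferred_deg, dtype=float)

    probe_deg = np.arange(-90.0, 90.0, probe_spacing_deg)
    n_probe = probe_deg.size
    rng = np.random.default_rng(rng_seed)

    # orientation energy axis at probe resolution
    psi = probe_deg
    profile = _wrapped_laplace_profile(psi, stim_sigma_deg)

    # tuning matrix: units x orientation bins (von Mises on doubled angles)
    dpsi = np.deg2rad(2.0 * (psi[None, :] - preferred_deg[:, None]))
    tuning = np.exp(tuning_kappa * (np.cos(dpsi) - 1.0))

    resp = np.zeros((preferred_deg.size, n_probe))
    for _ in range(n_stim_seeds):
        noise = rng.standard_normal(n_probe) ** 2     # energy sample per bin
        base = noise * profile                        # stimulus at orientation 0
        # responses to the pattern shifted to each probe orientation
        for j in range(n_probe):
            e = np.roll(base, j)
            resp[:, j] += tuning @ e
    resp /= n_stim_seeds
    resp = np.maximum(resp - rectification_threshold, 0.0)
    return ResponseCurveSet(theta_deg=probe_deg, responses=resp)
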