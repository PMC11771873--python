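"""Fisher-information allocation over orientation and sensory-space transforms.

The observer model represents how much encoding precision (square root of
Fisher information, "coding capacity") the visual system allocates to each
orientation, and how adaptation to an oriented stimulus reallocates it.

Conventions
-----------
* Orientation is 180-degree periodic. A stimulus orientation of ``d`` degrees
  (0 = vertical) is mapped to the full circle as ``d * pi / 90`` radians, so 0
  and +-pi are the cardinal orientations and +-pi/2 the obliques.
* Every square-root-Fisher field is normalized to unit circular integral. The
  allocation carries the *shape* of encoding precision; the overall magnitude
  (total capacity) is carried entirely by the sensory noise concentration
  ``kappa_i``. This makes the fixed-resource assumption explicit: reallocating
  the field never changes total Fisher information.

Under stationary (control) conditions the allocation is a symmetric mixture of
a uniform component and two identical von Mises peaks at the cardinals:

    sqrt(J)(theta) ~ k vm(theta; 0, kappa) + k vm(theta; pi, kappa) + (1-2k)/2pi

The sensory space ``theta~ = F(theta)`` is the normalized cumulative of
sqrt(J); in that space pre-adaptation encoding is homogeneous and the sensory
measurement is von Mises with concentration ``kappa_i``. Adaptation recenters
a reallocation kernel at the adaptor's sensory-space position, which defines a
second field ``J_a`` and a second transform ``F_a``; the measurement stays von
Mises (same ``kappa_i``, unless the variant allows it to change) in the final
space. Measurement densities in stimulus space follow by change of variables
through the inverse transform chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy.interpolate import PchipInterpolator

from ._angles import (
    TWO_PI,
    circular_grid,
    deg_to_circle,
    vm_fisher,
    vm_pdf,
    wrap_circle,
)
from .errors import DegenerateFieldError, ParameterError, VariantMismatchError

DEFAULT_N_GRID = 2048

KERNEL_VARIANTS = ("two_peak", "one_peak", "two_peak_fisher", "two_peak_kernel")

#: free-parameter count per fitted stage (used for BIC)
N_FREE_PARAMS = {
    "control": 3,
    "one_peak": 2,
    "two_peak": 4,
    "two_peak_fisher": 5,
    "two_peak_kernel": 8,
}


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StationaryParams:
    """Stationary (pre-adaptation) allocation and noise parameters.

    Parameters
    ----------
    k : float
        Relative amplitude of each cardinal peak, in [0, 0.5] so the uniform
        weight 1 - 2k stays nonnegative.
    kappa : float
        von Mises concentration of the cardinal peaks (> 0).
    kappa_i : float
        Sensory noise concentration in sensory space (> 0); larger means less
        noise and more total coding capacity.
    """

    k: float
    kappa: float
    kappa_i: float

    def __post_init__(self):
        if not (0.0 <= self.k <= 0.5):
            raise ParameterError(f"k must be in [0, 0.5], got {self.k}")
        if not self.kappa > 0:
            raise ParameterError(f"kappa must be > 0, got {self.kappa}")
        if not self.kappa_i > 0:
            raise ParameterError(f"kappa_i must be > 0, got {self.kappa_i}")

    def to_dict(self) -> dict:
        return {"k": self.k, "kappa": self.kappa, "kappa_i": self.kappa_i}

    @classmethod
    def from_dict(cls, d: dict) -> "StationaryParams":
        return cls(k=d["k"], kappa=d["kappa"], kappa_i=d["kappa_i"])


@dataclass(frozen=True)
class KernelParams:
    """Adaptation (reallocation) kernel parameters.

    The kernel is a probability density over sensory space, recentered at the
    adaptor. Variants:

    * ``two_peak`` -- uniform + von Mises peaks at the adaptor and orthogonal
      to it (weights k1, k2, concentrations kappa1, kappa2).
    * ``one_peak`` -- uniform + single peak at the adaptor (k2 absent).
    * ``two_peak_fisher`` -- two_peak shape, but the post-adaptation sensory
      noise ``kappa_i_adapted`` may differ from the stationary ``kappa_i``
      (relaxes the fixed-resource assumption).
    * ``two_peak_kernel`` -- a separate two_peak kernel per adaptor
      orientation, supplied in ``per_adaptor`` (relaxes the single-kernel
      assumption).
    """

    variant: str
    k1: float = 0.0
    k2: Optional[float] = None
    kappa1: float = 1.0
    kappa2: Optional[float] = None
    kappa_i_adapted: Optional[float] = None
    per_adaptor: Optional[dict] = None  # adaptor_deg -> KernelParams (two_peak_kernel)

    def __post_init__(self):
        if self.variant not in KERNEL_VARIANTS:
            raise ParameterError(f"unknown kernel variant {self.variant!r}")
        if self.variant == "two_peak_kernel":
            if not self.per_adaptor:
                raise VariantMismatchError(
                    "two_peak_kernel requires one kernel per adaptor in per_adaptor"
                )
            for sub in self.per_adaptor.values():
                if sub.variant != "two_peak":
                    raise VariantMismatchError(
                        "per-adaptor kernels must have variant 'two_peak'"
                    )
            return
        if self.variant == "one_peak":
            if self.k2 is not None or self.kappa2 is not None:
                raise VariantMismatchError("one_peak kernel must not set k2/kappa2")
            k2 = 0.0
        else:
            if self.k2 is None or self.kappa2 is None:
                raise VariantMismatchError(f"{self.variant} kernel requires k2 and kappa2")
            k2 = self.k2
            if not self.kappa2 > 0:
                raise ParameterError("kappa2 must be > 0")
        if self.k1 < 0 or k2 < 0 or self.k1 + k2 > 1.0 + 1e-12:
            raise ParameterError("peak weights must satisfy k1, k2 >= 0 and k1 + k2 <= 1")
        if not self.kappa1 > 0:
            raise ParameterError("kappa1 must be > 0")
        if self.kappa_i_adapted is not None:
            if self.variant != "two_peak_fisher":
                raise VariantMismatchError(
                    "kappa_i_adapted is only meaningful for two_peak_fisher"
                )
            if not self.kappa_i_adapted > 0:
                raise ParameterError("kappa_i_adapted must be > 0")

    def resolve(self, adaptor_deg: float) -> "KernelParams":
        """Concrete kernel for one adaptor (relevant for two_peak_kernel)."""
        if self.variant != "two_peak_kernel":
            return self
        for key, sub in self.per_adaptor.items():
            if np.isclose(float(key), adaptor_deg):
                return sub
        raise ParameterError(f"no kernel stored for adaptor {adaptor_deg} deg")

    def density(self, x: np.ndarray) -> np.ndarray:
        """Kernel density p_a evaluated at sensory-space offsets ``x``."""
        if self.variant == "two_peak_kernel":
            raise VariantMismatchError("resolve() a per-adaptor kernel first")
        k2 = 0.0 if self.k2 is None else self.k2
        out = self.k1 * vm_pdf(x, 0.0, self.kappa1) + (1.0 - self.k1 - k2) / TWO_PI
        if k2 > 0 or self.kappa2 is not None:
            out = out + k2 * vm_pdf(x, np.pi, self.kappa2)
        return out

    def to_dict(self) -> dict:
        if self.variant == "two_peak_kernel":
            return {
                "variant": self.variant,
                "per_adaptor": {str(a): s.to_dict() for a, s in self.per_adaptor.items()},
            }
        d = {"variant": self.variant, "k1": self.k1, "kappa1": self.kappa1}
        if self.k2 is not None:
            d.update(k2=self.k2, kappa2=self.kappa2)
        if self.kappa_i_adapted is not None:
            d["kappa_i_adapted"] = self.kappa_i_adapted
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KernelParams":
        d = dict(d)
        if d.get("variant") == "two_peak_kernel":
            per = {float(a): cls.from_dict(s) for a, s in d["per_adaptor"].items()}
            return cls(variant="two_peak_kernel", per_adaptor=per)
        return cls(**d)


# ---------------------------------------------------------------------------
# fields and transforms
# ---------------------------------------------------------------------------

@dataclass
class FisherField:
    """Gridded square-root-Fisher allocation, normalized to unit integral.

    ``space_tag`` records whether the grid lives in stimulus space (theta) or
    sensory space (theta~).
    """

    grid: np.ndarray
    sqrt_j: np.ndarray
    space_tag: str = "stimulus"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.sqrt_j = np.asarray(self.sqrt_j, dtype=float)
        if self.grid.shape != self.sqrt_j.shape:
            raise ValueError("grid and sqrt_j must have matching shapes")

    @property
    def n(self) -> int:
        return self.grid.size

    def integral(self) -> float:
        return float(np.mean(self.sqrt_j) * TWO_PI)

    def __call__(self, theta) -> np.ndarray:
        """Periodic linear interpolation of sqrt_j at arbitrary angles."""
        return np.interp(wrap_circle(theta), self.grid, self.sqrt_j, period=TWO_PI)


@dataclass
class SensoryTransform:
    """Monotone circular map built from the cumulative of a sqrt-Fisher field.

    forward(-pi) = -pi and forward(pi) = pi; monotone piecewise-cubic
    interpolation (PCHIP) is used for both directions, plus plain arrays for
    fast linear-interpolation evaluation in hot loops. The interpolants are
    built lazily: likelihood evaluations only touch the linear path.
    """

    x: np.ndarray          # source grid including the closing +pi point
    y: np.ndarray          # forward values at x, y[0] = -pi, y[-1] = +pi
    _fwd: PchipInterpolator | None = dc_field(repr=False, default=None)
    _inv: PchipInterpolator | None = dc_field(repr=False, default=None)

    def forward(self, theta) -> np.ndarray:
        if self._fwd is None:
            self._fwd = PchipInterpolator(self.x, self.y)
        out = self._fwd(wrap_circle(theta))
        return np.clip(out, -np.pi, np.pi)

    def inverse(self, tilde) -> np.ndarray:
        if self._inv is None:
            self._inv = PchipInterpolator(self.y, self.x)
        out = self._inv(wrap_circle(tilde))
        return np.clip(out, -np.pi, np.pi)

    def forward_lin(self, theta) -> np.ndarray:
        """Fast linear-interpolation forward map (fitting hot path)."""
        return np.interp(wrap_circle(theta), self.x, self.y)

    def derivative(self, theta) -> np.ndarray:
        """Derivative of the forward map (PCHIP-consistent, nonnegative)."""
        if self._fwd is None:
            self._fwd = PchipInterpolator(self.x, self.y)
        return np.maximum(self._fwd.derivative()(wrap_circle(theta)), 0.0)

    def inverse_lin(self, tilde) -> np.ndarray:
        return np.interp(wrap_circle(tilde), self.y, self.x)


def stationary_sqrt_fisher(params: StationaryParams, n_grid: int = DEFAULT_N_GRID) -> FisherField:
    """Stationary sqrt-Fisher allocation: uniform + two cardinal von Mises peaks."""
    if n_grid < 64:
        raise ParameterError("n_grid must be >= 64")
    grid = circular_grid(n_grid)
    vals = (
        params.k * vm_pdf(grid, 0.0, params.kappa)
        + params.k * vm_pdf(grid, np.pi, params.kappa)
        + (1.0 - 2.0 * params.k) / TWO_PI
    )
    vals = vals / (np.mean(vals) * TWO_PI)
    return FisherField(grid=grid, sqrt_j=vals, space_tag="stimulus")


def kernel_sqrt_fisher(
    kernel: KernelParams, adaptor_sensory: float, n_grid: int = DEFAULT_N_GRID
) -> FisherField:
    """Adapted sqrt-Fisher field in sensory space: the kernel recentered at the adaptor.

    The kernel's own 0 lands at the adaptor's sensory position theta~_a and
    its pi peak at theta~_a + pi (the recentering is done in sensory space).
    """
    grid = circular_grid(n_grid)
    vals = kernel.density(wrap_circle(grid - adaptor_sensory))
    vals = vals / (np.mean(vals) * TWO_PI)
    return FisherField(grid=grid, sqrt_j=vals, space_tag="sensory")


def build_transform(field: FisherField) -> SensoryTransform:
    """Monotone circular transform: cumulative of the sqrt-Fisher field.

    forward(theta) = -pi + 2 pi * integral_{-pi}^{theta} sqrt(J).
    """
    v = field.sqrt_j
    if np.any(v <= 0):
        raise DegenerateFieldError("sqrt-Fisher field must be strictly positive")
    n = v.size
    h = TWO_PI / n
    cum = np.empty(n + 1)
    cum[0] = 0.0
    panels = 0.5 * (v + np.roll(v, -1)) * h  # panel i spans grid[i]..grid[i+1]
    np.cumsum(panels, out=cum[1:])
    total = cum[-1]
    x = np.append(field.grid, np.pi)
    y = -np.pi + TWO_PI * cum / total
    # strict monotonicity guard: allocations with near-zero mass over long
    # arcs can produce flat cumulative stretches at float precision
    y = y + np.arange(n + 1) * 1e-12
    y = -np.pi + (y - y[0]) * (TWO_PI / (y[-1] - y[0]))
    y[0] = -np.pi
    y[-1] = np.pi
    return SensoryTransform(x=x, y=y)


# ---------------------------------------------------------------------------
# observer model
# ---------------------------------------------------------------------------

class ObserverModel:
    """Composed encoder: stationary allocation, optional adaptation state.

    A control observer carries only the stationary parameters; an adapted
    observer additionally carries a reallocation kernel and the adaptor
    orientation. The encoded position of a stimulus is ``F(theta)`` (control)
    or ``F_a(F(theta))`` (adapted); the measurement is von Mises around that
    position with concentration ``kappa_eff`` in the final space.
    """

    def __init__(
        self,
        stationary: StationaryParams,
        kernel: Optional[KernelParams] = None,
        adaptor_deg: Optional[float] = None,
        n_grid: int = DEFAULT_N_GRID,
    ):
        if (kernel is None) != (adaptor_deg is None):
            raise ParameterError("kernel and adaptor must be supplied together")
        self.stationary = stationary
        self.adaptor_deg = None if adaptor_deg is None else float(adaptor_deg)
        self.n_grid = int(n_grid)

        self.field_stimulus = stationary_sqrt_fisher(stationary, n_grid)
        self.F = build_transform(self.field_stimulus)

        if kernel is not None:
            kernel = kernel.resolve(self.adaptor_deg)
        self.kernel = kernel

        if kernel is None:
            self.field_sensory = None
            self.Fa = None
            self.adaptor_sensory = None
            self.kappa_eff = stationary.kappa_i
        else:
            theta_a = float(deg_to_circle(self.adaptor_deg))
            self.adaptor_sensory = float(self.F.forward(theta_a))
            self.field_sensory = kernel_sqrt_fisher(kernel, self.adaptor_sensory, n_grid)
            self.Fa = build_transform(self.field_sensory)
            if kernel.kappa_i_adapted is not None:
                self.kappa_eff = kernel.kappa_i_adapted
            else:
                self.kappa_eff = stationary.kappa_i

        # caches used by measurement densities and sampling; the Jacobian is
        # taken from the interpolated transforms themselves so the pushforward
        # density is conservative by construction
        g = self.field_stimulus.grid
        self._encoded_grid = np.asarray(self.encode(g), dtype=float)
        jac = self.F.derivative(g)
        if self.Fa is not None:
            jac = jac * self.Fa.derivative(self.F.forward(g))
        self._jacobian_grid = jac

    # -- encoding chain ----------------------------------------------------

    @property
    def is_adapted(self) -> bool:
        return self.kernel is not None

    def encode(self, theta) -> np.ndarray:
        """Stimulus-space angle -> final sensory-space position."""
        tilde = self.F.forward(theta)
        if self.Fa is None:
            return tilde
        return self.Fa.forward(tilde)

    def decode(self, m_star) -> np.ndarray:
        """Final sensory-space position -> stimulus-space angle."""
        if self.Fa is not None:
            m_star = self.Fa.inverse(m_star)
        return self.F.inverse(m_star)

    def sqrt_j_stimulus(self, theta) -> np.ndarray:
        """Effective normalized sqrt-Fisher allocation in stimulus space.

        For the control observer this is the stationary field; for an adapted
        observer it is the derivative of the composed transform divided by
        2 pi, i.e. 2 pi * sqrt(J)(theta) * sqrt(J_a)(F(theta)).
        """
        base = self.field_stimulus(theta)
        if self.field_sensory is None:
            return base
        return TWO_PI * base * self.field_sensory(self.F.forward(theta))

    # -- densities and sampling ---------------------------------------------

    def measurement_density(self, theta_deg: float) -> "MeasurementDensity":
        """Density of the stimulus-space measurement p(m | theta).

        A von Mises with concentration ``kappa_eff`` centered at the encoded
        position, pushed back through the inverse transform chain with the
        change-of-variables Jacobian.
        """
        theta = float(deg_to_circle(theta_deg))
        mu = float(self.encode(theta))
        dens = vm_pdf(self._encoded_grid, mu, self.kappa_eff) * self._jacobian_grid
        dens = dens / (np.mean(dens) * TWO_PI)  # remove O(h^2) quadrature residue
        return MeasurementDensity(grid=self.field_stimulus.grid, density=dens,
                                  theta_deg=float(theta_deg))

    def sample_measurements(self, theta_deg: float, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw stimulus-space measurements: von Mises in the final sensory
        space (Best-Fisher sampler), mapped back through the inverse chain."""
        theta = float(deg_to_circle(theta_deg))
        mu = float(self.encode(theta))
        m_star = wrap_circle(rng.vonmises(mu, self.kappa_eff, size=n))
        if self.Fa is not None:
            m_star = self.Fa.inverse_lin(m_star)
        return self.F.inverse_lin(m_star)


@dataclass
class MeasurementDensity:
    """p(m | theta) on the stimulus-space grid; integrates to 1."""

    grid: np.ndarray
    density: np.ndarray
    theta_deg: float = 0.0

    def integral(self) -> float:
        return float(np.mean(self.density) * TWO_PI)


def adapted_model(
    stationary: StationaryParams,
    kernel: KernelParams,
    adaptor_deg: float,
    n_grid: int = DEFAULT_N_GRID,
) -> ObserverModel:
    """Observer adapted to ``adaptor_deg`` (stimulus degrees) via ``kernel``."""
    return ObserverModel(stationary, kernel=kernel, adaptor_deg=adaptor_deg, n_grid=n_grid)


def control_model(stationary: StationaryParams, n_grid: int = DEFAULT_N_GRID) -> ObserverModel:
    """Pre-adaptation (control) observer."""
    return ObserverModel(stationary, n_grid=n_grid)


def measurement_density(model: ObserverModel, theta_deg: float) -> MeasurementDensity:
    return model.measurement_density(theta_deg)


def total_fisher(model: ObserverModel) -> float:
    """Total coding capacity of the observer.

    With unit-normalized allocation fields, the circular integral of sqrt(J)
    in stimulus space is 1 by construction, so total Fisher information
    reduces to the (constant) sensory-space Fisher information of a von Mises
    location measurement scaled by the squared circumference:
    J_vm(kappa_eff) * (2 pi)^2, with J_vm(kappa) = kappa I1(kappa)/I0(kappa).
    """
    return float(vm_fisher(model.kappa_eff) * TWO_PI**2)


# ---------------------------------------------------------------------------
# parameter JSON I/O
# ---------------------------------------------------------------------------

def params_to_dict(
    stationary: StationaryParams,
    kernel: Optional[KernelParams] = None,
    adaptor_deg: Optional[float] = None,
) -> dict:
    out = {"stationary": stationary.to_dict()}
    if kernel is not None:
        out["kernel"] = kernel.to_dict()
    if adaptor_deg is not None:
        out["adaptor_deg"] = adaptor_deg
    return out


def params_from_dict(d: dict):
    """Return (stationary, kernel-or-None, adaptor_deg-or-None) from JSON data."""
    stationary = StationaryParams.from_dict(d["stationary"])
    kernel = KernelParams.from_dict(d["kernel"]) if "kernel" in d and d["kernel"] else None
    return stationary, kernel, d.get("adaptor_deg")
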