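"""Staged maximum-likelihood fitting of the reallocation observer model.

The fitting procedure mirrors the two-stage design of the experiment:

1. ``fit_control`` -- the control-adaptor trials determine the stationary
   allocation and the sensory noise (k, kappa, kappa_i), i.e. the observer's
   sensory space and total coding capacity.
2. ``fit_adapted`` -- with the stationary parameters frozen, the oblique
   adaptor trials determine the reallocation kernel. For the shared-kernel
   variants (two_peak, one_peak, two_peak_fisher) the 45-degree and
   22.5-degree adaptor conditions are fit jointly with a single kernel;
   two_peak_kernel fits one kernel per adaptor.

Model variants are compared with BIC = p ln(n) - 2 lnL, n being the number
of oblique trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from ._angles import deg_to_circle, wrap_degrees
from .core_model import (
    KernelParams,
    N_FREE_PARAMS,
    ObserverModel,
    StationaryParams,
    adapted_model,
    build_transform,
    control_model,
    kernel_sqrt_fisher,
    stationary_sqrt_fisher,
)
from .decision_model import decision_table
from .errors import ConvergenceError, DegenerateDataError, ParameterError

PROB_FLOOR = 1e-12

TRIAL_COLUMNS = [
    "subject", "condition", "adaptor_deg", "test_deg",
    "reference_deg", "response_cw", "block",
]

#: optimizer bounds (natural / log space)
BOUNDS = {
    "k": (0.0, 0.5),
    "log_kappa": (np.log(0.1), np.log(100.0)),
    "log_kappa_i": (np.log(0.1), np.log(200.0)),
    "weight": (0.0, 1.0),
    "log_kappa_peak": (np.log(0.1), np.log(100.0)),
}


# ---------------------------------------------------------------------------
# trial containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trial:
    """One 2AFC trial."""

    subject: str
    condition: str               # "control" or "oblique"
    adaptor_deg: Optional[float]
    test_deg: float
    reference_deg: float
    response_cw: bool
    block: str = ""


class TrialDataset:
    """Ordered collection of trials, backed by a pandas DataFrame."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    def trials(self):
        for row in self.df.itertuples(index=False):
            adaptor = None if pd.isna(row.adaptor_deg) else float(row.adaptor_deg)
            yield Trial(row.subject, row.condition, adaptor, float(row.test_deg),
                        float(row.reference_deg), bool(row.response_cw), str(row.block))

    # -- selection -----------------------------------------------------------

    def select(self, condition: str | None = None, adaptor_deg: float | None = None) -> "TrialDataset":
        df = self.df
        if condition is not None:
            df = df[df["condition"] == condition]
        if adaptor_deg is not None:
            df = df[np.isclose(df["adaptor_deg"].to_numpy(dtype=float), adaptor_deg)]
        return TrialDataset(df.copy())

    def adaptors(self) -> list[float]:
        vals = self.df["adaptor_deg"].dropna().unique()
        return sorted(float(v) for v in vals)

    # -- I/O -------------------------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "TrialDataset":
        df = pd.read_csv(path)
        df["response_cw"] = df["response_cw"].astype(int)
        return cls(df)

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out["response_cw"] = out["response_cw"].astype(int)
        out.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def concat(cls, parts) -> "TrialDataset":
        return cls(pd.concat([p.df for p in parts], ignore_index=True))


def mirror_combine(dataset: TrialDataset) -> TrialDataset:
    """Fold negative-adaptor blocks onto their positive mirror images.

    Trials recorded under a negative (counter-clockwise) adaptor are
    reflected across vertical: adaptor, test and reference orientations are
    negated and the clockwise/counter-clockwise response is flipped. Trial
    count is conserved; control trials are untouched.
    """
    df = dataset.df.copy()
    neg = df["adaptor_deg"].to_numpy(dtype=float) < 0
    for col in ("adaptor_deg", "test_deg", "reference_deg"):
        vals = df[col].to_numpy(dtype=float)
        flipped = wrap_degrees(-vals[neg])
        flipped[flipped == -90.0] = 90.0
        vals[neg] = flipped
        df[col] = vals
    resp = df["response_cw"].to_numpy().astype(bool)
    resp[neg] = ~resp[neg]
    df["response_cw"] = resp.astype(int)
    return TrialDataset(df)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _unique_pairs(df: pd.DataFrame):
    """Group trials by unique (test, reference) pair; count CW/CCW responses."""
    test = df["test_deg"].to_numpy(dtype=float)
    ref = df["reference_deg"].to_numpy(dtype=float)
    cw = df["response_cw"].to_numpy().astype(bool)
    pairs = np.column_stack([test, ref])
    uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
    n_cw = np.bincount(inv, weights=cw, minlength=len(uniq))
    n_tot = np.bincount(inv, minlength=len(uniq))
    return uniq[:, 0], uniq[:, 1], n_cw, n_tot - n_cw


def _nll_from_probs(p_cw, n_cw, n_ccw):
    p = np.clip(p_cw, PROB_FLOOR, 1.0 - PROB_FLOOR)
    clamped = int(np.sum(((p_cw < PROB_FLOOR) & (n_cw > 0))
                         | ((p_cw > 1.0 - PROB_FLOOR) & (n_ccw > 0))))
    nll = -float(np.sum(n_cw * np.log(p) + n_ccw * np.log1p(-p)))
    return nll, clamped


class _ControlNLL:
    """Memoized control-condition negative log-likelihood over (k, kappa, kappa_i)."""

    def __init__(self, dataset: TrialDataset, n_grid: int):
        if len(dataset) == 0:
            raise DegenerateDataError("empty dataset")
        self.test, self.ref, self.n_cw, self.n_ccw = _unique_pairs(dataset.df)
        self.theta_t = deg_to_circle(self.test)
        self.theta_r = deg_to_circle(self.ref)
        self.n_grid = n_grid
        self.n = len(dataset)
        self.clamped = 0

    def __call__(self, x) -> float:
        k, kappa, kappa_i = x[0], np.exp(x[1]), np.exp(x[2])
        try:
            params = StationaryParams(k=k, kappa=kappa, kappa_i=kappa_i)
        except ParameterError:
            return 1e12
        field = stationary_sqrt_fisher(params, self.n_grid)
        F = build_transform(field)
        mu_t = F.forward_lin(self.theta_t)
        mu_r = F.forward_lin(self.theta_r)
        tab = decision_table(kappa_i, n_grid=self.n_grid)
        p = tab(mu_r - mu_t)
        nll, self.clamped = _nll_from_probs(p, self.n_cw, self.n_ccw)
        return nll


class _AdaptedNLL:
    """Joint oblique-condition NLL over kernel parameters, stationary frozen.

    The stationary field, transform and per-adaptor sensory-space encodings
    are computed once; each evaluation only rebuilds the kernel field, its
    transform and the decision table.
    """

    def __init__(self, datasets_by_adaptor: dict, stationary: StationaryParams,
                 variant: str, n_grid: int):
        self.variant = variant
        self.n_grid = n_grid
        self.stationary = stationary
        field = stationary_sqrt_fisher(stationary, n_grid)
        self.F = build_transform(field)
        self.conditions = []
        self.n = 0
        for adaptor_deg, ds in sorted(datasets_by_adaptor.items()):
            if len(ds) == 0:
                raise DegenerateDataError(f"empty dataset for adaptor {adaptor_deg}")
            test, ref, n_cw, n_ccw = _unique_pairs(ds.df)
            tilde_t = self.F.forward_lin(deg_to_circle(test))
            tilde_r = self.F.forward_lin(deg_to_circle(ref))
            tilde_a = float(self.F.forward_lin(deg_to_circle(adaptor_deg)))
            self.conditions.append(dict(
                adaptor_deg=float(adaptor_deg), tilde_a=tilde_a,
                tilde_t=tilde_t, tilde_r=tilde_r, n_cw=n_cw, n_ccw=n_ccw,
            ))
            self.n += len(ds)
        self.clamped = 0

    def kernel_from_x(self, x) -> KernelParams:
        """Natural kernel parameters from the optimizer vector.

        Simplex constraint k1 + k2 <= 1 is enforced by the reparameterization
        k1 = a, k2 = b (1 - a) with a, b in [0, 1]; concentrations in log
        space.
        """
        if self.variant == "one_peak":
            return KernelParams(variant="one_peak", k1=x[0], kappa1=np.exp(x[1]))
        k1 = x[0]
        k2 = x[1] * (1.0 - x[0])
        kp = dict(k1=k1, k2=k2, kappa1=np.exp(x[2]), kappa2=np.exp(x[3]))
        if self.variant == "two_peak_fisher":
            return KernelParams(variant="two_peak_fisher", kappa_i_adapted=np.exp(x[4]), **kp)
        return KernelParams(variant="two_peak", **kp)

    def __call__(self, x) -> float:
        try:
            kernel = self.kernel_from_x(x)
        except ParameterError:
            return 1e12
        kappa_eff = kernel.kappa_i_adapted or self.stationary.kappa_i
        tab = decision_table(kappa_eff, n_grid=self.n_grid)
        total = 0.0
        clamped = 0
        for cond in self.conditions:
            field_a = kernel_sqrt_fisher(kernel, cond["tilde_a"], self.n_grid)
            Fa = build_transform(field_a)
            mu_t = Fa.forward_lin(cond["tilde_t"])
            mu_r = Fa.forward_lin(cond["tilde_r"])
            p = tab(mu_r - mu_t)
            nll, c = _nll_from_probs(p, cond["n_cw"], cond["n_ccw"])
            total += nll
            clamped += c
        self.clamped = clamped
        return total


def negative_log_likelihood(
    param_vector,
    dataset: TrialDataset,
    variant: str = "control",
    fixed_stationary: Optional[StationaryParams] = None,
    n_grid: int = 1024,
    return_details: bool = False,
):
    """Negative log-likelihood of the observer model on a trial dataset.

    ``param_vector`` is in natural units: (k, kappa, kappa_i) for the control
    stage, (k1, kappa1) for one_peak, (k1, k2, kappa1, kappa2[, kappa_i_a])
    for the two-peak variants. Oblique datasets may contain several adaptors,
    which share the kernel. Probabilities are clamped at 1e-12; the clamp
    count is available via ``return_details``.
    """
    x = np.asarray(param_vector, dtype=float)
    if variant == "control":
        fn = _ControlNLL(dataset, n_grid)
        nll = fn(np.array([x[0], np.log(x[1]), np.log(x[2])]))
    else:
        if fixed_stationary is None:
            raise ParameterError("kernel variants require fixed_stationary")
        by_adaptor = {a: dataset.select(adaptor_deg=a) for a in dataset.adaptors()}
        fn = _AdaptedNLL(by_adaptor, fixed_stationary, variant, n_grid)
        if variant == "one_peak":
            z = np.array([x[0], np.log(x[1])])
        else:
            k1, k2 = x[0], x[1]
            b = 0.0 if k1 >= 1.0 else k2 / (1.0 - k1)
            z = [k1, b, np.log(x[2]), np.log(x[3])]
            if variant == "two_peak_fisher":
                z.append(np.log(x[4]))
            z = np.array(z)
        nll = fn(z)
    if return_details:
        return nll, fn.clamped
    return nll


def naive_negative_log_likelihood(
    param_vector, dataset, variant="control", fixed_stationary=None, n_grid=1024,
):
    """Per-trial (non-memoized) NLL; reference path for testing the memoization.

    Uses the same transform interpolation and decision table as the memoized
    path so the two differ only in the trial bookkeeping.
    """
    x = np.asarray(param_vector, dtype=float)
    total = 0.0
    if variant == "control":
        model = control_model(StationaryParams(x[0], x[1], x[2]), n_grid=n_grid)
        models = {None: model}
    else:
        if variant == "one_peak":
            kernel = KernelParams(variant="one_peak", k1=x[0], kappa1=x[1])
        elif variant == "two_peak":
            kernel = KernelParams(variant="two_peak", k1=x[0], k2=x[1], kappa1=x[2], kappa2=x[3])
        else:
            kernel = KernelParams(variant="two_peak_fisher", k1=x[0], k2=x[1],
                                  kappa1=x[2], kappa2=x[3], kappa_i_adapted=x[4])
        models = {a: adapted_model(fixed_stationary, kernel, a, n_grid=n_grid)
                  for a in dataset.adaptors()}
    tables = {a: decision_table(m, n_grid=n_grid) for a, m in models.items()}

    def encode_lin(model, theta):
        tilde = model.F.forward_lin(theta)
        return tilde if model.Fa is None else model.Fa.forward_lin(tilde)

    for trial in dataset.trials():
        key = trial.adaptor_deg if variant != "control" else None
        model, tab = models[key], tables[key]
        mu_t = encode_lin(model, float(deg_to_circle(trial.test_deg)))
        mu_r = encode_lin(model, float(deg_to_circle(trial.reference_deg)))
        p = float(tab(mu_r - mu_t))
        p = min(max(p, PROB_FLOOR), 1.0 - PROB_FLOOR)
        total -= np.log(p if trial.response_cw else 1.0 - p)
    return total


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: object               # StationaryParams or KernelParams
    log_likelihood: float
    n_params: int
    bic: float
    convergence: bool
    n_restarts_used: int
    variant: str = "control"
    clamped: int = 0
    meta: dict = dc_field(default_factory=dict)


def _multistart(objective, bounds, n_restarts, seed, x_center=None):
    """L-BFGS-B from Latin-hypercube starts; returns (x_best, nll_best, n_ok)."""
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
    starts = lo + sampler.random(n=max(n_restarts, 1)) * (hi - lo)
    if x_center is not None:
        starts[0] = np.clip(x_center, lo, hi)
    best_x, best_f, n_ok = None, np.inf, 0
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 200, "ftol": 1e-9})
        if np.isfinite(res.fun):
            n_ok += 1
            if res.fun < best_f:
                best_f, best_x = float(res.fun), res.x
    if best_x is None:
        raise ConvergenceError("no optimizer restart produced a finite likelihood")
    return best_x, best_f, n_ok


def fit_control(
    dataset: TrialDataset,
    n_grid: int = 1024,
    n_restarts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Stage 1: stationary parameters (k, kappa, kappa_i) from control trials."""
    if len(dataset) == 0:
        raise DegenerateDataError("empty control dataset")
    fn = _ControlNLL(dataset, n_grid)
    bounds = [BOUNDS["k"], BOUNDS["log_kappa"], BOUNDS["log_kappa_i"]]
    center = np.array([0.2, np.log(3.0), np.log(10.0)])
    x, f, n_ok = _multistart(fn, bounds, n_restarts, seed, x_center=center)
    params = StationaryParams(k=float(x[0]), kappa=float(np.exp(x[1])),
                              kappa_i=float(np.exp(x[2])))
    n = len(dataset)
    p = N_FREE_PARAMS["control"]
    fn(x)  # refresh clamp counter at the optimum
    return FitResult(params=params, log_likelihood=-f, n_params=p,
                     bic=p * np.log(n) + 2 * f, convergence=n_ok > 0,
                     n_restarts_used=n_ok, variant="control", clamped=fn.clamped,
                     meta={"n_trials": n, "n_grid": n_grid, "seed": seed})


def _fit_kernel_shared(datasets_by_adaptor, stationary, variant, n_grid, n_restarts, seed):
    fn = _AdaptedNLL(datasets_by_adaptor, stationary, variant, n_grid)
    if variant == "one_peak":
        bounds = [BOUNDS["weight"], BOUNDS["log_kappa_peak"]]
        center = np.array([0.3, np.log(5.0)])
    else:
        bounds = [BOUNDS["weight"], BOUNDS["weight"],
                  BOUNDS["log_kappa_peak"], BOUNDS["log_kappa_peak"]]
        center = np.array([0.3, 0.2, np.log(6.0), np.log(3.0)])
        if variant == "two_peak_fisher":
            bounds.append(BOUNDS["log_kappa_i"])
            center = np.append(center, np.log(stationary.kappa_i))
    x, f, n_ok = _multistart(fn, bounds, n_restarts, seed, x_center=center)
    kernel = fn.kernel_from_x(x)
    fn(x)
    return kernel, f, n_ok, fn.clamped, fn.n


def fit_adapted(
    dataset: TrialDataset,
    stationary: StationaryParams,
    variant: str = "two_peak",
    n_grid: int = 1024,
    n_restarts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Stage 2: reallocation kernel from oblique trials, stationary frozen.

    ``dataset`` should be mirror-combined oblique trials; all adaptors it
    contains are fit jointly with a shared kernel, except for the
    two_peak_kernel variant, which fits one kernel per adaptor.
    """
    adaptors = dataset.adaptors()
    if not adaptors:
        raise DegenerateDataError("oblique dataset carries no adaptor labels")
    by_adaptor = {a: dataset.select(adaptor_deg=a) for a in adaptors}

    if variant == "two_peak_kernel":
        per, lnl, n_ok_total, clamped = {}, 0.0, 0, 0
        for a in adaptors:
            kern, f, n_ok, cl, _ = _fit_kernel_shared(
                {a: by_adaptor[a]}, stationary, "two_peak", n_grid, n_restarts, seed)
            per[a] = kern
            lnl -= f
            n_ok_total += n_ok
            clamped += cl
        params = KernelParams(variant="two_peak_kernel", per_adaptor=per)
        n = len(dataset)
        p = N_FREE_PARAMS["two_peak_kernel"]
        return FitResult(params=params, log_likelihood=lnl, n_params=p,
                         bic=p * np.log(n) - 2 * lnl, convergence=n_ok_total > 0,
                         n_restarts_used=n_ok_total, variant=variant, clamped=clamped,
                         meta={"n_trials": n, "n_grid": n_grid, "seed": seed})

    kernel, f, n_ok, clamped, n = _fit_kernel_shared(
        by_adaptor, stationary, variant, n_grid, n_restarts, seed)
    p = N_FREE_PARAMS[variant]
    return FitResult(params=kernel, log_likelihood=-f, n_params=p,
                     bic=p * np.log(n) + 2 * f, convergence=n_ok > 0,
                     n_restarts_used=n_ok, variant=variant, clamped=clamped,
                     meta={"n_trials": n, "n_grid": n_grid, "seed": seed})


def compare_models(
    control_data: TrialDataset,
    oblique_data: TrialDataset,
    n_grid: int = 1024,
    n_restarts: int = 10,
    seed: int = 0,
    variants: tuple = ("two_peak", "two_peak_fisher", "two_peak_kernel", "one_peak"),
) -> dict:
    """Staged fit of every kernel variant; BIC with n = number of oblique trials.

    Returns {"control": FitResult, <variant>: FitResult, ...}.
    """
    ctrl = fit_control(control_data, n_grid=n_grid, n_restarts=n_restarts, seed=seed)
    oblique = mirror_combine(oblique_data)
    out = {"control": ctrl}
    for variant in variants:
        out[variant] = fit_adapted(oblique, ctrl.params, variant=variant,
                                   n_grid=n_grid, n_restarts=n_restarts, seed=seed)
    return out
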