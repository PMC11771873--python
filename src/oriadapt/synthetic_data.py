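"""Synthetic ground-truth data for every pipeline stage.

Two generators:

* ``simulate_experiment`` -- 2AFC orientation-discrimination trials produced
  by a known observer model under the adaptive experimental design: per test
  orientation, a 2-up-1-down staircase over 25 equally spaced reference-offset
  magnitudes, 192 trials per orientation, a control condition and two oblique
  adaptor conditions (45 and 22.5 degrees) with their characteristic test
  orientation sets.
* ``synth_frame_stack`` -- gaze-referenced grayscale video whose per-region
  latent orientation evolves as a wrapped autoregressive process with a
  controllable persistence, rendered as band-limited oriented texture. Stable
  regions produce low-circular-variance orientation histories that predict
  the next frame; unstable regions produce uniform next-frame distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from ._angles import wrap_degrees
from .core_model import (
    KernelParams,
    ObserverModel,
    StationaryParams,
    adapted_model,
    control_model,
    params_to_dict,
)
from .scene_stats import FrameStack

N_STAIRCASE_STEPS = 25

#: test orientations relative to the adaptor, as used in the experiment
TEST_OFFSETS = {
    45.0: (0.0, 10.0, -10.0, 30.0, -30.0, 45.0, -45.0, 90.0),
    22.5: (0.0, 10.0, -10.0, 22.5, -22.5, 45.0, -45.0, 90.0),
}


# ---------------------------------------------------------------------------
# experiment design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StaircaseSpec:
    """2-up-1-down staircase over 25 equally spaced offset magnitudes.

    The state indexes the magnitude lattice linspace(0, range_deg, 25);
    harder = smaller magnitude. The sign of the reference offset is
    randomized per trial.
    """

    range_deg: float = 15.0      # one of the ranges used in the experiment
    n_steps: int = N_STAIRCASE_STEPS
    start_index: int = 12        # middle step

    def magnitudes(self) -> np.ndarray:
        return np.linspace(0.0, self.range_deg, self.n_steps)


@dataclass(frozen=True)
class ExperimentDesign:
    """Adaptors, test orientations and trial counts of the 2AFC experiment.

    The experiment has two parts (one per oblique adaptor); each part pairs
    its oblique condition with a control condition measured at the same test
    orientations, so the control condition covers the union of both parts'
    test sets (6144 trials total at the default 192 per orientation).
    """

    adaptors_deg: tuple = (45.0, 22.5)
    trials_per_orientation: int = 192
    staircase: StaircaseSpec = dc_field(default_factory=StaircaseSpec)
    include_control: bool = True

    def test_orientations(self, adaptor_deg: float) -> np.ndarray:
        offsets = np.asarray(TEST_OFFSETS[float(adaptor_deg)])
        tests = wrap_degrees(adaptor_deg + offsets)
        tests[tests == -90.0] = 90.0
        return tests

    def control_test_orientations(self) -> list:
        """Per-part control test sets (one array per adaptor condition)."""
        return [self.test_orientations(a) for a in self.adaptors_deg]


@dataclass
class StaircaseState:
    level: int
    streak: int = 0  # consecutive correct responses since the last move


def staircase_update(state: StaircaseState, response_correct: bool,
                     n_steps: int = N_STAIRCASE_STEPS) -> StaircaseState:
    """One 2-up-1-down transition, clamped at the lattice boundaries.

    Two consecutive correct responses move one level toward harder (smaller
    offset magnitude); a single incorrect response moves one level easier.
    """
    if not 0 <= state.level < n_steps:
        raise ValueError(f"staircase level {state.level} outside [0, {n_steps - 1}]")
    if response_correct:
        streak = state.streak + 1
        if streak >= 2:
            return StaircaseState(level=max(state.level - 1, 0), streak=0)
        return StaircaseState(level=state.level, streak=streak)
    return StaircaseState(level=min(state.level + 1, n_steps - 1), streak=0)


def _run_staircase(model: ObserverModel, test_deg: float, n_trials: int,
                   spec: StaircaseSpec, rng: np.random.Generator):
    """Simulate one staircase; returns (reference_deg, response_cw) arrays.

    Correctness for the staircase bookkeeping uses the sign of the true
    offset (the subject received no feedback; the adaptive procedure still
    tracks it internally). A clockwise response is correct when the
    reference truly is clockwise, i.e. the offset is negative.
    """
    from ._angles import deg_to_circle, wrap_circle

    mags = spec.magnitudes()
    state = StaircaseState(level=spec.start_index)
    refs = np.empty(n_trials)
    resps = np.zeros(n_trials, dtype=bool)

    # fast generative path: encode the test and every lattice reference once
    lattice = wrap_degrees(test_deg + np.concatenate([-mags, mags]))
    mu_lattice = np.asarray(model.encode(deg_to_circle(lattice)), dtype=float)
    mu_t = float(model.encode(float(deg_to_circle(test_deg))))
    kappa = model.kappa_eff

    signs = np.where(rng.random(n_trials) < 0.5, -1.0, 1.0)
    for i in range(n_trials):
        level = state.level
        offset = signs[i] * mags[level]
        idx = level if signs[i] < 0 else spec.n_steps + level
        mu_r = mu_lattice[idx]
        m_t = rng.vonmises(mu_t, kappa)
        m_r = rng.vonmises(mu_r, kappa)
        cw = bool(wrap_circle(m_r - m_t) < 0)
        refs[i] = lattice[idx]
        resps[i] = cw
        correct = cw == (offset < 0 if offset != 0 else signs[i] < 0)
        state = staircase_update(state, correct, spec.n_steps)
    return refs, resps


def simulate_experiment(
    stationary: StationaryParams,
    kernel: KernelParams,
    design: ExperimentDesign = ExperimentDesign(),
    rng_seed: int = 0,
    subject: str = "synth",
    n_grid: int = 1024,
):
    """Simulate the full staged experiment from a known ground-truth observer.

    Returns (TrialDataset, ground_truth dict). The control condition uses the
    stationary observer; each oblique condition uses the kernel recentered at
    its adaptor.
    """
    from .inference import TrialDataset

    rng = np.random.default_rng(rng_seed)
    rows = []

    def run_condition(model, condition, adaptor_deg, tests):
        for test in tests:
            refs, resps = _run_staircase(
                model, float(test), design.trials_per_orientation, design.staircase, rng)
            for r, resp in zip(refs, resps):
                rows.append((subject, condition, adaptor_deg, float(test),
                             float(r), int(resp), f"{condition}"))

    if design.include_control:
        ctrl = control_model(stationary, n_grid=n_grid)
        for tests in design.control_test_orientations():
            run_condition(ctrl, "control", np.nan, tests)
    for adaptor in design.adaptors_deg:
        model = adapted_model(stationary, kernel, adaptor, n_grid=n_grid)
        run_condition(model, "oblique", float(adaptor),
                      design.test_orientations(adaptor))

    df = pd.DataFrame(rows, columns=[
        "subject", "condition", "adaptor_deg", "test_deg",
        "reference_deg", "response_cw", "block"])
    truth = params_to_dict(stationary, kernel)
    truth.update(adaptors_deg=list(design.adaptors_deg),
                 trials_per_orientation=design.trials_per_orientation,
                 staircase_range_deg=design.staircase.range_deg,
                 rng_seed=rng_seed)
    return TrialDataset(df), truth


# ---------------------------------------------------------------------------
# gaze-video generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneSpec:
    """Synthetic gaze-video with controlled temporal orientation statistics.

    The gaze-centered patch is tiled with square regions. Each region carries
    a latent orientation that jitters (von Mises with concentration
    ``orientation_noise_kappa`` on the doubled angle) around an anchor; the
    anchor persists from frame to frame with probability ``persistence`` and
    is otherwise redrawn uniformly. persistence = 1 with high concentration
    gives a frozen history (circular variance ~ 0); persistence = 0 gives an
    i.i.d. uniform history (variance ~ 1). A checkerboard of regions uses
    ``persistence`` ("stable" regions) and 0 ("random" regions), so default
    videos populate both the low- and high-variance analysis bands. Frames
    render each region as oriented band-pass texture.
    """

    n_frames: int = 160
    frame_rate: float = 24.0
    patch_px: int = 96
    patch_deg: float = 6.0
    region_px: int = 32
    margin_px: int = 16
    persistence: float = 1.0
    orientation_noise_kappa: float = 200.0
    stable_fraction: float = 0.5
    rendering: str = "noise"            # "noise" or "grating"
    sf_band: tuple = (0.03, 0.2)        # cycles / pixel
    orientation_filter_sigma_deg: float = 1.4
    contrast: float = 0.9

    @property
    def deg_per_pixel(self) -> float:
        return self.patch_deg / self.patch_px

    @property
    def n_regions_side(self) -> int:
        return self.patch_px // self.region_px


def _orientation_mask(n: int, theta: float, spec: SceneSpec) -> np.ndarray:
    """Fourier-domain filter: radial band times a wrapped-Laplace orientation
    profile centered on the wavevector direction orthogonal to the contours
    (the same stimulus construction as the psychophysical noise patterns)."""
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    fr = np.hypot(fx, fy)
    band = (fr >= spec.sf_band[0]) & (fr <= spec.sf_band[1])
    wave_angle = np.arctan2(fy, fx)                 # gradient / wavevector direction
    target = theta + np.pi / 2.0
    d = np.mod(wave_angle - target + np.pi / 2.0, np.pi) - np.pi / 2.0
    scale = np.deg2rad(spec.orientation_filter_sigma_deg) / np.sqrt(2.0)
    profile = np.exp(-np.abs(d) / scale)
    if spec.rendering == "grating":
        mask = np.zeros_like(fr)
        allowed = np.where(band, profile, -np.inf)
        mask.flat[np.argmax(allowed)] = 1.0
        return mask
    return band * profile


def _oriented_texture(noise_fft: np.ndarray, theta: float, spec: SceneSpec) -> np.ndarray:
    """Render one region: filter the region's fixed noise at ``theta``.

    The noise pattern is fixed per region so that a frozen latent orientation
    produces identical frames; all frame-to-frame variation comes from the
    latent dynamics.
    """
    mask = _orientation_mask(noise_fft.shape[0], theta, spec)
    img = np.real(np.fft.ifft2(noise_fft * mask))
    peak = np.max(np.abs(img))
    if peak > 0:
        img = img / peak
    return 0.5 + 0.5 * spec.contrast * img


def synth_frame_stack(spec: SceneSpec = SceneSpec(), rng_seed: int = 0):
    """Generate a synthetic gaze video.

    Returns (FrameStack, ground_truth) where ground_truth holds the latent
    per-region orientations (radians, (T, R, R)), the per-region persistence
    map and the region edge length in pixels.
    """
    rng = np.random.default_rng(rng_seed)
    R = spec.n_regions_side
    T = spec.n_frames

    stable = np.indices((R, R)).sum(axis=0) % 2 == 0  # checkerboard
    if spec.stable_fraction <= 0:
        stable[:] = False
    elif spec.stable_fraction >= 1:
        stable[:] = True
    persistence = np.where(stable, spec.persistence, 0.0)

    # latent orientations on doubled angles: each region jitters around an
    # anchor that is redrawn uniformly with probability 1 - persistence per
    # frame (stationary, so stable histories stay stable over any window)
    latent = np.empty((T, R, R))
    anchor = rng.uniform(-np.pi, np.pi, size=(R, R))  # doubled angle
    for t in range(T):
        if t > 0:
            redraw = rng.random((R, R)) >= persistence
            anchor = np.where(redraw, rng.uniform(-np.pi, np.pi, size=(R, R)), anchor)
        jitter = rng.vonmises(0.0, spec.orientation_noise_kappa, size=(R, R))
        phi = np.mod(anchor + jitter + np.pi, 2 * np.pi) - np.pi
        latent[t] = phi / 2.0

    H = W = spec.patch_px + 2 * spec.margin_px
    frames = np.full((T, H, W), 0.5)
    m = spec.margin_px
    noise_fft = np.fft.fft2(
        rng.standard_normal((R, R, spec.region_px, spec.region_px)), axes=(-2, -1))
    for t in range(T):
        for i in range(R):
            for j in range(R):
                tex = _oriented_texture(noise_fft[i, j], latent[t, i, j], spec)
                y0 = m + i * spec.region_px
                x0 = m + j * spec.region_px
                frames[t, y0:y0 + spec.region_px, x0:x0 + spec.region_px] = tex

    gaze = np.tile([[W / 2.0, H / 2.0]], (T, 1))
    stack = FrameStack(frames=frames, frame_rate=spec.frame_rate,
                       deg_per_pixel=spec.deg_per_pixel, gaze=gaze)
    truth = {
        "latent_orientation": latent,
        "persistence_map": persistence,
        "region_px": spec.region_px,
        "margin_px": spec.margin_px,
        "stable_mask": stable,
        "rng_seed": rng_seed,
    }
    return stack, truth
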