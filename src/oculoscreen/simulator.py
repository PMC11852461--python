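"""Ground-truthed synthetic data: eye images and binocular E-series cohorts.

Two layers, both seed-deterministic:

* **Image layer** — :func:`render_eye_frame` draws a single infrared-style
  eye image (dark elliptical pupil on an iris/sclera background inside a
  palpebral fissure, bright Purkinje-style glints that may straddle the
  pupil boundary, eyelash strokes, eyelid occlusion, an illumination
  gradient and sensor noise) from a fully specified :class:`SceneTruth`, so
  extraction accuracy can be scored against exact geometry.

* **Series layer** — :func:`simulate_target_template` produces the ideal
  binocular projection trajectory for the smooth-pursuit protocol (a 70-frame
  central fixation followed by a piecewise-linear sweep through screen
  positions visited in the order 1-2-3-4-5-2 over 540 frames), and
  :func:`simulate_subject_series` / :func:`generate_cohort` perturb it into
  per-subject recordings: kappa-angle baseline offsets, measurement noise,
  blink artifacts, and — for patients — intermittent monocular deviation
  episodes with known ground-truth windows.

The study conditions emulated by the cohort defaults: 35 normal + 35 patient
subjects, 540 frames per eye, deviation amplitude 0.15 E-units in episodes
of 60 frames (at least two per patient recording), E-measurement noise
sd 0.02, and about two blinks per recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from skimage.draw import line as draw_line

from .exceptions import InvalidSceneError
from .features import SubjectSeries
from .geometry import EyeFrame, Point, PupilEllipse

# rendering gray levels (8-bit)
GRAY_SKIN = 120.0
GRAY_SCLERA = 190.0
GRAY_IRIS = 90.0
GRAY_PUPIL = 30.0
GRAY_LASH = 45.0
GRAY_GLINT = 250.0

E_CLAMP = (-0.2, 1.2)
#: horizontal screen coordinate of each numbered target position, in the
#: order visited (fixation at center, then 1-2-3-4-5-2); layout: 1 upper
#: left, 2 center, 3 upper right, 4 lower right, 5 lower left.
_TARGET_PATH_X = (0.0, -1.0, 0.0, 1.0, 1.0, -1.0, 0.0)


@dataclass
class SceneTruth:
    """Complete ground truth for one rendered eye image."""

    pupil_ellipse: PupilEllipse
    canthus_inner: Point
    canthus_outer: Point
    glint_centers: list[Point] = field(default_factory=list)
    glint_radius: float = 5.0
    eyelash_segments: list[tuple[Point, Point]] = field(default_factory=list)
    eyelid_coverage: float = 0.0
    noise_sd: float = 0.0
    illumination_tilt: float = 0.0

    def validate(self, width: int, height: int) -> None:
        if self.glint_radius <= 0:
            raise InvalidSceneError("glint_radius must be > 0")
        if not 0.0 <= self.eyelid_coverage < 0.5:
            raise InvalidSceneError("eyelid_coverage must be in [0, 0.5)")
        pe = self.pupil_ellipse
        cx, cy = pe.center
        if not (pe.a <= cx <= width - 1 - pe.a and pe.a <= cy <= height - 1 - pe.a):
            raise InvalidSceneError("pupil ellipse extends outside the image frame")
        for p in (self.canthus_inner, self.canthus_outer):
            if not (0 <= p[0] < width and 0 <= p[1] < height):
                raise InvalidSceneError("canthus point outside the image frame")


@dataclass
class SubjectProfile:
    """Generative parameters for one subject's binocular recording.

    ``deviation_amplitude`` (E-units) is the magnitude of intermittent
    deviation episodes and must be 0 for normal subjects.  ``episode_mode``
    selects sustained monocular constant-shift episodes (``"shift"``, the
    exotropia-like default, one eye per episode) or zero-mean anti-phase
    binocular oscillation (``"oscillate"``, isolating dynamic vergence
    instability: the two eyes alternate in opposite directions each frame,
    leaving their average untouched).  ``wander_amplitude`` adds benign
    anti-symmetric constant-offset gaze-vergence windows (left and right
    shifted oppositely) and is used to match static deviation statistics
    between classes in dynamics-only experiments.
    """

    label: Literal["normal", "patient"] = "normal"
    kappa_offset_left: float = 0.0
    kappa_offset_right: float = 0.0
    deviation_amplitude: float = 0.0
    episode_rate: float = 0.0
    episode_duration: int = 60
    episode_mode: Literal["shift", "oscillate"] = "shift"
    wander_amplitude: float = 0.0
    wander_rate: float = 0.0
    blink_rate: float = 0.0
    noise_sd: float = 0.0
    canthus_inner_dist: float = 60.0
    canthus_outer_dist: float = 180.0

    def __post_init__(self) -> None:
        if self.label not in ("normal", "patient"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.label == "normal" and self.deviation_amplitude != 0.0:
            raise ValueError("normal subjects must have deviation_amplitude = 0")
        if self.episode_duration < 1:
            raise ValueError("episode_duration must be >= 1")
        for name in ("episode_rate", "blink_rate", "noise_sd", "wander_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CohortPriors:
    """Distribution parameters from which per-subject profiles are drawn."""

    kappa_sd: float = 0.02
    amplitude_mean: float = 0.15
    amplitude_sd: float = 0.0
    episode_rate: float = 3.0
    episode_duration: int = 60
    blink_rate: float = 2.0
    noise_sd: float = 0.02
    inner_dist_mean: float = 60.0
    inner_dist_sd: float = 2.0
    outer_dist_mean: float = 180.0
    outer_dist_sd: float = 4.0


# ---------------------------------------------------------------------------
# image layer


def _fissure_curves(truth: SceneTruth, width: int):
    """Upper/lower eyelid curves y_u(x), y_l(x) over the fissure span."""
    (xi, yi), (xo, yo) = truth.canthus_inner, truth.canthus_outer
    x0, x1 = sorted((xi, xo))
    xs = np.arange(width, dtype=float)
    mid, half = (x0 + x1) / 2.0, max((x1 - x0) / 2.0, 1.0)
    shape = np.clip(1.0 - ((xs - mid) / half) ** 2, 0.0, None)
    yline = np.interp(xs, [xi, xo] if xi < xo else [xo, xi],
                      [yi, yo] if xi < xo else [yo, yi])
    h_open = 1.4 * truth.pupil_ellipse.b + 8.0
    y_upper = yline - h_open * (1.0 - 2.0 * truth.eyelid_coverage) * shape
    y_lower = yline + h_open * shape
    span = (xs >= x0) & (xs <= x1)
    return y_upper, y_lower, span


def render_eye_frame(
    truth: SceneTruth,
    width: int = 320,
    height: int = 240,
    seed: int = 0,
    side: str = "left",
    index: int = 0,
) -> EyeFrame:
    """Render one synthetic infrared-style eye image from exact ground truth.

    The pupil interior is the darkest large region, glints the brightest
    pixels, eyelashes thin dark strokes; additive Gaussian noise has
    sd ``truth.noise_sd`` gray levels.  Identical ``(truth, seed)`` pairs
    render bit-identical images.
    """
    if width < 64 or height < 64:
        raise InvalidSceneError("image must be at least 64x64")
    truth.validate(width, height)
    rng = np.random.default_rng(seed)

    img = np.full((height, width), GRAY_SKIN, dtype=float)
    yy, xx = np.mgrid[0:height, 0:width]

    y_upper, y_lower, span = _fissure_curves(truth, width)
    fissure = span[None, :] & (yy >= y_upper[None, :]) & (yy <= y_lower[None, :])
    img[fissure] = GRAY_SCLERA

    pe = truth.pupil_ellipse
    cx, cy = pe.center
    iris_r = 2.1 * pe.a
    iris = (xx - cx) ** 2 + (yy - cy) ** 2 <= iris_r**2
    img[fissure & iris] = GRAY_IRIS

    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    pupil = pe.contains(pts).reshape(height, width)
    img[fissure & pupil] = GRAY_PUPIL

    for (x0, y0), (x1, y1) in truth.eyelash_segments:
        rr, cc = draw_line(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
        for dy, dx in ((0, 0), (0, 1), (1, 0)):  # ~2 px stroke
            r, c = rr + dy, cc + dx
            ok = (r >= 0) & (r < height) & (c >= 0) & (c < width)
            img[r[ok], c[ok]] = GRAY_LASH

    for gx, gy in truth.glint_centers:
        glint = (xx - gx) ** 2 + (yy - gy) ** 2 <= truth.glint_radius**2
        img[glint & fissure] = GRAY_GLINT

    img += truth.illumination_tilt * (xx - width / 2.0)
    if truth.noise_sd > 0:
        img += rng.normal(0.0, truth.noise_sd, size=img.shape)

    return EyeFrame(np.clip(img, 0, 255).astype(np.uint8), side=side, index=index)


def boundary_glint_radius(pupil_radius: float, arc_fraction: float) -> float:
    """Glint radius whose disc, centered on the pupil boundary, occludes the
    given fraction of a circular pupil's boundary arc.

    For a glint of radius g centered on a circle of radius r, boundary points
    within the glint subtend an arc of 4*asin(g/(2r)); inverting gives
    g = 2 r sin(pi f / 2) for arc fraction f.
    """
    if not 0 < arc_fraction < 1:
        raise ValueError("arc_fraction must be in (0, 1)")
    return 2.0 * pupil_radius * np.sin(np.pi * arc_fraction / 2.0)


def sample_scene(
    rng: np.random.Generator,
    width: int = 320,
    height: int = 240,
    glint_arc_fraction: tuple[float, float] | None = (0.10, 0.20),
    n_eyelashes: int = 6,
    noise_sd: float = 2.0,
    illumination_tilt: float = 0.05,
) -> SceneTruth:
    """Draw a randomized scene with a boundary-straddling glint and lashes.

    The glint is centered on the pupil boundary at a random angle with its
    radius chosen so it occludes a boundary-arc fraction drawn uniformly
    from ``glint_arc_fraction`` (pass ``None`` for a glint-free scene).
    """
    a = rng.uniform(26, 34)
    b = a * rng.uniform(0.85, 1.0)
    tilt = rng.uniform(0, np.pi)
    cx = rng.uniform(width * 0.38, width * 0.62)
    cy = rng.uniform(height * 0.42, height * 0.58)
    pe = PupilEllipse((cx, cy), a, b, tilt)

    fissure_half = rng.uniform(95, 115)
    canthus_inner = (cx + fissure_half, cy + rng.uniform(-3, 3))
    canthus_outer = (cx - fissure_half, cy + rng.uniform(-3, 3))

    glints: list[Point] = []
    glint_radius = 5.0
    if glint_arc_fraction is not None:
        frac = rng.uniform(*glint_arc_fraction)
        glint_radius = boundary_glint_radius(min(a, b), frac)
        ang = rng.uniform(0, 2 * np.pi)
        glints.append(tuple(pe.point_at(ang)))

    lashes = []
    for _ in range(n_eyelashes):
        x0 = cx + rng.uniform(-1.4 * a, 1.4 * a)
        y0 = cy - 1.4 * b - rng.uniform(6, 14)
        x1 = x0 + rng.uniform(-12, 12)
        y1 = y0 + rng.uniform(18, 30)
        lashes.append(((x0, y0), (x1, y1)))

    return SceneTruth(
        pupil_ellipse=pe,
        canthus_inner=canthus_inner,
        canthus_outer=canthus_outer,
        glint_centers=glints,
        glint_radius=float(glint_radius),
        eyelash_segments=lashes,
        eyelid_coverage=float(rng.uniform(0.0, 0.12)),
        noise_sd=noise_sd,
        illumination_tilt=illumination_tilt,
    )


# ---------------------------------------------------------------------------
# series layer


def simulate_target_template(
    n_frames: int = 540,
    fixation_frames: int = 70,
    vergence_offset: float = 0.0,
    e_range: tuple[float, float] = (0.25, 0.75),
) -> tuple[np.ndarray, np.ndarray]:
    """Ideal binocular E trajectories for the pursuit protocol.

    A constant central fixation for ``fixation_frames`` frames, then a
    piecewise-linear sweep through the numbered screen positions in the
    order 1-2-3-4-5-2, whose horizontal coordinate is mapped linearly into
    ``e_range``.  The two eyes differ only by ``vergence_offset``
    (left = E + offset/2, right = E - offset/2).
    """
    if not n_frames > fixation_frames >= 0:
        raise ValueError("need n_frames > fixation_frames >= 0")
    lo, hi = e_range
    path_e = (hi + lo) / 2.0 + np.asarray(_TARGET_PATH_X) * (hi - lo) / 2.0
    n_move = n_frames - fixation_frames
    knots = np.linspace(0, n_move - 1, num=len(path_e))
    move = np.interp(np.arange(n_move), knots, path_e)
    e = np.concatenate([np.full(fixation_frames, path_e[0]), move])
    return e + vergence_offset / 2.0, e - vergence_offset / 2.0


def _sample_windows(
    rng: np.random.Generator, n_windows: int, duration: int, lo: int, hi: int
) -> list[tuple[int, int]]:
    """Sample non-overlapping [start, end) windows of fixed duration."""
    windows: list[tuple[int, int]] = []
    for _ in range(n_windows):
        for _attempt in range(200):
            start = int(rng.integers(lo, max(hi - duration, lo + 1)))
            end = min(start + duration, hi)
            if all(end <= s or start >= e for s, e in windows):
                windows.append((start, end))
                break
    return sorted(windows)


def simulate_subject_series(
    profile: SubjectProfile,
    template: tuple[np.ndarray, np.ndarray],
    seed: int = 0,
    subject_id: str = "",
    episode_start_min: int = 70,
) -> SubjectSeries:
    """Perturb the ideal template into one subject's binocular recording.

    Normal subjects: template + per-eye kappa offset + Gaussian noise +
    blink artifacts (3-8 frame dips of both eyes toward the inner canthus).
    Patients additionally receive intermittent deviation episodes: in mode
    ``"shift"`` exactly one eye (chosen per episode with probability 1/2) is
    shifted by ``+-deviation_amplitude``; in mode ``"oscillate"`` the two
    eyes alternate anti-phase with that amplitude.  Episodes start no
    earlier than ``episode_start_min`` (deviation is induced by the pursuit
    task, not the initial fixation).  Ground-truth episode windows are
    recorded on the returned series.  E values are clamped to [-0.2, 1.2]
    with the number of clamped samples logged.
    """
    rng = np.random.default_rng(seed)
    tpl_left, tpl_right = (np.asarray(t, dtype=float) for t in template)
    n = tpl_left.size
    left = tpl_left + profile.kappa_offset_left
    right = tpl_right + profile.kappa_offset_right

    if profile.noise_sd > 0:
        left = left + rng.normal(0, profile.noise_sd, n)
        right = right + rng.normal(0, profile.noise_sd, n)

    win_lo = min(episode_start_min, n - 1)
    episodes: list[tuple[int, int, str]] = []
    if profile.label == "patient" and profile.episode_rate > 0:
        n_ep = max(2, int(rng.poisson(profile.episode_rate)))
        for start, end in _sample_windows(rng, n_ep, profile.episode_duration, win_lo, n):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            if profile.episode_mode == "shift":
                eye = "left" if rng.random() < 0.5 else "right"
                target = left if eye == "left" else right
                target[start:end] += sign * profile.deviation_amplitude
            else:
                eye = "both"
                alt = sign * profile.deviation_amplitude * (-1.0) ** np.arange(end - start)
                left[start:end] += alt
                right[start:end] -= alt
            episodes.append((start, end, eye))

    if profile.wander_amplitude > 0 and profile.wander_rate > 0:
        n_w = max(2, int(rng.poisson(profile.wander_rate)))
        for start, end in _sample_windows(rng, n_w, profile.episode_duration, win_lo, n):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            left[start:end] += sign * profile.wander_amplitude
            right[start:end] -= sign * profile.wander_amplitude

    if profile.blink_rate > 0:
        n_blinks = int(rng.poisson(profile.blink_rate))
        for _ in range(n_blinks):
            dur = int(rng.integers(3, 9))
            start = int(rng.integers(0, max(n - dur, 1)))
            depth = rng.uniform(0.15, 0.35)
            bump = depth * np.bartlett(dur + 2)[1:-1]
            left[start : start + dur] -= bump[: n - start]
            right[start : start + dur] -= bump[: n - start]

    lo, hi = E_CLAMP
    n_clamped = int(np.sum((left < lo) | (left > hi) | (right < lo) | (right > hi)))
    left = np.clip(left, lo, hi)
    right = np.clip(right, lo, hi)

    return SubjectSeries(
        E_left=left,
        E_right=right,
        canthus_dists=(profile.canthus_inner_dist, profile.canthus_outer_dist),
        subject_id=subject_id,
        label=profile.label,
        episodes=episodes,
        n_clamped=n_clamped,
    )


def draw_profile(
    rng: np.random.Generator, label: str, priors: CohortPriors
) -> SubjectProfile:
    """Draw one subject's generative parameters from the cohort priors."""
    amp = 0.0
    if label == "patient":
        amp = max(0.0, rng.normal(priors.amplitude_mean, priors.amplitude_sd))
    return SubjectProfile(
        label=label,  # type: ignore[arg-type]
        kappa_offset_left=rng.normal(0, priors.kappa_sd),
        kappa_offset_right=rng.normal(0, priors.kappa_sd),
        deviation_amplitude=amp,
        episode_rate=priors.episode_rate if label == "patient" else 0.0,
        episode_duration=priors.episode_duration,
        blink_rate=priors.blink_rate,
        noise_sd=priors.noise_sd,
        canthus_inner_dist=rng.normal(priors.inner_dist_mean, priors.inner_dist_sd),
        canthus_outer_dist=rng.normal(priors.outer_dist_mean, priors.outer_dist_sd),
    )


def generate_cohort(
    n_normal: int = 35,
    n_patient: int = 35,
    priors: CohortPriors | None = None,
    seed: int = 0,
    n_frames: int = 540,
    fixation_frames: int = 70,
) -> tuple[list[SubjectSeries], list[str], list[SubjectProfile]]:
    """Generate a labeled cohort of binocular recordings.

    Returns ``(series, labels, profiles)``; the drawn profiles enable
    parameter-recovery tests.  Deterministic in ``seed``.
    """
    if n_normal < 1 or n_patient < 1:
        raise ValueError("need at least one subject per class")
    priors = priors or CohortPriors()
    rng = np.random.default_rng(seed)
    template = simulate_target_template(n_frames, fixation_frames)
    series, labels, profiles = [], [], []
    for i, label in enumerate(["normal"] * n_normal + ["patient"] * n_patient):
        profile = draw_profile(rng, label, priors)
        sid = f"{'N' if label == 'normal' else 'P'}{i:03d}"
        s = simulate_subject_series(
            profile, template, seed=int(rng.integers(2**31)), subject_id=sid
        )
        series.append(s)
        labels.append(label)
        profiles.append(profile)
    return series, labels, profiles


def generate_dynamic_signal_cohort(
    n_normal: int = 35,
    n_patient: int = 35,
    priors: CohortPriors | None = None,
    seed: int = 0,
    n_frames: int = 540,
    fixation_frames: int = 70,
) -> tuple[list[SubjectSeries], list[str], list[SubjectProfile]]:
    """Cohort in which only the deviation *dynamics* separate the classes.

    Patients receive zero-mean frame-alternating oscillation episodes; normal
    subjects receive matched constant-offset gaze-wander windows of the same
    amplitude, rate and duration.  The magnitude of the instantaneous
    deviation |D| is thereby matched between classes, so the class signal is
    confined to the first-difference statistics F13-F16.
    """
    priors = priors or CohortPriors()
    rng = np.random.default_rng(seed)
    template = simulate_target_template(n_frames, fixation_frames)
    series, labels, profiles = [], [], []
    for i, label in enumerate(["normal"] * n_normal + ["patient"] * n_patient):
        profile = draw_profile(rng, label, priors)
        if label == "patient":
            profile = replace(profile, episode_mode="oscillate")
        else:
            profile = replace(
                profile,
                wander_amplitude=priors.amplitude_mean,
                wander_rate=priors.episode_rate,
            )
        sid = f"{'N' if label == 'normal' else 'P'}{i:03d}"
        s = simulate_subject_series(
            profile, template, seed=int(rng.integers(2**31)), subject_id=sid
        )
        series.append(s)
        labels.append(label)
        profiles.append(profile)
    return series, labels, profiles
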