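"""Gaze-series featurization.

From per-frame eye geometry this module assembles, per subject, the
dimensionless projection series for each eye (``E_left``/``E_right``, default
length 540) and their per-frame mean ``E_avg``, then reduces them to a
16-component oculomotor descriptor:

======  =======================================================================
F1-F4   mean, population sd, max, min of ``E_avg``
F5, F6  mean and sd of the absolute first difference of ``E_avg``
F7, F8  inner- and outer-canthus cross-eye distances (pixels)
F9, F10 mode of each eye's E over the initial fixation window (first 70 frames)
F11,F12 mean absolute deviation of each eye from a normal standard curve
F13-F16 mean and sd of the absolute first difference of those deviations
======  =======================================================================

F1-F6 capture binocular-average kinematics, F7/F8 facial structure, F9/F10
the fixation baseline, and F11-F16 per-eye departures from normal binocular
pursuit — the dynamic signature of intermittent deviation episodes.

Variance denominators are deliberately mixed: population form (1/N) for F2,
F11, F12; 1/(N-1) for the first-difference statistics F5, F6, F13-F16.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import AlignmentError, InvalidInputError
from .geometry import CanthusPair, PupilEllipse, compute_E

FEATURE_NAMES: tuple[str, ...] = tuple(f"F{i}" for i in range(1, 17))

#: frames of the initial central-fixation window used for F9/F10
FIXATION_FRAMES = 70
#: quantization bin width for the mode of the continuous E statistic
MODE_BIN_WIDTH = 0.01
#: longest run of missing frames bridged by linear interpolation
MAX_INTERP_GAP = 10
#: missing fraction above which a subject is flagged unusable
MAX_MISSING_FRACTION = 0.20


@dataclass
class SubjectSeries:
    """Per-subject binocular E-series plus canthus geometry.

    ``E_avg`` is the elementwise mean of the two eyes.  ``canthus_dists`` is
    ``(inner, outer)`` cross-eye distance in pixels.  ``missing_left/right``
    mark frames that could not be measured (blink, occlusion) before
    imputation.
    """

    E_left: np.ndarray
    E_right: np.ndarray
    canthus_dists: tuple[float, float]
    subject_id: str = ""
    label: str | None = None
    missing_left: np.ndarray | None = None
    missing_right: np.ndarray | None = None
    episodes: list[tuple[int, int, str]] = field(default_factory=list)
    n_clamped: int = 0
    flagged: bool = False

    def __post_init__(self) -> None:
        self.E_left = np.asarray(self.E_left, dtype=float)
        self.E_right = np.asarray(self.E_right, dtype=float)
        if self.E_left.shape != self.E_right.shape or self.E_left.ndim != 1:
            raise AlignmentError("E_left and E_right must be equal-length 1-D arrays")
        for attr in ("missing_left", "missing_right"):
            m = getattr(self, attr)
            if m is None:
                setattr(self, attr, np.zeros(self.E_left.shape, dtype=bool))
            else:
                setattr(self, attr, np.asarray(m, dtype=bool))

    @property
    def n_frames(self) -> int:
        return self.E_left.size

    @property
    def E_avg(self) -> np.ndarray:
        return (self.E_left + self.E_right) / 2.0


@dataclass
class StandardCurve:
    """Frame-wise normal binocular reference trajectory per eye."""

    E_left_std: np.ndarray
    E_right_std: np.ndarray
    provenance: Literal["analytic-template", "cohort-median"] = "cohort-median"

    def __post_init__(self) -> None:
        self.E_left_std = np.asarray(self.E_left_std, dtype=float)
        self.E_right_std = np.asarray(self.E_right_std, dtype=float)
        if self.E_left_std.shape != self.E_right_std.shape:
            raise AlignmentError("standard-curve eyes must have equal length")


def impute_series(values: np.ndarray, max_gap: int = MAX_INTERP_GAP) -> np.ndarray:
    """Linearly interpolate NaN runs of length <= ``max_gap``.

    Longer gaps are left as NaN.  Leading/trailing gaps are filled by edge
    extension when short enough.
    """
    v = np.asarray(values, dtype=float).copy()
    isnan = np.isnan(v)
    if not isnan.any():
        return v
    n = v.size
    idx = np.arange(n)
    # locate runs of NaN
    run_start = None
    for i in range(n + 1):
        if i < n and isnan[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            run_len = i - run_start
            if run_len <= max_gap:
                lo, hi = run_start - 1, i
                if lo < 0 and hi < n:
                    v[run_start:i] = v[hi]
                elif hi >= n and lo >= 0:
                    v[run_start:i] = v[lo]
                elif lo >= 0 and hi < n:
                    v[run_start:i] = np.interp(idx[run_start:i], [lo, hi], [v[lo], v[hi]])
            run_start = None
    return v


def assemble_series(
    pupils_left: Sequence[PupilEllipse | None],
    canthi_left: Sequence[CanthusPair | None],
    pupils_right: Sequence[PupilEllipse | None],
    canthi_right: Sequence[CanthusPair | None],
    cross_eye_offset: tuple[float, float] = (0.0, 0.0),
    subject_id: str = "",
    label: str | None = None,
) -> SubjectSeries:
    """Build a :class:`SubjectSeries` from aligned per-frame geometry streams.

    ``cross_eye_offset`` is the rigid translation placing right-camera
    coordinates into the left camera's frame (device calibration metadata);
    it only affects the cross-eye canthus distances, not E.  Frames with a
    missing pupil or canthus pair become NaN and are bridged by linear
    interpolation when the gap is at most :data:`MAX_INTERP_GAP` frames.
    """
    n = len(pupils_left)
    if not (len(canthi_left) == len(pupils_right) == len(canthi_right) == n):
        raise AlignmentError("per-eye frame streams must have equal lengths")

    def eye_series(pupils, canthi):
        E = np.full(n, np.nan)
        for i, (pe, ca) in enumerate(zip(pupils, canthi)):
            if pe is not None and ca is not None:
                E[i] = compute_E(pe.center, ca.inner, ca.outer)
        return E

    E_left_raw = eye_series(pupils_left, canthi_left)
    E_right_raw = eye_series(pupils_right, canthi_right)
    missing_left = np.isnan(E_left_raw)
    missing_right = np.isnan(E_right_raw)
    E_left = impute_series(E_left_raw)
    E_right = impute_series(E_right_raw)

    off = np.asarray(cross_eye_offset, dtype=float)
    inner_d, outer_d = [], []
    for cl, cr in zip(canthi_left, canthi_right):
        if cl is None or cr is None:
            continue
        inner_d.append(np.hypot(*(np.asarray(cr.inner) + off - np.asarray(cl.inner))))
        outer_d.append(np.hypot(*(np.asarray(cr.outer) + off - np.asarray(cl.outer))))
    if not inner_d:
        raise InvalidInputError("no frame has canthi for both eyes")

    missing_frac = max(
        float(np.isnan(E_left).mean()), float(np.isnan(E_right).mean())
    )
    return SubjectSeries(
        E_left=E_left,
        E_right=E_right,
        canthus_dists=(float(np.median(inner_d)), float(np.median(outer_d))),
        subject_id=subject_id,
        label=label,
        missing_left=missing_left,
        missing_right=missing_right,
        flagged=missing_frac > MAX_MISSING_FRACTION,
    )


def _require_finite(arr: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if np.isnan(arr).any():
        raise InvalidInputError(f"{what} contains missing values; impute first")
    return arr


def features_global(E_avg: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """F1-F6 from the binocular-average series.

    F1 mean, F2 population sd (1/N), F3 max, F4 min, F5 mean of the absolute
    first difference (1/(N-1)), F6 sd of that absolute difference about F5
    (1/(N-1) inside the root).
    """
    e = _require_finite(E_avg, "E_avg")
    if e.size < 2:
        raise InvalidInputError("need at least 2 frames")
    n = e.size
    f1 = float(e.mean())
    f2 = float(np.sqrt(np.mean((e - f1) ** 2)))
    f3 = float(e.max())
    f4 = float(e.min())
    d = np.abs(np.diff(e))
    f5 = float(d.sum() / (n - 1))
    f6 = float(np.sqrt(np.sum((d - f5) ** 2) / (n - 1)))
    return f1, f2, f3, f4, f5, f6


def features_canthus(
    canthi_left: Sequence[CanthusPair | None],
    canthi_right: Sequence[CanthusPair | None],
    cross_eye_offset: tuple[float, float] = (0.0, 0.0),
) -> tuple[float, float]:
    """F7/F8: median cross-eye inner- and outer-canthus distances in pixels."""
    off = np.asarray(cross_eye_offset, dtype=float)
    inner, outer = [], []
    for cl, cr in zip(canthi_left, canthi_right):
        if cl is None or cr is None:
            continue
        inner.append(np.hypot(*(np.asarray(cr.inner) + off - np.asarray(cl.inner))))
        outer.append(np.hypot(*(np.asarray(cr.outer) + off - np.asarray(cl.outer))))
    if not inner:
        raise InvalidInputError("no frame has canthi for both eyes")
    return float(np.median(inner)), float(np.median(outer))


def quantized_mode(values: np.ndarray, bin_width: float = MODE_BIN_WIDTH) -> float:
    """Mode of a continuous sample after quantization to ``bin_width`` bins.

    Ties between equally-populated bins are broken toward the bin whose
    center is nearest the sample median.
    """
    v = _require_finite(values, "mode window")
    bins = np.round(v / bin_width).astype(np.int64)
    uniq, counts = np.unique(bins, return_counts=True)
    top = uniq[counts == counts.max()]
    med = np.median(v)
    best = top[np.argmin(np.abs(top * bin_width - med))]
    return float(best * bin_width)


def features_fixation_mode(
    E_left: np.ndarray,
    E_right: np.ndarray,
    window: int = FIXATION_FRAMES,
    bin_width: float = MODE_BIN_WIDTH,
) -> tuple[float, float]:
    """F9/F10: per-eye mode of E over the initial fixation window."""
    if len(E_left) < window or len(E_right) < window:
        raise InvalidInputError(f"need at least {window} frames for the fixation mode")
    return (
        quantized_mode(np.asarray(E_left[:window]), bin_width),
        quantized_mode(np.asarray(E_right[:window]), bin_width),
    )


def deviation_series(series: SubjectSeries, std: StandardCurve) -> tuple[np.ndarray, np.ndarray]:
    """Per-eye deviation D = E - E_std, elementwise."""
    if std.E_left_std.size != series.n_frames:
        raise AlignmentError(
            f"standard curve length {std.E_left_std.size} != series length {series.n_frames}"
        )
    return series.E_left - std.E_left_std, series.E_right - std.E_right_std


def features_deviation(
    Dml: np.ndarray, Dmr: np.ndarray
) -> tuple[float, float, float, float, float, float]:
    """F11-F16 from per-eye deviation series.

    F11/F12 mean of |D| (1/N); F13/F14 mean of the absolute first difference
    of D (1/(N-1)); F15/F16 sd of that absolute difference about F13/F14.
    """
    dl = _require_finite(Dml, "Dml")
    dr = _require_finite(Dmr, "Dmr")
    if dl.size != dr.size:
        raise AlignmentError("deviation series must have equal length")
    if dl.size < 2:
        raise InvalidInputError("need at least 2 frames")
    n = dl.size
    f11 = float(np.abs(dl).mean())
    f12 = float(np.abs(dr).mean())
    adl = np.abs(np.diff(dl))
    adr = np.abs(np.diff(dr))
    f13 = float(adl.sum() / (n - 1))
    f14 = float(adr.sum() / (n - 1))
    f15 = float(np.sqrt(np.sum((adl - f13) ** 2) / (n - 1)))
    f16 = float(np.sqrt(np.sum((adr - f14) ** 2) / (n - 1)))
    return f11, f12, f13, f14, f15, f16


def build_standard_curve(
    training_series: Sequence[SubjectSeries],
    mode: Literal["cohort-median", "analytic-template"] = "cohort-median",
    normal_label: str = "normal",
    template: tuple[np.ndarray, np.ndarray] | None = None,
) -> StandardCurve:
    """Build the normal binocular reference trajectory.

    ``cohort-median`` takes the per-frame median across normal-labeled
    training subjects for each eye (requires >= 3 normals, else falls back
    to the analytic template).  ``analytic-template`` uses the ideal target
    trajectory rescaled to the training subjects' fixation modes.
    """
    normals = [s for s in training_series if s.label == normal_label]
    if mode == "cohort-median" and len(normals) >= 3:
        left = np.median(np.stack([s.E_left for s in normals]), axis=0)
        right = np.median(np.stack([s.E_right for s in normals]), axis=0)
        return StandardCurve(left, right, provenance="cohort-median")
    if template is None:
        from .simulator import simulate_target_template

        n = training_series[0].n_frames if training_series else 540
        template = simulate_target_template(n_frames=n)
    left, right = (np.asarray(t, dtype=float).copy() for t in template)
    if normals:
        # shift the ideal template to the cohort's fixation baseline
        f9s = [features_fixation_mode(s.E_left, s.E_right)[0] for s in normals]
        f10s = [features_fixation_mode(s.E_left, s.E_right)[1] for s in normals]
        left += np.median(f9s) - np.median(left[:FIXATION_FRAMES])
        right += np.median(f10s) - np.median(right[:FIXATION_FRAMES])
    return StandardCurve(left, right, provenance="analytic-template")


def build_feature_vector(series: SubjectSeries, std: StandardCurve) -> np.ndarray:
    """Concatenate F1-F16 for one subject (order fixed, length 16)."""
    f1_6 = features_global(series.E_avg)
    f7, f8 = series.canthus_dists
    f9, f10 = features_fixation_mode(series.E_left, series.E_right)
    dml, dmr = deviation_series(series, std)
    f11_16 = features_deviation(dml, dmr)
    vec = np.array([*f1_6, f7, f8, f9, f10, *f11_16], dtype=float)
    assert vec.size == 16
    return vec


class GazeFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer from :class:`SubjectSeries` lists to the 16-feature matrix.

    ``fit`` learns the normal standard curve from the *training* subjects
    only (their labels are taken from ``y`` when given, else from each
    series' ``label`` attribute), so that standard-curve-dependent features
    F11-F16 never leak information from held-out subjects.

    Parameters
    ----------
    standard_mode :
        ``"cohort-median"`` (default) or ``"analytic-template"``.
    normal_label :
        Label value identifying normal subjects (default ``"normal"``).
    """

    def __init__(
        self,
        standard_mode: str = "cohort-median",
        normal_label: str = "normal",
    ) -> None:
        self.standard_mode = standard_mode
        self.normal_label = normal_label

    def fit(self, X: Sequence[SubjectSeries], y: Sequence[str] | None = None):
        series = list(X)
        if y is not None:
            labeled = []
            for s, lab in zip(series, y):
                if s.label != lab:
                    s = SubjectSeries(
                        E_left=s.E_left,
                        E_right=s.E_right,
                        canthus_dists=s.canthus_dists,
                        subject_id=s.subject_id,
                        label=str(lab),
                    )
                labeled.append(s)
            series = labeled
        self.standard_curve_ = build_standard_curve(
            series, mode=self.standard_mode, normal_label=self.normal_label
        )
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def transform(self, X: Sequence[SubjectSeries]) -> np.ndarray:
        if not hasattr(self, "standard_curve_"):
            raise InvalidInputError("GazeFeaturizer must be fit before transform")
        return np.stack([build_feature_vector(s, self.standard_curve_) for s in X])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
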