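"""Core geometric types and the pupil-canthus projection statistic.

Coordinates are image pixels: origin at the top-left corner, x to the
right, y down, 0-based.  All downstream modules share this frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import UndefinedEError

Point = tuple[float, float]


@dataclass
class EyeFrame:
    """One grayscale eye image with its side tag and frame index."""

    image: np.ndarray
    side: str = "left"
    index: int = 0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError("EyeFrame.image must be a 2-D grayscale array")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


def as_image(frame) -> np.ndarray:
    """Accept an :class:`EyeFrame` or a bare 2-D array; return the array."""
    if isinstance(frame, EyeFrame):
        return frame.image
    arr = np.asarray(frame)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    return arr


@dataclass(frozen=True)
class PupilEllipse:
    """Fitted pupil ellipse: center O, semi-axes a >= b, tilt in [0, pi).

    ``tilt`` is the angle of the major axis measured from the image x-axis
    (y down), in radians.
    """

    center: Point
    a: float
    b: float
    tilt: float

    def __post_init__(self) -> None:
        a, b, tilt = self.a, self.b, self.tilt
        if b > a:
            a, b = b, a
            tilt = tilt + np.pi / 2
        tilt = float(np.mod(tilt, np.pi))
        if not (a >= b > 0):
            raise ValueError(f"ellipse axes must satisfy a >= b > 0, got a={a}, b={b}")
        object.__setattr__(self, "a", float(a))
        object.__setattr__(self, "b", float(b))
        object.__setattr__(self, "tilt", tilt)
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))

    def point_at(self, theta: float | np.ndarray) -> np.ndarray:
        """Boundary point(s) at parametric angle ``theta`` (shape (..., 2))."""
        ct, st = np.cos(self.tilt), np.sin(self.tilt)
        x = self.a * np.cos(theta)
        y = self.b * np.sin(theta)
        return np.stack(
            [self.center[0] + x * ct - y * st, self.center[1] + x * st + y * ct],
            axis=-1,
        )

    def contains(self, pts: np.ndarray, pad: float = 0.0) -> np.ndarray:
        """Boolean mask of points inside the ellipse grown by ``pad`` pixels."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        d = pts - np.asarray(self.center)
        ct, st = np.cos(self.tilt), np.sin(self.tilt)
        u = d[:, 0] * ct + d[:, 1] * st
        v = -d[:, 0] * st + d[:, 1] * ct
        return (u / (self.a + pad)) ** 2 + (v / (self.b + pad)) ** 2 <= 1.0


@dataclass
class CanthusPair:
    """Inner (nasal) and outer (temporal) eye-corner landmarks for one frame."""

    inner: Point
    outer: Point
    confidence_inner: float = 1.0
    confidence_outer: float = 1.0

    def __post_init__(self) -> None:
        if tuple(self.inner) == tuple(self.outer):
            raise ValueError("inner and outer canthus must be distinct points")

    @property
    def fissure_length(self) -> float:
        return float(np.hypot(self.outer[0] - self.inner[0], self.outer[1] - self.inner[1]))


@dataclass
class EyeGeometry:
    """Per-frame pupil center plus canthi and the scalar projection E."""

    pupil_center: Point
    canthi: CanthusPair
    E: float = field(init=False)

    def __post_init__(self) -> None:
        self.E = compute_E(self.pupil_center, self.canthi.inner, self.canthi.outer)


def compute_E(P: Point, CI: Point, CO: Point) -> float:
    """Normalized projection of the pupil center onto the palpebral-fissure axis.

    E = (CIP . CICO) / |CICO|^2 — the signed fraction of the inner-to-outer
    canthus baseline at which the pupil center projects.  E = 0 at the inner
    canthus, E = 1 at the outer; the component of CIP orthogonal to the
    baseline does not contribute.

    Raises
    ------
    UndefinedEError
        If CI and CO coincide.
    """
    ci = np.asarray(CI, dtype=float)
    co = np.asarray(CO, dtype=float)
    p = np.asarray(P, dtype=float)
    axis = co - ci
    denom = float(axis @ axis)
    if denom == 0.0:
        raise UndefinedEError("inner and outer canthus coincide; E is undefined")
    return float((p - ci) @ axis / denom)
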