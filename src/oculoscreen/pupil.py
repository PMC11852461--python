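"""Pupil ellipse extraction with constraint-based boundary refinement.

The pipeline is: Gaussian preprocessing, dark-region binarization, ordered
contour tracing, a coarse direct least-squares ellipse fit, and then a
refinement pass that screens every boundary point against three geometric
constraints before refitting:

1. **Curvature direction** — the local tangent (the chord through the
   point's neighbors) must be approximately perpendicular to the radial
   direction from the coarse center: |cos(angle(OC, PN))| < 0.3.
2. **Convexity** — the discrete second difference of the chain at the point
   must point toward the coarse center (obtuse angle with OC, cosine < 0).
3. **Radial extent** — the distance |OC| must lie in the annulus
   (b - delta_lo, a + delta_hi) around the coarse fit.

Points violating any constraint — typically those displaced by a corneal
glint straddling the boundary, by eyelashes, or by eyelid occlusion — are
discarded and the ellipse is refit on the survivors.  If fewer than 5
points (or under 10% of the chain) survive, the coarse fit is returned
flagged as refinement-degraded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import EllipseModel, label as cc_label

from .exceptions import (
    FitFailureError,
    InvalidInputError,
    NoPupilFoundError,
    UntraceableError,
)
from .geometry import EyeFrame, Point, PupilEllipse, as_image


@dataclass
class PupilConfig:
    """Tunable parameters of the extraction pipeline."""

    blur_kernel: int = 5
    min_area: int = 100
    cos_threshold: float = 0.3
    delta_hi: float = 3.0
    delta_lo: float = 1.5
    neighbor_stride: int = 4
    fill_glint_holes: bool = False
    max_refine_iter: int = 1
    #: mask area below this fraction of the running median flags a blink
    blink_area_fraction: float = 0.30


@dataclass
class BoundaryChain:
    """Ordered closed pixel contour of the pupil component ((x, y) points)."""

    points: np.ndarray
    source_image_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InvalidInputError("BoundaryChain.points must be (N, 2)")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PupilResult:
    """Per-frame extraction outcome: ellipse (or None) plus quality flags."""

    ellipse: PupilEllipse | None
    coarse: PupilEllipse | None = None
    flags: set[str] = field(default_factory=set)
    n_boundary: int = 0
    n_survivors: int = 0
    mask_area: int = 0

    @property
    def ok(self) -> bool:
        return self.ellipse is not None


def preprocess(frame, blur_kernel: int = 5):
    """Gaussian denoising; preserves dtype and shape.

    ``blur_kernel`` is the odd window size; the Gaussian sigma follows the
    usual 0.3*((k-1)/2 - 1) + 0.8 convention.
    """
    img = as_image(frame)
    if img.size == 0:
        raise InvalidInputError("empty image")
    sigma = 0.3 * ((blur_kernel - 1) * 0.5 - 1) + 0.8
    out = ndimage.gaussian_filter(img.astype(float), sigma=sigma, mode="nearest")
    out = out.astype(img.dtype) if np.issubdtype(img.dtype, np.integer) else out.astype(img.dtype)
    if isinstance(frame, EyeFrame):
        return EyeFrame(out, side=frame.side, index=frame.index)
    return out


def binarize_pupil(frame, min_area: int = 100, fill_glint_holes: bool = False) -> np.ndarray:
    """Segment the candidate pupil as the largest dark connected component.

    The threshold is Otsu's, computed on the darkest-quartile pixels only,
    which makes it robust to illumination gradients and to the bright
    sclera/skin dominating the histogram.  Glint holes inside the component
    are left open by default so that boundary distortion survives for the
    refinement stage to repair.
    """
    img = as_image(frame).astype(float)
    q25 = np.percentile(img, 25)
    dark = img[img <= q25]
    if dark.size == 0 or np.ptp(dark) == 0:
        raise NoPupilFoundError("image has no dark-intensity structure")
    try:
        t = threshold_otsu(dark)
    except ValueError as exc:
        raise NoPupilFoundError("degenerate dark-pixel histogram") from exc
    mask = img <= t
    labels = cc_label(mask, connectivity=2)
    if labels.max() == 0:
        raise NoPupilFoundError("no dark component found")
    areas = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(areas)) + 1
    if areas[best - 1] < min_area:
        raise NoPupilFoundError(
            f"largest dark component ({areas[best - 1]} px) below min_area={min_area}"
        )
    out = labels == best
    if fill_glint_holes:
        out = ndimage.binary_fill_holes(out)
    return out


# clockwise 8-neighborhood starting west, (row, col) offsets
_MOORE_OFFSETS = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))


def extract_boundary(mask: np.ndarray, source_image_id: str = "") -> BoundaryChain:
    """Trace the ordered outer contour of a binary component.

    Moore-neighbor tracing with Jacob's stopping criterion over the
    8-connected neighborhood; the chain is closed (first and last points are
    neighbors) and each border pixel appears once per visit.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise UntraceableError("empty mask")
    touches = (
        mask[0].any() and mask[-1].any() and mask[:, 0].any() and mask[:, -1].any()
    )
    if touches:
        raise UntraceableError("component touches all four image borders")
    m = np.pad(mask, 1)
    flat = int(np.argmax(m.ravel()))
    start = divmod(flat, m.shape[1])
    c, b = start, (start[0], start[1] - 1)
    b0 = b
    contour = [c]
    max_steps = 4 * int(mask.sum()) + 8
    for _ in range(max_steps):
        bi = _MOORE_OFFSETS.index((b[0] - c[0], b[1] - c[1]))
        for k in range(1, 9):
            o = _MOORE_OFFSETS[(bi + k) % 8]
            cand = (c[0] + o[0], c[1] + o[1])
            if m[cand]:
                prev = _MOORE_OFFSETS[(bi + k - 1) % 8]
                b = (c[0] + prev[0], c[1] + prev[1])
                c = cand
                break
        else:
            break  # isolated pixel
        if c == start and b == b0:
            break
        contour.append(c)
    pts = np.array([(col - 1, row - 1) for row, col in contour], dtype=float)
    return BoundaryChain(pts, source_image_id)


def fit_ellipse_lsq(chain: BoundaryChain | np.ndarray) -> PupilEllipse:
    """Direct algebraic least-squares ellipse fit (conic with ellipse constraint)."""
    pts = chain.points if isinstance(chain, BoundaryChain) else np.asarray(chain, float)
    if len(pts) < 5:
        raise FitFailureError(f"need >= 5 points, got {len(pts)}")
    # collinearity guard: rank of centered coordinates
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise FitFailureError("points are collinear")
    try:
        model = EllipseModel.from_estimate(pts)
    except Exception as exc:  # pragma: no cover - library-internal failures
        raise FitFailureError(str(exc)) from exc
    if not model:
        raise FitFailureError("ellipse estimation failed")
    xc, yc = model.center
    a, b = model.axis_lengths
    if not np.all(np.isfinite([xc, yc, a, b])) or min(a, b) <= 0:
        raise FitFailureError("degenerate ellipse parameters")
    return PupilEllipse((float(xc), float(yc)), float(a), float(b), float(model.theta))


def _unit(v: np.ndarray) -> np.ndarray | None:
    n = np.linalg.norm(v)
    if n == 0:
        return None
    return v / n


def constraint_curvature(
    C: Point, Pprev: Point, Nnext: Point, O: Point, cos_threshold: float = 0.3
) -> bool:
    """Tangent-perpendicularity screen: |cos(angle(OC, PN))| < threshold.

    Both vectors are normalized to unit length so the threshold is
    resolution-independent.  Zero-length vectors make the constraint
    undefined and reject the point.
    """
    oc = _unit(np.asarray(C, float) - np.asarray(O, float))
    pn = _unit(np.asarray(Nnext, float) - np.asarray(Pprev, float))
    if oc is None or pn is None:
        return False
    return bool(abs(oc @ pn) < cos_threshold)


def constraint_convexity(C: Point, Pprev: Point, Nnext: Point, O: Point) -> bool:
    """Convexity screen: the second difference (CN - PC) must make an obtuse
    angle with OC (cosine < 0), i.e. curve toward the center.

    A zero second difference (locally straight chain) is undefined and
    rejects the point.
    """
    c = np.asarray(C, float)
    d2 = np.asarray(Nnext, float) + np.asarray(Pprev, float) - 2 * c
    oc = c - np.asarray(O, float)
    nd, no = np.linalg.norm(d2), np.linalg.norm(oc)
    if nd == 0 or no == 0:
        return False
    return bool((d2 @ oc) / (nd * no) < 0)


def constraint_extent(
    C: Point, coarse: PupilEllipse, delta_hi: float = 3.0, delta_lo: float = 1.5
) -> bool:
    """Radial-extent screen: b - delta_lo < |OC| < a + delta_hi.

    ``delta_hi`` guards against keeping far outliers while not deleting too
    many true points near the major axis; ``delta_lo`` admits true boundary
    points at the minor-axis ends despite discretization.
    """
    d = float(np.hypot(C[0] - coarse.center[0], C[1] - coarse.center[1]))
    return coarse.b - delta_lo < d < coarse.a + delta_hi


def screen_boundary_points(
    chain: BoundaryChain, coarse: PupilEllipse, config: PupilConfig | None = None
) -> np.ndarray:
    """Boolean survivor mask: all three constraints applied to every point.

    Neighbors are taken at ``config.neighbor_stride`` positions along the
    closed chain, giving a longer tangent chord that is robust to pixel
    quantization.
    """
    config = config or PupilConfig()
    pts = chain.points
    n = len(pts)
    k = max(1, config.neighbor_stride)
    keep = np.zeros(n, dtype=bool)
    O = coarse.center
    for i in range(n):
        C = pts[i]
        P = pts[(i - k) % n]
        N = pts[(i + k) % n]
        keep[i] = (
            constraint_curvature(C, P, N, O, config.cos_threshold)
            and constraint_convexity(C, P, N, O)
            and constraint_extent(C, coarse, config.delta_hi, config.delta_lo)
        )
    return keep


def refine_and_refit(
    chain: BoundaryChain, coarse: PupilEllipse, config: PupilConfig | None = None
) -> tuple[PupilEllipse, set[str]]:
    """Screen the chain against the three constraints and refit on survivors.

    Returns the refined ellipse and a flag set; when fewer than 5 points or
    under 10% of the chain survive (or the refit fails), the coarse fit is
    returned with the ``"refinement-degraded"`` flag.  By default a single
    screen-and-refit pass is performed; ``config.max_refine_iter > 1``
    iterates the screen around each successive fit.
    """
    config = config or PupilConfig()
    flags: set[str] = set()
    current = coarse
    for _ in range(max(1, config.max_refine_iter)):
        keep = screen_boundary_points(chain, current, config)
        n_keep = int(keep.sum())
        if n_keep < 5 or n_keep < 0.10 * len(chain):
            return coarse, {"refinement-degraded"}
        try:
            refined = fit_ellipse_lsq(chain.points[keep])
        except FitFailureError:
            return coarse, {"refinement-degraded"}
        if (
            np.hypot(
                refined.center[0] - current.center[0],
                refined.center[1] - current.center[1],
            )
            < 1e-3
        ):
            current = refined
            break
        current = refined
    return current, flags


def extract_pupil(
    frame,
    config: PupilConfig | None = None,
    median_area: float | None = None,
) -> PupilResult:
    """Full per-frame pipeline: preprocess, binarize, trace, coarse fit, refine.

    Never raises on a bad frame: failures come back as a :class:`PupilResult`
    with ``ellipse=None`` and a ``"no-pupil"`` flag so sequence processing
    continues.  ``median_area`` (running median of recent mask areas) enables
    the ``"blink-suspect"`` flag when the current mask shrinks below 30% of it.
    """
    config = config or PupilConfig()
    result = PupilResult(ellipse=None)
    try:
        smooth = preprocess(frame, config.blur_kernel)
        mask = binarize_pupil(smooth, config.min_area, config.fill_glint_holes)
    except (NoPupilFoundError, InvalidInputError):
        result.flags.add("no-pupil")
        return result
    result.mask_area = int(mask.sum())
    if median_area is not None and result.mask_area < config.blink_area_fraction * median_area:
        result.flags.add("blink-suspect")
    try:
        chain = extract_boundary(mask)
        coarse = fit_ellipse_lsq(chain)
    except (UntraceableError, FitFailureError):
        result.flags.add("no-pupil")
        return result
    result.coarse = coarse
    result.n_boundary = len(chain)
    refined, rflags = refine_and_refit(chain, coarse, config)
    keep = screen_boundary_points(chain, coarse, config)
    result.n_survivors = int(keep.sum())
    result.flags |= rflags
    result.ellipse = refined
    return result


def extract_pupil_sequence(frames, config: PupilConfig | None = None) -> list[PupilResult]:
    """Run :func:`extract_pupil` over a frame sequence with a running-median
    mask-area reference for blink flagging (31-frame trailing window)."""
    config = config or PupilConfig()
    results: list[PupilResult] = []
    areas: list[int] = []
    for frame in frames:
        ref = float(np.median(areas[-31:])) if areas else None
        res = extract_pupil(frame, config, median_area=ref)
        if res.mask_area > 0 and "blink-suspect" not in res.flags:
            areas.append(res.mask_area)
        results.append(res)
    return results
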