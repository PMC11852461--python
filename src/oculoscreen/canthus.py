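"""Inner/outer canthus (eye-corner) landmark extraction.

Pipeline per frame: Gaussian blurring, an edge/corner response map
(Harris), coarse corner candidates restricted to the palpebral-fissure
band, per-candidate region-of-interest histogram equalization and
binarization, and fine apex localization as the extremal point of the
eyelid-junction wedge.  Confidence is the candidate's corner-response
percentile.

Side convention: in a head-mounted per-eye camera the nasal (inner)
canthus of the *left* eye lies on the image-right side, and on the
image-left side for the right eye.  Horizontally mirroring a frame and
flipping the side tag therefore swaps which corner is labeled inner.

Sequence-level tracking adds a temporal median smoother (the device is
head-mounted, so canthi are near-static) and fills failed frames from the
running median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.exposure import equalize_hist
from skimage.feature import corner_harris, corner_peaks
from skimage.filters import threshold_otsu

from .exceptions import CanthusNotFoundError, InvalidInputError
from .geometry import CanthusPair, as_image


@dataclass
class CanthusConfig:
    blur_sigma: float = 1.5
    roi_size: int = 31
    min_candidate_distance: int = 7
    corner_threshold_rel: float = 0.01
    band_margin: int = 12
    smoothing_window: int = 15


def _sclera_threshold(img: np.ndarray) -> float:
    """Gray level separating the bright sclera from the (darker) skin.

    The skin dominates the image area, so its level is near the median;
    the sclera sits near the upper intensity tail.  Midway between the two
    is robust to moderate illumination gradients.
    """
    return 0.5 * (float(np.median(img)) + float(np.percentile(img, 99.5)))


def _fissure_band(img: np.ndarray, margin: int) -> tuple[int, int]:
    """Row range containing the bright palpebral-fissure region."""
    t = _sclera_threshold(img)
    bright_rows = np.nonzero((img > t).any(axis=1))[0]
    if bright_rows.size == 0:
        raise CanthusNotFoundError("no bright fissure region found")
    return max(int(bright_rows[0]) - margin, 0), min(
        int(bright_rows[-1]) + margin, img.shape[0] - 1
    )


def _refine_apex(
    img: np.ndarray,
    candidate: tuple[int, int],
    toward: str,
    roi_size: int,
    sclera_t: float,
) -> tuple[float, float]:
    """Fine apex localization inside an equalized, binarized ROI.

    The fissure interior is brighter than the surrounding skin; after local
    histogram equalization and binarization the wedge of bright pixels ends
    at the canthus apex — the extremal-x wedge pixel in the direction of
    the corner.  The local binarization is intersected with the frame-level
    sclera threshold so that an illumination gradient across the ROI cannot
    pull bright skin into the wedge.
    """
    r, c = candidate
    h = roi_size // 2
    y0, y1 = max(r - h, 0), min(r + h + 1, img.shape[0])
    x0, x1 = max(c - h, 0), min(c + h + 1, img.shape[1])
    raw = img[y0:y1, x0:x1]
    roi = equalize_hist(raw)
    if np.ptp(roi) == 0:
        return float(c), float(r)
    wedge = (roi > threshold_otsu(roi)) & (raw > sclera_t)
    lbl, n = ndimage.label(wedge)
    if n == 0:
        return float(c), float(r)
    cr = int(np.clip(r - y0, 0, lbl.shape[0] - 1))
    cc = int(np.clip(c - x0, 0, lbl.shape[1] - 1))
    best = lbl[cr, cc]
    if best == 0:
        ys, xs = np.nonzero(lbl)
        k = np.argmin((ys - cr) ** 2 + (xs - cc) ** 2)
        best = lbl[ys[k], xs[k]]
    ys, xs = np.nonzero(lbl == best)
    idx = np.argmax(xs) if toward == "max" else np.argmin(xs)
    extremal = xs[idx]
    tie = xs == extremal
    y_apex = float(np.median(ys[tie]))
    return float(extremal + x0), float(y_apex + y0)


def extract_canthus(frame, side: str = "left", config: CanthusConfig | None = None) -> CanthusPair:
    """Locate inner and outer canthi in one eye image.

    Raises :class:`CanthusNotFoundError` when fewer than two stable corner
    candidates exist in the fissure band.
    """
    config = config or CanthusConfig()
    if side not in ("left", "right"):
        raise InvalidInputError("side must be 'left' or 'right'")
    img = as_image(frame).astype(float)
    if img.size == 0 or np.ptp(img) == 0:
        raise CanthusNotFoundError("blank image")
    blur = ndimage.gaussian_filter(img, config.blur_sigma)

    band_lo, band_hi = _fissure_band(blur, config.band_margin)
    eye_region = blur > _sclera_threshold(blur)
    eye_region[:band_lo] = False
    eye_region[band_hi + 1 :] = False
    ys, xs = np.nonzero(eye_region)
    if ys.size == 0:
        raise CanthusNotFoundError("no eye region in the fissure band")

    # lateral extremes of the eye region are the coarse corner locations;
    # Harris peaks near them refine the coarse position and give confidence
    def extreme(selector) -> tuple[int, int]:
        x_ext = selector(xs)
        rows = ys[xs == x_ext]
        return int(np.median(rows)), int(x_ext)

    left_cand = extreme(np.min)
    right_cand = extreme(np.max)
    if left_cand[1] == right_cand[1]:
        raise CanthusNotFoundError("eye region is not laterally extended")

    response = corner_harris(blur)
    peaks = corner_peaks(
        response,
        min_distance=config.min_candidate_distance,
        threshold_rel=config.corner_threshold_rel,
    )
    peaks = peaks[(peaks[:, 0] >= band_lo) & (peaks[:, 0] <= band_hi)]

    def snap(cand: tuple[int, int]) -> tuple[int, int]:
        if len(peaks) == 0:
            return cand
        d2 = (peaks[:, 0] - cand[0]) ** 2 + (peaks[:, 1] - cand[1]) ** 2
        k = int(np.argmin(d2))
        if d2[k] <= 25:  # within 5 px of the lateral extreme
            return int(peaks[k, 0]), int(peaks[k, 1])
        return cand

    left_cand = snap(left_cand)
    right_cand = snap(right_cand)
    if left_cand == right_cand:
        raise CanthusNotFoundError("fewer than 2 distinct corner candidates")

    all_resp = response[response > 0]

    def percentile_of(v: float) -> float:
        if all_resp.size == 0:
            return 1.0
        return float(np.mean(all_resp <= v))

    conf_left = percentile_of(response[left_cand])
    conf_right = percentile_of(response[right_cand])

    sclera_t = _sclera_threshold(blur)
    p_left = _refine_apex(blur, left_cand, "min", config.roi_size, sclera_t)
    p_right = _refine_apex(blur, right_cand, "max", config.roi_size, sclera_t)

    nasal_on_right = side == "left"
    if nasal_on_right:
        inner, outer = p_right, p_left
        ci, co = conf_right, conf_left
    else:
        inner, outer = p_left, p_right
        ci, co = conf_left, conf_right
    return CanthusPair(inner=inner, outer=outer, confidence_inner=ci, confidence_outer=co)


def track_canthus_sequence(
    frames, side: str = "left", config: CanthusConfig | None = None
) -> list[CanthusPair]:
    """Per-frame canthus extraction with temporal median stabilization.

    Each coordinate track is median-filtered over a centered
    ``config.smoothing_window`` window; frames where extraction failed are
    filled from the running median of successful frames.  Raises if every
    frame fails.
    """
    config = config or CanthusConfig()
    frames = list(frames)
    if not frames:
        raise InvalidInputError("need at least one frame")
    raw: list[CanthusPair | None] = []
    for f in frames:
        try:
            raw.append(extract_canthus(f, side, config))
        except CanthusNotFoundError:
            raw.append(None)
    ok = [p for p in raw if p is not None]
    if not ok:
        raise CanthusNotFoundError("canthus extraction failed on every frame")
    if len(frames) == 1:
        return [ok[0]]

    coords = np.full((len(raw), 4), np.nan)
    confs = np.full((len(raw), 2), np.nan)
    for i, p in enumerate(raw):
        if p is not None:
            coords[i] = (*p.inner, *p.outer)
            confs[i] = (p.confidence_inner, p.confidence_outer)
    # fill failures with the running median of prior successes
    med = np.nanmedian(coords, axis=0)
    for i in range(len(raw)):
        if np.isnan(coords[i, 0]):
            prior = coords[:i][~np.isnan(coords[:i, 0])]
            coords[i] = np.median(prior, axis=0) if len(prior) else med
            confs[i] = 0.0
    w = min(config.smoothing_window, len(raw))
    if w % 2 == 0:
        w -= 1
    if w >= 3:
        coords = np.stack(
            [ndimage.median_filter(coords[:, j], size=w, mode="nearest") for j in range(4)],
            axis=1,
        )
    out = []
    for i in range(len(raw)):
        out.append(
            CanthusPair(
                inner=(coords[i, 0], coords[i, 1]),
                outer=(coords[i, 2], coords[i, 3]),
                confidence_inner=float(np.nan_to_num(confs[i, 0])),
                confidence_outer=float(np.nan_to_num(confs[i, 1])),
            )
        )
    return out
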