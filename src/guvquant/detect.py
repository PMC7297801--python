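"""GUV detection in the membrane-marker channel.

Detection is a circular Hough transform on Canny edges of the marker
channel, followed by greedy non-maximum suppression (no two kept centers
closer than the smaller of their radii, ties broken by larger radius) and a
sub-pixel refinement that fits a circle to per-angle radial peak positions
of the marker rim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import canny
from skimage.transform import hough_circle

from .errors import QuantificationError
from .image import MARKER, MultiChannelImage

BORDER_TOUCHING = "border_touching"
OVERLAPPING = "overlapping"
TOO_SMALL = "too_small"
SATURATED = "saturated"


@dataclass
class DetectionConfig:
    """Tunables for Hough-based GUV detection.

    ``score_threshold`` is an absolute threshold on the normalized Hough
    accumulator (roughly the fraction of the circle perimeter supported by
    edge pixels); 0.25 keeps clean rims and rejects noise structures.
    """

    radius_min: float = 10.0
    radius_max: float = 40.0
    radius_step: float = 1.0
    score_threshold: float = 0.25
    canny_sigma: float = 2.0
    border_margin: float = 3.0        # px beyond the rim band
    exterior_margin: float = 5.0      # disk dilation for solution masking, px
    saturation_level: float | None = None
    refine: bool = True
    max_detections: int = 64


@dataclass
class GuvDetection:
    """One detected vesicle: sub-pixel center ``(x, y)``, radius, Hough
    score, and QC flags; any flag excludes it from quantification."""

    center_xy: tuple[float, float]
    radius: float
    score: float
    flags: set[str] = field(default_factory=set)

    @property
    def ok(self) -> bool:
        return not self.flags


def _refine_circle(marker: np.ndarray, cx: float, cy: float, radius: float,
                   band: float = 4.0, n_angles: int = 180) -> tuple[float, float, float]:
    """Sub-pixel circle fit from per-angle radial argmax of the rim.

    Samples the marker along rays, takes the parabola-refined radial peak
    per angle, and solves the algebraic (Kasa) least-squares circle through
    those points. Falls back to the input circle if the fit degenerates.
    """
    theta = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    radii = np.arange(max(radius - band, 1.0), radius + band + 0.25, 0.25)
    xs = cx + radii[:, None] * np.cos(theta)[None, :]
    ys = cy + radii[:, None] * np.sin(theta)[None, :]
    prof = ndimage.map_coordinates(marker, [ys, xs], order=1, mode="nearest")
    idx = np.argmax(prof, axis=0)
    interior = (idx > 0) & (idx < len(radii) - 1)   # drop band-edge peaks
    if interior.sum() < 8:
        return cx, cy, radius
    # parabolic sub-sample refinement of the peak radius
    i = idx[interior]
    cols = np.flatnonzero(interior)
    y0, y1, y2 = prof[i - 1, cols], prof[i, cols], prof[i + 1, cols]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    shift = np.clip(shift, -0.5, 0.5)
    r_peak = radii[i] + shift * 0.25
    px = cx + r_peak * np.cos(theta[cols])
    py = cy + r_peak * np.sin(theta[cols])
    # Kasa fit: minimize |(x-a)^2 + (y-b)^2 - r^2| linearized
    A = np.column_stack([2 * px, 2 * py, np.ones_like(px)])
    b = px ** 2 + py ** 2
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        return cx, cy, radius
    a, bb, c = sol
    r_fit = np.sqrt(max(c + a ** 2 + bb ** 2, 1e-12))
    if not np.isfinite(r_fit) or abs(r_fit - radius) > band:
        return cx, cy, radius
    return float(a), float(bb), float(r_fit)


def detect_guvs(image: MultiChannelImage,
                cfg: DetectionConfig | None = None) -> list[GuvDetection]:
    """Detect circular GUV rims in the marker channel.

    Returns all circles whose normalized Hough score exceeds
    ``cfg.score_threshold``, non-maximum suppressed, with QC flags set
    (border-touching, mutually overlapping, too small, saturated rim).
    Raises :class:`QuantificationError` if the image is smaller than the
    minimum detectable radius window.
    """
    cfg = cfg or DetectionConfig()
    marker = image.channel(MARKER)
    h, w = marker.shape
    if min(h, w) < 2 * cfg.radius_min + 1:
        raise QuantificationError(
            f"image {marker.shape} smaller than the minimum radius window")

    span = np.ptp(marker)
    if span <= 0:
        return []
    norm = (marker - marker.min()) / span
    edges = canny(norm, sigma=cfg.canny_sigma)
    if not edges.any():
        return []
    radii = np.arange(cfg.radius_min, cfg.radius_max + cfg.radius_step,
                      cfg.radius_step)
    accum = hough_circle(edges, radii, normalize=True, full_output=False)

    # candidate peaks per radius slice, then greedy NMS across radii
    candidates: list[tuple[float, float, float, float]] = []  # score, r, cx, cy
    for r_idx, r in enumerate(radii):
        layer = accum[r_idx]
        peak_mask = (layer == ndimage.maximum_filter(layer, size=5)) \
            & (layer >= cfg.score_threshold)
        for cy, cx in np.argwhere(peak_mask):
            candidates.append((float(layer[cy, cx]), float(r), float(cx), float(cy)))
    # ties broken by larger radius
    candidates.sort(key=lambda t: (t[0], t[1]), reverse=True)

    kept: list[GuvDetection] = []
    for score, r, cx, cy in candidates:
        # suppress candidates whose disk overlaps a kept (higher-score)
        # disk; this implies the weaker rule that no two kept centers lie
        # within the smaller of the two radii
        suppressed = any(
            np.hypot(cx - d.center_xy[0], cy - d.center_xy[1]) < r + d.radius
            for d in kept)
        if suppressed:
            continue
        if cfg.refine:
            cx, cy, r = _refine_circle(marker, cx, cy, r)
        kept.append(GuvDetection((cx, cy), r, score))
        if len(kept) >= cfg.max_detections:
            break

    _apply_qc_flags(kept, image, cfg)
    return kept


def _apply_qc_flags(dets: list[GuvDetection], image: MultiChannelImage,
                    cfg: DetectionConfig) -> None:
    marker = image.channel(MARKER)
    h, w = marker.shape
    for d in dets:
        cx, cy = d.center_xy
        reach = d.radius + cfg.border_margin
        if cx - reach < 0 or cy - reach < 0 or cx + reach > w - 1 or cy + reach > h - 1:
            d.flags.add(BORDER_TOUCHING)
        if d.radius < cfg.radius_min:
            d.flags.add(TOO_SMALL)
    for i, a in enumerate(dets):
        for b in dets[i + 1:]:
            dist = np.hypot(a.center_xy[0] - b.center_xy[0],
                            a.center_xy[1] - b.center_xy[1])
            if dist < a.radius + b.radius + 2 * cfg.border_margin:
                a.flags.add(OVERLAPPING)
                b.flags.add(OVERLAPPING)
    if cfg.saturation_level is not None:
        yy, xx = np.indices(marker.shape)
        for d in dets:
            r = np.hypot(xx - d.center_xy[0], yy - d.center_xy[1])
            band = np.abs(r - d.radius) <= cfg.border_margin
            for ch in range(image.data.shape[0]):
                if np.any(image.data[ch][band] >= cfg.saturation_level):
                    d.flags.add(SATURATED)
                    break


def exterior_mask(image: MultiChannelImage, detections: list[GuvDetection],
                  margin: float = 5.0) -> np.ndarray:
    """Boolean mask of pixels outside every detected GUV disk (dilated)."""
    shape = image.shape
    mask = np.ones(shape, dtype=bool)
    yy, xx = np.indices(shape)
    for d in detections:
        r = np.hypot(xx - d.center_xy[0], yy - d.center_xy[1])
        mask &= r > d.radius + margin
    return mask


def estimate_solution_intensity(image: MultiChannelImage,
                                detections: list[GuvDetection],
                                channel: str,
                                margin: float = 5.0) -> float:
    """Median intensity of the free solution: all pixels outside every
    detected GUV disk dilated by ``margin`` pixels.

    Raises :class:`QuantificationError` when no exterior pixel remains
    (image too crowded with GUVs to define a solution reference).
    """
    mask = exterior_mask(image, detections, margin)
    if not mask.any():
        raise QuantificationError(
            "no exterior pixels left after masking detected GUVs; "
            "free-solution intensity is unquantifiable")
    return float(np.median(image.channel(channel)[mask]))
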