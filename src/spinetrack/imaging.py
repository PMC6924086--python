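"""Marker-disc detection: edge enhancement, band thresholding, morphological
opening, connected-component centroid search, and track assembly.

The pipeline mirrors the rig's image-processing chain: a Sobel gradient
magnitude highlights disc rims, a brightness band keeps the rim pixels,
morphological opening removes specks smaller than the structuring element,
and per-component centroids give sub-pixel disc centers which are then
linked frame to frame into trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .datatypes import BinaryMask, DiscDetection, DiscTrack, GrayImage, Kernel, StructuringElement
from .errors import ParameterError

#: standard 3x3 horizontal/vertical derivative (Sobel) kernel pair
SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_Y = SOBEL_X.T


def convolve2d(img, kernel) -> GrayImage:
    """Discrete 2-D convolution g = f * h with reflective border padding.

    The kernel must have odd dimensions and fit inside the image; the output
    has the same size as the input.
    """
    img = GrayImage.coerce(img)
    k = Kernel.coerce(kernel)
    kh, kw = k.weights.shape
    if kh > img.height or kw > img.width:
        raise ParameterError(f"kernel {k.weights.shape} does not fit in image {img.shape}")
    out = ndimage.convolve(img.pixels, k.weights, mode="reflect")
    return GrayImage(out, mm_per_px=img.mm_per_px)


def edge_map(img) -> GrayImage:
    """Gradient-magnitude edge enhancement sqrt(gx^2 + gy^2) via the Sobel pair."""
    img = GrayImage.coerce(img)
    if img.height < 3 or img.width < 3:
        raise ParameterError("edge_map needs an image of at least 3x3 pixels")
    gx = convolve2d(img, SOBEL_X).pixels
    gy = convolve2d(img, SOBEL_Y).pixels
    return GrayImage(np.hypot(gx, gy), mm_per_px=img.mm_per_px)


def threshold_band(img, t_min: float, t_max: float) -> BinaryMask:
    """Band threshold: 1 where t_min <= f <= t_max (inclusive), else 0."""
    img = GrayImage.coerce(img)
    if t_min > t_max:
        raise ParameterError(f"inverted threshold band [{t_min}, {t_max}]")
    mask = (img.pixels >= t_min) & (img.pixels <= t_max)
    return BinaryMask(mask, t_min=float(t_min), t_max=float(t_max))


def _translated(mask: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """out[y, x] = mask[y + dy, x + dx], with outside-frame pixels taken as 0."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    ys0, ys1 = max(0, -dy), min(h, h - dy)
    xs0, xs1 = max(0, -dx), min(w, w - dx)
    if ys0 < ys1 and xs0 < xs1:
        out[ys0:ys1, xs0:xs1] = mask[ys0 + dy:ys1 + dy, xs0 + dx:xs1 + dx]
    return out


def erode(mask, element: StructuringElement) -> BinaryMask:
    """Erosion X Θ B = {d : d + b in X for all b in B}; outside the frame counts as 0."""
    mask = BinaryMask.coerce(mask)
    out = np.ones(mask.shape, dtype=bool)
    for dx, dy in element:
        out &= _translated(mask.pixels, dx, dy)
    return BinaryMask(out, t_min=mask.t_min, t_max=mask.t_max)


def dilate(mask, element: StructuringElement) -> BinaryMask:
    """Dilation X ⊕ B = {x + b : x in X, b in B} clipped to the frame."""
    mask = BinaryMask.coerce(mask)
    out = np.zeros(mask.shape, dtype=bool)
    for dx, dy in element:
        out |= _translated(mask.pixels, -dx, -dy)
    return BinaryMask(out, t_min=mask.t_min, t_max=mask.t_max)


def open_mask(mask, element: StructuringElement) -> BinaryMask:
    """Morphological opening X ∘ B = (X Θ B) ⊕ B.

    Removes detail smaller than the structuring element while preserving the
    overall shape; idempotent and anti-extensive.
    """
    return dilate(erode(mask, element), element)


def find_centers(mask, min_pixels: int = 1) -> list[DiscDetection]:
    """Centroids of 8-connected components with at least ``min_pixels`` pixels.

    Each center is the arithmetic mean of the member pixel coordinates
    ((x, y) = (mean column, mean row)).  Components are sorted by descending
    pixel count, ties broken by (y, x) of the center.
    """
    mask = BinaryMask.coerce(mask)
    labels = measure.label(mask.pixels, connectivity=2)
    dets = []
    for region in measure.regionprops(labels):
        if region.area < min_pixels:
            continue
        cy, cx = region.centroid  # (row, col) mean of member pixels
        dets.append(DiscDetection(center=(float(cx), float(cy)), pixel_count=int(region.area)))
    dets.sort(key=lambda d: (-d.pixel_count, d.center[1], d.center[0]))
    return dets


@dataclass(frozen=True)
class DetectConfig:
    """Parameters of the disc-detection pipeline.

    ``t_min``/``t_max`` bound the edge-map band; ``t_min=None`` uses an
    automatic threshold at ``auto_frac`` of the maximum edge response.
    ``struct_radius`` is the radius of the disc structuring element used for
    opening, ``min_pixels`` the smallest component kept.
    """

    t_min: Optional[float] = None
    t_max: float = math.inf
    auto_frac: float = 0.28
    struct_radius: float = 1.0
    min_pixels: int = 20

    def element(self) -> StructuringElement:
        return StructuringElement.disc(self.struct_radius)


def detect_discs(img, cfg: DetectConfig = DetectConfig(), frame_id: int = 0) -> list[DiscDetection]:
    """Full disc-detection chain: edge_map -> threshold_band -> open_mask -> find_centers."""
    img = GrayImage.coerce(img)
    edges = edge_map(img)
    if cfg.t_min is None and edges.pixels.max() == 0:
        return []  # featureless frame: no gradients, nothing to segment
    t_min = cfg.t_min if cfg.t_min is not None else cfg.auto_frac * float(edges.pixels.max())
    t_max = cfg.t_max if math.isfinite(cfg.t_max) else float(edges.pixels.max())
    if t_min > t_max:
        t_min = t_max
    mask = threshold_band(edges, t_min, t_max)
    opened = open_mask(mask, cfg.element())
    dets = find_centers(opened, min_pixels=cfg.min_pixels)
    return [DiscDetection(center=d.center, pixel_count=d.pixel_count, frame_id=frame_id) for d in dets]


def assemble_tracks(
    frames: Sequence[Sequence[DiscDetection]],
    max_jump_px: float = 15.0,
    camera_id: str = "front",
) -> list[DiscTrack]:
    """Greedy nearest-neighbour linking of per-frame detections into tracks.

    Frame lists must be in temporal order.  Each frame's detections are
    matched to the open tracks' last positions by ascending distance; pairs
    further apart than ``max_jump_px`` stay unmatched and unmatched
    detections open new tracks.  A missed detection simply leaves a gap.
    """
    tracks: list[DiscTrack] = []
    last_pos: dict[int, tuple[float, float]] = {}
    for t, dets in enumerate(frames):
        dets = list(dets)
        open_ids = list(last_pos)
        pairs = []
        for ti in open_ids:
            lx, ly = last_pos[ti]
            for j, d in enumerate(dets):
                dist = math.hypot(d.center[0] - lx, d.center[1] - ly)
                if dist <= max_jump_px:
                    pairs.append((dist, ti, j))
        pairs.sort()
        used_tracks, used_dets = set(), set()
        for dist, ti, j in pairs:
            if ti in used_tracks or j in used_dets:
                continue
            used_tracks.add(ti)
            used_dets.add(j)
            d = dets[j]
            det = DiscDetection(center=d.center, pixel_count=d.pixel_count, frame_id=t)
            tracks[ti].detections.append(det)
            last_pos[ti] = d.center
        for j, d in enumerate(dets):
            if j in used_dets:
                continue
            det = DiscDetection(center=d.center, pixel_count=d.pixel_count, frame_id=t)
            tracks.append(DiscTrack(disc_id=len(tracks), detections=[det], camera_id=camera_id))
            last_pos[len(tracks) - 1] = d.center
    return tracks
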