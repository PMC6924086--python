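"""Displacement estimation from pseudo-speckle image pairs by Fourier fringe
analysis.

When two recordings of the same random texture, mutually shifted by a vector
d, are summed, the Fourier power spectrum of the sum carries a cosine
envelope 2(1 + cos(k . d)) on top of the texture spectrum: a system of
straight interference strips.  By the shift theorem the strip spacing is
N/|d| frequency bins and the strips run perpendicular to d, so the strip
period encodes the displacement magnitude and the strip pitch its direction.
The strips are extracted automatically by a second FFT of the log-power
spectrum (cepstral detection), whose dominant non-DC peak sits at +/-d —
with parabolic sub-pixel interpolation this resolves displacements to a
small fraction of a pixel.  Summing the frames destroys the sign of d; an
explicit cross-correlation probe at +/-d restores it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .datatypes import DisplacementVector, FringeEstimate, GrayImage, SpectrumImage
from .errors import NoFringesError, ParameterError
from .synthetic import shift_image

#: shifts below this (px) leave no full fringe in the spectrum half-plane
MIN_DETECTABLE_SHIFT_PX = 2.0


@dataclass(frozen=True)
class SpeckleConfig:
    """Tunables of the displacement chain."""

    window: str = "hann"  # "hann" | "none"
    dc_suppress_radius: int = 2
    min_contrast: float = 5e-4
    mm_per_px: Optional[float] = None


def sum_frames(f1, f2) -> GrayImage:
    """Pixel-wise sum of two equal-size frames after per-frame mean removal."""
    f1 = GrayImage.coerce(f1)
    f2 = GrayImage.coerce(f2)
    if f1.shape != f2.shape:
        raise ParameterError(f"frame sizes differ: {f1.shape} vs {f2.shape}")
    out = (f1.pixels - f1.pixels.mean()) + (f2.pixels - f2.pixels.mean())
    return GrayImage(out, mm_per_px=f1.mm_per_px or f2.mm_per_px)


def _window(n: int, kind: str) -> np.ndarray:
    if kind == "none":
        return np.ones((n, n))
    if kind == "hann":
        w = np.hanning(n)
        return np.outer(w, w)
    raise ParameterError(f"unknown window {kind!r}")


def power_spectrum(img, window: str = "hann", dc_suppress_radius: int = 2) -> SpectrumImage:
    """Centered 2-D power spectrum |F(ς, ξ)|² of a square image.

    The image is windowed (Hann by default) after subtraction of its
    window-weighted mean, so the DC bin is exactly zero; a
    ``dc_suppress_radius``-bin neighbourhood of DC is additionally zeroed to
    keep the residual low-frequency pedestal out of later peak searches.
    """
    img = GrayImage.coerce(img)
    n = img.height
    if img.width != n:
        raise ParameterError("power_spectrum needs a square image")
    if n < 32:
        raise ParameterError("image side must be >= 32")
    w = _window(n, window)
    x = img.pixels
    x = (x - np.sum(x * w) / np.sum(w)) * w
    f = np.fft.fftshift(np.fft.fft2(x))
    p = np.abs(f) ** 2
    if dc_suppress_radius > 0:
        c = n // 2
        r = dc_suppress_radius
        yy, xx = np.ogrid[-r:r + 1, -r:r + 1]
        disc = (xx ** 2 + yy ** 2) <= r ** 2
        p[c - r:c + r + 1, c - r:c + r + 1][disc] = 0.0
    return SpectrumImage(power=p, n=n)


def _parabolic_offset(m1: float, m0: float, p1: float) -> float:
    """Sub-bin offset of a peak from three samples (neighbour, peak, neighbour)."""
    denom = m1 - 2.0 * m0 + p1
    if denom == 0:
        return 0.0
    off = 0.5 * (m1 - p1) / denom
    return float(np.clip(off, -0.5, 0.5))


def estimate_fringes(
    spec: SpectrumImage,
    min_contrast: float = 5e-4,
    min_shift_px: float = MIN_DETECTABLE_SHIFT_PX,
) -> FringeEstimate:
    """Read strip period and pitch off a fringe-modulated power spectrum.

    The log-power spectrum is Fourier-transformed once more; a cosine
    modulation of period p bins shows up as a pair of peaks at radius N/p
    from the origin, i.e. directly at +/- the displacement vector in pixel
    units.  The dominant non-DC peak is located, refined by per-axis
    parabolic interpolation, and converted to strip period and pitch.

    Raises :class:`NoFringesError` when no peak exceeds ``min_contrast``
    (share of the total non-DC cepstral magnitude) or the peak sits closer
    to DC than ``min_shift_px`` bins.
    """
    p = spec.power
    n = spec.n
    positive = p[p > 0]
    if positive.size == 0:
        raise NoFringesError("empty spectrum")
    floor = float(np.median(positive))
    logp = np.log(p + floor)
    # The texture's own spectral envelope is smooth and isotropic while the
    # fringes are directional: subtracting the mean log-power over each
    # radius annulus removes the envelope without touching the fringes.
    # The spectrum is then tapered so the fringe peak interpolates cleanly.
    c = n // 2
    yy_f, xx_f = np.ogrid[:n, :n]
    annulus = np.rint(np.hypot(xx_f - c, yy_f - c)).astype(int)
    profile = ndimage.mean(logp, labels=annulus, index=np.arange(annulus.max() + 1))
    logp = (logp - profile[annulus]) * _window(n, "hann")
    ceps = np.abs(np.fft.fftshift(np.fft.fft2(logp - logp.mean())))
    guard = max(int(math.floor(min_shift_px)), 1)
    yy, xx = np.ogrid[:n, :n]
    near_dc = (xx - c) ** 2 + (yy - c) ** 2 <= guard ** 2
    search = ceps.copy()
    search[near_dc] = 0.0
    total = float(search.sum())
    if total <= 0:
        raise NoFringesError("flat cepstrum")
    iy, ix = np.unravel_index(int(np.argmax(search)), search.shape)
    peak = float(search[iy, ix])
    contrast = peak / total
    if contrast < min_contrast:
        raise NoFringesError(f"no fringes above noise floor (contrast {contrast:.2e} < {min_contrast:.2e})")
    # parabolic sub-bin refinement along each axis (use unmasked cepstrum)
    ox = _parabolic_offset(ceps[iy, ix - 1], peak, ceps[iy, (ix + 1) % n]) if 0 < ix < n - 1 else 0.0
    oy = _parabolic_offset(ceps[iy - 1, ix], peak, ceps[(iy + 1) % n, ix]) if 0 < iy < n - 1 else 0.0
    qx = (ix + ox) - c
    qy = (iy + oy) - c
    radius = math.hypot(qx, qy)
    if radius < min_shift_px:
        raise NoFringesError(f"fringe radius {radius:.2f} bins below the detectable minimum")
    period = n / radius
    pitch = (math.degrees(math.atan2(qy, qx)) + 90.0) % 180.0
    return FringeEstimate(period_bins=period, pitch_deg=pitch, contrast=contrast)


def displacement_from_fringes(fr: Optional[FringeEstimate], n: int) -> DisplacementVector:
    """Convert strip geometry to an (unsigned) displacement vector.

    magnitude = N / period (the shift theorem identity); the displacement
    direction is the strip normal, pitch + 90 deg modulo 180.  ``fr=None``
    (or an infinite period) is the no-fringe path and maps to magnitude 0.
    """
    if fr is None or not math.isfinite(fr.period_bins):
        return DisplacementVector(magnitude_px=0.0, direction_deg=0.0, sign_resolved=True)
    magnitude = n / fr.period_bins
    direction = (fr.pitch_deg + 90.0) % 180.0
    return DisplacementVector(
        magnitude_px=magnitude, direction_deg=direction, sign_resolved=False, contrast=fr.contrast
    )


def _corr_score(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float((a * a).sum()) * float((b * b).sum()))
    return float((a * b).sum()) / denom if denom > 0 else 0.0


def resolve_sign(f1, f2, d: DisplacementVector, ambiguity_tol: float = 0.01) -> DisplacementVector:
    """Resolve the +/-d ambiguity of a summed-frame estimate.

    Shifts f1 by +d and by -d and keeps the sign whose shifted copy
    correlates better with f2.  If the two scores differ by less than
    ``ambiguity_tol`` (relative), the vector is returned unresolved with a
    warning.
    """
    if d.magnitude_px == 0:
        return DisplacementVector(0.0, 0.0, sign_resolved=True, magnitude_mm=d.magnitude_mm, contrast=d.contrast)
    if d.sign_resolved:
        return d
    f1 = GrayImage.coerce(f1)
    f2 = GrayImage.coerce(f2)
    dx, dy = d.components()
    plus = _corr_score(shift_image(f1, dx, dy).pixels, f2.pixels)
    minus = _corr_score(shift_image(f1, -dx, -dy).pixels, f2.pixels)
    scale = max(abs(plus), abs(minus), 1e-12)
    if abs(plus - minus) / scale < ambiguity_tol:
        warnings.warn("displacement sign ambiguous; leaving direction modulo 180 deg", stacklevel=2)
        return d
    direction = d.direction_deg if plus >= minus else (d.direction_deg + 180.0) % 360.0
    return DisplacementVector(
        magnitude_px=d.magnitude_px,
        direction_deg=direction,
        sign_resolved=True,
        magnitude_mm=d.magnitude_mm,
        contrast=d.contrast,
    )


def measure_displacement(f1, f2, cfg: SpeckleConfig = SpeckleConfig()) -> DisplacementVector:
    """Full chain: sum frames, power spectrum, fringe reading, sign resolution.

    Shifts smaller than ~2 px leave no full fringe and report magnitude 0.
    """
    f1 = GrayImage.coerce(f1)
    f2 = GrayImage.coerce(f2)
    s = sum_frames(f1, f2)
    spec = power_spectrum(s, window=cfg.window, dc_suppress_radius=cfg.dc_suppress_radius)
    try:
        fringes = estimate_fringes(spec, min_contrast=cfg.min_contrast)
    except NoFringesError:
        d = DisplacementVector(0.0, 0.0, sign_resolved=True)
        return _with_mm(d, cfg, f1)
    d = displacement_from_fringes(fringes, spec.n)
    d = resolve_sign(f1, f2, d)
    return _with_mm(d, cfg, f1)


def _with_mm(d: DisplacementVector, cfg: SpeckleConfig, f1: GrayImage) -> DisplacementVector:
    scale = cfg.mm_per_px or f1.mm_per_px
    if scale is None:
        return d
    return DisplacementVector(
        magnitude_px=d.magnitude_px,
        direction_deg=d.direction_deg,
        sign_resolved=d.sign_resolved,
        magnitude_mm=d.magnitude_px * scale,
        contrast=d.contrast,
    )
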