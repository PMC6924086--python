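"""Synthetic inputs emulating what the rig's cameras and strain gauges produce.

Everything here is a pure, seeded function of its spec: pseudo-speckle
targets of a requested brightness standard deviation, marker-disc scenes
with exactly known centers, rigid (sub-pixel) translations, and linear
voltage-force gauge records with additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import GrayImage
from .errors import ParameterError

BRIGHTNESS_RANGE = (0.0, 255.0)
MID_BRIGHTNESS = 128.0


@dataclass(frozen=True)
class SpeckleSpec:
    """Parameters of a pseudo-speckle target.

    ``sigma`` is the brightness standard deviation of the generated texture
    (the rig's targets use sigma = 50); ``corr_length_px`` the correlation
    length of the band-limited texture.
    """

    size_px: int
    sigma: float = 50.0
    seed: int = 0
    corr_length_px: float = 2.0

    def __post_init__(self):
        if int(self.size_px) != self.size_px or self.size_px < 32:
            raise ParameterError("size_px must be an integer >= 32")
        if not (self.sigma > 0):
            raise ParameterError("sigma must be positive")
        if not (self.corr_length_px > 0):
            raise ParameterError("corr_length_px must be positive")


@dataclass(frozen=True)
class DiscSceneSpec:
    """A scene of non-overlapping circular marker discs at known centers."""

    size_px: int
    centers: tuple = ()
    radius_px: float = 6.0
    foreground: float = 200.0
    background: float = 50.0
    noise_sd: float = 0.0
    seed: int = 0
    psf_sigma_px: float = 1.0  # camera point-spread blur; 0 disables

    def __post_init__(self):
        if int(self.size_px) != self.size_px or self.size_px < 1:
            raise ParameterError("size_px must be a positive integer")
        if not (self.radius_px > 0):
            raise ParameterError("radius_px must be positive")
        if self.psf_sigma_px < 0:
            raise ParameterError("psf_sigma_px must be non-negative")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        lo, hi = BRIGHTNESS_RANGE
        for v in (self.foreground, self.background):
            if not (lo <= v <= hi):
                raise ParameterError(f"brightness {v} outside range {BRIGHTNESS_RANGE}")
        centers = tuple((float(x), float(y)) for x, y in self.centers)
        margin = self.radius_px + 0.5  # anti-aliased rim must stay in frame
        for x, y in centers:
            if not (margin <= x <= self.size_px - 1 - margin and margin <= y <= self.size_px - 1 - margin):
                raise ParameterError(f"disc at ({x}, {y}) does not lie fully inside the frame")
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                dx = centers[i][0] - centers[j][0]
                dy = centers[i][1] - centers[j][1]
                if (dx * dx + dy * dy) ** 0.5 <= 2 * self.radius_px + 1:
                    raise ParameterError(f"discs {i} and {j} overlap")
        object.__setattr__(self, "centers", centers)


@dataclass(frozen=True)
class GaugeSimSpec:
    """Ground truth of a simulated strain gauge: force = a_true + b_true * voltage + noise."""

    a_true: float
    b_true: float
    voltages: tuple = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        volts = tuple(float(v) for v in self.voltages)
        if len(volts) < 3:
            raise ParameterError("need at least 3 voltage points")
        if max(volts) == min(volts):
            raise ParameterError("voltages must not all be equal")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        object.__setattr__(self, "voltages", volts)


def gen_speckle(spec: SpeckleSpec) -> GrayImage:
    """Generate a pseudo-speckle target of the requested brightness SD.

    White Gaussian noise is low-pass filtered with a periodic Gaussian
    kernel (correlation length ``spec.corr_length_px``), rescaled to sample
    standard deviation ``spec.sigma`` around mid-brightness, and clipped to
    the 8-bit brightness range.  Identical specs give bit-identical images.
    """
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal((spec.size_px, spec.size_px))
    smooth = ndimage.gaussian_filter(white, sigma=spec.corr_length_px, mode="wrap")
    sd = smooth.std()
    if sd == 0:  # pragma: no cover - cannot happen for size >= 32
        raise ParameterError("degenerate texture")
    scaled = (smooth - smooth.mean()) / sd * spec.sigma + MID_BRIGHTNESS
    return GrayImage(np.clip(scaled, *BRIGHTNESS_RANGE))


def shift_image(img, dx: float, dy: float) -> GrayImage:
    """Rigidly translate an image by (dx, dy) pixels (periodic boundary).

    Integer shifts are an exact roll of the pixel grid; sub-pixel shifts are
    realized by a spectral phase ramp, so composing shifts is exact up to
    floating-point error.  The content moves by +dx along x (columns) and
    +dy along y (rows, downward).
    """
    img = GrayImage.coerce(img)
    n = min(img.shape)
    if abs(dx) >= n / 4 or abs(dy) >= n / 4:
        raise ParameterError(f"shift ({dx}, {dy}) too large for a {img.shape} frame (< side/4)")
    if float(dx).is_integer() and float(dy).is_integer():
        out = np.roll(img.pixels, (int(dy), int(dx)), axis=(0, 1))
        return GrayImage(out, mm_per_px=img.mm_per_px)
    f = np.fft.fft2(img.pixels)
    ramp_x = np.exp(-2j * np.pi * np.fft.fftfreq(img.width) * dx)
    ramp_y = np.exp(-2j * np.pi * np.fft.fftfreq(img.height) * dy)
    # The unpaired Nyquist bin of an even-size real image has no well-defined
    # fractional phase; band-limited translation drops it.  This keeps the
    # output exactly real and makes fractional shifts compose exactly.
    if img.width % 2 == 0 and not float(dx).is_integer():
        ramp_x[img.width // 2] = 0.0
    if img.height % 2 == 0 and not float(dy).is_integer():
        ramp_y[img.height // 2] = 0.0
    out = np.fft.ifft2(f * (ramp_y[:, None] * ramp_x[None, :])).real
    return GrayImage(out, mm_per_px=img.mm_per_px)


def _render_disc(canvas: np.ndarray, cx: float, cy: float, radius: float, delta: float) -> None:
    """Add an anti-aliased disc: per-pixel coverage ramps linearly across the rim."""
    h, w = canvas.shape
    x0, x1 = int(np.floor(cx - radius - 2)), int(np.ceil(cx + radius + 2)) + 1
    y0, y1 = int(np.floor(cy - radius - 2)), int(np.ceil(cy + radius + 2)) + 1
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w), min(y1, h)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    coverage = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    canvas[y0:y1, x0:x1] += delta * coverage


def gen_disc_scene(spec: DiscSceneSpec) -> tuple[GrayImage, list]:
    """Render a marker-disc scene; returns (image, list of true (x, y) centers).

    Discs are drawn with anti-aliased rims, blurred by an isotropic Gaussian
    camera point-spread function (``psf_sigma_px``), and overlaid with
    additive Gaussian sensor noise.  The returned truth equals the requested
    centers exactly.
    """
    canvas = np.full((spec.size_px, spec.size_px), spec.background, dtype=float)
    for cx, cy in spec.centers:
        _render_disc(canvas, cx, cy, spec.radius_px, spec.foreground - spec.background)
    if spec.psf_sigma_px > 0:
        canvas = ndimage.gaussian_filter(canvas, sigma=spec.psf_sigma_px, mode="nearest")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        canvas = canvas + rng.normal(0.0, spec.noise_sd, canvas.shape)
    canvas = np.clip(canvas, *BRIGHTNESS_RANGE)
    return GrayImage(canvas), [tuple(c) for c in spec.centers]


def gen_gauge_data(spec: GaugeSimSpec) -> pd.DataFrame:
    """Simulate one gauge calibration table.

    Returns a DataFrame with columns ``voltage`` (V) and ``force`` (N) where
    force_i = a_true + b_true * voltage_i + eps_i, eps_i ~ N(0, noise_sd).
    """
    rng = np.random.default_rng(spec.seed)
    volts = np.asarray(spec.voltages, dtype=float)
    noise = rng.normal(0.0, spec.noise_sd, volts.size) if spec.noise_sd > 0 else np.zeros(volts.size)
    force = spec.a_true + spec.b_true * volts + noise
    return pd.DataFrame({"voltage": volts, "force": force})


def quantize_8bit(img) -> GrayImage:
    """Optional explicit 8-bit quantization of a real-valued brightness image."""
    img = GrayImage.coerce(img)
    q = np.clip(np.rint(img.pixels), 0, 255)
    return GrayImage(q, mm_per_px=img.mm_per_px)
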