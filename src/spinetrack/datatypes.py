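"""Core value types shared across the toolkit.

Conventions used throughout:

* images are 2-D float arrays indexed ``[row, column]``; the *x* coordinate is
  the column (rightward), *y* is the row (downward), both 0-based;
* sub-pixel positions are real-valued in the same frame;
* angles are degrees measured from +x toward +y (i.e. clockwise on screen,
  because y points down).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .errors import ParameterError

ArrayLike = Union[np.ndarray, Sequence[Sequence[float]]]


@dataclass(frozen=True)
class GrayImage:
    """A grayscale raster: the image function f(x, y) on a pixel grid.

    Parameters
    ----------
    pixels
        2-D float array of brightness values, shape ``(height, width)``.
    mm_per_px
        Optional physical scale of the pixel grid.
    """

    pixels: np.ndarray
    mm_per_px: Optional[float] = None

    def __post_init__(self):
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ParameterError(f"image must be a non-empty 2-D array, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ParameterError("image contains non-finite brightness values")
        if self.mm_per_px is not None and self.mm_per_px <= 0:
            raise ParameterError("mm_per_px must be positive")
        object.__setattr__(self, "pixels", arr)

    @property
    def width(self) -> int:
        """Number of columns M."""
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        """Number of rows N."""
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @classmethod
    def coerce(cls, img: Union["GrayImage", ArrayLike], mm_per_px: Optional[float] = None) -> "GrayImage":
        """Accept either a GrayImage or a bare array."""
        if isinstance(img, cls):
            return img
        return cls(np.asarray(img, dtype=float), mm_per_px=mm_per_px)

    def with_scale(self, mm_per_px: float) -> "GrayImage":
        return replace(self, mm_per_px=mm_per_px)


@dataclass(frozen=True)
class Kernel:
    """A discrete convolution core h: odd-sized 2-D weight matrix."""

    weights: np.ndarray
    normalization: str = "none"  # "none" | "sum-to-one"

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] % 2 == 0 or w.shape[1] % 2 == 0:
            raise ParameterError(f"kernel dimensions must be odd, got {w.shape}")
        if self.normalization not in ("none", "sum-to-one"):
            raise ParameterError("normalization must be 'none' or 'sum-to-one'")
        if self.normalization == "sum-to-one":
            s = w.sum()
            if s == 0:
                raise ParameterError("cannot normalize a zero-sum kernel")
            w = w / s
        object.__setattr__(self, "weights", w)

    @classmethod
    def coerce(cls, k: Union["Kernel", ArrayLike]) -> "Kernel":
        if isinstance(k, cls):
            return k
        return cls(np.asarray(k, dtype=float))


@dataclass(frozen=True)
class BinaryMask:
    """Segmented image g(i, j) in {0, 1} plus the threshold band that produced it."""

    pixels: np.ndarray
    t_min: float = math.nan
    t_max: float = math.nan

    def __post_init__(self):
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ParameterError("mask must be 2-D")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise ParameterError("mask values must be 0 or 1")
            arr = arr.astype(bool)
        if not (math.isnan(self.t_min) or math.isnan(self.t_max)) and self.t_min > self.t_max:
            raise ParameterError("t_min must not exceed t_max")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @classmethod
    def coerce(cls, mask: Union["BinaryMask", ArrayLike]) -> "BinaryMask":
        if isinstance(mask, cls):
            return mask
        return cls(np.asarray(mask))


@dataclass(frozen=True)
class StructuringElement:
    """The structural element B: a set of (dx, dy) pixel offsets containing (0, 0)."""

    offsets: frozenset

    def __post_init__(self):
        offs = frozenset((int(dx), int(dy)) for dx, dy in self.offsets)
        if not offs:
            raise ParameterError("structuring element must be non-empty")
        if (0, 0) not in offs:
            raise ParameterError("structuring element must contain the origin (0, 0)")
        object.__setattr__(self, "offsets", offs)

    @property
    def is_symmetric(self) -> bool:
        return all((-dx, -dy) in self.offsets for dx, dy in self.offsets)

    def reflected(self) -> "StructuringElement":
        """Point reflection through the origin (used by the erosion/dilation duality)."""
        return StructuringElement(frozenset((-dx, -dy) for dx, dy in self.offsets))

    @classmethod
    def disc(cls, radius: float) -> "StructuringElement":
        """Digital disc of the given radius (includes the origin for radius < 1)."""
        r = int(math.floor(radius))
        offs = {
            (dx, dy)
            for dx in range(-r, r + 1)
            for dy in range(-r, r + 1)
            if dx * dx + dy * dy <= radius * radius
        }
        offs.add((0, 0))
        return cls(frozenset(offs))

    @classmethod
    def box(cls, radius: int) -> "StructuringElement":
        """(2r+1) x (2r+1) square."""
        return cls(frozenset((dx, dy) for dx in range(-radius, radius + 1) for dy in range(-radius, radius + 1)))

    @classmethod
    def cross(cls, radius: int = 1) -> "StructuringElement":
        offs = {(0, 0)}
        for k in range(1, radius + 1):
            offs.update({(k, 0), (-k, 0), (0, k), (0, -k)})
        return cls(frozenset(offs))

    def __iter__(self) -> Iterable[tuple[int, int]]:
        return iter(sorted(self.offsets))

    def __len__(self) -> int:
        return len(self.offsets)


@dataclass(frozen=True)
class DiscDetection:
    """Centroid of one marker disc in one frame."""

    center: tuple[float, float]  # (x, y) in pixels
    pixel_count: int
    frame_id: int = 0

    def __post_init__(self):
        if self.pixel_count < 1:
            raise ParameterError("pixel_count must be >= 1")


@dataclass
class DiscTrack:
    """Temporal sequence of detections of one marker disc from one camera."""

    disc_id: int
    detections: list = field(default_factory=list)
    camera_id: str = "front"

    def __post_init__(self):
        frames = [d.frame_id for d in self.detections]
        if len(frames) != len(set(frames)):
            raise ParameterError("at most one detection per frame per track")

    @property
    def frames(self) -> list[int]:
        return [d.frame_id for d in self.detections]

    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) centers in temporal order."""
        return np.array([d.center for d in self.detections], dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class SpectrumImage:
    """Zero-frequency-centered 2-D power spectrum F(ς, ξ) of an N x N image."""

    power: np.ndarray
    n: int

    def __post_init__(self):
        arr = np.asarray(self.power, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ParameterError("power spectrum must be square")
        if np.any(arr < 0):
            raise ParameterError("power must be non-negative")
        if arr.shape[0] != self.n:
            raise ParameterError("spectrum side must equal source size n")
        object.__setattr__(self, "power", arr)


@dataclass(frozen=True)
class FringeEstimate:
    """Interference-strip geometry read off a power spectrum.

    ``period_bins`` is the strip spacing in frequency-plane pixels,
    ``pitch_deg`` the strip orientation in [0, 180).  The strips run
    perpendicular to the underlying target shift.
    """

    period_bins: float
    pitch_deg: float
    contrast: float

    def __post_init__(self):
        if not (self.period_bins >= 2):
            raise ParameterError("fringe period must be >= 2 bins")
        if not (0 <= self.pitch_deg < 180):
            raise ParameterError("pitch must lie in [0, 180)")
        if not math.isfinite(self.contrast):
            raise ParameterError("contrast must be finite")


@dataclass(frozen=True)
class DisplacementVector:
    """A planar target shift: magnitude in pixels, direction in degrees.

    Until the sign ambiguity of the summed-frame spectrum is resolved the
    direction is only known modulo 180 deg and ``sign_resolved`` is False.
    """

    magnitude_px: float
    direction_deg: float
    sign_resolved: bool = False
    magnitude_mm: Optional[float] = None
    contrast: Optional[float] = None

    def __post_init__(self):
        if self.magnitude_px < 0:
            raise ParameterError("magnitude must be non-negative")
        full = 360.0 if self.sign_resolved else 180.0
        d = self.direction_deg % 360.0
        if not self.sign_resolved:
            d %= 180.0
        if not (0 <= d < full):
            raise ParameterError("direction out of range")
        object.__setattr__(self, "direction_deg", float(d))

    def components(self) -> tuple[float, float]:
        """(dx, dy) under the y-down convention."""
        th = math.radians(self.direction_deg)
        return (self.magnitude_px * math.cos(th), self.magnitude_px * math.sin(th))

    def to_dict(self) -> dict:
        return {
            "magnitude_px": self.magnitude_px,
            "magnitude_mm": self.magnitude_mm,
            "direction_deg": self.direction_deg,
            "sign_resolved": self.sign_resolved,
            "contrast": self.contrast,
        }
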