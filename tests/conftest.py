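"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive each operation from its mathematical definition
(quadruple-loop convolution, set-definition morphology, phase correlation)
and stay independent of the implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from spinetrack import DiscSceneSpec, gen_disc_scene


# ----------------------------------------------------------------- oracles
def convolve_oracle(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct summation g(x,y) = sum_ij f(i,j) h(x-i, y-j), reflective padding."""
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    padded = np.pad(img, ((ph, ph), (pw, pw)), mode="symmetric")
    out = np.zeros_like(img, dtype=float)
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            acc = 0.0
            for j in range(kh):
                for i in range(kw):
                    acc += padded[y + kh - 1 - j, x + kw - 1 - i] * kernel[j, i]
            out[y, x] = acc
    return out


def erode_oracle(mask: np.ndarray, offsets) -> np.ndarray:
    """{d : d + b in X for all b in B}, outside-frame = 0, by enumeration."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            out[y, x] = all(
                0 <= x + dx < w and 0 <= y + dy < h and mask[y + dy, x + dx]
                for dx, dy in offsets
            )
    return out


def dilate_oracle(mask: np.ndarray, offsets) -> np.ndarray:
    """{x + b : x in X, b in B} clipped to the frame, by enumeration."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            for dx, dy in offsets:
                if 0 <= x + dx < w and 0 <= y + dy < h:
                    out[y + dy, x + dx] = True
    return out


def phase_correlation_shift(f1: np.ndarray, f2: np.ndarray, upsample: int = 50):
    """Sub-pixel (dx, dy) such that f2 ~= f1 translated by (dx, dy)."""
    from skimage.registration import phase_cross_correlation

    shift, _, _ = phase_cross_correlation(f1, f2, upsample_factor=upsample)
    return -shift[1], -shift[0]


def random_element_offsets(rng: np.random.Generator, max_radius: int = 2) -> frozenset:
    """A random structuring element containing the origin."""
    cand = [
        (dx, dy)
        for dx in range(-max_radius, max_radius + 1)
        for dy in range(-max_radius, max_radius + 1)
        if (dx, dy) != (0, 0)
    ]
    take = rng.random(len(cand)) < 0.3
    offs = {(0, 0)} | {c for c, t in zip(cand, take) if t}
    return frozenset(offs)


def make_disc_scene(seed: int, size: int = 96, n_discs: int = 3,
                    contrast: float = 150.0, noise_sd: float | None = None):
    """A seeded scene of well-separated discs (radius 4-8 px) with known truth."""
    rng = np.random.default_rng(seed)
    radius = rng.uniform(4, 8)
    noise = rng.uniform(0, 10) if noise_sd is None else noise_sd
    centers: list[tuple[float, float]] = []
    while len(centers) < n_discs:
        c = rng.uniform(radius + 4, size - radius - 4, 2)
        if all(np.hypot(c[0] - a, c[1] - b) > 2 * radius + 10 for a, b in centers):
            centers.append((float(c[0]), float(c[1])))
    spec = DiscSceneSpec(
        size_px=size,
        centers=tuple(centers),
        radius_px=radius,
        foreground=50.0 + contrast,
        background=50.0,
        noise_sd=noise,
        seed=seed,
    )
    return gen_disc_scene(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
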