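"""Synthetic target scenes and image-quality metrics.

Everything the simulator is tested on is generated here: USAF-style bar
groups, a centered disk (the canonical edge-enhancement object), random
glyph-like blob scenes, and Voronoi cell/membrane phantoms emulating
electron-microscopy tissue (bright cell interiors separated by dark
membranes, segmentation-ready).  Side lengths are restricted to powers of
two so one phantom drives Fourier, Hadamard, and random modulation alike.

PSNR/SSIM wrap scikit-image; identical images report the capped PSNR
sentinel instead of infinity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.metrics import peak_signal_noise_ratio, structural_similarity

__all__ = [
    "PSNR_CAP_DB",
    "Phantom",
    "make_bars",
    "make_disk",
    "make_glyphs",
    "make_cells",
    "make_phantom",
    "psnr",
    "ssim",
    "edge_oracle",
]

#: reported PSNR for (near-)identical images
PSNR_CAP_DB = 100.0


def _check_side(n: int) -> None:
    if n < 8 or (n & (n - 1)) != 0:
        raise ValueError(f"phantom side must be a power of two >= 8, got {n}")


@dataclass
class Phantom:
    """A test scene in [0, 1] with optional exact edge map of its geometry."""

    image: np.ndarray
    kind: Literal["bars", "glyphs", "disk", "cells"]
    seed: int
    ground_truth_edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        n = self.image.shape[0]
        _check_side(n)
        if self.image.shape != (n, n):
            raise ValueError("phantom must be square")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("phantom values must lie in [0, 1]")


def _binary_edges(binary: np.ndarray) -> np.ndarray:
    """Morphological gradient (dilation minus erosion) of a binary image."""
    b = binary.astype(bool)
    return (ndimage.binary_dilation(b) ^ ndimage.binary_erosion(b)).astype(np.float64)


def make_bars(shape: int, n_groups: int = 3, seed: int = 0) -> Phantom:
    """Resolution-target phantom: groups of 3 bars of geometrically shrinking width.

    Group g uses bar width ``max(shape // 16 // 2**g, 1)``; groups alternate
    between vertical and horizontal bars down the diagonal.  Binary image;
    the edge map is the morphological gradient of the geometry.
    """
    n = int(shape)
    _check_side(n)
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    base = n // 16
    if base < 1 or base // (2 ** (n_groups - 1)) < 1:
        raise ValueError(f"grid {n} too small for {n_groups} bar groups")
    img = np.zeros((n, n))
    cell = n // max(n_groups, 2)
    for g in range(n_groups):
        w = max(base // (2**g), 1)
        r0 = min(g * cell + w, n - 6 * w - 1)
        c0 = r0
        for b in range(3):
            if g % 2 == 0:  # vertical bars
                c = c0 + 2 * w * b
                img[r0 : r0 + 5 * w, c : c + w] = 1.0
            else:  # horizontal bars
                r = r0 + 2 * w * b
                img[r : r + w, c0 : c0 + 5 * w] = 1.0
    return Phantom(image=img, kind="bars", seed=seed, ground_truth_edges=_binary_edges(img))


def make_disk(shape: int, radius: float | None = None) -> Phantom:
    """Centered binary disk; the edge map is the lattice ring |r - radius| <= 1."""
    n = int(shape)
    _check_side(n)
    if radius is None:
        radius = n / 8.0
    if radius >= n / 2:
        raise ValueError("radius must be smaller than half the grid")
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(xx - c, yy - c)
    img = (r <= radius).astype(np.float64)
    edges = (np.abs(r - radius) <= 1.0).astype(np.float64)
    return Phantom(image=img, kind="disk", seed=0, ground_truth_edges=edges)


def make_glyphs(shape: int, n_blobs: int = 6, seed: int = 0) -> Phantom:
    """Glyph-like scene: seeded rectangles and disks of varying brightness."""
    n = int(shape)
    _check_side(n)
    rng = np.random.default_rng(seed)
    img = np.zeros((n, n))
    yy, xx = np.mgrid[0:n, 0:n]
    for _ in range(n_blobs):
        level = rng.uniform(0.4, 1.0)
        if rng.random() < 0.5:
            r0, c0 = rng.integers(0, n - n // 4, size=2)
            h, w = rng.integers(n // 16, n // 4, size=2)
            img[r0 : r0 + h, c0 : c0 + w] = level
        else:
            cy, cx = rng.integers(n // 8, n - n // 8, size=2)
            rad = rng.integers(n // 16, n // 6)
            img[np.hypot(xx - cx, yy - cy) <= rad] = level
    edges = _binary_edges(img > 0.05)
    return Phantom(image=img, kind="glyphs", seed=seed, ground_truth_edges=edges)


def make_cells(
    shape: int, n_cells: int = 8, membrane_width: int = 2, seed: int = 0
) -> Phantom:
    """Voronoi cell/membrane phantom: bright interiors, dark membranes.

    Seeded random sites with a minimum-spacing rejection rule are labeled by
    nearest site; membrane pixels (within ``membrane_width/2`` of a label
    boundary) take value 0.1 and interiors a per-cell brightness in
    [0.75, 1.0].  The edge map is the membrane mask.
    """
    n = int(shape)
    _check_side(n)
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if n_cells > (n // 4) ** 2:  # each cell needs ~4x4 px for a visible interior
        raise ValueError(f"cannot pack {n_cells} cells into a {n} grid")
    if membrane_width < 1:
        raise ValueError("membrane_width must be >= 1")
    rng = np.random.default_rng(seed)
    min_spacing = 0.55 * n / np.sqrt(n_cells)
    sites: list[tuple[float, float]] = []
    for _ in range(20000):
        if len(sites) == n_cells:
            break
        cand = rng.uniform(0.05 * n, 0.95 * n, size=2)
        if all(np.hypot(cand[0] - s[0], cand[1] - s[1]) >= min_spacing for s in sites):
            sites.append((cand[0], cand[1]))
    if len(sites) < n_cells:
        raise ValueError(f"cannot pack {n_cells} cells with spacing into a {n} grid")
    pts = np.array(sites)
    yy, xx = np.mgrid[0:n, 0:n]
    d2 = (yy[..., None] - pts[:, 0]) ** 2 + (xx[..., None] - pts[:, 1]) ** 2
    labels = np.argmin(d2, axis=-1)
    boundary = np.zeros((n, n), dtype=bool)
    boundary[:-1, :] |= labels[:-1, :] != labels[1:, :]
    boundary[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    membrane = ndimage.binary_dilation(
        boundary, iterations=max(membrane_width // 2, 1)
    ) if membrane_width > 1 else boundary
    brightness = rng.uniform(0.75, 1.0, size=n_cells)
    img = brightness[labels]
    img[membrane] = 0.1
    return Phantom(
        image=img, kind="cells", seed=seed, ground_truth_edges=membrane.astype(np.float64)
    )


def make_phantom(kind: str, shape: int, seed: int = 0) -> Phantom:
    """Dispatch by kind name with each generator's defaults."""
    if kind == "bars":
        return make_bars(shape, seed=seed)
    if kind == "disk":
        return make_disk(shape)
    if kind == "glyphs":
        return make_glyphs(shape, seed=seed)
    if kind == "cells":
        return make_cells(shape, seed=seed)
    raise ValueError(f"unknown phantom kind {kind!r}")


# ---------------------------------------------------------------------------
# Quality metrics


def psnr(a: np.ndarray, b: np.ndarray, data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB (capped at PSNR_CAP_DB for identical inputs)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if data_range is None:
        data_range = max(float(a.max() - a.min()), float(b.max() - b.min()), 1e-12)
    if np.array_equal(a, b):
        return PSNR_CAP_DB
    return float(min(peak_signal_noise_ratio(a, b, data_range=data_range), PSNR_CAP_DB))


def ssim(a: np.ndarray, b: np.ndarray, data_range: float | None = None) -> float:
    """Structural similarity index (mean over the image)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if data_range is None:
        data_range = max(float(a.max() - a.min()), float(b.max() - b.min()), 1e-12)
    return float(structural_similarity(a, b, data_range=data_range))


def edge_oracle(image: np.ndarray) -> np.ndarray:
    """Gradient-magnitude reference map via central differences."""
    gy, gx = np.gradient(np.asarray(image, dtype=np.float64))
    return np.hypot(gx, gy)
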