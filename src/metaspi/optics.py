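"""Polarization-dependent 4f optical computing model.

The imaging device places a metasurface in the Fourier plane of a 4f relay.
Under x-linearly-polarized (XLP) light the metasurface presents a spiral
(vortex) phase profile exp(i*(phi + C1)) that acts as an isotropic
differentiator and yields edge-enhanced output; under y-linear polarization
(YLP) it presents a uniform phase exp(i*C2) and the relay is a plain
bright-field imager.  This module builds the two transfer functions (ideal,
or quantized to the 16-nanobrick fabrication library), applies the 4f
filtering step, and models fabrication error as a seeded phase/amplitude
perturbation of the transfer function.

Discrete conventions: the spectrum is centered (DC at index ``N//2`` along
both axes), frequency axes are indexed in integer cycles per grid, and the
angle phi = atan2(v, u) is scale invariant, so no physical focal length is
needed.  Wavelength and nanobrick geometry are carried as metadata only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ComplexField",
    "OpticalConfig",
    "TransferFunction",
    "Nanobrick",
    "NanobrickLibrary",
    "wrap_phase",
    "freq_axis",
    "spiral_transfer",
    "constant_transfer",
    "quantize_transfer",
    "apply_4f",
    "perturb_transfer",
    "field_intensity",
    "circular_aperture",
    "build_transfer",
]

Mode = Literal["xlp", "ylp"]

#: nanobrick lattice constant, nm (informational)
LATTICE_CONSTANT_NM = 360.0
#: nanobrick height, nm (informational)
BRICK_HEIGHT_NM = 500.0
#: design wavelength, micrometres
DESIGN_WAVELENGTH_UM = 0.9


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the half-open interval (-pi, pi]."""
    return -(np.mod(-np.asarray(phi) + np.pi, 2.0 * np.pi)) + np.pi


def freq_axis(n: int) -> np.ndarray:
    """Centered integer frequency axis (cycles/grid); DC at index n//2."""
    return np.fft.fftshift(np.fft.fftfreq(n, d=1.0 / n)).astype(np.float64)


def _check_grid(n: int) -> None:
    if n < 8:
        raise ValueError(f"grid_size must be >= 8, got {n}")


@dataclass
class ComplexField:
    """A 2D complex optical field on a square pixel grid.

    ``pixel_pitch`` is informational (length units per pixel); the discrete
    model never uses it.
    """

    values: np.ndarray
    pixel_pitch: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"field must be square 2D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values.view(np.float64))):
            raise ValueError("field contains non-finite entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class TransferFunction:
    """Complex transfer function H(fx, fy) on the centered frequency grid."""

    values: np.ndarray
    mode: Mode
    quantized: bool = False
    fx: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    fy: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValueError(f"transfer function must be square, got {self.values.shape}")
        if self.fx is None:
            self.fx = freq_axis(n)
        if self.fy is None:
            self.fy = freq_axis(n)
        if np.max(np.abs(self.values)) > 1.0 + 1e-9:
            raise ValueError("|H| exceeds unity: passive transmission cannot amplify")

    @property
    def grid_size(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class Nanobrick:
    """One library entry: in-plane semi-axes and per-polarization response."""

    num: int
    a_nm: float
    b_nm: float
    delta_x: float  # XLP phase shift, rad
    t_x: float      # XLP transmission
    delta_y: float  # YLP phase shift, rad
    t_y: float      # YLP transmission


class NanobrickLibrary:
    """The 16-entry fabrication library of the metasurface.

    Each entry maps a nanobrick cross-section (a, b) to the propagation
    phase and transmission it imposes on XLP and YLP light.  Quantizing an
    ideal phase profile to this library is a nearest-circular-phase lookup.
    """

    def __init__(self, entries: Sequence[Nanobrick]):
        entries = list(entries)
        if len(entries) != 16:
            raise ValueError(f"library must hold exactly 16 nanobricks, got {len(entries)}")
        for e in entries:
            if not (0.0 <= e.t_x <= 1.0 and 0.0 <= e.t_y <= 1.0):
                raise ValueError(f"transmission outside [0, 1] in entry {e.num}")
            if not (-np.pi < e.delta_x <= np.pi and -np.pi < e.delta_y <= np.pi):
                raise ValueError(f"phase outside (-pi, pi] in entry {e.num}")
        self.entries = entries

    @classmethod
    def bundled(cls) -> "NanobrickLibrary":
        """Load the library shipped with the package (CSV, one row per brick)."""
        text = resources.files("metaspi.data").joinpath("nanobricks.csv").read_text()
        rows = list(csv.DictReader(text.splitlines()))
        return cls(
            [
                Nanobrick(
                    num=int(r["num"]),
                    a_nm=float(r["a_nm"]),
                    b_nm=float(r["b_nm"]),
                    delta_x=float(r["delta_x"]),
                    t_x=float(r["t_x"]),
                    delta_y=float(r["delta_y"]),
                    t_y=float(r["t_y"]),
                )
                for r in rows
            ]
        )

    def phases(self, mode: Mode) -> np.ndarray:
        return np.array([e.delta_x if mode == "xlp" else e.delta_y for e in self.entries])

    def transmissions(self, mode: Mode) -> np.ndarray:
        return np.array([e.t_x if mode == "xlp" else e.t_y for e in self.entries])

    def max_quantization_error(self, mode: Mode) -> float:
        """Worst-case circular distance from any phase to its nearest entry.

        Equals half the largest gap between adjacent sorted library phases,
        including the wrap-around gap.
        """
        p = np.sort(self.phases(mode))
        gaps = np.diff(np.concatenate([p, [p[0] + 2.0 * np.pi]]))
        return float(np.max(gaps) / 2.0)


@dataclass
class OpticalConfig:
    """Configuration of the metasurface 4f stage.

    C1 and C2 are the free phase constants of the XLP (spiral) and YLP
    (uniform) profiles.  The default C2 = 0.5 rad sits inside the library's
    delta_y span so the quantized bright-field profile is nearly uniform.
    """

    grid_size: int
    mode: Mode = "ylp"
    wavelength_um: float = DESIGN_WAVELENGTH_UM
    c1: float = 0.0
    c2: float = 0.5
    quantization: Literal["ideal", "library16"] = "ideal"

    def __post_init__(self) -> None:
        _check_grid(self.grid_size)
        if self.wavelength_um <= 0:
            raise ValueError("wavelength must be positive")
        if self.mode not in ("xlp", "ylp"):
            raise ValueError(f"mode must be 'xlp' or 'ylp', got {self.mode!r}")
        if self.quantization not in ("ideal", "library16"):
            raise ValueError(f"unknown quantization {self.quantization!r}")
        self.c1 = float(wrap_phase(self.c1))
        self.c2 = float(wrap_phase(self.c2))


def spiral_transfer(grid_size: int, c1: float = 0.0) -> TransferFunction:
    """Spiral (vortex) phase transfer function exp(i*(atan2(v,u) + C1)).

    The phase winds by 2*pi around the DC sample.  The DC sample itself is
    the vortex singularity: its phase is undefined (atan2(0, 0)) and a real
    spiral plate scatters the DC energy into the characteristic donut, so
    the sample is made opaque (H(0, 0) = 0).  This is what leaves flat
    interiors dark in the edge-enhanced mode; every other sample has unit
    modulus.
    """
    _check_grid(grid_size)
    u = freq_axis(grid_size)
    uu, vv = np.meshgrid(u, u)  # vv varies along rows (v), uu along columns (u)
    phi = np.arctan2(vv, uu)
    values = np.exp(1j * wrap_phase(phi + c1))
    center = grid_size // 2
    values[center, center] = 0.0  # vortex singularity blocks DC
    return TransferFunction(values=values, mode="xlp", quantized=False)


def constant_transfer(grid_size: int, c2: float = 0.0) -> TransferFunction:
    """Uniform-phase (bright-field) transfer function exp(i*C2)."""
    _check_grid(grid_size)
    values = np.full((grid_size, grid_size), np.exp(1j * wrap_phase(c2)), dtype=np.complex128)
    return TransferFunction(values=values, mode="ylp", quantized=False)


def quantize_transfer(
    h: TransferFunction, library: NanobrickLibrary, mode: Mode | None = None
) -> TransferFunction:
    """Snap each pixel to the nearest-phase nanobrick of the library.

    The pixel's phase becomes the library phase (delta_x for XLP, delta_y for
    YLP) at minimum circular distance from the ideal phase, and its modulus
    becomes that brick's transmission.  Transmission is kept as-is (not
    renormalized), which reproduces the generally fainter quantized output.
    Idempotent: library phases map to themselves.
    """
    if not isinstance(library, NanobrickLibrary):
        raise TypeError("library must be a NanobrickLibrary")
    if mode is None:
        mode = h.mode
    lib_phases = library.phases(mode)
    lib_t = library.transmissions(mode)
    ideal_phase = np.angle(h.values)
    dist = np.abs(wrap_phase(ideal_phase[..., None] - lib_phases[None, None, :]))
    idx = np.argmin(dist, axis=-1)
    values = lib_t[idx] * np.exp(1j * lib_phases[idx])
    values[np.abs(h.values) == 0.0] = 0.0  # opaque samples (vortex DC) stay opaque
    return TransferFunction(values=values, mode=mode, quantized=True, fx=h.fx, fy=h.fy)


def apply_4f(fld: ComplexField, h: TransferFunction) -> ComplexField:
    """Filter a field through the 4f relay: IFFT2( H * FFT2(E) ).

    Uses the centered-spectrum convention (DC at the grid-center sample of
    H).  Unit-modulus H conserves energy (Parseval); the operation is linear
    in the input field.
    """
    if fld.shape != h.values.shape:
        raise ValueError(f"field shape {fld.shape} != transfer shape {h.values.shape}")
    spectrum = np.fft.fftshift(np.fft.fft2(fld.values))
    out = np.fft.ifft2(np.fft.ifftshift(spectrum * h.values))
    return ComplexField(values=out, pixel_pitch=fld.pixel_pitch)


def perturb_transfer(
    h: TransferFunction,
    phase_sigma: float,
    amp_sigma: float = 0.0,
    seed: int | None = 0,
) -> TransferFunction:
    """Fabrication-error model: seeded per-pixel phase and amplitude jitter.

    Shape errors of fabricated nanobricks show up chiefly as phase errors of
    the realized profile; they are modeled as i.i.d. Gaussian phase offsets
    (sd ``phase_sigma``) plus optional multiplicative Gaussian amplitude
    factors (sd ``amp_sigma``), with the perturbed modulus clipped to [0, 1].
    """
    if phase_sigma < 0 or amp_sigma < 0:
        raise ValueError("perturbation sigmas must be non-negative")
    if phase_sigma == 0 and amp_sigma == 0:
        return TransferFunction(
            values=h.values.copy(), mode=h.mode, quantized=h.quantized, fx=h.fx, fy=h.fy
        )
    rng = np.random.default_rng(seed)
    dphi = rng.normal(0.0, phase_sigma, h.values.shape) if phase_sigma > 0 else 0.0
    amp = np.abs(h.values)
    if amp_sigma > 0:
        amp = amp * (1.0 + rng.normal(0.0, amp_sigma, h.values.shape))
    amp = np.clip(amp, 0.0, 1.0)
    values = amp * np.exp(1j * (np.angle(h.values) + dphi))
    return TransferFunction(values=values, mode=h.mode, quantized=h.quantized, fx=h.fx, fy=h.fy)


def field_intensity(fld: ComplexField) -> np.ndarray:
    """Detected intensity |E|^2 (what any square-law detector sees)."""
    return np.abs(fld.values) ** 2


def circular_aperture(h: TransferFunction, radius_frac: float = 0.5) -> TransferFunction:
    """Optionally crop the Fourier plane to a circular metasurface aperture.

    ``radius_frac`` is the aperture radius as a fraction of the grid
    half-width.  Off by default in every pipeline; exposed for studying a
    finite (e.g. 109 x 109 brick) metasurface extent.
    """
    if not 0.0 < radius_frac <= 1.0:
        raise ValueError("radius_frac must be in (0, 1]")
    n = h.grid_size
    uu, vv = np.meshgrid(h.fx, h.fy)
    mask = (uu**2 + vv**2) <= (radius_frac * n / 2.0) ** 2
    return TransferFunction(
        values=h.values * mask, mode=h.mode, quantized=h.quantized, fx=h.fx, fy=h.fy
    )


def build_transfer(
    cfg: OpticalConfig, library: NanobrickLibrary | None = None
) -> TransferFunction:
    """Build the transfer function selected by an OpticalConfig."""
    if cfg.mode == "xlp":
        h = spiral_transfer(cfg.grid_size, cfg.c1)
    else:
        h = constant_transfer(cfg.grid_size, cfg.c2)
    if cfg.quantization == "library16":
        h = quantize_transfer(h, library or NanobrickLibrary.bundled(), cfg.mode)
    return h
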