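"""Structured illumination patterns and bucket-detector measurement.

Three modulation families drive the single-pixel acquisition:

* **Fourier** — sinusoidal fringes ``0.5 + 0.5*sin(2*pi*(fx*x + fy*y)/N + phi)``
  projected at three initial phases (0, 2pi/3, 4pi/3) per spatial frequency;
  the three bucket values combine into one complex Fourier coefficient.
  Because a real scene has a Hermitian spectrum, only a non-redundant
  half-plane of frequencies is measured.
* **Hadamard** — binary patterns from the rows of the Sylvester Hadamard
  matrix; each coefficient takes one pattern and its complement.
* **Binary random** — i.i.d. Bernoulli(0.5) masks from a seeded PRNG.

The bucket detector reports ``D_j = sum_xy P_j(x,y) * I(x,y)``.  ``measure``
is the literal inner product; ``simulate_fourier_measurements`` and
``simulate_hadamard_measurements`` produce the identical measurement vectors
through FFT / fast-transform identities and are what the pipeline uses at
realistic grid sizes.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Literal

import numpy as np
from scipy.linalg import hadamard as _sylvester

__all__ = [
    "PHASE_STEPS",
    "Pattern",
    "SamplingPlan",
    "MeasurementSet",
    "fourier_pattern",
    "fourier_plan",
    "hadamard_pattern",
    "hadamard_plan",
    "random_pattern",
    "random_plan",
    "patterns_for",
    "measure",
    "simulate_fourier_measurements",
    "simulate_hadamard_measurements",
    "add_noise",
    "sigma_from_snr_db",
    "pattern_checksum",
]

PHASE_STEPS: tuple[float, float, float] = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)

PlanKind = Literal["fourier", "hadamard", "random"]


@dataclass
class Pattern:
    """One illumination pattern with its provenance metadata."""

    values: np.ndarray
    kind: Literal["fourier", "hadamard", "hadamard_complement", "random"]
    index: tuple
    phase_step: float | None = None


@dataclass(frozen=True)
class SamplingPlan:
    """Ordered set of transform coefficients (or random masks) to acquire."""

    kind: PlanKind
    shape: int
    coefficient_order: tuple
    sampling_ratio: float
    seed: int | None = None  # random plans only

    @property
    def patterns_per_coefficient(self) -> int:
        return {"fourier": 3, "hadamard": 2, "random": 1}[self.kind]

    @property
    def n_patterns(self) -> int:
        return len(self.coefficient_order) * self.patterns_per_coefficient


@dataclass
class MeasurementSet:
    """Bucket-detector values, one per pattern, in plan order."""

    values: np.ndarray
    plan: SamplingPlan
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("measurements must be a 1D vector")
        if len(self.values) != self.plan.n_patterns:
            raise ValueError(
                f"{len(self.values)} measurements for a plan of {self.plan.n_patterns} patterns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite measurement values")


# ---------------------------------------------------------------------------
# Fourier modulation


def fourier_pattern(shape: int, fx: float, fy: float, phi: float = 0.0) -> Pattern:
    """Sinusoidal fringe pattern at integer frequency (fx, fy) cycles/grid."""
    n = int(shape)
    if abs(fx) > n / 2 or abs(fy) > n / 2:
        raise ValueError(f"frequency ({fx}, {fy}) outside Nyquist range for N={n}")
    x = np.arange(n)
    xx, yy = np.meshgrid(x, x)  # yy rows, xx cols
    values = 0.5 + 0.5 * np.sin(2.0 * np.pi * (fx * xx + fy * yy) / n + phi)
    return Pattern(values=values, kind="fourier", index=(int(fx), int(fy)), phase_step=phi)


def half_plane_frequencies(n: int) -> list[tuple[int, int]]:
    """All non-redundant frequency pairs of an N x N real-image DFT.

    A pair (ku, kv) with ku, kv in [-N/2, N/2) is kept iff it is the
    canonical member of its conjugate pair {(ku, kv), (-ku, -kv)} (Nyquist
    components are their own negatives mod N).  For even N this set has
    N^2/2 + 2 members, including the four self-conjugate loci.
    """
    half = n // 2
    kept = []
    for kv in range(-half, half):
        for ku in range(-half, half):
            pu = -ku if ku != -half else -half
            pv = -kv if kv != -half else -half
            if (kv, ku) >= (pv, pu):
                kept.append((ku, kv))
    return kept


def fourier_plan(shape: int, sampling_ratio: float) -> SamplingPlan:
    """Low-frequency-first plan over the non-redundant half-plane.

    Coefficients are ordered by radial distance from DC (ties broken by
    angle, then index); each implies three patterns at the three phase
    steps.  ``sampling_ratio`` is the kept fraction of the half-plane.
    """
    n = int(shape)
    if not 0.0 < sampling_ratio <= 1.0:
        raise ValueError("sampling_ratio must be in (0, 1]")
    freqs = half_plane_frequencies(n)
    freqs.sort(key=lambda f: (f[0] ** 2 + f[1] ** 2, math.atan2(f[1], f[0]), f))
    n_coeff = min(len(freqs), math.ceil(sampling_ratio * len(freqs)))
    return SamplingPlan(
        kind="fourier",
        shape=n,
        coefficient_order=tuple(freqs[:n_coeff]),
        sampling_ratio=float(sampling_ratio),
    )


# ---------------------------------------------------------------------------
# Hadamard modulation


def _check_pow2(n: int) -> None:
    if n < 2 or (n & (n - 1)) != 0:
        raise ValueError(f"Hadamard modulation needs a power-of-two grid side, got {n}")


def hadamard_pattern(shape: int, u0: int, v0: int) -> tuple[Pattern, Pattern]:
    """Binary Hadamard pattern for locus (u0, v0) and its complement.

    The pattern is the inverse 2D (separable, Sylvester-ordered) Hadamard
    transform of a delta at (u0, v0), remapped from {-1, +1} to {0, 1};
    the differential measurement D+ - D- equals the scene's Hadamard
    coefficient at (u0, v0).
    """
    n = int(shape)
    _check_pow2(n)
    if not (0 <= u0 < n and 0 <= v0 < n):
        raise ValueError(f"locus ({u0}, {v0}) outside grid")
    h = _sylvester(n)
    core = np.outer(h[u0], h[v0])  # rows: x/row index, cols: y/col index
    p = (1.0 + core) / 2.0
    return (
        Pattern(values=p, kind="hadamard", index=(u0, v0)),
        Pattern(values=1.0 - p, kind="hadamard_complement", index=(u0, v0)),
    )


def _sequency(row: np.ndarray) -> int:
    return int(np.count_nonzero(np.diff(row) != 0))


def hadamard_plan(
    shape: int, sampling_ratio: float, ordering: Literal["natural", "sequency"] = "natural"
) -> SamplingPlan:
    """Plan over Hadamard loci; natural (Sylvester) or sequency ordering.

    Sequency ordering ranks loci by the total number of sign changes of the
    two generating rows, putting coarse structure first, and is the sensible
    choice below full sampling.
    """
    n = int(shape)
    _check_pow2(n)
    if not 0.0 < sampling_ratio <= 1.0:
        raise ValueError("sampling_ratio must be in (0, 1]")
    loci = [(u, v) for u in range(n) for v in range(n)]
    if ordering == "sequency":
        h = _sylvester(n)
        seq = [_sequency(h[i]) for i in range(n)]
        loci.sort(key=lambda f: (seq[f[0]] + seq[f[1]], max(seq[f[0]], seq[f[1]]), f))
    elif ordering != "natural":
        raise ValueError(f"unknown ordering {ordering!r}")
    n_coeff = min(len(loci), math.ceil(sampling_ratio * len(loci)))
    return SamplingPlan(
        kind="hadamard",
        shape=n,
        coefficient_order=tuple(loci[:n_coeff]),
        sampling_ratio=float(sampling_ratio),
    )


# ---------------------------------------------------------------------------
# Binary random modulation


def random_pattern(shape: int, j: int, seed: int = 0) -> Pattern:
    """I.i.d. Bernoulli(0.5) binary mask, reproducible from (seed, j)."""
    n = int(shape)
    rng = np.random.default_rng([int(seed), int(j)])
    values = rng.integers(0, 2, size=(n, n)).astype(np.float64)
    return Pattern(values=values, kind="random", index=(int(j),))


def random_plan(shape: int, sampling_ratio: float, seed: int = 0) -> SamplingPlan:
    """Plan of ceil(ratio * N^2) random masks (full sampling = N^2 masks)."""
    n = int(shape)
    if not 0.0 < sampling_ratio <= 1.0:
        raise ValueError("sampling_ratio must be in (0, 1]")
    m = math.ceil(sampling_ratio * n * n)
    return SamplingPlan(
        kind="random",
        shape=n,
        coefficient_order=tuple((j,) for j in range(m)),
        sampling_ratio=float(sampling_ratio),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Measurement


def patterns_for(plan: SamplingPlan) -> Iterator[Pattern]:
    """Lazily yield the patterns of a plan, in measurement order."""
    if plan.kind == "fourier":
        for fx, fy in plan.coefficient_order:
            for phi in PHASE_STEPS:
                yield fourier_pattern(plan.shape, fx, fy, phi)
    elif plan.kind == "hadamard":
        for u0, v0 in plan.coefficient_order:
            p, q = hadamard_pattern(plan.shape, u0, v0)
            yield p
            yield q
    else:
        for (j,) in plan.coefficient_order:
            yield random_pattern(plan.shape, j, plan.seed or 0)


def measure(
    image: np.ndarray, patterns: Iterable[Pattern] | SamplingPlan
) -> MeasurementSet | np.ndarray:
    """Bucket-detector inner products D_j = sum(P_j * I), in pattern order.

    Given a SamplingPlan, returns a MeasurementSet; given an iterable of
    patterns, returns the bare value vector.
    """
    image = np.asarray(image, dtype=np.float64)
    if isinstance(patterns, SamplingPlan):
        if image.shape != (patterns.shape, patterns.shape):
            raise ValueError(f"image shape {image.shape} does not match plan grid {patterns.shape}")
        values = np.fromiter(
            (float(np.sum(p.values * image)) for p in patterns_for(patterns)),
            dtype=np.float64,
            count=patterns.n_patterns,
        )
        return MeasurementSet(values=values, plan=patterns)
    out = []
    for p in patterns:
        if p.values.shape != image.shape:
            raise ValueError(f"pattern shape {p.values.shape} != image shape {image.shape}")
        out.append(float(np.sum(p.values * image)))
    return np.asarray(out)


def simulate_fourier_measurements(image: np.ndarray, plan: SamplingPlan) -> MeasurementSet:
    """Exact Fourier-plan measurements via one FFT instead of N patterns.

    For a fringe at (fx, fy) with phase phi, D = 0.5*S + 0.5*(Ss*cos(phi) +
    Cs*sin(phi)) where S = sum(I) and Cs - i*Ss is the DFT of I at (fx, fy);
    identical (to rounding) to the literal pattern inner products.
    """
    if plan.kind != "fourier":
        raise ValueError("plan is not a Fourier plan")
    image = np.asarray(image, dtype=np.float64)
    n = plan.shape
    if image.shape != (n, n):
        raise ValueError("image shape does not match plan grid")
    f = np.fft.fft2(image)
    s = float(np.sum(image))
    idx = np.array(plan.coefficient_order)
    coeffs = f[idx[:, 1] % n, idx[:, 0] % n]
    cs, ss = coeffs.real, -coeffs.imag
    phis = np.array(PHASE_STEPS)
    d = 0.5 * s + 0.5 * (ss[:, None] * np.cos(phis)[None, :] + cs[:, None] * np.sin(phis)[None, :])
    return MeasurementSet(values=d.ravel(), plan=plan)


def simulate_hadamard_measurements(image: np.ndarray, plan: SamplingPlan) -> MeasurementSet:
    """Exact Hadamard-plan measurements via the fast separable transform.

    D+ = (S + C[u0, v0]) / 2 and D- = (S - C[u0, v0]) / 2 with C = H I H.
    """
    if plan.kind != "hadamard":
        raise ValueError("plan is not a Hadamard plan")
    image = np.asarray(image, dtype=np.float64)
    n = plan.shape
    if image.shape != (n, n):
        raise ValueError("image shape does not match plan grid")
    h = _sylvester(n).astype(np.float64)
    c = h @ image @ h
    s = float(np.sum(image))
    idx = np.array(plan.coefficient_order)
    cv = c[idx[:, 0], idx[:, 1]]
    d = np.stack([(s + cv) / 2.0, (s - cv) / 2.0], axis=1)
    return MeasurementSet(values=d.ravel(), plan=plan)


def add_noise(m: MeasurementSet, sigma: float, seed: int = 0) -> MeasurementSet:
    """Add i.i.d. Gaussian detector noise N(0, sigma^2) to every bucket value."""
    if sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    if sigma == 0:
        return replace(m, values=m.values.copy(), noise_sigma=0.0, seed=seed)
    rng = np.random.default_rng(seed)
    noisy = m.values + rng.normal(0.0, sigma, size=len(m.values))
    return replace(m, values=noisy, noise_sigma=float(sigma), seed=seed)


def sigma_from_snr_db(values: np.ndarray, snr_db: float) -> float:
    """Noise sigma giving the requested SNR (dB) against the RMS of ``values``."""
    rms = float(np.sqrt(np.mean(np.square(np.asarray(values, dtype=np.float64)))))
    return rms * 10.0 ** (-snr_db / 20.0)


def pattern_checksum(plan: SamplingPlan) -> str:
    """SHA-256 over the byte stream of every pattern of a plan, in order."""
    digest = hashlib.sha256()
    for p in patterns_for(plan):
        digest.update(np.ascontiguousarray(p.values, dtype=np.float64).tobytes())
    return digest.hexdigest()
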