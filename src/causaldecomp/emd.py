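"""Empirical mode decomposition, ensemble EMD, and the analytic signal.

A time series is sifted into intrinsic mode functions (IMFs): narrow-band,
amplitude/frequency-modulated components ordered fine-to-coarse, plus a
residual trend.  Ensemble EMD (EEMD) stabilises the scale assignment by
averaging the decompositions of many white-noise-perturbed copies of the
signal; the noise amplitude ``r`` is expressed as a fraction of the signal's
standard deviation and the ensemble mean cancels the added noise as the
number of trials grows.

The instantaneous amplitude and phase of an IMF come from the discrete
analytic signal (Hilbert transform): ``S(t) = A(t) cos φ(t)`` with
``A = sqrt(S² + S_H²)`` and ``φ = arctan2(S_H, S)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from ._sift import emd_kernel, eemd_kernel

logger = logging.getLogger(__name__)

#: Minimum record length accepted for sifting.
MIN_LENGTH = 16

#: Sifting iterations per IMF (fixed-count sifting, after the classic
#: ensemble-EMD implementation lineage).
DEFAULT_SIFT_ITERATIONS = 10

#: Default ensemble size for EEMD.
DEFAULT_ENSEMBLE_SIZE = 1000

__all__ = [
    "TimeSeries",
    "IMFSet",
    "AnalyticIMF",
    "emd",
    "eemd",
    "analytic",
    "default_max_imfs",
    "MIN_LENGTH",
    "DEFAULT_SIFT_ITERATIONS",
    "DEFAULT_ENSEMBLE_SIZE",
]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled, finite, real-valued signal."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ValueError(f"time series must be 1-D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise ValueError(f"non-finite value at index {bad} in series {self.label!r}")

    def __len__(self) -> int:
        return self.values.size

    def require_length(self, floor: int = MIN_LENGTH) -> None:
        if len(self) < floor:
            raise ValueError(
                f"series {self.label!r} has {len(self)} samples; "
                f"at least {floor} are required for sifting"
            )


@dataclass(frozen=True)
class IMFSet:
    """Ordered IMFs (fine-to-coarse) plus a residual trend.

    ``imfs`` has shape (k, n); every component has the length of the source.
    For plain EMD the components sum exactly back to the source; for EEMD
    the reconstruction error scales like ``noise_level / sqrt(ensemble_size)``.
    """

    imfs: np.ndarray
    residual: np.ndarray
    noise_level: float = 0.0
    ensemble_size: int = 1
    source_std: float = float("nan")

    def __post_init__(self) -> None:
        imfs = np.atleast_2d(np.asarray(self.imfs, dtype=float))
        if imfs.size == 0:
            imfs = imfs.reshape(0, np.asarray(self.residual).size)
        object.__setattr__(self, "imfs", imfs)
        object.__setattr__(self, "residual", np.asarray(self.residual, dtype=float))
        if self.imfs.shape[0] and self.imfs.shape[1] != self.residual.size:
            raise ValueError("IMFs and residual must have equal length")

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    @property
    def length(self) -> int:
        return self.residual.size

    def reconstruction(self) -> np.ndarray:
        """Sum of all IMFs and the residual."""
        return self.imfs.sum(axis=0) + self.residual

    def components(self) -> np.ndarray:
        """All components (IMFs then residual) as rows."""
        return np.vstack([self.imfs, self.residual[None, :]])

    def variances(self) -> np.ndarray:
        """Per-IMF variance (residual excluded)."""
        return self.imfs.var(axis=1)


@dataclass(frozen=True)
class AnalyticIMF:
    """Instantaneous amplitude, phase (radians) and frequency (rad/sample)."""

    amplitude: np.ndarray
    phase: np.ndarray
    frequency: np.ndarray
    degenerate: bool = False  # True for an all-zero input, where phase is 0 by convention

    def __len__(self) -> int:
        return self.phase.size


def default_max_imfs(length: int) -> int:
    """Dyadic default for the number of IMFs: floor(log2 L) - 1.

    EMD acts as a dyadic filter bank on broadband signals, so a record of
    length L supports about log2(L) scales; one is reserved for the trend.
    """
    return max(1, int(math.floor(math.log2(length))) - 1)


def emd(
    x: TimeSeries,
    max_imfs: int | None = None,
    sift_iterations: int = DEFAULT_SIFT_ITERATIONS,
    min_length: int = MIN_LENGTH,
) -> IMFSet:
    """Plain EMD by fixed-count sifting with natural-cubic-spline envelopes.

    Extraction stops when the working residual has fewer than three local
    extrema or ``max_imfs`` components have been produced.  A constant (or
    monotone) series yields zero IMFs with the input as residual.
    """
    x.require_length(min_length)
    if max_imfs is None:
        max_imfs = default_max_imfs(len(x))
    if max_imfs < 1:
        raise ValueError("max_imfs must be >= 1")
    imfs, resid, count = emd_kernel(x.values, max_imfs, sift_iterations)
    return IMFSet(
        imfs=imfs[:count],
        residual=resid,
        noise_level=0.0,
        ensemble_size=1,
        source_std=float(np.std(x.values)),
    )


def eemd(
    x: TimeSeries,
    noise_level: float,
    ensemble_size: int = DEFAULT_ENSEMBLE_SIZE,
    max_imfs: int | None = None,
    seed: int | np.random.Generator = 0,
    sift_iterations: int = DEFAULT_SIFT_ITERATIONS,
    min_length: int = MIN_LENGTH,
) -> IMFSet:
    """Ensemble EMD: mean decomposition of noise-perturbed copies of ``x``.

    Each of ``ensemble_size`` trials decomposes ``x + noise_level·std(x)·w``
    with ``w`` fresh standard Gaussian white noise, forcing ``max_imfs``
    components per trial (zero-padded when a trial terminates early); the
    returned IMFs and residual are the per-index ensemble means.  A
    ``noise_level`` of zero collapses the ensemble to plain EMD.

    ``seed`` fixes the white-noise stream: equal seeds give bitwise-equal
    results.  A ``numpy.random.Generator`` may be passed directly when the
    caller manages the stream.
    """
    x.require_length(min_length)
    if not 0.0 <= noise_level <= 1.0:
        raise ValueError(f"noise_level must be within [0, 1], got {noise_level}")
    if ensemble_size < 1:
        raise ValueError(f"ensemble_size must be >= 1, got {ensemble_size}")
    if max_imfs is None:
        max_imfs = default_max_imfs(len(x))
    src_std = float(np.std(x.values))
    if noise_level == 0.0 or src_std == 0.0:
        base = emd(x, max_imfs=max_imfs, sift_iterations=sift_iterations,
                   min_length=min_length)
        return IMFSet(
            imfs=base.imfs,
            residual=base.residual,
            noise_level=noise_level,
            ensemble_size=ensemble_size,
            source_std=src_std,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.standard_normal((ensemble_size, len(x)))
    imfs, resid = eemd_kernel(
        x.values, noise, noise_level * src_std, max_imfs, sift_iterations
    )
    return IMFSet(
        imfs=imfs,
        residual=resid,
        noise_level=noise_level,
        ensemble_size=ensemble_size,
        source_std=src_std,
    )


def analytic(imf: np.ndarray, min_length: int = MIN_LENGTH) -> AnalyticIMF:
    """Instantaneous amplitude, phase and frequency of one IMF.

    Uses the discrete analytic-signal construction (frequency-domain Hilbert
    transform on the full record, no tapering).  The phase is the
    four-quadrant arctangent of (Hilbert transform, signal), and the
    instantaneous frequency is the discrete derivative (central gradient)
    of the unwrapped phase.

    An all-zero IMF has no meaningful phase; it is returned with zero
    amplitude and phase and flagged ``degenerate``.
    """
    s = np.asarray(imf, dtype=float)
    if s.ndim != 1 or s.size < min_length:
        raise ValueError(f"IMF must be 1-D with at least {min_length} samples")
    if not np.any(s):
        zeros = np.zeros_like(s)
        return AnalyticIMF(zeros, zeros, zeros, degenerate=True)
    z = hilbert(s)
    amplitude = np.abs(z)
    phase = np.angle(z)  # arctan2(imag, real)
    frequency = np.gradient(np.unwrap(phase))
    return AnalyticIMF(amplitude, phase, frequency)
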