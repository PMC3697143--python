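"""Fourier transformation, band partitioning and cross-spectral estimation.

The analysis operates on the discrete Fourier transforms of the stimulus
indicator sequences (the model inputs) and the per-voxel BOLD time series
(the outputs).  Second-order statistics are stabilised by averaging
periodograms over contiguous bands of ``2m + 1`` Fourier frequencies; all
downstream inference is carried out band by band.

Conventions
-----------
* The forward DFT is unnormalized (``sum_t x(t) exp(-i 2 pi k t / T)``) and
  only the nonnegative half-line ``k = 0 .. floor(T/2)`` is kept; negative
  frequencies are redundant for real data by Hermitian symmetry.
* The periodogram retains the classical ``(2 pi T)^{-1}`` scaling.  The test
  statistics built on top of these estimates are ratios in which any global
  scaling cancels, so the convention only matters when inspecting
  intermediate values.
* The band centered at zero frequency is always discarded: it collects the
  series means, slow drift and motion artifacts, and dropping it acts as a
  high-pass filter.  No detrending or demeaning is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusSet",
    "MultiRunSeries",
    "BandPartition",
    "SpectraBundle",
    "dft",
    "make_band_partition",
    "periodogram",
    "estimate_cross_spectra",
]

TWO_PI = 2.0 * np.pi


class DataQualityError(ValueError):
    """Raised when input data violate a basic quality contract."""


class ConfigurationError(ValueError):
    """Raised when parameters are inconsistent or infeasible."""


@dataclass(frozen=True)
class StimulusSet:
    """R binary stimulus indicator sequences of common length T.

    Parameters
    ----------
    indicators
        ``(T, R)`` array with entries in {0, 1}; column ``r`` is 1 at the
        timepoints where stimulus ``r`` is being presented.
    labels
        One name per stimulus type, e.g. ``("pos", "neg")``.
    sampling_interval
        Seconds per timepoint (the repetition time, TR).
    """

    indicators: np.ndarray
    labels: tuple[str, ...]
    sampling_interval: float = 2.0

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicators, dtype=float)
        if ind.ndim != 2:
            raise ConfigurationError("indicators must be a (T, R) matrix")
        object.__setattr__(self, "indicators", ind)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != ind.shape[1]:
            raise ConfigurationError(
                f"{len(self.labels)} labels for {ind.shape[1]} indicator columns"
            )
        if not np.isin(ind, (0.0, 1.0)).all():
            raise DataQualityError("stimulus indicators must contain only 0s and 1s")
        if (ind.sum(axis=0) < 1).any():
            missing = [l for l, n in zip(self.labels, ind.sum(axis=0)) if n < 1]
            raise DataQualityError(f"stimuli with no presentation: {missing}")
        if self.sampling_interval <= 0:
            raise ConfigurationError("sampling_interval must be positive")

    @property
    def T(self) -> int:
        return self.indicators.shape[0]

    @property
    def R(self) -> int:
        return self.indicators.shape[1]


@dataclass(frozen=True)
class MultiRunSeries:
    """Masked voxelwise BOLD time series for S repeated runs ("states").

    ``values[v, s, :]`` is the series of in-mask voxel ``v`` in run ``s``.
    Voxels follow C-order enumeration of ``True`` entries in ``mask``.
    """

    values: np.ndarray  # (V, S, T)
    run_labels: tuple[str, ...]
    grid_shape: tuple[int, int, int]
    mask: np.ndarray  # 3D bool
    sampling_interval: float = 2.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "run_labels", tuple(self.run_labels))
        object.__setattr__(self, "grid_shape", tuple(self.grid_shape))
        if vals.ndim != 3:
            raise ConfigurationError("values must be (voxels, runs, timepoints)")
        if len(self.run_labels) != vals.shape[1]:
            raise ConfigurationError("run_labels must match the number of runs")
        if mask.shape != self.grid_shape:
            raise ConfigurationError("mask shape must equal grid_shape")
        if int(mask.sum()) != vals.shape[0]:
            raise ConfigurationError(
                f"mask selects {int(mask.sum())} voxels but values has {vals.shape[0]}"
            )
        if not np.isfinite(vals).all():
            raise DataQualityError("non-finite values in BOLD series")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def S(self) -> int:
        return self.values.shape[1]

    @property
    def T(self) -> int:
        return self.values.shape[2]

    def unmask(self, flat: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a per-voxel vector back onto the full 3D grid."""
        out = np.full(self.grid_shape, fill, dtype=float)
        out[self.mask] = flat
        return out


@dataclass(frozen=True)
class BandPartition:
    """Disjoint bands of 2m+1 adjacent Fourier frequencies.

    Band ``j`` is centered at index ``k_c = (2m+1)(j+1)`` with members
    ``k_c - m .. k_c + m``; the zero-centered band is discarded, and so is
    any band extending past the Nyquist index ``floor(T/2)``.
    """

    T: int
    m: int
    centers: tuple[int, ...]

    @property
    def width(self) -> int:
        return 2 * self.m + 1

    @property
    def n_bands(self) -> int:
        return len(self.centers)

    @property
    def center_frequencies(self) -> np.ndarray:
        """Angular center frequencies lambda = 2 pi k_c / T."""
        return TWO_PI * np.asarray(self.centers, dtype=float) / self.T

    def members(self, band: int) -> np.ndarray:
        """Fourier indices belonging to one band."""
        k_c = self.centers[band]
        return np.arange(k_c - self.m, k_c + self.m + 1)

    def all_members(self) -> np.ndarray:
        """(n_bands, 2m+1) index matrix."""
        return np.stack([self.members(j) for j in range(self.n_bands)])


def dft(series: np.ndarray) -> np.ndarray:
    """Unnormalized DFT of real data at frequencies ``k = 0 .. floor(T/2)``.

    Accepts any array whose last axis is time; returns the complex
    coefficients along that axis (length ``floor(T/2) + 1``).  Any fixed
    global scaling convention would do — the final U and F statistics are
    invariant to it — but the plain forward transform is used so that
    intermediate quantities match their textbook definitions.
    """
    arr = np.asarray(series, dtype=float)
    if arr.shape[-1] < 2:
        raise ConfigurationError("need at least 2 timepoints")
    if not np.isfinite(arr).all():
        raise DataQualityError("non-finite values in series passed to dft")
    return np.fft.rfft(arr, axis=-1)


def make_band_partition(T: int, m: int) -> BandPartition:
    """Partition the Fourier frequencies of a length-T series into bands.

    Centers sit at consecutive multiples of ``2m + 1`` so the bands tile the
    frequency axis without gaps.  The zero-centered band (slow drift,
    motion) is discarded, as is any band whose top index exceeds the
    Nyquist index ``floor(T/2)``.

    For the demonstration design (T=156, m=6) this yields five bands of 13
    frequencies centered at k = 13, 26, 39, 52, 65.
    """
    if m < 1:
        raise ConfigurationError("band half-width m must be >= 1")
    width = 2 * m + 1
    if T < 2 * width:
        raise ConfigurationError(
            f"T={T} too short for any band of width {width} after the zero band"
        )
    nyquist = T // 2
    centers = []
    j = 1
    while True:
        k_c = width * j
        if k_c + m > nyquist:
            break
        centers.append(k_c)
        j += 1
    if not centers:
        raise ConfigurationError(
            f"no band of width {width} fits below the Nyquist index {nyquist}"
        )
    return BandPartition(T=T, m=m, centers=tuple(centers))


def periodogram(alpha: np.ndarray, beta: np.ndarray, T: int) -> np.ndarray:
    """Cross-periodogram ``I_ab = (2 pi T)^{-1} a^H b`` at one frequency.

    ``alpha`` and ``beta`` are the DFT coefficient row vectors (one complex
    number per series) evaluated at a common frequency; the result has shape
    (columns of alpha) x (columns of beta).
    """
    a = np.atleast_2d(np.asarray(alpha, dtype=complex))
    b = np.atleast_2d(np.asarray(beta, dtype=complex))
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"row mismatch: alpha {a.shape} vs beta {b.shape}")
    return (a.conj().T @ b) / (TWO_PI * T)


@dataclass(frozen=True)
class SpectraBundle:
    """Band-averaged cross-spectral matrices.

    ``f_rr[j]`` is the R x R stimulus auto-spectrum of band ``j`` (shared by
    all voxels since the stimuli carry no spatial dependency); ``f_rs[j, v]``
    (R x S) and ``f_ss[j, v]`` (S x S) are per-voxel.  ``f_sr`` is never
    stored: it is the Hermitian transpose of ``f_rs``.
    """

    f_rr: np.ndarray  # (n_bands, R, R)
    f_rs: np.ndarray  # (n_bands, V, R, S)
    f_ss: np.ndarray  # (n_bands, V, S, S)
    partition: BandPartition
    stim_labels: tuple[str, ...] = field(default=())
    run_labels: tuple[str, ...] = field(default=())

    @property
    def R(self) -> int:
        return self.f_rr.shape[-1]

    @property
    def S(self) -> int:
        return self.f_ss.shape[-1]

    @property
    def n_voxels(self) -> int:
        return self.f_rs.shape[1]


def estimate_cross_spectra(
    stim_dft: np.ndarray,
    bold_dft: np.ndarray,
    partition: BandPartition,
    stim_labels: tuple[str, ...] = (),
    run_labels: tuple[str, ...] = (),
) -> SpectraBundle:
    """Average cross-periodograms over each band.

    Parameters
    ----------
    stim_dft
        ``(K, R)`` stimulus DFT coefficients, ``K >= max band index + 1``.
    bold_dft
        ``(V, S, K)`` BOLD DFT coefficients (or ``(S, K)`` for one voxel).
    partition
        Band layout; every member index must be within ``K``.

    Returns
    -------
    SpectraBundle
        With ``f_ab`` equal to the arithmetic mean over the band's ``2m+1``
        member frequencies of ``(2 pi T)^{-1} a^H b``.
    """
    stim_dft = np.asarray(stim_dft, dtype=complex)
    bold_dft = np.asarray(bold_dft, dtype=complex)
    if bold_dft.ndim == 2:
        bold_dft = bold_dft[np.newaxis]
    if bold_dft.ndim != 3:
        raise ValueError("bold_dft must be (voxels, runs, frequencies)")
    members = partition.all_members()
    if members.max() >= stim_dft.shape[0] or members.max() >= bold_dft.shape[-1]:
        raise RuntimeError(
            "band member index beyond available DFT coefficients "
            f"(max index {members.max()})"
        )
    scale = 1.0 / (TWO_PI * partition.T * partition.width)
    # r: (n_bands, w, R); s: (V, S, n_bands, w)
    r = stim_dft[members]
    s = bold_dft[..., members]
    f_rr = scale * np.einsum("jka,jkb->jab", r.conj(), r)
    f_rs = scale * np.einsum("jka,vbjk->jvab", r.conj(), s)
    f_ss = scale * np.einsum("vajk,vbjk->jvab", s.conj(), s)
    return SpectraBundle(
        f_rr=f_rr,
        f_rs=f_rs,
        f_ss=f_ss,
        partition=partition,
        stim_labels=tuple(stim_labels),
        run_labels=tuple(run_labels),
    )


def cross_spectra_from_data(
    stimuli: StimulusSet, series: MultiRunSeries, m: int
) -> SpectraBundle:
    """Convenience chain: DFT both sides, build the partition, average."""
    if stimuli.T != series.T:
        raise ConfigurationError(
            f"stimuli have T={stimuli.T} but series have T={series.T}"
        )
    partition = make_band_partition(series.T, m)
    stim_dft = dft(stimuli.indicators.T).T  # (K, R)
    bold_dft = dft(series.values)  # (V, S, K)
    return estimate_cross_spectra(
        stim_dft,
        bold_dft,
        partition,
        stim_labels=stimuli.labels,
        run_labels=series.run_labels,
    )
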