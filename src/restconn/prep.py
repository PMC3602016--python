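"""Temporal and spatial preprocessing of resting-state fMRI data.

The canonical order is: discard initial volumes, remove linear trends,
band-pass filter (0.01-0.08 Hz), and — on the voxel path — Gaussian spatial
smoothing.  Band-pass filtering uses a zero-phase (forward-backward)
Butterworth design so no temporal shift is introduced, which matters for the
downstream lag-based causality analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import ndimage, signal

from .errors import DegenerateInputError, ValidationError
from .grid import VolumeGrid

#: FWHM-to-sigma conversion for a Gaussian kernel.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

Condition = Literal["abstinence", "satiety"]


@dataclass
class FmriSession:
    """One subject-condition 4-D dataset.

    ``data`` has shape ``(nx, ny, nz, T)``; ``tr_s`` is the sampling interval
    in seconds.
    """

    subject_id: str
    condition: Condition
    grid: VolumeGrid
    tr_s: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.tr_s <= 0:
            raise ValidationError(f"tr_s must be positive, got {self.tr_s}")
        if self.data.ndim != 4:
            raise ValidationError(f"session data must be 4-D, got shape {self.data.shape}")
        if self.data.shape[:3] != self.grid.dims:
            raise ValidationError(
                f"data spatial shape {self.data.shape[:3]} != grid dims {self.grid.dims}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("session data contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[3])

    def voxels_by_time(self) -> np.ndarray:
        """View of the data as (n_voxels, T)."""
        return self.data.reshape(-1, self.n_timepoints)


@dataclass
class TimeCourse:
    """A single sampled time series with its repetition time."""

    values: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.tr_s <= 0:
            raise ValidationError(f"tr_s must be positive, got {self.tr_s}")
        if self.values.size < 2:
            raise ValidationError("time course needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("time course contains non-finite values")

    def __len__(self) -> int:
        return self.values.size


def discard_initial_volumes(session: FmriSession, n: int) -> FmriSession:
    """Drop the first ``n`` volumes (magnetic-equilibration period)."""
    if n < 0:
        raise ValidationError(f"n must be >= 0, got {n}")
    if n >= session.n_timepoints:
        raise ValidationError(
            f"cannot discard {n} volumes from a session of {session.n_timepoints}"
        )
    return replace(session, data=session.data[..., n:].copy())


def _detrend_matrix(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """OLS removal of intercept and linear slope along ``axis``."""
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    if n < 3:
        raise ValidationError(f"detrending needs length >= 3, got {n}")
    t = np.arange(n, dtype=float)
    design = np.column_stack([np.ones(n), t])  # (n, 2)
    moved = np.moveaxis(x, axis, -1)
    flat = moved.reshape(-1, n)
    beta, *_ = np.linalg.lstsq(design, flat.T, rcond=None)
    resid = flat - (design @ beta).T
    return np.moveaxis(resid.reshape(moved.shape), -1, axis)


def remove_linear_trend(series: TimeCourse) -> TimeCourse:
    """Residual after jointly fitting intercept and slope by least squares.

    The output is orthogonal to both the constant and the linear regressor, so
    a pure line comes back as zeros and a constant is absorbed entirely.
    """
    return TimeCourse(_detrend_matrix(series.values), series.tr_s)


def detrend_session(session: FmriSession) -> FmriSession:
    """Voxelwise linear detrending of a whole session."""
    return replace(session, data=_detrend_matrix(session.data, axis=-1))


def _design_bandpass(low_hz: float, high_hz: float, tr_s: float, order: int = 4):
    nyquist = 0.5 / tr_s
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValidationError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < Nyquist={nyquist}"
        )
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_s)


def _bandpass_array(x: np.ndarray, low_hz: float, high_hz: float, tr_s: float,
                    axis: int = -1, order: int = 4) -> np.ndarray:
    b, a = _design_bandpass(low_hz, high_hz, tr_s, order)
    arr = np.asarray(x, dtype=float)
    default_pad = 3 * (max(len(a), len(b)) - 1)
    padlen = min(default_pad, arr.shape[axis] - 1)
    return signal.filtfilt(b, a, arr, axis=axis, padlen=padlen)


def bandpass_filter(series: TimeCourse, low_hz: float = 0.01, high_hz: float = 0.08) -> TimeCourse:
    """Zero-phase Butterworth band-pass (default 0.01-0.08 Hz).

    A fourth-order design applied forward and backward: unit gain in the
    passband interior, strong attenuation of the DC drift below the band and
    of high-frequency physiological noise above it, and no phase shift.
    """
    return TimeCourse(
        _bandpass_array(series.values, low_hz, high_hz, series.tr_s), series.tr_s
    )


def bandpass_session(session: FmriSession, low_hz: float = 0.01, high_hz: float = 0.08) -> FmriSession:
    """Voxelwise zero-phase band-pass of a whole session."""
    return replace(
        session, data=_bandpass_array(session.data, low_hz, high_hz, session.tr_s, axis=-1)
    )


def spatial_smooth(volume: np.ndarray, fwhm_mm, grid: VolumeGrid) -> np.ndarray:
    """Separable Gaussian smoothing with the kernel stated in mm FWHM.

    Sigma per axis is ``FWHM / (2 * sqrt(2 * ln 2))`` converted to voxel
    units.  Reflecting boundary handling preserves total mass on the small
    grids used here.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    if np.any(fwhm <= 0):
        raise ValidationError(f"FWHM must be positive, got {fwhm_mm}")
    vol = np.asarray(volume, dtype=float)
    if vol.shape[:3] != grid.dims:
        raise ValidationError(f"volume shape {vol.shape} does not match grid {grid.dims}")
    sigma_vox = fwhm * FWHM_TO_SIGMA / np.asarray(grid.voxel_size_mm)
    if vol.ndim == 3:
        return ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="reflect")
    sigmas = list(sigma_vox) + [0.0] * (vol.ndim - 3)
    return ndimage.gaussian_filter(vol, sigma=sigmas, mode="reflect")


def smooth_session(session: FmriSession, fwhm_mm=(8.0, 8.0, 8.0)) -> FmriSession:
    """Spatially smooth every volume of a session (default 8 mm FWHM)."""
    return replace(session, data=spatial_smooth(session.data, fwhm_mm, session.grid))


def standardize(series: TimeCourse, mode: Literal["zero_mean", "zscore"] = "zscore") -> TimeCourse:
    """Shift to zero mean, and for ``zscore`` scale to unit sample variance.

    The sample standard deviation uses the n-1 denominator.
    """
    v = series.values
    centered = v - v.mean()
    if mode == "zero_mean":
        return TimeCourse(centered, series.tr_s)
    if mode == "zscore":
        sd = v.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateInputError("z-scoring a constant series is undefined")
        return TimeCourse(centered / sd, series.tr_s)
    raise ValidationError(f"unknown standardize mode {mode!r}")
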