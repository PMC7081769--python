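"""Temporal conditioning of aligned 4D BOLD series.

The steps mirror the standard resting-state pipeline applied after spatial
normalization: discard the initial non-equilibrium volumes, remove the linear
trend and restrict the signal to the low-frequency band (0.01–0.1 Hz), then
regress out nuisance signals (six rigid-body motion parameters plus mean white
matter and cerebrospinal fluid time courses). Framewise displacement (FD) is
computed from the motion parameters in the Power convention: summed absolute
frame-to-frame changes of the translations (mm) plus rotations converted to
arc length on a 50 mm sphere.

Processing order is discard → detrend/band-pass → nuisance regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib

__all__ = [
    "BoldSeries",
    "MotionTrace",
    "FdSeries",
    "discard_initial",
    "compute_fd",
    "detrend_and_bandpass",
    "nuisance_regress",
    "extract_tissue_signal",
]


@dataclass
class BoldSeries:
    """A subject's 4D time series: (x, y, z, t) data, affine, repetition time."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BoldSeries.data must be 4D, got {self.data.ndim}D")
        if self.data.shape[3] < 1:
            raise ValueError("BoldSeries must contain at least one frame")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BoldSeries.data contains non-finite values")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @classmethod
    def from_nifti(cls, path, tr_seconds: float | None = None) -> "BoldSeries":
        img = nib.load(str(path))
        tr = tr_seconds if tr_seconds is not None else float(img.header.get_zooms()[3])
        return cls(np.asarray(img.dataobj, dtype=np.float64), img.affine, tr)

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*self.voxel_sizes_mm, self.tr_seconds))
        nib.save(img, str(path))


@dataclass
class MotionTrace:
    """Per-frame rigid-body parameters: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=np.float64))
        if self.params.shape[1] != 6:
            raise ValueError("MotionTrace requires 6 columns (3 translations, 3 rotations)")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("MotionTrace contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_rad(self) -> np.ndarray:
        return self.params[:, 3:]

    @classmethod
    def from_text(cls, path) -> "MotionTrace":
        return cls(np.loadtxt(str(path), ndmin=2))

    def to_text(self, path) -> None:
        np.savetxt(str(path), self.params, fmt="%.8f")


@dataclass
class FdSeries:
    """Per-frame framewise displacement in mm (first frame defined as 0)."""

    values: np.ndarray
    mean_fd: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("FD values must be non-negative")
        self.mean_fd = float(self.values.mean())


def discard_initial(series: BoldSeries, n_discard: int = 10) -> BoldSeries:
    """Drop the first ``n_discard`` frames (signal-equilibration volumes)."""
    if not 0 <= n_discard < series.n_frames:
        raise ValueError(
            f"n_discard must satisfy 0 <= n_discard < {series.n_frames}, got {n_discard}"
        )
    return BoldSeries(series.data[..., n_discard:], series.affine, series.tr_seconds)


def compute_fd(motion: MotionTrace, sphere_radius_mm: float = 50.0) -> FdSeries:
    """Framewise displacement, Power convention.

    FD_t = Σ|Δd_i| + r·Σ|Δθ_i| over the three translations d (mm) and three
    rotations θ (radians), with rotations mapped to displacement on a sphere
    of radius ``sphere_radius_mm``. FD of the first frame is 0.
    """
    if motion.n_frames < 2:
        raise ValueError("FD requires at least 2 frames")
    dt = np.abs(np.diff(motion.translations_mm, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(motion.rotations_rad, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], dt + sphere_radius_mm * dr])
    return FdSeries(fd)


def detrend_and_bandpass(
    series: BoldSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    method: str = "fourier",
) -> BoldSeries:
    """Remove per-voxel linear trend and mean, then band-pass to [low, high] Hz.

    The default filter is an ideal (Fourier-domain) filter realized as one
    least-squares projection: each voxel's course is residualized against the
    span of the constant, the linear ramp, and every out-of-band DFT basis
    vector. A projection is exactly idempotent, and out-of-band sinusoids are
    annihilated exactly. A 4th-order zero-phase Butterworth is available with
    ``method="butterworth"``.
    """
    nyquist = 1.0 / (2.0 * series.tr_seconds)
    if not (0 <= low_hz < high_hz <= nyquist + 1e-12):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz must lie within [0, Nyquist={nyquist:.4g}] Hz"
        )
    nt = series.n_frames
    flat = series.data.reshape(-1, nt)

    t = np.arange(nt, dtype=np.float64)
    t = (t - t.mean()) / max(t.std(), 1.0)

    if method == "fourier":
        freqs = np.fft.rfftfreq(nt, d=series.tr_seconds)
        drop = ~((freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12))
        vectors: list[np.ndarray] = [np.ones(nt), t]
        for k in np.flatnonzero(drop):
            if k == 0:
                continue  # DC is the constant already present
            phase = 2.0 * np.pi * k * np.arange(nt) / nt
            vectors.append(np.cos(phase))
            if k != nt - k:  # Nyquist bin has no independent sine component
                vectors.append(np.sin(phase))
        nuisance = np.column_stack(vectors)
        coef, *_ = np.linalg.lstsq(nuisance, flat.T, rcond=None)
        filtered = flat - (nuisance @ coef).T
    elif method == "butterworth":
        basis = np.column_stack([np.ones(nt), t])
        coef, *_ = np.linalg.lstsq(basis, flat.T, rcond=None)
        detrended = flat - (basis @ coef).T
        from scipy.signal import butter, filtfilt

        lo = max(low_hz, 1e-6) / nyquist
        hi = min(high_hz / nyquist, 1 - 1e-6)
        b, a = butter(4, [lo, hi], btype="band")
        filtered = filtfilt(b, a, detrended, axis=1)
        filtered -= filtered.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown filter method {method!r}")

    return BoldSeries(filtered.reshape(series.data.shape), series.affine, series.tr_seconds)


def nuisance_regress(series: BoldSeries, regressors: np.ndarray) -> BoldSeries:
    """Regress per-frame nuisance signals out of every voxel's time course.

    The design is [intercept | regressors]; the returned series holds the
    least-squares residuals, orthogonal to every regressor column.
    """
    regressors = np.atleast_2d(np.asarray(regressors, dtype=np.float64))
    if regressors.shape[0] != series.n_frames:
        raise ValueError(
            f"regressors have {regressors.shape[0]} rows but series has "
            f"{series.n_frames} frames"
        )
    x = np.column_stack([np.ones(series.n_frames), regressors])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify offending columns via the pivoted-QR-like diagnostic
        bad = []
        for j in range(1, x.shape[1]):
            if np.linalg.matrix_rank(x[:, : j + 1]) < j + 1:
                bad.append(j - 1)
        raise ValueError(f"nuisance design is rank deficient; collinear columns: {bad}")
    flat = series.data.reshape(-1, series.n_frames)
    coef, *_ = np.linalg.lstsq(x, flat.T, rcond=None)
    resid = flat - (x @ coef).T
    return BoldSeries(resid.reshape(series.data.shape), series.affine, series.tr_seconds)


def extract_tissue_signal(series: BoldSeries, mask: np.ndarray) -> np.ndarray:
    """Frame-wise mean signal over a tissue mask (e.g. WM or CSF)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.shape:
        raise ValueError(f"mask shape {mask.shape} != series grid {series.shape}")
    if not mask.any():
        raise ValueError("tissue mask is empty")
    return series.data[mask].mean(axis=0)
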