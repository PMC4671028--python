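"""ROI-level temporal cleaning and connectivity-matrix construction.

Frame censoring (framewise displacement and outlier-fraction rules),
simultaneous nuisance regression + band-pass filtering via least-squares
projection on the retained frames, and Pearson correlation matrices.

The band-pass is implemented as band-stop-by-regression: sine/cosine
regressors at all out-of-band Fourier frequencies of the original time
grid are projected out together with the confounds, evaluated only at
retained frames.  This avoids filtering across censored gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CensorMask",
    "ConnectivityMatrix",
    "framewise_displacement",
    "build_censor_mask",
    "clean_timeseries",
    "correlation_matrix",
    "group_average",
]

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_FD_THRESH_MM = 0.3
DEFAULT_OUTLIER_THRESH = 0.10
DEFAULT_BAND_HZ = (0.01, 0.1)


@dataclass
class CensorMask:
    """Per-frame retain/drop decisions with per-rule bookkeeping."""

    keep: np.ndarray  # bool, True = retain
    n_dropped_fd: int
    n_dropped_outlier: int

    @property
    def n_frames(self) -> int:
        return self.keep.size

    @property
    def n_retained(self) -> int:
        return int(self.keep.sum())

    @property
    def n_dropped(self) -> int:
        return self.n_frames - self.n_retained


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {V.shape}")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.all(np.isfinite(V)):
            raise ValueError("connectivity matrix must be finite")
        V = (V + V.T) / 2.0
        np.fill_diagonal(V, 1.0)
        self.values = V
        if len(self.labels) != V.shape[0]:
            raise ValueError("labels length must equal matrix size")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def framewise_displacement(motion, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM) -> np.ndarray:
    """Power-style framewise displacement in millimetres.

    FD[0] = 0; FD[t] = sum of |backward differences| of the three
    translations plus the three rotations converted to arc length at
    ``head_radius_mm``.
    """
    params = motion.params if hasattr(motion, "params") else np.asarray(motion, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError(f"motion must have 6 columns (3 trans mm, 3 rot rad), got {params.shape}")
    if params.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    d = np.abs(np.diff(params, axis=0))
    fd = np.zeros(params.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return fd


def build_censor_mask(
    fd: np.ndarray,
    outlier_fraction: np.ndarray,
    fd_thresh: float = DEFAULT_FD_THRESH_MM,
    outlier_thresh: float = DEFAULT_OUTLIER_THRESH,
) -> CensorMask:
    """Drop a frame iff FD > fd_thresh OR outlier fraction > outlier_thresh.

    Both inequalities are strict; a frame failing both rules is counted
    once in the union but appears in both per-rule tallies.
    """
    fd = np.asarray(fd, dtype=float)
    out = np.asarray(outlier_fraction, dtype=float)
    if fd.shape != out.shape:
        raise ValueError("fd and outlier_fraction must have equal length")
    bad_fd = fd > fd_thresh
    bad_out = out > outlier_thresh
    keep = ~(bad_fd | bad_out)
    return CensorMask(keep=keep, n_dropped_fd=int(bad_fd.sum()), n_dropped_outlier=int(bad_out.sum()))


def _bandstop_regressors(n_frames: int, tr: float, band: tuple[float, float]) -> np.ndarray:
    """Out-of-band sine/cosine columns on the original frame grid."""
    low, high = band
    nyquist = 0.5 / tr
    if not 0 < low < high < nyquist + 1e-12:
        raise ValueError(f"band {band} must satisfy 0 < low < high <= Nyquist ({nyquist})")
    freqs = np.fft.rfftfreq(n_frames, d=tr)
    out_of_band = (freqs > 0) & ((freqs < low) | (freqs > high))
    t = np.arange(n_frames)
    cols = []
    for f in freqs[out_of_band]:
        w = 2.0 * np.pi * f * t * tr
        cols.append(np.cos(w))
        if f < nyquist - 1e-12:  # sine at Nyquist is identically ~0
            cols.append(np.sin(w))
    return np.column_stack(cols) if cols else np.empty((n_frames, 0))


def clean_timeseries(
    ts: np.ndarray,
    confounds: np.ndarray | None,
    mask: CensorMask | None,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    tr: float = 2.0,
) -> np.ndarray:
    """Censor, regress and band-pass in a single projection.

    Returns residual series on the retained frames only.  The design
    matrix is intercept + confounds + out-of-band Fourier regressors,
    all evaluated at retained frames; residuals are orthogonal to every
    design column by construction.
    """
    X = np.asarray(ts, dtype=float)
    if X.ndim != 2:
        raise ValueError("ts must be 2-d (frames x ROIs)")
    n_frames = X.shape[0]
    keep = np.ones(n_frames, dtype=bool) if mask is None else np.asarray(mask.keep, dtype=bool)
    if keep.size != n_frames:
        raise ValueError("mask length must equal number of frames")

    design_cols: list[np.ndarray] = [np.ones(n_frames)]
    col_names = ["intercept"]
    if confounds is not None:
        C = np.asarray(confounds, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n_frames:
            raise ValueError("confounds must have one row per frame")
        for q in range(C.shape[1]):
            design_cols.append(C[:, q])
            col_names.append(f"confound{q}")
    F = _bandstop_regressors(n_frames, tr, band)
    for q in range(F.shape[1]):
        design_cols.append(F[:, q])
        col_names.append(f"fourier{q}")
    D = np.column_stack(design_cols)[keep]

    n_ret = int(keep.sum())
    if n_ret <= D.shape[1]:
        raise ValueError(
            f"only {n_ret} retained frames for {D.shape[1]} regressors; cannot project"
        )
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # name the offending columns via pivoted QR on the design
        from scipy.linalg import qr

        _, _, piv = qr(D, mode="economic", pivoting=True)
        collinear = sorted(col_names[i] for i in piv[rank:])
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")

    Y = X[keep]
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    return Y - D @ beta


def correlation_matrix(ts: np.ndarray, labels: list[str] | None = None) -> ConnectivityMatrix:
    """Pearson correlations between all ROI pairs of a retained-frame series."""
    X = np.asarray(ts, dtype=float)
    if X.ndim != 2:
        raise ValueError("ts must be 2-d (frames x ROIs)")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 retained frames")
    n_rois = X.shape[1]
    if labels is None:
        labels = [f"ROI{i:03d}" for i in range(n_rois)]
    sd = X.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [labels[i] for i in dead]
        raise ValueError(f"zero-variance ROI(s): {names}")
    R = np.corrcoef(X, rowvar=False)
    return ConnectivityMatrix(values=R, labels=list(labels))


def group_average(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of subject correlation matrices (no Fisher z)."""
    if not matrices:
        raise ValueError("need at least one matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if m.values.shape != first.values.shape:
            raise ValueError("matrix shape mismatch")
        if m.labels != first.labels:
            raise ValueError("ROI label mismatch")
    mean = np.mean([m.values for m in matrices], axis=0)
    return ConnectivityMatrix(values=mean, labels=list(first.labels))
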