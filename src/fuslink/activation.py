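"""Activation mapping: detrending, design matrix, per-pixel GLM, Bonferroni mask.

The power-Doppler movie is detrended pixel-wise (polynomial drift removal
that preserves the temporal mean, so later percent-change computations keep
their baseline), regressed on a stimulus boxcar, and thresholded: a pixel
is active when the one-sided p-value of its stimulus coefficient falls
below ``alpha_family / n_tests`` with ``n_tests`` the number of pixels in
the brain mask.  t statistics are converted to z scores by upper-tail
quantile matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .doppler import PowerDopplerMovie
from .synthetic import StimulusProtocol

__all__ = [
    "DesignMatrix",
    "ActivationMap",
    "detrend",
    "build_design_matrix",
    "glm_activation",
    "count_active",
]

logger = logging.getLogger(__name__)


@dataclass
class DesignMatrix:
    """Named regressors sampled on the power-Doppler frame grid."""

    matrix: np.ndarray  # (n_frames, n_regressors)
    names: tuple[str, ...]
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("matrix columns must match regressor names")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


@dataclass
class ActivationMap:
    """Per-pixel statistic map with its Bonferroni-thresholded active mask."""

    z: np.ndarray
    p: np.ndarray
    active: np.ndarray
    alpha_family: float
    n_tests: int
    brain_mask: np.ndarray

    @property
    def threshold(self) -> float:
        """Per-pixel p threshold alpha_family / n_tests."""
        return self.alpha_family / self.n_tests

    @property
    def n_active(self) -> int:
        return int(self.active.sum())


def detrend(movie: PowerDopplerMovie, order: int = 1) -> PowerDopplerMovie:
    """Remove per-pixel polynomial drift of the given degree, keeping the mean.

    Each pixel's least-squares polynomial over the whole time course is
    subtracted and the pixel's temporal mean added back, so baseline
    levels survive for percent-change computations.  ``order = 0`` is the
    identity.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    nz, nx, nt = movie.power.shape
    if nt <= order + 1:
        raise ValueError(f"need more than order+1={order + 1} frames, got {nt}")
    t = np.arange(nt, dtype=float)
    # Vandermonde least squares for all pixels at once
    basis = np.vander(t, order + 1, increasing=True)  # (nt, order+1)
    y = movie.power.reshape(nz * nx, nt).T  # (nt, npix)
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    trend = basis @ coef
    detrended = (y - trend + y.mean(axis=0, keepdims=True)).T.reshape(nz, nx, nt)
    # float error can push values a hair below zero on flat pixels
    np.clip(detrended, 0.0, None, out=detrended)
    return PowerDopplerMovie(power=detrended, frame_rate_hz=movie.frame_rate_hz,
                             block_size=movie.block_size)


def build_design_matrix(
    protocol: StimulusProtocol,
    frame_rate_hz: float,
    hrf_tau_s: float | None = None,
    n_frames: int | None = None,
) -> DesignMatrix:
    """Stimulus boxcar (optionally exponentially smoothed) plus intercept.

    Rows default to ``round(total_duration * frame_rate)``.  The stimulus
    column is the stimulation indicator sampled at frame start times; when
    ``hrf_tau_s`` is given it is convolved with a normalised causal
    exponential kernel ``exp(-t/tau)`` (peak <= 1; the raw boxcar is the
    tau -> 0 limit).
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be > 0")
    rows = int(round(protocol.total_duration_s * frame_rate_hz)) if n_frames is None else int(n_frames)
    if rows < 2:
        raise ValueError("design needs at least 2 frames")
    times = np.arange(rows) / frame_rate_hz
    stim = protocol.boxcar(times)
    if hrf_tau_s is not None:
        if hrf_tau_s <= 0:
            raise ValueError("hrf_tau_s must be > 0")
        dt = 1.0 / frame_rate_hz
        kt = np.arange(0, max(5 * hrf_tau_s, dt), dt)
        kernel = np.exp(-kt / hrf_tau_s)
        kernel /= kernel.sum()
        stim = np.convolve(stim, kernel)[:rows]
    matrix = np.column_stack([stim, np.ones(rows)])
    return DesignMatrix(matrix=matrix, names=("stimulus", "intercept"),
                        frame_rate_hz=frame_rate_hz)


def glm_activation(
    movie: PowerDopplerMovie,
    design: DesignMatrix,
    alpha_family: float = 0.05,
    brain_mask: np.ndarray | None = None,
    two_sided: bool = False,
) -> ActivationMap:
    """Per-pixel ordinary least squares on the design; Bonferroni thresholding.

    For every pixel of the brain mask the time course is regressed on the
    design; the stimulus coefficient's t statistic (df = rows - rank) gives
    a one-sided p (activation = positive coefficient; ``two_sided`` flips
    to |t|), converted to a z score by matching upper-tail probability.
    Active: ``p < alpha_family / n_masked_pixels``.  Zero-variance pixels
    get z = 0, p = 1.
    """
    nz, nx, nt = movie.power.shape
    x = design.matrix
    if x.shape[0] != nt:
        raise ValueError(f"design rows ({x.shape[0]}) must match movie frames ({nt})")
    if brain_mask is None:
        brain_mask = np.ones((nz, nx), dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != (nz, nx):
        raise ValueError("brain_mask shape mismatch")
    n_tests = int(brain_mask.sum())
    if n_tests == 0:
        raise ValueError("brain_mask is empty")

    y = movie.power.reshape(nz * nx, nt)[brain_mask.ravel()].T  # (nt, npix)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    dof = nt - rank
    if dof < 1:
        raise ValueError("not enough frames for the design degrees of freedom")

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y  # (nreg, npix)
    resid = y - x @ beta
    mse = (resid ** 2).sum(axis=0) / dof
    j = design.names.index("stimulus")
    se = np.sqrt(np.maximum(mse * xtx_inv[j, j], 0.0))

    tstat = np.zeros(y.shape[1])
    # constant pixels have exactly zero temporal variance up to float error
    var_y = y.var(axis=0)
    ok = (se > 0) & (var_y > 1e-20 * (1.0 + y.mean(axis=0) ** 2))
    if np.any(~ok):
        logger.info("glm_activation: %d zero-variance pixels set to p = 1", int((~ok).sum()))
    tstat[ok] = beta[j, ok] / se[ok]
    if two_sided:
        p = 2 * scipy.stats.t.sf(np.abs(tstat), dof)
    else:
        p = scipy.stats.t.sf(tstat, dof)
    p[~ok] = 1.0
    # z by upper-tail quantile matching, kept finite
    z = scipy.stats.norm.isf(np.clip(p, 1e-300, 1.0))
    z[~ok] = 0.0

    z_img = np.zeros((nz, nx))
    p_img = np.ones((nz, nx))
    z_img[brain_mask] = z
    p_img[brain_mask] = p
    active = np.zeros((nz, nx), dtype=bool)
    active[brain_mask] = p < alpha_family / n_tests
    return ActivationMap(z=z_img, p=p_img, active=active, alpha_family=alpha_family,
                         n_tests=n_tests, brain_mask=brain_mask)


def count_active(amap: ActivationMap, roi: np.ndarray | None = None) -> int:
    """Number of active pixels inside the region of interest."""
    if roi is None:
        return amap.n_active
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != amap.active.shape:
        raise ValueError(f"roi shape {roi.shape} != map shape {amap.active.shape}")
    return int((amap.active & roi).sum())
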