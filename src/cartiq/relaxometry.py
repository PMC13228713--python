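"""Voxel-wise mono-exponential T2 mapping.

Each voxel's multi-echo signal is fitted to ``S(TE) = PD * exp(-TE/T2)``
by Levenberg-Marquardt least squares, started from a log-linear estimate.
The first echo of a multi-echo spin-echo train carries stimulated-echo
contamination and is excluded from the decay curve by default; the fit is
otherwise unweighted, matching the proportional signal model.

Fits outside the configured T2 bounds, non-convergent fits, and voxels
failing the minimum-signal rule are flagged invalid and carry NaN in the
output maps so that downstream regional means exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .images import CartilageMask, EchoSeries, T2Map, same_grid


@dataclass(frozen=True)
class FitOptions:
    """Controls for the voxel fit.

    t2_bounds : (low, high) ms — fits clamped here are flagged invalid;
        the default [1, 500] covers the physiologic cartilage range with
        margin.
    exclude_first : drop echo 1 before fitting (stimulated-echo rule).
    min_signal : absolute floor on the mean included signal; voxels below
        it, or with any non-positive included echo, are invalid without
        fitting.
    rss_tol : relative RSS change defining convergence.
    """

    t2_bounds: tuple[float, float] = (1.0, 500.0)
    max_iter: int = 200
    rss_tol: float = 1e-10
    exclude_first: bool = True
    min_signal: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.t2_bounds
        if not (0 < lo < hi):
            raise ValueError("T2 bounds must satisfy 0 < low < high")


@dataclass
class VoxelFit:
    """Result of a single-voxel fit."""

    t2: float
    pd: float
    rss: float
    converged: bool
    valid: bool


def _invalid_fit() -> VoxelFit:
    return VoxelFit(t2=np.nan, pd=np.nan, rss=np.nan, converged=False, valid=False)


def loglinear_init(
    signal: np.ndarray,
    tes: np.ndarray,
    t2_bounds: tuple[float, float] = (1.0, 500.0),
) -> tuple[float, float]:
    """Log-linear starting point: OLS of ln(S) on TE.

    T2_0 = -1/slope and PD_0 = exp(intercept), with T2_0 clamped to the
    bounds.  A non-decaying (flat or rising) signal clamps to the upper
    bound; any non-positive signal falls back to (max signal, midpoint of
    the bounds).
    """
    signal = np.asarray(signal, dtype=float)
    tes = np.asarray(tes, dtype=float)
    lo, hi = t2_bounds
    if signal.size < 2 or np.any(signal <= 0):
        fallback_pd = float(signal.max()) if signal.size else 1.0
        return max(fallback_pd, np.finfo(float).tiny), (lo + hi) / 2.0
    slope, intercept = np.polyfit(tes, np.log(signal), 1)
    t20 = hi if slope >= 0 else -1.0 / slope
    return float(np.exp(intercept)), float(np.clip(t20, lo, hi))


def _residuals(params: np.ndarray, signal: np.ndarray, tes: np.ndarray) -> np.ndarray:
    pd_, t2 = params
    return signal - pd_ * np.exp(-tes / t2)


def _jacobian(params: np.ndarray, signal: np.ndarray, tes: np.ndarray) -> np.ndarray:
    pd_, t2 = params
    e = np.exp(-tes / t2)
    return np.column_stack([-e, -pd_ * e * tes / t2**2])


def fit_voxel(signal: np.ndarray, tes: np.ndarray, options: FitOptions | None = None) -> VoxelFit:
    """Fit one voxel's decay curve; never raises on bad data, flags instead.

    Applies first-echo exclusion, the minimum-signal rule, and the T2
    bounds; requires at least three usable echoes after exclusion.
    """
    options = options or FitOptions()
    signal = np.asarray(signal, dtype=float)
    tes = np.asarray(tes, dtype=float)
    if signal.shape != tes.shape:
        raise ValueError("signal and echo times must have the same length")

    if options.exclude_first:
        signal, tes = signal[1:], tes[1:]
    if signal.size < 3:
        return _invalid_fit()
    if np.any(signal <= 0) or signal.mean() < options.min_signal:
        return _invalid_fit()

    pd0, t20 = loglinear_init(signal, tes, options.t2_bounds)
    sol = least_squares(
        _residuals,
        x0=np.array([pd0, t20]),
        jac=_jacobian,
        args=(signal, tes),
        method="lm",
        ftol=options.rss_tol,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=options.max_iter * 3,
    )
    pd_fit, t2_fit = sol.x
    rss = float(np.sum(sol.fun**2))
    lo, hi = options.t2_bounds
    in_bounds = lo < t2_fit < hi and pd_fit > 0
    converged = bool(sol.success) and in_bounds
    if not in_bounds:
        t2_fit = float(np.clip(t2_fit, lo, hi))
    return VoxelFit(
        t2=float(t2_fit), pd=float(pd_fit), rss=rss, converged=converged, valid=converged
    )


def fit_map(
    series: EchoSeries,
    mask: CartilageMask,
    options: FitOptions | None = None,
    exclusion_mask: np.ndarray | None = None,
) -> T2Map:
    """Fit every cartilage voxel of ``mask``; unmasked voxels stay NaN.

    ``exclusion_mask`` (optional, boolean) removes voxels flagged upstream
    — e.g. chemical-shift-affected voxels identified during segmentation —
    before fitting.  Deterministic given its inputs.
    """
    options = options or FitOptions()
    if series.shape != mask.labels.shape or not same_grid(series.grid, mask.grid):
        raise ValueError("echo series and mask are on different grids")

    target = mask.cartilage
    if exclusion_mask is not None:
        if exclusion_mask.shape != target.shape:
            raise ValueError("exclusion mask shape mismatch")
        target = target & ~exclusion_mask.astype(bool)

    shape = series.shape
    t2 = np.full(shape, np.nan)
    pd_ = np.full(shape, np.nan)
    rss = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    tes = series.echo_times
    for idx in np.argwhere(target):
        s, r, c = idx
        fit = fit_voxel(series.data[:, s, r, c], tes, options)
        t2[s, r, c] = fit.t2
        pd_[s, r, c] = fit.pd
        rss[s, r, c] = fit.rss
        valid[s, r, c] = fit.valid
    t2[~valid] = np.nan
    pd_[~valid] = np.nan
    return T2Map(t2=t2, pd=pd_, rss=rss, valid=valid, grid=series.grid)
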