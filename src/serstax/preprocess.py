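"""Spectral preprocessing: airPLS baseline correction, min-max normalization
and resampling onto the canonical analysis grid.

The analysis window is 400-1800 cm^-1 sampled at 1200 evenly spaced points.
Baselines are estimated with airPLS (adaptive iteratively reweighted penalized
least squares): a Whittaker smoother with a second-difference roughness
penalty whose fidelity weights are driven to zero wherever the signal exceeds
the current baseline estimate, so peaks are excluded from the fit while the
smooth background is tracked.  The pipeline order is baseline correction,
then normalization, then regridding; regridding last keeps the measured
samples intact while the baseline is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .errors import CoverageError, DegenerateInputError, ValidationError
from .io import Spectrum

__all__ = [
    "WINDOW",
    "N_POINTS",
    "canonical_grid",
    "AirplsSettings",
    "airpls_baseline",
    "minmax_normalize",
    "to_canonical_grid",
    "preprocess_spectrum",
]

#: Analysis window in cm^-1.
WINDOW = (400.0, 1800.0)
#: Number of points on the canonical grid.
N_POINTS = 1200
#: Tolerance for window coverage at the endpoints, cm^-1.
COVERAGE_TOL = 5.0


def canonical_grid() -> np.ndarray:
    """The canonical 1200-point wavenumber axis over 400-1800 cm^-1."""
    return np.linspace(WINDOW[0], WINDOW[1], N_POINTS)


@dataclass(frozen=True)
class AirplsSettings:
    """airPLS tuning parameters.

    Parameters
    ----------
    lam
        Smoothness penalty weight (lambda > 0).  Larger values give stiffer
        baselines; 1e5 is a common choice for ~1000-point Raman spectra.
    max_iter
        Maximum number of reweighting iterations.
    convergence_ratio
        Iteration stops once the L1 mass of negative residuals falls below
        this fraction of the total absolute signal.
    """

    lam: float = 1e5
    max_iter: int = 30
    convergence_ratio: float = 1e-3

    def __post_init__(self):
        if not (self.lam > 0):
            raise ValidationError("airPLS lambda must be > 0")
        if self.max_iter < 1:
            raise ValidationError("airPLS max_iter must be >= 1")
        if not (0 < self.convergence_ratio < 1):
            raise ValidationError("airPLS convergence_ratio must be in (0,1)")


def _whittaker_penalty(n: int, lam: float) -> sparse.csc_matrix:
    """lam * D2' D2 for an order-2 Whittaker smoother on n points."""
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    return (lam * (d2.T @ d2)).tocsc()


def airpls_baseline(y, settings: AirplsSettings | None = None) -> np.ndarray:
    """Estimate the baseline of an intensity vector with airPLS.

    At each iteration the baseline z minimizes
    ``sum_i w_i (y_i - z_i)^2 + lam * sum (d2 z)^2``.  Weights are then
    updated: w_i = 0 where y_i >= z_i (points treated as peak), otherwise
    w_i = exp(t |y_i - z_i| / |d|_1) with d the negative residuals at
    iteration t.  Iteration stops at ``max_iter`` or once
    ``|d|_1 < convergence_ratio * |y|_1``.

    Returns the baseline (same length as ``y``).
    """
    if settings is None:
        settings = AirplsSettings()
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 5:
        raise ValidationError("airPLS input must be 1-D with >= 5 points")
    if not np.all(np.isfinite(y)):
        raise ValidationError("airPLS input must be finite")

    n = y.size
    penalty = _whittaker_penalty(n, settings.lam)
    w = np.ones(n)
    abs_y = np.abs(y).sum()
    z = y.copy()
    for t in range(1, settings.max_iter + 1):
        wmat = sparse.diags(w, 0, shape=(n, n), format="csc")
        z = spsolve(wmat + penalty, w * y)
        d = y - z
        neg = d < 0
        dssn = float(np.abs(d[neg]).sum())
        if dssn < settings.convergence_ratio * abs_y:
            break
        w[:] = 0.0
        if dssn > 0:
            w[neg] = np.exp(t * np.abs(d[neg]) / dssn)
            # endpoints keep maximal weight so the baseline stays anchored
            w[0] = np.exp(t * np.abs(d[neg]).max() / dssn)
            w[-1] = w[0]
    return z


def minmax_normalize(y) -> np.ndarray:
    """Rescale to min 0 / max 1.  A constant vector is rejected."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("cannot normalize non-finite intensities")
    lo = y.min()
    hi = y.max()
    if hi <= lo:
        raise DegenerateInputError("constant vector cannot be normalized")
    return (y - lo) / (hi - lo)


def to_canonical_grid(sp: Spectrum) -> Spectrum:
    """Linearly interpolate onto the canonical 1200-point grid.

    The spectrum must cover [400, 1800] cm^-1 with endpoints within
    ``COVERAGE_TOL``; larger gaps raise :class:`CoverageError` naming the gap.
    Within the tolerance, grid points beyond the measured range take the
    nearest measured value.
    """
    lo, hi = WINDOW
    gaps = []
    if sp.wavenumbers[0] > lo + COVERAGE_TOL:
        gaps.append(f"[{lo:g}, {sp.wavenumbers[0]:g}]")
    if sp.wavenumbers[-1] < hi - COVERAGE_TOL:
        gaps.append(f"[{sp.wavenumbers[-1]:g}, {hi:g}]")
    if gaps:
        raise CoverageError(
            "spectrum does not cover the analysis window; missing "
            + " and ".join(gaps)
        )
    grid = canonical_grid()
    y = np.interp(grid, sp.wavenumbers, sp.intensities)
    meta = dict(sp.meta)
    meta["canonical"] = "true"
    return Spectrum(grid, y, meta)


def preprocess_spectrum(sp: Spectrum,
                        settings: AirplsSettings | None = None) -> Spectrum:
    """Full pipeline: airPLS baseline removal, min-max normalization, then
    resampling onto the canonical grid.  Sets ``meta['state']`` to
    ``"preprocessed"`` and the ``canonical`` flag."""
    z = airpls_baseline(sp.intensities, settings)
    y = minmax_normalize(sp.intensities - z)
    corrected = sp.with_intensities(y, state="preprocessed")
    return to_canonical_grid(corrected)
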