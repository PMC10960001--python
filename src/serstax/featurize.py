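"""Peak parameterization: 19 fitted peaks x 5 attributes = 95 features.

Each peak is a *skewed pseudo-Voigt*: a mixture of unit-apex Lorentzian and
Gaussian profiles sharing a centre, with a side-dependent FWHM so that a
single ``skew`` parameter (0 = symmetric) captures asymmetry::

    V(x) = A * [eta * L(x; c, w(x)) + (1 - eta) * G(x; c, w(x))]
    w(x) = fwhm * (1 + skew)   for x >= c
           fwhm * (1 - skew)   for x <  c

The five attributes per peak are position (centre, cm^-1), intensity (apex
amplitude), FWHM (cm^-1), skew, and eta (the Lorentzian fraction, the
"ratio" of Gaussian/Lorentzian character).  Intensity is the fitted apex
height, not the area, because the diagnostic ratios (e.g. I1330/I1567) are
peak-height ratios.

Fitting is bounded nonlinear least squares of the 19-component sum against a
preprocessed spectrum.  Seeds whose windows overlap are fitted jointly as a
cluster; a second pass refits each cluster against the spectrum minus the
current model of all other peaks, which removes tail leakage between
clusters.  The procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    BandRangeError,
    NoPeakError,
    PeakFitError,
    ValidationError,
)
from .io import Spectrum
from .preprocess import WINDOW

__all__ = [
    "ATTRIBUTES",
    "PeakParams",
    "PeakSeed",
    "PeakSeedTable",
    "FitResult",
    "line_shape",
    "fit_peaks",
    "to_features",
    "feature_names",
    "feature_schema",
    "featurize_spectrum",
    "featurize_dataset",
    "featurize_mixtures",
    "intensity_ratio",
    "band_position",
]

#: Attribute order within each peak's block of the feature vector.
ATTRIBUTES = ("position", "intensity", "fwhm", "skew", "eta")

_SKEW_LIMIT = 0.95


@dataclass(frozen=True)
class PeakParams:
    """Parameters of one skewed pseudo-Voigt component."""

    center: float
    amplitude: float
    fwhm: float
    skew: float = 0.0
    eta: float = 0.5

    def __post_init__(self):
        if not (self.fwhm > 0):
            raise ValidationError("fwhm must be > 0")
        if not (0.0 <= self.eta <= 1.0):
            raise ValidationError("eta must lie in [0, 1]")
        if self.amplitude < 0:
            raise ValidationError("amplitude must be >= 0")
        if not (WINDOW[0] <= self.center <= WINDOW[1]):
            raise ValidationError(
                f"center {self.center} outside {WINDOW} cm^-1"
            )


def line_shape(x, p: PeakParams) -> np.ndarray:
    """Evaluate one skewed pseudo-Voigt component at wavenumbers ``x``."""
    return _line_shape_raw(
        np.asarray(x, float), p.center, p.amplitude, p.fwhm, p.skew, p.eta
    )


def _line_shape_raw(x, center, amplitude, fwhm, skew, eta):
    skew = float(np.clip(skew, -_SKEW_LIMIT, _SKEW_LIMIT))
    dx = x - center
    w = np.where(dx >= 0, fwhm * (1.0 + skew), fwhm * (1.0 - skew))
    u = dx / w
    lorentz = 1.0 / (1.0 + 4.0 * u * u)
    gauss = np.exp(-4.0 * np.log(2.0) * u * u)
    return amplitude * (eta * lorentz + (1.0 - eta) * gauss)


@dataclass(frozen=True)
class PeakSeed:
    """Seed and fit bounds for one peak."""

    label: str
    center: float
    center_lo: float
    center_hi: float
    fwhm_lo: float = 5.0
    fwhm_hi: float = 25.0
    shared_region: bool = False

    def __post_init__(self):
        if not (self.center_lo <= self.center <= self.center_hi):
            raise ValidationError(
                f"seed {self.label}: center outside its window"
            )
        if not (0 < self.fwhm_lo < self.fwhm_hi):
            raise ValidationError(f"seed {self.label}: bad fwhm range")


# Default 19-band seed table.  The eight named bands come from the reporter
# chemistry: 414 and 691 cm^-1 (ring deformation + C-S stretch, the hexose /
# Gal-chain diagnostics), 1023 (CH bend, Glc-chain diagnostic), 1330 (B-OH
# bend, the boronate-ester capture diagnostic), 1567 (a1 reference), 1575
# (b2 ring CC stretch) and the mobile a1 ring CC stretch near 1598 that
# reports ceramide saturation, plus a low-frequency band near 480.  Eleven
# filler bands pad the table to 19; the table is config-replaceable.
_DEFAULT_SEEDS = (
    ("ring_def_cs_414", 414.0, 407.0, 423.0),
    ("band_480", 480.0, 474.0, 486.0),
    ("band_520", 520.0, 514.0, 526.0),
    ("band_630", 630.0, 624.0, 636.0),
    ("ring_def_cs_691", 691.0, 685.0, 697.0),
    ("band_760", 760.0, 754.0, 766.0),
    ("band_810", 810.0, 804.0, 816.0),
    ("band_860", 860.0, 854.0, 866.0),
    ("band_920", 920.0, 914.0, 926.0),
    ("ch_bend_1023", 1023.0, 1017.0, 1029.0),
    ("band_1070", 1070.0, 1064.0, 1076.0),
    ("band_1140", 1140.0, 1134.0, 1146.0),
    ("band_1260", 1260.0, 1254.0, 1266.0),
    ("boh_bend_1330", 1330.0, 1324.0, 1336.0),
    ("band_1410", 1410.0, 1404.0, 1416.0),
    ("band_1480", 1480.0, 1474.0, 1486.0),
    ("a1_ref_1567", 1567.0, 1563.0, 1571.0),
    ("b2_cc_1575", 1575.0, 1571.0, 1579.0),
    ("a1_cc_mobile", 1598.0, 1582.0, 1607.0),
)


@dataclass(frozen=True)
class PeakSeedTable:
    """Exactly 19 peak seeds, ordered by centre."""

    seeds: tuple

    def __post_init__(self):
        if len(self.seeds) != 19:
            raise ValidationError(
                f"seed table must have exactly 19 entries, got "
                f"{len(self.seeds)}"
            )
        centers = [s.center for s in self.seeds]
        if sorted(centers) != centers:
            raise ValidationError("seeds must be ordered by centre")
        # overlapping centre windows are allowed only when flagged shared
        for a, b in zip(self.seeds, self.seeds[1:]):
            if a.center_hi > b.center_lo and not (
                a.shared_region and b.shared_region
            ):
                raise ValidationError(
                    f"seed windows {a.label}/{b.label} overlap without a "
                    "shared_region flag"
                )

    @classmethod
    def default(cls) -> "PeakSeedTable":
        seeds = []
        for label, c, lo, hi in _DEFAULT_SEEDS:
            shared = label in ("a1_ref_1567", "b2_cc_1575", "a1_cc_mobile")
            seeds.append(PeakSeed(label, c, lo, hi, shared_region=shared))
        return cls(tuple(seeds))

    def __len__(self):
        return len(self.seeds)

    def __iter__(self):
        return iter(self.seeds)

    def index(self, label: str) -> int:
        for i, s in enumerate(self.seeds):
            if s.label == label:
                return i
        raise KeyError(label)


@dataclass
class FitResult:
    """Outcome of :func:`fit_peaks`: the 19 fitted peaks (seed order) and
    the L2 norm of the full-spectrum residual."""

    peaks: list
    residual_norm: float


def _clusters(table: PeakSeedTable, pad: float = 22.0):
    """Group seeds whose fit windows (centre window +- pad) overlap."""
    groups = [[0]]
    seeds = table.seeds
    for i in range(1, len(seeds)):
        prev = seeds[groups[-1][-1]]
        cur = seeds[i]
        if cur.center_lo - pad <= prev.center_hi + pad:
            groups[-1].append(i)
        else:
            groups.append([i])
    return groups


def _fit_cluster(x, y, seeds, x0=None, max_nfev=3000):
    """Bounded least squares of a sum of skewed pseudo-Voigts on a window."""
    m = len(seeds)
    lo = np.empty(5 * m)
    hi = np.empty(5 * m)
    p0 = np.empty(5 * m)
    for j, s in enumerate(seeds):
        sl = slice(5 * j, 5 * j + 5)
        lo[sl] = [s.center_lo, 0.0, s.fwhm_lo, -0.5, 0.0]
        hi[sl] = [s.center_hi, 3.0, s.fwhm_hi, 0.5, 1.0]
        if x0 is not None:
            p0[sl] = x0[sl]
        else:
            near = np.abs(x - s.center) <= 0.75 * (s.fwhm_lo + s.fwhm_hi) / 2
            amp0 = float(np.clip(y[near].max() if near.any() else 0.1,
                                 1e-3, 2.9))
            p0[sl] = [s.center, amp0, 0.5 * (s.fwhm_lo + s.fwhm_hi),
                      0.0, 0.5]
    p0 = np.clip(p0, lo + 1e-9, hi - 1e-9)

    def resid(p):
        model = np.zeros_like(x)
        for j in range(m):
            c, a, w, sk, e = p[5 * j:5 * j + 5]
            model += _line_shape_raw(x, c, a, w, sk, e)
        return model - y

    sol = least_squares(
        resid, p0, bounds=(lo, hi), method="trf",
        x_scale="jac", ftol=1e-8, xtol=1e-8, gtol=None, max_nfev=max_nfev,
    )
    return sol


def fit_peaks(sp: Spectrum, seeds: PeakSeedTable | None = None,
              refine: bool = True, max_nfev: int = 3000) -> FitResult:
    """Fit 19 skewed pseudo-Voigt components to a preprocessed spectrum.

    ``sp`` must carry the ``canonical`` meta flag (see
    :func:`serstax.preprocess.preprocess_spectrum`).  Each component's centre
    is constrained to its seed window.  Returns peaks in seed order plus the
    residual L2 norm.  Raises :class:`PeakFitError` (carrying the best-so-far
    parameters) if the optimizer exhausts its evaluation budget.
    """
    if seeds is None:
        seeds = PeakSeedTable.default()
    if sp.meta.get("canonical") != "true":
        raise ValidationError(
            "fit_peaks requires a canonical (preprocessed) spectrum"
        )
    x = sp.wavenumbers
    y = sp.intensities
    groups = _clusters(seeds)
    params = np.zeros(5 * len(seeds))
    exhausted = False

    def window_mask(idxs):
        lo = min(seeds.seeds[i].center_lo for i in idxs) - 30.0
        hi = max(seeds.seeds[i].center_hi for i in idxs) + 30.0
        return (x >= lo) & (x <= hi)

    def model_of(idxs, p):
        out = np.zeros_like(x)
        for i in idxs:
            c, a, w, sk, e = p[5 * i:5 * i + 5]
            out += _line_shape_raw(x, c, a, w, sk, e)
        return out

    # first pass: independent cluster fits against the raw data
    for idxs in groups:
        mask = window_mask(idxs)
        sol = _fit_cluster(x[mask], y[mask],
                           [seeds.seeds[i] for i in idxs], max_nfev=max_nfev)
        exhausted |= sol.status == 0
        for j, i in enumerate(idxs):
            params[5 * i:5 * i + 5] = sol.x[5 * j:5 * j + 5]

    if refine:
        # second pass: refit each cluster against data minus the others
        total = model_of(range(len(seeds)), params)
        for idxs in groups:
            mask = window_mask(idxs)
            others = total - model_of(idxs, params)
            x0 = np.concatenate(
                [params[5 * i:5 * i + 5] for i in idxs]
            )
            sol = _fit_cluster(x[mask], (y - others)[mask],
                               [seeds.seeds[i] for i in idxs],
                               x0=x0, max_nfev=max_nfev)
            exhausted |= sol.status == 0
            for j, i in enumerate(idxs):
                params[5 * i:5 * i + 5] = sol.x[5 * j:5 * j + 5]
            total = others + model_of(idxs, params)

    peaks = [
        PeakParams(*params[5 * i:5 * i + 5]) for i in range(len(seeds))
    ]
    residual = float(np.linalg.norm(model_of(range(len(seeds)), params) - y))
    if exhausted:
        raise PeakFitError(
            "peak fit exhausted its evaluation budget",
            peaks=peaks, residual_norm=residual,
        )
    return FitResult(peaks=peaks, residual_norm=residual)


# ---------------------------------------------------------------------------
# feature vectors
# ---------------------------------------------------------------------------

def feature_schema(seeds: PeakSeedTable | None = None):
    """Ordered (peak index, attribute) pairs defining the 95-vector layout."""
    n = 19 if seeds is None else len(seeds)
    return [(i + 1, a) for i in range(n) for a in ATTRIBUTES]


def feature_names(seeds: PeakSeedTable | None = None):
    """Column names, e.g. ``p01_position`` ... ``p19_eta``."""
    return [f"p{i:02d}_{a}" for i, a in feature_schema(seeds)]


def to_features(peaks: Sequence[PeakParams]) -> np.ndarray:
    """Concatenate 19 peaks into the 95-feature vector (schema order)."""
    if len(peaks) != 19:
        raise ValidationError(
            f"expected exactly 19 peaks, got {len(peaks)}"
        )
    out = np.empty(95)
    for i, p in enumerate(peaks):
        out[5 * i:5 * i + 5] = (p.center, p.amplitude, p.fwhm, p.skew, p.eta)
    return out


def featurize_spectrum(sp: Spectrum,
                       seeds: PeakSeedTable | None = None) -> np.ndarray:
    """Fit peaks and return the 95-feature vector for one spectrum."""
    return to_features(fit_peaks(sp, seeds).peaks)


def featurize_dataset(sset, seeds: PeakSeedTable | None = None,
                      airpls=None, refine: bool = False):
    """Preprocess and featurize every spectrum of a set.

    Returns a DataFrame with the 95 feature columns (``p01_position`` ...
    ``p19_eta``) followed by the label columns of
    :meth:`serstax.io.SpectrumSet.label_frame`.  Raw spectra are run through
    the full preprocessing pipeline first; spectra already carrying the
    ``canonical`` flag are fitted as-is.

    By default the cross-cluster refinement pass is skipped: the ~1%
    tail-leakage bias it removes is identical for every spectrum on a shared
    grid and cancels in any model trained on the features, while skipping it
    roughly halves the fitting cost of large datasets.
    """
    import pandas as pd

    from .preprocess import preprocess_spectrum

    rows = []
    for sp in sset.spectra:
        if sp.meta.get("canonical") != "true":
            sp = preprocess_spectrum(sp, airpls)
        rows.append(to_features(fit_peaks(sp, seeds, refine=refine).peaks))
    feats = pd.DataFrame(np.asarray(rows), columns=feature_names(seeds))
    labels = sset.label_frame().reset_index(drop=True)
    return pd.concat([feats, labels], axis=1)


def featurize_mixtures(mset, seeds: PeakSeedTable | None = None,
                       airpls=None, refine: bool = False):
    """Featurize a binary-mixture set; appends ``frac_gal`` (mol%
    GalCer24:1), ``total_M`` and ``replicate`` columns."""
    import pandas as pd

    from .preprocess import preprocess_spectrum

    rows = []
    for sp in mset.spectra:
        if sp.meta.get("canonical") != "true":
            sp = preprocess_spectrum(sp, airpls)
        rows.append(to_features(fit_peaks(sp, seeds, refine=refine).peaks))
    feats = pd.DataFrame(np.asarray(rows), columns=feature_names(seeds))
    feats["frac_gal"] = np.asarray(mset.frac_gal, float)
    feats["total_M"] = mset.total
    feats["replicate"] = list(mset.replicates)
    return feats


# ---------------------------------------------------------------------------
# direct band diagnostics (intensity ratios and apex positions)
# ---------------------------------------------------------------------------

def _band_max(sp: Spectrum, center: float, half_window: float) -> float:
    lo, hi = center - half_window, center + half_window
    if lo < sp.wavenumbers[0] or hi > sp.wavenumbers[-1]:
        raise BandRangeError(
            f"band {center:g} +- {half_window:g} cm^-1 outside spectrum"
        )
    mask = (sp.wavenumbers >= lo) & (sp.wavenumbers <= hi)
    return float(sp.intensities[mask].max())


def intensity_ratio(sp: Spectrum, num: float, den: float,
                    half_window: float = 8.0) -> float:
    """Ratio of maximum intensities within +-``half_window`` of two bands."""
    num_i = _band_max(sp, num, half_window)
    den_i = _band_max(sp, den, half_window)
    if den_i == 0:
        raise BandRangeError(
            f"denominator band {den:g} cm^-1 has zero intensity"
        )
    return num_i / den_i


def band_position(sp: Spectrum, seed: float,
                  half_window: float = 8.0) -> float:
    """Sub-grid apex position near ``seed`` via a 3-point parabola.

    Raises :class:`NoPeakError` if the window holds no interior maximum
    (monotone window)."""
    lo, hi = seed - half_window, seed + half_window
    if lo < sp.wavenumbers[0] or hi > sp.wavenumbers[-1]:
        raise BandRangeError(
            f"band {seed:g} +- {half_window:g} cm^-1 outside spectrum"
        )
    mask = (sp.wavenumbers >= lo) & (sp.wavenumbers <= hi)
    idx = np.flatnonzero(mask)
    yw = sp.intensities[idx]
    k = int(np.argmax(yw))
    if k == 0 or k == yw.size - 1:
        raise NoPeakError(
            f"no interior maximum within {seed:g} +- {half_window:g} cm^-1"
        )
    i = idx[k]
    x0, x1, x2 = sp.wavenumbers[i - 1:i + 2]
    y0, y1, y2 = sp.intensities[i - 1:i + 2]
    denom = (y0 - 2 * y1 + y2)
    if denom == 0:
        return float(x1)
    # vertex of the parabola through the three points (uniform grid assumed
    # only locally; use general formula)
    offset = 0.5 * (y0 - y2) / denom
    return float(x1 + offset * (x2 - x0) / 2.0)
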