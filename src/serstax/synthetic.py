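"""Synthetic SERS spectrum generator.

Generates labelled reporter (4-MPBA) spectra whose class-dependent deviations
encode the five structure->spectrum correlations observed for cerebroside-MPBA
adducts:

R1  Capture: boronate-ester formation consumes the B-OH bend, so the
    1330 cm^-1 band (relative to the a1 reference at 1567 cm^-1) drops
    sharply from 0.6 for unreacted MPBA — below 0.07 for monosaccharide
    adducts and to ~0.125 for cerebroside adducts.  Binding also broadens
    the residual band and adds ceramide scattering mass at several marker
    bands (cerebrosides only).
R2  Saturation: the mobile a1 ring CC stretch sits at 1603 cm^-1 for the
    blank, redshifts slightly to 1601 for saturated cerebrosides, and
    redshifts further (1591 for GlcCer, 1595 for GalCer) with an intensity
    increase for mono-unsaturated ceramides.
R3  Hexose: the ring-deformation + C-S stretch band blueshifts from
    414 cm^-1 (blank) into 414-417 for GlcCer and 417-419 for GalCer,
    mapped linearly in chain length within each range.
R4  Glc chain length: I1023/I1567 increases linearly with chain length for
    glucocerebrosides.
R5  Gal chain length: I691/I1567 increases linearly with chain length for
    galactocerebrosides.

Concentration response
----------------------
``attenuation(c)`` is the log-linear response fraction,
``(log10 c - log10 LOD) / (log10 c_max - log10 LOD)`` clipped to [0, 1].
Each rule's deviation-from-blank is scaled by
``s_r = 1 - beta_r * (1 - attenuation(c))`` where ``beta_r`` is the rule's
concentration sensitivity.  Three class-independent "quant" bands track
coverage fully (beta = 1) and carry the log-linear quantification channel;
the capture ratio and the ceramide marker bands keep more than half of
their deviation at the LOD (beta < 0.5), so at the detection limit every
such feature still sits on the analyte side of the midpoint between its
blank and full-coverage values; and the identity rules (saturation, hexose,
chain length) are only weakly diluted (beta 0.02-0.10), so classifying and
sizing an analyte remains possible at the LOD while its concentration is
read off the coverage channels.  Below the LOD every deviation is zero:
the spectrum is a blank by construction and the metadata carries a
``below_lod`` flag.

Noise: additive Gaussian intensity noise (fraction of the unit maximum) per
grid point, Gaussian jitter on every peak centre, and a smooth broad
background that the airPLS preprocessing is expected to remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .featurize import _line_shape_raw
from .io import (
    AnalyteLabel,
    CHAIN_LENGTHS,
    Spectrum,
    SpectrumSet,
    all_labels,
)
from .preprocess import canonical_grid

__all__ = [
    "SyntheticConfig",
    "MixtureSet",
    "attenuation",
    "generate_spectrum",
    "generate_dataset",
    "generate_mixture",
    "generate_mixture_dataset",
]


# Base (blank MPBA) peak table, aligned with the default seed table:
# (label, center, amplitude, fwhm).  The a1 reference at 1567 cm^-1 has
# amplitude 1 so band amplitudes double as intensity ratios against it.
_BASE_PEAKS = (
    ("ring_def_cs_414", 414.0, 0.35, 9.0),
    ("band_480", 480.0, 0.15, 12.0),
    ("band_520", 520.0, 0.20, 10.0),
    ("band_630", 630.0, 0.15, 12.0),
    ("ring_def_cs_691", 691.0, 0.30, 10.0),
    ("band_760", 760.0, 0.25, 12.0),
    ("band_810", 810.0, 0.25, 12.0),
    ("band_860", 860.0, 0.25, 14.0),
    ("band_920", 920.0, 0.25, 14.0),
    ("ch_bend_1023", 1023.0, 0.25, 10.0),
    ("band_1070", 1070.0, 0.25, 12.0),
    ("band_1140", 1140.0, 0.25, 14.0),
    ("band_1260", 1260.0, 0.12, 12.0),
    ("boh_bend_1330", 1330.0, 0.60, 12.0),
    ("band_1410", 1410.0, 0.12, 10.0),
    ("band_1480", 1480.0, 0.12, 10.0),
    ("a1_ref_1567", 1567.0, 1.00, 9.0),
    ("b2_cc_1575", 1575.0, 0.35, 8.0),
    ("a1_cc_mobile", 1603.0, 0.45, 11.0),
)

#: Bands whose rule targets are *measured* intensity ratios against the
#: a1 reference; amplitudes are derived through the measurement calibration.
_RATIO_BANDS = ("boh_bend_1330", "ch_bend_1023", "ring_def_cs_691")

# Cerebroside enumeration for the R1 capture ratio: hexoses interleaved so
# the capture ratio encodes the analyte, not the hexose.
_R1_ORDER = (
    "GlcCer8", "GalCer8", "GlcCer12", "GalCer12", "GlcCer16", "GalCer16",
    "GlcCer18", "GalCer18", "GlcCer24:1", "GalCer24", "GalCer24:1",
)


def _chain_fraction(chain_length: int) -> float:
    lo, hi = CHAIN_LENGTHS[0], CHAIN_LENGTHS[-1]
    return (chain_length - lo) / (hi - lo)


@dataclass(frozen=True)
class SyntheticConfig:
    """Rule table, base peak table, noise model and replicate design.

    All rule values sit inside the observed ranges (see module docstring);
    chain-length maps are linear because only a monotone positive correlation
    is established.  ``beta_*`` are the per-rule concentration sensitivities.
    """

    # concentration response.  beta_capture stays below 0.5 so that at the
    # LOD every coverage-tracking feature still sits on the analyte side of
    # the midpoint between its blank and full-coverage values: the method
    # classifies correctly at its detection limit, so the capture signal
    # there must remain past halfway to saturation on the measured scale.
    c_max: float = 1e-4
    lod: float = 1e-10
    beta_capture: float = 0.45
    beta_capture_width: float = 0.10
    beta_saturation: float = 0.10
    beta_hexose: float = 0.05
    beta_chain: float = 0.02

    # noise model
    noise_sigma: float = 0.01       # intensity sigma, fraction of unit max
    center_jitter: float = 0.3      # cm^-1
    baseline_amplitude: float = 0.2  # broad background, fraction of unit max
    # per-replicate scatter of the measured-ratio targets (the within-class
    # variance of the capture / chain-length diagnostics) and of the mobile
    # a1 band amplitude; the chain-ratio scatter of the two C-S/ring bands
    # is correlated (a shared binding-geometry fluctuation)
    r1_noise: float = 0.003
    chain_ratio_noise: float = 0.03
    chain_ratio_corr: float = 0.8
    a1_amp_noise: float = 0.03

    # replicate design
    replicates: int = 60

    # R1 capture ratio (I1330/I1567): boronate-ester formation consumes the
    # B-OH bend, so the ratio drops sharply for every epimer (monosaccharide
    # adducts lowest).  All cerebrosides share one capture ratio: the
    # capture channel must carry no class information, otherwise a model
    # trained at one concentration reads its attenuation as a structural
    # change.  Binding also broadens the residual B-OH band.
    r1_blank: float = 0.6
    r1_mono: float = 0.0
    r1_cer_min: float = 0.125
    r1_cer_step: float = 0.0
    fwhm_1330_cer: float = 15.0
    fwhm_1330_mono: float = 17.0

    # cerebroside-loading bands, (band, delta, beta).  Six marker bands
    # gain ceramide CH2/skeletal scattering mass and keep most of their
    # deviation at the LOD (beta 0.35), so the monosaccharide/cerebroside
    # distinction survives at trace concentrations; the two narrow
    # high-frequency bands track coverage fully (beta 1) and carry the
    # log-linear quantification response.  Monosaccharide adducts are too
    # small to contribute measurably.
    analyte_band_load: tuple = (
        ("band_760", 0.55, 0.35),
        ("band_810", 0.55, 0.35),
        ("band_860", 0.55, 0.35),
        ("band_920", 0.55, 0.35),
        ("band_1070", 0.55, 0.35),
        ("band_1140", 0.55, 0.35),
        ("band_1260", 0.60, 1.0),
        ("band_1410", 0.60, 1.0),
        ("band_1480", 0.60, 1.0),
    )

    # R2 mobile a1 CC stretch; binding redshifts the mode and lowers its
    # intensity, a distal C=C raises it sharply
    a1_blank: float = 1603.0
    a1_mono: float = 1599.0
    a1_saturated: float = 1601.0
    a1_unsat_glc: float = 1591.0
    a1_unsat_gal: float = 1595.0
    a1_amp_blank: float = 0.45
    a1_amp_mono: float = 0.40
    a1_amp_saturated: float = 0.30
    a1_amp_unsaturated: float = 0.65
    a1_fwhm_unsaturated: float = 14.0

    # R3 hexose band position (414 cm^-1 band)
    pos_blank: float = 414.0
    pos_mono_glc: float = 414.9
    pos_mono_gal: float = 418.1
    pos_glc: tuple = (414.0, 416.8)
    pos_gal: tuple = (417.5, 419.0)

    # R4/R5 chain-length intensity ratios
    r4_base: float = 0.25
    r4_glc: tuple = (0.40, 0.80)
    r5_base: float = 0.30
    r5_gal: tuple = (0.45, 0.90)

    def __post_init__(self):
        if not (0 < self.lod < self.c_max):
            raise ValidationError("require 0 < LOD < c_max")
        if self.replicates < 2:
            raise ValidationError("replicate count must be >= 2")
        for name in ("beta_capture", "beta_saturation", "beta_hexose",
                     "beta_chain"):
            b = getattr(self, name)
            if not (0.0 <= b <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.r1_mono < 0.07):
            raise ValidationError("monosaccharide capture ratio must be <0.07")
        r1_max = self.r1_cer_min + self.r1_cer_step * (len(_R1_ORDER) - 1)
        if not (0.07 <= self.r1_cer_min and r1_max <= 2.2):
            raise ValidationError("cerebroside capture ratios must lie in "
                                  "[0.07, 2.2]")
        for lo, hi, rng in (
            (*self.pos_glc, (414.0, 417.0)),
            (*self.pos_gal, (417.0, 419.0)),
        ):
            if not (rng[0] <= lo < hi <= rng[1]):
                raise ValidationError(
                    f"hexose position range ({lo}, {hi}) outside {rng}"
                )

    def noise_free(self, **overrides) -> "SyntheticConfig":
        """Copy of this config with every noise source switched off
        (intensity noise, centre jitter, ratio scatter)."""
        from dataclasses import replace as _replace

        return _replace(
            self, noise_sigma=0.0, center_jitter=0.0, r1_noise=0.0,
            chain_ratio_noise=0.0, a1_amp_noise=0.0, **overrides,
        )

    # -- rule table -------------------------------------------------------
    def capture_ratio(self, label: AnalyteLabel) -> float:
        """Full-response I1330/I1567 target for a class (rule R1)."""
        if label.category == "blank":
            return self.r1_blank
        if label.category == "monosaccharide":
            return self.r1_mono
        k = _R1_ORDER.index(label.nomenclature())
        return self.r1_cer_min + self.r1_cer_step * k

    def a1_position(self, label: AnalyteLabel) -> float:
        if label.category == "blank":
            return self.a1_blank
        if label.category == "monosaccharide":
            return self.a1_mono
        if label.saturation == 0:
            return self.a1_saturated
        return self.a1_unsat_glc if label.hexose == "glc" \
            else self.a1_unsat_gal

    def a1_amplitude(self, label: AnalyteLabel) -> float:
        if label.category == "blank":
            return self.a1_amp_blank
        if label.category == "monosaccharide":
            return self.a1_amp_mono
        return self.a1_amp_unsaturated if label.saturation \
            else self.a1_amp_saturated

    def hexose_position(self, label: AnalyteLabel) -> float:
        if label.category == "blank":
            return self.pos_blank
        if label.category == "monosaccharide":
            return self.pos_mono_glc if label.hexose == "glc" \
                else self.pos_mono_gal
        lo, hi = self.pos_glc if label.hexose == "glc" else self.pos_gal
        return lo + (hi - lo) * _chain_fraction(label.chain_length)

    def glc_chain_ratio(self, label: AnalyteLabel) -> float:
        if label.category == "cerebroside" and label.hexose == "glc":
            lo, hi = self.r4_glc
            return lo + (hi - lo) * _chain_fraction(label.chain_length)
        return self.r4_base

    def gal_chain_ratio(self, label: AnalyteLabel) -> float:
        if label.category == "cerebroside" and label.hexose == "gal":
            lo, hi = self.r5_gal
            return lo + (hi - lo) * _chain_fraction(label.chain_length)
        return self.r5_base


def attenuation(conc: float, cfg: SyntheticConfig | None = None) -> float:
    """Log-linear concentration response fraction, clipped to [0, 1].

    ``attenuation(c_max) = 1`` and ``attenuation(LOD) = 0``; halfway in
    log-concentration gives 0.5.
    """
    if cfg is None:
        cfg = SyntheticConfig()
    if conc <= 0:
        return 0.0
    num = math.log10(conc) - math.log10(cfg.lod)
    den = math.log10(cfg.c_max) - math.log10(cfg.lod)
    return float(np.clip(num / den, 0.0, 1.0))


def _base_arrays():
    centers = np.array([row[1] for row in _BASE_PEAKS])
    amps = np.array([row[2] for row in _BASE_PEAKS])
    fwhms = np.array([row[3] for row in _BASE_PEAKS])
    return centers, amps, fwhms


_PEAK_INDEX = {row[0]: i for i, row in enumerate(_BASE_PEAKS)}

_RULE_BETA = {
    "capture": "beta_capture",
    "capture_width": "beta_capture_width",
    "saturation": "beta_saturation",
    "hexose": "beta_hexose",
    "chain": "beta_chain",
}


def _deviation_scales(label: AnalyteLabel, conc: float,
                      cfg: SyntheticConfig):
    """Per-rule deviation scale s_r at this concentration; None below LOD."""
    if label.category == "blank":
        return {rule: 1.0 for rule in _RULE_BETA}
    if conc < cfg.lod:
        return None
    alpha = attenuation(conc, cfg)
    return {
        rule: 1.0 - getattr(cfg, beta_name) * (1.0 - alpha)
        for rule, beta_name in _RULE_BETA.items()
    }


@lru_cache(maxsize=8)
def _measurement_calibration(cfg: SyntheticConfig):
    """Per-band affine map from intended measured ratio to raw amplitude.

    Rule targets like I1330/I1567 = 0.6 refer to ratios *measured* on a
    preprocessed spectrum, where neighbouring-peak tails inflate band maxima
    and the baseline-correction step shaves broad Lorentzian wings.  Both
    effects are affine in the band amplitude, so one noise-free blank
    rendering (plus one rendering per ratio band with that band removed)
    yields, for each band, a tail floor ``t`` and gain ``g`` such that
    ``measured = (g * amp + t) / A_ref``.  Returns ``{band: (g, t)}`` plus
    the reference apex ``A_ref``.
    """
    from .preprocess import airpls_baseline  # local import, avoids cycle

    x = canonical_grid()
    centers, amps, fwhms = _base_arrays()

    def corrected(amp_vec):
        y = np.zeros_like(x)
        for c, a, w in zip(centers, amp_vec, fwhms):
            y += _line_shape_raw(x, c, a, w, 0.0, 0.5)
        y += _baseline(x, cfg.baseline_amplitude)
        return y - airpls_baseline(y)

    def band_max(y, center, half=8.0):
        m = (x >= center - half) & (x <= center + half)
        return float(y[m].max())

    ref_center = _BASE_PEAKS[_PEAK_INDEX["a1_ref_1567"]][1]
    full = corrected(amps)
    a_ref = band_max(full, ref_center)
    cal = {}
    for band in _RATIO_BANDS:
        i = _PEAK_INDEX[band]
        without = amps.copy()
        without[i] = 0.0
        t = band_max(corrected(without), centers[i])
        g = (band_max(full, centers[i]) - t) / amps[i]
        cal[band] = (g, t)
    return cal, a_ref


def _amp_for_ratio(band: str, ratio: float, cfg: SyntheticConfig) -> float:
    cal, a_ref = _measurement_calibration(cfg)
    g, t = cal[band]
    return max((ratio * a_ref - t) / g, 0.0)


def _ratio_targets(label: AnalyteLabel, cfg: SyntheticConfig,
                   scales) -> dict:
    """Measured-ratio targets for the three ratio bands at deviation scales
    ``scales`` (rule -> s)."""
    return {
        "boh_bend_1330": cfg.r1_blank + scales["capture"]
        * (cfg.capture_ratio(label) - cfg.r1_blank),
        "ch_bend_1023": cfg.r4_base + scales["chain"]
        * (cfg.glc_chain_ratio(label) - cfg.r4_base),
        "ring_def_cs_691": cfg.r5_base + scales["chain"]
        * (cfg.gal_chain_ratio(label) - cfg.r5_base),
    }


def _signature(label: AnalyteLabel, conc: float, cfg: SyntheticConfig):
    """Noise-free peak parameter arrays (centers, amps, fwhms) for a class
    at a concentration; below-LOD collapses to the blank."""
    centers, amps, fwhms = _base_arrays()
    centers = centers.copy()
    amps = amps.copy()
    fwhms = fwhms.copy()
    scales = _deviation_scales(label, conc, cfg)
    below_lod = scales is None
    if below_lod:
        scales = {rule: 0.0 for rule in _RULE_BETA}

    # ratio bands: targets are measured ratios, converted via calibration
    for band, ratio in _ratio_targets(label, cfg, scales).items():
        amps[_PEAK_INDEX[band]] = _amp_for_ratio(band, ratio, cfg)

    # position/amplitude/width rules applied directly
    ia1 = _PEAK_INDEX["a1_cc_mobile"]
    i414 = _PEAK_INDEX["ring_def_cs_414"]
    i1330 = _PEAK_INDEX["boh_bend_1330"]
    centers[ia1] += scales["saturation"] * (
        cfg.a1_position(label) - cfg.a1_blank
    )
    amps[ia1] += scales["saturation"] * (
        cfg.a1_amplitude(label) - cfg.a1_amp_blank
    )
    centers[i414] += scales["hexose"] * (
        cfg.hexose_position(label) - cfg.pos_blank
    )
    if label.category == "cerebroside" and label.saturation:
        # symmetry disruption by the distal C=C also broadens the mode
        fwhms[ia1] += scales["saturation"] * (
            cfg.a1_fwhm_unsaturated - fwhms[ia1]
        )
    if label.category != "blank":
        target_w = (cfg.fwhm_1330_mono
                    if label.category == "monosaccharide"
                    else cfg.fwhm_1330_cer)
        fwhms[i1330] += scales["capture_width"] * (target_w - fwhms[i1330])
    if label.category == "cerebroside":
        alpha = 0.0 if below_lod else attenuation(conc, cfg)
        for band, delta, beta in cfg.analyte_band_load:
            s = 0.0 if below_lod else 1.0 - beta * (1.0 - alpha)
            amps[_PEAK_INDEX[band]] += s * delta
    return centers, amps, fwhms, below_lod


def _baseline(x: np.ndarray, amplitude: float) -> np.ndarray:
    u = (x - 1100.0) / 700.0
    return amplitude * (0.8 - 0.5 * u * u)


def _scatter_amps(amps: np.ndarray, cfg: SyntheticConfig,
                  rng) -> np.ndarray:
    """Per-replicate within-class scatter of the diagnostic band amplitudes.

    The scatter is specified on the measured-ratio scale and converted to
    amplitude units through the measurement calibration gain, so e.g.
    ``chain_ratio_noise = 0.05`` means the realized I691/I1567 of one
    replicate deviates by sigma = 0.05 from its class target.
    """
    amps = amps.copy()
    cal, a_ref = _measurement_calibration(cfg)

    def add_ratio_noise(band, delta):
        g, _ = cal[band]
        i = _PEAK_INDEX[band]
        amps[i] = max(amps[i] + delta * a_ref / g, 0.0)

    if cfg.r1_noise > 0:
        add_ratio_noise("boh_bend_1330", rng.normal(0.0, cfg.r1_noise))
    if cfg.chain_ratio_noise > 0:
        # shared binding-geometry latent + per-band residual
        rho = cfg.chain_ratio_corr
        shared = rng.normal()
        for band in ("ch_bend_1023", "ring_def_cs_691"):
            e = rng.normal()
            add_ratio_noise(band, cfg.chain_ratio_noise * (
                math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * e
            ))
    if cfg.a1_amp_noise > 0:
        ia1 = _PEAK_INDEX["a1_cc_mobile"]
        amps[ia1] = max(amps[ia1] + rng.normal(0.0, cfg.a1_amp_noise), 0.0)
    return amps


def _render(centers, amps, fwhms, cfg: SyntheticConfig, rng) -> np.ndarray:
    x = canonical_grid()
    if cfg.center_jitter > 0:
        centers = centers + rng.normal(0.0, cfg.center_jitter, centers.size)
    y = np.zeros_like(x)
    for c, a, w in zip(centers, amps, fwhms):
        y += _line_shape_raw(x, c, a, w, 0.0, 0.5)
    y += _baseline(x, cfg.baseline_amplitude)
    if cfg.noise_sigma > 0:
        y += rng.normal(0.0, cfg.noise_sigma, x.size)
    return y


def generate_spectrum(label: AnalyteLabel, conc: float,
                      cfg: SyntheticConfig | None = None,
                      seed: int | np.random.Generator = 0) -> Spectrum:
    """Generate one labelled synthetic spectrum.

    The blank ignores ``conc``.  Concentrations below the LOD yield a
    blank-identical signature and set ``meta['below_lod']``.
    """
    if cfg is None:
        cfg = SyntheticConfig()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    centers, amps, fwhms, below_lod = _signature(label, conc, cfg)
    amps = _scatter_amps(amps, cfg, rng)
    y = _render(centers, amps, fwhms, cfg, rng)
    meta = {
        "analyte": label.nomenclature(),
        "concentration_M": f"{conc:g}",
        "state": "raw",
    }
    if below_lod:
        meta["below_lod"] = "true"
    return Spectrum(canonical_grid(), y, meta)


def generate_dataset(cfg: SyntheticConfig | None = None,
                     conc_list: Sequence[float] | None = None,
                     seed: int = 0,
                     labels: Sequence[AnalyteLabel] | None = None,
                     replicates: int | None = None) -> SpectrumSet:
    """Generate the replicate design: every class at every concentration.

    Defaults reproduce the study design at 1e-4 M: 14 classes x 60
    replicates = 840 spectra.  Replicate generators are derived from the
    master seed by position (class, concentration, replicate), so the same
    seed always yields bit-identical datasets and any subset is reproducible.
    """
    if cfg is None:
        cfg = SyntheticConfig()
    if conc_list is None:
        conc_list = [cfg.c_max]
    if labels is None:
        labels = all_labels()
    n_rep = cfg.replicates if replicates is None else replicates
    spectra, labs, concs, reps = [], [], [], []
    for ci, conc in enumerate(conc_list):
        for li, label in enumerate(labels):
            for r in range(n_rep):
                rng = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(ci, li, r))
                )
                sp = generate_spectrum(label, conc, cfg, rng)
                sp.meta["replicate"] = str(r + 1)
                spectra.append(sp)
                labs.append(label)
                concs.append(conc if label.category != "blank" else 0.0)
                reps.append(r + 1)
    return SpectrumSet(spectra, labs, np.asarray(concs), reps)


@dataclass
class MixtureSet:
    """Binary GlcCer24:1 / GalCer24:1 mixture spectra at fixed total."""

    spectra: list
    frac_gal: np.ndarray        # mol% GalCer24:1
    total: float                # molar
    replicates: list

    def __len__(self):
        return len(self.spectra)


def generate_mixture(frac_gal: float, total: float = 1e-4,
                     cfg: SyntheticConfig | None = None,
                     seed: int | np.random.Generator = 0) -> Spectrum:
    """Generate one binary-mixture spectrum.

    The noise-free signature is the convex combination (by mol fraction) of
    the two endmember signatures at the total concentration; jitter and
    intensity noise are then applied once.
    """
    if cfg is None:
        cfg = SyntheticConfig()
    if not (0.0 <= frac_gal <= 100.0):
        raise ValidationError("frac_gal must lie in [0, 100] mol%")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    glc = AnalyteLabel.cerebroside("glc", 24, 1)
    gal = AnalyteLabel.cerebroside("gal", 24, 1)
    c_glc, a_glc, fwhms, _ = _signature(glc, total, cfg)
    c_gal, a_gal, _, _ = _signature(gal, total, cfg)
    f = frac_gal / 100.0
    centers = (1 - f) * c_glc + f * c_gal
    amps = _scatter_amps((1 - f) * a_glc + f * a_gal, cfg, rng)
    y = _render(centers, amps, fwhms, cfg, rng)
    meta = {
        "analyte": "GlcCer24:1+GalCer24:1",
        "frac_gal_molpct": f"{frac_gal:g}",
        "total_M": f"{total:g}",
        "state": "raw",
    }
    return Spectrum(canonical_grid(), y, meta)


def generate_mixture_dataset(fracs: Sequence[float],
                             total: float = 1e-4,
                             cfg: SyntheticConfig | None = None,
                             seed: int = 0,
                             replicates: int | None = None) -> MixtureSet:
    """Replicated mixture design, e.g. the {0,25,50,75,100} mol% calibration
    (5 x 60 = 300 spectra with the default replicate count)."""
    if cfg is None:
        cfg = SyntheticConfig()
    n_rep = cfg.replicates if replicates is None else replicates
    spectra, frac_col, reps = [], [], []
    for fi, frac in enumerate(fracs):
        for r in range(n_rep):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(fi, r))
            )
            sp = generate_mixture(frac, total, cfg, rng)
            sp.meta["replicate"] = str(r + 1)
            spectra.append(sp)
            frac_col.append(frac)
            reps.append(r + 1)
    return MixtureSet(spectra, np.asarray(frac_col, float), total, reps)
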