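"""Generator contracts: design counts, determinism, concentration response,
rule fidelity (measured diagnostics inside the documented ranges), and
mixture construction."""

import numpy as np
import pytest

import serstax as sx
from serstax.errors import ValidationError
from serstax.featurize import band_position, intensity_ratio
from serstax.io import AnalyteLabel, CLASS_ORDER
from serstax.preprocess import preprocess_spectrum
from serstax.synthetic import SyntheticConfig, attenuation


class TestDesignCounts:
    def test_default_design_is_840_spectra(self, cfg):
        sset = sx.generate_dataset(cfg, seed=0)
        assert len(sset) == 840
        counts = sset.replicate_counts()
        assert len(counts) == 14
        assert all(v == 60 for v in counts.values())

    def test_reduced_replicates(self, cfg):
        sset = sx.generate_dataset(cfg, seed=0, replicates=5)
        assert len(sset) == 14 * 5

    def test_same_seed_bit_identical(self, cfg):
        a = sx.generate_dataset(cfg, seed=42, replicates=3)
        b = sx.generate_dataset(cfg, seed=42, replicates=3)
        for sa, sb in zip(a.spectra, b.spectra):
            np.testing.assert_array_equal(sa.intensities, sb.intensities)

    def test_different_seeds_differ(self, cfg):
        a = sx.generate_dataset(cfg, seed=1, replicates=2)
        b = sx.generate_dataset(cfg, seed=2, replicates=2)
        assert not np.array_equal(a.spectra[0].intensities,
                                  b.spectra[0].intensities)


class TestAttenuation:
    def test_log_midpoint_is_half(self, cfg):
        assert attenuation(1e-7, cfg) == pytest.approx(0.5)

    def test_endpoints(self, cfg):
        assert attenuation(cfg.c_max, cfg) == 1.0
        assert attenuation(cfg.lod, cfg) == 0.0

    def test_monotone_in_log_concentration(self, cfg):
        concs = [10.0 ** -k for k in np.linspace(4, 10, 25)]
        vals = [attenuation(c, cfg) for c in concs]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_clipped_outside_range(self, cfg):
        assert attenuation(1e-2, cfg) == 1.0
        assert attenuation(1e-12, cfg) == 0.0
        assert attenuation(0.0, cfg) == 0.0

    def test_below_lod_spectrum_flagged_blank(self, cfg):
        lab = AnalyteLabel.cerebroside("gal", 16)
        sp = sx.generate_spectrum(lab, cfg.lod / 10, cfg, seed=0)
        assert sp.meta["below_lod"] == "true"
        blank = sx.generate_spectrum(AnalyteLabel.blank(), cfg.c_max, cfg,
                                     seed=0)
        np.testing.assert_allclose(sp.intensities, blank.intensities)


def _diag(sp):
    pp = preprocess_spectrum(sp)
    return {
        "r1": intensity_ratio(pp, 1330.0, 1567.0),
        "r4": intensity_ratio(pp, 1023.0, 1567.0),
        "r5": intensity_ratio(pp, 691.0, 1567.0),
        "pos414": band_position(pp, 416.5, 10.0),
        "a1": band_position(pp, 1597.0, 13.0),
    }


@pytest.fixture(scope="module")
def diags(cfg):
    out = {}
    for name in CLASS_ORDER:
        lab = AnalyteLabel.from_nomenclature(name)
        reps = [_diag(sx.generate_spectrum(lab, cfg.c_max, cfg, seed=s))
                for s in range(6)]
        out[name] = {k: np.mean([r[k] for r in reps]) for k in reps[0]}
    return out


class TestRuleFidelity:
    """Measured diagnostics of generated spectra fall inside the documented
    ranges for every class at full concentration."""

    def test_blank_capture_ratio(self, diags):
        assert diags["MPBA blank"]["r1"] == pytest.approx(0.6, abs=0.05)

    def test_monosaccharide_capture_below_threshold(self, diags):
        assert diags["glucose"]["r1"] < 0.07
        assert diags["galactose"]["r1"] < 0.07

    def test_cerebroside_capture_in_range(self, diags):
        for name in CLASS_ORDER:
            if "Cer" in name:
                assert 0.07 <= diags[name]["r1"] <= 2.2, name

    def test_capture_drops_for_all_epimers(self, diags):
        blank = diags["MPBA blank"]["r1"]
        for name in CLASS_ORDER:
            if name != "MPBA blank":
                assert diags[name]["r1"] < blank - 0.2, name

    def test_hexose_band_positions(self, diags):
        assert diags["MPBA blank"]["pos414"] == pytest.approx(414.0,
                                                              abs=0.6)
        for name in CLASS_ORDER:
            lab = AnalyteLabel.from_nomenclature(name)
            if lab.category != "cerebroside":
                continue
            lo, hi = (414.0, 417.0) if lab.hexose == "glc" else (417.0,
                                                                 419.0)
            assert lo - 0.4 <= diags[name]["pos414"] <= hi + 0.4, name

    def test_saturation_band_positions(self, diags):
        assert diags["MPBA blank"]["a1"] == pytest.approx(1603.0, abs=0.6)
        for name in CLASS_ORDER:
            lab = AnalyteLabel.from_nomenclature(name)
            if lab.category != "cerebroside":
                continue
            if lab.saturation == 0:
                assert diags[name]["a1"] == pytest.approx(1601.0, abs=0.7), \
                    name
            else:
                expected = 1591.0 if lab.hexose == "glc" else 1595.0
                assert diags[name]["a1"] == pytest.approx(expected,
                                                          abs=0.7), name

    def test_chain_ratios_strictly_increase_without_noise(self, cfg_quiet):
        for hexose, key in (("glc", "r4"), ("gal", "r5")):
            vals = []
            for x in sx.CHAIN_LENGTHS:
                sat = 1 if (hexose == "glc" and x == 24) else 0
                lab = AnalyteLabel.cerebroside(hexose, x, sat)
                vals.append(
                    _diag(sx.generate_spectrum(lab, cfg_quiet.c_max,
                                               cfg_quiet, seed=0))[key]
                )
            assert all(a < b for a, b in zip(vals, vals[1:])), hexose


class TestConcentrationResponse:
    def test_capture_deviation_shrinks_toward_blank(self, cfg_quiet):
        lab = AnalyteLabel.cerebroside("gal", 16)
        r1 = [
            _diag(sx.generate_spectrum(lab, c, cfg_quiet, seed=0))["r1"]
            for c in (1e-4, 1e-7, 1e-10)
        ]
        blank = _diag(sx.generate_spectrum(AnalyteLabel.blank(), 1e-4,
                                           cfg_quiet, seed=0))["r1"]
        # deviation from blank decreases monotonically with concentration
        devs = [abs(v - blank) for v in r1]
        assert devs[0] > devs[1] > devs[2]
        # but at the LOD the capture signal remains past halfway
        assert devs[2] > 0.5 * devs[0]

    def test_blank_ignores_concentration(self, cfg_quiet):
        a = sx.generate_spectrum(AnalyteLabel.blank(), 1e-4, cfg_quiet,
                                 seed=0)
        b = sx.generate_spectrum(AnalyteLabel.blank(), 1e-9, cfg_quiet,
                                 seed=0)
        np.testing.assert_array_equal(a.intensities, b.intensities)


class TestMixtures:
    def test_pure_endpoint_matches_single_analyte(self, cfg_quiet):
        mix = sx.generate_mixture(100.0, 1e-4, cfg_quiet, seed=0)
        pure = sx.generate_spectrum(
            AnalyteLabel.cerebroside("gal", 24, 1), 1e-4, cfg_quiet, seed=0
        )
        np.testing.assert_allclose(mix.intensities, pure.intensities)

    def test_midpoint_is_linear_in_mol_fraction(self, cfg_quiet):
        y0 = sx.generate_mixture(0.0, 1e-4, cfg_quiet, seed=0).intensities
        y100 = sx.generate_mixture(100.0, 1e-4, cfg_quiet,
                                   seed=0).intensities
        y50 = sx.generate_mixture(50.0, 1e-4, cfg_quiet, seed=0).intensities
        # centers average too, so linearity holds to first order in the
        # (noise-free) parameter combination; diagnostics must sit midway
        from serstax.io import Spectrum
        mid = _diag(Spectrum(sx.canonical_grid(), y50, {"state": "raw"}))
        lo = _diag(Spectrum(sx.canonical_grid(), y0, {"state": "raw"}))
        hi = _diag(Spectrum(sx.canonical_grid(), y100, {"state": "raw"}))
        for key in ("r4", "r5"):
            assert mid[key] == pytest.approx((lo[key] + hi[key]) / 2,
                                             abs=0.02)

    def test_calibration_design_count(self, cfg):
        mset = sx.generate_mixture_dataset([0, 25, 50, 75, 100], cfg=cfg,
                                           seed=0, replicates=60)
        assert len(mset) == 300

    def test_fraction_bounds_enforced(self, cfg):
        with pytest.raises(ValidationError):
            sx.generate_mixture(120.0, 1e-4, cfg, seed=0)


class TestConfigValidation:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(lod=1e-3)      # LOD above c_max
        with pytest.raises(ValidationError):
            SyntheticConfig(replicates=1)
        with pytest.raises(ValidationError):
            SyntheticConfig(r1_mono=0.2)
        with pytest.raises(ValidationError):
            SyntheticConfig(pos_gal=(410.0, 419.0))
        with pytest.raises(ValidationError):
            SyntheticConfig(beta_capture=1.5)
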