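import numpy as np
import pytest

from ramandecomp import (
    AMIDE_I_SCHEME,
    SS_CONFORMER_SCHEME,
    PeakComponent,
    Spectrum,
    detect_marker_bands,
    quantify_amide_i,
    quantify_ss_conformers,
    tryptophan_intensity,
    tyrosine_doublet_ratio,
)
from ramandecomp.banddecomp import DecompositionResult
from ramandecomp.quantify import UnassignedComponentWarning


def _result(components, region):
    x = np.arange(region[0], region[1] + 0.1, 0.5)
    y = np.zeros_like(x)
    for c in components:
        y = y + c(x)
    return DecompositionResult(
        region=region, baseline=None, components=components, wavenumber=x,
        fitted_curve=y, pearson_r=1.0, residual_rms=0.0, converged=True,
        n_iterations=1, data=y,
    )


def _gaussians(center_area_pairs, fwhm=16.0):
    ga = np.sqrt(np.pi / (4 * np.log(2)))
    return [
        PeakComponent(c, a / (fwhm * ga), fwhm, 0.0)
        for c, a in center_area_pairs
    ]


class TestAmideIQuantification:
    def test_single_structural_component_is_100pct(self):
        rep = quantify_amide_i(_result(_gaussians([(1650.0, 5.0)]), (1590.0, 1710.0)))
        assert rep.fractions == {"alpha_helix": 100.0}

    def test_area_scale_invariance(self):
        pairs = [(1637.0, 19.0), (1650.0, 25.0), (1663.0, 26.0), (1677.0, 27.0), (1691.0, 3.0)]
        r1 = quantify_amide_i(_result(_gaussians(pairs), (1590.0, 1710.0)))
        r2 = quantify_amide_i(_result(_gaussians([(c, 2 * a) for c, a in pairs]), (1590.0, 1710.0)))
        for k in r1.fractions:
            assert r1.fractions[k] == pytest.approx(r2.fractions[k], abs=1e-9)

    def test_aromatic_bands_excluded_from_denominator(self):
        pairs = [(1637.0, 19.0), (1650.0, 25.0), (1663.0, 26.0), (1677.0, 27.0), (1691.0, 3.0),
                 (1608.0, 10.0), (1623.0, 5.0)]
        rep = quantify_amide_i(_result(_gaussians(pairs, fwhm=10.0), (1590.0, 1710.0)))
        assert rep.fractions["beta_sheet"] == pytest.approx(19.0, abs=1e-9)
        assert set(rep.aromatic_areas) == {"aromatic_1607", "aromatic_1622"}
        assert sum(rep.fractions.values()) == pytest.approx(100.0, abs=1e-6)

    def test_component_outside_windows_goes_unassigned_with_warning(self):
        comps = _gaussians([(1650.0, 10.0), (1700.5, 2.0)])
        with pytest.warns(UnassignedComponentWarning):
            rep = quantify_amide_i(_result(comps, (1590.0, 1710.0)))
        assert len(rep.unassigned) == 1
        assert rep.fractions["alpha_helix"] == 100.0

    def test_zero_structural_area_rejected(self):
        comps = _gaussians([(1608.0, 4.0)])  # aromatic only
        with pytest.raises(ValueError):
            quantify_amide_i(_result(comps, (1590.0, 1710.0)))


class TestConformerQuantification:
    def test_single_band_is_100pct(self):
        rep = quantify_ss_conformers(_result(_gaussians([(510.0, 1.0)], fwhm=10.0), (500.0, 550.0)))
        assert rep.fractions == {"SSggg": 100.0}

    def test_subband_areas_summed_per_class(self):
        pairs = [(513.0, 15.0), (519.0, 19.0), (525.0, 20.0), (533.0, 21.0), (546.0, 25.0)]
        rep = quantify_ss_conformers(_result(_gaussians(pairs, fwhm=10.0), (500.0, 550.0)))
        assert rep.fractions["SSggg"] == pytest.approx(15.0, abs=1e-9)
        assert rep.fractions["SStgg"] == pytest.approx(39.0, abs=1e-9)
        assert rep.fractions["SStgt"] == pytest.approx(46.0, abs=1e-9)
        assert sorted(rep.member_bands["SStgg"]) == [519.0, 525.0]

    def test_order_invariance(self):
        pairs = [(513.0, 15.0), (525.0, 39.0), (546.0, 46.0)]
        r1 = quantify_ss_conformers(_result(_gaussians(pairs, fwhm=10.0), (500.0, 550.0)))
        r2 = quantify_ss_conformers(_result(_gaussians(pairs[::-1], fwhm=10.0), (500.0, 550.0)))
        assert r1.fractions == r2.fractions


def _doublet(h855, h835, extra=()):
    x = np.arange(700.0, 900.0, 0.5)
    y = (h835 * np.exp(-4 * np.log(2) * ((x - 835.0) / 10.0) ** 2)
         + h855 * np.exp(-4 * np.log(2) * ((x - 855.0) / 10.0) ** 2))
    for c, h, w in extra:
        y = y + h * np.exp(-4 * np.log(2) * ((x - c) / w) ** 2)
    return Spectrum(x, y)


class TestTyrosineDoublet:
    def test_equal_heights_donor_acceptor(self):
        rep = tyrosine_doublet_ratio(_doublet(1.0, 1.0))
        assert rep.tyr_ratio == pytest.approx(1.0, abs=0.02)
        assert rep.tyr_category == "donor_acceptor"
        assert not rep.tyr_exposed_anionic

    def test_ratio_2_53_flags_exposed_anionic(self):
        rep = tyrosine_doublet_ratio(_doublet(2.53, 1.0))
        assert rep.tyr_ratio == pytest.approx(2.53, abs=0.05)
        assert rep.tyr_category == "positive_charge_acceptor"
        assert rep.tyr_exposed_anionic

    def test_ratio_1_84_positive_charge_acceptor(self):
        rep = tyrosine_doublet_ratio(_doublet(1.84, 1.0))
        assert rep.tyr_ratio == pytest.approx(1.84, abs=0.04)
        assert rep.tyr_category == "positive_charge_acceptor"
        assert not rep.tyr_exposed_anionic

    def test_low_ratio_below_range(self):
        rep = tyrosine_doublet_ratio(_doublet(0.5, 1.0))
        assert rep.tyr_category == "below_range"

    def test_missing_peak_rejected(self):
        x = np.arange(700.0, 900.0, 0.5)
        with pytest.raises(ValueError):
            tyrosine_doublet_ratio(Spectrum(x, np.zeros_like(x)))


class TestTryptophan:
    def _with_trp(self, height):
        x = np.arange(700.0, 820.0, 0.5)
        y = height * np.exp(-4 * np.log(2) * ((x - 760.0) / 9.0) ** 2)
        return Spectrum(x, y)

    def test_height_0_12_recovered(self):
        h = tryptophan_intensity(self._with_trp(0.12))
        assert h == pytest.approx(0.12, abs=0.002)

    def test_absent_band_rejected(self):
        x = np.arange(700.0, 820.0, 0.5)
        with pytest.raises(ValueError):
            tryptophan_intensity(Spectrum(x, np.zeros_like(x)))

    def test_pipeline_scale_invariance(self):
        """Doubling raw intensities leaves the normalized Trp height unchanged."""
        import warnings

        from ramandecomp import baseline_correct, crop, generate_spectrum, normalize_to_band, random_truth
        from ramandecomp.pipeline import ENDOSPERM_BASELINE_ANCHORS

        truth = random_truth("endosperm", seed=9, noise_sigma=0.0)
        s, _ = generate_spectrum(truth)

        def run(spec):
            out = crop(spec, (300.0, 2000.0))
            out, _ = baseline_correct(out, "polynomial", ENDOSPERM_BASELINE_ANCHORS)
            out, _ = normalize_to_band(out)
            return tryptophan_intensity(out)

        assert run(s) == pytest.approx(run(s.replace(s.intensity * 2.0)), abs=1e-10)


class TestMarkerDetection:
    def test_endosperm_starch_markers_detected(self):
        import warnings

        from ramandecomp import baseline_correct, crop, generate_spectrum, normalize_to_band, random_truth
        from ramandecomp.pipeline import ENDOSPERM_BASELINE_ANCHORS

        truth = random_truth("endosperm", seed=2, noise_sigma=0.0)
        s, _ = generate_spectrum(truth)
        s = crop(s, (300.0, 2000.0))
        s, _ = baseline_correct(s, "polynomial", ENDOSPERM_BASELINE_ANCHORS)
        s, _ = normalize_to_band(s)
        table = {row["label"]: row for row in detect_marker_bands(s)}
        for label, center in (("starch_480", 480.0), ("starch_940", 940.0)):
            assert table[label]["present"]
            assert abs(table[label]["center"] - center) <= 3.0

    def test_flat_spectrum_all_absent(self, flat_spectrum):
        table = detect_marker_bands(flat_spectrum)
        assert not any(row["present"] for row in table)

    @pytest.mark.parametrize("include", [True, False])
    def test_cs_640_flag_tracks_generator_truth(self, include):
        from ramandecomp import generate_spectrum, random_truth

        truth = random_truth("endosperm", seed=4, noise_sigma=0.0, include_cs_640=include)
        s, _ = generate_spectrum(truth)
        from ramandecomp import baseline_correct, crop, normalize_to_band
        from ramandecomp.pipeline import ENDOSPERM_BASELINE_ANCHORS

        s = crop(s, (300.0, 2000.0))
        s, _ = baseline_correct(s, "polynomial", ENDOSPERM_BASELINE_ANCHORS)
        s, _ = normalize_to_band(s)
        table = {row["label"]: row for row in detect_marker_bands(s)}
        assert table["cs_gauche_640"]["present"] == include
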