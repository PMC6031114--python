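"""Synthetic scene generator: band rendering, library, scene contracts."""

import numpy as np
import pytest

import ramanmix as rm
from ramanmix.synth import BandSpec, ComponentSpectrum


class TestRenderComponent:
    def test_single_gaussian_peaks_at_center(self, axis):
        spec = ComponentSpectrum("x", [BandSpec(1600, 20, 1.0)])
        y = rm.render_component(spec, axis)
        assert axis.wavenumbers[np.argmax(y)] == pytest.approx(1600, abs=2)
        assert y.max() == pytest.approx(1.0, abs=1e-9)

    def test_height_ratio_of_separated_bands(self, axis):
        spec = ComponentSpectrum("x", [BandSpec(600, 20, 1.0), BandSpec(1400, 20, 0.5)])
        y = rm.render_component(spec, axis)
        i, j = axis.index_of(600), axis.index_of(1400)
        assert y[i] / y[j] == pytest.approx(2.0, abs=1e-6)

    def test_out_of_axis_band_skipped_with_warning(self, axis):
        spec = ComponentSpectrum("x", [BandSpec(1600, 20, 1.0), BandSpec(2900, 20, 1.0)])
        with pytest.warns(UserWarning, match="outside the axis"):
            y = rm.render_component(spec, axis)
        assert y.max() == pytest.approx(1.0, abs=1e-9)

    def test_nonnegative(self, axis):
        spec = ComponentSpectrum("x", [BandSpec(900, 30, 0.3, "lorentzian")])
        assert rm.render_component(spec, axis).min() >= 0


class TestLibrary:
    def test_expected_components_present(self, library):
        for name in ("lignin", "lignin_coniferyl", "cellulose",
                     "cellulose_oriented", "pectin", "protein_lipid", "water"):
            assert name in library

    def test_lignin_band_positions(self, library):
        centers = {b.center for b in library["lignin"].bands}
        assert {1600, 1660, 1140}.issubset(centers)

    def test_lignin_peaks_at_main_aromatic_band(self, axis, library):
        y = rm.render_component(library["lignin"], axis)
        assert abs(axis.wavenumbers[np.argmax(y)] - 1600) <= 4

    def test_coniferyl_shoulder(self, library):
        assert any(abs(b.center - 1634) < 2 for b in library["lignin_coniferyl"].bands)

    def test_orientation_enhances_1095(self, axis, library):
        i = axis.index_of(1095)
        plain = rm.render_component(library["cellulose"], axis)
        orient = rm.render_component(library["cellulose_oriented"], axis)
        assert orient[i] / plain[i] > 1.0

    def test_unit_maximum_and_nonnegative(self, axis, library):
        for spec in library.values():
            y = rm.render_component(spec, axis)
            assert y.min() >= 0
            assert y.max() == pytest.approx(1.0, abs=1e-9)


class TestScenes:
    def test_simplex_rank_equals_k(self, simplex_scene):
        s = np.linalg.svd(simplex_scene.image.D, compute_uv=False)
        assert s[3] < 1e-9 * s[0]

    def test_determinism(self):
        a = rm.make_scene("spruce", (24, 24), snr=20, background="poly3_mix",
                          spike_rate=0.001, seed=42)
        b = rm.make_scene("spruce", (24, 24), snr=20, background="poly3_mix",
                          spike_rate=0.001, seed=42)
        np.testing.assert_array_equal(a.image.D, b.image.D)
        assert a.spike_locations == b.spike_locations

    def test_closure_and_nonnegativity(self, spruce_scene):
        np.testing.assert_allclose(spruce_scene.C_true.sum(axis=1), 1.0,
                                   atol=1e-12)
        assert spruce_scene.S_true.min() >= 0

    def test_noiseless_background_free_is_exact_bilinear(self, simplex_scene):
        np.testing.assert_array_equal(simplex_scene.image.D,
                                      simplex_scene.signal)

    def test_spruce_water_confined_to_lumen(self, spruce_scene):
        k = spruce_scene.component_index("water")
        flat = spruce_scene.region_masks["lumen"].ravel()
        assert spruce_scene.C_true[flat, k].mean() > 0.9
        assert spruce_scene.C_true[~flat, k].mean() < 0.05

    def test_arabidopsis_has_six_regions(self):
        scene = rm.make_scene("arabidopsis", (24, 30), seed=2)
        assert len(scene.region_masks) >= 6
        assert all(m.any() for m in scene.region_masks.values())
        assert scene.C_true.shape[1] == 6

    def test_realized_snr_near_requested(self):
        """RMS signal-to-noise within 20% of requested, over 10 seeds."""
        target = 15.0
        ratios = []
        for seed in range(10):
            sc = rm.make_scene("spruce", (24, 24), snr=target, seed=seed)
            total = sc.signal + sc.background_true
            noise = sc.image.D - total
            ratios.append(np.sqrt((total**2).mean() / (noise**2).mean()))
        assert abs(np.mean(ratios) - target) < 0.2 * target

    def test_spike_count_and_determinism(self):
        n_entries = 24 * 24 * rm.regular_axis().n_channels
        rate = 0.002
        counts = [len(rm.make_scene("spruce", (24, 24), spike_rate=rate,
                                    seed=s).spike_locations)
                  for s in range(8)]
        mean, sd = n_entries * rate, np.sqrt(n_entries * rate)
        assert all(abs(c - mean) < 6 * sd for c in counts)
        assert len(set(counts)) > 1  # seed-dependent binomial draw

    def test_lowvar_water_contract(self):
        """Water < 1% of image variance yet spectrally distinct."""
        sc = rm.make_scene("lowvar_water", (40, 40), snr=30, seed=0)
        assert sc.manifest["water_variance_share"] < 0.01
        iw = sc.component_index("water")
        others = [i for i in range(3) if i != iw]
        R = rm.endmember_correlations(sc.S_true[[iw]], sc.S_true[others])
        assert np.abs(R).max() < 0.3

    def test_grid_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            rm.make_scene("spruce", (6, 6), seed=0)

    def test_invalid_layout(self):
        with pytest.raises(ValueError, match="layout"):
            rm.make_scene("maize", (20, 20), seed=0)


class TestDiffractionResolution:
    def test_green_laser_high_na(self):
        r = rm.diffraction_resolution(532, 1.4)
        assert r == pytest.approx(231.8, abs=0.05)
        assert round(r, -1) == 230

    def test_factors_cancel(self):
        assert rm.diffraction_resolution(500, 0.61) == pytest.approx(500.0)

    def test_linear_in_wavelength(self):
        assert rm.diffraction_resolution(1064, 1.4) == pytest.approx(
            2 * rm.diffraction_resolution(532, 1.4))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rm.diffraction_resolution(532, 0.0)
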