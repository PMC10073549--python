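"""Spectral preprocessing, standard-spectrum selection and transforms."""

import numpy as np
import pandas as pd
import pytest

from ricenni import spectra as spec


def make_set(refl, wavelengths=None, periods=None):
    refl = np.atleast_2d(np.asarray(refl, float))
    if wavelengths is None:
        wavelengths = np.arange(400, 400 + refl.shape[1])
    ids = [f"s{i}" for i in range(refl.shape[0])]
    if periods is None:
        periods = np.array(["d1"] * refl.shape[0])
    return spec.SpectrumSet(wavelengths, refl, ids, periods)


class TestResample:
    def test_constant_spectrum_stays_constant(self):
        native = np.arange(400, 1001, 3, dtype=float)
        sset = make_set(np.full((2, native.size), 0.3), wavelengths=native)
        out = spec.resample_to_1nm(sset, 400, 1000)
        assert np.array_equal(out.wavelengths, np.arange(400.0, 1001.0))
        np.testing.assert_allclose(out.reflectance, 0.3)

    def test_affine_spectrum_is_exact(self):
        native = np.arange(400, 1000, 3, dtype=float)
        sset = make_set((native / 2000.0)[None, :], wavelengths=native)
        out = spec.resample_to_1nm(sset, 401, 990)
        np.testing.assert_allclose(out.reflectance[0], out.wavelengths / 2000.0,
                                   rtol=1e-12)

    def test_no_extrapolation(self):
        native = np.arange(400, 998, 3, dtype=float)
        sset = make_set(np.full((1, native.size), 0.3), wavelengths=native)
        with pytest.raises(ValueError, match="outside native"):
            spec.resample_to_1nm(sset, 400, 1000)


class TestDenoise:
    def test_constant_unchanged(self):
        sset = make_set(np.full((1, 100), 0.4))
        out = spec.gaussian_denoise(sset, sigma=3.0)
        np.testing.assert_allclose(out.reflectance, 0.4, rtol=1e-12)

    def test_sigma_zero_is_identity(self):
        sset = make_set(np.random.default_rng(0).uniform(0.1, 0.9, (3, 50)))
        out = spec.gaussian_denoise(sset, sigma=0.0)
        np.testing.assert_array_equal(out.reflectance, sset.reflectance)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            spec.gaussian_denoise(make_set(np.full((1, 10), 0.3)), sigma=-1.0)

    def test_noise_variance_reduced(self, rng):
        wl = np.arange(400.0, 700.0)
        smooth = 0.3 + 0.1 * np.sin(wl / 40.0)
        worse = better = 0
        for _ in range(100):
            noisy = smooth + rng.normal(0, 0.01, wl.size)
            out = spec.gaussian_denoise(make_set(noisy[None, :], wl), sigma=2.0)
            var_in = np.var(noisy - smooth)
            var_out = np.var(out.reflectance[0] - smooth)
            better += var_out < var_in
        assert better == 100

    def test_band_mean_nearly_preserved(self, smoothed_spectra):
        raw = smoothed_spectra
        for sigma in (1.0, 3.0, 5.0):
            out = spec.gaussian_denoise(raw, sigma=sigma)
            rel = np.abs(out.reflectance.mean(1) - raw.reflectance.mean(1))
            assert (rel / raw.reflectance.mean(1) < 0.01).all()


def nni_frame(ids, values):
    return pd.DataFrame({"sample_id": ids, "nni": values})


class TestStandardSpectrum:
    def test_single_qualifier_returned_verbatim(self):
        sset = make_set([[0.2, 0.4], [0.6, 0.8]])
        std = spec.select_standard_spectrum(sset, nni_frame(["s0", "s1"], [1.005, 1.2]),
                                            "d1")
        np.testing.assert_array_equal(std.reflectance, [0.2, 0.4])
        assert std.n_contributing == 1
        assert not std.fallback_used

    def test_multiple_qualifiers_averaged(self):
        sset = make_set([[0.2, 0.4], [0.4, 0.6], [0.9, 0.9]])
        std = spec.select_standard_spectrum(
            sset, nni_frame(["s0", "s1", "s2"], [0.995, 1.005, 1.3]), "d1")
        np.testing.assert_allclose(std.reflectance, [0.3, 0.5])
        assert std.n_contributing == 2

    def test_fallback_to_nearest(self, caplog):
        sset = make_set([[0.2, 0.4], [0.6, 0.8]])
        with caplog.at_level("WARNING", logger="ricenni.spectra"):
            std = spec.select_standard_spectrum(
                sset, nni_frame(["s0", "s1"], [1.04, 1.2]), "d1")
        assert std.fallback_used
        np.testing.assert_array_equal(std.reflectance, [0.2, 0.4])
        assert any("falling back" in r.message for r in caplog.records)

    def test_unknown_period_rejected(self):
        sset = make_set([[0.2, 0.4]])
        with pytest.raises(ValueError, match="no samples"):
            spec.select_standard_spectrum(sset, nni_frame(["s0"], [1.0]), "d9")


class TestTransforms:
    def setup_method(self):
        self.sset = make_set([[0.4, 0.4], [0.2, 0.2]])
        self.standards = {"d1": spec.StandardSpectrum("d1", np.array([0.2, 0.2]),
                                                      1, ("s1",))}

    def test_standard_self_transform_is_zero(self):
        out = spec.apply_transform(self.sset, self.standards, "logdifference")
        np.testing.assert_array_equal(out.values[1], 0.0)
        out = spec.apply_transform(self.sset, self.standards, "difference")
        np.testing.assert_array_equal(out.values[1], 0.0)

    def test_hand_computed_difference_and_logdifference(self):
        diff = spec.apply_transform(self.sset, self.standards, "difference")
        logdiff = spec.apply_transform(self.sset, self.standards, "logdifference")
        assert diff.values[0, 0] == pytest.approx(0.2)
        assert logdiff.values[0, 0] == pytest.approx(np.log(2), rel=1e-12)

    def test_log_requires_positive_reflectance(self):
        bad = make_set([[0.0, 0.4]])
        with pytest.raises(ValueError, match="positive"):
            spec.apply_transform(bad, None, "log")

    def test_missing_standard_rejected(self):
        with pytest.raises(ValueError, match="missing standard"):
            spec.apply_transform(make_set([[0.3, 0.3]], periods=np.array(["d2"])),
                                 self.standards, "difference")

    def test_difference_inverts_by_adding_standard(self, smoothed_spectra,
                                                   curve_and_nni):
        _, nni = curve_and_nni
        standards = spec.select_standard_spectra(smoothed_spectra, nni)
        diff = spec.apply_transform(smoothed_spectra, standards, "difference")
        rebuilt = diff.values + np.array([standards[p].reflectance
                                          for p in diff.periods])
        np.testing.assert_allclose(rebuilt, smoothed_spectra.reflectance,
                                   rtol=0, atol=1e-15)

    def test_logdifference_is_log_of_ratio(self, smoothed_spectra, curve_and_nni):
        _, nni = curve_and_nni
        standards = spec.select_standard_spectra(smoothed_spectra, nni)
        logdiff = spec.apply_transform(smoothed_spectra, standards, "logdifference")
        log = spec.apply_transform(smoothed_spectra, None, "log")
        log_std = np.array([np.log(standards[p].reflectance)
                            for p in logdiff.periods])
        np.testing.assert_allclose(logdiff.values, log.values - log_std, atol=1e-12)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown transform"):
            spec.apply_transform(self.sset, self.standards, "sqrt")


def test_spectra_csv_round_trip(tmp_path, smoothed_spectra):
    path = tmp_path / "spectra.csv"
    spec.write_spectra_csv(path, smoothed_spectra)
    back = spec.read_spectra_csv(path)
    np.testing.assert_array_equal(back.wavelengths, smoothed_spectra.wavelengths)
    np.testing.assert_allclose(back.reflectance, smoothed_spectra.reflectance,
                               rtol=1e-12)
    assert back.sample_ids == smoothed_spectra.sample_ids
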