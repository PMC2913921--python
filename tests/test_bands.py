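"""Residual transform, preset-center k-means banding and unwrapping."""

import numpy as np
import pytest
from sklearn.base import clone

from hdpr.bands import (
    BandConfig,
    BandUnwrapper,
    HEAVY_CENTERS,
    LIGHT_CENTERS,
    band_table,
    centers_from_slope,
    classify_bands,
    decimal_residual,
    transform_mass,
    unwrap_residuals,
)
from hdpr.fitting import fit_slope_ols


def synthetic_line_points(b, n, rng, mass_range=(300.0, 5800.0)):
    """Masses whose residuals lie exactly on D_R = b*P_M (mod 1)."""
    masses = rng.uniform(*mass_range, size=n)
    for _ in range(4):  # fixed point of  frac(m) == frac(b*m)
        masses = np.floor(masses) + (b * masses) % 1.0
    true_offset = np.round(b * masses - decimal_residual(masses)).astype(int)
    return masses, true_offset


class TestDecimalResidual:
    @pytest.mark.parametrize(
        "mass, expected",
        [(203.126992, 0.126992), (500.0, 0.0), (1500.9992, 0.9992)],
    )
    def test_examples(self, mass, expected):
        assert decimal_residual(mass) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("bad", [0.0, -5.0])
    def test_nonpositive_mass_rejected(self, bad):
        with pytest.raises(ValueError):
            decimal_residual(bad)


class TestTransform:
    def test_examples(self):
        assert transform_mass(2000.5, 0.5) == pytest.approx(1100.5)
        assert transform_mass(300.0, 0.0) == pytest.approx(300.0)
        # a point on the unlabeled reference line maps near the first center
        assert transform_mass(1000.0, 0.51357) == pytest.approx(75.574, abs=1e-3)

    def test_residual_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            transform_mass(1000.0, 1.0)

    def test_monotone_within_true_band(self, rng):
        b = 5.1357e-4
        masses, offsets = synthetic_line_points(b, 500, rng)
        trans = transform_mass(masses, decimal_residual(masses))
        for k in np.unique(offsets):
            sel = offsets == k
            by_mass = np.argsort(masses[sel])
            assert np.all(np.diff(trans[sel][by_mass]) >= -1e-6)


class TestClassifyBands:
    def test_nearest_center_assignment(self):
        # residuals are 0, so transformed mass = mass
        masses = [10.0, 12.0, 2005.0]
        bands = classify_bands(masses, BandConfig(centers=(0.0, 2000.0, 4000.0)))
        assert list(bands) == [0, 0, 1]

    def test_single_mass_goes_to_first_band(self):
        bands = classify_bands([450.2], BandConfig(centers=LIGHT_CENTERS))
        assert list(bands) == [0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classify_bands([], BandConfig())

    def test_empty_cluster_without_dummies_retried_with_warning(self, caplog):
        config = BandConfig(centers=LIGHT_CENTERS, add_dummy_points=False)
        with caplog.at_level("WARNING"):
            bands = classify_bands([400.0, 410.0], config)
        assert list(bands) == [0, 0]
        assert "dummy" in caplog.text

    @pytest.mark.parametrize("b", [5.0e-4, 5.7e-4, 6.5e-4])
    def test_wrap_consistency_on_exact_lines(self, b, rng):
        masses, truth = synthetic_line_points(b, 3000, rng)
        config = BandConfig(centers=centers_from_slope(b, masses.max()))
        assigned = classify_bands(masses, config)
        assert np.mean(assigned == truth) >= 0.999

    def test_light_bands_track_residual_wraps(self, reference_peptides):
        # bands overlap in mass; classification must follow the true integer
        # offset, with band centers near odd multiples of half the wrap period
        from hdpr.simulate import true_band_offsets

        masses, truth = true_band_offsets(list(reference_peptides[:3000]), 0.0)
        bands = classify_bands(masses, BandConfig(centers=LIGHT_CENTERS))
        assert np.mean(bands == truth) >= 0.995
        wrap = 1.0 / 5.1357e-4  # ~1947 Da per band for unlabeled peptides
        for k in (0, 1, 2):
            med = np.median(masses[bands == k])
            assert wrap * k < med < wrap * (k + 1)

    def test_dummy_points_do_not_change_large_set_slope(self, rng):
        b = 5.2e-4
        masses, _ = synthetic_line_points(b, 200, rng)
        fits = []
        for dummies in (True, False):
            config = BandConfig(centers=LIGHT_CENTERS, add_dummy_points=dummies)
            bands = classify_bands(masses, config)
            unwrapped = unwrap_residuals(decimal_residual(masses), bands)
            fits.append(fit_slope_ols(masses, unwrapped).b)
        assert fits[0] == pytest.approx(fits[1], abs=1e-10)

    def test_idempotent_on_unwrapped_data_with_single_center(self, rng):
        masses, truth = synthetic_line_points(5.2e-4, 200, rng)
        residuals = decimal_residual(masses)
        bands = classify_bands(masses, BandConfig(centers=(0.0,)))
        assert np.all(bands == 0)
        assert np.array_equal(unwrap_residuals(residuals, bands), residuals)

    def test_agrees_with_sklearn_kmeans(self, rng):
        from sklearn.cluster import KMeans

        masses, _ = synthetic_line_points(5.1357e-4, 1000, rng)
        trans = transform_mass(masses, decimal_residual(masses))
        ours = classify_bands(masses, BandConfig(centers=LIGHT_CENTERS, add_dummy_points=False))
        km = KMeans(
            n_clusters=3, init=np.array(LIGHT_CENTERS)[:, None], n_init=1
        ).fit(trans[:, None])
        order = np.argsort(km.cluster_centers_[:, 0])
        relabel = np.empty(3, dtype=int)
        relabel[order] = np.arange(3)
        assert np.array_equal(ours, relabel[km.labels_])


class TestUnwrap:
    @pytest.mark.parametrize("band, dr, expected", [(0, 0.4, 0.4), (2, 0.1, 2.1)])
    def test_examples(self, band, dr, expected):
        assert unwrap_residuals([dr], [band])[0] == pytest.approx(expected)

    def test_negative_band_rejected(self):
        with pytest.raises(ValueError):
            unwrap_residuals([0.5], [-1])

    def test_reference_unwrapped_ordinate_range(self, reference_peptides):
        masses = np.array([p.mass_light for p in reference_peptides])
        tab = band_table(masses, BandConfig(centers=LIGHT_CENTERS))
        # unwrapped residual ~ b*mass: stays below ~3 Da for a 6,000 Da window
        assert tab["unwrapped_residual"].max() < 3.5
        assert (tab["unwrapped_residual"] - tab["residual"]).max() >= 1


class TestBandConfig:
    def test_nonincreasing_centers_rejected(self):
        with pytest.raises(ValueError):
            BandConfig(centers=(0.0, 2000.0, 1500.0))

    def test_nonpositive_transform_constant_rejected(self):
        with pytest.raises(ValueError):
            BandConfig(transform_constant=0.0)

    def test_centers_from_slope_counts_wraps(self):
        centers = centers_from_slope(5.1357e-4, 5800.0)
        assert len(centers) == 3
        assert centers[0] == 0.0
        assert centers[1] == pytest.approx(1947.2, abs=0.1)
        assert len(centers_from_slope(6.3347e-4, 6270.0)) == 4


class TestBandUnwrapper:
    def test_transform_returns_mass_and_unwrapped_residual(self, rng):
        masses, truth = synthetic_line_points(5.2e-4, 300, rng, mass_range=(300.0, 5500.0))
        est = BandUnwrapper(centers=LIGHT_CENTERS)
        out = est.fit_transform(masses[:, None])
        assert out.shape == (300, 2)
        assert np.allclose(out[:, 0], masses)
        assert np.allclose(
            out[:, 1], decimal_residual(masses) + truth, atol=1e-12
        )

    def test_centers_derived_from_slope_guess(self, rng):
        masses, _ = synthetic_line_points(6.3e-4, 300, rng)
        est = BandUnwrapper(slope_guess=6.3e-4).fit(masses)
        assert len(est.centers_) == len(centers_from_slope(6.3e-4, masses.max()))

    def test_requires_centers_or_slope_guess(self):
        with pytest.raises(ValueError):
            BandUnwrapper().fit([500.0, 600.0])

    def test_sklearn_clone_roundtrip(self):
        est = BandUnwrapper(transform_constant=1700.0, centers=HEAVY_CENTERS)
        assert clone(est).get_params() == est.get_params()
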