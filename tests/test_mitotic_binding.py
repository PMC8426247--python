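"""The image-quantification procedure, unit-by-unit and end to end."""

import numpy as np
import pytest
from scipy import ndimage

from mitoquant.mitotic_binding import (
    AxisUndeterminedError,
    IntensityProfile,
    NoNucleusError,
    NucleusFramePair,
    estimate_interphase_diameter,
    estimate_plate_axis,
    extract_profile,
    normalize_profile,
    percent_mitotic_binding,
    quantify_lines,
    rescale_pair,
    retention_ratio,
    total_signal,
    zone_enrichment,
)
from mitoquant.simulate.embryo import EmbryoSimParams, generate_embryo_pair


def _disk_image(size=100, radius=20, value=10.0):
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2
    return np.where((xx - c) ** 2 + (yy - c) ** 2 <= radius**2, value, 0.0)


def _line(bf, seed0, n=4, noise="poisson", **kw):
    return [
        generate_embryo_pair(
            EmbryoSimParams(bound_fraction=bf, seed=seed0 + i, noise_model=noise, **kw)
        )[0]
        for i in range(n)
    ]


class TestDiameter:
    def test_noise_free_disk(self):
        d = estimate_interphase_diameter(_disk_image(radius=20))
        assert d == pytest.approx(40.0, abs=1.0)

    def test_generator_ground_truth(self):
        pair, _ = generate_embryo_pair(
            EmbryoSimParams(interphase_diameter=74, noise_model="none", seed=2)
        )
        assert estimate_interphase_diameter(pair.interphase_image) == pytest.approx(74, abs=2)

    def test_flat_image_raises(self):
        with pytest.raises(NoNucleusError):
            estimate_interphase_diameter(np.zeros((50, 50)))


class TestRescale:
    def test_identity_at_target(self):
        pair, _ = generate_embryo_pair(EmbryoSimParams(seed=1))
        out = rescale_pair(pair, 37.0, target=37.0)
        assert out is pair

    def test_halving_preserves_total(self):
        pair, _ = generate_embryo_pair(EmbryoSimParams(seed=1))
        out = rescale_pair(pair, 74.0, target=37.0)
        assert out.interphase_image.shape[0] == pytest.approx(
            pair.interphase_image.shape[0] / 2, abs=1
        )
        assert out.interphase_image.sum() == pytest.approx(
            pair.interphase_image.sum(), rel=0.01
        )

    def test_doubling(self):
        pair, _ = generate_embryo_pair(EmbryoSimParams(seed=1))
        out = rescale_pair(pair, 18.5, target=37.0)
        assert out.metaphase_image.shape[0] == pytest.approx(
            pair.metaphase_image.shape[0] * 2, abs=1
        )

    def test_invalid_diameter(self):
        pair, _ = generate_embryo_pair(EmbryoSimParams(seed=1))
        with pytest.raises(ValueError):
            rescale_pair(pair, -3.0)


class TestTotalSignal:
    def test_uniform_counts_pixels(self):
        img = np.full((60, 60), 2.0)
        total = total_signal(img, (30, 30), 10.0)
        yy, xx = np.mgrid[0:60, 0:60]
        n_px = int(((xx - 30) ** 2 + (yy - 30) ** 2 <= 25).sum())
        assert total == pytest.approx(2.0 * n_px)

    def test_zero_image(self):
        assert total_signal(np.zeros((40, 40)), (20, 20), 10.0) == 0.0

    def test_matches_per_pixel_oracle(self):
        rng = np.random.default_rng(5)
        img = rng.random((50, 50))
        cx, cy, d = 24.0, 26.0, 17.0
        brute = 0.0
        for y in range(50):
            for x in range(50):
                if (x - cx) ** 2 + (y - cy) ** 2 <= (d / 2) ** 2:
                    brute += img[y, x]
        assert total_signal(img, (cx, cy), d) == pytest.approx(brute, rel=1e-12)

    def test_out_of_bounds_disk(self):
        with pytest.raises(ValueError):
            total_signal(np.ones((30, 30)), (2, 2), 20.0)


class TestRetention:
    def test_conserving_pair_at_reference_scale(self):
        """With the nucleus generated at the 37/52 px reference geometry and
        no degradation, the measured retention is exactly 1."""
        pair, _ = generate_embryo_pair(
            EmbryoSimParams(
                image_size=80,
                interphase_diameter=37,
                metaphase_zone_diameter=52,
                psf_sigma=0.0,
                background=0.0,
                noise_model="none",
                seed=3,
            )
        )
        assert retention_ratio(pair) == pytest.approx(1.0, abs=0.02)

    def test_zero_metaphase(self):
        pair, _ = generate_embryo_pair(
            EmbryoSimParams(image_size=80, interphase_diameter=37,
                            metaphase_zone_diameter=52, psf_sigma=0.0,
                            background=0.0, noise_model="none", seed=3)
        )
        pair.metaphase_image = np.zeros_like(pair.metaphase_image)
        assert retention_ratio(pair) == 0.0

    def test_half_signal_removed(self):
        pair, _ = generate_embryo_pair(
            EmbryoSimParams(image_size=80, interphase_diameter=37,
                            metaphase_zone_diameter=52, psf_sigma=0.0,
                            background=0.0, noise_model="none", seed=4)
        )
        pair.metaphase_image = pair.metaphase_image * 0.5
        assert retention_ratio(pair) == pytest.approx(0.5, abs=0.02)


class TestPlateAxis:
    @pytest.mark.parametrize("plate_angle,expected", [(0.0, 90.0), (45.0, 135.0)])
    def test_planted_angle(self, plate_angle, expected):
        pair, _ = generate_embryo_pair(
            EmbryoSimParams(
                bound_fraction=0.7, plate_axis_angle=plate_angle,
                noise_model="none", seed=5,
            )
        )
        axis = estimate_plate_axis(pair.metaphase_image, None, 104.0)
        assert axis == pytest.approx(expected, abs=3.0)

    def test_isotropic_zone_requires_manual_axis(self):
        pair, _ = generate_embryo_pair(
            EmbryoSimParams(bound_fraction=0.0, noise_model="none", seed=6)
        )
        with pytest.raises(AxisUndeterminedError):
            estimate_plate_axis(pair.metaphase_image, None, 104.0)


class TestProfile:
    def test_uniform_image_gives_constant_profile(self):
        prof = extract_profile(np.full((80, 80), 3.5), None, 90.0)
        np.testing.assert_allclose(prof.values, 3.5, rtol=1e-9)
        assert prof.values.shape == (46,)

    def test_ridge_peaks_at_center_positions(self):
        img = np.zeros((80, 80))
        img[:, 39:41] = 5.0  # vertical ridge through the center columns
        prof = extract_profile(img, None, 0.0)  # profile along x
        # 1-based center positions 23/24 = 0-based 22/23
        assert int(np.argmax(prof.values)) in (22, 23)

    def test_rotation_equivariance(self):
        pair, _ = generate_embryo_pair(
            EmbryoSimParams(bound_fraction=0.7, plate_axis_angle=0.0,
                            noise_model="none", seed=7)
        )
        img = pair.metaphase_image
        rot = ndimage.rotate(img, -30.0, reshape=False, order=1)
        p0 = extract_profile(img, None, 90.0)
        p30 = extract_profile(rot, None, 120.0)
        scale = p0.values.max()
        np.testing.assert_allclose(p30.values / scale, p0.values / scale, atol=0.04)


class TestNormalize:
    def test_area_equals_total(self):
        prof = IntensityProfile(values=np.random.default_rng(0).random(46) + 0.1)
        out = normalize_profile(prof, 1234.5)
        assert out.values.sum() == pytest.approx(1234.5, abs=1e-9)

    def test_two_lines_scale_linearly(self):
        v = np.random.default_rng(1).random(46) + 0.1
        a = normalize_profile(IntensityProfile(values=v), 100.0)
        b = normalize_profile(IntensityProfile(values=v), 200.0)
        np.testing.assert_allclose(b.values, 2.0 * a.values, rtol=1e-12)

    def test_idempotent(self):
        prof = IntensityProfile(values=np.linspace(1, 2, 46))
        once = normalize_profile(prof, 50.0)
        twice = normalize_profile(once, 50.0)
        np.testing.assert_allclose(once.values, twice.values, rtol=1e-12)

    def test_zero_sum_rejected(self):
        with pytest.raises(ValueError):
            normalize_profile(IntensityProfile(values=np.zeros(46)), 10.0)


class TestZoneEnrichment:
    def test_flat_profile_is_zero(self):
        prof = IntensityProfile(values=np.full(46, 7.0), normalization="normalized")
        assert zone_enrichment(prof) == pytest.approx(0.0, abs=1e-12)

    def test_mass_added_in_zone_only(self):
        base = np.full(46, 2.0)
        m = 4.2
        v = base.copy()
        v[15:30] += m / 15.0  # positions 16..30, 1-based
        prof = IntensityProfile(values=v, normalization="normalized")
        assert zone_enrichment(prof) == pytest.approx(m, rel=1e-12)

    def test_planted_fraction_ratio(self):
        """Noise-free pairs with bound fractions 0.5 and 0.25: enrichment ratio 2."""

        def enrich(bf, seed):
            from mitoquant.mitotic_binding import quantify_pair

            pair, _ = generate_embryo_pair(
                EmbryoSimParams(bound_fraction=bf, noise_model="none", seed=seed)
            )
            return quantify_pair(pair).enrichment

        ratio = enrich(0.5, 8) / enrich(0.25, 8)
        assert ratio == pytest.approx(2.0, rel=0.10)


class TestPercentBinding:
    def test_reference_vs_itself_is_100(self):
        e = np.array([1.0, 1.2, 0.9, 1.1])
        res = percent_mitotic_binding(e, e)
        assert res.percent_of_reference == pytest.approx(100.0, abs=1e-9)

    def test_zero_variant_is_zero(self):
        res = percent_mitotic_binding(np.zeros(5), np.ones(5))
        assert res.percent_of_reference == 0.0

    def test_negative_mean_floored_with_warning(self):
        with pytest.warns(UserWarning):
            res = percent_mitotic_binding(np.array([-1.0, -0.5]), np.ones(3))
        assert res.percent_of_reference == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_mitotic_binding(np.ones(3), np.zeros(3))

    def test_planted_fraction_recovery(self):
        res = quantify_lines(
            {"ref": _line(0.8, 10, noise="none"), "var": _line(0.2, 20, noise="none")},
            "ref",
        )
        assert res["var"].percent_of_reference == pytest.approx(25.0, abs=5.0)


class TestLineInvariants:
    def test_scale_invariance(self):
        """Multiplying every image by a constant leaves the percentage unchanged."""
        ref = _line(0.7, 30, n=3)
        var = _line(0.35, 40, n=3)
        base = quantify_lines({"r": ref, "v": var}, "r")["v"].percent_of_reference
        for p in ref + var:
            p.interphase_image = p.interphase_image * 7.3
            p.metaphase_image = p.metaphase_image * 7.3
        scaled = quantify_lines({"r": ref, "v": var}, "r")["v"].percent_of_reference
        assert scaled == pytest.approx(base, abs=1e-6)

    def test_size_invariance_across_cycles(self):
        """The same planted fraction at cycle-11 vs cycle-13 nuclear sizes
        yields the same percentage within 10%."""
        big = dict(interphase_diameter=74, metaphase_zone_diameter=104)
        small = dict(interphase_diameter=48, metaphase_zone_diameter=67, image_size=120)
        res = quantify_lines(
            {
                "ref": _line(0.8, 50, n=3, noise="none", **big),
                "var_big": _line(0.3, 60, n=3, noise="none", **big),
                "var_small": _line(0.3, 70, n=3, noise="none", **small),
            },
            "ref",
        )
        pb = res["var_big"].percent_of_reference
        ps = res["var_small"].percent_of_reference
        assert ps == pytest.approx(pb, rel=0.10)


def test_pair_center_validation():
    with pytest.raises(ValueError):
        NucleusFramePair(
            interphase_image=np.ones((20, 20)),
            metaphase_image=np.ones((20, 20)),
            interphase_center=(25.0, 5.0),
        )
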