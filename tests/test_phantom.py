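"""Tests of the synthetic phantom and cohort generators."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from bodycomp.models import density_weighted_predictor, fit_linear
from bodycomp.phantom import (
    GT_LEGEND,
    CohortSpec,
    PhantomSpec,
    analytic_areas,
    generate_cohort,
    generate_phantom,
)
from bodycomp.segmentation import DEFAULT_THRESHOLDS

_GT_ID = {v: k for k, v in GT_LEGEND.items()}


class TestPhantomGeometry:
    def test_seed_determinism(self, small_spec, small_phantom):
        slices, masks = small_phantom
        slices2, masks2 = generate_phantom(small_spec)
        for a, b in zip(slices, slices2):
            np.testing.assert_array_equal(a.hu, b.hu)
        for a, b in zip(masks, masks2):
            np.testing.assert_array_equal(a.labels, b.labels)

    def test_zero_sat_thickness_gives_no_sat(self, small_spec):
        spec = dataclasses.replace(small_spec, sat_thickness=0.0)
        _, masks = generate_phantom(spec)
        assert (masks[0].labels == _GT_ID["sat"]).sum() == 0

    def test_translation_invariant_stack_is_constant(self, small_spec):
        spec = dataclasses.replace(small_spec, n_slices=16, translation_invariant=True)
        slices, masks = generate_phantom(spec)
        assert len(slices) == 16
        for s, m in zip(slices[1:], masks[1:]):
            np.testing.assert_array_equal(s.hu, slices[0].hu)
            np.testing.assert_array_equal(m.labels, masks[0].labels)

    def test_labels_partition_body(self, small_phantom):
        """Tissue masks are mutually exclusive and cover the body exactly."""
        _, masks = small_phantom
        labels = masks[0].labels
        body = labels > 0
        total = sum((labels == k).sum() for k in GT_LEGEND)
        assert total == body.sum()

    def test_hu_inside_threshold_windows(self, small_phantom):
        """Every sampled tissue HU lies inside its segmentation window."""
        slices, masks = small_phantom
        hu, labels = slices[0].hu, masks[0].labels
        for tissue, window in (
            ("muscle", DEFAULT_THRESHOLDS.muscle),
            ("sat", DEFAULT_THRESHOLDS.sat),
            ("vat", DEFAULT_THRESHOLDS.vat),
            ("imat", DEFAULT_THRESHOLDS.sat),
        ):
            vals = hu[labels == _GT_ID[tissue]]
            assert vals.size > 0
            assert vals.min() >= window[0] and vals.max() <= window[1]

    def test_background_is_air(self, small_phantom):
        slices, masks = small_phantom
        assert np.all(slices[0].hu[masks[0].labels == 0] == -1000.0)

    def test_sat_ring_area_matches_analytic_annulus(self, small_spec, small_phantom):
        """Pixel-counted SAT area agrees with the continuous ellipse annulus
        to within one pixel-row of discretization error."""
        _, masks = small_phantom
        px_cm2 = small_spec.pixel_spacing[0] * small_spec.pixel_spacing[1] / 100.0
        sat_cm2 = (masks[0].labels == _GT_ID["sat"]).sum() * px_cm2
        expected = analytic_areas(small_spec)["sat_ring"]
        # one pixel row along the ring perimeter, in cm²
        a, b = small_spec.body_semiaxes
        perimeter_cm = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b))) / 10.0
        tol = perimeter_cm * small_spec.pixel_spacing[0] / 10.0
        assert sat_cm2 == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize(
        "field, value",
        [
            ("sat_thickness", -1.0),
            ("visceral_fat_fraction", 1.5),
            ("pixel_spacing", (0.0, 1.0)),
            ("n_slices", 0),
        ],
    )
    def test_invalid_spec_names_field(self, small_spec, field, value):
        spec = dataclasses.replace(small_spec, **{field: value})
        with pytest.raises(ValueError, match=field.split("_")[0]):
            spec.validate()


class TestCohort:
    def test_seed_determinism(self):
        spec = CohortSpec(seed=9)
        s1, c1 = generate_cohort(spec)
        s2, c2 = generate_cohort(spec)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(c1, c2)

    def test_noise_free_roundtrip_recovers_coefficients(self, noise_free_cohort):
        """Refitting the density-weighted model on a noise-free cohort
        returns the generative slope and intercept exactly."""
        spec, (subjects, ct) = noise_free_cohort
        x = np.array(
            [
                density_weighted_predictor(w, r, f, fh).predictor
                for w, r, f, fh in zip(
                    subjects["weight"], ct["roi_mean_hu"], ct["fat_pct"], ct["fat_mean_hu"]
                )
            ]
        )
        res = fit_linear(x, subjects["dxa_fm"].to_numpy(), "density_weighted_fat")
        assert res.model.slope == pytest.approx(spec.true_m, abs=1e-9)
        assert res.model.intercept == pytest.approx(spec.true_n, abs=1e-9)

    def test_masses_physiological(self, noise_free_cohort):
        _, (subjects, ct) = noise_free_cohort
        assert (subjects["dxa_fm"] > 0).all()
        assert (subjects["dxa_fm"] < subjects["weight"]).all()
        assert np.allclose(subjects["dxa_fm"] + subjects["dxa_ffm"], subjects["weight"])
        assert np.allclose(
            ct["fat_area_cm2"], ct["body_area_cm2"] * ct["fat_pct"] / 100.0
        )

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="n_subjects"):
            CohortSpec(n_subjects=1).validate()

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            CohortSpec(weight_range=(120.0, 60.0)).validate()
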