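"""Agreement-suite tests: Pearson, Bland-Altman, error grid, QQ, summary."""

import numpy as np
import pandas as pd
import pytest

from bodycomp.agreement import (
    PairedSeries,
    bland_altman,
    error_grid,
    pearson_with_ci,
    predict_cohort,
    qq_normality,
    summarize_table2,
)


def pairs_of(est, ref):
    return PairedSeries(np.asarray(est, float), np.asarray(ref, float))


class TestPearson:
    def test_identity_gives_unity(self):
        x = [1.0, 2.0, 4.0, 8.0]
        r, _ = pearson_with_ci(pairs_of(x, x))
        assert r == pytest.approx(1.0)

    def test_anti_identity(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        r, _ = pearson_with_ci(pairs_of(x, -x))
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self, rng):
        """Sample r equals the explicit covariance-formula computation."""
        x = rng.normal(50, 10, size=25)
        y = rng.normal(0.8 * x, 5)
        r, _ = pearson_with_ci(pairs_of(x, y))
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r == pytest.approx(num / den, abs=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(x, 0.5)
        r1, _ = pearson_with_ci(pairs_of(x, y))
        r2, _ = pearson_with_ci(pairs_of(3.0 * x + 7.0, y))
        assert r2 == pytest.approx(r1, abs=1e-12)

    def test_ci_brackets_r(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(x, 1.0)
        r, (lo, hi) = pearson_with_ci(pairs_of(x, y))
        assert lo < r < hi

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_with_ci(pairs_of([1, 1, 1, 1], [1, 2, 3, 4]))


class TestBlandAltman:
    def test_identical_series(self):
        ba = bland_altman(pairs_of([1, 2, 3], [1, 2, 3]))
        assert ba.bias == 0.0
        assert (ba.loa_low, ba.loa_high) == (0.0, 0.0)

    def test_constant_offset(self):
        ba = bland_altman(pairs_of([6, 7, 8], [1, 2, 3]))
        assert ba.bias == pytest.approx(5.0)
        assert ba.loa_low == pytest.approx(5.0)
        assert ba.loa_high == pytest.approx(5.0)

    def test_hand_computed_loa(self):
        # differences {-1, 0, 1}: bias 0, SD(n-1) = 1, LoA = ±1.96
        ba = bland_altman(pairs_of([0, 2, 4], [1, 2, 3]))
        assert ba.bias == pytest.approx(0.0)
        assert ba.loa_low == pytest.approx(-1.96)
        assert ba.loa_high == pytest.approx(1.96)

    def test_loa_coverage_on_normal_differences(self, rng):
        """~95% of differences fall inside the limits of agreement."""
        ref = rng.uniform(40, 80, size=20000)
        est = ref + rng.normal(2.0, 3.0, size=ref.size)
        ba = bland_altman(pairs_of(est, ref))
        inside = (ba.diffs >= ba.loa_low) & (ba.diffs <= ba.loa_high)
        assert inside.mean() == pytest.approx(0.95, abs=0.02)


class TestErrorGrid:
    def test_all_within_first_band(self):
        ref = np.array([10.0, 20.0, 40.0])
        out = error_grid(pairs_of(ref * 1.05, ref))
        assert out == {"<10%": 1.0, "10-25%": 0.0, ">=25%": 0.0}

    def test_one_subject_per_band(self):
        ref = np.array([100.0, 100.0, 100.0])
        est = np.array([105.0, 115.0, 130.0])  # 5%, 15%, 30%
        out = error_grid(pairs_of(est, ref))
        assert out["<10%"] == pytest.approx(1 / 3)
        assert out["10-25%"] == pytest.approx(1 / 3)
        assert out[">=25%"] == pytest.approx(1 / 3)

    def test_fractions_sum_to_one(self, rng):
        ref = rng.uniform(20, 60, 50)
        est = ref * rng.uniform(0.7, 1.3, 50)
        assert sum(error_grid(pairs_of(est, ref)).values()) == pytest.approx(1.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            error_grid(pairs_of([1, 2, 3], [0, 2, 3]))


class TestQQ:
    def test_exact_normal_quantiles_give_unit_line(self):
        from scipy import stats

        n = 200
        v = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        res = qq_normality(v)
        assert res.slope == pytest.approx(1.0, abs=1e-6)
        assert res.intercept == pytest.approx(0.0, abs=1e-6)

    def test_constant_vector_degenerate(self):
        res = qq_normality([3.0, 3.0, 3.0])
        assert res.degenerate

    def test_standard_normal_sample_slope_near_one(self, rng):
        res = qq_normality(rng.standard_normal(10_000))
        assert 0.95 <= res.slope <= 1.05
        assert not res.degenerate


class TestSummaryGrid:
    def test_generative_identity_for_density_weighted_model(self, noise_free_cohort):
        """On a noise-free cohort generated by the density-weighted model,
        that model agrees with the reference perfectly."""
        _, (subjects, ct) = noise_free_cohort
        est = predict_cohort(subjects, ct)
        grid = summarize_table2(subjects, {"1 slice": est})
        row = grid[(grid.model == "focusedon") & (grid.mass == "FM")].iloc[0]
        assert row.bias == pytest.approx(0.0, abs=1e-12)
        assert row.loa_low == pytest.approx(0.0, abs=1e-12)
        assert row.loa_high == pytest.approx(0.0, abs=1e-12)

    def test_fm_ffm_biases_mirror_for_derived_ffm(self, noise_free_cohort):
        """FFM = weight − FM on both sides, so FM and FFM rows carry
        equal-magnitude, opposite-sign biases and swapped limits."""
        spec, (subjects, ct) = noise_free_cohort
        import dataclasses

        from bodycomp.phantom import generate_cohort

        noisy_spec = dataclasses.replace(spec, noise_sd=3.0, seed=21)
        subjects, ct = generate_cohort(noisy_spec)
        est = predict_cohort(subjects, ct)
        grid = summarize_table2(subjects, {"1 slice": est})
        fm = grid[(grid.model == "focusedon") & (grid.mass == "FM")].iloc[0]
        ffm = grid[(grid.model == "focusedon") & (grid.mass == "FFM")].iloc[0]
        assert ffm.bias == pytest.approx(-fm.bias)
        assert ffm.loa_low == pytest.approx(-fm.loa_high)
        assert ffm.loa_high == pytest.approx(-fm.loa_low)

    def test_derived_ffm_pearson_omitted_by_default(self, noise_free_cohort):
        _, (subjects, ct) = noise_free_cohort
        est = predict_cohort(subjects, ct)
        grid = summarize_table2(subjects, {"1 slice": est})
        row = grid[(grid.model == "focusedon") & (grid.mass == "FFM")].iloc[0]
        assert pd.isna(row.pearson)
        assert pd.isna(row.r_ci_low)

    def test_grid_schema(self, noise_free_cohort):
        _, (subjects, ct) = noise_free_cohort
        est = predict_cohort(subjects, ct)
        grid = summarize_table2(subjects, {"1 slice": est, "16 slices": est})
        assert len(grid) == 2 * 3 * 2  # modes × models × mass types
        assert set(grid.columns) >= {
            "slice_mode", "model", "mass", "pearson", "loa_low", "bias", "loa_high",
        }

    def test_missing_dxa_columns_rejected(self, noise_free_cohort):
        _, (subjects, ct) = noise_free_cohort
        est = predict_cohort(subjects, ct)
        with pytest.raises(ValueError, match="dxa"):
            summarize_table2(subjects.drop(columns=["dxa_fm"]), {"1 slice": est})
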