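"""Tests for the synthetic ADC cohort generator."""

import numpy as np
import pytest

from adcradiomics.features import build_feature_table, extract_feature_vector
from adcradiomics.io import ADCImage, ROIMask
from adcradiomics.simulate import (
    Cohort,
    CohortSpec,
    TextureParams,
    generate_cohort,
    generate_lesion_texture,
)


class TestLesionTexture:
    def test_identical_seed_identical_patch(self, tiny_spec):
        v1, m1 = generate_lesion_texture(tiny_spec, gg=4, area=200, seed=3)
        v2, m2 = generate_lesion_texture(tiny_spec, gg=4, area=200, seed=3)
        np.testing.assert_array_equal(m1, m2)
        np.testing.assert_array_equal(v1, v2)

    def test_area_below_minimum_rejected(self, tiny_spec):
        with pytest.raises(ValueError):
            generate_lesion_texture(tiny_spec, gg=2, area=4, seed=0)

    def test_high_grade_patches_have_more_uniform_local_means(self, tiny_spec):
        """Extracted mu-u is higher on average for GG>=3 patches (the
        planted between-unit mean heterogeneity of low-grade tissue)."""
        rng = np.random.default_rng(11)
        mu_u = {2: [], 4: []}
        for gg in (2, 4):
            for _ in range(25):
                values, mask = generate_lesion_texture(
                    tiny_spec, gg=gg, area=600, rng=rng
                )
                patch = np.where(mask, values, 500.0)
                img = ADCImage(np.clip(patch, 1, None), (0.78, 0.78))
                fv = extract_feature_vector(
                    img, ROIMask(np.ones(mask.shape, bool), role="gland"),
                    ROIMask(mask, role="lesion", lesion_id="x"),
                )
                mu_u[gg].append(fv["mu-u"])
        assert np.mean(mu_u[4]) > np.mean(mu_u[2])

    def test_zero_separation_makes_classes_indistinguishable(self, tiny_spec):
        spec = tiny_spec.with_separation(0.0)
        low = spec.texture_for(1)
        high = spec.texture_for(5)
        assert low == high


class TestGenerateCohort:
    def test_default_spec_counts(self):
        spec = CohortSpec(seed=3)
        assert spec.n_lesions == 117
        assert sum(n for g, n in spec.n_per_gg.items() if g < 3) == 61
        assert sum(n for g, n in spec.n_per_gg.items() if g >= 3) == 56

    def test_tiny_cohort_structure(self, tiny_cohort, tiny_spec):
        assert tiny_cohort.n_lesions == tiny_spec.n_lesions
        assert len(tiny_cohort.slices) == tiny_spec.n_patients
        gg_counts = {}
        for r in tiny_cohort.records:
            gg_counts[r.gg] = gg_counts.get(r.gg, 0) + 1
        assert gg_counts == tiny_spec.n_per_gg

    def test_lesion_areas_within_configured_range(self, tiny_cohort, tiny_spec):
        lo, hi = tiny_spec.lesion_area_range
        for sl in tiny_cohort.slices:
            for lesion, record in sl.lesions:
                assert lo <= lesion.area_px <= hi
                # lesions sit inside the gland, off one another
                assert (lesion.mask & ~sl.gland.mask).sum() == 0

    def test_lesions_do_not_overlap(self, tiny_cohort):
        for sl in tiny_cohort.slices:
            if len(sl.lesions) > 1:
                total = sum(les.mask.sum() for les, _ in sl.lesions)
                union = np.zeros_like(sl.lesions[0][0].mask)
                for les, _ in sl.lesions:
                    union |= les.mask
                assert union.sum() == total

    def test_identical_seed_reproduces_cohort(self, tiny_spec):
        a = generate_cohort(tiny_spec)
        b = generate_cohort(tiny_spec)
        np.testing.assert_array_equal(
            a.slices[0].image.pixels, b.slices[0].image.pixels
        )
        assert [r.lesion_id for r in a.records] == [r.lesion_id for r in b.records]

    def test_save_load_round_trip(self, tiny_cohort, tmp_path):
        tiny_cohort.save(tmp_path / "cohort")
        back = Cohort.load(tmp_path / "cohort")
        assert back.n_lesions == tiny_cohort.n_lesions
        orig = tiny_cohort.slices[0]
        match = next(s for s in back.slices if s.image.patient_id == orig.image.patient_id)
        # pixels round to integers on disk (16-bit TIFF)
        np.testing.assert_allclose(
            match.image.pixels, np.round(orig.image.pixels), atol=0.5
        )
        np.testing.assert_array_equal(match.gland.mask, orig.gland.mask)

    def test_rician_noise_option(self, tiny_spec):
        from dataclasses import replace

        cohort = generate_cohort(replace(tiny_spec, noise_model="rician", seed=9))
        assert all((sl.image.pixels > 0).all() for sl in cohort.slices)


class TestSeparationKnob:
    def test_zero_separation_null_classes_have_no_signal(self, tiny_spec):
        """With identical class textures downstream discrimination collapses
        (a built-in negative control for the whole pipeline)."""
        from dataclasses import replace

        from sklearn.model_selection import cross_val_score
        from sklearn.svm import SVC

        # identical textures AND identical size distributions; median over
        # three cohorts tames the small-n variance of the CV estimate
        null_aucs = []
        for seed in (9, 10, 11):
            null_spec = replace(
                tiny_spec, separation=0.0, seed=seed,
                area_params={"low": (70.0, 0.5), "high": (70.0, 0.5)},
            )
            cohort = generate_cohort(null_spec)
            table = build_feature_table(cohort.slices)
            X = (table.features - table.features.min()) / (
                table.features.max() - table.features.min() + 1e-12
            )
            aucs = cross_val_score(
                SVC(kernel="linear"), X.to_numpy(), table.y, cv=4, scoring="roc_auc"
            )
            null_aucs.append(np.mean(aucs))
        assert abs(np.median(null_aucs) - 0.5) < 0.15

    def test_separation_monotonically_increases_signal(self, tiny_spec):
        """Median cross-validated informedness rises with the class-separation
        parameter (5 seeds per level on the scaled-down cohort)."""
        from dataclasses import replace

        from sklearn.model_selection import cross_val_predict
        from sklearn.svm import SVC

        medians = []
        for sep in (0.0, 0.5, 1.0):
            infs = []
            for seed in range(5):
                cohort = generate_cohort(
                    replace(tiny_spec, separation=sep, seed=100 + seed)
                )
                table = build_feature_table(cohort.slices)
                X = (table.features - table.features.min()) / (
                    table.features.max() - table.features.min() + 1e-12
                )
                pred = cross_val_predict(
                    SVC(kernel="linear"), X.to_numpy(), table.y, cv=4
                )
                y = table.y
                sn = ((pred == 1) & (y == 1)).sum() / max((y == 1).sum(), 1)
                sp = ((pred == 0) & (y == 0)).sum() / max((y == 0).sum(), 1)
                infs.append(sn + sp - 1)
            medians.append(np.median(infs))
        assert medians[0] < medians[2]
        assert medians[0] <= medians[1] + 0.15 <= medians[2] + 0.3
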