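"""Resampled mean-pairwise-distance distributions and their invariants."""

import numpy as np
import pytest

from gestaltcohort import (
    Cohort,
    Gallery,
    SyntheticConfig,
    build_random_distribution,
    build_same_distribution,
    compute_distribution_set,
    generate_gallery,
    mean_pairwise_distance,
    pair_distance,
    resample_test_distribution,
    sample_subcohort,
)
from gestaltcohort.embeddings import ValidationError

from conftest import make_item, random_item


class TestCohort:
    def test_requires_two_subjects(self, rng):
        with pytest.raises(ValidationError):
            Cohort([random_item(rng, "a1", "A"), random_item(rng, "a2", "A")])

    def test_subject_map(self, tiny_cohort):
        assert tiny_cohort.subjects == {"A": ["a1", "a2"], "B": ["b1"]}


class TestSampleSubcohort:
    def test_one_image_per_subject(self, tiny_cohort, rng):
        for _ in range(50):
            draw = sample_subcohort(tiny_cohort, rng)
            assert len(draw) == 2
            assert not ({"a1", "a2"} <= set(draw))  # never both images of A
            assert "b1" in draw

    def test_fixed_seed_reproducible(self, tiny_cohort):
        d1 = [sample_subcohort(tiny_cohort, np.random.default_rng(3)) for _ in range(5)]
        d2 = [sample_subcohort(tiny_cohort, np.random.default_rng(3)) for _ in range(5)]
        assert d1 == d2

    def test_output_length_equals_subject_count(self, rng):
        items = [random_item(rng, f"s{k}_i", f"S{k}") for k in range(4)]
        assert len(sample_subcohort(Cohort(items), rng)) == 4


class TestMeanPairwiseDistance:
    def test_two_ids_equal_pair_distance(self, tiny_cohort):
        a, b = tiny_cohort.get("a1"), tiny_cohort.get("b1")
        assert mean_pairwise_distance(["a1", "b1"], tiny_cohort) == pytest.approx(
            pair_distance(a, b)
        )

    def test_mean_over_all_unordered_pairs(self, tiny_cohort):
        ids = ["a1", "a2", "b1"]
        pairs = [
            pair_distance(tiny_cohort.get(i), tiny_cohort.get(j))
            for i, j in [("a1", "a2"), ("a1", "b1"), ("a2", "b1")]
        ]
        assert mean_pairwise_distance(ids, tiny_cohort) == pytest.approx(np.mean(pairs))

    def test_identical_images_give_zero(self, rng):
        v = rng.standard_normal((2, 4))
        items = [make_item(f"i{k}", f"s{k}", v) for k in range(4)]
        cohort = Cohort(items)
        assert mean_pairwise_distance(cohort.ids, cohort) == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_two_ids_rejected(self, tiny_cohort):
        with pytest.raises(ValidationError):
            mean_pairwise_distance(["a1"], tiny_cohort)


class TestResampleTestDistribution:
    def test_length_and_bounds(self, tiny_cohort):
        arr = resample_test_distribution(tiny_cohort, n=100, seed=1)
        assert arr.shape == (100,)
        assert np.all((arr >= 0) & (arr <= 2))

    def test_single_image_per_subject_is_constant(self, rng):
        items = [random_item(rng, f"s{k}_i", f"S{k}") for k in range(3)]
        arr = resample_test_distribution(Cohort(items), n=20, seed=0)
        assert np.ptp(arr) == 0.0

    def test_two_seeds_differ_but_overlap(self, tiny_cohort):
        a = resample_test_distribution(tiny_cohort, n=100, seed=1)
        b = resample_test_distribution(tiny_cohort, n=100, seed=2)
        assert not np.array_equal(a, b)
        assert max(a.min(), b.min()) <= min(a.max(), b.max())  # overlapping range


class TestNullDistributions:
    def test_same_constant_for_single_pair_gallery(self, rng):
        items = [
            random_item(rng, "a", "A", label="S"),
            random_item(rng, "b", "B", label="S"),
        ]
        g = Gallery(items)
        arr = build_same_distribution(g, size=2, n=30, seed=0)
        expected = pair_distance(items[0], items[1])
        np.testing.assert_allclose(arr, expected, atol=1e-12)

    def test_no_eligible_syndrome_rejected(self, rng):
        g = Gallery([random_item(rng, "a", "A", label="S1"),
                     random_item(rng, "b", "B", label="S2")])
        with pytest.raises(ValidationError):
            build_same_distribution(g, size=2, n=10, seed=0)

    def test_random_all_identical_embeddings_give_zero(self, rng):
        v = rng.standard_normal((2, 4))
        g = Gallery([make_item(f"i{k}", f"s{k}", v, label="S") for k in range(5)])
        arr = build_random_distribution(g, size=3, n=25, seed=0)
        np.testing.assert_allclose(arr, 0.0, atol=1e-12)

    def test_lengths_and_determinism(self, small_gallery):
        for builder in (build_same_distribution, build_random_distribution):
            a = builder(small_gallery, size=4, n=100, seed=9)
            b = builder(small_gallery, size=4, n=100, seed=9)
            assert a.shape == (100,)
            assert np.array_equal(a, b)
            assert np.all((a >= 0) & (a <= 2))

    def test_same_null_tighter_than_random_null(self, small_gallery):
        same = build_same_distribution(small_gallery, size=3, n=100, seed=4)
        rand = build_random_distribution(small_gallery, size=3, n=100, seed=4)
        assert same.mean() < rand.mean()

    def test_subcohorts_never_repeat_a_subject(self, small_gallery, monkeypatch):
        # instrument the mean-pairwise hook to inspect every sampled sub-cohort
        import gestaltcohort.cohort as cohort_mod

        seen = []
        original = cohort_mod.mean_pairwise_distance

        def spy(ids, source, **kw):
            seen.append(list(ids))
            return original(ids, source, **kw)

        monkeypatch.setattr(cohort_mod, "mean_pairwise_distance", spy)
        build_same_distribution(small_gallery, size=3, n=50, seed=2)
        build_random_distribution(small_gallery, size=4, n=50, seed=2)
        assert seen
        for ids in seen:
            subjects = [small_gallery.get(i).subject_id for i in ids]
            assert len(subjects) == len(set(subjects))

    def test_median_gap_grows_with_cluster_tightness(self):
        gaps = []
        for sigma in (1.2, 0.5, 0.2):  # tighter syndromes left to right
            cfg = SyntheticConfig(
                n_syndromes=25, subjects_per_syndrome=3, images_per_subject=1,
                d=32, E=2, sigma_subject=sigma, sigma_image=0.05,
                sigma_ensemble=0.02, seed=7,
            )
            g = generate_gallery(cfg)
            same = build_same_distribution(g, size=3, n=80, seed=3)
            rand = build_random_distribution(g, size=3, n=80, seed=3)
            gaps.append(np.median(rand) - np.median(same))
        assert gaps[0] < gaps[1] < gaps[2]
        assert gaps[2] > 0


class TestDistributionSet:
    def test_cohort_images_excluded_from_nulls(self, small_gallery, small_config, monkeypatch):
        import gestaltcohort.cohort as cohort_mod

        # plant the first gallery subject's images as the "cohort"
        ids = small_gallery.subject_index["S001_P01"] + small_gallery.subject_index["S001_P02"]
        cohort = Cohort([small_gallery.get(i) for i in ids])
        pools = []
        original = cohort_mod.build_same_distribution

        def spy(gallery, *a, **kw):
            pools.append(set(gallery.ids))
            return original(gallery, *a, **kw)

        monkeypatch.setattr(cohort_mod, "build_same_distribution", spy)
        compute_distribution_set(cohort, small_gallery, n_resamples=5, seed=1)
        assert pools and not (pools[0] & set(ids))

    def test_long_format_frame(self, small_gallery, small_config):
        from gestaltcohort import generate_cohort

        cohort = generate_cohort(small_config)
        ds = compute_distribution_set(cohort, small_gallery, n_resamples=10, seed=1)
        df = ds.to_frame()
        assert list(df.columns) == ["distribution", "draw_index", "value"]
        assert df["distribution"].value_counts().to_dict() == {
            "test": 10, "same": 10, "random": 10,
        }
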