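"""Tests of catalogs, the disease-name remap, splits, episodes, augmentation."""

import numpy as np
import pytest

from leafshot.catalog import (
    AugmentConfig,
    CropDiseaseClass,
    DomainSplit,
    augment,
    center_crop,
    coffee_as_catalog,
    load_coffee_catalog,
    load_crop_disease_catalog,
    load_disease_name_catalog,
    make_domain_split,
    remap_by_disease_name,
    sample_episode,
)
from leafshot.synthetic import LAB_DOMAIN, benchmark_class_specs, generate_dataset

from conftest import make_dummy_pool


@pytest.fixture(scope="module")
def table1():
    return load_crop_disease_catalog()


class TestRemap:
    def test_merges_multi_crop_disease(self, table1):
        """Bacterial spot rows (peach, pepper, tomato) merge into one class
        with summed counts."""
        remapped = {c.disease: c for c in remap_by_disease_name(table1)}
        bact = remapped["Bacterial spot"]
        assert bact.n_train == 4337
        assert bact.n_test == 1084
        assert set(bact.affected_plants) == {"Peach", "Pepper bell", "Tomato"}

    def test_single_crop_disease_unchanged(self, table1):
        remapped = {c.disease: c for c in remap_by_disease_name(table1)}
        scab = remapped["Apple scab"]
        assert (scab.n_train, scab.n_test) == (504, 126)
        assert scab.class_id == "CD1"

    def test_twenty_disease_classes_plus_healthy(self, table1):
        remapped = remap_by_disease_name(table1)
        non_healthy = [c for c in remapped if c.disease != "Healthy"]
        assert len(non_healthy) == 20
        assert len(remapped) == 21
        assert remapped[-1].disease == "Healthy"

    def test_non_healthy_counts_conserved(self, table1):
        remapped = remap_by_disease_name(table1)
        src = sum(r.n_train for r in table1 if r.disease != "Healthy")
        dst = sum(c.n_train for c in remapped if c.disease != "Healthy")
        assert src == dst

    def test_healthy_subsampled_to_target_size(self, table1):
        remapped = remap_by_disease_name(table1, healthy_target_size=5000)
        healthy = remapped[-1]
        assert healthy.n_train + healthy.n_test == 5000
        pool_train = sum(r.n_train for r in table1 if r.disease == "Healthy")
        pool_test = sum(r.n_test for r in table1 if r.disease == "Healthy")
        assert healthy.n_train / 5000 == pytest.approx(
            pool_train / (pool_train + pool_test), abs=0.01
        )

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            remap_by_disease_name([])


class TestDomainSplit:
    def test_crop_disease_split(self, table1):
        split = make_domain_split(table1, "crop_disease")
        assert len(split.source_classes) == 32
        assert split.target_classes == tuple(f"C{i}" for i in range(1, 7))

    def test_disease_name_target_totals(self, table1):
        remapped = remap_by_disease_name(table1)
        split = make_domain_split(remapped, "disease_name")
        assert set(split.target_classes) == {"CD1", "CD4", "CD19"}
        assert len(split.source_classes) == 18
        by_id = {c.class_id: c for c in remapped}
        total = sum(by_id[i].n_total for i in split.target_classes)
        assert total == 1278

    def test_coffee_all_target(self):
        coffee = coffee_as_catalog(load_coffee_catalog())
        split = make_domain_split(coffee, "crop_disease", all_target=True)
        assert split.source_classes == ()
        assert len(split.target_classes) == 6

    def test_missing_ids_rejected(self):
        rows = [CropDiseaseClass("X1", "Apple", "Scab", 10, 2)]
        with pytest.raises(ValueError, match="class ids"):
            make_domain_split(rows, "crop_disease")

    def test_overlapping_split_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            DomainSplit(("C1", "C2"), ("C2",))


class TestPublishedTables:
    def test_printed_disease_name_table_loads(self):
        table2 = load_disease_name_catalog()
        assert len(table2) == 21
        assert table2[1].n_train == 4337  # Bacterial spot as printed

    def test_coffee_total(self):
        assert int(load_coffee_catalog()["n_samples"].sum()) == 1747


class TestSampleEpisode:
    def test_sizes_and_disjointness(self):
        pool = make_dummy_pool(3, 60)
        classes = sorted({im.disease for im in pool})
        ep = sample_episode(pool, classes, K=5, Q=50, seed=0)
        assert len(ep.support) == 15 and len(ep.query) == 150
        assert ep.C == 3 and ep.K == 5 and ep.Q == 50
        assert not set(ep.support_indices) & set(ep.query_indices)
        for ci in range(3):
            assert sum(1 for _, c in ep.support if c == ci) == 5
            assert sum(1 for _, c in ep.query if c == ci) == 50

    def test_exhaustion_covers_class_exactly_once(self):
        pool = make_dummy_pool(2, 30)
        classes = sorted({im.disease for im in pool})
        ep = sample_episode(pool, classes, K=20, Q=10, seed=1)
        used = sorted(ep.support_indices) + sorted(ep.query_indices)
        assert sorted(used) == list(range(60))

    def test_insufficient_images_names_class(self):
        pool = make_dummy_pool(2, 10)
        classes = sorted({im.disease for im in pool})
        with pytest.raises(ValueError, match="class_00"):
            sample_episode(pool, classes, K=8, Q=5, seed=0)

    def test_support_inclusion_frequency_binomial(self):
        """Over 100 seeded draws (2 classes x 60 images, K=5) every image's
        support-inclusion frequency sits within 3 standard errors of K/n,
        i.e. per-class sampling is uniform without replacement."""
        pool = make_dummy_pool(2, 60)
        classes = sorted({im.disease for im in pool})
        counts = np.zeros(len(pool))
        n_draws = 100
        for s in range(n_draws):
            ep = sample_episode(pool, classes, K=5, Q=10, seed=s)
            counts[ep.support_indices] += 1
        p = 5 / 60
        se = np.sqrt(p * (1 - p) / n_draws)
        assert (np.abs(counts / n_draws - p) <= 3 * se).all()

    def test_deterministic_given_seed(self):
        pool = make_dummy_pool(3, 20)
        classes = sorted({im.disease for im in pool})
        a = sample_episode(pool, classes, K=4, Q=4, seed=5)
        b = sample_episode(pool, classes, K=4, Q=4, seed=5)
        assert np.array_equal(a.support_indices, b.support_indices)
        assert np.array_equal(a.query_indices, b.query_indices)


@pytest.fixture(scope="module")
def leaf():
    images, _ = generate_dataset(
        benchmark_class_specs()[:1], 1, LAB_DOMAIN, 0.5, seed=2, size=64
    )
    return images[0]


class TestAugment:
    def test_identity_limit_equals_center_crop(self, leaf):
        cfg = AugmentConfig(
            p_hflip=0.0, p_vflip=0.0, rotation_range=(0.0, 0.0), jitter=0.0
        )
        out = augment(leaf, seed=0, config=cfg)
        expected = center_crop(leaf.pixels, 0.875)
        assert np.allclose(out.pixels, expected, atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_output_range_and_labels_preserved(self, leaf, seed):
        out = augment(leaf, seed=seed)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0
        assert (out.crop, out.disease, out.domain, out.split) == (
            leaf.crop, leaf.disease, leaf.domain, leaf.split,
        )

    def test_forced_hflip_is_involution(self, leaf):
        cfg = AugmentConfig(
            p_hflip=1.0, p_vflip=0.0, rotation_range=(0.0, 0.0), jitter=0.0,
            crop_fraction=1.0,
        )
        once = augment(leaf, seed=0, config=cfg)
        twice = augment(once, seed=1, config=cfg)
        assert np.allclose(twice.pixels, leaf.pixels, atol=1e-6)
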