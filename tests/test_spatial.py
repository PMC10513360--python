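import numpy as np
import pytest

from compot import (
    CompositionMatrix,
    annotation_coordinate,
    co_occurrence,
    define_regions,
    enrichment_test,
    neighborhood_zscores,
)


def _layout(rng, n=120):
    """Two spatially segregated categories on the unit square (um units)."""
    left = rng.random((n // 2, 2)) * [40, 100]
    right = rng.random((n // 2, 2)) * [40, 100] + [60, 0]
    coords = np.vstack([left, right])
    w = np.zeros((n, 2))
    w[: n // 2, 0] = 1.0
    w[n // 2 :, 1] = 1.0
    comp = CompositionMatrix(
        [f"o{i}" for i in range(n)], ["A", "B"], w, "probability"
    )
    return coords, comp


def _brute_force_cooccurrence(coords, anno_w, center_w, edges):
    n = len(coords)
    n_a, n_c = anno_w.shape[1], center_w.shape[1]
    S = np.zeros((n_a, n_c, len(edges) - 1))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.linalg.norm(coords[i] - coords[j])
            for k in range(len(edges) - 1):
                if edges[k] <= d < edges[k + 1]:
                    S[:, :, k] += np.outer(anno_w[j], center_w[i])
    with np.errstate(invalid="ignore", divide="ignore"):
        p_cond = S / S.sum(axis=0, keepdims=True)
        return p_cond / anno_w.mean(axis=0)[:, None, None]


class TestCoOccurrence:
    def test_homogeneous_annotation_ratio_one(self, rng):
        coords = rng.random((80, 2)) * 100
        w = np.tile([0.3, 0.7], (80, 1))
        comp = CompositionMatrix(
            [f"o{i}" for i in range(80)], ["A", "B"], w, "probability"
        )
        res = co_occurrence(coords, comp, bins=(0, 25, 50, 150))
        vals = res.values[~np.isnan(res.values)]
        assert np.allclose(vals, 1.0, atol=1e-9)

    def test_segregated_categories_first_bin(self, rng):
        coords, comp = _layout(rng)
        res = co_occurrence(coords, comp, bins=(0, 20, 200))
        # same-category enrichment and cross-category depletion nearby
        assert res.values[0, 0, 0] > 1 > res.values[1, 0, 0]
        assert res.values[1, 1, 0] > 1 > res.values[0, 1, 0]

    def test_matches_brute_force(self, rng):
        n = 60
        coords = rng.random((n, 2)) * 50
        anno_w = rng.dirichlet(np.ones(3), size=n)
        center_w = rng.dirichlet(np.ones(2), size=n)
        anno = CompositionMatrix(
            [f"o{i}" for i in range(n)], ["a", "b", "c"], anno_w
        )
        center = CompositionMatrix(
            [f"o{i}" for i in range(n)], ["x", "y"], center_w
        )
        edges = (0.0, 10.0, 25.0, 80.0)
        res = co_occurrence(coords, anno, center, edges)
        brute = _brute_force_cooccurrence(coords, anno_w, center_w, edges)
        assert np.allclose(res.values, brute, atol=1e-9, equal_nan=True)

    def test_empty_bin_nan(self, rng):
        coords = np.array([[0.0, 0.0], [1.0, 0.0]])
        comp = CompositionMatrix(["a", "b"], ["A"], np.ones((2, 1)))
        res = co_occurrence(coords, comp, bins=(0, 0.5, 2.0))
        assert np.isnan(res.values[0, 0, 0])
        assert np.isfinite(res.values[0, 0, 1])


class TestZScores:
    def test_identical_annotation_gives_zero(self, rng):
        coords = rng.random((50, 2)) * 100
        w = np.tile([0.5, 0.5], (50, 1))
        comp = CompositionMatrix(
            [f"o{i}" for i in range(50)], ["A", "B"], w, "probability"
        )
        z = neighborhood_zscores(coords, comp, bins=(0, 30, 100), n_perm=30, seed=0)
        assert np.allclose(z, 0.0)

    def test_colocated_pair_strongly_enriched(self, rng):
        coords, comp = _layout(rng)
        z = neighborhood_zscores(coords, comp, bins=(0, 20), n_perm=100, seed=0)
        assert z[0, 0, 0] > 3
        assert z[1, 0, 0] < -3

    def test_null_calibration(self, rng):
        # under random labels z has mean ~0, sd ~1 across instances
        zs = []
        for rep in range(40):
            coords = rng.random((40, 2)) * 100
            w = rng.dirichlet(np.ones(2), size=40)
            comp = CompositionMatrix(
                [f"o{i}" for i in range(40)], ["A", "B"], w
            )
            z = neighborhood_zscores(
                coords, comp, bins=(0, 30), n_perm=60, seed=rep
            )
            zs.append(z[0, 1, 0])  # one fixed off-diagonal entry
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.35
        assert 0.6 < zs.std() < 1.6


class TestRegions:
    def test_pure_spatial_clusters(self, rng):
        a = rng.random((40, 2)) * 10
        b = rng.random((40, 2)) * 10 + [100, 0]
        coords = np.vstack([a, b])
        feats = rng.random((80, 3))
        labels = define_regions(
            feats, coords, position_weight=1.0, k_neighbors=8, resolution=0.1, seed=0
        )
        assert len(np.unique(labels[:40])) == 1
        assert len(np.unique(labels[40:])) == 1
        assert labels[0] != labels[-1]

    def test_strata_shared_across_samples(self, rng):
        # two samples, each with the same two feature strata
        n = 40
        feats, coords, samples = [], [], []
        for s in range(2):
            f = np.zeros((n, 4))
            f[: n // 2, 0] = 1
            f[n // 2 :, 1] = 1
            f += rng.normal(0, 0.05, f.shape)
            c = rng.random((n, 2)) * 100
            c[: n // 2, 1] += 200  # strata are spatially separated too
            feats.append(f)
            coords.append(c)
            samples += [s] * n
        feats = np.vstack(feats)
        coords = np.vstack(coords)
        labels = define_regions(
            feats,
            coords,
            samples,
            position_weight=0.5,
            k_neighbors=6,
            resolution=0.3,
            seed=0,
        )
        # stratum 0 of sample 0 shares its label with stratum 0 of sample 1
        s0a = labels[: n // 2]
        s0b = labels[2 * n // 2 + n // 2 : 2 * n // 2 + n // 2]  # noqa: unused
        first_strata = np.concatenate([labels[: n // 2], labels[n : n + n // 2]])
        second_strata = np.concatenate([labels[n // 2 : n], labels[n + n // 2 :]])
        assert len(np.unique(first_strata)) == 1
        assert len(np.unique(second_strata)) == 1
        assert first_strata[0] != second_strata[0]

    def test_order_permutation_stable(self, rng):
        # separable spatial clusters: the partition is order-invariant
        coords = np.vstack(
            [rng.random((30, 2)) * 10, rng.random((30, 2)) * 10 + [80, 0]]
        )
        feats = rng.random((60, 3))
        labels = define_regions(
            feats, coords, position_weight=1.0, seed=0, k_neighbors=6, resolution=0.1
        )
        perm = rng.permutation(60)
        labels_p = define_regions(
            feats[perm],
            coords[perm],
            position_weight=1.0,
            seed=0,
            k_neighbors=6,
            resolution=0.1,
        )
        # identical partition up to label renaming
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels[perm], labels_p) == pytest.approx(1.0)


class TestAnnotationCoordinate:
    def test_noise_free_categorical_equals_min_distance(self, rng):
        coords = rng.random((60, 2)) * 100
        labels = rng.random(60) < 0.25
        w = np.column_stack([labels, ~labels]).astype(float)
        comp = CompositionMatrix(
            [f"o{i}" for i in range(60)], ["A", "B"], w
        )
        bin_width = 0.5
        d0 = annotation_coordinate(coords, comp, "A", threshold=1.0, bin_width=bin_width)
        A_idx = np.flatnonzero(labels)
        for i in range(60):
            if labels[i]:
                # an A observation is at distance 0 from category A
                assert d0[i] <= 2 * bin_width
            else:
                mind = np.min(
                    np.linalg.norm(coords[A_idx] - coords[i], axis=1)
                )
                assert abs(d0[i] - mind) <= 2 * bin_width

    def test_homogeneous_annotation_near_zero(self, rng):
        coords = rng.random((50, 2)) * 20
        comp = CompositionMatrix(
            [f"o{i}" for i in range(50)], ["A"], np.ones((50, 1))
        )
        d0 = annotation_coordinate(coords, comp, "A", threshold=2.0, bin_width=1.0)
        assert np.all(d0 < 2.0)

    def test_threshold_monotone(self, rng):
        coords = rng.random((50, 2)) * 50
        w = rng.dirichlet(np.ones(2), size=50)
        comp = CompositionMatrix([f"o{i}" for i in range(50)], ["A", "B"], w)
        d1 = annotation_coordinate(coords, comp, "A", threshold=1.0, bin_width=1.0)
        d2 = annotation_coordinate(coords, comp, "A", threshold=2.0, bin_width=1.0)
        assert np.all(d2 >= d1 - 1e-9)

    def test_unreachable_threshold_inf(self):
        coords = np.array([[0.0, 0], [1, 0], [2, 0]])
        w = np.array([[1.0, 0], [0, 1], [0, 1]])
        comp = CompositionMatrix(["a", "b", "c"], ["A", "B"], w)
        d0 = annotation_coordinate(coords, comp, "A", threshold=2.0, bin_width=0.5)
        assert np.isinf(d0).all()

    def test_noise_stability(self, rng):
        # 5% annotation noise moves the median coordinate by < bin_width
        coords = rng.random((100, 2)) * 100
        labels = coords[:, 0] < 30
        w = np.column_stack([labels, ~labels]).astype(float)
        comp = CompositionMatrix([f"o{i}" for i in range(100)], ["A", "B"], w)
        noisy = w * 0.95 + 0.05 * rng.dirichlet(np.ones(2), size=100)
        noisy /= noisy.sum(axis=1, keepdims=True)
        comp_n = CompositionMatrix(comp.obs_ids, ["A", "B"], noisy)
        bw = 2.0
        d_clean = annotation_coordinate(coords, comp, "A", 2.0, bw)
        d_noisy = annotation_coordinate(coords, comp_n, "A", 2.0, bw)
        assert abs(np.median(d_clean) - np.median(d_noisy)) < bw


class TestRigidMotionInvariance:
    def test_cooccurrence_invariant(self, rng):
        coords, comp = _layout(rng, n=60)
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = coords @ R.T + [123.0, -45.0]
        a = co_occurrence(coords, comp, bins=(0, 20, 100))
        b = co_occurrence(moved, comp, bins=(0, 20, 100))
        assert np.allclose(a.values, b.values, equal_nan=True, atol=1e-9)


class TestEnrichment:
    def test_identical_units_p_one(self):
        n_units = 8
        w = np.tile([0.5, 0.5], (80, 1))
        comp = CompositionMatrix(
            [f"o{i}" for i in range(80)], ["A", "B"], w
        )
        samples = np.repeat(np.arange(n_units), 10)
        groups = np.repeat(["g1", "g2"], 40)
        res = enrichment_test(comp, groups, samples)
        assert np.allclose(res["pvalue"], 1.0)
        assert np.allclose(res["effect_log2"], 0.0)

    def test_planted_enrichment_detected(self):
        # 2x enrichment of category A in one group, 10 units per group
        rng = np.random.default_rng(0)
        detected, spurious = 0, 0
        for rep in range(30):
            units = []
            groups = []
            weights = []
            for u in range(20):
                g = "hi" if u < 10 else "lo"
                base = np.array([0.4, 0.3, 0.3]) if g == "hi" else np.array(
                    [0.2, 0.4, 0.4]
                )
                for _ in range(5):
                    w = base * rng.normal(1, 0.1, 3)
                    w = np.clip(w, 1e-3, None)
                    weights.append(w / w.sum())
                    units.append(u)
                    groups.append(g)
            comp = CompositionMatrix(
                [f"o{i}" for i in range(100)],
                ["A", "B", "C"],
                np.array(weights),
            )
            res = enrichment_test(comp, groups, units).set_index("category")
            if res.loc["A", "qvalue"] < 0.05:
                detected += 1
        assert detected >= 27  # >= 90 percent power

    def test_too_few_units_nan(self):
        w = np.tile([0.5, 0.5], (4, 1))
        comp = CompositionMatrix([f"o{i}" for i in range(4)], ["A", "B"], w)
        with pytest.warns(UserWarning):
            res = enrichment_test(
                comp, ["g1", "g1", "g1", "g2"], ["s1", "s1", "s2", "s3"]
            )
        assert res["pvalue"].isna().all()

    def test_spatial_splitting_creates_units(self, rng):
        coords = rng.random((100, 2)) * 100
        w = rng.dirichlet(np.ones(2), size=100)
        comp = CompositionMatrix([f"o{i}" for i in range(100)], ["A", "B"], w)
        groups = np.where(coords[:, 0] < 50, "left", "right")
        samples = np.zeros(100, dtype=int)
        res = enrichment_test(
            comp, groups, samples, n_splits_per_axis=3, positions=coords
        )
        assert res["pvalue"].notna().all()
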