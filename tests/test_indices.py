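import numpy as np
import pytest
from sklearn.metrics import calinski_harabasz_score, silhouette_samples

from dricluster.blockdkm import fit
from dricluster.indices import (
    IndexCurve,
    clustering_accuracy,
    deviation_ratio,
    dri_curve,
    msv,
    sdb,
    sdw,
    select_k,
    silhouette,
    vrc,
)
from dricluster.proximity import (
    DistanceSpec,
    MedoidDistances,
    distances_to_medoids,
    pairwise_distances,
)
from .conftest import make_numeric_table, random_numeric_table

EUCL = DistanceSpec(method="euclidean")


def _fixture_solution(env_table):
    res = fit(env_table, 3, EUCL)
    md = distances_to_medoids(env_table, res.medoids, EUCL)
    return res, md


class TestDeviationSums:
    def test_fixture_sdw(self, env_table):
        res, md = _fixture_solution(env_table)
        assert sdw(md, res.labels) == pytest.approx(6.71, abs=0.05)

    def test_fixture_sdb_near_published(self, env_table):
        # 47.03 from the 2-dp table values; the published 46.9 was summed
        # from unrounded distances
        res, md = _fixture_solution(env_table)
        assert sdb(md, res.labels) == pytest.approx(46.9, abs=0.2)

    def test_sdw_is_sum_of_min_distances_here(self, env_table):
        # at a converged solution every object sits with its nearest medoid
        res, md = _fixture_solution(env_table)
        assert sdw(md, res.labels) == pytest.approx(md.matrix.min(axis=1).sum())

    def test_sdw_zero_at_k_equals_n(self, rng):
        t = random_numeric_table(rng, 5, 2)
        md = distances_to_medoids(t, range(5), EUCL)
        assert sdw(md, np.arange(1, 6)) == 0.0

    def test_sdb_k2_identity(self, rng):
        # at k=2, SDB = total of both medoid columns minus SDW
        t = random_numeric_table(rng, 10, 3)
        res = fit(t, 2, EUCL)
        md = distances_to_medoids(t, res.medoids, EUCL)
        assert sdb(md, res.labels) == pytest.approx(
            md.matrix.sum() - sdw(md, res.labels)
        )

    def test_sdb_rejects_k1(self, rng):
        t = random_numeric_table(rng, 4, 2)
        md = distances_to_medoids(t, [0], EUCL)
        with pytest.raises(ValueError):
            sdb(md, np.ones(4, dtype=int))


class TestDeviationRatio:
    def test_fixture_value(self, env_table):
        res, md = _fixture_solution(env_table)
        dr = deviation_ratio(sdw(md, res.labels), sdb(md, res.labels), 25, 3)
        assert dr == pytest.approx(0.013, abs=0.0005)

    def test_perfect_separation_gives_zero(self):
        assert deviation_ratio(0.0, 10.0, 9, 3) == 0.0

    def test_balanced_cancellation(self):
        # n = 2k-1 makes (n-k) = (k-1), so SDW=SDB gives exactly 1
        assert deviation_ratio(7.3, 7.3, 9, 5) == pytest.approx(1.0)

    def test_zero_sdb_rejected(self):
        with pytest.raises(ValueError):
            deviation_ratio(1.0, 0.0, 10, 2)

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            deviation_ratio(1.0, 1.0, 10, 1)
        with pytest.raises(ValueError):
            deviation_ratio(1.0, 1.0, 10, 10)


def _curve_from_dri(dri_map):
    ks = tuple(sorted(dri_map))
    m = len(ks)
    dri = np.array([dri_map[k] for k in ks], dtype=float)
    fake = np.full(m, np.nan)
    return IndexCurve(ks=ks, sdw=fake, sdb=fake, dr=fake, dri=dri,
                      vrc=fake, silhouette=fake, msv=fake, results=())


class TestSelection:
    def test_first_k_below_one(self):
        sel = select_k(_curve_from_dri({2: 1.3, 3: 0.8, 4: 0.5}))
        assert sel.k == 3

    def test_none_in_range(self):
        sel = select_k(_curve_from_dri({2: 1.2, 3: 1.1, 4: 1.0}))
        assert sel.k is None and not sel.found

    def test_fixture_selects_three_groups(self, env_table):
        curve = dri_curve(env_table, EUCL)
        assert curve.dri[0] >= 1.0  # two groups rejected
        assert curve.dri[1] < 1.0
        assert select_k(curve, "dri").k == 3

    def test_early_stop_matches_full_scan_on_fixture(self, env_table):
        full = select_k(dri_curve(env_table, EUCL))
        early = select_k(dri_curve(env_table, EUCL, early_stop=True))
        assert early.k == full.k

    def test_unknown_rule(self, env_table):
        with pytest.raises(ValueError):
            select_k(dri_curve(env_table, EUCL, k_max=3), rule="gap")


class TestCurveInvariants:
    def test_dri_is_ratio_of_consecutive_dr(self, env_table):
        curve = dri_curve(env_table, EUCL)
        np.testing.assert_allclose(curve.dri[:-1], curve.dr[:-1] / curve.dr[1:])
        assert np.isnan(curve.dri[-1])

    def test_dri_below_one_iff_dr_increases(self, rng):
        t = random_numeric_table(rng, 40, 3)
        curve = dri_curve(t, EUCL, k_max=8, compute_comparators=False)
        for i in range(len(curve.ks) - 1):
            assert (curve.dri[i] < 1) == (curve.dr[i] < curve.dr[i + 1])

    def test_dr_recomputable_from_results(self, rng):
        t = random_numeric_table(rng, 30, 4)
        d = pairwise_distances(t, EUCL)
        curve = dri_curve(t, EUCL, k_max=6, compute_comparators=False)
        for i, k in enumerate(curve.ks):
            res = curve.results[i]
            md = MedoidDistances(matrix=d[:, np.asarray(res.medoids)],
                                 medoids=res.medoids)
            s_w, s_b = sdw(md, res.labels), sdb(md, res.labels)
            assert deviation_ratio(s_w, s_b, 30, k) == pytest.approx(
                curve.dr[i], abs=1e-12
            )


class TestVRC:
    def test_closed_form_equivalence_small_instance(self, rng):
        # VRC from the BGSS/WGSS sums equals the closed form
        # (db + A_k (n-k)/(k-1)) / (db - A_k) on explicit pairwise loops
        t = random_numeric_table(rng, 8, 2)
        labels = np.array([1, 1, 1, 2, 2, 2, 3, 3])
        d = pairwise_distances(t, EUCL)
        n, k = 8, 3
        sq = d**2
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        db = np.mean([sq[i, j] for i, j in pairs])
        db_g, sizes = {}, {}
        for g in (1, 2, 3):
            m = np.flatnonzero(labels == g)
            sizes[g] = m.size
            gp = [(i, j) for i in m for j in m if i < j]
            db_g[g] = np.mean([sq[i, j] for i, j in gp])
        a_k = sum((sizes[g] - 1) * (db - db_g[g]) for g in (1, 2, 3)) / (n - k)
        closed = (db + a_k * (n - k) / (k - 1)) / (db - a_k)
        assert vrc(d, labels) == pytest.approx(closed)

    def test_matches_classical_ch_for_squared_euclidean(self, rng):
        # with squared Euclidean dissimilarities the distance-based VRC
        # coincides with the classical variance-ratio (Calinski-Harabasz)
        x = rng.random((20, 3))
        labels = np.array([1] * 7 + [2] * 6 + [3] * 7)
        t = make_numeric_table(x)
        d = pairwise_distances(t, EUCL)
        assert vrc(d, labels) == pytest.approx(
            calinski_harabasz_score(x, labels)
        )

    def test_two_tight_far_clusters_large(self):
        x = np.vstack([np.zeros((5, 2)) + [[0, 0]], np.zeros((5, 2)) + [[100, 0]]])
        x += np.random.default_rng(0).normal(0, 0.01, x.shape)
        d = pairwise_distances(make_numeric_table(x), EUCL)
        labels = np.array([1] * 5 + [2] * 5)
        assert vrc(d, labels) > 1e4

    def test_zero_within_is_perfect_separation(self):
        x = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        d = pairwise_distances(make_numeric_table(x), EUCL)
        assert vrc(d, np.array([1, 1, 2, 2])) == np.inf

    def test_n_equals_k_rejected(self):
        d = pairwise_distances(make_numeric_table(np.eye(3)), EUCL)
        with pytest.raises(ValueError):
            vrc(d, np.array([1, 2, 3]))


class TestSilhouette:
    def test_matches_bruteforce_and_sklearn(self, rng):
        t = random_numeric_table(rng, 12, 3)
        labels = np.array([1] * 4 + [2] * 4 + [3] * 4)
        d = pairwise_distances(t, EUCL)
        s, _mean = silhouette(d, labels)
        # brute force by explicit loops
        for i in range(12):
            own = [j for j in range(12) if labels[j] == labels[i] and j != i]
            a = np.mean([d[i, j] for j in own])
            b = min(
                np.mean([d[i, j] for j in range(12) if labels[j] == g])
                for g in (1, 2, 3)
                if g != labels[i]
            )
            assert s[i] == pytest.approx((b - a) / max(a, b))
        np.testing.assert_allclose(s, silhouette_samples(d, labels,
                                                         metric="precomputed"))

    def test_separated_clusters_near_one(self):
        x = np.vstack([np.random.default_rng(1).normal(0, 0.01, (6, 2)),
                       np.random.default_rng(2).normal(50, 0.01, (6, 2))])
        d = pairwise_distances(make_numeric_table(x), EUCL)
        _, mean = silhouette(d, np.array([1] * 6 + [2] * 6))
        assert mean > 0.99

    def test_singleton_cluster_is_zero(self):
        x = np.array([[0.0], [1.0], [10.0]])
        d = pairwise_distances(make_numeric_table(x), EUCL)
        s, _ = silhouette(d, np.array([1, 1, 2]))
        assert s[2] == 0.0

    def test_bounds(self, rng):
        t = random_numeric_table(rng, 15, 2)
        d = pairwise_distances(t, EUCL)
        labels = rng.integers(1, 4, 15)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(1, 4, 15)
        s, mean = silhouette(d, labels)
        assert (s >= -1).all() and (s <= 1).all()
        assert -1 <= mean <= 1


class TestMSV:
    def test_object_on_its_medoid(self, env_table):
        res, md = _fixture_solution(env_table)
        vals, _ = msv(md, res.labels)
        for i in md.medoids:
            assert vals[i] == pytest.approx(1.0)

    def test_equidistant_is_zero(self):
        t = make_numeric_table(np.array([[0.0], [2.0], [1.0]]))
        md = distances_to_medoids(t, [0, 1], EUCL)
        vals, _ = msv(md)
        assert vals[2] == 0.0

    def test_coincident_medoids_defined_as_zero(self):
        t = make_numeric_table(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]))
        md = distances_to_medoids(t, [0, 1], EUCL)
        vals, _ = msv(md)
        assert vals[0] == 0.0 and vals[1] == 0.0

    def test_matches_bruteforce_two_smallest(self, rng):
        t = random_numeric_table(rng, 10, 3)
        md = distances_to_medoids(t, [0, 4, 7], EUCL)
        vals, mean = msv(md)
        for i in range(10):
            d1, d2 = sorted(md.matrix[i])[:2]
            assert vals[i] == pytest.approx((d2 - d1) / d2)
        assert (vals >= 0).all() and (vals <= 1).all()
        assert mean == pytest.approx(vals.mean())


class TestClusteringAccuracy:
    def test_perfect_and_permuted(self):
        truth = np.array([1, 1, 2, 2, 3, 3])
        assert clustering_accuracy(truth, truth) == 1.0
        relabelled = np.array([3, 3, 1, 1, 2, 2])
        assert clustering_accuracy(relabelled, truth) == 1.0

    def test_contingency_example(self):
        # 2x2 contingency {{40,10},{5,45}} -> best mapping scores 85/100
        truth = np.repeat([1, 2], [50, 50])
        pred = np.concatenate(
            [np.repeat([1, 2], [40, 10]), np.repeat([1, 2], [5, 45])]
        )
        assert clustering_accuracy(pred, truth) == pytest.approx(0.85)

    def test_relabelling_invariance(self, rng):
        truth = rng.integers(1, 4, 30)
        pred = rng.integers(1, 4, 30)
        base = clustering_accuracy(pred, truth)
        mapping = {1: 7, 2: 5, 3: 9}
        remapped = np.array([mapping[int(g)] for g in pred])
        assert clustering_accuracy(remapped, truth) == pytest.approx(base)
        assert 1 / 30 <= base <= 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            clustering_accuracy([1, 2], [1, 2, 3])
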