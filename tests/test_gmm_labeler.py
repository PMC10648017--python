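"""Mixture fitting, information criteria, merging, filtering, DB ranking."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal
from sklearn.metrics import davies_bouldin_score

from forestseg import gmm_labeler as gl
from forestseg import synthetic_scene as ss
from forestseg.gmm_labeler import BinaryMask, ClusterMap, GmmModel, MergeRule


def _model(means, covs=None, weights=None, seed=0):
    means = np.asarray(means, dtype=np.float64)
    K = len(means)
    covs = np.stack([np.eye(4)] * K) if covs is None else np.asarray(covs, float)
    weights = np.full(K, 1.0 / K) if weights is None else np.asarray(weights, float)
    return GmmModel(K=K, weights=weights, means=means, covariances=covs,
                    covariance_type="full", seed=seed, converged=True)


class TestFitGmm:
    def test_single_component_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(50, 5, size=(400, 4))
        model = gl.fit_gmm(x, K=1, seed=0)
        np.testing.assert_allclose(model.means[0], x.mean(axis=0), atol=1e-6)
        biased_cov = np.cov(x.T, bias=True)
        np.testing.assert_allclose(model.covariances[0], biased_cov, atol=1e-4)

    def test_two_blob_recovery(self):
        rng = np.random.default_rng(1)
        a = rng.normal(20, 1, size=(300, 4))
        b = rng.normal(80, 1, size=(300, 4))
        model = gl.fit_gmm(np.vstack([a, b]), K=2, seed=0)
        got = np.sort(model.means[:, 0])
        assert abs(got[0] - 20) < 1 and abs(got[1] - 80) < 1

    def test_em_loglik_nondecreasing(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, size=(500, 4)) + rng.integers(0, 2, (500, 1)) * 30
        model = gl.fit_gmm(x, K=3, seed=0, max_iter=50)
        traj = np.array(model.log_likelihood_trajectory)
        assert len(traj) >= 2
        assert np.all(np.diff(traj) >= -1e-6)

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 10, size=(300, 4))
        m1 = gl.fit_gmm(x, K=3, seed=5)
        m2 = gl.fit_gmm(x, K=3, seed=5)
        np.testing.assert_array_equal(m1.means, m2.means)

    def test_too_few_samples(self):
        with pytest.raises(gl.InputError):
            gl.fit_gmm(np.zeros((2, 4)), K=3)


class TestInformationCriteria:
    @pytest.mark.parametrize("logL,k,N,aic,bic", [
        (0.0, 0, 1, 0.0, 0.0),
        (-100.0, 59, 1, 318.0, 200.0),  # ln 1 = 0
    ])
    def test_closed_form(self, logL, k, N, aic, bic):
        got_aic, got_bic = gl.aic_bic(logL, k, N)
        assert got_aic == pytest.approx(aic)
        assert got_bic == pytest.approx(bic)

    def test_bic_minus_aic_identity(self):
        rng = np.random.default_rng(4)
        x = rng.normal(60, 10, size=(200, 4))
        for K in (1, 2, 3):
            model = gl.fit_gmm(x, K=K, seed=0, max_iter=20)
            logL, k, aic, bic = gl.information_criteria(model, x)
            assert bic - aic == pytest.approx(k * (np.log(len(x)) - 2), rel=1e-12)

    def test_single_component_loglik_vs_bruteforce(self):
        rng = np.random.default_rng(5)
        x = rng.normal(30, 8, size=(100, 4))
        model = gl.fit_gmm(x, K=1, seed=0)
        logL, _, _, _ = gl.information_criteria(model, x)
        oracle = multivariate_normal(model.means[0], model.covariances[0])
        assert logL == pytest.approx(np.sum(oracle.logpdf(x)), rel=1e-10)

    def test_mixture_loglik_vs_bruteforce_on_scene(self):
        img, _ = ss.generate_scene(ss.default_spec(32, seed=6))
        x = img.flat_pixels()
        model = gl.fit_gmm(x, K=3, seed=0, max_iter=30)
        # brute-force density summation per pixel
        dens = np.zeros(len(x))
        for w, mu, cov in zip(model.weights, model.means, model.covariances):
            dens += w * multivariate_normal(mu, cov).pdf(x)
        assert model.log_likelihood(x) == pytest.approx(np.sum(np.log(dens)),
                                                        rel=1e-6)

    def test_empty_pixels(self):
        model = _model([[0, 0, 0, 0]])
        with pytest.raises(gl.InputError):
            gl.information_criteria(model, np.empty((0, 4)))


class TestNFreeParams:
    @pytest.mark.parametrize("K,cov,expected", [
        (1, "full", 14),
        (4, "full", 59),
        (10, "diagonal", 89),
    ])
    def test_values(self, K, cov, expected):
        assert gl.n_free_params(K, d=4, covariance_type=cov) == expected

    def test_strictly_increasing_in_k(self):
        vals = [gl.n_free_params(K) for K in range(1, 11)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestRegressionLogLikelihood:
    def test_matches_formula(self):
        y = np.array([1.0, 2.0, 3.0])
        y_hat = np.array([1.5, 1.5, 2.0])
        s2 = 2.0
        expected = (-1.5 * np.log(2 * np.pi) - 1.5 * np.log(s2)
                    - ((0.5**2) + (0.5**2) + 1.0) / (2 * s2))
        assert gl.regression_log_likelihood(y, y_hat, s2) == pytest.approx(expected)


class TestScanAndElbow:
    def test_single_point_scan(self):
        img, _ = ss.generate_scene(ss.two_class_spec(48, seed=0))
        scan = gl.scan_k(img, 2, 2, seed=0, max_iter=30)
        assert len(scan.rows) == 1 and scan.rows[0][0] == 2

    def test_scan_k_rows_increasing_params(self):
        img, _ = ss.generate_scene(ss.two_class_spec(48, seed=1))
        scan = gl.scan_k(img, 2, 5, seed=0, max_iter=20)
        ks = [r[2] for r in scan.rows]
        assert all(b > a for a, b in zip(ks, ks[1:]))

    def test_four_class_scene_bic_minimum_region(self):
        img, _ = ss.generate_scene(ss.four_class_spec(96, seed=2))
        scan = gl.scan_k(img, 2, 5, seed=0, max_fit_pixels=6000)
        bic = {r[0]: r[4] for r in scan.rows}
        assert bic[4] < bic[2] and bic[4] < bic[3]

    def test_elbow_textbook_curve(self):
        rows = [(K, 0.0, K, float(v), float(v))
                for K, v in zip(range(2, 7), (1000, 400, 390, 385, 383))]
        scan = gl.CriterionScan(rows=rows)
        assert gl.select_k_elbow(scan, "BIC") == 3

    def test_elbow_linear_curve_tie_break(self):
        rows = [(K, 0.0, K, 1000.0 - 100 * K, 1000.0 - 100 * K)
                for K in range(2, 7)]
        scan = gl.CriterionScan(rows=rows)
        assert gl.select_k_elbow(scan, "AIC") == 3  # smallest interior K

    def test_elbow_needs_three_rows(self):
        scan = gl.CriterionScan(rows=[(2, 0, 2, 1.0, 1.0), (3, 0, 3, 0.5, 0.5)])
        with pytest.raises(gl.SelectionError):
            gl.select_k_elbow(scan)

    def test_manual_override(self):
        scan = gl.CriterionScan(rows=[])
        assert gl.select_k_elbow(scan, override=4) == 4

    def test_scan_csv_header(self):
        rows = [(2, -1.5, 29, 60.0, 70.0)]
        assert gl.CriterionScan(rows=rows).to_csv().splitlines()[0] == \
            "K,logL,k,AIC,BIC"


class TestPredictClusters:
    def test_pixel_at_component_mean(self):
        model = _model([[10, 10, 10, 10], [200, 200, 200, 200]])
        img = np.full((2, 2, 4), 200, dtype=np.uint8)
        cmap = gl.predict_clusters(model, img)
        assert np.all(cmap.labels == 1)

    def test_equidistant_tie_goes_to_lowest_index(self):
        model = _model([[10, 10, 10, 10], [20, 20, 20, 20]])
        img = np.full((1, 1, 4), 15, dtype=np.uint8)
        cmap = gl.predict_clusters(model, img)
        assert cmap.labels[0, 0] == 0

    def test_agreement_with_bruteforce_posterior(self):
        img, _ = ss.generate_scene(ss.default_spec(32, seed=8))
        x = img.flat_pixels()
        model = gl.fit_gmm(x, K=4, seed=0, max_iter=40)
        cmap = gl.predict_clusters(model, img)
        post = np.zeros((len(x), model.K))
        for k in range(model.K):
            post[:, k] = model.weights[k] * multivariate_normal(
                model.means[k], model.covariances[k]).pdf(x)
        np.testing.assert_array_equal(cmap.labels.ravel(), np.argmax(post, axis=1))


class TestMerging:
    def test_interleaved_shadow_merged(self):
        # component 0: lit forest (bright NIR); 1: darker shadow, checkerboard
        model = _model([[60, 80, 50, 180], [20, 30, 15, 80]])
        yy, xx = np.mgrid[0:8, 0:8]
        labels = ((yy + xx) % 2).astype(int)
        rule = gl.auto_merge_rule(model, ClusterMap(labels=labels, K=2))
        assert rule.forest_components == {0, 1}

    def test_disjoint_cluster_not_merged(self):
        model = _model([[60, 80, 50, 180], [20, 30, 15, 80]])
        labels = np.zeros((20, 40), dtype=int)
        labels[:, 20:] = 1  # single straight boundary: adjacency 20/400 < 0.1
        rule = gl.auto_merge_rule(model, ClusterMap(labels=labels, K=2))
        assert rule.forest_components == {0}

    def test_brighter_cluster_never_merged(self):
        # component 1 is adjacent everywhere but brighter than the seed
        model = _model([[60, 80, 50, 180], [200, 200, 200, 90]])
        yy, xx = np.mgrid[0:8, 0:8]
        labels = ((yy + xx) % 2).astype(int)
        rule = gl.auto_merge_rule(model, ClusterMap(labels=labels, K=2))
        assert rule.forest_components == {0}

    def test_manual_rule_passthrough(self):
        rule = MergeRule(forest_components={0, 2}, rationale="manual")
        assert rule.forest_components == {0, 2}
        assert rule.rationale == "manual"

    def test_apply_merge_all_components_warns(self):
        cmap = ClusterMap(labels=np.zeros((3, 3), int), K=1)
        with pytest.warns(UserWarning):
            mask = gl.apply_merge(cmap, MergeRule({0}, "manual"))
        assert mask.mask.all()

    def test_apply_merge_counting_identity(self):
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 4, (16, 16))
        cmap = ClusterMap(labels=labels, K=4)
        rule = MergeRule({1, 3}, "manual")
        mask = gl.apply_merge(cmap, rule)
        assert mask.mask.sum() == np.isin(labels, [1, 3]).sum()

    def test_apply_merge_out_of_range(self):
        cmap = ClusterMap(labels=np.zeros((2, 2), int), K=2)
        with pytest.raises(gl.RuleError):
            gl.apply_merge(cmap, MergeRule({5}, "manual"))


class TestPostprocess:
    def test_constant_mask_unchanged(self):
        mask = BinaryMask(np.ones((32, 32), np.uint8))
        out = gl.postprocess_mask(mask)
        assert out.mask.all()

    def test_isolated_pixel_removed_by_median(self):
        m = np.zeros((21, 21), np.uint8)
        m[10, 10] = 1
        out = gl.postprocess_mask(BinaryMask(m), median_size=9, closing_size=1)
        assert not out.mask.any()

    def test_small_hole_closed(self):
        m = np.ones((31, 31), np.uint8)
        m[14:17, 14:17] = 0  # 3×3 withered-tree void
        out = gl.postprocess_mask(BinaryMask(m), median_size=1, closing_size=9)
        assert out.mask.all()

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            gl.postprocess_mask(BinaryMask(np.ones((4, 4), np.uint8)),
                                median_size=4)


class TestDaviesBouldin:
    def test_zero_dispersion(self):
        pixels = np.array([[0, 0, 0, 0], [0, 0, 0, 0], [5, 0, 0, 0], [5, 0, 0, 0]],
                          dtype=float)
        mask = BinaryMask(np.array([[0, 0], [1, 1]], np.uint8))
        assert gl.davies_bouldin(pixels, mask) == pytest.approx(0.0)

    def test_hand_computed_case(self):
        pixels = np.array([[0, 0, 0, 0], [2, 0, 0, 0],
                           [10, 0, 0, 0], [12, 0, 0, 0]], dtype=float)
        mask = BinaryMask(np.array([[0, 0], [1, 1]], np.uint8))
        # centers 1 and 11, dispersions 1 and 1 → (1+1)/10
        assert gl.davies_bouldin(pixels, mask) == pytest.approx(0.2)

    def test_scale_invariance(self):
        rng = np.random.default_rng(10)
        pixels = rng.normal(50, 5, size=(64, 4))
        mask = BinaryMask(rng.integers(0, 2, (8, 8)).astype(np.uint8))
        db1 = gl.davies_bouldin(pixels, mask)
        db2 = gl.davies_bouldin(pixels * 7.3, mask)
        assert db1 == pytest.approx(db2, rel=1e-12)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(11)
        pixels = rng.normal(50, 5, size=(64, 4))
        labels = rng.integers(0, 2, (8, 8)).astype(np.uint8)
        db1 = gl.davies_bouldin(pixels, BinaryMask(labels))
        db2 = gl.davies_bouldin(pixels, BinaryMask(1 - labels))
        assert db1 == pytest.approx(db2, rel=1e-12)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(12)
        pixels = np.vstack([rng.normal(10, 2, (40, 4)), rng.normal(60, 3, (40, 4))])
        labels = np.repeat([0, 1], 40).astype(np.uint8)
        mask = BinaryMask(labels.reshape(8, 10))
        assert gl.davies_bouldin(pixels, mask) == pytest.approx(
            davies_bouldin_score(pixels, labels), rel=1e-10)

    def test_single_class_invalid(self):
        pixels = np.zeros((4, 4))
        with pytest.raises(gl.ValidityError):
            gl.davies_bouldin(pixels, BinaryMask(np.ones((2, 2), np.uint8)))


class TestRankAndSelect:
    def _items(self, dbs):
        """Build two-cluster items whose DB index is dispersion/10."""
        items = []
        for i, db in enumerate(dbs):
            half = db * 10 / 2  # dispersion per class
            pixels = np.array([[0 - half, 0, 0, 0], [0 + half, 0, 0, 0],
                               [10 - half, 0, 0, 0], [10 + half, 0, 0, 0]])
            mask = BinaryMask(np.array([[0, 0], [1, 1]], np.uint8))
            items.append((f"img{i}", pixels, mask))
        return items

    def test_sorted_selection(self):
        ranking = gl.rank_and_select(self._items([0.5, 0.2, 0.9]), top_n=2)
        assert ranking.selected == ["img1", "img0"]
        dbs = [d for _, d in ranking.entries]
        assert dbs == sorted(dbs)

    def test_all_selected_boundary(self):
        ranking = gl.rank_and_select(self._items([0.3, 0.1]), top_n=2)
        assert set(ranking.selected) == {"img0", "img1"}

    def test_insufficient_valid_items(self):
        items = self._items([0.5])
        items.append(("bad", np.zeros((4, 4)),
                      BinaryMask(np.zeros((2, 2), np.uint8))))
        with pytest.raises(gl.SelectionError):
            gl.rank_and_select(items, top_n=2)

    def test_csv_marks_selected(self):
        ranking = gl.rank_and_select(self._items([0.5, 0.2, 0.9]), top_n=1)
        lines = ranking.to_csv().splitlines()
        assert lines[0] == "image_id,db_index,selected"
        assert lines[1].startswith("img1") and lines[1].endswith(",1")


def test_noisier_scenes_rank_worse():
    """Injected per-band noise inflates within-class dispersion, so the
    Davies–Bouldin ranking must order scenes by noise level."""
    items = []
    for i, noise in enumerate(np.linspace(0, 40, 6)):
        img, truth = ss.generate_scene(ss.two_class_spec(64, seed=i,
                                                         noise_sd=float(noise)))
        items.append((f"n{i}", img, BinaryMask(truth.mask)))
    ranking = gl.rank_and_select(items, top_n=3)
    assert [e[0] for e in ranking.entries] == [f"n{i}" for i in range(6)]
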