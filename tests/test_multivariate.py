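"""PCA, sparse PCA and curve-shape clustering."""

import numpy as np
import pandas as pd
import pytest

from maldicrs.curves import CurveFit, ll4
from maldicrs.multivariate import (
    cluster_curve_shapes,
    curve_shape_grid,
    pca_global,
    sparse_pca,
)
from maldicrs.preprocess import IntensityMatrix
from maldicrs.spectra_io import PlateLayout


def _matrix(values, concs=None):
    values = np.asarray(values, float)
    n_feat, n_spot = values.shape
    spots = [f"s{j}" for j in range(n_spot)]
    concs = concs if concs is not None else np.geomspace(1e-9, 1e-3, n_spot)
    layout = PlateLayout(pd.DataFrame({
        "spot_id": spots, "concentration": concs,
        "replicate_index": 1, "compound_id": "c",
    }))
    mz = 400.0 + 10.0 * np.arange(n_feat)
    return IntensityMatrix(mz, spots, values, layout)


def _dose_matrix(n_responders=3, n_flat=30, n_spots=16, noise=0.02, seed=0, b=-2.0):
    rng = np.random.default_rng(seed)
    concs = np.repeat(np.geomspace(1e-9, 1e-3, n_spots // 2), 2)
    rows = []
    for _ in range(n_responders):
        rows.append(ll4(concs, b=b, c=1, d=8, e=1e-6))
    for _ in range(n_flat):
        rows.append(np.full(n_spots, rng.uniform(1, 5)))
    values = np.asarray(rows) * (1 + rng.normal(0, noise, (len(rows), n_spots)))
    return _matrix(values, concs), np.arange(n_responders)


class TestPCA:
    def test_rank_one_matrix_explained_by_pc1(self):
        u = np.array([1.0, 2.0, 0.5, 3.0])          # feature scales
        w = np.array([0.1, 0.5, 1.0, 2.0, 4.0, 8.0])  # shared spot profile
        m = _matrix(np.outer(u, w))
        res = pca_global(m, n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_dose_gradient_captured_by_pc1(self):
        m, _ = _dose_matrix(n_responders=6, n_flat=8, noise=0.01, seed=3, b=-1.0)
        res = pca_global(m, n_components=2)
        from scipy.stats import spearmanr

        rho = spearmanr(res.scores[:, 0],
                        np.log(m.layout.table["concentration"])).statistic
        assert abs(rho) >= 0.9

    def test_spot_permutation_equivariance(self):
        m, _ = _dose_matrix(seed=5)
        res = pca_global(m, n_components=2)
        perm = np.random.default_rng(0).permutation(len(m.spots))
        m2 = IntensityMatrix(m.feature_mz, [m.spots[j] for j in perm],
                             m.values[:, perm], None)
        res2 = pca_global(m2, n_components=2)
        # same scores up to per-component sign
        for k in range(2):
            match = np.allclose(res2.scores[:, k], res.scores[perm, k], atol=1e-8)
            flipped = np.allclose(res2.scores[:, k], -res.scores[perm, k], atol=1e-8)
            assert match or flipped

    def test_too_many_components_rejected(self):
        m, _ = _dose_matrix()
        with pytest.raises(ValueError):
            pca_global(m, n_components=100)


class TestSparsePCA:
    def test_zero_penalty_selects_all_features(self):
        m, _ = _dose_matrix(seed=7)
        res = sparse_pca(m, n_components=2, l1_penalty=0.0)
        assert len(res.selected) == len(res.feature_indices)

    def test_selected_set_shrinks_along_penalty_ladder(self):
        m, _ = _dose_matrix(seed=9)
        sizes = [
            len(sparse_pca(m, n_components=2, l1_penalty=a).selected)
            for a in (0.0, 0.1, 0.5, 2.0, 10.0, 50.0)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_huge_penalty_leaves_few_or_no_features(self):
        m, _ = _dose_matrix(seed=9)
        res = sparse_pca(m, n_components=2, l1_penalty=500.0)
        assert len(res.selected) <= 2

    def test_responders_in_selected_set(self):
        m, responders = _dose_matrix(n_responders=3, n_flat=40, seed=11)
        res = sparse_pca(m, n_components=2, l1_penalty=2.0)
        assert set(responders) <= set(res.selected)

    def test_loadings_contain_exact_zeros(self):
        m, _ = _dose_matrix(seed=13)
        res = sparse_pca(m, n_components=2, l1_penalty=5.0)
        assert np.sum(res.loadings == 0.0) > 0


def _fit(b, c, d, e):
    return CurveFit(b=b, c=c, d=d, e=e, rmse=0.0, converged=True,
                    conc_min=1e-9, conc_max=1e-3)


class TestCurveShapeClustering:
    def test_copies_and_mirrors_separate(self):
        curves = [_fit(-2, 1, 8, 1e-6), _fit(-2, 1, 8, 1e-6),
                  _fit(2, 1, 8, 1e-6), _fit(2, 1, 8, 1e-6)]
        labels = cluster_curve_shapes(curves, k=2)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_noisy_responders_co_cluster_against_flat(self):
        rng = np.random.default_rng(41)
        responders = [
            _fit(-2 * (1 + rng.normal(0, 0.1)), 1, 8 * (1 + rng.normal(0, 0.1)),
                 1e-6 * (1 + rng.normal(0, 0.2)))
            for _ in range(10)
        ]
        flats = [_fit(0.001, v, v * 1.0001, 1e-6) for v in rng.uniform(1, 5, 10)]
        labels = cluster_curve_shapes(responders + flats, k=2)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_shape_scaling_is_affine_invariant(self):
        a = curve_shape_grid([_fit(-2, 1, 8, 1e-6)])
        b = curve_shape_grid([_fit(-2, 1 * 5 + 2, 8 * 5 + 2, 1e-6)])
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_feature_permutation_consistency(self):
        curves = [_fit(-2, 1, 8, 1e-6), _fit(2, 1, 8, 1e-6),
                  _fit(-2, 2, 6, 1e-5), _fit(2, 3, 9, 1e-7)]
        labels = cluster_curve_shapes(curves, k=2)
        labels_rev = cluster_curve_shapes(curves[::-1], k=2)
        # same partition up to label renaming
        def partition(lab):
            groups = {}
            for i, l in enumerate(lab):
                groups.setdefault(l, set()).add(i)
            return {frozenset(v) for v in groups.values()}

        rev_mapped = [labels_rev[::-1][i] for i in range(4)]
        assert partition(labels) == partition(rev_mapped)

    def test_all_flat_single_cluster_with_warning(self):
        flats = [_fit(0.0, v, v, 1e-6) for v in (1.0, 2.0, 3.0)]
        with pytest.warns(UserWarning, match="flat"):
            labels = cluster_curve_shapes(flats, k="auto")
        assert set(labels) == {0}

    def test_auto_k_separates_three_shapes(self):
        curves = ([_fit(-2, 1, 8, 1e-7)] * 3 + [_fit(2, 1, 8, 1e-7)] * 3
                  + [_fit(-2, 1, 8, 1e-4)] * 3)
        labels = cluster_curve_shapes(curves, k="auto")
        assert len(set(labels)) >= 2

    def test_needs_two_converged_fits(self):
        bad = CurveFit(b=0, c=1, d=1, e=1e-6, rmse=0, converged=False)
        with pytest.raises(ValueError):
            cluster_curve_shapes([bad, bad], k=2)
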