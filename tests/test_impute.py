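import numpy as np
import pytest

from aktredox.stats import impute_knn, impute_random_tail

from conftest import make_omics


def brute_force_knn(values, k, max_missing_fraction=0.5, standardize_rows=False):
    """Independent reference kNN: per-column-normalized Euclidean distance
    on jointly observed entries, lexicographic tie-break, unweighted mean."""
    values = values.copy()
    n, m = values.shape
    obs = ~np.isnan(values)
    ids = [f"f{i:03d}" for i in range(n)]
    if standardize_rows:
        z = np.empty_like(values)
        for i in range(n):
            o = obs[i]
            mu, sd = values[i, o].mean(), values[i, o].std(ddof=0)
            z[i] = (values[i] - mu) / (sd if sd > 0 else 1.0)
    else:
        z = values
    out = values.copy()
    for i in range(n):
        if not obs[i].all() and (1 - obs[i].mean()) < max_missing_fraction:
            for j in range(m):
                if obs[i, j]:
                    continue
                cand = []
                for other in range(n):
                    if other == i or not obs[other, j]:
                        continue
                    joint = obs[other] & obs[i]
                    if not joint.any():
                        continue
                    d = np.sqrt(((z[other, joint] - z[i, joint]) ** 2).sum() / joint.sum())
                    cand.append((d, ids[other], other))
                cand.sort()
                if cand:
                    out[i, j] = np.mean([values[c[2], j] for c in cand[:k]])
    return out


class TestKnn:
    def test_duplicated_feature_imputes_shared_value(self):
        base = np.array([1.0, -0.5, 2.0, 0.3, -1.2, 0.8, 1.5, -0.9])
        vals = np.tile(base, (12, 1))
        vals += np.arange(12)[:, None] * 1e-9  # keep rows distinct but near-identical
        vals[0, 3] = np.nan
        m = make_omics(vals, ["a"] * 4 + ["b"] * 4)
        out = impute_knn(m, k=10)
        assert out.values.iloc[0, 3] == pytest.approx(base[3], abs=1e-6)

    def test_feature_above_missing_threshold_untouched(self):
        vals = np.random.default_rng(0).normal(0, 1, (12, 8))
        vals[0, :5] = np.nan  # 62.5% missing
        m = make_omics(vals, ["a"] * 4 + ["b"] * 4)
        out = impute_knn(m)
        assert np.isnan(out.values.iloc[0, :5]).all()

    @pytest.mark.parametrize("standardize", [False, True])
    def test_matches_brute_force_oracle(self, standardize):
        rng = np.random.default_rng(42)
        vals = rng.normal(0, 1, (20, 8))
        mask = rng.random((20, 8)) < 0.05
        vals[mask] = np.nan
        m = make_omics(vals, ["a"] * 4 + ["b"] * 4)
        for k in (3, 10):
            out = impute_knn(m, k=k, standardize_rows=standardize)
            expected = brute_force_knn(vals, k=k, standardize_rows=standardize)
            np.testing.assert_allclose(out.values.to_numpy(), expected, rtol=1e-10)

    def test_matches_sklearn_knnimputer_pipeline_counts(self):
        """Cross-check against the established kNN imputer: identical imputed
        matrix on a feature-row layout without column-j-missing donors."""
        from sklearn.impute import KNNImputer

        rng = np.random.default_rng(9)
        vals = rng.normal(20, 2, (60, 8)) + rng.normal(0, 0.3, (60, 8))
        mask = rng.random((60, 8)) < 0.04
        vals[mask] = np.nan
        m = make_omics(vals, ["a"] * 4 + ["b"] * 4)
        mine = impute_knn(m, k=10).values.to_numpy()
        ref = KNNImputer(n_neighbors=10).fit_transform(vals)
        np.testing.assert_allclose(mine, ref, rtol=1e-8)

    def test_k_equals_all_rows_is_column_mean_of_donors(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, (10, 6))
        vals[2, 1] = np.nan
        m = make_omics(vals, ["a"] * 3 + ["b"] * 3)
        out = impute_knn(m, k=9)
        donors = np.delete(vals[:, 1], 2)
        assert out.values.iloc[2, 1] == pytest.approx(np.nanmean(donors), rel=1e-12)

    def test_requires_normalized_matrix(self):
        m = make_omics([[1.0, 2.0]], ["a", "a"], scale="linear")
        with pytest.raises(ValueError, match="normalized"):
            impute_knn(m)


class TestRandomTail:
    def build(self, vals, n_groups=2):
        n = vals.shape[1] // 2
        return make_omics(
            vals,
            ["basal"] * n + ["insulin"] * n,
            times=["1 h"] * (2 * n),
        )

    def test_draws_downshifted_values(self):
        rng = np.random.default_rng(0)
        n_feat = 520
        vals = rng.normal(0, 1, (n_feat, 8))
        vals[:500, :4] = np.nan  # 500 insulin-only features
        m = self.build(vals)
        out = impute_random_tail(m, seed=9)
        col_means = np.nanmean(vals[:, :4], axis=0)
        col_sds = np.nanstd(vals[:, :4], axis=0, ddof=1)
        imputed = out.values.to_numpy()[:500, :4]
        shift = (col_means - imputed.mean(axis=0)) / col_sds
        # mean downshift ~1.8 column SDs, +-0.5 over 500 features
        assert np.all(np.abs(shift - 1.8) < 0.5)
        spread = imputed.std(axis=0, ddof=1) / col_sds
        assert np.all(np.abs(spread - 0.3) < 0.15)

    def test_min_present_rule(self):
        vals = np.full((1, 8), np.nan)
        vals[0, 4] = 1.0  # only 1/4 insulin present
        vals = np.vstack([vals, np.random.default_rng(1).normal(0, 1, (10, 8))])
        m = self.build(vals)
        out = impute_random_tail(m, seed=0)
        assert np.isnan(out.values.iloc[0, :4]).all()

    def test_partial_presence_both_groups_excluded(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, (10, 8))
        vals[0, [0, 4]] = np.nan  # 3/4 present in both groups: kNN territory
        m = self.build(vals)
        out = impute_random_tail(m, seed=0)
        assert np.isnan(out.values.iloc[0, 0]) and np.isnan(out.values.iloc[0, 4])

    def test_symmetric_vice_versa(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, (30, 8))
        vals[0, 4:] = np.nan  # basal-only feature: insulin cells imputed
        m = self.build(vals)
        out = impute_random_tail(m, seed=1)
        assert not np.isnan(out.values.iloc[0, 4:]).any()

    def test_deterministic_for_seed_and_errors_without_labels(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, (20, 8))
        vals[0, :4] = np.nan
        m = self.build(vals)
        a = impute_random_tail(m, seed=7).values
        b = impute_random_tail(m, seed=7).values
        assert a.equals(b)
        bad = make_omics(vals, ["x"] * 4 + ["y"] * 4)
        with pytest.raises(ValueError, match="lacks"):
            impute_random_tail(bad)
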