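"""PCA / KPCA / CVC selection against oracles and their algebraic invariants."""

import numpy as np
import pytest
from sklearn.decomposition import KernelPCA
from sklearn.preprocessing import KernelCenterer

from sekpca import (
    ConfigurationError,
    FeatureMatrix,
    KernelSpec,
    center_kernel,
    cvc_select,
    kernel_matrix,
    kpca_fit,
    kpca_project,
    kpca_scores,
    pca_fit,
    pca_project,
    standardize,
)
from sekpca.profiles import CONTRIBUTION_PROFILES, REPORTED_COMPONENT_COUNTS

from ._oracles import (
    correlation_eigenvalues_oracle,
    cvc_scan_oracle,
    kernel_oracle,
)


def matrix(seed: int, shape=(50, 8)) -> np.ndarray:
    return np.random.default_rng(seed).standard_normal(shape)


class TestStandardize:
    def test_idempotence(self):
        y, _ = standardize(matrix(0))
        y2, _ = standardize(y)
        np.testing.assert_allclose(y2, y, atol=1e-12)

    def test_single_column_mean_zero(self):
        y, _ = standardize(np.array([[1.0], [2.0], [3.0]]))
        assert abs(y.mean()) <= 1e-12

    def test_column_means_vanish(self):
        y, _ = standardize(matrix(1, (20, 5)))
        assert np.all(np.abs(y.mean(axis=0)) <= 1e-12)

    def test_zero_variance_column_named(self):
        x = matrix(2, (10, 3))
        x[:, 1] = 7.0
        fm = FeatureMatrix(x, feature_names=["a", "bad", "c"])
        with pytest.raises(ConfigurationError, match="bad"):
            standardize(fm)


class TestPca:
    def test_perfectly_correlated_columns_are_rank_one(self):
        x = matrix(3, (40, 1))
        fit = pca_fit(np.hstack([x, 3 * x + 1]))
        np.testing.assert_allclose(fit.contribution_rates, [1.0, 0.0], atol=1e-12)

    def test_independent_columns_near_uniform_rates(self):
        fit = pca_fit(matrix(4, (5000, 4)))
        np.testing.assert_allclose(fit.contribution_rates, 0.25, atol=0.02)

    def test_eigenvalues_match_dense_oracle(self):
        x = matrix(5)
        fit = pca_fit(x)
        np.testing.assert_allclose(
            fit.eigenvalues, correlation_eigenvalues_oracle(x), atol=1e-9
        )

    def test_components_unit_norm_and_rates_sorted(self):
        fit = pca_fit(matrix(6))
        np.testing.assert_allclose(
            np.linalg.norm(fit.components, axis=0), 1.0, atol=1e-12
        )
        assert np.all(np.diff(fit.contribution_rates) <= 1e-12)
        assert fit.contribution_rates.sum() <= 1 + 1e-10

    def test_projection_dimensions_and_bounds(self):
        x = matrix(7)
        fit = pca_fit(x)
        assert pca_project(x, fit, 3).shape == (50, 3)
        with pytest.raises(ConfigurationError):
            pca_project(x, fit, 99)


class TestCvcSelect:
    @pytest.mark.parametrize("key", sorted(CONTRIBUTION_PROFILES, key=str))
    def test_agrees_with_exhaustive_scan_on_all_profiles(self, key):
        rates = CONTRIBUTION_PROFILES[key]
        for threshold in (0.90, 0.95, 0.99):
            assert cvc_select(rates, threshold) == cvc_scan_oracle(rates, threshold)

    @pytest.mark.parametrize("key", sorted(REPORTED_COMPONENT_COUNTS, key=str))
    def test_reproduces_reported_component_counts(self, key):
        rates = CONTRIBUTION_PROFILES[key]
        for threshold, expected in REPORTED_COMPONENT_COUNTS[key].items():
            assert cvc_select(rates, threshold) == expected

    def test_trivial_and_error_cases(self):
        assert cvc_select([1.0], 0.99) == 1
        with pytest.raises(ConfigurationError):
            cvc_select([], 0.9)
        with pytest.raises(ConfigurationError):
            cvc_select([0.2, 0.5], 0.9)  # increasing rates
        with pytest.warns(UserWarning, match="below threshold"):
            assert cvc_select([0.4, 0.3], 0.9) == 2


KERNEL_SPECS = [
    KernelSpec("linear"),
    KernelSpec("polynomial", P=2.0),
    KernelSpec("polynomial", P=0.5),
    KernelSpec("rbf", delta=0.7),
    KernelSpec("mlp", v=0.5, c=0.1),
]


class TestKernels:
    def test_rbf_unit_diagonal(self):
        x = matrix(8, (10, 3))
        K = kernel_matrix(x, x, KernelSpec("rbf", delta=0.3))
        np.testing.assert_allclose(np.diag(K), 1.0, atol=1e-12)

    def test_linear_order_polynomial_is_linear_plus_one(self):
        x = matrix(9, (10, 3))
        K1 = kernel_matrix(x, x, KernelSpec("polynomial", P=1.0))
        np.testing.assert_allclose(
            K1, kernel_matrix(x, x, KernelSpec("linear")) + 1.0, atol=1e-12
        )

    @pytest.mark.parametrize("spec", KERNEL_SPECS, ids=lambda s: f"{s.family}-{s.P}")
    def test_matches_scalar_loop_oracle(self, spec):
        x, y = matrix(10, (10, 3)), matrix(11, (6, 3))
        if spec.family == "polynomial" and spec.P == 0.5:
            # fractional orders need (x.y + 1) >= 0, as with entropy features
            x, y = np.abs(x), np.abs(y)
        params = {k: v for k, v in spec.to_dict().items()
                  if k in {"P", "delta", "v", "c"} and v is not None}
        np.testing.assert_allclose(
            kernel_matrix(x, y, spec),
            kernel_oracle(x, y, spec.family, **params),
            atol=1e-12,
        )

    def test_dimension_mismatch_and_bad_specs(self):
        with pytest.raises(ConfigurationError):
            kernel_matrix(matrix(12, (5, 3)), matrix(13, (5, 4)), KernelSpec("linear"))
        with pytest.raises(ConfigurationError):
            KernelSpec("rbf")  # missing delta
        with pytest.raises(ConfigurationError):
            KernelSpec("polynomial", P=-1)


class TestCenterKernel:
    def test_row_and_column_sums_vanish(self):
        for seed in range(5):
            x = matrix(seed, (5, 3))
            K = x @ x.T
            centered, _ = center_kernel(K)
            assert np.max(np.abs(centered.sum(axis=0))) <= 1e-10
            assert np.max(np.abs(centered.sum(axis=1))) <= 1e-10

    def test_idempotence(self):
        K = matrix(20, (6, 3)) @ matrix(20, (6, 3)).T
        centered, _ = center_kernel(K)
        twice, _ = center_kernel(centered)
        np.testing.assert_allclose(twice, centered, atol=1e-12)

    def test_rank_one_ones_matrix_centres_to_zero(self):
        centered, _ = center_kernel(np.ones((5, 5)))
        np.testing.assert_allclose(centered, 0.0, atol=1e-12)

    def test_matches_sklearn_centerer(self):
        x = matrix(21, (8, 3))
        K = x @ x.T
        centered, stats = center_kernel(K)
        kc = KernelCenterer().fit(K)
        np.testing.assert_allclose(centered, kc.transform(K), atol=1e-12)
        # projection mode reproduces sklearn's out-of-sample centring too
        y = matrix(22, (4, 3))
        Kt = y @ x.T
        np.testing.assert_allclose(
            center_kernel(Kt, stats), kc.transform(Kt), atol=1e-12
        )

    def test_projection_mode_requires_stats(self):
        with pytest.raises(ConfigurationError):
            center_kernel(np.ones((3, 5)))


def _align_signs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Flip columns of b so each has positive dot product with a's column."""
    signs = np.sign(np.sum(a * b, axis=0))
    signs[signs == 0] = 1.0
    return b * signs


class TestKpca:
    @pytest.mark.parametrize("seed", range(20))
    def test_linear_kernel_reproduces_pca(self, seed):
        x = matrix(seed, (30, 5))
        pca = pca_fit(x)
        y, _ = standardize(x)
        kpca = kpca_fit(y, KernelSpec("linear"))
        n = min(pca.n_components, kpca.n_components)
        # eigenvalue ratios agree (Gram eigenvalues are (m-1) x correlation ones)
        np.testing.assert_allclose(
            kpca.eigenvalues[:n] / kpca.eigenvalues[0],
            pca.eigenvalues[:n] / pca.eigenvalues[0],
            atol=1e-8,
        )
        scores_pca = pca_project(x, pca, n)
        scores_kpca = kpca_scores(kpca, n)
        np.testing.assert_allclose(
            _align_signs(scores_pca, scores_kpca), scores_pca, atol=1e-8
        )

    def test_projection_of_training_set_equals_fit_scores(self):
        x = matrix(30, (25, 4))
        fit = kpca_fit(x, KernelSpec("rbf", delta=1.5))
        np.testing.assert_allclose(
            kpca_project(x, fit, fit.n_components),
            kpca_scores(fit),
            atol=1e-10,
        )

    def test_duplicated_sample_projects_onto_training_row(self):
        x = matrix(31, (20, 4))
        fit = kpca_fit(x, KernelSpec("rbf", delta=1.5))
        proj = kpca_project(x[7:8], fit, fit.n_components)
        np.testing.assert_allclose(proj[0], kpca_scores(fit)[7], atol=1e-10)

    def test_eigen_residual_of_defining_relation(self):
        # K~ a = mu a must hold for every retained component
        x = matrix(32, (30, 5))
        spec = KernelSpec("rbf", delta=1.0)
        fit = kpca_fit(x, spec)
        K = kernel_matrix(x, x, spec)
        centered, _ = center_kernel(K)
        for k in range(fit.n_components):
            a = fit.components[:, k]
            resid = np.linalg.norm(centered @ a - fit.eigenvalues[k] * a)
            assert resid <= 1e-8 * np.linalg.norm(a)

    def test_unit_norm_feature_space_components(self):
        fit = kpca_fit(matrix(33, (20, 4)), KernelSpec("polynomial", P=2.0))
        norms = fit.eigenvalues * np.sum(fit.components**2, axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-10)

    def test_mlp_negative_eigenvalues_truncated(self):
        x = matrix(34, (25, 4))
        spec = KernelSpec("mlp", v=2.0, c=-1.0)
        K = kernel_matrix(x, x, spec)
        centered, _ = center_kernel(K)
        assert np.linalg.eigvalsh(centered).min() < -1e-8  # genuinely indefinite
        fit = kpca_fit(x, spec)
        assert fit.n_truncated_negative > 0
        assert np.all(fit.eigenvalues > 0)
        assert fit.contribution_rates.sum() <= 1 + 1e-10
        assert np.all(np.diff(fit.contribution_rates) <= 1e-12)

    def test_matches_sklearn_kernel_pca(self):
        x = matrix(35, (25, 4))
        delta = 1.3
        fit = kpca_fit(x, KernelSpec("rbf", delta=delta))
        ref = KernelPCA(n_components=5, kernel="rbf", gamma=1.0 / delta**2)
        scores_ref = ref.fit_transform(x)
        scores = kpca_scores(fit, 5)
        np.testing.assert_allclose(
            np.abs(scores), np.abs(scores_ref), atol=1e-8
        )

    def test_k_too_large_is_an_error(self):
        fit = kpca_fit(matrix(36, (10, 3)), KernelSpec("linear"))
        with pytest.raises(ConfigurationError):
            kpca_project(matrix(37, (4, 3)), fit, fit.n_components + 1)

    def test_polynomial_order_shifts_concentration(self):
        # higher P concentrates variance in the leading component
        x = np.abs(matrix(38, (40, 6)))
        leading = [
            kpca_fit(x, KernelSpec("polynomial", P=p)).contribution_rates[0]
            for p in (0.5, 1.0, 2.0)
        ]
        assert leading[0] < leading[1] < leading[2]

    def test_model_json_roundtrip(self, tmp_path):
        from sekpca import DecompositionResult

        x = matrix(39, (15, 3))
        fit = kpca_fit(x, KernelSpec("rbf", delta=0.8))
        fit.select(0.9)
        path = tmp_path / "model.json"
        fit.to_json(path)
        back = DecompositionResult.from_json(path)
        np.testing.assert_allclose(back.eigenvalues, fit.eigenvalues)
        np.testing.assert_allclose(
            kpca_project(x[:5], back), kpca_project(x[:5], fit, back.n_selected)
        )
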