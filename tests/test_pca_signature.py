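import numpy as np
import pandas as pd
import pytest

from pcsig.pca_signature import (
    PCAResult,
    pc_factor_association,
    run_pca_svd,
    scale_center,
    select_signature,
)


def _random_matrix(rng, n_genes=10, n_samples=6):
    return pd.DataFrame(
        rng.normal(0, 1, (n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )


class TestScaleCenter:
    def test_rows_standardized(self, rng):
        out = scale_center(_random_matrix(rng))
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_center_only_keeps_row_variance(self, rng):
        m = _random_matrix(rng)
        out = scale_center(m, unit_variance=False)
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(
            out.std(axis=1, ddof=1), m.std(axis=1, ddof=1), rtol=1e-12
        )

    def test_constant_gene_excluded(self, rng):
        m = _random_matrix(rng)
        m.loc["flat"] = 3.14
        out = scale_center(m)
        assert "flat" not in out.index and len(out) == len(m) - 1

    def test_idempotent(self, rng):
        m = _random_matrix(rng)
        once = scale_center(m)
        pd.testing.assert_frame_equal(scale_center(once), once)

    def test_all_constant_is_error(self):
        m = pd.DataFrame(np.ones((3, 4)), index=list("abc"))
        with pytest.raises(ValueError):
            scale_center(m)


def _eig_oracle(scaled):
    """Brute-force PCA: eigendecomposition of the sample covariance."""
    x = scaled.to_numpy().T  # samples x genes, gene-centered
    n = x.shape[0]
    cov = x.T @ x  # gene-space scatter; eigenvectors = loadings
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]


class TestRunPcaSvd:
    def test_matches_eigendecomposition_oracle(self, rng):
        for _ in range(5):
            scaled = scale_center(_random_matrix(rng, 10, 6))
            pca = run_pca_svd(scaled)
            w, v = _eig_oracle(scaled)
            k = pca.k
            np.testing.assert_allclose(
                pca.variance_fraction.to_numpy(),
                (w[: len(pca.variance_fraction)] / w.sum()).clip(0),
                atol=1e-8,
            )
            for j in range(k):
                ours = pca.loadings.iloc[:, j].to_numpy()
                theirs = v[:, j]
                if np.dot(ours, theirs) < 0:
                    theirs = -theirs
                np.testing.assert_allclose(ours, theirs, atol=1e-8)
            # scores are the data projected on the loadings
            np.testing.assert_allclose(
                pca.scores.to_numpy(),
                scaled.to_numpy().T @ pca.loadings.to_numpy(),
                atol=1e-8,
            )

    def test_rank_one_data_has_all_variance_on_pc1(self):
        pattern = np.array([1.0, -1.0, 2.0, -2.0])
        m = pd.DataFrame(
            np.outer([1.0, 2.0, -1.5], pattern),
            index=list("abc"),
            columns=list("wxyz"),
        )
        pca = run_pca_svd(scale_center(m, unit_variance=False))
        assert pca.variance_fraction.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_duplicated_gene_rows_have_equal_loadings(self, rng):
        m = _random_matrix(rng, 6, 5)
        m.loc["g0copy"] = m.loc["g0"]
        pca = run_pca_svd(scale_center(m))
        np.testing.assert_allclose(
            pca.loadings.loc["g0"].abs(), pca.loadings.loc["g0copy"].abs(), atol=1e-10
        )

    def test_loadings_orthonormal_and_variance_sums_to_one(self, rng):
        pca = run_pca_svd(scale_center(_random_matrix(rng, 20, 7)))
        gram = pca.loadings.to_numpy().T @ pca.loadings.to_numpy()
        np.testing.assert_allclose(gram, np.eye(pca.k), atol=1e-10)
        assert pca.variance_fraction.sum() == pytest.approx(1.0, abs=1e-8)
        diffs = np.diff(pca.variance_fraction.to_numpy())
        assert (diffs <= 1e-12).all()

    def test_too_few_samples_rejected(self, rng):
        m = _random_matrix(rng, 5, 2)
        with pytest.raises(ValueError):
            run_pca_svd(scale_center(m))

    def test_deterministic_sign_convention(self, rng):
        scaled = scale_center(_random_matrix(rng, 15, 6))
        a, b = run_pca_svd(scaled), run_pca_svd(scaled.copy())
        pd.testing.assert_frame_equal(a.loadings, b.loadings)
        for j in range(a.k):
            col = a.loadings.iloc[:, j]
            assert col.iloc[int(np.argmax(col.abs()))] > 0


class TestSelectSignature:
    def _manual_pca(self):
        loadings = pd.DataFrame(
            {"PC1": [0.9, 0.3, 0.3, 0.1]}, index=["g1", "g2", "g3", "g4"]
        )
        scores = pd.DataFrame({"PC1": [0.0]}, index=["s1"])
        return PCAResult(loadings, scores, pd.Series({"PC1": 1.0}), n_genes=4)

    def test_hand_evaluated_threshold(self):
        sig = select_signature(self._manual_pca(), pc=1, w=1.0)
        assert sig.threshold == pytest.approx(0.5)
        assert sig.gene_ids == ["g1"]

    def test_vacuous_weight_selects_all_nonzero(self):
        sig = select_signature(self._manual_pca(), pc=1, w=1e-9)
        assert sig.gene_ids == ["g1", "g2", "g3", "g4"]  # sorted by |loading|

    def test_out_of_range_pc_rejected(self):
        with pytest.raises(ValueError):
            select_signature(self._manual_pca(), pc=2, w=1.0)

    def test_membership_invariant_under_sign_flip(self, rng):
        scaled = scale_center(_random_matrix(rng, 30, 6))
        pca = run_pca_svd(scaled)
        flipped = PCAResult(
            -pca.loadings, -pca.scores, pca.variance_fraction, pca.n_genes
        )
        a = select_signature(pca, 1, 1.5)
        b = select_signature(flipped, 1, 1.5)
        assert set(a.gene_ids) == set(b.gene_ids)

    def test_null_data_selects_few_genes_on_pc1(self):
        # regression envelope on iid normal data; no analytic claim
        fractions = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            m = pd.DataFrame(rng.normal(0, 1, (2000, 12)))
            m.index = [f"g{i}" for i in range(2000)]
            sig = select_signature(run_pca_svd(scale_center(m)), 1, 3.5)
            fractions.append(len(sig) / 2000)
        assert max(fractions) < 0.05


class TestFactorAssociation:
    def test_perfect_separation_gives_one(self):
        scores = pd.DataFrame({"PC1": [1.0, 1.0, 1.0, 5.0, 5.0, 5.0]},
                              index=[f"s{i}" for i in range(6)])
        pca = PCAResult(
            pd.DataFrame({"PC1": [1.0]}, index=["g"]), scores,
            pd.Series({"PC1": 1.0}), n_genes=1,
        )
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=scores.index)
        eta = pc_factor_association(pca, None, labels)
        assert eta["PC1"] == pytest.approx(1.0)

    def test_permuted_labels_match_exchangeable_expectation(self, rng):
        # E[eta^2] = (G-1)/(n-1) under exchangeability; permutation oracle
        n, n_perm = 12, 10000
        scores = pd.DataFrame({"PC1": rng.normal(0, 1, n)},
                              index=[f"s{i}" for i in range(n)])
        pca = PCAResult(
            pd.DataFrame({"PC1": [1.0]}, index=["g"]), scores,
            pd.Series({"PC1": 1.0}), n_genes=1,
        )
        base = np.array(["a"] * 6 + ["b"] * 6)
        etas = np.empty(n_perm)
        for i in range(n_perm):
            labels = pd.Series(rng.permutation(base), index=scores.index)
            etas[i] = pc_factor_association(pca, None, labels)["PC1"]
        expected = 1.0 / (n - 1)
        assert etas.mean() == pytest.approx(expected, abs=4 * etas.std() / np.sqrt(n_perm))
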