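import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pcsig.diffexpr import (
    ModeratedTestResult,
    bh_adjust,
    call_and_intersect,
    estimate_eb_prior,
    genewise_stats,
    moderated_t,
    run_contrast,
)


def _matrix(values, samples):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                        columns=samples)


class TestGenewiseStats:
    def test_hand_pooled_variance(self):
        m = _matrix([[1, 3, 0, 2]], ["a1", "a2", "b1", "b2"])
        out = genewise_stats(m, ["a1", "a2"], ["b1", "b2"])
        assert out["mean_diff"].iloc[0] == pytest.approx(1.0)
        assert out["s2_g"].iloc[0] == pytest.approx(2.0)
        assert out["d_g"].iloc[0] == 2

    def test_identical_groups_zero_stats(self):
        m = _matrix([[4, 4, 4, 4]], ["a1", "a2", "b1", "b2"])
        out = genewise_stats(m, ["a1", "a2"], ["b1", "b2"])
        assert out["mean_diff"].iloc[0] == 0 and out["s2_g"].iloc[0] == 0

    def test_within_group_permutation_invariance(self, rng):
        m = _matrix(rng.normal(0, 1, (30, 6)), list("abcdef"))
        a = genewise_stats(m, ["a", "b", "c"], ["d", "e", "f"])
        b = genewise_stats(m, ["c", "a", "b"], ["f", "d", "e"])
        pd.testing.assert_frame_equal(a, b)

    def test_overlapping_groups_rejected(self):
        m = _matrix([[1, 2, 3, 4]], list("abcd"))
        with pytest.raises(ValueError, match="overlap"):
            genewise_stats(m, ["a", "b"], ["b", "c"])


class TestEbPrior:
    def test_identical_variances_complete_shrinkage(self):
        d0, s2_0 = estimate_eb_prior(np.full(100, 0.25), d_g=4)
        assert np.isinf(d0) and s2_0 == pytest.approx(0.25)

    def test_parameter_recovery_from_simulation(self):
        rng = np.random.default_rng(42)
        d0_true, s2_0_true, d_g, n = 4.0, 0.05, 4, 10000
        sigma2 = s2_0_true * d0_true / rng.chisquare(d0_true, n)
        s2 = sigma2 * rng.chisquare(d_g, n) / d_g
        d0, s2_0 = estimate_eb_prior(s2, d_g)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s2_0 == pytest.approx(s2_0_true, rel=0.15)

    def test_scale_equivariance(self, rng):
        sigma2 = 0.05 * 4 / rng.chisquare(4, 5000)
        s2 = sigma2 * rng.chisquare(4, 5000) / 4
        d0_a, s2_0_a = estimate_eb_prior(s2, 4)
        d0_b, s2_0_b = estimate_eb_prior(2 * s2, 4)
        assert d0_b == pytest.approx(d0_a, rel=1e-9)
        assert s2_0_b == pytest.approx(2 * s2_0_a, rel=1e-9)


class TestModeratedT:
    def _stats(self, rng, n_genes=1000, na=3, nb=3):
        m = _matrix(rng.normal(0, 1, (n_genes, na + nb)),
                    [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)])
        m.iloc[: n_genes // 4] += rng.normal(0, 1)  # some shifts
        return m, genewise_stats(m, [f"a{i}" for i in range(na)],
                                 [f"b{i}" for i in range(nb)])

    def test_d0_zero_reduces_to_classical_t(self, rng):
        m, stats_table = self._stats(rng)
        result = moderated_t(stats_table, d0=0.0, s2_0=1.0)
        a = m.iloc[:, :3].to_numpy().T
        b = m.iloc[:, 3:].to_numpy().T
        t_ref, p_ref = sps.ttest_ind(a, b, equal_var=True)
        np.testing.assert_allclose(result.table["t_mod"], t_ref, atol=1e-12)
        np.testing.assert_allclose(result.table["p"], p_ref, atol=1e-12)

    def test_d0_infinite_forces_prior_variance(self, rng):
        _, stats_table = self._stats(rng, n_genes=50)
        result = moderated_t(stats_table, d0=np.inf, s2_0=0.5)
        assert (result.table["s2_post"] == 0.5).all()

    def test_hand_shrinkage_formula(self):
        stats_table = pd.DataFrame(
            {"mean_diff": [1.0], "s2_g": [3.0], "d_g": [2], "n_a": [2], "n_b": [2]},
            index=["g0"],
        )
        result = moderated_t(stats_table, d0=4.0, s2_0=1.0)
        assert result.table["s2_post"].iloc[0] == pytest.approx(5 / 3)
        assert result.table["df_total"].iloc[0] == 6

    def test_zero_diff_gives_p_one(self):
        stats_table = pd.DataFrame(
            {"mean_diff": [0.0], "s2_g": [1.0], "d_g": [4], "n_a": [3], "n_b": [3]},
            index=["g0"],
        )
        result = moderated_t(stats_table, d0=2.0, s2_0=1.0)
        assert result.table["t_mod"].iloc[0] == 0
        assert result.table["p"].iloc[0] == pytest.approx(1.0)

    def test_shrinkage_direction_invariant(self, rng):
        _, stats_table = self._stats(rng, n_genes=500)
        d0, s2_0 = estimate_eb_prior(stats_table["s2_g"], 4)
        result = moderated_t(stats_table, d0, s2_0)
        lo = np.minimum(result.table["s2_g"], s2_0)
        hi = np.maximum(result.table["s2_g"], s2_0)
        assert ((result.table["s2_post"] >= lo - 1e-12) &
                (result.table["s2_post"] <= hi + 1e-12)).all()

    def test_monotone_in_effect_size(self):
        base = pd.DataFrame(
            {"mean_diff": [0.5, 1.0, 2.0], "s2_g": [1.0] * 3, "d_g": [4] * 3,
             "n_a": [3] * 3, "n_b": [3] * 3},
            index=["g0", "g1", "g2"],
        )
        result = moderated_t(base, d0=2.0, s2_0=1.0)
        t = result.table["t_mod"]
        p = result.table["p"]
        assert t.is_monotonic_increasing and p.is_monotonic_decreasing


class TestBhAdjust:
    def _naive(self, p):
        """min over tail of p_(j) * m / rank(j), the defining formula."""
        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        ranked = p[order]
        adj = np.empty(m)
        for i in range(m):
            adj[i] = min(
                min(ranked[j] * m / (j + 1) for j in range(i, m)), 1.0
            )
        out = np.empty(m)
        out[order] = adj
        return out

    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_stepup_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_naive_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(1, 51))
            np.testing.assert_allclose(bh_adjust(p), self._naive(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestCallAndIntersect:
    def _result(self, adj, genes):
        table = pd.DataFrame({"adj_p": adj}, index=genes)
        return ModeratedTestResult(table=table, d0=1.0, s2_0=1.0)

    def test_intersection_of_identical_results(self):
        r = self._result([1e-6, 0.5], ["g1", "g2"])
        call = call_and_intersect({"A": r, "B": r}, 1e-4)
        assert call.intersection == {"g1"} == call.per_model["A"]

    def test_disjoint_sets_empty_intersection(self):
        a = self._result([1e-6, 0.5], ["g1", "g2"])
        b = self._result([0.5, 1e-6], ["g1", "g2"])
        call = call_and_intersect({"A": a, "B": b}, 1e-4)
        assert call.intersection == set()

    def test_universe_mismatch_names_difference(self):
        a = self._result([0.1], ["g1"])
        b = self._result([0.1], ["g2"])
        with pytest.raises(ValueError, match="g1"):
            call_and_intersect({"A": a, "B": b})


def test_null_simulations_rarely_reach_strict_threshold():
    """Type-I control: no planted effects, 2000 genes, n=3 per group."""
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        sigma2 = 0.05 * 4 / rng.chisquare(4, 2000)
        m = _matrix(rng.normal(0, np.sqrt(sigma2)[:, None], (2000, 6)),
                    ["a1", "a2", "a3", "b1", "b2", "b3"])
        stats_table = genewise_stats(m, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        d0, s2_0 = estimate_eb_prior(stats_table["s2_g"], 4)
        result = moderated_t(stats_table, d0, s2_0)
        if (result.table["adj_p"] < 1e-4).any():
            hits += 1
    assert hits <= 5


def test_moderated_t_agrees_with_limma_reference(tmp_path, default_bundle):
    """Independent cross-check of the full shrinkage path against the
    Bioconductor reference implementation on a small shared fixture."""
    matrix, ann, _, _ = default_bundle
    sub_ann = ann[(ann["cell_line"] == "LINE_A")
                  & ann["condition"].isin(["OVEREXPR", "VECTOR"])]
    sub = matrix.iloc[:300][list(sub_ann.index)]
    sub.to_csv(tmp_path / "expr.tsv", sep="\t")
    groups = np.where(sub_ann["condition"] == "OVEREXPR", "over", "ctrl")
    pd.Series(groups, index=sub_ann.index).to_csv(
        tmp_path / "groups.tsv", sep="\t", header=False
    )
    script = textwrap.dedent("""
        suppressMessages(library(limma))
        args <- commandArgs(trailingOnly=TRUE)
        x <- as.matrix(read.delim(args[1], row.names=1))
        g <- read.delim(args[2], header=FALSE, row.names=1)
        grp <- factor(g[colnames(x),1], levels=c("ctrl","over"))
        fit <- eBayes(lmFit(x, model.matrix(~grp)))
        tt <- topTable(fit, coef=2, number=Inf, sort.by="none")
        write.table(data.frame(gene=rownames(tt), t=tt$t, p=tt$P.Value),
                    args[3], sep="\\t", quote=FALSE, row.names=FALSE)
    """)
    (tmp_path / "ref.R").write_text(script)
    subprocess.run(
        ["Rscript", str(tmp_path / "ref.R"), str(tmp_path / "expr.tsv"),
         str(tmp_path / "groups.tsv"), str(tmp_path / "ref.tsv")],
        check=True, capture_output=True,
    )
    ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t", index_col=0)

    ours = run_contrast(sub, sub_ann, "LINE_A", control="VECTOR")
    joined = ours.table.join(ref, how="inner", rsuffix="_ref")
    assert len(joined) == 300
    np.testing.assert_allclose(joined["t_mod"], joined["t"], atol=1e-8)
    np.testing.assert_allclose(np.log(joined["p"]), np.log(joined["p_ref"]), atol=1e-8)
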