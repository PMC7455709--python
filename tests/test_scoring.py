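"""Scoring oracles: binning, module score, ssGSEA running sum, bulk index."""

import zlib

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import scsig
from scsig.scoring import GeneSignature, ScoringParams


def _norm_adata(n_cells, n_genes, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.lognormal(0, 1, size=(n_cells, n_genes))
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=[f"c{i}" for i in range(n_cells)]),
        var=pd.DataFrame(index=[f"g{i}" for i in range(n_genes)]),
    )


class TestBinning:
    def test_equal_frequency(self):
        norm = _norm_adata(5, 50)
        bins = scsig.bin_genes_by_expression(norm, 25)
        assert bins.value_counts().eq(2).all()

    def test_tied_means_stable_order(self):
        norm = ad.AnnData(X=np.ones((3, 6)))
        norm.var_names = [f"g{i}" for i in range(6)]
        bins = scsig.bin_genes_by_expression(norm, 3)
        # ties broken by input gene order: consecutive pairs share a bin
        assert list(bins) == [0, 0, 1, 1, 2, 2]

    def test_remainder_to_lowest_bins(self):
        # 7 genes, 3 bins -> sizes (3, 2, 2), lowest-expression bin largest
        norm = _norm_adata(4, 7, seed=1)
        bins = scsig.bin_genes_by_expression(norm, 3)
        sizes = bins.value_counts().sort_index()
        assert list(sizes) == [3, 2, 2]
        means = np.asarray(norm.X).mean(axis=0)
        # quantile-cut oracle: lowest 3 genes by mean land in bin 0
        order = np.argsort(means, kind="stable")
        assert set(bins.iloc[order[:3]].to_numpy()) == {0}
        assert set(bins.iloc[order[3:5]].to_numpy()) == {1}

    def test_too_many_bins_error(self):
        with pytest.raises(ValueError):
            scsig.bin_genes_by_expression(_norm_adata(3, 5), 6)


class TestModuleScore:
    def _full_bin_params(self):
        # one bin covering all 6 genes, controls drawn without replacement
        # exhaust the bin: the control pool is deterministic
        return ScoringParams(n_bins=1, n_ctrl_per_gene=6, seed=0)

    def test_exact_scores_match_explicit_loops(self, tiny_relative):
        rel = tiny_relative
        bins = pd.Series(0, index=rel.var_names)
        sig = GeneSignature("S", ["g0", "g2", "g4"])
        scores = scsig.module_score(rel, sig, self._full_bin_params(), bins=bins)

        X = np.asarray(rel.X)
        names = list(rel.var_names)
        for ci, cell in enumerate(rel.obs_names):
            sig_mean = sum(X[ci, names.index(g)] for g in ["g0", "g2", "g4"]) / 3
            ctrl_mean = sum(X[ci, j] for j in range(6)) / 6  # whole bin, x3 multiplicity
            assert scores[cell] == pytest.approx(sig_mean - ctrl_mean, abs=1e-12)

    def test_sampled_controls_match_explicit_loops(self, tiny_relative):
        # reproduce the documented control-sampling procedure with explicit
        # loops and an independently constructed RNG stream
        rel = tiny_relative
        params = ScoringParams(n_bins=2, n_ctrl_per_gene=2, seed=5)
        bins = scsig.bin_genes_by_expression(rel, 2)
        sig = GeneSignature("MYSIG", ["g1", "g3"])
        scores = scsig.module_score(rel, sig, params, bins=bins)

        rng = np.random.default_rng([5, zlib.crc32(b"MYSIG")])
        names = list(rel.var_names)
        ctrl = []
        for g in ["g1", "g3"]:
            members = [j for j in range(6) if bins.iloc[j] == bins[g]]
            ctrl.extend(rng.choice(members, size=2, replace=False))
        X = np.asarray(rel.X)
        for ci, cell in enumerate(rel.obs_names):
            sig_mean = (X[ci, names.index("g1")] + X[ci, names.index("g3")]) / 2
            ctrl_mean = sum(X[ci, j] for j in ctrl) / len(ctrl)
            assert scores[cell] == pytest.approx(sig_mean - ctrl_mean, abs=1e-12)

    def test_constant_offset_signature(self, tiny_relative):
        # signature genes at value c, control mean 0 -> score c
        X = np.zeros((2, 6))
        X[:, [0, 1]] = 3.5
        rel = ad.AnnData(X=X)
        rel.var_names = [f"g{i}" for i in range(6)]
        sig = GeneSignature("S", ["g0", "g1"])
        bins = pd.Series(0, index=rel.var_names)
        params = ScoringParams(n_bins=1, n_ctrl_per_gene=6, seed=0)
        scores = scsig.module_score(rel, sig, params, bins=bins)
        # control pool mean = (2*3.5 + 4*0)/6
        expected = 3.5 - 2 * 3.5 / 6
        assert np.allclose(scores, expected)

    def test_constant_matrix_scores_zero(self):
        rel = ad.AnnData(X=np.full((4, 8), 1.7))
        rel.var_names = [f"g{i}" for i in range(8)]
        bins = pd.Series(0, index=rel.var_names)
        sig = GeneSignature("S", ["g0", "g3"])
        scores = scsig.module_score(
            rel, sig, ScoringParams(n_bins=1, n_ctrl_per_gene=8, seed=0), bins=bins
        )
        assert np.allclose(scores, 0.0)

    @given(st.floats(-5, 5))
    def test_invariant_to_per_cell_constant_shift(self, shift):
        # adding a constant to every gene of one cell cancels in the
        # difference of means
        rel = _norm_adata(3, 12, seed=3)
        bins = scsig.bin_genes_by_expression(rel, 3)
        sig = GeneSignature("S", ["g0", "g5"])
        params = ScoringParams(n_bins=3, n_ctrl_per_gene=3, seed=2)
        base = scsig.module_score(rel, sig, params, bins=bins)
        shifted = rel.copy()
        X = np.asarray(shifted.X).copy()
        X[1, :] += shift
        shifted.X = X
        after = scsig.module_score(shifted, sig, params, bins=bins)
        np.testing.assert_allclose(base.to_numpy(), after.to_numpy(), atol=1e-9)

    def test_random_signature_mean_score_near_zero(self, normalized_null):
        # expected module score of a random signature on a null matrix ~ 0
        norm, rel, bins = normalized_null
        rng = np.random.default_rng(0)
        means = []
        for k in range(200):
            genes = list(rng.choice(rel.var_names, 25, replace=False))
            s = scsig.module_score(
                rel, GeneSignature(f"R{k}", genes), ScoringParams(seed=k), bins=bins
            )
            means.append(s.mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * se + 1e-12

    def test_missing_signature_error(self, tiny_relative):
        bins = pd.Series(0, index=tiny_relative.var_names)
        with pytest.raises(ValueError, match="no genes"):
            scsig.module_score(
                tiny_relative,
                GeneSignature("S", ["nope"]),
                ScoringParams(n_bins=1, n_ctrl_per_gene=1, seed=0),
                bins=bins,
            )

    def test_small_bin_samples_with_replacement_warns(self, tiny_relative):
        bins = pd.Series(0, index=tiny_relative.var_names)
        with pytest.warns(UserWarning, match="replacement"):
            scsig.module_score(
                tiny_relative,
                GeneSignature("S", ["g0"]),
                ScoringParams(n_bins=1, n_ctrl_per_gene=50, seed=0),
                bins=bins,
            )


def _ssgsea_oracle(values, gene_names, sig_genes, alpha):
    """Step-by-step running-sum computation for one sample."""
    n = len(values)
    order = sorted(range(n), key=lambda i: -values[i])
    rank_of = {i: r for r, i in enumerate(sorted(range(n), key=lambda i: values[i]), 1)}
    in_set = [gene_names[i] in sig_genes for i in range(n)]
    n_r = sum(in_set)
    denom_in = sum(rank_of[i] ** alpha for i in order if in_set[i])
    p_in = p_out = 0.0
    es = 0.0
    for i in order:
        if in_set[i]:
            p_in += rank_of[i] ** alpha / denom_in
        else:
            p_out += 1.0 / (n - n_r)
        es += p_in - p_out
    return es


class TestSsgsea:
    def _fixture(self):
        genes = [f"g{i}" for i in range(8)]
        values = [9.0, 1.0, 7.0, 3.0, 5.0, 8.0, 2.0, 6.0]
        expr = pd.DataFrame({"s0": values}, index=genes)
        return expr, genes, values

    @pytest.mark.parametrize("alpha", [0.25, 0.0])
    def test_running_sum_matches_oracle(self, alpha):
        expr, genes, values = self._fixture()
        sig_genes = {"g0", "g2", "g5"}
        sig = GeneSignature("TOP3", sorted(sig_genes))
        params = ScoringParams(ssgsea_alpha=alpha, ssgsea_normalize=False)
        score = scsig.ssgsea_score(expr, sig, params).iloc[0, 0]
        expected = _ssgsea_oracle(values, genes, sig_genes, alpha)
        assert score == pytest.approx(expected, rel=1e-12)

    def test_sign_property(self):
        expr, genes, values = self._fixture()
        top = [g for _, g in sorted(zip(values, genes), reverse=True)[:3]]
        bottom = [g for _, g in sorted(zip(values, genes))[:3]]
        params = ScoringParams(ssgsea_normalize=False)
        assert scsig.ssgsea_score(expr, GeneSignature("T", top), params).iloc[0, 0] > 0
        assert scsig.ssgsea_score(expr, GeneSignature("B", bottom), params).iloc[0, 0] < 0

    def test_rank_invariance_under_monotone_transform(self):
        expr, genes, _ = self._fixture()
        sig = GeneSignature("S", ["g0", "g4", "g7"])
        params = ScoringParams(ssgsea_normalize=False)
        a = scsig.ssgsea_score(expr, sig, params)
        b = scsig.ssgsea_score(np.exp(expr / 2) + 7, sig, params)
        pd.testing.assert_frame_equal(a, b)

    def test_gene_order_invariance(self):
        expr, genes, _ = self._fixture()
        sig = GeneSignature("S", ["g1", "g5"])
        params = ScoringParams(ssgsea_normalize=False)
        a = scsig.ssgsea_score(expr, sig, params)
        b = scsig.ssgsea_score(expr.iloc[::-1], sig, params)
        pd.testing.assert_frame_equal(a, b)

    def test_normalization_by_cohort_range(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(
            rng.lognormal(0, 1, (30, 5)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(5)],
        )
        sig = GeneSignature("S", [f"g{i}" for i in range(8)])
        raw = scsig.ssgsea_score(expr, sig, ScoringParams(ssgsea_normalize=False))
        normed = scsig.ssgsea_score(expr, sig, ScoringParams(ssgsea_normalize=True))
        rng_ = raw.to_numpy().max() - raw.to_numpy().min()
        np.testing.assert_allclose(normed.to_numpy(), raw.to_numpy() / rng_)

    def test_matches_external_implementation(self):
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(
            rng.lognormal(2, 1, (120, 4)),
            index=[f"g{i}" for i in range(120)],
            columns=[f"s{i}" for i in range(4)],
        )
        members = [f"g{i}" for i in range(20)]
        mine = scsig.ssgsea_score(
            expr, GeneSignature("SET", members), ScoringParams(ssgsea_normalize=False)
        )
        res = gseapy.ssgsea(
            data=expr, gene_sets={"SET": members}, sample_norm_method="rank",
            weight=0.25, outdir=None, threads=1,
        ).res2d.set_index("Name")["ES"].astype(float)
        for s in expr.columns:
            assert mine.loc[s, "SET"] == pytest.approx(res.loc[s], rel=1e-6)

    def test_full_coverage_signature_error(self):
        expr, genes, _ = self._fixture()
        with pytest.raises(ValueError, match="complement"):
            scsig.ssgsea_score(expr, GeneSignature("ALL", genes), ScoringParams())


class TestSignatureIndex:
    def test_mean_of_two_genes(self):
        expr = pd.DataFrame({"p0": [2.0, 4.0]}, index=["g0", "g1"])
        idx = scsig.signature_index(expr, GeneSignature("S", ["g0", "g1"]))
        assert idx["p0"] == pytest.approx(3.0)

    def test_singleton_signature(self):
        expr = pd.DataFrame({"p0": [2.0, 4.0]}, index=["g0", "g1"])
        idx = scsig.signature_index(expr, GeneSignature("S", ["g1"]))
        assert idx["p0"] == pytest.approx(4.0)

    def test_matches_explicit_loops(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(
            rng.normal(6, 2, (12, 5)),
            index=[f"g{i}" for i in range(12)],
            columns=[f"p{i}" for i in range(5)],
        )
        members = ["g0", "g3", "g7", "g9"]
        idx = scsig.signature_index(expr, GeneSignature("S", members))
        for p in expr.columns:
            expected = sum(expr.loc[g, p] for g in members) / len(members)
            assert idx[p] == pytest.approx(expected, abs=1e-12)

    def test_scaling_shifts_index_uniformly(self):
        # log2 of a-fold scaled data adds log2(a) to every index
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(
            rng.normal(6, 2, (10, 4)), index=[f"g{i}" for i in range(10)]
        )
        sig = GeneSignature("S", ["g1", "g4", "g6"])
        base = scsig.signature_index(expr, sig)
        shifted = scsig.signature_index(expr + np.log2(8), sig)
        np.testing.assert_allclose(shifted.to_numpy(), base.to_numpy() + 3.0)

    def test_mixed_direction_requires_choice(self):
        expr = pd.DataFrame({"p0": [1.0, 2.0]}, index=["g0", "g1"])
        sig = GeneSignature("S", ["g0", "g1"], direction="mixed")
        with pytest.raises(ValueError, match="mixed"):
            scsig.signature_index(expr, sig)
        down = scsig.signature_index(expr, sig, direction="down")
        assert down["p0"] == pytest.approx(-1.5)

    def test_absent_genes_dropped_with_warning(self):
        expr = pd.DataFrame({"p0": [2.0, 4.0]}, index=["g0", "g1"])
        with pytest.warns(UserWarning, match="absent"):
            idx = scsig.signature_index(expr, GeneSignature("S", ["g0", "zz"]))
        assert idx["p0"] == pytest.approx(2.0)
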