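"""Candidate pools, iterative t-test trimming and the permutation null."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import chemopath as cp
from conftest import block_design


class TestCandidatePool:
    def test_strong_correlation_retained(self, pipe):
        node = pipe["cluster_node"][0]
        profile = cp.codebook_profile(pipe["model"], node)
        pool = cp.candidate_pool(node, pipe["table"], pipe["expr_f"], profile,
                                 pipe["pw_f"], pipe["config"])
        assert not pool.empty
        assert (pool["p"] < pipe["config"].corr_alpha).all()
        # ordered most-negative correlation first
        assert list(pool["r"]) == sorted(pool["r"])

    def test_t_transform_of_r(self):
        # r=0.9, n=20 -> t = 0.9*sqrt(18/0.19) = 8.76, p << 0.05
        from chemopath._stats import corr_pvalues

        p = corr_pvalues(np.array([[0.9]]), np.array([[20]]))[0, 0]
        assert p < 1e-7

    def test_uncorrelated_member_of_top_pathway_excluded(self, pipe, bundle):
        node = pipe["cluster_node"][0]
        profile = cp.codebook_profile(pipe["model"], node)
        pool = cp.candidate_pool(node, pipe["table"], pipe["expr_f"], profile,
                                 pipe["pw_f"], pipe["config"])
        top = cp.top_percentile_pathways(pipe["table"], node,
                                         pipe["config"].h_top_percentile)
        members = set().union(*(pipe["pw_f"][t].genes for t in top))
        measured_members = members & set(pipe["expr_f"].gene_ids)
        excluded = measured_members - set(pool["gene"])
        # every excluded member genuinely fails the correlation test
        from chemopath._stats import corr_pvalues, masked_corr_matrix

        if excluded:
            sub = pipe["expr_f"].subset(sorted(excluded))
            R, N = masked_corr_matrix(sub.values(), profile[None, :])
            p = corr_pvalues(R, N)[:, 0]
            assert np.all(p >= pipe["config"].corr_alpha)


class TestTrim:
    def test_perfect_block_design_untouched_in_one_pass(self):
        expr, profile, pool = block_design()
        dset = cp.trim(pool, expr, profile, cp.RunConfig())
        assert dset.converged and dset.n_iterations == 1
        assert dset.n_genes == 10 and dset.n_cells == 20

    def test_noise_genes_dropped_planted_retained(self):
        """Across seeds, >=90% of injected pure-noise genes are trimmed away
        while >=90% of planted signal genes survive."""
        noise_total = noise_dropped = planted_total = planted_kept = 0
        for seed in range(20):
            expr, profile, pool = block_design(n_genes=12, n_cells=30, seed=seed)
            rng = np.random.default_rng(seed + 1000)
            noise = rng.standard_normal((5, 30))
            noise_names = [f"noise{i}" for i in range(5)]
            df = pd.concat([
                expr.data,
                pd.DataFrame(noise, index=noise_names, columns=expr.data.columns),
            ])
            expr2 = cp.ExpressionMatrix(df, expr.panel)
            pool2 = pd.concat([
                pool,
                pd.DataFrame({"gene": noise_names,
                              "r": 0.01 * rng.standard_normal(5), "p": 0.04}),
            ], ignore_index=True)
            dset = cp.trim(pool2, expr2, profile, cp.RunConfig())
            kept = set(dset.genes)
            noise_total += 5
            noise_dropped += sum(g not in kept for g in noise_names)
            planted_total += 12
            planted_kept += sum(g in kept for g in pool["gene"])
        assert noise_dropped / noise_total >= 0.90
        assert planted_kept / planted_total >= 0.90

    def test_invariant_to_input_ordering(self):
        expr, profile, pool = block_design(n_genes=8, n_cells=16, seed=3)
        rng = np.random.default_rng(0)
        shuffled_pool = pool.sample(frac=1, random_state=1).reset_index(drop=True)
        perm = rng.permutation(len(expr.panel))
        cells = [expr.panel.cell_ids[i] for i in perm]
        expr_shuffled = cp.ExpressionMatrix(
            expr.data[cells], cp.CellPanel(tuple(cells))
        )
        a = cp.trim(pool, expr, profile, cp.RunConfig())
        b = cp.trim(shuffled_pool, expr_shuffled, profile[perm], cp.RunConfig())
        assert a.genes == b.genes and a.cells == b.cells

    def test_tightening_alpha_never_adds_genes(self):
        expr, profile, pool = block_design(n_genes=12, n_cells=30, gap=0.8, seed=5)
        counts = []
        for alpha in (0.1, 0.05, 0.01, 0.001):
            dset = cp.trim(pool, expr, profile, cp.RunConfig(trim_alpha=alpha))
            counts.append(dset.n_genes if dset.converged else 0)
        assert counts == sorted(counts, reverse=True)

    def test_empty_pool_rejected(self, pipe):
        with pytest.raises(ValueError):
            cp.trim(pd.DataFrame(columns=["gene", "r", "p"]), pipe["expr_f"],
                    np.ones(59), pipe["config"])

    def test_emptied_class_reported_as_failure(self):
        # all genes positively associated: the over-with-insensitive class
        # can never hold two members
        expr, profile, pool = block_design(n_genes=6, n_cells=12)
        pool = pool.assign(r=np.abs(pool["r"]))
        dset = cp.trim(pool, expr, profile, cp.RunConfig())
        assert not dset.converged
        assert "class" in (dset.failure or "")

    def test_gene_and_cell_pvalues_below_alpha(self, converged_dset, pipe):
        alpha = pipe["config"].trim_alpha
        assert all(p < alpha for p in converged_dset.gene_p.values())
        assert all(p < alpha for p in converged_dset.cell_p.values())

    def test_termination_bound(self, converged_dset):
        bound = converged_dset.n_genes_input + converged_dset.n_cells_input
        assert converged_dset.n_iterations <= bound


class TestFourClassLabels:
    def test_partition_and_quadrant_sizes(self, converged_dset):
        grid = cp.four_class_labels(converged_dset)
        assert grid.shape == (converged_dset.n_genes, converged_dset.n_cells)
        counts = grid.stack().value_counts()
        n_neg = sum(v == "over_insensitive" for v in converged_dset.gene_class.values())
        n_pos = converged_dset.n_genes - n_neg
        n_ins = sum(v == "insensitive" for v in converged_dset.cell_class.values())
        n_sen = converged_dset.n_cells - n_ins
        assert counts.get("A", 0) == n_neg * n_ins
        assert counts.get("B", 0) == n_neg * n_sen
        assert counts.get("C", 0) == n_pos * n_ins
        assert counts.get("D", 0) == n_pos * n_sen

    def test_block_design_over_quadrants_have_higher_expression(self):
        expr, profile, pool = block_design()
        dset = cp.trim(pool, expr, profile, cp.RunConfig())
        grid = cp.four_class_labels(dset)
        X = expr.data.loc[dset.genes, dset.cells]
        means = {q: X.to_numpy()[(grid == q).to_numpy()].mean() for q in "ABCD"}
        assert means["A"] > means["B"] and means["A"] > means["C"]
        assert means["D"] > means["B"] and means["D"] > means["C"]


class TestShuffleNull:
    def test_sanity_unshuffled_set_is_a_fixed_point(self, converged_dset, pipe):
        again = cp.trim(
            pd.DataFrame({
                "gene": converged_dset.genes,
                "r": [converged_dset.gene_r[g] for g in converged_dset.genes],
                "p": 1e-6,
            }),
            pipe["expr_f"].subset(converged_dset.genes),
            _profile_for(converged_dset, pipe),
            pipe["config"],
        )
        assert again.converged
        assert set(again.genes) == set(converged_dset.genes)

    def test_small_n_perm_rejected(self, converged_dset, pipe):
        with pytest.raises(ValueError):
            cp.shuffle_null_fpr(converged_dset, pipe["expr_f"], pipe["config"],
                                n_perm=50, seed=0)

    def test_estimate_well_below_nominal_alpha(self, converged_dset, pipe):
        fpr = cp.shuffle_null_fpr(converged_dset, pipe["expr_f"], pipe["config"],
                                  n_perm=1000, seed=0)
        assert fpr <= pipe["config"].trim_alpha


def _profile_for(dset, pipe):
    """The node profile restricted (via masking) to the set's retained cells."""
    profile = cp.codebook_profile(pipe["model"], dset.node)
    keep = set(dset.cells)
    for i, c in enumerate(pipe["expr_f"].panel.cell_ids):
        if c not in keep:
            profile[i] = np.nan
    return profile
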