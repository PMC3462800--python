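"""Correlations, Kruskal-Wallis H, signed pathway scores, top-decile cuts."""
from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import chemopath as cp
from chemopath.hscore import HScoreTable


def brute_force_kw(a, b):
    """Independent midrank implementation: explicit sort-based ranks, direct formula."""
    vals = list(a) + list(b)
    order = sorted(range(len(vals)), key=lambda i: vals[i])
    ranks = [0.0] * len(vals)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and vals[order[j + 1]] == vals[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    N = len(vals)
    groups = [ranks[: len(a)], ranks[len(a) :]]
    H = 12.0 / (N * (N + 1)) * sum(
        len(g) * (sum(g) / len(g) - (N + 1) / 2.0) ** 2 for g in groups
    )
    counts = {}
    for v in vals:
        counts[v] = counts.get(v, 0) + 1
    tie = 1.0 - sum(t**3 - t for t in counts.values()) / (N**3 - N)
    if tie <= 0:
        return 0.0, 1.0
    H /= tie
    return H, float(stats.chi2.sf(H, 1))


class TestPearsonMasked:
    def test_self_and_negated(self):
        x = np.array([1.0, 2, 4, 8])
        assert cp.pearson_masked(x, x)[0] == pytest.approx(1.0)
        assert cp.pearson_masked(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_value(self):
        r, n = cp.pearson_masked(np.array([1.0, 2, 3, 4]), np.array([2.0, 1, 4, 3]))
        assert r == pytest.approx(0.6)
        assert n == 4

    def test_masked_overlap_counting(self):
        x = np.array([1.0, 2, 3, np.nan, 5])
        y = np.array([2.0, np.nan, 6, 8, 10])
        r, n = cp.pearson_masked(x, y)
        assert n == 3
        assert r == pytest.approx(np.corrcoef([1, 3, 5], [2, 6, 10])[0, 1])

    def test_too_few_or_degenerate_is_nan(self):
        assert math.isnan(cp.pearson_masked(np.array([1.0, 2]), np.array([3.0, 4]))[0])
        assert math.isnan(
            cp.pearson_masked(np.array([1.0, 1, 1]), np.array([1.0, 2, 3]))[0]
        )


class TestGeneNodeCorrelations:
    def test_dimensions(self, pipe):
        corr = pipe["corr"]
        assert corr.r.shape == (pipe["expr_f"].n_genes, pipe["model"].n_nodes)

    def test_gene_equal_to_codebook_has_unit_correlation(self, pipe):
        model, expr = pipe["model"], pipe["expr_f"]
        row = model.codebook[0]
        df = pd.DataFrame([row], index=["fake"], columns=expr.panel.cell_ids)
        fake = cp.ExpressionMatrix(df, expr.panel)
        corr = cp.gene_node_correlations(fake, model)
        assert corr.r.loc["fake", 0] == pytest.approx(1.0)

    def test_matches_looped_pearson_calls(self, pipe):
        corr, expr, model = pipe["corr"], pipe["expr_f"], pipe["model"]
        rng = np.random.default_rng(0)
        X = expr.values()
        for _ in range(20):
            gi = int(rng.integers(expr.n_genes))
            k = int(rng.integers(model.n_nodes))
            r, n = cp.pearson_masked(X[gi], model.codebook[k])
            assert corr.r.iloc[gi, k] == pytest.approx(r, abs=1e-12)
            assert corr.n_used.iloc[gi, k] == n

    def test_panel_mismatch_rejected(self, pipe, bundle):
        other = cp.CellPanel(tuple(f"X{i}" for i in range(59)))
        model = pipe["model"]
        alien = cp.SOMModel(model.rows, model.cols, model.codebook, other)
        with pytest.raises(ValueError):
            cp.gene_node_correlations(pipe["expr_f"], alien)


class TestKruskalWallis:
    def test_separated_groups_hand_value(self):
        H, p = cp.kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert H == pytest.approx(3.857142857, abs=1e-8)
        assert p == pytest.approx(0.0495, abs=1e-3)

    def test_interleaved_groups_near_zero(self):
        H, _ = cp.kruskal_wallis([1, 3, 5, 7], [2, 4, 6, 8])
        assert H == pytest.approx(1.0 / 3.0, abs=1e-9)

    def test_all_tied_returns_zero_and_one(self):
        assert cp.kruskal_wallis([2.0, 2.0], [2.0, 2.0, 2.0]) == (0.0, 1.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for i in range(1000):
            if i % 2:  # heavy ties
                a = rng.integers(0, 5, size=rng.integers(2, 10)).astype(float)
                b = rng.integers(0, 5, size=rng.integers(2, 10)).astype(float)
            else:
                a = rng.normal(size=rng.integers(2, 10))
                b = rng.normal(size=rng.integers(2, 10))
            H, p = cp.kruskal_wallis(a, b)
            Hb, pb = brute_force_kw(list(a), list(b))
            assert abs(H - Hb) <= 1e-9 and abs(p - pb) <= 1e-9

    def test_equals_squared_standardized_rank_sum(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.normal(size=rng.integers(2, 15))
            b = rng.normal(size=rng.integers(2, 15))
            H, _ = cp.kruskal_wallis(a, b)
            vals = np.concatenate([a, b])
            ranks = stats.rankdata(vals)
            N = len(vals)
            W = ranks[: len(a)].sum()
            var = len(a) * len(b) / (N * (N - 1)) * ((ranks**2).sum() - N * (N + 1) ** 2 / 4)
            assert H == pytest.approx((W - len(a) * (N + 1) / 2) ** 2 / var, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cp.kruskal_wallis([], [1.0])


class TestPathwayH:
    def test_top_k_membership_is_maximal_and_positive(self):
        # enumerate all placements of 3 members among 8 distinct correlations
        r = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        best_H = None
        for combo in itertools.combinations(range(8), 3):
            mask = np.zeros(8, dtype=bool)
            mask[list(combo)] = True
            rec = cp.pathway_h(r, mask)
            if combo == (5, 6, 7):
                best_H = rec.H
        for combo in itertools.combinations(range(8), 3):
            mask = np.zeros(8, dtype=bool)
            mask[list(combo)] = True
            assert cp.pathway_h(r, mask).H <= best_H + 1e-12
        assert best_H > 0

    def test_complement_flips_sign_keeps_magnitude(self):
        rng = np.random.default_rng(1)
        r = rng.normal(size=30)
        mask = np.zeros(30, dtype=bool)
        mask[:10] = True
        a = cp.pathway_h(r, mask)
        b = cp.pathway_h(r, ~mask)
        assert a.H == pytest.approx(-b.H, abs=1e-9)

    def test_undefined_correlations_excluded(self):
        r = np.array([0.9, 0.8, np.nan, -0.1, -0.2])
        mask = np.array([True, True, True, False, False])
        rec = cp.pathway_h(r, mask)
        assert rec.n_in == 2 and rec.n_out == 2

    def test_too_few_members_flagged_invalid(self):
        rec = cp.pathway_h(np.array([0.1, 0.2, 0.3]), np.array([True, False, False]))
        assert not rec.valid


class TestHScoreTable:
    def test_record_count_is_pathways_times_nodes(self, pipe):
        assert len(pipe["table"]) == len(pipe["pw_f"]) * pipe["model"].n_nodes

    def test_spot_checks_match_direct_pathway_h(self, pipe):
        table, corr, pw = pipe["table"], pipe["corr"], pipe["pw_f"]
        genes = corr.gene_ids
        rng = np.random.default_rng(2)
        for _ in range(10):
            name = pw.names[int(rng.integers(len(pw)))]
            node = int(rng.integers(pipe["model"].n_nodes))
            mask = np.array([g in pw[name].genes for g in genes])
            direct = cp.pathway_h(corr.r[node].to_numpy(), mask, name, node)
            rec = table.get(name, node)
            assert rec.H == pytest.approx(direct.H, abs=1e-9)
            assert rec.p_value == pytest.approx(direct.p_value, abs=1e-9)

    def test_sign_invariant_holds_everywhere(self, pipe):
        df = pipe["table"].df
        valid = df[df["valid"].astype(bool)]
        diff = (valid["mean_r_in"] - valid["mean_r_out"]).to_numpy()
        H = valid["H"].to_numpy()
        # a zero statistic carries no sign; otherwise sign(H) = sign(diff) exactly
        assert np.all((H == 0) | (np.sign(H) == np.sign(diff)))
        assert np.all(H[diff == 0] == 0)

    def test_works_against_raw_compound_profile(self, pipe, bundle):
        raw = pipe["norm"].profile(pipe["norm"].compound_ids[0])
        corr = cp.gene_profile_correlations(pipe["expr_f"], raw[None, :], ["cmp"])
        table = cp.h_score_table(corr, pipe["pw_f"])
        assert len(table) == len(pipe["pw_f"])


class TestTopPercentile:
    def _table(self, hs: dict[str, float]) -> HScoreTable:
        df = pd.DataFrame(
            [(k, 0, v, 0.01, 3, 10, 0.5, 0.0, True) for k, v in hs.items()],
            columns=HScoreTable.COLUMNS,
        )
        return HScoreTable(df)

    def test_decile_of_ten_is_single_best(self):
        tab = self._table({f"p{i}": float(i) for i in range(10)})
        assert cp.top_percentile_pathways(tab, 0, 10) == ["p9"]

    def test_complete_tie_returns_all(self):
        tab = self._table({f"p{i}": 1.0 for i in range(8)})
        assert len(cp.top_percentile_pathways(tab, 0, 10)) == 8

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_cut(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        hs = {f"p{i:02d}": float(rng.normal()) for i in range(n)}
        got = cp.top_percentile_pathways(self._table(hs), 0, 10)
        k = math.ceil(0.10 * n)
        ordered = sorted(hs, key=lambda nm: (-hs[nm], nm))
        threshold = hs[ordered[k - 1]]
        expected = [nm for nm in ordered if hs[nm] >= threshold]
        assert got == expected

    def test_null_membership_calibration(self, pipe):
        """Random pathway membership yields p < alpha at ~alpha rate."""
        r = pipe["corr"].r[0].to_numpy()
        r = r[np.isfinite(r)]
        rng = np.random.default_rng(0)
        hits = 0
        n_draws = 1000
        for _ in range(n_draws):
            mask = np.zeros(len(r), dtype=bool)
            mask[rng.choice(len(r), size=15, replace=False)] = True
            rec = cp.pathway_h(r, mask)
            hits += rec.p_value < 0.05
        # binomial 3-sigma band around 0.05
        assert abs(hits / n_draws - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n_draws)
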