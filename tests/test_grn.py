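"""Gene-pair inference: Pearson selection, IAMB blankets, list merging."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

from atrokg.grn import (
    DEFAULT_P_THRESHOLD,
    combine_pair_lists,
    equivalence_sample_size,
    fisher_z_partial_correlation,
    iamb_markov_blanket,
    pearson_pairs,
)
from atrokg.synthetic import (
    RegulatoryNetworkSpec,
    random_regulatory_network,
    simulate_expression,
)


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def brute_force_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """r from the definitional sum formula; p by numerically integrating the
    t density (no shared code with the implementation)."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx, syy, sxy = sum(v * v for v in x), sum(v * v for v in y), sum(a * b for a, b in zip(x, y))
    r = (n * sxy - sx * sy) / math.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
    df = n - 2
    t_stat = abs(r) * math.sqrt(df / (1 - r**2)) if abs(r) < 1 else math.inf

    def t_pdf(u):
        c = special.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * special.gamma(df / 2))
        return c * (1 + u * u / df) ** (-(df + 1) / 2)

    tail, _ = integrate.quad(t_pdf, t_stat, np.inf)
    return r, 2 * tail


def exhaustive_markov_blanket(expr: pd.DataFrame, target: str, alpha: float) -> set:
    """Smallest variable set rendering every other variable independent of the
    target (same CI test, exhaustive subset search)."""
    genes = [g for g in expr.index if g != target]
    corr = np.corrcoef(expr.to_numpy())
    pos = {g: i for i, g in enumerate(expr.index)}
    n = expr.shape[1]

    def independent(x, y, cond):
        _, p = fisher_z_partial_correlation(corr, n, pos[x], pos[y], tuple(pos[c] for c in cond))
        return p >= alpha

    for size in range(len(genes) + 1):
        for subset in itertools.combinations(genes, size):
            rest = [g for g in genes if g not in subset]
            if all(independent(target, g, subset) for g in rest):
                return set(subset)
    return set(genes)


# --------------------------------------------------------------------------
# Pearson selection
# --------------------------------------------------------------------------

class TestPearsonPairs:
    def test_identical_rows_are_perfectly_correlated_and_selected(self):
        rng = np.random.default_rng(0)
        row = rng.standard_normal(16)
        expr = pd.DataFrame([row, row], index=["a", "b"])
        out = pearson_pairs(expr, p_threshold=DEFAULT_P_THRESHOLD)
        assert len(out) == 1
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_selection_matches_brute_force_oracle(self):
        spec = random_regulatory_network(n_genes=5, n_edges=5, seed=3, noise_sd=0.4)
        expr = simulate_expression(spec, n_samples=16, seed=1)
        threshold = 1e-3
        got = pearson_pairs(expr, p_threshold=threshold)
        got_pairs = set(zip(got["gene_a"], got["gene_b"]))
        expected = set()
        genes = list(expr.index)
        for i, j in itertools.combinations(range(len(genes)), 2):
            r, p = brute_force_pearson(expr.iloc[i].tolist(), expr.iloc[j].tolist())
            if p < threshold:
                expected.add(tuple(sorted((genes[i], genes[j]))))
        assert got_pairs == expected
        # r and p values agree with the oracle, too
        for row in got.itertuples(index=False):
            r, p = brute_force_pearson(
                expr.loc[row.gene_a].tolist(), expr.loc[row.gene_b].tolist()
            )
            assert row.r == pytest.approx(r, abs=1e-10)
            assert row.p == pytest.approx(p, rel=1e-6)

    def test_invariant_to_row_order(self):
        spec = random_regulatory_network(n_genes=6, n_edges=7, seed=9, noise_sd=0.5)
        expr = simulate_expression(spec, n_samples=20, seed=4)
        a = pearson_pairs(expr, p_threshold=0.01)
        b = pearson_pairs(expr.iloc[::-1], p_threshold=0.01)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_variance_genes_skipped(self):
        expr = pd.DataFrame(
            {f"s{i}": [1.0, float(i), float(i) * 2] for i in range(5)},
            index=["flat", "a", "b"],
        )
        out = pearson_pairs(expr, p_threshold=0.5)
        assert "flat" not in set(out["gene_a"]) | set(out["gene_b"])

    def test_threshold_duality_at_equivalence_sample_size(self):
        """At n*, p < 5e-7 selects exactly the |r| >= 0.9 pairs."""
        n_star = equivalence_sample_size(0.9, DEFAULT_P_THRESHOLD)
        assert n_star == 18  # analytically: r-cutoff closest to 0.9
        rng = np.random.default_rng(12)
        rows = [rng.standard_normal(n_star) for _ in range(12)]
        # plant a few strongly correlated partners away from the cutoff gap
        for rho in (0.97, 0.95, 0.85, 0.5):
            base = rows[int(rng.integers(len(rows)))]
            rows.append(rho * base + np.sqrt(1 - rho**2) * rng.standard_normal(n_star))
        expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
        by_p = pearson_pairs(expr, p_threshold=DEFAULT_P_THRESHOLD)
        by_r = pearson_pairs(expr, r_threshold=0.9)
        assert set(zip(by_p["gene_a"], by_p["gene_b"])) == set(
            zip(by_r["gene_a"], by_r["gene_b"])
        )


# --------------------------------------------------------------------------
# IAMB
# --------------------------------------------------------------------------

class TestIamb:
    def test_isolated_gene_has_empty_blanket(self):
        spec = RegulatoryNetworkSpec(
            node_ids=["iso", "x", "y"],
            edges=[("x", "y")],
            coefficients=[1.0],
        )
        expr = simulate_expression(spec, n_samples=4000, seed=0)
        assert iamb_markov_blanket(expr, "iso", alpha=0.01).blanket == set()

    def test_chain_blanket_is_both_neighbors(self):
        spec = RegulatoryNetworkSpec(
            node_ids=["X", "Y", "Z"],
            edges=[("X", "Y"), ("Y", "Z")],
            coefficients=[1.0, 1.0],
        )
        expr = simulate_expression(spec, n_samples=5000, seed=1)
        assert iamb_markov_blanket(expr, "Y", alpha=0.01).blanket == {"X", "Z"}
        assert exhaustive_markov_blanket(expr, "Y", 0.01) == {"X", "Z"}

    def test_collider_recovers_spouse(self):
        spec = RegulatoryNetworkSpec(
            node_ids=["X", "Y", "Z"],
            edges=[("X", "Z"), ("Y", "Z")],
            coefficients=[1.0, 1.0],
        )
        expr = simulate_expression(spec, n_samples=5000, seed=2)
        assert iamb_markov_blanket(expr, "X", alpha=0.01).blanket == {"Z", "Y"}
        assert exhaustive_markov_blanket(expr, "X", 0.01) == {"Z", "Y"}

    def test_agrees_with_exhaustive_search_on_small_networks(self):
        for seed in range(3):
            spec = random_regulatory_network(n_genes=5, n_edges=4, seed=seed)
            expr = simulate_expression(spec, n_samples=3000, seed=seed + 10)
            for target in expr.index:
                got = iamb_markov_blanket(expr, target, alpha=0.01).blanket
                oracle = exhaustive_markov_blanket(expr, target, 0.01)
                assert got == oracle, f"seed {seed} target {target}"

    def test_constant_target_warns_and_returns_empty(self, caplog):
        expr = pd.DataFrame(
            np.vstack([np.ones(10), np.random.default_rng(0).standard_normal((2, 10))]),
            index=["flat", "a", "b"],
        )
        res = iamb_markov_blanket(expr, "flat", alpha=0.01)
        assert res.blanket == set()


# --------------------------------------------------------------------------
# merging
# --------------------------------------------------------------------------

class TestCombinePairLists:
    @staticmethod
    def _mb(target, members):
        from atrokg.grn import MarkovBlanketResult

        return MarkovBlanketResult(target=target, blanket=set(members), alpha=0.01)

    def test_disjoint_union_counts(self):
        pearson = pd.DataFrame(
            {
                "gene_a": ["a", "b", "c"],
                "gene_b": ["x", "y", "z"],
                "r": [0.95, 0.93, 0.91],
                "p": [1e-8] * 3,
                "source": ["pearson"] * 3,
            }
        )
        out = combine_pair_lists(pearson, [self._mb("m", ["n", "o"])])
        assert len(out) == 5

    def test_duplicate_pair_keeps_both_source_tags(self):
        pearson = pd.DataFrame(
            {
                "gene_a": ["a"],
                "gene_b": ["b"],
                "r": [0.99],
                "p": [1e-9],
                "source": ["pearson"],
            }
        )
        out = combine_pair_lists(pearson, [self._mb("b", ["a"])])
        assert len(out) == 1
        assert out.loc[0, "source"] == "markov_blanket,pearson"

    def test_empty_pearson_returns_blanket_pairs(self):
        out = combine_pair_lists(
            pd.DataFrame(columns=["gene_a", "gene_b", "r", "p", "source"]),
            [self._mb("t", ["u", "v"])],
        )
        assert set(zip(out["gene_a"], out["gene_b"])) == {("t", "u"), ("t", "v")}
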