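import itertools
import math

import numpy as np
import pytest

from refstab import (
    SyntheticConfig,
    delta_ct_transform,
    genorm_rank,
    normalization_factor,
    pairwise_v,
    pairwise_variation_series,
    simulate_ct,
    stability_m,
)
from refstab.relquant import RelQuantTable

from conftest import make_ct


def brute_force_m(q, genes):
    """Independent recomputation of M: all pairwise log-ratio SDs from scratch."""
    out = {}
    for i, g in enumerate(genes):
        vs = []
        for j, h in enumerate(genes):
            if i == j:
                continue
            ratios = [math.log2(q[i][s] / q[j][s]) for s in range(len(q[i]))]
            mean = sum(ratios) / len(ratios)
            var = sum((r - mean) ** 2 for r in ratios) / (len(ratios) - 1)
            vs.append(math.sqrt(var))
        out[g] = sum(vs) / len(vs)
    return out


def brute_force_elimination(q, genes):
    """Stepwise elimination recomputing every pairwise SD at every round."""
    q = {g: list(row) for g, row in zip(genes, q)}
    alive = list(genes)
    eliminated = []
    while len(alive) > 2:
        m = brute_force_m([q[g] for g in alive], alive)
        worst = max(alive, key=lambda g: (m[g], alive.index(g)))
        eliminated.append(worst)
        alive.remove(worst)
    return eliminated, tuple(alive)


def brute_force_v_series(q_by_gene, ranked):
    """NF geometric means and V(n/n+1) recomputed from first principles."""
    n_samples = len(next(iter(q_by_gene.values())))
    series = {}
    for n in range(2, len(ranked)):
        v_samples = []
        for s in range(n_samples):
            nf_n = math.prod(q_by_gene[g][s] for g in ranked[:n]) ** (1.0 / n)
            nf_n1 = math.prod(q_by_gene[g][s] for g in ranked[: n + 1]) ** (1.0 / (n + 1))
            v_samples.append(math.log2(nf_n / nf_n1))
        mean = sum(v_samples) / n_samples
        var = sum((x - mean) ** 2 for x in v_samples) / (n_samples - 1)
        series[n] = math.sqrt(var)
    return series


class TestPairwiseV:
    def test_proportional_genes_have_zero_v(self):
        assert pairwise_v([1, 2, 4, 8], [2, 4, 8, 16]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # log2 ratios are {0, 1, 2, 3}; sample SD = sqrt(5/3)
        assert pairwise_v([1, 2, 4, 8], [1, 1, 1, 1]) == pytest.approx(math.sqrt(5 / 3))

    def test_symmetry(self):
        a, b = [1.0, 0.5, 0.125], [0.9, 0.3, 0.8]
        assert pairwise_v(a, b) == pytest.approx(pairwise_v(b, a))

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            pairwise_v([1.0, 0.0], [1.0, 1.0])


class TestStabilityM:
    def test_three_gene_hand_example(self, three_gene_table):
        rq = delta_ct_transform(three_gene_table)
        m = stability_m(rq)
        v = math.sqrt(5 / 3)
        assert m["A"] == pytest.approx(v / 2)
        assert m["B"] == pytest.approx(v / 2)
        assert m["C"] == pytest.approx(v)

    def test_duplicated_genes_share_minimal_m(self):
        rng = np.random.default_rng(0)
        ct = rng.uniform(18, 24, size=(1, 6))
        table = make_ct(["a", "b", "c"], np.vstack([ct, ct, ct + rng.normal(0, 1, 6)]))
        m = stability_m(delta_ct_transform(table))
        assert m["a"] == pytest.approx(m["b"])
        assert m["a"] < m["c"]

    def test_per_sample_scaling_invariance(self):
        rng = np.random.default_rng(1)
        q = rng.uniform(0.1, 1.0, size=(4, 6))
        q = q / q.max(axis=1, keepdims=True)
        genes = list("abcd")
        base = stability_m(RelQuantTable(genes=genes, samples=[f"s{j}" for j in range(6)], q=q))
        scaled = q * np.array([1.0, 0.5, 0.25, 1.0, 0.8, 0.6])  # per-sample factor
        scaled = scaled / scaled.max(axis=1, keepdims=True)
        m2 = stability_m(RelQuantTable(genes=genes, samples=[f"s{j}" for j in range(6)], q=scaled))
        np.testing.assert_allclose(base.to_numpy(), m2.to_numpy(), atol=1e-10)

    def test_m_bounded_by_max_pairwise_v(self):
        rng = np.random.default_rng(2)
        q = rng.uniform(0.05, 1.0, size=(5, 8))
        q = q / q.max(axis=1, keepdims=True)
        genes = [f"g{i}" for i in range(5)]
        rq = RelQuantTable(genes=genes, samples=[f"s{j}" for j in range(8)], q=q)
        m = stability_m(rq)
        vmax = max(
            pairwise_v(q[i], q[j]) for i, j in itertools.combinations(range(5), 2)
        )
        assert all(m[g] <= vmax + 1e-12 for g in genes)


class TestGenormRank:
    def test_three_gene_elimination(self, three_gene_table):
        rq = delta_ct_transform(three_gene_table)
        result = genorm_rank(rq)
        assert result.elimination_order == ["C"]
        assert set(result.final_pair) == {"A", "B"}
        assert result.ranks == {"A": 1, "B": 1, "C": 3}

    def test_oracle_equivalence_on_random_tables(self):
        """Stepwise elimination and the V series match an independent
        brute-force recomputation on 200 random 5-gene x 8-sample tables."""
        rng = np.random.default_rng(42)
        genes = [f"g{i}" for i in range(5)]
        for _ in range(200):
            ct = rng.uniform(15, 30, size=(5, 8))
            rq = delta_ct_transform(make_ct(genes, ct))
            result = genorm_rank(rq)
            expect_elim, expect_pair = brute_force_elimination(rq.q.tolist(), genes)
            assert result.elimination_order == expect_elim
            assert result.final_pair == expect_pair
            q_by_gene = {g: rq.q[i].tolist() for i, g in enumerate(genes)}
            expect_v = brute_force_v_series(q_by_gene, result.ranking)
            for n, v in expect_v.items():
                assert result.v_series[n] == pytest.approx(v, abs=1e-10)
            m0 = brute_force_m(rq.q.tolist(), genes)
            for g in genes:
                assert result.m_trajectory[0][g] == pytest.approx(m0[g], abs=1e-10)

    def test_all_proportional_genes_tie_policy(self):
        base = np.array([[18.0, 19.0, 20.0]])
        ct = np.vstack([base, base + 1, base + 2, base + 3])
        result = genorm_rank(delta_ct_transform(make_ct(list("abcd"), ct)))
        # all M identical: the later-listed gene is removed at every round
        assert result.elimination_order == ["d", "c"]
        assert result.final_pair == ("a", "b")

    def test_high_noise_gene_eliminated_first(self):
        """A gene with 2.0-cycle noise among 0.1-cycle genes is removed in
        the first elimination round in >= 95% of 100 seeds."""
        hits = 0
        for seed in range(100):
            noise = np.full(6, 0.1)
            noise[3] = 2.0
            cfg = SyntheticConfig(
                n_genes=6, conditions=(0.0, 1.0, 6.0, 24.0), n_bio_replicates=3,
                loading_sd=0.5, noise_sd=noise, seed=seed,
            )
            table, _ = simulate_ct(cfg)
            result = genorm_rank(delta_ct_transform(table))
            hits += result.elimination_order[0] == "G4"
        assert hits >= 95

    def test_too_few_genes_rejected(self):
        rq = delta_ct_transform(make_ct(["a", "b"], [[18.0, 19.0], [20.0, 21.0]]))
        with pytest.raises(ValueError):
            genorm_rank(rq)


class TestNormalizationFactor:
    @pytest.fixture
    def rq(self, three_gene_table):
        return delta_ct_transform(three_gene_table)

    def test_n_one_rejected(self, rq):
        with pytest.raises(ValueError):
            normalization_factor(rq, ["A", "B", "C"], 1)

    def test_geometric_mean_hand_value(self):
        table = make_ct(["a", "b"], [[20.0, 20.0], [22.0, 20.0]])
        rq = delta_ct_transform(table)
        nf = normalization_factor(rq, ["a", "b"], 2)
        assert nf.iloc[0] == pytest.approx(0.5)  # sqrt(1 * 0.25)

    def test_full_nf_invariant_to_gene_order(self, rq):
        a = normalization_factor(rq, ["A", "B", "C"], 3)
        b = normalization_factor(rq, ["C", "A", "B"], 3)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())


class TestPairwiseVariationSeries:
    def test_identical_genes_recommend_two(self):
        ct = np.tile([[18.0, 19.0, 20.0, 21.0]], (4, 1))
        rq = delta_ct_transform(make_ct(list("abcd"), ct))
        series, recommended = pairwise_variation_series(rq, list("abcd"))
        np.testing.assert_allclose(series.to_numpy(), 0.0, atol=1e-12)
        assert recommended == 2

    def test_loading_only_tables_recommend_two(self):
        """With only a shared loading effect and 0.1-cycle noise, two
        reference genes suffice: V(2/3) < 0.15."""
        cfg = SyntheticConfig(
            n_genes=14, conditions=(0.0, 1.0, 6.0, 24.0), n_bio_replicates=3,
            loading_sd=0.5, noise_sd=0.1, seed=11,
        )
        table, _ = simulate_ct(cfg)
        result = genorm_rank(delta_ct_transform(table))
        assert result.v_series[2] < 0.15
        assert result.recommended_n == 2
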