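"""CAI, polymorphism summaries, F_ST, Q_ST, expression statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from constellation.evo_stats import (
    HaplotypeSample,
    cai,
    cai_weights,
    diversity_stats,
    expression_correlation,
    fst_hudson,
    qst,
    qst_pooled,
    rank_product_de,
    read_haplotype_fasta,
    tajima_constants,
)
from constellation.synthetic_data import (
    simulate_expression,
    simulate_haplotypes,
    write_haplotype_fasta,
)


class TestCai:
    def test_family_count_ratio(self):
        # 30 AAA vs 10 AAG within the Lys family
        ref = ["AAA" * 30 + "AAG" * 10]
        w = cai_weights(ref)
        assert w["AAA"] == 1.0
        assert w["AAG"] == pytest.approx(1 / 3)

    def test_single_codon_per_family_all_used_get_one(self):
        ref = ["AAATTTGGGCCC"]
        w = cai_weights(ref)
        for codon in ("AAA", "TTT", "GGG", "CCC"):
            assert w[codon] == 1.0

    def test_unseen_codons_floored(self):
        w = cai_weights(["AAA" * 10])
        assert w["AAG"] == 0.01

    def test_empty_reference_is_an_error(self):
        with pytest.raises(ValueError):
            cai_weights([])

    def test_internal_stop_rejected_with_warning(self):
        with pytest.warns(UserWarning, match="stop"):
            w = cai_weights(["AAATAAAAA", "GGGCCC"])
        assert w["AAA"] == 0.01  # only the clean sequence counted

    def test_geometric_mean(self):
        w = cai_weights(["AAA" * 2 + "GGG"])  # AAA w=1, GGG w=1, AAG floored
        # two informative codons with w = 1 and w = 0.5
        ref = ["AAA" * 10 + "AAG" * 5 + "GGG" * 10]
        weights = cai_weights(ref)
        assert weights["AAG"] == 0.5
        assert cai("AAAAAG", weights) == pytest.approx(math.sqrt(0.5))

    def test_maximal_codons_give_one(self):
        weights = cai_weights(["AAAGGGTTT"])
        assert cai("AAAGGGTTTAAA", weights) == pytest.approx(1.0)

    def test_met_trp_only_sequence_is_an_error(self):
        weights = cai_weights(["AAA"])
        with pytest.raises(ValueError):
            cai("ATGTGG", weights)

    def test_frame_violation_is_an_error(self):
        weights = cai_weights(["AAA"])
        with pytest.raises(ValueError):
            cai("AAAA", weights)

    def test_invariant_under_equal_weight_recoding(self):
        # CTT and CTC equally frequent: both w = 1 within the Leu family
        ref = ["CTT" * 5 + "CTC" * 5 + "AAA" * 5]
        weights = cai_weights(ref)
        assert cai("CTTAAA", weights) == pytest.approx(cai("CTCAAA", weights))


class TestDiversity:
    def test_no_segregating_sites(self):
        h = HaplotypeSample("g", "p", ["ACGT", "ACGT", "ACGT"])
        d = diversity_stats(h)
        assert (d.theta_w, d.theta_pi, d.s) == (0.0, 0.0, 0)
        assert d.tajimas_d is None

    def test_two_singleton_sites_hand_oracle(self):
        # n=4, L=2, both sites singletons: per-locus theta_W = 2/a1,
        # mean pairwise differences 1.0, D from the 1989 constants
        h = HaplotypeSample("g", "p", ["AA", "AC", "CA", "AA"])
        d = diversity_stats(h)
        assert d.s == 2
        assert d.theta_w * 2 == pytest.approx(1.090909090909091, abs=1e-12)
        assert d.theta_pi * 2 == pytest.approx(1.0, abs=1e-12)
        assert d.tajimas_d == pytest.approx(-0.709896167879475, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_pi_matches_exhaustive_pairwise_count(self, seed):
        rng = np.random.default_rng(seed)
        n, L = int(rng.integers(3, 9)), 40
        seqs = ["".join(rng.choice(list("ACGT"), L)) for _ in range(n)]
        h = HaplotypeSample("g", "p", seqs)
        d = diversity_stats(h)
        diffs = [
            sum(c1 != c2 for c1, c2 in zip(s1, s2)) / L
            for s1, s2 in itertools.combinations(seqs, 2)
        ]
        assert d.theta_pi == pytest.approx(np.mean(diffs), abs=1e-12)

    def test_missing_data_pairwise_complete(self):
        h = HaplotypeSample("g", "p", ["AC", "AN", "TC"])
        d = diversity_stats(h)
        # pair (1,2) compares only site 0; pairs with full data use both
        assert d.theta_pi == pytest.approx(np.mean([0.5, 0.0, 1.0]))

    def test_tajima_constants_published_form(self):
        c = tajima_constants(10)
        assert c["a1"] == pytest.approx(sum(1 / i for i in range(1, 10)))
        assert c["b1"] == pytest.approx(11 / 27)

    def test_matches_msprime_tskit_statistics(self):
        msprime = pytest.importorskip("msprime")
        ts = msprime.sim_ancestry(
            samples=10, ploidy=1, population_size=1, sequence_length=1000, random_seed=11
        )
        mts = msprime.sim_mutations(ts, rate=2e-3, random_seed=13, discrete_genome=False)
        geno = mts.genotype_matrix()  # variants x samples, infinite sites
        seqs = ["".join("ACGT"[a] for a in geno[:, j]) for j in range(geno.shape[1])]
        h = HaplotypeSample("g", "p", seqs)
        d = diversity_stats(h)
        assert d.s == mts.num_sites
        # mean pairwise differences per locus vs tskit's site diversity
        k_hat = d.theta_pi * mts.num_sites
        assert k_hat == pytest.approx(mts.diversity(span_normalise=False), rel=1e-9)
        assert d.tajimas_d == pytest.approx(mts.Tajimas_D(), rel=1e-9)


class TestFst:
    def test_fixed_difference_is_one(self):
        h1 = HaplotypeSample("g", "a", ["AAA", "AAA"])
        h2 = HaplotypeSample("g", "b", ["AAT", "AAT"])
        assert fst_hudson(h1, h2) == 1.0

    def test_identical_monomorphic_samples_undefined(self):
        h = HaplotypeSample("g", "a", ["AAA", "AAA"])
        assert fst_hudson(h, h) is None

    def test_panmictic_mean_near_zero(self):
        vals = []
        for seed in range(200):
            samples, _ = simulate_haplotypes((5, 5), L=400, theta=0.01, split_depth=0.0, seed=seed)
            f = fst_hudson(samples[0], samples[1])
            if f is not None:
                vals.append(f)
        assert abs(np.mean(vals)) < 0.05

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fst_hudson(
                HaplotypeSample("g", "a", ["AA", "AA"]),
                HaplotypeSample("g", "b", ["AAA", "AAA"]),
            )


class TestQst:
    def test_no_within_variance_gives_one(self):
        values = {"a1": 1.0, "a2": 1.0, "b1": 3.0, "b2": 3.0}
        pops = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        assert qst(values, pops) == 1.0

    def test_equal_means_truncates_to_zero(self):
        values = {"a1": 1.0, "a2": 3.0, "b1": 1.0, "b2": 3.0}
        pops = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        assert qst(values, pops) == 0.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        values = {f"s{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 10))}
        pops = {f"s{i}": ("A" if i < 5 else "B") for i in range(10)}
        shifted = {k: v + 100.0 for k, v in values.items()}
        assert qst(values, pops) == pytest.approx(qst(shifted, pops))

    def test_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            values = {f"s{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 8))}
            pops = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
            q = qst(values, pops)
            assert 0.0 <= q <= 1.0

    def test_pooled_recovery_planted_third(self):
        sim = simulate_expression(
            n_genes=500, n_samples=16, pop_effect_sd=1.0, strain_sd=1.0, seed=5
        )
        q = qst_pooled(
            (sim.matrix.loc[g].to_dict() for g in sim.matrix.index),
            sim.sample_populations,
        )
        assert q == pytest.approx(1 / 3, abs=0.05)

    def test_no_population_effect_gives_small_qst(self):
        sim = simulate_expression(n_genes=300, n_samples=16, pop_effect_sd=0.0, seed=6)
        q = qst_pooled(
            (sim.matrix.loc[g].to_dict() for g in sim.matrix.index),
            sim.sample_populations,
        )
        assert q < 0.05


class TestExpressionCorrelation:
    def test_perfect_linear_relationship_flagged(self):
        x = np.arange(25, dtype=float)
        matrix = pd.DataFrame({"s%d" % i: [x[i], 2 * x[i] + 3] for i in range(25)},
                              index=["g1", "g2"])
        res = expression_correlation([("g1", "g2")], matrix)
        row = res.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["coexpressed"]

    def test_too_few_points_unflagged(self):
        x = np.arange(19, dtype=float)
        matrix = pd.DataFrame({"s%d" % i: [x[i], 2 * x[i]] for i in range(19)},
                              index=["g1", "g2"])
        res = expression_correlation([("g1", "g2")], matrix)
        row = res.iloc[0]
        assert row["status"] == "insufficient"
        assert not row["coexpressed"]

    def test_null_rarely_flagged(self):
        flagged = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            matrix = pd.DataFrame(rng.standard_normal((2, 25)), index=["g1", "g2"])
            if expression_correlation([("g1", "g2")], matrix).iloc[0]["coexpressed"]:
                flagged += 1
        assert flagged <= 5

    def test_planted_pairs_recovered(self):
        sim = simulate_expression(n_genes=60, n_samples=30, n_planted_pairs=10,
                                  planted_r=0.9, seed=3)
        res = expression_correlation(sim.planted_pairs, sim.matrix)
        assert res["coexpressed"].mean() >= 0.9


class TestRankProduct:
    @staticmethod
    def _groups(seed=0, n_genes=150, sd=0.2):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_genes)]
        a = pd.DataFrame(rng.normal(0, sd, (n_genes, 4)), index=genes)
        b = pd.DataFrame(rng.normal(0, sd, (n_genes, 4)), index=genes)
        return a, b

    def test_extreme_gene_has_rank_product_one(self):
        a, b = self._groups()
        b.loc["g0"] += 10.0
        res = rank_product_de(a, b, n_perm=20, seed=1)
        assert res.loc["g0", "rp"] == 1.0
        assert res.loc["g0", "pfp"] <= 0.05

    def test_null_flags_almost_nothing(self):
        a, b = self._groups(seed=4)
        res = rank_product_de(a, b, n_perm=50, seed=2)
        assert (res["pfp"] <= 0.05).sum() <= 2

    def test_planted_twofold_shift_power(self):
        a, b = self._groups(seed=5, n_genes=200)
        shifted = [f"g{i}" for i in range(10)]
        b.loc[shifted] += 1.0  # two-fold change on the log2 scale
        res = rank_product_de(a, b, n_perm=100, seed=3)
        assert (res.loc[shifted, "pfp"] <= 0.05).mean() >= 0.8

    def test_too_few_permutations_rejected(self):
        a, b = self._groups()
        with pytest.raises(ValueError):
            rank_product_de(a, b, n_perm=5)


def test_haplotype_fasta_round_trip(tmp_path):
    samples, _ = simulate_haplotypes((3, 4), L=60, theta=0.05, seed=9)
    path = tmp_path / "g.fasta"
    write_haplotype_fasta(samples, path)
    back = read_haplotype_fasta(path, gene_id="gene")
    assert [s.population for s in back] == ["African", "American"]
    assert [s.sequences for s in back] == [s.sequences for s in samples]
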