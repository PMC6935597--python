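"""Diversity indices and hierarchical AMOVA against independent oracles.

The AMOVA oracle recomputes the three-level sums of squares by looping
over individual allele copies, with the unequal-sample-size coefficients
evaluated from their defining expectations -- an implementation kept
deliberately naive and separate from the vectorized production path.
"""

import numpy as np
import pandas as pd
import pytest

from cottonwood.diversity import (
    amova_hierarchical,
    diversity_indices,
    expected_heterozygosity,
)

from conftest import make_genotypes


@pytest.mark.parametrize("p,he", [(0.5, 0.5), (0.0, 0.0), (0.1, 0.18)])
def test_expected_heterozygosity_closed_form(p, he):
    assert expected_heterozygosity(p) == pytest.approx(he)


def test_expected_heterozygosity_rejects_bad_frequency():
    with pytest.raises(ValueError):
        expected_heterozygosity(1.2)


class TestDiversityIndices:
    def test_fixed_difference_gives_fst_one(self):
        calls = [[0, 0]] * 5 + [[2, 2]] * 5
        g = make_genotypes(calls, populations=["a"] * 5 + ["b"] * 5)
        div = diversity_indices(g, sample_size_correction=False)
        assert div.Fst_gst == pytest.approx(1.0)
        assert div.Fst_theta == pytest.approx(1.0)
        assert div.Ho == pytest.approx(0.0)

    def test_hand_evaluated_nei_gst_fixture(self):
        # pop1 genotype counts 0:4 1:4 2:2 -> p=0.4, pop2 0:1 1:4 2:5 -> p=0.7
        # Hs = (0.48 + 0.42)/2 = 0.45; pbar = 0.55, Ht = 0.495
        # Gst = (0.495 - 0.45)/0.495 = 1/11
        calls = [[0]] * 4 + [[1]] * 4 + [[2]] * 2 + [[0]] + [[1]] * 4 + [[2]] * 5
        g = make_genotypes(calls, populations=["a"] * 10 + ["b"] * 10)
        div = diversity_indices(g, sample_size_correction=False)
        assert div.Hs == pytest.approx(0.45, abs=1e-12)
        assert div.Ht == pytest.approx(0.495, abs=1e-12)
        assert div.Fst_gst == pytest.approx(1 / 11, abs=1e-12)
        assert div.Ho == pytest.approx(0.4, abs=1e-12)

    def test_null_panmixia_gives_near_zero_fst_and_fis(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(0.1, 0.9, 100)
        calls = rng.binomial(2, p, size=(150, 100)).astype(float)
        pops = [f"p{k}" for k in np.repeat(np.arange(3), 50)]
        div = diversity_indices(make_genotypes(calls, populations=pops))
        assert abs(div.Fst_theta_raw) < 0.02
        assert abs(div.Fis) < 0.02

    def test_gst_and_theta_agree_on_balanced_design(self):
        # Gst carries the classical (r-1)/r downward bias relative to theta
        # at small deme number, so the comparison uses many demes under
        # modest divergence where both target the same quantity
        rng = np.random.default_rng(23)
        p_anc = rng.uniform(0.2, 0.8, 120)
        f = 0.08
        calls, pops = [], []
        for k in range(10):
            pk = rng.beta(p_anc * (1 - f) / f, (1 - p_anc) * (1 - f) / f)
            calls.append(rng.binomial(2, pk, size=(50, 120)))
            pops += [f"p{k}"] * 50
        g = make_genotypes(np.vstack(calls).astype(float), populations=pops)
        div = diversity_indices(g)
        assert abs(div.Fst_gst_raw - div.Fst_theta_raw) < 0.02

    def test_small_populations_dropped_and_min_two_required(self):
        g = make_genotypes([[0], [1], [2]], populations=["a", "a", "b"])
        with pytest.raises(ValueError, match="two populations"):
            diversity_indices(g, min_pop_size=3)


def brute_force_amova(calls, pops, groups):
    """Oracle: allele-copy-level sums of squares and variance components."""
    calls = np.asarray(calls, dtype=float)
    pops = np.asarray(pops)
    groups = np.asarray(groups)
    s2a = s2b = s2c = 0.0
    for l in range(calls.shape[1]):
        alleles, apop, agrp = [], [], []
        for i in range(calls.shape[0]):
            gcode = calls[i, l]
            if np.isnan(gcode):
                continue
            # two allele copies per diploid: g of them are "1"
            for copy in range(2):
                alleles.append(1.0 if copy < gcode else 0.0)
                apop.append(pops[i])
                agrp.append(groups[i])
        alleles = np.array(alleles)
        apop = np.array(apop)
        agrp = np.array(agrp)
        N = len(alleles)
        pop_list = list(dict.fromkeys(apop))
        grp_list = list(dict.fromkeys(agrp))
        P, G = len(pop_list), len(grp_list)
        grand = alleles.mean()
        ss_w = sum(
            ((alleles[apop == p] - alleles[apop == p].mean()) ** 2).sum()
            for p in pop_list
        )
        grp_of_pop = {p: agrp[apop == p][0] for p in pop_list}
        ss_b = sum(
            (apop == p).sum()
            * (alleles[apop == p].mean() - alleles[agrp == grp_of_pop[p]].mean()) ** 2
            for p in pop_list
        )
        ss_a = sum(
            (agrp == g).sum() * (alleles[agrp == g].mean() - grand) ** 2
            for g in grp_list
        )
        df_w, df_b, df_a = N - P, P - G, G - 1
        n_p = {p: (apop == p).sum() for p in pop_list}
        n_g = {g: (agrp == g).sum() for g in grp_list}
        sum_np2_over_ng = sum(
            sum(n_p[p] ** 2 for p in pop_list if grp_of_pop[p] == g) / n_g[g]
            for g in grp_list
        )
        n1 = (N - sum_np2_over_ng) / df_b
        n2 = (sum_np2_over_ng - sum(v**2 for v in n_p.values()) / N) / df_a
        n3 = (N - sum(v**2 for v in n_g.values()) / N) / df_a
        msw, msb, msa = ss_w / df_w, ss_b / df_b, ss_a / df_a
        c = msw
        b = (msb - c) / n1
        a = (msa - c - n2 * b) / n3
        s2a += a
        s2b += b
        s2c += c
    return s2a, s2b, s2c


def _nested_groups(sim):
    """Group label per individual = its population's modal true lineage,
    so populations nest cleanly in groups even with admixed members."""
    lin = sim.ledger["lineage"]
    pop = sim.genotypes.individuals["population"]
    modal = lin.groupby(pop).agg(lambda s: s.mode().iloc[0])
    return pop.map(modal).map(lambda k: f"g{k}")


class TestAmova:
    def test_matches_brute_force_oracle_small_instance(self):
        # 2 groups, 3 unequal populations, 2 loci, with one missing call
        calls = np.array(
            [
                [0, 2], [1, 1], [0, 0], [2, 1],     # pop x (group A)
                [2, 2], [1, 0], [2, np.nan],        # pop y (group A)
                [0, 1], [0, 0], [1, 2], [0, 0],     # pop z (group B)
                [2, 0], [1, 1], [0, 2],             # pop w (group B)
            ]
        )
        pops = ["x"] * 4 + ["y"] * 3 + ["z"] * 4 + ["w"] * 3
        groups = ["A"] * 7 + ["B"] * 7
        g = make_genotypes(calls, populations=pops)
        res = amova_hierarchical(
            g, pd.Series(groups, index=g.calls.index), min_pop_size=2,
            n_permutations=0,
        )
        s2a, s2b, s2c = brute_force_amova(calls, pops, groups)
        assert res.sigma2_among_groups == pytest.approx(s2a, abs=1e-10)
        assert res.sigma2_among_pops == pytest.approx(s2b, abs=1e-10)
        assert res.sigma2_within == pytest.approx(s2c, abs=1e-10)

    def test_f_statistic_identity(self, structured_sim):
        g = structured_sim.genotypes
        groups = _nested_groups(structured_sim)
        res = amova_hierarchical(g, groups, n_permutations=0)
        assert (1 - res.Fct) * (1 - res.Fsc) == pytest.approx(1 - res.Fst, abs=1e-10)
        assert res.Fct > 0.05  # lineages genuinely differentiated

    def test_fixed_groups_give_fct_one(self):
        calls = [[0, 0]] * 6 + [[2, 2]] * 6
        pops = ["a"] * 3 + ["b"] * 3 + ["c"] * 3 + ["d"] * 3
        groups = ["G1"] * 6 + ["G2"] * 6
        g = make_genotypes(calls, populations=pops)
        res = amova_hierarchical(
            g, pd.Series(groups, index=g.calls.index), n_permutations=0
        )
        assert res.Fct == pytest.approx(1.0)

    def test_null_grouping_calibration(self):
        rng = np.random.default_rng(31)
        hits = 0
        n_reps = 40
        for rep in range(n_reps):
            p = rng.uniform(0.2, 0.8, 40)
            calls = rng.binomial(2, p, size=(60, 40)).astype(float)
            pops = [f"p{k}" for k in np.repeat(np.arange(6), 10)]
            groups = pd.Series(
                [f"G{k}" for k in np.repeat(np.arange(3), 20)],
            )
            g = make_genotypes(calls, populations=pops)
            groups.index = g.calls.index
            res = amova_hierarchical(g, groups, n_permutations=0)
            if abs(res.Fct) < 0.02:
                hits += 1
        assert hits / n_reps >= 0.95

    def test_permutation_pvalues_stable_across_seeds(self, structured_sim):
        g = structured_sim.genotypes
        groups = _nested_groups(structured_sim)
        p1 = amova_hierarchical(g, groups, n_permutations=99, seed=1).p_Fct
        p2 = amova_hierarchical(g, groups, n_permutations=99, seed=2).p_Fct
        # strong structure: both seeds should call it significant
        assert p1 <= 0.05 and p2 <= 0.05
        assert abs(p1 - p2) <= 2 * np.sqrt(0.05 * 0.95 / 99) + 1e-9
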