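import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import invgamma

from fbdmsc.msc import (IncompatibleError, MSCConfig, assign_lineages,
                        embed_stats, msc_log_density_explicit,
                        msc_log_density_integrated)
from fbdmsc.simulate import simulate_fbd_tree, simulate_gene_trees
from fbdmsc.fbd import FBDParams
from fbdmsc.trees import TaxonMap, TimeTree, TimeTreeNode, parse_tree

NEG_INF = float("-inf")


def one_species():
    return TimeTree(TimeTreeNode(label="S", age=0.0, is_sample=True))


def two_species(tau=1.0):
    a = TimeTreeNode(label="A", age=0.0, is_sample=True)
    b = TimeTreeNode(label="B", age=0.0, is_sample=True)
    return TimeTree(TimeTreeNode(age=tau, children=[a, b]))


class TestAssign:
    def test_single_lineage_probability_one(self):
        sp = one_species()
        gene = TimeTree(TimeTreeNode(label="S_1", age=0.0, is_sample=True))
        tm = TaxonMap.from_suffix(["S_1"])
        recs = assign_lineages(sp, gene, tm)
        cfg = MSCConfig(mode="explicit",
                        pop_sizes={r.branch_index: 0.5 for r in recs})
        assert msc_log_density_explicit(recs, cfg) == 0.0

    def test_fossil_only_branch_has_no_lineages(self):
        f = TimeTreeNode(label="F1", age=0.7, is_sample=True)
        a = TimeTreeNode(label="A", age=0.0, is_sample=True)
        b = TimeTreeNode(label="B", age=0.0, is_sample=True)
        inner = TimeTreeNode(age=1.0, children=[a, f])
        sp = TimeTree(TimeTreeNode(age=1.6, children=[inner, b]))
        gene = parse_tree("(A_1:1.9,B_1:1.9);")
        recs = assign_lineages(sp, gene, TaxonMap.from_suffix(
            ["A_1", "B_1"]))
        by_branch = {r.branch_index: r for r in recs}
        fb = by_branch[f.branch_index]
        assert fb.lineages_in == 0 and not fb.event_ages

    def test_two_species_forced_structure(self):
        sp = two_species(tau=1.0)
        gene = parse_tree("(A_1:1.6,B_1:1.6);")
        recs = assign_lineages(sp, gene, TaxonMap.from_suffix(
            ["A_1", "B_1"]))
        root_rec = [r for r in recs
                    if r.branch_index == sp.root.branch_index][0]
        assert root_rec.lineages_in == 2
        assert root_rec.event_ages == [pytest.approx(1.6)]

    def test_hand_tally_three_species(self):
        # ((A:1,B:1):1,C:2) with 2 samples in A; gene tree built by hand
        sp = parse_tree("((A:1,B:1):1,C:2);")
        gene = parse_tree(
            "(((A_1:0.5,A_2:0.5):1.0,B_1:1.5):1.0,C_1:2.5);")
        tm = TaxonMap.from_suffix(["A_1", "A_2", "B_1", "C_1"])
        recs = {r.branch_index: r
                for r in assign_lineages(sp, gene, tm)}
        a = sp.find("A")
        b = sp.find("B")
        c = sp.find("C")
        ab = sp.mrca(["A", "B"])
        root = sp.root
        assert recs[a.branch_index].lineages_in == 2
        assert len(recs[a.branch_index].event_ages) == 1  # coal at 0.5
        assert recs[b.branch_index].lineages_in == 1
        assert recs[ab.branch_index].lineages_in == 2
        assert len(recs[ab.branch_index].event_ages) == 1  # coal at 1.5
        assert recs[c.branch_index].lineages_in == 1
        assert recs[root.branch_index].lineages_in == 2
        assert len(recs[root.branch_index].event_ages) == 1  # coal at 2.5

    def test_incompatible_gene_tree(self):
        sp = two_species(tau=1.0)
        gene = parse_tree("(A_1:0.4,B_1:0.4);")  # coalesces below tau
        with pytest.raises(IncompatibleError):
            assign_lineages(sp, gene, TaxonMap.from_suffix(["A_1", "B_1"]))

    def test_unknown_species_is_error(self):
        sp = two_species()
        gene = parse_tree("(A_1:1.5,X_1:1.5);")
        with pytest.raises(ValueError):
            assign_lineages(sp, gene, TaxonMap.from_suffix(["A_1", "X_1"]))

    def test_fast_embedding_matches_reference(self, rng):
        params = FBDParams(1.0, 0.3, 0.6, 1.0, origin_age=3.5)
        for _ in range(20):
            sp = simulate_fbd_tree(params, n_extant=5, rng=rng)
            pop = {n.branch_index: 0.2 for n in sp.preorder()}
            cfg = MSCConfig(mode="explicit", pop_sizes=pop)
            genes, tm = simulate_gene_trees(sp, cfg, 2, 1, rng)
            ref = {r.branch_index: r.stats()
                   for r in assign_lineages(sp, genes[0], tm)}
            ref = {b: v for b, v in ref.items() if v != (0, 0.0)}
            tips = {id(t): sp.find(tm.species_of(t.label))
                    for t in genes[0].leaves()}
            fast = embed_stats(sp, genes[0], tips)
            assert set(fast) == set(ref)
            for b in ref:
                assert fast[b][0] == ref[b][0]
                assert fast[b][1] == pytest.approx(ref[b][1], abs=1e-12)


class TestExplicitDensity:
    def test_pair_closed_form(self):
        sp = one_species()
        gene = parse_tree("(S_1:0.7,S_2:0.7);")
        recs = assign_lineages(sp, gene, TaxonMap.from_suffix(
            ["S_1", "S_2"]))
        ne, ploidy = 0.4, 2.0
        cfg = MSCConfig(mode="explicit",
                        pop_sizes={r.branch_index: ne for r in recs},
                        ploidy=ploidy)
        got = msc_log_density_explicit(recs, cfg)
        want = -math.log(ploidy * ne) - 0.7 / (ploidy * ne)
        assert got == pytest.approx(want, abs=1e-12)

    def test_missing_population_size_is_error(self):
        sp = one_species()
        gene = parse_tree("(S_1:0.7,S_2:0.7);")
        recs = assign_lineages(sp, gene, TaxonMap.from_suffix(
            ["S_1", "S_2"]))
        with pytest.raises(KeyError):
            msc_log_density_explicit(
                recs, MSCConfig(mode="explicit", pop_sizes={}))

    def test_sa_split_same_size_is_neutral_explicit(self):
        # inserting a sampled ancestor splits a branch; with equal sizes
        # in both halves the explicit density is unchanged
        sp_plain = two_species(tau=1.0)
        f = TimeTreeNode(label="F1", age=0.5, is_sample=True)
        a = TimeTreeNode(label="A", age=0.0, is_sample=True)
        f.add_child(a)
        b = TimeTreeNode(label="B", age=0.0, is_sample=True)
        sp_sa = TimeTree(TimeTreeNode(age=1.0, children=[f, b]))
        gene = parse_tree("(A_1:1.4,B_1:1.4);")
        tm = TaxonMap.from_suffix(["A_1", "B_1"])
        d_plain = msc_log_density_explicit(
            assign_lineages(sp_plain, gene, tm),
            MSCConfig(mode="explicit", pop_sizes={
                n.branch_index: 0.3 for n in sp_plain.preorder()}))
        d_sa = msc_log_density_explicit(
            assign_lineages(sp_sa, gene, tm),
            MSCConfig(mode="explicit", pop_sizes={
                n.branch_index: 0.3 for n in sp_sa.preorder()}))
        assert d_sa == pytest.approx(d_plain, abs=1e-12)

    def test_sa_split_changes_integrated_density(self):
        # under marginalization each sub-branch is its own unit, so the
        # same insertion changes the integrated density
        sp_plain = two_species(tau=1.0)
        f = TimeTreeNode(label="F1", age=0.5, is_sample=True)
        a = TimeTreeNode(label="A", age=0.0, is_sample=True)
        f.add_child(a)
        b = TimeTreeNode(label="B", age=0.0, is_sample=True)
        sp_sa = TimeTree(TimeTreeNode(age=1.0, children=[f, b]))
        # two samples in A so that the split branch carries coalescent
        # exposure in both halves
        gene = parse_tree("((A_1:0.8,A_2:0.8):0.7,B_1:1.5);")
        tm = TaxonMap.from_suffix(["A_1", "A_2", "B_1"])
        cfg = MSCConfig(mode="integrated", ig_shape=3.0, ig_mean=0.3)
        d_plain = msc_log_density_integrated(
            [assign_lineages(sp_plain, gene, tm)], cfg)
        d_sa = msc_log_density_integrated(
            [assign_lineages(sp_sa, gene, tm)], cfg)
        assert abs(d_plain - d_sa) > 1e-6


class TestIntegratedDensity:
    def test_no_events_probability_one(self):
        sp = one_species()
        gene = TimeTree(TimeTreeNode(label="S_1", age=0.0, is_sample=True))
        recs = assign_lineages(sp, gene, TaxonMap.from_suffix(["S_1"]))
        cfg = MSCConfig(mode="integrated", ig_shape=3.0, ig_mean=0.5)
        assert msc_log_density_integrated([recs], cfg) == 0.0

    def test_matches_numerical_quadrature(self):
        # single branch, one pair coalescence: marginal over the
        # inverse-gamma prior to relative error < 1e-6
        t = 0.7
        alpha, mean, ploidy = 3.0, 0.4, 2.0
        beta = mean * (alpha - 1.0)
        sp = one_species()
        gene = parse_tree(f"(S_1:{t},S_2:{t});")
        recs = assign_lineages(sp, gene,
                               TaxonMap.from_suffix(["S_1", "S_2"]))
        cfg = MSCConfig(mode="integrated", ig_shape=alpha, ig_mean=mean,
                        ploidy=ploidy)
        got = msc_log_density_integrated([recs], cfg)

        def f(ne):
            dens = math.exp(-t / (ploidy * ne)) / (ploidy * ne)
            return dens * invgamma.pdf(ne, alpha, scale=beta)

        want = math.log(quad(f, 0, np.inf, limit=400)[0])
        assert got == pytest.approx(want, rel=1e-6)

    def test_large_shape_approaches_explicit(self):
        t = 0.7
        mean = 0.4
        sp = one_species()
        gene = parse_tree(f"(S_1:{t},S_2:{t});")
        tm = TaxonMap.from_suffix(["S_1", "S_2"])
        recs = assign_lineages(sp, gene, tm)
        explicit = msc_log_density_explicit(
            recs, MSCConfig(mode="explicit", pop_sizes={
                r.branch_index: mean for r in recs}))
        integ = msc_log_density_integrated(
            [recs], MSCConfig(mode="integrated", ig_shape=1e4,
                              ig_mean=mean))
        assert integ == pytest.approx(explicit, abs=1e-3)

    def test_monte_carlo_average_of_explicit(self, rng):
        # E_{Ne~IG}[exp(explicit)] converges to exp(integrated)
        t = 0.5
        alpha, mean = 3.0, 0.3
        beta = mean * (alpha - 1.0)
        sp = one_species()
        gene = parse_tree(f"(S_1:{t},S_2:{t});")
        recs = assign_lineages(sp, gene,
                               TaxonMap.from_suffix(["S_1", "S_2"]))
        cfg = MSCConfig(mode="integrated", ig_shape=alpha, ig_mean=mean)
        target = math.exp(msc_log_density_integrated([recs], cfg))
        ne = beta / rng.gamma(alpha, size=1_000_000)
        mc = np.mean(np.exp(-t / (2.0 * ne)) / (2.0 * ne))
        assert mc == pytest.approx(target, rel=0.02)

    def test_shape_below_one_is_error(self):
        with pytest.raises(ValueError):
            MSCConfig(mode="integrated", ig_shape=0.9,
                      ig_mean=1.0).validate()
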