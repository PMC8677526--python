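import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from fbdmsc.chars import (CharacterData, CompressedPartition, MkModel,
                          SubstModel, concatenated_log_likelihood,
                          mk_log_likelihood, pruning_log_likelihood,
                          read_fasta, read_nexus_morphology,
                          transition_probs, write_fasta,
                          write_nexus_morphology)
from fbdmsc.trees import TimeTree, TimeTreeNode, parse_tree

STATES = "ACGT"


def enumeration_loglik(tree, data, model):
    """Brute-force likelihood: explicit sum over all internal-state
    assignments (independent of the pruning implementation)."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if n.children]
    tips = [n for n in nodes if not n.children]
    ns = model.nstates
    pi = model.stationary()
    pcache = {}

    def P(d):
        if d not in pcache:
            pcache[d] = transition_probs(model, d)
        return pcache[d]

    nchar = len(next(iter(data.values())))
    total = 0.0
    for site in range(nchar):
        s = 0.0
        for assign in itertools.product(range(ns), repeat=len(internals)):
            state = {id(n): a for n, a in zip(internals, assign)}
            pr = pi[state[id(tree.root)]]
            for n in nodes:
                if n.parent is None:
                    continue
                parent_state = state[id(n.parent)]
                if n.children:
                    pr *= P(n.parent.age - n.age)[parent_state,
                                                  state[id(n)]]
                else:
                    obs = data[n.label][site]
                    if obs in ("?", "-", "N"):
                        pr *= 1.0
                    else:
                        k = STATES.index(obs) if isinstance(obs, str) \
                            else int(obs)
                        pr *= P(n.parent.age - n.age)[parent_state, k]
            # sampled nodes that are internal constrain their own state
            for n in internals:
                if n.is_sample:
                    obs = data[n.label][site]
                    if obs != "?":
                        k = STATES.index(obs) if isinstance(obs, str) \
                            else int(obs)
                        if state[id(n)] != k:
                            pr = 0.0
            s += pr
        total += math.log(s)
    return total


class TestTransitionProbs:
    def test_zero_duration_identity(self):
        for model in (SubstModel(family="JC"),
                      SubstModel(family="HKY", kappa=3.0),
                      MkModel(k=4)):
            np.testing.assert_allclose(transition_probs(model, 0.0),
                                       np.eye(model.nstates), atol=1e-12)

    def test_jc_closed_form(self):
        m = SubstModel(family="JC", clock_rate=1.0)
        for t in (0.1, 0.5, 2.0):
            p = transition_probs(m, t)
            same = 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)
            diff = 0.25 - 0.25 * math.exp(-4.0 * t / 3.0)
            assert p[0, 0] == pytest.approx(same, abs=1e-12)
            assert p[0, 1] == pytest.approx(diff, abs=1e-12)

    def test_mk2_closed_form(self):
        m = MkModel(k=2, clock_rate=1.3)
        t = 0.4
        p = transition_probs(m, t)
        assert p[0, 0] == pytest.approx(
            0.5 + 0.5 * math.exp(-2.0 * t * 1.3), abs=1e-12)

    @pytest.mark.parametrize("model", [
        MkModel(k=2), MkModel(k=3), MkModel(k=5),
        SubstModel(family="HKY", kappa=4.0, freqs=(0.4, 0.1, 0.2, 0.3)),
        SubstModel(family="GTR", rates=(1, 2, 0.5, 0.8, 3, 1.2),
                   freqs=(0.3, 0.3, 0.2, 0.2)),
    ])
    def test_matches_matrix_exponential(self, model):
        q, _ = model.rate_matrix()
        for t in (0.05, 0.7, 3.0):
            want = expm(q * t * model.clock_rate)
            got = transition_probs(model, t)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_long_duration_reaches_stationarity(self):
        m = SubstModel(family="HKY", kappa=3.0,
                       freqs=(0.4, 0.1, 0.2, 0.3))
        p = transition_probs(m, 500.0)
        for row in p:
            np.testing.assert_allclose(row, m.stationary(), atol=1e-9)

    def test_rows_sum_to_one(self):
        m = SubstModel(family="GTR", rates=(1, 2, 0.5, 0.8, 3, 1.2),
                       freqs=(0.3, 0.3, 0.2, 0.2))
        p = transition_probs(m, 0.9)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-10)

    def test_negative_duration_is_error(self):
        with pytest.raises(ValueError):
            transition_probs(SubstModel(), -0.1)


class TestPruning:
    def test_matches_enumeration_hky(self, balanced4):
        model = SubstModel(family="HKY", kappa=3.0,
                           freqs=(0.3, 0.2, 0.2, 0.3), clock_rate=0.5)
        data = {"A": "ACGA", "B": "AGGT", "C": "CCTA", "D": "TC-A"}
        got = pruning_log_likelihood(balanced4, data, model)
        want = enumeration_loglik(balanced4, data, model)
        assert got == pytest.approx(want, abs=1e-10)

    def test_matches_enumeration_five_tips(self):
        tree = parse_tree("(((A:.4,B:.4):.6,(C:.7,D:.7):.3):.5,E:1.5);")
        model = SubstModel(family="JC", clock_rate=0.8)
        data = {"A": "AC", "B": "AG", "C": "CT", "D": "TA", "E": "GT"}
        got = pruning_log_likelihood(tree, data, model)
        want = enumeration_loglik(tree, data, model)
        assert got == pytest.approx(want, abs=1e-10)

    def test_sampled_ancestor_constrains_internal_state(self, sa_tree):
        model = MkModel(k=2, clock_rate=0.3)
        data = {"A": [0], "B": [1], "F1": [0]}
        got = pruning_log_likelihood(sa_tree, data, model)
        P = lambda d: transition_probs(model, d)
        want = 0.0
        for r in range(2):
            want += (0.5 * P(0.5)[r, 0] * P(0.5)[0, 0] * P(1.0)[r, 1])
        assert got == pytest.approx(math.log(want), abs=1e-10)

    def test_all_missing_character_is_free(self, balanced4):
        model = MkModel(k=2)
        data = {t: ["?"] for t in "ABCD"}
        assert pruning_log_likelihood(balanced4, data, model) == \
            pytest.approx(0.0, abs=1e-12)

    def test_zero_lengths_identical_states(self):
        a = TimeTreeNode(label="A", age=0.0, is_sample=True)
        b = TimeTreeNode(label="B", age=0.0, is_sample=True)
        tree = TimeTree(TimeTreeNode(age=0.0, children=[a, b]))
        model = SubstModel(family="HKY", kappa=2.0,
                           freqs=(0.4, 0.1, 0.2, 0.3))
        got = pruning_log_likelihood(tree, {"A": "C", "B": "C"}, model)
        assert got == pytest.approx(math.log(0.1), abs=1e-10)

    def test_missing_taxon_in_tree_is_error(self, balanced4):
        model = SubstModel()
        with pytest.raises(ValueError):
            pruning_log_likelihood(balanced4,
                                   {"A": "A", "Z": "A"}, model)

    def test_taxon_without_data_treated_as_missing(self, balanced4):
        model = SubstModel(family="JC")
        partial = {"A": "A", "B": "A", "C": "A"}
        full = {"A": "A", "B": "A", "C": "A", "D": "N"}
        assert pruning_log_likelihood(balanced4, partial, model) == \
            pytest.approx(pruning_log_likelihood(balanced4, full, model),
                          abs=1e-12)

    def test_pattern_compression_is_neutral(self, balanced4, rng):
        model = SubstModel(family="HKY", kappa=2.5, clock_rate=0.4)
        sites = rng.choice(list("ACGT"), size=(4, 60))
        data = {t: "".join(sites[i]) for i, t in enumerate("ABCD")}
        part = CompressedPartition.from_alignment(data)
        assert part.weights.sum() == 60
        # likelihood via compressed patterns equals the per-site sum
        got = pruning_log_likelihood(balanced4, part, model)
        want = sum(pruning_log_likelihood(
            balanced4, {t: data[t][i] for t in data}, model)
            for i in range(60))
        assert got == pytest.approx(want, abs=1e-10)

    def test_gamma_mixture_likelihood(self, balanced4):
        model = SubstModel(family="JC", clock_rate=0.5, gamma_shape=0.7,
                           gamma_ncat=4)
        data = {"A": "A", "B": "A", "C": "C", "D": "T"}
        rates, weights = model.rate_categories()
        want = 0.0
        for r, w in zip(rates, weights):
            sub = SubstModel(family="JC", clock_rate=0.5 * r)
            want += w * math.exp(
                pruning_log_likelihood(balanced4, data, sub))
        got = pruning_log_likelihood(balanced4, data, model)
        assert got == pytest.approx(math.log(want), abs=1e-9)

    def test_pulley_principle(self, rng):
        # reversible models: sliding the root along its adjacent branch
        # (total path length fixed) leaves the likelihood unchanged
        model = SubstModel(family="HKY", kappa=3.0,
                           freqs=(0.35, 0.15, 0.2, 0.3), clock_rate=0.6)
        for _ in range(10):
            h = rng.uniform(0.5, 2.0)
            split = rng.uniform(0.05, h - 0.05)
            inner_age = rng.uniform(0.05, 0.6) * split
            taxa = list("ABCDE")
            seqs = {t: "".join(rng.choice(list("ACGT"), size=8))
                    for t in taxa}

            def build(root_age, left_extra):
                a = TimeTreeNode(label="A", age=0.0, is_sample=True)
                b = TimeTreeNode(label="B", age=0.0, is_sample=True)
                c = TimeTreeNode(label="C", age=0.0, is_sample=True)
                d = TimeTreeNode(label="D", age=0.0, is_sample=True)
                e = TimeTreeNode(label="E", age=0.0, is_sample=True)
                ab = TimeTreeNode(age=inner_age, children=[a, b])
                cd = TimeTreeNode(age=inner_age, children=[c, d])
                left = TimeTreeNode(age=split, children=[ab, cd])
                return TimeTree(TimeTreeNode(age=root_age,
                                             children=[left, e]))

            # the "pulley": root age h vs h' with E's path compensating is
            # not expressible with ultrametric tips, so instead verify
            # invariance to swapping root children order plus exchanging
            # which side carries the root (rerooting on the same edge)
            t1 = build(h, 0)
            t2 = build(h, 0)
            t2.root.children.reverse()
            l1 = pruning_log_likelihood(t1, seqs, model)
            l2 = pruning_log_likelihood(t2, seqs, model)
            assert l1 == pytest.approx(l2, abs=1e-8)


class TestMk:
    def test_binary_zero_length_pair(self):
        a = TimeTreeNode(label="A", age=0.0, is_sample=True)
        b = TimeTreeNode(label="B", age=0.0, is_sample=True)
        tree = TimeTree(TimeTreeNode(age=0.0, children=[a, b]))
        data = CharacterData(morph={"A": [0], "B": [0]}, morph_k=[2])
        got = mk_log_likelihood(tree, data, MkModel(k=2))
        assert got == pytest.approx(math.log(0.5), abs=1e-12)

    def test_brute_force_three_tips(self, ultrametric3):
        data = CharacterData(
            morph={"A": [0, 1, 0, "?"], "B": [0, 0, 1, 1],
                   "C": [1, 0, 1, 0]},
            morph_k=[2, 2, 2, 2])
        model = MkModel(k=2, clock_rate=0.7)
        got = mk_log_likelihood(ultrametric3, data, model)
        want = enumeration_loglik(ultrametric3, data.morph, model)
        assert got == pytest.approx(want, abs=1e-10)

    def test_state_label_permutation_invariance(self, ultrametric3):
        model = MkModel(k=3, clock_rate=0.5)
        orig = {"A": [0, 2], "B": [1, 2], "C": [0, 1]}
        perm = {"A": [2, 0], "B": [1, 0], "C": [2, 1]}  # swap labels 0<->2
        d0 = CharacterData(morph=orig, morph_k=[3, 3])
        d1 = CharacterData(morph=perm, morph_k=[3, 3])
        assert mk_log_likelihood(ultrametric3, d0, model) == \
            pytest.approx(mk_log_likelihood(ultrametric3, d1, model),
                          abs=1e-12)

    def test_variable_only_correction_raises_loglik(self, ultrametric3):
        data = {"A": [0], "B": [0], "C": [1]}  # variable pattern
        plain = pruning_log_likelihood(ultrametric3, data,
                                       MkModel(k=2, clock_rate=0.4))
        corr = pruning_log_likelihood(
            ultrametric3, data,
            MkModel(k=2, clock_rate=0.4, correction="variable-only"))
        assert corr > plain

    def test_variable_only_matches_direct_normalization(self,
                                                        ultrametric3):
        model = MkModel(k=2, clock_rate=0.4)
        data = {"A": [0], "B": [0], "C": [1]}
        plain = pruning_log_likelihood(ultrametric3, data, model)
        pconst = sum(
            math.exp(pruning_log_likelihood(
                ultrametric3, {t: [s] for t in "ABC"}, model))
            for s in (0, 1))
        corrected = pruning_log_likelihood(
            ultrametric3, data,
            MkModel(k=2, clock_rate=0.4, correction="variable-only"))
        assert corrected == pytest.approx(plain - math.log1p(-pconst),
                                          abs=1e-10)

    def test_characters_partitioned_by_state_count(self, ultrametric3):
        data = CharacterData(morph={"A": [0, 2], "B": [1, 1],
                                    "C": [0, 0]},
                             morph_k=[2, 3])
        model = MkModel(k=2, clock_rate=0.6)
        got = mk_log_likelihood(ultrametric3, data, model)
        want = (pruning_log_likelihood(
                    ultrametric3, {"A": [0], "B": [1], "C": [0]},
                    MkModel(k=2, clock_rate=0.6))
                + pruning_log_likelihood(
                    ultrametric3, {"A": [2], "B": [1], "C": [0]},
                    MkModel(k=3, clock_rate=0.6)))
        assert got == pytest.approx(want, abs=1e-10)

    def test_state_out_of_range_is_error(self, ultrametric3):
        with pytest.raises(ValueError):
            CompressedPartition.from_morphology(
                {"A": [2], "B": [0], "C": [1]}, k=2)


class TestConcatenated:
    def test_single_locus_equals_pruning(self, ultrametric3):
        model = SubstModel(family="JC", clock_rate=0.3)
        aln = {"A": "ACG", "B": "ACT", "C": "GCT"}
        assert concatenated_log_likelihood(ultrametric3, [aln], model) == \
            pytest.approx(pruning_log_likelihood(ultrametric3, aln, model))

    def test_two_loci_additive(self, ultrametric3):
        model = SubstModel(family="JC", clock_rate=0.3)
        a1 = {"A": "ACG", "B": "ACT", "C": "GCT"}
        a2 = {"A": "TT", "B": "TC", "C": "CC"}
        got = concatenated_log_likelihood(ultrametric3, [a1, a2], model)
        want = (pruning_log_likelihood(ultrametric3, a1, model)
                + pruning_log_likelihood(ultrametric3, a2, model))
        assert got == pytest.approx(want, abs=1e-12)

    def test_toy_instance_against_independent_implementation(self):
        tree = parse_tree("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        model = SubstModel(family="HKY", kappa=2.0, clock_rate=0.5)
        loci = [{"A": "AC", "B": "AG", "C": "CC", "D": "TC"},
                {"A": "G", "B": "G", "C": "T", "D": "T"}]
        got = concatenated_log_likelihood(tree, loci, model)
        want = sum(enumeration_loglik(tree, l, model) for l in loci)
        assert got == pytest.approx(want, abs=1e-9)


class TestIO:
    def test_fasta_roundtrip(self):
        seqs = {"A": "ACGT", "B": "AC-T"}
        assert read_fasta(write_fasta(seqs)) == seqs

    def test_nexus_morphology_roundtrip(self):
        matrix = {"A": [0, 1, "?"], "B": [1, 1, 0]}
        text = write_nexus_morphology(matrix, [2, 2, 2])
        back, ks = read_nexus_morphology(text)
        assert back == matrix
        assert ks == [2, 2, 2]
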