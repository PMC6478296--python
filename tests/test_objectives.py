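"""Objective functions: closed-form values, identities, independent oracles."""

import itertools
import math

import numpy as np
import pytest

from sbmbench.graph import Graph, Partition
from sbmbench.objectives import (OBJECTIVES, SBMParams, bernoulli_loglik_oracle,
                                 binary_entropy, get_objective, log_multiset,
                                 restricted_partitions_q)
from sbmbench._tables import log_q_table
from sbmbench.state import BlockState, MoveProposal

from conftest import random_simple_graph, random_state
from oracles import ORACLES, q_exact

ALL_NAMES = list(OBJECTIVES)
SIMPLE_ONLY = {"ICLexJ", "ICLexU"}


class TestPrimitives:
    def test_binary_entropy_closed_forms(self):
        assert binary_entropy(0.0) == 0.0
        assert binary_entropy(1.0) == 0.0
        assert binary_entropy(0.5) == pytest.approx(math.log(2))

    def test_binary_entropy_symmetry_and_domain(self):
        for x in np.linspace(0, 1, 13):
            assert binary_entropy(x) == pytest.approx(binary_entropy(1 - x))
        with pytest.raises(ValueError):
            binary_entropy(1.2)

    def test_log_multiset_against_exact_integers(self):
        assert log_multiset(5, 0) == 0.0
        assert log_multiset(2, 3) == pytest.approx(math.log(4))
        for n in range(1, 21):
            for k in range(0, 21):
                exact = math.comb(n + k - 1, k)
                assert log_multiset(n, k) == pytest.approx(math.log(exact))
        with pytest.raises(ValueError):
            log_multiset(-1, 2)

    def test_restricted_partitions(self):
        for m in range(12):
            assert restricted_partitions_q(m, 1) == 1
        assert restricted_partitions_q(4, 2) == 3   # {4, 3+1, 2+2}
        assert restricted_partitions_q(5, 5) == 7   # unrestricted p(5)
        with pytest.raises(ValueError):
            restricted_partitions_q(-1, 2)

    def test_log_q_table_matches_exact(self):
        table = log_q_table(15, 8)
        for m in range(16):
            for n in range(9):
                q = q_exact(m, n)
                if q == 0:
                    assert np.isneginf(table[m, n])
                else:
                    assert table[m, n] == pytest.approx(math.log(q))


class TestClosedFormValues:
    """Hand-evaluated toy values: two disjoint edges, matching blocks."""

    def test_skn(self, two_edges, two_edges_state):
        skn = get_objective("SKN")
        assert skn.value(two_edges_state) == pytest.approx(2 * math.log(0.5))
        one = BlockState(two_edges, Partition([0, 0, 0, 0]))
        assert skn.value(one) == pytest.approx(2 * math.log(0.25))

    def test_dckn(self, two_edges, two_edges_state):
        dckn = get_objective("DCKN")
        assert dckn.value(two_edges_state) == pytest.approx(-4 * math.log(2))
        one = BlockState(two_edges, Partition([0, 0, 0, 0]))
        assert dckn.value(one) == pytest.approx(4 * math.log(4 / 16))

    def test_empty_graph_entropy_forms(self):
        g = Graph([], n_nodes=4)
        st = BlockState(g, Partition([0, 0, 1, 1]))
        assert get_objective("SPC_dense").value(st) == 0.0
        assert get_objective("SPC_sparse").value(st) == 0.0

    def test_single_node_spc_priors_vanish(self):
        g = Graph([], n_nodes=1)
        st = BlockState(g, Partition([0]))
        assert get_objective("SPC").value(st) == pytest.approx(0.0)

    def test_dense_form_rejects_multigraph_density(self):
        g = Graph([(0, 1)] * 3, n_nodes=2)  # 3 parallel edges, 1 pair
        st = BlockState(g, Partition([0, 1]))
        with pytest.raises(ValueError, match="density"):
            get_objective("SPC_dense").value(st)

    def test_empty_block_rejected_unless_allowed(self, two_edges):
        st = BlockState(two_edges, Partition([0, 0, 0, 0], K=2,
                                             allow_empty=True))
        with pytest.raises(ValueError, match="empty"):
            get_objective("SKN").value(st)
        # SNR explicitly permits empty blocks
        assert np.isfinite(get_objective("SNR").value(st))


class TestIdentities:
    def test_constant_offsets_across_partitions(self):
        g = random_simple_graph(16, 32, seed=21)
        rng = np.random.default_rng(22)
        sparse, skn = get_objective("SPC_sparse"), get_objective("SKN")
        dcp, dckn = get_objective("DCP"), get_objective("DCKN")
        c_k = sum(math.log(math.factorial(k)) for k in g.degrees)
        for _ in range(50):
            st = random_state(g, int(rng.integers(2, 6)), int(rng.integers(1e6)))
            assert sparse.value(st) - skn.value(st) == pytest.approx(-g.M)
            assert dcp.value(st) - 0.5 * dckn.value(st) == \
                pytest.approx(g.M + c_k)

    def test_degree_one_graph_offset_is_m(self, two_edges):
        st = BlockState(two_edges, Partition([0, 0, 1, 1]))
        dcp, dckn = get_objective("DCP"), get_objective("DCKN")
        assert dcp.value(st) - 0.5 * dckn.value(st) == pytest.approx(two_edges.M)

    @pytest.mark.parametrize("name", ALL_NAMES)
    def test_relabel_invariance(self, name):
        g = random_simple_graph(14, 28, seed=23)
        st = random_state(g, 3, seed=24)
        obj = get_objective(name)
        v = obj.value(st)
        perm = np.array([1, 2, 0])
        st_p = BlockState(g, st.partition.relabel(perm))
        assert obj.value(st_p) == pytest.approx(v, rel=1e-12)

    def test_jeffrey_vs_uniform_prior_differ(self):
        g = random_simple_graph(12, 20, seed=25)
        st = random_state(g, 3, seed=26)
        vj = get_objective("ICLexJ").value(st)
        vu = get_objective("ICLexU").value(st)
        assert vj != pytest.approx(vu)

    def test_dcpu_equals_dcpuh_on_singleton_partition(self):
        g = random_simple_graph(8, 14, seed=27)
        st = BlockState(g, Partition(np.arange(8), K=8))
        # both degree priors degenerate when every block has one node
        assert get_objective("DCPU").value(st) == \
            pytest.approx(get_objective("DCPUH").value(st))

    def test_dcpuh_regular_graph_reduction(self):
        # 3-regular graph: one occupied histogram bin per block, so
        # DCPUH - DCPU = sum_r [ log((n_r, e_r)) - log q(e_r, n_r) ]
        g = Graph([(0, 1), (1, 2), (2, 3), (3, 0), (0, 2), (1, 3),
                   (4, 5), (5, 6), (6, 7), (7, 4), (4, 6), (5, 7)],
                  n_nodes=8, simple=True)
        assert np.all(g.degrees == 3)
        st = BlockState(g, Partition([0, 0, 0, 0, 1, 1, 1, 1]))
        diff = get_objective("DCPUH").value(st) - get_objective("DCPU").value(st)
        expect = sum(log_multiset(int(n), int(e))
                     - math.log(q_exact(int(e), int(n)))
                     for n, e in zip(st.n_r, st.e_r))
        assert diff == pytest.approx(expect)


@pytest.mark.parametrize("name", ALL_NAMES)
def test_value_matches_independent_transcription(name):
    """Dual-route check: kernel vs direct log-gamma / exact-integer oracle."""
    g = random_simple_graph(11, 22, seed=31)
    edges = [tuple(e) for e in g.edges]
    for K, seed in ((2, 32), (4, 33)):
        st = random_state(g, K, seed)
        expect = ORACLES[name](edges, st.labels.tolist(), K)
        assert get_objective(name).value(st) == \
            pytest.approx(expect, rel=1e-10, abs=1e-10)


@pytest.mark.parametrize("name", sorted(set(ALL_NAMES) - SIMPLE_ONLY))
def test_multigraph_value_matches_oracle(name):
    edges = [(0, 1), (0, 1), (2, 2), (1, 2), (3, 0), (3, 2)]
    g = Graph(edges, n_nodes=4)
    st = BlockState(g, Partition([0, 0, 1, 1]))
    expect = ORACLES[name](edges, [0, 0, 1, 1], 2)
    assert get_objective(name).value(st) == pytest.approx(expect, rel=1e-10)


class TestDeltaContract:
    def test_identity_move_zero(self, two_edges_state):
        for name in ALL_NAMES:
            assert get_objective(name).delta(
                two_edges_state, MoveProposal(0, 0, 0)) == 0.0

    @pytest.mark.parametrize("name", ALL_NAMES)
    def test_antisymmetry_after_applying(self, name):
        g = random_simple_graph(13, 26, seed=35)
        st = random_state(g, 3, seed=36, allow_empty=OBJECTIVES[name].allow_empty)
        obj = get_objective(name)
        rng = np.random.default_rng(37)
        done = 0
        while done < 10:
            i = int(rng.integers(g.N))
            r = int(st.labels[i])
            s = int(rng.integers(3))
            if s == r or (not obj.allow_empty and st.n_r[r] == 1):
                continue
            fwd = obj.delta(st, MoveProposal(i, r, s))
            st.apply_move(MoveProposal(i, r, s))
            back = obj.delta(st, MoveProposal(i, s, r))
            assert back == pytest.approx(-fwd, rel=1e-9, abs=1e-9)
            done += 1


class TestBernoulliOracle:
    def test_erdos_renyi_closed_form(self):
        g = random_simple_graph(10, 18, seed=41)
        st = BlockState(g, Partition(np.zeros(10, dtype=int), K=1))
        p = 0.3
        ll = bernoulli_loglik_oracle(st, SBMParams(np.array([[p]])),
                                     np.array([1.0]))
        n_pairs = 10 * 11 // 2  # diagonal pair convention n_r(n_r+1)/2
        assert ll == pytest.approx(g.M * math.log(p)
                                   + (n_pairs - g.M) * math.log(1 - p))

    def test_uniform_btilde_partition_term(self):
        g = Graph([], n_nodes=6)
        st = BlockState(g, Partition([0, 0, 1, 1, 2, 2]))
        omega = np.full((3, 3), 0.5)
        ll = bernoulli_loglik_oracle(st, SBMParams(omega), np.full(3, 1 / 3))
        # no edges: every pair contributes log(1-w); partition term N log(1/K)
        total_pairs = sum(4 if r != s else 3
                          for r in range(3) for s in range(r, 3))
        assert ll == pytest.approx(6 * math.log(1 / 3)
                                   + total_pairs * math.log(0.5))

    def test_profile_likelihood_ranking_matches_skn(self):
        """With ML-plug-in omega, the Bernoulli likelihood ranks partitions
        like the Poisson profile log-likelihood on sparse toy graphs."""
        g = random_simple_graph(6, 7, seed=43)
        skn = get_objective("SKN")
        scored = []
        for lab in itertools.product(range(2), repeat=6):
            if len(set(lab)) < 2:
                continue
            st = BlockState(g, Partition(np.array(lab), K=2))
            omega = np.empty((2, 2))
            for r in range(2):
                for s in range(2):
                    n_rs = (st.n_r[r] * st.n_r[s] if r != s
                            else st.n_r[r] * (st.n_r[r] + 1) // 2)
                    omega[r, s] = min(max(st.m(r, s) / n_rs, 1e-9), 1 - 1e-9)
            ll = bernoulli_loglik_oracle(st, SBMParams(omega), np.full(2, 0.5))
            scored.append((ll, skn.value(st), lab))
        def canon(lab):  # both scores are label-symmetric
            return lab if lab[0] == 0 else tuple(1 - x for x in lab)

        best_bern = canon(max(scored)[2])
        best_skn = canon(max(scored, key=lambda t: t[1])[2])
        assert best_bern == best_skn


def test_planted_partition_beats_random_partitions():
    """Strongly assortative planted 2-block SBM: the planted labels score
    highest among 1000 random 2-block labelings for every objective."""
    from sbmbench.generators import sample_sbm

    rng = np.random.default_rng(51)
    omega = np.array([[0.6, 0.02], [0.02, 0.6]])
    g, planted = sample_sbm([20, 20], SBMParams(omega), rng)
    planted_states = {}
    for name in ALL_NAMES:
        obj = get_objective(name)
        planted_states[name] = obj.value(
            BlockState(g, Partition(planted.labels, K=2)))
    best_random = {name: -np.inf for name in ALL_NAMES}
    for _ in range(1000):
        labels = rng.integers(0, 2, size=40)
        if len(np.unique(labels)) < 2:
            continue
        st = BlockState(g, Partition(labels, K=2))
        for name in ALL_NAMES:
            v = get_objective(name).value(st)
            best_random[name] = max(best_random[name], v)
    for name in ALL_NAMES:
        assert planted_states[name] > best_random[name], name
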