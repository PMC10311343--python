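from fractions import Fraction

import pytest

from splicewire import (
    IlpParams,
    build_ilp,
    consensus,
    diff_networks,
    enumerate_solutions,
    validate_solution,
)
from splicewire.ilp import SolutionNetwork, load_solution, write_solution
from splicewire.pool import load_consensus, write_consensus
from splicewire.prior import InputError
from tests.conftest import make_skip_table, make_tf_table

PARAMS = IlpParams(alpha=0.1, lam=0.01)


@pytest.fixture
def two_path_instance(two_path_net):
    tf_table = make_tf_table([("T", 1.0, True)])
    return two_path_net, build_ilp(two_path_net, tf_table, make_skip_table([]), "hard", PARAMS)


class TestEnumerateSolutions:
    def test_two_equal_cost_paths_two_solutions(self, two_path_instance):
        net, inst = two_path_instance
        pool = enumerate_solutions(inst, k_max=10, objective_tolerance=0.0)
        assert len(pool) == 2
        assert all(s.objective_value == pytest.approx(0.90) for s in pool)
        sigs = {s.edge_signature for s in pool}
        assert len(sigs) == 2  # pairwise distinct edge sets
        for s in pool:
            assert validate_solution(net, set(), s) == []

    def test_unique_optimum_single_solution(self, chain_net, chain_tf_table, empty_skips):
        inst = build_ilp(chain_net, chain_tf_table, empty_skips, "hard", PARAMS)
        pool = enumerate_solutions(inst, k_max=50, objective_tolerance=0.0)
        assert len(pool) == 1

    def test_k_max_one_matches_single_solve(self, two_path_instance):
        from splicewire import solve

        net, inst = two_path_instance
        pool = enumerate_solutions(inst, k_max=1)
        assert len(pool) == 1
        assert pool[0].edge_signature == solve(inst).edge_signature

    def test_tolerance_admits_near_optima(self, two_path_instance):
        # with a loose tolerance the pool also includes costlier selections
        net, inst = two_path_instance
        strict = enumerate_solutions(inst, k_max=20, objective_tolerance=0.0)
        loose = enumerate_solutions(inst, k_max=20, objective_tolerance=0.5)
        assert len(loose) > len(strict)

    def test_invalid_arguments(self, two_path_instance):
        _, inst = two_path_instance
        with pytest.raises(InputError):
            enumerate_solutions(inst, k_max=0)
        with pytest.raises(InputError):
            enumerate_solutions(inst, objective_tolerance=-0.1)


from hypothesis import given, settings
from hypothesis import strategies as st


def _sol(ddis, mode="hard"):
    return SolutionNetwork(ddis=frozenset(ddis), mode=mode)


E1 = ((("A", "a"), ("B", "b")), "ab")
E2 = ((("B", "b"), ("C", "c")), "ab")
E3 = ((("C", "c"), ("D", "d")), "ab")


class TestConsensus:
    def test_weights_are_exact_counts_over_pool_size(self):
        cn = consensus([_sol({E1, E2}), _sol({E1, E3})])
        assert Fraction(cn.ddi_counts[E1], cn.n_solutions) == Fraction(1, 1)
        assert Fraction(cn.ddi_counts[E2], cn.n_solutions) == Fraction(1, 2)
        assert Fraction(cn.ddi_counts[E3], cn.n_solutions) == Fraction(1, 2)

    def test_pool_of_one_all_weights_one(self):
        cn = consensus([_sol({E1, E2})])
        assert all(c == cn.n_solutions for c in cn.ddi_counts.values())

    def test_empty_pool_rejected(self):
        with pytest.raises(InputError):
            consensus([])

    def test_mixed_modes_rejected(self):
        with pytest.raises(InputError):
            consensus([_sol({E1}, "hard"), _sol({E1}, "soft")])


@given(
    st.lists(
        st.sets(st.sampled_from([E1, E2, E3])),
        min_size=1,
        max_size=8,
    )
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_consensus_counts_equal_membership_exactly(edge_sets):
    pool = [_sol(edges) for edges in edge_sets]
    cn = consensus(pool)
    assert cn.n_solutions == len(pool)
    for key in (E1, E2, E3):
        members = sum(1 for s in pool if key in s.ddis)
        assert cn.ddi_counts.get(key, 0) == members
        if members:
            assert 0 < Fraction(members, len(pool)) <= 1


class TestDiffNetworks:
    def test_partition_and_abrogation_flag(self):
        aware = consensus([_sol({E2})])
        unaware = consensus([_sol({E1, E2})])
        skips = make_skip_table([("A", "a", 0.001, -0.5, True)])
        rep = diff_networks(aware, unaware, skips=skips)
        by_key = {(r.protein_a, r.domain_a, r.protein_b, r.domain_b): r
                  for r in rep.itertuples(index=False)}
        e1 = by_key[("A", "a", "B", "b")]
        assert e1.status == "unaware_only"
        assert e1.splice_abrogated
        e2 = by_key[("B", "b", "C", "c")]
        assert e2.status == "shared" and not e2.splice_abrogated

    def test_identical_pools_all_shared(self):
        cn = consensus([_sol({E1, E2})])
        rep = diff_networks(cn, cn)
        assert (rep.status == "shared").all()

    def test_empty_aware_pool_everything_unaware_only(self):
        aware = consensus([_sol(set())])
        unaware = consensus([_sol({E1, E2})])
        rep = diff_networks(aware, unaware)
        assert (rep.status == "unaware_only").all()

    def test_antisymmetry(self):
        a = consensus([_sol({E1, E2})])
        b = consensus([_sol({E2, E3})])
        fwd = diff_networks(a, b)
        rev = diff_networks(b, a)
        fwd_only = set(map(tuple, fwd[fwd.status == "aware_only"][["protein_a", "domain_a"]].values))
        rev_only = set(map(tuple, rev[rev.status == "unaware_only"][["protein_a", "domain_a"]].values))
        assert fwd_only == rev_only


def test_solution_and_consensus_round_trip(tmp_path):
    sol = SolutionNetwork(
        proteins=frozenset({"A", "B"}),
        domains=frozenset({("A", "a"), ("B", "b")}),
        ddis=frozenset({E1}),
        ppis=frozenset({(("A", "B"), "ab")}),
        roots=frozenset({"A"}),
        tfs_reached=frozenset({"B"}),
        objective_value=0.5,
        mode="soft",
    )
    path = tmp_path / "sol.tsv"
    write_solution(sol, path)
    back = load_solution(path)
    assert back.ddis == sol.ddis
    assert back.roots == sol.roots
    assert back.mode == "soft"
    assert back.objective_value == pytest.approx(0.5)

    cn = consensus([sol, SolutionNetwork(ddis=frozenset({E1, E2}), mode="soft")])
    cpath = tmp_path / "cons.tsv"
    write_consensus(cn, cpath)
    cback = load_consensus(cpath)
    assert cback.n_solutions == 2
    assert cback.ddi_counts == cn.ddi_counts
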