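import pytest

from splicewire import (
    InteractionRecord,
    IlpParams,
    SolutionNetwork,
    attach_perturbation,
    build_ilp,
    build_network,
    enumerate_optimum,
    solve,
    validate_solution,
)
from splicewire.ilp import BackendError, ParameterError, export_lp, export_mps
from splicewire.prior import InputError
from splicewire.splice import skip_scores, skipped_domains
from tests.conftest import make_skip_table, make_tf_table


PARAMS = IlpParams(alpha=0.1, lam=0.01)


class TestChainInstance:
    """PERTURBATION -> A(a1) -- T(t1), one significant TF of weight 1."""

    def test_full_path_selected_objective(self, chain_net, chain_tf_table, empty_skips):
        inst = build_ilp(chain_net, chain_tf_table, empty_skips, "hard", PARAMS)
        sol = solve(inst)
        # 1 - 0.01 * (2 proteins + 2 domains + 1 DDI + 1 PPI)
        assert sol.objective_value == pytest.approx(0.94, abs=1e-9)
        assert sol.solver_status == "optimal"
        assert sol.tfs_reached == {"T"}
        assert sol.roots == {"A"}
        assert validate_solution(chain_net, empty_skips, sol) == []

    def test_matches_enumeration(self, chain_net, chain_tf_table, empty_skips):
        obj, osol = enumerate_optimum(
            chain_net, {"T": 1.0}, {"T": True}, set(), mode="hard", lam=0.01
        )
        assert obj == pytest.approx(0.94, abs=1e-12)
        assert osol.ddis == solve(
            build_ilp(chain_net, chain_tf_table, empty_skips, "hard", PARAMS)
        ).ddis

    def test_hard_mode_skipped_tf_domain_empties_network(self, chain_net, chain_tf_table):
        skips = make_skip_table([("T", "t1", 0.01, -0.4, True)])
        sol = solve(build_ilp(chain_net, chain_tf_table, skips, "hard", PARAMS))
        assert sol.is_empty()
        assert sol.objective_value == 0.0

    def test_soft_mode_penalty_arithmetic(self, chain_net, chain_tf_table):
        # s = -log10(0.01) = 2; beta=0.6: 1 - 0.06 - 1.2 < 0 -> empty wins
        skips = make_skip_table([("T", "t1", 0.01, -0.4, True)])
        heavy = IlpParams(alpha=0.1, lam=0.01, beta=0.6)
        sol = solve(build_ilp(chain_net, chain_tf_table, skips, "soft", heavy))
        assert sol.is_empty()
        # beta=0.3: 1 - 0.06 - 0.6 = 0.34 > 0 -> path survives the penalty
        light = IlpParams(alpha=0.1, lam=0.01, beta=0.3)
        sol = solve(build_ilp(chain_net, chain_tf_table, skips, "soft", light))
        assert sol.objective_value == pytest.approx(0.34, abs=1e-9)
        assert sol.tfs_reached == {"T"}

    def test_zero_significant_tfs_empty_network(self, chain_net, empty_skips):
        tf_table = make_tf_table([("T", 1.0, False)])
        sol = solve(build_ilp(chain_net, tf_table, empty_skips, "hard", PARAMS))
        assert sol.is_empty()
        assert sol.objective_value == 0.0

    def test_lambda_zero_still_reaches_tf(self, chain_net, chain_tf_table, empty_skips):
        inst = build_ilp(chain_net, chain_tf_table, empty_skips, "hard",
                         IlpParams(alpha=0.1, lam=0.0))
        sol = solve(inst)
        assert sol.objective_value == pytest.approx(1.0, abs=1e-9)
        assert sol.tfs_reached == {"T"}


class TestBuildErrors:
    def test_no_tf_in_prior_raises(self, chain_net, empty_skips):
        tf_table = make_tf_table([("NOT_IN_NET", 1.0, True)])
        with pytest.raises(InputError):
            build_ilp(chain_net, tf_table, empty_skips, "hard", PARAMS)

    def test_negative_parameters_rejected(self, chain_net, chain_tf_table, empty_skips):
        with pytest.raises(ParameterError):
            build_ilp(chain_net, chain_tf_table, empty_skips, "hard", IlpParams(lam=-1))
        with pytest.raises(ParameterError):
            build_ilp(chain_net, chain_tf_table, empty_skips, "hard", IlpParams(alpha=-1))

    def test_unknown_backend_names_alternatives(self, chain_net, chain_tf_table, empty_skips):
        inst = build_ilp(chain_net, chain_tf_table, empty_skips, "hard", PARAMS)
        with pytest.raises(BackendError, match="highs"):
            solve(inst, backend="cplex")

    def test_brute_backend_agrees(self, chain_net, chain_tf_table, empty_skips):
        inst = build_ilp(chain_net, chain_tf_table, empty_skips, "hard", PARAMS)
        assert solve(inst, backend="brute").objective_value == pytest.approx(0.94)


class TestValidateSolution:
    def test_hand_built_skipped_domain_violation(self, chain_net):
        skips = make_skip_table([("T", "t1", 0.01, -0.4, True)])
        key = next(iter(chain_net.ddis))
        sol = SolutionNetwork(
            proteins=frozenset({"A", "T"}),
            domains=frozenset({("A", "a1"), ("T", "t1")}),
            ddis=frozenset({(key, "ab")}),
            ppis=frozenset({(("A", "T"), "ab")}),
            roots=frozenset({"A"}),
            tfs_reached=frozenset({"T"}),
            mode="hard",
        )
        kinds = {v.kind for v in validate_solution(chain_net, skips, sol)}
        assert kinds == {"skipped_domain_selected"}

    def test_two_cycle_detected(self):
        net = build_network(
            [
                InteractionRecord("A", "a1", "B", "b1"),
                InteractionRecord("A", "a2", "B", "b2"),
            ]
        )
        attach_perturbation(net, roots=["A"])
        k1 = (("A", "a1"), ("B", "b1"))
        k2 = (("A", "a2"), ("B", "b2"))
        sol = SolutionNetwork(
            proteins=frozenset({"A", "B"}),
            domains=frozenset({("A", "a1"), ("B", "b1"), ("A", "a2"), ("B", "b2")}),
            ddis=frozenset({(k1, "ab"), (k2, "ba")}),
            ppis=frozenset({(("A", "B"), "ab"), (("A", "B"), "ba")}),
            roots=frozenset({"A"}),
            mode="hard",
        )
        kinds = {v.kind for v in validate_solution(net, set(), sol)}
        assert "cycle" in kinds

    def test_solver_output_always_certifies(self, chain_net, chain_tf_table, empty_skips):
        sol = solve(build_ilp(chain_net, chain_tf_table, empty_skips, "hard", PARAMS))
        assert validate_solution(chain_net, empty_skips, sol) == []


class TestDirectionHandling:
    def test_annotated_direction_restricts_orientation(self, two_path_net):
        for key in two_path_net.ddis:
            assert len(two_path_net.allowed_orientations(key)) == 1

    def test_self_interaction_never_selected(self):
        net = build_network(
            [
                InteractionRecord("A", "a1", "A", "a2"),
                InteractionRecord("A", "a1", "T", "t1"),
            ]
        )
        attach_perturbation(net, roots=["A"])
        tf_table = make_tf_table([("T", 1.0, True)])
        sol = solve(build_ilp(net, tf_table, make_skip_table([]), "hard", PARAMS))
        assert all(key[0][0] != key[1][0] for key, _d in sol.ddis)
        assert ("A", "a2") not in sol.domains


def test_oracle_tracks_min_size_optimum(two_path_net):
    obj, sol = enumerate_optimum(
        two_path_net, {"T": 1.0}, {"T": True}, set(), mode="hard", lam=0.01
    )
    # one route: 3 proteins + 3 domains + 2 DDIs + 2 PPIs = 10 elements
    assert obj == pytest.approx(1.0 - 0.10, abs=1e-12)
    assert sol.n_elements == 10


def test_instance_export_formats(tmp_path, chain_net, chain_tf_table, empty_skips):
    inst = build_ilp(chain_net, chain_tf_table, empty_skips, "hard", PARAMS)
    lp, mps = tmp_path / "m.lp", tmp_path / "m.mps"
    export_lp(inst, lp)
    export_mps(inst, mps)
    text = lp.read_text()
    assert "Minimize" in text and "Binaries" in text and "t_T" in text
    assert "ENDATA" in mps.read_text()


def test_monotone_regularization_on_oracle(two_path_net):
    sizes = []
    for lam in (0.0, 0.01, 0.05, 0.2):
        _, sol = enumerate_optimum(
            two_path_net, {"T": 1.0}, {"T": True}, set(), mode="hard", lam=lam
        )
        sizes.append(sol.n_elements)
    assert sizes == sorted(sizes, reverse=True)
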