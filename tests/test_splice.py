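import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from splicewire import (
    FeatureEvidence,
    InteractionRecord,
    build_network,
    call_skipped_domains,
    fisher_aggregate,
    mean_effect,
    skipped_domains,
)
from splicewire.prior import InputError
from splicewire.splice import skip_scores


def closed_form_fisher(p_values):
    """Chi-square upper tail at X=-2*sum(ln p) with df=2k, via the closed form
    for even df: exp(-x/2) * sum_{j<k} (x/2)^j / j!."""
    k = len(p_values)
    x = -2.0 * sum(math.log(p) for p in p_values)
    half = x / 2.0
    return math.exp(-half) * sum(half**j / math.factorial(j) for j in range(k))


class TestFisherAggregate:
    def test_single_p_is_identity(self):
        assert fisher_aggregate([0.05]) == pytest.approx(0.05, abs=1e-12)

    def test_two_value_example(self):
        # X = -2(ln 0.01 + ln 0.04) ~= 15.65, df=4
        expected = closed_form_fisher([0.01, 0.04])
        assert expected == pytest.approx(3.52e-3, rel=2e-2)
        assert fisher_aggregate([0.01, 0.04]) == pytest.approx(expected, abs=1e-12)

    def test_all_ones_gives_one(self):
        assert fisher_aggregate([1.0, 1.0, 1.0]) == 1.0

    def test_matches_closed_form_on_random_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = int(rng.integers(1, 6))
            ps = list(rng.uniform(1e-6, 1.0, size=k))
            assert fisher_aggregate(ps) == pytest.approx(closed_form_fisher(ps), abs=1e-9)

    def test_matches_numerical_integration(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            k = int(rng.integers(1, 5))
            ps = list(rng.uniform(1e-4, 1.0, size=k))
            x = -2.0 * sum(math.log(p) for p in ps)
            oracle, _ = integrate.quad(lambda t: stats.chi2.pdf(t, df=2 * k), x, np.inf)
            assert fisher_aggregate(ps) == pytest.approx(oracle, abs=1e-9)

    @pytest.mark.parametrize("bad", [[], [0.0], [-0.1], [1.5]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(InputError):
            fisher_aggregate(bad)

    def test_adding_null_feature_never_flips_towards_significance(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            ps = list(rng.uniform(1e-4, 1.0, size=int(rng.integers(1, 4))))
            base = fisher_aggregate(ps)
            augmented = fisher_aggregate(ps + [1.0])
            # same X, one more df: the tail probability can only grow
            assert augmented >= base - 1e-12


@given(
    st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=6)
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_fisher_is_a_permutation_invariant_probability(ps):
    p = fisher_aggregate(ps)
    assert 0.0 < p <= 1.0
    assert fisher_aggregate(list(reversed(ps))) == pytest.approx(p, abs=1e-12)
    # combining k copies of 1.0 stays at 1.0; any p<1 pulls X above 0
    assert fisher_aggregate([1.0] * len(ps)) == 1.0


class TestMeanEffect:
    @pytest.mark.parametrize(
        "effects,expected",
        [([-0.3, -0.5], -0.4), ([0.2], 0.2), ([-1.0, 1.0], 0.0)],
    )
    def test_examples(self, effects, expected):
        assert mean_effect(effects) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            mean_effect([])


@pytest.fixture
def mapped_net():
    return build_network(
        [
            InteractionRecord(
                "A", "d1", "B", "d2",
                exons_a=("e1", "e2"), exons_b=("e3",), transcripts_b=("t1",),
            )
        ]
    )


class TestCallSkippedDomains:
    def test_exclusion_evidence_calls_skip(self, mapped_net):
        evidence = [
            FeatureEvidence("e1", -0.4, 0.01),
            FeatureEvidence("e2", -0.2, 0.04),
        ]
        table = call_skipped_domains(mapped_net, evidence)
        row = table[(table.protein == "A") & (table.domain == "d1")].iloc[0]
        assert row.aggregated_p == pytest.approx(closed_form_fisher([0.01, 0.04]), abs=1e-12)
        assert row.mean_effect == pytest.approx(-0.3)
        assert row.n_features == 2
        assert bool(row.skipped)

    def test_inclusion_direction_blocks_skip(self, mapped_net):
        evidence = [
            FeatureEvidence("e1", +0.4, 0.01),
            FeatureEvidence("e2", +0.2, 0.04),
        ]
        table = call_skipped_domains(mapped_net, evidence)
        assert not table.skipped.any()

    def test_unmatched_domain_absent(self, mapped_net):
        table = call_skipped_domains(mapped_net, [FeatureEvidence("e1", -0.4, 0.01)])
        assert ("B", "d2") not in set(zip(table.protein, table.domain))

    def test_no_matches_yields_empty_table(self, mapped_net):
        table = call_skipped_domains(mapped_net, [FeatureEvidence("zz", -0.4, 0.01)])
        assert table.empty

    def test_transcript_and_exon_evidence_pooled(self, mapped_net):
        evidence = [
            FeatureEvidence("e3", -0.4, 0.03, "exon"),
            FeatureEvidence("t1", -1.2, 0.02, "transcript"),
        ]
        table = call_skipped_domains(mapped_net, evidence)
        row = table[(table.protein == "B")].iloc[0]
        assert row.n_features == 2
        assert row.aggregated_p == pytest.approx(closed_form_fisher([0.03, 0.02]), abs=1e-12)

    def test_lower_threshold_never_adds_skips(self, mapped_net):
        rng = np.random.default_rng(11)
        evidence = [
            FeatureEvidence(f, float(rng.uniform(-0.5, 0.1)), float(rng.uniform(0.001, 0.5)))
            for f in ("e1", "e2", "e3", "t1")
        ]
        loose = skipped_domains(call_skipped_domains(mapped_net, evidence, p_threshold=0.1))
        tight = skipped_domains(call_skipped_domains(mapped_net, evidence, p_threshold=0.01))
        assert tight <= loose

    def test_strict_mode_requires_every_feature(self, mapped_net):
        evidence = [
            FeatureEvidence("e1", -0.4, 0.001),
            FeatureEvidence("e2", -0.2, 0.2),  # individually insignificant
        ]
        default = call_skipped_domains(mapped_net, evidence)
        strict = call_skipped_domains(mapped_net, evidence, strict_all_features=True)
        assert bool(default.iloc[0].skipped)
        assert not strict.iloc[0].skipped

    def test_dpsi_clipped(self):
        ev = FeatureEvidence("e1", -1.7, 0.01, "exon")
        assert ev.effect == -1.0

    def test_skip_scores_are_neg_log10(self, mapped_net):
        table = call_skipped_domains(
            mapped_net, [FeatureEvidence("e1", -0.4, 0.01), FeatureEvidence("e2", -0.4, 0.01)]
        )
        scores = skip_scores(table)
        (dom, s), = scores.items()
        assert s == pytest.approx(-math.log10(table.iloc[0].aggregated_p))
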