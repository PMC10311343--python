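import pandas as pd
import pytest

from splicewire import InteractionRecord, attach_perturbation, build_network
from splicewire.splice import SKIP_COLUMNS
from splicewire.tf import TF_COLUMNS


def make_tf_table(rows):
    """rows: list of (tf, weight, significant)."""
    return pd.DataFrame(
        [
            {"tf": t, "score": w, "empirical_p": 0.001 if s else 0.5,
             "significant": s, "weight": abs(w)}
            for t, w, s in rows
        ],
        columns=TF_COLUMNS,
    )


def make_skip_table(rows):
    """rows: list of (protein, domain, aggregated_p, mean_effect, skipped)."""
    return pd.DataFrame(
        [
            {"protein": p, "domain": d, "aggregated_p": ap, "mean_effect": me,
             "n_features": 1, "skipped": sk}
            for p, d, ap, me, sk in rows
        ],
        columns=SKIP_COLUMNS,
    )


@pytest.fixture
def empty_skips():
    return make_skip_table([])


@pytest.fixture
def chain_net():
    """PERTURBATION -> A(a1) -- DDI -- T(t1), T a significant TF of weight 1."""
    net = build_network(
        [InteractionRecord(protein_a="A", domain_a="a1", protein_b="T", domain_b="t1")]
    )
    attach_perturbation(net, roots=["A"])
    return net


@pytest.fixture
def chain_tf_table():
    return make_tf_table([("T", 1.0, True)])


@pytest.fixture
def two_path_net():
    """R -> B -> T and R -> C -> T: two equal-cost routes to one TF."""
    net = build_network(
        [
            InteractionRecord("R", "r1", "B", "b1", direction="ab"),
            InteractionRecord("R", "r1", "C", "c1", direction="ab"),
            InteractionRecord("B", "b1", "T", "t1", direction="ab"),
            InteractionRecord("C", "c1", "T", "t1", direction="ab"),
        ]
    )
    attach_perturbation(net, roots=["R"])
    return net
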