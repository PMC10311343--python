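"""Over-representation analysis of inferred network node sets.

One-sided hypergeometric upper-tail test of the overlap between the proteins
of an inferred network and each gene set of a GMT collection; scores are
reported as -log10(p). The default background universe is the prior network's
protein complement, since the inference can only ever select prior proteins.
"""

from __future__ import annotations

import logging
import math

import pandas as pd
from scipy import stats

from .prior import InputError

logger = logging.getLogger(__name__)

ORA_COLUMNS = [
    "set_name", "overlap", "set_size", "network_size", "universe_size", "p_value", "score",
]


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection (set name, description, tab-joined genes)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            genes = {g for g in parts[2:] if g}
            if genes:
                sets[parts[0]] = genes
    if not sets:
        raise InputError(f"no gene sets parsed from {path}")
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, description, *sorted(sets[name])]) + "\n")


def ora(network_genes: set, gene_set: set, universe: set) -> tuple[float, int]:
    """Hypergeometric upper-tail p-value of the network/gene-set overlap.

    P(X >= k) with population N = |universe|, K = |gene_set ∩ universe| marked
    successes, n = |network_genes| draws and observed overlap k. Network genes
    outside the universe are dropped with a warning.
    """
    if not universe:
        raise InputError("ORA requires a non-empty universe")
    universe = set(universe)
    outside = set(network_genes) - universe
    if outside:
        logger.warning("%d network genes outside the universe dropped", len(outside))
    draws = set(network_genes) & universe
    if not draws:
        raise InputError("ORA requires a non-empty network gene set (within the universe)")
    marked = set(gene_set) & universe
    n_pop, n_marked, n_draws = len(universe), len(marked), len(draws)
    k = len(draws & marked)
    p = float(stats.hypergeom.sf(k - 1, n_pop, n_marked, n_draws))
    return min(p, 1.0), k


def enrichment_score(p: float) -> float:
    """-log10 of an ORA p-value."""
    if p <= 0 or p > 1:
        raise InputError(f"p must be in (0, 1], got {p}")
    return -math.log10(p)


def run_ora(
    network_genes: set,
    collection: dict[str, set[str]],
    universe: set,
    benjamini_hochberg: bool = False,
) -> pd.DataFrame:
    """ORA over every set of a collection; optionally BH-adjusted p-values."""
    draws = set(network_genes) & set(universe)
    rows = []
    for name in sorted(collection):
        gene_set = collection[name]
        p, k = ora(network_genes, gene_set, universe)
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": len(set(gene_set) & set(universe)),
                "network_size": len(draws),
                "universe_size": len(set(universe)),
                "p_value": p,
                "score": enrichment_score(p),
            }
        )
    df = pd.DataFrame(rows, columns=ORA_COLUMNS)
    if benjamini_hochberg and not df.empty:
        m = len(df)
        order = df["p_value"].rank(method="first")
        adj = (df["p_value"] * m / order).clip(upper=1.0)
        # enforce monotonicity of the step-up procedure
        df = df.assign(p_adjusted=adj)
        df = df.sort_values("p_value")
        df["p_adjusted"] = df["p_adjusted"][::-1].cummin()[::-1]
        df = df.sort_index()
    return df
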