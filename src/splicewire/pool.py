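"""Solution pools, consensus networks and splice-aware/unaware differencing.

Alternative (near-)optimal subnetworks are enumerated by re-solving with
no-good cuts that exclude each previously returned selected-edge set. The pool
is integrated into a consensus network in which every element carries the
fraction of pool members containing it; differencing a splice-aware against a
splice-unaware consensus exposes the interactions abrogated by domain skipping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ilp import IlpInstance, SolutionNetwork, solve, validate_solution
from .prior import InputError
from .splice import skipped_domains

logger = logging.getLogger(__name__)


def enumerate_solutions(
    instance: IlpInstance,
    k_max: int = 100,
    objective_tolerance: float = 0.0,
    min_hamming: int = 1,
    backend: str = "highs",
    time_limit: float = 3600.0,
    mip_gap: float = 0.0,
) -> list[SolutionNetwork]:
    """Enumerate up to ``k_max`` distinct solutions in decreasing objective.

    After each solve, a cut excludes every assignment within ``min_hamming - 1``
    edge flips of the returned selected-edge signature (directed DDIs plus
    active perturbation links); ``min_hamming=1`` is the plain no-good cut.
    Enumeration stops at ``k_max``, when the incumbent objective degrades more
    than ``objective_tolerance`` below the optimum, or at infeasibility.
    """
    if k_max < 1:
        raise InputError("k_max must be >= 1")
    if objective_tolerance < 0:
        raise InputError("objective_tolerance must be >= 0")
    signature_vars = [instance.u_index[k] for k in instance.u_keys] + [
        instance.r_index[p] for p in instance.roots
    ]
    cuts: list = []
    pool: list[SolutionNetwork] = []
    best: float | None = None
    for _ in range(k_max):
        sol = solve(instance, backend=backend, time_limit=time_limit,
                    mip_gap=mip_gap, extra_constraints=cuts)
        if sol.solver_status == "infeasible":
            break  # the signature space is exhausted
        if sol.solver_status == "timeout":
            logger.warning("pool enumeration hit the time limit after %d solutions", len(pool))
            if not sol.is_empty():
                pool.append(sol)
            break
        if best is None:
            best = sol.objective_value
        elif sol.objective_value < best - objective_tolerance - 1e-9:
            break
        pool.append(sol)
        cuts.append(_exclusion_cut(instance, sol, signature_vars, min_hamming))
    return pool


def _exclusion_cut(instance, sol, signature_vars, min_hamming):
    """Hamming-distance cut: sum over flips of signature variables >= d."""
    selected = {instance.u_index[k] for k in sol.ddis}
    selected |= {instance.r_index[p] for p in sol.roots if p in instance.r_index}
    coefs: dict[int, float] = {}
    rhs = float(min_hamming)
    for vi in signature_vars:
        if vi in selected:
            coefs[vi] = -1.0
            rhs -= 1.0
        else:
            coefs[vi] = 1.0
    return (coefs, rhs, np.inf, "no_good")


@dataclass
class ConsensusNetwork:
    """Union of a solution pool with per-element appearance counts.

    Weights are exact rationals count / n_solutions, reported as floats; an
    element with weight 1 appears in every pool member. DDI/PPI counts are
    kept per directed key; orientation exclusivity within a solution makes the
    undirected count the sum over the two orientations.
    """

    n_solutions: int = 0
    mode: str = "hard"
    ddi_counts: dict = field(default_factory=dict)
    ppi_counts: dict = field(default_factory=dict)
    protein_counts: dict = field(default_factory=dict)
    domain_counts: dict = field(default_factory=dict)

    def weight(self, counts: dict, key) -> float:
        return counts.get(key, 0) / self.n_solutions

    def undirected_ddi_counts(self) -> dict:
        out: dict = {}
        for (key, _d), n in self.ddi_counts.items():
            out[key] = out.get(key, 0) + n
        return out


def consensus(pool: list[SolutionNetwork]) -> ConsensusNetwork:
    """Integrate a homogeneous-mode pool into a consensus network."""
    if not pool:
        raise InputError("consensus requires a non-empty solution pool")
    modes = {s.mode for s in pool}
    if len(modes) > 1:
        raise InputError(f"pool mixes modes {sorted(modes)}")
    cn = ConsensusNetwork(n_solutions=len(pool), mode=modes.pop())
    for sol in pool:
        for k in sol.ddis:
            cn.ddi_counts[k] = cn.ddi_counts.get(k, 0) + 1
        for k in sol.ppis:
            cn.ppi_counts[k] = cn.ppi_counts.get(k, 0) + 1
        for p in sol.proteins:
            cn.protein_counts[p] = cn.protein_counts.get(p, 0) + 1
        for d in sol.domains:
            cn.domain_counts[d] = cn.domain_counts.get(d, 0) + 1
    return cn


def diff_networks(
    aware: ConsensusNetwork,
    unaware: ConsensusNetwork,
    skips: pd.DataFrame | set | None = None,
) -> pd.DataFrame:
    """Partition undirected DDIs into aware-only / unaware-only / shared.

    Each edge is annotated with both consensus weights and whether one of its
    endpoint domains is skipped; unaware-only edges with a skipped endpoint are
    flagged ``splice_abrogated`` — interactions that disappear once splicing is
    accounted for.
    """
    skipset = set()
    if skips is not None:
        skipset = skips if isinstance(skips, (set, frozenset)) else skipped_domains(skips)
    a_counts = aware.undirected_ddi_counts()
    u_counts = unaware.undirected_ddi_counts()
    rows = []
    for key in sorted(set(a_counts) | set(u_counts)):
        (pa, da), (pb, db) = key
        in_a, in_u = key in a_counts, key in u_counts
        status = "shared" if (in_a and in_u) else ("aware_only" if in_a else "unaware_only")
        endpoint_skipped = (pa, da) in skipset or (pb, db) in skipset
        rows.append(
            {
                "protein_a": pa,
                "domain_a": da,
                "protein_b": pb,
                "domain_b": db,
                "status": status,
                "weight_aware": a_counts.get(key, 0) / aware.n_solutions,
                "weight_unaware": u_counts.get(key, 0) / unaware.n_solutions,
                "endpoint_skipped": endpoint_skipped,
                "splice_abrogated": status == "unaware_only" and endpoint_skipped,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_a", "domain_a", "protein_b", "domain_b", "status",
            "weight_aware", "weight_unaware", "endpoint_skipped", "splice_abrogated",
        ],
    )


def write_consensus(cn: ConsensusNetwork, edge_path, node_path=None, skips=None) -> None:
    """Consensus edge list TSV (one row per directed DDI) plus node attributes."""
    skipset = set()
    if skips is not None:
        skipset = skips if isinstance(skips, (set, frozenset)) else skipped_domains(skips)
    rows = []
    for (key, dr) in sorted(cn.ddi_counts):
        (pa, da), (pb, db) = key if dr == "ab" else (key[1], key[0])
        flag = ""
        if (pa, da) in skipset or (pb, db) in skipset:
            flag = "skipped_endpoint"
        rows.append(
            {
                "source_protein": pa,
                "source_domain": da,
                "target_protein": pb,
                "target_domain": db,
                "weight": cn.ddi_counts[(key, dr)] / cn.n_solutions,
                "splice_flag": flag,
            }
        )
    header = ["source_protein", "source_domain", "target_protein", "target_domain",
              "weight", "splice_flag"]
    with open(edge_path, "w") as fh:
        fh.write(f"# mode={cn.mode}\n# n_solutions={cn.n_solutions}\n")
        pd.DataFrame(rows, columns=header).to_csv(fh, sep="\t", index=False)
    if node_path is not None:
        nrows = [
            {"node": p, "kind": "protein", "weight": n / cn.n_solutions}
            for p, n in sorted(cn.protein_counts.items())
        ] + [
            {"node": f"{p}:{d}", "kind": "domain", "weight": n / cn.n_solutions}
            for (p, d), n in sorted(cn.domain_counts.items())
        ]
        pd.DataFrame(nrows, columns=["node", "kind", "weight"]).to_csv(
            node_path, sep="\t", index=False
        )


def load_consensus(edge_path) -> ConsensusNetwork:
    """Re-read a consensus edge TSV written by :func:`write_consensus`."""
    mode, n_solutions = "hard", 1
    with open(edge_path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            if k == "mode":
                mode = v
            elif k == "n_solutions":
                n_solutions = int(v)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", keep_default_na=False)
    cn = ConsensusNetwork(n_solutions=n_solutions, mode=mode)
    for r in df.itertuples(index=False):
        a = (str(r.source_protein), str(r.source_domain))
        b = (str(r.target_protein), str(r.target_domain))
        key, dr = ((a, b), "ab") if a <= b else ((b, a), "ba")
        count = round(float(r.weight) * n_solutions)
        cn.ddi_counts[(key, dr)] = count
        for p, d in (a, b):
            cn.domain_counts[(p, d)] = max(cn.domain_counts.get((p, d), 0), count)
            cn.protein_counts[p] = max(cn.protein_counts.get(p, 0), count)
    return cn
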