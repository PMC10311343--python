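"""Exhaustive enumeration of the optimal subnetwork on tiny priors.

Independent reference for the MILP: every assignment of each usable DDI to
{off, forward, reverse} is enumerated directly on the network structure, the
implied domains/proteins/PPIs derived, rooted-DAG feasibility checked, and the
objective computed from first principles. Intended for instances with at most
a dozen DDIs; guards against larger inputs.
"""

from __future__ import annotations

import itertools

from .ilp import SolutionNetwork
from .prior import InputError, PriorNetwork

MAX_DDIS = 12


def enumerate_optimum(
    net: PriorNetwork,
    tf_weight: dict[str, float],
    tf_significant: dict[str, bool],
    skipset: set,
    soft_scores: dict | None = None,
    mode: str = "hard",
    lam: float = 0.01,
    beta: float = 0.01,
) -> tuple[float, SolutionNetwork]:
    """Return (optimal objective, one optimal solution) by brute force.

    Among equal-objective optima the solution with fewer elements, then the
    lexicographically smallest edge signature, is returned.
    """
    soft_scores = soft_scores or {}
    roots_cand = net.perturbation_targets & net.proteins

    usable: list[tuple] = []
    options: list[tuple] = []
    for key in sorted(net.ddis):
        dirs = net.allowed_orientations(key)
        if not dirs:
            continue
        if mode == "hard" and any(ep in skipset for ep in key):
            continue  # a skipped endpoint renders the DDI non-functional
        usable.append(key)
        options.append((None,) + dirs)
    if len(usable) > MAX_DDIS:
        raise InputError(f"enumeration oracle limited to {MAX_DDIS} DDIs, got {len(usable)}")

    best_obj = 0.0
    best_key = (0, ())
    best_sol = SolutionNetwork(mode=mode, solver_status="optimal")

    for assignment in itertools.product(*options):
        sel_u = [(usable[i], d) for i, d in enumerate(assignment) if d is not None]
        if not sel_u:
            continue
        # directed PPIs implied by the selected DDIs; both directions on one
        # PPI violates orientation exclusivity
        ppi_dir: dict = {}
        ok = True
        for key, d in sel_u:
            ppi = net.ppi_key_of(key)
            if ppi_dir.setdefault(ppi, d) != d:
                ok = False
                break
        if not ok:
            continue
        domains = {ep for key, _d in sel_u for ep in key}
        proteins = {p for p, _ in domains}
        edges = []
        indeg = {p: 0 for p in proteins}
        for ppi, d in ppi_dir.items():
            src, tgt = (ppi[0], ppi[1]) if d == "ab" else (ppi[1], ppi[0])
            edges.append((src, tgt))
            indeg[tgt] += 1
        sources = {p for p, k in indeg.items() if k == 0}
        if not sources <= roots_cand:
            continue  # an unreachable component
        if _has_cycle(proteins, edges):
            continue
        reached_tf = set()
        gain = 0.0
        for t in proteins:
            if t in tf_weight and indeg[t] > 0 and tf_significant.get(t, False):
                w = tf_weight[t]
                if w > 0:
                    reached_tf.add(t)
                    gain += w
        n_elem = len(proteins) + len(domains) + len(sel_u) + len(ppi_dir)
        obj = gain - lam * n_elem
        if mode == "soft":
            obj -= beta * sum(soft_scores.get(d, 0.0) for d in domains)
        signature = (tuple(sorted(sel_u)), tuple(sorted(sources)))
        cand_key = (n_elem, signature)
        if obj > best_obj + 1e-12 or (abs(obj - best_obj) <= 1e-12 and cand_key < best_key):
            best_obj = max(obj, best_obj)
            best_key = cand_key
            best_sol = SolutionNetwork(
                proteins=frozenset(proteins),
                domains=frozenset(domains),
                ddis=frozenset(sel_u),
                ppis=frozenset(ppi_dir.items()),
                roots=frozenset(sources),
                tfs_reached=frozenset(reached_tf),
                objective_value=obj,
                mode=mode,
                solver_status="optimal",
            )
    return best_obj, best_sol


def _has_cycle(nodes, edges) -> bool:
    adj: dict = {n: [] for n in nodes}
    indeg = {n: 0 for n in nodes}
    for s, t in edges:
        adj[s].append(t)
        indeg[t] += 1
    queue = [n for n in nodes if indeg[n] == 0]
    seen = 0
    while queue:
        n = queue.pop()
        seen += 1
        for m in adj[n]:
            indeg[m] -= 1
            if indeg[m] == 0:
                queue.append(m)
    return seen != len(nodes)
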