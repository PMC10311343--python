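"""Integer linear program for splice-consistent subnetwork selection.

The prior's undirected edges expand into two mutually exclusive directed
candidates; binary variables select proteins (y), domains (z), directed DDIs
(u), directed PPIs (v), perturbation links to candidate roots (r) and reached
TFs (t). Integer depth variables impose acyclicity, so every selected protein
sits on a directed path from the Perturbation root.

Objective (maximized): sum of significant-TF weights over reached TFs, minus a
penalty for reaching non-significant TFs, minus a size regularization on all
selected elements, and — in soft mode — minus a skip penalty proportional to
-log10 of each selected evidence domain's aggregated p-value. In hard mode
skipped domains are fixed to zero instead, which renders every DDI with a
skipped endpoint non-functional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .prior import PERTURBATION, InputError, PriorNetwork
from .splice import skip_scores, skipped_domains

logger = logging.getLogger(__name__)


class ParameterError(ValueError):
    pass


class BackendError(RuntimeError):
    pass


@dataclass
class IlpParams:
    """Tunable weights of the selection objective.

    alpha : penalty per reached non-significant TF. Default (None) resolves to
        half the median weight of the significant TFs (0.1 when none).
    lam : size regularization per selected element.
    beta : soft-mode scale on the -log10(p) skip penalties. Default (None)
        resolves to ``lam`` (penalties on the regularization scale).
    tie_eps : total budget of the secondary edge-index cost used to break ties
        deterministically; small enough never to reorder distinct objective
        values.
    skip_score_cap : cap on -log10(p) skip scores.
    """

    alpha: float | None = None
    lam: float = 0.01
    beta: float | None = None
    tie_eps: float = 1e-7
    skip_score_cap: float = 300.0

    def validated(self) -> "IlpParams":
        if self.lam < 0:
            raise ParameterError("lam must be >= 0")
        if self.alpha is not None and self.alpha < 0:
            raise ParameterError("alpha must be >= 0")
        if self.beta is not None and self.beta < 0:
            raise ParameterError("beta must be >= 0")
        return self


@dataclass
class IlpInstance:
    """A built MILP: variables, linear constraints, objective, and the maps
    back to network elements."""

    net: PriorNetwork
    mode: str
    alpha: float
    lam: float
    beta: float
    tie_eps: float

    proteins: list[str] = field(default_factory=list)
    domains: list[tuple[str, str]] = field(default_factory=list)
    u_keys: list[tuple] = field(default_factory=list)   # (ddi_key, dir)
    v_keys: list[tuple] = field(default_factory=list)   # (ppi_pair, dir)
    roots: list[str] = field(default_factory=list)
    tfs: list[str] = field(default_factory=list)

    y_index: dict = field(default_factory=dict)
    z_index: dict = field(default_factory=dict)
    u_index: dict = field(default_factory=dict)
    v_index: dict = field(default_factory=dict)
    r_index: dict = field(default_factory=dict)
    t_index: dict = field(default_factory=dict)
    depth_index: dict = field(default_factory=dict)

    n_vars: int = 0
    lb: np.ndarray | None = None
    ub: np.ndarray | None = None
    c: np.ndarray | None = None           # minimization objective incl. tie costs
    gain: np.ndarray | None = None        # pure maximization coefficients
    constraints: list = field(default_factory=list)  # (coef dict, lb, ub, name)

    tf_weight: dict = field(default_factory=dict)
    tf_significant: dict = field(default_factory=dict)
    skipped: set = field(default_factory=set)
    soft_scores: dict = field(default_factory=dict)

    def pure_objective(self, selected: set[int]) -> float:
        return float(sum(self.gain[i] for i in selected))


@dataclass(frozen=True)
class SolutionNetwork:
    """One selected subnetwork: element sets, pure objective, solver status."""

    proteins: frozenset = frozenset()
    domains: frozenset = frozenset()
    ddis: frozenset = frozenset()        # (ddi_key, dir)
    ppis: frozenset = frozenset()        # ((pa, pb), dir)
    roots: frozenset = frozenset()
    tfs_reached: frozenset = frozenset()
    objective_value: float = 0.0
    mode: str = "hard"
    solver_status: str = "optimal"

    @property
    def n_elements(self) -> int:
        return len(self.proteins) + len(self.domains) + len(self.ddis) + len(self.ppis)

    @property
    def edge_signature(self) -> tuple:
        """Canonical identity of the solution: directed DDIs plus active roots."""
        return (tuple(sorted(self.ddis)), tuple(sorted(self.roots)))

    def is_empty(self) -> bool:
        return self.n_elements == 0


def _tf_tables(tf_table: pd.DataFrame, net: PriorNetwork):
    weights, significant = {}, {}
    for row in tf_table.itertuples(index=False):
        if row.tf in net.proteins:
            weights[row.tf] = float(row.weight)
            significant[row.tf] = bool(row.significant)
    return weights, significant


def build_ilp(
    net: PriorNetwork,
    tf_table: pd.DataFrame,
    skips: pd.DataFrame,
    mode: str = "hard",
    params: IlpParams | None = None,
) -> IlpInstance:
    """Translate prior + TF activities + skip calls into a MILP instance."""
    if mode not in ("hard", "soft"):
        raise ParameterError(f"mode must be hard|soft, got {mode!r}")
    params = (params or IlpParams()).validated()

    tf_weight, tf_significant = _tf_tables(tf_table, net)
    if not tf_weight:
        raise InputError("no regulon TF is present in the prior network")
    sig_weights = sorted(w for t, w in tf_weight.items() if tf_significant[t])
    alpha = params.alpha
    if alpha is None:
        alpha = 0.5 * float(np.median(sig_weights)) if sig_weights else 0.1
    beta = params.lam if params.beta is None else params.beta

    skipset = skipped_domains(skips)
    soft_scores = skip_scores(skips, cap=params.skip_score_cap) if mode == "soft" else {}

    inst = IlpInstance(
        net=net, mode=mode, alpha=alpha, lam=params.lam, beta=beta,
        tie_eps=params.tie_eps,
    )
    inst.tf_weight, inst.tf_significant = tf_weight, tf_significant
    inst.skipped, inst.soft_scores = skipset, soft_scores

    inst.proteins = sorted(net.proteins)
    inst.domains = sorted(net.domains)
    inst.roots = sorted(net.perturbation_targets & net.proteins)
    inst.tfs = sorted(tf_weight)
    if not inst.roots:
        logger.warning("no perturbation targets: only the empty network is feasible")

    for key in sorted(net.ddis):
        for d in net.allowed_orientations(key):
            inst.u_keys.append((key, d))
    ppi_dirs: dict = {}
    for (key, d) in inst.u_keys:
        ppi_dirs.setdefault(net.ppi_key_of(key), set()).add(d)
    for ppi in sorted(ppi_dirs):
        for d in sorted(ppi_dirs[ppi]):
            inst.v_keys.append((ppi, d))

    idx = 0
    for p in inst.proteins:
        inst.y_index[p] = idx; idx += 1
    for d in inst.domains:
        inst.z_index[d] = idx; idx += 1
    for k in inst.u_keys:
        inst.u_index[k] = idx; idx += 1
    for k in inst.v_keys:
        inst.v_index[k] = idx; idx += 1
    for p in inst.roots:
        inst.r_index[p] = idx; idx += 1
    for t in inst.tfs:
        inst.t_index[t] = idx; idx += 1
    for p in inst.proteins:
        inst.depth_index[p] = idx; idx += 1
    inst.n_vars = idx

    n_prot = len(inst.proteins)
    big_m = n_prot + 1
    lb = np.zeros(idx)
    ub = np.ones(idx)
    for p in inst.proteins:
        ub[inst.depth_index[p]] = n_prot
    if mode == "hard":
        for d in skipset:
            if d in inst.z_index:
                ub[inst.z_index[d]] = 0.0  # (C7) skipped domain non-selectable

    cons = inst.constraints

    def row(coefs, lo, hi, name):
        cons.append((coefs, lo, hi, name))

    inf = np.inf
    # (C1) domain implies protein
    for d in inst.domains:
        row({inst.z_index[d]: 1.0, inst.y_index[d[0]]: -1.0}, -inf, 0.0, f"C1[{d}]")
    # (C2) directed DDI implies both endpoint domains
    for (key, dr) in inst.u_keys:
        ui = inst.u_index[(key, dr)]
        for endpoint in key:
            row({ui: 1.0, inst.z_index[endpoint]: -1.0}, -inf, 0.0, f"C2[{key},{dr}]")
    # (C3) PPI iff >=1 constituent DDI, per direction
    for (ppi, dr) in inst.v_keys:
        vi = inst.v_index[(ppi, dr)]
        members = [
            inst.u_index[(k, dr)]
            for k in net.ppis[ppi]
            if (k, dr) in inst.u_index
        ]
        coefs = {vi: 1.0}
        for m in members:
            coefs[m] = coefs.get(m, 0.0) - 1.0
        row(coefs, -inf, 0.0, f"C3a[{ppi},{dr}]")
        for m in members:
            row({m: 1.0, vi: -1.0}, -inf, 0.0, f"C3b[{ppi},{dr}]")
    # (C4) orientation exclusivity
    for key in sorted({k for (k, _) in inst.u_keys}):
        dirs = [inst.u_index[(key, d)] for d in ("ab", "ba") if (key, d) in inst.u_index]
        if len(dirs) == 2:
            row({dirs[0]: 1.0, dirs[1]: 1.0}, -inf, 1.0, f"C4u[{key}]")
    for ppi in sorted({p for (p, _) in inst.v_keys}):
        dirs = [inst.v_index[(ppi, d)] for d in ("ab", "ba") if (ppi, d) in inst.v_index]
        if len(dirs) == 2:
            row({dirs[0]: 1.0, dirs[1]: 1.0}, -inf, 1.0, f"C4v[{ppi}]")
    # (C5) rooted, acyclic selection
    incoming_v: dict[str, list[int]] = {p: [] for p in inst.proteins}
    for (ppi, dr) in inst.v_keys:
        src, tgt = (ppi[0], ppi[1]) if dr == "ab" else (ppi[1], ppi[0])
        vi = inst.v_index[(ppi, dr)]
        incoming_v[tgt].append(vi)
        # depth_tgt >= depth_src + 1 - bigM * (1 - v)
        row(
            {inst.depth_index[tgt]: 1.0, inst.depth_index[src]: -1.0, vi: -big_m},
            1.0 - big_m, inf, f"C5b[{ppi},{dr}]",
        )
    for p in inst.roots:
        # active root sits at depth 0
        row({inst.depth_index[p]: 1.0, inst.r_index[p]: float(n_prot)}, -inf,
            float(n_prot), f"C5a[{p}]")
        row({inst.r_index[p]: 1.0, inst.y_index[p]: -1.0}, -inf, 0.0, f"C5r[{p}]")
    for p in inst.proteins:
        coefs = {inst.y_index[p]: 1.0}
        for vi in incoming_v[p]:
            coefs[vi] = coefs.get(vi, 0.0) - 1.0
        if p in inst.r_index:
            coefs[inst.r_index[p]] = coefs.get(inst.r_index[p], 0.0) - 1.0
        row(coefs, -inf, 0.0, f"C5c[{p}]")
    # (C6) a TF counts as reached only through an incoming selected PPI
    for t in inst.tfs:
        ti = inst.t_index[t]
        row({ti: 1.0, inst.y_index[t]: -1.0}, -inf, 0.0, f"C6y[{t}]")
        coefs = {ti: 1.0}
        for vi in incoming_v[t]:
            coefs[vi] = coefs.get(vi, 0.0) - 1.0
        row(coefs, -inf, 0.0, f"C6v[{t}]")

    # objective
    gain = np.zeros(idx)
    for p in inst.proteins:
        gain[inst.y_index[p]] = -inst.lam
    for d in inst.domains:
        gain[inst.z_index[d]] = -inst.lam
        if mode == "soft" and d in soft_scores:
            gain[inst.z_index[d]] -= beta * soft_scores[d]
    for k in inst.u_keys:
        gain[inst.u_index[k]] = -inst.lam
    for k in inst.v_keys:
        gain[inst.v_index[k]] = -inst.lam
    for t in inst.tfs:
        gain[inst.t_index[t]] = tf_weight[t] if tf_significant[t] else -alpha

    c = -gain.copy()
    edge_vars = [inst.u_index[k] for k in inst.u_keys] + [inst.v_index[k] for k in inst.v_keys]
    if edge_vars and inst.tie_eps > 0:
        total = sum(range(1, len(edge_vars) + 1))
        for rank, vi in enumerate(edge_vars, start=1):
            c[vi] += inst.tie_eps * rank / total

    inst.lb, inst.ub, inst.c, inst.gain = lb, ub, c, gain
    return inst


BACKENDS = ("highs", "brute")


def solve(
    instance: IlpInstance,
    backend: str = "highs",
    time_limit: float = 3600.0,
    mip_gap: float = 0.0,
    threads: int = 1,
    seed: int = 0,
    extra_constraints=None,
) -> SolutionNetwork:
    """Solve an instance and return the incumbent subnetwork.

    The default backend is HiGHS through ``scipy.optimize.milp`` (deterministic,
    single-threaded; ``threads`` and ``seed`` are accepted for interface parity
    and ignored). The ``brute`` backend exhaustively enumerates tiny instances.
    The empty network is feasible by construction, so an infeasible status
    signals a modelling bug and is reported on an empty solution.
    """
    if time_limit <= 0:
        raise ParameterError("time_limit must be > 0")
    if backend == "highs":
        return _solve_highs(instance, time_limit, mip_gap, extra_constraints)
    if backend == "brute":
        from .oracle import enumerate_optimum

        if extra_constraints:
            raise BackendError("brute backend does not support solution-pool cuts")
        _, sol = enumerate_optimum(
            instance.net,
            tf_weight=instance.tf_weight,
            tf_significant=instance.tf_significant,
            skipset=instance.skipped,
            soft_scores=instance.soft_scores,
            mode=instance.mode,
            lam=instance.lam,
            beta=instance.beta,
        )
        return sol
    raise BackendError(
        f"unknown MILP backend {backend!r}; available: {BACKENDS} "
        "(the default needs scipy >= 1.9 with HiGHS)"
    )


def _solve_highs(instance, time_limit, mip_gap, extra_constraints) -> SolutionNetwork:
    from scipy.optimize import Bounds, LinearConstraint, milp
    from scipy.sparse import csr_matrix

    rows = list(instance.constraints)
    if extra_constraints:
        rows.extend(extra_constraints)
    data, ri, ci, lbs, ubs = [], [], [], [], []
    for i, (coefs, lo, hi, _name) in enumerate(rows):
        for col, val in coefs.items():
            ri.append(i); ci.append(col); data.append(val)
        lbs.append(lo); ubs.append(hi)
    a_mat = csr_matrix((data, (ri, ci)), shape=(len(rows), instance.n_vars))
    res = milp(
        c=instance.c,
        constraints=LinearConstraint(a_mat, lbs, ubs),
        integrality=np.ones(instance.n_vars),
        bounds=Bounds(instance.lb, instance.ub),
        options={"time_limit": time_limit, "mip_rel_gap": mip_gap, "presolve": True},
    )
    status = {0: "optimal", 1: "timeout", 2: "infeasible", 3: "unbounded"}.get(
        res.status, "feasible"
    )
    if res.x is None:
        if status == "infeasible":
            logger.error("MILP reported infeasible; the empty network should always "
                         "be feasible — model bug suspected")
        return SolutionNetwork(mode=instance.mode, solver_status=status)
    x = np.asarray(res.x)
    return _extract(instance, x, status)


def _extract(instance: IlpInstance, x: np.ndarray, status: str) -> SolutionNetwork:
    on = lambda i: x[i] > 0.5
    proteins = frozenset(p for p in instance.proteins if on(instance.y_index[p]))
    domains = frozenset(d for d in instance.domains if on(instance.z_index[d]))
    ddis = frozenset(k for k in instance.u_keys if on(instance.u_index[k]))
    ppis = frozenset(k for k in instance.v_keys if on(instance.v_index[k]))
    roots = frozenset(p for p in instance.roots
                      if on(instance.r_index[p]) and on(instance.y_index[p]))
    tfs = frozenset(t for t in instance.tfs if on(instance.t_index[t]))
    # pure objective: recomputed from gains over selected binaries only
    sel_idx = set()
    for group, index in (
        (proteins, instance.y_index), (domains, instance.z_index),
        (ddis, instance.u_index), (ppis, instance.v_index),
        (tfs, instance.t_index),
    ):
        sel_idx.update(index[k] for k in group)
    objective = instance.pure_objective(sel_idx)
    return SolutionNetwork(
        proteins=proteins, domains=domains, ddis=ddis, ppis=ppis, roots=roots,
        tfs_reached=tfs, objective_value=objective, mode=instance.mode,
        solver_status=status,
    )


@dataclass(frozen=True)
class Violation:
    kind: str
    detail: str


def validate_solution(
    net: PriorNetwork,
    skips: pd.DataFrame | set,
    sol: SolutionNetwork,
    mode: str | None = None,
) -> list[Violation]:
    """Certify a solution against the selection rules; empty list = valid."""
    mode = mode or sol.mode
    skipset = skips if isinstance(skips, (set, frozenset)) else skipped_domains(skips)
    out: list[Violation] = []

    ppi_selected = set(sol.ppis)
    for (key, dr) in sol.ddis:
        for endpoint in key:
            if endpoint not in sol.domains:
                out.append(Violation("ddi_endpoint_missing", f"{key} {dr} misses {endpoint}"))
            elif endpoint[0] not in sol.proteins:
                out.append(Violation("ddi_protein_missing", f"{key} {dr}"))
        if (net.ppi_key_of(key), dr) not in ppi_selected:
            out.append(Violation("ddi_without_ppi", f"{key} {dr}"))
    for (ppi, dr) in sol.ppis:
        members = net.ppis.get(ppi, [])
        if not any((k, dr) in sol.ddis for k in members):
            out.append(Violation("ppi_without_ddi", f"{ppi} {dr}"))

    g = nx.DiGraph()
    g.add_nodes_from(sol.proteins)
    for (ppi, dr) in sol.ppis:
        src, tgt = (ppi[0], ppi[1]) if dr == "ab" else (ppi[1], ppi[0])
        g.add_edge(src, tgt)
    if not nx.is_directed_acyclic_graph(g):
        out.append(Violation("cycle", "selected directed PPIs contain a cycle"))
    g.add_node(PERTURBATION)
    for root in sol.roots:
        if root not in net.perturbation_targets:
            out.append(Violation("invalid_root", root))
        g.add_edge(PERTURBATION, root)
    reachable = nx.descendants(g, PERTURBATION) if PERTURBATION in g else set()
    for p in sol.proteins:
        if p not in reachable:
            out.append(Violation("unreachable_protein", p))

    for d in sol.domains:
        if d[0] not in sol.proteins:
            out.append(Violation("domain_without_protein", str(d)))
    if mode == "hard":
        for d in sol.domains:
            if d in skipset:
                out.append(Violation("skipped_domain_selected", str(d)))
    for t in sol.tfs_reached:
        if t not in sol.proteins or g.in_degree(t) == 0:
            out.append(Violation("tf_not_reached", t))
    return out


# -- instance export ---------------------------------------------------------

def export_lp(instance: IlpInstance, path) -> None:
    """Write the instance in CPLEX LP format (minimization, tie costs included)."""
    names = _var_names(instance)
    lines = ["Minimize", " obj: " + _lincomb(instance.c, names)]
    lines.append("Subject To")
    for i, (coefs, lo, hi, name) in enumerate(instance.constraints):
        expr = " + ".join(f"{v:+.12g} {names[c]}" for c, v in sorted(coefs.items()))
        tag = f"c{i}"
        if np.isfinite(hi) and not np.isfinite(lo):
            lines.append(f" {tag}: {expr} <= {hi:.12g}")
        elif np.isfinite(lo) and not np.isfinite(hi):
            lines.append(f" {tag}: {expr} >= {lo:.12g}")
        else:
            lines.append(f" {tag}a: {expr} >= {lo:.12g}")
            lines.append(f" {tag}b: {expr} <= {hi:.12g}")
    lines.append("Bounds")
    for j, nm in enumerate(names):
        lines.append(f" {instance.lb[j]:.12g} <= {nm} <= {instance.ub[j]:.12g}")
    binaries = [nm for j, nm in enumerate(names) if instance.ub[j] <= 1.0]
    generals = [nm for j, nm in enumerate(names) if instance.ub[j] > 1.0]
    if binaries:
        lines.append("Binaries")
        lines.append(" " + " ".join(binaries))
    if generals:
        lines.append("Generals")
        lines.append(" " + " ".join(generals))
    lines.append("End")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def export_mps(instance: IlpInstance, path) -> None:
    """Write the instance in free-form MPS (all variables integer)."""
    names = _var_names(instance)
    out = ["NAME splicewire", "ROWS", " N  COST"]
    row_names = []
    for i, (coefs, lo, hi, _n) in enumerate(instance.constraints):
        rn = f"R{i}"
        row_names.append(rn)
        if np.isfinite(lo) and np.isfinite(hi):
            out.append(f" L  {rn}")  # ranged rows handled via RANGES
        elif np.isfinite(hi):
            out.append(f" L  {rn}")
        else:
            out.append(f" G  {rn}")
    out.append("COLUMNS")
    out.append("    MARKER                 'MARKER'                 'INTORG'")
    col_rows: dict[int, list[tuple[str, float]]] = {j: [] for j in range(instance.n_vars)}
    for i, (coefs, lo, hi, _n) in enumerate(instance.constraints):
        for cidx, val in coefs.items():
            col_rows[cidx].append((row_names[i], val))
    for j, nm in enumerate(names):
        if instance.c[j]:
            out.append(f"    {nm}  COST  {instance.c[j]:.12g}")
        for rn, val in col_rows[j]:
            out.append(f"    {nm}  {rn}  {val:.12g}")
    out.append("    MARKER                 'MARKER'                 'INTEND'")
    out.append("RHS")
    for i, (coefs, lo, hi, _n) in enumerate(instance.constraints):
        rhs = hi if np.isfinite(hi) else lo
        out.append(f"    RHS  {row_names[i]}  {rhs:.12g}")
    ranges = [
        f"    RNG  {row_names[i]}  {hi - lo:.12g}"
        for i, (coefs, lo, hi, _n) in enumerate(instance.constraints)
        if np.isfinite(lo) and np.isfinite(hi)
    ]
    if ranges:
        out.append("RANGES")
        out.extend(ranges)
    out.append("BOUNDS")
    for j, nm in enumerate(names):
        out.append(f" LO BND  {nm}  {instance.lb[j]:.12g}")
        out.append(f" UP BND  {nm}  {instance.ub[j]:.12g}")
    out.append("ENDATA")
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def _var_names(instance: IlpInstance) -> list[str]:
    names = [""] * instance.n_vars

    def clean(s):
        return str(s).replace(" ", "").replace(",", "_").replace("'", "").replace("(", "").replace(")", "")

    for p, i in instance.y_index.items():
        names[i] = f"y_{clean(p)}"
    for d, i in instance.z_index.items():
        names[i] = f"z_{clean(d)}"
    for k, i in instance.u_index.items():
        names[i] = f"u_{clean(k)}"
    for k, i in instance.v_index.items():
        names[i] = f"v_{clean(k)}"
    for p, i in instance.r_index.items():
        names[i] = f"r_{clean(p)}"
    for t, i in instance.t_index.items():
        names[i] = f"t_{clean(t)}"
    for p, i in instance.depth_index.items():
        names[i] = f"depth_{clean(p)}"
    return names


def _lincomb(c, names) -> str:
    terms = [f"{c[j]:+.12g} {names[j]}" for j in range(len(names)) if c[j]]
    return " ".join(terms) if terms else "0 " + names[0]


# -- solution I/O ------------------------------------------------------------

def write_solution(sol: SolutionNetwork, path) -> None:
    """TSV export of a single solution with header metadata comments."""
    with open(path, "w") as fh:
        fh.write(f"# mode={sol.mode}\n")
        fh.write(f"# objective={sol.objective_value!r}\n")
        fh.write(f"# status={sol.solver_status}\n")
        fh.write("kind\tsource_protein\tsource_domain\ttarget_protein\ttarget_domain\n")
        for (key, dr) in sorted(sol.ddis):
            (pa, da), (pb, db) = key if dr == "ab" else (key[1], key[0])
            fh.write(f"ddi\t{pa}\t{da}\t{pb}\t{db}\n")
        for (ppi, dr) in sorted(sol.ppis):
            src, tgt = (ppi[0], ppi[1]) if dr == "ab" else (ppi[1], ppi[0])
            fh.write(f"ppi\t{src}\t\t{tgt}\t\n")
        for root in sorted(sol.roots):
            fh.write(f"root\t{PERTURBATION}\t\t{root}\t\n")
        for t in sorted(sol.tfs_reached):
            fh.write(f"tf\t\t\t{t}\t\n")


def load_solution(path) -> SolutionNetwork:
    mode, objective, status = "hard", 0.0, "optimal"
    ddis, ppis, roots, tfs = set(), set(), set(), set()
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                if k == "mode":
                    mode = v
                elif k == "objective":
                    objective = float(v)
                elif k == "status":
                    status = v
                continue
            if not header_seen:
                header_seen = True
                continue
            if not line:
                continue
            kind, sp, sd, tp, td = (line.split("\t") + [""] * 5)[:5]
            if kind == "ddi":
                a, b = (sp, sd), (tp, td)
                key, dr = ((a, b), "ab") if a <= b else ((b, a), "ba")
                ddis.add((key, dr))
            elif kind == "ppi":
                pair, dr = ((sp, tp), "ab") if sp <= tp else ((tp, sp), "ba")
                ppis.add((pair, dr))
            elif kind == "root":
                roots.add(tp)
            elif kind == "tf":
                tfs.add(tp)
    domains = frozenset(ep for (key, _d) in ddis for ep in key)
    proteins = frozenset(p for p, _ in domains) | frozenset(roots) | frozenset(tfs)
    return SolutionNetwork(
        proteins=proteins, domains=domains, ddis=frozenset(ddis),
        ppis=frozenset(ppis), roots=frozenset(roots), tfs_reached=frozenset(tfs),
        objective_value=objective, mode=mode, solver_status=status,
    )
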