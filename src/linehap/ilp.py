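"""Integer programs that edit a Clark-consistency graph into a line graph.

The estimator's core: given the CC graph, find the minimum-cost set of edge
deletions (and optionally node deletions or edge insertions) after which the
graph is allelable — each node carries two colors, adjacent nodes share
exactly one, non-adjacent nodes share none.  The surviving coloring *is* the
haplotype assignment, and the number of distinct colors is the population
size estimate.

Five model variants are built on one binary-variable scaffold:

========  ==========================================================
edge      minimise deleted edges (Problem: line-graph edge deletion)
node      hitting set over all forbidden-subgraph occurrences
combined  edges cost 1, nodes cost alpha (genotyping-failure model)
edit      weighted edge deletions + insertions (genotyping errors)
parsimony minimise the number of colors; edges may drop silently
========  ==========================================================

Variables follow the roles: d_e (edge deleted), x[v,j] (node v uses color
j), s[e,j] (edge e's endpoints share color j), t_v (node deleted), r_e
(edge removed for any reason), c_e (edge inserted).  Colors 1..2n with
color j "owned" by node ceil(j/2); symmetry breaking forces every color's
first user to be its owner, which both kills permutation symmetry and lets
most x/s variables be fixed to zero in advance.

The solver backend is SciPy's ``milp`` (HiGHS branch-and-cut): open source,
single-threaded and deterministic, with a relative gap of 0 and a
configurable time limit.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from . import genotypes as gt
from . import linegraph as lg

DEFAULT_TIME_LIMIT = 600.0


# ---------------------------------------------------------------------------
# Generic 0/1 model + solver contract


class ILPModel:
    """A 0/1 integer program with named variables.

    Thin container feeding :func:`scipy.optimize.milp`; keeps the graph and
    build flags so that symmetry breaking / variable pruning can be applied
    as model rewrites.
    """

    def __init__(self, graph: nx.Graph | None = None, kind: str = "", **meta):
        self.graph = graph
        self.kind = kind
        self.meta = meta
        self.var_index: dict = {}
        self.obj: list[float] = []
        self.fixed: dict = {}
        # each constraint: (dict var-key -> coefficient, lower, upper)
        self.constraints: list[tuple[dict, float, float]] = []

    def add_var(self, key, obj: float = 0.0) -> None:
        if key in self.var_index:
            raise KeyError(f"duplicate variable {key!r}")
        self.var_index[key] = len(self.obj)
        self.obj.append(obj)

    def has_var(self, key) -> bool:
        return key in self.var_index

    def fix_var(self, key, value: int) -> None:
        self.fixed[key] = value

    def add_constr(self, coeffs: dict, lo: float, hi: float) -> None:
        self.constraints.append((coeffs, lo, hi))

    @property
    def n_vars(self) -> int:
        return len(self.obj)


@dataclass
class SolveResult:
    status: str  # optimal | feasible | infeasible | timeout
    objective: float | None
    values: dict
    solve_seconds: float
    optimal: bool = False


def solve_model(model: ILPModel, time_limit: float = DEFAULT_TIME_LIMIT,
                seed: int | None = None) -> SolveResult:
    """Solve a 0/1 model with HiGHS.

    The backend is deterministic for a fixed model and single thread, so
    ``seed`` is accepted for interface uniformity but has no effect.
    """
    t0 = time.perf_counter()
    nv = model.n_vars
    if nv == 0:
        return SolveResult("optimal", 0.0, {}, time.perf_counter() - t0, True)
    lb = np.zeros(nv)
    ub = np.ones(nv)
    for key, val in model.fixed.items():
        idx = model.var_index[key]
        lb[idx] = ub[idx] = val
    c = np.asarray(model.obj, dtype=float)

    cons = []
    if model.constraints:
        rows, cols, data, blo, bhi = [], [], [], [], []
        for r, (coeffs, lo, hi) in enumerate(model.constraints):
            for key, coef in coeffs.items():
                rows.append(r)
                cols.append(model.var_index[key])
                data.append(coef)
            blo.append(lo)
            bhi.append(hi)
        a = sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(model.constraints), nv)
        )
        cons = [LinearConstraint(a, blo, bhi)]

    res = milp(
        c,
        constraints=cons,
        bounds=Bounds(lb, ub),
        integrality=np.ones(nv),
        options={"time_limit": float(time_limit), "mip_rel_gap": 0.0},
    )
    elapsed = time.perf_counter() - t0
    if res.status == 0:
        status, optimal = "optimal", True
    elif res.status == 1:
        status, optimal = "timeout", False
    elif res.status == 2:
        return SolveResult("infeasible", None, {}, elapsed, False)
    else:
        return SolveResult("infeasible" if res.x is None else "feasible", None, {}, elapsed, False)
    if res.x is None:
        return SolveResult("timeout", None, {}, elapsed, False)
    values = {key: int(round(res.x[i])) for key, i in model.var_index.items()}
    return SolveResult(status, round(float(res.fun), 9), values, elapsed, optimal)


# ---------------------------------------------------------------------------
# Shared scaffolding


def _node_order(g: nx.Graph) -> list:
    """Symmetry-breaking node order: descending degree, then label."""
    return sorted(g.nodes(), key=lambda v: (-g.degree(v), str(v)))


def _owner(j: int) -> int:
    """Color j is owned by node index ceil(j/2) (1-based)."""
    return (j + 1) // 2


def _allowed_colors(g, order, index, prune: bool) -> dict:
    """Free color set per node.

    Unpruned: every color 1..2n.  Pruned (requires symmetry breaking): node
    v keeps its own two colors plus the colors owned by earlier neighbors —
    a color owned by a later node would make v its first user (forbidden by
    the first-use ordering), and a color owned by an earlier non-neighbor
    cannot be shared with its owner.
    """
    n = len(order)
    allowed = {}
    for v in order:
        iv = index[v]
        if not prune:
            allowed[v] = list(range(1, 2 * n + 1))
        else:
            cols = [2 * iv - 1, 2 * iv]
            for u in g[v]:
                iu = index[u]
                if iu < iv:
                    cols += [2 * iu - 1, 2 * iu]
            allowed[v] = sorted(cols)
    return allowed


def _add_symmetry_constraints(model, order, index, allowed) -> None:
    for v in order:
        iv = index[v]
        if model.has_var(("x", v, 2 * iv)) and model.has_var(("x", v, 2 * iv - 1)):
            model.add_constr(
                {("x", v, 2 * iv): 1, ("x", v, 2 * iv - 1): -1}, -np.inf, 0
            )
    for u in order:
        iu = index[u]
        for v in order:
            if index[v] <= iu:
                continue
            for j in (2 * iu - 1, 2 * iu):
                if model.has_var(("x", v, j)):
                    model.add_constr(
                        {("x", v, j): 1, ("x", u, j): -1}, -np.inf, 0
                    )


def _nonadjacency_constraints(model, g, order, allowed) -> None:
    aset = {v: set(c) for v, c in allowed.items()}
    for u, v in itertools.combinations(order, 2):
        if g.has_edge(u, v):
            continue
        for j in aset[u] & aset[v]:
            model.add_constr({("x", u, j): 1, ("x", v, j): 1}, -np.inf, 1)


def _sharing_constraints(model, e, u, v, scols) -> None:
    """s[e,j] = 1 iff both endpoints of e carry color j."""
    for j in scols:
        model.add_constr(
            {("x", u, j): 1, ("x", v, j): 1, ("s", e, j): -1}, -np.inf, 1
        )
        model.add_constr({("s", e, j): 1, ("x", u, j): -1}, -np.inf, 0)
        model.add_constr({("s", e, j): 1, ("x", v, j): -1}, -np.inf, 0)


def _ekey(u, v):
    return frozenset((u, v))


# ---------------------------------------------------------------------------
# Edge deletion


def _edge_deletion_model(g: nx.Graph, symmetry: bool, prune: bool) -> ILPModel:
    if prune and not symmetry:
        raise ValueError("variable pruning requires symmetry breaking")
    order = _node_order(g)
    index = {v: i + 1 for i, v in enumerate(order)}
    allowed = _allowed_colors(g, order, index, prune)
    model = ILPModel(g, "edge", symmetry=symmetry, prune=prune,
                     order=order, index=index, allowed=allowed)

    for v in order:
        for j in allowed[v]:
            model.add_var(("x", v, j))
    edges = [(_ekey(u, v), u, v) for u, v in sorted(g.edges(), key=lambda e: tuple(sorted(map(str, e))))]
    for e, u, v in edges:
        model.add_var(("d", e), obj=1.0)
    scols = {}
    for e, u, v in edges:
        scols[e] = sorted(set(allowed[u]) & set(allowed[v]))
        for j in scols[e]:
            model.add_var(("s", e, j))

    for v in order:
        model.add_constr({("x", v, j): 1 for j in allowed[v]}, 2, 2)
    _nonadjacency_constraints(model, g, order, allowed)
    for e, u, v in edges:
        coeffs = {("s", e, j): 1 for j in scols[e]}
        coeffs[("d", e)] = 1
        model.add_constr(coeffs, 1, 1)
        _sharing_constraints(model, e, u, v, scols[e])
    if symmetry:
        _add_symmetry_constraints(model, order, index, allowed)
    return model


def build_edge_deletion_ilp(g: nx.Graph) -> ILPModel:
    """The basic edge-deletion program: min sum(d_e) over allelable colorings."""
    return _edge_deletion_model(g, symmetry=False, prune=False)


def add_symmetry_breaking(model: ILPModel) -> ILPModel:
    """Rebuild with first-use color ownership constraints added."""
    return _edge_deletion_model(model.graph, symmetry=True, prune=model.meta.get("prune", False))


def prune_variables(model: ILPModel, g: nx.Graph | None = None) -> ILPModel:
    """Rebuild with provably-zero x and s variables removed."""
    if not model.meta.get("symmetry"):
        raise ValueError("apply symmetry breaking before pruning")
    return _edge_deletion_model(g if g is not None else model.graph, symmetry=True, prune=True)


# ---------------------------------------------------------------------------
# Solutions


@dataclass
class DeletionSolution:
    """Outcome of one graph-modification solve."""

    deleted_edges: set = field(default_factory=set)
    deleted_nodes: set = field(default_factory=set)
    inserted_edges: set = field(default_factory=set)
    assignment: lg.AlleleAssignment | None = None
    objective: float = 0.0
    status: str = "optimal"
    estimated_haplotypes: int = 0
    solve_seconds: float = 0.0
    optimal: bool = True


def _assignment_from_values(values, order, surviving, tag: str) -> lg.AlleleAssignment:
    colors = {}
    for v in surviving:
        cols = frozenset(
            f"{tag}c{key[2]}"
            for key, val in values.items()
            if key[0] == "x" and key[1] == v and val == 1
        )
        colors[v] = cols
    return lg.AlleleAssignment(colors)


def _assignment_from_root(comp: nx.Graph, tag: str) -> tuple[lg.AlleleAssignment, int]:
    root = lg.reconstruct_root(comp)
    a = lg.allele_assignment_from_root(root)
    colors = {v: frozenset(f"{tag}{c}" for c in pair) for v, pair in a.colors.items()}
    return lg.AlleleAssignment(colors), root.n_haplotypes


def _merge(parts: list[DeletionSolution]) -> DeletionSolution:
    out = DeletionSolution(assignment=lg.AlleleAssignment({}))
    used = set()
    for p in parts:
        out.deleted_edges |= p.deleted_edges
        out.deleted_nodes |= p.deleted_nodes
        out.inserted_edges |= p.inserted_edges
        out.objective += p.objective if p.objective is not None else 0.0
        out.solve_seconds += p.solve_seconds
        out.optimal = out.optimal and p.optimal
        if p.status != "optimal" and out.status == "optimal":
            out.status = p.status
        if p.assignment is not None:
            out.assignment.colors.update(p.assignment.colors)
            for pair in p.assignment.colors.values():
                used.update(pair)
    out.estimated_haplotypes = len(used)
    return out


def _is_line_fast(comp: nx.Graph) -> bool:
    """Cheap line-graph fast path; False also when recognition is undecided
    (the ILP then answers the question within its own time limit)."""
    try:
        return lg.is_line_graph(comp, method="krausz")
    except lg.LineGraphUndecided:
        return False


def solve_edge_deletion(g: nx.Graph, time_limit: float = DEFAULT_TIME_LIMIT,
                        seed: int | None = None, decompose: bool = True,
                        shortcut: bool = True) -> DeletionSolution:
    """Minimum edge deletions making g a line graph, with haplotype coloring.

    Solved independently per connected component (edge deletions never merge
    components, so the optimum is additive); components that are already
    line graphs are colored directly from their Krausz root without
    invoking the solver.
    """
    comps = (
        sorted(nx.connected_components(g), key=lambda c: tuple(sorted(map(str, c))))
        if decompose
        else [set(g.nodes())]
    )
    parts = []
    for ci, nodes in enumerate(comps):
        comp = g.subgraph(nodes).copy()
        tag = f"g{ci}:"
        if shortcut and _is_line_fast(comp):
            a, nh = _assignment_from_root(comp, tag)
            parts.append(DeletionSolution(assignment=a, estimated_haplotypes=nh))
            continue
        model = _edge_deletion_model(comp, symmetry=True, prune=True)
        res = solve_model(model, time_limit=time_limit, seed=seed)
        if res.values:
            deleted = {k[1] for k, val in res.values.items() if k[0] == "d" and val == 1}
            a = _assignment_from_values(res.values, model.meta["order"], comp.nodes(), tag)
            parts.append(DeletionSolution(
                deleted_edges={tuple(sorted(e, key=str)) for e in deleted},
                assignment=a, objective=res.objective, status=res.status,
                solve_seconds=res.solve_seconds, optimal=res.optimal,
            ))
        else:
            parts.append(DeletionSolution(
                assignment=lg.AlleleAssignment({v: frozenset() for v in comp}),
                status=res.status, solve_seconds=res.solve_seconds,
                objective=0.0, optimal=False,
            ))
    return _merge(parts)


# ---------------------------------------------------------------------------
# Node deletion (hitting set over forbidden occurrences)


def build_node_deletion_ilp(g: nx.Graph) -> ILPModel:
    """min sum(t_v) s.t. every forbidden occurrence loses at least one node."""
    model = ILPModel(g, "node")
    for v in sorted(g.nodes(), key=str):
        model.add_var(("t", v), obj=1.0)
    for occ in lg.find_forbidden_occurrences(g):
        model.add_constr({("t", v): 1 for v in occ}, 1, np.inf)
    return model


def solve_node_deletion(g: nx.Graph, time_limit: float = DEFAULT_TIME_LIMIT,
                        seed: int | None = None) -> DeletionSolution:
    model = build_node_deletion_ilp(g)
    res = solve_model(model, time_limit=time_limit, seed=seed)
    deleted = {k[1] for k, v in res.values.items() if k[0] == "t" and v == 1}
    surviving = g.subgraph([v for v in g if v not in deleted]).copy()
    # deleting a node never creates a forbidden occurrence, so the survivor
    # is a line graph and can be colored from its root
    a, nh = _assignment_from_root(surviving, "g0:")
    return DeletionSolution(
        deleted_nodes=deleted, assignment=a, objective=res.objective,
        status=res.status, estimated_haplotypes=nh,
        solve_seconds=res.solve_seconds, optimal=res.optimal,
    )


# ---------------------------------------------------------------------------
# Combined edge + node deletion


def build_combined_ilp(g: nx.Graph, alpha: float, symmetry: bool = True,
                       prune: bool = True) -> ILPModel:
    """Edges cost 1, nodes cost alpha; r_e marks removal for either reason."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    order = _node_order(g)
    index = {v: i + 1 for i, v in enumerate(order)}
    allowed = _allowed_colors(g, order, index, prune)
    model = ILPModel(g, "combined", alpha=alpha, symmetry=symmetry, prune=prune,
                     order=order, index=index, allowed=allowed)
    for v in order:
        model.add_var(("t", v), obj=float(alpha))
        for j in allowed[v]:
            model.add_var(("x", v, j))
    edges = [(_ekey(u, v), u, v) for u, v in sorted(g.edges(), key=lambda e: tuple(sorted(map(str, e))))]
    scols = {}
    for e, u, v in edges:
        model.add_var(("d", e), obj=1.0)
        model.add_var(("r", e))
        scols[e] = sorted(set(allowed[u]) & set(allowed[v]))
        for j in scols[e]:
            model.add_var(("s", e, j))

    for v in order:
        coeffs = {("x", v, j): 1 for j in allowed[v]}
        coeffs[("t", v)] = 2
        model.add_constr(coeffs, 2, 2)
    _nonadjacency_constraints(model, g, order, allowed)
    for e, u, v in edges:
        coeffs = {("s", e, j): 1 for j in scols[e]}
        coeffs[("r", e)] = 1
        model.add_constr(coeffs, 1, 1)
        _sharing_constraints(model, e, u, v, scols[e])
        model.add_constr(
            {("r", e): 1, ("t", u): -1, ("t", v): -1, ("d", e): -1}, -np.inf, 0
        )
        model.add_constr({("d", e): 1, ("r", e): -1}, -np.inf, 0)
        model.add_constr({("t", u): 1, ("r", e): -1}, -np.inf, 0)
        model.add_constr({("t", v): 1, ("r", e): -1}, -np.inf, 0)
    if symmetry:
        _add_symmetry_constraints(model, order, index, allowed)
    return model


def solve_combined(g: nx.Graph, alpha: float,
                   time_limit: float = DEFAULT_TIME_LIMIT,
                   seed: int | None = None, decompose: bool = True,
                   shortcut: bool = True) -> DeletionSolution:
    comps = (
        sorted(nx.connected_components(g), key=lambda c: tuple(sorted(map(str, c))))
        if decompose
        else [set(g.nodes())]
    )
    parts = []
    for ci, nodes in enumerate(comps):
        comp = g.subgraph(nodes).copy()
        tag = f"g{ci}:"
        if shortcut and _is_line_fast(comp):
            a, nh = _assignment_from_root(comp, tag)
            parts.append(DeletionSolution(assignment=a, estimated_haplotypes=nh))
            continue
        model = build_combined_ilp(comp, alpha)
        res = solve_model(model, time_limit=time_limit, seed=seed)
        if not res.values:
            parts.append(DeletionSolution(
                assignment=lg.AlleleAssignment({v: frozenset() for v in comp}),
                status=res.status, solve_seconds=res.solve_seconds, optimal=False,
            ))
            continue
        del_nodes = {k[1] for k, v in res.values.items() if k[0] == "t" and v == 1}
        del_edges = {
            tuple(sorted(k[1], key=str))
            for k, v in res.values.items()
            if k[0] == "d" and v == 1 and not (set(k[1]) & del_nodes)
        }
        surviving = [v for v in comp if v not in del_nodes]
        a = _assignment_from_values(res.values, model.meta["order"], surviving, tag)
        parts.append(DeletionSolution(
            deleted_edges=del_edges, deleted_nodes=del_nodes, assignment=a,
            objective=res.objective, status=res.status,
            solve_seconds=res.solve_seconds, optimal=res.optimal,
        ))
    return _merge(parts)


# ---------------------------------------------------------------------------
# Edge editing (insertions and deletions, weighted)


def build_edit_ilp(g: nx.Graph, weights: dict | None = None,
                   insert_candidates=None, symmetry: bool = True) -> ILPModel:
    """Weighted line-graph editing: delete existing edges, insert others.

    ``weights`` maps frozenset pairs to positive costs (default 1 for every
    pair).  ``insert_candidates`` restricts insertable non-edges; by default
    every non-adjacent pair may be inserted (the full V x V program).
    """
    order = _node_order(g)
    index = {v: i + 1 for i, v in enumerate(order)}
    n = len(order)
    # symmetry breaking caps node v's colors at [1, 2v]; no adjacency
    # pruning here since insertions can make any pair adjacent
    allowed = {v: list(range(1, (2 * index[v] if symmetry else 2 * n) + 1)) for v in order}
    weights = weights or {}
    non_edges = [
        _ekey(u, v) for u, v in itertools.combinations(sorted(g.nodes(), key=str), 2)
        if not g.has_edge(u, v)
    ]
    if insert_candidates is None:
        candidates = set(non_edges)
    else:
        candidates = {_ekey(*e) for e in insert_candidates}
    model = ILPModel(g, "edit", symmetry=symmetry, order=order, index=index,
                     allowed=allowed, candidates=candidates)
    for v in order:
        for j in allowed[v]:
            model.add_var(("x", v, j))
    edges = [(_ekey(u, v), u, v) for u, v in sorted(g.edges(), key=lambda e: tuple(sorted(map(str, e))))]
    pairs = edges + [
        (e, *sorted(e, key=str)) for e in sorted(candidates, key=lambda e: tuple(sorted(map(str, e))))
    ]
    scols = {}
    for e, u, v in edges:
        model.add_var(("d", e), obj=float(weights.get(e, 1.0)))
    for e in sorted(candidates, key=lambda e: tuple(sorted(map(str, e)))):
        model.add_var(("c", e), obj=float(weights.get(e, 1.0)))
    for e, u, v in pairs:
        scols[e] = sorted(set(allowed[u]) & set(allowed[v]))
        for j in scols[e]:
            model.add_var(("s", e, j))

    for v in order:
        model.add_constr({("x", v, j): 1 for j in allowed[v]}, 2, 2)
    for e, u, v in pairs:
        coeffs = {("s", e, j): 1 for j in scols[e]}
        if g.has_edge(u, v):
            coeffs[("d", e)] = 1  # sum s = 1 - d
            model.add_constr(coeffs, 1, 1)
        else:
            coeffs[("c", e)] = -1  # sum s = c
            model.add_constr(coeffs, 0, 0)
        _sharing_constraints(model, e, u, v, scols[e])
    for e in non_edges:
        if e in candidates:
            continue
        u, v = sorted(e, key=str)
        for j in set(allowed[u]) & set(allowed[v]):
            model.add_constr({("x", u, j): 1, ("x", v, j): 1}, -np.inf, 1)
    if symmetry:
        _add_symmetry_constraints(model, order, index, allowed)
    return model


def solve_edit(g: nx.Graph, weights: dict | None = None, insert_candidates=None,
               time_limit: float = DEFAULT_TIME_LIMIT,
               seed: int | None = None) -> DeletionSolution:
    model = build_edit_ilp(g, weights, insert_candidates)
    res = solve_model(model, time_limit=time_limit, seed=seed)
    if not res.values:
        return DeletionSolution(
            assignment=lg.AlleleAssignment({v: frozenset() for v in g}),
            status=res.status, solve_seconds=res.solve_seconds, optimal=False,
        )
    deleted = {tuple(sorted(k[1], key=str)) for k, v in res.values.items() if k[0] == "d" and v == 1}
    inserted = {tuple(sorted(k[1], key=str)) for k, v in res.values.items() if k[0] == "c" and v == 1}
    a = _assignment_from_values(res.values, model.meta["order"], g.nodes(), "g0:")
    used = set().union(*a.colors.values()) if a.colors else set()
    return DeletionSolution(
        deleted_edges=deleted, inserted_edges=inserted, assignment=a,
        objective=res.objective, status=res.status,
        estimated_haplotypes=len(used), solve_seconds=res.solve_seconds,
        optimal=res.optimal,
    )


# ---------------------------------------------------------------------------
# Parsimony haplotype count


def build_min_haplotypes_ilp(g: nx.Graph, cuts=()) -> ILPModel:
    """min number of colors; edges may silently drop (sum_j s_ej <= 1).

    ``cuts`` is an iterable of edge collections C adding the constraint
    sum_{e in C} sum_j s_ej <= |C| - 1 (used by the phasing loop to outlaw
    sharing patterns proven genotype-inconsistent).
    """
    order = _node_order(g)
    index = {v: i + 1 for i, v in enumerate(order)}
    allowed = _allowed_colors(g, order, index, prune=True)
    model = ILPModel(g, "parsimony", order=order, index=index, allowed=allowed)
    for v in order:
        iv = index[v]
        for j in allowed[v]:
            own = 1.0 if j in (2 * iv - 1, 2 * iv) else 0.0
            model.add_var(("x", v, j), obj=own)
    edges = [(_ekey(u, v), u, v) for u, v in sorted(g.edges(), key=lambda e: tuple(sorted(map(str, e))))]
    scols = {}
    for e, u, v in edges:
        scols[e] = sorted(set(allowed[u]) & set(allowed[v]))
        for j in scols[e]:
            model.add_var(("s", e, j))

    for v in order:
        model.add_constr({("x", v, j): 1 for j in allowed[v]}, 2, 2)
    _nonadjacency_constraints(model, g, order, allowed)
    for e, u, v in edges:
        if scols[e]:
            model.add_constr({("s", e, j): 1 for j in scols[e]}, -np.inf, 1)
        _sharing_constraints(model, e, u, v, scols[e])
    _add_symmetry_constraints(model, order, index, allowed)
    for cut in cuts:
        coeffs: dict = {}
        nc = 0
        for e in cut:
            e = _ekey(*e)
            nc += 1
            for j in scols.get(e, ()):
                coeffs[("s", e, j)] = 1
        model.add_constr(coeffs, -np.inf, nc - 1)
    return model


def solve_min_haplotypes(g: nx.Graph, cuts=(),
                         time_limit: float = DEFAULT_TIME_LIMIT,
                         seed: int | None = None):
    """Returns (count, AlleleAssignment, sharing set I, SolveResult).

    I maps each sharing edge (a sorted tuple) to the color its endpoints
    share — two sharings with the same color claim the same haplotype.
    """
    model = build_min_haplotypes_ilp(g, cuts)
    res = solve_model(model, time_limit=time_limit, seed=seed)
    if not res.values:
        return None, None, {}, res
    a = _assignment_from_values(res.values, model.meta["order"], g.nodes(), "")
    sharing = {
        tuple(sorted(k[1], key=str)): f"c{k[2]}"
        for k, v in res.values.items()
        if k[0] == "s" and v == 1
    }
    used = set().union(*a.colors.values()) if a.colors else set()
    return len(used), a, sharing, res


# ---------------------------------------------------------------------------
# End-to-end pipeline


def estimate_population_size(m: gt.GenotypeMatrix, mode: str = "edge",
                             alpha: float = 1.5,
                             time_limit: float = DEFAULT_TIME_LIMIT,
                             seed: int | None = None,
                             edit_cap: int = 2) -> dict:
    """Preprocess genotypes, build the CC graph, solve, and report.

    Modes: ``edge`` (the default estimator), ``node`` (hitting set),
    ``combined`` (alpha-weighted node+edge deletion), ``edit`` (weighted
    deletion+insertion, insertion weight = number of opposite-homozygote
    sites, candidates capped at ``edit_cap`` incompatibilities), and
    ``parsimony`` (minimum-color relaxation; a lower bound).
    """
    t0 = time.perf_counter()
    clean, prep_report = gt.preprocess(m)
    g = gt.build_cc_graph(clean)
    report = {
        "mode": mode,
        "n_genotypes": clean.n_individuals,
        "n_sites": clean.n_sites,
        "n_edges": g.number_of_edges(),
        "preprocessing": prep_report,
    }
    if mode == "edge":
        sol = solve_edge_deletion(g, time_limit=time_limit, seed=seed)
    elif mode == "node":
        sol = solve_node_deletion(g, time_limit=time_limit, seed=seed)
    elif mode == "combined":
        sol = solve_combined(g, alpha, time_limit=time_limit, seed=seed)
    elif mode == "edit":
        weights, candidates = {}, set()
        idx = {v: i for i, v in enumerate(clean.individual_ids)}
        for u, v in itertools.combinations(clean.individual_ids, 2):
            incompat = gt.incompatibility_count(clean.calls[idx[u]], clean.calls[idx[v]])
            e = _ekey(u, v)
            if incompat == 0:
                weights[e] = 1.0
            elif incompat <= edit_cap:
                candidates.add(e)
                weights[e] = float(incompat)
        sol = solve_edit(g, weights, candidates, time_limit=time_limit, seed=seed)
    elif mode == "parsimony":
        count, a, sharing, res = solve_min_haplotypes(g, time_limit=time_limit, seed=seed)
        sol = DeletionSolution(
            assignment=a, objective=res.objective or 0.0, status=res.status,
            estimated_haplotypes=count or 0, solve_seconds=res.solve_seconds,
            optimal=res.optimal,
        )
        report["sharing_edges"] = sorted(sharing)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    report.update(
        estimated_haplotypes=sol.estimated_haplotypes,
        edges_removed=len(sol.deleted_edges),
        nodes_removed=len(sol.deleted_nodes),
        edges_inserted=len(sol.inserted_edges),
        removed_edges=sorted(map(list, sol.deleted_edges)),
        removed_nodes=sorted(map(str, sol.deleted_nodes)),
        inserted_edges=sorted(map(list, sol.inserted_edges)),
        status=sol.status,
        optimal=sol.optimal,
        solve_seconds=round(sol.solve_seconds, 3),
        total_seconds=round(time.perf_counter() - t0, 3),
    )
    # collapsed duplicates share both haplotypes with their representative:
    # they add no new haplotypes but are listed for bookkeeping
    report["collapsed_duplicates"] = prep_report["duplicate_groups"]
    report["_solution"] = sol
    return report
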