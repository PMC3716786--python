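"""Line-graph recognition, root-graph reconstruction and allele assignments.

If every Clark-consistency edge were a true haplotype sharing, the CC graph
would be the line graph L(G) of a "root" graph G whose nodes are haplotypes
and whose edges are genotypes.  Reconstructing G from L(G) therefore counts
the haplotypes in the sample.  Two classical characterisations are used
side by side and cross-validated:

* a graph is a line graph iff it contains none of the nine minimal
  forbidden induced subgraphs (the claw K_{1,3} and eight others on 5-6
  nodes), shipped here as a packaged catalog;
* a graph is a line graph iff its edges admit a Krausz partition into
  cliques with every node in at most two cliques — the cliques are exactly
  the root-graph nodes.

Equivalently (and this is what the integer programs exploit), a graph is a
line graph iff it is *allelable*: each node can be given an unordered pair
of colors so that adjacent nodes share exactly one color and non-adjacent
nodes share none.  Colors are haplotype labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx

__all__ = [
    "LineGraphError",
    "RootGraph",
    "AlleleAssignment",
    "forbidden_catalog",
    "is_even_triangle",
    "is_line_graph",
    "find_forbidden_occurrences",
    "find_one_forbidden",
    "reconstruct_root",
    "allele_assignment_from_root",
    "verify_allelable",
    "count_haplotypes",
]


class LineGraphError(ValueError):
    """Raised when root reconstruction is attempted on a non-line graph."""


class LineGraphUndecided(RuntimeError):
    """Krausz backtracking exceeded its step budget (dense adversarial input)."""


@dataclass
class RootGraph:
    """A root graph G with L(G) isomorphic to the input.

    ``graph`` has fresh haplotype labels; ``edge_to_individual`` maps each
    root edge (a frozenset of two haplotype labels) to the line-graph node
    (individual) it represents.
    """

    graph: nx.Graph
    edge_to_individual: dict[frozenset, object]

    @property
    def n_haplotypes(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class AlleleAssignment:
    """Map node -> unordered pair of distinct color (haplotype) labels."""

    colors: dict

    def pair(self, node) -> frozenset:
        return self.colors[node]


# ---------------------------------------------------------------------------
# Forbidden-subgraph catalog

_catalog_cache: list[nx.Graph] | None = None


def forbidden_catalog() -> list[nx.Graph]:
    """The nine minimal non-line graphs, claw K_{1,3} first.

    Loaded from the packaged edge-list file; each member has 4-6 nodes and
    at most 10 edges, is not a line graph, and every proper induced subgraph
    of it is one.
    """
    global _catalog_cache
    if _catalog_cache is None:
        text = (resources.files("linehap") / "data" / "forbidden_subgraphs.tsv").read_text()
        graphs: dict[str, nx.Graph] = {}
        for ln in text.splitlines():
            if not ln.strip() or ln.startswith("#"):
                continue
            gid, u, v = ln.split("\t")
            graphs.setdefault(gid, nx.Graph()).add_edge(int(u), int(v))
        _catalog_cache = [graphs[k] for k in sorted(graphs)]
    return _catalog_cache


def is_even_triangle(g: nx.Graph, t) -> bool:
    """A triangle is even if every outside node has 0 or 2 neighbors in it."""
    t = tuple(t)
    if len(set(t)) != 3 or not all(g.has_edge(a, b) for a, b in itertools.combinations(t, 2)):
        raise ValueError(f"{t} does not induce a triangle")
    ts = set(t)
    return all(len(ts & set(g[v])) in (0, 2) for v in g if v not in ts)


def find_forbidden_occurrences(g: nx.Graph) -> list[frozenset]:
    """All induced occurrences of catalog members, deduplicated by node set."""
    found: set[frozenset] = set()
    for f in forbidden_catalog():
        gm = nx.algorithms.isomorphism.GraphMatcher(g, f)
        for mapping in gm.subgraph_isomorphisms_iter():
            found.add(frozenset(mapping))
    return sorted(found, key=lambda s: tuple(sorted(map(str, s))))


def find_one_forbidden(g: nx.Graph) -> frozenset | None:
    """First induced forbidden occurrence, or None if g is a line graph."""
    for f in forbidden_catalog():
        gm = nx.algorithms.isomorphism.GraphMatcher(g, f)
        for mapping in gm.subgraph_isomorphisms_iter():
            return frozenset(mapping)
    return None


def is_line_graph(g: nx.Graph, method: str = "catalog") -> bool:
    """Line-graph test, by forbidden-subgraph scan or Krausz reconstruction."""
    if method == "catalog":
        return find_one_forbidden(g) is None
    if method == "krausz":
        try:
            reconstruct_root(g)
            return True
        except LineGraphError:
            return False
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Krausz partition and root reconstruction


def _krausz_partition(comp: nx.Graph, max_steps: int = 500_000) -> list[set] | None:
    """Partition the edges of a connected graph into cliques with every node
    in at most two cliques; None if impossible (i.e. not a line graph).

    Plain backtracking over the edges in sorted order; adequate for the
    small, sparse components seen here (linear-time recognition exists but
    is unnecessary at these sizes).  On dense far-from-line inputs the
    search can blow up, so it raises :class:`LineGraphUndecided` after
    ``max_steps`` backtracking calls; callers that only use recognition as
    a fast path then fall back to other machinery.
    """
    edges = [frozenset(e) for e in sorted(comp.edges(), key=lambda e: tuple(sorted(map(str, e))))]
    steps = [0]
    cliques: list[set] = []
    nclq: dict = {v: 0 for v in comp}  # node -> number of cliques containing it
    covered: set[frozenset] = set()

    def next_uncovered() -> frozenset | None:
        for e in edges:
            if e not in covered:
                return e
        return None

    def extend(clq: set, w) -> list[frozenset] | None:
        """Edges newly covered by adding w to clq, or None if illegal."""
        new = []
        for u in clq:
            e = frozenset((u, w))
            if not comp.has_edge(u, w) or e in covered:
                return None
            new.append(e)
        return new

    def backtrack() -> bool:
        steps[0] += 1
        if steps[0] > max_steps:
            raise LineGraphUndecided(
                f"Krausz search exceeded {max_steps} steps on a "
                f"{comp.number_of_nodes()}-node, {comp.number_of_edges()}-edge component"
            )
        e = next_uncovered()
        if e is None:
            return True
        u, v = sorted(e, key=str)
        # option: grow an existing clique of one endpoint with the other
        for w, anchor in ((v, u), (u, v)):
            if nclq[w] >= 2:
                continue
            for clq in cliques:
                if anchor in clq and w not in clq:
                    new = extend(clq, w)
                    if new is None:
                        continue
                    clq.add(w)
                    nclq[w] += 1
                    covered.update(new)
                    if backtrack():
                        return True
                    clq.remove(w)
                    nclq[w] -= 1
                    covered.difference_update(new)
        # option: open a fresh clique on this edge
        if nclq[u] < 2 and nclq[v] < 2:
            cliques.append({u, v})
            nclq[u] += 1
            nclq[v] += 1
            covered.add(e)
            if backtrack():
                return True
            cliques.pop()
            nclq[u] -= 1
            nclq[v] -= 1
            covered.discard(e)
        return False

    if backtrack():
        return cliques
    return None


def reconstruct_root(g: nx.Graph) -> RootGraph:
    """Reconstruct a root graph whose line graph is isomorphic to g.

    Component-wise.  An isolated node (a genotype sharing with nobody) maps
    to a root edge between two fresh haplotype nodes.  A K3 component is
    Whitney's ambiguous case — both K3 and the star K_{1,3} are roots — and
    is resolved toward the K3 root (3 haplotypes rather than 4), keeping the
    estimate a lower bound in line with the parsimony objective.
    """
    root = nx.Graph()
    edge_map: dict[frozenset, object] = {}
    counter = itertools.count()

    def fresh():
        return f"h{next(counter)}"

    for comp_nodes in sorted(nx.connected_components(g), key=lambda c: tuple(sorted(map(str, c)))):
        comp = g.subgraph(comp_nodes)
        if comp.number_of_nodes() == 1:
            a, b = fresh(), fresh()
            root.add_edge(a, b)
            edge_map[frozenset((a, b))] = next(iter(comp_nodes))
            continue
        if comp.number_of_nodes() == 3 and comp.number_of_edges() == 3:
            labels = {v: fresh() for v in sorted(comp_nodes, key=str)}
            # K3 root: each line-graph node is one edge of a root triangle
            vs = sorted(comp_nodes, key=str)
            tri = [labels[v] for v in vs]
            pairs = [(tri[0], tri[1]), (tri[1], tri[2]), (tri[0], tri[2])]
            for v, (a, b) in zip(vs, pairs):
                root.add_edge(a, b)
                edge_map[frozenset((a, b))] = v
            continue
        part = _krausz_partition(comp)
        if part is None:
            occ = find_one_forbidden(comp)
            raise LineGraphError(
                f"component {sorted(map(str, comp_nodes))} is not a line graph; "
                f"forbidden occurrence: {sorted(map(str, occ)) if occ else 'n/a'}"
            )
        clq_label = [fresh() for _ in part]
        node_cliques: dict = {v: [] for v in comp_nodes}
        for i, clq in enumerate(part):
            for v in clq:
                node_cliques[v].append(i)
        for v in sorted(comp_nodes, key=str):
            cl = node_cliques[v]
            if len(cl) == 2:
                a, b = clq_label[cl[0]], clq_label[cl[1]]
            elif len(cl) == 1:
                a, b = clq_label[cl[0]], fresh()
            else:  # pragma: no cover - every node of a component with edges is in >=1 clique
                a, b = fresh(), fresh()
            root.add_edge(a, b)
            edge_map[frozenset((a, b))] = v
    return RootGraph(root, edge_map)


# ---------------------------------------------------------------------------
# Allele assignments (Krausz cliques / root nodes as colors)


def allele_assignment_from_root(r: RootGraph) -> AlleleAssignment:
    """Color each individual with the labels of its root edge's endpoints."""
    colors = {}
    for e, individual in r.edge_to_individual.items():
        colors[individual] = frozenset(e)
    return AlleleAssignment(colors)


def verify_allelable(g: nx.Graph, a: AlleleAssignment) -> bool:
    """Adjacent nodes share exactly one color; non-adjacent nodes share none."""
    for v in g:
        if v not in a.colors:
            raise ValueError(f"node {v!r} has no color assignment")
        if len(a.colors[v]) != 2:
            return False
    nodes = sorted(g, key=str)
    for u, v in itertools.combinations(nodes, 2):
        shared = len(a.colors[u] & a.colors[v])
        if g.has_edge(u, v):
            if shared != 1:
                return False
        elif shared != 0:
            return False
    return True


def count_haplotypes(a: AlleleAssignment) -> int:
    """Number of distinct colors (haplotypes) used across all nodes."""
    used = set()
    for pair in a.colors.values():
        used.update(pair)
    return len(used)


# ---------------------------------------------------------------------------
# Root graph I/O


def write_root(r: RootGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#hap1\thap2\tindividual\n")
        for e, ind in sorted(r.edge_to_individual.items(), key=lambda kv: str(kv[1])):
            a, b = sorted(e)
            fh.write(f"{a}\t{b}\t{ind}\n")
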