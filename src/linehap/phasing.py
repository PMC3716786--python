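"""Constraint-generation haplotype phasing on top of the parsimony program.

The minimum-color integer program proposes a sharing pattern I: a set of CC
edges whose endpoints are claimed to share a haplotype.  The pattern only
respects the graph, not the underlying SNP data, so each proposal is
validated by actually trying to phase it:

1. seed a set S with the two endpoints of a sharing edge and partially
   phase them (every site where either endpoint is homozygous forces the
   shared haplotype's allele);
2. repeatedly attach an I-neighbor v of S, identify *which* haplotype of
   its neighbor it shares (the triangle rule), merge v's genotype
   constraints into it, and propagate complements through S to a fixed
   point;
3. if a forced allele ever contradicts a homozygous call, the sharings
   used so far cannot all hold: a cut  sum_{e in I cap S} sum_j s_ej <=
   |I cap S| - 1  is added and the program re-solved.

Haplotypes are shared mutable objects: an individual's slot and its
partner's slot reference the same :class:`PartialHaplotype`, so fixing a
site anywhere propagates to everyone sharing that haplotype.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import genotypes as gt
from . import ilp

UNKNOWN = -1


class PhasingConflict(Exception):
    """A forced allele contradicts a genotype; carries the witnessing edges."""

    def __init__(self, message: str, edges: set):
        super().__init__(message)
        self.edges = edges


@dataclass(eq=False)  # identity semantics: a haplotype is shared by reference
class PartialHaplotype:
    """Allele vector with UNKNOWN (-1) for undetermined sites."""

    alleles: np.ndarray

    @classmethod
    def blank(cls, n_sites: int) -> "PartialHaplotype":
        return cls(np.full(n_sites, UNKNOWN, dtype=np.int8))

    def set(self, site: int, allele: int) -> bool:
        """Fix a site; returns True if newly fixed; raises on contradiction."""
        cur = int(self.alleles[site])
        if cur == allele:
            return False
        if cur != UNKNOWN:
            raise ValueError(f"site {site} already {cur}, cannot set {allele}")
        self.alleles[site] = allele
        return True

    def as_string(self) -> str:
        return "".join("?" if a == UNKNOWN else str(int(a)) for a in self.alleles)


@dataclass
class PhasingState:
    """Grown set S with two haplotype slots per member node."""

    members: set = field(default_factory=set)
    slots: dict = field(default_factory=dict)  # node -> [PartialHaplotype, PartialHaplotype]
    used_edges: set = field(default_factory=set)  # I-edges consumed so far


def _propagate(state: PhasingState, m: gt.GenotypeMatrix, row_of: dict) -> None:
    """Push genotype constraints through shared haplotypes to a fixed point."""
    changed = True
    while changed:
        changed = False
        for v in state.members:
            h1, h2 = state.slots[v]
            if h1 is h2:
                raise PhasingConflict(
                    f"{v}: both haplotypes collapse to one", set(state.used_edges)
                )
            calls = m.calls[row_of[v]]
            for site in range(m.n_sites):
                c = int(calls[site])
                try:
                    if c == gt.HOM0:
                        changed |= h1.set(site, 0)
                        changed |= h2.set(site, 0)
                    elif c == gt.HOM1:
                        changed |= h1.set(site, 1)
                        changed |= h2.set(site, 1)
                    elif c == gt.HET:
                        a1, a2 = int(h1.alleles[site]), int(h2.alleles[site])
                        if a1 != UNKNOWN and a2 == UNKNOWN:
                            changed |= h2.set(site, 1 - a1)
                        elif a2 != UNKNOWN and a1 == UNKNOWN:
                            changed |= h1.set(site, 1 - a2)
                        elif a1 != UNKNOWN and a1 == a2:
                            raise ValueError(f"HET site {site} phased homozygous")
                except ValueError as exc:
                    raise PhasingConflict(f"{v}: {exc}", set(state.used_edges)) from None


def seed_set(e, m: gt.GenotypeMatrix, row_of: dict | None = None) -> PhasingState:
    """Start S from one sharing edge; returns the seeded, propagated state.

    The endpoints reference a common shared haplotype object; every site
    where either endpoint is homozygous forces that haplotype's allele (a
    heterozygous partner then gets the complement on its other haplotype).
    """
    u, v = e
    if row_of is None:
        row_of = {ind: i for i, ind in enumerate(m.individual_ids)}
    if not gt.genotypes_consistent(m.calls[row_of[u]], m.calls[row_of[v]]):
        raise gt.GenotypeError(f"endpoints of {e} are not consistent")
    shared = PartialHaplotype.blank(m.n_sites)
    state = PhasingState(
        members={u, v},
        slots={
            u: [shared, PartialHaplotype.blank(m.n_sites)],
            v: [shared, PartialHaplotype.blank(m.n_sites)],
        },
        used_edges={frozenset(e)},
    )
    _propagate(state, m, row_of)
    return state


def _identify_shared_slot(state: PhasingState, u, v, sharing: nx.Graph):
    """Which of u's two haplotypes does the new node v share? (triangle rule)

    For each partner w already sharing a slot with u: if I also makes v and
    w share, v must take the same slot; otherwise v must take the other
    one.  Contradictory demands mean the sharing pattern is unphaseable.
    """
    h1, h2 = state.slots[u]
    demanded = set()
    for k, hap in ((0, h1), (1, h2)):
        for w in state.members:
            if w == u or not any(hap is s for s in state.slots[w]):
                continue
            if sharing.has_edge(v, w):
                demanded.add(k)
            else:
                demanded.add(1 - k)
    if len(demanded) == 2:
        raise PhasingConflict(
            f"{v} would need to share both haplotypes of {u}",
            set(state.used_edges) | {frozenset((u, v))},
        )
    if len(demanded) == 1:
        return demanded.pop()
    return 0  # no sharing partner constrains the choice


def extend(state: PhasingState, v, sharing: nx.Graph, m: gt.GenotypeMatrix,
           row_of: dict | None = None) -> PhasingState:
    """Attach v to S through every I-edge it has into S; propagate.

    Raises :class:`PhasingConflict` (with the witnessing edge set for cut
    generation) if v cannot be phased consistently with S's partial phasing.
    """
    if row_of is None:
        row_of = {ind: i for i, ind in enumerate(m.individual_ids)}
    anchors = [u for u in sorted(state.members, key=str) if sharing.has_edge(u, v)]
    if not anchors:
        raise ValueError(f"{v} has no sharing edge into S")
    shared_objs = []
    for u in anchors:
        slot = _identify_shared_slot(state, u, v, sharing)
        obj = state.slots[u][slot]
        if not any(obj is o for o in shared_objs):
            shared_objs.append(obj)
        state.used_edges.add(frozenset((u, v)))
    if len(shared_objs) > 2:
        # v has only two haplotypes; three distinct shared objects cannot
        # all belong to it (conservative: cut rather than attempt unification)
        raise PhasingConflict(
            f"{v} would share >2 distinct haplotypes", set(state.used_edges)
        )
    if len(shared_objs) == 2:
        state.slots[v] = [shared_objs[0], shared_objs[1]]
    else:
        state.slots[v] = [shared_objs[0], PartialHaplotype.blank(m.n_sites)]
    state.members.add(v)
    _propagate(state, m, row_of)
    return state


def generate_cut(state: PhasingState, sharing: nx.Graph | None = None) -> list:
    """Edge set for the constraint sum_{e} sum_j s_ej <= |edges| - 1."""
    return [tuple(sorted(e, key=str)) for e in sorted(
        state.used_edges, key=lambda e: tuple(sorted(map(str, e)))
    )]


@dataclass
class PhasingResult:
    haplotypes: dict  # label -> allele string ('?' = unphased)
    pairing: dict  # individual -> (label, label)
    n_haplotypes: int
    rounds: int
    status: str  # complete | max_rounds_reached | timeout | infeasible
    cuts: list = field(default_factory=list)


def _validate_with_colors(g_nodes, sharing: nx.Graph, colors, m, row_of):
    """Color-aware pattern check: one shared haplotype object per color.

    The parsimony program labels every sharing edge with the color its
    endpoints share, and two sharings claim the same haplotype exactly when
    they carry the same color, so slot identification is direct (no
    triangle rule needed).  Genotype constraints are then propagated per
    sharing component; a contradiction raises :class:`PhasingConflict`
    carrying that component's sharing edges.
    """
    shared_colors = {d["color"] for _, _, d in sharing.edges(data=True)}
    obj_of_color: dict = {}
    slots: dict = {}
    for v in g_nodes:
        pair = []
        for c in sorted(colors[v]):
            if c in shared_colors:
                if c not in obj_of_color:
                    obj_of_color[c] = PartialHaplotype.blank(m.n_sites)
                pair.append(obj_of_color[c])
            else:
                pair.append(PartialHaplotype.blank(m.n_sites))
        while len(pair) < 2:  # degenerate assignment; keep two slots
            pair.append(PartialHaplotype.blank(m.n_sites))
        slots[v] = pair
    for comp in sorted(nx.connected_components(sharing), key=lambda c: tuple(sorted(map(str, c)))):
        state = PhasingState(
            members=set(comp),
            slots={v: slots[v] for v in comp},
            used_edges={frozenset(e) for e in sharing.subgraph(comp).edges()},
        )
        _propagate(state, m, row_of)
    return slots


def _validate_pattern(g_nodes, sharing: nx.Graph, m, row_of, colors=None):
    """Check one sharing pattern by actually phasing it.

    When ``colors`` (node -> set of color labels, with each sharing edge's
    color stored on the graph's ``color`` edge attribute) is available,
    haplotype identity is read off directly.  Otherwise phasing states are
    grown edge by edge with the triangle rule.

    Returns node -> [hap, hap] on success; raises PhasingConflict otherwise.
    """
    if colors is not None:
        return _validate_with_colors(g_nodes, sharing, colors, m, row_of)
    slots: dict = {}
    done: set = set()
    for comp in sorted(nx.connected_components(sharing), key=lambda c: tuple(sorted(map(str, c)))):
        comp_edges = sorted(
            sharing.subgraph(comp).edges(), key=lambda e: tuple(sorted(map(str, e)))
        )
        if not comp_edges:
            continue
        state = seed_set(tuple(sorted(comp_edges[0], key=str)), m, row_of)
        frontier = set(comp) - state.members
        while frontier:
            candidates = sorted(
                (v for v in frontier if any(sharing.has_edge(v, u) for u in state.members)),
                key=str,
            )
            v = candidates[0]
            extend(state, v, sharing, m, row_of)
            frontier.discard(v)
        slots.update(state.slots)
        done |= state.members
    for v in g_nodes:
        if v not in done:
            h1 = PartialHaplotype.blank(m.n_sites)
            h2 = PartialHaplotype.blank(m.n_sites)
            slots[v] = [h1, h2]
    # propagate genotype constraints for singletons too
    singleton_state = PhasingState(
        members=set(g_nodes) - done,
        slots={v: slots[v] for v in set(g_nodes) - done},
    )
    _propagate(singleton_state, m, row_of)
    return slots


def phase(m: gt.GenotypeMatrix, max_rounds: int = 50,
          time_limit: float = ilp.DEFAULT_TIME_LIMIT,
          seed: int | None = None) -> PhasingResult:
    """Iterative parsimony phasing: solve, validate, cut, repeat.

    On completion every genotype equals the site-wise combination of its
    two output haplotypes at all fixed sites; sites no constraint reaches
    stay ``?`` (any resolution is valid).  The final haplotype count can
    only grow across rounds (cuts shrink the feasible region).
    """
    clean, _ = gt.preprocess(m)
    row_of = {ind: i for i, ind in enumerate(clean.individual_ids)}
    g = gt.build_cc_graph(clean)
    cuts: list = []
    rounds = 0
    status = "max_rounds_reached"
    slots = None
    while rounds < max_rounds:
        rounds += 1
        count, assignment, sharing_edges, res = ilp.solve_min_haplotypes(
            g, cuts=cuts, time_limit=time_limit, seed=seed
        )
        if count is None:
            status = res.status
            break
        sharing = nx.Graph()
        sharing.add_nodes_from(g.nodes())
        for e, color in sharing_edges.items():
            sharing.add_edge(*e, color=color)
        try:
            slots = _validate_pattern(
                list(g.nodes()), sharing, clean, row_of, colors=assignment.colors
            )
            status = "complete"
            break
        except PhasingConflict as conflict:
            cuts.append(sorted(conflict.edges, key=lambda e: tuple(sorted(map(str, e)))))
    if slots is None:
        return PhasingResult({}, {}, 0, rounds, status, cuts)

    labels: dict[int, str] = {}
    haplotypes: dict[str, str] = {}
    pairing = {}
    counter = itertools.count()
    for v in clean.individual_ids:
        pair = []
        for hap in slots[v]:
            key = id(hap)
            if key not in labels:
                labels[key] = f"h{next(counter)}"
                haplotypes[labels[key]] = hap.as_string()
            pair.append(labels[key])
        pairing[v] = tuple(pair)
    return PhasingResult(haplotypes, pairing, len(haplotypes), rounds, status, cuts)
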