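"""Regenerate the packaged forbidden-subgraph catalog.

Searches all connected graphs on 4-6 nodes (networkx graph atlas, one per
isomorphism class) for the minimal non-line graphs: graphs that admit no
Krausz partition while every single-node-deleted induced subgraph does.
Every candidate is cross-checked against networkx's independent
inverse_line_graph recognizer.  The classical result is that exactly nine
such graphs exist, the claw K_{1,3} among them; the claw is written first
(id f0) and the rest ordered by node count, edge count and degree sequence.
"""

from pathlib import Path

import networkx as nx
from networkx.generators.atlas import graph_atlas_g

from linehap.linegraph import _krausz_partition


def krausz_is_line(g: nx.Graph) -> bool:
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_nodes() > 1 and _krausz_partition(sub) is None:
            return False
    return True


def nx_is_line(g: nx.Graph) -> bool:
    if g.number_of_edges() == 0:
        return True
    try:
        nx.inverse_line_graph(g)
        return True
    except nx.NetworkXError:
        return False


def main() -> None:
    minimal = []
    for g in graph_atlas_g():
        n = g.number_of_nodes()
        if not 4 <= n <= 6 or not nx.is_connected(g):
            continue
        ours, theirs = krausz_is_line(g), nx_is_line(g)
        assert ours == theirs, f"recognizer disagreement on atlas graph {g}"
        if ours:
            continue
        if all(
            krausz_is_line(g.subgraph([u for u in g if u != v]))
            for v in g
        ):
            minimal.append(g)
    assert len(minimal) == 9, f"expected 9 minimal non-line graphs, found {len(minimal)}"

    def is_claw(g):
        return g.number_of_nodes() == 4 and sorted(d for _, d in g.degree()) == [1, 1, 1, 3]

    claw = [g for g in minimal if is_claw(g)]
    rest = sorted(
        (g for g in minimal if not is_claw(g)),
        key=lambda g: (
            g.number_of_nodes(),
            g.number_of_edges(),
            sorted((d for _, d in g.degree()), reverse=True),
        ),
    )
    out = Path(__file__).resolve().parent.parent / "src" / "linehap" / "data" / "forbidden_subgraphs.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as fh:
        fh.write("# nine minimal forbidden induced subgraphs of line graphs (claw first)\n")
        for i, g in enumerate(claw + rest):
            relab = {v: j for j, v in enumerate(sorted(g, key=lambda v: (-g.degree(v), v)))}
            for u, v in sorted(tuple(sorted((relab[a], relab[b]))) for a, b in g.edges()):
                fh.write(f"f{i}\t{u}\t{v}\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
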