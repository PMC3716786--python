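"""Genotype matrices and the Clark-consistency (CC) graph.

A genotype is the unordered combination of an individual's two haplotypes at
each bi-allelic site, coded HOM0 (homozygous reference), HET, HOM1 (homozygous
alternate) or MISSING.  Two genotypes are *consistent* — able to share a
haplotype — when no site pairs opposite homozygotes.  The CC graph has one
node per individual and an edge for every consistent pair; every true
haplotype sharing is a CC edge, but not conversely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

# Call codes (int8).  TSV files use the characters 0/1/2/. for these.
HOM0 = 0
HET = 1
HOM1 = 2
MISSING = -1

VALID_CALLS = frozenset({HOM0, HET, HOM1, MISSING})

_TSV_CODE = {"0": HOM0, "1": HET, "2": HOM1, ".": MISSING}
_CODE_TSV = {v: k for k, v in _TSV_CODE.items()}


class GenotypeError(ValueError):
    """Raised on malformed genotype input."""


@dataclass
class GenotypeMatrix:
    """Individuals x sites call matrix.

    Parameters
    ----------
    individual_ids : list of str
        Unique labels, one per row.
    site_ids : list of str
        Unique labels, one per column (positions or marker names).
    calls : ndarray of int8, shape (n_individuals, n_sites)
        Values in {HOM0, HET, HOM1, MISSING}.
    """

    individual_ids: list[str]
    site_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, s = self.calls.shape
        if n != len(self.individual_ids) or s != len(self.site_ids):
            raise GenotypeError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.site_ids)} sites"
            )
        if len(set(self.individual_ids)) != n:
            raise GenotypeError("duplicate individual ids")
        if len(set(self.site_ids)) != s:
            raise GenotypeError("duplicate site ids")
        bad = set(np.unique(self.calls)) - VALID_CALLS
        if bad:
            raise GenotypeError(f"unknown call codes: {sorted(bad)}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def row(self, individual: str) -> np.ndarray:
        return self.calls[self.individual_ids.index(individual)]


def _check_call(c: int) -> None:
    if c not in VALID_CALLS:
        raise GenotypeError(f"unknown call code: {c!r}")


def site_consistent(a: int, b: int) -> bool:
    """Can two calls at one site be explained by a shared haplotype?

    Only opposite homozygotes (HOM0 vs HOM1) are inconsistent.  HET is
    compatible with anything, and MISSING is treated as a wildcard.
    """
    _check_call(a)
    _check_call(b)
    return {a, b} != {HOM0, HOM1}


def _conflict_mask(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    g1 = np.asarray(g1, dtype=np.int8)
    g2 = np.asarray(g2, dtype=np.int8)
    if g1.shape != g2.shape:
        raise GenotypeError(f"genotype length mismatch: {g1.shape} vs {g2.shape}")
    return ((g1 == HOM0) & (g2 == HOM1)) | ((g1 == HOM1) & (g2 == HOM0))


def genotypes_consistent(g1, g2) -> bool:
    """True iff the two call vectors are site-consistent everywhere."""
    return not bool(_conflict_mask(g1, g2).any())


def incompatibility_count(g1, g2) -> int:
    """Number of sites with opposite homozygotes (0 iff consistent)."""
    return int(_conflict_mask(g1, g2).sum())


def preprocess(m: GenotypeMatrix) -> tuple[GenotypeMatrix, dict]:
    """Enforce the model's standing assumptions on the input matrix.

    Drops individuals with no HET call (their single haplotype is directly
    observable, and the line-graph model requires two distinct haplotypes per
    node) and collapses identical call vectors to one representative (two
    individuals with the same haplotype pair cannot be told apart by the CC
    graph).  The report preserves what was removed and the multiplicity of
    each collapsed group.
    """
    removed_homozygous: list[str] = []
    keep_rows: list[int] = []
    for i, ind in enumerate(m.individual_ids):
        if np.any(m.calls[i] == HET):
            keep_rows.append(i)
        else:
            removed_homozygous.append(ind)

    representatives: dict[bytes, str] = {}
    multiplicity: dict[str, list[str]] = {}
    final_rows: list[int] = []
    for i in keep_rows:
        key = m.calls[i].tobytes()
        ind = m.individual_ids[i]
        if key in representatives:
            multiplicity[representatives[key]].append(ind)
        else:
            representatives[key] = ind
            multiplicity[ind] = [ind]
            final_rows.append(i)

    out = GenotypeMatrix(
        [m.individual_ids[i] for i in final_rows],
        list(m.site_ids),
        m.calls[final_rows] if final_rows else np.zeros((0, m.n_sites), dtype=np.int8),
    )
    report = {
        "removed_homozygous": removed_homozygous,
        "duplicate_groups": {k: v for k, v in multiplicity.items() if len(v) > 1},
        "n_input": m.n_individuals,
        "n_retained": out.n_individuals,
    }
    if out.n_individuals == 0:
        report["warning"] = "empty matrix after preprocessing"
    return out, report


def build_cc_graph(m: GenotypeMatrix) -> nx.Graph:
    """All-pairs Clark-consistency graph (isolated nodes kept)."""
    g = nx.Graph()
    g.add_nodes_from(m.individual_ids)
    calls = m.calls
    hom0 = calls == HOM0
    hom1 = calls == HOM1
    for i in range(m.n_individuals):
        # vectorised conflict test of row i against all later rows
        conf = (hom0[i] & hom1[i + 1 :]) | (hom1[i] & hom0[i + 1 :])
        for off in np.flatnonzero(~conf.any(axis=1)):
            g.add_edge(m.individual_ids[i], m.individual_ids[i + 1 + int(off)])
    return g


# ---------------------------------------------------------------------------
# I/O


def read_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a genotype TSV: header row of site ids; rows of id + codes 0/1/2/."""
    lines = Path(path).read_text().splitlines()
    rows = [ln.rstrip("\n").split("\t") for ln in lines if ln.strip()]
    if not rows:
        raise GenotypeError(f"{path}: empty file")
    site_ids = rows[0][1:]
    ids, calls = [], []
    for r in rows[1:]:
        if len(r) != len(site_ids) + 1:
            raise GenotypeError(f"{path}: row {r[0]!r} has {len(r) - 1} calls, expected {len(site_ids)}")
        ids.append(r[0])
        try:
            calls.append([_TSV_CODE[c] for c in r[1:]])
        except KeyError as exc:
            raise GenotypeError(f"{path}: bad call code {exc.args[0]!r} in row {r[0]!r}") from None
    return GenotypeMatrix(ids, site_ids, np.array(calls, dtype=np.int8))


def write_tsv(m: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(m.site_ids) + "\n")
        for i, ind in enumerate(m.individual_ids):
            fh.write(ind + "\t" + "\t".join(_CODE_TSV[int(c)] for c in m.calls[i]) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF (bi-allelic SNPs only).

    0/0 -> HOM0, 1/1 -> HOM1, 0/1 or 1/0 -> HET, ./. -> MISSING.
    Multi-allelic records are rejected.
    """
    import pysam

    _GT = {
        (0, 0): HOM0,
        (1, 1): HOM1,
        (0, 1): HET,
        (1, 0): HET,
        (None, None): MISSING,
        (None,): MISSING,
    }
    with pysam.VariantFile(str(path)) as vf:
        ids = list(vf.header.samples)
        site_ids: list[str] = []
        cols: list[list[int]] = []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise GenotypeError(
                    f"{path}: record {rec.chrom}:{rec.pos} is not bi-allelic"
                )
            site_ids.append(f"{rec.chrom}:{rec.pos}")
            col = []
            for s in ids:
                gt = rec.samples[s]["GT"]
                try:
                    col.append(_GT[tuple(gt)])
                except KeyError:
                    raise GenotypeError(
                        f"{path}: unsupported GT {gt} at {rec.chrom}:{rec.pos} sample {s}"
                    ) from None
            cols.append(col)
    calls = np.array(cols, dtype=np.int8).T if cols else np.zeros((len(ids), 0), np.int8)
    return GenotypeMatrix(ids, site_ids, calls)


def write_graph(g: nx.Graph, edge_path: str | Path, node_path: str | Path | None = None) -> None:
    """Write a graph as a 2-column edge-list TSV plus a node list (isolated nodes)."""
    with open(edge_path, "w") as fh:
        for u, v in sorted(tuple(sorted(map(str, e))) for e in g.edges()):
            fh.write(f"{u}\t{v}\n")
    if node_path is not None:
        with open(node_path, "w") as fh:
            for n in sorted(map(str, g.nodes())):
                fh.write(f"{n}\n")


def read_graph(edge_path: str | Path, node_path: str | Path | None = None) -> nx.Graph:
    g = nx.Graph()
    for ln in Path(edge_path).read_text().splitlines():
        if ln.strip():
            u, v = ln.split("\t")[:2]
            g.add_edge(u, v)
    if node_path is not None and Path(node_path).exists():
        for ln in Path(node_path).read_text().splitlines():
            if ln.strip():
                g.add_node(ln.strip())
    return g


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=str) + "\n")
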