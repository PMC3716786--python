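"""Coalescent simulators with ground truth for validating the estimator.

Two population scenarios:

* **bottleneck** — a small ancestral pool of ``k`` distinct haplotypes
  (neutral coalescent, no recombination) rapidly expanded; present-day
  genotypes are pairs drawn uniformly *with replacement* from the pool.
  All sharing is identity by descent, and with thousands of sites identity
  by state between distinct pool haplotypes is essentially impossible, so
  the CC graph is (with high probability) exactly the line graph of the
  true pairing graph.

* **recombinant** — a population of effective size ``N0`` evolving under
  mutation and recombination over a 1 Mb region; each simulated diploid is
  one genotype.  Here "sharing" means identity by state of the full
  region, which becomes rare as ``N0`` grows, while spurious CC edges
  (consistency without sharing) become common — the hard regime in which
  the estimator is a lower bound.

Both return the genotype matrix together with a :class:`GroundTruth`
(haplotype pool, pairing, distinct-haplotype count, true sharing edges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import msprime
import numpy as np

from . import genotypes as gt

# Per-bp per-generation defaults for the recombinant scenario, calibrated
# against the validation tables this package reproduces: their SNP counts
# match Watterson's E[S] = 4*N0*mu*L*a_{2n-1} for mu = 1e-8, and their
# distinct-haplotype counts match an Ewens-type calculation for r = 1e-7
# (the 10:1 recombination:mutation ratio is preserved).  Equivalently, the
# same process arises from rates 10x lower with effective sizes 10x larger.
DEFAULT_MUTATION_RATE = 1e-8
DEFAULT_RECOMBINATION_RATE = 1e-7
DEFAULT_REGION_BP = 1_000_000


@dataclass
class SimulationConfig:
    scenario: str = "bottleneck"
    ancestral_haplotypes: int = 100  # bottleneck pool size k
    n_genotypes: int = 50
    n_sites: int = 3000  # bottleneck target SNP count (~5 cM locus)
    N0: int = 1000
    region_bp: int = DEFAULT_REGION_BP
    mutation_rate: float = DEFAULT_MUTATION_RATE
    recombination_rate: float = DEFAULT_RECOMBINATION_RATE
    seed: int = 1


@dataclass
class GroundTruth:
    haplotype_pool: list[str]
    pairing: dict[str, tuple[int, int]]
    true_count: int
    true_sharing_edges: set = field(default_factory=set)


def _truth_from_pairing(ids, pairing) -> GroundTruth:
    sampled = sorted({h for p in pairing.values() for h in p})
    edges = set()
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            if set(pairing[ids[a]]) & set(pairing[ids[b]]):
                edges.add((ids[a], ids[b]))
    return GroundTruth([], dict(pairing), len(sampled), edges)


def _genotype_codes(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
    # allele sums coincide with the call codes: 0=HOM0, 1=HET, 2=HOM1
    return (h1.astype(np.int8) + h2.astype(np.int8)).astype(np.int8)


def _harmonic(k: int) -> float:
    return float(np.sum(1.0 / np.arange(1, k)))


def simulate_bottleneck(k: int = 100, n_genotypes: int = 50, n_sites: int = 3000,
                        seed: int = 1, max_retries: int = 5):
    """Bottleneck scenario: pool of ``k`` distinct haplotypes sampled with
    replacement into genotype pairs; pairs of identical haplotypes are
    redrawn (every individual must be heterozygous somewhere).

    Returns ``(GenotypeMatrix, GroundTruth)``.
    """
    if k < 2:
        raise ValueError("need at least 2 ancestral haplotypes")
    rng = np.random.default_rng(seed)
    # a ~5 cM locus (5 Mb at 1e-8/bp/gen): the ancestral pool evolves with
    # recombination, which decorrelates sites so that genotypes built from
    # four distinct haplotypes are essentially never consistent by chance;
    # sharing between sampled genotypes is identity by descent only
    ne, region, recomb = 10_000.0, 5_000_000.0, 1e-8
    # mutation rate tuned so E[segregating sites] ~ n_sites (Watterson;
    # haploid samples coalesce on the N timescale, hence theta = 2*N*mu)
    mu = n_sites / (2 * ne * region * _harmonic(k))
    pool = None
    extra = max(5, k // 2)
    for _ in range(max_retries):
        # quick coalescences can leave identical haplotypes; oversample and
        # keep the first k distinct ones so the pool is k distinct haplotypes
        anc_seed, mut_seed = rng.integers(1, 2**31 - 1, size=2)
        ts = msprime.sim_ancestry(
            samples=k + extra, ploidy=1, population_size=ne,
            sequence_length=region, recombination_rate=recomb,
            random_seed=int(anc_seed),
        )
        ts = msprime.sim_mutations(
            ts, rate=mu, random_seed=int(mut_seed),
            model=msprime.BinaryMutationModel(), discrete_genome=False,
        )
        haps = ts.genotype_matrix().T  # (k+extra) x sites, 0/1
        distinct_rows, seen = [], set()
        for row in haps:
            key = row.tobytes()
            if key not in seen:
                seen.add(key)
                distinct_rows.append(row)
        if haps.shape[1] > 0 and len(distinct_rows) >= k:
            pool = np.stack(distinct_rows[:k])
            break
        extra *= 2
    if pool is None:
        raise RuntimeError("could not generate a pool of distinct haplotypes")

    ids = [f"g{i}" for i in range(n_genotypes)]
    pairing = {}
    calls = np.empty((n_genotypes, pool.shape[1]), dtype=np.int8)
    for i, ind in enumerate(ids):
        a, b = rng.integers(0, k, size=2)
        while a == b:
            a, b = rng.integers(0, k, size=2)
        pairing[ind] = (int(a), int(b))
        calls[i] = _genotype_codes(pool[a], pool[b])
    m = gt.GenotypeMatrix(ids, [f"s{j}" for j in range(pool.shape[1])], calls)
    truth = _truth_from_pairing(ids, pairing)
    truth.haplotype_pool = ["".join(map(str, row)) for row in pool]
    return m, truth


def simulate_recombinant(N0: int = 1000, n_genotypes: int = 100,
                         region_bp: int = DEFAULT_REGION_BP,
                         mutation_rate: float = DEFAULT_MUTATION_RATE,
                         recombination_rate: float = DEFAULT_RECOMBINATION_RATE,
                         seed: int = 1, max_retries: int = 5):
    """Recombinant scenario: coalescent with recombination; each simulated
    diploid is one genotype; sharing is identity by state of the region.

    Returns ``(GenotypeMatrix, GroundTruth)``.
    """
    rng = np.random.default_rng(seed)
    haps = None
    for _ in range(max_retries):
        anc_seed, mut_seed = rng.integers(1, 2**31 - 1, size=2)
        ts = msprime.sim_ancestry(
            samples=n_genotypes, ploidy=2, population_size=N0,
            sequence_length=region_bp, recombination_rate=recombination_rate,
            random_seed=int(anc_seed),
        )
        ts = msprime.sim_mutations(
            ts, rate=mutation_rate, random_seed=int(mut_seed),
            model=msprime.BinaryMutationModel(), discrete_genome=False,
        )
        if ts.num_sites > 0:
            haps = ts.genotype_matrix().T  # 2n x sites
            break
        warnings.warn("no segregating sites; retrying with a new seed")
    if haps is None:
        raise RuntimeError("no segregating sites after retries")

    # identity-by-state pool: distinct haplotype sequences
    pool_index: dict[bytes, int] = {}
    pool_rows: list[np.ndarray] = []
    hap_of = []
    for row in haps:
        key = row.tobytes()
        if key not in pool_index:
            pool_index[key] = len(pool_rows)
            pool_rows.append(row)
        hap_of.append(pool_index[key])

    ids = [f"g{i}" for i in range(n_genotypes)]
    pairing = {ind: (hap_of[2 * i], hap_of[2 * i + 1]) for i, ind in enumerate(ids)}
    calls = np.stack([
        _genotype_codes(haps[2 * i], haps[2 * i + 1]) for i in range(n_genotypes)
    ])
    m = gt.GenotypeMatrix(ids, [f"s{j}" for j in range(haps.shape[1])], calls)
    # an individual pairing the same sequence twice is fully homozygous and
    # is dropped by preprocessing, mirroring the heterozygosity assumption
    truth = _truth_from_pairing(ids, pairing)
    truth.true_count = len(pool_rows)
    truth.haplotype_pool = ["".join(map(str, row)) for row in pool_rows]
    return m, truth


def mask_partial(m: gt.GenotypeMatrix, targets, observed_fraction: float = 0.3,
                 seed: int = 0) -> gt.GenotypeMatrix:
    """Set a random (1 - observed_fraction) of each target's sites MISSING."""
    if not 0 < observed_fraction <= 1:
        raise ValueError("observed_fraction must be in (0, 1]")
    targets = set(targets)
    if not targets:
        return m
    rng = np.random.default_rng(seed)
    calls = m.calls.copy()
    n_mask = int(round((1 - observed_fraction) * m.n_sites))
    for i, ind in enumerate(m.individual_ids):
        if ind in targets:
            sites = rng.choice(m.n_sites, size=n_mask, replace=False)
            calls[i, sites] = gt.MISSING
    return gt.GenotypeMatrix(list(m.individual_ids), list(m.site_ids), calls)


def evaluate(report: dict, truth: GroundTruth, masked=()) -> dict:
    """Compare an estimate report against simulation ground truth."""
    known = set(truth.pairing)
    for key in ("removed_nodes",):
        for v in report.get(key, []):
            if v not in known:
                raise ValueError(f"unknown individual {v!r} in report")
    removed_edges = {tuple(sorted(e)) for e in report.get("removed_edges", [])}
    true_edges = {tuple(sorted(e)) for e in truth.true_sharing_edges}
    masked = set(masked)
    removed_nodes = set(report.get("removed_nodes", []))
    est = report["estimated_haplotypes"]
    return {
        "estimated": est,
        "true_count": truth.true_count,
        "ratio": est / truth.true_count if truth.true_count else float("nan"),
        "edges_removed": report.get("edges_removed", 0),
        "false_edge_removals": len(removed_edges & true_edges),
        "nodes_removed_masked": len(removed_nodes & masked),
        "nodes_removed_unmasked": len(removed_nodes - masked),
    }
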