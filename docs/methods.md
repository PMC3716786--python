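# Methods

## Model

An individual's genotype over a set of bi-allelic SNPs is the unordered
site-wise combination of its two haplotypes. Genotypes `g1`, `g2` are
*Clark-consistent* when no site makes them opposite homozygotes; this is
necessary (not sufficient) for them to share a haplotype. The CC graph
collects these potential sharings.

The central equivalence: a graph H admits an *allele assignment* — two
colors per node, adjacent nodes sharing exactly one, non-adjacent nodes
sharing none — iff H is a line graph. The root graph's nodes are the
colors (haplotypes) and its edges the genotypes, so the number of distinct
colors in any valid assignment of the (possibly edited) CC graph estimates
the haplotype population size. We implement the non-adjacency clause as
"share **no** color": a shared color is a shared haplotype, which would
force an edge.

Assumptions inherited from the model:

* every individual is heterozygous somewhere (fully homozygous rows are
  removed in preprocessing — their single haplotype is directly readable
  and carries no sharing ambiguity);
* no two individuals carry the same haplotype *pair* (duplicate call
  vectors are collapsed to one representative; the report keeps the
  multiplicities; the collapsed copies add no new haplotypes);
* sites are bi-allelic SNPs; a MISSING call is compatible with anything
  (a wildcard), which is what makes partially observed genotypes gain
  spurious edges.

## Recognition and root reconstruction

Two independent routes are implemented and cross-validated:

* **Forbidden-subgraph scan** against the packaged catalog of the nine
  minimal non-line graphs (claw K₁,₃ first). The catalog was generated by
  exhaustive search over all isomorphism classes on ≤ 6 nodes, requiring
  each member to fail Krausz reconstruction while every single-node-deleted
  induced subgraph passes; an independent recognizer (networkx's
  `inverse_line_graph`) agrees on every class. The edge counts run 3 to 11.
* **Krausz partition**: backtracking partition of each component's edges
  into cliques with every node in at most two cliques; cliques become root
  nodes. Linear-time recognition algorithms exist but are unnecessary at
  these instance sizes; the backtracking carries a step budget
  (`max_steps=500 000`) and reports "undecided" on dense adversarial
  components, in which case callers fall back to the integer program,
  which answers the same question within its own time limit.

Degenerate cases: an isolated CC node maps to a root edge between two
fresh haplotypes (2 colors). A K₃ *component* is Whitney's ambiguous case
(roots K₃ and K₁,₃ both have line graph K₃); we take the K₃ root — 3
haplotypes, not 4 — keeping the estimate a lower bound, in the spirit of
the parsimony objective. In bottleneck-type data a sharing triangle more
often arises from one haplotype drawn three times (the star root), so this
choice can undercount by one per triangle component; the parameter-recovery
tests bound the aggregate effect.

## Integer programs

All five programs run on one scaffold of binary variables (see the module
docstring of `linehap.ilp` for the constraint families): edge deletion,
hitting-set node deletion, combined deletion with node cost α, weighted
editing with insertions, and the parsimony (minimum-color) program.

Numerical and design choices:

* **Backend**: SciPy's `milp` (HiGHS branch-and-cut), single thread,
  relative gap 0, configurable time limit (default 600 s). HiGHS is
  deterministic for a fixed model, so a seed parameter is accepted for
  interface uniformity but has no effect. On timeout the incumbent is
  returned with `status="timeout"` and `optimal=False`.
* **Symmetry breaking**: nodes ordered by descending degree then label
  (the ordering is otherwise free; high-degree nodes first tightens the
  owner constraints). Node i owns colors 2i−1, 2i; a color's first user is
  its owner; owners use their odd color first. Under this first-use
  convention x_{v,j} = 0 for j > 2v, which together with the published
  pruning rules (no color sharing without an edge to the owner) removes
  the bulk of the x and s variables. Paired solves verify that symmetry
  breaking and pruning preserve the optimum.
* **Decomposition**: edge-deletion and combined objectives are additive
  over connected components, so components are solved independently, and
  components that already pass recognition are colored directly from
  their Krausz root without invoking the solver.
* **Editing mode**: insertion candidates default to all non-edges for bare
  graphs; when genotypes are available they are restricted to pairs with
  at most `edit_cap=2` opposite-homozygote sites, with insertion weight
  equal to that count (an insertion asserts those sites are miscalls) and
  deletion weight 1.
* **Ties** among optimal solutions are broken arbitrarily by the solver;
  reported deleted-edge sets are *one* optimal solution, not a unique one.
* The reported estimate is the color count of the assignment found at the
  deletion optimum. The parsimony program (which may drop edges freely) is
  exposed separately and is a lower bound on any such count.

## Phasing by constraint generation

The parsimony program proposes a sharing pattern I, each sharing edge
labeled with the color (haplotype) its endpoints share. Validation
instantiates one shared partial haplotype per color and propagates
genotype constraints to a fixed point: HOM sites fix both haplotypes, HET
sites force complements once one side is known. A contradiction (a forced
allele against a homozygous call, or an individual's two haplotypes
collapsing into one) yields the cut Σ_{e∈I∩S} Σ_j s_{e,j} ≤ |I∩S|−1 over
the affected sharing component S, and the program is re-solved. Cuts only
shrink the feasible region, so the color count is non-decreasing across
rounds and the loop terminates (each cut outlaws the current pattern); a
`max_rounds` guard (default 50; small dense instances have been observed
to need ~25 rounds) bounds the work regardless.

An incremental grow-one-node interface (`seed_set` / `extend`) is also
provided for patterns without color labels; it identifies the shared
haplotype by the triangle rule (a neighbor that also shares with the
anchor's partner takes the same haplotype, otherwise the other one) and is
deliberately conservative: a node that would need three distinct shared
haplotypes triggers a cut rather than an attempted unification. Cuts from
this path can therefore discard phaseable patterns; completeness of the
returned phasing is never affected, only the number of rounds and the
final count. Sites that no homozygous call reaches stay `?` — any
resolution of them is valid, so exact haplotype recovery is only asserted
on instances where every site is anchored.

## Simulators

**Bottleneck**: an ancestral pool of k distinct haplotypes is simulated
with msprime over a ~5 cM region (5 Mb at crossover rate 1e-8 /bp/gen,
haploid samples, N = 10 000) with the per-bp mutation rate set by
Watterson's formula so the expected SNP count matches `n_sites` (default
3000). Recombination *within the pool's ancestry* decorrelates sites, so
genotypes built from four distinct haplotypes are essentially never
consistent by chance — sampled sharing is identity by descent only, which
is exactly the regime the estimator assumes. Oversampling covers the rare
identical pair so the pool is truly k distinct sequences. Present-day
genotypes draw two pool haplotypes uniformly with replacement (identical
pairs redrawn, enforcing heterozygosity at generation time). Coverage is
defined as 2 × genotypes / k.

**Recombinant**: a diploid coalescent of effective size N₀ over a 1 Mb
region. The defaults are mutation 1e-8 and recombination 1e-7 per bp per
generation, calibrated jointly so that (i) expected segregating sites
match Watterson's formula against the validation tables this package
reproduces and (ii) the expected number of *distinct* sampled sequences
matches an Ewens-type calculation with θ' = 4N₀(μ+r)L; the same process
arises from rates ten times lower with effective sizes ten times larger.
Here "true haplotype count" means distinct sequences (identity by state),
the quantity the estimator bounds from below.

**Masking** sets a uniform random (1 − observed_fraction) of a target's
sites to MISSING (default 30% observed), which only ever *adds* CC edges.

What the simulators do not emulate: genotyping error (no miscalls — the
editing mode is validated on constructed weights instead), linkage to a
genetic map, gene conversion, population structure, and ascertainment of
SNP panels. Passing tests therefore certify the graph-theoretic machinery
and the estimator's behavior under clean identity-by-descent/-state
sharing, not robustness to assay noise.

## Problem sizes and limits

Validation runs use 50-genotype instances for the recombinant and masking
experiments and k=100 pools for bottleneck parameter recovery, with
per-solve time limits of 90–180 s; these sizes already reproduce the
qualitative regimes (near-line CC graphs at high diversity, dense spurious
graphs at N₀=500) while keeping a full validation pass to minutes.
Estimates on graphs whose solve hits the time limit are reported from the
incumbent and flagged `timeout`.

Known limitations: the estimate is a lower bound whenever spurious
consistency is common (low-diversity recombining populations); K₃
components systematically undercount by one when the true root is a star;
duplicate haplotype *pairs* are invisible to the CC graph; and the phasing
loop guarantees soundness but not global parsimony optimality of its final
phasing.
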