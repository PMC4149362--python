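# Methods

This note records the statistical procedures, parameter choices and
numerical conventions behind `qqppi`, and what the synthetic-data tests do
and do not demonstrate.

## Data model and assumptions

All statistics operate on a log2-scale expression matrix (genes × samples)
with a two-group phenotype (control/disease).  The pipeline assumes the
matrix is already normalized; no raw-intensity or probe-level noise model
is simulated.  Duplicate gene symbols (probe multiplicity) are collapsed at
read time — elementwise mean by default, `max-mean-row` and `first`
available — because symmetric, order-independent averaging is the least
surprising policy when the upstream probe→symbol mapping is opaque.  Gene
symbols are case-sensitive and whitespace-trimmed; alias resolution is out
of scope.

## Two-sample t

The default variant is Welch's t with Welch–Satterthwaite degrees of
freedom; the classical pooled-variance form is available
(`variant="pooled"`).  Both groups need n ≥ 2.  Genes with zero variance in
both groups and equal means have an undefined statistic; they are returned
as flagged records and excluded from calling rather than silently reported
as t = 0, since a silent zero would deflate the selected set invisibly.
Selection is strict raw p < α with no multiplicity adjustment — the
workflow treats the enrichment filter and network topology as the
subsequent specificity stages.

## SAM

The relative difference is dᵢ = (ȳᵢ − x̄ᵢ)/(sᵢ + s₀) with pooled scatter
sᵢ = √{[(1/n + 1/m)/(n + m − 2)]·[Σ(x−x̄)² + Σ(y−ȳ)²]}.  The
exchangeability constant s₀ is chosen from the 0, 5, …, 100 percentiles of
the sᵢ distribution to minimize the coefficient of variation of the
window-wise median absolute deviation of d across 100 s-quantile windows
(`s0_policy="median"` shortcut available).  The null ensemble permutes
group labels: all distinct splits are enumerated when their count fits the
permutation budget (default 200), otherwise distinct splits are sampled
with the run seed; the identity split is excluded from the null.  The
expected order statistics d̄₍ᵢ₎ are permutation means of the sorted d.

Calling at threshold Δ uses the original cut-point rule: scanning outward
from the sign change of the sorted d, the first position whose gap
|d₍ᵢ₎ − d̄₍ᵢ₎| reaches Δ fixes the upper (and, on the negative side, lower)
cut value; all genes beyond the cuts are called.  The FDR estimate at Δ is
the median over permutations of the count of permuted d values beyond the
cuts, divided by the observed called count, with no π₀ correction.  Zero
called genes report FDR 0 with a log note (avoiding 0/0).

Candidate Δ values are the achieved gap values themselves, rank-sampled
down to a 200-point budget.  Value-interpolated quantiles are deliberately
not used: when planted signal separates cleanly from the null, the gap
distribution has an empty interval, interpolated candidates fall inside it,
and the selected threshold overshoots into the signal cluster.  Threshold
selection for a target uses the per-Δ (raw) estimates; the reported
FDR-versus-Δ curve is additionally monotonized (running minimum from large
Δ), so the reported estimate is non-increasing in the threshold.

The optional fold-change filter requires the group-mean difference to
exceed log2 of the configured ratio; it is off by default.

## Over-representation filter

Per term, p = P(X ≥ k) for a hypergeometric population N = background
(all genes in the expression dataset after collapse), K = background genes
in the term, n = query size, k = query genes in the term; term gene sets
are clipped to the background first.  Selection takes the union of query ∩
term members over terms with raw p < α (default 0.05) in one namespace
(default biological process); Benjamini–Hochberg adjustment is available
but off by default, mirroring the unadjusted-threshold convention of the
emulated workflow.  α ≥ 1 disables the filter entirely — a term covering
the whole background has p exactly 1, and "no filter" must pass it.

## Networks and topology

A QQPPI network is the interactome subgraph induced on the query set; query
genes without any intra-query interaction are dropped by default (only
interacting queries become nodes), retainable via `keep_isolated`.  Merging
is edge-set union with concatenated per-edge source tags; intersection
semantics exist behind a flag but union is the default because the
workflow's purpose in merging several database exports is coverage.

Betweenness is Brandes' accumulation on unweighted undirected graphs:
unordered pairs counted once, endpoints excluded, no normalization (this is
networkx's unnormalized convention, cross-checked in the tests against an
independent BFS pair-dependency oracle).  Disconnected inputs are handled
per component with the classification rules applied globally.

The hub cutoff is mean + 2·SD of the degree distribution, sample SD (n−1)
by default with a population-SD option; classification compares integer
degrees against the unrounded cutoff (for integer degrees, ≥ 11.8 and ≥ 12
select the same nodes).  A regular graph (SD = 0) makes every node satisfy
the rule; this degenerate case is logged as a warning rather than being an
error.  The bottleneck rule is positional: nodes ranked by betweenness
descending, the first ⌈|V|/2⌉ ranks qualify with boundary ties included,
intersected with degree < cutoff and ≥ 2 hub neighbors.  Tie inclusion at
the 50% boundary is a documented choice; excluding ties would make the
selection depend on sort stability.

## Cliques, complexes, co-expression, markers

Triangles come from edge iteration with sorted-neighbor intersection;
4-cliques extend each triangle by a common neighbor above its maximum node,
so each clique appears once in canonical sorted form.  By default all
complete subgraphs are counted (triangles inside 4-cliques count among the
3-cliques); `maximal_only` suppresses k-cliques inside a (k+1)-clique.  The
enumerator warns if any 5-clique exists, since the downstream module
analysis assumes none.  The core functional module is the union of all 3-
and 4-cliques with per-node occurrence counts.

Complex matching reports every catalog entry whose membership intersects
the query (by default all clique-forming proteins) in at least `min_query`
genes, sorted by match size then id; no enrichment p-value is attached.

Per-edge co-expression is the Pearson correlation across samples within
each group separately (n ≥ 3 per group required); change = C − D and
percent-of-maximum = 100·(C−D)/2 since r ∈ [−1, 1].  Undefined correlations
(constant vectors) exclude the record with a logged warning — zeros would
corrupt downstream change statistics.  Reported floats use 6 decimals;
recomputing published change values from published (already rounded)
correlations can disagree in the sixth decimal, which the tests allow for
except on rounding-consistent rows.

Novel markers per network are (hubs ∪ bottlenecks) minus the user-supplied
known-disease-gene list; the known list is an opaque curated input, never
computed.  The multiplicity total counts candidates per network; the unique
set is the union with per-network provenance.  Neurotransmitter
associations are likewise consumed from a curated table.

## Synthetic data: what it emulates and what it does not

The generator defaults encode the emulated study conditions: 2000 genes,
15 control / 24 disease samples, 10% DE genes with mean log2 shift 2 and
within-group noise SD 0.5, 20% of DE genes up-regulated; a 500-protein
interactome with ~2 edges per node.  Expression is generated directly on
the log2 scale with Gaussian per-cell noise and shared baselines.  Half of
the DE genes are drawn from the interactome's symbol range by default
(`de_protein_fraction`), reflecting that disease-relevant DE genes
concentrate in the well-studied interactome; when an expression ground
truth is passed to the interactome generator, planted cliques and hubs are
placed preferentially on DE genes so the planted structure can survive the
DE/enrichment filters in end-to-end runs.

Not emulated: batch effects, probe-level noise, heavy-tailed or
heteroscedastic expression noise, correlated gene blocks (except the
explicit correlated-pair generator), interactome false-positive structure.
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under clean Gaussian conditions, not performance on
real microarray data.

The variance structure of the original study's data is unknown; the
generator's noise parameters are free choices of this package, not
estimates of that dataset.

## Problem sizes and numerical conventions

Oracle-equivalence tests run on random graphs of ≤ 30 nodes where
exhaustive enumeration is feasible; calibration/recovery suites use 10–20
seeds at the default 2000-gene scale, sizes chosen to give stable rates
while keeping the default test run fast.  Floating-point comparisons in
tests use absolute tolerances of 1e-12 for closed-form identities and 1e-8
for accumulated graph quantities.  All randomness flows through
`numpy.random.default_rng` seeded from the spec or CLI seed; derived seeds
stay below 2³¹.

## Known limitations

- The SAM Δ grid is rank-sampled (200 points); called sets can differ by a
  few genes from an exhaustive-grid run near the target FDR.
- The hub/bottleneck rules are scale-dependent heuristics; on very small or
  regular networks they degenerate (warned, not prevented).
- GraphML is the only network export; no interactive visualization.
- GO-style annotation is consumed flat; no ancestor propagation.
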