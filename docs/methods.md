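# Methods

`txdyn` re-implements, as a tested pipeline, the analysis pattern used in
multi-timepoint whole-transcriptome studies of developing tissue: one pooled
RNA library per timepoint for each of four RNA classes (mRNA, lncRNA,
circRNA, miRNA), differential expression between adjacent timepoints,
trajectory-pattern encoding, interaction-network module and hub analysis,
and ceRNA network assembly. This note records the models, the defaults and
the design choices that were genuinely open.

## Synthetic data

Counts are negative binomial via a gamma–Poisson mixture with the
DESeq-style parameterization `var = mu + alpha * mu^2`. Gene baselines are
log-normal (`exp(N(4, 1))` by default, i.e. median ≈ 55 counts) unless given
explicitly. A gene's dynamics are planted as a U/D/M string over the k =
n_timepoints − 1 adjacent intervals: a U at interval i multiplies the mean by
`fold_step` from timepoint i+1 onward (a step, not a pulse — matching the
cumulative reading of U/D/M trajectories), a D divides it. One library per
timepoint is the default, mirroring the pooled design; `n_replicates` exists
for power studies. All randomness flows from the config seed; nothing reads
global RNG state.

What the generator does **not** emulate: within-week biological variance
between animals (pooling hides it in the real design — the dispersion
default 0.05 is a free parameter, not an estimate of any study), read-level
artifacts (GC bias, mapping ambiguity), gene–gene correlation, and
compositional effects of a few very highly expressed genes. Passing
recovery tests therefore show the pipeline's stages are correct and
internally consistent, not that the study's specific gene lists would be
reproduced from raw data.

Interaction graphs are planted-partition: module nodes wired with
`intra_p`, everything else with `inter_p`, uniform edge scores. miRNA-target
tables plant shared-miRNA (sponge, miRNA, mRNA) triples at a configurable
`sharing_rate`; the recorded truth tracks every realized shared triple so
recovery checks are exact set equality even in degenerate configurations.

## Normalization and profiling

CPM, TPM and FPKM follow their standard definitions (TPM = length-rate
renormalized to 10⁶; FPKM = count·10⁹ / (length·library size)); size
factors are median-of-ratios against a geometric-mean pseudo-reference.
The choice of median-of-ratios (over, say, TMM) keeps the normalization
consistent with the negative-binomial test downstream. Abundance profiling
uses seven half-open, left-closed decade bins [0, 0.01) … [1000, ∞); the
left-closed convention is a choice — printed category labels like "1–10" do
not state edge ownership. PCA and sample correlation act on log2(x+1)
values with per-gene centering; PCA components are sign-fixed so the
largest-magnitude gene loading is positive. Reported percentages round
half-up to two decimals, the convention of printed summary tables.

## Differential expression without replicates

With one library per condition, dispersion cannot be estimated per
condition. The blind estimator treats all timepoints as pseudo-replicates:
per-gene method-of-moments `alpha_hat = max(0, (s² − mu) / mu²)` on
size-factor-normalized counts, then a trend `alpha(mu) = a0/mu + a1` fitted
by non-negative least squares with three rounds of residual trimming at
3 MAD about the median residual (plain least squares is dragged upward by
genuinely dynamic genes, whose own signal inflates their blind estimate).

The working dispersion handed to the test is the **fitted trend only**
("fit-only"), the established convention for no-replicate designs. The
conservative alternative `max(alpha_hat_g, trend)` is available
(`sharing="maximum"`), but it vetoes exactly the strongly dynamic genes the
analysis is after: an 8-fold step gives that gene a blind `alpha_hat` near 1
and a p-value near 1. Fit-only is an approximation, not a clone of any
particular DESeq version, and is documented as such. The trade-off is
visible in the test suite: type-I error stays controlled (the |log2fc| > 1
gate is itself conservative), and planted-pattern recovery at 8-fold steps
exceeds 90%.

The per-interval test is a two-sided NB exact test conditioning on the
rounded normalized sum N of the two samples: both samples are modelled with
common mean N/2 and the working dispersion, and the p-value is the total
conditional probability of splits no more probable than the observed one
(ties included in the rejection mass; a 1 + 1e-12 relative tolerance keeps
symmetric ties inside). At dispersion 0 the components are Poisson and the
test reduces exactly to the conditional binomial (N, 1/2) test. Fold
changes use pseudocount 1 on normalized counts. Calls follow the standard
rule: U if log2fc > 1 and p < 0.05, D if log2fc < −1 and p < 0.05, else M.
Raw p-values are used (no multiple-testing correction), matching the DEG
convention this pipeline targets; `bh_adjust` is provided but off by
default.

## Trajectory patterns

A gene's pattern is the concatenation of its per-interval statuses — a
string over {U, D, M} of length k, one of 3^k possibilities (6,561 at
k = 8). Frequency tables rank patterns by descending count with
lexicographic tie-break (observed zero-count ties are otherwise
unordered); percentages round half-up to two decimals. Coverage is
100·n_unique/3^k with the all-M pattern included in n_unique — at k = 8,
455 unique patterns give 6.93%, which fixes the convention (excluding all-M
would print 6.92%).

## Interaction-graph modules (MCODE scheme)

Graphs come from STRING-like weighted edge lists; scores on the integer
0–999 dialect are auto-detected (any score > 1) and rescaled. The
confidence threshold (default 0.400) is inclusive, matching "minimum
required score" semantics; nodes left without edges are dropped.

Vertex weight = (core number k of the highest k-core of the node's closed
neighborhood) × (density of that core subgraph). Modules grow greedily from
the highest-weighted unvisited seed, admitting neighbors with weight ≥
seed_weight·(1 − node_score_cutoff); defaults are the plug-in's published
ones (cutoff 0.2, k-core 2, haircut on, fluff off). Haircut iteratively
removes within-module degree-1 nodes; fluff (if enabled) adds fringe
neighbors above a closed-neighborhood density threshold, kept node-disjoint
across modules. Module score is density × size. Preliminary hubs are the
top-5 module genes by within-module degree (ties: total-graph degree, then
lexicographic) — "order of the topology" is not a defined term, so the
scores are emitted for re-ranking.

A property worth knowing: when two planted dense blocks are bridged by
even a couple of edges between high-weight nodes, greedy expansion merges
them into one module. This is faithful MCODE behavior, and it is why module
recovery on planted-partition graphs is assessed as union-of-top-modules
against union-of-planted-truth.

## Hub centralities and consensus

The twelve measures (MCC, DMNC, MNC, Degree, EPC, BottleNeck, EcCentricity,
Closeness, Radiality, Betweenness, Stress, Clustering Coefficient) follow
the cytoHubba conventions; every formula is printed in
`txdyn/centrality.py`'s module docstring so deviations are auditable.
Choices for disconnected graphs: Closeness is harmonic (unreachable nodes
contribute 0), EcCentricity and Radiality are computed within the node's
component — this avoids infinities without dropping nodes. BottleNeck
routes one unit of flow per target back to the source along the
shortest-path DAG, splitting equally over tied predecessors (with unique
paths this is the classic shortest-path-tree descendant count; the equal
split keeps the measure constant on vertex-transitive graphs). The
threshold is n_s/4, and EPC uses 1000 seeded edge-percolation realizations
(edge kept with probability = its score) with the Monte-Carlo standard
error reported; both are configurable.

"Top five intersections of all 12 algorithms" is ambiguous — a strict
12-way intersection is often empty. The consensus rule used here scores
each node by how many per-measure top-k lists contain it (0–12), ranks by
that count, then by mean rank across measures, then lexicographically; the
full membership matrix and the strict intersection are both emitted.

## ceRNA networks

Pairs (molecule, miRNA) are kept only when both endpoints are differential
(status ≠ M) on the interval of interest; molecules absent from the DE
records are treated as non-differential. Triples (x, m, g) join a
sponge-class pair table with the miRNA–mRNA table on the shared miRNA;
quadruples (c, m, l, g) join circRNA sponges onto lncRNA triples on the
miRNA again, all combinations, deduplicated. A molecule–miRNA link is one
edge regardless of how many triples traverse it — the only convention under
which a single-hub star of 431 + 21 molecules has 452 edges. Prediction
scores are pass-through; an optional threshold exists but no default is
imposed.

## Over-representation

Hypergeometric upper tail P(X ≥ k) for overlap k between an n-gene query
and a K-gene set in an N-gene universe, user-supplied GMT collections,
significance raw p < alpha (default 0.05) with BH-adjusted values reported
alongside. Pattern-wise enrichment groups genes by identical trajectory
string; groups below `min_genes` (default 3, configurable — small groups
cannot support a stable test) are reported as skipped.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run entirely on synthetic data:
pattern recovery uses 16-gene cohorts at baseline mean 250, dispersion
0.01, fold step 8 over 200 seeded runs (60 in the script); module recovery
plants a K8 in a 200-node background over 20 seeds; centrality oracles are
exhaustive on graphs of ≤ 10 nodes; ORA oracles enumerate universes of
≤ 15 genes. These sizes give stable statistics in seconds while exercising
every code path end to end.

## Known limitations

- The NB exact test is a stand-in for the original DESeq analysis; version,
  dispersion mode and zero handling of that package are not replicated, and
  no claim is made that the study's DEG counts would be reproduced.
- Blind dispersion under fit-only slightly understates uncertainty for
  genes whose true dispersion exceeds the trend; with a single library per
  condition this is irreducible.
- MCODE module boundaries are sensitive to bridging edges (see above).
- EPC is Monte-Carlo; ranks of near-tied nodes can flip between seeds at
  low round counts.
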