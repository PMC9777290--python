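# Methods

This note records the statistical models, the crosstalk score, the
cascade simulator, and the design choices made where the problem left
room — in enough detail that every number the package produces can be
re-derived.

## Differential expression

Each gene is tested with a two-tailed, two-sample unpaired t-test
(pooled-variance by default, Welch by option; `scipy.stats.ttest_ind`
does the arithmetic). The t sign convention is mean(target) −
mean(control). Degenerate genes with zero variance in both groups are
flagged: equal means give (t = 0, p = 1), unequal means the smallest
positive double. Multiple testing is controlled with Benjamini–Hochberg
(via `statsmodels`), with Storey's pFDR-style q-value (π₀ estimated at
λ = 0.5, floored at 1/m) as an alternative. The DEG rule is q < α
(default α = 0.05). log2 fold change — mean difference on the log2
scale — is reported but does not gate calls by default (`fc_min = 0`):
expression matrices are assumed already normalized and log2-scaled, with
`log2(x+1)` available at ingest for raw-scale inputs. Duplicate gene rows
collapse by mean (order-independent); rows with missing values are
dropped at ingest and counted in the log.

## Enrichment

The one-sided hypergeometric tail P(X ≥ k) for a pathway with m genes in
an N-gene universe against an n-gene DEG list is computed with exact
integer arithmetic (`math.comb` and a single rational division), so it is
correct to full double precision at any size this pipeline meets; the
test suite cross-checks it against `scipy.stats.hypergeom.sf` and against
exhaustive draw enumeration for all universes N ≤ 12. The default
universe is the intersection of measured and pathway-annotated genes —
genes that could never appear in the DEG list should not inflate
significance; `all-annotated` gives the literal genome-wide reading.
Gene-set classes tagged "human diseases" or "drug development" are
filtered out before testing (their members duplicate the five retained
classes). BH-FDR runs across tested pathways; enrichment means
FDR < 0.05; p-ties rank lexicographically for determinism.

## Crosstalk degree

The score for pathways s, t over the DEG subnetwork (see README for the
formula) is a sum over *ordered* adjacent cross-pathway gene pairs; the
multiplicative factors — degree `conn` and pathway-`sharing` count — are
taken from the source gene of each ordered pair, and the denominator uses
source + target degree. Summing both orientations makes the matrix
symmetric by construction. Specific readings fixed here:

- degrees and `C_total` are computed on the DEG-induced subnetwork, not
  the full network; isolated DEG nodes stay in the subnetwork with
  degree 0 (they can contribute no terms);
- `sharing` counts membership among **enriched** pathways by default
  (an all-pathway variant is a flag) — the sharing map is computed once
  over the collection actually being scored;
- a gene in both pathways of a pair contributes in both orientations,
  but never pairs with itself; the diagonal is 0 by convention
  (within-pathway crosstalk is undefined, and the public pairwise API
  rejects identical sets);
- `C_total` multiplies each term; since it is constant for a dataset it
  factors out of the whole matrix, which is why the normalized matrix
  (divided by its maximum) is emitted alongside — raw CTdegree scales
  with network size and is not comparable across datasets;
- no significance is attached to the raw score; a label-permutation null
  (`crosstalk.permutation_null`, seeded) exists for calibration studies
  but is off by default.

Every term is recorded in a contribution ledger (source gene, target
gene, pair, value), so alternative readings can be recomputed from the
output and per-gene summaries (`top_contributors`: summed source terms,
ties by degree then symbol) are exact, not re-estimated.

## Network diagnostics

Degree distribution and a log10 CCDF vs log10 degree least-squares slope
are reported as a qualitative scale-free diagnostic only — deliberately
not a maximum-likelihood tail fit, and omitted below 10 positive-degree
nodes. The 3-node motif census counts induced connected subgraphs: open
triads (= Σ C(deg,2) − 3·triangles) and triangles; z-scores come from a
degree-preserving null of double-edge-swap rewirings (10·|E| attempted
swaps per sample, seeded, degree sequence asserted unchanged). With an
ensemble smaller than 2 the z-scores are omitted.

## Cascade simulator

Cascades are chains of proteins (receptor R, kinase K, target T), each
with un-/mono-/dual-phosphorylated states. Every reaction converts one
state of one protein into another state of the same protein — the
stoichiometry matrix has one +1 and one −1 per column inside a single
protein block, so each protein's total is conserved exactly in the
mathematics and to ≤ 1e-6 relative numerically (checked along every
trajectory). Activation steps are bimolecular mass action
(rate = k · [substrate] · [catalyst]), with the external signal strength
as the catalyst of receptor phosphorylation; deactivation is first-order.
Loops and crosstalk edges are just additional catalysed reactions, so
conservation can never be violated by topology extensions; reactions
crossing protein boundaries are rejected at build time. Each protein
starts with a pool of 10 a.u., fully unphosphorylated, which makes the
inactive state (verified by simulating at signal 0) globally stable.

Integration uses LSODA (`scipy.integrate.odeint`) with rtol 1e-6 /
atol 1e-9 on a fixed 500-point grid over t ∈ [0, 100] a.u. for fitness
evaluation. Threshold crossings are read off the grid; halving the
tolerances changes no fitness decision on the shipped fixtures (tested).
Population fitness stacks all candidate parameterisations into one
block-diagonal ODE system per signal — trajectories agree with per-model
integration to within the shared tolerance, and the per-model and
population paths are tested against each other.

**Fitness.** Six signals (1e-4 … 10). A cascade is responsive for a
signal when its dual-phosphorylated target exceeds TL = 1/10 of the
target-protein pool at any grid point (the pool equals the initial
concentration here, since everything starts unphosphorylated, so the
"fraction of total" and "fraction of initial" readings coincide). Per
responsive signal: factor 1.0 alone; 0.5 per responsive cascade in
two-cascade mode (cascade 1 → Ffactor1, cascade 2 → Ffactor2). F is the
mean over the six signals, hence F ∈ [0, 1], and F = 1 is attained by the
shipped responsive example (`fit_example_rates`).

**Evolution.** Population 200, random initial rates U[0.001, 0.1]; each
generation keeps the 50 fittest and refills with 4 copies each — one
elite copy with unchanged rates and cached fitness (best F is therefore
non-decreasing by construction), three mutated (each rate × U[0.5, 2]
with probability 0.5, clipped to [0.01, 100]). Selection sorts by fitness
with a stable index tie-break; mutated copies are assigned lower indices
than their elite parents and interleaved one per parent, so on the broad
fitness plateaus this step landscape produces, ties resolve toward
drifted copies across *all* surviving lineages — without this, the
population freezes on a plateau and selection cannot ratchet. Runs are
bit-reproducible from the seed.

**Shipped example topologies.** The "normal" model adds negative feedback
through a slowly induced two-state inhibitor protein (ppTP activates it;
its active form dephosphorylates the receptor and kinase levels) — the
induction delay produces an overshoot and the accumulated inhibitor
clamps the steady state low, after the fashion of ppERK-induced DUSP
phosphatases. Direct proportional feedback from ppTP cannot do this at
strong signals (its steady state tracks the drive), which is why the
mediator protein is part of the example. The "cancer" model deletes the
loop, leaving a monotone relay. Classification of an output trace:
*transient* if the final value falls below 50 % of the peak within the
horizon, *sustained* otherwise, *none* if the peak never exceeds 1e-9 of
the pool; comparisons use a longer horizon (t = 2000, 2000 points) so the
weakest signal completes its transient. Under these settings the normal
model is transient and the lesioned model sustained at all six signals.
Receptor activation constants are large (200) in the examples so the
weakest signal still drives dynamics inside the horizon. These example
placements are illustrative of the feedback-vs-lesion contrast, not a
claim about any particular biological wiring.

## Synthetic fixtures

The generator emulates a two-group log2 microarray study: per-gene
baselines U[4, 12], unit-SD Gaussian noise, 10 + 10 samples, 50 of 1000
genes shifted by 2 SD (alternating sign) in the target group. Gene sets:
three planted 20-gene pathways containing 15 planted DEGs each (A and B
overlap in 3), 20 decoys of 10–30 random non-DEG genes. Network: a
Barabási–Albert backbone (m = 2) over all genes — enough scale-free
structure to exercise the topology diagnostics — densified within and
between the DEG members of A and B (edge probabilities 0.6 / 0.5), while
pathway C's members keep only edges among themselves, guaranteeing
CT(·, C) = 0. All draws flow from a single seed through named substreams.

What passing recovery tests do **not** show about real data: no
probe-level structure, no normalization artefacts, no gene–gene noise
correlation, no heavy-tailed effect sizes, and a network far smaller and
cleaner than a real association database.

A note on recovery power: with effect 2 SD at n = 10 + 10 and BH control
over 1000 genes, the per-gene power at the BH-effective per-test
threshold (≈ 0.002 when ~40 genes are discovered) is about 0.81 by the
noncentral-t calculation — so typical per-seed recovery of the planted
genes sits near 0.8, not above 0.9; the recovery suite records exactly
this. False positives stay at a handful per run, and pathway-level and
crosstalk-level recovery are unaffected (the planted pathways contain
enough recovered DEGs regardless).

## Problem sizes in the test suite

The validation suite runs at desk scale: enumeration oracles to N ≤ 12,
100 random crosstalk fixtures of ≤ 50 genes, 20 generator seeds for the
end-to-end recovery study, and 20 seeds of a scaled evolutionary run
(population 40, 10 survivors × 4 copies, 20 generations) — the same
selection ratio as the full configuration at a size chosen to keep the
whole suite a matter of minutes.

## Known limitations

- CTdegree has no attached null distribution by default; raw values are
  network-size dependent (use the normalized matrix across datasets).
- The score treats the interaction network as binary and undirected;
  edge confidences beyond the cutoff are discarded.
- Moderated (empirical-Bayes) tests, paired designs and >2 groups are out
  of scope; so are rank-based (GSEA-style) enrichment statistics.
- The cascade simulator is deterministic mass action — no stochasticity,
  no spatial effects, no explicit phosphatase species except where a
  topology adds one.
- The evolutionary fitness is a step function; progress relies on
  neutral drift across plateaus, so small populations can stagnate for
  many generations.
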