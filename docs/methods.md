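# Methods

## The score and its rationale

For a miRNA *m* with validated target set *T(m)* and a PPI graph *G*, the
package computes `S(m) = Σ_{t ∈ T(m) ∩ V(G)} deg_G(t)`. The premise is the
well-established centrality–lethality pattern in interactomes: highly
connected proteins are disproportionately essential, so a miRNA whose
targets concentrate on hubs has more leverage over cellular state than its
fold change alone suggests. `S` deliberately stays a plain unweighted sum:
it is monotone in both the number of targets and their connectivity, additive
over disjoint target sets, and trivially auditable against the interaction
table. No weighting by expression, binding strength or target count is
applied — a miRNA with many mid-degree targets is *meant* to compete with
one hitting a single huge hub.

By default degrees are taken from the full user-supplied global PPI graph;
`degrees_from: seed-network` switches to the targets' subnetwork. The global
graph is the default because it is reproducible from the input file alone
and monotone-comparable across runs, whereas any subnetwork depends on the
seed-expansion choices below. Whether targets are first filtered to an
expressed-gene universe is likewise the caller's choice; the pipeline filters
when a universe file is configured, since targets not expressed in the
tissue cannot mediate the miRNA's effect there.

## Centralities

All three centralities operate on a simple undirected unweighted graph
(self-loops dropped at load time):

- **degree** — incident edge count.
- **closeness** — `1 / Σ_{u ∈ comp(v), u≠v} d(v,u)`, with 0 for isolated
  nodes. This is the unnormalised reciprocal-farness variant; distances to
  unreachable nodes are *excluded*, not infinite. A consequence worth
  knowing: closeness values of graphs with different component sizes are on
  different scales (a node in a large component accumulates more distance,
  hence smaller closeness), so cross-network closeness comparisons are about
  distributions, not absolute magnitudes.
- **stress** — the Shimbel count of shortest paths through a node, each
  unordered source/target pair counted once. Computed with one BFS per
  source and Brandes-style dependency accumulation
  (`δ_s(v) = Σ_{w : v ∈ pred(w)} σ_sv · (1 + δ_s(w)/σ_sw)`), O(n·m) overall;
  the per-pair definition (`σ_sv · σ_vt` when `d(s,v)+d(v,t)=d(s,t)`) is
  kept in the test oracles as an independent exhaustive check.

## Seed subnetworks

`build_seed_network` offers two constructions. `induced` (default) keeps
exactly the seeds present in the global graph and the edges among them —
fully reproducible. `bridged` additionally recruits every non-seed node on
a shortest path of length ≤ `max_bridge_len` (default 2) between two seeds,
then induces on the retained set. Bridging is this package's stand-in for
literature-expansion tools that grow a network around a protein list; it is
documented as such and off by default because the recruited set depends on
the bridge length in ways a user should opt into consciously.

## Comparing a target network with a random baseline

The random baseline samples the same number of proteins uniformly (without
replacement, seeded) from the background — proteins "chosen without regard
to miRNA status". Centrality distributions are compared with a classical
one-way ANOVA (kept for comparability with common practice) *and* a
label-permutation test on the difference of means with add-one smoothing,
`p = (1 + #{perm ≥ obs}) / (n_perm + 1)`. The permutation p is the one to
trust: degree and stress in scale-free networks are heavy-tailed enough
that the F test's normality assumption is badly violated. Both are reported
side by side.

## qPCR processing

The model is the standard 2^-ΔΔCt chain with amplification efficiency fixed
at 2 (one PCR cycle per twofold abundance change):

1. **Interplate calibration.** Each plate carries a spike-in calibrator.
   Plate offset = plate's mean calibrator Ct − grand mean of the per-plate
   calibrator means; all detected Cts on a plate are reduced by its offset
   and calibrator rows are then dropped. Offsets are identifiable only up
   to a common constant (the grand mean is the anchor), which is harmless:
   a constant cancels in ΔCt.
2. **Global-mean normalisation.** ΔCt = Ct − mean Ct of all detected,
   non-calibrator assays in the same (sample, replicate). This replaces
   fixed reference genes and is unbiased exactly when the planted/true
   changes cancel in the per-sample mean — the standard "most miRNAs are
   unchanged" assumption. It is *not* robust to grossly asymmetric global
   shifts; that limitation is inherited from the method, not an
   implementation artefact.
3. **Fold changes.** Per replicate, ΔΔCt = ΔCt(case) − ΔCt(reference) and
   fold = 2^−ΔΔCt. Dropouts: case-only dropout → fold floored at 0;
   reference-only dropout → fold capped at `fc_cap` (default 2¹², i.e. the
   most extreme change representable within a 12-cycle detection window;
   capped values are flagged and a warning logged); dropout in both →
   replicate undefined, and a miRNA undefined on every replicate is removed.
   The consensus fold is the geometric mean of the finite replicate folds;
   floored/capped replicates are excluded from the geometric mean when they
   agree in direction with the finite ones and invalidate the consensus
   (NaN, class "unclassified") when they conflict.
4. **Dysregulation filter.** A miRNA is dysregulated iff *every* replicate
   is defined and shows ≥ `min_fold` (default 2) change in the same
   direction, floored/capped replicates counting as down/up. Requiring
   concordance across all replicate arrays trades a little sensitivity near
   the threshold for a much lower false-call rate.
5. **Classes and reporting.** OncomiR iff consensus fold > 1, suppressor
   iff < 1, unclassified at exactly 1 or undefined. The quadrant plot's
   vertical line sits at log₁₀ fold = 0 (ratio 1). A consensus of 0
   (case-side dropout on all replicates) stays in the ranking with its
   log-fold drawn at −log₁₀(`fc_cap`), flagged — a complete expression loss
   is the strongest possible "suppressor lost" signal and must not be
   silently discarded. The report counts dysregulated/oncomiR/suppressor
   miRNAs and those beyond an `extreme_fold` (default 8) change, and bins
   log₁₀ folds at width 0.25.

## The synthetic generator

`SyntheticSpec` describes one dataset; generation is a pure function of the
spec, with all randomness flowing from one seed through named substreams
(graph / targets / plates), so regenerating one artifact never perturbs
another.

- **Graph:** Barabási–Albert preferential attachment (default 500 nodes,
  2 edges per new node) — connected and scale-free, matching the
  heavy-tailed degree distributions of real interactomes. It does not
  emulate interactome artefacts such as study bias, clique-forming
  complexes or literature redundancy.
- **Targets:** each of `n_mirnas` (default 40) synthetic miRNAs draws
  `targets_per_mirna` (default 10) nodes without replacement with weight
  `(degree + 1)^alpha`; `alpha = 1` plants the hub preference the method
  detects, `alpha = 0` is the uniform null, and the +1 keeps every node
  sampleable.
- **Plates:** two samples (reference P69-like, case M12-like) × duplicate
  RNA inputs, one plate each. Ct = per-miRNA baseline ~ U(18, 28) + plate
  offset − planted log₂ effect (case only) + N(0, `ct_noise_sd`), with
  `ct_noise_sd` defaulting to 0.2 cycles (typical array-card replicate
  noise) and Cts above `detection_limit` (default 37) emitted as
  undetected. Planted effects default to a direction-balanced design
  (equal up/down at 2 log₂ units, i.e. ~4-fold — the middle of the 2–8-fold
  band where most real changes fall); balance makes global-mean
  normalisation exactly unbiased, the generator's stand-in for "most miRNAs
  unchanged". The calibrator is emitted noise-free, so plate offsets are
  recoverable to machine precision; real spike-ins carry pipetting noise,
  so offset recovery on real data is good to ~noise/√(assays) rather than
  exact. Homoscedastic Gaussian Ct noise is the standard qPCR assumption;
  heavier-tailed noise is not modelled.

Passing tests on these data show the pipeline's arithmetic and its planted-
signal recovery are correct; they do not certify performance on real
arrays, where dropout is abundance-dependent, noise grows near the
detection limit, and interaction databases are incomplete and biased
toward well-studied genes.

## Enrichment

Over-representation uses the exact hypergeometric upper tail
`P(X ≥ overlap)` with population = background, successes = pathway ∩
background, draws = query ∩ background (query genes outside the background
are dropped and logged). The Bonferroni multiplier is the number of
pathways actually tested (non-empty background intersection), not the raw
GMT size: correcting for never-performed tests would only add conservatism
without protecting any additional error. Significance is `p_bonferroni <
alpha` (default 0.05). No FDR option is provided; the package mirrors the
conservative Bonferroni family on purpose, and the discrete test is already
conservative under the null (type-I rate below nominal, as the test suite
measures).

## Numerical and tie-break conventions

- Ranking ties on `S` break lexicographically on the normalised miRNA id,
  so ranks are bit-stable across runs and platforms.
- miRNA ids are normalised by lower-casing every "-"-separated token except
  "mir" → "miR" (`HSA-MIR-1` ≡ `hsa-miR-1`); gene symbols are upper-cased.
- Candidate selection is strictly greater than the cut (default 1000).
- The "mean" degree threshold is resolved over the ranked (dysregulated)
  set before quadrants are assigned; a fixed numeric threshold is accepted
  for replicating published figures.
- Permutation tests use add-one smoothing so p = 0 is impossible; the
  exhaustive mode enumerates all C(n, n_a) label assignments and is used by
  the tests as its own oracle on small vectors.
- Stress accumulation uses floating-point dependency sums and rounds once
  at the end; path counts in graphs of the sizes used here are far below
  the 2⁵³ integer-exactness limit of doubles.

## Problem sizes

The test suite and acceptance script run on synthetic instances sized to
exercise every code path while keeping the whole suite fast on one CPU:
500-node graphs with 40 miRNAs per class for the hub-bias property (100
seeds in the test suite, 50 in the acceptance script), 100-miRNA duplicate
plates over 20 seeds for filter sensitivity/specificity, 1000 simulations
for the enrichment null, and exhaustive centrality oracles on graphs of ≤ 20
nodes. These sizes give Monte-Carlo error comfortably below the margins
asserted.

## Known limitations

- Interaction tables are only as good as the source dumps; the package
  de-duplicates and normalises but cannot detect wrong or retracted
  interactions, and validated-target collections under-cover recently
  studied miRNAs.
- `S` inherits the ascertainment bias of both the interaction table and
  the PPI graph: well-studied genes have more recorded edges and targets.
  Comparisons against the random baseline partially control for this only
  if the baseline is drawn from the same background.
- Absolute centrality values depend strongly on how the input network was
  assembled; only within-run comparisons (target set vs matched baseline)
  are interpretable.
- The expression model assumes perfect doubling per cycle and shared
  efficiency across assays; no efficiency correction is implemented.
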