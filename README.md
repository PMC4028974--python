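# mirdegree

Rank dysregulated microRNAs by the network importance of their validated
protein targets.

## The problem

Expression profiling of a tumour versus a matched control typically yields
one or two hundred miRNAs with >2-fold changes — far more than any lab can
validate. The usual triage, "take the most extremely dysregulated", ignores
*what the miRNA regulates*: a miRNA with a modest fold change whose targets
are hubs of the protein–protein interaction (PPI) network can move the cell
far more than a wildly dysregulated miRNA with peripheral targets.

`mirdegree` implements a network triage. For each dysregulated miRNA *m*
with validated target set *T(m)* it computes the **summed target degree**

```
S(m) = Σ_{t ∈ T(m)}  deg(t)
```

where `deg(t)` is the node degree of protein *t* in a PPI network. miRNAs
are ranked by *S* and placed in the plane of log₁₀ fold change (x) versus
*S* (y): points right of x = 0 behave as **oncomiRs** (up in the case
condition), points left as candidate **tumour suppressors**; points above
the mean of *S* regulate unusually well-connected proteins and are the
candidates worth carrying into wet-lab validation.

The package covers the whole workflow:

- **`interactions`** — load/merge/de-duplicate validated miRNA→target
  tables (Tarbase/miRecords-style TSV dumps), filter against an
  expressed-gene universe;
- **`network`** — SIF/edge-list PPI graphs, induced or shortest-path
  "bridged" seed subnetworks, and three node centralities: degree,
  closeness (reciprocal farness within the component) and Shimbel stress;
- **`stats`** — random-protein baselines, one-way ANOVA plus a permutation
  test for centrality comparisons, exact hypergeometric pathway
  over-representation with Bonferroni correction;
- **`expression`** — qPCR Ct plates → interplate calibration (spike-in) →
  global-mean ΔCt → 2^-ΔΔCt fold changes, with the concordance filter that
  demands ≥2-fold change on *every* replicate array;
- **`ranking`** — the summed-degree score, quadrants, candidate selection;
- **`synthetic`** — scale-free graphs, hub-biased target maps and
  two-condition duplicate plates with planted effects, for testing every
  stage without downloads;
- **`pipeline`** — one-config orchestration with a checksummed manifest,
  plus replay of published fold/degree tables. A thin `mirdegree` CLI
  mirrors the stages (`run`, `network`, `express`, `rank`, `enrich`,
  `compare`, `synth`, `replay`).

## Worked example

The package ships a fixture with a published top-25 ranking from a prostate
cancer progression model (non-tumorigenic P69 line versus its metastatic
derivative M12): per miRNA, the consensus fold change and the summed PPI
degree of its validated targets.

```python
from mirdegree import replay_fixture, select_candidates

ranking = replay_fixture()
print(ranking.table.head(6).to_string(index=False))
print(select_candidates(ranking, 1000))
```

prints

```
    mirna_id    fold  log10_fc n_targets_in_network  sum_degree  quadrant  rank
   hsa-miR-1    8.53  0.930949                 <NA>      1330.0 high-onco     1
  hsa-miR-21    0.26 -0.585027                 <NA>      1302.0 high-supp     2
 hsa-miR-124    9.48  0.976808                 <NA>      1242.0 high-onco     3
 hsa-miR-34a 1850.82  3.267364                 <NA>      1208.0 high-onco     4
hsa-miR-125b    0.00 -3.612360                 <NA>      1194.0 high-supp     5
 hsa-miR-19a    0.09 -1.045757                 <NA>       701.0 high-supp     6
['hsa-miR-1', 'hsa-miR-21', 'hsa-miR-124', 'hsa-miR-34a', 'hsa-miR-125b']
```

Five miRNAs stand clear of the rest with summed target degrees above 1000.
Note how the ranking reorders priorities: hsa-miR-1 (fold 8.53) and
hsa-miR-21 (fold 0.26, i.e. ~4-fold *down*) outrank hsa-miR-34a despite its
1850-fold change, because their targets are better connected. hsa-miR-125b
was undetected in the case sample (fold printed 0.00) and enters the plot
at the floored log-fold position on the suppressor side.

The `examples/` directory holds one short script per capability
(fixture replay, centrality comparison, qPCR fold changes, pathway
enrichment, full synthetic pipeline); each prints its results with a short
interpretation.

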