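# red-metrics

Conservation-priority indices from phylogenies: fair-proportion
**ED** (evolutionary distinctness), threat-weighted **EDGE**, and the
range-weighted surrogate **RED** (relative evolutionary distinctness),
with random imputation of unsequenced species over replicate trees and
rank-concordance validation.

## The problem

Priority lists such as EDGE combine two ingredients: how much unique
evolutionary history a species represents, and how threatened it is. For
most regional floras the second ingredient is missing — only a small
fraction of plant species carry red-list assessments. Geographic range,
however, is usually known, and range size is one of the strongest
correlates of extinction risk. RED exploits this: compute ED on a tree
whose branches have been divided by the number of occupied grid cells, and
narrow endemics on long branches rise to the top — no assessments needed.
Where threat really is range-driven, RED ranks species much like EDGE and
can serve as an interim prioritization until assessments catch up.

## The indices

For a tip *i* of a rooted ultrametric tree,

- **ED(i)** = Σₑ ℓ(e)/n(e) over the edges *e* on the root→*i* path, with
  ℓ(e) the branch length and n(e) its number of descendant tips. ED sums
  to the total branch length of the tree.
- **EDGE(i)** = ln(1 + ED) + GE·ln 2 under the `isaac` scheme (GE = 0…4
  for LC…CR), or ED × p(category) under the `iucn50/100/500`
  extinction-probability horizons.
- **RED(i)** = ED computed on the range-weighted tree, where each branch
  length is divided by |∪ cells of its descendant species| on a 0.5°
  occurrence grid.

Species without sequence data are grafted onto the backbone — at the
midpoint of a named sister branch, or uniformly at random within their
genus — and the random placements are replicated (default 100×); all
scores are medians across replicates. Agreement between two rankings is
measured with tie-corrected Kendall's W (two judges), Spearman's rho, and
top-k overlap with dense ranks (ties share a rank).

## Worked example

Simulate a small flora (60 species in 25 genera, 26 evaluated, 20% of
species withheld from the backbone), then run the full pipeline with 25
replicate trees:

```sh
red-metrics simulate --config sim.yaml --seed 11 --out data
red-metrics pipeline --tree data/tree.nwk --plan data/plan.csv \
    --occ data/occ.csv --status data/status.csv \
    --n 25 --seed 11 --k 10 --out run
```

with `sim.yaml`:

```yaml
n_species: 60
n_genera: 25
status_counts: {CR: 3, EN: 12, VU: 6, NT: 3, LC: 2}
missing_fraction: 0.2
```

The pipeline writes `ed.tsv`, `red.tsv`, `edge_<scheme>.tsv` (four
schemes), `compare_<scheme>.json`, and a `manifest.json`, and prints the
comparisons; for this seed:

```json
{
  "isaac":   {"w": 0.8875, "rho": 0.7750, "p_value": 3.34e-06,
              "n": 26, "k": 10, "topk_shared": 7, "topk_pct": 70.0},
  "iucn50":  {"w": 0.8308, "rho": 0.6615, "p_value": 2.33e-04,
              "n": 26, "k": 10, "topk_shared": 7, "topk_pct": 70.0},
  "iucn100": {"w": 0.8356, "rho": 0.6711, "p_value": 1.75e-04,
              "n": 26, "k": 10, "topk_shared": 7, "topk_pct": 70.0},
  "iucn500": {"w": 0.8667, "rho": 0.7333, "p_value": 2.03e-05,
              "n": 26, "k": 10, "topk_shared": 8, "topk_pct": 80.0}
}
```

Read: over the 26 evaluated species, the median-RED ranking agrees with
each median-EDGE ranking with W ≈ 0.83–0.89 (rho ≈ 0.66–0.78, all
p < 10⁻³), and RED's top-10 shares 7–8 species with each EDGE top-10 —
the simulated statuses were coupled to range size, which is exactly the
regime in which RED stands in for EDGE. The head of `run/red.tsv`:

```text
species	median
Genus006 species02	13.01123877
Genus006 species01	7.45758211
Genus005 species04	6.031999537
```

Other subcommands: `red-metrics tree check|calibrate|prune`, `impute`,
`ed`, `edge`, `rangeweight`, `red`, `compare` — see `--help` for each.
The library API mirrors the CLI (`red_metrics.fair_proportion_ed`,
`edge_table`, `red_scores`, `compare_rankings`, `simulate_dataset`, …).

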