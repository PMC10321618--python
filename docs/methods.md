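# Methods

## The indices

All scores are computed on a rooted ultrametric phylogeny whose tips are
species labeled with binomials (`Genus species`). Branch lengths are in
arbitrary relative time units; by convention the root-to-tip depth is
calibrated to 100 (`calibrate_root_depth`). Every index here is used only
through its *ranking*, and every functional form below is strictly
monotone, so the calibration depth — and, within a scheme, the exact
extinction-probability constants — do not affect priorities.

**Evolutionary distinctness (ED, "fair proportion").** Each branch is
split equally among the tips descending from it:

    ED(i) = sum over edges e on the root→i path of  l(e) / n(e)

where `l(e)` is the branch length and `n(e)` the number of descendant
tips. Summed over all tips, ED returns exactly the total branch length of
the tree; this conservation identity is the main correctness oracle and is
tested on thousands of random trees, including polytomies.

**EDGE.** ED combined with the threat level of a species, given as an
IUCN red-list category (LC, NT, VU, EN, CR; NE = not evaluated, DD treated
as NE). Two forms, selected by the scheme:

* `isaac`: `EDGE = ln(1 + ED) + GE·ln 2`, with GE the integer category
  rank (LC=0 … CR=4). This is the classic log form; the `GE·ln 2` term
  corresponds to an extinction probability that doubles per category.
* `iucn50`, `iucn100`, `iucn500`: `EDGE = ED × p(category)`, the expected
  loss of unique history under a category→probability transformation for
  a 50-, 100- or 500-year horizon. The constants are not univerally
  standardized; we ship the conventional 100-year table (CR 0.999,
  EN 2/3, VU 0.1, NT 0.01, LC 0.0001) and extrapolate the other horizons
  as `1 − (1 − p100)^(h/100)`. The table is attached to each
  `ExtinctionScheme`, logged on every run, and replaceable; because both
  forms are strictly increasing in ED and in category severity, rankings
  within a scheme are invariant to the exact values.

**RED (relative evolutionary distinctness).** ED computed on a
*range-weighted* tree: every branch length is divided by the number of
grid cells occupied by the union of its descendant species' occurrences.
Branches subtending narrow endemics keep their length; widespread clades
shrink. RED needs occurrences only — no threat assessments — which is the
point: where range size drives threat status, RED ranks species similarly
to EDGE and can serve as an interim priority signal for floras with many
unevaluated species.

## Occurrence gridding

Occurrences are either point records (`species,lon,lat`, decimal degrees)
or precomputed presences (`species,cell_i,cell_j`); the CSV dialect is
auto-detected from the header. Points map to half-open cells
`(floor(lon/s), floor(lat/s))` at cell size `s` (default 0.5°); a point on
a boundary belongs to the higher-index cell. No map projection is applied:
the grid is a plain degree grid, and only cell-set cardinalities enter the
computation (RED is invariant to relabeling cells). Species without any
occurrence are a hard error by default; `assume_range_one` grants them one
private cell each, because silently dropping a tip would corrupt the cell
unions of every ancestral branch.

## Imputing species without sequence data

Species absent from the sequence-based backbone are grafted on:

* **Midpoint sister** (deterministic): the new tip becomes sister to a
  named tip or clade, attached at the midpoint of the branch subtending
  the target. Used when the literature fixes the sister relationship;
  applied identically in every replicate.
* **Random within genus** (stochastic): an attachment edge is drawn
  uniformly among the edges of the genus clade — terminal edges of
  congeners, internal edges inside the genus MRCA, and the MRCA's stem —
  then an attachment height uniformly along that edge. A genus with a
  single backbone tip yields a cherry. Uniform-per-edge (rather than
  length-weighted) choice is the simplest defensible rule; it is isolated
  in one function so a length-weighted variant is a local change.

Grafts preserve ultrametricity exactly (the new terminal branch length
equals the attachment height), so tree height never changes. The random
directives are replicated — 100 times by default — and every downstream
score table carries per-replicate columns plus a per-species median (true
median; mean of the central pair for even counts). Replicate `i` is a pure
function of `(backbone, plan, master seed, i)` via independent
`SeedSequence` substreams, so replicates are reproducible in isolation.

Directives are applied in plan order within a replicate, so a species
added earlier is valid attachment context for a later congener.

## Rankings and concordance

Presentation tables use **dense ranks**: tied scores share a rank and the
next distinct score takes the next integer (so a "top 20" can hold more
than 20 species; ties at the boundary are included). The concordance
statistics use **midranks**, the standard tie treatment:

* Spearman's rho with the large-sample two-sided p (scipy).
* Kendall's W for m=2 judges with tie correction,
  `W = 12·S / (m²(n³−n) − m·ΣTⱼ)`, where S is the sum of squared
  deviations of per-species rank sums and `Tⱼ = Σ(t³−t)` over tie groups
  of judge j. For untied rankings `W = (1+rho)/2` exactly; this identity
  and a hand-worked tied example are the tests.
* Top-k overlap: shared species among those ranked ≤ k in both lists,
  reported as a count and as a percentage of k.

The RED-vs-EDGE validation universe is the evaluated species only.

## The synthetic-data generator

`simulate_dataset` produces a complete study from one seed:

* **Tree**: a crown-conditioned pure-birth (Yule) tree over genera
  (waiting times `Exp(λk)`, all lineages extended to the present), each
  multi-species genus expanded with a faster within-genus Yule subtree
  occupying a uniform 20–80% fraction of the genus terminal branch —
  genera are monophyletic by construction. Depth calibrated to 100.
  Defaults: 200 species in 85 genera (study scale).
* **Ranges**: per-species size drawn log-normally (μ=1.8, σ=1.1 on the
  log scale: median ≈ 6 cells, long right tail), truncated at 1 and placed
  as a contiguous run of cells in a 12 × 80-cell extent (long and narrow,
  like a 0.5° grid over Chile). Contiguous blocks give internal branches
  realistically nested cell unions.
* **Statuses**: exact per-category counts over a randomly chosen evaluated
  subset (defaults 7 CR / 54 EN / 23 VU / 7 NT / 4 LC = 95 evaluated),
  remainder NE. With `couple_to_range` (the default), the narrowest-ranged
  evaluated species receive the most severe categories — the regime in
  which a range-weighted index is expected to track a threat-weighted one;
  with coupling off, categories are assigned independently of range.
* **Plan**: a fraction of species (default 25%) is withheld from the
  backbone for random re-imputation, only ever leaving ≥ 1 congener
  behind.

What the generator does *not* emulate: spatial autocorrelation of
diversification, coastline geometry, sampling bias in occurrence records,
and errors in the backbone topology itself. Passing the surrogacy test on
these data therefore shows that the pipeline recovers the RED–EDGE
agreement *when threat is range-driven*, not that any real flora satisfies
that premise.

## Numerical choices and degenerate inputs

* Ultrametricity is measured as the maximum relative deviation of tip
  depths from their mean; default tolerance 1e-6 (the paper-style inputs
  are rate-smoothed trees, effectively exact). Calibration refuses
  non-ultrametric or zero-height trees.
* A Newick root edge length parses as a unifurcation above the root; it is
  suppressed on read, since a root edge contributes equally to every tip
  and cannot change any ranking.
* Zero-length branches are legal in general but cannot be midpoint-bisected
  (hard error naming the target).
* Grafting onto a genus whose MRCA is the tree root excludes the
  (nonexistent) stem edge from the candidate set.
* Score tables refuse non-finite values; species listed in the status
  table but absent from the trees are reported in `attrs["missing"]`
  rather than raised, since regional red lists routinely include taxa
  outside the phylogeny.

## Problem sizes used in tests and the acceptance script

The library and CLI default to 100 replicates. The test suite and
`scripts/acceptance.py` use smaller, explicitly chosen sizes: 3–6
replicates for determinism and plumbing checks, 5 replicates × 20 seeds at
full study scale (200 species, 95 evaluated) for the surrogacy experiment,
1,000 random trees for the ED conservation identity, and 20–25 random
trees for the brute-force oracles. Medians over 5 replicates are noisier
than over 100, which makes the surrogacy thresholds conservative rather
than lenient.

## Known limitations

* The published species-level scores (and the study's W/rho coefficients)
  depend on the deposited phylogeny and the Dryad occurrence matrix, which
  are not bundled; reproducing them (e.g. the top-ranked species in every
  published list) is an optional external check, not part of the test
  suite. The bundled fixtures are the *printed* summary tables only.
* Only the two-judge W is implemented (the validation never compares more
  than two rankings at once).
* HEDGE/EDGE2-style methods that propagate extinction risk across
  relatives are out of scope.
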