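# cwrplan

In-situ conservation planning for crop wild relatives (CWR): a desk-scale,
fully testable re-implementation of the global workflow that takes species
occurrence records and environmental layers to a ranked network of reserve
sites that would conserve every species together with its environmental
(proxy-genetic) diversity under climate change.

## Who this is for

Conservation planners and biodiversity informaticians who want the complete
analysis chain — species distribution modelling, ecogeographic zonation,
protected-area gap analysis and minimum-set reserve selection — as an
importable, seeded, oracle-tested Python library rather than a collection of
GIS scripts. A synthetic-landscape generator supplies ground-truth worlds,
so the entire pipeline runs and validates itself without any external
downloads.

## The method

1. **Occurrence QC.** Records are cleaned (cultivated flags, missing
   coordinates, coordinate uncertainty > 10 km, points outside the native
   range, exact duplicates) and each species is routed by its unique-record
   count: ≥ 10 → distribution model, 1–9 → 50-km occurrence buffers, 0 →
   excluded.
2. **Distribution models.** Environmental variables (27 layers in edaphic /
   geophysical / climatic sets) are screened by iterated variance inflation
   factor removal (VIF ≥ 10). A presence–background maximum-entropy model is
   fitted over 10,000 background cells from the native range: the Gibbs
   distribution `P(x) ∝ exp(η·f(x))` with L1-penalised matching of presence
   feature means (linear + quadratic features), solved as a convex program.
   Five-fold cross-validation gates adequacy (mean AUC ≥ 0.7, fold sd ≤
   0.15); inadequate models fall back to buffers. Continuous suitability is
   binarised at the maximum training sensitivity plus specificity (MAXTRSS)
   threshold. Future climate realizations are projected individually,
   averaged into an ensemble, re-thresholded, and intersected with the
   current range to give the climate-stable range and the range-loss
   fraction.
3. **ELC zonation.** Each variable set is clustered (seeded k-means) over
   the species' native range; the label triple is one composite Ecogeographic
   Land Characterization category — an *adaptive scenario*, the proxy unit of
   genetic diversity.
4. **Gap analysis.** Percent of range and of adaptive scenarios inside
   protected areas, climate-driven losses, the 50% scenario-coverage
   adequacy rule, and consolidated crop-type tables.
5. **Reserve selection.** A Marxan-style minimum-set problem: planning units
   are grid cells (cost 10 inside protected areas, 50 outside), every
   species × scenario combination needs ≥ 1 selected unit (SPF = 1), and a
   boundary-length modifier (BLM = 0.001) rewards compactness. Solved by
   simulated annealing with repair and drop passes; runs are ranked by
   fewest units, then cost.
6. **Prioritization.** Units of the best solution are ordered by greedy
   complementarity; the *pragmatic* mode ranks all protected sites first and
   then complementary outside sites, yielding top-100 + top-50 site tables.

## Worked example

```bash
python examples/04_reserve_selection.py
```

prints (seed 1, 12 species on a 50 × 50 grid):

```
12 species assessed -> 280 species x scenario combinations over 2364 candidate planning units
best of 5 annealing runs: 104 units, cost 4080, objective 4080.382
 rank  unit_id    pa  n_cwr  unique_cwr_added  combos_added
    1      114  True      6                 6             6
    2      449  True      6                 3             6
    3      529  True      6                 0             6
 ...
top sites cover 30.4% of all combinations; full tables written to scratch/example_run/
```

Each row is one 5-km planning unit: `combos_added` is the number of
species × adaptive-scenario combinations the site contributes beyond all
higher-ranked sites, so the first rows are the highest-leverage places to
start a reserve network. Other examples build a synthetic world
(`01_synthetic_world.py`), fit and validate one species' model against its
known niche (`02_distribution_model.py`), and run the gap analysis
(`03_elc_gap_analysis.py`). A thin CLI wraps the same pipeline:
`cwrplan run --out dir/ --seed 1`.

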