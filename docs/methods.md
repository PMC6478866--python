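# Methods

This note documents the models, the numerical choices, what the synthetic
generator does and does not emulate, and the limits of what the passing
test suite demonstrates.

## Spatial model

All analysis runs on a flat Cartesian grid of square cells with
coordinates in kilometres (default cell edge 5 km, mirroring a global
5-km analysis grid treated as equal-area). No geodesy is performed:
distances are Euclidean, cell areas are uniform. This is deliberate — the
statistical machinery under test (models, zonation, selection) is
unaffected by projection detail, and an equal-area abstraction keeps every
oracle exact. Rasters are numpy arrays; on disk they are ESRI ASCII grids
(plain text) with a CSV sidecar for variable-set tags.

## Synthetic worlds

The generator produces the full input suite the analysis assumes, with
known truth:

* **Environmental layers.** Independent Gaussian random fields: white
  noise smoothed with a Gaussian kernel (periodic boundaries for
  stationarity), standardized per layer. `autocorr_length_km` is defined
  as the *practical variogram range* — the distance at which semivariance
  reaches 95% of the sill; the smoothing sigma is `L / (2√(ln 20) ·
  cell)`. Default 27 variables split 9 edaphic / 6 geophysical / 12
  climatic, a plausible split of the kind of 27-variable suite global
  analyses use; the split is configurable because real suites vary.
* **Niches.** Logistic in the layers: each species responds to two
  climatic variables (weights 1–2, the axis climate change acts on) plus
  one edaphic and one geophysical variable (weights 0.2–0.6). The
  intercept is calibrated so the true range (suitability ≥ 0.5) covers a
  random 5–15% of the grid — large enough to model, small enough to be a
  meaningful target. The native range is the bounding box of the true
  range padded by 10 cells.
* **Occurrences.** Cells drawn with probability proportional to true
  suitability, jittered within the cell; gamma-distributed coordinate
  uncertainty capped at 10 km so clean records survive QC. Configurable
  fractions of exact duplicates, out-of-native-range points and
  high-uncertainty (> 10 km) records are appended, with a hidden truth
  label the QC filters never see.
* **Protected areas.** A union of random discs; a shared radius
  multiplier is bisected until the protected fraction is within ±2
  points of the target (default 15%, a realistic terrestrial protection
  level).
* **Future climate.** Each realization adds a scalar offset — mean shift
  plus a per-realization normal deviation — to every climatic layer;
  edaphic and geophysical layers are untouched. Defaults: +0.75 sd mean
  shift, 0.15 sd realization noise, 5 realizations. The shift size was
  chosen once so that species losses span roughly 0–0.5 with a tail
  above 0.5, the regime the gap statistics discriminate on; the
  realization count is a desk-scale stand-in for a 30-member circulation-
  model ensemble.

What the generator does **not** emulate: sampling bias (roadside/herbarium
clustering), taxonomic error, spatially correlated climate-model
disagreement, dispersal limits, and coastline/landmask geometry. Passing
recovery tests therefore show the chain is *correct and well-calibrated
under its own assumptions*, not that real-data artefacts are handled.

## Occurrence QC

Filters run in a fixed order (cultivated flag, missing coordinates,
uncertainty strictly > 10 km, outside native range, exact-coordinate
duplicates after rounding to the nearest metre) and each removal is
attributed to the first failing rule, so `raw = final + Σ removals` holds
exactly. Records with *missing* uncertainty are retained but counted — the
choice is auditable in the report. Species without a native-range mask are
flagged rather than silently passed or dropped. Pathways: ≥ 10 unique
records → model, 1–9 → buffer, 0 → excluded.

## Distribution models

* **VIF screening.** `VIF_j = 1/(1−R²_j)` from OLS of variable j on the
  rest; the highest-VIF variable is removed and VIFs recomputed until all
  are below 10. Perfect collinearity gives VIF = ∞ and is removed first;
  ties remove the later-listed variable so earlier variables are kept —
  any fixed rule works, this one is deterministic. A single variable is
  defined to have VIF 1.
* **Maximum entropy.** The fitted object is the Gibbs distribution over
  background cells minimizing `−mean_pres(η·f) + log Σ_bg exp(η·f) +
  β‖η‖₁`; the L1 term is handled exactly by the positive/negative split
  with L-BFGS-B bounds (gtol 1e-8, max 500 iterations; non-convergence
  sets a flag and warns). Features are linear + quadratic in the retained
  variables, standardized by background mean/sd; β defaults to 0.05 on
  that scale — enough to keep separable fits bounded without visibly
  biasing recovery. Suitability is the logistic transform `r/(1+r)` of
  the relative occurrence rate (Gibbs density × number of background
  cells), computed as `expit(log r)` for stability; a constant feature
  yields exactly uniform suitability.
* **Background.** 10,000 cells uniform without replacement from the
  native-range mask (all cells when the mask is smaller).
* **Cross-validation and adequacy.** Seeded shuffle into 5 folds; AUC of
  held-out presences against the background as pseudo-absences. Adequacy
  = mean AUC ≥ 0.7 and fold sd ≤ 0.15 — published adequacy protocols vary,
  so both cuts are configurable; the flag's only role is routing species
  to the buffer pathway.
* **MAXTRSS.** Candidates are the observed scores; presences count as
  predicted-present at score ≥ t; ties break to the smallest threshold,
  i.e. the largest range — conservative for conservation. Training
  (not cross-validated) scores are used, per the name.
* **Buffers.** A cell is in the range iff its centre lies within 50 km of
  any record, clipped to the native range. Buffer species carry no future
  model; their loss fields are null and their current range enters
  planning unchanged (treated as climate-invariant for lack of a model).
* **Futures.** Continuous projections per realization are averaged
  cellwise, then binarized at the current model's threshold; the stable
  range is current ∧ future and `loss = 1 − |stable|/|current|`.

## ELC zonation

Seeded k-means (10 restarts) per variable set on standardized cell values
inside the native range; the composite category is the mixed-radix
encoding of the three labels (+1, with 0 reserved for cells with missing
data, which never count as scenarios). k defaults to 5 per set at
production scale and 3 in the bundled pipeline configuration to keep
scenario counts proportionate to a small grid; the right k for real data
is a substantive choice the library deliberately leaves exposed. ELC is
built on baseline climate only; scenario loss under climate change is
range-driven (scenarios present now but absent from the stable range).

## Gap analysis

Coverage is cell counting: `100·|range ∧ PA|/|range|`; polygon protected
areas are rasterized by the cell-centre rule (point geometries dropped
with a logged count). A species with < 50% of its current adaptive
scenarios inside protected areas is under-conserved; zero range coverage
flags it exclusively-outside. Protected-cover loss is
`100·(1 − |stable ∧ PA|/|current ∧ PA|)`. Crop-type tables de-duplicate a
species within a type and count it once per type it belongs to. Reported
percentages round half-up at one decimal (or zero decimals where integer
style is wanted).

## Reserve selection

Objective: `Σ cost(S) + BLM·boundary(S) + Σ_unmet SPF·penalty`. Boundary
is counted in exposed rook edges (grid exterior included), so BLM is in
cost-per-edge units. The penalty per combination is the cheapest covering
unit's cost **plus 4·BLM** — the worst-case boundary increment — so
covering a combination is never dearer than paying its penalty; with the
bare cheapest-cost penalty an optimal solution could strictly prefer
leaving a feature unmet, which would contradict the all-targets-met
repair guarantee. Planning units are restricted to cells carrying at
least one combination (other cells can never enter an optimal solution).

Annealing: random initial selection (p = 0.3), single-unit flips,
Metropolis acceptance under geometric cooling from `max cost + max
penalty` down to `1e-5·max(BLM, 1e-3)` — far below the smallest
meaningful objective delta so late annealing resolves boundary-scale
differences. After annealing, a repair pass gives each still-unmet
combination its cheapest-marginal covering unit (provably never worsening
the objective), then a drop pass removes units whose removal keeps
coverage and lowers the objective. Runs are ranked by fewest units, then
cost, then run index. Iteration counts are configurable; the bundled
configurations use 10³–10⁴ iterations and 10–20 runs, which attain
exhaustive-enumeration optima on ≥ 95% of random ≤ 15-unit instances.

## Prioritization

Greedy complementarity over the best solution's units: most combinations
added, ties by most species added, then lowest unit id (the tie rules are
a package choice — any deterministic rule works, and determinism is what
the oracle tests need). Pragmatic mode exhausts protected-area units
before considering outside units, so every protected site precedes every
outside site while final coverage equals adaptive mode's. Top-site tables
slice the first 100 protected and 50 outside sites.

## Problem sizes

The bundled pipeline runs 20 species on a 60 × 60 grid with 5 future
realizations; recovery validation uses 20 species on 100 × 100. These
sizes were chosen as the smallest at which every statistical behaviour of
interest (autocorrelation, niche recovery, ensemble averaging, annealer
convergence) is clearly expressed.

## Known limitations

* The maximum-entropy feature set is linear + quadratic only; hinge /
  product / threshold features and clamping are out of scope, so strongly
  non-monotone real niches would be under-fitted.
* Buffer-pathway species are carried as climate-invariant; their true
  sensitivity is unknown by construction.
* The annealer is a faithful small-scale solver, not a byte-compatible
  reimplementation of production Marxan (no zoning, no probabilistic
  threats, no separation constraints).
* Equal-area flat geometry: results near poles or across datelines are
  outside the model.
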