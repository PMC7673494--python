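# sdmconnect

Habitat-suitability ensemble modelling and circuit-theory landscape
connectivity on raster landscapes.

`sdmconnect` replays, end to end, the analysis workflow behind a
climate-change assessment for a range-restricted large carnivore: from
presence-only field records to an ensemble habitat suitability map,
binary range maps under alternative climate scenarios with
protected-area accounting, electric-circuit connectivity between
protected areas, and random-forest variable importance.  Because field
occurrences and regional climate rasters of such studies are rarely
redistributable, the package ships a synthetic-landscape generator with
a known species-environment truth, so every stage is fully testable —
and the whole analysis reproducible — without any download.

It is aimed at quantitative ecologists and methodologists who want a
transparent, scripted version of a workflow usually spread across
several GUI tools.

## The methods

**Pseudo-absence construction.**  Three presence-only models score the
landscape: a BIOCLIM percentile envelope (score `min_j 2 min(p_j, 1-p_j)`
over mid-rank percentiles `p_j`), a Domain model (maximum Gower
similarity `1 - mean_j |x_j - t_j| / range_j` to any training presence),
and a one-class RBF SVM.  Binarized at each model's zero-omission
threshold and combined by majority vote, they delimit the unsuitable
cells from which pseudo-absences are drawn — two per presence, each at
least 5 km from every presence and every other pseudo-absence.

**Suitability ensemble.**  Four presence/absence learners — a binomial
GLM fit by IRLS, a maximum-entropy Gibbs model (L1-penalized, linear +
quadratic features over background cells), an RBF SVM with Platt
scaling, and a single-hidden-layer backprop network — are trained on a
stratified 80/20 split and combined by *accuracy rate as weight*:

    w_i = AUC_i / sum_j AUC_j,        ensemble(x) = sum_i w_i s_i(x)

with AUC the Mann-Whitney rank statistic on the held-out split and a
Hanley-McNeil test against the chance value 0.5.

**Range maps.**  The continuous ensemble is binarized at the threshold
maximizing the true skill statistic, TSS = sensitivity + specificity - 1
(prediction positive when score > threshold, strict).  Suitable area is
reported in km², as a share of the study area, and split inside/outside
the protected-area boundaries — for the current climate and for each
shifted climate stack.

**Connectivity.**  Resistance is inverted suitability,
`R = 1 / max(s, 0.01)`.  Valid cells become nodes of a resistor network
(orthogonal conductance `g = 2/(R_i + R_j)`, diagonals divided by √2);
each protected area is contracted to a supernode.  For every node pair,
1 A is injected and the sparse graph Laplacian solved, giving the
pairwise effective resistance and a per-cell current map; the per-pair
maps sum to the cumulative current map whose top cells are the movement
pinch points.

**Variable importance.**  A bootstrap CART forest (Gini splitting,
`mtry = floor(sqrt(p))`) with per-tree out-of-bag sets yields
permutation importance — overall and per class — and mean decrease in
Gini impurity.

## Worked example

The numbered drivers under `analysis/` replay the study on the default
synthetic landscape (150×150 km at 1 km resolution, 80 presences, six
protected areas, seed 1):

```bash
python analysis/01_simulate_landscape.py
python analysis/02_prepare_occurrences.py
python analysis/03_fit_and_evaluate.py
python analysis/04_range_scenarios.py
python analysis/05_connectivity.py
python analysis/06_variable_importance.py
```

Stage 2 prints the occurrence bookkeeping — one collinear layer dropped,
thinning and the 2× pseudo-absence rule:

```
layers dropped (|r| > 0.75): ['bio3']
presences after 5 km thinning: 67 of 80
pseudo-absences placed: 134 (2 per presence)
```

Stage 3 prints the validation table (held-out 20%):

```
   model  tss_max   auc  auc_se  p_two_tailed
     glm    0.658 0.872   0.068           0.0
  maxent    0.621 0.818   0.079           0.0
     svm    0.581 0.860   0.070           0.0
     ann    0.621 0.869   0.069           0.0
ensemble    0.658 0.852   0.072           0.0
```

Every model beats chance decisively (the two-tailed test of AUC = 0.5
rejects at any conventional level), and the ensemble discriminates
held-out presences from pseudo-absences with AUC 0.85.  Stage 4 shows
the range contracting as the climate shift hardens (suitable area
8 908 km² currently, 4 489 km² under the severe scenario), stage 5
ranks protected-area pairs by effective resistance and finds 23 pinch
cells, and stage 6 recovers exactly the three variables that drive the
synthetic truth:

```
top-3 variables: ['bio19', 'bio17', 'bio7']
true drivers of the synthetic landscape: ['bio17', 'bio19', 'bio7']
```

The same pipeline is scriptable through the `sdmconnect` CLI
(`simulate`, `prep`, `fit`, `run-all`, `info`) and configurable through
a single YAML file; see `docs/methods.md` for the modelling choices and
their rationale.

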