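# Methods

## Model and assumptions

The pipeline assumes the screen phenotype is *linear in kinase inhibition*:
the cell-index perturbation caused by an inhibitor is the sum over kinases
of a kinase-specific, time-windowed effect scaled by how strongly that
inhibitor hits the kinase (1 − residual activity/100). This is the standard
kinase-regression (KiR) assumption; everything downstream — the per-window
elastic net, the sign rule, the synthetic-data generator — embodies it.
No saturation, no inhibitor pharmacokinetics (effects switch on/off
instantaneously at their window boundaries), and no kinase–kinase epistasis
are modeled.

## Kinetics and windowing

* **Baseline.** Default `mode="delta"` subtracts the cell index at the last
  sample before agonist addition; `ratio_minus_one` (the instrument
  convention) is selectable. Both pin the reference sample to exactly 0;
  delta is preferred as the default because it is scale-preserving under
  the later AUC subtraction.
* **Windows.** Width 5 min; starts advance 1 min for the first 120 min
  and 5 min thereafter over a 360-min span → 164 windows, midpoints
  2.5 … 357.5 min. Spans not divisible by the step truncate the last start
  downward. Windows are closed intervals; AUC boundaries interpolate
  linearly between bracketing samples, so window AUC is exact for
  piecewise-linear signals and additive over adjacent windows.
* **Anchoring.** Per window, delta = AUC − AUC(control); with
  m = min(delta) < 0 the affine map 100·(delta − m)/(−m) puts the control
  at exactly 100 and the minimum at exactly 0 (the division happens before
  the multiplication so both anchors are bit-exact). When m ≥ 0 no
  inhibitor fell below the control and the map would divide by zero; the
  fallback 100 + delta keeps the control anchor unscaled and logs a
  warning.
* **Replicates** are averaged per inhibitor before AUC (the screen's unit
  of analysis is the inhibitor); per-replicate AUC is available via a flag.

## Per-window elastic net

* Design matrix: residual activity rescaled to fraction in [0, 1], **not**
  standardized, so coefficient signs keep their physical reading; the
  intercept is always fit and never penalized. The control (DMSO) row is
  excluded from the response.
* Mixing α = 0.9 (near-lasso, sparse kinase sets); λ over a 50-point log
  grid chosen by leave-one-out CV (n = 28 observations favors LOO).
* **Null gate.** The anchored 0/100 scale has a side effect: in a window
  with no genuine kinase-dependent signal, m is at noise scale and the
  map amplifies noise to full scale. Such windows are detected by
  comparing CV errors: if the best model does not beat the intercept-only
  model by more than one standard error, the window yields no calls.
* **λ rule.** Default is the sparsest λ within one standard error of the
  CV minimum (glmnet's `lambda.1se`); plain CV-minimum via
  `lambda_rule="min"`.
* **Call rule.** The elastic net's grouping property spreads weight onto
  kinases whose inhibition profiles are correlated with a true signal
  carrier, so "any nonzero coefficient" has no kinase-level specificity
  (zero-noise experiments still produce dozens of small satellite
  coefficients per window). The default call rule therefore requires a
  coefficient within a factor of two of the window's largest
  (`call_rule="dominant"`, `call_frac=0.5`); the permissive
  `call_rule="nonzero"` (|β| > 1e−8) remains available.
* λ below 1e−15 falls back to unpenalized least squares (coordinate
  descent does not converge at exactly 0); λ = 1e−10 through the ordinary
  path reproduces least squares to ≈1e−8.
* Determinism: cyclic coordinate descent, fixed fold order — identical
  inputs give identical fits regardless of seed.

## Self-organizing map

Classical online SOM, authored here: random codebook initialization from
the data range, random-sampling training, best-matching unit by Euclidean
distance on the raw {−1, 0, +1} profiles, Gaussian neighborhood on the
grid, and asymptotic decay of both σ (default 1.0) and learning rate
(default 0.5) over 500 × n_profiles iterations. Ties in the BMU search
break to the lowest (i, j) in row-major order. Quantization error (mean
distance of each profile to its BMU) is recorded before and after training
and final ≤ initial is asserted; topographic error is reported as a
diagnostic only. The distance map (U-matrix) sums Euclidean distances to
the 8-connected neighborhood and normalizes by the maximum cell. The
published analyses do not state SOM hyperparameters or seeds, so occupied
neuron counts are run-specific, not reproduction targets.

## Network generation

* Kinase–substrate tables are filtered to one organism on both the kinase
  and substrate side, restricted to substrates in a kinome list, and
  deduplicated across phosphosites (one directed edge per kinase →
  substrate pair; autophosphorylation rows become self-loops). The
  packaged `human_kinome.txt` is a curated, editable starter list of
  ~300 well-established human protein-kinase gene symbols; replace it with
  a full (~518-gene) kinome for production analyses.
* Local networks take **all** shortest directed paths for every **ordered**
  member pair (unions of single arbitrary paths would be nondeterministic
  and drop parallel routes); a single-path mode is available. A singleton
  member forms a network only through a self-loop; an empty combined edge
  set returns no network.
* `max_path_nodes` counts kinases on the longest shortest path (direct
  edge = 2; lone self-loop node = 1).
* Name mapping between panel and network namespaces goes through an
  explicit synonym CSV; unmapped members are logged and counted, never
  silently dropped.

## Synthetic screens

The generator emulates the screen geometry: 28 inhibitors in triplicate,
cell index sampled 1/min for 2 h then 1/5 min for 4 h plus a 7-min
pre-treatment baseline, agonist at t = −6 min, inhibitors at t = 0.

* **Control curve** c(t) = b₀ − D·(s/t_min)·e^(1−s/t_min) with D = 0.4
  index units and t_min = 25 min — an acute drop bottoming out 20–30 min
  after the agonist, then recovery.
* **Panel.** Residual activities are drawn near full activity
  (clipped normal, mean 92) except each kinase's strong inhibitors
  (2 + Poisson draws, ~4 on average) which draw uniform [0, 50). This
  mirrors real inhibitor selectivity and gives the identifiability
  guarantee (every kinase inhibited below 50% by ≥ 2 inhibitors). A flat
  uniform panel makes many kinases near-proxies of each other and is not
  used.
* **Planted effects** (defaults): six kinases with signed, windowed
  effects of 0.2–0.3 index units spanning 5–340 min; the first kinase is
  a switch (−1 over 5–35 min, +1 over 100–245 min). Noise is Gaussian per
  sample with sd 0.01 index units (5% of the smallest planted magnitude),
  independent across replicate wells.
* **What it does not emulate:** instrument drift, edge-well artifacts,
  inhibitor toxicity, nonlinearity at strong inhibition, or correlated
  (structured) noise. Passing recovery tests therefore demonstrates the
  pipeline's correctness under its own linear model, not performance on
  real screens.

## Recovery scoring

Kinase-level precision/recall on detected sets (precision defined as 1
when nothing is predicted); sign accuracy over predicted calls inside the
±slack-dilated true support; symmetric slack-tolerant window-overlap
Jaccard averaged over true positives (slack default ±2 windows). On the
default screen, recall and sign accuracy are consistently at ceiling while
precision fluctuates with the panel draw: kinases whose inhibitor hit-sets
overlap heavily are genuinely indistinguishable to any regression on the
panel — the same identifiability limit the screen design itself faces.

## Problem sizes

Default analyses run 164 windows × 28 observations × 60 kinases (the
elastic-net stage, ≈40 s on one core, dominates); oracle-equivalence
checks use 50–100 random fixtures; shortest-path cross-validation uses
100 random digraphs of ≤ 12 nodes. These sizes were chosen so a complete
pipeline run plus the full test suite stays interactive on a laptop core.

## Known limitations

* Kinases absent from the panel cannot be predicted.
* Collinear inhibition profiles bound kinase-level precision (see above).
* The functionality matrix records signs only; coefficient magnitudes are
  available on the `WindowFit` objects but are not propagated to SOM or
  network stages.
* The null gate trades a small amount of sensitivity in weak-signal
  windows for large specificity gains in empty ones.
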