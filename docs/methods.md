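# Methods

## The kinetic scheme

The simulator implements a four-state continuous-time Markov chain:

```
talin_folded  <-->  talin_unfolded  <-->  vinculin_weak  -->  vinculin_mature
     (unfold/fold)        (bind/unbind)        (mature)            |
                                ^----------- unbind ---------------'
```

All force-dependent transitions follow the Bell–Evans law
`k(F) = k0·exp(±F·x†/kT)`; the weak→mature maturation step is constant
(force-independent) by default, and irreversible — no reversal of the
matured complex has been observed, so none is modelled. Unbinding from
either bound mode returns the system to `talin_unfolded`: the
vinculin-binding site uncoils (the +3 nm upward step) but talin stays
unfolded.

Simulation is exact (Gillespie): within a constant-force protocol segment,
waiting times are exponential in the total exit rate at that force; when a
segment boundary is crossed the waiting time is redrawn at the new force
without forcing a transition, which is statistically exact for memoryless
kinetics. All randomness flows from a single `numpy` generator seeded by the
caller; identical inputs give bit-identical event lists.

## Parameters and their provenance

Measured quantities (the package's reference parameter set, `presets`):

| quantity | value | role |
|---|---|---|
| full-length vinculin (FLV) unbinding | k0 = 6.6·10⁻³ s⁻¹, x† = 0.72 nm | weak-mode off-rate law |
| vinculin D1 domain unbinding | k0 = 6.8·10⁻⁶ s⁻¹, x† = 0.81 nm | comparison off-rate law |
| FLV / D1 helix-unraveling (simulation) | k0 = 2.6·10⁻⁷ / 4.5·10⁻⁸ s⁻¹, x† = 0.25 / 0.23 nm | high-force (200–260 pN) first-passage laws |
| weak / mature unbinding timescales at the 40 pN probe | 0.4 s / 7.4 s | mixture components of probe-force dwells |
| maturation timescale | 37 s (rate ≈ 0.03 s⁻¹) | weak→mature transition |
| working concentration | 20 nM | scale for per-molar on-rates |

Two parameterizations of the weak mode coexist and are both exposed: the
zero-force fit above extrapolates to ≈ 0.14 s at 40 pN, while the measured
weak-mode probe timescale is ≈ 0.4 s; similarly at 8.5 pN the fit gives
≈ 0.029 s⁻¹ where ≈ 0.01 s⁻¹ has been quoted. The discrepancy is a property
of the source data (the extrapolation convention is not recorded); the
package does not force agreement. `presets.weak_unbinding_at_probe()` /
`mature_unbinding_at_probe()` anchor laws at the probe-force timescales;
`presets.FLV_UNBINDING` carries the zero-force fit. Simulated probe-force
experiments use the probe-anchored laws, Bell–Evans fitting examples the
zero-force fit.

Placeholder defaults (documented as such, configurable, never baked into an
algorithm): the talin R3 folding/unfolding branch
(k0ᵁ = 10⁻⁴ s⁻¹, x†ᵁ = 5 nm; k0ᶠ = 1.5·10³ s⁻¹, x†ᶠ = 2.5 nm; unfolding
midpoint ≈ 9 pN) and the binding branch at 20 nM
(k0 = 1 s⁻¹, x† = 1 nm; biphasic peak ≈ 9–10 pN). These reproduce the
qualitative behaviour of the R3-IVVI sensor; the quantitative values were
published separately and are supplied via configuration when available.

Thermal energy defaults to kT = 4.114 pN·nm (298 K) and is configurable;
every fit records the kT it used.

## Synthetic data: what it emulates and what it does not

* Extension traces: piecewise-constant state levels (unfolded gain 20 nm —
  a typical rod-domain value, not a fitted one — and 3 nm binding
  contraction) plus i.i.d. Gaussian noise, default 1 kHz / 0.8 nm.
  Not emulated: drift, bead-tracking artifacts, camera blur, 1/f noise,
  force-calibration error. Passing round-trip tests therefore demonstrates
  detector correctness on idealized traces, not robustness to instrumental
  artifacts.
* Hold-and-probe experiments: by default the hold phase races maturation
  only, i.e. replicates are conditioned on the complex surviving the hold
  (the experimental convention — lifetimes are measured on complexes still
  bound at probe onset); the matured fraction at lifetime t is then exactly
  1 − e^(−t/τ). Weak-mode unbinding during the hold can be enabled
  (`allow_unbind_during_hold`), which tilts survivors toward early
  maturation. Maturation during the brief probe itself is neglected (at
  40 pN unbinding outpaces maturation ~100-fold).
* Dose–response and cell fixtures: straight-segment filaments with bundles
  at exactly twice the single-filament intensity and Poisson noise; disk
  cells with elliptical adhesions at controlled normalized edge distances.
  Real images have curved filaments, overlapping structures, uneven
  illumination; the fixtures validate the estimators' arithmetic, not their
  robustness to those.

## Estimators and numerical choices

* **Step detection** solves the penalized least-squares objective
  (residual sum of squares + penalty × number of change points) *exactly*
  with the PELT dynamic program (numba-compiled). A top-down binary
  segmentation was considered and rejected: the best single split across a
  brief bound-state excursion of width w inside an n-sample segment gains
  only ~Δ²·w²/n, so short dwells vanish below any sensible penalty.
  Default penalty 2σ̂²·ln N (BIC-style) with σ̂ = 1.4826·MAD(Δy)/√2 from
  first differences; minimum segment 2 samples; steps below 1.5 nm are
  merged away. The detector is deterministic and translation-invariant.
* **Event classification** pairs downward/upward steps within ±1 nm of the
  3 nm contraction into bound dwells; unmatched events produce flagged
  records rather than silent drops; a dwell open at the end of the record is
  censored at the record length.
* **MFPT** uses the censored-exponential MLE: total observed time divided by
  the number of uncensored events, SE = MFPT/√n_events.
* **Bell–Evans fits** are weighted least squares on ln(rate) vs force
  (weights from rate SEs by the delta method); the biphasic binding fit
  holds the talin branch fixed and fits the binding branch on a log-k0
  scale for positivity.
* **Dwell mixtures** are fitted by EM on the raw dwell times (never on
  binned data, so results are bin-width independent; the log-binned
  histogram with its √counts display convention is a visualization and
  peak-finding device). 1 vs 2 components chosen by BIC; a 2-component
  optimum with timescales within 5% collapses to one component. Eight
  seeded restarts guard against local optima. Synthetic two-mode samples
  default to weights 0.6/0.4 (pooled event counts suggest roughly 2:1
  weak:mature; exact weights are not recorded).
* **Maturation fit**: the mechanistic first-order relaxation
  T(t) = t_w + (t_m − t_w)(1 − e^(−t/τ)) is the default, since the scheme's
  irreversible weak→mature step implies it; a phenomenological logistic in
  ln t is available behind a flag for data described only as "sigmoidal".
  `fit_maturation_from_dwells` fits per-lifetime mean unbinding times with
  iteratively reweighted least squares, the weights taken from the
  model-implied mixture variance at each lifetime (empirical SEs at tens of
  replicates are too noisy to weight with safely).
  The default hold-and-probe design (500 replicates over a 2–150 s lifetime
  grid, replicate mass concentrated near the timescale and at the plateau)
  minimizes the Cramér–Rao bound of τ̂ for this estimator. That bound is
  intrinsically loose — the exponential scatter of individual mature dwells
  (sd ≈ 7.4 s) is pure nuisance noise in a mean-based fit — so τ̂ from 500
  replicates carries a standard deviation of roughly 10 s around 37 s;
  single runs scatter accordingly.
* **Binding probability** is the simulated fraction of replicates bound at
  the end of the observation window (with binomial SE); an "ever bound
  within the window" definition is selectable, and the definition used is
  recorded with the output.
* **Bundle ratio**: rolling-ball background subtraction (radius 50 px
  default), gray values binned at 256 levels over the 16-bit range, pixels
  above 1.5 × the mean single-filament calibration intensity counted as
  bundled. The 1.5 multiplier is this package's surrogate for an
  under-specified classification rule and is validated on synthetic truth
  only.
* **Hill fits** run in percent units with EC50, Hill slope and baseline free
  per dataset and the saturation plateau optionally shared globally
  (lmfit); an EC50 outside the sampled concentration range is flagged, not
  rejected.
* **Focal adhesions**: Otsu threshold on the full histogram, largest
  component as the cell body, equivalent radius r = √(area/π); strict
  inequalities for both the 0.3 µm² size filter and the 0.3·r central rule
  (following the "larger than" convention); centroids intensity-weighted by
  default (binary optional); boundary distance from the exact Euclidean
  distance transform sampled bilinearly at the centroid; local background
  from a 5-px dilation annulus excluding other adhesions and
  extra-cellular pixels, falling back (flagged) to the whole-cell
  non-adhesion mean.

## Degenerate inputs

Constant traces yield no steps (no error); all-censored dwell sets make the
MFPT and histogram estimators raise explicitly; a maturation fit whose
optimum orders t_m ≤ t_w fails loudly; bundle-ratio computation on an image
with no filament pixels raises rather than returning 0/0; adhesion centroids
outside the cell mask are flagged with distance 0.

## Known limitations

* Polymer elasticity (WLC/FJC) and loading-rate rupture theory are out of
  scope; extension levels are state offsets, not force-dependent polymer
  models.
* No hidden-Markov idealization; detection is purely change-point based and
  dwells shorter than ~2 samples are invisible.
* Rupture-force distributions from steered-MD-style pulling are not
  reproduced (they require cluster-scale molecular dynamics); the
  high-force first-passage generator mimics only the two-level observable.
* The simulator's event-calling thresholds are validated against its own
  ground truth; no claim is made about matching any particular instrument's
  event-calling pipeline.
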