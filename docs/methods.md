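# Methods

This note documents the models and procedures smolbind implements, the
assumptions behind them, the synthetic data they are validated on, and
the numerical choices that were genuinely open.

## Scientific setting

The package quantifies ligand–receptor engagement at the single-molecule
level for a membrane receptor system (the motivating case is TGF-β1
binding to its type II receptor TβRII, and the suppression of that
binding by a small-molecule competitor):

1. **Receptor stoichiometry by photobleaching step counting.** Under
   TIRF illumination, a GFP-tagged receptor appears as a
   diffraction-limited spot whose intensity decays in discrete steps as
   individual GFP molecules irreversibly photobleach. One downward step
   means one fluorophore (a monomer), two steps a dimer, three a trimer.
   The fraction of two-step spots — the dimer percentage — is the
   readout of ligand-induced receptor dimerization.
2. **Bond strength and binding probability by AFM force spectroscopy.**
   A ligand-functionalized cantilever is pressed onto and retracted from
   the cell surface. A specific ligand–receptor bond produces a sawtooth
   rupture on the retract curve; the rupture-force histogram peak is the
   binding force, and the fraction of curves showing a specific rupture
   is the binding probability. Keeping that probability below ~30%
   makes multiple simultaneous bonds unlikely, so single-bond statistics
   apply.
3. **Equilibrium binding constants.** A steady-state 1:1 Langmuir
   isotherm fitted to plateau SPR responses yields K_D; a one-site
   competition curve fitted to radioligand specific binding yields
   log10 IC50.

## Photobleaching step model and change-point search

A background-corrected trace is modelled as piecewise constant plus
noise. `StepModel` finds, for each candidate step count k up to
`max_steps` (default 5), the segmentation minimizing the residual sum of
squares, by exact dynamic programming over all admissible change-point
placements (minimum segment length `min_size` = 2 frames). k is selected
by minimizing RSS(k) + β·σ̂²·log(n)·k, a BIC-style penalty with
β = `penalty_mult` (default 2.0) and σ̂ estimated robustly from first
differences (MAD-based, so the sparse true steps do not inflate it).
Traces are 200–300 frames, so the exact O(k·n²) solver costs about a
millisecond; unlike greedy binary segmentation it attains the global
optimum, which the test suite verifies against an independently coded
brute-force enumeration.

Post-selection, any step smaller than `min_step_sd` (3) residual SDs is
merged by refitting at the next-smaller k (again globally optimal). A
trace is **accepted** for counting only if every step is downward, the
final level lies within `zero_tol_sd` (2) residual SDs of zero (complete
bleaching), and the initial level exceeds `dim_sd` (4) residual SDs.
Otherwise the rejection reason is recorded: `incomplete_bleaching`
(fluorophores outlasting the movie), `upward_step` (blinking or
aggregation), or `too_dim`. The rejection policy is this package's
explicit formulation of the implicit requirement that only cleanly,
completely bleaching spots be counted; classification maps accepted
1/2/3-step fits to monomer/dimer/trimer and everything else to
"rejected".

Segmentation (change points, step sizes) is invariant to adding a
constant offset to a trace; the zero-final-level acceptance rule is not,
by design — it references the absolute zero defined by background
correction, which is why correction precedes fitting.

## TIRFM detection and extraction

Detection operates on the mean of the first `k_frames` (10) frames,
Gaussian-smoothed by `smooth_sigma` (1 px) as a matched-filter aid. Local
maxima (3×3) above the image median plus `threshold_sd` (5) robust SDs
are candidates; any pair of candidates closer than 5 px is discarded
entirely (both members), and spots whose 5×5 region leaves the image are
dropped. Ordering is row-major, so detection is deterministic. This is
an automated, reproducible proxy for the manual circle-selection used at
the microscope.

Per frame, the trace is the 5×5 region sum minus 25× the median of a
surrounding annulus (7×7 excluded, out to 11×11, clipped at borders).
The median makes the local background estimate robust to a neighboring
spot clipping the annulus. Two spots closer than about 3 px merge into a
single smoothed maximum and are then *not* caught by the pair-exclusion
rule; the simulator's placement floor (≥ max(4σ_PSF, 6 px)) keeps the
synthetic data out of that regime, and real data relies on low spot
density — a documented limitation.

Condition-level statistics run on per-cell dimer percentages (cells are
the replicates, not pooled spots): one-way ANOVA with Tukey HSD
pairwise comparisons. Per-movie dimer-fraction confidence intervals are
exact Clopper–Pearson binomial intervals on counted spots. Printed-style
percentages round half away from zero to one decimal.

## AFM model and rupture detection

Forces come from cantilever deflection via F = k·d (0.06 N/m × 1 nm =
60 pN); curves are stored in a plain-text dialect with the spring
constant and loading rate (default 1.0 × 10⁴ pN/s) in headers. A linear
baseline fitted to the far 25% of the retract is subtracted from both
segments; the contact point is the zero crossing where the corrected
approach enters the repulsive regime.

Ruptures are detected as discontinuous force relaxations on the retract:
the median-filtered (5-sample) force is differenced over a 3-sample gap
and compared against `n_sigma` (4) robust noise SDs (MAD of first
differences). The event magnitude is measured on the raw trace at the
drop sample — the force at the last loaded point — so the per-event read
noise enters symmetrically and the histogram peak stays unbiased;
median-based level estimates were rejected because they clip the
sawtooth apex and bias forces low by several pN. Events within `d_min`
(10 nm) of contact are classified nonspecific adhesion; among the
remainder only the event at the largest separation is *the* specific
event (last-rupture rule: in tip-tethered geometry the final detachment
reflects the ligand–receptor bond). Worm-like-chain fitting is
deliberately not used: derivative thresholding is deterministic and
directly checkable against simulator ground truth (sensitivity ≥ 0.95,
false-event rate ≤ 0.02 at the default noise level).

The rupture-force histogram uses Freedman–Diaconis bins with a single
Gaussian fitted by least squares to bin counts, mean constrained to the
observed force range and initialized at the sample mean/SD. R² against
the bin counts is the goodness measure; below 0.8 the fit is flagged as
poorly described by a single maximum (the threshold separates clean
unimodal samples, R² ≳ 0.95 at n ≥ 10³, from bimodal mixtures, R² ≲ 0.5).
Binding probability is the per-experiment fraction of curves with a
specific event, summarized as mean ± SEM across (typically 3)
independent experiments, with a flag when the mean reaches 30% and
single-molecule statistics become doubtful.

## Exact nonparametric tests

`mannwhitney_exact` enumerates all C(n1+n2, n1) group assignments of the
pooled mid-ranks for combined n ≤ 12 (924 assignments at 6 vs 6), which
conditions on the observed tie pattern; beyond that it uses the
tie-corrected normal approximation with continuity correction. The
two-sided exact p is the probability of |U − n1·n2/2| at least as large
as observed. `kruskal_dunn` computes the tie-corrected H and an exact
permutation p whenever the multinomial arrangement count is ≤ 20 000
(1680 for three groups of three), the chi-square tail otherwise; Dunn
pairwise z statistics use the pooled-rank variance with tie correction
and Holm adjustment by default (the adjustment method is configurable —
Holm controls FWER without independence assumptions, a conservative
default where no adjustment was specified). Both enumerations are tested
against independent full-permutation oracles.

The choice of cutoffs is practical: n ≤ 12 keeps enumeration below a
thousand arrangements, and factorial growth makes larger exact MW tables
pointless when the normal approximation is already accurate there.

## Equilibrium binding fits

The steady-state model R(C) = Rmax·C/(K_D + C) is fitted by
Levenberg–Marquardt/TRF least squares with an analytic Jacobian,
initialized at Rmax₀ = max response and K_D₀ = the interpolated
half-maximal concentration. Standard errors come from the Jacobian
covariance; a 95% CI built with the t(n−2) quantile is calibrated
(90–98% empirical coverage at 2% noise in the test suite). The
competition model B(c) = 100/(1 + 10^(log10 c − logIC50)) fixes the
asymptotes at 100/0 and the Hill slope at 1 — the fewest assumptions
consistent with reporting a single logIC50 — with a free-slope variant
behind a flag; the free-slope fit also runs internally to warn when the
slope CI spans zero (no dose dependence). log[IC50] is interpreted as
log10 of molar concentration (−4.16 ≈ 69 μM), recorded here as the
package's convention. Both fits are exactly scale-equivariant
(concentration units cancel), which the suite asserts to 1e-9.

Radioligand normalization: specific = total − mean(nonspecific wells);
percentages are of the mean zero-competitor specific binding. Negative
specific counts are floored at zero with a warning; if there is no
specific binding anywhere the percentages are all zero rather than an
error. Kinetic sensorgram modelling, Cheng–Prusoff conversion and
Scatchard analysis are out of scope.

## Synthetic data: what it emulates and what it does not

The generators are first-class, tested code; their defaults define the
validation conditions.

**Traces/movies** (`MovieConfig`): 250 frames at 10 Hz (acquisitions of
200–300 frames), PSF σ = 1.3 px rendered as a 2-D Gaussian, 600 photons
per fluorophore per frame, 200 photons background per pixel, Gaussian
read noise SD 10 counts, Poisson shot noise — together giving per-trace
step SNR ≈ 5, comparable to published single-GFP traces. Bleach times
are exponential (rate 0.2 s⁻¹, the physical default for constant
illumination; the distribution is a package choice); fluorophores
surviving the movie yield incomplete traces that exercise the rejection
logic (ground truth records them with sentinel frame `n_frames`). GFP
blinking and immature (dark) GFP are off by default — counting assumes
every subunit fluoresces — but both exist behind config flags
(`blink_off_rate`, `p_dark`) for sensitivity studies. EMCCD excess noise
and camera gain are not modelled (unidentifiable from published
acquisition settings and unnecessary to stress the detector); neither
are drift, stage jitter, or spot overlap. Spot density, photon budget
and bit depth beyond "14-bit" are package choices, not published values.

**Force curves** (`ForceConfig`): 0.06 N/m cantilever, 1.0 × 10⁴ pN/s
loading rate; specific ruptures Gaussian (mean 49.5 pN, SD 10 pN —
control-condition scale) at separations 20–45 nm with a 3 pN/nm loading
slope; nonspecific adhesion confined to within 5 nm of contact (the
specific/nonspecific split at 10 nm therefore has a well-defined
synthetic target); 3 pN Gaussian noise plus a random linear baseline
drift. Single loading rate only — Bell–Evans dynamic force spectroscopy
is out of scope, as is cantilever calibration and any vendor binary
format.

**Binding series** (`BindingSimConfig`): the steady-state default is the
two-fold dilution series 1.9–62.5 μM with true K_D 15.9 μM; competition
uses half-decade molar doses spanning ~0.3–4000 μM around logIC50
−4.16. Full kinetic sensorgrams are not simulated — steady-state values
only.

Passing on these data shows the estimators recover known truth under
the stated noise model; it does not certify performance under real-data
pathologies the generators omit (drift, blinking, heterogeneous
background, multiple simultaneous bonds).

Determinism contract: every generator takes a mandatory seed (or an
explicitly spawned generator); same seed + same config is bit-identical.
The workflow derives per-stage streams from the single top-level seed
via `SeedSequence` spawning.

## Validation problem sizes

The end-to-end suite uses: 500 simulated traces for the
step-search-vs-oracle comparison; 200 seeded runs × 200-spot movies
(180×180 px, 200 frames) per dimer fraction (0.10, 0.30) for
confidence-interval coverage; 200 seeded runs of 3 experiments × 200
curves per condition for the AFM effect signature (probabilities 0.217
vs 0.099 at equal ~49.4 pN force means must yield a significant
one-sided exact probability test and a non-significant force test);
1000 noisy replicates for K_D calibration; and a 10⁻⁴-resolution grid
oracle over logIC50 ∈ [−7, −1]. These sizes give Monte-Carlo error
comfortably below the asserted margins while keeping the default test
run fast.

## Known limitations

- Step counting reports raw dimer fractions; no correction for
  non-fluorescent GFP or pre-bleached subunits is applied (matching the
  raw-percentage convention of the motivating experiments). An optional
  correction would multiply the apparent dimer odds by 1/(1−p_dark) and
  is left to the caller via the generator's `p_dark` for sensitivity
  analysis rather than asserted on real data.
- Near-coincident bleaching (two fluorophores within ~2 frames) is
  fundamentally unresolvable by step counting and slightly depresses
  dimer estimates; at the default bleach rate this is a ≲4% relative
  effect, inside the binomial CI width at 200 spots.
- Whether "binding probability" should count any rupture or only
  specific ruptures is a definitional choice; this package counts
  specific events only, and supports a "blocked" control condition for
  empirical validation of specificity.
- The exact Mann–Whitney two-sided p uses the |U − mean| criterion;
  with heavy ties other exact two-sided definitions can differ.
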