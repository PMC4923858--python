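# smolbind

Single-molecule and binding-assay analysis for quantifying ligand–receptor
engagement, built around three experimental readouts and their matched
synthetic-data generators:

- **TIRFM photobleaching-step stoichiometry** — detect diffraction-limited
  spots of a GFP-tagged membrane receptor, extract background-corrected
  intensity traces, count discrete bleaching steps by exact penalized
  change-point fitting, and tally monomer/dimer/trimer percentages per
  condition (one step ⇒ one fluorophore). The two-step fraction is the
  *dimer percentage*, the readout of ligand-induced receptor dimerization.
- **AFM single-molecule force spectroscopy** — parse force–distance
  curves (F = k·d), correct baselines, detect specific rupture events on
  the retract, fit the rupture-force histogram with a single Gaussian
  (the peak is the binding force), and estimate the *binding
  probability* (fraction of curves with a specific rupture) per
  condition with exact nonparametric comparisons.
- **Equilibrium binding fits** — steady-state single-site affinity
  R(C) = R_max·C/(K_D + C) from concentration–response series, and
  one-site competition B(c) = 100/(1 + 10^(log₁₀c − logIC₅₀)) from
  % specific radioligand binding, with the total-minus-nonspecific
  normalization.

Every analysis stage can be exercised end-to-end on simulated data with
known ground truth (`smolbind.simulate`): movies of bleaching spots
under Poisson shot noise, retract curves with sawtooth ruptures and
nonspecific adhesion, and noisy binding isotherms. Exact small-sample
tests (enumeration Mann–Whitney U; Kruskal–Wallis with Dunn's post-hoc)
live in `smolbind.stats`. See `docs/methods.md` for models, defaults and
assumptions.

## Worked example

Simulate a movie of 120 receptor spots at a true dimer fraction of 30%,
then run the full counting pipeline on it:

```python
from smolbind import (MovieConfig, simulate_tirfm_movie, detect_spots,
                      extract_trace, StepModel, classify_stoichiometry,
                      tally_stoichiometry, dimer_confidence_interval)

cfg = MovieConfig(seed=7, n_spots=120, image_size=(180, 180), n_frames=200,
                  fraction_monomer=0.70, fraction_dimer=0.30, fraction_trimer=0.0)
stack, truth = simulate_tirfm_movie(cfg)

classes = []
for spot in detect_spots(stack):
    trace = extract_trace(stack, spot, cfg.frame_interval)
    classes.append(classify_stoichiometry(StepModel(trace).fit()))

tally = tally_stoichiometry(classes, condition="TGF-b1")
print(tally.summary())
lo, hi = dimer_confidence_interval(tally)
print(f"dimer 95% CI: {lo:.1f}-{hi:.1f}%  (true fraction: 30%)")
```

```
TGF-b1: 105 counted spots (13 rejected) -> 77.1% monomer, 22.9% dimer, 0.0% trimer
dimer 95% CI: 15.2-32.1%  (true fraction: 30%)
```

Of 118 detected spots, 13 were rejected (incomplete bleaching, upward
steps, or too dim) and the remaining 105 counted; the estimated dimer
percentage is 22.9% with an exact binomial CI that covers the simulated
truth — single movies of ~100 counted spots carry several points of
binomial uncertainty, which is why conditions are compared across
replicate cells.

Fitting a steady-state affinity series (two-fold dilutions, 1.9–62.5 μM,
true K_D = 15.9 μM, 1.5 RU noise):

```python
from smolbind import BindingSimConfig, simulate_binding_series, SingleSiteBindingModel

series = simulate_binding_series(
    BindingSimConfig(seed=11, true_KD=15.9, Rmax=100.0, noise_sd=1.5))
print(SingleSiteBindingModel.from_series(series).fit().summary())
```

```
Single-site steady-state binding fit
------------------------------------
n obs:       6
KD:          16.74 uM  (SE 0.81)
Rmax:        100.5  (SE 1.91)
RSS:         3.826
converged:   True
```

## Command line

Batch runs are driven by a YAML config through the `smolbind` CLI:

```sh
smolbind simulate --config sim.yaml --seed 3 --out out/
smolbind tirfm    --config tirfm.yaml
smolbind afm      --config afm.yaml
smolbind bind     --config bind.yaml
```

Each run validates the config strictly (unknown keys rejected), derives
all randomness from the single seed, and writes CSV tables plus a
`report.json` carrying results, warnings, the package version and a
config hash. Exit codes: 0 ok, 1 user error, 2 internal error.

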