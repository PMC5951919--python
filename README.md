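# smkinetics

Single-molecule fluorescence kinetics of riboswitch–tRNA binding: trace
simulation, quality control, two-state idealization, censored dwell-time
kinetics, FRET/distance analysis, spot colocalization and Hill binding
curves.

## The problem

T-box riboswitches are mRNA leader elements in Gram-positive bacteria
that read the aminoacylation state of a tRNA and decide, during
transcription, whether to terminate. Prism-TIRF single-molecule
experiments on the *B. subtilis glyQS* T-box measure this interaction
directly: a surface-immobilized, Cy3-labelled riboswitch is visited by
Cy5-labelled tRNA from solution, producing intensity traces whose
bound/unbound dwell times encode the association and dissociation rate
constants, and smFRET trajectories whose apparent efficiency reports
inter-fluorophore distance.

This package implements the full analysis chain for such experiments —
and, because raw microscope data for this system are not deposited, a
synthetic-data module that generates every input with the statistical
structure the analysis assumes (two-state Markov binding with static
molecule-to-molecule heterogeneity, camera noise, single-step
photobleaching, multi-state FRET, exponential spot loss, Hill-shaped
titrations). Every stage is therefore testable against exact generator
truth.

## The models

* **Binding kinetics.** Per molecule, a continuous-time two-state Markov
  chain: unbound → bound at `kon·c` (s⁻¹), bound → unbound at a
  per-molecule-class `koff` (static heterogeneity: fast / medium /
  ultra-stable / inactive classes). Idealized dwell times are fitted with
  1–2-component exponential survival models by right-censored maximum
  likelihood (least squares on the empirical survival is kept as the
  classical alternative), with a dead-time-renormalized likelihood for the
  100 ms frame interval. Rates follow `koff = 1/τ_bound`,
  `kon = 1/(τ_unbound·c)`, `K_d = koff/kon`.
* **Idealization.** Two-state segmental k-means: iterated Viterbi
  segmentation under Gaussian emissions with re-estimation of class
  levels, widths and transition probabilities from the segmentation.
* **FRET.** `E = I_A/(I_A+I_D)` (background-corrected, apparent);
  ensemble histograms of the first 50 frames per trace; sum-of-Gaussian
  fits; distances via the Förster relation `E = 1/(1+(R/R₀)⁶)` with
  `R₀ = 54 Å` for Cy3–Cy5.
* **Ultra-stable complexes.** Colocalized-spot survival over 20-minute
  time-lapses fit with `f(t) = A₀·exp(−t/τ)`; `koff_slow = 1/τ`.
* **Titrations.** Hill curves `f = plateau·cⁿ/(K_dⁿ+cⁿ)`, `n = 1` for
  non-cooperative binding.

Five condition parameter sets (Stem-I fragment, riboswitch core, ΔDTM
variant, glycyl-charged tRNA, and the aa-tRNA:EF-Tu:GTP ternary complex)
ship in `smkinetics.conditions` and drive end-to-end runs.

## Worked example

```python
import smkinetics as sk

# Distance of the Stem-I:tRNA FRET peak (E = 0.28, R0 = 54 Å)
sk.fret_to_distance(0.28)          # 63.2 (Å)

# Recover a dissociation rate constant from simulated bound dwells
d = sk.discretize_durations(sk.simulate_dwells([(0.24, 1.0)], 1500, seed=101), 0.1)
fit = sk.fit_exponential_survival(d, n_components=1, n_bootstrap=200, seed=0)
fit.rates[0], fit.rate_se[0]       # (0.2375, 0.007)  -> tau_bound = 4.21 s

# Equilibrium constant from the measured rates
sk.kd_from_rates(0.24, 0.79e6) * 1e9   # 304.0 (nM)
```

The first number is the donor–acceptor distance implied by the mean FRET
efficiency of the Stem-I:tRNA complex; the second shows the survival
fitter recovering the generating `koff = 0.24 s⁻¹` from 1500 discretized
dwells with a bootstrap standard error; the third combines `koff` and
`kon` into a ~300 nM dissociation constant.

The same stages are scriptable from a shell:

```sh
smkin pipeline run --condition stem1 --seed 3 --n-molecules 30 --n-frames 3000
# condition: stem1  (hash f81523d9e56a4380)
# kept traces: 17/30
# kon = 8.29e+05 /M/s
# koff = 0.209 /s  (weight 1.00)
# Kd (fast) = 253 nM
```

(a deliberately small run — 30 molecules, 5-minute traces — so the rate
estimates carry visible sampling error; `smkin --help` lists the
simulate/qc/idealize/kinetics/fret/hill subcommands).

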