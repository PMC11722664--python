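# gripalpha

Neural mass modeling of the motor-cortex alpha rhythm under static grip
force.

When a person holds a sustained grip, the average power of the alpha
rhythm (8–12 Hz) recorded over the contralateral motor cortex (electrode
C3) rises with the grip-force level. `gripalpha` implements the full
computational pipeline for studying this effect with a single-column
Jansen neural mass model: it simulates the model, cleans and spectrally
analyzes single-channel EEG, tests the grip-level effect statistically,
and fits the model's synaptic parameters so that simulated alpha power
matches measured alpha power — turning the EEG observation into a
statement about synaptic connectivity and gain.  It is written for
researchers in computational neuroscience and motor neurophysiology who
want a tested, scriptable version of this analysis.

## The model

A cortical column is lumped into three populations — pyramidal cells,
excitatory interneurons, inhibitory interneurons.  Average membrane
potential v is converted to average firing rate by the sigmoid

    S(v) = 2·e0 / (1 + exp(r·(v0 − v)))

and firing rate is converted back to postsynaptic potential by the
synaptic impulse responses

    he(t) = Ge·ωe·t·exp(−ωe·t),    hi(t) = Gi·ωi·t·exp(−ωi·t),   t ≥ 0.

Writing each synaptic kinetic as a second-order ODE and wiring the
populations in the canonical single-column arrangement gives a
6-dimensional system

    y0'' = Ge·ωe·S(y1 − y2) − 2ωe·y0' − ωe²·y0
    y1'' = Ge·ωe·(p(t) + C2·S(C1·y0)) − 2ωe·y1' − ωe²·y1
    y2'' = Gi·ωi·C4·S(C3·y0) − 2ωi·y2' − ωi²·y2

with connectivities C1 = J, C2 = 0.8·J, C3 = C4 = 0.25·J and Gaussian
drive p(t) (mean 220 s⁻¹, SD 22 s⁻¹).  The EEG-like output is y1 − y2,
the net membrane potential of the pyramidal population.  At the standard
parameters (Ge = 3.25 mV, Gi = 22 mV, 1/ωe = 10.8 ms, 1/ωi = 20 ms,
J = 135) the output oscillates at ~10 Hz.  Integration is classical RK4
at 1000 Hz.

Alpha power is the integral of the Welch (smoothed-periodogram) power
spectral density over 8–12 Hz.  The grip-force link is made by fitting:
(J, Ge, Gi) are adjusted synchronously along the ray
(135, 3.25, 22) + k·(0.1, 0.001, 0.01) until simulated alpha power
matches a measured value; higher grip force maps to larger fitted
parameters.

Because the original recordings are not distributable, the package ships
a synthetic-study generator (11 subjects × 3 grip levels × 10 trials of
a 15-s hold) whose alpha source is the model itself at a known ray index
per grip level, plus realistic nuisances (1/f background, baseline
drift, 50 Hz mains, high-amplitude artifacts).  Every stage of the
pipeline is therefore testable against exact ground truth.

## Worked example

```python
import gripalpha as ga

# 1. the model oscillates in the alpha band at the typical parameters
params = ga.ModelParameters.typical_alpha()
sig = ga.simulate(params, ga.NoiseSpec(mean=220, std=22, seed=1),
                  ga.SimulationConfig(duration=30, burn_in=2))
psd = ga.welch_psd(sig.samples, ga.WelchConfig())
ga.peak_frequency(psd, 1, 45)        # -> 10.0   (Hz)
ga.band_power(psd, 8, 12).power      # -> 5.77   (mV², alpha average power)

# 2. a synthetic grip-force study, preprocessed and summarized
spec = ga.GeneratorSpec(n_subjects=4, trials_per_level=4, master_seed=0)
study = ga.generate_study(spec, compute_expected=False)
table = ga.summarize_powers(study.recordings)
print(ga.report_text(table))
```

```
Alpha band (8-12 Hz) average power by grip level

  20% MVC: mean power 6.218
  40% MVC: mean power 7.657
  60% MVC: mean power 9.299

One-way ANOVA: F(2, 9) = 125.812, p = 2.643e-07 (significant)

Tukey HSD pairwise contrasts:
  20% vs 40%: diff = +1.439, p = 0.0001084 *
  20% vs 60%: diff = +3.081, p = 1.88e-07 *
  40% vs 60%: diff = +1.642, p = 3.803e-05 *
```

Alpha power rises with grip level and the 60% vs 20% contrast is
significant.  Fitting the model to each (subject, level) cell recovers
parameters that increase with grip force:

```python
fits = ga.fit_study(table, evaluator=ga.RayPowerEvaluator(seeds=range(10)))
fits.groupby("grip_level")[["J", "Ge", "Gi"]].median()
#                  J      Ge      Gi
# grip_level
# 20          135.45  3.2545  22.045
# 40          136.90  3.2690  22.190
# 60          138.50  3.2850  22.350
```

A command-line interface exposes the same stages
(`gripalpha simulate|psd|analyze|sweep|fit|report|synth`); see
`gripalpha --help`.

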