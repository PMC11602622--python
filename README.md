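# ortune

Analysis pipeline for odorant-receptor tuning experiments: calcium-imaging
signal processing, tuning-breadth statistics, dose-response fitting, spectrum
clustering, the accompanying hypothesis tests, and spike-rate summaries for
single-sensillum recordings — together with a synthetic-data generator that
produces every input with known ground truth, so the whole chain is testable
without any raw recordings.

It is aimed at insect olfaction labs doing receptor deorphanization screens:
recordings of odor-evoked calcium responses (single-wavelength GCaMP in
*Drosophila* antennae, or ratiometric Fura-2 in the honeybee antennal lobe)
are reduced to response amplitudes, receptor × odorant tuning matrices,
EC₅₀/Hill estimates and receptor-similarity dendrograms.

## The signal chain

Single-wavelength ("fly") recordings, 100 frames at 5 Hz with a 1 s odor
stimulus at frames 15–20:

1. ΔF/F₀ = (F − F₀)/F₀, with F₀ the mean over frames 10–14 (pre-stimulus);
2. photobleaching correction by framewise subtraction of a stimulus-free
   (blank) recording's ΔF/F₀;
3. response amplitude = mean ΔF/F₀ over frames 17–31.

Ratiometric Fura-2 ("bee") recordings at 340/380 nm excitation:

1. R = F340/F380 per pixel and frame; ΔR/R = (R − R₀)/R₀ with R₀ the mean
   over frames 10–14;
2. width-3 median filter along x, y and t (three separable passes);
3. subtraction of a fitted logarithmic decay a + b·ln(t + 1), with the
   interval from stimulus onset until 5 s after onset excluded from the fit;
4. response amplitude = mean(frames 17–19) − mean(frames 9–11).

## Statistics

* **Lifetime sparseness** of a response spectrum r₁..rₙ (negatives clamped
  to 0):

  S = (1 − (Σᵢ rᵢ/n)² / Σᵢ rᵢ²/n) / (1 − 1/n),  S ∈ [0, 1]

  S = 0 for a uniform responder, S = 1 for a single-stimulus specialist.
* **Dose–response**: four-parameter logistic
  y(d) = bottom + (top − bottom)/(1 + (EC₅₀/d)^h) fitted by bounded least
  squares on log dose; solvent (0 μg) replicates anchor the bottom
  asymptote. Pooled and per-animal fitting modes.
* **Hypothesis tests** implemented from the rank / sums-of-squares formulas:
  Friedman + Dunn (vs control), repeated-measures ANOVA with
  Greenhouse–Geisser correction + Dunnett many-to-one, Kruskal–Wallis +
  Dunn pairwise; exact permutation p-values for small tables.
* **Clustering**: UPGMA (average linkage) on Euclidean distances between
  normalized mean spectra; Newick export and heatmap rendering.

## Worked example

```python
import numpy as np
from ortune import SimulationConfig, ROISet, PROTOCOL_PRESETS, bee_pipeline, sparseness
from ortune.synthetic import simulate_ratiometric_stack

config = SimulationConfig(noise_sd=0.0, seed=1)
rois = ROISet.from_rectangles({"MG2": (6, 6, 18, 18), "bg": (30, 6, 45, 20)})
f340, f380, rois, truth = simulate_ratiometric_stack(config, rois, {"MG2": 0.01})
amps = bee_pipeline(f340, f380, rois, PROTOCOL_PRESETS["bee"])
print({name: round(a.percent, 4) for name, a in amps.items()})
print(sparseness([2, 1, 0, 0]).value)
```

prints

```
{'MG2': 1.0, 'bg': 0.0}
0.7333333333333334
```

The planted 1% ΔR/R amplitude in the MG2 region is recovered exactly by the
full ratio → median-filter → bleach-correction chain (the shared bleach
profile cancels in the excitation ratio), the background region reads zero,
and the graded spectrum [2, 1, 0, 0] has sparseness 11/15.

The same stages are available from the shell:

```bash
ortune simulate --kind stack --noise-sd 0 --out /tmp/demo
ortune extract /tmp/demo_F340.tif /tmp/demo_rois.json --out /tmp/traces.csv
ortune tuning panel.csv --out /tmp/tuning
ortune dose doses.csv --out /tmp/fits.csv
```

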