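# sanmap

Contrast-agent-free detection of the sinoatrial node (SAN) from quantitative
MRI relaxation-time maps, as a tested, reusable Python pipeline.

The SAN — the heart's primary pacemaker — is an ellipsoidal, strongly
fibrotic structure (2–3 mm thick, 10–20 mm long) at the junction of the
superior vena cava and the right atrium, lateral to the crista terminalis.
Its high collagen content (~74% in swine) prolongs rotating-frame relaxation
times relative to the surrounding working myocardium, which makes the node
visible in T_RAFF2 (relaxation along a fictitious field in the second
rotating frame) and T1ρ maps without gadolinium. This package implements the
complete analysis around that idea for ex vivo swine-heart-style data:

* **phantom** — a digital SAN-in-myocardium phantom: four tissue classes
  (signal-free perfluoropolyether background, myocardium, SAN, epicardial
  fibrotic layer), per-contrast weighted-image series under 7 T and 3 T
  acquisition protocols, Rician (magnitude-MRI) noise, and matched synthetic
  trichrome histology whose blue channel encodes fibrosis.
* **relaxometry** — pixel-wise two-parameter fits
  `S(t) = S0 · exp(−t/T)` for RAFF2 / T1ρ / T2,
  `S0 · |1 − 2 exp(−TI/T1)|` (magnitude inversion recovery) or
  `S0 · (1 − exp(−TI/T1))` (saturation recovery) for T1, the magnetization
  transfer ratio `MTR = 100 · (S0 − S_MT)/S0`, and B0/B1 field-map QC
  (±100 Hz, ±10%).
* **segmentation** — multi-Otsu thresholding (N = 3 thresholds → background,
  myocardium, SAN, epicardial layer) by exhaustive between-class-variance
  maximization, blue-channel histology analysis at 200 µm, the relative SAN
  threshold rule (≈20% above the mean myocardium T_RAFF2, 15% for T1ρ), and
  2D/3D SAN mask extraction with largest-component retention.
* **quantify** — regional statistics; the contrast metrics
  `RRTD = 2(T_SAN − T_myo)/(T_SAN + T_myo)` and
  `MTC = 2(MTR_myo − MTR_SAN)/(MTR_SAN + MTR_myo)`; Pearson correlation and
  Bland–Altman bias / 95% limits of agreement between MRI- and
  histology-derived SAN areas; independent t-tests and one-way ANOVA with
  Benjamini–Hochberg correction.
* **I/O and CLI** — NIfTI maps and series with JSON sidecars, TIFF
  histology, CSV tables, a YAML-validated pipeline configuration and a
  `sanmap` command with `simulate / fit / segment / quantify / run`
  subcommands.

## Worked example

```python
from sanmap import rrtd, raff2_pulse_duration
from sanmap.config import PipelineConfig
from sanmap.pipeline import run_pipeline

# contrast metric from the published 7 T cohort-mean T1rho times
print(rrtd(60.0, 43.0).value)            # 0.3301  -> prints as 0.33
print(raff2_pulse_duration(1250.0, 2))   # 2.26 ms RAFF2 pulse pair

# simulate and analyze a 7-heart cohort at 7 T, SNR 50
summary = run_pipeline(PipelineConfig(n_hearts=7, seed=0), write=False)
```

The run simulates seven hearts (per-heart tissue-parameter and SAN-geometry
variation), fits all five contrasts pixel-by-pixel, segments each map and
the matched histology, and prints regional means ± SD with the
SAN/myocardium contrast per method:

```
RAFF2  SAN   125.0 +/-  15.3   myo    93.2 +/-  7.2   RRTD 0.29 +/- 0.08
T1RHO  SAN    58.5 +/-   6.5   myo    43.5 +/-  4.6   RRTD 0.29 +/- 0.06
T2     SAN    43.3 +/-   6.3   myo    30.8 +/-  8.3   RRTD 0.36 +/- 0.15
T1_IR  SAN  1297.4 +/-  90.0   myo  1143.9 +/- 72.1   RRTD 0.13 +/- 0.04
MT     SAN    35.3 +/-   3.4   myo    46.1 +/-  7.1   MTC  0.26 +/- 0.09
RAFF2 SAN-area agreement vs histology: r^2 = 0.976,
bias = -0.58 mm^2, LOA = (-1.30, 0.15)
```

The rotating-frame contrasts (RAFF2, T1ρ) separate the SAN from myocardium
most reliably, MTR runs the opposite direction (the fibrotic node has the
*lower* MTR), T1 gives the weakest contrast — the behavior the method is
designed to exploit. The same pipeline is available from the shell:

```sh
sanmap run --config config.yaml --out results_dir
```

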