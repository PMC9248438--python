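# hypoximap

Quantitative-MRI detection of tumor hypoxia: an analysis pipeline
linking **IVIM** (intravoxel incoherent motion) diffusion parameters
and **R2\*** relaxometry to grid-wise **HIF-1α** immunohistochemistry
scores in a glioma model, with a digital rat-head phantom so that the
entire analysis is runnable and testable without any animal data.

It is written for imaging scientists who want to (a) prototype or
validate IVIM/R2\*-vs-histology analyses on synthetic ground truth, or
(b) run the same grid-wise co-registration and statistics on their own
NIfTI/CSV data.

## The models

Diffusion-weighted signal follows the biexponential IVIM model

    S(b)/S(0) = (1 − f)·exp(−b·D) + f·exp(−b·D*)

with tissue diffusion coefficient `D`, pseudo-diffusion coefficient
`D* ≥ D` (capillary microcirculation), perfusion fraction `f ∈ [0,1]`,
and perfusion `f·D*`.  Gradient-echo signal decays as
`S(TE) = S0·exp(−TE·R2*)` with `R2* = 1/T2*`.

Histology slices are scored on a shared 1 mm² grid: each ROI's HIF-1α
score is (percent positive cells) × (mean intensity category 0–3),
range 0–300, with scores above 150 marking high expression.  ROIs
must be purely tumor or purely normal tissue, contain no air, and
carry less than 25% vessel/necrosis/calcification; tumor ROIs whose
center lies within 1 mm of the tumor edge are peripheral, the rest
central.  Group comparisons use the Mann–Whitney U test (exact by
enumeration when tractable), correlations report Spearman's ρ
(headline) and Pearson's r with a simple linear regression.

## Worked example

Fit one noisy voxel synthesized at the glioma parameter means:

```python
import numpy as np
import hypoximap as hm

b = np.array(hm.B_VALUES)                      # 0 ... 2000 s/mm^2
signal = hm.ivim_signal(b, d=419.50e-6, dstar=2850.23e-6, f=0.5109)
noisy = hm.add_rician_noise(signal[None, :], sigma=0.01,
                            rng=np.random.default_rng(0))
fit = hm.fit_ivim_full(noisy, b)
print(f"D  = {fit.d[0]*1e6:7.2f} x1e-6 mm^2/s")
print(f"D* = {fit.dstar[0]*1e6:7.2f} x1e-6 mm^2/s")
print(f"f  = {fit.f[0]*100:7.2f} %")
print(f"perfusion = {fit.perfusion[0]*1e6:7.2f} x1e-6 mm^2/s")
```

```
D  =  386.93 x1e-6 mm^2/s
D* = 2478.64 x1e-6 mm^2/s
f  =   56.21 %
perfusion = 1393.22 x1e-6 mm^2/s
```

The fitted values scatter around the generating ones (419.5, 2850.2,
51.1%): at this parameter scale the two exponentials are only weakly
separable, so single-voxel D and f estimates are noisy even at high
SNR — which is exactly why the pipeline averages parameters over 1 mm²
ROIs before correlating them with histology (see `docs/methods.md`).

A complete synthetic study — 6 phantom animals, slice selection, IVIM
and R2\* fitting, ROI grid, HIF scoring and the statistics report —
runs from the command line:

```bash
hypoximap run-all --out study/ --seed 0
```

and writes `study/roi_table.csv` (one row per grid cell),
`study/report.json` / `report.md` (tumor-vs-normal,
central-vs-peripheral and high-vs-low-HIF comparisons plus
correlations), `correlation_scatter.csv`, and a provenance
`manifest.json`.  On the default configuration with seed 0 the report
shows ~260 tumor and ~160 matched contralateral normal ROIs, a tumor
HIF score far above normal tissue (≈123 vs ≈16, p < 0.001), higher
HIF in the tumor core than the rim, and ROI-level Spearman
correlations of the HIF score of ≈ +0.40 with R2\* (p < 10⁻¹⁰) and
≈ −0.28 with D* (p < 10⁻⁵).

Individual stages are exposed as `simulate`, `fit-ivim`, `fit-r2star`,
`grid`, `score-hif` and `stats`, all reading/writing NIfTI (with JSON
sidecars for b-values and echo times) and CSV, so real acquisitions
can replace the simulator stage unchanged.

## Layout

```
src/hypoximap/
  protocol.py   acquisition constants (b-values, echo times, geometry)
  config.py     pydantic configs incl. tissue parameter tables
  phantom.py    digital phantom: labels, truth maps, MR signal, cells
  ivim.py       segmented + full biexponential fitting
  r2star.py     weighted log-linear + profiled NLS relaxometry
  hif.py        cell-level categories and ROI scoring
  roi.py        1 mm² grid, inclusion rules, region classes, pairing
  stats.py      Mann-Whitney / Spearman / Pearson / OLS and the report
  pipeline.py   end-to-end orchestration and provenance
  cli.py        `hypoximap` command-line interface
```
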