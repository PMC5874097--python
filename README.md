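# dcequant

Quantitative dynamic contrast-enhanced (DCE) MRI pharmacokinetics for
tumor-subregion analysis, built around the question of whether the fitted
perfusion parameters are real imaging biomarkers of microvasculature: in an
ablated hypervascular liver-tumor model, does the volume transfer constant
K<sup>trans</sup> track the microvessel density (MVD) counted on CD31-stained
histology in each tumor subregion?

The package is for imaging scientists who need a tested, reproducible
implementation of the full quantification chain —

1. **T1 mapping** — per-voxel precontrast T1 (T10) and equilibrium signal S0
   from variable-flip-angle (VFA) spoiled gradient-echo images,
   S = S0 · sin α · (1 − E1)/(1 − E1 · cos α) with E1 = exp(−TR/T1), solved by
   the linearised S/sin α vs S/tan α regression;
2. **Concentration** — C(t) = (1/T1(t) − 1/T10)/r1 after inverting the SPGR
   equation frame by frame on the dynamic series (r1 = 4.39 s⁻¹mM⁻¹);
3. **Arterial input** — blood-pool voxels ranked by a bolus-shape score
   (peak height / (time-to-peak × FWHM)), averaged, and converted to plasma
   by Cp = Cb/(1 − Hct) with Hct = 0.45;
4. **Kinetic modelling** — the extended Kety (extended Tofts) model fitted
   voxel-wise by bounded nonlinear least squares:

   C<sub>t</sub>(t) = v<sub>p</sub>·C<sub>p</sub>(t−t₀) +
   K<sup>trans</sup>·C<sub>p</sub>(t−t₀) ⊗ exp(−(K<sup>trans</sup>/v<sub>e</sub>)·t)

   giving K<sup>trans</sup> (1/min), v<sub>e</sub>, v<sub>p</sub> (fractions)
   and the bolus delay t₀ (s) per voxel;
5. **Subregion summaries** — labels for the completely necrotic area (CNA),
   partially necrotic area (PNA) and viable tumor area (VTA) resampled to the
   DCE grid, each region summarised by a 3×3 (9-voxel) in-plane neighborhood
   mean placed at the region's median-Ktrans window;
6. **Statistics** — Wilcoxon signed-rank contrasts between subregions and
   Pearson correlations of each parameter with MVD, including the combined
   PNA+VTA per-tumor-mean analysis.

A digital phantom (`dcequant.phantom`) renders the whole study synthetically —
ground-truth parameter maps over concentric tumor subregions, a gamma-variate
bolus, VFA and 4D dynamic image series, and MVD counts linearly linked to
regional K<sup>trans</sup> — so every stage is testable end to end without any
scan data.  A 15-tumor per-subregion summary table (K<sup>trans</sup>,
v<sub>e</sub>, v<sub>p</sub>, MVD for CNA/PNA/VTA) ships as a CSV fixture.

## Worked example

Correlating the bundled cohort's fitted parameters with its MVD counts:

```python
from dcequant.io import load_table1_fixture
from dcequant.stats import run_full_analysis

corr, paired, report = run_full_analysis(load_table1_fixture())
print(report)
```

prints (abridged):

```
Parameter-MVD correlations (Pearson, two-sided):
  CNA      ktrans r=+0.0075 p=0.9788 n=15
  PNA      ktrans r=+0.8124 p=0.0002 n=15 *
  VTA      ktrans r=+0.5743 p=0.0252 n=15 *
  PNA+VTA  ktrans r=+0.8470 p=0.0001 n=15 *
Subregion contrasts (Wilcoxon signed-rank, two-sided):
  ktrans CNA vs PNA: W=0.0 p=0.00006 (n=15)
  ktrans PNA vs VTA: W=0.0 p=0.00012 (n=14)
  vp     CNA vs VTA: W=17.5 p=0.01263 (n=15)
  ve     PNA vs VTA: W=27.0 p=0.36963 (n=12)
```

Reading it: K<sup>trans</sup> is uncorrelated with MVD in complete necrosis
(r ≈ 0), strongly correlated in the partially necrotic transition zone
(r = 0.81) and viable rim (r = 0.57), and strongest when each tumor is
summarised by the mean of its two perfused regions (r = 0.85) — while
K<sup>trans</sup> separates all three subregions (p < 0.001) and
v<sub>e</sub> separates none.

The synthetic pipeline end to end, from the shell:

```sh
dcequant simulate --seed 1 --out study/
dcequant run --data study/ --out study_results/
```

which writes parameter maps (NIfTI), the extracted AIF (CSV), per-tumor
subregion summaries and the same statistics grid for the simulated cohort.

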