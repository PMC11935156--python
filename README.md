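# libsquant

Quantitative elemental imaging for laser-induced breakdown spectroscopy
(LIBS). The package turns a hyperspectral LIBS cube — one single-shot atomic
emission spectrum per pixel, e.g. over 249–333 nm at ≈0.15 nm resolution —
into calibrated element concentrations for biological tissue sections
embedded in paraffin, with a quantified uncertainty budget.

It is aimed at analytical spectroscopists and toxicologists who map
exogenous metals (the canonical case: titanium from inhaled TiO₂
nanoparticles in lung tissue) and need a *decision-free*, reproducible
number per specimen rather than a qualitative image.

## The method

1. **Element maps.** For each emission line (P I 253.56 nm as the tissue
   proxy, Ti II 323.65 nm as the analyte) the per-pixel background-free line
   intensity *I* is extracted: a linear baseline is least-squares fitted on
   flanking windows and the residual is summed over the fit window (a
   Gaussian-profile fit is available as an alternative).
2. **Noise thresholds.** Detector noise is sampled in a line-free window
   (320–322 nm) through the same extraction operator and summarized by a
   Gaussian fit to its histogram, giving x̄_c and σ. Then

   LoD = x̄_c + 3σ  (tissue threshold),  LoQ = x̄_c + 10σ  (signal threshold).

3. **Tissue mask.** Pixels whose P intensity exceeds the LoD are tissue;
   their count times the squared pixel pitch is the tissue area A_tissue
   (cm²). Paraffin, which is P-free, is excluded.
4. **Svalue.** The metric is the area-normalized aggregate of significant
   analyte intensities:

   Svalue = Σ I(Ti ≥ LoQ, in mask) / A_tissue   [counts/cm²]

5. **Calibration and inverse prediction.** Svalue is regressed on reference
   concentrations (μg g⁻¹, e.g. ICP-MS on matched specimens) by OLS with a
   70% mean-response confidence band; method detection limits follow
   LoD = 3.3 σ_fit/m and LoQ = 10 σ_fit/m, and unknown specimens are
   quantified by inverting the line.
6. **Uncertainty budget.** Four relative components — lateral-resolution
   Monte-Carlo SD (σ_Δx, from random k×k-block pixel subsampling), tissue
   threshold sensitivity (σ_surf, 3σ → 2σ/4σ), signal threshold sensitivity
   (σ_ΣI, 10σ ± 3σ) and the calibration band at the median concentration
   (σ_CC) — combine in quadrature to σ_tot.

Because no public LIBS cubes of embedded tissue exist, the package ships a
first-class phantom generator (`libsquant.phantom`) producing cubes with a
porous tissue geometry, sparse log-normal "particle" signals whose mean
scales with a nominal concentration, and Gaussian detector noise — with the
full ground truth, so every stage is testable.

## Worked example

```python
from libsquant import PhantomSpec, generate_cube, analyze_cube, RunConfig, total_uncertainty

spec = PhantomSpec(ny=64, nx=64, step_um=20.0, concentration=2.0, seed=5)
cube, truth = generate_cube(spec)          # 64×64 px, 561 spectral samples
a = analyze_cube(cube, RunConfig())        # extract → noise → mask → Svalue
print(f"noise: mean={a.noise.mean:.3f} sigma={a.noise.sigma:.3f} counts")
print(f"thresholds: LoD={a.thresholds.lod:.1f}  LoQ={a.thresholds.loq:.1f} counts")
print(f"tissue: {a.mask.n_tissue} px = {a.mask.area_cm2:.5f} cm^2")
print(f"Svalue(Ti) = {a.svalue.svalue:.4g} counts/cm^2")
print(f"sigma_surf = {a.sigma_surf_pct:.2f}%  sigma_sumI = {a.sigma_sum_pct:.2f}%")
print(f"sigma_tot = {total_uncertainty(1.8, 6.0, 0.89, 2.2).as_report()['sigma_tot_pct']}%")
```

prints

```
noise: mean=-0.120 sigma=14.244 counts
thresholds: LoD=42.6  LoQ=142.3 counts
tissue: 1720 px = 0.00688 cm^2
Svalue(Ti) = 9.54e+06 counts/cm^2
sigma_surf = 1.63%  sigma_sumI = 0.76%
sigma_tot = 6.7%
```

Reading: after baseline subtraction the extracted noise is centred near 0
with σ ≈ 14 counts, so the tissue threshold is ≈43 counts and the signal
threshold ≈142 counts. 1720 of 4096 pixels are tissue (0.0069 cm²); 92 of
them carry Ti above the LoQ, and their summed intensity per tissue area is
the Svalue. The two threshold sensitivities are small (1.6% and 0.8%); the
last line combines four example components in quadrature into a 6.7% total.

The same workflow is available from the shell:

```
libsquant simulate --seed 5 --concentration 2 --out work/
libsquant svalue   --cube work/phantom.h5 --sensitivity
libsquant degrade  --cube work/phantom.h5 --factors 2,3,4,5,10 --reps 100 --seed 1
libsquant run      --config run.yaml      # end-to-end, incl. calibration CSV
```

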