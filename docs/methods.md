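# Methods

## Signal model and extraction

A LIBS acquisition is modelled as `y(p, λ) = b(λ) + Σ_j A_j(p)·g_j(λ) + ε`,
one spectrum per pixel p: a smooth background b, Gaussian emission-line
profiles g_j of instrumental width (FWHM ≈ 0.15 nm, comparable to the
sampling step), and detector noise ε that is well approximated as i.i.d.
Gaussian per spectral sample within a narrow window.

The extracted intensity of a line is the background-free *summed* count over
a fit window of half-width 0.3 nm around the line center (≈ 2× the
instrumental resolution). The baseline is a straight line least-squares
fitted on two flanking windows 0.35–0.95 nm from the center. The flank
offsets guarantee at least four samples per flank at 0.15 nm sampling while
staying clear of the line core; both windows are configurable per line. An
alternative `fit` method fits amplitude, center (constrained to ±0.05 nm of
the nominal line) and width of a Gaussian plus linear baseline over the
window union; its result is the fitted profile summed over the sample grid
of the fit window, which keeps the two methods on one scale. With line
width ≈ sampling step, a continuous-area convention would differ from the
summed scale by a grid-alignment aliasing term of up to ~6%; all internal
scales (extraction, noise, phantom injection) therefore use discrete sums.

Negative background-subtracted intensities are clipped to zero in element
maps — the Svalue aggregates non-negative abundances and noise handling is
delegated to the thresholds — but noise characterization uses the
*unclipped* operator, since clipping halves and skews the noise
distribution.

Extraction is a fixed linear functional of the spectrum (for the summation
method), `I = wᵀy`, which has two consequences used throughout: the noise of
I under i.i.d. sample noise σ is exactly σ·‖w‖ (`propagated_sum_noise_sd`),
and intensity is linear in peak amplitude and invariant to constant offsets.

## Noise, LoD and LoQ

Noise is sampled in a line-free window (default 320–322 nm, just short of
the Ti 323.65 nm line) by applying the same extraction operator to a
pseudo-line centred in the window, so noise and signal share units. The
default estimator is a least-squares Gaussian fit to the Freedman–Diaconis
histogram of these samples; it discounts the right tail that weak analyte
emission leaks into the window, which a moment estimator would absorb into
σ. Moment and median/MAD estimators are available, and the pipeline falls
back to moments if the histogram fit cannot proceed (e.g. zero spread).

Thresholds follow the analytical-chemistry convention
`LoD = x̄_c + 3σ`, `LoQ = x̄_c + 10σ`; the multipliers are configurable.
By default the pipeline runs two passes: a provisional all-pixel noise fit
gives a provisional tissue mask, then the fit is repeated on tissue spectra
only. Whether tissue-only selection should precede or follow masking is
genuinely open; two-pass is the self-consistent choice and a single-pass
mode remains available (`noise.two_pass: false`).

## Tissue mask and Svalue

A pixel is tissue when its P intensity strictly exceeds the LoD (a value
exactly at the threshold is noise-indistinguishable). No morphological
cleanup is applied by default — lung parenchyma is genuinely porous and
hole-filling would inflate A_tissue — an optional binary closing exists for
other tissue types. A_tissue = (pixel count)·(step in cm)².

Svalue sums analyte intensities that are both inside the mask and ≥ LoQ
(equality passes: only values *below* the cutoff are excluded), divided by
A_tissue. Out-of-mask pixels never contribute. Svalue is only comparable
between acquisitions at equal sampling density; cross-resolution comparison
goes through the extrapolated normalization of the resolution study below.

Threshold sensitivities are reported as relative deviations: σ_surf is the
maximum tissue-area deviation when the LoD multiplier moves from 3 to 2 or
4 (a conservative single-number summary — the maximum rather than the mean
of the two deviations); σ_ΣI is the larger relative Svalue change when the
LoQ multiplier moves from 10 to 7 or 13, with the full 0–20σ curve exported.

## Calibration

Svalue is regressed on reference concentration by unweighted OLS with a free
intercept (statsmodels); whether the line passes through the origin is
*checked* against the intercept's confidence interval at the model level,
not imposed. A 1/x-weighted option exists behind config. σ_fit is the
residual standard error √(SS_res/(n−2)) — the ICH-style reading of "standard
error of the fit"; the intercept-SE alternative is noted as ambiguous and
not used. Method limits are LoD = 3.3 σ_fit/m and LoQ = 10 σ_fit/m, so
LoQ/LoD = 10/3.3 identically.

The confidence band is the *mean-response* band at the configured level
(default 0.70): half-width `t_{(1+L)/2, n−2}·σ_fit·√(1/n + (x−x̄)²/S_xx)`.
A prediction band would be wider; the mean-response reading matches a band
meant to qualify the calibration model itself. σ_CC is the relative band
half-width at the median design concentration, in percent. Inverse
prediction is x̂ = (y−b)/m with first-order propagation of the (b, m)
covariance; estimates below the method LoQ/LoD are flagged, negative
inverses report as 0 with a flag.

A small-n caveat established during validation: a case-resampling bootstrap
percentile band (n = 12, 10⁴ resamples) reproduces the analytic band within
≈15% of the half-width, running slightly narrow at the design edges — the
expected small-sample behaviour of the percentile bootstrap, not a defect of
the analytic form.

## Resolution degradation

Coarser lateral resolution is emulated by drawing one pixel uniformly at
random from every k×k block (the same position in the P and analyte maps:
both values originate from one laser shot), giving a ⌈ny/k⌉×⌈nx/k⌉ map at
k-fold step; partial edge blocks draw over their actual extent. Thresholds
are *not* re-estimated (degradation simulates fewer shots, not a different
instrument state); the mask is re-derived on the degraded P map. The
degraded Svalue is extrapolated to the full sampled area — mean above-LoQ
intensity per sampled tissue pixel divided by the *native* pixel area —
because raw summed counts drop as 1/k² and would not be comparable across
step sizes. Uniform block sampling makes this extrapolation exactly unbiased
when the mask is stable (proved by enumeration on small grids in the tests).
Replicate r of factor k uses the deterministic substream (seed, k, r);
replicates with an empty degraded mask are dropped with a warning and more
than 20% drops at a factor is an error. σ_Δx is the replicate SD relative to
the full-resolution reference at the operating step (default: the factor
closest to 50 μm).

## Error budget

σ_tot = √(σ_Δx² + σ_surf² + σ_ΣI² + σ_CC²), components in percent, treated
as independent (no covariance model). No intermediate rounding; the report
rounds the total to one decimal.

## Phantom generator

The phantom emulates the features the pipeline is sensitive to:

- **Geometry**: a porous mask (union of 3 random ellipses minus 8 random
  holes) on the pixel grid, or `tissue_model="full"` for homogeneous-field
  studies.
- **Tissue proxy**: a constant P-line intensity on tissue pixels,
  parameterized as a signal-to-noise ratio of the *extracted* intensity
  (default SNR 10) via the exact noise propagation above, so phantoms stay
  meaningful when windows or noise levels change.
- **Analyte**: sparse particles — each tissue pixel hits with probability
  0.05 and draws a log-normal intensity (shape 0.8) whose mean is
  proportional to the nominal concentration (30 noise-SD units per μg g⁻¹)
  — reproducing the isolated-pixel character of particulate metal maps. The
  expected Svalue is linear in concentration by construction. A homogeneous
  Gaussian alternative (`particle_model="gaussian"`) covers diffuse
  analytes.
- **Noise**: additive i.i.d. Gaussian counts per spectral sample (σ = 5 on a
  flat baseline of 100), homoscedastic across wavelength. Right-tail
  contamination is injected explicitly in tests rather than modelled.
- Default grid 64×64 at 20 μm with the 249–333 nm / 0.15 nm axis
  (561 samples). Larger grids are used where a study needs them (200×200 for
  the resolution statistics, 96×96 for the exposure series) — desk-scale
  stand-ins for megapixel acquisitions.

Peaks are injected with profiles normalized by their *discrete* sum, so the
stored truth is exact on the extracted scale. `generate_maps` is a map-level
shortcut that draws extracted intensities directly (Gaussian with the
propagated SD, clipped at 0) without materializing spectra.

What the phantom does **not** emulate — and hence what passing tests do not
show about real data: matrix effects and line self-absorption, wavelength-
dependent or per-pixel (heteroscedastic) noise, spectral interferents under
the analyte line, ablation-crater/step-size interaction, spatial correlation
of particle deposition, and paraffin autofluorescence-like backgrounds.
Real-data validation still requires reference measurements (e.g. ICP-MS).

For calibration statistics, `simulate_calibration_points` bypasses imaging
and draws Svalues directly around a known line. Its default noise is
homoscedastic with SD equal to the relative level (default 6.7%) times the
mean design response, and responses are deliberately *not* truncated at
zero: under this model the t-based 70% slope CI is exactly calibrated, which
the coverage study verifies (truncation, or per-point relative noise fitted
by unweighted OLS, would make 70% nominal coverage unattainable — measured
at ≈66% and ≈43% respectively). A per-point `relative` mode exists for
generating realistic positive-valued tables.

## Numerical choices and degenerate inputs

- Baseline fits use the pseudo-inverse of the shared design matrix,
  vectorized across pixels; an all-equal wavelength axis raises a linear-
  algebra error (and is rejected earlier by cube validation).
- The Gaussian line fit falls back to the summation estimate if it fails to
  converge; the histogram noise fit falls back to moments in the pipeline.
- Empty tissue mask: a warning and a valid zero-area mask at masking time;
  a hard error at Svalue time (the metric is undefined).
- Ties at thresholds: strict `>` for the tissue LoD, inclusive `≥` for the
  signal LoQ (see above).
- All randomness flows through `numpy.random.Generator` seeded from explicit
  integers; replicated studies use `SeedSequence`-derived substreams, so
  identical configs reproduce bitwise-identical outputs.

## Default problem sizes

Unit tests run on grids ≤ 120×120; validation studies use 200×200 (resolution
statistics, 100 replicates × 5 factors), 96×96 × 12 cubes (exposure-series
linearity), 2000 replicates (slope-CI coverage), and 32 000 spectra for noise
characterization — the same order as a real acquisition's noise dataset.
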