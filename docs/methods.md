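# Methods

## Exposure model

The model is a deliberately minimal one-compartment description of menthol
inhalation during EC vaping. A session of `n` puffs consumes
`n × m_puff` mg of liquid; dividing by the liquid density ρ (mg/mL) gives the
consumed volume, multiplying by the liquid's menthol content (mg/mL) gives the
inhaled menthol mass, and a lung retention fraction gives the mass retained.
A transfer fraction of that mass divided by plasma volume gives the blood
concentration; molar conversion uses M = 156.27 g/mol (C₁₀H₂₀O). The chain is
linear in every factor, which the property tests assert by random rescaling.

Defaults and their provenance:

| parameter | default | rationale |
|---|---|---|
| retention fraction | 0.96 | measured lung retention in menthol-EC users |
| transfer fraction | 0.50 | assumed lung→blood transfer |
| plasma volume | 2650 mL | week-2-of-pregnancy plasma volume |
| liquid density ρ | 1000 mg/mL | see note below |
| per-puff liquid mass | 3.342 mg | calibrated, see below |
| half-life | 1.0 h | literature bound is "< 1 h"; 1 h is the conservative (slowest-elimination) choice |
| molar mass | 156.27 g/mol | L-menthol |

Two parameters of the published worked example are not stated explicitly, so
the package pins them by calibration: with ρ = 1000 mg/mL,
`calibrate_liquid_mass_per_puff` inverts the linear chain against the
published single-puff result (11.62 nM in maternal blood for one puff of a
3 mg/mL liquid) and yields m_puff = 3.3417 mg — a plausible per-puff liquid
consumption. Only the ratio m_puff/ρ is identified by that calibration;
choosing ρ in mg/mL keeps the mass/density quotient in mL as the retained-mass
formula requires, and both values are ordinary config parameters. The
acceptance script re-derives m_puff at run time rather than hard-coding it.

Repeated vaping is simulated as instantaneous boluses (a session is short
relative to the half-life) with first-order elimination between sessions.
The implementation superposes exact exponential decays,
`C(t) = Σ_s D·2^(−(t−s)/t½)`, so grid values match the closed-form geometric
series `D(1−r^k)/(1−r)`, `r = 2^(−Δt/t½)`, to numerical precision at any time
step. Out of scope by design: multi-compartment kinetics, placental transfer,
protein binding, metabolites, inter-individual variability.

## Dose–response

Viability plates are normalized to percent of the untreated control (control
mean ≡ 100). The inhibition model is the four-parameter variable-slope Hill
curve, decreasing in concentration for h > 0. Fitting is plain least squares
(`scipy.optimize.curve_fit`) on log₁₀-concentration with the IC50
parameterized as log₁₀(IC50): initial top/bottom from the max/min mean
response, initial IC50 at the concentration nearest the half-response, slope
seeds (1, 0.5, 3) tried in order with the first convergent fit kept, so the
procedure is deterministic. Parameters are unconstrained. Flat plates and
non-convergent fits return `converged=False` rather than raising. A fit
whose best solution has negative slope is re-expressed with top/bottom
swapped (the two parameterizations are the same curve).

ICp uses the closed form `(p/(100−p))^(1/h) × IC50`; at p = 50 it returns the
IC50 bit-exactly. The LOAEL is the lowest tested concentration whose Dunnett-
adjusted p-value against the untreated control falls below α (default 0.05).
Because Dunnett controls the family-wise error at α, about α of null plates
still produce a spurious LOAEL; the calibration tests quantify this.

Recovery under the default plate design (8 half-log concentrations spanning
1 µM–3.2 mM around a programmed IC50 of 100 µM, slope 1.5, triplicates, 5
percentage-point noise) places the fitted IC50 within 15% of truth in ≈ 91%
of seeded plates (first 100 seeds benchmarked in the tests).

## Calcium transients

The baseline is the mean RFU before the addition time (nominally a 20 s
window); peak height is the maximum of the baseline-subtracted post-addition
signal after a centered 3-sample moving average, measured over a 4-minute
window. A trace "returns to baseline" when the mean of the final 10% of the
window is below 20% of the peak; flat or non-responding traces trivially
return. Percent block compares peak heights (not AUC, which is provided as an
optional metric) between agonist-only and agonist-plus-inhibitor conditions
and is clipped to [0, 100] with a warning outside that range.

The synthetic transient is a gamma-shaped pulse
`(t/t_peak)^k · exp(k(1 − t/t_peak))` with k = 4 and t_peak = 60 s: it peaks
at one minute and decays below 0.2% of peak by four minutes, matching the
assay's observed kinetics. A difference of two exponentials cannot satisfy
both constraints at once — pairs of time constants late enough to peak near
60 s leave more than 20% of the peak at 240 s — which is why the gamma shape
was chosen. The sustained mode (`1 − exp(−(t−t₀)/τ)` plateau) emulates the
highest-concentration behaviour where fluorescence keeps rising over the
recording. Noise is Gaussian and scales with each condition's effective
amplitude (constant SNR, shot-noise-like); a zero-amplitude condition is
exactly flat. Taking the maximum of a noisy smoothed trace biases single-well
peaks upward by ~2–3% at SNR 20 with 4 s sampling; condition means over
replicate wells (the quantity the assay reports) recover programmed
amplitudes within 5% and programmed block fractions within 2 percentage
points. Not modelled: photobleaching drift, oscillations, ratiometric
calibration to absolute calcium concentration.

## Colony features

Masks are integer label images (0 = background); features are computed on the
label's exact pixel set. Area is the pixel count (optionally × pixel-size²
for µm²). The brightness/total-area death proxy counts within-colony phase
pixels above an adaptive threshold, colony mean + 2 SD (the field's tools do
not publish their threshold; an absolute threshold is available via
argument). The axis ratio is √(λ₁/λ₂) of the second central moments of the
pixel coordinates — the moment-equivalent ellipse, identical to the standard
regionprops definition (cross-checked in the tests) — and is invariant to
translation and, within ~3% discretization error for axes ≥ 20 px, to
rotation. Coordinates are (row, column) pixel centers.

Tracking links labels frame-to-frame by nearest centroid under a gate of 25%
of the colony's equivalent diameter per 4 h frame; conflicts are resolved
globally by ascending distance with ties to the lower label id. Colonies that
leave the field are truncated and flagged, and only full-length tracks enter
the feature table — mirroring the practice of analysing only colonies that
remain in the field for the whole incubation. Motility features are the
centroid path length (total distance) and net start-to-end separation (total
displacement); displacement ≤ distance always. Growth series are normalized
to the first frame. Segmentation itself is out of scope: masks are inputs.

## Statistics layer

One-way analyses report the omnibus F and either Dunnett many-to-one
(multivariate-t critical points via `scipy.stats.dunnett`) or Tukey HSD
all-pairs comparisons. Two-way (time × treatment) designs are fitted by OLS
with both factors and their interaction for the omnibus table; post-hoc,
treatments are compared with the control within each time slice by Dunnett
and the resulting p-values are Šidák-corrected across the time slices, so the
family-wise error over the entire time × treatment grid is held at α. The
"first significant time" per group — the earliest time surviving both
corrections — is the package's analogue of marking the first time point at
which a treated group departs from control. Without the across-time
correction a 12-frame movie would produce a spurious onset in roughly half of
all null experiments; with it, null experiments stay clean ≈ 95% of the time
while a 4-SD effect (n = 9 per cell) is located within one frame of its
programmed onset in ≈ 97% of runs. Time is treated as a fixed factor with
independent colonies; repeated-measures covariance modelling is out of scope.

Assumption checking applies log(y) iff normality or variance homogeneity
fails at α = 0.05. Normality is tested once on the pooled within-group
centered residuals (the quantity ANOVA assumes normal) rather than per group:
per-group testing inflates the null trigger rate with the number of groups
(~15% for three groups), whereas the residual test keeps the no-transform
rate at ≈ 94% on null data while flagging skewed, heteroscedastic data in
> 95% of runs (benchmarked at 27 observations per group, e.g. 9 colonies ×
3 experiments). Homogeneity uses median-centered Levene. Per-group
Shapiro-Wilk p-values are retained in the report as diagnostics.

## Synthetic-data benchmarks: problem sizes

The simulation benchmarks in the tests use: 100 plates for IC50 recovery;
1000 null datasets (4 groups, n = 5) for Dunnett FWER; 1000 null plates for
LOAEL calibration; 200 null and 100–200 effect movies' worth of grouped data
(2 groups × 12 times × n = 9) for the two-way onset analysis; 500 runs for
the transform calibration; 500 random walks of 30–40 steps for motility.
These sizes give Monte-Carlo standard errors comfortably below the margins
being asserted. Image-based tests use 256–512 px frames and colonies of
20–25 px initial radius, where rasterization error in area and axis ratio is
below the stated 2–3% tolerances.

## What passing tests do and do not show

The generators reproduce the statistical structure each stage assumes —
variable-slope inhibition with i.i.d. noise, smooth transients with constant
SNR, clean elliptical masks with known correspondence, Gaussian or log-normal
group errors. They do not emulate plate-position effects, segmentation
errors, colony merging/splitting, photobleaching, or correlated
within-colony time series. Passing recovery benchmarks therefore validates
the estimators and their calibration under the stated models, not robustness
to those real-data pathologies.
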