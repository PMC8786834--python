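# Methods

## The two-site exchange model and k_PL estimation

Hyperpolarised [1-¹³C]pyruvate delivered to tissue exchanges its ¹³C label
with the endogenous lactate pool through LDH. Over the ~80 s of a dynamic
acquisition the label transfer is well described by a unidirectional
"inputless" model driven by the *measured* pyruvate signal:

    dL/dt = k_PL · P(t) − ρ_eff · L(t),    L(0) = 0.

`k_PL` (s⁻¹) is the apparent pyruvate→lactate exchange rate constant;
`ρ_eff` (s⁻¹) lumps every loss channel of the lactate signal — T₁
relaxation and RF consumption of longitudinal magnetisation — into one
effective decay. Lumping is the standard identifiable choice for
constant-flip dynamic acquisitions: with P(t) measured, back-exchange,
perfusion and pyruvate T₁ need not be modelled separately, and the pair
(k_PL, ρ_eff) is identifiable from a single curve pair.

`solve_two_site` evaluates the convolution solution
L(t) = k_PL ∫₀ᵗ P(τ)·e^{−ρ_eff(t−τ)} dτ by trapezoidal accumulation of the
exact exponential kernel, so the discrete recursion is exact for the decay
part and second-order accurate in the pyruvate interpolation.

### Frequency-domain linear least squares

Fourier transforming the ODE gives iω·L̂(ω) = k_PL·P̂(ω) − ρ_eff·L̂(ω); with
DFTs on the uniform frame grid, real and imaginary parts at every
frequency stacked as separate equations, this is an ordinary linear
least-squares problem in (k_PL, ρ_eff) — no iteration, no starting values.

Two numerical points matter:

- **Truncation bias.** The DFT derivative identity treats the window as
  periodic, but a clinical acquisition ends while lactate is still
  decaying. Applied naively to a 20-frame/4-s window this biases k_PL by
  18–26% (measured across k_PL 0.003–0.018 s⁻¹, ρ_eff 0.02–0.05 s⁻¹).
  Both curves are therefore apodised by e^{−αt} before the transform
  (default α = 0.05 s⁻¹): the weighted signals satisfy the same ODE with
  ρ_eff + α in place of ρ_eff, so k_PL is untouched and the known α is
  subtracted from the decay estimate afterwards. With α = 0.05 s⁻¹ the
  worst-case noiseless bias over the same grid drops to 2.1%, dominated by
  plain discretisation. α is exposed as a parameter; values in
  0.03–0.08 s⁻¹ perform equivalently.
- **Noise attenuation.** Because L̂ appears among the regressors, additive
  noise in the lactate curve attenuates the estimate (classical
  errors-in-variables). At peak-pyruvate SNR ≈ 30 (lactate peak SNR ≈ 8)
  the median k_PL is biased low by roughly 60%; frequency truncation does
  not repair this. The package therefore ships the nonlinear time-domain
  fit (`fit_kpl_time_domain`, bounded least squares of the forward model,
  noise only in the dependent variable) as the independent cross-check and
  the estimator of choice at low lactate SNR: its median error at the same
  noise level is < 1%. The attenuation behaviour is asserted in the test
  suite rather than hidden.

Negative least-squares solutions are clipped to zero (rates are physical)
with a diagnostic flag. An identically zero lactate curve returns
k_PL = ρ_eff = 0; an identically zero pyruvate curve is an unidentifiable
fit and raises.

Per-tumour "mean k_PL" is the mean of a voxelwise k_PL map over the ROI
(`fit_kpl_map`), not a fit of ROI-averaged curves; the ROI-mean-curve
variant can be obtained by fitting the averaged pair directly.

## Simulation layer

The phantom places disc lesions with prescribed (k_PL, extra loss) on a
uniform perfusion background; only lesions produce lactate. The arterial
input is a gamma-variate (arrival 8 s, shape 2.5, scale 4 s — a plausible
human bolus; nothing downstream depends on these defaults). Pyruvate is
the bolus passed through the lumped pyruvate decay 1/T₁p + r_RF, lactate
the two-site response; T₁ defaults are 30 s (pyruvate) and 25 s (lactate),
typical in vivo values at 3 T. RF consumption is modelled as the
continuous-rate equivalent of multiplying longitudinal magnetisation by
cos(θ)^E between frames (E excitations per frame at flip θ, per metabolite
under a spectral-spatial schedule, single nominal flip under an IDEAL-like
schedule). Because the excitation count per frame of a multi-echo readout
is sequence-dependent, E is configurable rather than fixed.

Kinetics are integrated on an internal 0.05 s grid and sampled at frame
times, so forward-model accuracy (checked against dense RK4 integration to
1e-4 relative) is not limited by the 4 s frame interval. Noise is always
added in the complex domain and the magnitude taken — never Gaussian on
magnitudes — so the Rayleigh background statistics assumed by the √2 SNR
correction hold exactly. Voxels are independent: no point-spread blurring,
coil combination or spectral decomposition is simulated.

## SNR and ADC quantification

SNR follows (mean SI_ROI − mean SI_noise)/(√2·SD SI_noise) with the sample
SD (n−1) over a background-only ROI; the per-voxel SNR map uses the same
noise statistics everywhere, so the ROI mean of the map equals the SNR of
the ROI mean signal. Total-carbon maps sum all metabolite channels over
all frames (sum first, mask later, integrating the full bolus passage) and
estimate noise from the final-frame pyruvate image, by which time the
hyperpolarised signal has decayed; a diagnostic warns if the synthetic
ground truth violates that assumption. The noise ROI in synthetic frames
is a fixed rectangular corner recorded in the series sidecar. ROI transfer
between the 128×128 display grid and the 32×32 native grid is
nearest-neighbour with pixel-centre alignment and half-open indices.

ADC is ordinary least squares on log S = log S₀ − b·ADC over
b = 150–1400 s/mm² (the separate b = 2000 acquisition excluded by
default), matching deterministic scanner-style maps; Rician noise at 2% of
S₀ leaves the median ADC within 5% of truth (asserted over 500
replicates).

## Synthetic histology and cohort

Per-cell copy counts are negative binomial (dispersion 4 by default;
RNAscope counts are overdispersed, Poisson is the dispersion→∞ limit);
staining categories are multinomial: positive with the configured
probability, then weak/moderate/strong in ratio 0.5/0.3/0.2. All
generative parameters live in `hpmri/data/effects.yaml`. The defaults are
calibrated only to reproduce the qualitative biology — epithelial-dominant
MCT1, stromal-dominant MCT4 with an epithelial shift in aggressive
disease, LDHA up / LDHB down / PDHA1 down / nuclear HIF-1α up with
Gleason pattern — never any measured group mean.

The cohort generator couples lesions through a Gaussian copula: a latent
aggressiveness score per lesion (blended with the %GP4 rank, weight 0.5)
drives ground-truth k_PL across 0.003–0.018 s⁻¹, and one correlation knob
r loads lactate SNR, epithelial cell count, combined epithelial LDH and
the epithelium-to-stroma MCT4 ratio on the shared factor; r = 0 gives
independent metrics, r→1 co-monotone ones. Imaging metrics are either
drawn from the latent model directly (fast, used for statistical
calibration at hundreds of seeds) or produced by the full chain —
simulation, Rician noise, SNR mapping, voxelwise k_PL fitting, ADC
fitting — per lesion.

What the generator does *not* emulate: spatial autocorrelation of cells,
partial-volume mixing of compartments, slide-level staining batch effects,
and the attenuation of fitted k_PL at very low lactate SNR is inherited
from the estimator rather than tuned. Passing tests therefore demonstrate
correctness of the quantification chain and the calibration of its
statistics under the stated generative assumptions, not fidelity to any
particular patient data.

## Statistics

Spearman correlations use midranks for ties with the t-approximation for
p; censored "<5" %GP4 entries map to 2.5 — any value strictly inside
(0, 5) yields identical ranks (tied with each other, above exact 0, below
exact 5), so the choice is rank-safe. Pure Gleason 3+3 lesions carry
%GP4 = 0 exactly. Mann-Whitney comparisons are two-sided, exact for
combined n ≤ 12 without ties and tie-corrected normal otherwise; an
all-identical pooled sample returns p = 1 with a flag. The %GP4 grouping
of ISUP 2–3 lesions places the boundary value 10 in the low group, which
reproduces the 6-lesion low stratum of the reference cohort. No
multiplicity correction is applied anywhere by default (every comparison
is exploratory); Benjamini-Hochberg is available opt-in. The RSEM
transform defaults to log2(value+1); the literal log2(value−1) variant is
retained but masks values ≤ 1 to NaN and records the choice in metadata.

The reference cohort ships with an `excluded_from_correlation` flag on one
lesion whose %GP4 assessment was uncertain; default correlation runs keep
all 13 lesions for imaging-only pairs and drop flagged lesions for %GP4
pairs, and the reproduction report evaluates both conventions side by
side.

## Problem sizes

The test suite and acceptance script use: 20-frame/4-s single-lesion
phantoms for kinetics; 100 seeds for the SNR null; 200 noisy replicates
for estimator bias; 500 enumeration cases for the rank-sum oracle; 500
seeds for null rejection rates and 100 seeds for direction detection, at
group sizes of 30 gland ROIs per Gleason pattern and 197/250/50
expression samples; and a 13-lesion fully simulated cohort. These sizes
were chosen so every Monte-Carlo bound is stable at its stated tolerance
while the whole suite runs on a laptop in a few minutes.
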