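# hpmri

Quantification pipeline for hyperpolarised [1-¹³C]pyruvate MRI of prostate
cancer, with a synthetic-data layer so that every stage runs at desk scale.

Dissolution-DNP hyperpolarisation boosts the ¹³C signal of injected
[1-¹³C]pyruvate by four to five orders of magnitude, enough to image its
enzymatic conversion to [1-¹³C]lactate in vivo during the ~1 minute the
polarisation survives. In prostate cancer the lactate signal reflects
tumour-epithelial LDH activity and rises with the proportion of Gleason
pattern 4 — a metabolic window on tumour aggressiveness. This package
implements the full quantification chain such a study needs:

- **`hpmri.simulate`** — dynamic metabolite image series on a 32×32 grid
  (20 frames, 4 s apart, 15°/40° flips) with known ground-truth kinetics,
  a gamma-variate bolus, and Rician (magnitude-of-complex-Gaussian) noise.
- **`hpmri.kinetics`** — the two-site exchange model
  dL/dt = k_PL·P(t) − ρ_eff·L(t), a frequency-domain linear least-squares
  estimator of the apparent exchange rate constant k_PL (s⁻¹), and a
  nonlinear time-domain estimator as an independent cross-check.
- **`hpmri.quantify`** — SNR maps
  SNR = (mean SI_ROI − mean SI_noise) / (√2 · SD SI_noise)
  (the √2 corrects for the narrowed Rayleigh distribution of magnitude
  noise), total-carbon SNR with noise taken from the final-frame pyruvate
  image, time-summed metabolite maps, and log-linear ADC fitting over
  b = 150–1400 s/mm².
- **`hpmri.histo_synth` / `hpmri.histo_metrics`** — synthetic per-cell
  histology tables (epithelial/stromal compartments, MCT1/MCT4/nuclear
  HIF-1α staining categories, negative-binomial LDHA/LDHB/PDHA1 copy
  counts) and the compartmentalised biomarkers computed from them:
  percent-positive per marker, epithelium-to-stroma MCT4 ratio, combined
  epithelial LDH (summed LDHA+LDHB copies), LDHA/LDHB and LDHA/PDHA1
  ratios, and cell counts.
- **`hpmri.cohort_stats`** — tie-aware Spearman correlations (censored
  "<5" %GP4 entries handled by midrank ties), exact and tie-corrected
  Mann-Whitney U tests, %GP4 ≤10 / >10 grouping of ISUP 2–3 lesions, and
  the log2(RSEM+1) transform.
- **`hpmri.io` / `hpmri.cli`** — cohort CSV parsing, NIfTI series I/O,
  round-trippable run configs, and a one-command reproduction run.

A reference cohort of 13 intermediate-risk prostate tumours (per-lesion
%GP4, mean ADC, lactate/pyruvate/total-carbon SNR, mean k_PL) is packaged
as `hpmri/data/reference_cohort.csv` and drives the correlation checks.

## Worked example

```python
>>> import numpy as np, hpmri
>>> sch = hpmri.AcquisitionSchedule()            # 20 frames x 4 s, 32 x 32
>>> lesion = hpmri.Lesion(center=(16, 16), radius=3.0,
...                       params=hpmri.KineticParams(kpl=0.015, rho_eff=0.0))
>>> series = hpmri.simulate_dynamic_series(
...     hpmri.Phantom(shape=sch.matrix, lesions=[lesion]), sch)
>>> pair = hpmri.TimeSeriesPair(series.times,
...                             series.signal[16, 16, :, 0],   # pyruvate
...                             series.signal[16, 16, :, 1])   # lactate
>>> params, diag = hpmri.fit_kpl_frequency_domain(pair)
>>> round(params.kpl, 5)
0.01504
```

The estimator recovers the simulated exchange rate of 0.015 s⁻¹ to 0.3%
on the clinical 20-frame/4-s grid; the residual discrepancy is the
documented discretisation bias of the frequency-domain linearisation.

Correlations on the packaged reference cohort:

```python
>>> cohort = hpmri.reference_cohort()
>>> sub = cohort[cohort.excluded_from_correlation == 0]      # n = 12
>>> round(hpmri.spearman(sub.lactateSNR, sub.meanADC).rs, 2)
-0.7
```

Lactate SNR correlates negatively with mean ADC (a cellularity marker:
denser, more aggressive tumours restrict water diffusion), consistent with
lactate labelling tracking aggressive, glycolytic disease.

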