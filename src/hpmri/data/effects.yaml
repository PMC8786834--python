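# Default generative parameters for the synthetic histology layer.
#
# The defaults encode the qualitative biology of intermediate-risk prostate
# cancer: MCT1 predominantly epithelial, MCT4 predominantly stromal with an
# epithelial shift in aggressive disease, LDHA rising and LDHB falling with
# Gleason pattern, PDHA1 falling and nuclear HIF-1a positivity rising in
# GP5 glands.  Groups are either single Gleason growth patterns (GP3/GP4/
# GP5 gland ROIs) or whole-lesion strata by percent Gleason pattern 4
# (low_gp4: <=10%, high_gp4: >10%).
seed: null
nb_dispersion: 4.0            # negative-binomial size; Poisson as -> inf
staining_split: [0.5, 0.3, 0.2]   # weak / moderate / strong among positives
roi_lognorm_sd: 0.25          # between-ROI jitter of gene means (log scale)

groups:
  GP3:
    epithelial:
      n_cells: 300
      genes: {LDHA: 8.0, LDHB: 6.0, PDHA1: 4.0}
      markers: {MCT1: 0.55, MCT4: 0.20, HIF1A_nuclear: 0.05}
    stromal:
      n_cells: 250
      genes: {LDHA: 3.0, LDHB: 3.0, PDHA1: 2.0}
      markers: {MCT1: 0.12, MCT4: 0.60, HIF1A_nuclear: 0.03}
  GP4:
    epithelial:
      n_cells: 300
      genes: {LDHA: 10.0, LDHB: 5.0, PDHA1: 3.5}
      markers: {MCT1: 0.60, MCT4: 0.30, HIF1A_nuclear: 0.08}
    stromal:
      n_cells: 250
      genes: {LDHA: 3.5, LDHB: 3.0, PDHA1: 2.0}
      markers: {MCT1: 0.15, MCT4: 0.65, HIF1A_nuclear: 0.04}
  GP5:
    epithelial:
      n_cells: 300
      genes: {LDHA: 16.0, LDHB: 3.0, PDHA1: 2.0}
      markers: {MCT1: 0.75, MCT4: 0.55, HIF1A_nuclear: 0.25}
    stromal:
      n_cells: 250
      genes: {LDHA: 4.0, LDHB: 2.5, PDHA1: 1.8}
      markers: {MCT1: 0.30, MCT4: 0.75, HIF1A_nuclear: 0.08}
  low_gp4:
    epithelial:
      n_cells: 300
      genes: {LDHA: 8.0, LDHB: 6.0, PDHA1: 4.0}
      markers: {MCT1: 0.55, MCT4: 0.20, HIF1A_nuclear: 0.05}
    stromal:
      n_cells: 250
      genes: {LDHA: 3.0, LDHB: 3.0, PDHA1: 2.0}
      markers: {MCT1: 0.12, MCT4: 0.60, HIF1A_nuclear: 0.03}
  high_gp4:
    epithelial:
      n_cells: 300
      genes: {LDHA: 14.0, LDHB: 3.5, PDHA1: 2.5}
      markers: {MCT1: 0.65, MCT4: 0.45, HIF1A_nuclear: 0.12}
    stromal:
      n_cells: 250
      genes: {LDHA: 3.8, LDHB: 2.8, PDHA1: 1.9}
      markers: {MCT1: 0.18, MCT4: 0.65, HIF1A_nuclear: 0.05}

expression:
  sigma_log2: 1.0
  base_log2: {SLC16A1: 9.0, SLC16A3: 7.0, LDHA: 11.0, LDHB: 10.0}
  shifts_log2:
    GP3: {SLC16A1: 0.0, SLC16A3: 0.0, LDHA: 0.0, LDHB: 0.0}
    GP4: {SLC16A1: 0.0, SLC16A3: 0.5, LDHA: 0.5, LDHB: -0.5}
    GP5: {SLC16A1: 0.6, SLC16A3: 1.0, LDHA: 0.9, LDHB: -0.9}

cohort:
  kpl_range: [0.003, 0.018]     # s^-1, ground-truth lesion exchange rates
  adc_base: 1150.0              # 1e-6 mm^2/s at lowest aggressiveness
  adc_span: 500.0               # ADC drop from least to most aggressive
  adc_noise_sd: 80.0
  lactate_snr_log_mean: 2.55    # lognormal location of lesion lactate SNR
  lactate_snr_log_sd: 0.45
  latent_cell_scale: 0.30       # loading of the latent factor on cell count
  latent_gene_scale: 0.40       # loading on epithelial LDH means
  latent_mct4_scale: 1.00       # loading on epithelial MCT4 log-odds
  n_epithelial: 200
  n_stromal: 160
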