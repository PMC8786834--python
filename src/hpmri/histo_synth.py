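"""Synthetic per-cell histology tables and cohort generation.

The generator emulates the data structures produced by automated
digital-pathology analysis of IHC and RNAscope slides: per-cell records
with an epithelial/stromal compartment label, ordinal staining categories
for MCT1, MCT4 and nuclear HIF-1a, and per-cell mRNA copy counts for LDHA,
LDHB and PDHA1.  Copy counts are negative binomial (RNAscope counts are
overdispersed; Poisson is the dispersion -> infinity limit) and staining
categories multinomial.

:func:`generate_cohort` builds a joint synthetic cohort: per-lesion
ground-truth exchange rates increase stochastically with a latent
aggressiveness covariate, and a single correlation knob sets the rank
coupling between lactate SNR, epithelial cell count, combined epithelial
LDH and the epithelium-to-stroma MCT4 ratio through a shared-factor
(Gaussian copula) construction.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit
from scipy.stats import rankdata, norm

from . import histo_metrics as hm

__all__ = [
    "EffectConfig",
    "GlandROI",
    "CohortResult",
    "load_effect_config",
    "generate_cell_table",
    "generate_cohort",
    "generate_expression_table",
    "TABLE1_GP4",
]

GROUPS = ("GP3", "GP4", "GP5", "low_gp4", "high_gp4")

#: default %GP4 values of a 13-lesion cohort (2.5 encodes censored "<5")
TABLE1_GP4 = (2.5, 2.5, 10.0, 60.0, 5.0, 0.0, 15.0, 30.0, 20.0, 2.5, 2.5, 50.0, 0.0)
TABLE1_GP4_CENSORED = (1, 1, 0, 0, 0, 0, 0, 0, 0, 1, 1, 0, 0)


@dataclass
class EffectConfig:
    """Generative parameters for the synthetic histology and cohort layers."""

    raw: dict

    def __post_init__(self) -> None:
        for g, spec in self.raw["groups"].items():
            for comp in ("epithelial", "stromal"):
                for p in spec[comp]["markers"].values():
                    if not (0.0 <= p <= 1.0):
                        raise ValueError(f"positivity probability out of [0,1] in {g}/{comp}")
                for m in spec[comp]["genes"].values():
                    if m < 0:
                        raise ValueError(f"negative gene mean in {g}/{comp}")
        split = self.raw["staining_split"]
        if abs(sum(split) - 1.0) > 1e-9 or any(s < 0 for s in split):
            raise ValueError("staining_split must be a probability vector")

    def group(self, label: str) -> dict:
        try:
            return self.raw["groups"][label]
        except KeyError:
            raise ValueError(f"unknown group label {label!r}") from None

    @property
    def dispersion(self) -> float:
        return float(self.raw["nb_dispersion"])

    @property
    def staining_split(self) -> np.ndarray:
        return np.asarray(self.raw["staining_split"], dtype=float)

    @property
    def expression(self) -> dict:
        return self.raw["expression"]

    @property
    def cohort(self) -> dict:
        return self.raw["cohort"]

    @property
    def seed(self):
        return self.raw.get("seed")


@dataclass
class GlandROI:
    """One histology ROI: malignant glands plus adjacent stroma."""

    gleason_pattern: str
    lesion_id: str
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        n_epi = (self.cells["compartment"] == "epithelial").sum()
        n_str = (self.cells["compartment"] == "stromal").sum()
        if n_epi < 1 or n_str < 1:
            raise ValueError("ROI needs at least one epithelial and one stromal cell")


@dataclass
class CohortResult:
    table: pd.DataFrame
    rois: list[GlandROI]
    truth: pd.DataFrame
    series: dict = field(default_factory=dict)


def load_effect_config(path: str | Path | None = None) -> EffectConfig:
    """Load an effect configuration; None loads the packaged defaults."""
    if path is None:
        text = resources.files("hpmri.data").joinpath("effects.yaml").read_text()
    else:
        text = Path(path).read_text()
    return EffectConfig(yaml.safe_load(text))


def _draw_counts(rng: np.random.Generator, mean: float, n: int, dispersion: float) -> np.ndarray:
    if mean <= 0:
        return np.zeros(n, dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def _draw_staining(rng: np.random.Generator, p_pos: float, split: np.ndarray, n: int) -> np.ndarray:
    probs = np.concatenate([[1.0 - p_pos], p_pos * split])
    return rng.choice(np.array(hm.STAIN_LEVELS, dtype=object), size=n, p=probs)


def _compartment_cells(
    rng: np.random.Generator,
    comp_spec: dict,
    compartment: str,
    n: int,
    dispersion: float,
    split: np.ndarray,
    gene_scale: dict[str, float] | None = None,
    marker_shift: dict[str, float] | None = None,
) -> pd.DataFrame:
    cols: dict = {"compartment": np.full(n, compartment, dtype=object)}
    for marker, p in comp_spec["markers"].items():
        if marker_shift and marker in marker_shift:
            p = float(expit(logit(np.clip(p, 1e-6, 1 - 1e-6)) + marker_shift[marker]))
        cols[marker] = _draw_staining(rng, p, split, n)
    for gene, mean in comp_spec["genes"].items():
        scale = gene_scale.get(gene, 1.0) if gene_scale else 1.0
        cols[gene] = _draw_counts(rng, mean * scale, n, dispersion)
    return pd.DataFrame(cols)


def generate_cell_table(
    config: EffectConfig,
    group: str,
    n_cells: int | None = None,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    lesion_id: str = "roi-0",
    gene_scale: dict[str, float] | None = None,
    marker_shift: dict[str, float] | None = None,
    cell_scale: float = 1.0,
) -> GlandROI:
    """Draw one synthetic gland ROI for a named group.

    ``n_cells`` overrides the total cell count (split between compartments
    in the configured proportion); otherwise compartment counts are Poisson
    around the configured means.  ``gene_scale``/``marker_shift``/
    ``cell_scale`` are per-ROI modifiers used by the cohort generator to
    impose latent structure.
    """
    spec = config.group(group)
    if rng is None:
        rng = np.random.default_rng(seed)
    me = spec["epithelial"]["n_cells"] * cell_scale
    ms = spec["stromal"]["n_cells"] * cell_scale
    if n_cells is not None:
        frac = me / (me + ms)
        n_epi = max(1, int(round(n_cells * frac)))
        n_str = max(1, n_cells - n_epi)
    else:
        n_epi = max(1, int(rng.poisson(me)))
        n_str = max(1, int(rng.poisson(ms)))
    split = config.staining_split
    disp = config.dispersion
    epi = _compartment_cells(
        rng, spec["epithelial"], "epithelial", n_epi, disp, split, gene_scale, marker_shift
    )
    stroma = _compartment_cells(rng, spec["stromal"], "stromal", n_str, disp, split)
    cells = pd.concat([epi, stroma], ignore_index=True)
    gp = group if group.startswith("GP") else "GP4"
    return GlandROI(gleason_pattern=gp, lesion_id=lesion_id, cells=cells)


def generate_expression_table(
    config: EffectConfig,
    group_sizes: dict[str, int] | None = None,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """RSEM-like expression values grouped by primary Gleason pattern.

    Per-gene values are log-normal: configured base log2 level plus a group
    shift plus Gaussian scatter.  Default group sizes mirror a large public
    prostatectomy RNA-seq cohort (GP3 n=197, GP4 n=250, GP5 n=50).
    """
    if group_sizes is None:
        group_sizes = {"GP3": 197, "GP4": 250, "GP5": 50}
    if any(n < 2 for n in group_sizes.values()):
        raise ValueError("each group needs at least 2 samples")
    if rng is None:
        rng = np.random.default_rng(seed)
    expr = config.expression
    sigma = float(expr["sigma_log2"])
    frames = []
    for grp, n in group_sizes.items():
        shifts = expr["shifts_log2"][grp]
        cols = {"primary_gp": np.full(n, grp, dtype=object)}
        for gene, base in expr["base_log2"].items():
            log2v = base + shifts[gene] + rng.standard_normal(n) * sigma
            cols[gene] = np.exp2(log2v)
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def _gp4_to_isup(gp4: float) -> tuple[str, int]:
    if gp4 <= 0:
        return "3+3=6", 1
    if gp4 < 50:
        return "3+4=7", 2
    return "4+3=7", 3


def generate_cohort(
    config: EffectConfig,
    n_lesions: int = 13,
    gp4_distribution=None,
    *,
    correlation: float = 0.7,
    gp4_coupling: float = 0.5,
    seed: int | None = None,
    imaging: str = "latent",
    schedule=None,
    noise_sigma: float = 0.5,
) -> CohortResult:
    """Joint synthetic cohort of lesions with imaging and histology metrics.

    Each lesion carries a latent aggressiveness score a_i (coupled to its
    %GP4 rank with weight ``gp4_coupling``).  Ground-truth kPL increases
    stochastically with a_i over the configured range.  The correlation
    knob r couples lactate SNR, epithelial cell count, combined epithelial
    LDH and the epithelium-to-stroma MCT4 ratio: each metric's latent is
    ``r * a_i + sqrt(1 - r^2) * noise``, so r = 0 gives independent metrics
    and r -> 1 co-monotone ones.

    ``imaging="latent"`` draws SNR metrics directly from the latent model
    (fast; used for statistical calibration).  ``imaging="simulate"`` runs
    the full chain per lesion: dynamic-series simulation, Rician noise,
    SNR mapping, voxelwise kPL fitting and DWI ADC fitting.
    """
    if n_lesions < 2:
        raise ValueError("n_lesions must be >= 2")
    if not (0.0 <= correlation <= 1.0):
        raise ValueError("correlation knob must lie in [0, 1]")
    if imaging not in ("latent", "simulate"):
        raise ValueError("imaging must be 'latent' or 'simulate'")
    rng = np.random.default_rng(seed)
    cfg = config.cohort

    if gp4_distribution is None:
        reps = int(np.ceil(n_lesions / len(TABLE1_GP4)))
        gp4 = np.array((TABLE1_GP4 * reps)[:n_lesions], dtype=float)
        censored = np.array((TABLE1_GP4_CENSORED * reps)[:n_lesions], dtype=bool)
    else:
        gp4 = np.asarray(gp4_distribution, dtype=float)
        censored = np.zeros(gp4.size, dtype=bool)
        n_lesions = gp4.size
    if np.unique(gp4).size < 2:
        raise ValueError("degenerate %GP4 distribution")

    # latent aggressiveness: %GP4 normal scores blended with fresh noise
    gp4_score = norm.ppf((rankdata(gp4) - 0.375) / (n_lesions + 0.25))
    a = gp4_coupling * gp4_score + np.sqrt(1 - gp4_coupling**2) * rng.standard_normal(n_lesions)

    r = correlation
    lat = {
        key: r * a + np.sqrt(1 - r**2) * rng.standard_normal(n_lesions)
        for key in ("snr", "cells", "ldh", "mct4")
    }

    k_lo, k_hi = cfg["kpl_range"]
    kpl_latent = 0.8 * a + 0.6 * rng.standard_normal(n_lesions)
    kpl_true = k_lo + (k_hi - k_lo) * norm.cdf(kpl_latent)

    adc_true = (
        cfg["adc_base"]
        - cfg["adc_span"] * norm.cdf(a)
        + rng.standard_normal(n_lesions) * cfg["adc_noise_sd"]
    )

    rows = []
    rois: list[GlandROI] = []
    series_store: dict[str, object] = {}
    for i in range(n_lesions):
        lesion_id = f"lesion-{i + 1:02d}"
        roi = generate_cell_table(
            config,
            "low_gp4",
            rng=rng,
            lesion_id=lesion_id,
            cell_scale=float(np.exp(cfg["latent_cell_scale"] * lat["cells"][i])),
            gene_scale={"LDHA": float(np.exp(cfg["latent_gene_scale"] * lat["ldh"][i]))},
            marker_shift={"MCT4": float(cfg["latent_mct4_scale"] * lat["mct4"][i])},
        )
        rois.append(roi)
        summ = hm.summarise_roi(roi.cells)

        if imaging == "latent":
            lactate_snr = float(
                np.exp(cfg["lactate_snr_log_mean"] + cfg["lactate_snr_log_sd"] * lat["snr"][i])
            )
            pyruvate_snr = float(np.exp(3.4 + 0.4 * rng.standard_normal()))
            total_snr = lactate_snr + pyruvate_snr + float(np.abs(rng.standard_normal()))
            mean_kpl = float(np.clip(kpl_true[i] * np.exp(0.05 * rng.standard_normal()), 0, None))
            mean_adc = float(adc_true[i])
        else:
            lactate_snr, pyruvate_snr, total_snr, mean_kpl, series = _simulate_lesion_imaging(
                rng, kpl_true[i], lat["snr"][i], cfg, schedule, noise_sigma
            )
            series_store[lesion_id] = series
            mean_adc = _simulate_adc(rng, adc_true[i])

        gleason, isup = _gp4_to_isup(gp4[i])
        rows.append(
            {
                "lesion_id": lesion_id,
                "FinalGleason": gleason,
                "ISUP": isup,
                "pctGP4": "<5" if censored[i] else gp4[i],
                "pctGP4_value": gp4[i],
                "pctGP4_censored": bool(censored[i]),
                "meanADC": mean_adc,
                "lactateSNR": lactate_snr,
                "pyruvateSNR": pyruvate_snr,
                "totalCarbonSNR": total_snr,
                "meanKPL": mean_kpl,
                "epithelial_cells": summ.epithelial_cells,
                "stromal_cells": summ.stromal_cells,
                "epi_stroma_count_ratio": summ.epi_stroma_count_ratio,
                "MCT1_epi_pct": summ.percent_positive["MCT1"]["epithelial"],
                "MCT4_epi_pct": summ.percent_positive["MCT4"]["epithelial"],
                "MCT4_stromal_pct": summ.percent_positive["MCT4"]["stromal"],
                "MCT4_epi_stroma_ratio": summ.mct4_epi_stroma_ratio,
                "LDHA_epi_mean": summ.mean_copies["LDHA"]["epithelial"],
                "LDHB_epi_mean": summ.mean_copies["LDHB"]["epithelial"],
                "combined_LDH_total": summ.combined_ldh_total,
                "combined_LDH_per_cell": summ.combined_ldh_per_cell,
                "HIF1A_nuclear_epi_pct": summ.percent_positive["HIF1A_nuclear"]["epithelial"],
            }
        )

    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "lesion_id": table["lesion_id"],
            "kpl_true": kpl_true,
            "adc_true": adc_true,
            "aggressiveness": a,
        }
    )
    return CohortResult(table=table, rois=rois, truth=truth, series=series_store)


def _simulate_lesion_imaging(rng, kpl_true, snr_latent, cfg, schedule, noise_sigma):
    """Full imaging chain for one lesion: simulate, noise, SNR, kPL map."""
    from .kinetics import KineticParams, fit_kpl_map
    from .quantify import compute_snr, sum_time_then_quantify, total_carbon_map
    from .simulate import AcquisitionSchedule, Lesion, Phantom, add_noise, simulate_dynamic_series

    if schedule is None:
        schedule = AcquisitionSchedule()
    amp = float(np.exp(cfg["lactate_snr_log_mean"] + cfg["lactate_snr_log_sd"] * snr_latent))
    lesion = Lesion(
        center=(schedule.matrix[0] // 2, schedule.matrix[1] // 2),
        radius=3.0,
        params=KineticParams(kpl=float(kpl_true), rho_eff=0.0),
        amplitude=amp,
    )
    phantom = Phantom(shape=schedule.matrix, lesions=[lesion], background_amplitude=0.0)
    clean = simulate_dynamic_series(phantom, schedule)
    noisy = add_noise(clean, noise_sigma, seed=int(rng.integers(2**31)))

    roi = lesion.mask(schedule.matrix)
    noise_roi = np.zeros(schedule.matrix, dtype=bool)
    noise_roi[:6, :6] = True  # fixed background-only corner
    summed = sum_time_then_quantify(noisy)
    lac = compute_snr(summed["lactate"], roi, noise_roi).roi_mean_snr
    pyr = compute_snr(summed["pyruvate"], roi, noise_roi).roi_mean_snr
    _, tc_res = total_carbon_map(noisy, noise_roi, roi=roi)
    _, mean_kpl = fit_kpl_map(noisy, roi)
    return lac, pyr, tc_res.roi_mean_snr, mean_kpl, noisy


def _simulate_adc(rng, adc_true, s0: float = 100.0, noise_frac: float = 0.02):
    """Rician-noised diffusion decay fitted log-linearly."""
    from .quantify import DWI_B_VALUES, fit_adc

    clean = s0 * np.exp(-DWI_B_VALUES * max(adc_true, 1.0) * 1e-6)
    sigma = noise_frac * s0
    g1, g2 = rng.standard_normal((2, DWI_B_VALUES.size)) * sigma
    noisy = np.hypot(clean + g1, g2)
    return float(fit_adc(noisy).adc)
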