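"""SNR maps, total-carbon SNR, time-summed signals and ADC fitting.

The metabolite SNR follows the magnitude-image convention

    SNR = (mean(SI_ROI) - mean(SI_noise)) / (sqrt(2) * SD(SI_noise)),

where the noise statistics come from a background-only ROI and the sqrt(2)
corrects for the narrowed Rayleigh distribution of magnitude noise.  The
apparent diffusion coefficient is fitted log-linearly across b-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import DynamicSeries, ROIMask

__all__ = [
    "SNRResult",
    "ADCFit",
    "compute_snr",
    "sum_time_then_quantify",
    "total_carbon_map",
    "fit_adc",
    "resample_mask",
    "DWI_B_VALUES",
]

#: default diffusion weightings (s/mm^2) for the ADC fit; a separate
#: high-b acquisition (b = 2000) is excluded from fitting by default
DWI_B_VALUES = np.array([150.0, 550.0, 750.0, 1000.0, 1400.0])

SQRT2 = np.sqrt(2.0)


@dataclass
class SNRResult:
    snr_map: np.ndarray
    roi_mean_snr: float
    noise_mean: float
    noise_sd: float
    noise_label: str = "noise"


@dataclass
class ADCFit:
    """Log-linear mono-exponential diffusion fit.

    ``adc`` is reported in 10^-6 mm^2/s; ``s0`` is the extrapolated b=0
    signal; ``r_squared`` the coefficient of determination in log space.
    """

    adc: float
    s0: float
    r_squared: float


def _as_mask(roi) -> tuple[np.ndarray, str]:
    if isinstance(roi, ROIMask):
        return roi.mask, roi.label
    return np.asarray(roi, dtype=bool), "roi"


def compute_snr(signal_map: np.ndarray, roi, noise_roi) -> SNRResult:
    """Rayleigh-corrected SNR of a magnitude signal map within an ROI.

    The per-voxel SNR map applies the same noise statistics everywhere;
    ``roi_mean_snr`` is the mean of the map over the ROI (identical, by
    linearity, to the SNR of the ROI-mean signal).
    """
    signal_map = np.asarray(signal_map, dtype=float)
    mask, _ = _as_mask(roi)
    nmask, nlabel = _as_mask(noise_roi)
    if mask.shape != signal_map.shape or nmask.shape != signal_map.shape:
        raise ValueError("ROI shapes must match the signal map")
    if not mask.any() or not nmask.any():
        raise ValueError("ROIs must be non-empty")
    if np.any(mask & nmask):
        raise ValueError("signal ROI and noise ROI overlap")
    noise = signal_map[nmask]
    mu, sd = float(noise.mean()), float(noise.std(ddof=1))
    if sd == 0:
        raise ValueError("noise ROI has zero variance")
    snr_map = (signal_map - mu) / (SQRT2 * sd)
    return SNRResult(
        snr_map=snr_map,
        roi_mean_snr=float(snr_map[mask].mean()),
        noise_mean=mu,
        noise_sd=sd,
        noise_label=nlabel,
    )


def sum_time_then_quantify(series: DynamicSeries) -> dict[str, np.ndarray]:
    """Per-metabolite maps summed over all frames (sum first, mask later).

    Summing the dynamic data over time before any ROI statistics mirrors
    integrating the full bolus passage and minimises noise propagation.
    """
    return {met: series.channel(met).sum(axis=2) for met in series.metabolites}


def total_carbon_map(
    series: DynamicSeries,
    noise_roi,
    roi=None,
) -> tuple[np.ndarray, SNRResult]:
    """Voxelwise total 13C signal (all metabolites, all frames) and its SNR.

    Noise statistics are estimated from the final-frame pyruvate image
    restricted to the noise ROI — by the last frame the hyperpolarised
    signal has decayed and that image is background noise.  If ground-truth
    noiseless signal remains in that frame a diagnostic warning is issued.
    """
    if "pyruvate" not in series.metabolites or series.n_frames < 2:
        raise ValueError("need a pyruvate channel and >= 2 frames")
    summed = sum_time_then_quantify(series)
    total = np.sum([summed[m] for m in series.metabolites], axis=0)

    nmask, nlabel = _as_mask(noise_roi)
    last_pyr = series.channel("pyruvate")[..., -1]
    noise = last_pyr[nmask]
    mu, sd = float(noise.mean()), float(noise.std(ddof=1))
    if sd == 0:
        raise ValueError("noise ROI has zero variance in the final pyruvate frame")
    if series.noise_sigma > 0 and mu > 5.0 * series.noise_sigma:
        warnings.warn("final-frame pyruvate is not signal-free in the noise ROI", stacklevel=2)

    snr_map = (total - mu) / (SQRT2 * sd)
    if roi is not None:
        mask, _ = _as_mask(roi)
        roi_mean = float(snr_map[mask].mean())
    else:
        roi_mean = float("nan")
    res = SNRResult(
        snr_map=snr_map, roi_mean_snr=roi_mean, noise_mean=mu, noise_sd=sd, noise_label=nlabel
    )
    return total, res


def resample_mask(mask: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour ROI transfer between display and native grids.

    Pixel-centre alignment with half-open [0, N) indices: output pixel i
    samples input pixel ``floor((i + 0.5) * N_in / N_out)``.  Upsampling by
    an integer factor and sampling back is the identity.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.empty(out_shape, dtype=bool)
    ix = np.floor((np.arange(out_shape[0]) + 0.5) * mask.shape[0] / out_shape[0]).astype(int)
    iy = np.floor((np.arange(out_shape[1]) + 0.5) * mask.shape[1] / out_shape[1]).astype(int)
    out[:] = mask[np.ix_(ix, iy)]
    return out


def fit_adc(signals: np.ndarray, bvalues: np.ndarray = DWI_B_VALUES) -> ADCFit:
    """Mono-exponential ADC from signals at several diffusion weightings.

    Ordinary least squares on ``log S = log S0 - b * ADC``.  ADC is clipped
    at zero (rates are physical) and returned in 10^-6 mm^2/s.  Non-positive
    signals make the log undefined and raise.
    """
    S = np.asarray(signals, dtype=float)
    b = np.asarray(bvalues, dtype=float)
    if S.shape != b.shape or b.size < 2:
        raise ValueError("need matching signals for >= 2 b-values")
    if np.unique(b).size < 2:
        raise ValueError("b-values must include >= 2 distinct values")
    if np.any(S <= 0):
        raise ValueError("non-positive signal: log-linear ADC fit undefined")
    y = np.log(S)
    slope, intercept = np.polyfit(b, y, 1)
    adc_mm2s = max(-slope, 0.0)
    yhat = intercept + slope * b
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ADCFit(adc=adc_mm2s * 1e6, s0=float(np.exp(intercept)), r_squared=r2)
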