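"""Synthetic dynamic hyperpolarised 13C image series with known ground truth.

Emulates a clinical dynamic [1-13C]pyruvate prostate acquisition: a coarse
32 x 32 metabolite grid sampled every 4 s for 20 frames, lesion regions with
prescribed exchange kinetics, a gamma-variate arterial bolus, and Rician
(magnitude-of-complex-Gaussian) noise.  Voxels are treated as independent;
no point-spread blurring is applied.

RF consumption of longitudinal magnetisation is modelled as an effective
continuous decay rate ``-E ln(cos theta) / dt`` per metabolite, the
continuous equivalent of multiplying the stored magnetisation by
``cos(theta)^E`` between frames (E excitations per frame at flip angle
theta).  Under a constant-flip schedule this folds exactly into the lumped
decay rates of the two-site model, keeping the simulated series consistent
with the inputless fitting model in :mod:`hpmri.kinetics`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kinetics import KineticParams, solve_two_site

__all__ = [
    "AcquisitionSchedule",
    "BolusInput",
    "Lesion",
    "Phantom",
    "ROIMask",
    "DynamicSeries",
    "simulate_dynamic_series",
    "add_noise",
    "write_series",
]

METABOLITES = ("pyruvate", "lactate")

#: in vivo 13C T1 defaults (s) at 3 T, pyruvate and lactate
T1_PYRUVATE = 30.0
T1_LACTATE = 25.0


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Frame timing, grid and RF schedule of the dynamic 13C acquisition."""

    n_frames: int = 20
    frame_interval: float = 4.0
    matrix: tuple[int, int] = (32, 32)
    flip_pyruvate: float = 15.0
    flip_lactate: float = 40.0
    excitations_per_frame: int = 1
    mode: str = "ideal"  # "ideal" (single flip for all metabolites) | "spsp"

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        for name in ("flip_pyruvate", "flip_lactate"):
            v = getattr(self, name)
            if not (0.0 < v <= 90.0):
                raise ValueError(f"{name} must lie in (0, 90] degrees")
        if self.excitations_per_frame < 1:
            raise ValueError("excitations_per_frame must be >= 1")
        if self.mode not in ("ideal", "spsp"):
            raise ValueError("mode must be 'ideal' or 'spsp'")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def rf_decay_rate(self, metabolite: str) -> float:
        """Effective decay rate (s^-1) from RF consumption for one metabolite."""
        if self.mode == "ideal":
            theta = self.flip_pyruvate
        else:
            theta = self.flip_pyruvate if metabolite == "pyruvate" else self.flip_lactate
        c = np.cos(np.deg2rad(theta))
        return float(-self.excitations_per_frame * np.log(c) / self.frame_interval)


@dataclass(frozen=True)
class BolusInput:
    """Gamma-variate arterial input: zero before arrival, non-negative after.

    ``b(t) = amplitude * ((t - t0)/scale)^shape * exp(-(t - t0)/scale)``
    """

    arrival: float = 8.0
    shape: float = 2.5
    scale: float = 4.0
    amplitude: float = 1.0
    form: str = "gamma-variate"

    def __post_init__(self) -> None:
        if self.form != "gamma-variate":
            raise ValueError("only the gamma-variate form is implemented")
        if self.scale <= 0 or self.shape <= 0 or self.amplitude < 0:
            raise ValueError("invalid bolus parameters")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tt = (t - self.arrival) / self.scale
        out = np.where(tt > 0, np.power(np.clip(tt, 0, None), self.shape) * np.exp(-tt), 0.0)
        return self.amplitude * out


@dataclass(frozen=True)
class Lesion:
    """Disc-shaped lesion region with its own kinetics and bolus amplitude."""

    center: tuple[int, int]
    radius: float
    params: KineticParams
    amplitude: float = 1.0

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        xx, yy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        return (xx - self.center[0]) ** 2 + (yy - self.center[1]) ** 2 <= self.radius**2


@dataclass
class Phantom:
    """Digital prostate phantom: lesions on a uniform perfusion background."""

    shape: tuple[int, int] = (32, 32)
    lesions: list[Lesion] = field(default_factory=list)
    background_amplitude: float = 0.2

    def __post_init__(self) -> None:
        if self.background_amplitude < 0:
            raise ValueError("background amplitude must be >= 0")
        for les in self.lesions:
            if les.amplitude < 0:
                raise ValueError("lesion amplitude must be >= 0")
            x, y = les.center
            if not (0 <= x < self.shape[0] and 0 <= y < self.shape[1]):
                raise ValueError("lesion centre outside grid")


@dataclass(frozen=True)
class ROIMask:
    """Labelled boolean region on the image grid (tumour / noise / benign)."""

    mask: np.ndarray
    label: str = "tumour"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if not self.mask.any():
            raise ValueError("ROI mask is empty")


@dataclass
class DynamicSeries:
    """4-D dynamic metabolite stack: (x, y, frame, metabolite)."""

    signal: np.ndarray
    times: np.ndarray
    metabolites: tuple[str, ...] = METABOLITES
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, frame, metabolite)")
        if self.signal.shape[2] != self.times.size:
            raise ValueError("frame count does not match time stamps")
        if self.signal.shape[3] != len(self.metabolites):
            raise ValueError("metabolite axis does not match metabolite names")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time stamps must be strictly increasing")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.signal.shape[:2]

    @property
    def n_frames(self) -> int:
        return self.signal.shape[2]

    def metabolite_index(self, name: str) -> int:
        return self.metabolites.index(name)

    def channel(self, name: str) -> np.ndarray:
        """(x, y, frame) stack for one metabolite."""
        return self.signal[..., self.metabolite_index(name)]


def simulate_dynamic_series(
    phantom: Phantom,
    schedule: AcquisitionSchedule,
    bolus: BolusInput | None = None,
    *,
    t1_pyruvate: float = T1_PYRUVATE,
    t1_lactate: float = T1_LACTATE,
    internal_dt: float = 0.05,
) -> DynamicSeries:
    """Noiseless dynamic series from a phantom, schedule and bolus.

    Per voxel, the pyruvate channel is the bolus convolved with the lumped
    pyruvate decay (T1 + RF consumption), and the lactate channel the
    two-site exchange response to that pyruvate curve.  The kinetics are
    integrated on a fine internal grid (``internal_dt``) and sampled at the
    frame times, so the coarse 4 s sampling does not limit forward-model
    accuracy.  Background voxels carry pyruvate perfusion only; lactate is
    produced only inside lesions.
    """
    if bolus is None:
        bolus = BolusInput()
    if phantom.shape != schedule.matrix:
        raise ValueError("phantom grid does not match schedule matrix")
    times = schedule.times
    n_sub = max(1, int(round(schedule.frame_interval / internal_dt)))
    dt_f = schedule.frame_interval / n_sub
    t_fine = np.arange(int(round(times[-1] / dt_f)) + 1) * dt_f
    frame_idx = np.round(times / dt_f).astype(int)

    r_pyr = 1.0 / t1_pyruvate + schedule.rf_decay_rate("pyruvate")
    rho_rf = schedule.rf_decay_rate("lactate")

    b = bolus(t_fine)
    # unit-amplitude perfused pyruvate curve: bolus through lumped pyruvate decay
    p_unit = solve_two_site(KineticParams(1.0, r_pyr), b, t_fine)

    nx, ny = phantom.shape
    signal = np.zeros((nx, ny, times.size, 2))
    signal[..., 0] = phantom.background_amplitude * p_unit[frame_idx]

    for les in phantom.lesions:
        mask = les.mask(phantom.shape)
        p_les = les.amplitude * p_unit
        rho_eff = 1.0 / t1_lactate + rho_rf + les.params.rho_eff
        l_les = solve_two_site(KineticParams(les.params.kpl, rho_eff), p_les, t_fine)
        signal[mask, :, 0] = p_les[frame_idx]
        signal[mask, :, 1] = l_les[frame_idx]

    return DynamicSeries(signal=signal, times=times)


def add_noise(series: DynamicSeries, sigma: float, seed: int) -> DynamicSeries:
    """Rician noise: magnitude of the complex signal plus complex Gaussian.

    Each voxel value v becomes ``|(v + g1) + i g2|`` with g1, g2 independent
    zero-mean Gaussians of standard deviation sigma, reproducible for a
    fixed seed.  Noise is added in the complex domain so that the Rayleigh
    background statistics assumed by the sqrt(2) SNR correction hold.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return DynamicSeries(
            signal=series.signal.copy(),
            times=series.times.copy(),
            metabolites=series.metabolites,
            noise_sigma=0.0,
            seed=seed,
        )
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((2,) + series.signal.shape) * sigma
    noisy = np.hypot(series.signal + g[0], g[1])
    return DynamicSeries(
        signal=noisy,
        times=series.times.copy(),
        metabolites=series.metabolites,
        noise_sigma=sigma,
        seed=seed,
    )


def write_series(series: DynamicSeries, out_dir: str | Path, *, sidecar: dict | None = None) -> dict:
    """Write one 4-D NIfTI per metabolite plus a JSON sidecar.

    Frames are stacked along the 4th axis.  The sidecar records noise sigma,
    seed, frame times and any caller-provided ground-truth metadata.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for i, met in enumerate(series.metabolites):
        vol = series.signal[..., i][:, :, None, :]  # (x, y, z=1, t)
        img = nib.Nifti1Image(vol, affine=np.eye(4))
        img.header.set_xyzt_units("mm", "sec")
        p = out_dir / f"{met}.nii"
        nib.save(img, str(p))
        paths[met] = str(p)
    meta = {
        "frame_times_s": series.times.tolist(),
        "noise_sigma": series.noise_sigma,
        "seed": series.seed,
        "metabolites": list(series.metabolites),
    }
    if sidecar:
        meta.update(sidecar)
    sc = out_dir / "series.json"
    sc.write_text(json.dumps(meta, indent=2, sort_keys=True))
    paths["sidecar"] = str(sc)
    return paths
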