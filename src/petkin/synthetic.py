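"""Synthetic dynamic-PET data emulating the six-group mouse study.

No raw data accompanies the study this package models, so every pipeline
stage is exercised on simulated data built from the published summaries:

* six group presets carrying the reported group-mean rate constants
  (subcutaneous/in-situ tumor, three inflammation locations, spontaneous
  liver inflammation) and group sizes (5, 5, 4, 4, 9, 6);
* a Feng-type bolus standing in for the measured left-ventricle curve;
* the 27-frame, 3093 s acquisition schedule;
* frame-integrated measurements with Gaussian noise;
* small 4D phantoms with a blood-pool region (painted with WHOLE-BLOOD
  activity, i.e. plasma divided by the plasma-to-whole-blood ratio, so the
  calibration step is exercised non-trivially) and ellipsoidal lesions.

Between-subject spread is modelled as mean-preserving log-normal jitter
of the rate constants (default CV 30%): only group means were published,
and rate constants are positive, making the log-normal the minimal
positive-support choice.

All randomness flows through explicit seeds / generators.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .compartment import (
    KineticParams,
    frame_average,
    frame_weight_matrix,
    impulse_response_convolution,
    influx_constant,
)
from .imaging import ImageVolume4D, ROIMask
from .input_function import BolusModelParams, PlasmaRatioParams, plasma_ratio
from .schedule import FrameSchedule, TimeActivityCurve

__all__ = [
    "GroupPreset",
    "NoiseModel",
    "GROUP_PRESETS",
    "tissue_frame_tac",
    "simulate_subject_tacs",
    "Region",
    "PhantomResult",
    "build_phantom",
]

#: Fractional vascular volume assumed for all presets; the study reports
#: no per-group VB estimates, and 5% is a typical soft-tissue value.
DEFAULT_VB = 0.05


@dataclass(frozen=True)
class GroupPreset:
    """One experimental group: published mean rate constants + cohort size."""

    name: str
    params: KineticParams
    n_subjects: int
    between_subject_cv: float = 0.30
    suvmax_mean: float | None = None
    suvmax_sd: float | None = None
    #: published group-mean Ki (mL/s/g); averages per-animal Ki values, so it
    #: does NOT equal influx_constant(params) of the group-mean rates
    published_ki_mean: float | None = None

    @property
    def true_ki(self) -> float:
        """Influx constant of the preset's mean parameters.

        Note: this is Ki of the group-MEAN rate constants, which is not the
        published group-mean Ki (the study averaged per-animal Ki values).
        """
        return influx_constant(self.params)


def _preset(name, k1, k2, k3, k4, n, suv_mean, suv_sd, ki_mean):
    return GroupPreset(
        name=name,
        params=KineticParams(k1, k2, k3, k4, DEFAULT_VB),
        n_subjects=n,
        suvmax_mean=suv_mean,
        suvmax_sd=suv_sd,
        published_ki_mean=ki_mean,
    )


#: The six experimental groups with their published group-mean rate
#: constants (mL/s/g for K1, s^-1 for k2..k4), cohort sizes and SUVmax
#: summaries.  The spontaneous-liver group's published mean Ki appears as
#: 0.0033 mL/s/g in the results table but 0.033 mL/s/g in the running
#: text; the rate constants themselves (reproduced here) imply ~7.5e-3.
GROUP_PRESETS: dict[str, GroupPreset] = {
    p.name: p
    for p in [
        _preset("subcutaneous_tumor", 0.00229, 0.042, 0.0104, 0.00177, 5, 1.66, 0.34, 3.95e-4),
        _preset("in_situ_tumor", 0.185, 0.459, 0.00166, 0.00499, 5, 1.62, 0.25, 4.38e-4),
        _preset("subcutaneous_inflammation_with_tumor", 0.00326, 0.0124, 0.00119, 0.000706, 4, 0.78, 0.05, 2.49e-4),
        _preset("subcutaneous_inflammation_without_tumor", 0.00531, 0.0578, 0.19, 0.00993, 4, 2.32, 0.43, 1.08e-3),
        _preset("in_situ_inflammation", 0.0241, 0.674, 0.148, 0.56, 9, 1.73, 0.59, 1.12e-3),
        _preset("spontaneous_liver_inflammation", 0.00817, 0.00982, 0.109, 0.418, 6, 1.40, 0.32, 3.3e-3),
    ]
}

#: The study's comparison layout: lesion types contrasted at the same body
#: location, and the same lesion type contrasted across locations.
STUDY_CONTRASTS: dict[str, list[str]] = {
    "subcutaneous_lesions": [
        "subcutaneous_tumor",
        "subcutaneous_inflammation_with_tumor",
        "subcutaneous_inflammation_without_tumor",
    ],
    "in_situ_lesions": ["in_situ_tumor", "in_situ_inflammation"],
    "tumors_by_location": ["subcutaneous_tumor", "in_situ_tumor"],
    "inflammations_by_location": [
        "subcutaneous_inflammation_with_tumor",
        "subcutaneous_inflammation_without_tumor",
        "in_situ_inflammation",
        "spontaneous_liver_inflammation",
    ],
}


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement noise on frame-averaged activity.

    Standard deviation per frame is ``proportional_sd * value`` plus an
    additive ``floor_sd``; with ``duration_scaling`` the proportional part
    is divided by sqrt(duration / duration_ref_s), emulating the lower
    count variance of longer frames.  Identical seed and inputs give
    identical output.
    """

    proportional_sd: float = 0.05
    floor_sd: float = 0.0
    duration_scaling: bool = False
    duration_ref_s: float = 60.0
    seed: int = 0

    def sd(self, values: np.ndarray, durations: np.ndarray) -> np.ndarray:
        prop = self.proportional_sd * np.abs(values)
        if self.duration_scaling:
            prop = prop / np.sqrt(durations / self.duration_ref_s)
        return prop + self.floor_sd

    def apply(self, tac: TimeActivityCurve, rng: np.random.Generator) -> TimeActivityCurve:
        sd = self.sd(tac.values, tac.schedule.durations)
        noisy = np.clip(tac.values + rng.normal(0.0, 1.0, tac.values.shape) * sd, 0.0, None)
        return TimeActivityCurve(tac.schedule, noisy)


# cache of (t, runs, W, cp) keyed by schedule + grid spacings + bolus, so
# cohort simulations pay the grid setup once
_GRID_CACHE: dict[tuple, tuple] = {}


def _forward_grid(
    schedule: FrameSchedule, bolus: BolusModelParams, dt_fast: float, dt_slow: float, t_fast: float
) -> tuple:
    from .compartment import _segment_runs

    key = (
        tuple(schedule.starts.tolist()),
        tuple(schedule.durations.tolist()),
        dt_fast,
        dt_slow,
        t_fast,
        bolus,
    )
    hit = _GRID_CACHE.get(key)
    if hit is None:
        t0, t_end = float(schedule.starts[0]), float(schedule.ends[-1])
        tf = min(max(t_fast, t0), t_end)
        parts = [np.arange(t0, tf, dt_fast)]
        if t_end > tf:
            parts.append(np.arange(tf, t_end, dt_slow))
        parts.append([t_end])
        t = np.unique(np.concatenate(parts))
        hit = (t, _segment_runs(t), frame_weight_matrix(t, schedule), bolus(t))
        if len(_GRID_CACHE) > 8:
            _GRID_CACHE.clear()
        _GRID_CACHE[key] = hit
    return hit


def tissue_frame_tac(
    params: KineticParams,
    bolus: BolusModelParams,
    schedule: FrameSchedule,
    dt_fast: float = 0.05,
    dt_slow: float = 0.5,
    t_fast: float = 150.0,
) -> TimeActivityCurve:
    """Noiseless frame-averaged tissue curve for one parameter set.

    The closed-form tissue response to the continuous bolus is evaluated
    on a dense grid and averaged exactly over each acquisition frame.
    """
    t, runs, W, cp = _forward_grid(schedule, bolus, dt_fast, dt_slow, t_fast)
    conv = impulse_response_convolution(params, t, cp, runs)
    values = W @ conv + params.vb * (W @ cp)
    return TimeActivityCurve(schedule, values)


def jitter_params(
    params: KineticParams, cv: float, rng: np.random.Generator
) -> KineticParams:
    """Mean-preserving log-normal jitter of the four rate constants.

    sigma^2 = ln(1 + cv^2); vb is left at its preset value.  cv = 0
    returns the parameters unchanged.
    """
    if cv <= 0:
        return params
    sigma = np.sqrt(np.log1p(cv * cv))
    factors = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, 4))
    return KineticParams(
        params.K1 * factors[0],
        params.k2 * factors[1],
        params.k3 * factors[2],
        params.k4 * factors[3],
        params.vb,
    )


def simulate_subject_tacs(
    preset: GroupPreset,
    bolus: BolusModelParams,
    schedule: FrameSchedule,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
    jitter_cv: float | None = None,
    plasma_noise: bool = False,
) -> tuple[TimeActivityCurve, TimeActivityCurve, KineticParams]:
    """One simulated subject: (plasma TAC, tissue TAC, true parameters).

    The preset's rate constants are jittered log-normally (CV from the
    preset unless overridden), the forward model is run against the bolus,
    frame averages are taken, and measurement noise is added to the tissue
    curve (and, optionally, the plasma curve; by default the blood-pool
    ROI is treated as large enough that its TAC noise is negligible).
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    cv = preset.between_subject_cv if jitter_cv is None else jitter_cv
    truth = jitter_params(preset.params, cv, rng)
    plasma = frame_average(bolus, schedule)
    tissue = tissue_frame_tac(truth, bolus, schedule)
    tissue = noise.apply(tissue, rng)
    if plasma_noise:
        plasma = noise.apply(plasma, rng)
    return plasma, tissue, truth


# ---------------------------------------------------------------------------
# 4D phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Region:
    """One painted phantom region.

    ``params`` holds the tissue kinetics; ``params=None`` marks the blood
    pool, painted with whole-blood activity.  ``center`` is in voxel
    coordinates (z, y, x); ``semi_axes_mm`` in mm.
    """

    name: str
    center: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    params: KineticParams | None = None


#: Low-uptake background tissue (resting muscle scale).
BACKGROUND_PARAMS = KineticParams(0.001, 0.05, 0.001, 0.001, 0.03)


@dataclass(frozen=True)
class PhantomResult:
    volume: ImageVolume4D
    masks: dict[str, ROIMask]
    region_tacs: dict[str, TimeActivityCurve]
    region_params: dict[str, KineticParams | None]
    plasma_tac: TimeActivityCurve


def build_phantom(
    regions: list[Region],
    bolus: BolusModelParams,
    schedule: FrameSchedule,
    noise: NoiseModel | None = None,
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size_mm: float = 0.5,
    background_params: KineticParams = BACKGROUND_PARAMS,
    ratio_params: PlasmaRatioParams = PlasmaRatioParams(),
    seed: int = 0,
) -> PhantomResult:
    """Paint a 4D phantom with a blood pool and lesion regions.

    Every voxel of a region carries that region's frame-averaged TAC;
    the blood pool carries whole-blood activity (frame-averaged plasma
    divided by the plasma ratio at the frame midpoint, the same
    convention the calibration step applies, so the round trip is exact
    at zero noise).  Background voxels carry a low-uptake tissue curve.
    Regions must be disjoint and inside the grid.

    Voxel-level Gaussian noise is added when a :class:`NoiseModel` is
    given, seeded from ``seed``.
    """
    from .imaging import ellipsoid_roi  # local import to avoid cycle at module load

    plasma = frame_average(bolus, schedule)
    whole_blood_values = plasma.values / plasma_ratio(schedule.mid_times, ratio_params)

    background = tissue_frame_tac(background_params, bolus, schedule)
    nf = schedule.n_frames
    data = np.broadcast_to(background.values[:, None, None, None], (nf, *shape)).copy()

    # one shared dummy volume for ellipsoid rasterization
    probe = ImageVolume4D(
        np.zeros((1, *shape)),
        (voxel_size_mm,) * 3,
        FrameSchedule(np.array([0.0]), np.array([1.0])),
    )

    masks: dict[str, ROIMask] = {}
    tacs: dict[str, TimeActivityCurve] = {}
    params_out: dict[str, KineticParams | None] = {}
    occupied = np.zeros(shape, dtype=bool)
    for region in regions:
        mask = ellipsoid_roi(region.center, region.semi_axes_mm, probe)
        boolean = mask.to_boolean()
        if (boolean & occupied).any():
            raise ValueError(f"region '{region.name}' overlaps a previous region")
        occupied |= boolean
        if region.params is None:
            values = whole_blood_values
        else:
            values = tissue_frame_tac(region.params, bolus, schedule).values
        z, y, x = mask.indices.T
        data[:, z, y, x] = values[:, None]
        masks[region.name] = mask
        tacs[region.name] = TimeActivityCurve(schedule, values)
        params_out[region.name] = region.params

    if noise is not None:
        rng = np.random.default_rng(seed)
        sd = noise.sd(data, schedule.durations[:, None, None, None])
        data = np.clip(data + rng.normal(0.0, 1.0, data.shape) * sd, 0.0, None)

    volume = ImageVolume4D(data, (voxel_size_mm,) * 3, schedule)
    return PhantomResult(
        volume=volume,
        masks=masks,
        region_tacs=tacs,
        region_params=params_out,
        plasma_tac=plasma,
    )
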