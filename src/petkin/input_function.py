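"""Plasma input functions: simulated bolus, image-derived curve, plasma calibration.

The compartment model is driven by the plasma FDG concentration Cp(t).
In imaging practice Cp is obtained noninvasively from the blood pool of
the left ventricle (the image-derived input function, IDIF), which
measures WHOLE-BLOOD activity; plasma concentration is recovered by the
time-dependent plasma-to-whole-blood ratio

    R_PB(t) = 0.432 * exp(-0.168 * t[min]) + 1.158

with t in MINUTES (the only place the package leaves seconds).  For
simulation a Feng-type bolus model stands in for the measured curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import TimeActivityCurve

__all__ = [
    "BolusModelParams",
    "PlasmaRatioParams",
    "plasma_ratio",
    "calibrate_to_plasma",
    "image_derived_input",
    "default_mouse_bolus",
]


@dataclass(frozen=True)
class BolusModelParams:
    """Feng-type arterial bolus model.

    Cp(t) = (A1*(t-d) - A2 - A3) e^{-l1 (t-d)} + A2 e^{-l2 (t-d)} + A3 e^{-l3 (t-d)}
    for t >= d (delay d, seconds), zero before.  A1 in MBq mL^-1 s^-1; A2,
    A3 in MBq/mL; l1 > l2 > l3 >= 0 in s^-1.  Instances are callable and
    vectorized over t.
    """

    a1: float
    a2: float
    a3: float
    lambda1: float
    lambda2: float
    lambda3: float
    delay: float = 5.0
    t_end: float = 3600.0

    def __post_init__(self) -> None:
        if not (self.lambda1 > self.lambda2 > self.lambda3 >= 0.0):
            raise ValueError("decay rates must satisfy lambda1 > lambda2 > lambda3 >= 0")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")
        # non-negativity of the curve is checked numerically on a dense grid
        t = np.linspace(0.0, self.t_end, 4001)
        if np.any(self(t) < -1e-12):
            raise ValueError("bolus model is negative on [0, t_end]")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        u = t - self.delay
        with np.errstate(over="ignore"):
            cp = (
                (self.a1 * u - self.a2 - self.a3) * np.exp(-self.lambda1 * u)
                + self.a2 * np.exp(-self.lambda2 * u)
                + self.a3 * np.exp(-self.lambda3 * u)
            )
        return np.where(u >= 0.0, cp, 0.0)


def default_mouse_bolus(scale: float = 1.0, delay: float = 5.0) -> BolusModelParams:
    """Default simulation bolus for a ~21 g mouse receiving ~5.55 MBq.

    Shape constants follow the classic FDG arterial-curve fit converted to
    per-second units; amplitudes are set so the peak plasma concentration
    is ~21 MBq/mL, the scale expected when ~5.55 MBq distributes through
    a mouse-sized blood pool.  ``scale`` multiplies all amplitudes (e.g.
    to model a different injected dose).
    """
    return BolusModelParams(
        a1=4.0 * scale,
        a2=0.60 * scale,
        a3=0.30 * scale,
        lambda1=0.0689,
        lambda2=0.0021,
        lambda3=1.7e-4,
        delay=delay,
    )


@dataclass(frozen=True)
class PlasmaRatioParams:
    """Coefficients of the plasma-to-whole-blood ratio R_PB(t) = a e^{-b t[min]} + c.

    b is in min^-1.  The ratio is > c > 1 for all t, i.e. plasma activity
    always exceeds whole-blood activity.
    """

    a: float = 0.432
    b: float = 0.168
    c: float = 1.158

    def __post_init__(self) -> None:
        if self.c <= 1.0 or self.a < 0 or self.b < 0:
            raise ValueError("require a, b >= 0 and asymptote c > 1")


def plasma_ratio(t_seconds, params: PlasmaRatioParams = PlasmaRatioParams()) -> np.ndarray:
    """Plasma-to-whole-blood concentration ratio at time t (seconds).

    Converts t to minutes and evaluates a*exp(-b*t_min) + c.  Negative
    times are rejected.
    """
    t = np.asarray(t_seconds, dtype=float)
    if np.any(t < 0):
        raise ValueError("plasma_ratio is defined for t >= 0 only")
    out = params.a * np.exp(-params.b * t / 60.0) + params.c
    return out if out.ndim else float(out)


def calibrate_to_plasma(
    whole_blood: TimeActivityCurve, params: PlasmaRatioParams = PlasmaRatioParams()
) -> TimeActivityCurve:
    """Convert a whole-blood TAC to plasma by the ratio R_PB.

    Each frame value is multiplied by the ratio evaluated at the frame
    midpoint, the package's fixed convention for per-frame time stamps.
    """
    ratios = plasma_ratio(whole_blood.mid_times, params)
    return TimeActivityCurve(whole_blood.schedule, whole_blood.values * ratios)


def image_derived_input(volume, blood_roi) -> TimeActivityCurve:
    """Whole-blood TAC from a blood-pool (left-ventricle) ROI.

    Per-frame mean concentration over the ROI voxels; no partial-volume or
    spill-over correction is applied.
    """
    from .imaging import extract_tac

    return extract_tac(volume, blood_roi)
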