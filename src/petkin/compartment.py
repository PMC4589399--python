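"""Two-tissue (three-compartment) FDG kinetic model.

The model tracks free intracellular FDG, Ce(t), and phosphorylated
FDG-6-PO4, Cm(t), driven by the plasma concentration Cp(t):

    dCe/dt = K1*Cp(t) - (k2 + k3)*Ce(t) + k4*Cm(t)
    dCm/dt = k3*Ce(t) - k4*Cm(t)
    CT(t)  = [Ce(t) + Cm(t)] + VB*Cp(t)

K1 (mL s^-1 g^-1) is delivery from plasma, k2 (s^-1) efflux back to
plasma, k3 (s^-1) phosphorylation by hexokinase, k4 (s^-1)
dephosphorylation, and VB the fractional vascular volume contributing
blood signal to the measured tissue curve.  The homogeneous system has
eigenrates

    alpha_{1,2} = [(k2+k3+k4) -/+ sqrt((k2+k3+k4)^2 - 4 k2 k4)] / 2

(always real and non-negative for non-negative rates), and the measured
curve admits the closed form

    CT(t) = K1/(a2-a1) * [(k3+k4-a1) e^{-a1 t} + (a2-k3-k4) e^{-a2 t}]
            (convolved with Cp) + VB*Cp(t).

The net trapping (influx) constant is Ki = K1*k3/(k2+k3).

All times are seconds; concentrations MBq/mL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .schedule import FrameSchedule, TimeActivityCurve

__all__ = [
    "KineticParams",
    "AlphaPair",
    "compute_alphas",
    "influx_constant",
    "solve_tissue_ode",
    "analytic_tissue_curve",
    "frame_average",
]


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the two-tissue FDG model.

    K1 in mL s^-1 g^-1; k2, k3, k4 in s^-1; vb dimensionless in [0, 1).
    """

    K1: float
    k2: float
    k3: float
    k4: float
    vb: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if not (0.0 <= self.vb < 1.0):
            raise ValueError(f"vb must lie in [0, 1), got {self.vb}")

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.k2, self.k3, self.k4, self.vb])

    def to_dict(self) -> dict:
        return {
            "K1_mL_per_s_per_g": self.K1,
            "k2_per_s": self.k2,
            "k3_per_s": self.k3,
            "k4_per_s": self.k4,
            "vb": self.vb,
        }


@dataclass(frozen=True)
class AlphaPair:
    """Eigenrates of the tissue system; 0 <= alpha1 <= alpha2.

    Satisfy alpha1 + alpha2 = k2 + k3 + k4 and alpha1*alpha2 = k2*k4.
    """

    alpha1: float
    alpha2: float


def compute_alphas(params: KineticParams) -> AlphaPair:
    """Eigenrates alpha_{1,2} = [(k2+k3+k4) -/+ sqrt(disc)] / 2.

    The discriminant (k2+k3+k4)^2 - 4 k2 k4 equals
    (k2-k4)^2 + k3^2 + 2 k3 (k2+k4) >= 0, so both roots are real; clipping
    guards against negative round-off.
    """
    s = params.k2 + params.k3 + params.k4
    disc = s * s - 4.0 * params.k2 * params.k4
    root = np.sqrt(max(disc, 0.0))
    alpha1 = max((s - root) / 2.0, 0.0)
    alpha2 = (s + root) / 2.0
    return AlphaPair(alpha1, alpha2)


def influx_constant(params: KineticParams) -> float:
    """Net FDG influx (trapping) constant Ki = K1*k3/(k2+k3), mL s^-1 g^-1.

    When k2 + k3 = 0 there is no plasma-tissue exchange and Ki is 0 by
    convention.
    """
    denom = params.k2 + params.k3
    if denom == 0.0:
        return 0.0
    return params.K1 * params.k3 / denom


# ---------------------------------------------------------------------------
# Exponential convolution on piecewise-uniform grids
# ---------------------------------------------------------------------------


def _segment_runs(t: np.ndarray) -> list[tuple[int, int, float]]:
    """Split a monotone grid into maximal runs of constant spacing.

    Returns (i0, i1, h) triples: samples t[i0]..t[i1] are uniformly spaced
    by h (i1 > i0).
    """
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time grid must be strictly increasing")
    rel = np.abs(np.diff(dt)) > 1e-9 * np.maximum(dt[1:], dt[:-1])
    breaks = np.flatnonzero(rel) + 1
    edges = np.concatenate([[0], breaks, [dt.size]])
    return [(int(a), int(b), float(dt[a])) for a, b in zip(edges[:-1], edges[1:])]


def _exp_conv(t: np.ndarray, f: np.ndarray, alpha: float, runs=None) -> np.ndarray:
    """y(t_n) = int_0^{t_n} e^{-alpha (t_n - s)} f(s) ds, f piecewise linear.

    Exact for the linear interpolant of f through the samples; evaluated by
    the one-step recursion y_{n+1} = e^{-alpha h} y_n + (local integral),
    run segment-wise with :func:`scipy.signal.lfilter`.
    """
    y = np.zeros_like(f)
    for i0, i1, h in (runs if runs is not None else _segment_runs(t)):
        e = np.exp(-alpha * h)
        if alpha * h > 1e-8:
            i0c = (1.0 - e) / alpha
            i1c = (1.0 - (1.0 + alpha * h) * e) / (alpha * alpha)
        else:  # series limits, exact at alpha == 0
            i0c = h - alpha * h * h / 2.0
            i1c = h * h / 2.0 - alpha * h**3 / 3.0
        fl = f[i0:i1]  # left endpoints of the intervals in this run
        fr = f[i0 + 1 : i1 + 1]
        b = fr * (i0c - i1c / h) + fl * (i1c / h)
        seg, _ = lfilter([1.0], [1.0, -e], b, zi=[e * y[i0]])
        y[i0 + 1 : i1 + 1] = seg
    return y


def _texp_conv(t: np.ndarray, f: np.ndarray, alpha: float, u: np.ndarray, runs=None) -> np.ndarray:
    """v(t_n) = int_0^{t_n} (t_n - s) e^{-alpha (t_n - s)} f(s) ds.

    `u` must be the plain exponential convolution from :func:`_exp_conv`
    with the same alpha; the recursion is
    v_{n+1} = e^{-alpha h} (v_n + h u_n) + (local integral).
    """
    v = np.zeros_like(f)
    for i0, i1, h in (runs if runs is not None else _segment_runs(t)):
        e = np.exp(-alpha * h)
        if alpha * h > 1e-8:
            a2 = alpha * alpha
            i1c = (1.0 - (1.0 + alpha * h) * e) / a2
            i2c = (2.0 - (2.0 + 2.0 * alpha * h + a2 * h * h) * e) / (a2 * alpha)
        else:
            i1c = h * h / 2.0 - alpha * h**3 / 3.0
            i2c = h**3 / 3.0 - alpha * h**4 / 4.0
        fl = f[i0:i1]
        fr = f[i0 + 1 : i1 + 1]
        local = fr * (i1c - i2c / h) + fl * (i2c / h)
        b = e * h * u[i0:i1] + local
        seg, _ = lfilter([1.0], [1.0, -e], b, zi=[e * v[i0]])
        v[i0 + 1 : i1 + 1] = seg
    return v


_CONFLUENT_RTOL = 1e-12


def impulse_response_convolution(
    params: KineticParams, t: np.ndarray, cp_values: np.ndarray, runs=None
) -> np.ndarray:
    """Tissue response (Ce + Cm) to a sampled plasma curve.

    Evaluates the closed-form kernel convolved with the piecewise-linear
    interpolant of ``cp_values`` on grid ``t`` (monotone, piecewise-uniform
    spacing; must start where the tissue is tracer-free).  The vascular
    term VB*Cp is NOT included.
    """
    pair = compute_alphas(params)
    a1, a2 = pair.alpha1, pair.alpha2
    s = params.k3 + params.k4
    if runs is None:
        runs = _segment_runs(t)
    if (a2 - a1) <= _CONFLUENT_RTOL * max(a2, 1.0e-30):
        # Confluent limit: kernel K1 * [(k3+k4-a) t + 1] e^{-a t}
        a = 0.5 * (a1 + a2)
        u = _exp_conv(t, cp_values, a, runs)
        v = _texp_conv(t, cp_values, a, u, runs)
        return params.K1 * ((s - a) * v + u)
    c1 = params.K1 * (s - a1) / (a2 - a1)
    c2 = params.K1 * (a2 - s) / (a2 - a1)
    return c1 * _exp_conv(t, cp_values, a1, runs) + c2 * _exp_conv(t, cp_values, a2, runs)


def _as_curve_values(cp, t: np.ndarray) -> np.ndarray:
    vals = np.asarray(cp(t), dtype=float) if callable(cp) else np.asarray(cp, dtype=float)
    if vals.shape != t.shape:
        raise ValueError("cp values must match the time grid")
    return vals


def analytic_tissue_curve(
    params: KineticParams,
    cp,
    t_grid: np.ndarray,
    dt: float = 0.1,
    t_fine: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form tissue curve CT sampled on ``t_grid``.

    Cp is represented piecewise-linearly on a fine uniform grid (default
    0.1 s) and convolved with the bi-exponential kernel by exact
    per-segment integration; the vascular contribution VB*Cp(t) is added
    at the requested times.

    Parameters
    ----------
    cp
        Callable t -> plasma concentration (MBq/mL).
    t_grid
        Strictly increasing sample times starting at >= 0.
    dt
        Fine-grid spacing for the convolution (s).
    t_fine
        Optional explicit convolution grid (monotone, piecewise-uniform,
        starting at 0), overriding ``dt``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be 1-D and strictly increasing")
    if t_grid[0] < 0:
        raise ValueError("t_grid must start at t >= 0")
    if t_fine is None:
        n = int(np.ceil(t_grid[-1] / dt)) + 1
        t_fine = np.linspace(0.0, dt * (n - 1), n)
    cp_fine = _as_curve_values(cp, t_fine)
    conv = impulse_response_convolution(params, t_fine, cp_fine)
    ct = np.interp(t_grid, t_fine, conv)
    if params.vb:
        ct = ct + params.vb * _as_curve_values(cp, t_grid)
    return ct


def solve_tissue_ode(
    params: KineticParams,
    cp,
    t_grid: np.ndarray,
    h_fast: float = 0.05,
    h_slow: float = 0.5,
    t_switch: float = 120.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-step RK4 integration of the compartment ODEs.

    Independent numerical route to the same CT as
    :func:`analytic_tissue_curve`; serves as the oracle in equivalence
    tests.  Steps 0.05 s while the bolus varies fast (t < 120 s by
    default) and 0.5 s thereafter, always landing exactly on the
    requested output times.

    Returns ``(ce, cm, ct)`` sampled on ``t_grid``; initial condition
    Ce(0) = Cm(0) = 0.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be 1-D and strictly increasing")
    if t_grid[0] < 0:
        raise ValueError("t_grid must start at t >= 0")
    t_end = t_grid[-1]
    fine = [np.arange(0.0, min(t_switch, t_end), h_fast)]
    if t_end > t_switch:
        fine.append(np.arange(t_switch, t_end, h_slow))
    t_all = np.unique(np.concatenate(fine + [t_grid, [t_end]]))

    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4

    def rhs(t, ce, cm):
        cpv = float(cp(t))
        return (K1 * cpv - (k2 + k3) * ce + k4 * cm, k3 * ce - k4 * cm)

    ce = np.empty_like(t_all)
    cm = np.empty_like(t_all)
    ce[0] = cm[0] = 0.0
    for i in range(t_all.size - 1):
        t0, h = t_all[i], t_all[i + 1] - t_all[i]
        y1, z1 = ce[i], cm[i]
        k1a, k1b = rhs(t0, y1, z1)
        k2a, k2b = rhs(t0 + h / 2, y1 + h / 2 * k1a, z1 + h / 2 * k1b)
        k3a, k3b = rhs(t0 + h / 2, y1 + h / 2 * k2a, z1 + h / 2 * k2b)
        k4a, k4b = rhs(t0 + h, y1 + h * k3a, z1 + h * k3b)
        ce[i + 1] = y1 + h / 6 * (k1a + 2 * k2a + 2 * k3a + k4a)
        cm[i + 1] = z1 + h / 6 * (k1b + 2 * k2b + 2 * k3b + k4b)

    idx = np.searchsorted(t_all, t_grid)
    ce_out, cm_out = ce[idx], cm[idx]
    cp_out = np.asarray([float(cp(t)) for t in t_grid])
    ct_out = (ce_out + cm_out) + params.vb * cp_out
    return ce_out, cm_out, ct_out


# ---------------------------------------------------------------------------
# Frame averaging
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(24)


def frame_average(curve, schedule: FrameSchedule) -> TimeActivityCurve:
    """Average a continuous curve over each acquisition frame.

    Each frame value is (1/duration) * int over [start, start+duration] of
    the curve, by 24-point Gauss-Legendre quadrature per frame.  The curve
    may expose a ``t_end`` attribute; frames extending beyond it are
    rejected.
    """
    t_end = getattr(curve, "t_end", None)
    if t_end is not None and schedule.ends[-1] > t_end + 1e-9:
        raise ValueError(
            f"schedule extends to {schedule.ends[-1]:.1f} s beyond the curve domain ({t_end:.1f} s)"
        )
    half = 0.5 * schedule.durations
    mid = schedule.mid_times
    # (n_frames, n_nodes) sample times
    tt = mid[:, None] + half[:, None] * _GL_NODES[None, :]
    vals = np.asarray(curve(tt.ravel()), dtype=float).reshape(tt.shape)
    means = vals @ _GL_WEIGHTS / 2.0
    return TimeActivityCurve(schedule, means)


def frame_weight_matrix(t: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Weights W such that W @ y gives frame averages of the piecewise-linear
    curve through samples ``(t, y)``.

    Exact for piecewise-linear curves whose grid covers every frame; used
    by the fitter so model frame averages cost one matrix product.
    """
    t = np.asarray(t, dtype=float)
    if t[0] > schedule.starts[0] + 1e-9 or t[-1] < schedule.ends[-1] - 1e-9:
        raise ValueError("sample grid must cover the full schedule")
    h = np.diff(t)
    W = np.zeros((schedule.n_frames, t.size))
    for f, (s, e) in enumerate(zip(schedule.starts, schedule.ends)):
        ilo = max(np.searchsorted(t, s, side="right") - 1, 0)
        ihi = np.searchsorted(t, e, side="left")
        idx = np.arange(ilo, min(ihi, t.size - 1))
        a = np.maximum(t[idx], s)
        b = np.minimum(t[idx + 1], e)
        length = np.clip(b - a, 0.0, None)
        u = (a + b - 2.0 * t[idx]) / h[idx]
        np.add.at(W[f], idx, 0.5 * length * (2.0 - u))
        np.add.at(W[f], idx + 1, 0.5 * length * u)
    return W / schedule.durations[:, None]
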