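"""Kinetic model fitting: one-site binding, calibration, and Patlak analysis.

Implements the fits applied to the tracer data:

* exponential association ``B_eq·(1 − e^(−k_obs t))`` with
  ``k_obs = k_on·[L] + k_off`` and derived half-time ``ln2/k_obs``;
* mono-exponential dissociation ``B0·e^(−k_off t)``;
* the equilibrium affinity ``K_D = k_off / k_on``;
* the log–log concentration–response calibration line;
* Patlak graphical analysis of dynamic studies — slope Ki (net tracer influx,
  ml·cm⁻³·min⁻¹) and intercept V (effective distribution volume), fitted on
  points from the equilibrium cutoff (10 min) onwards;
* biexponential plasma-curve fitting.

All nonlinear fits use Levenberg–Marquardt least squares with log-linear
heuristic starting values, suited to the sparse 5–9-point curves these
experiments produce.  Standard errors come from the Jacobian-based covariance
at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import integrate, optimize, stats

from .imaging import PlasmaModel

__all__ = [
    "TimeActivityCurve",
    "KineticFit",
    "CalibrationFit",
    "PatlakResult",
    "FitConvergenceError",
    "fit_association",
    "fit_dissociation",
    "derive_kd",
    "fit_concentration_response",
    "patlak",
    "fit_plasma_biexponential",
]

LN2 = float(np.log(2.0))


class FitConvergenceError(RuntimeError):
    """A nonlinear fit failed to converge or produced an unphysical optimum."""


@dataclass
class TimeActivityCurve:
    """(time, concentration) series for tissue, blood or plasma.

    Times are minutes and must be strictly increasing; values must be finite.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = "tissue"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1D arrays of equal length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class KineticFit:
    """Result of a one-site association or dissociation fit.

    ``k_obs`` is the observed association rate (min⁻¹); ``k_on``
    (M⁻¹·min⁻¹), ``k_off`` (min⁻¹) and ``kd_m``/``kd_pm`` are populated
    where derivable.  Half-times are ln2/rate; ``stderr`` maps parameter
    names to Jacobian-based standard errors; ``rss`` is the residual sum of
    squares of the fit.
    """

    amplitude: float
    k_obs: Optional[float] = None
    k_on: Optional[float] = None
    k_off: Optional[float] = None
    kd_m: Optional[float] = None
    kd_pm: Optional[float] = None
    half_time_assoc: Optional[float] = None
    half_time_dissoc: Optional[float] = None
    stderr: dict = field(default_factory=dict)
    rss: float = float("nan")


@dataclass
class CalibrationFit:
    """Log–log concentration–response line: log10(y) = slope·log10(x) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    stderr_slope: float


@dataclass
class PatlakResult:
    """Patlak graphical-analysis estimates.

    ``ki``: slope, net influx (ml·cm⁻³·min⁻¹); ``v``: intercept, effective
    distribution volume; fitted on Patlak-transformed points with
    ``t >= t_start`` only.
    """

    ki: float
    v: float
    r_squared: float
    t_start: float
    n_points: int
    stderr_ki: float


def _curve_fit(model, t, y, p0, param_names):
    try:
        popt, pcov = optimize.curve_fit(model, t, y, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitConvergenceError(
            f"nonlinear fit did not converge (initial values {dict(zip(param_names, p0))}); "
            f"residuals at start: {np.round(y - model(t, *p0), 6).tolist()}"
        ) from exc
    resid = y - model(t, *popt)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    stderr = {n: float(s) for n, s in zip(param_names, se)}
    return popt, stderr, float(resid @ resid)


def fit_association(
    tac: TimeActivityCurve,
    ligand_conc: float,
    k_off_known: Optional[float] = None,
) -> KineticFit:
    """Fit B_eq·(1 − e^(−k_obs t)) and derive the association constants.

    ``k_on = (k_obs − k_off)/[L]`` is reported when ``k_off_known`` is
    supplied (e.g. from a separate dissociation fit); with it, K_D and the
    dissociation half-time are filled in too.  Amplitude is treated as a
    free nuisance parameter.
    """
    if ligand_conc <= 0:
        raise ValueError("ligand_conc must be positive")
    if len(tac) < 4:
        raise ValueError("association fit needs at least 4 points")
    t, y = tac.times, tac.values
    if np.max(np.abs(y)) <= 0:
        raise FitConvergenceError("association curve is identically zero")

    # heuristic start: plateau from the last value, rate from the first
    # crossing of half-plateau
    b0 = float(np.max(y))
    half_idx = np.argmax(y >= 0.5 * b0)
    t_half = t[half_idx] if t[half_idx] > 0 else (t[t > 0][0] if np.any(t > 0) else 1.0)
    p0 = [b0, LN2 / float(t_half)]

    def model(tt, beq, kobs):
        return beq * -np.expm1(-kobs * tt)

    (beq, kobs), stderr, rss = _curve_fit(model, t, y, p0, ("amplitude", "k_obs"))
    if kobs <= 0:
        raise FitConvergenceError(f"fitted k_obs {kobs} is non-positive")

    fit = KineticFit(
        amplitude=float(beq),
        k_obs=float(kobs),
        half_time_assoc=LN2 / float(kobs),
        stderr=stderr,
        rss=rss,
    )
    if k_off_known is not None:
        if kobs <= k_off_known:
            raise FitConvergenceError(
                f"fitted k_obs {kobs:.4g} min⁻¹ does not exceed k_off "
                f"{k_off_known:.4g} min⁻¹ (k_on would be non-positive)"
            )
        fit.k_off = float(k_off_known)
        fit.k_on = (float(kobs) - k_off_known) / ligand_conc
        fit.kd_m = derive_kd(fit.k_on, fit.k_off)
        fit.kd_pm = fit.kd_m * 1e12
        fit.half_time_dissoc = LN2 / k_off_known if k_off_known > 0 else float("inf")
        fit.stderr["k_on"] = fit.stderr.get("k_obs", float("nan")) / ligand_conc
    return fit


def fit_dissociation(tac: TimeActivityCurve) -> KineticFit:
    """Fit the washout B0·e^(−k_off t); reports k_off and its half-time."""
    if len(tac) < 4:
        raise ValueError("dissociation fit needs at least 4 points")
    t, y = tac.times, tac.values
    if y[0] <= 0:
        raise ValueError("dissociation curve must start positive")

    # rate start value from the log slope across the extremes, floored at 0
    if y[-1] > 0 and y[-1] < y[0] and t[-1] > t[0]:
        k0 = float(np.log(y[0] / y[-1]) / (t[-1] - t[0]))
    else:
        k0 = 1e-6
    p0 = [float(y[0]), max(k0, 1e-6)]

    def model(tt, b0, koff):
        return b0 * np.exp(-koff * tt)

    (b0, koff), stderr, rss = _curve_fit(model, t, y, p0, ("amplitude", "k_off"))
    koff = float(max(koff, 0.0))
    return KineticFit(
        amplitude=float(b0),
        k_off=koff,
        half_time_dissoc=LN2 / koff if koff > 0 else float("inf"),
        stderr=stderr,
        rss=rss,
    )


def derive_kd(k_on: float, k_off: float) -> float:
    """Equilibrium dissociation constant K_D = k_off / k_on, in molar."""
    if k_on <= 0:
        raise ValueError("k_on must be positive")
    if k_off < 0:
        raise ValueError("k_off must be non-negative")
    return k_off / k_on


def fit_concentration_response(concs, activities) -> CalibrationFit:
    """Ordinary least squares of log10(activity) on log10(concentration)."""
    x = np.asarray(concs, dtype=float)
    y = np.asarray(activities, dtype=float)
    if x.size < 3:
        raise ValueError("calibration fit needs at least 3 points")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if np.any(y <= 0):
        raise ValueError("activities must be positive for a log-log fit")
    res = stats.linregress(np.log10(x), np.log10(y))
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        stderr_slope=float(res.stderr),
    )


def patlak(
    tissue: TimeActivityCurve,
    plasma: TimeActivityCurve,
    t_start: float = 10.0,
    frame_durations_min: Optional[np.ndarray] = None,
) -> PatlakResult:
    """Patlak graphical analysis of an irreversibly trapping tracer.

    Transforms the curves to ``x = ∫₀ᵗ C_b dτ / C_b(t)`` and ``y = C_t/C_b``,
    then fits a least-squares line over points with ``t >= t_start``; the
    slope estimates Ki, the intercept V.  The tissue curve is interpolated
    onto the plasma time grid when the grids differ.

    Integration: for plain sampled curves, trapezoidal cumulative integration
    (the segment before the first sample is a rectangle at the first value).
    When ``frame_durations_min`` is given the samples are treated as
    duration-weighted frame means at frame midpoints: the integral through
    each frame start is then the exact cumulative sum of ``mean × duration``,
    and the within-frame remainder is interpolated with a biexponential
    fitted to the frame means (the form clearance curves take), scaled to
    match each frame's mean.  Sparse late frames turn plain trapezoid
    integration into a percent-level bias; the frame-aware scheme removes it.
    """
    if np.any(plasma.values <= 0):
        raise ValueError("plasma values must be positive for Patlak analysis")
    t = plasma.times
    if np.array_equal(tissue.times, t):
        ct = tissue.values
    else:
        ct = np.interp(t, tissue.times, tissue.values)

    if frame_durations_min is not None:
        d = np.asarray(frame_durations_min, dtype=float)
        if d.shape != t.shape:
            raise ValueError("frame durations must align with the time grid")
        cum = _frame_mean_cumulative_integral(t, plasma.values, d)
    else:
        cum = integrate.cumulative_trapezoid(plasma.values, t, initial=0.0)
        cum = cum + plasma.values[0] * t[0]  # pre-first-sample rectangle
    x = cum / plasma.values
    y = ct / plasma.values

    use = t >= t_start
    if int(use.sum()) < 3:
        raise ValueError(
            f"fewer than 3 usable points at t >= {t_start} min for the Patlak fit"
        )
    res = stats.linregress(x[use], y[use])
    return PatlakResult(
        ki=float(res.slope),
        v=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        t_start=float(t_start),
        n_points=int(use.sum()),
        stderr_ki=float(res.stderr),
    )


def _frame_mean_cumulative_integral(
    t: np.ndarray, v: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """∫₀^frame C_b dτ, frame-averaged, from frame-mean samples.

    The cumulative sum of mean × duration gives the integral through every
    frame start exactly.  The remaining piece — the frame average of the
    integral inside the current frame — needs a within-frame model: a
    biexponential is fitted to the frame means through its own frame-mean
    prediction (so noiseless biexponential blood data are reproduced
    exactly), and each frame's model remainder is rescaled to match the
    observed mean.  Falls back to a half-frame rectangle where the fit fails.
    """
    a_edge, b_edge = t - d / 2.0, t + d / 2.0

    def _int1(tt, a1, l1, a2, l2):
        return a1 / l1 * -np.expm1(-l1 * tt) + a2 / l2 * -np.expm1(-l2 * tt)

    def _int2(tt, a1, l1, a2, l2):
        return a1 / l1 * (tt + np.expm1(-l1 * tt) / l1) + a2 / l2 * (
            tt + np.expm1(-l2 * tt) / l2
        )

    def mean_model(_, a1, l1, a2, l2):
        return (_int1(b_edge, a1, l1, a2, l2) - _int1(a_edge, a1, l1, a2, l2)) / d

    cum_starts = np.concatenate([[0.0], np.cumsum(v * d)[:-1]])
    try:
        l2_0 = max(np.log(max(v[-2], 1e-300) / max(v[-1], 1e-300)) / (t[-1] - t[-2]), 1e-4)
        a2_0 = v[-1] * np.exp(min(l2_0 * t[-1], 50.0))
        p0 = [max(v[0] - a2_0, 0.1 * v[0]), max(10 * l2_0, 0.1), a2_0, l2_0]
        popt, _ = optimize.curve_fit(mean_model, t, v, p0=p0, maxfev=20000)
        vhat = mean_model(None, *popt)
        if np.any(vhat <= 0):
            raise RuntimeError("non-positive model means")
        half = (
            (_int2(b_edge, *popt) - _int2(a_edge, *popt)) / d - _int1(a_edge, *popt)
        ) * (v / vhat)
    except (RuntimeError, ValueError):
        half = v * d / 2.0
    return cum_starts + half


def fit_plasma_biexponential(tac: TimeActivityCurve) -> tuple[PlasmaModel, dict]:
    """Fit A1·e^(−λ1 t) + A2·e^(−λ2 t) to a plasma curve.

    Components are ordered λ1 > λ2 after the fit.  Returns the fitted model
    and a diagnostics dict (standard errors, residual sum of squares, and a
    ``degenerate`` flag raised when the two rates are within 5% of each other
    or one amplitude collapses to ~0 — i.e. the curve is effectively a single
    exponential).
    """
    if len(tac) < 5:
        raise ValueError("biexponential fit needs at least 5 points")
    t, y = tac.times, tac.values
    if np.any(y <= 0):
        raise ValueError("plasma values must be positive")

    # tail gives the slow component, early residual the fast one
    lam2_0 = max(np.log(y[-2] / y[-1]) / (t[-1] - t[-2]), 1e-4)
    a2_0 = y[-1] * np.exp(lam2_0 * t[-1])
    resid0 = max(y[0] - a2_0, 0.1 * y[0])
    lam1_0 = max(10 * lam2_0, 0.1)
    p0 = [resid0, lam1_0, a2_0, lam2_0]

    def model(tt, a1, l1, a2, l2):
        return a1 * np.exp(-l1 * tt) + a2 * np.exp(-l2 * tt)

    popt, stderr, rss = _curve_fit(model, t, y, p0, ("a1", "lam1", "a2", "lam2"))
    a1, l1, a2, l2 = (float(v) for v in popt)
    if l1 < l2:
        a1, a2, l1, l2 = a2, a1, l2, l1
        stderr = {
            "a1": stderr["a2"],
            "lam1": stderr["lam2"],
            "a2": stderr["a1"],
            "lam2": stderr["lam1"],
        }
    if min(a1, a2) < 0:  # single-exponential data can push an amplitude negative
        a1, a2 = max(a1, 0.0), max(a2, 0.0)
    total = a1 + a2
    degenerate = (l1 - l2) <= 0.05 * l1 or min(a1, a2) <= 1e-3 * total
    if l2 <= 0 or l1 <= l2:
        # rates collapsed; report as degenerate single exponential via nudge
        l2 = min(l2 if l2 > 0 else 0.5 * l1, 0.999 * l1)
        degenerate = True
    model_out = PlasmaModel(a1=a1, a2=a2, lam1=l1, lam2=l2)
    diagnostics = {"stderr": stderr, "rss": rss, "degenerate": bool(degenerate)}
    return model_out, diagnostics
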