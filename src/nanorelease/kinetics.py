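"""Closed-form release kinetics.

Contents: the Einstein-Stokes free diffusion coefficient, Amsden-type
obstruction estimates of the in-gel diffusion coefficient, the Fickian
series solution for the fraction released from a sphere under perfect-sink
conditions, Ritger-Peppas and delayed power-law fitting, the k(Dg, Rng, n)
relation and its inverse, and a two-parameter Weibull comparison fit.

The Fickian solution for a sphere of radius Rng with internal diffusion
coefficient Dg and an initially uniform load is

    f(t) = 1 - (6/pi^2) sum_{n>=1} n^-2 exp(-Dg n^2 pi^2 t / Rng^2).

Its first 60% is well approximated by the Ritger-Peppas power law
f = k t^n with n = 0.43 for spheres and k ~= 2.246 (Dg/Rng^2)^n, which is
what makes (n, k) fitted from release data physically interpretable.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import curve_fit

from .model import KB, KineticsFit, ReleaseCurve

#: Prefactor of the power-law approximation to the Fickian sphere solution.
K_SPHERE_PREFACTOR = 2.246
#: Classical diffusive exponent for spherical matrices.
N_SPHERE = 0.43


def stokes_einstein(R: float, T: float = 293.0, eta: float = 1.002e-3) -> float:
    """Free diffusion coefficient D0 = kBT / (6 pi eta R), in nm^2/ns.

    Parameters are the particle radius in nm, temperature in K and solvent
    viscosity in Pa s (default: water at 293 K).
    """
    if R <= 0:
        raise ValueError("radius must be positive")
    if T <= 0 or eta <= 0:
        raise ValueError("temperature and viscosity must be positive")
    d0_si = KB * T / (6.0 * math.pi * eta * R * 1e-9)  # m^2/s
    return d0_si * 1e9  # 1 m^2/s = 1e9 nm^2/ns


def ke_to_reduced(ke_si: float, T: float = 293.0) -> float:
    """Convert a spring constant from N/m to kBT/nm^2 at temperature T."""
    return ke_si * 1e-18 / (KB * T)


def dg_obstruction(
    D0: float, phi: float, Rs: float, Rp: float, mode: str = "rigid"
) -> float:
    """Obstruction-model in-gel diffusion coefficient.

    rigid:    Dg = D0 exp(-0.84 (phi (1 + Rs/Rp)^2)^1.09)
    flexible: Dg = D0 exp(-1.77 (phi (1 + Rs/Rp)^1.3)^1.07)

    Rs is the solute radius and Rp the polymer-bead radius (both nm).
    """
    if not (0 <= phi < 1):
        raise ValueError("phi must lie in [0, 1)")
    ratio = 1.0 + Rs / Rp
    if mode == "rigid":
        return D0 * math.exp(-0.84 * (phi * ratio**2) ** 1.09)
    if mode == "flexible":
        return D0 * math.exp(-1.77 * (phi * ratio**1.3) ** 1.07)
    raise ValueError(f"unknown mode {mode!r}")


def fickian_fraction(t, Dg: float, Rng: float, tol: float = 1e-10):
    """Fraction released from a uniformly loaded sphere (perfect sink).

    Adaptive truncation of the series with remainder bound < ``tol``; for
    reduced times x = Dg t / Rng^2 < 1e-3 the short-time expansion
    f ~= 6 sqrt(x/pi) - 3x is used instead of summing thousands of terms.
    Accepts scalar or array ``t`` (ns).
    """
    if Dg < 0 or Rng <= 0:
        raise ValueError("Dg must be >= 0 and Rng > 0")
    t_arr = np.asarray(t, dtype=np.float64)
    scalar = t_arr.ndim == 0
    x = Dg * np.atleast_1d(t_arr) / Rng**2
    if np.any(x < 0):
        raise ValueError("t must be >= 0")
    out = np.empty_like(x)
    short = x < 1e-3
    out[short] = 6.0 * np.sqrt(x[short] / math.pi) - 3.0 * x[short]
    xs = x[~short]
    if xs.size:
        acc = np.zeros_like(xs)
        pref = 6.0 / math.pi**2
        for n in range(1, 100_001):
            term = np.exp(-(n**2) * math.pi**2 * xs) / n**2
            acc += term
            # remainder < pref * exp(-(n+1)^2 pi^2 x_min) * sum_{m>n} m^-2
            #           < pref * term_{n+1,max} * (1/n)
            if pref * np.max(term) / n < tol:
                break
        out[~short] = 1.0 - pref * acc
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def _window(curve: ReleaseCurve, f_cut: float) -> np.ndarray:
    """Indices of samples up to (and including) the first with f >= f_cut."""
    above = np.nonzero(curve.f >= f_cut)[0]
    last = above[0] if len(above) else len(curve.f) - 1
    return np.arange(last + 1)


def _r2(f_obs: np.ndarray, f_model: np.ndarray) -> float:
    ss_res = float(np.sum((f_obs - f_model) ** 2))
    ss_tot = float(np.sum((f_obs - np.mean(f_obs)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -math.inf
    return 1.0 - ss_res / ss_tot


def _power_model(t, k, n):
    t = np.asarray(t, dtype=np.float64)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = k * t[pos] ** n
    return out


def _fit_kt_n(t: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    """Nonlinear least squares of f = k t^n in linear f-space."""
    pos = (t > 0) & (f > 0)
    if pos.sum() >= 2:
        # log-log regression for the starting point only
        slope, logk = np.polyfit(np.log(t[pos]), np.log(f[pos]), 1)
        p0 = (math.exp(logk), slope if slope > 0 else 0.5)
    else:
        p0 = (1.0, 0.5)
    popt, _ = curve_fit(_power_model, t, f, p0=p0, maxfev=20_000)
    k, n = float(popt[0]), float(popt[1])
    if k <= 0 or n <= 0:
        raise RuntimeError("power-law fit converged to non-physical parameters")
    return k, n


def fit_power_law(curve: ReleaseCurve, f_cut: float = 0.6) -> KineticsFit:
    """Ritger-Peppas fit f = k t^n over the first ``f_cut`` of the curve.

    Least squares in linear f-space with uniform weights, over all samples
    up to the first with f >= f_cut.  R2 is reported both on the fitted
    window and on the whole curve.
    """
    idx = _window(curve, f_cut)
    t, f = curve.times[idx], curve.f[idx]
    if np.count_nonzero((f > 0) & (f <= f_cut)) < 3:
        raise ValueError("fewer than 3 usable samples below f_cut")
    k, n = _fit_kt_n(t, f)
    return KineticsFit(
        model="power_law",
        n=n,
        k=k,
        td=0.0,
        R2=_r2(f, _power_model(t, k, n)),
        R2_full=_r2(curve.f, _power_model(curve.times, k, n)),
        window_t=(float(t[0]), float(t[-1])),
        window_f=(float(f[0]), float(f[-1])),
    )


def fit_delayed_power_law(curve: ReleaseCurve, f_cut: float = 0.6) -> KineticsFit:
    """Delayed power law f = k (t - td)^n for core-loaded release.

    td is not adjustable: it is read off the data as the last sampled time
    with f = 0 (release cannot have begun earlier).  With td = 0 the fit
    reduces exactly to :func:`fit_power_law`.
    """
    zero = np.nonzero(curve.f == 0)[0]
    td = float(curve.times[zero[-1]]) if len(zero) else 0.0
    idx = _window(curve, f_cut)
    keep = idx[curve.times[idx] >= td]
    t, f = curve.times[keep] - td, curve.f[keep]
    if np.count_nonzero((f > 0) & (f <= f_cut)) < 3:
        raise ValueError("fewer than 3 usable samples below f_cut")
    k, n = _fit_kt_n(t, f)
    full_model = _power_model(np.maximum(curve.times - td, 0.0), k, n)
    return KineticsFit(
        model="delayed_power_law",
        n=n,
        k=k,
        td=td,
        R2=_r2(f, _power_model(t, k, n)),
        R2_full=_r2(curve.f, full_model),
        window_t=(float(curve.times[keep][0]), float(curve.times[keep][-1])),
        window_f=(float(f[0]), float(f[-1])),
    )


def k_from_parameters(Dg: float, Rng: float, n: float) -> float:
    """k ~= 2.246 (Dg/Rng^2)^n, the prefactor of the sphere power law."""
    if Dg <= 0 or Rng <= 0 or n <= 0:
        raise ValueError("Dg, Rng and n must be positive")
    return K_SPHERE_PREFACTOR * (Dg / Rng**2) ** n


def dg_from_fit(k: float, n: float, Rng: float) -> float:
    """Invert k ~= 2.246 (Dg/Rng^2)^n for Dg (preliminary Dg estimate)."""
    if n == 0:
        raise ZeroDivisionError("cannot invert the k-Dg relation at n = 0")
    if k <= 0 or Rng <= 0:
        raise ValueError("k and Rng must be positive")
    return Rng**2 * (k / K_SPHERE_PREFACTOR) ** (1.0 / n)


def _weibull_model(t, a, b):
    t = np.asarray(t, dtype=np.float64)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = 1.0 - np.exp(-a * t[pos] ** b)
    return out


def fit_weibull(curve: ReleaseCurve) -> KineticsFit:
    """Weibull fit f = 1 - exp(-a t^b) over the full curve.

    Returned with the (a, b) parameters stored in the (k, n) slots of
    :class:`KineticsFit` (model = "weibull").
    """
    t, f = curve.times, curve.f
    if len(t) < 4:
        raise ValueError("need at least 4 samples for a Weibull fit")
    interior = (f > 0) & (f < 1) & (t > 0)
    if interior.sum() >= 2:
        y = np.log(-np.log1p(-f[interior]))
        b0, loga = np.polyfit(np.log(t[interior]), y, 1)
        p0 = (math.exp(loga), max(b0, 0.1))
    else:
        p0 = (1.0, 1.0)
    try:
        popt, _ = curve_fit(_weibull_model, t, f, p0=p0, maxfev=20_000)
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise RuntimeError(f"Weibull fit did not converge: {exc}") from exc
    a, b = float(popt[0]), float(popt[1])
    model = _weibull_model(t, a, b)
    r2 = _r2(f, model)
    return KineticsFit(
        model="weibull",
        n=b,
        k=a,
        td=0.0,
        R2=r2,
        R2_full=r2,
        window_t=(float(t[0]), float(t[-1])),
        window_f=(float(f[0]), float(f[-1])),
    )


def fickian_curve(
    Dg: float,
    Rng: float,
    t_max: float,
    n_points: int = 256,
    t_min: float | None = None,
) -> ReleaseCurve:
    """Sample the Fickian sphere solution on a log grid as a ReleaseCurve."""
    if t_min is None:
        # start two decades below the time at which f ~ 1% is reached
        t_min = 1e-2 * Rng**2 / (Dg * 1e4)
    times = np.geomspace(t_min, t_max, n_points)
    f = fickian_fraction(times, Dg, Rng)
    return ReleaseCurve(
        times=times,
        f=f,
        n_drug=0,
        replicate_ids=["analytic"],
        mode="analytic",
        loading="throughout",
        meta={"Dg": Dg, "Rng": Rng},
    )
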