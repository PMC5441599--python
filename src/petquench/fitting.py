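"""Weighted nonlinear least-squares fitting of correlation curves.

Fits minimize the weighted residual sum sum((G_data - G_model)/sigma)^2
(lmfit/Levenberg-Marquardt); 95% confidence intervals come from the
covariance matrix at the optimum, with the covariance *not* rescaled by the
reduced chi-square, so the stated per-lag uncertainties are taken at face
value (doubling every sigma doubles every CI but leaves the point estimates
unchanged).

Parameter bounds keep the optimizer in the physical region: all times in
[1 ps, 10 s], amplitudes in [0, 10], triplet fraction in [0, 0.99].  A
fit that does not converge, or that ends on a bound, is returned flagged
rather than raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import stats

from .datatypes import CorrelationCurve
from .models import (DynamicFit, FCSModelParams, dyn_model, fcs_model,
                     rates_from_dynamics)

__all__ = [
    "ParamEstimate",
    "FitResult",
    "ModelComparison",
    "fit_fcs",
    "fit_two_state",
    "compare_dynamic_models",
]

TIME_BOUNDS = (1e-12, 10.0)
AMP_BOUNDS = (0.0, 10.0)
Z95 = 1.959963984540054


@dataclass
class ParamEstimate:
    value: float
    stderr: float | None
    ci95: tuple | None

    @classmethod
    def from_lmfit(cls, par) -> "ParamEstimate":
        if par.stderr is None or not np.isfinite(par.stderr):
            return cls(par.value, None, None)
        half = Z95 * par.stderr
        return cls(par.value, par.stderr, (par.value - half, par.value + half))

    def covers(self, truth: float) -> bool:
        return self.ci95 is not None and self.ci95[0] <= truth <= self.ci95[1]


@dataclass
class FitResult:
    """Point estimates with 95% CIs, weighted residuals and fit diagnostics."""

    params: dict
    chisqr: float
    redchi: float
    residuals: np.ndarray
    lags_s: np.ndarray
    success: bool
    flags: list = field(default_factory=list)
    model_desc: str = ""
    nvarys: int = 0

    def __getitem__(self, name: str) -> ParamEstimate:
        return self.params[name]

    def summary(self) -> dict:
        out = {"model": self.model_desc, "success": self.success,
               "flags": list(self.flags), "chisqr": float(self.chisqr),
               "redchi": float(self.redchi)}
        for name, est in self.params.items():
            out[name] = {"value": float(est.value),
                         "stderr": None if est.stderr is None else float(est.stderr),
                         "ci95": None if est.ci95 is None else
                         [float(est.ci95[0]), float(est.ci95[1])]}
        return out


def _weights(curve: CorrelationCurve, flags: list) -> np.ndarray:
    if curve.sigma is None or np.any(curve.sigma <= 0):
        warnings.warn("missing or non-positive sigma: using unit weights",
                      stacklevel=3)
        flags.append("unit_weights")
        return np.ones(len(curve))
    return 1.0 / curve.sigma


def _finish(minres, curve, flags, model_desc) -> FitResult:
    if not minres.success:
        flags.append("non_convergence")
    params = {}
    for name, par in minres.params.items():
        if par.vary:
            if par.stderr is None:
                flags.append(f"no_stderr:{name}")
            scale = max(abs(par.value), abs(par.min), 1e-300)
            if np.isfinite(par.min) and par.value - par.min <= 1e-6 * scale:
                flags.append(f"at_lower_bound:{name}")
            scale = max(abs(par.value), 1e-300)
            if np.isfinite(par.max) and par.max - par.value <= 1e-6 * scale:
                flags.append(f"at_upper_bound:{name}")
        params[name] = ParamEstimate.from_lmfit(par)
    ndata = len(curve)
    nfree = max(ndata - minres.nvarys, 1)
    return FitResult(params=params, chisqr=float(minres.chisqr),
                     redchi=float(minres.chisqr) / nfree,
                     residuals=np.asarray(minres.residual),
                     lags_s=curve.lags_s.copy(),
                     success=bool(minres.success), flags=flags,
                     model_desc=model_desc, nvarys=minres.nvarys)


# ---- composite FCS model fit -------------------------------------------

_DEFAULT_VARY = ("n", "tau_d", "triplet_frac", "tau_t", "a_r1", "tau_r1",
                 "a_r2", "tau_r2", "a_ab", "tau_ab", "p", "offset")


def _build_fcs_params(init: FCSModelParams, vary, n_dyn: int) -> lmfit.Parameters:
    """lmfit parameter set with the timescale hierarchy enforced.

    The three bunching decays of the composite model are mutually
    exchangeable for the optimizer unless identified by their timescale
    ordering, which is how the curve regimes are read physically:
    dynamics faster than triplet blinking, triplet faster than diffusion.
    Each free time below tau_D is therefore fit as a ratio in (0, 1] of
    the next slower one.
    """
    p = lmfit.Parameters()
    lo_t, hi_t = TIME_BOUNDS

    def add(name, value, vmin, vmax):
        p.add(name, value=value, min=vmin, max=vmax, vary=name in vary)

    def add_chained(name, value, anchor):
        if name not in vary:
            add(name, value, lo_t, hi_t)
            return name
        ratio = min(max(value / p[anchor].value, 1e-6), 1.0)
        p.add(f"{name}_ratio", value=ratio, min=1e-6, max=1.0, vary=True)
        p.add(name, expr=f"{anchor} * {name}_ratio")
        return name

    add("n", init.n, 1e-6, 1e6)
    add("tau_d", init.tau_d_s, lo_t, hi_t)
    # small constant baseline: finite particle numbers leave a -1/M term
    # in the excess correlation that the product model does not carry
    add("offset", 0.0, -1.0, 1.0)
    add("p", init.p, 0.5, 100.0)
    add("gamma", init.gamma, 1e-3, 10.0)
    add("a_ab", init.a_ab, *AMP_BOUNDS)
    add("tau_ab", init.tau_ab_s, lo_t, hi_t)
    add("triplet_frac", init.triplet_frac, 0.0, 0.99)
    anchor = "tau_d"
    triplet_active = "triplet_frac" in vary or init.triplet_frac > 0
    if triplet_active:
        anchor = add_chained("tau_t", init.tau_t_s, anchor)
    else:
        add("tau_t", init.tau_t_s, lo_t, hi_t)
    dyn_init = list(init.dyn_terms) + [(0.0, 1e-7)] * (2 - len(init.dyn_terms))
    if n_dyn == 2:
        add("a_r2", dyn_init[1][0], *AMP_BOUNDS)
        anchor = add_chained("tau_r2", dyn_init[1][1], anchor)
    else:
        add("a_r2", dyn_init[1][0], *AMP_BOUNDS)
        add("tau_r2", dyn_init[1][1], lo_t, hi_t)
    add("a_r1", dyn_init[0][0], *AMP_BOUNDS)
    if n_dyn >= 1:
        add_chained("tau_r1", dyn_init[0][1], anchor)
    else:
        add("tau_r1", dyn_init[0][1], lo_t, hi_t)
    return p


def _params_to_model(p: lmfit.Parameters, n_dyn: int) -> FCSModelParams:
    dyn = tuple((p[f"a_r{i}"].value, p[f"tau_r{i}"].value)
                for i in range(1, n_dyn + 1))
    return FCSModelParams(n=p["n"].value, tau_d_s=p["tau_d"].value,
                          p=p["p"].value, gamma=p["gamma"].value,
                          a_ab=p["a_ab"].value, tau_ab_s=p["tau_ab"].value,
                          triplet_frac=p["triplet_frac"].value,
                          tau_t_s=p["tau_t"].value, dyn_terms=dyn)


def guess_fcs_init(curve: CorrelationCurve, n_dyn: int = 1,
                   with_triplet: bool = True) -> FCSModelParams:
    """Heuristic starting point from curve features: the amplitude at the
    smallest lag approximates gamma/N * (1 + sum a); the half-decay lag
    approximates tau_D."""
    excess = curve.to_excess()
    g0 = max(float(excess.values[0]), 1e-3)
    half = g0 / 2.0
    below = np.flatnonzero(excess.values < half)
    tau_d = float(excess.lags_s[below[0]]) if below.size else float(excess.lags_s[-1] / 10)
    a_each = 0.5 if n_dyn else 0.0
    n0 = FCSModelParams().gamma * (1 + a_each * n_dyn) / g0
    dyn = tuple((a_each, excess.lags_s[0] * 10 * 4 ** i) for i in range(n_dyn))
    return FCSModelParams(n=max(n0, 1e-4), tau_d_s=tau_d, p=2.0,
                          triplet_frac=0.1 if with_triplet else 0.0,
                          tau_t_s=tau_d / 10.0, dyn_terms=dyn)


def fit_fcs(curve: CorrelationCurve, init: FCSModelParams | None = None,
            vary: tuple = ("n", "tau_d", "triplet_frac", "tau_t",
                           "a_r1", "tau_r1"),
            n_starts: int = 1) -> FitResult:
    """Fit the composite FCS model to a correlation curve.

    ``init`` supplies starting values and which factors exist (number of
    dynamic terms, antibunching on/off); ``vary`` names the free
    parameters, everything else is held fixed.  The model adds a baseline
    of 1 when the curve is in raw convention.  Deterministic for identical
    inputs and starting point.

    ``n_starts > 1`` restarts the optimization from diffusion times spread
    logarithmically over the lag range and keeps the lowest chi-square;
    curves whose amplitude is dominated by fast dynamics otherwise pull a
    single half-decay-based start orders of magnitude below the true
    tau_D.
    """
    if init is None:
        init = guess_fcs_init(curve)
    unknown = set(vary) - set(_DEFAULT_VARY) - {"gamma"}
    if unknown:
        raise ValueError(f"unknown parameter names in vary: {sorted(unknown)}")
    n_dyn = max(len(init.dyn_terms),
                max((int(v[-1]) for v in vary if v.startswith(("a_r", "tau_r"))
                     and v[-1].isdigit()), default=0))
    flags: list = []
    wts = _weights(curve, flags)
    baseline = 1.0 if curve.convention == "raw" else 0.0

    def resid(p):
        model = (fcs_model(curve.lags_s, _params_to_model(p, n_dyn))
                 + baseline + p["offset"].value)
        return (curve.values - model) * wts

    def minimize_from(setup) -> object:
        pars = _build_fcs_params(init, vary, n_dyn)
        for name, value in setup.items():
            if name in pars and pars[name].expr is None:
                pars[name].value = value
        return lmfit.minimize(resid, pars, method="leastsq", scale_covar=False)

    starts: list[dict] = []
    if n_starts > 1:
        # stage A: diffusion-only fit of the long-lag tail pins down
        # (N, tau_D, offset) before the fast components are released
        stage_a = _tail_diffusion_fit(curve, init, vary, baseline, wts, n_starts)
        lag0 = curve.lags_s[0]
        for tau_t_ratio in (0.005, 0.05):
            for tau_r_lag in (3.0, 15.0):
                starts.append({**stage_a,
                               "tau_t_ratio": tau_t_ratio,
                               "tau_r1_ratio": min(tau_r_lag * lag0
                                                   / (stage_a["tau_d"] * tau_t_ratio), 1.0),
                               "tau_r2_ratio": 0.3,
                               "triplet_frac": 0.15, "a_r1": 0.8, "a_r2": 0.2})
        # fallback: plain geometric tau_D starts with the caller's init
        for tau_d0 in np.geomspace(lag0 * 30, curve.lags_s[-1], 3):
            starts.append({"tau_d": tau_d0})
    else:
        starts.append({})
    minres = None
    for setup in starts:
        attempt = minimize_from(setup)
        if minres is None or attempt.chisqr < minres.chisqr:
            minres = attempt
    desc = f"fcs[{n_dyn} dyn{', ab' if init.a_ab or 'a_ab' in vary else ''}]"
    result = _finish(minres, curve, flags, desc)
    result.best_model = _params_to_model(minres.params, n_dyn)
    return result


def _tail_diffusion_fit(curve: CorrelationCurve, init: FCSModelParams, vary,
                        baseline: float, wts: np.ndarray, n_starts: int) -> dict:
    """Fit N, tau_D (and offset) alone on the upper half of the lag range,
    where triplet and quenching terms have decayed; used only to seed the
    full fit."""
    mask = curve.lags_s >= np.sqrt(curve.lags_s[0] * curve.lags_s[-1])
    if mask.sum() < 8:
        mask = np.ones(len(curve), dtype=bool)
    lags = curve.lags_s[mask]
    vals = curve.values[mask]
    w = wts[mask]
    fit_offset = "offset" in vary

    def resid(p):
        model = (fcs_model(lags, FCSModelParams(
            n=p["n"].value, tau_d_s=p["tau_d"].value, p=init.p,
            gamma=init.gamma)) + baseline + p["offset"].value)
        return (vals - model) * w

    best = None
    for tau_d0 in np.geomspace(lags[0], lags[-1], max(n_starts, 3)):
        pars = lmfit.Parameters()
        pars.add("n", value=init.n, min=1e-6, max=1e6)
        pars.add("tau_d", value=tau_d0, min=TIME_BOUNDS[0], max=TIME_BOUNDS[1])
        pars.add("offset", value=0.0, min=-1.0, max=1.0, vary=fit_offset)
        attempt = lmfit.minimize(resid, pars, method="leastsq", scale_covar=False)
        if best is None or attempt.chisqr < best.chisqr:
            best = attempt
    return {"n": best.params["n"].value, "tau_d": best.params["tau_d"].value,
            "offset": best.params["offset"].value}


# ---- two-state dynamic fit ---------------------------------------------

def fit_two_state(curve: CorrelationCurve, convention: str = "as_printed") -> DynamicFit:
    """Fit ``a_r exp(-tau/tau_r)`` to an excess-convention dynamic curve
    and attach microscopic rates via :func:`rates_from_dynamics`.

    A curve that does not decay toward zero yields a flagged
    (non-converged) result instead of an exception.
    """
    excess = curve.to_excess()
    flags: list = []
    wts = _weights(excess, flags)
    a0 = float(excess.values[0])
    tail = float(np.mean(excess.values[-max(2, len(excess) // 5):]))
    if a0 <= 0 or tail >= a0:
        flags.append("non_decaying_input")
        a0 = max(a0, 1e-3)
    below = np.flatnonzero(excess.values < a0 / np.e)
    tau0 = float(excess.lags_s[below[0]]) if below.size else float(np.median(excess.lags_s))

    pars = lmfit.Parameters()
    pars.add("a_r", value=max(a0, 1e-6), min=AMP_BOUNDS[0], max=AMP_BOUNDS[1])
    pars.add("tau_r", value=tau0, min=TIME_BOUNDS[0], max=TIME_BOUNDS[1])

    def resid(p):
        return (excess.values - dyn_model(excess.lags_s, p["a_r"].value,
                                          p["tau_r"].value)) * wts

    minres = lmfit.minimize(resid, pars, method="leastsq", scale_covar=False)
    fitres = _finish(minres, excess, flags, "two_state_exponential")
    a_r = fitres["a_r"].value
    tau_r = fitres["tau_r"].value
    try:
        k_on, k_off = rates_from_dynamics(a_r, tau_r, convention)
    except ValueError:
        k_on = k_off = float("nan")
        fitres.flags.append("rates_undefined")
    return DynamicFit(a_r=a_r, tau_r_s=tau_r, k_on_per_s=k_on,
                      k_off_per_s=k_off, convention=convention, fit=fitres)


# ---- one- vs two-component comparison ----------------------------------

@dataclass
class ModelComparison:
    """Nested-model comparison between 1- and 2-component dynamic fits.

    ``f_pvalue`` is from an F-test on the chi-square decrease;
    ``resid_lag1`` is the lag-1 autocorrelation of the single-component
    weighted residuals (structure there also signals a missing component).
    The recommendation is advisory.
    """

    fit1: FitResult
    fit2: FitResult | None
    f_stat: float
    f_pvalue: float
    resid_lag1: float
    alpha: float
    prefer_two: bool
    partial: bool = False


def _fit_dyn_n(curve: CorrelationCurve, n_comp: int) -> FitResult:
    excess = curve.to_excess()
    flags: list = []
    wts = _weights(excess, flags)
    a0 = max(float(excess.values[0]), 1e-3)
    below = np.flatnonzero(excess.values < a0 / np.e)
    tau0 = float(excess.lags_s[below[0]]) if below.size else float(np.median(excess.lags_s))
    pars = lmfit.Parameters()
    if n_comp == 1:
        pars.add("a_r1", value=a0, min=AMP_BOUNDS[0], max=AMP_BOUNDS[1])
        pars.add("tau_r1", value=tau0, min=TIME_BOUNDS[0], max=TIME_BOUNDS[1])
    else:
        pars.add("a_r1", value=0.5 * a0, min=AMP_BOUNDS[0], max=AMP_BOUNDS[1])
        pars.add("tau_r1", value=tau0 / 4, min=TIME_BOUNDS[0], max=TIME_BOUNDS[1])
        pars.add("a_r2", value=0.5 * a0, min=AMP_BOUNDS[0], max=AMP_BOUNDS[1])
        pars.add("tau_r2", value=tau0 * 4, min=TIME_BOUNDS[0], max=TIME_BOUNDS[1])

    def resid(p):
        model = dyn_model(excess.lags_s, p["a_r1"].value, p["tau_r1"].value)
        if n_comp == 2:
            model = model + dyn_model(excess.lags_s, p["a_r2"].value,
                                      p["tau_r2"].value)
        return (excess.values - model) * wts

    minres = lmfit.minimize(resid, pars, method="leastsq", scale_covar=False)
    return _finish(minres, excess, flags, f"dyn[{n_comp}]")


def compare_dynamic_models(curve: CorrelationCurve, alpha: float = 0.05,
                           fitter=None) -> ModelComparison:
    """Fit one and two dynamic components and test whether the second
    improves the fit (F-test on nested chi-squares at level ``alpha``).

    ``fitter(curve, n_comp) -> FitResult`` can replace the default
    dynamic-only fit, e.g. to compare full composite-model fits.  If the
    two-component fit fails, a partial report with only the one-component
    result is returned.
    """
    fitter = fitter or _fit_dyn_n
    fit1 = fitter(curve, 1)
    r = fit1.residuals
    denom = float(np.sum((r - r.mean()) ** 2))
    resid_lag1 = float(np.sum((r[1:] - r.mean()) * (r[:-1] - r.mean())) / denom) \
        if denom > 0 else 0.0
    try:
        fit2 = fitter(curve, 2)
    except Exception:
        fit2 = None
    if fit2 is None or not fit2.success:
        return ModelComparison(fit1, fit2, np.nan, np.nan, resid_lag1,
                               alpha, prefer_two=False, partial=True)
    n = fit1.lags_s.size
    dof2 = n - fit2.nvarys
    d_nv = fit2.nvarys - fit1.nvarys
    if fit2.chisqr <= 0 or dof2 <= 0 or d_nv <= 0:
        f_stat, pval = np.nan, 1.0
    elif fit2.chisqr >= fit1.chisqr:
        f_stat, pval = 0.0, 1.0
    else:
        f_stat = ((fit1.chisqr - fit2.chisqr) / d_nv) / (fit2.chisqr / dof2)
        pval = float(stats.f.sf(f_stat, d_nv, dof2))
    return ModelComparison(fit1, fit2, float(f_stat), float(pval), resid_lag1,
                           alpha, prefer_two=bool(pval < alpha))
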