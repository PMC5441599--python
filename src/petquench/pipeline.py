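"""End-to-end orchestration of the two analyses and the comparison report.

``run_fcs_pipeline`` processes a photon stream (measured-style input or a
simulation spec) through: multiple-tau cross-correlation with ten-segment
standard errors -> composite-model fits with one and two dynamic
components -> nested model comparison -> isolation of the dynamic part ->
microscopic contact rates.

``run_md_pipeline`` processes a trajectory (or a planted binary quenching
signal) through: dark/fluorescent classification -> quenching
autocorrelation and two-state fit on the full record and again after
discarding an initial equilibration window -> rates; plus end-to-end regime
transition statistics and an optional clustering summary.

Reports are plain JSON-serializable dicts; with fixed seeds they are
byte-identical between runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np

from .correlate import segment_curves, segment_errors
from .datatypes import CorrelationCurve, PhotonStream, StateSequence
from .fitting import compare_dynamic_models, fit_fcs, fit_two_state, guess_fcs_init
from .models import (combine_two_component, dynamics_from_rates, isolate_dynamic,
                     rates_from_dynamics)
from .synthetic_data import PhotonSimParams, simulate_photons
from .traj_analysis import (QuenchCriterion, RegimeThresholds, TrajectoryEnsemble,
                            count_transitions, end_to_end_series,
                            quench_autocorrelation, quench_series,
                            single_linkage_cluster)

__all__ = ["run_fcs_pipeline", "run_md_pipeline", "write_report"]


def _rates_block(a_r: float, tau_r_s: float, convention: str) -> dict:
    k_on, k_off = rates_from_dynamics(a_r, tau_r_s, convention)
    return {"a_r": float(a_r), "tau_r_ns": float(tau_r_s * 1e9),
            "convention": convention,
            "k_on_per_us": float(k_on * 1e-6), "k_off_per_us": float(k_off * 1e-6)}


def run_fcs_pipeline(source, config: dict | None = None) -> dict:
    """Correlate, fit and convert a photon stream to contact rates.

    ``source`` is a :class:`PhotonStream` or a :class:`PhotonSimParams`
    spec (simulated first).  Config keys (all optional): ``n_segments``
    (10), ``m`` (16), ``base_bin_s``, ``max_lag_s``, ``vary`` (free
    parameters of the composite fit), ``alpha`` (0.05),
    ``convention`` ("as_printed").
    """
    cfg = dict(config or {})
    convention = cfg.get("convention", "as_printed")
    report: dict = {"kind": "fcs", "stages": {}, "provenance": {}}
    try:
        if isinstance(source, PhotonSimParams):
            report["provenance"]["simulation"] = _clean(asdict(source))
            stream = simulate_photons(source)
        else:
            stream = source
        report["provenance"]["n_photons"] = stream.n_photons
        report["stages"]["input"] = "ok"

        corr_kwargs = {k: cfg[k] for k in ("m", "base_bin_s", "max_lag_s") if k in cfg}
        channels = (0, 1) if stream.n_channels >= 2 else (0, 0)
        curve = segment_errors(stream, n_segments=cfg.get("n_segments", 10),
                               channels=channels, **corr_kwargs)
        report["provenance"]["correlator"] = {"n_segments": cfg.get("n_segments", 10),
                                              "channels": list(channels), **_clean(corr_kwargs)}
        report["stages"]["correlate"] = "ok"

        vary1 = tuple(cfg.get("vary", ("n", "tau_d", "triplet_frac", "tau_t",
                                       "a_r1", "tau_r1", "offset")))
        init1 = guess_fcs_init(curve, n_dyn=1)

        n_starts = int(cfg.get("n_starts", 5))

        def fitter(c, n_comp):
            if n_comp == 1:
                return fit_fcs(c, init1, vary=vary1, n_starts=n_starts)
            init2 = guess_fcs_init(c, n_dyn=2)
            return fit_fcs(c, init2, vary=vary1 + ("a_r2", "tau_r2"),
                           n_starts=n_starts)

        comparison = compare_dynamic_models(curve, alpha=cfg.get("alpha", 0.05),
                                            fitter=fitter)
        fit1, fit2 = comparison.fit1, comparison.fit2
        fit1_summary = fit1.summary()
        if cfg.get("segment_cis", True):
            _attach_segment_cis(fit1_summary, fit1, stream, curve, channels,
                                cfg.get("n_segments", 10), corr_kwargs, vary1)
        report["fcs_fit_1"] = fit1_summary
        report["fcs_fit_2"] = None if fit2 is None else fit2.summary()
        report["model_comparison"] = {
            "f_stat": _f(comparison.f_stat), "f_pvalue": _f(comparison.f_pvalue),
            "redchi_1": _f(fit1.redchi),
            "redchi_2": None if fit2 is None else _f(fit2.redchi),
            "resid_lag1_autocorr": _f(comparison.resid_lag1),
            "prefer_two_components": comparison.prefer_two,
            "alpha": comparison.alpha}
        report["stages"]["fit"] = "ok"

        chosen = fit2 if comparison.prefer_two else fit1
        best = chosen.best_model
        if len(best.dyn_terms) == 2:
            (a1, t1), (a2, t2) = best.dyn_terms
            a_r, tau_r = combine_two_component(a1, t1, a2, t2)
        else:
            a_r, tau_r = best.dyn_terms[0]
        report["dynamic"] = _rates_block(a_r, tau_r, convention)

        offset = chosen.params.get("offset")
        iso_input = curve.to_excess()
        if offset is not None and offset.value != 0.0:
            iso_input = CorrelationCurve(iso_input.lags_s,
                                         iso_input.values - offset.value,
                                         iso_input.sigma, "excess",
                                         iso_input.npairs)
        isolated = isolate_dynamic(iso_input, best)
        iso_fit = fit_two_state(isolated, convention=convention)
        report["isolated_dynamic_fit"] = _rates_block(iso_fit.a_r, iso_fit.tau_r_s,
                                                      convention)
        report["stages"]["isolate"] = "ok"
        report["success"] = True
    except Exception as exc:  # stage-level status for the CLI
        report["success"] = False
        report["error"] = f"{type(exc).__name__}: {exc}"
    return report


def _attach_segment_cis(summary: dict, fit1, stream, curve, channels,
                        n_segments: int, corr_kwargs: dict, vary) -> None:
    """Replace covariance-based 95% CIs by leave-one-segment-out jackknife CIs.

    The per-lag SEM weighting treats lags as independent, but multiple-tau
    lags share photons and slow occupancy fluctuations correlate whole lag
    regions, so covariance CIs understate parameter uncertainty.  Refitting
    the curve with each segment deleted in turn and taking the jackknife
    standard error captures the record's true information content while
    each refit keeps (n-1)/n of the photons, so the fits stay
    well-conditioned.  The covariance CIs are kept under ``ci95_covar``.
    """
    from scipy import stats as sps

    seg_list = segment_curves(stream, n_segments=n_segments,
                              channels=channels, **corr_kwargs)
    n_lags = len(curve)
    stack = np.vstack([c.values[:n_lags] for c in seg_list])
    names = [n for n, est in summary.items()
             if isinstance(est, dict) and "value" in est]
    collected: dict = {n: [] for n in names}
    n_fail = 0
    for leave_out in range(n_segments):
        keep = [i for i in range(n_segments) if i != leave_out]
        loo_vals = stack[keep].mean(axis=0)
        loo_sem = stack[keep].std(axis=0, ddof=1) / np.sqrt(len(keep))
        scurve = CorrelationCurve(curve.lags_s, loo_vals, loo_sem, "raw",
                                  curve.npairs)
        try:
            fr = fit_fcs(scurve, init=fit1.best_model, vary=tuple(vary),
                         n_starts=1)
        except (ValueError, RuntimeError):
            n_fail += 1
            continue
        if not fr.success:
            n_fail += 1
            continue
        for n in names:
            if n in fr.params:
                collected[n].append(fr.params[n].value)
    k = n_segments - n_fail
    if k < n_segments - 2:
        summary["segment_ci_note"] = (f"only {k} jackknife refits converged; "
                                      "covariance CIs kept")
        return
    tq = float(sps.t.ppf(0.975, k - 1))
    for n in names:
        vals = np.asarray(collected[n])
        # jackknife SE: sqrt((k-1)/k * sum((theta_i - mean)^2))
        se = np.sqrt((k - 1) / k * np.sum((vals - vals.mean()) ** 2))
        est = summary[n]
        est["ci95_covar"] = est.get("ci95")
        est["ci95"] = [est["value"] - tq * se, est["value"] + tq * se]
        est["jackknife_values"] = [float(v) for v in vals]
    summary["segment_ci_note"] = (f"95% CIs from leave-one-segment-out "
                                  f"jackknife over {k} refits (t-interval)")


def run_md_pipeline(source, config: dict | None = None) -> dict:
    """Quenching autocorrelation, rates and transition statistics from a
    trajectory or a planted binary quenching signal.

    ``source`` is a :class:`TrajectoryEnsemble` (needs a quench criterion
    in ``config['quench']`` unless the default resolves) or a binary
    :class:`StateSequence`.  Config keys: ``start_offset_us`` (12-style
    equilibration window to discard in the second fit; 0 disables),
    ``convention``, ``quench`` (QuenchCriterion), ``thresholds``
    (RegimeThresholds), ``cluster`` (bool), ``cluster_cutoff_nm`` (0.25),
    ``max_lag_frames``, ``n_segments``.
    """
    cfg = dict(config or {})
    convention = cfg.get("convention", "as_printed")
    offset = float(cfg.get("start_offset_us", 0.0))
    report: dict = {"kind": "md", "stages": {}, "provenance": {}}
    try:
        if isinstance(source, TrajectoryEnsemble):
            criterion = cfg.get("quench")
            if criterion is None:
                raise ValueError("a QuenchCriterion is required for trajectory input")
            states = quench_series(source, criterion)
        elif isinstance(source, StateSequence):
            states = source
        else:
            raise TypeError("source must be a TrajectoryEnsemble or StateSequence")
        duration_us = states.duration_us
        if offset < 0 or offset >= duration_us:
            raise ValueError("analysis window after the offset is empty")
        report["provenance"].update({"n_frames": int(states.n),
                                     "dt_frame_ns": float(states.dt_ns),
                                     "start_offset_us": offset})
        report["stages"]["quench_series"] = "ok"

        ac_kwargs = {k: cfg[k] for k in ("max_lag_frames", "n_segments") if k in cfg}
        windows = {"full": 0.0}
        if offset > 0:
            windows["post_offset"] = offset
        report["quench_fits"] = {}
        for name, start in windows.items():
            _, dynfit = quench_autocorrelation(states, start_time_us=start,
                                               convention=convention, **ac_kwargs)
            report["quench_fits"][name] = _rates_block(dynfit.a_r, dynfit.tau_r_s,
                                                       convention)
        report["stages"]["autocorrelation"] = "ok"

        if isinstance(source, TrajectoryEnsemble):
            thresholds = cfg.get("thresholds", RegimeThresholds())
            try:
                _, regimes = end_to_end_series(source, thresholds)
                stats = count_transitions(regimes)
                report["transitions"] = {"n_transitions": stats.n_transitions,
                                         "rate_per_us": _f(stats.rate_per_us),
                                         "total_time_us": _f(stats.total_time_us)}
                report["stages"]["transitions"] = "ok"
            except ValueError as exc:
                report["stages"]["transitions"] = f"skipped: {exc}"
            if cfg.get("cluster", False):
                res = single_linkage_cluster(source,
                                             cutoff_nm=cfg.get("cluster_cutoff_nm", 0.25))
                report["clusters"] = {
                    "n_clusters": int(res.n_clusters),
                    "populations_pct": [_f(x) for x in res.populations_pct[:10]],
                    "medoid_frames": [int(x) for x in res.medoid_frames[:10]],
                    "cutoff_nm": _f(res.cutoff_nm)}
                report["stages"]["cluster"] = "ok"
        report["success"] = True
    except Exception as exc:
        report["success"] = False
        report["error"] = f"{type(exc).__name__}: {exc}"
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _f(x) -> float | None:
    return None if x is None or (np.isscalar(x) and not np.isfinite(x)) else float(x)


def _clean(obj):
    """Make dataclass dumps JSON-serializable (tuples/np scalars -> plain)."""
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
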