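"""Intensity auto/cross-correlation of photon streams and sampled signals.

The normalized second-order correlation between channels i and j is

    G_ij(tau) = <I_i(t) I_j(t+tau)> / (<I_i(t)> <I_j(t)>)

with <> a time average.  On finite records the means are computed over the
two overlapping windows at each lag ("symmetric normalization"), which
removes the linear bias of finite-length estimates; :func:`direct_correlation`
is the brute-force evaluation of this definition and serves as the oracle
for the multiple-tau correlator.

:func:`multiple_tau_correlation` implements the standard quasi-logarithmic
scheme: ``m`` linear lags on the first level, then ``m/2`` lags per level
with the bin width doubling from level to level (both signals re-binned at
the current width).  For photon timestamp input the identical arithmetic is
carried out sparsely on the timestamps, so photon-mode and binned-mode
results agree to rounding.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import CorrelationCurve, PhotonStream, StateSequence

__all__ = [
    "direct_correlation",
    "multiple_tau_correlation",
    "cross_correlate_channels",
    "segment_errors",
    "segment_curves",
    "log_lag_indices",
]

logger = logging.getLogger("petquench")


def log_lag_indices(n: int, n_per_decade: int = 16, max_lag: int | None = None) -> np.ndarray:
    """Approximately log-spaced unique integer lags in [1, max_lag]."""
    if max_lag is None:
        max_lag = max(1, n // 8)
    max_lag = min(max_lag, n - 2)
    grid = np.logspace(0, np.log10(max_lag), int(np.log10(max_lag) * n_per_decade) + 1)
    return np.unique(np.round(grid).astype(np.int64))


def _signal_and_dt(data, dt_s):
    if isinstance(data, StateSequence):
        return data.values.astype(float), data.dt_ns * 1e-9
    sig = np.asarray(data, dtype=float)
    if dt_s is None:
        raise ValueError("dt_s is required for plain array input")
    return sig, float(dt_s)


def direct_correlation(data, dt_s: float | None = None,
                       lags: np.ndarray | None = None) -> CorrelationCurve:
    """Brute-force symmetric-normalized autocorrelation of a sampled signal.

    ``lags`` are integer multiples of the sampling interval; by default an
    approximately logarithmic subset up to an eighth of the record length.
    Raw convention (G -> 1).
    """
    sig, dt = _signal_and_dt(data, dt_s)
    n = sig.size
    if n < 3:
        raise ValueError("signal too short to correlate")
    if lags is None:
        lags = log_lag_indices(n)
    lags = np.asarray(lags, dtype=np.int64)
    if np.any(lags < 1) or np.any(lags >= n):
        raise ValueError("lags must satisfy 1 <= lag < len(signal)")
    values = np.empty(lags.size)
    npairs = (n - lags).astype(np.int64)
    for idx, k in enumerate(lags):
        a = sig[: n - k]
        b = sig[k:]
        m1 = a.mean()
        m2 = b.mean()
        if m1 <= 0.0 or m2 <= 0.0:
            raise ValueError(f"zero-mean window at lag {k}: normalization undefined")
        values[idx] = (a * b).mean() / (m1 * m2)
    return CorrelationCurve(lags * dt, values, None, "raw", npairs)


def _mtau_levels(n0: int, m: int, max_lag_bins: int):
    """Yield (level, bin_factor, lag list in current bins) for the scheme."""
    level = 0
    while True:
        factor = 2 ** level
        n = n0 // factor
        ks = np.arange(1, m + 1) if level == 0 else np.arange(m // 2 + 1, m + 1)
        ks = ks[(ks * factor) <= max_lag_bins]
        ks = ks[ks < n - 1]
        if ks.size == 0 or n < m + 2:
            return
        yield level, factor, ks
        if ks.size < (m if level == 0 else m // 2):
            return  # hit the max-lag ceiling
        level += 1


def _mtau_dense(x, dt_s, m, max_lag_s):
    n0 = x.size
    max_lag_bins = int(max_lag_s / dt_s)
    lags, values, npairs = [], [], []
    xl = x
    done = 0
    for level, factor, ks in _mtau_levels(n0, m, max_lag_bins):
        while done < level:
            xl = xl[: 2 * (xl.size // 2)].reshape(-1, 2).mean(axis=1)
            done += 1
        n = xl.size
        for k in ks:
            a = xl[: n - k]
            b = xl[k:]
            m1 = a.mean()
            m2 = b.mean()
            if m1 <= 0.0 or m2 <= 0.0:
                raise ValueError("zero-mean window: normalization undefined")
            lags.append(k * factor * dt_s)
            values.append((a * b).mean() / (m1 * m2))
            npairs.append(n - k)
    return lags, values, npairs


def _mtau_sparse(ticks_i, ticks_j, tick_s, duration_ticks, base_bin_ticks, m, max_lag_s):
    n0 = duration_ticks // base_bin_ticks
    if n0 < m + 2:
        raise ValueError("record shorter than one correlator level")
    max_lag_bins = int(max_lag_s / (base_bin_ticks * tick_s))
    lags, values, npairs = [], [], []
    for level, factor, ks in _mtau_levels(n0, m, max_lag_bins):
        width = base_bin_ticks * factor
        n = n0 // factor
        idx_i = ticks_i // width
        idx_j = ticks_j // width
        idx_i = idx_i[idx_i < n]
        idx_j = idx_j[idx_j < n]
        for k in ks:
            a = idx_i[idx_i <= n - 1 - k]
            cnt_j = idx_j.size - np.searchsorted(idx_j, k, side="left")
            if a.size == 0 or cnt_j == 0:
                raise ValueError("empty correlation window: normalization undefined")
            targets = a + k
            pairs = (np.searchsorted(idx_j, targets, side="right")
                     - np.searchsorted(idx_j, targets, side="left")).sum()
            # G = (pairsum/(n-k)) / ((cnt_i/(n-k)) * (cnt_j/(n-k)))
            lags.append(k * width * tick_s)
            values.append(pairs * (n - k) / (a.size * cnt_j))
            npairs.append(n - k)
    return lags, values, npairs


def multiple_tau_correlation(data, dt_s: float | None = None, *,
                             channels: tuple[int, int] = (0, 0),
                             m: int = 16,
                             base_bin_s: float | None = None,
                             max_lag_s: float | None = None) -> CorrelationCurve:
    """Multiple-tau correlation of a photon stream or a sampled signal.

    Parameters
    ----------
    data : PhotonStream, StateSequence or ndarray
        Photon input is correlated sparsely on timestamps; sampled input is
        correlated on the (re-)binned array.  Both paths evaluate the same
        estimator.
    channels : pair of channel indices (photon input only); equal indices
        give the autocorrelation.
    m : points per level; must be even and >= 8.
    base_bin_s : width of the finest level's bins.  Defaults to the sampling
        interval for sampled input and to 64 ticks for photon input.
    max_lag_s : deepest lag retained (default: an eighth of the record).
    """
    if m < 8 or m % 2:
        raise ValueError("m must be even and >= 8")
    if isinstance(data, PhotonStream):
        i, j = channels
        ti, tj = data.channels[i], data.channels[j]
        if ti.size == 0 or tj.size == 0:
            raise ValueError("empty photon channel")
        if ti.size < 2 and tj.size < 2:
            raise ValueError("need more than one photon to correlate")
        tick_s = data.tick_ps * 1e-12
        if base_bin_s is None:
            base_bin_ticks = 64
        else:
            base_bin_ticks = max(1, int(round(base_bin_s / tick_s)))
        if max_lag_s is None:
            max_lag_s = data.duration_s / 8.0
        lags, values, npairs = _mtau_sparse(
            ti, tj, tick_s, data.duration_ticks, base_bin_ticks, m, max_lag_s)
    else:
        sig, dt = _signal_and_dt(data, dt_s)
        if base_bin_s is not None and base_bin_s > dt:
            factor = int(round(base_bin_s / dt))
            sig = sig[: factor * (sig.size // factor)].reshape(-1, factor).mean(axis=1)
            dt = factor * dt
        if sig.size < m + 2:
            raise ValueError("record shorter than one correlator level")
        if max_lag_s is None:
            max_lag_s = sig.size * dt / 8.0
        lags, values, npairs = _mtau_dense(sig, dt, m, max_lag_s)
    order = np.argsort(lags)
    return CorrelationCurve(np.asarray(lags)[order], np.asarray(values)[order],
                            None, "raw", np.asarray(npairs, np.int64)[order])


def cross_correlate_channels(stream: PhotonStream, **kwargs) -> CorrelationCurve:
    """Cross-correlation between the two detector channels of a stream.

    With the beam-splitter arrangement this suppresses single-detector
    artifacts (dead time, afterpulsing) at antibunching lags by
    construction.  Falls back to the autocorrelation for a single-channel
    stream.
    """
    channels = (0, 1) if stream.n_channels >= 2 else (0, 0)
    return multiple_tau_correlation(stream, channels=channels, **kwargs)


def segment_curves(data, dt_s: float | None = None, *, n_segments: int = 10,
                   mode: str = "multiple_tau", **corr_kwargs) -> list:
    """Correlation curves of the ``n_segments`` equal-duration parts of a
    record, all computed with identical settings (shared lag grid).

    The deepest lags are limited to a quarter of the segment duration; if
    that clips a requested ``max_lag_s``, a warning is logged.
    """
    if n_segments < 2:
        raise ValueError("need at least two segments")
    if isinstance(data, PhotonStream):
        seg_duration = data.duration_s / n_segments
        segments = [data.segment(i, n_segments) for i in range(n_segments)]
    else:
        sig, dt = _signal_and_dt(data, dt_s)
        seg_len = sig.size // n_segments
        if seg_len < 16:
            raise ValueError("segments too short to correlate")
        seg_duration = seg_len * dt
        segments = [sig[i * seg_len:(i + 1) * seg_len] for i in range(n_segments)]
        dt_s = dt
    max_lag_s = corr_kwargs.pop("max_lag_s", None)
    ceiling = seg_duration / 4.0
    if max_lag_s is not None and max_lag_s > ceiling:
        logger.warning("max_lag_s=%.3g exceeds a quarter segment; clipped to %.3g",
                       max_lag_s, ceiling)
    max_lag_s = ceiling if max_lag_s is None else min(max_lag_s, ceiling)

    curves = []
    for seg in segments:
        if mode == "multiple_tau":
            curves.append(multiple_tau_correlation(seg, dt_s, max_lag_s=max_lag_s,
                                                   **corr_kwargs))
        elif mode == "direct":
            curves.append(direct_correlation(seg, dt_s, **corr_kwargs))
        else:
            raise ValueError(f"unknown correlator mode {mode!r}")
    return curves


def segment_errors(data, dt_s: float | None = None, *, n_segments: int = 10,
                   mode: str = "multiple_tau", **corr_kwargs) -> CorrelationCurve:
    """Correlation with per-lag standard errors from equal-length segments.

    The record is split into ``n_segments`` equal-duration parts, each is
    correlated with identical settings, and the curve value/sigma are the
    across-segment mean and standard error of the mean.
    """
    curves = segment_curves(data, dt_s, n_segments=n_segments, mode=mode,
                            **corr_kwargs)
    n_lags = min(len(c) for c in curves)
    stack = np.vstack([c.values[:n_lags] for c in curves])
    ref = curves[0]
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n_segments)
    npairs = None
    if ref.npairs is not None:
        npairs = ref.npairs[:n_lags] * n_segments
    return CorrelationCurve(ref.lags_s[:n_lags], stack.mean(axis=0), sem, "raw", npairs)
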