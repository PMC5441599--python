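"""Synthetic inputs with known ground truth for the full pipeline.

Four generators cover every input class the analysis consumes:

* :func:`simulate_telegraph` — exact continuous-time two-state Markov
  (bright/dark) process sampled on a uniform grid; the oracle for the
  single-exponential quenching correlation.
* :func:`simulate_two_well_distance` — end-to-end distance series hopping
  between a "close" and an "open" well with Gaussian observation noise.
* :func:`simulate_ensemble` — conformational ensemble with planted cluster
  structure; each frame additionally receives a random rigid rotation and
  translation so downstream clustering must superpose.
* :func:`simulate_photons` — confocal photon stream from Brownian particles
  in a periodic box with a 3D-Gaussian detection profile, per-particle
  triplet blinking, quenching telegraph dynamics and optional antibunching.

The photon simulator is hybrid: diffusion is propagated on a coarse grid
(default tau_D/50) to form a piecewise-constant emission-rate envelope from
which candidate photons are drawn as an inhomogeneous Poisson process; the
fast two-state factors (triplet, quenching) are then applied by *exact*
continuous-time Markov propagation of each particle's state at the candidate
times, so blinking kinetics carry no time-step error at all.  The expected
correlation of the output is the composite model of
:mod:`petquench.models` factor by factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .datatypes import BRIGHT, CLOSE, DARK, OPEN, PhotonStream, StateSequence

__all__ = [
    "TelegraphParams",
    "PhotonSimParams",
    "EnsembleSpec",
    "TwoWellResult",
    "telegraph_events",
    "simulate_telegraph",
    "simulate_two_well_distance",
    "simulate_ensemble",
    "simulate_photons",
    "default_atom_table",
    "standard_photon_spec",
]


@dataclass
class TelegraphParams:
    """Two-state quenching telegraph: rates of end-to-end contact formation
    (bright -> dark) and dissociation (dark -> bright), per microsecond.

    Stationary bright fraction: k_diss/(k_form + k_diss).
    """

    k_form_per_us: float = 8.4
    k_diss_per_us: float = 5.5
    dt_ns: float = 30.0
    n_steps: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_form_per_us <= 0 or self.k_diss_per_us <= 0:
            raise ValueError("telegraph rates must be positive")
        if self.dt_ns <= 0:
            raise ValueError("dt_ns must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be positive")

    @property
    def bright_fraction(self) -> float:
        return self.k_diss_per_us / (self.k_form_per_us + self.k_diss_per_us)

    @property
    def relax_time_ns(self) -> float:
        return 1e3 / (self.k_form_per_us + self.k_diss_per_us)


def telegraph_events(k_form_per_us: float, k_diss_per_us: float,
                     duration_us: float, rng: np.random.Generator,
                     initial_state: int | None = None):
    """Event-driven two-state trajectory over [0, duration_us].

    Returns ``(switch_times_us, initial_state)``; the state flips at each
    switch time.  The initial state is drawn from the stationary
    distribution unless given.  Dwell times are exponential with the
    respective exit rate.
    """
    f_bright = k_diss_per_us / (k_form_per_us + k_diss_per_us)
    if initial_state is None:
        state = BRIGHT if rng.random() < f_bright else DARK
    else:
        state = initial_state
    init = state
    rate_out = {BRIGHT: k_form_per_us, DARK: k_diss_per_us}
    t = 0.0
    times = []
    while True:
        t += rng.exponential(1.0 / rate_out[state])
        if t >= duration_us:
            break
        times.append(t)
        state = BRIGHT if state == DARK else DARK
    return np.asarray(times), init


def simulate_telegraph(params: TelegraphParams) -> StateSequence:
    """Sample an exact continuous-time telegraph process on a uniform grid.

    The analytic autocorrelation of the bright indicator is
    ``G(tau) = 1 + ((1-F)/F) exp(-(k_form+k_diss) tau)`` with F the
    stationary bright fraction.
    """
    rng = np.random.default_rng(params.seed)
    duration_us = params.n_steps * params.dt_ns * 1e-3
    times, init = telegraph_events(params.k_form_per_us, params.k_diss_per_us,
                                   duration_us, rng)
    grid_us = np.arange(params.n_steps) * params.dt_ns * 1e-3
    flips = np.searchsorted(times, grid_us, side="right")
    values = np.where(flips % 2 == 0, init, 1 - init).astype(np.int8)
    return StateSequence(values, params.dt_ns, "binary")


@dataclass
class TwoWellResult:
    """Distance series with its hidden two-state trajectory."""

    distances_nm: np.ndarray
    hidden: StateSequence          # ternary codes, CLOSE/OPEN only
    n_hidden_transitions: int

    @property
    def dt_ns(self) -> float:
        return self.hidden.dt_ns


def simulate_two_well_distance(d_close_nm: float = 1.0, d_open_nm: float = 3.0,
                               hop_rates_per_us=(1.0, 1.0),
                               noise_sd_nm: float = 0.05,
                               dt_ns: float = 30.0, n_steps: int = 100_000,
                               seed: int = 0,
                               d_close_thresh: float = 1.3,
                               d_open_thresh: float = 2.5) -> TwoWellResult:
    """Two-well end-to-end distance series with Gaussian observation noise.

    ``hop_rates_per_us`` = (close->open, open->close) rates, or a scalar for
    symmetric hopping.  Wells that reach into the intermediate band
    [d_close_thresh, d_open_thresh] within 3 noise SDs trigger a warning
    (regime assignment then becomes ambiguous) but are allowed.
    """
    if np.isscalar(hop_rates_per_us):
        k_co = k_oc = float(hop_rates_per_us)
    else:
        k_co, k_oc = map(float, hop_rates_per_us)
    if k_co < 0 or k_oc < 0:
        raise ValueError("hop rates must be non-negative")
    if dt_ns <= 0 or n_steps < 2:
        raise ValueError("need dt_ns > 0 and at least two steps")
    if noise_sd_nm < 0:
        raise ValueError("noise_sd_nm must be non-negative")
    if (d_close_nm > d_close_thresh - 3 * noise_sd_nm
            or d_open_nm < d_open_thresh + 3 * noise_sd_nm):
        warnings.warn("well positions reach into the intermediate band; "
                      "regime assignment may be ambiguous", stacklevel=2)

    rng = np.random.default_rng(seed)
    duration_us = n_steps * dt_ns * 1e-3
    if k_co == 0.0 and k_oc == 0.0:
        init = CLOSE if rng.random() < 0.5 else OPEN
        hidden = np.full(n_steps, init, dtype=np.int8)
        n_trans = 0
    else:
        # map onto the telegraph machinery: "bright" := close state
        k_co_eff = max(k_co, 1e-12)
        k_oc_eff = max(k_oc, 1e-12)
        times, init_bright = telegraph_events(k_co_eff, k_oc_eff, duration_us, rng)
        grid_us = np.arange(n_steps) * dt_ns * 1e-3
        flips = np.searchsorted(times, grid_us, side="right")
        is_close = np.where(flips % 2 == 0, init_bright, 1 - init_bright)
        hidden = np.where(is_close == BRIGHT, CLOSE, OPEN).astype(np.int8)
        n_trans = int(times.size)
    levels = np.where(hidden == CLOSE, d_close_nm, d_open_nm)
    noise = rng.normal(0.0, noise_sd_nm, n_steps) if noise_sd_nm > 0 else 0.0
    return TwoWellResult(levels + noise, StateSequence(hidden, dt_ns, "ternary"), n_trans)


def default_atom_table(n_atoms: int) -> pd.DataFrame:
    """Generic atom metadata: one C-beta pseudo-atom per residue.

    Residue indices are 1-based, so an n-atom ensemble directly supports
    end-to-end distance analysis between residues 1 and n.
    """
    return pd.DataFrame({
        "resid": np.arange(1, n_atoms + 1),
        "resname": ["ALA"] * n_atoms,
        "name": ["CB"] * n_atoms,
        "element": ["C"] * n_atoms,
    })


@dataclass
class EnsembleSpec:
    """Planted-cluster conformational ensemble.

    Frames are drawn by picking a center structure according to ``weights``,
    adding isotropic Gaussian coordinate noise of ``within_cluster_sd_nm``,
    then applying a random rigid rotation and translation.

    Separability: after superposition, the pairwise RMSD between two frames
    of the same cluster concentrates around sqrt(2)*sd, while frames of
    different clusters sit near the center-center RMSD.  Planted clusters
    are recoverable by single-linkage at cutoff c when
    ``sqrt(2)*sd + 3*sd/sqrt(n_atoms) < c`` and every pair of centers is
    farther than ``c + 6*sd`` apart (no chaining across clusters).
    """

    center_structures: list            # list of (n_atoms, 3) arrays, nm
    weights: tuple = None
    within_cluster_sd_nm: float = 0.03
    n_frames: int = 500
    seed: int = 0
    dt_frame_ns: float = 1.0
    atoms: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.center_structures = [np.asarray(c, dtype=float) for c in self.center_structures]
        if not self.center_structures:
            raise ValueError("need at least one center structure")
        shapes = {c.shape for c in self.center_structures}
        if len(shapes) != 1 or self.center_structures[0].ndim != 2 \
                or self.center_structures[0].shape[1] != 3:
            raise ValueError("centers must share one (n_atoms, 3) shape")
        k = len(self.center_structures)
        if self.weights is None:
            self.weights = tuple([1.0 / k] * k)
        self.weights = tuple(float(w) for w in self.weights)
        if len(self.weights) != k or any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative, one per center")
        if not math.isclose(sum(self.weights), 1.0, rel_tol=1e-9):
            raise ValueError("weights must sum to 1")
        if self.within_cluster_sd_nm < 0:
            raise ValueError("within_cluster_sd_nm must be non-negative")

    @property
    def k_clusters(self) -> int:
        return len(self.center_structures)

    @property
    def n_atoms(self) -> int:
        return self.center_structures[0].shape[0]


def simulate_ensemble(spec: EnsembleSpec):
    """Draw a :class:`~petquench.traj_analysis.TrajectoryEnsemble` from a
    planted-cluster spec.  Returns the ensemble and the true per-frame
    cluster assignment (0-based center index)."""
    from .traj_analysis import TrajectoryEnsemble  # deferred: avoid cycle

    rng = np.random.default_rng(spec.seed)
    assignment = rng.choice(spec.k_clusters, size=spec.n_frames, p=spec.weights)
    frames = np.empty((spec.n_frames, spec.n_atoms, 3))
    rots = Rotation.random(spec.n_frames, rng=rng)
    shifts = rng.normal(0.0, 1.0, (spec.n_frames, 3))
    for i, c in enumerate(assignment):
        coords = spec.center_structures[c]
        if spec.within_cluster_sd_nm > 0:
            coords = coords + rng.normal(0.0, spec.within_cluster_sd_nm,
                                         coords.shape)
        frames[i] = rots[i].apply(coords) + shifts[i]
    atoms = spec.atoms if spec.atoms is not None else default_atom_table(spec.n_atoms)
    ens = TrajectoryEnsemble(atoms=atoms,
                             reference=spec.center_structures[0].copy(),
                             frames=frames, dt_frame_ns=spec.dt_frame_ns)
    return ens, assignment


@dataclass
class PhotonSimParams:
    """Confocal photon-stream simulation parameters.

    ``n_particles`` is the composite model's N in the gamma-convention:
    the mean number of molecules inside the detection-profile integral
    volume ``V_obs = (pi/2)^(3/2) w^2 (p w)``, so the correlation
    amplitude extrapolates to ``gamma/N`` with ``gamma = 2^(-3/2)``.  The
    particle count in the periodic box is ``N * V_box / V_obs``.
    ``brightness_per_ms`` is the detected count rate of one permanently
    bright particle at the focus center; the mean detected rate is then
    ``brightness * N`` times the bright-state fractions.  With
    ``diff_coeff_um2_s = 0`` all particles sit immobile at the focus
    center (point-emitter mode).
    """

    n_particles: float = 1.0
    focus_lateral_nm: float = 195.0     # 1/e^2 lateral radius w
    axial_ratio: float = 2.0            # p
    diff_coeff_um2_s: float = 190.0
    brightness_per_ms: float = 400.0    # photons/ms at focus center
    box_size_nm: tuple | None = None    # default: 10 w in every direction
    triplet_fraction: float = 0.0
    tau_t_us: float = 2.0
    quench: TelegraphParams | None = None
    excited_lifetime_ns: float | None = None
    duration_s: float = 0.3
    tick_ps: float = 16.0
    dt_sim_s: float | None = None       # diffusion-envelope step
    split_channels: bool = True         # 50:50 beam-splitter emulation
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("focus_lateral_nm", "axial_ratio", "brightness_per_ms",
                     "duration_s", "tick_ps", "tau_t_us"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.triplet_fraction < 1.0:
            raise ValueError("triplet fraction must be in [0, 1)")
        if self.n_particles <= 0:
            raise ValueError("n_particles must be positive")
        if self.diff_coeff_um2_s < 0:
            raise ValueError("diffusion coefficient must be non-negative")
        if self.box_size_nm is None:
            self.box_size_nm = (10.0 * self.focus_lateral_nm,) * 3
        self.box_size_nm = tuple(float(b) for b in self.box_size_nm)

    @property
    def tau_d_s(self) -> float | None:
        if self.diff_coeff_um2_s == 0:
            return None
        w_um = self.focus_lateral_nm * 1e-3
        return w_um ** 2 / (4.0 * self.diff_coeff_um2_s)

    @property
    def v_obs_nm3(self) -> float:
        w = self.focus_lateral_nm
        return (math.pi / 2.0) ** 1.5 * w ** 3 * self.axial_ratio


def standard_photon_spec(seed: int = 0, duration_s: float = 0.3) -> PhotonSimParams:
    """The package's standard confocal study conditions.

    Diffusion in the measured physical regime (w = 195 nm, tau_D = 50 us,
    D ~ 190 um^2/s), triplet blinking (T = 0.2, tau_T = 2 us) and
    end-to-end quenching at the equilibrated-trajectory rates
    (k_form = 8.4, k_diss = 5.5 per us, i.e. tau_r = 72 ns).  Occupancy
    N = 0.3 and a bright emitter compress the statistics of a long
    measurement into a desk-scale record; see docs/methods.md.
    """
    w = 195.0
    tau_d_us = 50.0
    return PhotonSimParams(
        n_particles=0.3,
        focus_lateral_nm=w,
        axial_ratio=2.0,
        diff_coeff_um2_s=w ** 2 / (4.0 * tau_d_us),
        brightness_per_ms=2000.0,
        triplet_fraction=0.2,
        tau_t_us=2.0,
        quench=TelegraphParams(k_form_per_us=8.4, k_diss_per_us=5.5, seed=seed + 1),
        duration_s=duration_s,
        tick_ps=16.0,
        seed=seed,
    )


class _TelegraphThinner:
    """Exact state propagation of a stationary two-state process at
    arbitrary (sorted) query times; used to thin candidate photons."""

    def __init__(self, bright_fraction: float, relax_time_s: float):
        self.f = bright_fraction
        self.tau = relax_time_s

    def bright_at(self, times_s: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        n = times_s.size
        out = np.empty(n, dtype=bool)
        if n == 0:
            return out
        u = rng.random(n)
        f, tau = self.f, self.tau
        state = u[0] < f
        out[0] = state
        for i in range(1, n):
            e = math.exp(-(times_s[i] - times_s[i - 1]) / tau)
            p_bright = f + (state - f) * e
            state = u[i] < p_bright
            out[i] = state
        return out


def simulate_photons(params: PhotonSimParams) -> PhotonStream:
    """Simulate a confocal photon arrival-time stream.

    Brownian particles move in a periodic box; the instantaneous detected
    rate is ``brightness * sum_i exp(-2x^2/w^2 - 2y^2/w^2 - 2z^2/(p w)^2)``
    modulated per particle by triplet and quenching telegraph factors.
    Candidate photons are drawn from the diffusion envelope (inhomogeneous
    Poisson), attributed to particles by their intensity share, thinned by
    the exact per-particle blinking states, optionally spaced by an
    exponential excited-state dwell (antibunching), quantized to the tick
    resolution and optionally split 50:50 onto two channels.
    """
    rng = np.random.default_rng(params.seed)
    w = params.focus_lateral_nm
    wz = params.axial_ratio * w
    box = np.asarray(params.box_size_nm)
    brightness_hz = params.brightness_per_ms * 1e3

    immobile = params.diff_coeff_um2_s == 0.0
    if immobile:
        n_part = max(1, int(round(params.n_particles)))
        cand_t, cand_p = _candidates_immobile(params, n_part, brightness_hz, rng)
    else:
        tau_d = params.tau_d_s
        dt = params.dt_sim_s if params.dt_sim_s is not None else tau_d / 50.0
        if dt > tau_d / 10.0:
            raise ValueError("diffusion step coarser than tau_D/10: refusing "
                             "(correlation shape would be distorted)")
        v_box = float(np.prod(box))
        n_part = max(1, int(round(params.n_particles * v_box / params.v_obs_nm3)))
        cand_t, cand_p = _candidates_diffusing(params, n_part, brightness_hz,
                                               w, wz, box, dt, rng)

    keep = np.ones(cand_t.size, dtype=bool)
    trip = quench = None
    if params.triplet_fraction > 0:
        trip = _TelegraphThinner(1.0 - params.triplet_fraction, params.tau_t_us * 1e-6)
    if params.quench is not None:
        q = params.quench
        quench = _TelegraphThinner(q.bright_fraction, q.relax_time_ns * 1e-9)
    if trip is not None or quench is not None:
        order = np.lexsort((cand_t, cand_p))
        for thinner in (trip, quench):
            if thinner is None:
                continue
            ok = np.ones(cand_t.size, dtype=bool)
            for pid in range(n_part):
                sel = order[cand_p[order] == pid]
                if sel.size:
                    ok[sel] = thinner.bright_at(cand_t[sel], rng)
            keep &= ok
    cand_t, cand_p = cand_t[keep], cand_p[keep]

    if params.excited_lifetime_ns is not None:
        cand_t, cand_p = _apply_antibunching(cand_t, cand_p, n_part,
                                             params.excited_lifetime_ns * 1e-9, rng)

    tick_s = params.tick_ps * 1e-12
    ticks = np.sort(np.floor(cand_t / tick_s).astype(np.int64))
    if params.split_channels:
        to_b = rng.random(ticks.size) < 0.5
        chans = (np.unique(ticks[~to_b]), np.unique(ticks[to_b]))
    else:
        chans = (np.unique(ticks),)
    return PhotonStream(chans, params.tick_ps, params.duration_s)


def _candidates_immobile(params, n_part, brightness_hz, rng):
    rate = brightness_hz * n_part
    n = rng.poisson(rate * params.duration_s)
    t = np.sort(rng.random(n) * params.duration_s)
    p = rng.integers(0, n_part, size=n)
    return t, p


def _candidates_diffusing(params, n_part, brightness_hz, w, wz, box, dt, rng):
    n_steps = int(math.ceil(params.duration_s / dt))
    d_nm2_s = params.diff_coeff_um2_s * 1e6
    step_sd = math.sqrt(2.0 * d_nm2_s * dt)
    # positions kept as (n_part*3, time) so the Brownian cumsum runs along a
    # contiguous axis; float32 rounding (~1e-7 of the box) is far below the
    # Brownian step itself
    pos = ((rng.random(n_part * 3) - 0.5) * np.tile(box, n_part)).astype(np.float32)
    box32 = np.tile(box, n_part).astype(np.float32)[:, None]
    inv = np.array([2.0 / w ** 2, 2.0 / w ** 2, 2.0 / wz ** 2], dtype=np.float32)
    chunk = max(1, int(4e6 // n_part))
    all_t, all_p = [], []
    start = 0
    while start < n_steps:
        size = min(chunk, n_steps - start)
        steps = rng.standard_normal((n_part * 3, size), dtype=np.float32)
        steps *= np.float32(step_sd)
        traj = np.cumsum(steps, axis=1)
        traj += pos[:, None]
        pos = traj[:, -1].copy()
        traj += 0.5 * box32
        traj %= box32
        traj -= 0.5 * box32
        view = traj.reshape(n_part, 3, size)
        wgt = np.exp(-(np.square(view) * inv[None, :, None]).sum(axis=1,
                                                                 dtype=np.float32))
        wgt = wgt.astype(float)                          # (n_part, size)
        tot = wgt.sum(axis=0)
        counts = rng.poisson(brightness_hz * dt * tot)
        k = int(counts.sum())
        if k:
            step_idx = np.repeat(np.arange(size), counts)
            csum = np.cumsum(wgt[:, step_idx], axis=0)   # (n_part, k)
            u = rng.random(k) * tot[step_idx]
            # particle attribution by intensity share within the step
            pid = (csum < u[None, :]).sum(axis=0)
            t = (start + step_idx + rng.random(k)) * dt
            all_t.append(t)
            all_p.append(pid.astype(np.int64))
        start += size
    if all_t:
        t = np.concatenate(all_t)
        p = np.concatenate(all_p)
        ok = t < params.duration_s
        return t[ok], p[ok]
    return np.empty(0), np.empty(0, np.int64)


def _apply_antibunching(t, p, n_part, tau_ab_s, rng):
    order = np.lexsort((t, p))
    keep = np.ones(t.size, dtype=bool)
    blocked_until = np.zeros(n_part)
    for idx in order:
        pid = p[idx]
        if t[idx] < blocked_until[pid]:
            keep[idx] = False
        else:
            blocked_until[pid] = t[idx] + rng.exponential(tau_ab_s)
    return t[keep], p[keep]
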