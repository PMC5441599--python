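"""Closed-form FCS model functions and kinetic parameter transformations.

The composite correlation model for a freely diffusing fluorophore with
photophysics and conformational quenching reads

    G(tau) = gamma/N * (1 + tau/tau_D)^-1 * (1 + tau/(p^2 tau_D))^-1/2
             * (1 - A_ab exp(-tau/tau_ab))
             * (1 + T/(1-T) exp(-tau/tau_T))
             * (1 + sum_i a_r,i exp(-tau/tau_r,i))

i.e. the fluctuation (excess) part including the diffusion decay; a measured
raw correlation that converges to 1 at large lags equals 1 + G(tau).
``gamma = 2**-1.5`` corrects for the 3D-Gaussian shape of the confocal
volume and ``p`` is the axial/lateral aspect ratio.

The dynamic (quenching) term ``a_r exp(-tau/tau_r)`` maps onto microscopic
contact formation/dissociation rates.  Two conventions are provided because
the commonly printed relations

    tau_r = 1/(k_on + k_off),    a_r = k_off/k_on        ("as_printed")

assign the amplitude to the rate ratio opposite to what the two-state
telegraph closed form gives, where the amplitude equals
(dark fraction)/(bright fraction) = k_on/k_off for k_on the rate *into* the
dark (contact-formed) state ("telegraph_oracle").  Both are exact inverses
of each other's round trip; they differ only in which physical rate is
called k_on.  See docs/methods.md for the full discussion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import CorrelationCurve

__all__ = [
    "GAMMA_3D_GAUSSIAN",
    "FCSModelParams",
    "DynamicFit",
    "FocalGeometry",
    "fcs_model",
    "dyn_model",
    "rates_from_dynamics",
    "dynamics_from_rates",
    "isolate_dynamic",
    "diffusion_coefficient",
    "diffusion_time",
    "combine_two_component",
]

#: shape correction for a 3D-Gaussian confocal volume
GAMMA_3D_GAUSSIAN = 2.0 ** -1.5


@dataclass
class FCSModelParams:
    """Parameter set of the composite FCS model (times in seconds)."""

    n: float = 1.0                 # mean particles in focus
    tau_d_s: float = 1e-4          # diffusion time
    p: float = 5.0                 # axial/lateral aspect ratio
    gamma: float = GAMMA_3D_GAUSSIAN
    a_ab: float = 0.0              # antibunching amplitude
    tau_ab_s: float = 2e-9
    triplet_frac: float = 0.0      # triplet fraction T in [0, 1)
    tau_t_s: float = 2e-6
    dyn_terms: tuple = ()          # ((a_r, tau_r_s), ...) with 0..2 entries

    def __post_init__(self) -> None:
        self.dyn_terms = tuple((float(a), float(t)) for a, t in self.dyn_terms)
        if self.n <= 0:
            raise ValueError("N must be positive")
        for name in ("tau_d_s", "tau_ab_s", "tau_t_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.triplet_frac < 1.0:
            raise ValueError("triplet fraction must be in [0, 1)")
        if self.a_ab < 0:
            raise ValueError("antibunching amplitude must be non-negative")
        if len(self.dyn_terms) > 2:
            raise ValueError("at most two dynamic terms are supported")
        for a, t in self.dyn_terms:
            if a < 0 or t <= 0:
                raise ValueError("dynamic terms need a >= 0 and tau > 0")

    def without_dynamics(self) -> "FCSModelParams":
        return replace(self, dyn_terms=())


@dataclass
class DynamicFit:
    """Single-exponential dynamic term with attached microscopic rates.

    Invariant (either convention): tau_r = 1/(k_on + k_off) and the
    amplitude equals the printed rate ratio for that convention, to machine
    precision (round trip with :func:`dynamics_from_rates`).
    """

    a_r: float
    tau_r_s: float
    k_on_per_s: float
    k_off_per_s: float
    convention: str = "as_printed"
    fit: object = field(default=None, repr=False, compare=False)

    @property
    def tau_r_ns(self) -> float:
        return self.tau_r_s * 1e9

    @property
    def k_on_per_us(self) -> float:
        return self.k_on_per_s * 1e-6

    @property
    def k_off_per_us(self) -> float:
        return self.k_off_per_s * 1e-6


@dataclass
class FocalGeometry:
    """Confocal focus geometry linking diffusion time and coefficient.

    Stores the 1/e^2 lateral radius ``w`` (nm), the axial/lateral ratio
    ``p`` and the diffusion time ``tau_D``; ``D = w^2/(4 tau_D)``.
    """

    w_lateral_nm: float
    tau_d_us: float
    p: float = 5.0

    def __post_init__(self) -> None:
        if self.w_lateral_nm <= 0 or self.tau_d_us <= 0 or self.p <= 0:
            raise ValueError("focal geometry values must be positive")

    @property
    def d_um2_s(self) -> float:
        return diffusion_coefficient(self.w_lateral_nm, self.tau_d_us)


def fcs_model(tau_s, params: FCSModelParams):
    """Evaluate the composite model at lag(s) ``tau_s`` (excess form)."""
    tau = np.asarray(tau_s, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("the model is defined for tau > 0")
    if params.triplet_frac >= 1.0:
        raise ValueError("triplet fraction T = 1 is singular")
    g = (params.gamma / params.n
         / (1.0 + tau / params.tau_d_s)
         / np.sqrt(1.0 + tau / (params.p ** 2 * params.tau_d_s)))
    if params.a_ab != 0.0:
        g = g * (1.0 - params.a_ab * np.exp(-tau / params.tau_ab_s))
    if params.triplet_frac != 0.0:
        t = params.triplet_frac
        g = g * (1.0 + t / (1.0 - t) * np.exp(-tau / params.tau_t_s))
    if params.dyn_terms:
        dyn = 1.0
        for a, tr in params.dyn_terms:
            dyn = dyn + a * np.exp(-tau / tr)
        g = g * dyn
    return g if g.shape else float(g)


def dyn_model(tau_s, a_r: float, tau_r_s: float):
    """Single-exponential dynamic correlation ``a_r exp(-tau/tau_r)``."""
    tau = np.asarray(tau_s, dtype=float)
    out = a_r * np.exp(-tau / tau_r_s)
    return out if out.shape else float(out)


def rates_from_dynamics(a_r: float, tau_r_s: float,
                        convention: str = "as_printed") -> tuple[float, float]:
    """Convert a dynamic-term (amplitude, relaxation time) to (k_on, k_off).

    Both conventions share tau_r = 1/(k_on + k_off); they differ in whether
    the amplitude is read as k_off/k_on (``as_printed``) or k_on/k_off
    (``telegraph_oracle``).  Rates are returned per second for tau in
    seconds.
    """
    if a_r <= 0:
        raise ValueError("amplitude must be positive")
    if tau_r_s <= 0:
        raise ValueError("relaxation time must be positive")
    k_sum = 1.0 / tau_r_s
    if convention == "as_printed":
        k_on = k_sum / (1.0 + a_r)
        k_off = a_r * k_on
    elif convention == "telegraph_oracle":
        k_off = k_sum / (1.0 + a_r)
        k_on = a_r * k_off
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return k_on, k_off


def dynamics_from_rates(k_on_per_s: float, k_off_per_s: float,
                        convention: str = "as_printed") -> tuple[float, float]:
    """Inverse of :func:`rates_from_dynamics`; round trip is the identity."""
    if k_on_per_s <= 0 or k_off_per_s <= 0:
        raise ValueError("rates must be positive")
    tau_r = 1.0 / (k_on_per_s + k_off_per_s)
    if convention == "as_printed":
        a_r = k_off_per_s / k_on_per_s
    elif convention == "telegraph_oracle":
        a_r = k_on_per_s / k_off_per_s
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return a_r, tau_r


def isolate_dynamic(curve: CorrelationCurve, params: FCSModelParams) -> CorrelationCurve:
    """Divide out diffusion, photophysics and antibunching; return the
    excess dynamic part ``sum_i a_r,i exp(-tau/tau_r,i)``.

    ``params`` holds the fitted non-dynamic parameters (any dyn_terms on it
    are ignored).  The input curve may be raw (baseline 1, which is removed
    first) or already in the excess form of the composite model.
    """
    excess = curve.to_excess()
    base = fcs_model(excess.lags_s, params.without_dynamics())
    base = np.asarray(base, dtype=float)
    if np.any(base <= 0):
        raise ValueError("non-dynamic model factor is non-positive at some lag "
                         "(check the antibunching amplitude)")
    values = excess.values / base - 1.0
    sigma = None if excess.sigma is None else excess.sigma / base
    return CorrelationCurve(excess.lags_s, values, sigma, "excess", excess.npairs)


def diffusion_coefficient(w_lateral_nm: float, tau_d_us: float) -> float:
    """D = w^2/(4 tau_D), returned in um^2/s for w in nm and tau_D in us."""
    if w_lateral_nm <= 0 or tau_d_us <= 0:
        raise ValueError("w and tau_D must be positive")
    # nm^2/us happens to equal um^2/s exactly
    return w_lateral_nm ** 2 / (4.0 * tau_d_us)


def diffusion_time(w_lateral_nm: float, d_um2_s: float) -> float:
    """tau_D = w^2/(4 D) in us; inverse of :func:`diffusion_coefficient`."""
    if w_lateral_nm <= 0 or d_um2_s <= 0:
        raise ValueError("w and D must be positive")
    return w_lateral_nm ** 2 / (4.0 * d_um2_s)


def combine_two_component(a1: float, tau1: float, a2: float, tau2: float,
                          average: str = "amplitude") -> tuple[float, float]:
    """Total amplitude and average relaxation time of two dynamic terms.

    The default is the amplitude-weighted mean
    (a1 tau1 + a2 tau2)/(a1 + a2); ``average="arithmetic"`` uses the plain
    mean of the two times.
    """
    if a1 < 0 or a2 < 0:
        raise ValueError("amplitudes must be non-negative")
    if a1 + a2 == 0:
        raise ValueError("at least one amplitude must be positive")
    a_total = a1 + a2
    if average == "amplitude":
        tau_avg = (a1 * tau1 + a2 * tau2) / a_total
    elif average == "arithmetic":
        tau_avg = 0.5 * (tau1 + tau2)
    else:
        raise ValueError(f"unknown averaging mode {average!r}")
    return a_total, tau_avg
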