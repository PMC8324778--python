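"""Kinetics of thrombin inactivation by plasma inhibitors.

Free thrombin is removed by three channels: a second-order reaction with
antithrombin (AT), a second-order reaction with alpha2-macroglobulin (a2M),
and a first-order miscellaneous loss. With inhibitor consumption tracked,

    d(T-AT)/dt  = k_AT  * [AT]_t  * T_free
    d(T-a2M)/dt = k_a2M * [a2M]_t * T_free
    d(T-MS)/dt  = k_MS * T_free
    -d(T_free)/dt = sum of the three

where [AT]_t = [AT]_0 - T-AT(t) and likewise for a2M. The pseudo-first-order
summary of a plasma's inhibitory potential is the thrombin decay capacity
TDC = k_AT*[AT]_0 + k_a2M*[a2M]_0 + k_MS (min^-1), the decay rate an
impulse of thrombin sees at the initial inhibitor levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .curves import PlasmaProfile

__all__ = [
    "RateConstants",
    "InactivationOptions",
    "InactivationState",
    "TDCValue",
    "thrombin_decay_capacity",
    "inactivation_rates",
    "simulate_decay",
]


@dataclass(frozen=True)
class RateConstants:
    """Second- and first-order thrombin inactivation rate constants.

    ``k_at`` and ``k_a2m`` are nM^-1 min^-1, ``k_ms`` is min^-1. The
    optional fibrinogen slopes modify the second-order constants linearly
    per g/L of fibrinogen (default 0: no dependence). Shipped defaults are
    placeholders intended for re-calibration against a reference plasma;
    all downstream results echo the constants actually used.
    """

    k_at: float = 3.0e-4
    k_a2m: float = 1.0e-5
    k_ms: float = 0.01
    fibrinogen_slope_at: float = 0.0
    fibrinogen_slope_a2m: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_at", "k_a2m", "k_ms"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def k_at_eff(self, fibrinogen: float = 0.0) -> float:
        """AT rate constant at a given fibrinogen level (g/L)."""
        k = self.k_at * (1.0 + self.fibrinogen_slope_at * fibrinogen)
        if k < 0:
            raise ValueError(
                f"effective k_at negative at fibrinogen={fibrinogen:g} g/L"
            )
        return k

    def k_a2m_eff(self, fibrinogen: float = 0.0) -> float:
        k = self.k_a2m * (1.0 + self.fibrinogen_slope_a2m * fibrinogen)
        if k < 0:
            raise ValueError(
                f"effective k_a2m negative at fibrinogen={fibrinogen:g} g/L"
            )
        return k

    def as_dict(self) -> dict[str, float]:
        return {
            "k_at": self.k_at,
            "k_a2m": self.k_a2m,
            "k_ms": self.k_ms,
            "fibrinogen_slope_at": self.fibrinogen_slope_at,
            "fibrinogen_slope_a2m": self.fibrinogen_slope_a2m,
        }


@dataclass(frozen=True)
class TDCValue:
    """Thrombin decay capacity, min^-1."""

    tdc: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.tdc) or self.tdc < 0:
            raise ValueError(f"tdc must be finite and >= 0, got {self.tdc!r}")


@dataclass(frozen=True)
class InactivationOptions:
    """Integration settings for the decay simulator.

    ``step`` is the fixed RK4 step in minutes; ``consume_inhibitors``
    selects whether [AT]_t and [a2M]_t are depleted by complex formation
    (True, the physical model) or held at their initial values (False,
    the pseudo-first-order limit with closed-form solution).
    """

    step: float = 0.01
    t_end: float = 20.0
    consume_inhibitors: bool = True

    def __post_init__(self) -> None:
        if not (self.step > 0):
            raise ValueError(f"step must be > 0, got {self.step!r}")
        if not (self.t_end > 0):
            raise ValueError(f"t_end must be > 0, got {self.t_end!r}")


@dataclass
class InactivationState:
    """Trajectories of all thrombin pools from a decay simulation.

    All arrays share the time grid. ``t_at``/``t_a2m``/``t_ms`` are the
    cumulative complex/loss pools; ``at_remaining``/``a2m_remaining`` the
    free inhibitor levels; ``t_inh`` the total inhibited thrombin.
    """

    time: np.ndarray
    t_free: np.ndarray
    t_at: np.ndarray
    t_a2m: np.ndarray
    t_ms: np.ndarray
    at_remaining: np.ndarray
    a2m_remaining: np.ndarray

    @property
    def t_inh(self) -> np.ndarray:
        return self.t_at + self.t_a2m + self.t_ms

    @property
    def total(self) -> np.ndarray:
        """Conserved total: free + inhibited thrombin."""
        return self.t_free + self.t_inh


def thrombin_decay_capacity(plasma: PlasmaProfile, k: RateConstants) -> TDCValue:
    """TDC = k_AT*[AT]_0 + k_a2M*[a2M]_0 + k_MS at the plasma's levels.

    Fibrinogen modifiers, when configured, act through the effective rate
    constants.
    """
    kat = k.k_at_eff(plasma.fibrinogen)
    ka2m = k.k_a2m_eff(plasma.fibrinogen)
    return TDCValue(kat * plasma.at_level + ka2m * plasma.a2m_level + k.k_ms)


def inactivation_rates(
    t_free: float, at_t: float, a2m_t: float, k: RateConstants,
    fibrinogen: float = 0.0,
) -> tuple[float, float, float]:
    """Instantaneous complex-formation rates (d t_at, d t_a2m, d t_ms)/dt.

    Single source of truth for the rate law; used by both the inverse
    problem (conversion extraction) and the forward simulator.
    """
    if t_free < 0 or at_t < 0 or a2m_t < 0:
        raise ValueError("inactivation_rates requires non-negative inputs")
    return (
        k.k_at_eff(fibrinogen) * at_t * t_free,
        k.k_a2m_eff(fibrinogen) * a2m_t * t_free,
        k.k_ms * t_free,
    )


def simulate_decay(
    t0: float,
    plasma: PlasmaProfile,
    k: RateConstants,
    options: InactivationOptions | None = None,
) -> InactivationState:
    """Decay of an initial thrombin impulse ``t0`` (nM) in a given plasma.

    Fixed-step classical RK4; with consumption disabled the trajectory is
    the closed-form exponential t0*exp(-TDC*t). Conservation
    t_free + t_at + t_a2m + t_ms = t0 holds to integrator tolerance.
    """
    if t0 < 0:
        raise ValueError(f"t0 must be >= 0, got {t0!r}")
    opt = options or InactivationOptions()
    kat = k.k_at_eff(plasma.fibrinogen)
    ka2m = k.k_a2m_eff(plasma.fibrinogen)
    kms = k.k_ms
    at0 = plasma.at_level
    a2m0 = plasma.a2m_level
    consume = opt.consume_inhibitors

    n = int(round(opt.t_end / opt.step))
    time = np.linspace(0.0, n * opt.step, n + 1)
    t_free = np.empty(n + 1)
    t_at = np.empty(n + 1)
    t_a2m = np.empty(n + 1)
    t_ms = np.empty(n + 1)
    t_free[0], t_at[0], t_a2m[0], t_ms[0] = t0, 0.0, 0.0, 0.0

    h = opt.step

    def deriv(T: float, cat: float, ca2m: float):
        at_t = max(at0 - cat, 0.0) if consume else at0
        a2m_t = max(a2m0 - ca2m, 0.0) if consume else a2m0
        r_at = kat * at_t * T
        r_a2m = ka2m * a2m_t * T
        r_ms = kms * T
        return (-(r_at + r_a2m + r_ms), r_at, r_a2m, r_ms)

    T, cat, ca2m, cms = t0, 0.0, 0.0, 0.0
    for i in range(1, n + 1):
        k1 = deriv(T, cat, ca2m)
        k2 = deriv(T + 0.5 * h * k1[0], cat + 0.5 * h * k1[1], ca2m + 0.5 * h * k1[2])
        k3 = deriv(T + 0.5 * h * k2[0], cat + 0.5 * h * k2[1], ca2m + 0.5 * h * k2[2])
        k4 = deriv(T + h * k3[0], cat + h * k3[1], ca2m + h * k3[2])
        T += h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        cat += h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        ca2m += h / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        cms += h / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        T = max(T, 0.0)
        t_free[i], t_at[i], t_a2m[i], t_ms[i] = T, cat, ca2m, cms

    at_rem = np.maximum(at0 - t_at, 0.0) if consume else np.full(n + 1, at0)
    a2m_rem = np.maximum(a2m0 - t_a2m, 0.0) if consume else np.full(n + 1, a2m0)
    return InactivationState(time, t_free, t_at, t_a2m, t_ms, at_rem, a2m_rem)
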