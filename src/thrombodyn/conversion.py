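"""Prothrombin-conversion extraction from measured TG curves.

The measured free-thrombin curve T(t) is the net of a source (prothrombin
conversion by prothrombinase) and a sink (inactivation by plasma
inhibitors):

    dT/dt = -dP/dt - d(T-inh)/dt

so the conversion rate is recovered as

    -dP/dt = dT/dt + k_AT*[AT]_t*T + k_a2M*[a2M]_t*T   (+ k_MS*T, optional)

with the inhibitor levels depleted along the curve by the accumulating
complexes. The curve is quantified by PCtot (total prothrombin converted,
nM), PCmax (maximum conversion rate, nM/min) and the complex totals T-AT
and T-a2M.

The first-order k_MS channel is excluded from the inversion by default;
``include_ms=True`` adds it for sensitivity analysis. Forward and inverse
runs must use the same setting for round trips to close.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import savgol_filter

from .curves import AnalysisError, PlasmaProfile, TGCurve, TGParameters, compute_tg_parameters
from .inactivation import RateConstants, TDCValue, thrombin_decay_capacity

__all__ = [
    "PCCurve",
    "InversionOptions",
    "ThrombinDynamicsResult",
    "DerivativeResult",
    "differentiate_curve",
    "extract_prothrombin_conversion",
    "write_pc_curve",
    "read_pc_curve",
    "results_to_frame",
]


@dataclass
class PCCurve:
    """A prothrombin-conversion rate time series.

    ``rate`` is -dP/dt in nM/min (non-negative); ``prothrombin_consumed``
    is its running trapezoidal integral (computed automatically when not
    supplied) and is non-decreasing.
    """

    time: np.ndarray
    rate: np.ndarray
    prothrombin_consumed: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.rate.shape:
            raise ValueError("time and rate must be 1-D and equal length")
        if self.time.size < 2:
            raise ValueError("PC curve needs at least 2 samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid not strictly increasing")
        if not np.all(np.isfinite(self.rate)):
            raise ValueError("non-finite conversion rates")
        if self.rate.min() < -1e-9:
            raise ValueError(
                f"negative conversion rate {self.rate.min():g}; clip before constructing"
            )
        self.rate = np.clip(self.rate, 0.0, None)
        if self.prothrombin_consumed is None:
            self.prothrombin_consumed = cumulative_trapezoid(
                self.rate, self.time, initial=0.0
            )
        else:
            self.prothrombin_consumed = np.asarray(self.prothrombin_consumed, float)

    @property
    def pc_tot(self) -> float:
        """Total prothrombin converted, nM."""
        return float(self.prothrombin_consumed[-1])

    @property
    def pc_max(self) -> float:
        """Maximum conversion rate, nM/min."""
        return float(self.rate.max())

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))


@dataclass(frozen=True)
class InversionOptions:
    """Settings for the conversion extraction.

    ``smooth_window``/``polyorder`` control the local-polynomial smoothing
    used for the thrombin series and its derivative; ``rate_smooth_window``
    applies one further pass to the assembled rate before clipping.
    Windows are sample counts (odd); the default ``"auto"`` estimates the
    record's noise level from second differences and disables smoothing on
    clean records (where smoothing bias, not noise, limits accuracy).
    ``restrict_to_main_pulse`` zeroes the rate outside the contiguous
    positive region around its maximum, removing the positive bias that
    rectified baseline noise would otherwise add to PCtot; the removed
    mass is reported. ``include_ms`` adds the first-order loss channel to
    the inversion; ``consume_inhibitors`` depletes [AT]_t/[a2M]_t along
    the curve (the physical default).
    """

    smooth_window: int | str = "auto"
    polyorder: int = 2
    rate_smooth_window: int | str = "auto"
    include_ms: bool = False
    consume_inhibitors: bool = True
    restrict_to_main_pulse: bool = True
    noise_sd_threshold: float = 0.2
    max_clip_fraction: float = 0.25
    terminal_free_fraction: float = 0.02

    def resolve_windows(self, curve: TGCurve) -> tuple[int, int]:
        """Concrete (smooth_window, rate_smooth_window) for a record."""
        auto = self.smooth_window == "auto" or self.rate_smooth_window == "auto"
        if auto:
            sigma = estimate_noise_sd(curve)
            auto_w = 1 if sigma < self.noise_sd_threshold else 9
        w1 = auto_w if self.smooth_window == "auto" else int(self.smooth_window)
        w2 = auto_w if self.rate_smooth_window == "auto" else int(self.rate_smooth_window)
        return w1, w2


@dataclass
class ThrombinDynamicsResult:
    """Full output of a thrombin-dynamics analysis of one TG curve."""

    pc_tot: float
    pc_max: float
    t_at_total: float
    t_a2m_total: float
    t_ms_total: float
    terminal_free: float
    tdc: float
    tg_params: TGParameters
    pc_curve: PCCurve
    clipped_mass: float
    clip_fraction: float
    trimmed_mass: float
    settings: dict
    warnings: list[str] = field(default_factory=list)
    incomplete_decay: bool = False
    label: str = ""

    def conservation_residual(self) -> float:
        """Relative gap in PCtot = T-AT + T-a2M (+ T-MS) + terminal free."""
        rhs = self.t_at_total + self.t_a2m_total + self.t_ms_total + self.terminal_free
        denom = max(self.pc_tot, 1e-12)
        return (self.pc_tot - rhs) / denom

    def as_row(self) -> dict[str, float]:
        row = {
            "label": self.label,
            "pc_tot_nM": self.pc_tot,
            "pc_max_nM_min": self.pc_max,
            "t_at_nM": self.t_at_total,
            "t_a2m_nM": self.t_a2m_total,
            "tdc_per_min": self.tdc,
        }
        row.update(self.tg_params.as_dict())
        return row


@dataclass(frozen=True)
class DerivativeResult:
    """A numerical derivative with its smoothing settings echoed."""

    values: np.ndarray
    window: int
    polyorder: int
    method: str


def estimate_noise_sd(curve: TGCurve) -> float:
    """Robust noise SD (nM) from second differences of the record.

    For i.i.d. noise the second difference has variance 6*sigma^2; the
    median absolute deviation makes the estimate insensitive to the
    smooth curve itself.
    """
    d2 = np.diff(curve.thrombin, 2)
    if d2.size == 0:
        return 0.0
    mad = float(np.median(np.abs(d2 - np.median(d2))))
    return mad / 0.6744897501960817 / math.sqrt(6.0)


def _smooth(y: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    if window <= 1:
        return y.copy()
    return savgol_filter(y, window_length=window, polyorder=polyorder, mode="interp")


def _central_diff(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Central differences with one-sided ends.

    On a uniform grid the trapezoidal integral of this derivative
    telescopes exactly to y[-1] - y[0].
    """
    d = np.empty_like(y)
    d[1:-1] = (y[2:] - y[:-2]) / (t[2:] - t[:-2])
    d[0] = (y[1] - y[0]) / (t[1] - t[0])
    d[-1] = (y[-1] - y[-2]) / (t[-1] - t[-2])
    return d


def _diff4(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fourth-order central differences (uniform grid), second-order ends.

    Used in the smoothing-free path, where derivative bias rather than
    noise limits accuracy.
    """
    h = t[1] - t[0]
    d = np.empty_like(y)
    d[2:-2] = (-y[4:] + 8 * y[3:-1] - 8 * y[1:-3] + y[:-4]) / (12 * h)
    d[1] = (y[2] - y[0]) / (2 * h)
    d[-2] = (y[-1] - y[-3]) / (2 * h)
    d[0] = (y[1] - y[0]) / h
    d[-1] = (y[-1] - y[-2]) / h
    return d


def differentiate_curve(
    curve: TGCurve, window: int = 9, polyorder: int = 2
) -> DerivativeResult:
    """Smoothed numerical dT/dt on the curve's own grid.

    The series is smoothed by a local polynomial fit (Savitzky-Golay) and
    differenced centrally; with ``window=1`` (no smoothing) the trapezoidal
    integral of the derivative reproduces the endpoint difference of the
    data exactly.
    """
    if len(curve) < 5:
        raise AnalysisError("need at least 5 samples to differentiate")
    if window > len(curve):
        raise ValueError(f"window {window} larger than record ({len(curve)})")
    if window > 1 and window % 2 == 0:
        raise ValueError("window must be odd")
    t = curve.time
    if window > 1 and not curve.is_uniform(rtol=1e-3):
        # savgol assumes uniform spacing; go through a uniform working grid
        tu = np.linspace(t[0], t[-1], t.size)
        yu = _smooth(np.interp(tu, t, curve.thrombin), window, polyorder)
        ys = np.interp(t, tu, yu)
        d, method = _central_diff(t, ys), "savgol+central"
    elif window <= 1 and curve.is_uniform(rtol=1e-3):
        ys = curve.thrombin
        d, method = _diff4(t, ys), "central4"
    else:
        ys = _smooth(curve.thrombin, window, polyorder)
        d, method = _central_diff(t, ys), "savgol+central"
    # integral-consistent boundary closure: the trapezoidal integral of the
    # derivative reproduces the (smoothed) series' endpoint difference
    delta = (ys[-1] - ys[0]) - float(np.trapezoid(d, t))
    span = 0.5 * ((t[1] - t[0]) + (t[-1] - t[-2]))
    d[0] += delta / span
    d[-1] += delta / span
    return DerivativeResult(d, window, polyorder, method)


def extract_prothrombin_conversion(
    curve: TGCurve,
    plasma: PlasmaProfile,
    k: RateConstants,
    options: InversionOptions | None = None,
) -> ThrombinDynamicsResult:
    """Reconstruct the prothrombin-conversion curve behind a TG curve.

    The thrombin series is smoothed, differentiated, and combined with the
    inactivation rate law evaluated at running (depleted) inhibitor levels.
    Negative rate excursions (noise) are clipped to zero after smoothing
    and the clipped mass is reported, never silently discarded.
    """
    opt = options or InversionOptions()
    curve.require_analyzable()
    t = curve.time
    n = t.size
    w1, w2 = opt.resolve_windows(curve)
    for name, w in (("smooth_window", w1), ("rate_smooth_window", w2)):
        if w > n:
            raise ValueError(f"{name} {w} larger than record ({n})")

    deriv = differentiate_curve(curve, w1, opt.polyorder)
    tsm = _smooth(curve.thrombin, w1, opt.polyorder)
    tpos = np.clip(tsm, 0.0, None)

    kat = k.k_at_eff(plasma.fibrinogen)
    ka2m = k.k_a2m_eff(plasma.fibrinogen)
    kms = k.k_ms if opt.include_ms else 0.0
    at0 = plasma.at_level
    a2m0 = plasma.a2m_level

    r_at = np.empty(n)
    r_a2m = np.empty(n)
    r_at[0] = kat * at0 * tpos[0]
    r_a2m[0] = ka2m * a2m0 * tpos[0]
    cat = 0.0   # cumulative T-AT
    ca2m = 0.0  # cumulative T-a2M
    for i in range(1, n):
        h = t[i] - t[i - 1]
        if opt.consume_inhibitors:
            # trapezoidal predictor-corrector for the depletion integral
            at_i = max(at0 - (cat + h * r_at[i - 1]), 0.0)
            a2m_i = max(a2m0 - (ca2m + h * r_a2m[i - 1]), 0.0)
            ri_at = kat * at_i * tpos[i]
            ri_a2m = ka2m * a2m_i * tpos[i]
            at_i = max(at0 - (cat + 0.5 * h * (r_at[i - 1] + ri_at)), 0.0)
            a2m_i = max(a2m0 - (ca2m + 0.5 * h * (r_a2m[i - 1] + ri_a2m)), 0.0)
        else:
            at_i, a2m_i = at0, a2m0
        r_at[i] = kat * at_i * tpos[i]
        r_a2m[i] = ka2m * a2m_i * tpos[i]
        cat += 0.5 * h * (r_at[i - 1] + r_at[i])
        ca2m += 0.5 * h * (r_a2m[i - 1] + r_a2m[i])

    r_ms = kms * tpos
    raw_rate = deriv.values + r_at + r_a2m + r_ms
    if w2 > 1:
        rate_s = _smooth(raw_rate, w2, opt.polyorder)
    else:
        rate_s = raw_rate

    neg = np.clip(rate_s, None, 0.0)
    clipped_mass = float(-np.trapezoid(neg, t))
    rate = np.clip(rate_s, 0.0, None)
    trimmed_mass = 0.0
    if opt.restrict_to_main_pulse and rate.max() > 0:
        ipk = int(np.argmax(rate))
        lo = ipk
        while lo > 0 and rate[lo - 1] > 0:
            lo -= 1
        hi = ipk
        while hi < n - 1 and rate[hi + 1] > 0:
            hi += 1
        outside = np.ones(n, dtype=bool)
        outside[lo:hi + 1] = False
        if outside.any():
            trimmed_mass = float(np.trapezoid(np.where(outside, rate, 0.0), t))
            rate = np.where(outside, 0.0, rate)
    pc_curve = PCCurve(t, rate, label=curve.label)
    pc_tot = pc_curve.pc_tot
    clip_fraction = clipped_mass / max(pc_tot, 1e-12)

    warnings: list[str] = []
    if clip_fraction > opt.max_clip_fraction:
        warnings.append(
            f"clipped negative-rate mass is {clip_fraction:.1%} of PCtot "
            f"(limit {opt.max_clip_fraction:.0%}); curve may be too noisy"
        )
    peak = float(tpos.max())
    incomplete = bool(peak > 0 and tpos[-1] > opt.terminal_free_fraction * peak)
    if incomplete:
        warnings.append(
            "free thrombin at end of record exceeds "
            f"{opt.terminal_free_fraction:.0%} of peak; PCtot may be truncated"
        )

    tg_params = compute_tg_parameters(curve)
    result = ThrombinDynamicsResult(
        pc_tot=pc_tot,
        pc_max=pc_curve.pc_max,
        t_at_total=float(cat),
        t_a2m_total=float(ca2m),
        t_ms_total=float(np.trapezoid(r_ms, t)),
        terminal_free=float(tpos[-1] - tpos[0]),
        tdc=thrombin_decay_capacity(plasma, k).tdc,
        tg_params=tg_params,
        pc_curve=pc_curve,
        clipped_mass=clipped_mass,
        clip_fraction=clip_fraction,
        trimmed_mass=trimmed_mass,
        settings={
            "smooth_window": w1,
            "polyorder": opt.polyorder,
            "rate_smooth_window": w2,
            "include_ms": opt.include_ms,
            "consume_inhibitors": opt.consume_inhibitors,
            "restrict_to_main_pulse": opt.restrict_to_main_pulse,
            "rate_constants": k.as_dict(),
        },
        warnings=warnings,
        incomplete_decay=incomplete,
        label=curve.label,
    )
    return result


def write_pc_curve(pc: PCCurve, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("time_min,rate_nM_min,prothrombin_consumed_nM\n")
        for t, r, c in zip(pc.time, pc.rate, pc.prothrombin_consumed):
            fh.write(f"{t:.9g},{r:.9g},{c:.9g}\n")
    return path


def read_pc_curve(path: str | Path, *, label: str | None = None) -> PCCurve:
    path = Path(path)
    df = pd.read_csv(path)
    return PCCurve(
        df["time_min"].to_numpy(),
        df["rate_nM_min"].to_numpy(),
        label=label if label is not None else path.stem,
    )


def results_to_frame(results: list[ThrombinDynamicsResult]) -> pd.DataFrame:
    """One row per analysed sample, mirroring the standard summary table."""
    return pd.DataFrame([r.as_row() for r in results])
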