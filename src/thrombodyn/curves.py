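"""Thrombin generation (TG) curves and their standard summary parameters.

A TG curve is the free-thrombin concentration (nM) over time (min) measured
in clotting plasma by calibrated automated thrombinography. Curves are
summarised by five conventional descriptors: lag time, time-to-peak, peak
height, endogenous thrombin potential (ETP, the area under the curve) and
velocity index (peak / (time-to-peak - lag time)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "TGCurve",
    "TGParameters",
    "PlasmaProfile",
    "CurveValidationError",
    "AnalysisError",
    "CurveParseError",
    "compute_tg_parameters",
    "read_tg_curve",
    "write_tg_curve",
    "write_tg_parameters",
]

#: minimum record accepted by analysis operations
MIN_SAMPLES = 10
MIN_SPAN_MIN = 15.0
#: default noise floor: thrombin below this (nM) is rejected as non-physical
DEFAULT_NOISE_FLOOR = -5.0
#: default lag threshold as a fraction of peak height
DEFAULT_LAG_FRACTION = 1.0 / 6.0


class CurveValidationError(ValueError):
    """A curve violates a structural invariant (grid, finiteness, floor)."""


class AnalysisError(ValueError):
    """A curve is structurally valid but unsuitable for analysis."""


class CurveParseError(ValueError):
    """A curve file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


@dataclass
class TGCurve:
    """A sampled free-thrombin time series.

    Parameters
    ----------
    time
        Sampling times in minutes; strictly increasing, first point >= 0.
    thrombin
        Free thrombin in nM, same length as ``time``. Small negative values
        (assay noise) are tolerated down to ``noise_floor``.
    label
        Free-text sample identifier.
    tf_trigger
        Tissue-factor trigger concentration in pM (metadata only).
    """

    time: np.ndarray
    thrombin: np.ndarray
    label: str = ""
    tf_trigger: float | None = None
    noise_floor: float = DEFAULT_NOISE_FLOOR

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.thrombin = np.asarray(self.thrombin, dtype=float)
        if self.time.ndim != 1 or self.thrombin.ndim != 1:
            raise CurveValidationError("time and thrombin must be 1-D")
        if self.time.size != self.thrombin.size:
            raise CurveValidationError(
                f"length mismatch: {self.time.size} times, {self.thrombin.size} values"
            )
        if self.time.size == 0:
            raise CurveValidationError("empty curve")
        if not np.all(np.isfinite(self.time)) or not np.all(np.isfinite(self.thrombin)):
            raise CurveValidationError("non-finite values in curve")
        if self.time[0] < 0:
            raise CurveValidationError("first time point must be >= 0")
        if np.any(np.diff(self.time) <= 0):
            i = int(np.argmax(np.diff(self.time) <= 0))
            raise CurveValidationError(
                f"time grid not strictly increasing at index {i + 1} (t={self.time[i + 1]:g})"
            )
        low = float(self.thrombin.min())
        if low < self.noise_floor:
            raise CurveValidationError(
                f"thrombin {low:g} nM below noise floor {self.noise_floor:g} nM"
            )

    def __len__(self) -> int:
        return self.time.size

    @property
    def span(self) -> float:
        """Record length in minutes."""
        return float(self.time[-1] - self.time[0])

    @property
    def dt(self) -> float:
        """Median sampling interval in minutes."""
        return float(np.median(np.diff(self.time)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        steps = np.diff(self.time)
        return bool(np.all(np.abs(steps - steps.mean()) <= rtol * max(steps.mean(), 1e-12)))

    def require_analyzable(self) -> None:
        """Raise :class:`AnalysisError` if the record is too short for analysis."""
        if len(self) < MIN_SAMPLES or self.span < MIN_SPAN_MIN:
            raise AnalysisError(
                f"curve '{self.label}': need >= {MIN_SAMPLES} samples spanning "
                f">= {MIN_SPAN_MIN:g} min, got {len(self)} samples over {self.span:g} min"
            )

    def with_thrombin(self, thrombin: np.ndarray, **changes) -> "TGCurve":
        return replace(self, thrombin=np.asarray(thrombin, dtype=float), **changes)


@dataclass(frozen=True)
class TGParameters:
    """The five standard TG descriptors.

    ``lag_time`` and ``time_to_peak`` are NaN for an all-zero curve, where
    they are undefined; ``velocity_index`` is NaN whenever
    ``time_to_peak <= lag_time``.
    """

    lag_time: float
    time_to_peak: float
    peak_height: float
    etp: float
    velocity_index: float

    def as_dict(self) -> dict[str, float]:
        return {
            "lag_time_min": self.lag_time,
            "ttp_min": self.time_to_peak,
            "peak_nM": self.peak_height,
            "etp_nM_min": self.etp,
            "velocity_index_nM_min": self.velocity_index,
        }


SEVERITY_GROUPS = ("control", "mild", "moderate", "severe")


@dataclass
class PlasmaProfile:
    """One subject's plasma composition relevant to thrombin inactivation.

    Attributes
    ----------
    at_level : float
        Antithrombin, nM (absolute).
    a2m_level : float
        alpha2-macroglobulin, nM.
    fibrinogen : float
        g/L.
    fviii : float
        Factor VIII activity, IU/mL.
    group : str
        ``control`` / ``mild`` / ``moderate`` / ``severe``.
    at_fraction : float
        AT as a fraction of a reference plasma level (1.0 = native).
    """

    at_level: float
    a2m_level: float
    fibrinogen: float
    fviii: float
    group: str = "control"
    at_fraction: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("at_level", "a2m_level", "fibrinogen", "fviii"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.group not in SEVERITY_GROUPS:
            raise ValueError(f"group must be one of {SEVERITY_GROUPS}, got {self.group!r}")


def _first_crossing(time: np.ndarray, values: np.ndarray, threshold: float) -> float:
    """Earliest time at which ``values`` first exceeds ``threshold``.

    Linear interpolation between the bracketing samples; the curve's own
    resolution does not quantise the estimate.
    """
    above = values > threshold
    if not above.any():
        return math.nan
    i = int(np.argmax(above))
    if i == 0:
        return float(time[0])
    t0, t1 = time[i - 1], time[i]
    v0, v1 = values[i - 1], values[i]
    return float(t0 + (threshold - v0) / (v1 - v0) * (t1 - t0))


def compute_tg_parameters(
    curve: TGCurve,
    lag_threshold: float | None = None,
    *,
    lag_fraction: float = DEFAULT_LAG_FRACTION,
    smooth_window: int | None = None,
) -> TGParameters:
    """Extract lag time, time-to-peak, peak height, ETP and velocity index.

    Parameters
    ----------
    curve
        A validated TG curve satisfying the analysis preconditions.
    lag_threshold
        Absolute lag threshold in nM. If None (default), the threshold is
        ``lag_fraction * peak_height`` (peak-relative, so the lag time is
        invariant under rescaling of the curve).
    smooth_window
        Optional odd local-quadratic (Savitzky-Golay) window (samples)
        applied only for peak/lag localisation, never altering ETP.
        Default: no smoothing.
    """
    curve.require_analyzable()
    t = curve.time
    y = curve.thrombin
    if smooth_window is not None and smooth_window > 1:
        if smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd")
        if smooth_window > len(curve):
            raise AnalysisError("smooth_window larger than record")
        from scipy.signal import savgol_filter

        yloc = savgol_filter(y, smooth_window, min(2, smooth_window - 1))
    else:
        yloc = y

    # unclipped area: zero-mean noise cancels instead of rectifying
    etp = max(float(np.trapezoid(y, t)), 0.0)
    peak = float(yloc.max())
    if peak <= 0.0:
        return TGParameters(math.nan, math.nan, 0.0, etp, math.nan)
    ipeak = int(np.argmax(yloc))  # earliest index attaining the max
    ttp = float(t[ipeak])
    threshold = lag_threshold if lag_threshold is not None else lag_fraction * peak
    lag = _first_crossing(t, yloc, threshold)
    if math.isfinite(lag) and math.isfinite(ttp) and ttp > lag:
        vi = peak / (ttp - lag)
    else:
        vi = math.nan
    return TGParameters(lag, ttp, peak, etp, vi)


# ---------------------------------------------------------------------------
# curve file I/O: CSV, columns time_min,thrombin_nM, "." decimal, UTF-8


CURVE_HEADER = ("time_min", "thrombin_nM")


def read_tg_curve(path: str | Path, *, label: str | None = None,
                  tf_trigger: float | None = None) -> TGCurve:
    """Read a two-column (time_min, thrombin_nM) CSV into a :class:`TGCurve`.

    A header row is tolerated but not required; malformed rows raise
    :class:`CurveParseError` with the line number.
    """
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 2:
                raise CurveParseError(f"expected 2 columns, got {len(parts)}", lineno)
            if lineno == 1:
                try:
                    float(parts[0])
                except ValueError:
                    continue  # header row
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise CurveParseError(f"non-numeric value: {exc}", lineno) from exc
    if not times:
        raise CurveParseError(f"no data rows in {path}")
    try:
        return TGCurve(np.array(times), np.array(values),
                       label=label if label is not None else path.stem,
                       tf_trigger=tf_trigger)
    except CurveValidationError as exc:
        raise CurveParseError(str(exc)) from exc


def write_tg_curve(curve: TGCurve, path: str | Path) -> Path:
    """Write a curve as CSV with a mandatory header; returns the path."""
    if len(curve) == 0:  # unreachable through the constructor; belt and braces
        raise ValueError("refusing to write an empty curve")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(CURVE_HEADER) + "\n")
        for t, v in zip(curve.time, curve.thrombin):
            fh.write(f"{t:.9g},{v:.9g}\n")
    return path


def write_tg_parameters(rows: dict[str, TGParameters], path: str | Path) -> Path:
    """Write one CSV row of TG parameters per labelled sample."""
    path = Path(path)
    cols = ["label", "lag_time_min", "ttp_min", "peak_nM", "etp_nM_min",
            "velocity_index_nM_min"]
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(cols) + "\n")
        for label, p in rows.items():
            d = p.as_dict()
            fh.write(",".join([label] + [f"{d[c]:.9g}" for c in cols[1:]]) + "\n")
    return path
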