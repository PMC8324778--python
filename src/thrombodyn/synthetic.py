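"""Synthetic plasmas, conversion pulses and TG curves with known truth.

The generator emulates a haemophilia A case-control study: a control
group and a patient group split into mild / moderate / severe by factor
VIII activity (severe < 0.01, moderate < 0.05, mild < 0.40 IU/mL). Each
virtual subject gets plasma inhibitor levels, a parametric
prothrombin-conversion pulse (a gamma-density pulse with closed-form
PCtot and PCmax), a forward-simulated TG curve, and additive Gaussian
measurement noise. The true conversion curve is stored alongside every
sample so analysis stages can be scored by parameter recovery.

Group-level targets (means +/- SD of FVIII, fibrinogen, thrombin decay
capacity, PCtot, PCmax at the 1 pM tissue-factor trigger) follow the
published case-control distributions for 27 controls and 26 patients
(11 mild / 10 moderate / 5 severe); AT levels are derived from the decay
capacity via TDC = k_AT*[AT]_0 + k_a2M*[a2M]_0 + k_MS. The maximum
conversion rate is coupled to FVIII through a saturating (Hill) curve so
that the control and pooled-patient PCmax means land on their targets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .curves import PlasmaProfile, TGCurve
from .conversion import PCCurve
from .inactivation import RateConstants
from .insilico import ForwardOptions, forward_simulate_tg

__all__ = [
    "GroupParams",
    "CohortSpec",
    "GroundTruth",
    "CohortSample",
    "classify_severity",
    "generate_pc_curve",
    "generate_plasma",
    "generate_sample",
    "generate_cohort",
    "add_noise",
    "write_cohort",
]

#: FVIII class boundaries, IU/mL (strict upper bounds)
SEVERE_MAX = 0.01
MODERATE_MAX = 0.05
MILD_MAX = 0.40
CONTROL_MIN_FVIII = 0.85


def classify_severity(fviii: float) -> str:
    """Haemophilia A severity from FVIII activity (IU/mL).

    Severe below 0.01, moderate below 0.05, mild below 0.40; anything at
    or above 0.40 is not classified as haemophilia ("control").
    """
    if not math.isfinite(fviii) or fviii < 0:
        raise ValueError(f"fviii must be finite and >= 0, got {fviii!r}")
    if fviii < SEVERE_MAX:
        return "severe"
    if fviii < MODERATE_MAX:
        return "moderate"
    if fviii < MILD_MAX:
        return "mild"
    return "control"


@dataclass(frozen=True)
class GroupParams:
    """Sampling distributions (mean, SD) for one severity group."""

    fviii: tuple[float, float]
    fviii_bounds: tuple[float, float]
    fibrinogen: tuple[float, float]
    tdc: tuple[float, float]          # min^-1; sets the AT level
    pc_tot: tuple[float, float]       # nM
    onset: tuple[float, float]        # min; conversion pulse delay


# 1 pM tissue-factor trigger. Pulse onsets are a generator calibration so
# that control lag/time-to-peak land near their cohort targets.
GROUPS_1PM: dict[str, GroupParams] = {
    "control": GroupParams((1.41, 0.44), (CONTROL_MIN_FVIII, np.inf),
                           (3.3, 1.0), (0.712, 0.089), (619.0, 106.0), (3.6, 0.8)),
    "mild": GroupParams((0.16, 0.11), (MODERATE_MAX, MILD_MAX),
                        (5.3, 1.6), (0.497, 0.122), (327.0, 140.0), (2.5, 1.2)),
    "moderate": GroupParams((0.03, 0.01), (SEVERE_MAX, MODERATE_MAX),
                            (5.2, 1.9), (0.536, 0.138), (335.0, 172.0), (2.5, 1.2)),
    "severe": GroupParams((0.005, 0.003), (0.0, SEVERE_MAX),
                          (4.9, 1.8), (0.541, 0.171), (330.0, 154.0), (2.5, 1.2)),
}

# 5 pM trigger variant (faster onset, stronger conversion).
GROUPS_5PM: dict[str, GroupParams] = {
    "control": GroupParams((1.41, 0.44), (CONTROL_MIN_FVIII, np.inf),
                           (3.3, 1.0), (0.712, 0.089), (892.0, 147.0), (1.7, 0.3)),
    "mild": GroupParams((0.16, 0.11), (MODERATE_MAX, MILD_MAX),
                        (5.3, 1.6), (0.497, 0.122), (769.0, 199.0), (1.8, 0.5)),
    "moderate": GroupParams((0.03, 0.01), (SEVERE_MAX, MODERATE_MAX),
                            (5.2, 1.9), (0.536, 0.138), (756.0, 224.0), (1.8, 0.5)),
    "severe": GroupParams((0.005, 0.003), (0.0, SEVERE_MAX),
                          (4.9, 1.8), (0.541, 0.171), (755.0, 205.0), (1.8, 0.5)),
}

# PCmax ~ FVIII coupling: pc_max = floor + amp * f^2 / (f^2 + half^2).
# Calibrated once so the control mean (FVIII 1.41) lands near 169 nM/min
# and the pooled patient mean (11/10/5 mild/moderate/severe) near 27.
PCMAX_COUPLING_1PM = {"floor": 24.0, "amp": 228.4, "half": 1.07, "cv": 0.25}
# 5 pM: controls 484, pooled patients ~154; subgroup means are flat so the
# floor carries most of the patient signal.
PCMAX_COUPLING_5PM = {"floor": 140.0, "amp": 475.0, "half": 1.25, "cv": 0.20}

DEFAULT_A2M = (3000.0, 600.0)  # nM; adult reference range, not cohort data
DEFAULT_SHAPE_K = 4.0          # gamma pulse shape parameter


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a reproducible synthetic cohort.

    Same seed, same spec -> bit-identical cohort. Seeds are split per
    sample index so changing the cohort size does not reshuffle earlier
    samples.
    """

    n_controls: int = 27
    n_patients: int = 26
    severity_mix: tuple[float, float, float] = (11 / 26, 10 / 26, 5 / 26)
    noise_sd: float = 2.0
    seed: int = 0
    tf_trigger: float = 1.0
    t_end: float = 60.0
    dt: float = 1.0 / 3.0
    a2m: tuple[float, float] = DEFAULT_A2M
    shape_k: float = DEFAULT_SHAPE_K
    groups: dict[str, GroupParams] | None = None
    pcmax_coupling: dict[str, float] | None = None
    rate_constants: RateConstants = field(default_factory=RateConstants)

    def __post_init__(self) -> None:
        if self.n_controls < 0 or self.n_patients < 0:
            raise ValueError("cohort sizes must be >= 0")
        if abs(sum(self.severity_mix) - 1.0) > 1e-9:
            raise ValueError(f"severity_mix must sum to 1, got {self.severity_mix}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.tf_trigger not in (1.0, 5.0):
            raise ValueError("tf_trigger must be 1 or 5 pM")
        if not (self.dt > 0 and self.t_end > self.dt):
            raise ValueError("invalid time grid")

    @property
    def group_params(self) -> dict[str, GroupParams]:
        if self.groups is not None:
            return self.groups
        return GROUPS_1PM if self.tf_trigger == 1.0 else GROUPS_5PM

    @property
    def coupling(self) -> dict[str, float]:
        if self.pcmax_coupling is not None:
            return self.pcmax_coupling
        return PCMAX_COUPLING_1PM if self.tf_trigger == 1.0 else PCMAX_COUPLING_5PM

    @property
    def grid(self) -> np.ndarray:
        n = int(round(self.t_end / self.dt))
        return np.arange(n + 1) * self.dt

    def severity_counts(self) -> dict[str, int]:
        """Largest-remainder apportionment of patients over severities."""
        raw = [m * self.n_patients for m in self.severity_mix]
        counts = [int(math.floor(r)) for r in raw]
        rem = self.n_patients - sum(counts)
        order = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
        for i in order[:rem]:
            counts[i] += 1
        return dict(zip(("mild", "moderate", "severe"), counts))

    def as_dict(self) -> dict:
        return {
            "n_controls": self.n_controls,
            "n_patients": self.n_patients,
            "severity_mix": list(self.severity_mix),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "tf_trigger": self.tf_trigger,
            "t_end": self.t_end,
            "dt": self.dt,
            "a2m": list(self.a2m),
            "shape_k": self.shape_k,
            "rate_constants": self.rate_constants.as_dict(),
        }


@dataclass
class GroundTruth:
    """Per-sample ground truth; consumed only by tests and scoring."""

    pc_curve: PCCurve
    pc_tot: float
    pc_max: float
    theta: float
    shape_k: float
    onset: float
    clean_thrombin: np.ndarray
    noise_sd: float
    seed_key: tuple


@dataclass
class CohortSample:
    curve: TGCurve
    plasma: PlasmaProfile
    truth: GroundTruth


def _gamma_peak_factor(shape_k: float) -> float:
    """Max of the gamma density with unit scale: pdf at its mode."""
    if shape_k <= 1:
        raise ValueError("shape_k must be > 1 for a unimodal pulse")
    m = shape_k - 1.0
    return float(m ** m * math.exp(-m) / math.gamma(shape_k))


def generate_pc_curve(
    pc_tot: float,
    shape_k: float = DEFAULT_SHAPE_K,
    theta: float = 1.5,
    onset: float = 0.0,
    grid: np.ndarray | None = None,
    *,
    label: str = "",
    max_integral_error: float = 0.01,
) -> PCCurve:
    """A gamma-density conversion pulse with exact closed-form summaries.

    rate(t) = pc_tot * gamma_pdf(t - onset; shape_k, theta); the analytic
    maximum is pc_tot * C(shape_k) / theta at t = onset + (shape_k-1)*theta.
    Raises if the grid is too coarse (or too short) to hold the stated
    total within ``max_integral_error``.
    """
    if pc_tot < 0:
        raise ValueError("pc_tot must be >= 0")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if grid is None:
        grid = np.arange(0.0, 60.0 + 1e-9, 1.0 / 3.0)
    grid = np.asarray(grid, dtype=float)
    rate = pc_tot * sps.gamma.pdf(grid - onset, a=shape_k, scale=theta)
    pc = PCCurve(grid, rate, label=label)
    if pc_tot > 0:
        err = abs(pc.pc_tot - pc_tot) / pc_tot
        if err > max_integral_error:
            raise ValueError(
                f"grid too coarse/short for the pulse: integral off by {err:.2%}"
            )
    return pc


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               low: float = 0.0, high: float = np.inf) -> float:
    """One truncated-normal draw; rejects infeasible (mostly-truncated) specs."""
    if sd == 0:
        if not (low <= mean <= high):
            raise ValueError(f"degenerate draw {mean} outside [{low}, {high}]")
        return mean
    a, b = (low - mean) / sd, (high - mean) / sd
    mass = sps.norm.cdf(b) - sps.norm.cdf(a)
    if mass < 0.5:
        raise ValueError(
            f"infeasible distribution: only {mass:.0%} of N({mean}, {sd}) "
            f"lies in [{low}, {high}]"
        )
    return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _pcmax_from_fviii(fviii: float, coupling: dict[str, float],
                      rng: np.random.Generator) -> float:
    """Saturating FVIII -> PCmax coupling with unbiased lognormal jitter."""
    f2 = fviii * fviii
    h2 = coupling["half"] ** 2
    mean = coupling["floor"] + coupling["amp"] * f2 / (f2 + h2)
    cv = coupling["cv"]
    jitter = math.exp(rng.normal(0.0, cv) - 0.5 * cv * cv)
    return mean * jitter


def generate_plasma(
    group: str, spec: CohortSpec, rng: np.random.Generator, label: str = ""
) -> PlasmaProfile:
    """Draw one subject's plasma levels for a severity group."""
    gp = spec.group_params[group]
    k = spec.rate_constants
    fviii = _truncnorm(rng, *gp.fviii, low=gp.fviii_bounds[0],
                       high=min(gp.fviii_bounds[1], 1e6) - 1e-12)
    fib = _truncnorm(rng, *gp.fibrinogen, low=0.0)
    a2m = _truncnorm(rng, *spec.a2m, low=0.0)
    tdc = _truncnorm(rng, *gp.tdc, low=0.05)
    kat = k.k_at_eff(fib)
    at0 = max((tdc - k.k_a2m_eff(fib) * a2m - k.k_ms) / kat, 0.0)
    return PlasmaProfile(at_level=at0, a2m_level=a2m, fibrinogen=fib,
                         fviii=fviii, group=group, label=label)


def generate_sample(
    group: str, spec: CohortSpec, seed_key: tuple, label: str = ""
) -> CohortSample:
    """One virtual subject: plasma, true conversion pulse, noisy TG curve."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=seed_key))
    gp = spec.group_params[group]
    plasma = generate_plasma(group, spec, rng, label=label)
    pc_tot = _truncnorm(rng, *gp.pc_tot, low=1.0)
    pc_max = _pcmax_from_fviii(plasma.fviii, spec.coupling, rng)
    onset = _truncnorm(rng, *gp.onset, low=0.5)
    theta = pc_tot * _gamma_peak_factor(spec.shape_k) / pc_max
    # keep the pulse resolvable on the sampling grid (caps extreme PCmax draws)
    # and short enough that it decays within the record (floors slow draws)
    theta_max = (spec.t_end - onset) / float(sps.gamma.ppf(0.9995, spec.shape_k))
    theta = min(max(theta, 1.5 * spec.dt), theta_max)
    grid = spec.grid
    pc = generate_pc_curve(pc_tot, spec.shape_k, theta, onset, grid, label=label,
                           max_integral_error=0.02)
    clean = forward_simulate_tg(
        pc, plasma, spec.rate_constants, at_fraction=1.0,
        options=ForwardOptions(t_max=spec.t_end, stop_threshold=0.0,
                               output_dt=spec.dt),
    )
    # forward run covers the full grid; enforce the cohort grid exactly
    thrombin = np.interp(grid, clean.time, clean.thrombin)
    noise = rng.normal(0.0, spec.noise_sd, grid.size) if spec.noise_sd > 0 else 0.0
    noisy = np.clip(thrombin + noise, -4.999, None)
    curve = TGCurve(grid, noisy, label=label, tf_trigger=spec.tf_trigger)
    truth = GroundTruth(
        pc_curve=pc, pc_tot=pc.pc_tot, pc_max=pc.pc_max,
        theta=theta, shape_k=spec.shape_k, onset=onset,
        clean_thrombin=thrombin, noise_sd=spec.noise_sd, seed_key=seed_key,
    )
    return CohortSample(curve, plasma, truth)


def generate_cohort(spec: CohortSpec) -> list[CohortSample]:
    """Generate the full cohort; deterministic under the spec's seed."""
    counts = spec.severity_counts()
    plan: list[str] = (["control"] * spec.n_controls
                       + ["mild"] * counts["mild"]
                       + ["moderate"] * counts["moderate"]
                       + ["severe"] * counts["severe"])
    samples = []
    for i, group in enumerate(plan):
        label = f"{group[:3]}_{i:03d}"
        samples.append(generate_sample(group, spec, seed_key=(i,), label=label))
    return samples


def add_noise(curve: TGCurve, sd: float, seed: int) -> TGCurve:
    """Additive i.i.d. Gaussian perturbation of a curve; sd = 0 is identity."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return curve.with_thrombin(curve.thrombin.copy())
    rng = np.random.default_rng(seed)
    noisy = curve.thrombin + rng.normal(0.0, sd, curve.thrombin.size)
    return curve.with_thrombin(np.clip(noisy, curve.noise_floor + 1e-3, None))


def write_cohort(samples: Sequence[CohortSample], spec: CohortSpec,
                 out_dir: str | Path) -> Path:
    """Write curves/, plasma.csv, ground_truth.csv and the resolved spec."""
    from .curves import write_tg_curve

    out = Path(out_dir)
    (out / "curves").mkdir(parents=True, exist_ok=True)
    plasma_rows, truth_rows = [], []
    for s in samples:
        write_tg_curve(s.curve, out / "curves" / f"{s.curve.label}.csv")
        plasma_rows.append({
            "label": s.plasma.label, "group": s.plasma.group,
            "fviii_iu_ml": s.plasma.fviii, "at_nM": s.plasma.at_level,
            "a2m_nM": s.plasma.a2m_level, "fibrinogen_g_L": s.plasma.fibrinogen,
        })
        truth_rows.append({
            "label": s.plasma.label, "pc_tot_nM": s.truth.pc_tot,
            "pc_max_nM_min": s.truth.pc_max, "theta_min": s.truth.theta,
            "shape_k": s.truth.shape_k, "onset_min": s.truth.onset,
            "noise_sd_nM": s.truth.noise_sd,
        })
    pd.DataFrame(plasma_rows).to_csv(out / "plasma.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
    (out / "cohort_spec.json").write_text(json.dumps(spec.as_dict(), indent=2) + "\n")
    return out
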