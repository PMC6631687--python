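"""Microsomal substrate-depletion kinetics and scaling to intrinsic clearance.

The substrate-depletion (half-life) approach estimates hepatic intrinsic
clearance from the monoexponential disappearance of parent compound in a
liver-microsome incubation:

    C(t) = C0 * exp(-ln2 * t / t_half)

The apparent in vitro half-life is corrected for nonspecific binding of the
substrate to microsomal material via the lipophilicity relationship

    f_mic = 1 / (1 + P * 10**(0.072*logP**2 + 0.067*logP - 1.126))

with P the microsomal protein concentration (mg/mL), and scaled to whole-body
intrinsic clearance (mL/min/kg) with physiological scaling factors
(mg microsomal protein per g liver, g liver per kg body weight).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitFailureError, InvalidInputError

LN2 = np.log(2.0)

#: Optimizer half-lives outside this window (minutes) are reported as fit
#: failures rather than clamped: they are outside what the 20-min assay can
#: plausibly resolve.
T_HALF_BOUNDS = (0.1, 10_000.0)


@dataclass(frozen=True)
class DepletionTimecourse:
    """One replicate of a microsomal depletion assay.

    ``remaining`` is percent of the t=0 peak-area ratio; by convention the
    value at t=0 is 100.
    """

    compound_id: str
    times: np.ndarray
    remaining: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        remaining = np.asarray(self.remaining, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "remaining", remaining)
        if times.ndim != 1 or times.shape != remaining.shape:
            raise InvalidInputError("times and remaining must be matching 1-D arrays")
        if times.size and times[0] != 0.0:
            raise InvalidInputError("first sampling time must be 0")
        if np.any(np.diff(times) <= 0):
            raise InvalidInputError("times must be strictly ascending")
        if np.any(remaining < 0):
            raise InvalidInputError("remaining percentages must be >= 0")
        if remaining.size and abs(remaining[0] - 100.0) > 1e-6:
            raise InvalidInputError("remaining at t=0 must be 100 (normalized)")


@dataclass(frozen=True)
class MonoexpFit:
    """Least-squares estimates for the monoexponential depletion model."""

    c0: float
    t_half: float
    residual_sse: float
    n_points: int


@dataclass(frozen=True)
class AssayContext:
    """Incubation conditions needed for binding correction and scaling."""

    protein_conc: float = 0.5   # mg microsomal protein / mL incubation
    incubation_volume: float = 1.0  # mL
    log_p: float = 0.0

    def __post_init__(self):
        if self.protein_conc <= 0:
            raise InvalidInputError("protein_conc must be > 0")
        if self.incubation_volume <= 0:
            raise InvalidInputError("incubation_volume must be > 0")


@dataclass(frozen=True)
class ScalingFactors:
    """Physiological constants for in vitro -> in vivo scaling (rat defaults)."""

    mg_protein_per_g_liver: float = 60.0
    g_liver_per_kg_bw: float = 40.0
    hepatic_blood_flow_q: float = 55.0  # mL/min/kg
    blood_plasma_ratio: float = 1.0

    def __post_init__(self):
        for name in (
            "mg_protein_per_g_liver",
            "g_liver_per_kg_bw",
            "hepatic_blood_flow_q",
            "blood_plasma_ratio",
        ):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class IntrinsicClearanceResult:
    compound_id: str
    t_half_vitro: float      # min
    f_mic: float             # fraction in (0, 1]
    cl_int: float            # mL/min/kg
    t_half_sd: float | None = None
    cl_int_sd: float | None = None
    n_replicates: int = 1


def _loglinear_seed(times: np.ndarray, remaining: np.ndarray) -> tuple[float, float]:
    """Log-linear regression on positive points; returns (c0, t_half) seed."""
    mask = remaining > 0
    t, y = times[mask], np.log(remaining[mask])
    slope, intercept = np.polyfit(t, y, 1)
    if slope >= 0:
        # no decay visible; seed with a long half-life and let the optimizer
        # (or the bounds check) decide
        return float(np.exp(intercept)), T_HALF_BOUNDS[1]
    return float(np.exp(intercept)), float(LN2 / -slope)


def fit_monoexponential(tc: DepletionTimecourse) -> MonoexpFit:
    """Fit ``C(t) = C0 * exp(-ln2 * t / t_half)`` by nonlinear least squares.

    The fit is performed in natural (percent) space with uniform weights and
    an unconstrained C0 — replicate noise makes a free intercept more robust
    than pinning C0 = 100. The log-linear regression serves only to seed the
    optimizer.

    Raises
    ------
    InvalidInputError
        Fewer than 3 time points.
    FitFailureError
        Optimum half-life non-positive, non-finite, or outside
        ``T_HALF_BOUNDS`` (e.g. data showing no decay).
    """
    t = tc.times
    y = tc.remaining
    if t.size < 3:
        raise InvalidInputError("monoexponential fit needs at least 3 time points")

    c0_seed, th_seed = _loglinear_seed(t, y)
    th_seed = float(np.clip(th_seed, *T_HALF_BOUNDS))

    def resid(p):
        c0, th = p
        return c0 * np.exp(-LN2 * t / th) - y

    sol = least_squares(
        resid,
        x0=[c0_seed, th_seed],
        bounds=([0.0, 1e-6], [np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    c0, t_half = sol.x
    sse = float(np.sum(sol.fun**2))
    diagnostics = {
        "c0": float(c0),
        "t_half": float(t_half),
        "sse": sse,
        "optimizer_status": sol.status,
    }
    if not np.isfinite(t_half) or t_half <= 0:
        raise FitFailureError("non-positive or non-finite half-life", diagnostics)
    if not T_HALF_BOUNDS[0] <= t_half <= T_HALF_BOUNDS[1]:
        raise FitFailureError(
            f"fitted half-life {t_half:.3g} min outside plausible range "
            f"{T_HALF_BOUNDS} — no measurable decay?",
            diagnostics,
        )
    return MonoexpFit(
        c0=float(c0), t_half=float(t_half), residual_sse=sse, n_points=int(t.size)
    )


def microsomal_unbound_fraction(log_p: float, protein_conc: float) -> float:
    """Fraction of substrate unbound in the microsomal incubation.

    Lipophilicity relationship: higher log P and higher protein concentration
    both increase nonspecific binding. Returns a value in (0, 1]; exactly 1
    when no protein is present.
    """
    if protein_conc < 0:
        raise InvalidInputError("protein_conc must be >= 0")
    exponent = 0.072 * log_p**2 + 0.067 * log_p - 1.126
    return float(1.0 / (1.0 + protein_conc * 10.0**exponent))


def scale_intrinsic_clearance(
    t_half_vitro: float,
    f_mic: float,
    ctx: AssayContext,
    sf: ScalingFactors = ScalingFactors(),
) -> float:
    """Scale an in vitro depletion half-life to intrinsic clearance, mL/min/kg.

    CL_int = ln2 / (t_half * f_mic)            [1/min, unbound]
             * 1/protein_conc                  [mL incubation / mg protein]
             * mg_protein_per_g_liver * g_liver_per_kg_bw

    Dividing by f_mic converts the apparent half-life to the unbound scale,
    which is what recovers observed clearance for lipophilic compounds.
    """
    if t_half_vitro <= 0:
        raise InvalidInputError("t_half_vitro must be > 0")
    if not 0 < f_mic <= 1:
        raise InvalidInputError("f_mic must be in (0, 1]")
    ml_per_mg = 1.0 / ctx.protein_conc
    return (
        LN2
        / (t_half_vitro * f_mic)
        * ml_per_mg
        * sf.mg_protein_per_g_liver
        * sf.g_liver_per_kg_bw
    )


def summarize_replicates(
    fits: list[MonoexpFit],
    compound_id: str,
    ctx: AssayContext,
    sf: ScalingFactors = ScalingFactors(),
) -> IntrinsicClearanceResult:
    """Combine per-replicate fits into the reported stability result.

    Replicates are fitted individually; the reported half-life is their
    arithmetic mean with sample SD, and CL_int is computed per replicate and
    averaged the same way (matching a triplicate-assay reporting convention).
    """
    if not fits:
        raise InvalidInputError("need at least one replicate fit")
    f_mic = microsomal_unbound_fraction(ctx.log_p, ctx.protein_conc)
    t_halves = np.array([f.t_half for f in fits])
    cl_ints = np.array(
        [scale_intrinsic_clearance(th, f_mic, ctx, sf) for th in t_halves]
    )
    n = len(fits)
    return IntrinsicClearanceResult(
        compound_id=compound_id,
        t_half_vitro=float(t_halves.mean()),
        f_mic=f_mic,
        cl_int=float(cl_ints.mean()),
        t_half_sd=float(t_halves.std(ddof=1)) if n > 1 else None,
        cl_int_sd=float(cl_ints.std(ddof=1)) if n > 1 else None,
        n_replicates=n,
    )
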