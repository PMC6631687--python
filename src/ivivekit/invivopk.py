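"""Plasma pharmacokinetics of radiotracers from arterial sampling data.

Raw γ-counter measurements of plasma samples are transformed into
decay- and metabolite-corrected radiotracer concentration curves, optionally
aggregated across animals, and fitted with a triexponential bolus model

    C_p(t) = A1*exp(-lam1*t) + A2*exp(-lam2*t) + A3*exp(-lam3*t)

from whose macroconstants plasma clearance, volume of distribution and the
terminal half-life follow in closed form:

    CL_p       = D / sum_i(A_i / lam_i)      (D = injected activity)
    V_d        = CL_p / lam3
    t_half,term = ln2 / lam3

Plasma is assumed to have a specific density of 1 g/mL, so activity per gram
of plasma is used directly as activity per mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FitFailureError, InvalidInputError

LN2 = np.log(2.0)

#: Half-life of fluorine-18 in minutes (physical constant).
F18_HALF_LIFE_MIN = 109.77

#: Default number of perturbed restarts for the triexponential refinement.
N_RESTARTS = 20


@dataclass(frozen=True)
class PlasmaSample:
    """One arterial blood sample after centrifugation and counting."""

    time_pi: float          # minutes post injection
    activity_measured: float  # counting units (e.g. Bq), decay-uncorrected
    plasma_mass: float      # g

    def __post_init__(self):
        if self.time_pi < 0:
            raise InvalidInputError("time_pi must be >= 0")
        if self.plasma_mass <= 0:
            raise InvalidInputError("plasma_mass must be > 0")
        if self.activity_measured < 0:
            raise InvalidInputError("activity_measured must be >= 0")


@dataclass(frozen=True)
class ParentFractionSeries:
    """Fraction of plasma radioactivity that is unmetabolized tracer."""

    times: np.ndarray      # minutes
    fractions: np.ndarray  # in [0, 1]

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fractions", f)
        if t.size == 0:
            raise InvalidInputError("parent-fraction series is empty")
        if t.shape != f.shape:
            raise InvalidInputError("times and fractions must match in length")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("parent-fraction times must be ascending")
        if np.any((f < 0) | (f > 1)):
            raise InvalidInputError("parent fractions must lie in [0, 1]")

    def at(self, times) -> np.ndarray:
        """Linear interpolation, clamped to the nearest measured fraction
        outside the measured range."""
        return np.interp(np.asarray(times, dtype=float), self.times, self.fractions)


@dataclass(frozen=True)
class AnimalStudy:
    """Everything measured for one animal in a PK experiment."""

    animal_id: str
    injected_activity: float   # counting units; D in the clearance equation
    injected_amount: float     # nmol
    body_weight: float         # kg
    samples: list[PlasmaSample]
    parent_fractions: ParentFractionSeries
    isotope_half_life: float = F18_HALF_LIFE_MIN

    def __post_init__(self):
        if self.injected_activity <= 0:
            raise InvalidInputError("injected_activity must be > 0")
        if self.body_weight <= 0:
            raise InvalidInputError("body_weight must be > 0")


@dataclass(frozen=True)
class PlasmaCurve:
    """A (possibly corrected/aggregated) concentration-time curve."""

    times: np.ndarray
    conc: np.ndarray            # activity per mL plasma
    suv: np.ndarray | None = None
    conc_sd: np.ndarray | None = None  # per-point SD when aggregated

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", c)
        if t.shape != c.shape:
            raise InvalidInputError("times and conc must match in length")
        if np.any(c < 0):
            raise InvalidInputError("concentrations must be >= 0")


@dataclass(frozen=True)
class TriexpFit:
    """Macroconstants of the fitted triexponential, lam sorted descending."""

    a: np.ndarray            # A1, A2, A3 (conc units)
    lam: np.ndarray          # lam1 > lam2 > lam3 > 0 (1/min)
    residual_sse: float
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self):
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "lam", np.asarray(self.lam, dtype=float))

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = self.a @ np.exp(-np.multiply.outer(self.lam, t))
        return float(out) if out.ndim == 0 else out

    @property
    def auc(self) -> float:
        """Analytic area under the curve on [0, inf): sum A_i/lam_i."""
        return float(np.sum(self.a / self.lam))


@dataclass(frozen=True)
class PKParameters:
    cl_p: float         # mL/min (/kg when body weight supplied)
    v_d: float          # mL (/kg)
    t_half_term: float  # min


def decay_correct(
    activity: float | np.ndarray, time_pi: float | np.ndarray,
    isotope_half_life: float = F18_HALF_LIFE_MIN,
) -> float | np.ndarray:
    """Correct measured activity back to injection time (t = 0 reference)."""
    if isotope_half_life <= 0:
        raise InvalidInputError("isotope_half_life must be > 0")
    return activity * 2.0 ** (np.asarray(time_pi, dtype=float) / isotope_half_life)


def metabolite_correct(curve: PlasmaCurve, pf: ParentFractionSeries) -> PlasmaCurve:
    """Multiply total-radioactivity concentrations by the parent fraction.

    The parent fraction is linearly interpolated at each sample time and
    clamped to the nearest measured value outside the measured range.
    """
    factors = pf.at(curve.times)
    suv = None if curve.suv is None else np.asarray(curve.suv) * factors
    return PlasmaCurve(times=curve.times, conc=curve.conc * factors, suv=suv)


def compute_suv(
    conc: float | np.ndarray, injected_activity: float, body_weight: float
) -> float | np.ndarray:
    """Standardized uptake value: conc / (injected activity per g body mass).

    With plasma density 1 g/mL, SUV = 1 when one mL of plasma holds exactly
    the injected activity divided by the body mass in grams.
    """
    if injected_activity <= 0:
        raise InvalidInputError("injected_activity must be > 0")
    if body_weight <= 0:
        raise InvalidInputError("body_weight must be > 0")
    return np.asarray(conc, dtype=float) / (injected_activity / (body_weight * 1000.0))


def parent_fraction_hill(t, f_end: float, t50: float, h: float):
    """Hill-type parent-fraction model: pf(0) = 1, plateau at ``f_end``.

    pf(t) = f_end + (1 - f_end) / (1 + (t/t50)**h) — the standard sigmoid
    family for metabolite correction of radiotracer input functions.
    """
    t = np.asarray(t, dtype=float)
    return f_end + (1.0 - f_end) / (1.0 + (t / t50) ** h)


def smooth_parent_fractions(
    series: list[ParentFractionSeries],
) -> ParentFractionSeries:
    """Population parent-fraction curve: a Hill model fitted to pooled data.

    Individual TLC parent-fraction measurements are noisy, and random error
    at late times (where the parent fraction is small) distorts the terminal
    phase of metabolite-corrected curves. Fitting one smooth monotone model
    to all animals' measurements jointly — population-based metabolite
    correction — replaces that point noise with a far smaller, smoothly
    varying error. Returns the fitted curve tabulated on the pooled time
    grid (ready for the usual linear interpolation).
    """
    if not series:
        raise InvalidInputError("no parent-fraction series to pool")
    t = np.concatenate([s.times for s in series])
    f = np.concatenate([s.fractions for s in series])
    grid = np.unique(t)

    def resid(x):
        return parent_fraction_hill(t, *x) - f

    f_end0 = max(float(np.mean(f[t >= 0.8 * t.max()])), 1e-3)
    sol = least_squares(
        resid, x0=[f_end0, max(np.median(t) / 10.0, 1.0), 1.5],
        bounds=([0.0, 1e-3, 0.2], [1.0, t.max(), 6.0]),
    )
    fitted = np.clip(parent_fraction_hill(grid, *sol.x), 0.0, 1.0)
    return ParentFractionSeries(times=grid, fractions=fitted)


def corrected_curve(
    study: AnimalStudy, parent_fractions: ParentFractionSeries | None = None
) -> PlasmaCurve:
    """Decay- and metabolite-corrected parent concentration curve for one animal.

    ``parent_fractions`` overrides the animal's own measured series (e.g. a
    pooled population curve from :func:`smooth_parent_fractions`).
    """
    times = np.array([s.time_pi for s in study.samples], dtype=float)
    order = np.argsort(times)
    times = times[order]
    activity = np.array(
        [study.samples[i].activity_measured for i in order], dtype=float
    )
    mass = np.array([study.samples[i].plasma_mass for i in order], dtype=float)
    conc_total = decay_correct(activity, times, study.isotope_half_life) / mass
    total = PlasmaCurve(times=times, conc=conc_total)
    parent = metabolite_correct(total, parent_fractions or study.parent_fractions)
    suv = compute_suv(parent.conc, study.injected_activity, study.body_weight)
    return PlasmaCurve(times=parent.times, conc=parent.conc, suv=suv)


def aggregate_mean_curve(
    studies: list[AnimalStudy],
    use_suv: bool = False,
    parent_fractions: ParentFractionSeries | None = None,
) -> PlasmaCurve:
    """Pointwise mean (and sample SD) of corrected curves across animals.

    All animals must be sampled on the same nominal time grid; no resampling
    is attempted. By default concentrations are averaged; ``use_suv=True``
    averages the dose/weight-normalized SUV curves instead. A shared
    ``parent_fractions`` series applies one population metabolite correction
    to every animal.
    """
    if len(studies) < 2:
        raise InvalidInputError("aggregation needs at least 2 studies")
    curves = [corrected_curve(s, parent_fractions) for s in studies]
    grid = curves[0].times
    for c in curves[1:]:
        if c.times.shape != grid.shape or not np.array_equal(c.times, grid):
            raise InvalidInputError(
                "studies are not sampled on a common nominal time grid"
            )
    values = np.vstack(
        [(c.suv if use_suv else c.conc) for c in curves]
    )
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    return PlasmaCurve(times=grid, conc=mean, conc_sd=sd)


# ---------------------------------------------------------------------------
# Triexponential fitting


def _strip_initial_guess(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Curve-stripping initialization: log-linear fit of the tail for the
    terminal phase, peel it off, and repeat for the faster phases.

    Returns packed parameters [A1, A2, A3, lam1, lam2, lam3] with lam
    descending. Falls back to heuristic splits when a peeled residual goes
    non-positive (heavy noise)."""
    n = t.size
    amps, lams = [], []
    resid = y.astype(float).copy()
    # segment the grid into early/middle/tail thirds by index
    bounds = [0, n // 3, 2 * n // 3, n]
    # strip from the tail backwards
    for lo, hi in ((bounds[2], bounds[3]), (bounds[1], bounds[2]), (bounds[0], bounds[1])):
        seg_t, seg_y = t[lo:hi], resid[lo:hi]
        mask = seg_y > 0
        if mask.sum() >= 2:
            slope, intercept = np.polyfit(seg_t[mask], np.log(seg_y[mask]), 1)
            lam = max(-slope, 1e-6)
            amp = float(np.exp(intercept))
        else:
            # peel destroyed the segment; seed with a scaled copy of the
            # previous phase
            lam = (lams[-1] * 5.0) if lams else 1e-2
            amp = max(float(np.max(y)) * 0.1, 1e-12)
        lams.append(lam)
        amps.append(amp)
        resid = resid - amp * np.exp(-lam * t)
    # collected slow -> fast; return fast -> slow
    a = np.array(amps[::-1])
    lam = np.array(lams[::-1])
    # enforce strictly decreasing rate seeds
    for i in range(1, 3):
        if lam[i] >= lam[i - 1]:
            lam[i] = lam[i - 1] / 5.0
    return np.concatenate([np.maximum(a, 1e-12), lam])


def _identifiability_bounds(t: np.ndarray, y: np.ndarray):
    """Log-space box constraints keeping all three phases resolvable.

    A component decaying entirely before the first sample (lam*t_first >> 1)
    or flat over the whole observation window is invisible to the data yet
    can contribute arbitrary area A/lam, corrupting the clearance estimate.
    Rates are therefore confined to [0.05/t_last, 3/t_first] and amplitudes
    to at most 50x the observed maximum (the back-extrapolated intercept
    cannot exceed the first measurement by orders of magnitude).
    """
    t_first = t[t > 0].min() if np.any(t > 0) else 1.0
    ymax = float(y.max())
    lam_lo, lam_hi = 0.05 / t[-1], 3.0 / t_first
    a_lo, a_hi = 1e-9 * ymax, 50.0 * ymax
    lo = np.log([a_lo] * 3 + [lam_lo] * 3)
    hi = np.log([a_hi] * 3 + [lam_hi] * 3)
    return lo, hi


def _refine(t: np.ndarray, y: np.ndarray, x0: np.ndarray, lo, hi,
            w: np.ndarray | None = None):
    """Bounded nonlinear least squares in log-parameter space."""

    def resid(logx):
        a = np.exp(logx[:3])
        lam = np.exp(logx[3:])
        r = a @ np.exp(-np.outer(lam, t)) - y
        return r if w is None else r * w

    x0 = np.clip(np.log(x0), lo, hi)
    sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14,
                        gtol=1e-14)
    return np.exp(sol.x), float(np.sum(sol.fun**2)), sol.success


def fit_triexponential(
    curve: PlasmaCurve,
    n_restarts: int = N_RESTARTS,
    weights: np.ndarray | None = None,
    seed: int = 0,
) -> TriexpFit:
    """Fit the triexponential bolus model by multi-start least squares.

    Initialization is by curve stripping (log-linear tail fit, peel,
    repeat), followed by ``n_restarts`` log-normally perturbed restarts of
    the full nonlinear refinement. Ties are broken by lowest residual sum of
    squares, then by the largest spread between rate constants. Fitting is
    unweighted by default; pass ``weights`` (e.g. 1/yhat**2) to weight.

    Requires at least 7 points spanning an early (< 5 min) and a late
    (> 60 min) phase — the model is not identifiable otherwise.
    """
    t, y = curve.times, curve.conc
    if t.size < 7:
        raise InvalidInputError("triexponential fit needs >= 7 points")
    if t.min() >= 5.0 or t.max() <= 60.0:
        raise InvalidInputError(
            "sampling must span early (< 5 min) and late (> 60 min) phases"
        )
    w = None if weights is None else np.sqrt(np.asarray(weights, dtype=float))

    rng = np.random.default_rng(seed)
    lo, hi = _identifiability_bounds(t, y)
    x0 = _strip_initial_guess(t, y)
    starts = [x0]
    # restart cloud around the stripping seed (local and wide perturbations
    # to escape the lam2/lam3 trade-off valley), plus box-uniform probes so
    # boundary optima of the constrained problem are reachable
    for i in range(n_restarts):
        sigma = 0.3 if i < n_restarts // 2 else 1.0
        starts.append(x0 * np.exp(rng.normal(0.0, sigma, size=6)))
    for _ in range(n_restarts):
        starts.append(np.exp(rng.uniform(lo, hi)))
    # deterministic probes at the rate-constant bounds: the constrained
    # optimum can sit on the boundary (fastest resolvable phase, slowest
    # resolvable tail)
    for idx, bound, amp_scale in ((3, hi[3], 1.0), (3, hi[3], 5.0),
                                  (5, lo[5], 1.0), (5, lo[5], 0.2)):
        xb = x0.copy()
        xb[idx] = np.exp(bound) * (0.999 if idx == 3 else 1.001)
        xb[idx - 3] *= amp_scale
        starts.append(xb)

    best = None  # ((sse, -lam_spread), params)
    for x in starts:
        try:
            params, sse, _ok = _refine(t, y, x, lo, hi, w)
        except (ValueError, FloatingPointError):
            continue
        if not np.all(np.isfinite(params)):
            continue
        lam = np.sort(params[3:])[::-1]
        spread = lam[0] / lam[-1]
        key = (sse, -spread)
        if best is None or key < best[0]:
            best = (key, params)

    if best is None:
        raise FitFailureError("all triexponential starts failed", {"x0": x0.tolist()})

    params = best[1]
    a, lam = params[:3], params[3:]
    order = np.argsort(lam)[::-1]
    a, lam = a[order], lam[order]
    sse = best[0][0]

    if not np.all(np.isfinite(lam)) or np.any(lam <= 0):
        raise FitFailureError(
            "non-positive rate constant at optimum",
            {"a": a.tolist(), "lam": lam.tolist(), "sse": sse},
        )

    warn = []
    if np.any(a < 1e-6 * a.max()):
        warn.append("near-zero amplitude component (model may be over-specified)")
    if np.any(lam[:-1] / lam[1:] < 1.2):
        warn.append("poorly separated rate constants")
    return TriexpFit(a=a, lam=lam, residual_sse=sse, warnings=tuple(warn))


def pk_parameters(
    fit: TriexpFit, injected_dose: float, body_weight: float | None = None
) -> PKParameters:
    """Clearance, volume of distribution and terminal half-life from a fit.

    With ``body_weight`` (kg) given, CL_p and V_d are normalized per kg
    (mL/min/kg and mL/kg); otherwise they are absolute (mL/min and mL).
    """
    if injected_dose <= 0:
        raise InvalidInputError("injected_dose must be > 0")
    lam3 = float(fit.lam[-1])
    if lam3 <= 0:
        raise InvalidInputError("terminal rate constant must be > 0")
    cl = injected_dose / fit.auc
    if body_weight is not None:
        if body_weight <= 0:
            raise InvalidInputError("body_weight must be > 0")
        cl /= body_weight
    return PKParameters(cl_p=cl, v_d=cl / lam3, t_half_term=LN2 / lam3)


def relative_weights(conc: np.ndarray) -> np.ndarray:
    """1/y**2 least-squares weights (constant relative error model).

    Plasma curves span a ~50-fold concentration range while their dominant
    error sources (counting statistics, metabolite-correction error) are
    roughly proportional to the signal; relative weighting keeps the
    information-rich terminal phase from being drowned out by the large
    early-time concentrations.
    """
    c = np.asarray(conc, dtype=float)
    return 1.0 / np.maximum(c, 1e-300) ** 2


def _weights_for(curve: PlasmaCurve, weighting: str) -> np.ndarray | None:
    if weighting == "relative":
        return relative_weights(curve.conc)
    if weighting == "uniform":
        return None
    raise InvalidInputError(f"unknown weighting {weighting!r}")


def study_pk(
    study: AnimalStudy,
    parent_fractions: ParentFractionSeries | None = None,
    weighting: str = "relative",
    **fit_kwargs,
) -> PKParameters:
    """Full per-animal pipeline: correct, fit, derive PK parameters."""
    curve = corrected_curve(study, parent_fractions)
    fit = fit_triexponential(curve, weights=_weights_for(curve, weighting),
                             **fit_kwargs)
    return pk_parameters(fit, study.injected_activity, study.body_weight)


def mean_curve_pk(
    studies: list[AnimalStudy],
    use_suv: bool = False,
    pooled_parent_fractions: bool = True,
    weighting: str = "relative",
    **fit_kwargs,
) -> tuple[PKParameters, TriexpFit]:
    """PK parameters from the aggregated mean curve.

    By default the metabolite correction is population-based: one Hill
    parent-fraction model fitted to all animals' measurements
    (:func:`smooth_parent_fractions`) corrects every curve, and the fit uses
    relative (1/y**2) weighting. The mean curve is fitted once; dose and
    body weight are the arithmetic means across animals (for SUV averaging
    the curve is already normalized, so a unit dose per gram body weight is
    used).
    """
    pf = (
        smooth_parent_fractions([s.parent_fractions for s in studies])
        if pooled_parent_fractions
        else None
    )
    mean_curve = aggregate_mean_curve(studies, use_suv=use_suv,
                                      parent_fractions=pf)
    fit = fit_triexponential(mean_curve,
                             weights=_weights_for(mean_curve, weighting),
                             **fit_kwargs)
    if use_suv:
        # SUV curves are dose/(g body weight)-normalized: CL in mL/min/g -> /kg
        bw = None
        dose = 1000.0  # activity units per kg body mass
        return pk_parameters(fit, dose, bw), fit
    dose = float(np.mean([s.injected_activity for s in studies]))
    bw = float(np.mean([s.body_weight for s in studies]))
    return pk_parameters(fit, dose, bw), fit
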