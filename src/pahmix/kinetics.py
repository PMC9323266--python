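"""Microsomal substrate-depletion kinetics.

Estimates initial metabolism rates from substrate-depletion time courses
(exponential regression of concentration vs. time) and fits biphasic rate
laws to rate-vs-concentration data. Three candidate rate laws describe the
disappearance rate v(S) (nmol/min/mg microsomal protein) of a substrate at
concentration S (µM):

* ``MM`` — single Michaelis–Menten phase: v = Vmax·S/(Km+S)
* ``MM_CLEARANCE`` — a saturable high-affinity phase plus a linear
  (non-saturating, low-affinity/high-capacity) clearance phase:
  v = Vmax1·S/(Km1+S) + Clint2·S
* ``DOUBLE_MM`` — two saturable phases (Km2 > Km1 by construction)

Fitting uses a Gaussian maximum-likelihood objective with a common unknown
residual SD profiled out, which makes point estimation equivalent to
unweighted least squares; models are compared by BIC and parameter
uncertainty comes from seeded parametric bootstrap.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ModelForm",
    "DepletionTimeCourse",
    "ExponentialFit",
    "RateEstimate",
    "KineticModelSpec",
    "KineticFit",
    "KineticsError",
    "DegenerateDataError",
    "FitConvergenceError",
    "fit_exponential_depletion",
    "initial_rate",
    "bootstrap_rate_ci",
    "rate_model_eval",
    "fit_rate_model",
    "bic",
    "select_model",
    "parametric_bootstrap_params",
    "clint_first_phase",
]

# native-unit optimisation bounds shared by all kinetic fits
PARAM_LOWER = 1e-9
PARAM_UPPER = 1e3
_LOG_LO = math.log(PARAM_LOWER)
_LOG_HI = math.log(PARAM_UPPER)
_SIGMA_FLOOR = 1e-12

# default assay geometry: 500 µL incubations at 2.0 mg microsomal protein/mL
DEFAULT_VOLUME_ML = 0.5
DEFAULT_PROTEIN_MG_PER_ML = 2.0


class KineticsError(Exception):
    """Base class for kinetics fitting errors."""


class DegenerateDataError(KineticsError):
    """Raised when a dataset cannot support the requested fit."""


class FitConvergenceError(KineticsError):
    """Raised when no multistart converges; carries the best point found."""

    def __init__(self, message: str, best_params: dict | None = None):
        super().__init__(message)
        self.best_params = best_params


class ModelForm(str, enum.Enum):
    MM = "MM"
    MM_CLEARANCE = "MM_CLEARANCE"
    DOUBLE_MM = "DOUBLE_MM"


_PARAM_NAMES: dict[ModelForm, tuple[str, ...]] = {
    ModelForm.MM: ("vmax1", "km1"),
    ModelForm.MM_CLEARANCE: ("vmax1", "km1", "clint2"),
    ModelForm.DOUBLE_MM: ("vmax1", "km1", "vmax2", "km2"),
}

# deterministic simplicity order used for BIC tie-breaks
_FORM_ORDER = {ModelForm.MM: 0, ModelForm.MM_CLEARANCE: 1, ModelForm.DOUBLE_MM: 2}


@dataclass(frozen=True)
class KineticModelSpec:
    """A parameterised rate law.

    Units: vmax* in nmol/min/mg, km* in µM, clint2 in mL/min/mg
    (mL/min/mg × nmol/mL ≡ nmol/min/mg, since µM ≡ nmol/mL).
    """

    form: ModelForm
    vmax1: float
    km1: float
    clint2: float | None = None
    vmax2: float | None = None
    km2: float | None = None

    def __post_init__(self):
        for name in self.param_names():
            value = getattr(self, name)
            if value is None or not value > 0:
                raise ValueError(f"{self.form.value} requires {name} > 0, got {value}")
        if self.form is ModelForm.DOUBLE_MM and not self.km2 > self.km1:
            raise ValueError(
                "DOUBLE_MM requires km2 > km1 (phase 1 is the high-affinity phase)"
            )

    def param_names(self) -> tuple[str, ...]:
        return _PARAM_NAMES[self.form]

    def param_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.param_names()], dtype=float)

    @classmethod
    def from_vector(cls, form: ModelForm, theta: Sequence[float]) -> "KineticModelSpec":
        theta = np.asarray(theta, dtype=float)
        if form is ModelForm.DOUBLE_MM and theta[3] < theta[1]:
            # relabel so phase 1 is the high-affinity (low-Km) phase
            theta = np.array([theta[2], theta[3], theta[0], theta[1]])
        return cls(form, **dict(zip(_PARAM_NAMES[form], theta)))

    def as_dict(self) -> dict:
        d = {"form": self.form.value}
        d.update({n: float(getattr(self, n)) for n in self.param_names()})
        return d

    def rate(self, S):
        return rate_model_eval(self, S)


def rate_model_eval(spec: KineticModelSpec, S):
    """Disappearance rate (nmol/min/mg) of the rate law at concentration S (µM)."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be non-negative")
    v = spec.vmax1 * S / (spec.km1 + S)
    if spec.form is ModelForm.MM_CLEARANCE:
        v = v + spec.clint2 * S
    elif spec.form is ModelForm.DOUBLE_MM:
        v = v + spec.vmax2 * S / (spec.km2 + S)
    return v if v.ndim else float(v)


@dataclass
class DepletionTimeCourse:
    """Replicate substrate-concentration measurements over time for one assay.

    ``observations`` holds (time_min, replicate_index, conc_uM) triples; all
    replicates of a condition live in one course and are pooled when fitting.
    """

    substrate_id: str
    nominal_S0: float
    observations: list[tuple[float, int, float]]
    inhibitor_id: str | None = None
    inhibitor_conc: float = 0.0
    protein_conc: float = DEFAULT_PROTEIN_MG_PER_ML
    volume: float = DEFAULT_VOLUME_ML
    is_control: bool = False

    def __post_init__(self):
        if self.protein_conc <= 0 or self.volume <= 0:
            raise ValueError("protein_conc and volume must be positive")
        if self.inhibitor_conc < 0:
            raise ValueError("inhibitor_conc must be non-negative")
        for t, _, c in self.observations:
            if t < 0:
                raise ValueError(f"negative time {t}")
            if c < 0:
                raise ValueError(f"negative concentration {c}")

    @property
    def times(self) -> np.ndarray:
        return np.array([o[0] for o in self.observations], dtype=float)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([o[2] for o in self.observations], dtype=float)

    def n_distinct_times(self) -> int:
        return len(set(o[0] for o in self.observations))


@dataclass(frozen=True)
class ExponentialFit:
    """Least-squares fit of S(t) = S0·exp(−k·t) on the concentration scale."""

    k: float  # 1/min
    s0: float  # µM

    @property
    def no_depletion(self) -> bool:
        return self.k <= 1e-10

    def __iter__(self) -> Iterator[float]:
        return iter((self.k, self.s0))


@dataclass
class RateEstimate:
    """Initial substrate-disappearance rate at one (S, I) condition."""

    S: float  # µM, nominal starting substrate concentration
    I: float  # µM, inhibitor concentration (0 when absent)
    rate: float  # nmol/min/mg microsomal protein
    ci_low: float
    ci_high: float
    n_boot: int
    decay_k: float  # 1/min
    fitted_S0: float  # µM

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if not (self.ci_low <= self.rate + 1e-12 and self.rate <= self.ci_high + 1e-12):
            raise ValueError("CI must bracket the point estimate")


def _fit_exp(t: np.ndarray, y: np.ndarray) -> ExponentialFit:
    if np.all(y == 0):
        raise DegenerateDataError("all concentrations are zero")
    s0_guess = max(float(np.mean(y[t == t.min()])), 1e-12)
    pos = y > 0
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
        k_guess = max(-slope, 0.0)
    else:
        k_guess = 0.0

    def resid(p):
        return p[1] * np.exp(-p[0] * t) - y

    sol = least_squares(
        resid,
        x0=[k_guess, s0_guess],
        bounds=([0.0, 1e-12], [np.inf, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    return ExponentialFit(k=float(sol.x[0]), s0=float(sol.x[1]))


def fit_exponential_depletion(course: DepletionTimeCourse) -> ExponentialFit:
    """Fit S(t) = S0·exp(−k·t) to a pooled-replicate depletion course.

    Fitting is on the raw concentration scale (additive measurement noise),
    not log-linear. A fit pinned at k = 0 is flagged via
    :attr:`ExponentialFit.no_depletion`.
    """
    if course.n_distinct_times() < 3:
        raise DegenerateDataError(
            f"need ≥3 distinct time points, got {course.n_distinct_times()}"
        )
    return _fit_exp(course.times, course.concentrations)


def initial_rate(
    decay_k: float, fitted_S0: float, volume: float, protein_conc: float
) -> float:
    """Initial disappearance rate in nmol/min/mg microsomal protein.

    nmol lost/min = k·S0 (µM ≡ nmol/mL) × volume (mL); dividing by the protein
    mass (volume × protein_conc) cancels the volume: rate = k·S0/protein_conc.
    """
    if volume <= 0 or protein_conc <= 0:
        raise ValueError("volume and protein_conc must be positive")
    if decay_k < 0 or fitted_S0 < 0:
        raise ValueError("decay_k and fitted_S0 must be non-negative")
    return decay_k * fitted_S0 * volume / (volume * protein_conc)


def bootstrap_rate_ci(
    course: DepletionTimeCourse, n_boot: int = 1000, seed: int | None = None
) -> RateEstimate:
    """Nonparametric bootstrap CI for the initial rate of one course.

    Replicate measurements are resampled with replacement within each time
    point, the exponential regression is repeated, and the 2.5/97.5 percentile
    interval of the recomputed rates is reported. Deterministic given seed.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be ≥ 2")
    base = fit_exponential_depletion(course)
    rate = initial_rate(base.k, base.s0, course.volume, course.protein_conc)

    t = course.times
    y = course.concentrations
    rng = np.random.default_rng(seed)
    groups = [np.flatnonzero(t == tv) for tv in np.unique(t)]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(g, size=g.size, replace=True) for g in groups])
        try:
            f = _fit_exp(t[idx], y[idx])
            boots[b] = initial_rate(f.k, f.s0, course.volume, course.protein_conc)
        except DegenerateDataError:
            boots[b] = 0.0
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RateEstimate(
        S=course.nominal_S0,
        I=course.inhibitor_conc,
        rate=rate,
        ci_low=min(float(lo), rate),
        ci_high=max(float(hi), rate),
        n_boot=n_boot,
        decay_k=base.k,
        fitted_S0=base.s0,
    )


# ---------------------------------------------------------------------------
# rate-law fitting


@dataclass
class KineticFit:
    """A fitted rate law with its Gaussian-likelihood summary.

    ``loglik`` is the full Gaussian log-likelihood at the profiled ML sigma
    (2π terms included); ``bic = −2·loglik + k·ln(n)`` where k counts the
    kinetic parameters plus sigma.
    """

    spec: KineticModelSpec
    sigma_hat: float
    loglik: float
    bic: float
    n_obs: int
    rss: float
    degenerate: bool = False
    param_cis: dict[str, tuple[float, float]] | None = None

    @property
    def clint1(self) -> float:
        """First-phase intrinsic clearance Vmax1/Km1, mL/min/mg."""
        return clint_first_phase(self.spec.vmax1, self.spec.km1)

    @property
    def n_params(self) -> int:
        """Number of estimated parameters, counting sigma."""
        return len(self.spec.param_names()) + 1

    def as_dict(self) -> dict:
        d = {
            "form": self.spec.form.value,
            "parameters": {n: float(getattr(self.spec, n)) for n in self.spec.param_names()},
            "param_cis": {k: [float(a), float(b)] for k, (a, b) in self.param_cis.items()}
            if self.param_cis
            else None,
            "loglik": float(self.loglik),
            "bic": float(self.bic),
            "n": int(self.n_obs),
            "sigma_hat": float(self.sigma_hat),
            "clint1": float(self.clint1),
            "degenerate": bool(self.degenerate),
        }
        return d


def _extract_sy(rates) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(rates, tuple) and len(rates) == 2:
        S, y = (np.asarray(a, dtype=float) for a in rates)
    else:
        S = np.array([r.S for r in rates], dtype=float)
        y = np.array([r.rate for r in rates], dtype=float)
    return S, y


def _gaussian_summary(rss: float, n: int) -> tuple[float, float]:
    sigma = max(math.sqrt(rss / n), _SIGMA_FLOOR)
    loglik = -0.5 * (n * math.log(2 * math.pi * sigma**2) + rss / sigma**2)
    return sigma, loglik


def _heuristic_start(form: ModelForm, S: np.ndarray, y: np.ndarray) -> np.ndarray:
    vmax0 = max(float(np.max(y)), 1e-6)
    km0 = float(np.median(S))
    if form is ModelForm.MM:
        return np.array([vmax0, km0])
    hi = int(np.argmax(S))
    clint0 = max(float(y[hi] / S[hi]) * 0.3, 1e-6)
    if form is ModelForm.MM_CLEARANCE:
        return np.array([vmax0, km0, clint0])
    return np.array([vmax0, km0, vmax0, km0 * 10])


def _multistarts(base: np.ndarray) -> list[np.ndarray]:
    """Coordinate-wise multistart: 8 log-spaced multipliers per parameter."""
    starts = [base]
    multipliers = np.logspace(-2, 2, 8)
    for i in range(base.size):
        for m in multipliers:
            s = base.copy()
            s[i] *= m
            starts.append(s)
    return starts


def fit_rate_model(rates, form: ModelForm) -> KineticFit:
    """Fit one rate law to (S, rate) data by Gaussian maximum likelihood.

    With i.i.d. additive Gaussian error of common unknown SD, profiling sigma
    reduces the ML problem to unweighted least squares; parameters are kept
    strictly positive by optimising their logarithms, with bounded multistart
    over log-spaced initial values.

    ``rates`` is a list of :class:`RateEstimate` (uninhibited, I = 0) or a
    ``(S_array, rate_array)`` tuple.
    """
    S, y = _extract_sy(rates)
    n_par = len(_PARAM_NAMES[form])
    if np.unique(S).size < n_par + 1:
        raise DegenerateDataError(
            f"{form.value} needs ≥{n_par + 1} distinct S values, got {np.unique(S).size}"
        )

    def resid(logtheta):
        theta = np.exp(logtheta)
        spec = dict(zip(_PARAM_NAMES[form], theta))
        v = spec["vmax1"] * S / (spec["km1"] + S)
        if form is ModelForm.MM_CLEARANCE:
            v = v + spec["clint2"] * S
        elif form is ModelForm.DOUBLE_MM:
            v = v + spec["vmax2"] * S / (spec["km2"] + S)
        return v - y

    best = None
    for start in _multistarts(_heuristic_start(form, S, y)):
        x0 = np.clip(np.log(start), _LOG_LO, _LOG_HI)
        try:
            sol = least_squares(
                resid,
                x0=x0,
                bounds=(_LOG_LO, _LOG_HI),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitConvergenceError(f"no multistart converged for {form.value}")

    theta = np.exp(best.x)
    spec = KineticModelSpec.from_vector(form, theta)
    rss = float(2 * best.cost)
    n = y.size
    sigma, loglik = _gaussian_summary(rss, n)
    k = n_par + 1
    degenerate = bool(np.all(y == 0) or spec.vmax1 <= PARAM_LOWER * 1.01)
    return KineticFit(
        spec=spec,
        sigma_hat=sigma,
        loglik=loglik,
        bic=-2 * loglik + k * math.log(n),
        n_obs=n,
        rss=rss,
        degenerate=degenerate,
    )


def bic(fit: KineticFit) -> float:
    """BIC = −2·loglik + k·ln(n), k counting kinetic parameters plus sigma."""
    return -2 * fit.loglik + fit.n_params * math.log(fit.n_obs)


def select_model(fits: Iterable[KineticFit]) -> KineticFit:
    """Return the lowest-BIC fit; BIC ties (|ΔBIC| < 1e-9) go to fewer parameters."""
    fits = list(fits)
    if not fits:
        raise ValueError("select_model requires at least one fit")
    best_bic = min(f.bic for f in fits)
    candidates = [f for f in fits if f.bic <= best_bic + 1e-9]
    return min(candidates, key=lambda f: (f.n_params, _FORM_ORDER[f.spec.form]))


def parametric_bootstrap_params(
    fit: KineticFit, rates, n_boot: int = 1000, seed: int | None = None
) -> dict[str, tuple[float, float]]:
    """Parametric-bootstrap 95% percentile CIs for the kinetic parameters.

    Simulates rates ~ Normal(fitted rate at each concentration, sigma_hat),
    truncated at 0 by clipping, refits, and takes per-parameter 2.5/97.5
    percentiles. The CIs are attached to ``fit.param_cis`` and returned.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be ≥ 2")
    S, _ = _extract_sy(rates)
    form = fit.spec.form
    names = fit.spec.param_names()
    mu = np.asarray(rate_model_eval(fit.spec, S), dtype=float)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, len(names)))
    x0 = np.clip(np.log(fit.spec.param_vector()), _LOG_LO, _LOG_HI)
    for b in range(n_boot):
        yb = np.maximum(mu + rng.normal(0.0, fit.sigma_hat, size=mu.size), 0.0)

        def resid(logtheta, yb=yb):
            theta = np.exp(logtheta)
            p = dict(zip(names, theta))
            v = p["vmax1"] * S / (p["km1"] + S)
            if form is ModelForm.MM_CLEARANCE:
                v = v + p["clint2"] * S
            elif form is ModelForm.DOUBLE_MM:
                v = v + p["vmax2"] * S / (p["km2"] + S)
            return v - yb

        sol = least_squares(
            resid, x0=x0, bounds=(_LOG_LO, _LOG_HI), xtol=1e-12, ftol=1e-12
        )
        theta = np.exp(sol.x)
        if form is ModelForm.DOUBLE_MM and theta[3] < theta[1]:
            theta = np.array([theta[2], theta[3], theta[0], theta[1]])
        draws[b] = theta
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    point = fit.spec.param_vector()
    cis = {
        name: (min(float(l), point[i]), max(float(h), point[i]))
        for i, (name, l, h) in enumerate(zip(names, lo, hi))
    }
    fit.param_cis = cis
    return cis


def clint_first_phase(vmax1: float, km1: float) -> float:
    """First-phase intrinsic clearance Clint1 = Vmax1/Km1 (mL/min/mg)."""
    if km1 <= 0:
        raise ValueError("km1 must be positive")
    return vmax1 / km1
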