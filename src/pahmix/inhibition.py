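"""Competitive-inhibition constants and mixture handling.

Once the baseline (uninhibited) rate law of a substrate is fixed to the
Michaelis–Menten-clearance form v(S) = Vmax1·S/(Km1+S) + Clint2·S, a
co-incubated inhibitor at concentration I can act on either enzymatic phase:

* ``PHASE1`` — competition with the high-affinity/low-capacity enzyme:
  v = Vmax1·S/(Km1·(1+I/Ki)+S) + Clint2·S
* ``PHASE2`` — competition with the low-affinity/high-capacity enzyme:
  v = Vmax1·S/(Km1+S) + Clint2·S/(1+I/Ki)

The apparent inhibition constant Ki (µM) is estimated with the baseline
kinetic parameters held fixed (a single nominal substrate concentration
cannot identify them jointly), and the two placements are compared by BIC.

A defined PAH mixture (e.g. Supermix-10) is treated as a single lumped
inhibitor at its total molar concentration.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .kinetics import (
    KineticFit,
    KineticModelSpec,
    ModelForm,
    RateEstimate,
    _gaussian_summary,
    rate_model_eval,
)

__all__ = [
    "InhibitionPlacement",
    "InhibitionDataset",
    "KiFit",
    "MixtureComponent",
    "MixtureComposition",
    "inhibited_rate_eval",
    "percent_inhibition",
    "fit_ki",
    "select_inhibition_model",
    "mixture_molar_fractions",
    "lumped_inhibitor_conc",
    "component_concentrations",
]

KI_LOWER = 1e-9
KI_UPPER = 1e3


class InhibitionPlacement(str, enum.Enum):
    PHASE1 = "PHASE1"  # inhibitor scales Km1 of the high-affinity phase
    PHASE2 = "PHASE2"  # inhibitor suppresses the linear clearance phase


def inhibited_rate_eval(
    baseline: KineticModelSpec,
    placement: InhibitionPlacement,
    S,
    I,
    ki: float,
):
    """Inhibited disappearance rate (nmol/min/mg) at substrate S, inhibitor I (µM)."""
    if baseline.form is not ModelForm.MM_CLEARANCE:
        raise ValueError("inhibition models extend the MM_CLEARANCE baseline")
    if ki <= 0:
        raise ValueError("ki must be positive")
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    if np.any(S < 0) or np.any(I < 0):
        raise ValueError("concentrations must be non-negative")
    shift = 1.0 + I / ki
    if placement is InhibitionPlacement.PHASE1:
        v = baseline.vmax1 * S / (baseline.km1 * shift + S) + baseline.clint2 * S
    else:
        v = baseline.vmax1 * S / (baseline.km1 + S) + baseline.clint2 * S / shift
    return v if v.ndim else float(v)


def percent_inhibition(
    baseline: KineticModelSpec,
    placement: InhibitionPlacement,
    S: float,
    I: float,
    ki: float,
) -> float:
    """Fractional rate reduction 1 − v(S, I)/v(S, 0), in [0, 1)."""
    v0 = rate_model_eval(baseline, S)
    if v0 == 0:
        raise ValueError("uninhibited rate is zero; percent inhibition undefined")
    return 1.0 - inhibited_rate_eval(baseline, placement, S, I, ki) / v0


@dataclass
class InhibitionDataset:
    """Inhibited rate observations at a fixed nominal substrate concentration.

    ``points`` holds (I µM, rate nmol/min/mg) pairs; ``baseline`` is the
    substrate's uninhibited MM_CLEARANCE fit. If no I = 0 point is present,
    the baseline model prediction at ``substrate_conc`` anchors the fit.
    """

    substrate_id: str
    baseline: KineticModelSpec
    substrate_conc: float
    inhibitor_id: str
    points: list[tuple[float, float]]

    def __post_init__(self):
        if isinstance(self.baseline, KineticFit):
            self.baseline = self.baseline.spec
        if self.baseline.form is not ModelForm.MM_CLEARANCE:
            raise ValueError("baseline must be an MM_CLEARANCE fit")
        if self.substrate_conc <= 0:
            raise ValueError("substrate_conc must be positive")
        if any(i < 0 for i, _ in self.points):
            raise ValueError("inhibitor concentrations must be non-negative")

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        pts = list(self.points)
        if not any(i == 0 for i, _ in pts):
            pts = [(0.0, rate_model_eval(self.baseline, self.substrate_conc))] + pts
        pts.sort(key=lambda p: p[0])
        I = np.array([p[0] for p in pts], dtype=float)
        y = np.array([p[1] for p in pts], dtype=float)
        return I, y


@dataclass
class KiFit:
    """A fitted competitive-inhibition constant under one placement."""

    ki: float  # µM
    ci_low: float
    ci_high: float
    placement: InhibitionPlacement
    loglik: float
    bic: float
    n_obs: int
    sigma_hat: float
    no_inhibition: bool = False
    bic_phase1: float | None = None
    bic_phase2: float | None = None

    def as_dict(self) -> dict:
        return {
            "placement": self.placement.value,
            "ki": float(self.ki),
            "ci": [float(self.ci_low), float(self.ci_high)],
            "bic_phase1": None if self.bic_phase1 is None else float(self.bic_phase1),
            "bic_phase2": None if self.bic_phase2 is None else float(self.bic_phase2),
            "n": int(self.n_obs),
            "sigma_hat": float(self.sigma_hat),
            "no_inhibition": bool(self.no_inhibition),
        }


def _fit_ki_point(
    baseline: KineticModelSpec,
    placement: InhibitionPlacement,
    S: float,
    I: np.ndarray,
    y: np.ndarray,
) -> tuple[float, float]:
    """Least-squares Ki on the log scale with log-spaced multistart; returns (ki, rss)."""

    def resid(logki, yv=y):
        return inhibited_rate_eval(baseline, placement, S, I, float(np.exp(logki[0]))) - yv

    best = None
    for ki0 in np.logspace(-4, 2.5, 8):
        sol = least_squares(
            resid,
            x0=[math.log(ki0)],
            bounds=(math.log(KI_LOWER), math.log(KI_UPPER)),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError(f"Ki fit failed to converge ({placement.value})")
    return float(np.exp(best.x[0])), float(2 * best.cost)


def fit_ki(
    dataset: InhibitionDataset,
    placement: InhibitionPlacement,
    n_boot: int = 1000,
    seed: int | None = None,
) -> KiFit:
    """Estimate Ki under one inhibition placement, baseline parameters fixed.

    Gaussian ML (equivalent to least squares over log Ki) with a parametric
    bootstrap 95% percentile CI: rates are resampled from
    Normal(fitted rate, sigma_hat) truncated at 0 and Ki is refit. Pass
    ``n_boot=0`` to skip the bootstrap (CI collapses to the point estimate).
    Rates flat in I drive Ki to its upper bound, flagged ``no_inhibition``.
    """
    I, y = dataset.arrays()
    if np.unique(I).size < 3:
        raise ValueError("need ≥3 distinct inhibitor concentrations")
    S = dataset.substrate_conc
    ki, rss = _fit_ki_point(dataset.baseline, placement, S, I, y)
    n = y.size
    sigma, loglik = _gaussian_summary(rss, n)
    k = 2  # ki + sigma
    no_inhibition = ki >= KI_UPPER * 0.999

    ci_low = ci_high = ki
    if n_boot:
        if n_boot < 2:
            raise ValueError("n_boot must be ≥ 2 (or 0 to skip)")
        rng = np.random.default_rng(seed)
        mu = np.asarray(inhibited_rate_eval(dataset.baseline, placement, S, I, ki))
        draws = np.empty(n_boot)
        for b in range(n_boot):
            yb = np.maximum(mu + rng.normal(0.0, sigma, size=n), 0.0)
            draws[b], _ = _fit_ki_point(dataset.baseline, placement, S, I, yb)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        ci_low, ci_high = min(float(lo), ki), max(float(hi), ki)

    return KiFit(
        ki=ki,
        ci_low=ci_low,
        ci_high=ci_high,
        placement=placement,
        loglik=loglik,
        bic=-2 * loglik + k * math.log(n),
        n_obs=n,
        sigma_hat=sigma,
        no_inhibition=no_inhibition,
    )


def select_inhibition_model(
    dataset: InhibitionDataset, n_boot: int = 1000, seed: int | None = None
) -> KiFit:
    """Fit both inhibition placements and return the lower-BIC one.

    Both BICs are recorded on the returned fit; an exact tie goes to PHASE1
    (the high-affinity placement, fitted first).
    """
    f1 = fit_ki(dataset, InhibitionPlacement.PHASE1, n_boot=n_boot, seed=seed)
    f2 = fit_ki(dataset, InhibitionPlacement.PHASE2, n_boot=n_boot, seed=seed)
    winner = f1 if f1.bic <= f2.bic else f2
    winner.bic_phase1 = f1.bic
    winner.bic_phase2 = f2.bic
    return winner


# ---------------------------------------------------------------------------
# defined mixtures as lumped inhibitors


@dataclass(frozen=True)
class MixtureComponent:
    name: str
    cas: str
    molecular_weight: float  # g/mol
    molar_ratio: float  # normalized to the least-abundant component

    def __post_init__(self):
        if self.molar_ratio <= 0 or self.molecular_weight <= 0:
            raise ValueError("molar_ratio and molecular_weight must be positive")


@dataclass(frozen=True)
class MixtureComposition:
    """A defined multi-PAH mixture with molar ratios normalized to one component."""

    components: tuple[MixtureComponent, ...]

    def __post_init__(self):
        if not self.components:
            raise ValueError("mixture must have at least one component")

    @property
    def reference_component(self) -> MixtureComponent:
        return min(self.components, key=lambda c: abs(c.molar_ratio - 1.0))

    @property
    def total_ratio(self) -> float:
        return sum(c.molar_ratio for c in self.components)


def mixture_molar_fractions(mix: MixtureComposition) -> dict[str, float]:
    """Per-component molar fractions, ratio_i / Σ ratios (sum to 1)."""
    total = mix.total_ratio
    return {c.name: c.molar_ratio / total for c in mix.components}


def lumped_inhibitor_conc(mix: MixtureComposition, total_conc: float) -> float:
    """Total molar concentration of the mixture treated as a single inhibitor."""
    if total_conc < 0:
        raise ValueError("total_conc must be non-negative")
    return float(total_conc)


def component_concentrations(
    mix: MixtureComposition, total_conc: float
) -> dict[str, float]:
    """Per-component concentrations (µM) at a given total mixture concentration."""
    if total_conc < 0:
        raise ValueError("total_conc must be non-negative")
    fr = mixture_molar_fractions(mix)
    return {name: f * total_conc for name, f in fr.items()}
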