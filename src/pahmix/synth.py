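"""Seeded synthetic in vitro datasets.

Emulates microsomal substrate-depletion assays with the statistical
structure the fitting pipeline assumes: substrate disappears according to a
chosen rate law (optionally under competitive inhibition), sampled at
discrete times in replicate with additive Gaussian measurement noise whose
SD is a fixed fraction of the starting concentration (mimicking HPLC
quantitation noise near a fixed limit of quantification). Inactivated
(no-cofactor) control incubations hold a constant concentration.

Depletion curves are integrated with a fixed-step RK4 scheme independent of
the solver paths used by the fitters, so generator → fitter round-trip tests
are not self-confirming.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inhibition import InhibitionPlacement, inhibited_rate_eval
from .kinetics import (
    DEFAULT_PROTEIN_MG_PER_ML,
    DEFAULT_VOLUME_ML,
    DepletionTimeCourse,
    KineticModelSpec,
    RateEstimate,
    rate_model_eval,
)

__all__ = ["AssayDesign", "generate_depletion_courses", "generate_rate_table"]


@dataclass(frozen=True)
class AssayDesign:
    """Layout of a synthetic depletion assay.

    Defaults mirror a BaP-like assay: substrate 0.05–2.5 µM, 0–30 min
    incubations, triplicate measurements, 2.0 mg/mL microsomal protein in
    0.5 mL. For a DBC-like assay use S0 0.025–1 µM over 0–60 min.
    """

    substrate_id: str = "BaP"
    s0_list: tuple[float, ...] = tuple(np.geomspace(0.05, 2.5, 12).round(4))
    inhibitor_id: str | None = None
    i_list: tuple[float, ...] = ()
    time_points: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0, 30.0)
    replicates: int = 3
    noise_cv: float = 0.05
    protein_conc: float = DEFAULT_PROTEIN_MG_PER_ML
    volume: float = DEFAULT_VOLUME_ML
    include_controls: bool = False

    def __post_init__(self):
        if any(s <= 0 for s in self.s0_list):
            raise ValueError("substrate concentrations must be positive")
        if any(i < 0 for i in self.i_list):
            raise ValueError("inhibitor concentrations must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be ≥ 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


def _integrate_depletion(
    s0: float,
    inhibitor_conc: float,
    model: KineticModelSpec,
    placement: InhibitionPlacement | None,
    ki: float | None,
    protein_conc: float,
    times: np.ndarray,
    n_steps: int = 3000,
) -> np.ndarray:
    """Fixed-step RK4 integration of dS/dt = −v(S)·protein_conc (µM/min)."""

    if placement is not None and ki is not None and inhibitor_conc > 0:
        def v(s):
            return inhibited_rate_eval(model, placement, max(s, 0.0), inhibitor_conc, ki)
    else:
        def v(s):
            return rate_model_eval(model, max(s, 0.0))

    def dsdt(s):
        return -v(s) * protein_conc  # nmol/min/mg × mg/mL = µM/min

    t_end = float(times.max())
    if t_end == 0:
        return np.full_like(times, s0)
    dt = t_end / n_steps
    grid_t = np.linspace(0.0, t_end, n_steps + 1)
    grid_s = np.empty(n_steps + 1)
    s = s0
    grid_s[0] = s
    for n in range(n_steps):
        k1 = dsdt(s)
        k2 = dsdt(s + 0.5 * dt * k1)
        k3 = dsdt(s + 0.5 * dt * k2)
        k4 = dsdt(s + dt * k3)
        s = max(s + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
        grid_s[n + 1] = s
    return np.interp(times, grid_t, grid_s)


def generate_depletion_courses(
    design: AssayDesign,
    true_model: KineticModelSpec,
    placement: InhibitionPlacement | None = None,
    ki: float | None = None,
    seed: int | None = None,
) -> list[DepletionTimeCourse]:
    """Generate one depletion course per (S0, inhibitor-level) combination.

    Noise is additive Gaussian with SD = noise_cv × S0 per measurement,
    truncated at zero by clipping; replicates are independent. Control
    courses (inactivated microsomes) hold the nominal concentration plus the
    same noise. Fully deterministic given ``seed``.
    """
    if (placement is None) != (ki is None):
        raise ValueError("placement and ki must be given together")
    rng = np.random.default_rng(seed)
    times = np.asarray(design.time_points, dtype=float)
    i_levels = design.i_list if design.i_list else (0.0,)
    courses = []
    for s0 in design.s0_list:
        for i_conc in i_levels:
            clean = _integrate_depletion(
                s0, i_conc, true_model, placement, ki, design.protein_conc, times
            )
            obs = []
            for rep in range(design.replicates):
                noise = rng.normal(0.0, design.noise_cv * s0, size=times.size)
                vals = np.maximum(clean + noise, 0.0)
                obs.extend(
                    (float(t), rep, float(v)) for t, v in zip(times, vals)
                )
            courses.append(
                DepletionTimeCourse(
                    substrate_id=design.substrate_id,
                    nominal_S0=float(s0),
                    observations=obs,
                    inhibitor_id=design.inhibitor_id if i_conc > 0 else None,
                    inhibitor_conc=float(i_conc),
                    protein_conc=design.protein_conc,
                    volume=design.volume,
                    is_control=False,
                )
            )
            if design.include_controls:
                obs_c = []
                for rep in range(design.replicates):
                    noise = rng.normal(0.0, design.noise_cv * s0, size=times.size)
                    vals = np.maximum(s0 + noise, 0.0)
                    obs_c.extend((float(t), rep, float(v)) for t, v in zip(times, vals))
                courses.append(
                    DepletionTimeCourse(
                        substrate_id=design.substrate_id,
                        nominal_S0=float(s0),
                        observations=obs_c,
                        inhibitor_id=design.inhibitor_id if i_conc > 0 else None,
                        inhibitor_conc=float(i_conc),
                        protein_conc=design.protein_conc,
                        volume=design.volume,
                        is_control=True,
                    )
                )
    return courses


def generate_rate_table(
    design: AssayDesign,
    true_model: KineticModelSpec,
    noise_cv: float | None = None,
    seed: int | None = None,
    placement: InhibitionPlacement | None = None,
    ki: float | None = None,
    substrate_conc: float | None = None,
) -> list[RateEstimate]:
    """Generate rate-level observations directly (shortcut past depletion fits).

    Baseline mode: one rate per (S0, replicate), v(S0) plus Gaussian noise of
    SD = noise_cv × v(S0), clipped at 0. Inhibition mode (placement+ki+
    substrate_conc given): rates over ``design.i_list`` at the fixed
    substrate concentration.
    """
    cv = design.noise_cv if noise_cv is None else noise_cv
    rng = np.random.default_rng(seed)
    out = []
    if placement is not None:
        if ki is None or substrate_conc is None:
            raise ValueError("inhibition mode needs placement, ki and substrate_conc")
        for i_conc in design.i_list:
            mu = inhibited_rate_eval(true_model, placement, substrate_conc, i_conc, ki)
            for _ in range(design.replicates):
                val = max(mu + rng.normal(0.0, cv * mu), 0.0) if cv > 0 else mu
                out.append(
                    RateEstimate(
                        S=float(substrate_conc),
                        I=float(i_conc),
                        rate=float(val),
                        ci_low=float(val),
                        ci_high=float(val),
                        n_boot=0,
                        decay_k=0.0,
                        fitted_S0=float(substrate_conc),
                    )
                )
        return out
    for s0 in design.s0_list:
        mu = rate_model_eval(true_model, s0)
        for _ in range(design.replicates):
            val = max(mu + rng.normal(0.0, cv * mu), 0.0) if cv > 0 else mu
            out.append(
                RateEstimate(
                    S=float(s0),
                    I=0.0,
                    rate=float(val),
                    ci_low=float(val),
                    ci_high=float(val),
                    n_boot=0,
                    decay_k=0.0,
                    fitted_S0=float(s0),
                )
            )
    return out
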