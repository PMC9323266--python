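"""Two-compound PBPK interaction model with mutual competitive inhibition.

A flow-limited, venous-equilibrium compartment model (gut lumen, liver, fat,
richly perfused, slowly perfused, blood) for two co-administered compounds.
Hepatic metabolism of each parent follows the Michaelis–Menten-clearance law
with the other compound acting as a competitive inhibitor of the
high-affinity phase:

    Rate_s = Vmax_s · Cvl_s / (Km1_s · (1 + Cvl_i/Ki_i) + Cvl_s) + Clint_s · Cvl_s

where Cvl is the venous-equilibrated liver concentration C_liver/P_liver.
Microsomal parameters are scaled to the whole liver (IVIVE) using
30 mg microsomal protein per g of liver tissue. Metabolized mass accumulates
in a terminal sink; metabolism is the only elimination route.

The interaction metric is the per-compound ratio of blood-concentration AUC
with competitive inhibition enabled to the AUC with inhibition disabled
(Ki → ∞); a ratio of 1 means the co-exposure does not alter internal dose.

Internal units: amounts nmol, volumes L, time h, blood concentration nM.
µM ≡ nmol/mL makes the in vitro units compose cleanly: Clint in mL/min
applied to a concentration in µM yields nmol/min.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "TISSUES",
    "PhysiologyParams",
    "CompoundParams",
    "PBPKScenario",
    "CompoundResult",
    "PBPKResult",
    "IviveScaled",
    "RatioResult",
    "GridResult",
    "load_config",
    "default_physiology",
    "default_compounds",
    "ivive_scale",
    "derivatives",
    "simulate",
    "auc_ratio",
    "dose_grid",
    "dose_ng_to_nmol",
    "dose_nmol_to_ng",
]

TISSUES = ("liver", "fat", "richly_perfused", "slowly_perfused")

KI_DISABLED_UM = 1e99  # inhibition "off" ⇒ an unattainably high Ki


class PBPKError(Exception):
    pass


@dataclass(frozen=True)
class PhysiologyParams:
    """Reference-human physiology for the flow-limited compartment model."""

    body_weight: float = 73.0  # kg
    cardiac_output: float = 5.2  # L/min
    volume_fractions: dict = field(
        default_factory=lambda: {
            "liver": 0.026,
            "fat": 0.21,
            "richly_perfused": 0.05,
            "slowly_perfused": 0.545,
            "blood": 0.079,
        }
    )
    flow_fractions: dict = field(
        default_factory=lambda: {
            "liver": 0.25,
            "fat": 0.05,
            "richly_perfused": 0.45,
            "slowly_perfused": 0.25,
        }
    )
    microsomal_protein_per_g_liver: float = 30.0  # mg/g
    liver_density: float = 1.05  # g/mL

    def __post_init__(self):
        if "liver" not in self.volume_fractions or "liver" not in self.flow_fractions:
            raise PBPKError("physiology must include a liver compartment")
        flows = sum(self.flow_fractions[t] for t in TISSUES)
        if abs(flows - 1.0) > 1e-9:
            raise PBPKError(f"flow fractions must sum to 1, got {flows}")
        vols = sum(self.volume_fractions.values())
        if vols > 1.0 + 1e-9:
            raise PBPKError(f"volume fractions sum to {vols} > 1")
        if any(v <= 0 for v in self.volume_fractions.values()) or any(
            v <= 0 for v in self.flow_fractions.values()
        ):
            raise PBPKError("fractions must be positive")
        if self.body_weight <= 0 or self.cardiac_output <= 0 or self.liver_density <= 0:
            raise PBPKError("body_weight, cardiac_output, liver_density must be positive")

    @property
    def liver_mass_g(self) -> float:
        return self.body_weight * self.volume_fractions["liver"] * 1000.0

    def volume_L(self, tissue: str) -> float:
        """Compartment volume in L (tissue density 1 g/mL except the liver)."""
        frac = self.volume_fractions[tissue]
        if tissue == "liver":
            return self.liver_mass_g / self.liver_density / 1000.0
        return self.body_weight * frac  # kg ≈ L at unit density


@dataclass(frozen=True)
class CompoundParams:
    """Compound-specific parameters: absorption, partitioning, metabolism."""

    name: str
    molecular_weight: float  # g/mol
    oral_absorption_k: float  # 1/h
    partition_coefficients: dict  # tissue:blood, per TISSUES entry
    vmax1_invitro: float  # nmol/min/mg microsomal protein
    km1: float  # µM
    clint2_invitro: float  # mL/min/mg
    ki_as_inhibitor: float  # µM, against the partner compound's phase-1 metabolism

    def __post_init__(self):
        for t in TISSUES:
            if self.partition_coefficients.get(t, 0) <= 0:
                raise PBPKError(f"{self.name}: partition coefficient for {t} must be > 0")
        for attr in (
            "molecular_weight",
            "oral_absorption_k",
            "vmax1_invitro",
            "km1",
            "clint2_invitro",
            "ki_as_inhibitor",
        ):
            if getattr(self, attr) <= 0:
                raise PBPKError(f"{self.name}: {attr} must be positive")


@dataclass(frozen=True)
class PBPKScenario:
    """A two-compound oral co-exposure and solver settings."""

    doses_ng: tuple[float, float]  # oral dose of (compound A, compound B), ng
    interaction_enabled: bool = True
    rtol: float = 1e-8
    atol: float = 1e-12  # nmol
    initial_horizon_h: float = 240.0
    max_horizon_h: float = 1e6
    termination_fraction: float = 1e-6  # stop once blood conc < frac × running Cmax
    samples_per_chunk: int = 201

    def __post_init__(self):
        if any(d < 0 for d in self.doses_ng):
            raise PBPKError("doses must be non-negative")


@dataclass(frozen=True)
class IviveScaled:
    """Whole-liver metabolic capacity scaled from microsomal measurements."""

    vmax_nmol_min: float
    clint_ml_min: float
    liver_mass_g: float
    protein_mg: float


def ivive_scale(compound: CompoundParams, physiology: PhysiologyParams) -> IviveScaled:
    """Scale microsomal Vmax and Clint to the whole liver.

    Total microsomal protein = (mg protein / g liver) × liver mass (g);
    both terms scale linearly with it.
    """
    mass = physiology.liver_mass_g
    protein = physiology.microsomal_protein_per_g_liver * mass
    return IviveScaled(
        vmax_nmol_min=compound.vmax1_invitro * protein,
        clint_ml_min=compound.clint2_invitro * protein,
        liver_mass_g=mass,
        protein_mg=protein,
    )


def dose_ng_to_nmol(dose_ng: float, molecular_weight: float) -> float:
    """Oral dose ng → nmol (MW in g/mol is numerically ng/nmol)."""
    if molecular_weight <= 0:
        raise PBPKError("molecular weight must be positive")
    return dose_ng / molecular_weight


def dose_nmol_to_ng(dose_nmol: float, molecular_weight: float) -> float:
    if molecular_weight <= 0:
        raise PBPKError("molecular weight must be positive")
    return dose_nmol * molecular_weight


# ---------------------------------------------------------------------------
# model assembly

# per-compound state layout
_GUT, _LIVER, _FAT, _RICH, _SLOW, _BLOOD, _MET, _AUC = range(8)
N_STATE_PER_COMPOUND = 8


class _Prepared:
    """Precomputed arrays for the ODE right-hand side (index 0 = compound A)."""

    def __init__(
        self,
        physiology: PhysiologyParams,
        compounds: tuple[CompoundParams, CompoundParams],
        interaction_enabled: bool,
    ):
        self.v_blood = physiology.volume_L("blood")
        self.v_tis = np.array([physiology.volume_L(t) for t in TISSUES])
        q_total = physiology.cardiac_output * 60.0  # L/h
        self.q_tis = np.array([physiology.flow_fractions[t] * q_total for t in TISSUES])
        self.q_total = float(self.q_tis.sum())
        self.ka = np.array([c.oral_absorption_k for c in compounds])
        self.part = np.array(
            [[c.partition_coefficients[t] for t in TISSUES] for c in compounds]
        )  # shape (2, 4)
        scaled = [ivive_scale(c, physiology) for c in compounds]
        self.vmax_h = np.array([s.vmax_nmol_min * 60.0 for s in scaled])  # nmol/h
        self.clint_Lh = np.array([s.clint_ml_min * 60.0 / 1000.0 for s in scaled])  # L/h
        self.km_uM = np.array([c.km1 for c in compounds])
        if interaction_enabled:
            self.ki_uM = np.array([c.ki_as_inhibitor for c in compounds])
        else:
            self.ki_uM = np.array([KI_DISABLED_UM, KI_DISABLED_UM])

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        y2 = y.reshape(2, N_STATE_PER_COMPOUND)
        amounts = y2[:, _LIVER : _SLOW + 1]  # (2, 4)
        c_bl = y2[:, _BLOOD] / self.v_blood  # nM
        c_vt = amounts / (self.v_tis * self.part)  # venous-equilibrated, nM

        cvl_uM = c_vt[:, 0] / 1000.0  # liver venous conc, µM
        inhib = 1.0 + cvl_uM[::-1] / self.ki_uM[::-1]  # partner inhibits
        rate = (
            self.vmax_h * cvl_uM / (self.km_uM * inhib + cvl_uM)
            + self.clint_Lh * c_vt[:, 0]
        )  # nmol/h

        dy = np.zeros_like(y2)
        dy[:, _LIVER : _SLOW + 1] = self.q_tis * (c_bl[:, None] - c_vt)
        absorbed = self.ka * y2[:, _GUT]
        dy[:, _GUT] = -absorbed
        dy[:, _LIVER] += absorbed - rate
        dy[:, _BLOOD] = (c_vt * self.q_tis).sum(axis=1) - self.q_total * c_bl
        dy[:, _MET] = rate
        dy[:, _AUC] = c_bl
        return dy.ravel()


def derivatives(
    state,
    t: float,
    scenario: PBPKScenario,
    physiology: PhysiologyParams,
    compounds: tuple[CompoundParams, CompoundParams],
) -> np.ndarray:
    """Time-derivatives of the full state vector (for inspection and testing)."""
    state = np.asarray(state, dtype=float)
    if state.size != 2 * N_STATE_PER_COMPOUND:
        raise PBPKError(f"state must have {2 * N_STATE_PER_COMPOUND} entries")
    prep = _Prepared(physiology, compounds, scenario.interaction_enabled)
    return prep.rhs(t, state)


@dataclass
class CompoundResult:
    name: str
    dose_ng: float
    dose_nmol: float
    auc_nM_h: float
    cmax_nM: float
    tmax_h: float
    metabolized_nmol: float
    unabsorbed_nmol: float
    mass_balance_residual: float  # |dose − accounted| / dose

    def as_dict(self) -> dict:
        return {k: (v if isinstance(v, str) else float(v)) for k, v in self.__dict__.items()}


@dataclass
class PBPKResult:
    times_h: np.ndarray
    blood_nM: np.ndarray  # shape (2, n_times)
    compounds: tuple[CompoundResult, CompoundResult]
    terminated: bool  # termination criterion met before the horizon cap

    def compound(self, name: str) -> CompoundResult:
        for c in self.compounds:
            if c.name == name:
                return c
        raise KeyError(name)


def simulate(
    scenario: PBPKScenario,
    physiology: PhysiologyParams,
    compounds: tuple[CompoundParams, CompoundParams],
) -> PBPKResult:
    """Integrate the two-compound model from oral dosing to washout.

    A stiff solver (LSODA) runs over doubling horizon chunks until the blood
    concentration of every dosed compound falls below
    ``termination_fraction`` of its running peak, or the horizon cap is hit.
    AUC comes from an integrated auxiliary state, so it is independent of the
    output sampling grid; Cmax/Tmax are read off the sampled series.
    """
    doses_nmol = np.array(
        [dose_ng_to_nmol(d, c.molecular_weight) for d, c in zip(scenario.doses_ng, compounds)]
    )
    prep = _Prepared(physiology, compounds, scenario.interaction_enabled)

    y0 = np.zeros(2 * N_STATE_PER_COMPOUND)
    y0[_GUT] = doses_nmol[0]
    y0[N_STATE_PER_COMPOUND + _GUT] = doses_nmol[1]

    times = [0.0]
    blood = [np.zeros(2)]
    if doses_nmol.sum() == 0:
        y_end = y0
        terminated = True
    else:
        t0, t1 = 0.0, scenario.initial_horizon_h
        y = y0
        cmax_run = np.zeros(2)
        terminated = False
        while True:
            t_eval = np.linspace(t0, t1, scenario.samples_per_chunk)[1:]
            sol = solve_ivp(
                prep.rhs,
                (t0, t1),
                y,
                method="LSODA",
                t_eval=t_eval,
                rtol=scenario.rtol,
                atol=scenario.atol,
            )
            if not sol.success:
                raise PBPKError(f"ODE solver failed on [{t0}, {t1}] h: {sol.message}")
            cb = sol.y.reshape(2, N_STATE_PER_COMPOUND, -1)[:, _BLOOD, :] / prep.v_blood
            times.extend(sol.t.tolist())
            blood.extend(cb.T)
            y = sol.y[:, -1]
            cmax_run = np.maximum(cmax_run, cb.max(axis=1))
            c_now = y.reshape(2, -1)[:, _BLOOD] / prep.v_blood
            dosed = doses_nmol > 0
            if np.all(c_now[dosed] <= scenario.termination_fraction * cmax_run[dosed]):
                terminated = True
                break
            if t1 >= scenario.max_horizon_h:
                break
            t0, t1 = t1, min(t1 * 2.0, scenario.max_horizon_h)
        y_end = y

    times_arr = np.asarray(times)
    blood_arr = np.asarray(blood).T  # (2, n)
    results = []
    for i, (c, dose_nmol) in enumerate(zip(compounds, doses_nmol)):
        yc = y_end.reshape(2, N_STATE_PER_COMPOUND)[i]
        accounted = yc[_GUT : _MET + 1].sum()  # gut + tissues + blood + metabolized
        residual = abs(dose_nmol - accounted) / dose_nmol if dose_nmol > 0 else 0.0
        j = int(np.argmax(blood_arr[i]))
        results.append(
            CompoundResult(
                name=c.name,
                dose_ng=scenario.doses_ng[i],
                dose_nmol=float(dose_nmol),
                auc_nM_h=float(yc[_AUC]),
                cmax_nM=float(blood_arr[i, j]),
                tmax_h=float(times_arr[j]),
                metabolized_nmol=float(yc[_MET]),
                unabsorbed_nmol=float(yc[_GUT]),
                mass_balance_residual=float(residual),
            )
        )
    return PBPKResult(
        times_h=times_arr,
        blood_nM=blood_arr,
        compounds=(results[0], results[1]),
        terminated=terminated,
    )


@dataclass
class RatioResult:
    """Per-compound AUC ratios (interaction on / interaction off)."""

    ratios: dict[str, float]
    zero_dose_flags: dict[str, bool]
    with_interaction: PBPKResult
    without_interaction: PBPKResult


def auc_ratio(
    doses_ng: tuple[float, float],
    physiology: PhysiologyParams,
    compounds: tuple[CompoundParams, CompoundParams],
    scenario_kwargs: dict | None = None,
) -> RatioResult:
    """AUC ratio per compound: competitive-metabolism scenario over no-interaction.

    A zero-dose compound has 0/0 AUC; its ratio is reported as 1 by
    convention and flagged.
    """
    kw = dict(scenario_kwargs or {})
    kw.pop("interaction_enabled", None)
    res_on = simulate(
        PBPKScenario(doses_ng=doses_ng, interaction_enabled=True, **kw), physiology, compounds
    )
    res_off = simulate(
        PBPKScenario(doses_ng=doses_ng, interaction_enabled=False, **kw), physiology, compounds
    )
    ratios, flags = {}, {}
    for c_on, c_off in zip(res_on.compounds, res_off.compounds):
        if c_off.auc_nM_h == 0.0:
            ratios[c_on.name] = 1.0
            flags[c_on.name] = True
        else:
            ratios[c_on.name] = c_on.auc_nM_h / c_off.auc_nM_h
            flags[c_on.name] = False
    return RatioResult(ratios, flags, res_on, res_off)


GRID_DOSES_NG = 10.0 ** np.arange(-1, 15)  # 0.1 ng … 1e14 ng (= 100 kg), 16 doses


@dataclass
class GridResult:
    """AUC-ratio matrices over the oral co-exposure dose grid.

    ``ratio[name][i, j]`` is the AUC ratio of compound ``name`` when
    compound A receives dose ``doses_ng[i]`` and compound B ``doses_ng[j]``.
    """

    doses_ng: np.ndarray
    ratio: dict[str, np.ndarray]
    max_mass_balance_residual: float

    def to_frames(self):
        import pandas as pd

        labels = [f"{d:g}" for d in self.doses_ng]
        return {
            name: pd.DataFrame(mat, index=labels, columns=labels)
            for name, mat in self.ratio.items()
        }


def dose_grid(
    physiology: PhysiologyParams,
    compounds: tuple[CompoundParams, CompoundParams],
    doses_ng: np.ndarray | None = None,
    scenario_kwargs: dict | None = None,
) -> GridResult:
    """Run every dose combination and collect per-compound AUC-ratio matrices.

    The default grid is 16 log-spaced doses per compound (256 combinations).
    The worst mass-balance residual across all simulations is recorded.
    """
    doses = GRID_DOSES_NG if doses_ng is None else np.asarray(doses_ng, dtype=float)
    names = [c.name for c in compounds]
    mats = {name: np.empty((doses.size, doses.size)) for name in names}
    worst = 0.0
    for i, da in enumerate(doses):
        for j, db in enumerate(doses):
            rr = auc_ratio((float(da), float(db)), physiology, compounds, scenario_kwargs)
            for res in (rr.with_interaction, rr.without_interaction):
                worst = max(worst, max(c.mass_balance_residual for c in res.compounds))
            for name in names:
                mats[name][i, j] = rr.ratios[name]
    return GridResult(doses_ng=doses, ratio=mats, max_mass_balance_residual=worst)


# ---------------------------------------------------------------------------
# configuration


def _physiology_from_dict(d: dict) -> PhysiologyParams:
    return PhysiologyParams(
        body_weight=d["body_weight_kg"],
        cardiac_output=d["cardiac_output_L_min"],
        volume_fractions=dict(d["volume_fractions"]),
        flow_fractions=dict(d["flow_fractions"]),
        microsomal_protein_per_g_liver=d["microsomal_protein_mg_per_g_liver"],
        liver_density=d["liver_density_g_per_ml"],
    )


def _compound_from_dict(d: dict) -> CompoundParams:
    return CompoundParams(
        name=d["name"],
        molecular_weight=d["molecular_weight"],
        oral_absorption_k=d["oral_absorption_k_per_h"],
        partition_coefficients=dict(d["partition_coefficients"]),
        vmax1_invitro=d["vmax1_invitro_nmol_min_mg"],
        km1=d["km1_uM"],
        clint2_invitro=d["clint2_invitro_ml_min_mg"],
        ki_as_inhibitor=d["ki_as_inhibitor_uM"],
    )


def load_config(path: str | None = None) -> tuple[PhysiologyParams, tuple[CompoundParams, CompoundParams]]:
    """Load a PBPK parameter file (YAML); ``None`` loads the shipped default fixture."""
    if path is None:
        text = (
            importlib.resources.files("pahmix") / "data" / "pbpk_default.yaml"
        ).read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    phys = _physiology_from_dict(cfg["physiology"])
    comps = tuple(_compound_from_dict(c) for c in cfg["compounds"])
    if len(comps) != 2:
        raise PBPKError("config must define exactly two compounds")
    return phys, comps


def default_physiology() -> PhysiologyParams:
    return load_config()[0]


def default_compounds() -> tuple[CompoundParams, CompoundParams]:
    return load_config()[1]
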