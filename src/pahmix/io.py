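"""CSV/JSON interchange for assay data and fit reports.

Depletion CSV schema (one row per measurement): substrate, inhibitor,
inhibitor_conc_uM, nominal_S0_uM, time_min, replicate, conc_uM, is_control,
protein_mg_per_ml, volume_ml. UTF-8, header required, '.' decimal.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .kinetics import DepletionTimeCourse, RateEstimate

DEPLETION_COLUMNS = [
    "substrate",
    "inhibitor",
    "inhibitor_conc_uM",
    "nominal_S0_uM",
    "time_min",
    "replicate",
    "conc_uM",
    "is_control",
    "protein_mg_per_ml",
    "volume_ml",
]

RATE_COLUMNS = [
    "S_uM",
    "I_uM",
    "rate_nmol_min_mg",
    "ci_low",
    "ci_high",
    "k_per_min",
    "S0_uM",
]


def courses_to_frame(courses: list[DepletionTimeCourse]) -> pd.DataFrame:
    rows = []
    for c in courses:
        for t, rep, conc in c.observations:
            rows.append(
                {
                    "substrate": c.substrate_id,
                    "inhibitor": c.inhibitor_id or "",
                    "inhibitor_conc_uM": c.inhibitor_conc,
                    "nominal_S0_uM": c.nominal_S0,
                    "time_min": t,
                    "replicate": rep,
                    "conc_uM": conc,
                    "is_control": c.is_control,
                    "protein_mg_per_ml": c.protein_conc,
                    "volume_ml": c.volume,
                }
            )
    return pd.DataFrame(rows, columns=DEPLETION_COLUMNS)


def frame_to_courses(df: pd.DataFrame) -> list[DepletionTimeCourse]:
    missing = set(DEPLETION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"depletion CSV missing columns: {sorted(missing)}")
    keys = [
        "substrate",
        "inhibitor",
        "inhibitor_conc_uM",
        "nominal_S0_uM",
        "is_control",
        "protein_mg_per_ml",
        "volume_ml",
    ]
    courses = []
    for key, grp in df.groupby(keys, sort=True, dropna=False):
        (sub, inh, iconc, s0, ctrl, prot, vol) = key
        obs = [
            (float(r.time_min), int(r.replicate), float(r.conc_uM))
            for r in grp.itertuples()
        ]
        courses.append(
            DepletionTimeCourse(
                substrate_id=str(sub),
                nominal_S0=float(s0),
                observations=obs,
                inhibitor_id=str(inh) if inh not in ("", None) and not pd.isna(inh) else None,
                inhibitor_conc=float(iconc),
                protein_conc=float(prot),
                volume=float(vol),
                is_control=bool(ctrl),
            )
        )
    return courses


def write_depletion_csv(courses: list[DepletionTimeCourse], path: str | Path) -> None:
    courses_to_frame(courses).to_csv(path, index=False)


def read_depletion_csv(path: str | Path) -> list[DepletionTimeCourse]:
    return frame_to_courses(pd.read_csv(path))


def rates_to_frame(rates: list[RateEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "S_uM": r.S,
                "I_uM": r.I,
                "rate_nmol_min_mg": r.rate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "k_per_min": r.decay_k,
                "S0_uM": r.fitted_S0,
            }
            for r in rates
        ],
        columns=RATE_COLUMNS,
    )


def write_rates_csv(rates: list[RateEstimate], path: str | Path) -> None:
    rates_to_frame(rates).to_csv(path, index=False)


def read_rates_csv(path: str | Path) -> list[RateEstimate]:
    df = pd.read_csv(path)
    return [
        RateEstimate(
            S=float(r.S_uM),
            I=float(r.I_uM),
            rate=float(r.rate_nmol_min_mg),
            ci_low=float(r.ci_low),
            ci_high=float(r.ci_high),
            n_boot=0,
            decay_k=float(r.k_per_min),
            fitted_S0=float(r.S0_uM),
        )
        for r in df.itertuples()
    ]


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
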