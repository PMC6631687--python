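"""CSV dialects read and written by the pipeline.

All tables are plain CSV with a header row; readers validate the expected
columns and return the package's domain objects.

Dialects
--------
depletion:        compound_id, replicate, time_min, remaining_pct
plasma samples:   animal_id, time_min, activity_bq, plasma_mass_g
study metadata:   animal_id, injected_activity_bq, injected_amount_nmol,
                  body_weight_kg
parent fractions: animal_id, time_min, fraction
ultrafiltration:  animal_id, compound_id, counts_plasma, counts_filtrate
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .binding import UltrafiltrationMeasurement
from .errors import InvalidInputError
from .invitro import DepletionTimecourse, IntrinsicClearanceResult
from .invivopk import (
    F18_HALF_LIFE_MIN,
    AnimalStudy,
    ParentFractionSeries,
    PlasmaSample,
)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise InvalidInputError(
            f"{path}: missing column(s) {sorted(missing)}; found {list(df.columns)}"
        )


def read_depletion_csv(path) -> dict[str, list[DepletionTimecourse]]:
    """Depletion time-courses keyed by compound id, one entry per replicate."""
    df = pd.read_csv(path)
    _require_columns(df, ["compound_id", "replicate", "time_min", "remaining_pct"], path)
    out: dict[str, list[DepletionTimecourse]] = {}
    for (cid, _rep), grp in df.groupby(["compound_id", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        out.setdefault(str(cid), []).append(
            DepletionTimecourse(
                compound_id=str(cid),
                times=grp["time_min"].to_numpy(float),
                remaining=grp["remaining_pct"].to_numpy(float),
            )
        )
    return out


def write_depletion_csv(courses: list[DepletionTimecourse], path) -> None:
    rows = []
    rep_counter: dict[str, int] = {}
    for tc in courses:
        rep = rep_counter.get(tc.compound_id, 0) + 1
        rep_counter[tc.compound_id] = rep
        for t, r in zip(tc.times, tc.remaining):
            rows.append(
                {"compound_id": tc.compound_id, "replicate": rep,
                 "time_min": t, "remaining_pct": r}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_pk_study_csvs(
    samples_path, metadata_path, parent_fraction_path,
    isotope_half_life: float = F18_HALF_LIFE_MIN,
) -> list[AnimalStudy]:
    """Assemble per-animal studies from the three in vivo tables."""
    samples = pd.read_csv(samples_path)
    meta = pd.read_csv(metadata_path)
    pf = pd.read_csv(parent_fraction_path)
    _require_columns(samples, ["animal_id", "time_min", "activity_bq", "plasma_mass_g"],
                     samples_path)
    _require_columns(meta, ["animal_id", "injected_activity_bq",
                            "injected_amount_nmol", "body_weight_kg"], metadata_path)
    _require_columns(pf, ["animal_id", "time_min", "fraction"], parent_fraction_path)

    studies = []
    for _, mrow in meta.iterrows():
        aid = str(mrow["animal_id"])
        srows = samples[samples["animal_id"].astype(str) == aid].sort_values("time_min")
        pfrows = pf[pf["animal_id"].astype(str) == aid].sort_values("time_min")
        if srows.empty:
            raise InvalidInputError(f"no plasma samples for animal {aid}")
        if pfrows.empty:
            raise InvalidInputError(f"no parent fractions for animal {aid}")
        studies.append(
            AnimalStudy(
                animal_id=aid,
                injected_activity=float(mrow["injected_activity_bq"]),
                injected_amount=float(mrow["injected_amount_nmol"]),
                body_weight=float(mrow["body_weight_kg"]),
                samples=[
                    PlasmaSample(time_pi=float(r["time_min"]),
                                 activity_measured=float(r["activity_bq"]),
                                 plasma_mass=float(r["plasma_mass_g"]))
                    for _, r in srows.iterrows()
                ],
                parent_fractions=ParentFractionSeries(
                    times=pfrows["time_min"].to_numpy(float),
                    fractions=pfrows["fraction"].to_numpy(float),
                ),
                isotope_half_life=isotope_half_life,
            )
        )
    return studies


def write_pk_study_csvs(
    studies: list[AnimalStudy], samples_path, metadata_path, parent_fraction_path
) -> None:
    srows, mrows, pfrows = [], [], []
    for st in studies:
        mrows.append(
            {"animal_id": st.animal_id,
             "injected_activity_bq": st.injected_activity,
             "injected_amount_nmol": st.injected_amount,
             "body_weight_kg": st.body_weight}
        )
        for s in st.samples:
            srows.append(
                {"animal_id": st.animal_id, "time_min": s.time_pi,
                 "activity_bq": s.activity_measured,
                 "plasma_mass_g": s.plasma_mass}
            )
        for t, f in zip(st.parent_fractions.times, st.parent_fractions.fractions):
            pfrows.append({"animal_id": st.animal_id, "time_min": t, "fraction": f})
    pd.DataFrame(srows).to_csv(samples_path, index=False)
    pd.DataFrame(mrows).to_csv(metadata_path, index=False)
    pd.DataFrame(pfrows).to_csv(parent_fraction_path, index=False)


def read_ultrafiltration_csv(path) -> dict[str, list[UltrafiltrationMeasurement]]:
    df = pd.read_csv(path)
    _require_columns(df, ["animal_id", "compound_id", "counts_plasma",
                          "counts_filtrate"], path)
    out: dict[str, list[UltrafiltrationMeasurement]] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["compound_id"]), []).append(
            UltrafiltrationMeasurement(
                animal_id=str(r["animal_id"]),
                counts_plasma=float(r["counts_plasma"]),
                counts_filtrate=float(r["counts_filtrate"]),
            )
        )
    return out


def write_ultrafiltration_csv(
    measurements: dict[str, list[UltrafiltrationMeasurement]], path
) -> None:
    rows = [
        {"animal_id": m.animal_id, "compound_id": cid,
         "counts_plasma": m.counts_plasma, "counts_filtrate": m.counts_filtrate}
        for cid, ms in measurements.items()
        for m in ms
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def stability_table(results: list[IntrinsicClearanceResult],
                    log_p: dict[str, float]) -> pd.DataFrame:
    """Microsomal-stability summary (log P, f_mic, t1/2 (SD), CL_int (SD))."""
    rows = []
    for r in results:
        rows.append(
            {"compound_id": r.compound_id,
             "log_p": log_p.get(r.compound_id, np.nan),
             "f_mic": round(r.f_mic, 2),
             "t_half_min": round(r.t_half_vitro, 1),
             "t_half_sd": None if r.t_half_sd is None else round(r.t_half_sd, 1),
             "cl_int_ml_min_kg": round(r.cl_int, 1),
             "cl_int_sd": None if r.cl_int_sd is None else round(r.cl_int_sd, 1)}
        )
    return pd.DataFrame(rows)
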