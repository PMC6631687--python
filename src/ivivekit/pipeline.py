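"""End-to-end orchestration: simulate or load data, run every stage, report.

The full extrapolation chain is

    depletion fits -> t_half -> f_mic -> CL_int --(f_p, Q)--> predicted CL_p
    plasma samples -> corrections -> mean curve -> triexponential -> observed CL_p
    ultrafiltration -> f_p

and the report compares predicted against observed clearance per compound
(fold errors) and overall (AFE, fold underprediction, RMSE).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .binding import summarize_free_fraction
from .errors import CrossReferenceError, InvalidInputError
from .invitro import (
    AssayContext,
    ScalingFactors,
    fit_monoexponential,
    summarize_replicates,
)
from .ivive import AccuracyReport, accuracy_report, well_stirred_clearance
from .invivopk import mean_curve_pk, study_pk
from .synth import (
    PROFILES,
    CompoundProfile,
    NoiseConfig,
    generate_depletion,
    generate_pk_study,
    generate_ultrafiltration,
)

logger = logging.getLogger(__name__)


def _checksum(path: Path) -> str:
    return hashlib.sha1(path.read_bytes()).hexdigest()[:12]


def rank_order(
    values: list[tuple[str, float]], descending: bool = True
) -> list[tuple[str, float]]:
    """Stable sort of (id, value) pairs; ties keep input order."""
    if not values:
        raise InvalidInputError("rank_order of an empty list")
    return sorted(values, key=lambda kv: -kv[1] if descending else kv[1])


def self_consistent_profile(
    profile: CompoundProfile,
    ctx: AssayContext | None = None,
    sf: ScalingFactors = ScalingFactors(),
) -> CompoundProfile:
    """Replace the in vivo clearance truth by the model's own prediction.

    With this profile the generator and the extrapolation chain share one
    truth, so a noiseless synthetic run yields fold errors of exactly 1.
    The terminal half-life is kept; V_d follows from CL_p/lam3.
    """
    from .invitro import microsomal_unbound_fraction, scale_intrinsic_clearance

    ctx = ctx or AssayContext(log_p=profile.log_p)
    f_mic = microsomal_unbound_fraction(profile.log_p, ctx.protein_conc)
    cl_int = scale_intrinsic_clearance(profile.t_half_vitro_true, f_mic, ctx, sf)
    cl_p = well_stirred_clearance(cl_int, profile.f_p_true,
                                  sf.hepatic_blood_flow_q)
    lam3 = np.log(2.0) / profile.t_half_term_true
    return dataclasses.replace(
        profile, cl_p_true=cl_p, v_d_true=cl_p / lam3
    )


@dataclass
class PipelineConfig:
    """Inputs and knobs for one end-to-end run.

    In synthetic mode all inputs are generated from ``profiles``; in
    analysis mode the CSV paths must exist. ``observed_cl_p`` short-circuits
    the in vivo stage with externally determined clearances (e.g. published
    values) — useful for pure prediction-accuracy runs.
    """

    profiles: dict[str, CompoundProfile] = field(
        default_factory=lambda: dict(PROFILES)
    )
    synthetic: bool = True
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0
    n_animals: int = 8
    n_replicates: int = 3
    n_uf_animals: int = 7
    self_consistent: bool = False
    # analysis-mode inputs
    depletion_csv: Path | None = None
    ultrafiltration_csv: Path | None = None
    pk_csvs: dict[str, tuple[Path, Path, Path]] | None = None
    observed_cl_p: dict[str, float] | None = None
    f_p_override: dict[str, float] | None = None
    # context and output
    assay: AssayContext = field(default_factory=AssayContext)
    scaling: ScalingFactors = field(default_factory=ScalingFactors)
    out_dir: Path | None = None


def _validate_analysis_inputs(config: PipelineConfig) -> None:
    for p in filter(None, [config.depletion_csv, config.ultrafiltration_csv]):
        if not Path(p).exists():
            raise InvalidInputError(f"input file does not exist: {p}")


def run_ivive(config: PipelineConfig) -> AccuracyReport:
    """Run the whole pipeline and (optionally) write the report tables.

    Returns the accuracy report; when ``config.out_dir`` is set, writes
    ``stability.csv`` (in vitro summary with predicted CL_p),
    ``pk_observed.csv`` (in vivo parameters), ``accuracy.csv`` and
    ``report.md``, logging a checksum for each artifact.
    """
    compounds = list(config.profiles)
    seed = config.seed

    # ---- stage 1: microsomal stability -----------------------------------
    if config.synthetic:
        profiles = config.profiles
        if config.self_consistent:
            profiles = {
                cid: self_consistent_profile(
                    p, AssayContext(
                        protein_conc=config.assay.protein_conc,
                        incubation_volume=config.assay.incubation_volume,
                        log_p=p.log_p),
                    config.scaling)
                for cid, p in profiles.items()
            }
        depletion = {
            cid: generate_depletion(
                p, config.noise, config.n_replicates, seed=seed + 11 + i)
            for i, (cid, p) in enumerate(profiles.items())
        }
    else:
        profiles = config.profiles
        _validate_analysis_inputs(config)
        depletion = _io.read_depletion_csv(config.depletion_csv)
        missing = set(compounds) - set(depletion)
        if missing:
            raise CrossReferenceError(missing, "depletion input")

    stability = []
    for cid in compounds:
        ctx = AssayContext(
            protein_conc=config.assay.protein_conc,
            incubation_volume=config.assay.incubation_volume,
            log_p=profiles[cid].log_p,
        )
        fits = [fit_monoexponential(tc) for tc in depletion[cid]]
        res = summarize_replicates(fits, cid, ctx, config.scaling)
        stability.append(res)
        logger.info(
            "invitro %s: t_half=%.2f min f_mic=%.3f CL_int=%.1f mL/min/kg",
            cid, res.t_half_vitro, res.f_mic, res.cl_int,
        )

    # ---- stage 2: plasma free fraction -----------------------------------
    if config.f_p_override is not None:
        f_p = dict(config.f_p_override)
    elif config.synthetic:
        f_p = {}
        for i, cid in enumerate(compounds):
            ms = generate_ultrafiltration(
                profiles[cid], config.noise, config.n_uf_animals,
                seed=seed + 211 + i)
            f_p[cid], _, _ = summarize_free_fraction(ms)
    else:
        uf = _io.read_ultrafiltration_csv(config.ultrafiltration_csv)
        missing = set(compounds) - set(uf)
        if missing:
            raise CrossReferenceError(missing, "ultrafiltration input")
        f_p = {cid: summarize_free_fraction(uf[cid])[0] for cid in compounds}
    for cid in compounds:
        logger.info("binding %s: f_p=%.4f", cid, f_p[cid])

    # ---- stage 3: prediction ---------------------------------------------
    predicted = {
        res.compound_id: well_stirred_clearance(
            res.cl_int, f_p[res.compound_id], config.scaling.hepatic_blood_flow_q
        )
        for res in stability
    }

    # ---- stage 4: observed in vivo clearance -----------------------------
    pk_rows = []
    if config.observed_cl_p is not None:
        missing = set(compounds) - set(config.observed_cl_p)
        if missing:
            raise CrossReferenceError(missing, "observed clearance input")
        observed = dict(config.observed_cl_p)
    else:
        observed = {}
        for i, cid in enumerate(compounds):
            if config.synthetic:
                studies = generate_pk_study(
                    profiles[cid], config.noise, config.n_animals,
                    seed=seed + 307 + i)
            else:
                if not config.pk_csvs or cid not in config.pk_csvs:
                    raise CrossReferenceError({cid}, "in vivo input")
                studies = _io.read_pk_study_csvs(*config.pk_csvs[cid])
            if len(studies) >= 2:
                pk, _fit = mean_curve_pk(studies, seed=seed)
            else:
                pk = study_pk(studies[0], seed=seed)
            observed[cid] = pk.cl_p
            pk_rows.append(
                {"compound_id": cid, "v_d_ml_kg": round(pk.v_d, 0),
                 "t_half_term_min": round(pk.t_half_term, 1),
                 "cl_p_ml_min_kg": round(pk.cl_p, 2)}
            )
            logger.info(
                "invivopk %s: CL_p=%.2f V_d=%.0f t_half_term=%.1f (n=%d)",
                cid, pk.cl_p, pk.v_d, pk.t_half_term, len(studies),
            )

    # ---- stage 5: accuracy ------------------------------------------------
    report = accuracy_report(
        [(cid, predicted[cid], observed[cid]) for cid in compounds]
    )

    if config.out_dir is not None:
        _write_artifacts(config, stability, f_p, predicted, pk_rows, report)
    return report


def _write_artifacts(config, stability, f_p, predicted, pk_rows, report):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stab = _io.stability_table(
        stability, {cid: p.log_p for cid, p in config.profiles.items()}
    )
    stab["f_p"] = [round(f_p[c], 4) for c in stab["compound_id"]]
    stab["cl_p_predicted_ml_min_kg"] = [
        round(predicted[c], 2) for c in stab["compound_id"]
    ]
    stab_path = out / "stability.csv"
    stab.to_csv(stab_path, index=False)

    acc = pd.DataFrame(
        [{"compound_id": cid, "cl_p_predicted": round(p, 2),
          "cl_p_observed": round(o, 2), "fold_error": round(fe, 2),
          "fold_underprediction": round(1.0 / fe, 1)}
         for cid, p, o, fe in report.per_compound]
    )
    acc_path = out / "accuracy.csv"
    acc.to_csv(acc_path, index=False)

    paths = [stab_path, acc_path]
    if pk_rows:
        pk_path = out / "pk_observed.csv"
        pd.DataFrame(pk_rows).to_csv(pk_path, index=False)
        paths.append(pk_path)

    md = out / "report.md"
    md.write_text(render_markdown(report, stab, pk_rows))
    paths.append(md)
    for p in paths:
        logger.info("wrote %s (sha1 %s)", p, _checksum(p))


def render_markdown(report: AccuracyReport, stability: pd.DataFrame | None = None,
                    pk_rows: list[dict] | None = None) -> str:
    """Human-readable accuracy report (markdown)."""
    lines = ["# IVIVE accuracy report", ""]
    if stability is not None:
        lines += ["## Microsomal stability and prediction", "",
                  stability.to_markdown(index=False), ""]
    if pk_rows:
        lines += ["## Observed pharmacokinetics", "",
                  pd.DataFrame(pk_rows).to_markdown(index=False), ""]
    lines += ["## Prediction accuracy", "",
              "| compound | predicted | observed | fold error |",
              "|---|---|---|---|"]
    for cid, p, o, fe in report.per_compound:
        lines.append(f"| {cid} | {p:.2f} | {o:.2f} | {fe:.2f} |")
    lines += ["",
              f"AFE = {report.afe:.2f}, fold underprediction = "
              f"{report.fold_underprediction:.1f}, RMSE = {report.rmse:.1f} "
              "mL/min/kg", ""]
    return "\n".join(lines)
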