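"""End-to-end pipeline: chemistry → partitioning → priming → screens → drivers."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, drivers, io, partitioning
from .chemistry import TRAITS, chemistry_to_frame
from .errors import ValidationError
from .partitioning import CONTROL_CODE

log = logging.getLogger("primesplit")

RESPONSES = (
    "SOC_mineralized",
    "litter_released_C",
    "priming_effect",
    "priming_efficiency",
)


@dataclass
class PipelineConfig:
    """Paths, seeds and knobs for one pipeline run."""

    jars: str
    chemistry: str
    abundance: str | None = None
    out_dir: str = "results"
    mc_draws: int = 2000
    seed: int = 17
    efficiency_scale: str = "milli"
    selection_strategy: str = "auto"     # exhaustive ≤12 candidates, else bidirectional
    display_threshold: float = 0.01
    bh_correction: bool = False
    include_control_uncertainty: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _strategy_for(config: PipelineConfig, n_candidates: int) -> str:
    if config.selection_strategy != "auto":
        return config.selection_strategy
    return "exhaustive" if n_candidates <= drivers.EXHAUSTIVE_LIMIT else "bidirectional"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all outputs; returns the run report.

    Stage outputs: ``partition_results.csv``, ``priming_results.csv``,
    ``treatment_summaries.csv``, ``screen.csv`` (+ taxa screen) and
    ``drivers.csv``; the JSON report embeds the config hash and seed.
    Any stage failure aborts with the stage name and offending record.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- stage: validate & load ------------------------------------------
    report = io.validate_inputs(config.jars, config.chemistry, config.abundance)
    for w in report.warnings:
        log.warning("[validate] %s", w)
    if not report.ok:
        raise ValidationError("[validate] " + "; ".join(report.errors))
    jars = io.load_jars(config.jars)
    chem = io.load_chemistry(config.chemistry)

    # -- stage: partition -------------------------------------------------
    results = partitioning.partition_jars(jars)
    for r in results:
        for flag in r.flags:
            log.warning("[partition] jar %s: %s", r.jar_id, flag)
    part_df = partitioning.results_to_frame(results)
    part_df.to_csv(out / "partition_results.csv", index=False)

    # -- stage: priming ---------------------------------------------------
    controls = [r for r in results if r.treatment_code == CONTROL_CODE]
    if not controls:
        raise ValidationError(
            "[priming] no control jars: the treatment-minus-control contrast "
            "requires a no-litter control group"
        )
    by_code: dict[str, list] = {}
    for r in results:
        by_code.setdefault(r.treatment_code, []).append(r)
    jar_by_id = {o.jar_id: o for o in jars}
    priming_rows = []
    per_jar_pe: dict[str, float] = {}
    per_jar_eff: dict[str, float] = {}
    for code, group in by_code.items():
        if code == CONTROL_CODE:
            continue
        litter_mass = jar_by_id[group[0].jar_id].litter_mass
        soil_mass = jar_by_id[group[0].jar_id].soil_mass
        pr = partitioning.priming_effect(
            group,
            controls,
            litter_mass=litter_mass,
            soil_mass=soil_mass,
            scale=config.efficiency_scale,
            include_control_uncertainty=config.include_control_uncertainty,
        )
        priming_rows.append(pr)
        for jar, pe in zip(group, pr.per_jar_pe):
            per_jar_pe[jar.jar_id] = pe
            per_jar_eff[jar.jar_id] = partitioning.priming_efficiency(
                pe, litter_mass, soil_mass, scale=config.efficiency_scale
            )
    priming_df = partitioning.priming_to_frame(priming_rows)
    priming_df.to_csv(out / "priming_results.csv", index=False)

    # -- stage: summaries -------------------------------------------------
    summaries = []
    for code, group in sorted(by_code.items()):
        for var in ("SOC_mineralized", "litter_released_C", "C_litter_remaining"):
            vals = [getattr(r, var) for r in group]
            summaries.append(partitioning.summarize_treatment(vals, code, var))
    summary_df = pd.DataFrame(
        [
            {
                "treatment_code": s.treatment_code,
                "variable": s.variable,
                "mean": s.mean,
                "se": s.se,
                "n": s.n,
            }
            for s in summaries
        ]
    )
    summary_df.to_csv(out / "treatment_summaries.csv", index=False)

    # -- stage: per-jar response table -----------------------------------
    resp = part_df.set_index("jar_id")[["SOC_mineralized", "litter_released_C"]].copy()
    resp["priming_effect"] = pd.Series(per_jar_pe)
    resp["priming_efficiency"] = pd.Series(per_jar_eff)

    chem_traits = chemistry_to_frame(chem).set_index("litter_code")[list(TRAITS[:-1])]
    treat_of = part_df.set_index("jar_id")["treatment_code"]
    pred_chem = chem_traits.reindex(treat_of.values)
    pred_chem.index = treat_of.index
    pred_chem = pred_chem.dropna(how="all")

    # -- stage: correlation screens ---------------------------------------
    screen_rows = community.spearman_screen(resp, pred_chem)
    screen_df = community.screen_to_frame(screen_rows)
    if config.bh_correction:
        log.info("[screen] applying Benjamini–Hochberg correction")
        screen_df["p_adjusted"] = community.benjamini_hochberg(screen_df["p_value"])
    screen_df.to_csv(out / "screen.csv", index=False)

    taxa_rel = None
    if config.abundance:
        ab = io.load_abundance(config.abundance)
        table = community.AbundanceTable.from_long(ab)
        taxa_rel = table.to_relative().data
        taxa_screen = community.spearman_screen(resp, taxa_rel)
        taxa_df = community.screen_to_frame(taxa_screen)
        if config.bh_correction:
            taxa_df["p_adjusted"] = community.benjamini_hochberg(taxa_df["p_value"])
        taxa_df.to_csv(out / "screen_taxa.csv", index=False)

    # -- stage: driver selection ------------------------------------------
    fitted = []
    joined = resp.join(pred_chem, how="inner").dropna()
    strategy = _strategy_for(config, pred_chem.shape[1])
    model_chem = drivers.select_model(
        joined["priming_effect"].values,
        joined[list(pred_chem.columns)],
        strategy=strategy,
        response="priming_effect~chemistry",
    )
    fitted.append(model_chem)
    model_taxa = None
    if taxa_rel is not None:
        jt = resp.join(taxa_rel, how="inner").dropna()
        strategy_t = _strategy_for(config, taxa_rel.shape[1])
        model_taxa = drivers.select_model(
            jt["priming_effect"].values,
            jt[list(taxa_rel.columns)],
            strategy=strategy_t,
            response="priming_effect~taxa",
        )
        fitted.append(model_taxa)
    drivers.models_to_frame(fitted).to_csv(out / "drivers.csv", index=False)

    # -- report ------------------------------------------------------------
    run_report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_jars": len(jars),
        "n_treatments": len(by_code) - 1,
        "priming": priming_df.to_dict(orient="records"),
        "summaries": summary_df.to_dict(orient="records"),
        "chemistry_driver_model": {
            "predictors": list(model_chem.predictors),
            "coefficients": list(model_chem.coefficients),
            "r_squared": model_chem.r_squared,
            "p_value": model_chem.p_value,
            "aicc": model_chem.aicc,
            "n": model_chem.n,
        },
        "warnings": report.warnings,
    }
    if model_taxa is not None:
        run_report["taxa_driver_model"] = {
            "predictors": list(model_taxa.predictors),
            "coefficients": list(model_taxa.coefficients),
            "r_squared": model_taxa.r_squared,
            "p_value": model_taxa.p_value,
            "aicc": model_taxa.aicc,
            "n": model_taxa.n,
        }
    with open(out / "run_report.json", "w") as fh:
        json.dump(run_report, fh, indent=2, sort_keys=True)
    return run_report
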