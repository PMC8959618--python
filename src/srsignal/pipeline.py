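"""End-to-end orchestration: simulate/load -> preprocess -> signals ->
descriptive -> risk factors -> off-label, with a reproducible run manifest.

A run directory always contains ``exclusions.csv``, ``combinations.csv``,
``signals.csv``, ``descriptive_report.json``, ``risk_factors.csv``,
``offlabel_signals.csv`` and ``run_manifest.json``. Reruns with identical
config and seed reproduce the outputs byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels
import yaml

from . import __version__
from .descriptive import (
    drug_seriousness_table,
    onset_distribution,
    outcome_table,
    pt_table,
    soc_table,
    yearly_trend,
)
from .fixtures import bundled_dictionaries
from .io import load_dictionaries, read_reports, write_reports
from .offlabel import flag_offlabel
from .preprocess import (
    Covariates,
    DrugEventCombination,
    Season,
    apply_inclusion_exclusion,
    expand_combinations,
)
from .records import APDClass, Sex
from .riskfactors import ModelFitError, risk_factor_table
from .signals import SignalConfig, compute_signals, rank_signals, signals_to_frame
from .simulate import SyntheticConfig, generate_reports, paperlike_config

_FLOAT_FORMAT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def combinations_to_frame(combos: Sequence[DrugEventCombination]) -> pd.DataFrame:
    rows = []
    for c in combos:
        cov = c.covariates
        rows.append(
            {
                "report_id": c.report_id,
                "generic_drug": c.generic_drug,
                "apd_class": c.apd_class.value,
                "pt": c.pt,
                "soc": c.soc,
                "serious": c.serious,
                "sex": cov.sex.value,
                "age": cov.age,
                "age_bin": cov.age_bin,
                "year": cov.year,
                "season": cov.season.value,
                "hospital_level": cov.hospital_level,
                "hospital_type": cov.hospital_type,
                "polypharmacy": cov.polypharmacy,
                "multiple_disease": cov.multiple_disease,
            }
        )
    columns = [
        "report_id", "generic_drug", "apd_class", "pt", "soc", "serious",
        "sex", "age", "age_bin", "year", "season", "hospital_level",
        "hospital_type", "polypharmacy", "multiple_disease",
    ]
    return pd.DataFrame(rows, columns=columns)


def frame_to_combinations(frame: pd.DataFrame) -> list[DrugEventCombination]:
    combos = []
    for row in frame.itertuples(index=False):
        age = None if pd.isna(row.age) else float(row.age)
        cov = Covariates(
            sex=Sex(row.sex),
            age=age,
            age_bin=None if pd.isna(row.age_bin) else str(row.age_bin),
            year=int(row.year),
            season=Season(row.season),
            hospital_level=int(row.hospital_level),
            hospital_type=str(row.hospital_type),
            polypharmacy=bool(row.polypharmacy),
            multiple_disease=bool(row.multiple_disease),
            apd_class=APDClass(row.apd_class),
        )
        combos.append(
            DrugEventCombination(
                report_id=str(row.report_id),
                generic_drug=str(row.generic_drug),
                apd_class=APDClass(row.apd_class),
                pt=str(row.pt),
                soc=str(row.soc),
                serious=bool(row.serious),
                covariates=cov,
            )
        )
    return combos


def _descriptive_report(reports, combos, drug_dict, year_window) -> dict:
    trend = yearly_trend(reports, year_window)
    onset = onset_distribution(reports, drug_dict)
    seriousness = drug_seriousness_table(reports, drug_dict)
    return {
        "yearly_trend": [dataclasses.asdict(r) for r in trend],
        "onset_distribution": {
            "table": onset.table.as_dict(),
            "n_missing": onset.n_missing,
            "n_negative": onset.n_negative,
        },
        "drug_seriousness": [dataclasses.asdict(r) for r in seriousness],
        "soc_table": soc_table(combos).as_dict(),
        "pt_table_total": pt_table(combos).as_dict(),
        "pt_table_typical": pt_table(combos, APDClass.TYPICAL).as_dict(),
        "pt_table_atypical": pt_table(combos, APDClass.ATYPICAL).as_dict(),
        "outcome_table": outcome_table(reports).as_dict(),
    }


def _signal_config(options: dict) -> SignalConfig:
    return SignalConfig(
        z=float(options.get("z", 1.96)),
        min_a=int(options.get("min_a", 3)),
        ror_li_threshold=float(options.get("ror_li_threshold", 1.0)),
        prr_li_threshold=float(options.get("prr_li_threshold", 1.0)),
        mhra_prr_threshold=float(options.get("mhra_prr_threshold", 2.0)),
        mhra_chi2_threshold=float(options.get("mhra_chi2_threshold", 4.0)),
        ic_li_threshold=float(options.get("ic_li_threshold", 0.0)),
        ic_multiplier=float(options.get("ic_multiplier", 2.0)),
        chi2_variant=str(options.get("chi2_variant", "yates")),
        ic_variant=str(options.get("ic_variant", "n4")),
    )


def _config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canonical).hexdigest()


def load_pipeline_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise PipelineError(f"config: expected a mapping at top level in {path}")
    return config


def run_pipeline(config: dict, outdir: str | Path, seed: Optional[int] = None) -> dict:
    """Execute all stages and write the artifact set to ``outdir``.

    ``config`` keys: ``simulate`` (either ``paperlike: true`` with optional
    ``n_reports``, or a path to a generator YAML under ``config``) or
    ``inputs`` (paths to reports/drugs/reactions CSVs); optional
    ``dictionaries`` (drug/term/label paths; bundled ones by default);
    ``year_window``; ``signal`` method options; ``seed``.
    Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    manifest: dict = {
        "config_sha256": _config_hash(config),
        "seed": seed,
        "versions": {
            "srsignal": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "counts": {},
        "complete": False,
    }

    dict_paths = config.get("dictionaries") or {}
    try:
        if dict_paths.get("drug") or dict_paths.get("term") or dict_paths.get("label"):
            drug_dict, term_dict, labels = load_dictionaries(
                dict_paths["drug"], dict_paths["term"], dict_paths["label"]
            )
        else:
            drug_dict, term_dict, labels = bundled_dictionaries()
    except Exception as exc:
        raise PipelineError(f"dictionaries: {exc}") from exc

    # --- acquire reports -------------------------------------------------
    try:
        if "simulate" in config:
            sim = config["simulate"] or {}
            if sim.get("config"):
                syn_config = SyntheticConfig.from_yaml(sim["config"])
            else:
                syn_config = paperlike_config(int(sim.get("n_reports", 50_000)))
            reports, truth = generate_reports(syn_config, seed=seed)
            write_reports(
                reports,
                outdir / "reports.csv",
                outdir / "drugs.csv",
                outdir / "reactions.csv",
            )
            truth.to_json(outdir / "ground_truth.json")
            errors = []
        elif "inputs" in config:
            paths = config["inputs"]
            result = read_reports(paths["reports"], paths["drugs"], paths["reactions"])
            reports, errors = result.reports, result.errors
        else:
            raise ValueError("config needs either a 'simulate' or an 'inputs' section")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"acquire: {exc}") from exc
    manifest["counts"]["parsed_reports"] = len(reports)
    manifest["counts"]["read_errors"] = len(errors)

    year_window = tuple(config.get("year_window", (2016, 2020)))

    # --- preprocess ------------------------------------------------------
    try:
        included, exclusions = apply_inclusion_exclusion(
            reports, drug_dict, year_window=year_window
        )
        pd.DataFrame(
            [{"report_id": e.report_id, "reason": e.reason.value} for e in exclusions],
            columns=["report_id", "reason"],
        ).to_csv(outdir / "exclusions.csv", index=False)
        combos, expansion_log = expand_combinations(included, drug_dict, term_dict)
        combinations_to_frame(combos).to_csv(
            outdir / "combinations.csv", index=False, float_format=_FLOAT_FORMAT
        )
    except Exception as exc:
        raise PipelineError(f"preprocess: {exc}") from exc
    manifest["counts"]["included_reports"] = len(included)
    manifest["counts"]["excluded_reports"] = len(exclusions)
    manifest["counts"]["combinations"] = len(combos)
    manifest["counts"]["unmapped_drug_names"] = len(expansion_log.unmapped_drugs)
    manifest["counts"]["unmapped_terms"] = len(expansion_log.unmapped_terms)

    # --- signals ---------------------------------------------------------
    try:
        signal_config = _signal_config(config.get("signal") or {})
        results = compute_signals(combos, signal_config)
        flag_offlabel(results, labels)
        frame = signals_to_frame(results)
        frame.to_csv(outdir / "signals.csv", index=False, float_format=_FLOAT_FORMAT)
        ranked = rank_signals(results)
        signals_to_frame(ranked).to_csv(
            outdir / "offlabel_signals.csv", index=False, float_format=_FLOAT_FORMAT
        )
    except Exception as exc:
        raise PipelineError(f"signals: {exc}") from exc
    manifest["counts"]["pairs_evaluated"] = len(results)
    manifest["counts"]["consensus_signals"] = len(ranked)
    manifest["signal_config"] = dataclasses.asdict(signal_config)

    # --- descriptive -----------------------------------------------------
    try:
        report = _descriptive_report(included, combos, drug_dict, year_window)
        with open(outdir / "descriptive_report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
    except Exception as exc:
        raise PipelineError(f"descriptive: {exc}") from exc

    # --- risk factors ----------------------------------------------------
    try:
        risk = risk_factor_table(included, drug_dict)
        risk.to_frame().to_csv(
            outdir / "risk_factors.csv", index=False, float_format=_FLOAT_FORMAT
        )
        manifest["counts"]["risk_model_n"] = risk.n_used
        manifest["counts"]["risk_model_excluded_missing"] = risk.n_excluded_missing
    except ModelFitError as exc:
        raise PipelineError(f"risk_factors: {exc}") from exc

    manifest["complete"] = True
    with open(outdir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
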