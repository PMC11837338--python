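"""End-to-end pipeline: records -> onsets -> climate -> sensitivity -> traits.

Each run writes stage artifacts into a run directory together with a
JSON manifest (config hash, input checksums, per-stage row counts, seed,
version) and a plain-text report tabulating the per-species summary and
the meta-model results.  Outputs are write-once per run directory; a
re-run with identical inputs and config reproduces identical manifest
counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .records import (
    DEFAULT_COUNTIES,
    apply_inclusion,
    build_series,
    deduplicate,
    load_records,
    series_summary,
)
from .onset import estimate_onset, onset_table
from .climate import DEFAULT_MONTHS, spring_index
from .sensitivity import fit_sensitivities
from .traits_meta import (
    TRAIT_MODEL_FORMULAS,
    compare_models,
    fit_trait_models,
    meta_table,
    type3_anova,
    variance_components,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """All analysis thresholds, with the study defaults.

    Everything an analyst might vary — inclusion thresholds, onset
    quantile, influence cutoff, window months, weight rule, outlier
    switch — lives here, so the pipeline doubles as a sensitivity-
    analysis harness.
    """

    counties: tuple[str, ...] = DEFAULT_COUNTIES
    year_range: tuple[int, int] = (1993, 2020)
    aliases: dict[str, str] = field(default_factory=dict)
    exclusions: tuple[str, ...] = ()  # e.g. migratory species
    min_obs_dates_per_year: int = 10
    min_years: int = 10
    onset_quantile: float = 0.10
    onset_rule: str = "ceil"
    months: tuple[int, ...] = DEFAULT_MONTHS
    remove_outliers: bool = True
    min_points: int = 5
    weight_rule: str = "inv_sd"
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.onset_quantile < 1.0):
            raise ValueError("onset_quantile must lie in (0, 1)")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be increasing")
        if self.min_obs_dates_per_year < 1 or self.min_years < 1:
            raise ValueError("inclusion thresholds must be positive")
        if self.weight_rule not in ("inv_sd", "inv_var"):
            raise ValueError(f"unknown weight_rule: {self.weight_rule!r}")
        if self.onset_rule not in ("ceil", "strict"):
            raise ValueError(f"unknown onset_rule: {self.onset_rule!r}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("counties", "exclusions", "year_range", "months"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunResult:
    outdir: Path
    manifest: dict
    sensitivity_temperature: pd.DataFrame
    sensitivity_year: pd.DataFrame
    meta_anova: pd.DataFrame
    comparisons: pd.DataFrame
    varcomp: dict


def run_all(
    records_path,
    climate_path,
    traits_path,
    outdir,
    config: AnalysisConfig | None = None,
) -> RunResult:
    """Run every stage in dependency order and write all artifacts.

    A failure inside a stage is re-raised with the stage name so the
    point of failure is unambiguous.
    """
    cfg = config or AnalysisConfig()
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if (out / "manifest.json").exists():
        raise FileExistsError(
            f"{out} already holds a completed run; outputs are write-once"
        )
    inputs = {
        "records": Path(records_path),
        "climate": Path(climate_path),
        "traits": Path(traits_path),
    }
    for name, p in inputs.items():
        if not p.exists():
            raise FileNotFoundError(f"{name} input not found: {p}")

    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.hash(),
        "inputs": {n: _checksum(p) for n, p in inputs.items()},
        "counts": {},
    }

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("dedup")
        raw = load_records(inputs["records"])
        keys, rejects = deduplicate(raw, aliases=cfg.aliases, counties=cfg.counties)
        keys.to_csv(out / "records_dedup.csv", index=False)
        if len(rejects):
            rejects.to_csv(out / "rejects.csv", index=False)
        manifest["counts"]["records_in"] = int(len(raw))
        manifest["counts"]["records_dedup"] = int(len(keys))
        manifest["counts"]["records_rejected"] = int(len(rejects))
    except Exception as e:
        raise RuntimeError(f"stage 'dedup' failed: {e}") from e

    try:
        stage("series")
        series = build_series(keys, year_range=cfg.year_range)
        kept, audit = apply_inclusion(
            series,
            min_obs_dates_per_year=cfg.min_obs_dates_per_year,
            min_years=cfg.min_years,
            exclusions=cfg.exclusions,
        )
        series_summary(kept, audit).to_csv(out / "series_summary.csv", index=False)
        manifest["counts"]["species_retained"] = len({s.species for s in kept})
        manifest["counts"]["species_years_retained"] = len(kept)
    except Exception as e:
        raise RuntimeError(f"stage 'series' failed: {e}") from e

    try:
        stage("onset")
        estimates = [
            estimate_onset(s, q=cfg.onset_quantile, rule=cfg.onset_rule)
            for s in kept
        ]
        onsets = onset_table(estimates)
        onsets.to_csv(out / "onsets.csv", index=False)
        manifest["counts"]["onsets"] = int(len(onsets))
    except Exception as e:
        raise RuntimeError(f"stage 'onset' failed: {e}") from e

    try:
        stage("climate")
        climate = pd.read_csv(inputs["climate"])
        spring = spring_index(
            climate, months=cfg.months, counties=cfg.counties, missing="strict"
        )
        spring.to_csv(out / "spring_temp.csv", index=False)
        manifest["counts"]["spring_years"] = int(len(spring))
    except Exception as e:
        raise RuntimeError(f"stage 'climate' failed: {e}") from e

    try:
        stage("sensitivity")
        fits_t = fit_sensitivities(
            onsets,
            spring,
            predictor="temperature",
            remove_outliers=cfg.remove_outliers,
            min_points=cfg.min_points,
        )
        fits_y = fit_sensitivities(
            onsets,
            predictor="year",
            remove_outliers=cfg.remove_outliers,
            min_points=cfg.min_points,
        )
        fits_t.to_csv(out / "sensitivity_temperature.csv", index=False)
        fits_y.to_csv(out / "sensitivity_year.csv", index=False)
        manifest["counts"]["outliers_removed_temperature"] = int(
            fits_t["n_removed"].sum()
        )
        manifest["counts"]["outliers_removed_year"] = int(fits_y["n_removed"].sum())
    except Exception as e:
        raise RuntimeError(f"stage 'sensitivity' failed: {e}") from e

    try:
        stage("meta")
        traits = pd.read_csv(inputs["traits"])
        meta = meta_table(fits_t, traits)
        from .traits_meta import make_weights, weighted_lm

        w = make_weights(meta["sd_onset"], rule=cfg.weight_rule)
        models = {}
        skipped = []
        for name, formula in TRAIT_MODEL_FORMULAS.items():
            try:
                models[name] = weighted_lm(formula, meta, w)
            except ValueError as err:  # e.g. rank-deficient with few species
                skipped.append((name, str(err)))
                logger.warning("meta-model %s not estimable: %s", name, err)
        anova_rows = []
        for name, res in models.items():
            tab = type3_anova(res).assign(model=name, r_squared=res.rsquared)
            anova_rows.append(tab)
        anova = pd.concat(anova_rows, ignore_index=True)
        manifest["counts"]["meta_models_skipped"] = len(skipped)
        anova.to_csv(out / "anova_tables.csv", index=False)

        comp_rows = []
        for small, large in [
            ("voltinism_only", "interaction"),
            ("additive", "interaction"),
            ("interaction", "interaction_plus_stage"),
        ]:
            if small not in models or large not in models:
                continue
            f, df1, df2, p = compare_models(models[small], models[large])
            comp_rows.append(
                {
                    "smaller": small,
                    "larger": large,
                    "F": f,
                    "df_num": df1,
                    "df_den": df2,
                    "p_value": p,
                }
            )
        comparisons = pd.DataFrame(comp_rows)
        comparisons.to_csv(out / "model_comparisons.csv", index=False)

        coef_rows = []
        for name, res in models.items():
            for term, est, se in zip(res.params.index, res.params, res.bse):
                coef_rows.append(
                    {"model": name, "term": term, "estimate": est, "se": se}
                )
        pd.DataFrame(coef_rows).to_csv(out / "meta_models.csv", index=False)

        vc = variance_components(meta)
        vc_pct = vc.percentages()
        vc_df = pd.DataFrame(
            {
                "level": list(vc_pct),
                "variance": [vc.family, vc.subfamily, vc.genus, vc.residual],
                "pct_of_total": list(vc_pct.values()),
            }
        )
        vc_df.to_csv(out / "variance_components.csv", index=False)
        manifest["counts"]["meta_species"] = int(len(meta))
    except Exception as e:
        raise RuntimeError(f"stage 'meta' failed: {e}") from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    _write_report(out, fits_t, anova, comparisons, vc_df)
    return RunResult(
        outdir=out,
        manifest=manifest,
        sensitivity_temperature=fits_t,
        sensitivity_year=fits_y,
        meta_anova=anova,
        comparisons=comparisons,
        varcomp={"variance": vc, "percentages": vc_pct},
    )


def _write_report(out: Path, fits_t, anova, comparisons, vc_df) -> None:
    lines = ["Per-species sensitivity to spring temperature (days/degC)", ""]
    header = (
        f"{'species':<14}{'slope':>8}{'r2':>7}{'p':>8}"
        f"{'mean':>9}{'sd':>7}{'n':>5}{'removed':>9}"
    )
    lines.append(header)
    for r in fits_t.itertuples(index=False):
        if not r.ok:
            lines.append(f"{r.species:<14}  (no fit: {r.note})")
            continue
        lines.append(
            f"{r.species:<14}{r.slope:>8.2f}{r.r_squared:>7.2f}{r.p_value:>8.3f}"
            f"{r.mean_onset:>9.2f}{r.sd_onset:>7.2f}{r.n_used:>5d}{r.n_removed:>9d}"
        )
    lines += ["", "Trait meta-models (Type III tests)", anova.to_string(index=False)]
    lines += ["", "Model comparisons", comparisons.to_string(index=False)]
    lines += ["", "Taxonomic variance components", vc_df.to_string(index=False)]
    (out / "report.txt").write_text("\n".join(lines) + "\n")
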