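"""End-to-end orchestration of the density-distribution analysis.

Stages run in the order of the study they emulate: (1) data synthesis
or loading, (2) aggregation of repeated estimates plus the
island/mainland comparison, (3) zero-density background sampling,
(4) multi-scale covariate construction, scale selection,
standardization and correlation pruning, (5) all-subsets AICc
enumeration, model averaging and variable importance, (6) the
potential-density and density-class maps, and (7) k-fold
cross-validation.  Every stage writes a plain-text artifact with a
stable schema, and a YAML manifest records the config and seed so a
run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariates import (
    CovariateSpec,
    DesignTable,
    build_blocks,
    default_analysis_specs,
    extract_covariates,
    focal_mean,
    prune_correlated,
    select_scale,
    standardize,
)
from .design import aggregate_records, compare_island_mainland, sample_background
from .mmi import AveragedModel, ModelSet, enumerate_models, model_average
from .prediction import classify_density, predict_map
from .raster import RasterGrid, write_ascii_grid
from .records import read_records, write_records
from .reference_tables import (
    REFERENCE_BLOCK_NAMES,
    REFERENCE_N,
    recompute_selection_table,
)
from .synthetic import (
    LandscapeConfig,
    default_true_model,
    generate_island_mask,
    generate_landscape,
    generate_true_density,
    sample_study_sites,
)
from .validation import CVResult, cross_validate, huberty_k

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline", "paper_fixture_report"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults reproduce the synthetic study design."""

    seed: int = 0
    out_dir: str = "pigdensity_run"
    records_path: str | None = None  # None => synthesize
    # synthetic landscape
    extent: tuple[float, float] = (8000.0, 8000.0)
    cell_size: float = 10.0
    island_fraction: float = 0.005
    n_mainland: int = 118
    n_island: int = 11
    # study design
    buffer_inner_km: float = 100.0
    buffer_outer_km: float = 1000.0
    welch_log_scale: bool = True
    # covariates
    log_offset: float = 1.0
    corr_threshold: float = 0.70
    covariate_specs: list[CovariateSpec] = field(default_factory=default_analysis_specs)
    # model averaging & validation
    averaging_variant: str = "full"  # full | conditional
    k: int | str = "huberty"
    refit_selection: bool = False
    classification_breaks: tuple[float, float, float] = (1.0, 6.0, 11.0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariate_specs"] = [dataclasses.asdict(s) for s in self.covariate_specs]
        return d

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        if "covariate_specs" in d:
            d["covariate_specs"] = [
                CovariateSpec(
                    name=s["name"],
                    category=s.get("category", "biotic-vegetation"),
                    candidate_radii_km=tuple(s.get("candidate_radii_km", (10.0, 40.0))),
                    allow_quadratic=bool(s.get("allow_quadratic", False)),
                    expected_sign=s.get("expected_sign", "positive"),
                )
                for s in d["covariate_specs"]
            ]
        for key in ("extent", "classification_breaks"):
            if key in d:
                d[key] = tuple(d[key])
        return PipelineConfig(**d)

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    config: PipelineConfig
    records: pd.DataFrame
    analysis_records: pd.DataFrame
    design: DesignTable
    retained: list[str]
    model_set: ModelSet
    averaged: AveragedModel
    density_map: RasterGrid
    class_map: RasterGrid
    cv: CVResult
    welch: dict
    out_dir: Path


def model_selection_frame(model_set: ModelSet, top: int | None = None) -> pd.DataFrame:
    """Selection table: one row per candidate model, membership flags,
    K, AICc, delta, weight, logL — the layout of a published AICc table."""
    rows = []
    models = model_set.models if top is None else model_set.models[:top]
    for m in models:
        row = {name: ("*" if name in m.included_blocks else "") for name in model_set.block_names}
        row.update(
            K=m.K,
            AICc=round(m.aicc, 2),
            delta=round(m.delta, 2),
            weight=round(m.weight, 4),
            logL=round(m.fit.logL, 2),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def averaged_frame(avg: AveragedModel) -> pd.DataFrame:
    """Averaged-model report: importance, coefficient and unconditional
    SE per block (main and quadratic rows where present)."""
    rows = [
        {
            "block": "(Intercept)",
            "term": "m",
            "importance": 1.0,
            "estimate": round(avg.coefficients["(Intercept)"], 4),
            "unconditional_se": round(avg.unconditional_se["(Intercept)"], 4),
        }
    ]
    for name in avg.block_names:
        rows.append(
            {
                "block": name,
                "term": "m",
                "importance": round(avg.importance[name], 4),
                "estimate": round(avg.coefficients[name], 4),
                "unconditional_se": round(avg.unconditional_se[name], 4),
            }
        )
        if name in avg.quadratic_blocks:
            rows.append(
                {
                    "block": name,
                    "term": "q",
                    "importance": round(avg.importance[name], 4),
                    "estimate": round(avg.coefficients[f"{name}^2"], 4),
                    "unconditional_se": round(avg.unconditional_se[f"{name}^2"], 4),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- stage 1: data -------------------------------------------------
    try:
        land_cfg = LandscapeConfig(
            seed=config.seed,
            extent=config.extent,
            cell_size=config.cell_size,
            island_fraction=config.island_fraction,
        )
        grids = generate_landscape(land_cfg)
        island_mask = generate_island_mask(land_cfg)
        truth = default_true_model()
        density_surface = generate_true_density(grids, truth, seed=config.seed, island_mask=island_mask)
        if config.records_path is not None:
            records = read_records(config.records_path)
        else:
            records = sample_study_sites(
                density_surface,
                n_mainland=config.n_mainland,
                n_island=config.n_island,
                seed=config.seed,
                island_mask=island_mask,
                native_polygon=land_cfg.native_polygon,
            )
        write_records(records, out / "records.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("data", "E_DATA", str(exc)) from exc

    # ---- stage 2: aggregation + island/mainland comparison -------------
    try:
        aggregated = aggregate_records(records)
        welch = {}
        if aggregated["is_island"].any() and (~aggregated["is_island"]).any():
            welch["raw"] = compare_island_mainland(aggregated, log_scale=False)
            if (aggregated.loc[aggregated["region"] != "background", "density"] > 0).all():
                welch["log"] = compare_island_mainland(aggregated, log_scale=True)
        mainland = aggregated[~aggregated["is_island"]].reset_index(drop=True)
    except Exception as exc:
        raise PipelineError("prepare", "E_PREPARE", str(exc)) from exc

    # ---- stage 3: background sampling ----------------------------------
    try:
        n_native = int((mainland["region"] == "native").sum())
        background = sample_background(
            land_cfg.native_polygon,
            n_native_estimates=n_native,
            seed=config.seed,
            buffer_inner_km=config.buffer_inner_km,
            buffer_outer_km=config.buffer_outer_km,
        )
        write_records(background, out / "background.tsv")
        analysis_records = pd.concat([mainland, background], ignore_index=True)
    except Exception as exc:
        raise PipelineError("background", "E_BACKGROUND", str(exc)) from exc

    # ---- stage 4: covariates -------------------------------------------
    try:
        focal_surfaces: dict[str, dict[float, RasterGrid]] = {}
        for spec in config.covariate_specs:
            focal_surfaces[spec.name] = {
                r: focal_mean(grids[spec.name], r) for r in spec.candidate_radii_km
            }
        raw_all = extract_covariates(analysis_records, focal_surfaces)
        response_for_selection = np.log(
            analysis_records["density"].to_numpy(dtype=float) + config.log_offset
        )
        chosen_radius: dict[str, float] = {}
        chosen_form: dict[str, str] = {}
        raw_selected = pd.DataFrame(index=raw_all.index)
        for spec in config.covariate_specs:
            cands = {
                r: raw_all[f"{spec.name}@{r:g}km"].to_numpy(dtype=float)
                for r in spec.candidate_radii_km
            }
            choice = select_scale(response_for_selection, cands, spec)
            chosen_radius[spec.name] = choice.radius_km
            chosen_form[spec.name] = choice.form
            raw_selected[spec.name] = cands[choice.radius_km]
        design = standardize(
            raw_selected,
            analysis_records["density"].to_numpy(dtype=float),
            log_offset=config.log_offset,
            chosen_radius=chosen_radius,
            chosen_form=chosen_form,
        )
        retained, prune_log = prune_correlated(design, threshold=config.corr_threshold)
        quad_names = {n for n, f in chosen_form.items() if f == "quadratic" and n in retained}
        blocks = build_blocks(design, retained, quad_names)
        design_out = design.columns[retained].copy()
        design_out.insert(0, "log_density", design.response)
        design_out.to_csv(out / "design.tsv", sep="\t", index=False)
        pd.DataFrame(prune_log, columns=["dropped", "kept", "r"]).to_csv(
            out / "pruning.tsv", sep="\t", index=False
        )
        scaling_rows = [
            {
                "name": name,
                "mean": mean,
                "sd": sd,
                "chosen_radius_km": design.chosen_radius.get(name.removesuffix("^2"), ""),
                "form": design.chosen_form.get(name.removesuffix("^2"), ""),
                "log_offset": design.log_offset,
            }
            for name, (mean, sd) in design.scaling.items()
        ]
        pd.DataFrame(scaling_rows).to_csv(out / "scaling.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("covariates", "E_COVARIATES", str(exc)) from exc

    # ---- stage 5: enumeration + averaging ------------------------------
    try:
        model_set = enumerate_models(design.response, blocks)
        averaged = model_average(model_set, variant=config.averaging_variant)
        averaged.scaling = design.scaling
        averaged.log_offset = design.log_offset
        model_selection_frame(model_set).to_csv(out / "model_selection.tsv", sep="\t", index=False)
        averaged_frame(averaged).to_csv(out / "averaged_model.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("fit", "E_FIT", str(exc)) from exc

    # ---- stage 6: prediction maps --------------------------------------
    try:
        chosen_surfaces = {
            name: focal_surfaces[name][design.chosen_radius[name]] for name in retained
        }
        density_map = predict_map(
            averaged, chosen_surfaces, design.scaling, log_offset=design.log_offset
        )
        class_map = classify_density(density_map, breaks=config.classification_breaks)
        write_ascii_grid(density_map, out / "density_map.asc")
        write_ascii_grid(class_map, out / "class_map.asc")
    except Exception as exc:
        raise PipelineError("predict", "E_PREDICT", str(exc)) from exc

    # ---- stage 7: cross-validation -------------------------------------
    try:
        k = huberty_k(len(blocks)) if config.k == "huberty" else int(config.k)
        cv = cross_validate(
            design,
            blocks,
            k=k,
            seed=config.seed,
            refit_selection=config.refit_selection,
            variant=config.averaging_variant,
        )
        cv_frame = pd.DataFrame(
            {
                "fold": list(range(cv.k)) + ["pooled"],
                "mspe": [round(v, 6) for v in cv.per_fold_mspe] + [round(cv.mspe, 6)],
            }
        )
        cv_frame["pearson_r"] = [""] * cv.k + [round(cv.pearson_r, 4)]
        cv_frame["t"] = [""] * cv.k + [round(cv.t, 3)]
        cv_frame["df"] = [""] * cv.k + [cv.df]
        cv_frame["k"] = cv.k
        cv_frame["seed"] = config.seed
        cv_frame.to_csv(out / "cv.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("validate", "E_VALIDATE", str(exc)) from exc

    # ---- manifest ------------------------------------------------------
    manifest = {
        "package": "pigdensity",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "counts": {
            "records_in": int(len(records)),
            "records_aggregated": int(len(aggregated)),
            "mainland": int(len(mainland)),
            "background": int(len(background)),
            "analysis_n": int(len(analysis_records)),
            "models_fit": len(model_set),
            "columns_pruned": len(prune_log),
            "columns_retained": len(retained),
        },
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    return PipelineResult(
        config=config,
        records=records,
        analysis_records=analysis_records,
        design=design,
        retained=retained,
        model_set=model_set,
        averaged=averaged,
        density_map=density_map,
        class_map=class_map,
        cv=cv,
        welch={k_: dataclasses.asdict(v) for k_, v in welch.items()},
        out_dir=out,
    )


def paper_fixture_report(out_path: str | Path | None = None) -> pd.DataFrame:
    """Regenerate AICc / delta / weight columns and the importance row
    from the published log-likelihoods and parameter counts at n = 183.

    This exercises the selection arithmetic against the published
    global wild pig analysis without any geodata; see
    :mod:`pigdensity.reference_tables`.
    """
    rec = recompute_selection_table()
    rows = []
    for row, aicc, delta, weight in zip(rec["rows"], rec["aicc"], rec["delta"], rec["weight"]):
        r = {name: ("*" if name in row.blocks else "") for name in REFERENCE_BLOCK_NAMES}
        r.update(
            K=row.K,
            logL=row.logL,
            AICc=round(float(aicc), 2),
            delta=round(float(delta), 2),
            weight=round(float(weight), 2),
        )
        rows.append(r)
    frame = pd.DataFrame(rows)
    importance = {name: round(v, 2) for name, v in rec["importance"].items()}
    frame.attrs["importance"] = importance
    frame.attrs["n"] = REFERENCE_N
    if out_path is not None:
        out_path = Path(out_path)
        frame.to_csv(out_path, sep="\t", index=False)
        with open(out_path.with_suffix(".importance.tsv"), "w") as fh:
            fh.write("\t".join(REFERENCE_BLOCK_NAMES) + "\n")
            fh.write("\t".join(f"{importance[n]:.2f}" for n in REFERENCE_BLOCK_NAMES) + "\n")
    return frame
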