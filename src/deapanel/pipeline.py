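"""Seeded orchestration of the four analysis steps.

Stage order: (1) descriptive summary of the panel, (2) DEA with the
smoothed bootstrap, (3) random-forest determinants of the bias-corrected
scores, (4) regional subgroup refits — followed by the report stage that
writes the yearly/regional summary tables.  Every stage writes its
artifacts under the configured output directory and registers them in a
JSON manifest with SHA-256 digests, so two runs with the same config and
seed are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

import deapanel
from deapanel.bootstrap import BootstrapConfig, bootstrap_panel
from deapanel.determinants import (
    FEATURE_COLS,
    RFConfig,
    fit_regional,
    fit_rf,
    partial_dependence,
    perturbation_importance,
)
from deapanel.io import RunConfig, load_panel, validate_panel, write_csv
from deapanel.summary import (
    format_region_table,
    region_difference_by_year,
    summarize_regions,
    summarize_years,
)
from deapanel.synthetic import (
    CONTEXT_COLS,
    INPUT_COLS,
    OUTPUT_COLS,
    SyntheticConfig,
    generate_panel,
)

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _describe(panel: pd.DataFrame, anchor_years: tuple[int, ...]) -> pd.DataFrame:
    """Mean (SE) of every input/output/context variable at the anchor years."""
    cols = INPUT_COLS + OUTPUT_COLS + CONTEXT_COLS
    years = [y for y in anchor_years if y in set(panel["year"])]
    rows = []
    for col in cols:
        row: dict = {"variable": col}
        for y in years:
            vals = panel.loc[panel["year"] == y, col]
            row[f"mean_{y}"] = vals.mean()
            row[f"se_{y}"] = vals.std(ddof=1) / np.sqrt(len(vals))
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest.

    Any stage failure halts the run with the stage named in the raised
    error; artifacts of completed stages are left on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": deapanel.__version__,
        "seed": config.seed,
        "stages_run": [],
        "stages_skipped": [],
        "files": {},
        "warnings": [],
    }

    def register(name: str, path: Path) -> None:
        manifest["files"][name] = {
            "path": str(path.relative_to(outdir)),
            "sha256": _sha256(path),
        }

    def stage_enabled(name: str) -> bool:
        return name in config.stages

    panel = None
    estimates = None
    current = "setup"
    try:
        # --- input panel ---
        current = "simulate"
        if config.panel_path is not None:
            panel = load_panel(config.panel_path)
            manifest["panel_source"] = str(config.panel_path)
        elif stage_enabled("simulate"):
            syn = SyntheticConfig(
                **{**config.synthetic, "seed": config.stage_seed("simulate")}
            )
            panel, truth = generate_panel(syn)
            panel = validate_panel(panel)
            ppath, tpath = outdir / "panel.csv", outdir / "truth.csv"
            write_csv(panel, ppath)
            write_csv(truth, tpath)
            register("panel", ppath)
            register("truth", tpath)
            manifest["stages_run"].append("simulate")
        if panel is None:
            raise RuntimeError("no panel: enable 'simulate' or set panel_path")

        current = "describe"
        if stage_enabled("describe"):
            anchor = tuple(config.summary.get("anchor_years", (2009, 2015, 2020)))
            desc = _describe(panel, anchor)
            dpath = outdir / "descriptives.csv"
            write_csv(desc, dpath)
            register("descriptives", dpath)
            manifest["stages_run"].append("describe")

        current = "dea/bootstrap"
        if stage_enabled("dea") or stage_enabled("bootstrap"):
            bcfg = BootstrapConfig(
                **{**config.bootstrap, "seed": config.stage_seed("bootstrap")}
            )
            estimates = bootstrap_panel(
                panel, list(INPUT_COLS), list(OUTPUT_COLS), bcfg
            )
            epath = outdir / "estimates.csv"
            write_csv(estimates, epath)
            register("estimates", epath)
            manifest["stages_run"].append("dea+bootstrap")

        current = "rf"
        if stage_enabled("rf"):
            if estimates is None:
                raise RuntimeError("rf stage needs the dea/bootstrap stage")
            rfc = RFConfig(
                **{**config.determinants, "seed": config.stage_seed("rf")}
            )
            feats = (
                estimates[["jurisdiction_id", "year"]]
                .merge(
                    panel[["jurisdiction_id", "year"] + CONTEXT_COLS],
                    on=["jurisdiction_id", "year"],
                )[CONTEXT_COLS + ["year"]]
                .astype(float)
            )
            feats = feats[FEATURE_COLS]
            target = estimates["bias_corrected_efficiency"].to_numpy()
            model, metrics = fit_rf(feats, target, rfc)
            (outdir / "rf_metrics.json").write_text(
                json.dumps(metrics.as_dict(), indent=2)
            )
            register("rf_metrics", outdir / "rf_metrics.json")
            imp = perturbation_importance(
                model, feats, target, rfc,
                rng=np.random.default_rng(rfc.seed + 1),
            )
            write_csv(imp, outdir / "importance.csv")
            register("importance", outdir / "importance.csv")
            pd_frames = [
                partial_dependence(
                    model, feats, var, rfc,
                    rng=np.random.default_rng(rfc.seed + 2),
                )
                for var in FEATURE_COLS
            ]
            write_csv(pd.concat(pd_frames, ignore_index=True),
                      outdir / "partial_dependence.csv")
            register("partial_dependence", outdir / "partial_dependence.csv")
            # predicted-vs-observed yearly series (the close "predicted" curve)
            pred = model.predict(feats.to_numpy(float))
            series = (
                pd.DataFrame(
                    {"year": estimates["year"], "predicted": pred,
                     "observed": target}
                ).groupby("year").mean().reset_index()
            )
            write_csv(series, outdir / "predicted_series.csv")
            register("predicted_series", outdir / "predicted_series.csv")
            manifest["stages_run"].append("rf")

            current = "regional"
            if stage_enabled("regional"):
                region = (
                    estimates[["jurisdiction_id", "year"]]
                    .merge(
                        panel[["jurisdiction_id", "year", "region"]],
                        on=["jurisdiction_id", "year"],
                    )["region"]
                    .to_numpy()
                )
                results, skipped = fit_regional(feats, target, region, rfc)
                for reg, (met, rimp) in results.items():
                    rdir = outdir / f"region_{reg}"
                    rdir.mkdir(exist_ok=True)
                    (rdir / "rf_metrics.json").write_text(
                        json.dumps(met.as_dict(), indent=2)
                    )
                    register(f"region_{reg}_metrics", rdir / "rf_metrics.json")
                    write_csv(rimp, rdir / "importance.csv")
                    register(f"region_{reg}_importance", rdir / "importance.csv")
                manifest["regions_skipped"] = skipped
                manifest["stages_run"].append("regional")

        current = "report"
        if stage_enabled("report"):
            if estimates is None:
                raise RuntimeError("report stage needs the dea/bootstrap stage")
            ysum = summarize_years(estimates)
            write_csv(ysum, outdir / "year_summary.csv")
            register("year_summary", outdir / "year_summary.csv")
            if "region" in estimates.columns:
                anchor = tuple(
                    config.summary.get("anchor_years", (2009, 2015, 2020))
                )
                rsum = summarize_regions(estimates, report_years=anchor)
                diff = region_difference_by_year(estimates)
                write_csv(rsum, outdir / "region_summary.csv")
                register("region_summary", outdir / "region_summary.csv")
                (outdir / "region_report.txt").write_text(
                    format_region_table(rsum, diff) + "\n"
                )
                register("region_report", outdir / "region_report.txt")
            manifest["stages_run"].append("report")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest["stages_skipped"] = [
        s for s in ("simulate", "describe", "dea", "bootstrap", "rf",
                    "regional", "report")
        if s not in config.stages
    ]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
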