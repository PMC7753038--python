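"""End-to-end orchestration: fixtures -> coloc -> morphometry -> spatial.

One seeded run produces the full result surface: co-localization
coefficient tables with translated controls, the vessel classification
report with quartile cut-offs and the caliber-complexity contingency test,
and the spatial distance-distribution verdicts.  A single seed fans out to
per-stage child seeds so any stage can be re-run alone and reproduce its
part of the report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd
from pydantic import ValidationError

from . import coloc as coloc_mod
from . import fixtures as fx
from . import io as mio
from . import morphometry as morpho
from . import spatial as sp
from .config import RunConfig

log = logging.getLogger("marrowmap")

STAGE_ORDER = ("fixtures", "coloc", "morphometry", "spatial")


def validate_config(raw: Union[dict, str, Path, None]) -> RunConfig:
    """Validate a raw config mapping (or file path); raises ValueError
    listing every violation at once."""
    if raw is None:
        raw = {}
    if isinstance(raw, (str, Path)):
        raw = mio.read_config(raw)
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        msgs = [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        ]
        raise ValueError("invalid config:\n" + "\n".join(msgs)) from exc


def _stage_seed(seed: int, stage: str) -> int:
    return int(
        np.random.SeedSequence([seed, STAGE_ORDER.index(stage)]).generate_state(1)[0]
        % (2**31)
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: Union[RunConfig, dict, None] = None) -> dict:
    """Execute the enabled stages in dependency order and return the run
    report (a JSON-serializable dict).  A failing stage is isolated: its
    error lands in the report and downstream stages that can still run do."""
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    report: dict = {
        "seed": cfg.seed,
        "mode": cfg.mode,
        "stages": list(cfg.stages),
        "decisions": {
            "above_threshold_rule": cfg.coloc.above_threshold_rule,
            "m1_channel": cfg.coloc.m1_channel,
            "dunn_adjust": cfg.coloc.dunn_adjust,
            "percentile_method": "linear interpolation",
            "quartile_pool": "non-zero calibers",
            "ic_operator": "minor axis of largest lumen component",
            "distance_floor": "normalized distances floored at 0",
            "qq_plotting_positions": cfg.analysis.qq_plotting_positions,
            "cooccurrence_test": "Pearson chi-square, Fisher fallback",
            "z_rounding": cfg.analysis.z_rounding,
        },
        "outputs": {},
        "errors": {},
    }

    sets: List[fx.MicrographSet] = []
    truth: Optional[fx.GroundTruth] = None
    vessel_table: Optional[pd.DataFrame] = None
    distance_table: Optional[pd.DataFrame] = None

    if cfg.mode == "tables":
        if cfg.vessel_table:
            vessel_table = mio.read_table(cfg.vessel_table)
        if cfg.distance_table:
            distance_table = mio.read_table(cfg.distance_table)

    if "fixtures" in cfg.stages and cfg.mode == "synthetic":
        try:
            fix_cfg = cfg.fixture.model_copy(
                update={"seed": _stage_seed(cfg.seed, "fixtures")}
            )
            sets, truth = fx.generate_dataset(fix_cfg)
            report["outputs"]["fixtures"] = {
                "n_images": len(sets),
                "n_vessels": int(len(truth.vessel_table)),
                "n_imhcs": int(len(truth.imhc_points)),
            }
        except Exception as exc:  # noqa: BLE001 - stage isolation
            log.exception("fixtures stage failed")
            report["errors"]["fixtures"] = repr(exc)

    if "coloc" in cfg.stages and sets:
        try:
            results = []
            for mset in sets[: min(4, len(sets))]:
                pair = coloc_mod.ChannelPair(
                    green=mset.channels["nestin"], red=mset.channels["endothelial"]
                )
                res = coloc_mod.coloc_analysis(
                    pair,
                    offsets=cfg.coloc.offsets_px,
                    above_rule=cfg.coloc.above_threshold_rule,
                    uncorrelated_band=cfg.coloc.uncorrelated_band,
                )
                results.append(res.to_dict())
            report["outputs"]["coloc"] = results
        except Exception as exc:  # noqa: BLE001
            log.exception("coloc stage failed")
            report["errors"]["coloc"] = repr(exc)

    if "morphometry" in cfg.stages:
        try:
            if truth is not None:
                rows = []
                for mset in sets:
                    for vid in np.unique(mset.lumen_labels):
                        if vid == 0:
                            continue
                        ic = morpho.measure_inner_caliber(
                            mset.lumen_labels == vid, mset.um_per_px
                        )
                        rows.append({"id": int(vid), "ic_um": ic})
                measured = pd.DataFrame(rows)
                vessel_table = truth.vessel_table.merge(
                    measured, on="id", how="left"
                )
                vessel_table["ic_um"] = vessel_table["ic_um"].fillna(0.0)
            if vessel_table is None:
                raise ValueError("no vessel table available")
            classified, cutoffs = morpho.classify_table(vessel_table)
            table = morpho.build_contingency(classified, cutoffs)
            chi2, dof, p = morpho.chi_square(table)
            report["outputs"]["morphometry"] = {
                "cutoffs_um": [cutoffs.q25, cutoffs.q50, cutoffs.q75],
                "class_counts": classified["assigned_class"]
                .value_counts()
                .to_dict(),
                "class_percentages": morpho.class_percentages(classified),
                "contingency": table.counts.to_dict(),
                "excluded_columns": table.excluded_columns,
                "chi_square": {"statistic": chi2, "df": dof, "p": p},
            }
            vessel_table = classified
        except Exception as exc:  # noqa: BLE001
            log.exception("morphometry stage failed")
            report["errors"]["morphometry"] = repr(exc)

    if "spatial" in cfg.stages:
        try:
            if distance_table is None and truth is not None:
                bone = truth.distance_table.copy()
                imhc_rows = []
                vt = truth.vessel_table
                pts = truth.imhc_points
                for img, grp in vt.groupby("image"):
                    p_img = pts[pts["image"] == img]
                    if not len(p_img):
                        continue
                    pxy = p_img[["row", "col"]].to_numpy(dtype=float)
                    for _, v in grp.iterrows():
                        diff = pxy - np.array([v["row"], v["col"]], dtype=float)
                        d = float(
                            np.sqrt((diff**2).sum(axis=1)).min()
                            * cfg.fixture.um_per_px
                        )
                        imhc_rows.append(
                            {
                                "structure_id": v["id"],
                                "class": v["class"],
                                "target_kind": "imHC",
                                "d_raw_um": d,
                                "ic_um": v["true_ic_um"],
                            }
                        )
                distance_table = pd.concat(
                    [bone, pd.DataFrame(imhc_rows)], ignore_index=True
                )
            if distance_table is None:
                raise ValueError("no distance table available")
            summaries = sp.clustering_inference(distance_table, cfg.analysis)
            out = {
                f"{cls}|{kind}": summ.to_dict()
                for (cls, kind), summ in summaries.items()
            }
            spatial_out = {"summaries": out}
            if vessel_table is not None and "bone_in_fov" in vessel_table:
                cls_col = (
                    "assigned_class"
                    if "assigned_class" in vessel_table
                    else "class"
                )
                nclt = vessel_table[cls_col] == "NCLT"
                tubular = vessel_table["tubular"].astype(bool)
                if nclt.any() and (~nclt & tubular).any():
                    pg, pr, p = sp.cooccurrence_test(
                        vessel_table.loc[nclt, "bone_in_fov"],
                        vessel_table.loc[~nclt & tubular, "bone_in_fov"],
                    )
                    spatial_out["bone_cooccurrence_nclt"] = {
                        "percent_nclt": pg,
                        "percent_rest": pr,
                        "p": p,
                    }
            report["outputs"]["spatial"] = spatial_out
        except Exception as exc:  # noqa: BLE001
            log.exception("spatial stage failed")
            report["errors"]["spatial"] = repr(exc)

    report = _jsonable(report)
    if cfg.output_dir:
        outdir = Path(cfg.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        if truth is not None:
            mio.save_ground_truth(truth, outdir / "truth")
        (outdir / "manifest.json").write_text(
            json.dumps(
                {"seed": cfg.seed, "stages": list(cfg.stages), "mode": cfg.mode}
            )
        )
    return report
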