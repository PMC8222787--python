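"""End-to-end orchestration: cohort -> LOD filter -> GTA -> fusion -> OPLS-DA -> MCCV.

``run_pipeline`` produces, in the output directory:

* ``validation_table.csv`` — one row per requested block combination with
  per-class AUROC, overall AUROC and pooled accuracy (the cross-validation
  summary table);
* ``biomarker_table.csv`` — features ranked by the VIP of the rhGH-arm
  (EGH) one-vs-rest model fitted on the full fused matrix;
* ``trend_summary.csv`` — per-(analyte, arm, day) mean/SD/n of the GTA
  values (the tabular trend bands);
* ``model.json`` — the fitted scaler + OPLS-DA ensemble, bit-stable;
* ``run_log.txt`` — dropped analytes, per-stage record counts, and all
  resolved defaults.

Outputs are deterministic given the seed; a stage failure removes partial
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortDesign, default_design, generate_cohort
from .fusion import ColumnScaler, FusedMatrix, block_to_matrix, fuse
from .gta import GtaTransformer, GtaPanel, trend_summary
from .opls import OplsDaClassifier
from .panel import LongitudinalPanel, lod_filter, read_panel
from .schema import Block, read_schema
from .validation import MccvConfig, mccv_run

DEFAULT_BLOCK_COMBOS = (
    ("ENDOCRINE",),
    ("CBC",),
    ("STEROID",),
    ("CBC", "STEROID"),
    ("CBC", "STEROID", "ENDOCRINE"),
)


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run."""

    design: CohortDesign | None = None
    panel_path: str | None = None
    schema_path: str | None = None
    max_missing_frac: float = 0.5
    block_combos: tuple = DEFAULT_BLOCK_COMBOS
    n_orth: int = 1
    mccv: MccvConfig = field(default_factory=MccvConfig)
    vip_class: str = "EGH"
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.design is None) == (self.panel_path is None):
            raise ValueError("provide exactly one of design or panel_path")
        for combo in self.block_combos:
            for b in combo:
                Block(b)  # raises on unknown block names


def serialize_model(
    scaler: ColumnScaler, model: OplsDaClassifier, fused: FusedMatrix
) -> dict:
    """JSON-safe representation of a fitted scaler + OPLS-DA ensemble."""
    payload = {
        "format_version": 1,
        "package_version": __version__,
        "feature_names": list(fused.feature_names),
        "feature_blocks": list(fused.feature_blocks),
        "classes": model.classes_,
        "n_orthogonal": model.n_orthogonal,
        "scaler": {
            "center": scaler.center_.tolist(),
            "scale": scaler.scale_.tolist(),
        },
        "models": {},
    }
    for cls, m in model.models_.items():
        payload["models"][cls] = {
            "x_mean": m.x_mean_.tolist(),
            "y_mean": m.y_mean_,
            "w": m.w_.tolist(),
            "p": m.p_.tolist(),
            "c": m.c_,
            "ortho_weights": m.ortho_weights_.tolist(),
            "ortho_loadings": m.ortho_loadings_.tolist(),
            "vip": m.vip_.tolist(),
        }
    return payload


def _float_str(v: float) -> str:
    return np.format_float_positional(v, trim="0")


def biomarker_table(model: OplsDaClassifier, fused: FusedMatrix, vip_class: str) -> pd.DataFrame:
    """Features ranked by the VIP of one class's one-vs-rest model."""
    vips = model.vip_[vip_class]
    df = pd.DataFrame(
        {
            "feature": fused.feature_names,
            "block": fused.feature_blocks,
            "vip": vips,
        }
    )
    return df.sort_values(
        ["vip", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def run_pipeline(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, out, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run(config: PipelineConfig, out: Path, written: list[Path]) -> Path:
    log: list[str] = [f"trajdope {__version__}"]

    # -- stage: input ------------------------------------------------------
    if config.design is not None:
        design = config.design
        panel = generate_cohort(design)
        log.append(
            f"simulate: {design.n_subjects_per_arm} subjects/arm, "
            f"days {list(design.days)}, {len(design.schema)} analytes, "
            f"seed {design.seed}"
        )
    else:
        schema = read_schema(config.schema_path)
        panel = read_panel(config.panel_path, schema)
        log.append(f"ingest: {config.panel_path} ({len(panel.records)} records)")
    log.append(f"records: {len(panel.records)}; samples: {len(panel.sample_keys())}")

    # -- stage: LOD filter -------------------------------------------------
    panel, dropped = lod_filter(panel, config.max_missing_frac)
    log.append(
        f"lod_filter: max_missing_frac={config.max_missing_frac}; "
        f"dropped {len(dropped)} analyte(s): {dropped}"
    )
    log.append(f"retained analytes: {len(panel.schema)}")

    # -- stage: GTA --------------------------------------------------------
    gta = GtaTransformer().fit_transform(panel)
    log.append(f"gta: baseline_days=(0,), records {len(gta.records)}")

    trends = trend_summary(gta, grouping="arm")
    trend_path = out / "trend_summary.csv"
    trends.to_csv(trend_path, index=False, encoding="utf-8",
                  float_format="%.10g")
    written.append(trend_path)

    # -- stage: fusion + validation per block combination ------------------
    blocks_cache = {
        b: block_to_matrix(gta, b)
        for b in sorted({b for combo in config.block_combos for b in combo})
    }
    mccv_config = MccvConfig(**{**asdict(config.mccv), "seed": config.seed})
    val_rows = []
    for combo in config.block_combos:
        fused = fuse([blocks_cache[b] for b in combo])
        report = mccv_run(fused, mccv_config, n_orth=config.n_orth)
        row = {
            "blocks": "+".join(combo),
            "n_features": fused.n_features,
        }
        for cls in report.classes:
            row[f"auroc_{cls}"] = report.per_class_auroc[cls]
        row["auroc_overall"] = report.overall_auroc
        row["accuracy"] = report.accuracy
        val_rows.append(row)
        log.append(
            f"mccv[{row['blocks']}]: n_features={fused.n_features} "
            f"overall_auroc={report.overall_auroc:.4f} "
            f"accuracy={report.accuracy:.4f} redraws={report.n_redraws}"
        )
    val_path = out / "validation_table.csv"
    pd.DataFrame(val_rows).to_csv(val_path, index=False, encoding="utf-8",
                                  float_format="%.10g")
    written.append(val_path)
    log.append(
        f"mccv config: n_reps={mccv_config.n_reps} "
        f"test_fraction={mccv_config.test_fraction:.6f} "
        f"stratified={mccv_config.stratified} split_unit={mccv_config.split_unit} "
        f"seed={mccv_config.seed}"
    )

    # -- stage: full-data model + biomarker ranking ------------------------
    full_combo = max(config.block_combos, key=len)
    fused_full = fuse([blocks_cache[b] for b in full_combo])
    scaler = ColumnScaler().fit(fused_full.matrix)
    model = OplsDaClassifier(n_orthogonal=config.n_orth).fit(
        scaler.transform(fused_full.matrix), fused_full.class_labels
    )
    model_path = out / "model.json"
    model_path.write_text(
        json.dumps(serialize_model(scaler, model, fused_full), indent=1,
                   ensure_ascii=False, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    written.append(model_path)

    bio = biomarker_table(model, fused_full, config.vip_class)
    bio_path = out / "biomarker_table.csv"
    bio.to_csv(bio_path, index=False, encoding="utf-8", float_format="%.10g")
    written.append(bio_path)
    log.append(
        f"biomarkers: VIP of {config.vip_class}-vs-rest model on "
        f"{'+'.join(full_combo)} ({fused_full.n_features} features); "
        f"top feature {bio.iloc[0]['feature']}"
    )

    log_path = out / "run_log.txt"
    log_path.write_text("\n".join(log) + "\n", encoding="utf-8")
    written.append(log_path)
    return out
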