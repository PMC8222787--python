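"""Long-format longitudinal panel: data model, CSV I/O, class labels, LOD filter.

The :class:`LongitudinalPanel` is the interchange object of the whole
pipeline: one record per (subject, arm, day, analyte) with an optional value
and a below-limit-of-detection flag. Records live in a tidy pandas DataFrame;
the analyte catalogue travels alongside as a schema.

Class labels follow the study's three-class convention: all pre-treatment
(day 0) samples form the CONTROL class regardless of arm; post-treatment
samples are labeled by their arm (EPO or EGH).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import AnalyteDef, Block, BLOCK_ORDER, schema_names, validate_schema

ARMS = ("EPO", "EGH")
CONTROL = "CONTROL"
CLASSES = (CONTROL, "EGH", "EPO")  # lexicographic, the pipeline's canonical order

RECORD_COLUMNS = ["subject_id", "arm", "day", "analyte", "value", "below_lod"]


class PanelSchemaError(ValueError):
    """A required column or analyte definition is missing."""


class PanelValidationError(ValueError):
    """Panel records violate an invariant."""


class PanelParseError(ValueError):
    """A CSV cell could not be parsed."""


@dataclass
class LongitudinalPanel:
    """Tidy subject x timepoint x analyte measurement table.

    ``records`` columns: subject_id (str), arm (str in {EPO, EGH}),
    day (int >= 0), analyte (str), value (float, NaN = absent),
    below_lod (bool).
    """

    schema: list[AnalyteDef]
    records: pd.DataFrame

    def __post_init__(self) -> None:
        self.records = _normalize_records(self.records)
        self.validate()

    def validate(self) -> None:
        validate_schema(self.schema)
        rec = self.records
        missing = [c for c in RECORD_COLUMNS if c not in rec.columns]
        if missing:
            raise PanelSchemaError(f"missing record columns: {missing}")

        bad_arms = sorted(set(rec["arm"]) - set(ARMS))
        if bad_arms:
            raise PanelValidationError(
                f"unknown arm labels {bad_arms}; this study design has arms {ARMS}"
            )
        if (rec["day"] < 0).any():
            raise PanelValidationError("negative sampling day")

        known = set(schema_names(self.schema))
        unknown = sorted(set(rec["analyte"]) - known)
        if unknown:
            raise PanelValidationError(f"analytes absent from schema: {unknown}")

        dup = rec.duplicated(["subject_id", "day", "analyte"])
        if dup.any():
            first = rec.loc[dup, ["subject_id", "day", "analyte"]].iloc[0]
            raise PanelValidationError(
                "duplicate (subject, day, analyte) record: "
                f"({first.subject_id}, {first.day}, {first.analyte})"
            )

        if len(rec):
            day0 = set(rec.loc[rec["day"] == 0, "subject_id"])
            no_baseline = sorted(set(rec["subject_id"]) - day0)
            if no_baseline:
                raise PanelValidationError(
                    f"subjects without a day-0 baseline record: {no_baseline}"
                )

        lod = {a.name: a.lod for a in self.schema}
        flagged = rec[rec["below_lod"] & rec["value"].notna()]
        if len(flagged):
            limits = flagged["analyte"].map(lambda n: lod.get(n))
            bad_rows = limits.isna() | (flagged["value"] > limits.astype(float))
            if bad_rows.any():
                row = flagged[bad_rows].iloc[0]
                raise PanelValidationError(
                    f"below_lod record with value above LOD: "
                    f"({row.subject_id}, {row.day}, {row.analyte})"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def analyte_blocks(self) -> dict[str, Block]:
        return {a.name: a.block for a in self.schema}

    def sample_keys(self) -> list[tuple[str, int]]:
        """Distinct (subject_id, day) pairs in sorted order."""
        pairs = self.records[["subject_id", "day"]].drop_duplicates()
        return sorted(map(tuple, pairs.itertuples(index=False)))

    def arms_by_subject(self) -> dict[str, str]:
        return dict(
            self.records[["subject_id", "arm"]].drop_duplicates().itertuples(index=False)
        )


def _normalize_records(rec: pd.DataFrame) -> pd.DataFrame:
    rec = rec.copy().reset_index(drop=True)
    if "day" in rec.columns and len(rec):
        rec["day"] = rec["day"].astype(int)
    if "value" in rec.columns:
        rec["value"] = rec["value"].astype(float)
    if "below_lod" in rec.columns:
        rec["below_lod"] = rec["below_lod"].astype(bool)
    return rec


def _sorted_records(panel: LongitudinalPanel) -> pd.DataFrame:
    """Canonical record order: (subject, day, block, analyte)."""
    block_rank = {a.name: BLOCK_ORDER.index(a.block) for a in panel.schema}
    rec = panel.records.copy()
    rec["_block_rank"] = rec["analyte"].map(block_rank)
    rec = rec.sort_values(
        ["subject_id", "day", "_block_rank", "analyte"], kind="mergesort"
    )
    return rec.drop(columns="_block_rank").reset_index(drop=True)


def read_panel(path, schema: list[AnalyteDef]) -> LongitudinalPanel:
    """Read a long-format panel CSV and validate it against *schema*.

    Expected header: subject_id, arm, day, analyte, value, below_lod.
    Empty value cells encode absent (e.g. censored) measurements.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in RECORD_COLUMNS if c not in raw.columns]
    if missing:
        raise PanelSchemaError(f"panel CSV is missing columns: {missing}")

    # float() is correctly rounded (pd.to_numeric's fast parser is not, which
    # would break exact round-trips)
    parsed = []
    bad_rows = []
    for i, cell in enumerate(raw["value"]):
        if cell == "":
            parsed.append(np.nan)
            continue
        try:
            parsed.append(float(cell))
        except ValueError:
            parsed.append(np.nan)
            bad_rows.append(i + 2)  # 1-based incl. header
    if bad_rows:
        raise PanelParseError(f"non-numeric value cells at CSV line(s) {bad_rows[:5]}")
    values = pd.Series(parsed, index=raw.index, dtype=float)

    flag_map = {"true": True, "false": False, "1": True, "0": False, "": False}
    flags = raw["below_lod"].str.lower().map(flag_map)
    if flags.isna().any():
        rows = [i + 2 for i in raw.index[flags.isna()][:5]]
        raise PanelParseError(f"unparseable below_lod cells at CSV line(s) {rows}")

    try:
        days = raw["day"].astype(int)
    except ValueError as exc:
        raise PanelParseError(f"non-integer day column: {exc}") from None

    rec = pd.DataFrame(
        {
            "subject_id": raw["subject_id"],
            "arm": raw["arm"],
            "day": days,
            "analyte": raw["analyte"],
            "value": values.astype(float),
            "below_lod": flags.astype(bool),
        }
    )
    return LongitudinalPanel(schema=schema, records=rec)


def write_panel(panel: LongitudinalPanel, path) -> Path:
    """Write a panel CSV; deterministic record order, full float precision.

    ``read_panel(write_panel(p), p.schema)`` reproduces ``p`` exactly.
    """
    path = Path(path)
    rec = _sorted_records(panel)
    out = rec.copy()
    out["value"] = [
        "" if np.isnan(v) else np.format_float_positional(v, trim="0")
        for v in rec["value"]
    ]
    out["below_lod"] = np.where(rec["below_lod"], "true", "false")
    out.to_csv(path, index=False, encoding="utf-8")
    return path


def assign_classes(panel: LongitudinalPanel) -> dict[tuple[str, int], str]:
    """Map every (subject, day) sample to its class label.

    Day-0 samples of both arms are CONTROL (pre-treatment); later samples
    take their arm label. The result partitions the panel's samples.
    """
    arms = panel.arms_by_subject()
    return {
        (subject, day): CONTROL if day == 0 else arms[subject]
        for subject, day in panel.sample_keys()
    }


def lod_filter(
    panel: LongitudinalPanel, max_missing_frac: float = 0.5
) -> tuple[LongitudinalPanel, list[str]]:
    """Drop analytes dominated by censored/absent values; impute survivors.

    An analyte is dropped when its fraction of absent-or-below-LOD records
    exceeds ``max_missing_frac``. Surviving below-LOD records are imputed at
    LOD/2 (standard left-censoring convention); absent values for analytes
    without a defined LOD stay absent. Samples (rows) are never removed.
    """
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in [0, 1]")
    rec = panel.records
    censored = rec["below_lod"] | rec["value"].isna()
    frac = censored.groupby(rec["analyte"]).mean()
    dropped = sorted(frac.index[frac > max_missing_frac])

    keep = ~rec["analyte"].isin(dropped)
    new_rec = rec[keep].reset_index(drop=True)
    lod = {a.name: a.lod for a in panel.schema}
    impute = new_rec["below_lod"] & new_rec["value"].isna()
    if impute.any():
        fill = new_rec.loc[impute, "analyte"].map(
            lambda n: np.nan if lod.get(n) is None else lod[n] / 2.0
        )
        new_rec.loc[impute, "value"] = fill.astype(float)
        new_rec.loc[impute & new_rec["value"].notna(), "below_lod"] = True

    new_schema = [a for a in panel.schema if a.name not in dropped]
    return LongitudinalPanel(schema=new_schema, records=new_rec), dropped
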