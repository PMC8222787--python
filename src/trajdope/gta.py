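"""Geometric trajectory analysis (GTA).

GTA re-expresses every measurement as the deviation from the subject's own
pre-treatment baseline, in units of the population baseline SD of that
analyte::

    g_ijt = (x_ijt - x_ij0) / sigma_j,   sigma_j = SD over subjects of x_ij0

The transform has three consequences the pipeline relies on:

* every pre-treatment sample maps to exactly 0 (all control samples collapse
  to a single point in any downstream score plot);
* the output is dimensionless, so heterogeneous assay blocks can be fused;
* it is invariant to positive affine rescaling of any analyte's raw values,
  so unit conventions cannot alter classification.

The population SD is computed across subjects from day-0 values only; since
day 0 precedes any treatment, fitting it on the full cohort introduces no
train/test leakage in cross-validation.

When the design has several pre-treatment days, the subject baseline is
their average (real biological-passport data has repeated baselines); with a
single day 0 — the default — baseline rows are exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import CONTROL, LongitudinalPanel, PanelValidationError
from .schema import AnalyteDef


@dataclass
class BaselineStats:
    """Fitted per-analyte population SD and per-(subject, analyte) baseline."""

    sigma: "pd.Series"           # index: analyte
    baseline: "pd.DataFrame"     # index: subject_id, columns: analyte


@dataclass
class GtaPanel:
    """GTA-transformed panel: dimensionless baseline-SD deviations.

    ``records`` columns: subject_id, arm, day, analyte, value.
    """

    schema: list[AnalyteDef]
    records: pd.DataFrame

    def sample_keys(self):
        pairs = self.records[["subject_id", "day"]].drop_duplicates()
        return sorted(map(tuple, pairs.itertuples(index=False)))

    def arms_by_subject(self):
        return dict(
            self.records[["subject_id", "arm"]].drop_duplicates().itertuples(index=False)
        )


class GtaTransformer:
    """Baseline-anchored trajectory normalizer (fit on day-0, then transform).

    Parameters
    ----------
    baseline_days : days treated as pre-treatment; the subject baseline is
        their mean. Default ``(0,)``.
    sd_floor : optional floor substituted for a degenerate (zero) population
        SD. By default a constant baseline raises an error instead.

    Attributes (after fit)
    ----------------------
    baseline_stats_ : BaselineStats
    """

    def __init__(self, baseline_days=(0,), sd_floor: float | None = None):
        self.baseline_days = tuple(baseline_days)
        self.sd_floor = sd_floor

    def get_params(self, deep=True):
        return {"baseline_days": self.baseline_days, "sd_floor": self.sd_floor}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, panel: LongitudinalPanel) -> "GtaTransformer":
        rec = panel.records
        base = rec[rec["day"].isin(self.baseline_days)]
        wide = base.pivot_table(
            index="subject_id", columns="analyte", values="value", aggfunc="mean"
        )
        analytes = [a.name for a in panel.schema]
        wide = wide.reindex(columns=analytes)
        subjects = sorted(set(rec["subject_id"]))
        wide = wide.reindex(index=subjects)

        if wide.isna().any().any():
            stacked = wide.isna().stack()
            subj, anl = stacked.index[stacked.to_numpy()][0]
            raise PanelValidationError(
                f"missing baseline value for subject {subj!r}, analyte {anl!r}"
            )

        sigma = wide.std(axis=0, ddof=1)
        degenerate = ~(sigma > 0)
        if degenerate.any():
            if self.sd_floor is None:
                bad = sorted(sigma.index[degenerate])
                raise PanelValidationError(
                    f"degenerate (zero) baseline SD for analytes {bad}; "
                    "pass sd_floor to substitute a floor"
                )
            sigma = sigma.where(~degenerate, self.sd_floor)

        self.baseline_stats_ = BaselineStats(sigma=sigma, baseline=wide)
        return self

    def transform(self, panel: LongitudinalPanel) -> GtaPanel:
        stats = self.baseline_stats_
        rec = panel.records
        missing = sorted(set(rec["analyte"]) - set(stats.sigma.index))
        if missing:
            raise PanelValidationError(
                f"analytes absent from fitted baseline stats: {missing}"
            )
        base_long = stats.baseline.stack()
        keys = pd.MultiIndex.from_arrays([rec["subject_id"], rec["analyte"]])
        unknown = sorted(
            {s for s, _ in set(keys) if s not in stats.baseline.index}
        )
        if unknown:
            raise PanelValidationError(
                f"subjects absent from fitted baseline stats: {unknown}"
            )
        base_vals = base_long.reindex(keys).to_numpy()
        sig_vals = stats.sigma.reindex(rec["analyte"]).to_numpy()
        g = (rec["value"].to_numpy() - base_vals) / sig_vals

        out = rec[["subject_id", "arm", "day", "analyte"]].copy()
        out["value"] = g
        return GtaPanel(schema=list(panel.schema), records=out.reset_index(drop=True))

    def fit_transform(self, panel: LongitudinalPanel) -> GtaPanel:
        return self.fit(panel).transform(panel)


def fit_baseline_stats(panel: LongitudinalPanel, baseline_days=(0,)) -> BaselineStats:
    """Population baseline SD per analyte and per-subject baseline values."""
    return GtaTransformer(baseline_days=baseline_days).fit(panel).baseline_stats_


def gta_transform(panel: LongitudinalPanel, stats: BaselineStats) -> GtaPanel:
    """Apply a fitted baseline normalization to *panel*."""
    t = GtaTransformer()
    t.baseline_stats_ = stats
    return t.transform(panel)


def trend_summary(panel, grouping: str = "arm") -> pd.DataFrame:
    """Per-(group, day, analyte) mean / SD / n — the tabular trend bands.

    ``grouping="arm"`` groups by treatment arm; ``grouping="class"`` by the
    three-class label (day-0 samples pooled as CONTROL). Works on raw or
    GTA panels. Single-sample cells report sd = 0.
    """
    rec = panel.records
    if grouping == "arm":
        group = rec["arm"]
    elif grouping == "class":
        group = np.where(rec["day"] == 0, CONTROL, rec["arm"])
    else:
        raise ValueError("grouping must be 'arm' or 'class'")

    df = rec.assign(group=group)
    agg = (
        df.groupby(["analyte", "group", "day"], sort=True)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    agg.loc[agg["n"] == 1, "sd"] = 0.0
    return agg


def mean_trajectory_deviation(gta: GtaPanel, group_a, group_b) -> float:
    """Mean over analytes and days of |mean_a(g) - mean_b(g)|, in SD units.

    ``group_a`` / ``group_b`` are collections of (subject_id, day) sample
    keys; both must be non-empty and post-baseline (day > 0). Cells are
    (analyte, day) pairs present in both groups.
    """
    group_a, group_b = set(map(tuple, group_a)), set(map(tuple, group_b))
    if not group_a or not group_b:
        raise PanelValidationError("empty sample group")
    if any(day == 0 for _, day in group_a | group_b):
        raise PanelValidationError("trajectory deviation uses post-baseline samples only")

    rec = gta.records
    keys = list(zip(rec["subject_id"], rec["day"]))
    in_a = np.fromiter((k in group_a for k in keys), dtype=bool, count=len(keys))
    in_b = np.fromiter((k in group_b for k in keys), dtype=bool, count=len(keys))

    mean_a = rec[in_a].groupby(["analyte", "day"])["value"].mean()
    mean_b = rec[in_b].groupby(["analyte", "day"])["value"].mean()
    diff = (mean_a - mean_b).dropna().abs()
    if not len(diff):
        raise PanelValidationError("groups share no (analyte, day) cells")
    return float(diff.mean())


def write_gta(gta: GtaPanel, path) -> None:
    """Write a GTA panel CSV (subject_id, arm, day, analyte, value)."""
    rec = gta.records.sort_values(
        ["subject_id", "day", "analyte"], kind="mergesort"
    ).reset_index(drop=True)
    out = rec.copy()
    out["value"] = [
        "" if np.isnan(v) else np.format_float_positional(v, trim="0")
        for v in rec["value"]
    ]
    out.to_csv(path, index=False, encoding="utf-8")


def read_gta(path, schema) -> GtaPanel:
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    df["value"] = df["value"].astype(float)
    df["day"] = df["day"].astype(int)
    return GtaPanel(schema=list(schema), records=df)


def arm_deviation(gta: GtaPanel) -> float:
    """Between-arm mean trajectory deviation over post-baseline samples."""
    arms = gta.arms_by_subject()
    post = [(s, d) for s, d in gta.sample_keys() if d > 0]
    group_a = [k for k in post if arms[k[0]] == "EPO"]
    group_b = [k for k in post if arms[k[0]] == "EGH"]
    return mean_trajectory_deviation(gta, group_a, group_b)
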