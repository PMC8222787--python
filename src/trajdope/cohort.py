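"""Synthetic two-arm micro-dosing cohort generator.

Emulates the statistical structure of a two-week EPO vs EPO+rhGH
administration study: 7 male subjects per arm sampled at days 0, 4, 11 and
14, with 33 CBC parameters, 33 urinary steroids and the two serum GH
biomarkers measured at every timepoint.

Generative model (per subject *i*, analyte *j*, day *t*)::

    baseline   b_ij  = ref_mean_j * exp(eps_ij),  eps_ij ~ N(0, ln(1+ref_cv_j^2))
    value      x_ijt = b_ij + shift(arm_i, j, t) * sigma_j + eta_ijt
    noise      eta_ijt ~ N(0, (noise_cv_j * ref_mean_j)^2)

where ``sigma_j`` is the theoretical SD of an observed day-0 value
(log-normal baseline spread plus analytical noise), so a shift expressed in
"baseline SD units" is recovered unbiasedly by the downstream trajectory
normalization. Values are truncated at 0 after noise; censoring (value <=
LOD) is applied after generation. Treatment effects are additive on this SD
scale and zero at day 0 by construction.

Default effect trajectories encode the study's reported trends:

* reticulocyte indices rise in BOTH arms from day 4 (the EPO effect);
* the rhGH arm (EGH) shows lower WBC / neutrophil / monocyte levels, raised
  eosinophil and basophil fractions, a broad day-4 urinary steroid surge
  that is largely mitigated by day 11, and elevated IGF-I and P-III-NP;
* effect magnitudes are calibrated so that the mean between-arm trajectory
  deviation is about 0.3 baseline SD.

Randomness is counter-based: one global seed plus (arm, subject, analyte)
indices key an independent stream per subject-analyte series, so record
ordering or added analytes never perturb existing draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import ARMS, LongitudinalPanel, PanelValidationError
from .schema import (
    AnalyteDef,
    DEFAULT_CENSORED_STEROIDS,
    default_schema,
    schema_names,
)


@dataclass(frozen=True)
class EffectProfile:
    """Additive treatment effect for one (analyte, arm) trajectory.

    ``shift_by_day`` maps day -> shift in units of the analyte's baseline
    SD. Day 0 must map to 0 (or be absent): no pre-treatment effect.
    """

    analyte: str
    arm: str
    shift_by_day: dict[int, float]

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.shift_by_day.get(0, 0.0) != 0.0:
            raise ValueError(f"{self.analyte}: non-zero effect at day 0")

    def shift(self, day: int) -> float:
        return float(self.shift_by_day.get(day, 0.0))


@dataclass
class CohortDesign:
    """Parametric description of the simulated study."""

    n_subjects_per_arm: int = 7
    days: tuple[int, ...] = (0, 4, 11, 14)
    schema: list[AnalyteDef] = field(default_factory=default_schema)
    censored_analytes: tuple[str, ...] = ()
    effects: list[EffectProfile] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.days = tuple(int(d) for d in self.days)
        if self.n_subjects_per_arm < 1:
            raise ValueError("n_subjects_per_arm must be positive")
        if self.days[0] != 0 or any(
            b <= a for a, b in zip(self.days, self.days[1:])
        ):
            raise ValueError("days must be strictly increasing and start at 0")
        names = set(schema_names(self.schema))
        stray = sorted(set(self.censored_analytes) - names)
        if stray:
            raise ValueError(f"censored analytes absent from schema: {stray}")
        for eff in self.effects:
            if eff.analyte not in names:
                raise ValueError(f"effect on unknown analyte {eff.analyte!r}")


def baseline_sd(analyte: AnalyteDef) -> float:
    """Theoretical SD of an observed day-0 value for *analyte*.

    Log-normal between-subject spread plus additive analytical noise:
    ``ref_mean * sqrt(ref_cv^2 * (1 + ref_cv^2) + noise_cv^2)``.
    """
    cv2 = analyte.ref_cv**2
    return analyte.ref_mean * float(np.sqrt(cv2 * (1.0 + cv2) + analyte.noise_cv**2))


# --------------------------------------------------------------------------
# Default effect trajectories (shifts in baseline-SD units).

# EPO response, common to both arms: reticulocytosis building over the
# two weeks, with a late rise of immature fractions and hemoglobin.
_EPO_COMMON = {
    "RET%": {4: 1.2, 11: 1.8, 14: 2.0},
    "RET/": {4: 1.2, 11: 1.8, 14: 2.0},
    "IRF": {4: 0.8, 11: 1.2, 14: 1.2},
    "HFR": {4: 0.6, 11: 0.9, 14: 0.9},
    "MFR": {4: 0.4, 11: 0.6, 14: 0.6},
    "HBG": {11: 0.3, 14: 0.5},
    "HCT": {11: 0.25, 14: 0.4},
}

# rhGH-specific leukocyte redistribution in the EGH arm.
_EGH_LEUKO = {
    "WBC": {4: -0.9, 11: -0.7, 14: -0.6},
    "NEUT/": {4: -0.9, 11: -0.7, 14: -0.6},
    "MONO/": {4: -0.9, 11: -0.7, 14: -0.6},
    "NEUT%": {4: -0.7, 11: -0.55, 14: -0.45},
    "MONO%": {4: -0.7, 11: -0.55, 14: -0.45},
    "EO%": {4: 0.9, 11: 0.75, 14: 0.6},
    "BASO%": {4: 0.9, 11: 0.75, 14: 0.6},
    "EO/": {4: 0.7, 11: 0.55, 14: 0.45},
    "BASO/": {4: 0.7, 11: 0.55, 14: 0.45},
}

# Steroids with the clearest sustained between-arm difference.
_EGH_STEROIDS_STRONG = (
    "5β-androstanedione",
    "5α-androstanedione",
    "5β-androstane-3α,17α-diol",
    "17β-estradiol",
)
# Remaining steroids showing the day-4 surge mitigated by day 11.
_EGH_STEROIDS_SURGE = (
    "5β-androstane-3α,17β-diol",
    "5α-androstane-3β,17α-diol",
    "5β-DHT",
    "5α-DHT",
    "Androsterone",
    "Etiocholanolone",
    "5-androstene-3β,17α-diol",
    "DHEA",
    "5α-androstane-3α,17β-diol",
    "5α-androstane-3β,17β-diol",
    "17α-testosterone",
    "17β-testosterone",
    "Estrone",
    "Allopregnanolone",
    "5α-pregnane-3α,17α-diol-20-one",
)

_EGH_ONLY = {
    "IGF-I": {4: 1.6, 11: 1.3, 14: 1.1},
    "P-III-NP": {4: 1.1, 11: 0.9, 14: 0.7},
    "4-androstenedione": {4: -0.4, 11: -0.2, 14: -0.1},
    **_EGH_LEUKO,
    **{n: {4: 1.3, 11: 0.6, 14: 0.4} for n in _EGH_STEROIDS_STRONG},
    **{n: {4: 0.95, 11: 0.3, 14: 0.15} for n in _EGH_STEROIDS_SURGE},
}


def default_effects() -> list[EffectProfile]:
    effects = []
    for arm in ARMS:
        for analyte, shifts in _EPO_COMMON.items():
            effects.append(EffectProfile(analyte, arm, dict(shifts)))
    for analyte, shifts in _EGH_ONLY.items():
        effects.append(EffectProfile(analyte, "EGH", dict(shifts)))
    return effects


def default_design(seed: int = 0, effect_scale: float = 1.0) -> CohortDesign:
    """The study-emulating design: 2x7 subjects, 4 days, 68 analytes.

    ``effect_scale`` multiplies every treatment shift (1.0 = the calibrated
    defaults; 0.0 = a null cohort; 5.0 = a strongly separable cohort).
    """
    effects = default_effects()
    if effect_scale != 1.0:
        effects = [
            EffectProfile(
                e.analyte,
                e.arm,
                {d: s * effect_scale for d, s in e.shift_by_day.items()},
            )
            for e in effects
        ]
    schema = []
    for a in default_schema():
        if a.name in DEFAULT_CENSORED_STEROIDS:
            # LOD far above the plausible range: never detected.
            a = AnalyteDef(
                a.name, a.block, a.units, a.ref_mean * 1e3,
                a.ref_mean, a.ref_cv, a.noise_cv,
            )
        schema.append(a)
    return CohortDesign(
        n_subjects_per_arm=7,
        days=(0, 4, 11, 14),
        schema=schema,
        censored_analytes=tuple(DEFAULT_CENSORED_STEROIDS),
        effects=effects,
        seed=seed,
    )


def _series_rng(seed: int, arm_idx: int, subj_idx: int, analyte: str):
    key = zlib.crc32(analyte.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                                spawn_key=(arm_idx, subj_idx, key))
    return np.random.default_rng(ss)


def generate_cohort(design: CohortDesign) -> LongitudinalPanel:
    """Draw one longitudinal panel from *design*'s generative model."""
    effect = {(e.arm, e.analyte): e for e in design.effects}
    days = np.asarray(design.days)
    rows_subject, rows_arm, rows_day, rows_analyte = [], [], [], []
    values = []

    n_days = len(days)
    for arm_idx, arm in enumerate(ARMS):
        for subj_idx in range(design.n_subjects_per_arm):
            subject = f"{arm}{subj_idx + 1:03d}"
            for analyte in design.schema:
                rng = _series_rng(design.seed, arm_idx, subj_idx, analyte.name)
                sigma_ln = float(np.sqrt(np.log1p(analyte.ref_cv**2)))
                b = analyte.ref_mean * np.exp(rng.normal(0.0, sigma_ln))
                eta = rng.normal(0.0, analyte.noise_cv * analyte.ref_mean, n_days)
                prof = effect.get((arm, analyte.name))
                shifts = (
                    np.array([prof.shift(d) for d in days])
                    if prof is not None
                    else np.zeros(n_days)
                )
                x = np.maximum(b + shifts * baseline_sd(analyte) + eta, 0.0)
                rows_subject.extend([subject] * n_days)
                rows_arm.extend([arm] * n_days)
                rows_day.extend(days)
                rows_analyte.extend([analyte.name] * n_days)
                values.extend(x)

    rec = pd.DataFrame(
        {
            "subject_id": rows_subject,
            "arm": rows_arm,
            "day": rows_day,
            "analyte": rows_analyte,
            "value": np.asarray(values, dtype=float),
            "below_lod": False,
        }
    )
    # Censoring: applied after generation; censored values are stored as
    # absent (the panel CSV writes an empty cell for them).
    lod = {a.name: a.lod for a in design.schema if a.lod is not None}
    if lod:
        limits = rec["analyte"].map(lod)
        censored = limits.notna() & (rec["value"] <= limits.astype(float))
        rec.loc[censored, "below_lod"] = True
        rec.loc[censored, "value"] = np.nan
    return LongitudinalPanel(schema=list(design.schema), records=rec)


def inject_effect(
    panel: LongitudinalPanel,
    profile: EffectProfile,
    baseline_sd: dict[str, float] | float,
) -> LongitudinalPanel:
    """Additively shift matching (arm, day) values by shift x baseline SD.

    Exposes the generator's effect step for targeted tests; day-0 values are
    untouched by the EffectProfile invariant.
    """
    if profile.analyte not in schema_names(panel.schema):
        raise PanelValidationError(f"unknown analyte {profile.analyte!r}")
    sd = (
        baseline_sd[profile.analyte]
        if isinstance(baseline_sd, dict)
        else float(baseline_sd)
    )
    rec = panel.records.copy()
    mask = (rec["arm"] == profile.arm) & (rec["analyte"] == profile.analyte)
    add = rec.loc[mask, "day"].map(lambda d: profile.shift(int(d)) * sd)
    rec.loc[mask, "value"] = rec.loc[mask, "value"] + add
    return LongitudinalPanel(schema=list(panel.schema), records=rec)


# --------------------------------------------------------------------------
# Design (de)serialization

def write_design(design: CohortDesign, path) -> Path:
    path = Path(path)
    payload = {
        "format_version": 1,
        "n_subjects_per_arm": design.n_subjects_per_arm,
        "days": list(design.days),
        "seed": design.seed,
        "censored_analytes": list(design.censored_analytes),
        "schema": [
            {**asdict(a), "block": a.block.value} for a in design.schema
        ],
        "effects": [
            {
                "analyte": e.analyte,
                "arm": e.arm,
                "shift_by_day": {int(d): float(s) for d, s in e.shift_by_day.items()},
            }
            for e in design.effects
        ],
    }
    path.write_text(
        yaml.safe_dump(payload, sort_keys=False, allow_unicode=True),
        encoding="utf-8",
    )
    return path


def read_design(path) -> CohortDesign:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return CohortDesign(
        n_subjects_per_arm=payload["n_subjects_per_arm"],
        days=tuple(payload["days"]),
        schema=[AnalyteDef(**a) for a in payload["schema"]],
        censored_analytes=tuple(payload.get("censored_analytes", ())),
        effects=[
            EffectProfile(e["analyte"], e["arm"],
                          {int(d): float(s) for d, s in e["shift_by_day"].items()})
            for e in payload.get("effects", ())
        ],
        seed=payload.get("seed", 0),
    )
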