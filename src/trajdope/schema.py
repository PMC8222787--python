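"""Analyte schema for the longitudinal anti-doping biomarker panels.

Three measurement blocks are modeled:

* ``CBC`` -- the 33 parameters of an automated complete blood count
  (Sysmex-style erythrocyte, leukocyte, reticulocyte and platelet indices);
* ``STEROID`` -- a 33-analyte urinary steroidomics panel (androgens,
  estrogens and pregnanes quantified after deconjugation);
* ``ENDOCRINE`` -- the two serum growth-hormone biomarkers IGF-I and
  P-III-NP.

Every analyte carries population parameters used only by the synthetic
cohort generator: ``ref_mean`` and ``ref_cv`` describe the between-subject
baseline distribution, ``noise_cv`` the within-subject/analytical
repeatability. These are plausible adult-male reference-range stand-ins for
simulation, not measured study values; the downstream trajectory analysis is
invariant to them by construction (it is affine-invariant per analyte).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Optional


class Block(str, Enum):
    """Assay block an analyte belongs to."""

    CBC = "CBC"
    STEROID = "STEROID"
    ENDOCRINE = "ENDOCRINE"


BLOCK_ORDER = (Block.CBC, Block.STEROID, Block.ENDOCRINE)


@dataclass(frozen=True)
class AnalyteDef:
    """Definition of one measured analyte.

    Parameters
    ----------
    name : unique analyte name within a schema.
    block : assay block (CBC, STEROID or ENDOCRINE).
    units : measurement units (informational).
    lod : limit of detection in measurement units, or None when the assay
        has no relevant detection limit (e.g. cell counters).
    ref_mean, ref_cv : population baseline mean and between-subject
        coefficient of variation (synthesis only).
    noise_cv : within-subject / analytical coefficient of variation
        (synthesis only).
    """

    name: str
    block: Block
    units: str = ""
    lod: Optional[float] = None
    ref_mean: float = 1.0
    ref_cv: float = 0.2
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("analyte name must be non-empty")
        object.__setattr__(self, "block", Block(self.block))
        if self.lod is not None and self.lod < 0:
            raise ValueError(f"{self.name}: lod must be non-negative")
        if self.ref_mean <= 0:
            raise ValueError(f"{self.name}: ref_mean must be positive")
        for attr in ("ref_cv", "noise_cv"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{self.name}: {attr} must be non-negative")


def _cbc(name, units, ref_mean, ref_cv, noise_cv=0.05):
    return AnalyteDef(name, Block.CBC, units, None, ref_mean, ref_cv, noise_cv)


def _steroid(name, ref_mean, ref_cv=0.5, noise_cv=0.12, lod_frac=0.02):
    return AnalyteDef(
        name, Block.STEROID, "ng/mL", ref_mean * lod_frac, ref_mean, ref_cv, noise_cv
    )


# 33 CBC parameters as reported by automated hematology analyzers.
CBC_ANALYTES = (
    _cbc("WBC", "10^9/L", 6.3, 0.18),
    _cbc("RBC", "10^12/L", 5.0, 0.07, 0.03),
    _cbc("HBG", "g/dL", 15.0, 0.06, 0.03),
    _cbc("HCT", "%", 44.0, 0.06, 0.03),
    _cbc("MCV", "fL", 90.0, 0.05, 0.02),
    _cbc("MCHC", "g/dL", 34.0, 0.02, 0.01),
    _cbc("MCHT", "pg", 30.0, 0.04, 0.02),
    _cbc("PTL", "10^9/L", 250.0, 0.20),
    _cbc("RCDW_SD", "fL", 42.0, 0.07, 0.03),
    _cbc("RCDW_CV", "%", 13.0, 0.05, 0.03),
    _cbc("PDW", "fL", 12.0, 0.15, 0.06),
    _cbc("MPV", "fL", 10.5, 0.08, 0.03),
    _cbc("PCT", "%", 0.25, 0.20),
    _cbc("P-RGC", "%", 30.0, 0.25, 0.06),
    _cbc("NEUT%", "%", 55.0, 0.12),
    _cbc("NEUT/", "10^9/L", 3.5, 0.25, 0.06),
    _cbc("LYMPH%", "%", 32.0, 0.15),
    _cbc("LYMPH/", "10^9/L", 2.0, 0.25, 0.06),
    _cbc("MONO%", "%", 8.0, 0.20, 0.06),
    _cbc("MONO/", "10^9/L", 0.5, 0.25, 0.07),
    _cbc("EO%", "%", 2.5, 0.40, 0.08),
    _cbc("EO/", "10^9/L", 0.15, 0.45, 0.09),
    _cbc("BASO%", "%", 0.6, 0.35, 0.09),
    _cbc("BASO/", "10^9/L", 0.04, 0.40, 0.10),
    _cbc("IG%", "%", 0.3, 0.50, 0.15),
    _cbc("IGconc", "10^9/L", 0.02, 0.50, 0.15),
    _cbc("RET%", "%", 1.2, 0.30, 0.06),
    _cbc("RET/", "10^12/L", 0.06, 0.30, 0.06),
    _cbc("RET_He", "pg", 32.0, 0.05, 0.02),
    _cbc("IRF", "%", 8.0, 0.30, 0.08),
    _cbc("LFR", "%", 92.0, 0.03, 0.01),
    _cbc("MFR", "%", 6.0, 0.30, 0.08),
    _cbc("HFR", "%", 2.0, 0.40, 0.10),
)

# 33 urinary steroids. The five names in DEFAULT_CENSORED_STEROIDS are the
# analytes that never reach the limit of detection in the emulated study.
# Note: the study's discard list includes "17αOH-dihydroprogesterone", which
# has no exact counterpart in the assay catalogue; the closest catalogue
# entry, 5α-pregnane-17α-ol-3,20-dione, stands in for it here.
STEROID_ANALYTES = (
    _steroid("5β-androstane-3α,17α-diol", 45.0),
    _steroid("5β-androstane-3β,17α-diol", 8.0),
    _steroid("5α-androstane-3α,17α-diol", 15.0),
    _steroid("5β-androstane-3α,17β-diol", 60.0),
    _steroid("5β-androstane-3β,17β-diol", 6.0),
    _steroid("5α-androstane-3β,17α-diol", 12.0),
    _steroid("5α-androstane-3α,17β-diol", 55.0),
    _steroid("5α-androstane-3β,17β-diol", 10.0),
    _steroid("5β-DHT", 9.0),
    _steroid("5α-DHT", 11.0),
    _steroid("Epiandrosterone", 350.0),
    _steroid("Androsterone", 2400.0),
    _steroid("Etiocholanolone", 2100.0),
    _steroid("5-androstene-3α,17β-diol", 7.0),
    _steroid("5-androstene-3β,17α-diol", 25.0),
    _steroid("5-androstene-3β,17β-diol", 30.0),
    _steroid("5β-androstanedione", 70.0),
    _steroid("5α-androstanedione", 45.0),
    _steroid("DHEA", 60.0),
    _steroid("4-androstenedione", 12.0),
    _steroid("17α-testosterone", 35.0),
    _steroid("17β-testosterone", 40.0),
    _steroid("17α-estradiol", 2.0),
    _steroid("Estrone", 8.0),
    _steroid("17β-estradiol", 3.0),
    _steroid("Allopregnanolone", 25.0),
    _steroid("5α-pregnane-3α,17α-diol-20-one", 40.0),
    _steroid("5α-pregnane-17α-ol-3,20-dione", 14.0),
    _steroid("Pregnenolone", 30.0),
    _steroid("17α-hydroxy-pregnenolone", 45.0),
    _steroid("17α-hydroxy-progesterone", 60.0),
    _steroid("Progesterone", 5.0),
    _steroid("5α-pregnane-3,20-dione", 7.0),
)

ENDOCRINE_ANALYTES = (
    AnalyteDef("IGF-I", Block.ENDOCRINE, "ng/mL", None, 200.0, 0.25, 0.06),
    AnalyteDef("P-III-NP", Block.ENDOCRINE, "ng/mL", None, 7.0, 0.20, 0.07),
)

# Steroids fully below LOD in the emulated study (dropped by the LOD filter,
# leaving 28 retained steroids).
DEFAULT_CENSORED_STEROIDS = (
    "5β-androstane-3β,17α-diol",
    "5β-androstane-3β,17β-diol",
    "5-androstene-3α,17β-diol",
    "5α-pregnane-3,20-dione",
    "5α-pregnane-17α-ol-3,20-dione",
)


def default_schema() -> list[AnalyteDef]:
    """The full 68-analyte study schema (33 CBC + 33 steroid + 2 endocrine)."""
    return list(CBC_ANALYTES) + list(STEROID_ANALYTES) + list(ENDOCRINE_ANALYTES)


def schema_names(schema) -> list[str]:
    return [a.name for a in schema]


def validate_schema(schema) -> None:
    names = schema_names(schema)
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate analyte names in schema: {dupes}")


def write_schema(schema, path) -> Path:
    """Serialize a schema to JSON (list of analyte definitions)."""
    path = Path(path)
    payload = {
        "format_version": 1,
        "analytes": [
            {**asdict(a), "block": a.block.value} for a in schema
        ],
    }
    path.write_text(json.dumps(payload, indent=1, ensure_ascii=False) + "\n",
                    encoding="utf-8")
    return path


def read_schema(path) -> list[AnalyteDef]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    schema = [AnalyteDef(**a) for a in payload["analytes"]]
    validate_schema(schema)
    return schema
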