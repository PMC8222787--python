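"""Block matrices, low-level data fusion, and train-set column scaling.

Each assay block (CBC, steroidomics, endocrine) becomes a samples x features
matrix; low-level fusion is plain column-wise concatenation of blocks that
share an identical sample ordering. Class labels (CONTROL / EPO / EGH)
travel with the fused matrix.

Column scaling is unit-variance autoscaling (center to mean 0, scale to SD 1)
fitted on training rows only and applied unchanged to test rows; constant
columns get a scale floor of 1 so they contribute zeros after centering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gta import GtaPanel
from .panel import CONTROL, PanelValidationError
from .schema import Block

SCALE_FLOOR_TOL = 1e-12


@dataclass
class FeatureBlock:
    """One assay block as a numeric matrix with sample metadata."""

    name: str
    matrix: np.ndarray                  # samples x features
    sample_keys: list[tuple[str, int]]  # ordered (subject_id, day)
    feature_names: list[str]
    arms: list[str]                     # per-sample arm, parallel to sample_keys


@dataclass
class FusedMatrix:
    """Low-level fused samples x features matrix with class labels."""

    matrix: np.ndarray
    sample_keys: list[tuple[str, int]]
    class_labels: list[str]             # CONTROL / EPO / EGH per sample
    feature_names: list[str]            # block-prefixed, e.g. "CBC:WBC"
    feature_blocks: list[str]           # block tag per feature

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def block_to_matrix(gta: GtaPanel, block) -> FeatureBlock:
    """Pivot one block of a GTA panel into a samples x features matrix.

    Rows are ordered by (subject_id, day); columns follow schema order.
    Missing cells are imputed by their (class-blind) column mean.
    """
    block = Block(block)
    analytes = [a.name for a in gta.schema if a.block == block]
    if not analytes:
        raise PanelValidationError(f"no retained analytes in block {block.value}")

    rec = gta.records[gta.records["analyte"].isin(analytes)]
    wide = rec.pivot_table(
        index=["subject_id", "day"], columns="analyte", values="value",
        aggfunc="first", dropna=False,
    )
    wide = wide.reindex(columns=analytes).sort_index()
    m = wide.to_numpy(dtype=float)
    # column-mean imputation for stray missing values
    col_mean = np.nanmean(m, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(m))
    m[nan_rows, nan_cols] = col_mean[nan_cols]

    keys = [(s, int(d)) for s, d in wide.index]
    arms = gta.arms_by_subject()
    return FeatureBlock(
        name=block.value,
        matrix=m,
        sample_keys=keys,
        feature_names=analytes,
        arms=[arms[s] for s, _ in keys],
    )


def fuse(blocks: list[FeatureBlock]) -> FusedMatrix:
    """Concatenate feature blocks column-wise (low-level fusion)."""
    if not blocks:
        raise PanelValidationError("fuse requires at least one block")
    ref = blocks[0]
    for b in blocks[1:]:
        if b.sample_keys != ref.sample_keys:
            offender = next(
                (x for x, y in zip(b.sample_keys, ref.sample_keys) if x != y),
                b.sample_keys[min(len(ref.sample_keys), len(b.sample_keys) - 1)]
                if b.sample_keys else None,
            )
            raise PanelValidationError(
                f"sample keys differ between blocks {ref.name} and {b.name}; "
                f"first mismatch: {offender}"
            )
    matrix = np.hstack([b.matrix for b in blocks])
    names = [f"{b.name}:{f}" for b in blocks for f in b.feature_names]
    tags = [b.name for b in blocks for _ in b.feature_names]
    arms = dict(zip([s for s, _ in ref.sample_keys], ref.arms))
    labels = [
        CONTROL if day == 0 else arm
        for (subject, day), arm in zip(ref.sample_keys, ref.arms)
    ]
    return FusedMatrix(
        matrix=matrix,
        sample_keys=list(ref.sample_keys),
        class_labels=labels,
        feature_names=names,
        feature_blocks=tags,
    )


class ColumnScaler:
    """Unit-variance column autoscaler with a constant-column floor.

    Fitted on training rows only; ``transform`` never re-estimates, so test
    matrices keep any shift relative to the training distribution.
    """

    def __init__(self, scale_floor: float = 1.0):
        self.scale_floor = scale_floor

    def get_params(self, deep=True):
        return {"scale_floor": self.scale_floor}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray) -> "ColumnScaler":
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise PanelValidationError("cannot fit scaler on an empty matrix")
        self.center_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        self.scale_ = np.where(sd > SCALE_FLOOR_TOL, sd, self.scale_floor)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def fit_scaler(train: FusedMatrix) -> ColumnScaler:
    return ColumnScaler().fit(train.matrix)


def apply_scaler(scaler: ColumnScaler, m: FusedMatrix) -> FusedMatrix:
    return FusedMatrix(
        matrix=scaler.transform(m.matrix),
        sample_keys=list(m.sample_keys),
        class_labels=list(m.class_labels),
        feature_names=list(m.feature_names),
        feature_blocks=list(m.feature_blocks),
    )


# --------------------------------------------------------------------------
# Fused-matrix CSV I/O (subject_id, day, label columns + one column per feature)

def write_fused(m: FusedMatrix, path) -> None:
    df = pd.DataFrame(m.matrix, columns=m.feature_names)
    df.insert(0, "label", m.class_labels)
    df.insert(0, "day", [d for _, d in m.sample_keys])
    df.insert(0, "subject_id", [s for s, _ in m.sample_keys])
    df.to_csv(path, index=False, encoding="utf-8",
              float_format=None)


def read_fused(path) -> FusedMatrix:
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    meta = ["subject_id", "day", "label"]
    features = [c for c in df.columns if c not in meta]
    tags = [f.split(":", 1)[0] for f in features]
    return FusedMatrix(
        matrix=df[features].to_numpy(dtype=float),
        sample_keys=[(s, int(d)) for s, d in zip(df["subject_id"], df["day"])],
        class_labels=list(df["label"]),
        feature_names=features,
        feature_blocks=tags,
    )
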