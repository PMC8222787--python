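"""Monte Carlo cross-validation, ROC/accuracy metrics, and a permutation null.

MCCV repeatedly draws a stratified random train/test split of the fused
matrix, fits the column scaler and the OPLS-DA ensemble on the training rows
only, scores the held-out rows, and pools all test predictions across
repetitions before computing per-class AUROCs (one-vs-rest), their unweighted
mean ("overall" AUROC), pooled accuracy and the confusion matrix. The
baseline normalization upstream uses only pre-treatment samples, so fitting
it on the full cohort leaks nothing.

Splitting can be done at the sample level (a subject's timepoints may fall
on both sides — mirrors pooled-sample analyses) or at the subject level
(all of a subject's samples stay together — the honest generalization
estimate for longitudinal data; see the methods note).

AUROC uses the Mann-Whitney rank formulation with ties counted 1/2. The
permutation null re-runs the full MCCV with permuted class labels and
reports the add-one empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix as _sk_confusion

from .fusion import ColumnScaler, FusedMatrix
from .opls import OplsDaClassifier


class MetricInputError(ValueError):
    """Invalid input to a metric (e.g. single-class AUROC)."""


class SplitError(RuntimeError):
    """A valid train/test split could not be drawn."""


@dataclass
class MccvConfig:
    """Monte Carlo cross-validation settings."""

    n_reps: int = 100
    test_fraction: float = 1.0 / 3.0
    stratified: bool = True
    split_unit: str = "subject"  # "subject" keeps a subject's timepoints
    # together across the split; "sample" mirrors pooled-sample analyses but
    # leaks subject identity through the shared baseline term of GTA values
    # (see the methods note) and is kept for comparison only.
    seed: int = 0
    max_redraws: int = 50

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.split_unit not in ("sample", "subject"):
            raise ValueError("split_unit must be 'sample' or 'subject'")


@dataclass
class MccvReport:
    """Pooled MCCV result."""

    predictions: pd.DataFrame  # rep, subject_id, day, true, assigned, score:<class>...
    per_class_auroc: dict[str, float]
    overall_auroc: float
    accuracy: float
    confusion: pd.DataFrame    # rows = true classes, cols = assigned
    classes: list[str]
    config: MccvConfig
    n_redraws: int = 0

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "classes": self.classes,
            "per_class_auroc": self.per_class_auroc,
            "overall_auroc": self.overall_auroc,
            "accuracy": self.accuracy,
            "confusion": self.confusion.to_dict(),
            "config": asdict(self.config),
            "n_redraws": self.n_redraws,
        }


@dataclass
class PermutationNull:
    n_perm: int
    observed_auroc: float
    null_aurocs: np.ndarray
    p_value: float


def auroc(scores, is_positive) -> float:
    """Mann-Whitney AUROC of *scores* against boolean positivity; ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(is_positive, dtype=bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricInputError("AUROC needs at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks: ties count 1/2
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def confusion_accuracy(true, assigned, classes=None):
    """Confusion matrix (rows = true classes) and pooled accuracy."""
    true = np.asarray(true)
    assigned = np.asarray(assigned)
    if len(true) != len(assigned):
        raise MetricInputError("label vectors differ in length")
    if len(true) == 0:
        raise MetricInputError("no samples")
    if classes is None:
        classes = sorted(set(true.tolist()) | set(assigned.tolist()))
    m = _sk_confusion(true, assigned, labels=classes)
    cm = pd.DataFrame(m, index=classes, columns=classes)
    return cm, float(np.trace(m) / m.sum())


def _draw_split(fused: FusedMatrix, config: MccvConfig, rng):
    """One train/test index split; raises SplitError if a class is untrainable."""
    labels = np.asarray(fused.class_labels)
    n = len(labels)
    if config.split_unit == "subject":
        subjects = np.asarray([s for s, _ in fused.sample_keys])
        uniq = sorted(set(subjects.tolist()))
        # stratify subjects by arm (a subject's post-baseline class)
        subj_arm = {}
        for (s, day), lab in zip(fused.sample_keys, labels):
            if day > 0:
                subj_arm[s] = lab
        test_subjects = []
        if config.stratified:
            arms = sorted(set(subj_arm.values()))
            for arm in arms:
                members = [s for s in uniq if subj_arm.get(s) == arm]
                k = max(1, int(round(config.test_fraction * len(members))))
                if k >= len(members):
                    k = len(members) - 1
                if k < 1:
                    raise SplitError(
                        f"cannot split arm {arm!r} with {len(members)} subject(s)"
                    )
                test_subjects.extend(rng.choice(members, size=k, replace=False))
        else:
            k = max(1, int(round(config.test_fraction * len(uniq))))
            test_subjects = rng.choice(uniq, size=k, replace=False)
        test_mask = np.isin(subjects, list(test_subjects))
    else:
        idx = np.arange(n)
        test_mask = np.zeros(n, dtype=bool)
        if config.stratified:
            for cls in sorted(set(labels.tolist())):
                members = idx[labels == cls]
                k = max(1, int(round(config.test_fraction * len(members))))
                if k >= len(members):
                    raise SplitError(
                        f"class {cls!r} has too few samples ({len(members)}) "
                        "for a stratified split"
                    )
                test_mask[rng.choice(members, size=k, replace=False)] = True
        else:
            k = max(1, int(round(config.test_fraction * n)))
            test_mask[rng.choice(idx, size=k, replace=False)] = True

    train_mask = ~test_mask
    if set(labels[train_mask].tolist()) != set(labels.tolist()):
        raise SplitError("a class is missing from the training split")
    return train_mask, test_mask


def mccv_run(
    fused: FusedMatrix,
    config: MccvConfig,
    n_orth: int = 1,
    scale_on: str = "train",
) -> MccvReport:
    """Monte Carlo cross-validation of scaler + OPLS-DA on a fused matrix.

    Per repetition the scaler and ensemble see training rows only; test
    predictions are pooled across repetitions. Deterministic given
    ``config.seed``; per-repetition RNG streams are counter-derived, so
    changing ``n_reps`` does not reshuffle earlier repetitions.

    ``scale_on="all"`` deliberately fits the column scaler on all rows
    (train + test). It exists only to demonstrate information leakage in
    tests and must not be used for reported results.
    """
    if scale_on not in ("train", "all"):
        raise ValueError("scale_on must be 'train' or 'all'")
    labels = np.asarray(fused.class_labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise MetricInputError("MCCV needs at least two classes")

    rows = []
    n_redraws = 0
    for rep in range(config.n_reps):
        attempt = 0
        while True:
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    entropy=int(config.seed) & 0x7FFFFFFF,
                    spawn_key=(rep, attempt),
                )
            )
            try:
                train_mask, test_mask = _draw_split(fused, config, rng)
                break
            except SplitError:
                attempt += 1
                n_redraws += 1
                if attempt > config.max_redraws:
                    raise SplitError(
                        f"no valid split after {config.max_redraws} redraws "
                        f"(repetition {rep})"
                    ) from None

        fit_rows = fused.matrix if scale_on == "all" else fused.matrix[train_mask]
        scaler = ColumnScaler().fit(fit_rows)
        model = OplsDaClassifier(n_orthogonal=n_orth).fit(
            scaler.transform(fused.matrix[train_mask]), labels[train_mask]
        )
        X_test = scaler.transform(fused.matrix[test_mask])
        scores = model.decision_function(X_test)
        assigned = model.predict(X_test)

        test_idx = np.nonzero(test_mask)[0]
        for i, row_idx in enumerate(test_idx):
            subject, day = fused.sample_keys[row_idx]
            row = {
                "rep": rep,
                "subject_id": subject,
                "day": day,
                "true": labels[row_idx],
                "assigned": assigned[i],
            }
            for j, cls in enumerate(model.classes_):
                row[f"score:{cls}"] = scores[i, j]
            rows.append(row)

    pred = pd.DataFrame(rows)
    per_class = {
        cls: auroc(pred[f"score:{cls}"], pred["true"] == cls) for cls in classes
    }
    cm, acc = confusion_accuracy(pred["true"], pred["assigned"], classes)
    return MccvReport(
        predictions=pred,
        per_class_auroc=per_class,
        overall_auroc=float(np.mean(list(per_class.values()))),
        accuracy=acc,
        confusion=cm,
        classes=classes,
        config=config,
        n_redraws=n_redraws,
    )


def permutation_null(
    fused: FusedMatrix, config: MccvConfig, n_perm: int, n_orth: int = 1
) -> PermutationNull:
    """Label-permutation null distribution of the pooled overall AUROC."""
    if n_perm < 1:
        raise MetricInputError("n_perm must be at least 1")
    observed = mccv_run(fused, config, n_orth=n_orth).overall_auroc
    labels = np.asarray(fused.class_labels)
    nulls = np.empty(n_perm)
    for i in range(n_perm):
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=int(config.seed) & 0x7FFFFFFF, spawn_key=(7001, i)
            )
        )
        if config.split_unit == "subject":
            # the exchangeable units are subjects: permute each subject's
            # label block so per-subject label consistency is preserved
            subjects = [s for s, _ in fused.sample_keys]
            uniq = sorted(set(subjects))
            subj_labels = {}
            for (s, _d), lab in zip(fused.sample_keys, labels):
                subj_labels.setdefault(s, []).append(lab)
            shuffled = dict(zip(uniq, rng.permutation(uniq)))
            counters = {s: 0 for s in uniq}
            perm_labels = []
            for s in subjects:
                src = shuffled[s]
                perm_labels.append(subj_labels[src][counters[src] % len(subj_labels[src])])
                counters[src] += 1
        else:
            perm_labels = list(rng.permutation(labels))
        perm = FusedMatrix(
            matrix=fused.matrix,
            sample_keys=list(fused.sample_keys),
            class_labels=perm_labels,
            feature_names=list(fused.feature_names),
            feature_blocks=list(fused.feature_blocks),
        )
        nulls[i] = mccv_run(perm, config, n_orth=n_orth).overall_auroc
    p = float((1 + np.sum(nulls >= observed)) / (n_perm + 1))
    return PermutationNull(
        n_perm=n_perm, observed_auroc=observed, null_aurocs=nulls, p_value=p
    )
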