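"""Cohort-level training and evaluation protocol.

Runs the reference evaluation protocol at any scale: train a variant with the
Dice-loss/Adam recipe on the training patients, then report the mean
per-image Dice over two test groups — "normal" (the held-out patients'
slices untouched) and "augmented" (the same slices expanded through the
full flip x 15°-rotation grid, 40x more images).  Augmentation for the
augmented group is applied to test patients only, after the split, so no
transformed copy of a test slice can have influenced training.
:func:`compare_variants` replicates the reference comparison-table layout
(variants x filter schedules x test groups) on phantom cohorts with
seed-replicated medians.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .metrics import auxiliary_metrics, dice_coefficient
from .model import TrainHistory, WNetSegmenter
from .pipeline import (
    AugmentationConfig,
    SplitManifest,
    augment,
    records_to_arrays,
    split_patients,
)

__all__ = [
    "TrainConfig",
    "EvalReport",
    "LeakageError",
    "train",
    "evaluate",
    "audit_no_leakage",
    "compare_variants",
    "summarize_comparison",
]


class LeakageError(RuntimeError):
    """A test patient's slice appeared in a training/validation set."""


@dataclass(frozen=True)
class TrainConfig:
    """Training recipe; defaults are the full-scale reference settings.

    10 epochs of Adam at learning rate 1e-5 with batchwise Dice loss,
    dropout 0.5 / 0.4 on contracting / expanding paths.  Desk-scale runs
    override filters, input size, learning rate and epochs.
    """

    variant: str = "compound"
    base_filters: int = 64
    input_size: int = 256
    levels: int = 5
    learning_rate: float = 1e-5
    epochs: int = 10
    batch_size: int = 8
    dropout_contracting: float = 0.5
    dropout_expanding: float = 0.4
    smooth: float = 1.0
    relu_levels: tuple = (4, 5)
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("rates and counts must be positive")
        for rate in (self.dropout_contracting, self.dropout_expanding):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"dropout rate {rate} outside [0, 1)")

    def make_estimator(self) -> WNetSegmenter:
        return WNetSegmenter(**asdict(self))


@dataclass
class EvalReport:
    """Per-image and aggregated Dice for one named test group."""

    group: str
    model_id: str
    per_image_dice: list
    aux: list = field(default_factory=list)

    @property
    def mean_dice(self) -> float:
        return float(np.mean(self.per_image_dice))

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for i, d in enumerate(self.per_image_dice):
            row = {"image_id": i, "group": self.group, "dice": d}
            if self.aux:
                row.update(self.aux[i])
            rows.append(row)
        return pd.DataFrame(rows)


def audit_no_leakage(train_records, val_records, manifest: SplitManifest) -> None:
    """Assert no slice of a test patient reached training or validation."""
    test = set(manifest.test_patients)
    for name, records in (("training", train_records), ("validation", val_records)):
        leaked = sorted({r.patient_id for r in records} & test)
        if leaked:
            raise LeakageError(
                f"test patients {leaked} found in the {name} set"
            )


def train(records, manifest: SplitManifest, config: TrainConfig) -> tuple:
    """Fit ``config`` on the manifest's training patients.

    Returns ``(model, history)``; validation-patient Dice is logged per
    epoch.  Raises :class:`LeakageError` before the first step if any test
    patient's slice is present in the training or validation sets.
    """
    train_recs = [r for r in records if r.patient_id in manifest.train_patients]
    val_recs = [r for r in records if r.patient_id in manifest.val_patients]
    if not train_recs:
        raise ValueError("no training records for this manifest")
    audit_no_leakage(train_recs, val_recs, manifest)
    X, y = records_to_arrays(train_recs)
    val = records_to_arrays(val_recs) if val_recs else None
    model = config.make_estimator()
    model.fit(X, y, validation_data=val)
    return model, model.history_


def evaluate(
    model: WNetSegmenter,
    test_records,
    group: str = "normal",
    augmentation: AugmentationConfig | None = None,
    with_aux: bool = True,
) -> EvalReport:
    """Mean per-image Dice on a test group.

    ``group="normal"`` scores the records as given; ``group="augmented"``
    first expands them through the flip/rotation grid (default
    :class:`AugmentationConfig`, 40 variants per slice).
    """
    test_records = list(test_records)
    if not test_records:
        raise ValueError("empty test set")
    if group == "augmented":
        test_records = augment(test_records, augmentation or AugmentationConfig())
    elif group != "normal":
        raise ValueError(f"unknown test group {group!r}")
    X, y = records_to_arrays(test_records)
    probs = model.predict_proba(X)
    dices, aux = [], []
    for p, t in zip(probs, y[:, 0]):
        dices.append(dice_coefficient(p, t, threshold=model.threshold))
        if with_aux:
            aux.append(auxiliary_metrics(p, t, threshold=model.threshold))
    model_id = f"{model.variant}-{model.base_filters}x{model.input_size}"
    return EvalReport(group=group, model_id=model_id,
                      per_image_dice=dices, aux=aux)


def compare_variants(
    cohort,
    variants=("unet", "original_bridge", "modified_bridge", "compound"),
    base_filters=(4,),
    seeds=(0, 1, 2),
    test_ids=None,
    val_count: int = 4,
    config: TrainConfig | None = None,
    groups=("normal", "augmented"),
) -> pd.DataFrame:
    """Train every (variant, schedule, seed) cell on one shared split.

    All cells share the cohort and the patient split (test defaults to the
    two highest patient ids, echoing held-out patients 5 and 20 in the
    20-patient design).  Returns a tidy frame with one row per
    (variant, base_filters, seed, group); aggregate with
    :func:`summarize_comparison`.
    """
    cohort = list(cohort)
    patients = sorted({r.patient_id for r in cohort})
    if test_ids is None:
        test_ids = patients[-2:]
    base = config or TrainConfig()
    size = cohort[0].image.shape[0]
    manifest = split_patients(patients, test_ids, val_count, seed=base.seed)
    test_recs = [r for r in cohort if r.patient_id in manifest.test_patients]
    rows = []
    for bf in base_filters:
        for variant in variants:
            for seed in seeds:
                cfg_kwargs = asdict(base)
                cfg_kwargs.update(
                    variant=variant, base_filters=bf, input_size=size, seed=seed
                )
                cfg = TrainConfig(**cfg_kwargs)
                model, _ = train(cohort, manifest, cfg)
                for group in groups:
                    report = evaluate(model, test_recs, group=group,
                                      with_aux=False)
                    rows.append(
                        {
                            "variant": variant,
                            "base_filters": bf,
                            "seed": seed,
                            "group": group,
                            "mean_dice": report.mean_dice,
                            "n_images": len(report.per_image_dice),
                        }
                    )
    return pd.DataFrame(rows)


def summarize_comparison(results: pd.DataFrame) -> pd.DataFrame:
    """Median over seeds, shaped variants x (schedule, group) like the
    reference comparison table."""
    return results.pivot_table(
        index="variant", columns=["base_filters", "group"],
        values="mean_dice", aggfunc="median",
    )
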