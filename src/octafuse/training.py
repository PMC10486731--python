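"""Patient-level dataset splitting, augmentation and the training loop.

Splitting follows the clinical protocol: the test set is drawn only from
patients whose every eye carries both acquisitions (so every fusion variant
can be scored on the identical eyes), and the remaining patients are dealt
into five cross-validation folds stratified by their worst-eye grade so each
fold approximately preserves the cohort severity distribution.  All splits
are at the patient level — both eyes of a patient always land on the same
side of every boundary.

Training uses one random crop per example per epoch, mild augmentation
(random gamma, Gaussian noise, lateral flips — never depth flips, the retina
is oriented), unweighted 6-class cross-entropy, Adam at 1e-4 with per-epoch
exponential decay (gamma 0.99), batch size 2, and checkpoint selection on
the validation mean of AUC0..AUC3 (kappa as tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .evaluate import (EyePrediction, aggregate_severest, evaluate_model,
                       predict_eye_center)
from .preprocess import center_crop, random_crop
from .synthetic import ACQUISITIONS, ValidationError

N_FOLDS = 5


@dataclass
class SplitPlan:
    test_patient_ids: list
    fold_assignments: dict              # patient_id -> fold in 0..4
    seed: int

    def fold_patients(self, fold: int) -> list:
        return sorted(p for p, f in self.fold_assignments.items() if f == fold)


@dataclass
class AugmentConfig:
    gamma: bool = True
    noise: bool = True
    flip: bool = True
    gamma_range: tuple = (0.7, 1.5)
    noise_sigma: float = 0.02           # fraction of the dynamic range
    flip_prob: float = 0.5              # per lateral axis


@dataclass
class TrainConfig:
    lr: float = 1e-4
    lr_decay_gamma: float = 0.99
    epochs: int = 50
    batch_size: int = 2
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    patch_shape: tuple = (56, 56, 56, 2)
    seed: int = 0
    val_every: int = 5

    def validate(self) -> None:
        if self.lr <= 0:
            raise ValidationError("lr must be positive")
        if not 0 < self.lr_decay_gamma <= 1:
            raise ValidationError("lr_decay_gamma must lie in (0, 1]")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _patients(cohort) -> dict:
    by_pid: dict = {}
    for eye in cohort:
        by_pid.setdefault(eye.patient_id, []).append(eye)
    return by_pid


def _fully_paired(eyes) -> bool:
    return all(set(ACQUISITIONS) <= set(e.volumes) for e in eyes)


def split_dataset(cohort, seed: int, test_fraction: float = 0.12) -> SplitPlan:
    """Patient-level test/fold split; test patients are fully paired."""
    if not cohort:
        raise ValidationError("cohort is empty")
    by_pid = _patients(cohort)
    rng = np.random.default_rng(seed)
    n_test = max(1, round(test_fraction * len(by_pid)))
    eligible = sorted(p for p, eyes in by_pid.items() if _fully_paired(eyes))
    if len(eligible) < n_test:
        raise ValidationError(
            f"need {n_test} fully paired patients for the test set but only "
            f"{len(eligible)} of {len(by_pid)} have both acquisitions in every eye")
    test_ids = sorted(rng.choice(eligible, size=n_test, replace=False).tolist())

    remaining = sorted(set(by_pid) - set(test_ids))
    worst = {p: max(e.grade for e in by_pid[p]) for p in remaining}
    folds: dict = {}
    counts = np.zeros(N_FOLDS, dtype=np.int64)
    for grade in range(6):
        group = [p for p in remaining if worst[p] == grade]
        rng.shuffle(group)
        for p in group:
            f = int(counts.argmin())
            folds[p] = f
            counts[f] += 1
    return SplitPlan(test_patient_ids=test_ids, fold_assignments=folds, seed=seed)


def build_task_subsets(cohort, task: str):
    """Eyes possessing the acquisitions a task requires.

    ``task`` is 'hr6' or 'uwf15' for single-acquisition fusion (any eye with
    that scan) or 'paired' for cross-acquisition fusion (matched pairs only).
    """
    if task == "paired":
        return [e for e in cohort if set(ACQUISITIONS) <= set(e.volumes)]
    if task in ACQUISITIONS:
        return [e for e in cohort if task in e.volumes]
    raise ValidationError(f"unknown task {task!r}")


def leakage_check(plan: SplitPlan) -> None:
    overlap = set(plan.test_patient_ids) & set(plan.fold_assignments)
    if overlap:
        raise ValidationError(f"patients in both test set and folds: {sorted(overlap)}")


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment_patch(patch: np.ndarray, rng: np.random.Generator,
                  cfg: AugmentConfig) -> np.ndarray:
    """Random gamma, additive Gaussian noise and lateral flips.

    Operates on an (X, Y, Z, C) patch with nonnegative intensities.  Depth
    (axis 1) is never flipped: the retina has a fixed inner-to-outer
    orientation that flipping would destroy.
    """
    out = patch
    if cfg.gamma:
        g = rng.uniform(*cfg.gamma_range)
        scale = float(out.max())
        if scale > 0:
            out = ((np.clip(out, 0, None) / scale) ** g * scale).astype(np.float32)
    if cfg.noise and cfg.noise_sigma > 0:
        rng_range = float(out.max() - out.min()) or 1.0
        out = out + (cfg.noise_sigma * rng_range) * \
            rng.standard_normal(out.shape).astype(np.float32)
    if cfg.flip:
        for axis in (0, 2):             # lateral axes only
            if rng.uniform() < cfg.flip_prob:
                out = np.flip(out, axis=axis)
    return np.ascontiguousarray(out, dtype=np.float32)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _to_input(patch: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(patch.transpose(3, 0, 1, 2))


def _make_batch(items, idx, cfg, rng):
    """Random-crop and augment the selected examples; returns (x, y).

    An item is ``(volume, grade)`` for single-acquisition models or
    ``({acq: volume, ...}, grade)`` for cross-acquisition models (cropped
    independently per acquisition — the pair is unregistered).
    """
    xs, ys = [], []
    multi = isinstance(items[idx[0]][0], dict)
    for i in idx:
        vol, grade = items[i]
        if multi:
            sample = tuple(
                _to_input(augment_patch(
                    random_crop(vol[acq], cfg.patch_shape, rng).data, rng,
                    cfg.augment))
                for acq in sorted(vol))
        else:
            patch = random_crop(vol, cfg.patch_shape, rng).data
            sample = _to_input(augment_patch(patch, rng, cfg.augment))
        xs.append(sample)
        ys.append(grade)
    y = np.asarray(ys, dtype=np.int64)
    if multi:
        x = tuple(np.stack([s[j] for s in xs]) for j in range(len(xs[0])))
    else:
        x = np.stack(xs)
    return x, y


def _validation_metric(model, val_items, patch_shape):
    """Mean AUC over defined tasks from deterministic center-crop predictions."""
    preds, labels = [], []
    multi = val_items and isinstance(val_items[0][0], dict)
    for vol, grade in val_items:
        if multi:
            patches = tuple(_to_input(center_crop(vol[acq], patch_shape).data)[None]
                            for acq in sorted(vol))
            probs = model.predict_proba(patches)
            p, s, g = aggregate_severest(list(probs))
            preds.append(EyePrediction(probs, p, s, g))
        else:
            preds.append(predict_eye_center(model, vol, patch_shape))
        labels.append(grade)
    report = evaluate_model(preds, labels)
    mean_auc = report.mean_auc if not np.all(np.isnan(report.auc)) else 0.0
    kappa = report.kappa if np.isfinite(report.kappa) else 0.0
    return mean_auc, kappa


def train_model(model, train_items, cfg: TrainConfig, val_items=None):
    """Train with per-epoch random crops; return (model, history).

    The best checkpoint (validation mean AUC0..AUC3, kappa tie-break) is
    restored into the model before returning; the test set is never touched
    here.  Raises on divergence (non-finite loss).
    """
    cfg.validate()
    if not train_items:
        raise ValidationError("training dataset is empty")
    rng = np.random.default_rng(cfg.seed)
    optimizer = nn.Adam(model.parameters(), lr=cfg.lr)
    scheduler = nn.ExponentialLR(optimizer, cfg.lr_decay_gamma)
    history = {"loss": [], "lr": [], "val_metric": [], "val_epochs": []}
    best = (-np.inf, -np.inf)
    best_state = None

    n = len(train_items)
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x, y = _make_batch(train_items, idx, cfg, rng)
            model.zero_grad()
            loss = model.training_loss(x, y)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data!r}")
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        history["loss"].append(float(np.mean(losses)))
        history["lr"].append(optimizer.lr)
        scheduler.step()

        if val_items and ((epoch + 1) % cfg.val_every == 0 or
                          epoch == cfg.epochs - 1):
            metric = _validation_metric(model, val_items, cfg.patch_shape)
            history["val_metric"].append(metric)
            history["val_epochs"].append(epoch)
            if metric > best:
                best = metric
                best_state = model.state_arrays()
    if best_state is not None:
        model.load_state_arrays(best_state)
    history["best_val_metric"] = best if best[0] > -np.inf else None
    model.eval()
    return model, history
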