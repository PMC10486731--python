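"""End-to-end experiment drivers: cohort preparation, per-acquisition
hierarchical fusion training, hybrid decision fusion, and the cropping
strategy comparison.

Two scale profiles are provided.  The *nominal* profile mirrors the clinical
acquisition geometry (500x224x500 and 834x224x834 volumes, 224^3 patches,
N = 10/20 inference crops, full-width backbones, 500 epochs at batch 2) and
exists so the configuration of a full-size run is explicit.  The *desk*
profile divides the geometry by 14 (36x16x36 and 60x16x60 volumes, 16^3
patches) — preserving the 3x1x3 / 4x1x4 patch-traversal tilings — scales the
inference crops proportionally (N = 5/8), uses quarter-width backbones and a
correspondingly shorter, larger-batch, higher-learning-rate schedule, and
runs end to end on one CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbones import BackboneSpec
from .evaluate import evaluate_model, predict_eye, predict_eye_hybrid
from .fusion import FusionSpec, HybridModel, build_fusion_model, build_hierarchical_fusion
from .preprocess import preprocess_volume
from .synthetic import ACQUISITIONS, CohortSpec, iter_cohort
from .training import TrainConfig, split_dataset, train_model


@dataclass
class ScaleProfile:
    name: str
    volume_scale: float
    d_target: int
    patch_shape: tuple
    n_crops: dict
    width_mult: float
    lr: float
    batch_size: int
    epochs: int
    n_patients: int = 100
    test_fraction: float = 0.25


NOMINAL = ScaleProfile(name="nominal", volume_scale=1.0, d_target=224,
                       patch_shape=(224, 224, 224, 2),
                       n_crops={"hr6": 10, "uwf15": 20},
                       width_mult=1.0, lr=1e-4, batch_size=2, epochs=500,
                       n_patients=444, test_fraction=0.12)

DESK = ScaleProfile(name="desk", volume_scale=1 / 14, d_target=16,
                    patch_shape=(16, 16, 16, 2),
                    n_crops={"hr6": 5, "uwf15": 8},
                    width_mult=0.25, lr=1e-3, batch_size=4, epochs=20,
                    n_patients=120, test_fraction=0.25)


@dataclass
class PreppedEye:
    """One eye after preprocessing: flattened volumes plus its grade."""

    patient_id: str
    laterality: str
    grade: int
    volumes: dict = field(default_factory=dict)   # acquisition -> PreprocessedVolume


def prepare_cohort(profile: ScaleProfile, seed: int,
                   cohort_spec: CohortSpec | None = None,
                   use_true_surfaces: bool = False) -> list[PreppedEye]:
    """Generate a synthetic cohort and preprocess every volume.

    Raw volumes are discarded eye by eye so peak memory stays proportional
    to one raw volume plus the preprocessed cohort.
    """
    spec = cohort_spec or CohortSpec(n_patients=profile.n_patients,
                                     p_both_eyes=1.0, p_both_acquisitions=1.0,
                                     volume_scale=profile.volume_scale, seed=seed)
    prepped = []
    for eye in iter_cohort(spec):
        vols = {acq: preprocess_volume(raw, profile.d_target,
                                       use_true_surfaces=use_true_surfaces)
                for acq, raw in eye.volumes.items()}
        prepped.append(PreppedEye(patient_id=eye.patient_id,
                                  laterality=eye.laterality,
                                  grade=eye.grade, volumes=vols))
    return prepped


def _train_config(profile: ScaleProfile, seed: int) -> TrainConfig:
    return TrainConfig(lr=profile.lr, epochs=profile.epochs,
                       batch_size=profile.batch_size,
                       patch_shape=profile.patch_shape, seed=seed, val_every=5)


def train_acquisition_model(cohort, acquisition: str, plan, profile: ScaleProfile,
                            seed: int, arch: str = "resnet50_3d",
                            val_fold: int = 0):
    """Train one per-acquisition structure+flow hierarchical fusion model."""
    test_ids = set(plan.test_patient_ids)
    val_ids = set(plan.fold_patients(val_fold))
    train_items = [(e.volumes[acquisition], e.grade) for e in cohort
                   if acquisition in e.volumes
                   and e.patient_id not in test_ids and e.patient_id not in val_ids]
    val_items = [(e.volumes[acquisition], e.grade) for e in cohort
                 if acquisition in e.volumes and e.patient_id in val_ids]
    branch = BackboneSpec(arch, in_channels=1, n_classes=6,
                          width_mult=profile.width_mult)
    model = build_hierarchical_fusion(
        FusionSpec("hierarchical", [branch, branch]),
        seed=seed * 10 + ACQUISITIONS.index(acquisition))
    model, history = train_model(model, train_items, _train_config(profile, seed),
                                 val_items)
    return model, history


def run_hybrid_experiment(seed: int, profile: ScaleProfile = DESK,
                          arch: str = "resnet50_3d",
                          cohort=None) -> dict:
    """The full study in miniature: single-acquisition hierarchical fusion
    models for both acquisitions, then hybrid decision-average fusion,
    all scored on the same held-out fully paired test eyes.

    Returns per-model :class:`~octafuse.evaluate.EvalReport` objects under
    keys 'hr6', 'uwf15' and 'hybrid'.
    """
    if cohort is None:
        cohort = prepare_cohort(profile, seed)
    plan = split_dataset(cohort, seed=seed, test_fraction=profile.test_fraction)
    test_ids = set(plan.test_patient_ids)

    models = {acq: train_acquisition_model(cohort, acq, plan, profile, seed,
                                           arch)[0]
              for acq in ACQUISITIONS}
    hybrid = HybridModel(models, "avg")

    test_eyes = [e for e in cohort if e.patient_id in test_ids]
    labels = [e.grade for e in test_eyes]
    rng = np.random.default_rng(seed + 999)
    patch_shapes = {acq: profile.patch_shape for acq in ACQUISITIONS}
    preds = {"hr6": [], "uwf15": [], "hybrid": []}
    for eye in test_eyes:
        for acq in ACQUISITIONS:
            preds[acq].append(predict_eye(models[acq], eye.volumes[acq],
                                          profile.n_crops[acq],
                                          profile.patch_shape, rng))
        preds["hybrid"].append(predict_eye_hybrid(hybrid, eye.volumes,
                                                  patch_shapes,
                                                  profile.n_crops, rng))
    reports = {k: evaluate_model(v, labels) for k, v in preds.items()}
    reports["n_test_eyes"] = len(test_eyes)
    reports["models"] = models
    return reports


def run_learning_smoke(seed: int, profile: ScaleProfile = DESK,
                       n_patients: int = 150, epochs: int = 30) -> float:
    """Train an input-fusion backbone on a 2-grade separable toy cohort and
    return its training accuracy (deterministic center-crop readout).

    The toy uses healthy eyes versus moderate NPDR with the generator's
    strong central lesions, high-resolution acquisition only.
    """
    from .preprocess import center_crop
    from .training import _to_input

    spec = CohortSpec(n_patients=n_patients, p_both_eyes=1.0,
                      p_both_acquisitions=1.0,
                      severity_distribution=np.array([.5, 0, .5, 0, 0, 0]),
                      volume_scale=profile.volume_scale, seed=seed)
    items = []
    for eye in iter_cohort(spec):
        pv = preprocess_volume(eye.volumes["hr6"], profile.d_target)
        items.append((pv, 0 if eye.grade == 0 else 1))
    model = build_fusion_model(
        FusionSpec("input", [BackboneSpec("resnet50_3d", 2, 2,
                                          profile.width_mult)]), seed=seed)
    cfg = _train_config(profile, seed)
    cfg.epochs = epochs
    model, _ = train_model(model, items, cfg)
    correct = 0
    for vol, y in items:
        patch = _to_input(center_crop(vol, profile.patch_shape).data)[None]
        correct += int(model.predict_proba(patch)[0].argmax() == y)
    return correct / len(items)


def run_crop_benchmark(seed: int, profile: ScaleProfile = DESK,
                       cohort=None) -> dict:
    """Compare inference strategies on one trained widefield input-fusion model:
    whole-volume resize, single center crop, exhaustive subvolume grid, and
    N-times random crop, each scored on the same test eyes."""
    from .evaluate import EyePrediction, aggregate_severest
    from .preprocess import center_crop, resize_volume, subvolume_grid
    from .training import _to_input

    if cohort is None:
        cohort = prepare_cohort(profile, seed)
    plan = split_dataset(cohort, seed=seed, test_fraction=profile.test_fraction)
    test_ids = set(plan.test_patient_ids)
    val_ids = set(plan.fold_patients(0))
    acq = "uwf15"
    train_items = [(e.volumes[acq], e.grade) for e in cohort
                   if e.patient_id not in test_ids and e.patient_id not in val_ids]
    val_items = [(e.volumes[acq], e.grade) for e in cohort if e.patient_id in val_ids]
    model = build_fusion_model(
        FusionSpec("input", [BackboneSpec("resnet50_3d", 2, 6,
                                          profile.width_mult)]), seed=seed)
    model, _ = train_model(model, train_items, _train_config(profile, seed),
                           val_items)

    test_eyes = [e for e in cohort if e.patient_id in test_ids]
    labels = [e.grade for e in test_eyes]
    rng = np.random.default_rng(seed + 777)
    ps = profile.patch_shape
    preds: dict = {k: [] for k in ("resize", "center_crop", "subvolume", "random_crop")}
    for eye in test_eyes:
        vol = eye.volumes[acq]
        batches = {
            "resize": [resize_volume(vol, ps)],
            "center_crop": [center_crop(vol, ps).data],
            "subvolume": [p.data for p in subvolume_grid(vol, ps)],
        }
        for name, patches in batches.items():
            probs = model.predict_proba(np.stack([_to_input(p) for p in patches]))
            p, s, g = aggregate_severest(list(probs))
            preds[name].append(EyePrediction(probs, p, s, g))
        preds["random_crop"].append(
            predict_eye(model, vol, profile.n_crops[acq], ps, rng))
    return {name: evaluate_model(v, labels) for name, v in preds.items()}
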