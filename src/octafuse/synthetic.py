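"""Seeded synthetic OCTA cohorts with acquisition-complementary disease signal.

Real paired high-resolution (6x6 mm) and ultra-widefield (15x15 mm) OCTA
datasets with severity labels are clinical and private, so this module
generates volumes that carry the statistical structure the fusion framework
relies on:

* curved ILM/RPE retinal surfaces embedded in a raw depth axis, with a bright
  RPE line and a dark vitreous so surface segmentation is well posed;
* two registered channels per acquisition — a layered reflectance (structure)
  channel and a filamentous decorrelation (flow) channel;
* paired acquisitions of different lateral extents rendered from one shared
  physical lesion layout, but *unregistered* (independent lateral jitter);
* severity-dependent lesions whose detectability differs by acquisition:
  small central flow voids (microvascular dropout near the fovea) that only
  the high-resolution scan resolves well, and large peripheral non-perfusion
  patches that lie outside the 6x6 mm field of view entirely and therefore
  only appear in the widefield scan.  Central lesion burden saturates at
  moderate disease while peripheral burden keeps growing, so early grades are
  easier to separate on the 6x6 mm scan and late grades on the 15x15 mm scan.

The generator targets this qualitative complementarity, not OCT physics:
there is no speckle statistics model and no vascular physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

# nominal acquisition geometry (voxels / millimetres)
HR_LATERAL = 500
UWF_LATERAL = 834
RAW_DEPTH = 1536
TARGET_DEPTH = 224
HR_FOV_MM = 6.0
UWF_FOV_MM = 15.0

ACQUISITIONS = ("hr6", "uwf15")
GRADE_NAMES = ("no DR", "mild NPDR", "moderate NPDR", "severe NPDR", "PDR", "PRP")
N_GRADES = 6

# eyes per severity level in a paired clinical cohort, normalised
DEFAULT_SEVERITY_DISTRIBUTION = np.array(
    [127, 68, 321, 97, 20, 43], dtype=np.float64) / 676.0

# lesion burden by grade: central voids saturate, peripheral patches keep growing
CENTRAL_COUNTS = (0, 2, 4, 5, 5, 5)
PERIPHERAL_COUNTS = (0, 0, 0, 2, 5, 9)
CENTRAL_AMP = {"hr6": 0.85, "uwf15": 0.30}   # widefield under-resolves small voids
PERIPHERAL_AMP = 0.85                          # rendered only where inside the FOV


class ValidationError(ValueError):
    """Raised when a generator specification violates its invariants."""


@dataclass
class RawVolume:
    """Rank-4 volume (X_lateral, Y_depth, Z_lateral, C=[structure, flow])."""

    data: np.ndarray
    acquisition: str
    ilm_surface: np.ndarray            # (X, Z) depth indices, ground truth
    rpe_surface: np.ndarray
    lesion_masks: dict = field(default_factory=dict)   # kind -> (X, Y, Z) bool
    fov_mm: float = HR_FOV_MM
    jitter_mm: tuple = (0.0, 0.0)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class EyeRecord:
    patient_id: str
    laterality: str                    # OD | OS
    grade: int
    volumes: dict = field(default_factory=dict)    # acquisition -> RawVolume


@dataclass
class CohortSpec:
    n_patients: int = 50
    p_both_acquisitions: float = 0.9
    p_both_eyes: float = 0.9
    severity_distribution: np.ndarray = field(
        default_factory=lambda: DEFAULT_SEVERITY_DISTRIBUTION.copy())
    volume_scale: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        dist = np.asarray(self.severity_distribution, dtype=np.float64)
        if dist.shape != (N_GRADES,) or (dist < 0).any() or \
                abs(dist.sum() - 1.0) > 1e-6:
            raise ValidationError("severity_distribution must be a 6-point simplex")
        if not 0 < self.volume_scale <= 1:
            raise ValidationError("volume_scale must lie in (0, 1]")
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        for name in ("p_both_acquisitions", "p_both_eyes"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def acquisition_geometry(acquisition: str, scale: float):
    """(lateral_size, raw_depth, fov_mm) for an acquisition at a given scale."""
    depth = max(12, _round_half_up(RAW_DEPTH * scale))
    if acquisition == "hr6":
        return max(8, _round_half_up(HR_LATERAL * scale)), depth, HR_FOV_MM
    if acquisition == "uwf15":
        return max(8, _round_half_up(UWF_LATERAL * scale)), depth, UWF_FOV_MM
    raise ValidationError(f"unknown acquisition {acquisition!r}")


# ---------------------------------------------------------------------------
# lesion layout (physical coordinates shared by both acquisitions of an eye)
# ---------------------------------------------------------------------------

def draw_lesion_layout(grade: int, rng: np.random.Generator) -> list[dict]:
    """Lesion positions/sizes in millimetres, fovea at the origin.

    Central voids sit within 2.2 mm of the fovea; peripheral non-perfusion
    patches are placed with Chebyshev radius > 3.4 mm so they fall outside
    the 6x6 mm field of view.
    """
    if not 0 <= grade < N_GRADES:
        raise ValidationError(f"grade must be in 0..{N_GRADES - 1}")
    layout = []
    for _ in range(CENTRAL_COUNTS[grade]):
        r = rng.uniform(0.2, 2.2)
        theta = rng.uniform(0, 2 * np.pi)
        layout.append({"kind": "central",
                       "x": r * np.cos(theta), "z": r * np.sin(theta),
                       "radius_mm": rng.uniform(0.55, 0.95)})
    for _ in range(PERIPHERAL_COUNTS[grade]):
        cheb = rng.uniform(3.4, 6.8)
        theta = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(theta), np.sin(theta)
        f = cheb / max(abs(c), abs(s))
        layout.append({"kind": "peripheral", "x": f * c, "z": f * s,
                       "radius_mm": rng.uniform(1.2, 2.2)})
    return layout


# ---------------------------------------------------------------------------
# volume rendering
# ---------------------------------------------------------------------------

def _smooth_field(shape, sigma_px, rng, amplitude=1.0):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px, mode="nearest")
    sd = f.std()
    return (f / sd * amplitude) if sd > 0 else f


def _surfaces(L, Dr, px_per_mm, rng, curved=True):
    xs = (np.arange(L) + 0.5) / L * 2.0 - 1.0
    r2 = xs[:, None] ** 2 + xs[None, :] ** 2
    if curved:
        ilm = Dr * (0.22 + 0.06 * r2) + _smooth_field((L, L), max(1.0, px_per_mm), rng,
                                                      amplitude=0.02 * Dr)
        thick = Dr * 0.30 * (1.0 + 0.1 * _smooth_field((L, L), max(1.0, px_per_mm), rng))
    else:
        ilm = np.full((L, L), Dr * 0.25)
        thick = np.full((L, L), Dr * 0.30)
    ilm = np.clip(ilm, 1, Dr * 0.6)
    thick = np.clip(thick, max(4.0, Dr * 0.1), Dr * 0.38)
    rpe = np.clip(ilm + thick, None, Dr - 2.0)
    return ilm.astype(np.float32), rpe.astype(np.float32)


def _structure_profile(u):
    """Layered reflectance as a function of relative depth u in [0, 1]."""
    return (0.50 + 0.18 * np.exp(-((u - 0.35) / 0.15) ** 2)
            + 0.35 * np.exp(-((u - 1.0) / 0.05) ** 2))


def _flow_profile(u):
    """Vascular plexuses concentrated in the inner retina."""
    return np.exp(-((u - 0.2) / 0.25) ** 2) + 0.5 * np.exp(-((u - 0.6) / 0.2) ** 2)


def generate_raw_volume(acquisition: str, grade: int, scale: float,
                        rng: np.random.Generator,
                        layout: list[dict] | None = None,
                        curved: bool = True,
                        jitter: bool = True) -> RawVolume:
    """Render one synthetic acquisition of an eye with the given severity.

    When ``layout`` is None a fresh lesion layout is drawn from ``rng`` first,
    so two calls at the same rng state render the same physical eye.
    """
    if not 0 < scale <= 1:
        raise ValidationError("scale must lie in (0, 1]")
    if layout is None:
        layout = draw_lesion_layout(grade, rng)
    L, Dr, fov = acquisition_geometry(acquisition, scale)
    px_per_mm = L / fov

    ilm, rpe = _surfaces(L, Dr, px_per_mm, rng, curved=curved)
    thick = rpe - ilm

    jit = (rng.uniform(-0.25, 0.25), rng.uniform(-0.25, 0.25)) if jitter else (0.0, 0.0)
    coord = (np.arange(L) + 0.5) / px_per_mm - fov / 2.0
    px = coord + jit[0]
    pz = coord + jit[1]

    y = np.arange(Dr, dtype=np.float32)
    u = (y[None, :, None] - ilm[:, None, :]) / thick[:, None, :]   # (X, Y, Z)
    band = (u >= 0.0) & (u <= 1.0)
    uc = np.clip(u, 0.0, 1.0)

    structure = np.where(band, _structure_profile(uc), 0.0).astype(np.float32)
    below = u > 1.0
    structure[below] = 0.85 * np.exp(-np.clip(u[below] - 1.0, 0, None) * 8.0)
    structure[u < 0] = 0.03

    vessels = _smooth_field((L, L), max(0.5, 0.15 * px_per_mm), rng)
    vessels = np.clip((vessels - vessels.mean()) * 2.0 / (vessels.std() + 1e-9) + 0.5, 0, 1)
    flow = (0.15 + 0.55 * vessels[:, None, :] * _flow_profile(uc)).astype(np.float32)
    flow[~band] = 0.05

    # lesions: multiplicative flow voids with matched structural dimming
    deficit = {"central": np.zeros((L, L), dtype=np.float32),
               "peripheral": np.zeros((L, L), dtype=np.float32)}
    footprint = {"central": np.zeros((L, L), dtype=bool),
                 "peripheral": np.zeros((L, L), dtype=bool)}
    for les in layout:
        dx = px[:, None] - les["x"]
        dz = pz[None, :] - les["z"]
        d2 = dx * dx + dz * dz
        r = les["radius_mm"]
        g = np.exp(-d2 / (2 * (r / 2.0) ** 2)).astype(np.float32)
        amp = CENTRAL_AMP[acquisition] if les["kind"] == "central" else PERIPHERAL_AMP
        deficit[les["kind"]] = np.maximum(deficit[les["kind"]], amp * g)
        footprint[les["kind"]] |= d2 < r * r
    total = np.maximum(deficit["central"], deficit["peripheral"])
    if total.any():
        flow *= (1.0 - total[:, None, :])
        structure *= (1.0 - 0.5 * total[:, None, :])

    noise = rng.standard_normal(structure.shape).astype(np.float32)
    structure = np.clip(structure + 0.04 * noise, 0, None)
    flow = np.clip(flow + 0.04 * rng.standard_normal(flow.shape).astype(np.float32), 0, None)

    data = np.stack([structure, flow.astype(np.float32)], axis=-1)
    masks = {kind: (footprint[kind][:, None, :] & band)
             for kind in ("central", "peripheral") if footprint[kind].any()}
    return RawVolume(data=data, acquisition=acquisition,
                     ilm_surface=ilm, rpe_surface=rpe,
                     lesion_masks=masks, fov_mm=fov, jitter_mm=jit)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def generate_eye(patient_id: str, laterality: str, grade: int,
                 acquisitions, scale: float, rng: np.random.Generator) -> EyeRecord:
    """Render all requested acquisitions of one eye from a shared lesion layout."""
    layout = draw_lesion_layout(grade, rng)
    volumes = {acq: generate_raw_volume(acq, grade, scale, rng, layout=layout)
               for acq in acquisitions}
    return EyeRecord(patient_id=patient_id, laterality=laterality,
                     grade=grade, volumes=volumes)


def iter_cohort(spec: CohortSpec):
    """Lazily yield the EyeRecords of a seeded synthetic cohort."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    dist = np.asarray(spec.severity_distribution, dtype=np.float64)
    dist = dist / dist.sum()
    for i in range(spec.n_patients):
        pid = f"P{i:04d}"
        lateralities = ["OD", "OS"] if rng.uniform() < spec.p_both_eyes else \
            [("OD", "OS")[rng.integers(2)]]
        for lat in lateralities:
            grade = int(rng.choice(N_GRADES, p=dist))
            if rng.uniform() < spec.p_both_acquisitions:
                acqs = list(ACQUISITIONS)
            else:
                acqs = [ACQUISITIONS[rng.integers(2)]]
            yield generate_eye(pid, lat, grade, acqs, spec.volume_scale, rng)


def generate_cohort(spec: CohortSpec) -> list[EyeRecord]:
    """Materialise a full cohort (use :func:`iter_cohort` for large runs)."""
    return list(iter_cohort(spec))


def mean_band_flow(raw: RawVolume) -> float:
    """Mean flow intensity within the ground-truth retinal band.

    A fixed linear probe on this value (lower flow = more disease) is the
    simplest possible severity detector and is used to audit that the
    acquisition-complementary lesion design actually carries signal.
    """
    y = np.arange(raw.data.shape[1], dtype=np.float32)
    u = (y[None, :, None] - raw.ilm_surface[:, None, :]) / \
        (raw.rpe_surface - raw.ilm_surface)[:, None, :]
    band = (u >= 0) & (u <= 1)
    return float(raw.data[..., 1][band].mean())
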