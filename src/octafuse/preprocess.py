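"""Depth-band extraction, flattening and the four cropping strategies.

Raw volumes keep the full depth axis; only the band between the internal
limiting membrane (ILM) and the retinal pigment epithelium (RPE) carries
retinal signal.  Preprocessing estimates those two surfaces per A-scan,
shifts every A-scan so the ILM sits at depth 0 (flattening) and resamples
the band to a fixed number of depth samples.  Nominally 500x1536x500x2
raw volumes become 500x224x500x2 network-ready volumes.

Because preprocessed volumes are still too large for a 3D classifier input,
four strategies reduce them to patches: whole-volume resizing, a single
deterministic center crop, uniformly random crops (used during training and,
N times, at inference), and an exhaustive subvolume grid whose patch count
is the product of per-axis ceilings of volume/patch size.

Axis convention throughout: 0-based (X_lateral, Y_depth, Z_lateral, channel),
channels ordered [structure, flow].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synthetic import RawVolume, ValidationError


class SurfaceNotFoundError(RuntimeError):
    """No detectable retinal band in the structure channel."""


@dataclass
class PreprocessedVolume:
    """Flattened, depth-resampled rank-4 volume (X, D_target, Z, 2)."""

    data: np.ndarray
    acquisition: str
    d_target: int

    @property
    def shape(self):
        return self.data.shape


@dataclass
class CropPatch:
    """A view of a sub-volume: integer origin plus (sx, sy, sz, c) size."""

    origin: tuple
    size: tuple
    data: np.ndarray


# ---------------------------------------------------------------------------
# surface segmentation and flattening
# ---------------------------------------------------------------------------

def segment_surfaces(raw: RawVolume, smooth_sigma: float = 1.5,
                     median_size: int = 5, min_gradient: float = 0.05):
    """Estimate per-A-scan ILM and RPE depth indices from the structure channel.

    The ILM is taken as the maximum positive depth gradient of the
    depth-smoothed structure channel (the vitreous-to-retina jump); the RPE
    as the brightest voxel below it (the hyper-reflective RPE line).  Both
    surface maps are median filtered laterally to suppress per-A-scan noise.
    """
    structure = raw.data[..., 0].astype(np.float32)
    sm = ndimage.gaussian_filter1d(structure, smooth_sigma, axis=1, mode="nearest")
    grad = np.diff(sm, axis=1)
    ilm = grad.argmax(axis=1)
    if grad.max() < min_gradient:
        raise SurfaceNotFoundError("no depth gradient above threshold; "
                                   "volume has no detectable retinal band")
    ilm = ndimage.median_filter(ilm.astype(np.float32), size=median_size,
                                mode="nearest")

    depth = raw.data.shape[1]
    min_thick = max(2, int(0.05 * depth))
    y = np.arange(depth)[None, :, None]
    below = y > (ilm[:, None, :] + min_thick)
    masked = np.where(below, sm, -np.inf)
    rpe = masked.argmax(axis=1)
    rpe = ndimage.median_filter(rpe.astype(np.float32), size=median_size,
                                mode="nearest")
    rpe = np.maximum(rpe, ilm + min_thick)
    return ilm, rpe


def flatten_and_crop(raw: RawVolume, ilm_map: np.ndarray, rpe_map: np.ndarray,
                     d_target: int) -> PreprocessedVolume:
    """Shift each A-scan so the ILM sits at depth 0 and resample the band.

    The [ILM, RPE] band of every A-scan is linearly resampled to exactly
    ``d_target`` depth samples; lateral extent is unchanged.
    """
    if d_target < 2:
        raise ValidationError("d_target must be >= 2")
    X, D, Z, C = raw.data.shape
    frac = np.linspace(0.0, 1.0, d_target, dtype=np.float32)
    pos = ilm_map[:, None, :] + frac[None, :, None] * (rpe_map - ilm_map)[:, None, :]
    pos = np.clip(pos, 0, D - 1)
    lo = np.floor(pos).astype(np.int64)
    hi = np.minimum(lo + 1, D - 1)
    w = (pos - lo)[..., None].astype(np.float32)
    out = (1.0 - w) * np.take_along_axis(raw.data, lo[..., None], axis=1) + \
        w * np.take_along_axis(raw.data, hi[..., None], axis=1)
    return PreprocessedVolume(data=out.astype(np.float32),
                              acquisition=raw.acquisition, d_target=d_target)


def preprocess_volume(raw: RawVolume, d_target: int,
                      use_true_surfaces: bool = False) -> PreprocessedVolume:
    """Segment surfaces (or reuse generator ground truth) and flatten."""
    if use_true_surfaces:
        ilm, rpe = raw.ilm_surface, raw.rpe_surface
    else:
        ilm, rpe = segment_surfaces(raw)
    return flatten_and_crop(raw, ilm, rpe, d_target)


# ---------------------------------------------------------------------------
# cropping strategies
# ---------------------------------------------------------------------------

def _volume_array(v) -> np.ndarray:
    if isinstance(v, np.ndarray):
        return v
    if hasattr(v, "data"):
        return np.asarray(v.data)
    return np.asarray(v)


def resize_volume(v, out_shape) -> np.ndarray:
    """Trilinear resize of the three spatial axes; channels resized separately."""
    arr = _volume_array(v)
    out_shape = tuple(int(s) for s in out_shape)
    if len(out_shape) == 4 and out_shape[3] != arr.shape[3]:
        raise ValidationError("channel count cannot be resized")
    spatial_out = out_shape[:3]
    if any(s < 1 for s in spatial_out):
        raise ValidationError("out_shape must be positive")
    if spatial_out == arr.shape[:3]:
        return arr.copy()
    grids = [((np.arange(o) + 0.5) * n / o - 0.5).astype(np.float32)
             for o, n in zip(spatial_out, arr.shape[:3])]
    mesh = np.meshgrid(*grids, indexing="ij")
    coords = np.stack([m.ravel() for m in mesh])
    out = np.empty(spatial_out + (arr.shape[3],), dtype=np.float32)
    for c in range(arr.shape[3]):
        out[..., c] = ndimage.map_coordinates(
            arr[..., c], coords, order=1, mode="nearest").reshape(spatial_out)
    return out


def _pad_to_fit(arr: np.ndarray, patch_shape) -> tuple[np.ndarray, tuple]:
    """Zero-pad symmetrically on any axis smaller than the patch."""
    pads = []
    for dim, p in zip(arr.shape, patch_shape):
        short = max(0, p - dim)
        pads.append((short // 2, short - short // 2))
    if any(a or b for a, b in pads):
        arr = np.pad(arr, pads)
    return arr, tuple(p[0] for p in pads)


def center_crop(v, patch_shape) -> CropPatch:
    """Deterministic crop centered on every axis (origin = floor((dim-patch)/2))."""
    arr = _volume_array(v)
    patch_shape = tuple(int(s) for s in patch_shape)
    arr, _ = _pad_to_fit(arr, patch_shape)
    origin = tuple((d - p) // 2 for d, p in zip(arr.shape, patch_shape))
    sl = tuple(slice(o, o + p) for o, p in zip(origin, patch_shape))
    return CropPatch(origin=origin, size=patch_shape, data=arr[sl])


def random_crop(v, patch_shape, rng: np.random.Generator) -> CropPatch:
    """Crop with origin uniform over all in-bounds positions."""
    arr = _volume_array(v)
    patch_shape = tuple(int(s) for s in patch_shape)
    arr, _ = _pad_to_fit(arr, patch_shape)
    origin = tuple(int(rng.integers(0, d - p + 1))
                   for d, p in zip(arr.shape, patch_shape))
    sl = tuple(slice(o, o + p) for o, p in zip(origin, patch_shape))
    return CropPatch(origin=origin, size=patch_shape, data=arr[sl])


def _axis_starts(dim: int, patch: int) -> list[int]:
    starts = list(range(0, max(dim - patch, 0) + 1, patch))
    if starts[-1] + patch < dim:
        starts.append(dim - patch)
    return starts


def subvolume_grid(v, patch_shape) -> list[CropPatch]:
    """Non-overlapping patch tiling with the last patch clamped flush to the edge.

    The grid covers every voxel at least once and its length equals
    :func:`traversal_patch_count` of the (padded) volume.
    """
    arr = _volume_array(v)
    patch_shape = tuple(int(s) for s in patch_shape)
    arr, _ = _pad_to_fit(arr, patch_shape)
    axis_starts = [_axis_starts(d, p) for d, p in zip(arr.shape, patch_shape)]
    patches = []
    for ox in axis_starts[0]:
        for oy in axis_starts[1]:
            for oz in axis_starts[2]:
                for oc in axis_starts[3]:
                    origin = (ox, oy, oz, oc)
                    sl = tuple(slice(o, o + p) for o, p in zip(origin, patch_shape))
                    patches.append(CropPatch(origin=origin, size=patch_shape,
                                             data=arr[sl]))
    return patches


def traversal_patch_count(volume_shape, patch_shape) -> int:
    """Product over all four axes of ceil(volume_dim / patch_dim)."""
    volume_shape = tuple(int(s) for s in volume_shape)
    patch_shape = tuple(int(s) for s in patch_shape)
    if len(volume_shape) != len(patch_shape):
        raise ValidationError("volume and patch must have the same rank")
    if any(p <= 0 for p in patch_shape) or any(d <= 0 for d in volume_shape):
        raise ValidationError("shapes must be positive")
    count = 1
    for d, p in zip(volume_shape, patch_shape):
        count *= -(-d // p)
    return count
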