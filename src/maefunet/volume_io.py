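"""NIfTI volume I/O, isotropic resampling, stride slicing, preprocessing,
and joint geometric augmentation.

Conventions: volume axes are indexed 0, 1, 2 in stored order — no anatomical
reorientation is attempted. All indices are 0-based; slice ranges half-open.
Intensity interpolation is linear; masks and label grids are always resampled
nearest-neighbour so no new label values can appear.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .seeding import substream

__all__ = [
    "AugmentConfig",
    "PreprocessConfig",
    "SliceSample",
    "StridePlan",
    "Volume",
    "augment",
    "extract_slices",
    "preprocess",
    "read_slice_manifest",
    "read_volume",
    "resample_isotropic",
    "write_slice_manifest",
    "write_volume",
]


@dataclass
class Volume:
    """A 3D scalar grid plus voxel spacing in millimetres."""

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    source_path: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"volume grid must be 3D, got ndim={self.grid.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")


@dataclass(frozen=True)
class StridePlan:
    """Take every ``stride``-th slice along each requested axis."""

    stride: int
    axes: tuple[int, ...] = (0,)
    offset: int = 0

    def __post_init__(self):
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not (0 <= self.offset < self.stride):
            raise ValueError("offset must satisfy 0 <= offset < stride")
        if any(a not in (0, 1, 2) for a in self.axes):
            raise ValueError(f"axes must be within {{0,1,2}}, got {self.axes}")

    def count(self, axis_len: int) -> int:
        """Number of slices on one axis: ceil((len - offset) / stride)."""
        return -((axis_len - self.offset) // -self.stride)


@dataclass(frozen=True)
class PreprocessConfig:
    clamp_low: float = 0.1
    clamp_high: float = 99.9
    target_size: tuple[int, int] = (224, 224)

    def __post_init__(self):
        if not (0 <= self.clamp_low < self.clamp_high <= 100):
            raise ValueError("need 0 <= clamp_low < clamp_high <= 100")


@dataclass(frozen=True)
class AugmentConfig:
    max_rotation_deg: float = 10.0
    flip_probability: float = 0.5
    crop_fraction_range: tuple[float, float] = (0.8, 1.0)
    rotate: bool = True
    flip: bool = True
    crop: bool = True

    def __post_init__(self):
        if not (0 <= self.flip_probability <= 1):
            raise ValueError("flip_probability must be in [0, 1]")

    @property
    def enabled(self) -> bool:
        return self.rotate or self.flip or self.crop


@dataclass
class SliceSample:
    """A preprocessed 2D slice in [0, 1] with optional mask / labels / class."""

    image: np.ndarray
    brain_mask: np.ndarray | None = None
    label_grid: np.ndarray | None = None
    class_label: int | None = None
    provenance: tuple = ()
    constant_input: bool = False


def read_volume(path) -> Volume:
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several parse error types
        raise IOError(f"cannot parse {path} as NIfTI: {exc}") from exc
    grid = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(grid=grid, spacing=spacing, source_path=str(path))


def write_volume(vol: Volume, path) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(vol.grid, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def resample_isotropic(vol: Volume, is_label: bool = False) -> Volume:
    """Resample to isotropic voxels at the finest input spacing.

    Axis lengths scale by the spacing ratio (rounded to nearest integer);
    intensities interpolate linearly, labels nearest-neighbour.
    """
    target = min(vol.spacing)
    factors = tuple(s / target for s in vol.spacing)
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        return Volume(vol.grid.copy(), vol.spacing, vol.source_path)
    order = 0 if is_label else 1
    out = ndimage.zoom(vol.grid, zoom=factors, order=order, mode="nearest")
    return Volume(out, (target, target, target), vol.source_path)


def preprocess(
    raw_slice: np.ndarray,
    cfg: PreprocessConfig = PreprocessConfig(),
    brain_mask: np.ndarray | None = None,
    label_grid: np.ndarray | None = None,
    class_label: int | None = None,
    provenance: tuple = (),
) -> SliceSample:
    """Percentile clamp, min-max normalise to [0, 1], resize to target.

    A constant slice (max == min after clamping) maps to all zeros and is
    flagged rather than raising: aggregated cohorts contain empty slices,
    which the coverage-weighted loss simply down-weights.
    """
    raw_slice = np.asarray(raw_slice, dtype=np.float64)
    if raw_slice.size == 0:
        raise ValueError("empty slice")
    lo, hi = np.percentile(raw_slice, [cfg.clamp_low, cfg.clamp_high])
    clamped = np.clip(raw_slice, lo, hi)
    constant = bool(hi <= lo or np.ptp(clamped) == 0)
    if constant:
        normed = np.zeros_like(clamped)
    else:
        normed = (clamped - clamped.min()) / np.ptp(clamped)
    image = _resize2d(normed, cfg.target_size, order=1)
    image = np.clip(image, 0.0, 1.0)
    mask = None
    if brain_mask is not None:
        mask = _resize2d(np.asarray(brain_mask), cfg.target_size, order=0)
    labels = None
    if label_grid is not None:
        labels = _resize2d(np.asarray(label_grid), cfg.target_size, order=0)
    return SliceSample(
        image=image,
        brain_mask=mask,
        label_grid=labels,
        class_label=class_label,
        provenance=provenance,
        constant_input=constant,
    )


def _resize2d(arr: np.ndarray, size: tuple[int, int], order: int) -> np.ndarray:
    if arr.shape == tuple(size):
        return arr.copy()
    out = _sk_resize(
        arr.astype(np.float64),
        size,
        order=order,
        preserve_range=True,
        anti_aliasing=False,
    )
    if order == 0:
        return out.astype(arr.dtype)
    return out


def extract_slices(
    vol: Volume,
    plan: StridePlan,
    cfg: PreprocessConfig = PreprocessConfig(),
    mask_volume: Volume | None = None,
    label_volume: Volume | None = None,
    class_label: int | None = None,
    volume_id: str | None = None,
) -> list[SliceSample]:
    """Stride-sampled, preprocessed slices along each axis of ``plan``."""
    vid = volume_id if volume_id is not None else vol.source_path
    for aux, name in ((mask_volume, "mask"), (label_volume, "label")):
        if aux is not None and aux.grid.shape != vol.grid.shape:
            raise ValueError(f"{name} volume shape {aux.grid.shape} != {vol.grid.shape}")
    samples = []
    for axis in plan.axes:
        for idx in range(plan.offset, vol.grid.shape[axis], plan.stride):
            raw = np.take(vol.grid, idx, axis=axis)
            m = np.take(mask_volume.grid, idx, axis=axis) if mask_volume else None
            lab = np.take(label_volume.grid, idx, axis=axis) if label_volume else None
            samples.append(
                preprocess(
                    raw,
                    cfg,
                    brain_mask=m,
                    label_grid=lab,
                    class_label=class_label,
                    provenance=(vid, axis, idx),
                )
            )
    return samples


def write_slice_manifest(samples: list[SliceSample], path) -> None:
    """Plain-text manifest: one row per sample (volume id, axis, index, label)."""
    lines = ["volume\taxis\tindex\tlabel"]
    for s in samples:
        vid, axis, idx = (s.provenance + ("", "", ""))[:3]
        label = "" if s.class_label is None else str(s.class_label)
        lines.append(f"{vid}\t{axis}\t{idx}\t{label}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_slice_manifest(path) -> list[dict]:
    rows = Path(path).read_text().rstrip("\n").split("\n")
    header = rows[0].split("\t")
    return [dict(zip(header, r.split("\t"))) for r in rows[1:]]


def augment(sample: SliceSample, cfg: AugmentConfig, seed: int) -> SliceSample:
    """Random rotation, flipping and cropping, applied jointly to the image
    and any mask / label grid; deterministic under a fixed seed."""
    if not cfg.enabled:
        return sample
    rng = substream(seed, "augment")
    image = sample.image
    mask = sample.brain_mask
    labels = sample.label_grid

    def joint(fn_img, fn_nn):
        nonlocal image, mask, labels
        image = fn_img(image)
        if mask is not None:
            mask = fn_nn(mask)
        if labels is not None:
            labels = fn_nn(labels)

    if cfg.flip and rng.random() < cfg.flip_probability:
        joint(lambda a: a[:, ::-1].copy(), lambda a: a[:, ::-1].copy())
    if cfg.rotate and cfg.max_rotation_deg > 0:
        angle = rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg)
        joint(
            lambda a: ndimage.rotate(a, angle, reshape=False, order=1, mode="nearest"),
            lambda a: ndimage.rotate(a, angle, reshape=False, order=0, mode="nearest"),
        )
    if cfg.crop:
        f = rng.uniform(*cfg.crop_fraction_range)
        h, w = image.shape
        ch, cw = max(1, int(round(h * f))), max(1, int(round(w * f)))
        top = rng.integers(0, h - ch + 1)
        left = rng.integers(0, w - cw + 1)
        size = (h, w)
        joint(
            lambda a: _resize2d(a[top : top + ch, left : left + cw], size, order=1),
            lambda a: _resize2d(a[top : top + ch, left : left + cw], size, order=0),
        )
    image = np.clip(image, 0.0, 1.0)
    return replace(sample, image=image, brain_mask=mask, label_grid=labels)
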