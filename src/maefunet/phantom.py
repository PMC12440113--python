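"""Synthetic multi-tissue head phantoms.

Stands in for restricted clinical cohorts: nested-ellipsoid head geometry
(skull rim, CSF layer, cortical gray matter, white matter, paired
ventricles, and k small deep gray structures), rendered under several
pseudo-sequences whose tissue-contrast orderings differ (so sequence
classification is learnable), with additive Gaussian noise and a smooth
multiplicative bias field. Geometry is jittered per subject by a random
affine so no two subjects are identical.

Not goals: anatomical realism, pathology, or acquisition physics. The value
of the phantom is that masks and labels are exact by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seeding import substream
from .volume_io import PreprocessConfig, SliceSample, Volume, preprocess

__all__ = [
    "BACKGROUND",
    "CSF",
    "DEEP_FIRST",
    "GRAY",
    "PhantomSpec",
    "SKULL",
    "VENTRICLE",
    "WHITE",
    "brain_mask_from_labels",
    "default_contrast_table",
    "make_classification_set",
    "make_phantom_volume",
    "render_sequence",
]

BACKGROUND, SKULL, CSF, GRAY, WHITE, VENTRICLE = 0, 1, 2, 3, 4, 5
DEEP_FIRST = 6  # deep structures occupy labels 6 .. 5 + n_deep

#: per-tissue mean intensity, one column per pseudo-sequence. Orderings are
#: chosen so each sequence has a distinct tissue-contrast signature
#: (pseudo-T1: white > gray > CSF; pseudo-T2: CSF > gray > white; FLAIR:
#: CSF suppressed; etc.), mimicking how real sequences separate.
_TISSUE_ROWS = ("background", "skull", "csf", "gray", "white", "ventricle", "deep")


def default_contrast_table() -> dict[str, dict[str, float]]:
    cols = {
        "pseudo_t1":     (0.0, 25.0, 20.0, 60.0, 85.0, 18.0, 55.0),
        "pseudo_t2":     (0.0, 20.0, 95.0, 55.0, 40.0, 97.0, 60.0),
        "pseudo_flair":  (0.0, 22.0, 12.0, 68.0, 45.0, 10.0, 62.0),
        "pseudo_pd":     (0.0, 30.0, 80.0, 72.0, 55.0, 82.0, 68.0),
        "pseudo_t2star": (0.0, 18.0, 90.0, 50.0, 35.0, 92.0, 55.0),
        "pseudo_swi":    (0.0, 15.0, 85.0, 45.0, 30.0, 88.0, 36.0),
        "pseudo_dwi":    (0.0, 10.0, 28.0, 70.0, 52.0, 26.0, 78.0),
    }
    return {
        seq: dict(zip(_TISSUE_ROWS, vals)) for seq, vals in cols.items()
    }


@dataclass
class PhantomSpec:
    grid_size: int = 96
    n_deep: int = 3
    skull_thickness: float = 3.0  # voxels
    geometry_jitter: float = 0.05  # relative affine perturbation per subject
    noise_sd: float = 3.0  # intensity units (contrast table spans ~0-97)
    bias_field_order: int = 2  # polynomial order of multiplicative field
    bias_amplitude: float = 0.15
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    contrast_table: dict[str, dict[str, float]] = field(
        default_factory=default_contrast_table
    )

    def __post_init__(self):
        if self.grid_size < 32:
            raise ValueError(
                f"grid_size {self.grid_size} too small to host all structures (min 32)"
            )
        if self.n_deep < 0:
            raise ValueError("n_deep must be >= 0")

    @property
    def tissue_labels(self) -> dict[str, int]:
        out = {
            "background": BACKGROUND,
            "skull": SKULL,
            "csf": CSF,
            "gray": GRAY,
            "white": WHITE,
            "ventricle": VENTRICLE,
        }
        for i in range(self.n_deep):
            out[f"deep_{i}"] = DEEP_FIRST + i
        return out


# anchor directions (unit-ish, normalised head coords) for deep structures;
# jittered per subject, checked to sit strictly inside white matter
_DEEP_ANCHORS = np.array(
    [
        (0.30, 0.10, -0.12),
        (-0.30, 0.10, -0.12),
        (0.00, -0.30, 0.05),
        (0.22, -0.22, 0.18),
        (-0.22, -0.22, 0.18),
        (0.00, 0.28, 0.22),
    ]
)


def _tissue_lut(spec: PhantomSpec, sequence: str) -> np.ndarray:
    col = spec.contrast_table[sequence]
    lut = np.zeros(DEEP_FIRST + spec.n_deep)
    lut[BACKGROUND] = col["background"]
    lut[SKULL] = col["skull"]
    lut[CSF] = col["csf"]
    lut[GRAY] = col["gray"]
    lut[WHITE] = col["white"]
    lut[VENTRICLE] = col["ventricle"]
    for i in range(spec.n_deep):
        lut[DEEP_FIRST + i] = col["deep"]
    return lut


def make_phantom_volume(
    spec: PhantomSpec, subject_seed: int
) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Generate (label_volume, brain_mask, spacing) for one subject.

    Deterministic: the same (spec, subject_seed) reproduces the volume
    bit-for-bit. Labels partition the grid; the brain mask is the union of
    the intracranial classes (everything except background and skull).
    """
    if spec.n_deep > len(_DEEP_ANCHORS):
        raise ValueError(
            f"n_deep={spec.n_deep} exceeds available anchor sites ({len(_DEEP_ANCHORS)})"
        )
    n = spec.grid_size
    rng = substream(subject_seed, "phantom-geometry")

    ax = np.linspace(-1.0, 1.0, n)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    coords = np.stack([x, y, z])

    # per-subject affine jitter: anisotropic scale + small rotation + shift
    j = spec.geometry_jitter
    scale = 1.0 + rng.uniform(-j, j, size=3)
    theta = rng.uniform(-j, j)  # radians, about z
    phi = rng.uniform(-j, j)  # about y
    shift = rng.uniform(-j / 2, j / 2, size=3)
    rz = np.array(
        [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
    )
    ry = np.array(
        [[np.cos(phi), 0, np.sin(phi)], [0, 1, 0], [-np.sin(phi), 0, np.cos(phi)]]
    )
    affine = (rz @ ry) * scale[None, :]
    u = np.einsum("ab,bijk->aijk", affine, coords) + shift[:, None, None, None]

    # nested shells of one base ellipsoid (semi-axes of the skull's outside)
    semi = np.array([0.88, 0.76, 0.70])
    r = np.sqrt(((u / semi[:, None, None, None]) ** 2).sum(axis=0))
    t_skull = spec.skull_thickness / (n / 2.0) / semi.mean()
    s_csf = 1.0 - t_skull  # skull inner surface
    s_gray = s_csf - 0.07
    s_white = s_gray - 0.16
    if s_white <= 0.25:
        raise ValueError("grid/skull configuration leaves no room for white matter")

    labels = np.zeros((n, n, n), dtype=np.uint8)
    labels[r <= 1.0] = SKULL
    labels[r <= s_csf] = CSF
    labels[r <= s_gray] = GRAY
    labels[r <= s_white] = WHITE

    # paired elongated ventricles inside white matter
    for side in (-1.0, 1.0):
        centre = np.array([side * 0.13, -0.02, 0.06])
        vsemi = np.array([0.055, 0.20, 0.085])
        d = ((u - centre[:, None, None, None]) / vsemi[:, None, None, None]) ** 2
        labels[(d.sum(axis=0) <= 1.0) & (labels == WHITE)] = VENTRICLE

    # small deep structures, strictly inside white matter
    for i in range(spec.n_deep):
        base = _DEEP_ANCHORS[i]
        placed = False
        for attempt in range(20):
            centre = base + rng.uniform(-0.02, 0.02, size=3)
            radius = 0.055
            d = (((u - centre[:, None, None, None]) / radius) ** 2).sum(axis=0)
            inside = d <= 1.0
            if inside.sum() == 0:
                continue
            if np.all(labels[inside] == WHITE):
                labels[inside] = DEEP_FIRST + i
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place deep structure {i} strictly inside white matter; "
                "grid too small or jitter too large"
            )

    mask = brain_mask_from_labels(labels)
    return labels, mask, spec.spacing


def brain_mask_from_labels(labels: np.ndarray) -> np.ndarray:
    """Union of intracranial classes: everything except background and skull."""
    return (labels >= CSF).astype(np.uint8)


def render_sequence(
    label_volume: np.ndarray,
    sequence_name: str,
    spec: PhantomSpec,
    noise_seed: int = 0,
) -> np.ndarray:
    """Render one pseudo-sequence: LUT intensity x bias field + noise."""
    if sequence_name not in spec.contrast_table:
        raise ValueError(
            f"unknown sequence {sequence_name!r}; known: {sorted(spec.contrast_table)}"
        )
    lut = _tissue_lut(spec, sequence_name)
    if label_volume.max() >= lut.size:
        raise ValueError("label volume contains labels beyond the spec's tissue set")
    out = lut[label_volume].astype(np.float64)
    rng = substream(noise_seed, f"render:{sequence_name}")
    if spec.bias_field_order > 0 and spec.bias_amplitude > 0:
        out = out * _bias_field(label_volume.shape, spec, rng)
    if spec.noise_sd > 0:
        out = out + rng.normal(0.0, spec.noise_sd, size=out.shape)
    return out


def _bias_field(shape, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Low-order multiplicative polynomial field, mean-normalised to 1."""
    grids = [np.linspace(-1, 1, s) for s in shape]
    x, y, z = np.meshgrid(*grids, indexing="ij")
    poly = np.zeros(shape)
    for i in range(spec.bias_field_order + 1):
        for j_ in range(spec.bias_field_order + 1 - i):
            for k in range(spec.bias_field_order + 1 - i - j_):
                if i + j_ + k == 0:
                    continue
                poly += rng.normal() * (x**i) * (y**j_) * (z**k)
    sd = poly.std()
    if sd > 0:
        poly = poly / sd * spec.bias_amplitude
    fieldv = 1.0 + poly - poly.mean()
    return np.clip(fieldv, 0.1, None)


def make_classification_set(
    n_per_class: int,
    sequences: list[str],
    seed: int,
    spec: PhantomSpec | None = None,
    preprocess_cfg: PreprocessConfig | None = None,
) -> list[SliceSample]:
    """Balanced labelled slice set for sequence classification.

    Slices are drawn from distinct subject seeds and axial positions within
    the mid-band of each phantom; class index = position in ``sequences``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not sequences:
        raise ValueError("sequence list must be non-empty")
    spec = spec if spec is not None else PhantomSpec()
    cfg = preprocess_cfg if preprocess_cfg is not None else PreprocessConfig()
    rng = substream(seed, "classification-set")
    samples: list[SliceSample] = []
    for class_idx, seq in enumerate(sequences):
        for i in range(n_per_class):
            subject = int(rng.integers(0, 2**31 - 1))
            labels, _, _ = make_phantom_volume(spec, subject)
            vol = render_sequence(labels, seq, spec, noise_seed=subject + 1)
            lo = int(0.30 * vol.shape[2])
            hi = int(0.70 * vol.shape[2])
            idx = int(rng.integers(lo, hi))
            samples.append(
                preprocess(
                    vol[:, :, idx],
                    cfg,
                    class_label=class_idx,
                    provenance=(f"phantom-{subject}", 2, idx),
                )
            )
    return samples
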