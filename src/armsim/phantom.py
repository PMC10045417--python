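"""Parametric layered-arm phantom.

Generates a ground-truth :class:`LabelVolume` for a tapered, concentric-but-
eccentric five-tissue limb (skin, fat, muscle, cortical bone, marrow) and
renders it into a noisy grayscale :class:`SliceStack` emulating a serial
cryosection acquisition.

Conventions
-----------
* Axial slices are stacked along z; arrays are indexed ``[z, y, x]``.
* Voxel center physical position = ``origin + (index + 0.5) * spacing`` (mm).
* Labels: 0 = background, then tissues numbered innermost→outermost
  (marrow=1 … skin=5), so the outermost layer carries the highest label.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import tifffile
import yaml

__all__ = [
    "BACKGROUND",
    "MARROW",
    "CORTICAL",
    "MUSCLE",
    "FAT",
    "SKIN",
    "TISSUE_NAMES",
    "TISSUE_LABELS",
    "BoneSpec",
    "PhantomSpec",
    "GrayIndex",
    "LabelVolume",
    "SliceStack",
    "build_phantom",
    "render_slices",
]

BACKGROUND = 0
MARROW = 1
CORTICAL = 2
MUSCLE = 3
FAT = 4
SKIN = 5

#: label → human-readable tissue name (outermost layer has the highest label)
TISSUE_NAMES: dict[int, str] = {
    MARROW: "marrow",
    CORTICAL: "cortical_bone",
    MUSCLE: "muscle",
    FAT: "fat",
    SKIN: "skin",
}
TISSUE_LABELS: dict[str, int] = {v: k for k, v in TISSUE_NAMES.items()}


class PhantomSpecError(ValueError):
    """Raised when a :class:`PhantomSpec` is geometrically inconsistent."""


@dataclass(frozen=True)
class BoneSpec:
    """One eccentric bone: a cortical shell around a marrow core.

    ``center`` is the (x, y) offset of the bone axis from the limb axis in mm;
    ``outer_radius`` is the cortical outer radius; the marrow core radius is
    ``outer_radius - cortical_thickness``.
    """

    center: tuple[float, float] = (3.0, 2.0)
    outer_radius: float = 6.0
    cortical_thickness: float = 2.0

    def __post_init__(self) -> None:
        if self.outer_radius <= 0:
            raise PhantomSpecError("bone outer_radius must be > 0")
        if not 0 < self.cortical_thickness < self.outer_radius:
            raise PhantomSpecError(
                "cortical_thickness must be in (0, outer_radius)"
            )

    @property
    def marrow_radius(self) -> float:
        return self.outer_radius - self.cortical_thickness


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the synthetic layered limb.

    ``outer_radius_profile`` gives the outer (skin) radius per slice; the
    default factory builds a linear taper.  ``layer_thicknesses`` holds the
    skin and fat annulus thicknesses; the ``muscle`` entry is the minimum
    guaranteed muscle margin between fat and any bone (muscle itself fills
    everything inside the fat annulus that is not bone).
    """

    n_slices: int = 96
    slice_spacing: float = 1.0
    pixel_spacing: float = 1.0
    image_size: int = 48
    outer_radius_profile: tuple[float, ...] = ()
    layer_thicknesses: Mapping[str, float] = field(
        default_factory=lambda: {"skin": 1.5, "fat": 3.0, "muscle": 2.0}
    )
    bones: tuple[BoneSpec, ...] = (BoneSpec(),)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise PhantomSpecError("n_slices must be >= 1")
        if self.slice_spacing <= 0 or self.pixel_spacing <= 0:
            raise PhantomSpecError("spacings must be > 0")
        profile = self.outer_radius_profile
        if len(profile) == 0:
            # default linear taper: proximal 20 mm → distal 16 mm (scaled to grid)
            rmax = 0.42 * self.image_size * self.pixel_spacing
            profile = tuple(np.linspace(rmax, 0.8 * rmax, self.n_slices))
            object.__setattr__(self, "outer_radius_profile", profile)
        if len(profile) != self.n_slices:
            raise PhantomSpecError(
                f"outer_radius_profile has {len(profile)} entries, "
                f"expected n_slices={self.n_slices}"
            )
        for name, t in self.layer_thicknesses.items():
            if t < 0:
                raise PhantomSpecError(f"layer thickness {name!r} must be >= 0")
        t_skin = self.layer_thicknesses.get("skin", 0.0)
        t_fat = self.layer_thicknesses.get("fat", 0.0)
        t_muscle = self.layer_thicknesses.get("muscle", 0.0)
        for k, r_outer in enumerate(profile):
            if r_outer <= 0:
                raise PhantomSpecError(f"outer radius <= 0 at slice {k}")
            if t_skin + t_fat >= r_outer:
                raise PhantomSpecError(
                    f"annulus thicknesses ({t_skin + t_fat} mm) >= outer "
                    f"radius ({r_outer} mm) at slice {k}"
                )
            r_muscle = r_outer - t_skin - t_fat
            for b in self.bones:
                d = float(np.hypot(*b.center))
                if d + b.outer_radius + t_muscle >= r_muscle:
                    raise PhantomSpecError(
                        f"bone at {b.center} not strictly inside the muscle "
                        f"region at slice {k} (needs margin {t_muscle} mm)"
                    )

    @property
    def skin_thickness(self) -> float:
        return float(self.layer_thicknesses.get("skin", 0.0))

    @property
    def fat_thickness(self) -> float:
        return float(self.layer_thicknesses.get("fat", 0.0))


@dataclass(frozen=True)
class GrayIndex:
    """Per-tissue mean gray values and noise levels (16-bit intensity scale)."""

    means: Mapping[int, float] = field(
        default_factory=lambda: {
            SKIN: 60.0,
            FAT: 110.0,
            MUSCLE: 160.0,
            CORTICAL: 210.0,
            MARROW: 245.0,
        }
    )
    sds: Mapping[int, float] = field(default_factory=dict)
    background: float = 10.0
    background_sd: float = 0.0
    intensity_max: float = 255.0
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        vals = list(self.means.values()) + [self.background]
        if len(set(vals)) != len(vals):
            raise ValueError("mean gray values must be pairwise distinct")
        if not self.allow_overlap:
            entries = sorted(
                [(self.background, self.background_sd)]
                + [(m, self.sds.get(lab, 0.0)) for lab, m in self.means.items()]
            )
            for (m0, s0), (m1, s1) in zip(entries, entries[1:]):
                if m0 + 2 * s0 > m1 - 2 * s1:
                    raise ValueError(
                        f"±2sd intervals of gray means {m0} and {m1} overlap; "
                        "pass allow_overlap=True to permit"
                    )

    def sd_for(self, label: int) -> float:
        return float(self.sds.get(label, 0.0))


@dataclass
class LabelVolume:
    """3-D voxel grid of tissue labels with physical spacing (mm)."""

    labels: np.ndarray  # (nz, ny, nx) integer array
    spacing: tuple[float, float, float]  # (dz, dy, dx) mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # corner, mm

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def voxel_centers_1d(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical center coordinates along each axis: (z, y, x) in mm."""
        nz, ny, nx = self.labels.shape
        dz, dy, dx = self.spacing
        oz, oy, ox = self.origin
        return (
            oz + (np.arange(nz) + 0.5) * dz,
            oy + (np.arange(ny) + 0.5) * dy,
            ox + (np.arange(nx) + 0.5) * dx,
        )

    def tissue_volume(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)) * self.voxel_volume

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            labels=self.labels.astype(np.int16),
            spacing=np.asarray(self.spacing, dtype=float),
            origin=np.asarray(self.origin, dtype=float),
        )

    @classmethod
    def load(cls, path: str | Path) -> "LabelVolume":
        with np.load(path) as data:
            return cls(
                labels=data["labels"].astype(np.int64),
                spacing=tuple(data["spacing"]),
                origin=tuple(data["origin"]),
            )


@dataclass
class SliceStack:
    """Ordered grayscale image stack plus spacing metadata."""

    images: list[np.ndarray]  # each (ny, nx) float
    slice_spacing: float
    pixel_spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("stack must contain at least one image")
        shape = self.images[0].shape
        for i, img in enumerate(self.images):
            if img.ndim != 2 or img.shape != shape:
                raise ValueError(f"image {i} has shape {img.shape} != {shape}")
        if self.slice_spacing <= 0 or self.pixel_spacing <= 0:
            raise ValueError("spacing must be > 0")

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.images)

    def as_array(self) -> np.ndarray:
        return np.stack(self.images, axis=0)

    def save(self, directory: str | Path) -> None:
        """Write numbered 16-bit TIFFs plus a YAML stack manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        names = []
        for i, img in enumerate(self.images):
            name = f"slice_{i:04d}.tif"
            tifffile.imwrite(
                directory / name,
                np.clip(np.rint(img), 0, 65535).astype(np.uint16),
            )
            names.append(name)
        manifest = {
            "slice_spacing_mm": float(self.slice_spacing),
            "pixel_spacing_mm": float(self.pixel_spacing),
            "origin_mm": [float(v) for v in self.origin],
            "slices": names,
        }
        (directory / "stack.yaml").write_text(yaml.safe_dump(manifest))

    @classmethod
    def load(cls, directory: str | Path) -> "SliceStack":
        directory = Path(directory)
        manifest = yaml.safe_load((directory / "stack.yaml").read_text())
        images = [
            tifffile.imread(directory / name).astype(np.float64)
            for name in manifest["slices"]
        ]
        return cls(
            images=images,
            slice_spacing=manifest["slice_spacing_mm"],
            pixel_spacing=manifest["pixel_spacing_mm"],
            origin=tuple(manifest.get("origin_mm", (0.0, 0.0, 0.0))),
        )


def classify_point(spec: PhantomSpec, x: float, y: float, z_index: int) -> int:
    """Label of the innermost analytic region containing physical point (x, y).

    Scalar reference implementation used as the brute-force oracle; the
    vectorized :func:`build_phantom` must agree with it voxel-for-voxel.
    Coordinates are relative to the limb axis, in mm.
    """
    r_outer = spec.outer_radius_profile[z_index]
    for b in spec.bones:
        d = np.hypot(x - b.center[0], y - b.center[1])
        if d < b.marrow_radius:
            return MARROW
        if d < b.outer_radius:
            return CORTICAL
    r = np.hypot(x, y)
    if r < r_outer - spec.skin_thickness - spec.fat_thickness:
        return MUSCLE
    if r < r_outer - spec.skin_thickness:
        return FAT
    if r < r_outer:
        return SKIN
    return BACKGROUND


def build_phantom(spec: PhantomSpec) -> LabelVolume:
    """Voxelize the analytic phantom; innermost region wins at each center."""
    n = spec.image_size
    half = n * spec.pixel_spacing / 2.0
    origin = (0.0, -half, -half)
    coords = -half + (np.arange(n) + 0.5) * spec.pixel_spacing
    X, Y = np.meshgrid(coords, coords, indexing="xy")  # X varies along axis 1
    r = np.hypot(X, Y)
    labels = np.zeros((spec.n_slices, n, n), dtype=np.int16)
    t_skin, t_fat = spec.skin_thickness, spec.fat_thickness
    for k in range(spec.n_slices):
        r_outer = spec.outer_radius_profile[k]
        sl = np.zeros((n, n), dtype=np.int16)
        sl[r < r_outer] = SKIN
        sl[r < r_outer - t_skin] = FAT
        sl[r < r_outer - t_skin - t_fat] = MUSCLE
        for b in spec.bones:
            d = np.hypot(X - b.center[0], Y - b.center[1])
            sl[d < b.outer_radius] = CORTICAL
            sl[d < b.marrow_radius] = MARROW
        labels[k] = sl
    return LabelVolume(
        labels=labels,
        spacing=(spec.slice_spacing, spec.pixel_spacing, spec.pixel_spacing),
        origin=origin,
    )


def analytic_volume(spec: PhantomSpec, label: int) -> float:
    """Analytic (non-discretized) volume of one tissue region in mm^3."""
    dz = spec.slice_spacing
    t_skin, t_fat = spec.skin_thickness, spec.fat_thickness
    bone_area = sum(np.pi * b.outer_radius**2 for b in spec.bones)
    marrow_area = sum(np.pi * b.marrow_radius**2 for b in spec.bones)
    total = 0.0
    for r_outer in spec.outer_radius_profile:
        if label == SKIN:
            total += np.pi * (r_outer**2 - (r_outer - t_skin) ** 2)
        elif label == FAT:
            total += np.pi * (
                (r_outer - t_skin) ** 2 - (r_outer - t_skin - t_fat) ** 2
            )
        elif label == MUSCLE:
            total += np.pi * (r_outer - t_skin - t_fat) ** 2 - bone_area
        elif label == CORTICAL:
            total += bone_area - marrow_area
        elif label == MARROW:
            total += marrow_area
        else:  # whole body
            total += np.pi * r_outer**2
    return total * dz


def render_slices(vol: LabelVolume, gi: GrayIndex, seed: int = 0) -> SliceStack:
    """Render a label volume into a noisy grayscale stack.

    Each pixel is its tissue's mean gray plus clipped Gaussian noise;
    bit-identical for a given ``seed``.
    """
    present = np.unique(vol.labels)
    for lab in present:
        if lab != BACKGROUND and int(lab) not in gi.means:
            raise KeyError(
                f"gray index has no entry for label {int(lab)} "
                f"({TISSUE_NAMES.get(int(lab), 'unknown')})"
            )
    nz = vol.labels.shape[0]
    mean_lut = np.zeros(int(present.max()) + 1, dtype=np.float64)
    sd_lut = np.zeros_like(mean_lut)
    mean_lut[BACKGROUND] = gi.background
    sd_lut[BACKGROUND] = gi.background_sd
    for lab in present:
        if lab != BACKGROUND:
            mean_lut[lab] = gi.means[int(lab)]
            sd_lut[lab] = gi.sd_for(int(lab))
    rng = np.random.default_rng(seed)
    images = []
    for k in range(nz):
        sl = vol.labels[k]
        img = mean_lut[sl]
        sd = sd_lut[sl]
        if np.any(sd > 0):
            img = img + rng.standard_normal(sl.shape) * sd
        images.append(np.clip(img, 0.0, gi.intensity_max))
    return SliceStack(
        images=images,
        slice_spacing=vol.spacing[0],
        pixel_spacing=vol.spacing[1],
        origin=vol.origin,
    )


def spec_from_yaml(path: str | Path) -> PhantomSpec:
    """Load a :class:`PhantomSpec` from a YAML mapping."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "bones" in raw:
        raw["bones"] = tuple(
            BoneSpec(
                center=tuple(b.get("center", (3.0, 2.0))),
                outer_radius=b.get("outer_radius", 6.0),
                cortical_thickness=b.get("cortical_thickness", 2.0),
            )
            for b in raw["bones"]
        )
    if "outer_radius_profile" in raw:
        raw["outer_radius_profile"] = tuple(raw["outer_radius_profile"])
    allowed = {f.name for f in dataclasses.fields(PhantomSpec)}
    unknown = set(raw) - allowed
    if unknown:
        raise PhantomSpecError(f"unknown phantom spec fields: {sorted(unknown)}")
    return PhantomSpec(**raw)


def gray_index_to_csv(gi: GrayIndex, path: str | Path) -> None:
    lines = ["label,tissue,mean_gray,noise_sd"]
    lines.append(f"0,background,{gi.background},{gi.background_sd}")
    for lab in sorted(gi.means):
        lines.append(
            f"{lab},{TISSUE_NAMES.get(lab, str(lab))},{gi.means[lab]},{gi.sd_for(lab)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
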