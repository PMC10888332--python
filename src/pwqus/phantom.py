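"""Breast-tissue-mimicking acoustic phantoms.

A phantom is a set of co-registered 2D property maps over a square region of
interest (ROI): attenuation coefficient (AC, dB/cm/MHz), speed of sound
(SoS, m/s), mass density (kg/m^3), effective scatterer diameter (ESD, um)
and effective scatterer concentration (ESC, scatterers per squared
wavelength).  Phantoms are built from a layered background (skin / fat /
gland) with an optional embedded lesion (cyst, benign or malignant tumor)
whose outline is an ellipse or a boundary-perturbed polygon.

Property values per tissue class are drawn uniformly from configurable
ranges chosen to bracket published group statistics for benign and
malignant breast lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LesionClass",
    "TissuePhantom",
    "LesionSpec",
    "LayerSpec",
    "TISSUE_PROPERTY_RANGES",
    "sample_tissue_properties",
    "rasterize_lesion",
    "generate_phantom",
    "uniform_phantom",
    "default_breast_layers",
    "save_phantom",
    "load_phantom",
]

PROPERTY_NAMES = ("ac", "sos", "density", "esd", "esc")


class LesionClass(str, Enum):
    none = "none"
    cyst = "cyst"
    benign = "benign"
    malignant = "malignant"


#: Per-class (low, high) uniform sampling ranges.
#: ac: dB/cm/MHz, sos: m/s, density: kg/m^3, esd: um, esc: /wavelength^2
TISSUE_PROPERTY_RANGES: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "fat": {
        "ac": (0.3, 0.8),
        "sos": (1420, 1490),
        "density": (930, 970),
        "esd": (75, 105),
        "esc": (1.2, 4.2),
    },
    "gland": {
        "ac": (0.3, 0.8),
        "sos": (1500, 1580),
        "density": (1000, 1060),
        "esd": (75, 105),
        "esc": (1.2, 4.2),
    },
    "skin": {
        "ac": (0.6, 1.2),
        "sos": (1590, 1640),
        "density": (1050, 1120),
        "esd": (60, 90),
        "esc": (2.0, 5.0),
    },
    "cyst": {
        "ac": (0.05, 0.2),
        "sos": (1480, 1540),
        "density": (990, 1010),
        "esd": (30, 60),
        "esc": (0.4, 1.2),
    },
    "benign": {
        "ac": (0.35, 0.65),
        "sos": (1520, 1560),
        "density": (1000, 1080),
        "esd": (85, 105),
        "esc": (1.2, 4.2),
    },
    "malignant": {
        "ac": (0.6, 1.1),
        "sos": (1545, 1600),
        "density": (1000, 1100),
        "esd": (70, 92),
        "esc": (1.2, 4.2),
    },
}


def sample_tissue_properties(
    tissue_class: str, rng_seed: int | np.random.Generator
) -> dict[str, float]:
    """Draw one value per acoustic/structural property for a tissue class.

    Parameters
    ----------
    tissue_class : str
        One of ``fat, gland, skin, cyst, benign, malignant``.
    rng_seed : int or numpy Generator
        Seed (or generator) controlling the draw; the same seed always
        yields the same values.
    """
    if tissue_class not in TISSUE_PROPERTY_RANGES:
        raise ValueError(
            f"unknown tissue class {tissue_class!r}; expected one of "
            f"{sorted(TISSUE_PROPERTY_RANGES)}"
        )
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator
    ) else rng_seed
    ranges = TISSUE_PROPERTY_RANGES[tissue_class]
    return {name: float(rng.uniform(*ranges[name])) for name in PROPERTY_NAMES}


@dataclass
class LesionSpec:
    """Geometric + acoustic description of one embedded lesion.

    ``shape`` is ``"ellipse"`` or ``"perturbed-polygon"``; for the latter the
    ellipse boundary radius is modulated by a random smooth angular
    perturbation of relative amplitude ``boundary_roughness``.
    """

    shape: str = "ellipse"
    center_mm: tuple[float, float] = (25.0, 25.0)  # (lateral, depth)
    axes_mm: tuple[float, float] = (5.0, 5.0)  # semi-axes (lateral, depth)
    boundary_roughness: float = 0.0
    property_values: dict[str, float] = field(default_factory=dict)
    class_label: LesionClass = LesionClass.benign

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse", "perturbed-polygon"):
            raise ValueError(f"unknown lesion shape {self.shape!r}")
        if min(self.axes_mm) <= 0:
            raise ValueError("lesion axes must be positive")
        self.class_label = LesionClass(self.class_label)


@dataclass
class LayerSpec:
    """One horizontal background layer: a tissue class and its thickness.

    ``thickness_mm=None`` means "fill the remaining depth".
    """

    tissue_class: str
    thickness_mm: float | None = None
    property_values: dict[str, float] | None = None


@dataclass
class TissuePhantom:
    """Co-registered property maps over the region of interest."""

    ac_map: np.ndarray  # dB/cm/MHz
    sos_map: np.ndarray  # m/s
    density_map: np.ndarray  # kg/m^3
    esd_map: np.ndarray  # um
    esc_map: np.ndarray  # /wavelength^2
    pixel_pitch_mm: float
    lesion_mask: np.ndarray
    lesion_class: LesionClass = LesionClass.none
    seed: int | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.ac_map.shape

    @property
    def roi_mm(self) -> tuple[float, float]:
        """(lateral width, depth) of the ROI in mm."""
        ny, nx = self.ac_map.shape
        return (nx * self.pixel_pitch_mm, ny * self.pixel_pitch_mm)

    def maps(self) -> dict[str, np.ndarray]:
        return {
            "ac": self.ac_map,
            "sos": self.sos_map,
            "density": self.density_map,
            "esd": self.esd_map,
            "esc": self.esc_map,
        }

    def validate(self) -> None:
        shapes = {m.shape for m in self.maps().values()}
        shapes.add(self.lesion_mask.shape)
        if len(shapes) != 1:
            raise ValueError("all property maps must share one grid")
        if np.any(self.ac_map < 0):
            raise ValueError("ac_map must be non-negative")
        if np.any((self.sos_map < 1300) | (self.sos_map > 1700)):
            raise ValueError("sos_map outside [1300, 1700] m/s")
        if np.any(self.esd_map <= 0) or np.any(self.esc_map <= 0):
            raise ValueError("esd_map and esc_map must be positive")
        if (self.lesion_class == LesionClass.none) != (not self.lesion_mask.any()):
            raise ValueError("lesion_mask must be empty iff lesion_class is none")


def _pixel_centers(n: int, pitch_mm: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * pitch_mm


def rasterize_lesion(
    spec: LesionSpec,
    grid_shape: tuple[int, int],
    pixel_pitch_mm: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the lesion outline.

    The perturbed-polygon shape modulates the ellipse radius with a low-order
    Fourier series in polar angle, giving irregular but smooth boundaries.
    """
    ny, nx = grid_shape
    x = _pixel_centers(nx, pixel_pitch_mm)[None, :] - spec.center_mm[0]
    z = _pixel_centers(ny, pixel_pitch_mm)[:, None] - spec.center_mm[1]
    a, b = spec.axes_mm
    # normalized radius: 1 on the unperturbed ellipse boundary
    r = np.sqrt((x / a) ** 2 + (z / b) ** 2)
    if spec.shape == "ellipse" or spec.boundary_roughness == 0:
        return r <= 1.0
    if rng is None:
        rng = np.random.default_rng(0)
    phi = np.arctan2(z / b, x / a)
    bound = np.ones_like(phi)
    for k in range(2, 6):  # low-order harmonics -> smooth lobes
        amp = rng.normal(0.0, spec.boundary_roughness / 2)
        ph = rng.uniform(0, 2 * np.pi)
        bound = bound + amp * np.cos(k * phi + ph)
    return r <= np.clip(bound, 0.2, None)


def default_breast_layers(skin_mm: float = 2.0, fat_mm: float = 8.0) -> list[LayerSpec]:
    """Skin / subcutaneous fat / gland background stack."""
    return [
        LayerSpec("skin", skin_mm),
        LayerSpec("fat", fat_mm),
        LayerSpec("gland", None),
    ]


def generate_phantom(
    layers: Sequence[LayerSpec] | None = None,
    lesion: LesionSpec | None = None,
    rng_seed: int = 0,
    pixel_pitch_mm: float = 0.2,
    grid_shape: tuple[int, int] = (256, 256),
) -> TissuePhantom:
    """Build a layered phantom with an optional embedded lesion.

    The result is a pure function of the specs and the seed.  Layer property
    values not pinned in the spec are drawn once per layer from the class
    ranges; lesion values similarly, unless ``lesion.property_values`` pins
    them.

    Raises
    ------
    ValueError
        If the lesion does not fit inside the region of interest.
    """
    rng = np.random.default_rng(rng_seed)
    ny, nx = grid_shape
    roi = (nx * pixel_pitch_mm, ny * pixel_pitch_mm)
    if layers is None:
        layers = default_breast_layers()

    maps = {name: np.zeros(grid_shape, dtype=np.float64) for name in PROPERTY_NAMES}
    z = _pixel_centers(ny, pixel_pitch_mm)
    top = 0.0
    for i, layer in enumerate(layers):
        props = layer.property_values or sample_tissue_properties(layer.tissue_class, rng)
        bottom = roi[1] if layer.thickness_mm is None or i == len(layers) - 1 else (
            top + layer.thickness_mm
        )
        rows = (z >= top) & (z < bottom if bottom < roi[1] else z <= roi[1] + 1)
        for name in PROPERTY_NAMES:
            maps[name][rows, :] = props[name]
        top = bottom

    lesion_mask = np.zeros(grid_shape, dtype=bool)
    lesion_class = LesionClass.none
    if lesion is not None:
        cx, cz = lesion.center_mm
        a, b = lesion.axes_mm
        if not (0 <= cx - a and cx + a <= roi[0] and 0 <= cz - b and cz + b <= roi[1]):
            raise ValueError(
                f"lesion (center {lesion.center_mm} mm, axes {lesion.axes_mm} mm) "
                f"does not fit inside the {roi[0]:.1f} x {roi[1]:.1f} mm region"
            )
        lesion_mask = rasterize_lesion(lesion, grid_shape, pixel_pitch_mm, rng)
        lesion_class = lesion.class_label
        props = dict(
            sample_tissue_properties(lesion.class_label.value, rng),
            **lesion.property_values,
        )
        for name in PROPERTY_NAMES:
            maps[name][lesion_mask] = props[name]
        # density contrast default: +-5% around background handled by ranges

    phantom = TissuePhantom(
        ac_map=maps["ac"],
        sos_map=maps["sos"],
        density_map=maps["density"],
        esd_map=maps["esd"],
        esc_map=maps["esc"],
        pixel_pitch_mm=pixel_pitch_mm,
        lesion_mask=lesion_mask,
        lesion_class=lesion_class,
        seed=rng_seed if isinstance(rng_seed, int) else None,
    )
    phantom.validate()
    return phantom


def uniform_phantom(
    ac: float = 0.5,
    sos: float = 1540.0,
    esd: float = 85.0,
    esc: float = 2.0,
    density: float = 1000.0,
    pixel_pitch_mm: float = 0.2,
    grid_shape: tuple[int, int] = (256, 256),
) -> TissuePhantom:
    """Homogeneous phantom, e.g. the reference for spectral normalization."""
    full = lambda v: np.full(grid_shape, float(v))
    p = TissuePhantom(
        ac_map=full(ac),
        sos_map=full(sos),
        density_map=full(density),
        esd_map=full(esd),
        esc_map=full(esc),
        pixel_pitch_mm=pixel_pitch_mm,
        lesion_mask=np.zeros(grid_shape, dtype=bool),
        lesion_class=LesionClass.none,
    )
    p.validate()
    return p


def save_phantom(phantom: TissuePhantom, path) -> None:
    """Write a phantom to HDF5 (one dataset per map + grid attributes)."""
    import h5py

    with h5py.File(path, "w") as f:
        for name, arr in phantom.maps().items():
            f.create_dataset(name, data=arr)
        f.create_dataset("lesion_mask", data=phantom.lesion_mask)
        f.attrs["pixel_pitch_mm"] = phantom.pixel_pitch_mm
        f.attrs["lesion_class"] = phantom.lesion_class.value
        if phantom.seed is not None:
            f.attrs["seed"] = phantom.seed


def load_phantom(path) -> TissuePhantom:
    import h5py

    with h5py.File(path, "r") as f:
        maps = {name: f[name][...] for name in PROPERTY_NAMES}
        phantom = TissuePhantom(
            ac_map=maps["ac"],
            sos_map=maps["sos"],
            density_map=maps["density"],
            esd_map=maps["esd"],
            esc_map=maps["esc"],
            pixel_pitch_mm=float(f.attrs["pixel_pitch_mm"]),
            lesion_mask=f["lesion_mask"][...].astype(bool),
            lesion_class=LesionClass(f.attrs["lesion_class"]),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )
    phantom.validate()
    return phantom
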