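"""Digital abdominal phantom for diffusion-weighted MRI simulation.

The phantom is a 2-D section through a mouse abdomen at the level of a
pancreatic tumor: an elliptical body, a tumor, a band of spinal muscle, and
two 5-mm reference tubes (water and 1-butanol) resting under the animal.
Each compartment carries a proton-density amplitude ``s0``, a true
diffusivity ``d_true`` (mm^2/s) and an optional chemical-shift offset (ppm
relative to water) used by the EPI simulator.  T1/T2 weighting is not
modeled separately; ``s0`` absorbs all relaxation weighting, matching a fit
in which the zero-b amplitude is a free parameter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import nibabel as nib

__all__ = [
    "Compartment",
    "PhantomSpec",
    "ParameterImages",
    "rasterize",
    "true_signal",
    "default_phantom",
    "roi_masks",
]


@dataclass
class Compartment:
    """One geometric compartment (ellipse; a disk is the equal-axes case).

    ``center`` and ``semi_axes`` are in mm, in a coordinate frame whose
    origin is the FOV center (x to the right, y up).  ``priority`` resolves
    overlaps: the higher value wins; equal-priority overlap is an error.
    """

    name: str
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    s0: float
    d_true: float
    chem_shift: float = 0.0  # ppm relative to water
    priority: int = 0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError(f"compartment {self.name!r}: s0 must be >= 0")
        if self.d_true < 0:
            raise ValueError(f"compartment {self.name!r}: d_true must be >= 0")
        if min(self.semi_axes) <= 0:
            raise ValueError(f"compartment {self.name!r}: semi-axes must be > 0")

    def covers(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        ax, ay = self.semi_axes
        cx, cy = self.center
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0


@dataclass
class PhantomSpec:
    """A square field of view populated with compartments."""

    fov: float = 32.0  # mm
    compartments: list[Compartment] = field(default_factory=list)
    field_strength: float = 4.7  # Tesla

    def __post_init__(self) -> None:
        if self.fov <= 0:
            raise ValueError("fov must be > 0")
        if not self.compartments:
            raise ValueError("phantom requires at least one compartment")
        half = self.fov / 2
        for c in self.compartments:
            if abs(c.center[0]) > half or abs(c.center[1]) > half:
                raise ValueError(f"compartment {c.name!r} center outside FOV")

    # -- JSON round trip ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "fov": self.fov,
            "field_strength": self.field_strength,
            "compartments": [asdict(c) for c in self.compartments],
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        doc = json.loads(Path(path).read_text())
        comps = [
            Compartment(
                name=c["name"],
                center=tuple(c["center"]),
                semi_axes=tuple(c["semi_axes"]),
                s0=c["s0"],
                d_true=c["d_true"],
                chem_shift=c.get("chem_shift", 0.0),
                priority=c.get("priority", 0),
            )
            for c in doc["compartments"]
        ]
        return cls(fov=doc["fov"], compartments=comps,
                   field_strength=doc.get("field_strength", 4.7))


@dataclass
class ParameterImages:
    """Rasterized per-pixel parameter maps.

    ``label_map`` holds the index (into ``names``) of the compartment owning
    each pixel, or -1 outside all compartments.
    """

    s0_map: np.ndarray
    d_map: np.ndarray
    shift_map: np.ndarray
    label_map: np.ndarray
    pixel_mm: float
    fov: float
    field_strength: float
    names: list[str]

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.s0_map, self.d_map,
                                    self.shift_map, self.label_map)}
        if len(shapes) != 1:
            raise ValueError("all maps must share one shape")
        if np.any(self.s0_map < 0):
            raise ValueError("s0_map must be non-negative")

    @property
    def matrix(self) -> int:
        return self.s0_map.shape[0]

    def to_nifti(self, path: str | Path) -> None:
        """One 4-D volume: s0, d, shift, label stacked along the last axis."""
        vol = np.stack(
            [self.s0_map, self.d_map, self.shift_map,
             self.label_map.astype(float)], axis=-1)
        aff = np.diag([self.pixel_mm, self.pixel_mm, 1.0, 1.0])
        nib.save(nib.Nifti1Image(vol[:, :, None, :], aff), str(path))


def pixel_centers(fov: float, matrix: int) -> np.ndarray:
    """1-D array of pixel-center coordinates (mm), origin at FOV center."""
    pix = fov / matrix
    return (np.arange(matrix) - matrix / 2) * pix + pix / 2


def rasterize(spec: PhantomSpec, matrix: int, oversample: int = 1) -> ParameterImages:
    """Rasterize a phantom spec by pixel-center point sampling.

    With ``oversample`` > 1 each pixel is subdivided (anti-aliasing of the
    label is still winner-takes-all on the sub-grid majority; parameter maps
    then average compartment values over sub-pixels).
    """
    if matrix < 16:
        raise ValueError("matrix must be >= 16")
    if oversample < 1:
        raise ValueError("oversample must be >= 1")

    ordered = sorted(range(len(spec.compartments)),
                     key=lambda i: spec.compartments[i].priority)
    # equal-priority overlap check (pairwise on the sampling grid)
    xc = pixel_centers(spec.fov, matrix * oversample)
    X, Y = np.meshgrid(xc, xc)

    cover = [spec.compartments[i].covers(X, Y) for i in range(len(spec.compartments))]
    for a in range(len(spec.compartments)):
        for b in range(a + 1, len(spec.compartments)):
            ca, cb = spec.compartments[a], spec.compartments[b]
            if ca.priority == cb.priority and np.any(cover[a] & cover[b]):
                raise ValueError(
                    f"compartments {ca.name!r} and {cb.name!r} overlap "
                    f"with equal priority {ca.priority}")

    fine = matrix * oversample
    label = np.full((fine, fine), -1, dtype=int)
    for i in ordered:  # ascending priority; later (higher) overwrite
        label[cover[i]] = i

    s0 = np.zeros((fine, fine))
    d = np.zeros((fine, fine))
    shift = np.zeros((fine, fine))
    for i, c in enumerate(spec.compartments):
        sel = label == i
        s0[sel] = c.s0
        d[sel] = c.d_true
        shift[sel] = c.chem_shift

    if oversample > 1:
        def block_mean(a):
            return a.reshape(matrix, oversample, matrix, oversample).mean(axis=(1, 3))
        s0 = block_mean(s0)
        d = block_mean(d)
        shift = block_mean(shift)
        # label by sub-grid majority (background competes too)
        lab = np.full((matrix, matrix), -1, dtype=int)
        blocks = label.reshape(matrix, oversample, matrix, oversample)
        counts = np.stack(
            [(blocks == i).sum(axis=(1, 3)) for i in range(-1, len(spec.compartments))])
        lab = counts.argmax(axis=0) - 1
        label = lab

    return ParameterImages(
        s0_map=s0, d_map=d, shift_map=shift, label_map=label,
        pixel_mm=spec.fov / matrix, fov=spec.fov,
        field_strength=spec.field_strength,
        names=[c.name for c in spec.compartments])


def true_signal(maps: ParameterImages, b: float) -> np.ndarray:
    """Noise-free diffusion-weighted signal S0 * exp(-b * D) per pixel."""
    if b < 0:
        raise ValueError("b must be >= 0")
    return maps.s0_map * np.exp(-b * maps.d_map)


# ---------------------------------------------------------------------------
# Default study phantom
# ---------------------------------------------------------------------------

#: Effective 1-butanol resonance offset relative to water, ppm.  Butanol's
#: aliphatic protons (1.56, 1.25, 0.8 ppm, with most signal near 1.56 ppm)
#: sit ~3.1 ppm upfield of water at 4.7 ppm; a single effective resonance is
#: enough to reproduce the EPI off-resonance corruption of the butanol tube.
BUTANOL_SHIFT_PPM = -3.1

# Reference diffusivities, mm^2/s: free water at 37 C, murine PDAC tumor,
# skeletal muscle, 1-butanol.
D_WATER_37C = 3.20e-3
D_TUMOR = 1.3e-3
D_MUSCLE = 1.8e-3
D_BUTANOL = 0.44e-3


def default_phantom(
    d_water: float = D_WATER_37C,
    d_tumor: float = D_TUMOR,
    d_muscle: float = D_MUSCLE,
    d_butanol: float = D_BUTANOL,
    fov: float = 32.0,
    tube_radius: float = 2.1,
) -> PhantomSpec:
    """Mouse-abdomen section: body, tumor, spinal muscle, two 5-mm tubes.

    Tube inner radius defaults to 2.1 mm (5-mm NMR tubes).  Compartment
    placement is a geometric convention, not fitted to any image.
    """
    comps = [
        Compartment("body", (0.0, 2.0), (13.0, 9.5), s0=0.7,
                    d_true=2.0e-3, priority=1),
        Compartment("tumor", (4.0, 1.0), (5.0, 4.0), s0=0.9,
                    d_true=d_tumor, priority=2),
        Compartment("muscle", (0.0, 8.0), (6.5, 2.2), s0=0.8,
                    d_true=d_muscle, priority=3),
        Compartment("water", (-8.0, -11.0), (tube_radius, tube_radius),
                    s0=1.0, d_true=d_water, priority=4),
        Compartment("butanol", (8.0, -11.0), (tube_radius, tube_radius),
                    s0=0.9, d_true=d_butanol,
                    chem_shift=BUTANOL_SHIFT_PPM, priority=4),
    ]
    return PhantomSpec(fov=fov, compartments=comps)


def roi_masks(maps: ParameterImages, erode: int = 2) -> dict[str, np.ndarray]:
    """Per-compartment ROI masks from the label map, eroded to avoid edge
    pixels (partial volume / reconstruction ringing)."""
    from scipy.ndimage import binary_erosion

    out: dict[str, np.ndarray] = {}
    for i, name in enumerate(maps.names):
        m = maps.label_map == i
        if erode > 0:
            m = binary_erosion(m, iterations=erode)
        out[name] = m
    return out
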