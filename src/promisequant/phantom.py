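"""Synthetic whole-body PSMA PET phantom generator.

Produces a co-registered SUV volume, organ label map and lesion ground truth
with the statistical structure the analysis pipeline assumes: organ-specific
tracer uptake following the PSMA biodistribution ordering (excretory organs
>> liver >> blood pool >> bone/background), spherical lesions in the bone /
lymph / prostate compartments, a breathing-attenuation artifact in the liver
(a superior slab of artifactually low uptake), Gaussian point-spread blur,
and SUV-dependent Gaussian noise as a variance-scaling surrogate for Poisson
counting noise.

The phantom is piecewise-constant before degradation, so every organ's clean
mean uptake and every lesion's true extent are known exactly; "realized"
lesion values (what detection actually sees) are recorded after blur and
noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import ndimage

from . import vocabulary as vb
from .grid import VoxelGrid, write_volume

__all__ = [
    "Shape",
    "OrganSpec",
    "LesionSpec",
    "PhantomSpec",
    "LesionTruth",
    "GroundTruth",
    "make_phantom",
    "SuiteVariability",
    "phantom_suite",
    "default_spec",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class Shape(BaseModel):
    """One geometric primitive: ellipsoid, z-axis elliptical cylinder, or box.

    Cylinders and boxes are half-open at their upper bound so that stacked
    primitives sharing a face do not claim the same voxel centers.
    """

    model_config = ConfigDict(extra="forbid")

    kind: Literal["ellipsoid", "cylinder", "box"]
    center: Optional[tuple[float, float, float]] = None  # ellipsoid/cylinder (mm)
    radii: Optional[tuple[float, ...]] = None  # ellipsoid (3) / cylinder (2), mm
    z_range: Optional[tuple[float, float]] = None  # cylinder, mm
    low: Optional[tuple[float, float, float]] = None  # box, mm
    high: Optional[tuple[float, float, float]] = None

    def rasterize(self, coords: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
        X, Y, Z = coords
        if self.kind == "ellipsoid":
            cx, cy, cz = self.center
            rx, ry, rz = self.radii
            return ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 + ((Z - cz) / rz) ** 2 < 1.0
        if self.kind == "cylinder":
            cx, cy, _ = (*self.center, 0.0) if len(self.center) == 2 else self.center
            rx, ry = self.radii
            zmin, zmax = self.z_range
            return (
                (((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 < 1.0)
                & (Z >= zmin)
                & (Z < zmax)
            )
        lo, hi = self.low, self.high
        return (
            (X >= lo[0]) & (X < hi[0])
            & (Y >= lo[1]) & (Y < hi[1])
            & (Z >= lo[2]) & (Z < hi[2])
        )

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        if self.kind == "ellipsoid":
            c, r = np.asarray(self.center), np.asarray(self.radii)
            return c - r, c + r
        if self.kind == "cylinder":
            cx, cy = self.center[0], self.center[1]
            rx, ry = self.radii
            zmin, zmax = self.z_range
            return np.array([cx - rx, cy - ry, zmin]), np.array([cx + rx, cy + ry, zmax])
        return np.asarray(self.low, float), np.asarray(self.high, float)


class OrganSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    label_id: int
    name: str
    suv: float = Field(ge=0)
    shapes: list[Shape]


class LesionSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    center_mm: tuple[float, float, float]
    diameter_mm: float = Field(gt=0)
    peak_suv: float = Field(gt=0)
    compartment: Literal["bone", "lymph", "prostate"]


class PhantomSpec(BaseModel):
    """Declarative description of one phantom (geometry, uptake, degradation)."""

    model_config = ConfigDict(extra="forbid")

    shape: tuple[int, int, int] = (128, 128, 160)
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    background_suv: float = 0.8
    body: Shape = Field(
        default_factory=lambda: Shape(
            kind="cylinder", center=(192.0, 192.0, 0.0), radii=(180.0, 150.0),
            z_range=(6.0, 474.0),
        )
    )
    organs: list[OrganSpec] = Field(default_factory=list)
    lesions: list[LesionSpec] = Field(default_factory=list)
    psf_fwhm_mm: float = Field(default=6.0, ge=0)
    noise_sigma_scale: float = Field(default=0.1, ge=0)  # sigma = scale * sqrt(SUV)
    liver_artifact: Optional[tuple[float, float]] = (0.3, 0.5)  # (fraction, multiplier)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PhantomSpec":
        if self.liver_artifact is not None:
            frac, mult = self.liver_artifact
            if not (0.0 <= frac < 1.0):
                raise ValueError(f"liver artifact fraction must be in [0, 1), got {frac}")
            if mult < 0:
                raise ValueError("liver artifact multiplier must be >= 0")
        extent = np.asarray(self.shape) * np.asarray(self.spacing_mm)
        for organ in self.organs:
            for shp in organ.shapes:
                lo, hi = shp.bounds()
                if np.any(lo < -1e-9) or np.any(hi > extent + 1e-9):
                    raise ValueError(f"organ {organ.name!r} extends outside the grid")
        return self


@dataclass
class LesionTruth:
    mask: np.ndarray  # bool, phantom grid
    center_mm: tuple[float, float, float]
    diameter_mm: float
    peak_suv: float  # clean (pre-blur) plateau value
    realized_suvmax: float  # after PSF + noise
    compartment: str

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass
class GroundTruth:
    lesions: list[LesionTruth]
    organ_clean_means: dict[str, float]
    clean_suv: np.ndarray = field(repr=False, default=None)  # pre-artifact/blur/noise

    def to_json(self, path: str | Path) -> None:
        doc = {
            "organ_clean_means": self.organ_clean_means,
            "lesions": [
                {
                    "center_mm": list(l.center_mm),
                    "diameter_mm": l.diameter_mm,
                    "peak_suv": l.peak_suv,
                    "realized_suvmax": l.realized_suvmax,
                    "compartment": l.compartment,
                    "n_voxels": int(l.mask.sum()),
                }
                for l in self.lesions
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2))


def _grid_coords(spec: PhantomSpec):
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing_mm
    return (
        (np.arange(nx) * sx)[:, None, None],
        (np.arange(ny) * sy)[None, :, None],
        (np.arange(nz) * sz)[None, None, :],
    )


def _sphere_mask(coords, center, radius) -> np.ndarray:
    X, Y, Z = coords
    cx, cy, cz = center
    return (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= radius**2


def make_phantom(
    spec: PhantomSpec, vocab: vb.LabelVocabulary | None = None
) -> tuple[VoxelGrid, VoxelGrid, GroundTruth]:
    """Build (SUV volume, label map, ground truth) from a phantom spec.

    Deterministic given ``spec.seed``. Raises on overlapping organ geometries
    and on lesions whose centers are outside their declared compartment.
    """
    vocab = vocab or vb.default_vocabulary()
    coords = _grid_coords(spec)
    body = spec.body.rasterize(coords)

    labels = np.zeros(spec.shape, dtype=np.int16)
    for organ in spec.organs:
        organ_mask = np.zeros(spec.shape, dtype=bool)
        for shp in organ.shapes:
            organ_mask |= shp.rasterize(coords)
        clash = labels[organ_mask]
        clash = clash[clash != 0]
        if clash.size:
            other = vocab.name_of(int(clash[0])) if int(clash[0]) in vocab.known_ids else int(clash[0])
            raise ValueError(f"organ {organ.name!r} overlaps {other!r}")
        labels[organ_mask] = organ.label_id

    suv = np.where(body, spec.background_suv, 0.0)
    for organ in spec.organs:
        suv[labels == organ.label_id] = organ.suv

    bone_ids = set(vocab.bone_to_region) | set(vocab.region_names)
    lesion_masks: list[np.ndarray] = []
    for les in spec.lesions:
        idx = tuple(
            int(round(c / s)) for c, s in zip(les.center_mm, spec.spacing_mm)
        )
        if not all(0 <= i < n for i, n in zip(idx, spec.shape)):
            raise ValueError(f"lesion center {les.center_mm} outside grid")
        lab = int(labels[idx])
        ok = (
            (les.compartment == "bone" and lab in bone_ids)
            or (les.compartment == "prostate" and lab == vb.PROSTATE_ID)
            or (les.compartment == "lymph" and lab == 0 and body[idx])
        )
        if not ok:
            raise ValueError(
                f"{les.compartment} lesion at {les.center_mm} lies in label {lab}"
            )
        mask = _sphere_mask(coords, les.center_mm, les.diameter_mm / 2.0)
        if not mask.any():
            raise ValueError(f"lesion at {les.center_mm} covers no voxel centers")
        for prev in lesion_masks:
            if (mask & prev).any():
                raise ValueError("lesion masks overlap")
        lesion_masks.append(mask)
        suv[mask] = les.peak_suv

    clean = suv.copy()
    organ_clean_means = {
        organ.name: float(clean[labels == organ.label_id].mean())
        for organ in spec.organs
        if (labels == organ.label_id).any()
    }

    # breathing-attenuation artifact: superior slab of the liver at reduced uptake
    if spec.liver_artifact is not None and (labels == vb.LIVER_ID).any():
        frac, mult = spec.liver_artifact
        if frac > 0:
            liver = labels == vb.LIVER_ID
            n_target = int(round(frac * liver.sum()))
            zvox = np.nonzero(liver)[2]
            zcut = np.quantile(zvox, 1.0 - frac, method="higher")
            slab = liver & (np.arange(spec.shape[2])[None, None, :] > zcut)
            # fill the boundary slice partially (lexicographic order) so the
            # affected fraction is exact to one voxel
            short = n_target - int(slab.sum())
            if short > 0:
                edge = np.argwhere(liver & (np.arange(spec.shape[2])[None, None, :] == zcut))
                for idx in edge[:short]:
                    slab[tuple(idx)] = True
            suv[slab] *= mult

    if spec.psf_fwhm_mm > 0:
        sigma_vox = [
            spec.psf_fwhm_mm * FWHM_TO_SIGMA / s for s in spec.spacing_mm
        ]
        suv = ndimage.gaussian_filter(suv, sigma=sigma_vox, mode="constant")

    if spec.noise_sigma_scale > 0:
        rng = np.random.default_rng(spec.seed)
        suv = suv + rng.normal(size=spec.shape) * (
            spec.noise_sigma_scale * np.sqrt(np.clip(suv, 0, None))
        )
        suv = np.clip(suv, 0.0, None)

    truth = GroundTruth(
        lesions=[
            LesionTruth(
                mask=m,
                center_mm=les.center_mm,
                diameter_mm=les.diameter_mm,
                peak_suv=les.peak_suv,
                realized_suvmax=float(suv[m].max()),
                compartment=les.compartment,
            )
            for les, m in zip(spec.lesions, lesion_masks)
        ],
        organ_clean_means=organ_clean_means,
        clean_suv=clean,
    )
    frame = f"phantom-{spec.seed}"
    suv_grid = VoxelGrid(data=suv, spacing=spec.spacing_mm, frame=frame)
    label_grid = VoxelGrid(data=labels, spacing=spec.spacing_mm, frame=frame)
    return suv_grid, label_grid, truth


def default_organs(
    background: float = 0.8,
    blood_pool: float = 1.8,
    liver: float = 6.0,
    kidney: float = 30.0,
    bladder: float = 60.0,
    bone: float = 1.0,
    lung: float = 0.4,
    prostate: float = 1.2,
    include_prostate: bool = True,
) -> list[OrganSpec]:
    """Trunk-scale organ geometry with configurable mean uptakes."""
    E, C, B = "ellipsoid", "cylinder", "box"
    organs = [
        OrganSpec(label_id=vb.LIVER_ID, name="liver", suv=liver, shapes=[
            Shape(kind=E, center=(112, 182, 295), radii=(55, 48, 55))]),
        OrganSpec(label_id=vb.AORTA_THORACIC_ID, name="aorta_thoracic", suv=blood_pool,
                  shapes=[Shape(kind=C, center=(200, 215, 0), radii=(12, 12),
                                z_range=(330, 460))]),
        OrganSpec(label_id=vb.AORTA_ABDOMINAL_ID, name="aorta_abdominal", suv=blood_pool,
                  shapes=[Shape(kind=C, center=(200, 215, 0), radii=(12, 12),
                                z_range=(150, 330))]),
        OrganSpec(label_id=4, name="kidney_left", suv=kidney, shapes=[
            Shape(kind=E, center=(120, 205, 200), radii=(24, 20, 30))]),
        OrganSpec(label_id=5, name="kidney_right", suv=kidney, shapes=[
            Shape(kind=E, center=(264, 205, 200), radii=(24, 20, 30))]),
        OrganSpec(label_id=vb.BLADDER_ID, name="urinary_bladder", suv=bladder, shapes=[
            Shape(kind=E, center=(192, 170, 90), radii=(32, 30, 28))]),
        OrganSpec(label_id=8, name="lung_left", suv=lung, shapes=[
            Shape(kind=E, center=(118, 185, 415), radii=(46, 52, 55))]),
        OrganSpec(label_id=9, name="lung_right", suv=lung, shapes=[
            Shape(kind=E, center=(266, 185, 415), radii=(46, 52, 55))]),
        # the five skeletal regions, labelled directly at region level
        OrganSpec(label_id=101, name="femur", suv=bone, shapes=[
            Shape(kind=C, center=(130, 190, 0), radii=(14, 14), z_range=(6, 60)),
            Shape(kind=C, center=(254, 190, 0), radii=(14, 14), z_range=(6, 60))]),
        OrganSpec(label_id=102, name="pelvic region", suv=bone, shapes=[
            Shape(kind=B, low=(108, 158, 60), high=(150, 222, 120)),
            Shape(kind=B, low=(234, 158, 60), high=(276, 222, 120))]),
        OrganSpec(label_id=103, name="lumbar vertebrae", suv=bone, shapes=[
            Shape(kind=C, center=(192, 245, 0), radii=(14, 14), z_range=(120, 210))]),
        OrganSpec(label_id=104, name="thoracic vertebrae", suv=bone, shapes=[
            Shape(kind=C, center=(192, 245, 0), radii=(14, 14), z_range=(210, 330))]),
        OrganSpec(label_id=105, name="thorax", suv=bone, shapes=[
            Shape(kind=B, low=(36, 150, 230), high=(54, 230, 420)),
            Shape(kind=B, low=(330, 150, 230), high=(348, 230, 420))]),
    ]
    if include_prostate:
        organs.insert(6, OrganSpec(label_id=vb.PROSTATE_ID, name="prostate", suv=prostate,
                                   shapes=[Shape(kind=E, center=(192, 195, 48),
                                                 radii=(18, 16, 16))]))
    return organs


def default_spec(seed: int = 0, lesions: list[LesionSpec] | None = None,
                 **uptakes) -> PhantomSpec:
    """A ready-to-use phantom spec with the default trunk geometry."""
    spec_kwargs = {}
    for key in ("psf_fwhm_mm", "noise_sigma_scale", "liver_artifact", "background_suv"):
        if key in uptakes:
            spec_kwargs[key] = uptakes.pop(key)
    if "background" in uptakes:
        spec_kwargs["background_suv"] = uptakes["background"]
    organs = default_organs(**uptakes)
    return PhantomSpec(organs=organs, lesions=lesions or [], seed=seed, **spec_kwargs)


class SuiteVariability(BaseModel):
    """Across-patient distributions for a phantom suite.

    Reference-organ spreads default to inter-patient SDs on the order of
    those observed clinically (blood pool ~0.2 SUV, liver ~1 SUV).
    """

    model_config = ConfigDict(extra="forbid")

    blood_pool_mean: float = 1.8
    blood_pool_sd: float = 0.2
    liver_mean: float = 6.0
    liver_sd: float = 1.0
    kidney_mean: float = 30.0
    kidney_sd: float = 4.0
    bladder_mean: float = 60.0
    bladder_sd: float = 8.0
    n_bone_lesions: tuple[int, int] = (1, 3)  # inclusive range per patient
    n_lymph_lesions: tuple[int, int] = (1, 3)
    n_prostate_lesions: tuple[int, int] = (0, 1)
    lesion_diameter_mm: tuple[float, float] = (10.0, 16.0)
    lesion_peak_suv: tuple[float, float] = (4.0, 9.0)
    liver_artifact: Optional[tuple[float, float]] = (0.3, 0.5)
    psf_fwhm_mm: float = 6.0
    noise_sigma_scale: float = 0.1


def _place_lesions(
    rng: np.random.Generator,
    var: SuiteVariability,
    spec: PhantomSpec,
    vocab: vb.LabelVocabulary,
) -> list[LesionSpec]:
    """Sample non-overlapping lesion centers inside their compartments."""
    if all(
        hi == 0
        for _, hi in (var.n_bone_lesions, var.n_lymph_lesions, var.n_prostate_lesions)
    ):
        return []
    coords = _grid_coords(spec)
    labels = np.zeros(spec.shape, dtype=np.int16)
    for organ in spec.organs:
        for shp in organ.shapes:
            labels[shp.rasterize(coords)] = organ.label_id
    body = spec.body.rasterize(coords)
    spacing = np.asarray(spec.spacing_mm)
    cache: dict[str, np.ndarray] = {}

    def bone_core() -> np.ndarray:
        if "bone" not in cache:
            bone_mask = np.isin(labels, list(vocab.region_names))
            cache["bone"] = ndimage.binary_erosion(
                bone_mask, structure=_ball_structure(6.0, spacing)
            )
        return cache["bone"]

    def soft_tissue_distances() -> tuple[np.ndarray, np.ndarray]:
        # lymph = soft tissue well clear of organs, bones and the body surface
        if "d_lab" not in cache:
            cache["d_lab"] = ndimage.distance_transform_edt(labels == 0, sampling=spacing)
            cache["d_air"] = ndimage.distance_transform_edt(body, sampling=spacing)
        return cache["d_lab"], cache["d_air"]

    zmm = coords[2]

    def sample(compartment: str, diameter: float) -> np.ndarray | None:
        r = diameter / 2.0
        if compartment == "bone":
            allowed = bone_core()
        elif compartment == "lymph":
            d_lab, d_air = soft_tissue_distances()
            allowed = (
                (labels == 0) & body
                & (d_lab >= r + 8.0)
                & (d_air >= r + 10.0)
                & (np.broadcast_to(zmm, spec.shape) >= 130.0)
                & (np.broadcast_to(zmm, spec.shape) <= 330.0)
            )
        else:  # prostate
            allowed = ndimage.binary_erosion(
                labels == vb.PROSTATE_ID, structure=_ball_structure(r * 0.6 + 1.0, spacing)
            )
        idx = np.flatnonzero(allowed)
        if idx.size == 0:
            return None
        choice = np.unravel_index(rng.choice(idx), spec.shape)
        return np.asarray(choice) * spacing

    lesions: list[LesionSpec] = []
    for compartment, (lo, hi) in (
        ("bone", var.n_bone_lesions),
        ("lymph", var.n_lymph_lesions),
        ("prostate", var.n_prostate_lesions),
    ):
        n = int(rng.integers(lo, hi + 1))
        for _ in range(n):
            diameter = float(rng.uniform(*var.lesion_diameter_mm))
            peak = float(rng.uniform(*var.lesion_peak_suv))
            for _try in range(100):
                center = sample(compartment, diameter)
                if center is None:
                    break
                sep_ok = all(
                    np.linalg.norm(center - np.asarray(l.center_mm))
                    >= (diameter + l.diameter_mm) / 2.0 + 12.0
                    for l in lesions
                )
                if sep_ok:
                    lesions.append(
                        LesionSpec(
                            center_mm=tuple(float(c) for c in center),
                            diameter_mm=diameter,
                            peak_suv=peak,
                            compartment=compartment,
                        )
                    )
                    break
    return lesions


def _ball_structure(radius_mm: float, spacing) -> np.ndarray:
    from .reference import ball_structure  # shared helper

    return ball_structure(radius_mm, tuple(spacing))


def phantom_suite(
    n_patients: int,
    variability: SuiteVariability | None = None,
    seed: int = 0,
    vocab: vb.LabelVocabulary | None = None,
) -> list[tuple[VoxelGrid, VoxelGrid, GroundTruth]]:
    """Generate ``n_patients`` phantoms with across-patient variability.

    Organ uptakes are drawn per patient (truncated at small positive floors);
    lesion count, size, intensity and placement are random within the stated
    ranges. Fully reproducible from ``seed``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    var = variability or SuiteVariability()
    vocab = vocab or vb.default_vocabulary()
    out = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_patients):
        rng = np.random.default_rng(child)
        uptakes = dict(
            blood_pool=max(0.5, float(rng.normal(var.blood_pool_mean, var.blood_pool_sd))),
            liver=max(1.0, float(rng.normal(var.liver_mean, var.liver_sd))),
            kidney=max(5.0, float(rng.normal(var.kidney_mean, var.kidney_sd))),
            bladder=max(10.0, float(rng.normal(var.bladder_mean, var.bladder_sd))),
        )
        patient_seed = int(child.generate_state(1)[0] % (2**31))
        spec = default_spec(
            seed=patient_seed,
            psf_fwhm_mm=var.psf_fwhm_mm,
            noise_sigma_scale=var.noise_sigma_scale,
            liver_artifact=var.liver_artifact,
            **uptakes,
        )
        spec = spec.model_copy(
            update={"lesions": _place_lesions(rng, var, spec, vocab)}
        )
        out.append(make_phantom(spec, vocab))
    return out


def write_phantom(
    spec: PhantomSpec, out_dir: str | Path, vocab: vb.LabelVocabulary | None = None
) -> None:
    """Materialize a phantom to pet.nii.gz, labels.nii.gz and truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suv, labels, truth = make_phantom(spec, vocab)
    write_volume(suv, out_dir / "pet.nii.gz")
    write_volume(labels, out_dir / "labels.nii.gz")
    truth.to_json(out_dir / "truth.json")
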