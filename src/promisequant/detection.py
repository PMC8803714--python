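"""Candidate lesion detection.

Potential lesions are found per tissue compartment (bone, lymph, prostate)
as local maxima of the scale-normalized Laplacian-of-Gaussian response over a
set of physical blob diameters. Before the soft-tissue searches, a model of
normal uptake in the liver, kidneys and urinary bladder — a fitted, blurred
template per organ — is subtracted so the excretory signal does not dominate
lymph-node and prostate detection. Candidates are subsequently filtered by
SUVmax, SUVmean, uptake volume and location.

A fixed-SUV-threshold detector (connected components above a cut such as
SUV 4.3 or 3.0) is provided as the baseline that blob detection is compared
against: a fixed cut necessarily misses lesions whose realized SUVmax falls
below it, while the blob response depends on local contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy import ndimage

from . import vocabulary as vb
from .grid import BinaryMask, VoxelGrid
from .reference import ball_structure

logger = logging.getLogger(__name__)

__all__ = [
    "CompartmentConfig",
    "SuppressionConfig",
    "FilterRules",
    "DetectionConfig",
    "LesionCandidate",
    "SuppressionField",
    "fit_suppression",
    "suppress",
    "blob_detect",
    "detect_lesions",
    "threshold_detect",
    "filter_candidates",
    "body_mask",
]

FULL_CONNECTIVITY = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


class CompartmentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    scales_mm: list[float] = Field(default=[9.0, 12.0, 16.0, 20.0, 25.0])
    response_threshold: float = Field(default=0.6, ge=0)

    def model_post_init(self, _ctx) -> None:
        if any(s <= 0 for s in self.scales_mm):
            raise ValueError("scales must be positive")
        if list(self.scales_mm) != sorted(self.scales_mm):
            raise ValueError("scales must be sorted ascending")


class SuppressionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    organ_ids: list[int] = Field(
        default=[vb.LIVER_ID, *vb.KIDNEY_IDS, vb.BLADDER_ID]
    )
    dilation_mm: float = Field(default=3.0, ge=0)
    blur_sigma_mm: float = Field(default=3.0, ge=0)


class FilterRules(BaseModel):
    """Uptake/volume/location acceptance rules applied after pre-segmentation.

    ``min_suvmax_rel_blood_pool`` scales the blood-pool reference; the
    effective SUVmax cut is the larger of it and ``min_suvmax``.
    """

    model_config = ConfigDict(extra="forbid")

    min_suvmax: float = 2.0
    min_suvmax_rel_blood_pool: float = 1.5
    min_suvmean: float = 0.0
    min_volume_ml: float = 0.1
    max_volume_ml: float | None = None
    excluded_location_ids: list[int] = Field(
        default=[vb.BLADDER_ID, *vb.KIDNEY_IDS]
    )


class DetectionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bone: CompartmentConfig = Field(default_factory=CompartmentConfig)
    lymph: CompartmentConfig = Field(default_factory=CompartmentConfig)
    prostate: CompartmentConfig = Field(default_factory=CompartmentConfig)
    suppression: SuppressionConfig = Field(default_factory=SuppressionConfig)
    filters: FilterRules = Field(default_factory=FilterRules)
    body_mask_rel_blood_pool: float = 0.2

    def for_compartment(self, name: str) -> CompartmentConfig:
        return getattr(self, name)


@dataclass
class LesionCandidate:
    """A detected seed: where, at what scale, and how salient."""

    seed_index: tuple[int, int, int]
    position_mm: tuple[float, float, float]
    scale_mm: float
    response: float
    compartment: str

    def to_dict(self) -> dict:
        return {
            "seed_index": list(self.seed_index),
            "position_mm": list(self.position_mm),
            "scale_mm": self.scale_mm,
            "response": self.response,
            "compartment": self.compartment,
        }


@dataclass
class SuppressionField:
    field: np.ndarray
    amplitudes: dict[str, float] = None  # type: ignore[assignment]


def fit_suppression(
    suv: VoxelGrid,
    labels: VoxelGrid,
    cfg: SuppressionConfig | None = None,
    vocab: vb.LabelVocabulary | None = None,
) -> SuppressionField:
    """Fit the normal-uptake model for the liver, kidneys and bladder.

    Each organ contributes a template — its mask dilated and Gaussian-blurred
    to mimic spill-out — whose amplitude is the least-squares fit of the
    template to the PET within the dilated organ. The summed field is
    clamped nonnegative. Missing organs are skipped with a warning.
    """
    cfg = cfg or SuppressionConfig()
    vocab = vocab or vb.default_vocabulary()
    spacing = suv.spacing
    total = np.zeros(suv.shape, dtype=float)
    amplitudes: dict[str, float] = {}
    sigma_vox = [cfg.blur_sigma_mm / s for s in spacing]
    for organ_id in cfg.organ_ids:
        mask = labels.data == organ_id
        name = vocab.name_of(organ_id) if organ_id in vocab.known_ids else str(organ_id)
        if not mask.any():
            logger.warning("suppression: organ %s absent, skipped", name)
            continue
        if cfg.dilation_mm > 0:
            support = ndimage.binary_dilation(
                mask, structure=ball_structure(cfg.dilation_mm, spacing)
            )
        else:
            support = mask
        template = support.astype(float)
        if cfg.blur_sigma_mm > 0:
            template = ndimage.gaussian_filter(template, sigma=sigma_vox, mode="constant")
        t = template[support]
        denom = float((t * t).sum())
        amp = float((t * suv.data[support]).sum() / denom) if denom > 0 else 0.0
        amp = max(amp, 0.0)
        amplitudes[name] = amp
        total += amp * template
    return SuppressionField(field=np.clip(total, 0.0, None), amplitudes=amplitudes)


def suppress(suv: VoxelGrid, sup: SuppressionField) -> VoxelGrid:
    """Subtract the normal-uptake field, clamped so SUV stays nonnegative."""
    return suv.with_data(np.clip(suv.data - sup.field, 0.0, None))


def _log_response_stack(
    data: np.ndarray, spacing: tuple[float, float, float], scales_mm: list[float]
) -> np.ndarray:
    """Scale-normalized negated LoG responses, one slab per blob diameter.

    The Gaussian scale sigma is matched to blob diameter d via d = 2*sigma*sqrt(3)
    (the diameter at which a solid sphere maximizes the normalized response).
    Derivatives are taken in physical units (per-axis voxel derivatives divided
    by spacing^2), so the response is comparable across anisotropic grids and
    has the units of SUV.
    """
    stack = np.zeros((len(scales_mm), *data.shape), dtype=np.float32)
    data = np.asarray(data, dtype=np.float32)
    for i, d in enumerate(scales_mm):
        sigma_mm = d / (2.0 * np.sqrt(3.0))
        # a sampled Gaussian-derivative kernel needs sigma >= ~0.85 voxels;
        # below that the response aliases badly, so clamp and warn
        sigma_vox = [sigma_mm / s for s in spacing]
        if min(sigma_vox) < 0.85:
            logger.warning(
                "blob scale %.1f mm under-resolved on spacing %s; clamping sigma",
                d, spacing,
            )
            sigma_vox = [max(sv, 0.85) for sv in sigma_vox]
        for axis in range(3):
            order = [0, 0, 0]
            order[axis] = 2
            stack[i] -= (
                sigma_mm**2 / spacing[axis] ** 2
            ) * ndimage.gaussian_filter(data, sigma=sigma_vox, order=order, mode="nearest")
    return stack


def blob_detect(
    suv: VoxelGrid,
    compartment_mask: BinaryMask | np.ndarray,
    cfg: CompartmentConfig,
    compartment: str = "",
    _stack: np.ndarray | None = None,
) -> list[LesionCandidate]:
    """Multi-scale LoG blob detection restricted to a compartment mask.

    Candidates are local maxima over the joint (scale, x, y, z) neighborhood
    (full 26-connectivity in space, plus adjacent scales) whose normalized
    response meets the threshold, returned sorted by descending response
    (ties broken by voxel index) — fully deterministic. ``_stack`` lets the
    orchestrator reuse one response stack across compartments.
    """
    mask = compartment_mask.data if isinstance(compartment_mask, BinaryMask) else compartment_mask
    if not mask.any():
        return []
    stack = _stack if _stack is not None else _log_response_stack(
        suv.data, suv.spacing, cfg.scales_mm
    )
    local_max = stack == ndimage.maximum_filter(stack, size=3, mode="nearest")
    local_max &= stack >= cfg.response_threshold
    local_max &= np.broadcast_to(mask, stack.shape)
    cands: list[LesionCandidate] = []
    s_idx, xi, yi, zi = np.nonzero(local_max)
    for s, i, j, k in zip(s_idx, xi, yi, zi):
        pos = suv.index_to_world((int(i), int(j), int(k)))
        cands.append(
            LesionCandidate(
                seed_index=(int(i), int(j), int(k)),
                position_mm=tuple(float(p) for p in pos),
                scale_mm=float(cfg.scales_mm[s]),
                response=float(stack[s, i, j, k]),
                compartment=compartment,
            )
        )
    cands.sort(key=lambda c: (-c.response, c.seed_index))
    # a plateau maximum can fire at several adjacent (scale, voxel) nodes;
    # keep the strongest within one voxel+scale step
    dedup: list[LesionCandidate] = []
    for c in cands:
        clash = any(
            all(abs(a - b) <= 1 for a, b in zip(c.seed_index, d.seed_index))
            and abs(cfg.scales_mm.index(c.scale_mm) - cfg.scales_mm.index(d.scale_mm)) <= 1
            for d in dedup
        )
        if not clash:
            dedup.append(c)
    return dedup


def body_mask(
    suv: VoxelGrid, blood_pool: float, rel_threshold: float = 0.2
) -> np.ndarray:
    """Largest connected component above a fraction of the blood-pool SUV."""
    fg = suv.data > rel_threshold * blood_pool
    lab, n = ndimage.label(fg, structure=FULL_CONNECTIVITY)
    if n == 0:
        return fg
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == int(counts.argmax())


def detect_lesions(
    suv: VoxelGrid,
    labels: VoxelGrid,
    cfg: DetectionConfig | None = None,
    vocab: vb.LabelVocabulary | None = None,
    blood_pool: float | None = None,
) -> tuple[list[LesionCandidate], SuppressionField]:
    """Per-compartment candidate search.

    Bone: union of the five skeletal regions, searched on the raw PET.
    Lymph: soft-tissue body volume minus all labeled structures, searched on
    the suppression-subtracted PET. Prostate: the prostate label on the
    suppressed PET; skipped with a warning when absent (post-prostatectomy).
    """
    cfg = cfg or DetectionConfig()
    vocab = vocab or vb.default_vocabulary()
    if blood_pool is None:
        from .reference import compute_references

        blood_pool = compute_references(suv, labels, vocab).blood_pool

    bone_ids = list(vocab.region_names) + [
        b for b in vocab.bone_to_region if b not in vocab.region_names
    ]
    bones = np.isin(labels.data, bone_ids)
    if not bones.any():
        raise ValueError("no bone labels present in label map")

    sup = fit_suppression(suv, labels, cfg.suppression, vocab)
    suppressed = suppress(suv, sup)

    body = body_mask(suv, blood_pool, cfg.body_mask_rel_blood_pool)
    lymph = body & (labels.data == 0)

    # one response stack per (input volume, scale list)
    stacks: dict[tuple[int, tuple[float, ...]], np.ndarray] = {}

    def stack_for(grid: VoxelGrid, ccfg: CompartmentConfig) -> np.ndarray:
        key = (id(grid), tuple(ccfg.scales_mm))
        if key not in stacks:
            stacks[key] = _log_response_stack(grid.data, grid.spacing, ccfg.scales_mm)
        return stacks[key]

    candidates = blob_detect(suv, bones, cfg.bone, "bone", _stack=stack_for(suv, cfg.bone))
    candidates += blob_detect(
        suppressed, lymph, cfg.lymph, "lymph", _stack=stack_for(suppressed, cfg.lymph)
    )

    prostate = labels.data == vb.PROSTATE_ID
    if prostate.any():
        candidates += blob_detect(
            suppressed, prostate, cfg.prostate, "prostate",
            _stack=stack_for(suppressed, cfg.prostate),
        )
    else:
        logger.warning("prostate label absent (post-prostatectomy?); skipped")
    return candidates, sup


def threshold_detect(
    suv: VoxelGrid, mask: BinaryMask | np.ndarray, suv_threshold: float
) -> list[LesionCandidate]:
    """Fixed-cut baseline: one candidate per 26-connected supra-threshold component."""
    if suv_threshold <= 0:
        raise ValueError("threshold must be > 0")
    m = mask.data if isinstance(mask, BinaryMask) else mask
    above = (suv.data >= suv_threshold) & m
    lab, n = ndimage.label(above, structure=FULL_CONNECTIVITY)
    cands = []
    for comp_id in range(1, n + 1):
        comp = lab == comp_id
        flat = np.where(comp, suv.data, -np.inf)
        seed = np.unravel_index(int(flat.argmax()), suv.shape)
        vol_ml = comp.sum() * suv.voxel_volume_ml
        diameter = 2.0 * (3.0 * vol_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        pos = suv.index_to_world([int(i) for i in seed])
        cands.append(
            LesionCandidate(
                seed_index=tuple(int(i) for i in seed),
                position_mm=tuple(float(p) for p in pos),
                scale_mm=float(diameter),
                response=float(suv.data[seed]),
                compartment="threshold",
            )
        )
    cands.sort(key=lambda c: (-c.response, c.seed_index))
    return cands


def filter_candidates(
    records: list,
    labels: VoxelGrid,
    rules: FilterRules | None = None,
    blood_pool: float = 0.0,
) -> tuple[list, list[tuple[object, str]]]:
    """Apply uptake/volume/location rules to pre-segmented lesion records.

    Rules are checked in a fixed order — location, SUVmax, SUVmean, minimum
    volume, maximum volume — and each rejection carries the first rule that
    failed. An empty rule set keeps everything.
    """
    rules = rules or FilterRules()
    min_suvmax = max(rules.min_suvmax, rules.min_suvmax_rel_blood_pool * blood_pool)
    kept, rejected = [], []
    for rec in records:
        seed = rec.candidate.seed_index
        reason = None
        if int(labels.data[seed]) in rules.excluded_location_ids:
            reason = "location"
        elif rec.suv_max < min_suvmax:
            reason = "SUVmax"
        elif rec.suv_mean < rules.min_suvmean:
            reason = "SUVmean"
        elif rec.volume_ml < rules.min_volume_ml:
            reason = "volume_min"
        elif rules.max_volume_ml is not None and rec.volume_ml > rules.max_volume_ml:
            reason = "volume_max"
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((rec, reason))
    return kept, rejected
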