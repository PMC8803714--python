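"""End-to-end orchestration and the packaged experiment suites.

``analyze`` runs reference quantification -> normal-uptake suppression ->
per-compartment blob detection -> fast-marching pre-segmentation ->
quantification -> rule filtering, and is deterministic for a fixed
(input, config) pair. ``run_experiment`` generates a phantom suite and runs
the pipeline slice matching one of the packaged study designs: reference
consistency (automated vs emulated manual spherical VOIs), detection
sensitivity against ground truth, blob-vs-fixed-threshold comparison, and
run-to-run reproducibility of lesion SUV measures.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import vocabulary as vb
from .detection import DetectionConfig, detect_lesions, filter_candidates, threshold_detect
from .evaluation import (
    AgreementReport,
    MatchResult,
    make_report,
    match_lesions,
    reference_sd,
    sensitivity,
)
from .grid import VoxelGrid, read_volume, write_volume
from .phantom import SuiteVariability, default_spec, make_phantom, phantom_suite
from .reference import ReferenceConfig, ReferenceValues, compute_references, sphere_roi_reference
from .segmentation import FastMarchConfig, LesionRecord, quantify, segment_and_quantify

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "AnalysisResult",
    "analyze",
    "analyze_grids",
    "run_experiment",
    "EXPERIMENTS",
]


class PipelineConfig(BaseModel):
    """Full pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    reference: ReferenceConfig = Field(default_factory=ReferenceConfig)
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    fastmarch: FastMarchConfig = Field(default_factory=FastMarchConfig)
    match_distance_floor_mm: float = 10.0
    seed: int = 0

    def config_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode()
        ).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage {stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisResult:
    references: ReferenceValues
    lesions: list[LesionRecord]
    rejected: list[tuple[LesionRecord, str]]
    config_hash: str
    flags: list[str] = field(default_factory=list)

    def lesions_doc(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "lesions": [r.to_dict() for r in self.lesions],
            "rejected": [
                {**r.to_dict(), "rejection_reason": why} for r, why in self.rejected
            ],
        }


def analyze_grids(
    suv: VoxelGrid,
    labels: VoxelGrid,
    config: PipelineConfig | None = None,
    vocab: vb.LabelVocabulary | None = None,
) -> AnalysisResult:
    """Run the full pipeline on in-memory grids."""
    config = config or PipelineConfig()
    vocab = vocab or vb.default_vocabulary()
    try:
        refs = compute_references(suv, labels, vocab, config.reference)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("reference", exc) from exc
    try:
        candidates, _sup = detect_lesions(
            suv, labels, config.detection, vocab, blood_pool=refs.blood_pool
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("detection", exc) from exc
    try:
        records = segment_and_quantify(
            suv, candidates, config.fastmarch, refs.blood_pool
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("segmentation", exc) from exc
    kept, rejected = filter_candidates(
        records, labels, config.detection.filters, refs.blood_pool
    )
    return AnalysisResult(
        references=refs,
        lesions=kept,
        rejected=rejected,
        config_hash=config.config_hash(),
    )


def analyze(
    pet_path: str | Path,
    labels_path: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    vocab: vb.LabelVocabulary | None = None,
) -> AnalysisResult:
    """Run the pipeline on NIfTI inputs; optionally write JSON/NIfTI outputs."""
    try:
        suv = read_volume(pet_path)
        labels = read_volume(labels_path)
        if not labels.is_integer:
            raise ValueError("label map must be an integer volume")
        if suv.shape != labels.shape:
            raise ValueError(
                f"PET {suv.shape} and label map {labels.shape} shapes differ"
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("grid_io", exc) from exc
    result = analyze_grids(suv, labels, config, vocab)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "lesions.json").write_text(
            json.dumps(result.lesions_doc(), indent=2, sort_keys=True)
        )
        (out_dir / "references.json").write_text(
            json.dumps(
                {**result.references.to_dict(), "config_hash": result.config_hash},
                indent=2,
                sort_keys=True,
            )
        )
        lesion_map = np.zeros(suv.shape, dtype=np.int16)
        for i, rec in enumerate(result.lesions, start=1):
            lesion_map[rec.mask.data] = i
        write_volume(suv.with_data(lesion_map), out_dir / "lesion_masks.nii.gz")
    return result


# --------------------------------------------------------------------------
# packaged experiments


def _jittered_sphere_reading(
    suv: VoxelGrid, rng: np.random.Generator
) -> tuple[float, float]:
    """Emulate a manual reader: fixed-size spherical VOIs at jittered positions.

    1 cm sphere in the descending thoracic aorta, 3 cm sphere in the liver;
    the center is perturbed around each organ's nominal location the way a
    human places a VOI by eye (2 mm in-plane jitter, free choice of level).
    Positions refer to the default phantom geometry.
    """
    aorta_center = np.array([200.0, 215.0, float(rng.uniform(350, 440))])
    aorta_center[:2] += rng.normal(0, 2.0, size=2)
    blood = sphere_roi_reference(suv, tuple(aorta_center), 10.0)
    liver_center = np.array([112.0, 182.0, 280.0])
    liver_center += rng.normal(0, 4.0, size=3)
    liver = sphere_roi_reference(suv, tuple(liver_center), 30.0)
    return blood, liver


def _experiment_reference_sd(n: int, seed: int, config: PipelineConfig) -> AgreementReport:
    var = SuiteVariability(
        n_bone_lesions=(0, 0), n_lymph_lesions=(0, 0), n_prostate_lesions=(0, 0)
    )
    suite = phantom_suite(n, var, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    auto_bp, auto_lv, man_bp, man_lv = [], [], [], []
    for suv, labels, _truth in suite:
        refs = compute_references(suv, labels, cfg=config.reference)
        auto_bp.append(refs.blood_pool)
        auto_lv.append(refs.liver)
        b, l = _jittered_sphere_reading(suv, rng)
        man_bp.append(b)
        man_lv.append(l)
    return make_report(
        values_per_method={
            "blood_pool_automated": auto_bp,
            "blood_pool_manual_sphere": man_bp,
            "liver_automated": auto_lv,
            "liver_manual_sphere": man_lv,
        },
        pearson_pairs={
            "blood_pool_auto_vs_manual": (np.array(auto_bp), np.array(man_bp)),
        },
    )


def _pooled_match(per_patient: list[MatchResult]) -> MatchResult:
    pairs, missed, fps = [], [], []
    t_off = d_off = 0
    for m in per_patient:
        pairs += [(t + t_off, d + d_off) for t, d in m.pairs]
        missed += [t + t_off for t in m.missed_truth]
        fps += [d + d_off for d in m.false_positives]
        t_off += m.n_truth
        d_off += m.n_matched + len(m.false_positives)
    return MatchResult(pairs=pairs, missed_truth=missed, false_positives=fps)


def _experiment_detection_sensitivity(
    n: int, seed: int, config: PipelineConfig
) -> AgreementReport:
    suite = phantom_suite(n, SuiteVariability(), seed=seed)
    matches = []
    for suv, labels, truth in suite:
        result = analyze_grids(suv, labels, config)
        matches.append(
            match_lesions(truth, result.lesions, config.match_distance_floor_mm)
        )
    return make_report(match=_pooled_match(matches), n_patients=n)


def _experiment_threshold_comparison(
    n: int, seed: int, config: PipelineConfig, suv_threshold: float = 4.3
) -> AgreementReport:
    # lesion intensities chosen so realized SUVmax straddles/falls below the cut
    var = SuiteVariability(lesion_peak_suv=(3.5, 5.5))
    suite = phantom_suite(n, var, seed=seed)
    vocab = vb.default_vocabulary()
    blob_matches, thr_matches = [], []
    for suv, labels, truth in suite:
        result = analyze_grids(suv, labels, config)
        blob_matches.append(
            match_lesions(truth, result.lesions, config.match_distance_floor_mm)
        )
        # fixed-cut baseline over the same searchable tissue
        bones = np.isin(labels.data, list(vocab.region_names))
        from .detection import body_mask as _body_mask

        body = _body_mask(
            suv, result.references.blood_pool, config.detection.body_mask_rel_blood_pool
        )
        searchable = bones | (body & (labels.data == 0)) | (labels.data == vb.PROSTATE_ID)
        cands = threshold_detect(suv, searchable, suv_threshold)
        records = []
        for c in cands:
            comp = (suv.data >= suv_threshold) & searchable
            from scipy import ndimage as ndi

            lab, _ = ndi.label(comp, structure=np.ones((3, 3, 3), bool))
            mask = lab == lab[c.seed_index]
            records.append(quantify(suv, mask, c))
        thr_matches.append(
            match_lesions(truth, records, config.match_distance_floor_mm)
        )
    blob = _pooled_match(blob_matches)
    thr = _pooled_match(thr_matches)
    report = make_report(match=blob, n_patients=n)
    report.sensitivity_by_method = {
        "blob": sensitivity(blob)[0],
        f"threshold_{suv_threshold}": sensitivity(thr)[0] if thr.n_truth else 0.0,
    }
    return report


def reproducibility_spec(seed: int = 42):
    """The fixed phantom used by the reproducibility experiment (>= 5 lesions)."""
    from .phantom import LesionSpec

    lesions = [
        LesionSpec(center_mm=(130, 190, 30), diameter_mm=14, peak_suv=7.0, compartment="bone"),
        LesionSpec(center_mm=(192, 245, 160), diameter_mm=12, peak_suv=5.5, compartment="bone"),
        LesionSpec(center_mm=(254, 190, 30), diameter_mm=10, peak_suv=8.0, compartment="bone"),
        LesionSpec(center_mm=(250, 140, 160), diameter_mm=14, peak_suv=6.0, compartment="lymph"),
        LesionSpec(center_mm=(130, 120, 200), diameter_mm=12, peak_suv=4.5, compartment="lymph"),
        LesionSpec(center_mm=(192, 120, 260), diameter_mm=16, peak_suv=5.0, compartment="lymph"),
        LesionSpec(center_mm=(192, 195, 48), diameter_mm=12, peak_suv=6.5, compartment="prostate"),
    ]
    return default_spec(seed=seed, lesions=lesions)


def _experiment_reproducibility(
    n: int, seed: int, config: PipelineConfig
) -> AgreementReport:
    """ICC(2,1) of lesion SUV measures across two identical pipeline runs."""
    spec = reproducibility_spec(seed=seed)
    suv, labels, _truth = make_phantom(spec)
    runs = [analyze_grids(suv, labels, config) for _ in range(max(2, n if n >= 2 else 2))]
    key = lambda r: r.candidate.seed_index  # noqa: E731
    per_run = [sorted(run.lesions, key=key) for run in runs]
    n_lesions = min(len(lr) for lr in per_run)
    if n_lesions < 2:
        raise RuntimeError("reproducibility experiment needs >= 2 detected lesions")
    matrices = {
        measure: np.array(
            [
                [getattr(lr[i], attr) for lr in per_run]
                for i in range(n_lesions)
            ]
        )
        for measure, attr in (
            ("SUVmax", "suv_max"),
            ("SUVpeak", "suv_peak"),
            ("SUVmean", "suv_mean"),
        )
    }
    return make_report(icc_matrices=matrices)


EXPERIMENTS = {
    "reference_sd": _experiment_reference_sd,
    "detection_sensitivity": _experiment_detection_sensitivity,
    "threshold_comparison": _experiment_threshold_comparison,
    "reproducibility": _experiment_reproducibility,
}


def run_experiment(
    name: str, n: int = 20, seed: int = 0, config: PipelineConfig | None = None
) -> AgreementReport:
    """Run one packaged experiment; reproducible from ``seed``."""
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; choose from {sorted(EXPERIMENTS)}")
    return EXPERIMENTS[name](n, seed, config or PipelineConfig())
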