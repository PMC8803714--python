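"""Agreement and detection-performance statistics.

Dice overlap, one-to-one lesion matching against ground truth, detection
sensitivity with a Wilson 95% CI, Pearson correlation with a Fisher-z CI,
per-method standard deviation across patients, and the intraclass
correlation ICC(2,1) — two-way random effects, absolute agreement, single
measurement — used to quantify reproducibility of lesion SUV measures.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

__all__ = [
    "dice",
    "MatchResult",
    "match_lesions",
    "sensitivity",
    "pearson",
    "icc2",
    "reference_sd",
    "AgreementReport",
    "make_report",
]

REPORT_SCHEMA_VERSION = 1


def dice(a, b) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of two binary masks.

    Two empty masks are perfect agreement on absence and return 1 (with a
    warning, since the case is degenerate).
    """
    da = np.asarray(a.data if hasattr(a, "data") else a, dtype=bool)
    db = np.asarray(b.data if hasattr(b, "data") else b, dtype=bool)
    if da.shape != db.shape:
        raise ValueError(f"mask shapes differ: {da.shape} vs {db.shape}")
    denom = int(da.sum()) + int(db.sum())
    if denom == 0:
        warnings.warn("Dice of two empty masks defined as 1", stacklevel=2)
        return 1.0
    return 2.0 * int((da & db).sum()) / denom


@dataclass
class MatchResult:
    """One-to-one pairing of ground-truth lesions with detections."""

    pairs: list[tuple[int, int]]  # (truth index, detection index)
    missed_truth: list[int]
    false_positives: list[int]
    criterion: str = "center_in_mask_or_centroid_distance"

    @property
    def n_truth(self) -> int:
        return len(self.pairs) + len(self.missed_truth)

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def _centroid_mm(record) -> np.ndarray:
    idx = np.argwhere(record.mask.data)
    return record.mask.grid.index_to_world(idx.mean(axis=0))


def match_lesions(
    truth, detections: list, distance_floor_mm: float = 10.0
) -> MatchResult:
    """Greedy one-to-one matching by descending detection response.

    A detection matches a truth lesion if the true center falls inside the
    detected mask, or the detected centroid lies within
    max(true radius, ``distance_floor_mm``) of the true center. Each truth
    lesion and each detection is used at most once.
    """
    lesions = truth.lesions if hasattr(truth, "lesions") else truth
    order = sorted(
        range(len(detections)), key=lambda i: -detections[i].candidate.response
    )
    taken: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for di in order:
        det = detections[di]
        grid = det.mask.grid
        centroid = _centroid_mm(det)
        best, best_d = None, np.inf
        for ti, tl in enumerate(lesions):
            if ti in taken:
                continue
            center = np.asarray(tl.center_mm, dtype=float)
            cidx = np.round(grid.world_to_index(center)).astype(int)
            inside = (
                all(0 <= i < n for i, n in zip(cidx, grid.shape))
                and det.mask.data[tuple(cidx)]
            )
            d = float(np.linalg.norm(centroid - center))
            if inside or d <= max(tl.radius_mm, distance_floor_mm):
                if d < best_d:
                    best, best_d = ti, d
        if best is not None:
            taken.add(best)
            pairs.append((best, di))
    matched_d = {di for _, di in pairs}
    return MatchResult(
        pairs=sorted(pairs),
        missed_truth=[i for i in range(len(lesions)) if i not in taken],
        false_positives=[i for i in range(len(detections)) if i not in matched_d],
    )


def sensitivity(match: MatchResult) -> tuple[float, tuple[float, float]]:
    """Detection sensitivity in percent with a Wilson 95% CI."""
    n = match.n_truth
    if n == 0:
        raise ValueError("sensitivity undefined with zero truth lesions")
    k = match.n_matched
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return 100.0 * k / n, (100.0 * lo, 100.0 * hi)


def pearson(x, y) -> tuple[float, tuple[float, float]]:
    """Sample Pearson r with a Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input has undefined correlation")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(0.95)
    return float(res.statistic), (float(ci.low), float(ci.high))


def icc2(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an n_subjects x k_raters matrix with no missing cells.
    Computed from the two-way ANOVA mean squares as
    (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters matrix")
    if np.isnan(m).any():
        raise ValueError("ratings matrix has missing cells")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:  # all ratings identical
        return 1.0
    return float((msr - mse) / denom)


def reference_sd(values_per_method: dict[str, np.ndarray]) -> dict[str, float]:
    """Sample SD (n-1 denominator) of each method's values across patients."""
    out = {}
    for method, vals in values_per_method.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValueError(f"method {method!r} needs >= 2 patients")
        out[method] = float(v.std(ddof=1))
    return out


@dataclass
class AgreementReport:
    """Aggregated evaluation statistics in the shape of the study tables."""

    schema_version: int = REPORT_SCHEMA_VERSION
    dice_per_region: dict[str, float] = field(default_factory=dict)
    sensitivity_pct: float | None = None
    sensitivity_ci: tuple[float, float] | None = None
    fp_per_patient: float | None = None
    sensitivity_by_method: dict[str, float] = field(default_factory=dict)
    pearson_r: dict[str, tuple[float, tuple[float, float]]] = field(default_factory=dict)
    sd_per_method: dict[str, float] = field(default_factory=dict)
    icc2: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sensitivity_pct is not None and not (0 <= self.sensitivity_pct <= 100):
            raise ValueError("sensitivity must be a percentage in [0, 100]")
        for name, val in self.icc2.items():
            if val > 1 + 1e-12:
                raise ValueError(f"ICC2 for {name!r} exceeds 1")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AgreementReport":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        doc["sensitivity_ci"] = (
            tuple(doc["sensitivity_ci"]) if doc.get("sensitivity_ci") else None
        )
        doc["pearson_r"] = {
            k: (v[0], tuple(v[1])) for k, v in doc.get("pearson_r", {}).items()
        }
        return cls(**doc)

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for region, d in self.dice_per_region.items():
            rows.append({"kind": "dice", "name": region, "value": d})
        if self.sensitivity_pct is not None:
            rows.append({
                "kind": "sensitivity_pct", "name": "detection",
                "value": self.sensitivity_pct,
                "ci_low": self.sensitivity_ci[0] if self.sensitivity_ci else None,
                "ci_high": self.sensitivity_ci[1] if self.sensitivity_ci else None,
            })
        if self.fp_per_patient is not None:
            rows.append({"kind": "fp_per_patient", "name": "detection",
                         "value": self.fp_per_patient})
        for method, s in self.sensitivity_by_method.items():
            rows.append({"kind": "sensitivity_pct", "name": method, "value": s})
        for pair, (r, (lo, hi)) in self.pearson_r.items():
            rows.append({"kind": "pearson_r", "name": pair, "value": r,
                         "ci_low": lo, "ci_high": hi})
        for method, sd in self.sd_per_method.items():
            rows.append({"kind": "sd", "name": method, "value": sd})
        for measure, val in self.icc2.items():
            rows.append({"kind": "icc2", "name": measure, "value": val})
        pd.DataFrame(rows).to_csv(path, index=False)


def make_report(
    dice_per_region: dict[str, float] | None = None,
    match: MatchResult | None = None,
    n_patients: int | None = None,
    pearson_pairs: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    values_per_method: dict[str, np.ndarray] | None = None,
    icc_matrices: dict[str, np.ndarray] | None = None,
) -> AgreementReport:
    """Aggregate available components into one :class:`AgreementReport`."""
    report = AgreementReport(dice_per_region=dict(dice_per_region or {}))
    if match is not None and match.n_truth > 0:
        pct, ci = sensitivity(match)
        report.sensitivity_pct = pct
        report.sensitivity_ci = ci
        if n_patients:
            report.fp_per_patient = len(match.false_positives) / n_patients
    for name, (x, y) in (pearson_pairs or {}).items():
        report.pearson_r[name] = pearson(x, y)
    if values_per_method:
        report.sd_per_method = reference_sd(values_per_method)
    for name, mat in (icc_matrices or {}).items():
        report.icc2[name] = icc2(mat)
    return report
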