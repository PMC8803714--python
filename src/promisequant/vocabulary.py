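"""Fixed organ-label vocabulary and the bone-region grouping.

The segmentation upstream of this package delineates 51 bones and 8-9
visceral organs (the prostate is absent post-prostatectomy). For analysis the
bones are collapsed into 5 skeletal regions: femur, pelvic region, lumbar
vertebrae, thoracic vertebrae, and thorax. Label ids are package-defined
integers — the upstream tool publishes organ names, not ids — so any external
label map must be remapped to this vocabulary before use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grid import VoxelGrid

__all__ = [
    "Compartment",
    "LabelVocabulary",
    "default_vocabulary",
    "group_bones",
    "BONE_REGIONS",
]

# compartment tags
BONE = "bone"
VISCERAL = "visceral"
REFERENCE = "reference"
EXCRETORY = "excretory"
Compartment = str

# region ids for the five analysis bone regions; individual bones map onto these
BONE_REGIONS: dict[int, str] = {
    101: "femur",
    102: "pelvic region",
    103: "lumbar vertebrae",
    104: "thoracic vertebrae",
    105: "thorax",
}

# visceral / reference / excretory organ ids
ORGANS: dict[int, tuple[str, str]] = {
    1: ("liver", REFERENCE),
    2: ("aorta_thoracic", REFERENCE),
    3: ("aorta_abdominal", REFERENCE),
    4: ("kidney_left", EXCRETORY),
    5: ("kidney_right", EXCRETORY),
    6: ("urinary_bladder", EXCRETORY),
    7: ("prostate", VISCERAL),
    8: ("lung_left", VISCERAL),
    9: ("lung_right", VISCERAL),
}

PROSTATE_ID = 7
LIVER_ID = 1
AORTA_THORACIC_ID = 2
AORTA_ABDOMINAL_ID = 3
KIDNEY_IDS = (4, 5)
BLADDER_ID = 6
LUNG_IDS = (8, 9)


def _individual_bones() -> dict[int, tuple[str, int]]:
    """The 51 individual bones: id -> (name, region id)."""
    bones: dict[int, tuple[str, int]] = {}
    nid = 110
    for side in ("left", "right"):  # 2 femurs
        bones[nid] = (f"femur_{side}", 101)
        nid += 1
    for name in ("hip_bone_left", "hip_bone_right", "sacrum"):  # 3 pelvic
        bones[nid] = (name, 102)
        nid += 1
    for i in range(1, 6):  # 5 lumbar vertebrae
        bones[nid] = (f"vertebra_L{i}", 103)
        nid += 1
    for i in range(1, 13):  # 12 thoracic vertebrae
        bones[nid] = (f"vertebra_T{i}", 104)
        nid += 1
    # 29 thorax bones: 24 ribs, sternum, 2 clavicles, 2 scapulae
    for side in ("left", "right"):
        for i in range(1, 13):
            bones[nid] = (f"rib_{side}_{i}", 105)
            nid += 1
    for name in ("sternum", "clavicle_left", "clavicle_right", "scapula_left", "scapula_right"):
        bones[nid] = (name, 105)
        nid += 1
    assert len(bones) == 51
    return bones


@dataclass
class LabelVocabulary:
    """Maps organ ids to names/compartments and bone ids to the 5 regions."""

    organs: dict[int, tuple[str, str]] = field(default_factory=dict)
    bone_to_region: dict[int, int] = field(default_factory=dict)
    region_names: dict[int, str] = field(default_factory=lambda: dict(BONE_REGIONS))

    def __post_init__(self) -> None:
        overlap = set(self.organs) & set(self.bone_to_region)
        if overlap:
            raise ValueError(f"ids used as both organ and bone: {sorted(overlap)}")
        bad = set(self.bone_to_region.values()) - set(self.region_names)
        if bad:
            raise ValueError(f"bone ids map to unknown regions: {sorted(bad)}")

    @property
    def known_ids(self) -> set[int]:
        return set(self.organs) | set(self.bone_to_region) | set(self.region_names)

    @property
    def bone_region_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.region_names))

    def name_of(self, label_id: int) -> str:
        if label_id in self.organs:
            return self.organs[label_id][0]
        if label_id in self.region_names:
            return self.region_names[label_id]
        raise KeyError(label_id)

    def compartment_of(self, label_id: int) -> str:
        if label_id in self.organs:
            return self.organs[label_id][1]
        if label_id in self.bone_to_region or label_id in self.region_names:
            return BONE
        raise KeyError(label_id)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "organs": {str(k): list(v) for k, v in self.organs.items()},
            "bone_to_region": {str(k): v for k, v in self.bone_to_region.items()},
            "region_names": {str(k): v for k, v in self.region_names.items()},
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LabelVocabulary":
        doc = json.loads(Path(path).read_text())
        return cls(
            organs={int(k): tuple(v) for k, v in doc["organs"].items()},
            bone_to_region={int(k): int(v) for k, v in doc["bone_to_region"].items()},
            region_names={int(k): v for k, v in doc["region_names"].items()},
        )


def default_vocabulary(include_prostate: bool = True) -> LabelVocabulary:
    """The shipped vocabulary: Table-style organ set plus 51 bones in 5 regions.

    Region ids themselves are accepted as bone labels (mapping to their own
    region), so pre-grouped label maps — e.g. phantom output — are valid input.
    """
    organs = dict(ORGANS)
    if not include_prostate:
        organs.pop(PROSTATE_ID)
    bone_to_region = {bid: region for bid, (_, region) in _individual_bones().items()}
    bone_to_region.update({rid: rid for rid in BONE_REGIONS})
    return LabelVocabulary(organs=organs, bone_to_region=bone_to_region)


def group_bones(labels: VoxelGrid, vocab: LabelVocabulary) -> VoxelGrid:
    """Relabel each individual bone to its skeletal region.

    Visceral/reference/excretory labels pass through unchanged; voxel counts
    are conserved within each region (the region's count is the sum of its
    member bones'). Unknown nonzero ids are an error.
    """
    if not labels.is_integer:
        raise ValueError("label map must have integer dtype")
    present = set(np.unique(labels.data).tolist()) - {0}
    unknown = sorted(present - vocab.known_ids)
    if unknown:
        raise ValueError(f"unknown label id(s): {unknown}")
    out = labels.data.copy()
    for bone_id in present & set(vocab.bone_to_region):
        out[labels.data == bone_id] = vocab.bone_to_region[bone_id]
    return labels.with_data(out)
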