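"""Tumor voxel counting and deterministic osteomeningioma subtype assignment.

Each tumor voxel inherits the label of the compartment it intersects on the
exclusive map. The subtype is a pure function of the three compartment counts:

* POM      — confined to bone: N_bone > 0, N_dura = 0, N_intra = 0
* SOM-I    — bone plus the juxta-osseous band, no intradural extension:
             N_bone > 0, N_dura > 0, N_intra = 0
* SOM-IIA  — all three compartments, osseous >= intradural (ties -> IIA)
* SOM-IIB  — all three compartments, intradural > osseous

Patterns outside these rules are flagged, never forced into a class:
``not_osteomeningioma`` when N_bone = 0, and ``skipped_layer`` for the
geometrically anomalous N_bone > 0, N_dura = 0, N_intra > 0. Tumor voxels
outside every compartment (e.g. subcutaneous extension) are tallied as
``n_other`` and reported, but never influence the call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .compartments import (
    LABEL_INTRADURAL,
    LABEL_JUXTAOSSEOUS,
    LABEL_OSSEOUS,
    CompartmentMap,
    LayerSpec,
    compartment_map_for_skull,
)
from .grids import BinaryMask, CaseInputs

logger = logging.getLogger(__name__)


class Subtype(str, Enum):
    POM = "POM"
    SOM_I = "SOM-I"
    SOM_IIA = "SOM-IIA"
    SOM_IIB = "SOM-IIB"


#: severity ordering used by the thickness-monotonicity property
SUBTYPE_ORDER = [Subtype.POM, Subtype.SOM_I, Subtype.SOM_IIA, Subtype.SOM_IIB]


class Anomaly(str, Enum):
    NOT_OSTEOMENINGIOMA = "not_osteomeningioma"
    SKIPPED_LAYER = "skipped_layer"


@dataclass(frozen=True)
class CompartmentCounts:
    """Exact tumor voxel tallies per compartment."""

    n_bone: int
    n_dura: int
    n_intra: int
    n_other: int
    voxel_volume_mm3: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_bone", "n_dura", "n_intra", "n_other"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.voxel_volume_mm3 <= 0:
            raise ValueError("voxel_volume_mm3 must be positive")

    @property
    def total(self) -> int:
        return self.n_bone + self.n_dura + self.n_intra + self.n_other

    def percentages(self) -> dict[str, float]:
        """Fractions of total tumor voxels per compartment (denominator includes n_other)."""
        t = self.total
        if t == 0:
            return {"bone": 0.0, "dura": 0.0, "intra": 0.0, "other": 0.0}
        return {
            "bone": self.n_bone / t,
            "dura": self.n_dura / t,
            "intra": self.n_intra / t,
            "other": self.n_other / t,
        }


@dataclass(frozen=True)
class ComponentVolumes:
    """Component volumes in cm^3 derived from voxel counts."""

    osseous_cm3: float
    intracranial_soft_tissue_cm3: float
    other_cm3: float

    @property
    def total_cm3(self) -> float:
        return self.osseous_cm3 + self.intracranial_soft_tissue_cm3 + self.other_cm3


@dataclass(frozen=True)
class SubtypeCall:
    """Outcome of the deterministic classification for one tumor."""

    counts: CompartmentCounts
    thickness_mm: float
    subtype: Optional[Subtype] = None
    anomaly: Optional[Anomaly] = None

    @property
    def valid(self) -> bool:
        return self.subtype is not None

    def __post_init__(self) -> None:
        if (self.subtype is None) == (self.anomaly is None):
            raise ValueError("exactly one of subtype / anomaly must be set")


def count_compartment_voxels(
    tumor: BinaryMask, cmap: CompartmentMap
) -> CompartmentCounts:
    """Tally tumor voxels per compartment on the exclusive label map."""
    tumor.grid.require_compatible(cmap.grid, "tumor mask and compartment map")
    inside = tumor.as_bool()
    labels = cmap.labels[inside]
    n_bone = int((labels == LABEL_OSSEOUS).sum())
    n_dura = int((labels == LABEL_JUXTAOSSEOUS).sum())
    n_intra = int((labels == LABEL_INTRADURAL).sum())
    n_other = int(inside.sum()) - n_bone - n_dura - n_intra
    return CompartmentCounts(
        n_bone=n_bone, n_dura=n_dura, n_intra=n_intra, n_other=n_other,
        voxel_volume_mm3=tumor.grid.voxel_volume_mm3,
    )


def classify_osteomeningioma(
    counts: CompartmentCounts, thickness_mm: float = 5.0
) -> SubtypeCall:
    """Apply the deterministic subtype rules to a count triple.

    Total and single-valued for every non-negative integer triple; ``n_other``
    never affects the result.
    """
    b, d, i = counts.n_bone, counts.n_dura, counts.n_intra
    if b == 0:
        return SubtypeCall(counts, thickness_mm, anomaly=Anomaly.NOT_OSTEOMENINGIOMA)
    if d == 0 and i == 0:
        return SubtypeCall(counts, thickness_mm, subtype=Subtype.POM)
    if d > 0 and i == 0:
        return SubtypeCall(counts, thickness_mm, subtype=Subtype.SOM_I)
    if d == 0 and i > 0:
        return SubtypeCall(counts, thickness_mm, anomaly=Anomaly.SKIPPED_LAYER)
    # all three involved; ties go to IIA
    if b >= i:
        return SubtypeCall(counts, thickness_mm, subtype=Subtype.SOM_IIA)
    return SubtypeCall(counts, thickness_mm, subtype=Subtype.SOM_IIB)


def component_volumes(counts: CompartmentCounts) -> ComponentVolumes:
    """Counts -> cm^3. The intracranial soft-tissue component pools the
    juxta-osseous and intradural counts (dural enhancement plus intradural
    expansion)."""
    f = counts.voxel_volume_mm3 / 1000.0
    return ComponentVolumes(
        osseous_cm3=counts.n_bone * f,
        intracranial_soft_tissue_cm3=(counts.n_dura + counts.n_intra) * f,
        other_cm3=counts.n_other * f,
    )


def classify_case(case: CaseInputs, spec: LayerSpec) -> SubtypeCall:
    """Full per-case pipeline: cavity -> band -> map -> counts -> subtype."""
    cmap = compartment_map_for_skull(case.skull, spec)
    counts = count_compartment_voxels(case.tumor, cmap)
    call = classify_osteomeningioma(counts, thickness_mm=spec.thickness_mm)
    logger.info(
        "case %s: N_bone=%d N_dura=%d N_intra=%d N_other=%d -> %s",
        case.case_id, counts.n_bone, counts.n_dura, counts.n_intra,
        counts.n_other,
        call.subtype.value if call.valid else f"anomaly:{call.anomaly.value}",
    )
    return call


@dataclass(frozen=True)
class ReclassificationTable:
    """Per-case subtype across several layer thicknesses."""

    table: pd.DataFrame  # index case_id, one column per thickness (str labels)
    thicknesses: tuple[float, ...]

    @property
    def n_cases(self) -> int:
        return len(self.table)

    @property
    def n_stable(self) -> int:
        return int((self.table.nunique(axis=1) == 1).sum())

    @property
    def stability_fraction(self) -> float:
        return self.n_stable / self.n_cases if self.n_cases else float("nan")

    def transition_matrix(self, t_from: float, t_to: float) -> pd.DataFrame:
        """Counts of subtype moves between two thicknesses."""
        cats = [s.value for s in SUBTYPE_ORDER] + [a.value for a in Anomaly]
        src = self.table[t_from]
        dst = self.table[t_to]
        mat = pd.crosstab(src, dst).reindex(index=cats, columns=cats, fill_value=0)
        return mat.loc[mat.sum(axis=1) > 0, :]


def thickness_sensitivity(
    cases: Iterable[CaseInputs],
    thicknesses: Sequence[float] = (2.0, 3.0, 5.0),
    base_spec: LayerSpec | None = None,
) -> ReclassificationTable:
    """Re-classify every case at each layer thickness.

    The cavity and skull do not depend on the thickness, so the compartment
    map is rebuilt per thickness from one cavity extraction per case.
    """
    if not thicknesses:
        raise ValueError("thicknesses must be non-empty")
    if any(t < 0 for t in thicknesses):
        raise ValueError("thicknesses must be >= 0")
    base = base_spec or LayerSpec()
    rows = {}
    for case in cases:
        row = {}
        for t in thicknesses:
            spec = LayerSpec(thickness_mm=float(t), connectivity=base.connectivity,
                             closing_radius_mm=base.closing_radius_mm)
            call = classify_case(case, spec)
            row[float(t)] = call.subtype.value if call.valid else call.anomaly.value
        rows[case.case_id] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "case_id"
    return ReclassificationTable(table=table, thicknesses=tuple(float(t) for t in thicknesses))


def call_to_record(case_id: str, call: SubtypeCall) -> dict:
    """Flatten a call into a serializable report row."""
    vols = component_volumes(call.counts)
    pct = call.counts.percentages()
    return {
        "case_id": case_id,
        "thickness_mm": call.thickness_mm,
        "n_bone": call.counts.n_bone,
        "n_dura": call.counts.n_dura,
        "n_intra": call.counts.n_intra,
        "n_other": call.counts.n_other,
        "pct_bone": pct["bone"],
        "pct_dura": pct["dura"],
        "pct_intra": pct["intra"],
        "pct_other": pct["other"],
        "osseous_cm3": vols.osseous_cm3,
        "soft_tissue_cm3": vols.intracranial_soft_tissue_cm3,
        "other_cm3": vols.other_cm3,
        "total_cm3": vols.total_cm3,
        "subtype": call.subtype.value if call.valid else "",
        "anomaly": call.anomaly.value if call.anomaly else "",
    }
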