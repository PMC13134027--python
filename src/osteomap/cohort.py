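"""Cohort-level aggregation: frequency maps, index tumors, rater agreement."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import BinaryMask, VolumeGrid

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DensityMap:
    """Voxelwise count of cases whose tumor covers each voxel."""

    grid: VolumeGrid
    counts: np.ndarray
    n_cases: int
    subtype: Optional[str] = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.min() < 0 or counts.max() > self.n_cases:
            raise ValueError("counts must lie in [0, n_cases]")
        object.__setattr__(self, "counts", counts.astype(np.int32))

    def normalized(self) -> np.ndarray:
        """Fraction-of-cases variant for display; counts stay the stored truth."""
        return self.counts / self.n_cases

    def save(self, path: str | Path) -> None:
        path = Path(path)
        img = nib.Nifti1Image(self.counts.astype(np.int32), affine=self.grid.affine)
        img.header.set_zooms(self.grid.spacing)
        nib.save(img, str(path))
        sidecar = path.parent / (path.name.split(".")[0] + ".json")
        sidecar.write_text(json.dumps(
            {"n_cases": self.n_cases, "subtype": self.subtype}, indent=2))


def frequency_map(
    masks: Sequence[BinaryMask], subtype: Optional[str] = None
) -> DensityMap:
    """Sum binary masks voxelwise into a per-subgroup density map."""
    if not masks:
        raise ValueError("frequency_map needs at least one mask")
    grid = masks[0].grid
    total = np.zeros(grid.shape, dtype=np.int32)
    for m in masks:
        grid.require_compatible(m.grid, "frequency-map inputs")
        total += m.voxels
    return DensityMap(grid=grid, counts=total, n_cases=len(masks), subtype=subtype)


def select_index_tumors(volumes: pd.DataFrame) -> pd.DataFrame:
    """Keep one index tumor per patient: the lesion with the largest total
    volume; exact ties break to the lexicographically smallest case_id and
    are logged.

    ``volumes`` needs columns patient_id, case_id, total_cm3.
    """
    required = {"patient_id", "case_id", "total_cm3"}
    missing = required - set(volumes.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = []
    for patient, group in volumes.groupby("patient_id", sort=True):
        best = group.sort_values(["total_cm3", "case_id"],
                                 ascending=[False, True]).iloc[0]
        ties = group[group["total_cm3"] == best["total_cm3"]]
        if len(ties) > 1:
            logger.warning(
                "patient %s: %d tumors tie at %.3f cm^3; keeping %s",
                patient, len(ties), best["total_cm3"], best["case_id"])
        out.append(best)
    return pd.DataFrame(out).reset_index(drop=True)


def _overlap_counts(a: BinaryMask, b: BinaryMask) -> tuple[int, int, int]:
    a.grid.require_compatible(b.grid, "agreement masks")
    av, bv = a.as_bool(), b.as_bool()
    return int((av & bv).sum()), int(av.sum()), int(bv.sum())


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|); both-empty scores 1.0 (logged)."""
    inter, na, nb = _overlap_counts(a, b)
    if na + nb == 0:
        logger.warning("dice of two empty masks defined as 1.0")
        return 1.0
    return 2.0 * inter / (na + nb)


def jaccard(a: BinaryMask, b: BinaryMask) -> float:
    """Jaccard index |A∩B| / |A∪B|; both-empty scores 1.0 (logged)."""
    inter, na, nb = _overlap_counts(a, b)
    union = na + nb - inter
    if union == 0:
        logger.warning("jaccard of two empty masks defined as 1.0")
        return 1.0
    return inter / union


def volume_correlation(
    pairs: Sequence[tuple[float, float]], alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Pearson r between paired volumes with a Fisher-z confidence interval."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 volume pairs")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("degenerate variance in one coordinate")
    r = float(np.corrcoef(x, y)[0, 1])
    n = len(pairs)
    from scipy import stats as sps
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    q = sps.norm.ppf(1 - alpha / 2)
    lo, hi = np.tanh(z - q * se), np.tanh(z + q * se)
    return r, (float(lo), float(hi))


def agreement_report(
    pairs: Sequence[tuple[str, BinaryMask, BinaryMask]]
) -> pd.DataFrame:
    """Per-pair Dice/Jaccard and volumes, one row per rater pair."""
    rows = []
    for name, a, b in pairs:
        rows.append({
            "pair": name,
            "dice": dice(a, b),
            "jaccard": jaccard(a, b),
            "volume_a_cm3": a.volume_mm3() / 1000.0,
            "volume_b_cm3": b.volume_mm3() / 1000.0,
        })
    return pd.DataFrame(rows)
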