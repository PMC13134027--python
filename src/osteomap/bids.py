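"""BIDS-style cohort layout: case discovery, loading, and writing.

Expected tree::

    <root>/participants.tsv                      # optional covariates
    <root>/sub-<ID>/anat/sub-<ID>_desc-tumor_mask.nii.gz
    <root>/sub-<ID>/anat/sub-<ID>_desc-skull_mask.nii.gz

Subjects with several lesions carry ``_desc-tumor<k>_`` suffixes and share the
subject's single skull mask; such lesions get case ids ``<ID>-tumor<k>``.

``participants.tsv`` columns: case_id, age, sex, location, edema, mass_effect,
seizure, icp, exophthalmos, subcutaneous_mass, incidental (0/1 flags, empty =
missing).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd

from .grids import BinaryMask, CaseInputs, read_mask, write_mask

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = [
    "case_id", "age", "sex", "location", "edema", "mass_effect", "seizure",
    "icp", "exophthalmos", "subcutaneous_mass", "incidental",
]

_TUMOR_RE = re.compile(r"^sub-(?P<sub>[^_]+)_desc-tumor(?P<k>\d*)_mask\.nii(\.gz)?$")


def _split_case_id(case_id: str) -> tuple[str, str]:
    """Return (subject label, tumor suffix) for a case id."""
    if "-tumor" in case_id:
        sub, _, k = case_id.rpartition("-tumor")
        return sub, k
    return case_id, ""


def list_cases(root: str | Path) -> list[str]:
    """Discover case ids (one per tumor mask) under a BIDS-style root."""
    root = Path(root)
    cases = []
    for tumor_path in sorted(root.glob("sub-*/anat/*_desc-tumor*_mask.nii*")):
        m = _TUMOR_RE.match(tumor_path.name)
        if m is None:
            continue
        sub, k = m.group("sub"), m.group("k")
        cases.append(sub if not k else f"{sub}-tumor{k}")
    return cases


def load_participants(root: str | Path) -> pd.DataFrame | None:
    """Read the cohort covariate table if present."""
    tsv = Path(root) / "participants.tsv"
    if not tsv.exists():
        return None
    return pd.read_csv(tsv, sep="\t", dtype={"case_id": str})


def load_bids_case(root: str | Path, case_id: str) -> CaseInputs:
    """Load one case's tumor and skull masks plus covariates.

    Raises a descriptive error on missing files, and a grid-mismatch error
    (naming both grids) when tumor and skull disagree.
    """
    root = Path(root)
    sub, k = _split_case_id(case_id)
    anat = root / f"sub-{sub}" / "anat"
    suffix = f"tumor{k}" if k else "tumor"
    tumor_path = _find_mask(anat, sub, suffix)
    skull_path = _find_mask(anat, sub, "skull")
    if tumor_path is None:
        raise FileNotFoundError(f"case {case_id!r} not found: no {suffix} mask under {anat}")
    if skull_path is None:
        raise FileNotFoundError(f"case {case_id!r}: no skull mask under {anat}")
    tumor = read_mask(tumor_path)
    skull = read_mask(skull_path)
    covariates = None
    participants = load_participants(root)
    if participants is not None:
        row = participants[participants["case_id"] == case_id]
        if len(row):
            covariates = row.iloc[0].to_dict()
    return CaseInputs(case_id=case_id, tumor=tumor, skull=skull, covariates=covariates)


def _find_mask(anat: Path, sub: str, desc: str) -> Path | None:
    for ext in (".nii.gz", ".nii"):
        p = anat / f"sub-{sub}_desc-{desc}_mask{ext}"
        if p.exists():
            return p
    return None


def write_bids_case(
    root: str | Path, case_id: str, tumor: BinaryMask, skull: BinaryMask
) -> None:
    """Write one case into the BIDS-style layout (creates directories)."""
    root = Path(root)
    sub, k = _split_case_id(case_id)
    anat = root / f"sub-{sub}" / "anat"
    anat.mkdir(parents=True, exist_ok=True)
    suffix = f"tumor{k}" if k else "tumor"
    write_mask(tumor, anat / f"sub-{sub}_desc-{suffix}_mask.nii.gz")
    skull_path = anat / f"sub-{sub}_desc-skull_mask.nii.gz"
    if not skull_path.exists():
        write_mask(skull, skull_path)


def write_participants(root: str | Path, table: pd.DataFrame) -> None:
    Path(root).mkdir(parents=True, exist_ok=True)
    table.to_csv(Path(root) / "participants.tsv", sep="\t", index=False)
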