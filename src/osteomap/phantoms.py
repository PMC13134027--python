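"""Seeded synthetic skulls, lesions, and clinical tables.

Phantoms stand in for the patient masks the pipeline was designed for: a
closed skull shell (or slab) on a small isotropic grid, plus lesions either
placed voxel-by-voxel with an exactly known compartment composition
(``make_lesion_by_counts``) or as a transmural sphere crossing the inner
table. By-counts lesions record their ground truth by construction, which
makes the voxel-counting and classification stages testable without any
patient data. All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import Subtype, CompartmentCounts
from .compartments import (
    LABEL_INTRADURAL,
    LABEL_JUXTAOSSEOUS,
    LABEL_OSSEOUS,
    CompartmentMap,
    LayerSpec,
    compartment_map_for_skull,
)
from .grids import BinaryMask, VolumeGrid

_LABEL_NAMES = {LABEL_OSSEOUS: "osseous", LABEL_JUXTAOSSEOUS: "juxta-osseous",
                LABEL_INTRADURAL: "intradural", 0: "background"}


class InfeasibleLesionError(ValueError):
    """A lesion request exceeds the voxels available in a compartment."""


@dataclass(frozen=True)
class ShellGeometry:
    """Closed spherical skull shell: inner_r < |x - center| <= outer_r (mm)."""

    center: tuple[float, float, float]
    outer_r_mm: float
    inner_r_mm: float

    def __post_init__(self) -> None:
        if not (self.outer_r_mm > self.inner_r_mm > 0):
            raise ValueError(
                f"need outer_r > inner_r > 0, got outer={self.outer_r_mm} inner={self.inner_r_mm}"
            )


@dataclass(frozen=True)
class SlabGeometry:
    """Half-space skull along one axis: bone occupies voxel indices in
    bone_range, the declared cavity occupies cavity_range (both inclusive)."""

    axis: int
    bone_range: tuple[int, int]
    cavity_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")
        for name, (lo, hi) in (("bone_range", self.bone_range),
                               ("cavity_range", self.cavity_range)):
            if lo > hi:
                raise ValueError(f"{name} must be (lo, hi) with lo <= hi")


def make_skull(grid: VolumeGrid, geometry: ShellGeometry | SlabGeometry) -> BinaryMask:
    """Build a skull mask from an analytic geometry description."""
    if isinstance(geometry, ShellGeometry):
        d = _center_distances(grid, geometry.center)
        vox = (d > geometry.inner_r_mm) & (d <= geometry.outer_r_mm)
        return BinaryMask(grid=grid, voxels=vox)
    if isinstance(geometry, SlabGeometry):
        vox = np.zeros(grid.shape, dtype=bool)
        sl = [slice(None)] * 3
        sl[geometry.axis] = slice(geometry.bone_range[0], geometry.bone_range[1] + 1)
        vox[tuple(sl)] = True
        return BinaryMask(grid=grid, voxels=vox)
    raise TypeError(f"unknown geometry {type(geometry).__name__}")


def slab_cavity(grid: VolumeGrid, geometry: SlabGeometry) -> BinaryMask:
    """The declared cavity of a slab phantom (slabs enclose nothing, so the
    cavity is given by construction rather than extracted)."""
    vox = np.zeros(grid.shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[geometry.axis] = slice(geometry.cavity_range[0], geometry.cavity_range[1] + 1)
    vox[tuple(sl)] = True
    return BinaryMask(grid=grid, voxels=vox)


def _center_distances(grid: VolumeGrid, center: tuple[float, float, float]) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(grid.shape, grid.spacing)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    cz, cy, cx = center
    return np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)


def make_transmural_sphere(
    cmap: CompartmentMap, center: tuple[float, float, float], radius_mm: float
) -> BinaryMask:
    """Ball of voxel centers within ``radius_mm`` of ``center`` (world mm),
    clipped to the grid — a continuous lesion that can cross the inner table."""
    if radius_mm <= 0:
        raise ValueError("radius_mm must be > 0")
    d = _center_distances(cmap.grid, center)
    return BinaryMask(grid=cmap.grid, voxels=d <= radius_mm)


def make_lesion_by_counts(
    cmap: CompartmentMap,
    n_bone: int,
    n_dura: int,
    n_intra: int,
    n_other: int = 0,
    contiguous: bool = False,
    seed: int = 0,
) -> tuple[BinaryMask, CompartmentCounts]:
    """Place a lesion with an exactly known per-compartment composition.

    Returns the mask and its ground-truth counts (equal to the request by
    construction). With ``contiguous=True`` the lesion is grown as a single
    connected region crossing compartments where the geometry allows,
    falling back to random placement inside a compartment that cannot be
    reached contiguously. Deterministic per seed.
    """
    request = {LABEL_OSSEOUS: n_bone, LABEL_JUXTAOSSEOUS: n_dura,
               LABEL_INTRADURAL: n_intra, 0: n_other}
    for lab, want in request.items():
        if want < 0:
            raise ValueError("requested counts must be >= 0")
        have = int((cmap.labels == lab).sum())
        if want > have:
            raise InfeasibleLesionError(
                f"requested {want} voxels in the {_LABEL_NAMES[lab]} compartment "
                f"but only {have} are available"
            )
    rng = np.random.default_rng(seed)
    chosen = (_grow_contiguous(cmap, request, rng) if contiguous
              else _pick_random(cmap, request, rng))
    vox = np.zeros(cmap.grid.shape, dtype=bool)
    if chosen.size:
        vox[tuple(chosen.T)] = True
    counts = CompartmentCounts(
        n_bone=n_bone, n_dura=n_dura, n_intra=n_intra, n_other=n_other,
        voxel_volume_mm3=cmap.grid.voxel_volume_mm3,
    )
    return BinaryMask(grid=cmap.grid, voxels=vox), counts


def _pick_random(cmap: CompartmentMap, request: dict[int, int],
                 rng: np.random.Generator) -> np.ndarray:
    picks = []
    for lab, want in request.items():
        if want == 0:
            continue
        pool = np.argwhere(cmap.labels == lab)
        idx = rng.choice(len(pool), size=want, replace=False)
        picks.append(pool[np.sort(idx)])
    return np.concatenate(picks) if picks else np.empty((0, 3), dtype=int)


_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def _grow_contiguous(cmap: CompartmentMap, request: dict[int, int],
                     rng: np.random.Generator) -> np.ndarray:
    """Sequential per-compartment growth keeping the whole lesion connected.

    Compartments are grown in order osseous -> juxta-osseous -> intradural ->
    background; each subsequent compartment is seeded from its voxels
    6-adjacent to the already-grown region, then filled by breadth-first
    search within the compartment. The first compartment is seeded next to
    the following one so the crossing is possible. A compartment that cannot
    be reached contiguously falls back to random placement.
    """
    from scipy import ndimage

    labels = cmap.labels
    order = [lab for lab in (LABEL_OSSEOUS, LABEL_JUXTAOSSEOUS, LABEL_INTRADURAL, 0)
             if request.get(lab, 0) > 0]
    chosen: list[tuple[int, int, int]] = []
    region = np.zeros(labels.shape, dtype=bool)
    struct = ndimage.generate_binary_structure(3, 1)
    for pos, lab in enumerate(order):
        comp = labels == lab
        if pos == 0:
            seeds = comp.copy()
            if len(order) > 1:  # start next to the following compartment
                near_next = ndimage.binary_dilation(labels == order[1], struct) & comp
                if near_next.any():
                    seeds = near_next
            pool = np.argwhere(seeds)
            starts = [tuple(pool[rng.integers(len(pool))])]
        else:
            frontier = ndimage.binary_dilation(region, struct) & comp
            starts = [tuple(p) for p in np.argwhere(frontier)]
            rng.shuffle(starts)
        # carve a path to the next needed compartment first so the crossing
        # stays reachable, then fill the remaining quota around it
        taken: list[tuple[int, int, int]] = []
        if starts and pos + 1 < len(order):
            targets = ndimage.binary_dilation(labels == order[pos + 1], struct) & comp
            path = _bfs_path(comp, starts, targets)
            taken = path[: request[lab]]
        if starts and len(taken) < request[lab]:
            seeds = taken if taken else starts
            taken += _bfs_fill(comp, list(seeds), request[lab] - len(taken), rng,
                               exclude=set(taken))
        if len(taken) < request[lab]:  # unreachable remainder: random fallback
            have = {tuple(t) for t in taken}
            avail = [tuple(p) for p in np.argwhere(comp) if tuple(p) not in have]
            idx = np.atleast_1d(rng.choice(len(avail), size=request[lab] - len(taken),
                                           replace=False))
            taken.extend(avail[i] for i in idx)
        for v in taken:
            region[v] = True
        chosen.extend(taken)
    return np.array(chosen, dtype=int).reshape(-1, 3)


def _bfs_path(comp: np.ndarray, starts: list[tuple[int, int, int]],
              targets: np.ndarray) -> list[tuple[int, int, int]]:
    """Shortest 6-connected path within ``comp`` from any start to any voxel of
    ``targets``; empty when unreachable."""
    shape = comp.shape
    parent: dict[tuple[int, int, int], tuple[int, int, int] | None] = \
        {s: None for s in starts}
    queue = deque(starts)
    while queue:
        v = queue.popleft()
        if targets[v]:
            path = []
            node: tuple[int, int, int] | None = v
            while node is not None:
                path.append(node)
                node = parent[node]
            return path[::-1]
        for o in _OFFSETS:
            nb = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
            if (all(0 <= nb[k] < shape[k] for k in range(3)) and nb not in parent
                    and comp[nb]):
                parent[nb] = v
                queue.append(nb)
    return []


def _bfs_fill(comp: np.ndarray, starts: list[tuple[int, int, int]], want: int,
              rng: np.random.Generator,
              exclude: set | None = None) -> list[tuple[int, int, int]]:
    """Multi-source BFS inside one compartment, taking up to ``want`` voxels."""
    shape = comp.shape
    taken: list[tuple[int, int, int]] = []
    exclude = exclude or set()
    seen = set(starts) | exclude
    queue = deque(starts)
    while queue and len(taken) < want:
        v = queue.popleft()
        if v not in exclude:  # path seeds are expanded but already counted
            taken.append(v)
        neighbors = [(v[0] + o[0], v[1] + o[1], v[2] + o[2]) for o in _OFFSETS]
        rng.shuffle(neighbors)
        for nb in neighbors:
            if (all(0 <= nb[k] < shape[k] for k in range(3)) and nb not in seen
                    and comp[nb]):
                seen.add(nb)
                queue.append(nb)
    return taken


# ---------------------------------------------------------------------------
# whole-cohort phantom construction


@dataclass(frozen=True)
class PhantomCohortSpec:
    """A shell-skull phantom cohort with subtype-targeted by-counts lesions."""

    grid_size: int = 32
    spacing_mm: float = 1.0
    outer_r_mm: float = 13.0
    inner_r_mm: float = 10.0
    layer: LayerSpec = field(default_factory=lambda: LayerSpec(thickness_mm=5.0))
    seed: int = 0


#: representative count triples per target subtype (bone, dura, intra)
_SUBTYPE_TEMPLATES = {
    Subtype.POM: (60, 0, 0),
    Subtype.SOM_I: (50, 30, 0),
    Subtype.SOM_IIA: (80, 40, 30),
    Subtype.SOM_IIB: (20, 40, 90),
}


def make_phantom_case(
    spec: PhantomCohortSpec, subtype: Subtype, seed: int
) -> tuple[BinaryMask, BinaryMask, CompartmentCounts]:
    """One shell phantom with a lesion whose true counts match ``subtype``.

    Returns (tumor, skull, ground-truth counts).
    """
    grid = VolumeGrid(
        shape=(spec.grid_size,) * 3, spacing=(spec.spacing_mm,) * 3
    )
    c = (spec.grid_size - 1) * spec.spacing_mm / 2.0
    skull = make_skull(grid, ShellGeometry((c, c, c), spec.outer_r_mm, spec.inner_r_mm))
    cmap = compartment_map_for_skull(skull, spec.layer)
    rng = np.random.default_rng(seed)
    b, d, i = _SUBTYPE_TEMPLATES[subtype]
    jitter = lambda n: int(n * (0.5 + rng.random())) if n else 0  # noqa: E731
    b, d, i = jitter(b), jitter(d), jitter(i)
    if subtype is Subtype.SOM_IIA and b < i:
        b = i  # keep the tie-or-greater relation that defines IIA
    if subtype is Subtype.SOM_IIB and i <= b:
        i = b + 1
    tumor, truth = make_lesion_by_counts(cmap, b, d, i, seed=seed)
    return tumor, skull, truth


# ---------------------------------------------------------------------------
# synthetic clinical tables

SYMPTOMS = ["edema", "mass_effect", "seizure", "icp", "exophthalmos",
            "subcutaneous_mass", "incidental"]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Class-conditional generator for clinical covariate tables.

    ``symptom_probs`` maps subtype -> {symptom: Bernoulli probability}.
    Ages are normal (mean 56.4, SD 12.5 years by default, the scale typical
    of meningioma cohorts); total volumes are log-normal.
    """

    n_per_subtype: dict[Subtype, int]
    symptom_probs: dict[Subtype, dict[str, float]]
    age_mean: float = 56.4
    age_sd: float = 12.5
    p_female: float = 0.90
    p_skull_base: float = 0.49
    log_volume_mean: float = 2.5
    log_volume_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for st, probs in self.symptom_probs.items():
            for sym, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability for {st}/{sym} outside [0,1]: {p}")
        if any(n < 0 for n in self.n_per_subtype.values()):
            raise ValueError("n_per_subtype entries must be >= 0")


def make_synthetic_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Draw a per-case table with class-conditional symptom flags.

    Columns: case_id, subtype (ground truth), age, sex, location,
    total_cm3, and one 0/1 column per symptom. Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    k = 0
    for subtype in SUBTYPE_ENUM_ORDER:
        n = spec.n_per_subtype.get(subtype, 0)
        probs = spec.symptom_probs.get(subtype, {})
        for _ in range(n):
            k += 1
            row = {
                "case_id": f"case-{k:04d}",
                "subtype": subtype.value,
                "age": float(rng.normal(spec.age_mean, spec.age_sd)),
                "sex": "F" if rng.random() < spec.p_female else "M",
                "location": ("skull_base" if rng.random() < spec.p_skull_base
                             else "convexity"),
                "total_cm3": float(rng.lognormal(spec.log_volume_mean,
                                                 spec.log_volume_sd)),
            }
            for sym in SYMPTOMS:
                p = probs.get(sym, 0.0)
                row[sym] = int(rng.random() < p)
            rows.append(row)
    columns = ["case_id", "subtype", "age", "sex", "location", "total_cm3", *SYMPTOMS]
    return pd.DataFrame(rows, columns=columns)


SUBTYPE_ENUM_ORDER = [Subtype.POM, Subtype.SOM_I, Subtype.SOM_IIA, Subtype.SOM_IIB]
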