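"""Core domain containers: labeled template volume, injections, cell tables.

Coordinates are millimetres in template stereotaxic space throughout; voxel
indices are 0-based and never serialized.  The label convention follows the
volumetric atlas template: 0 = outside the brain, 1 = white matter, and
integer codes >= 2 are cortical areas.  Laminar position of gray-matter
voxels is stored as a parallel grid with 0 = not assigned, 1 = supragranular
(above layer 4), 2 = infragranular (below layer 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

OUTSIDE = 0
WHITE = 1
FIRST_AREA_LABEL = 2

LAMINA_NONE = 0
LAMINA_SUPRA = 1
LAMINA_INFRA = 2

LAMINA_TOKENS = {"none": LAMINA_NONE, "supra": LAMINA_SUPRA, "infra": LAMINA_INFRA}
LAMINA_NAMES = {v: k for k, v in LAMINA_TOKENS.items()}

#: Columns of a validated cell table (one row per labeled neuron).
CELL_COLUMNS = ["injection_id", "tracer", "x_mm", "y_mm", "z_mm", "area", "lamina"]

#: Retrograde tracers used in the connectivity dataset.
TRACERS = ("FB", "DY", "FE", "FR", "CTBgr", "CTBr")


class DegenerateGeometryError(ValueError):
    """Raised when a template's geometry cannot support the analyses."""


class UnassignableError(ValueError):
    """Raised when a point cannot be assigned to any cortical area."""


@dataclass
class TemplateVolume:
    """A labeled 3D brain volume with laminar annotations.

    Parameters
    ----------
    labels
        Integer grid; 0 outside, 1 white matter, >=2 cortical area codes.
    lamina
        Grid of laminar codes over gray voxels (0 none, 1 supra, 2 infra).
    voxel_size
        Voxel edge lengths in mm per axis (supports anisotropy).
    affine
        4x4 voxel-index -> mm map (NIfTI convention, voxel centers).
    midthickness
        (M, 3) mm coordinates of the cortical mid-thickness surface.
    area_names
        Optional map from integer area code to atlas area name.
    """

    labels: np.ndarray
    lamina: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray
    midthickness: np.ndarray
    area_names: dict[int, str] | None = None

    _area_tree: cKDTree | None = field(default=None, repr=False, compare=False)
    _area_points: np.ndarray | None = field(default=None, repr=False, compare=False)
    _area_labels_flat: np.ndarray | None = field(default=None, repr=False, compare=False)
    _mid_tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer grid")
        if self.lamina.shape != self.labels.shape:
            raise ValueError("lamina grid must match labels shape")
        self.affine = np.asarray(self.affine, dtype=float)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        self.midthickness = np.asarray(self.midthickness, dtype=float).reshape(-1, 3)

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def origin(self) -> np.ndarray:
        """mm coordinate of voxel (0, 0, 0)'s center."""
        return self.affine[:3, 3].copy()

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        out = idx @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if out.shape[0] == 1 and np.asarray(idx).ndim else out

    def world_to_voxel(self, pos: np.ndarray) -> np.ndarray:
        """Nearest voxel index containing each mm position (no bounds clip)."""
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        inv = np.linalg.inv(self.affine)
        cont = pos @ inv[:3, :3].T + inv[:3, 3]
        idx = np.rint(cont).astype(np.int64)
        return idx[0] if pos.shape[0] == 1 else idx

    def world_to_voxel_continuous(self, pos: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        inv = np.linalg.inv(self.affine)
        cont = pos @ inv[:3, :3].T + inv[:3, 3]
        return cont[0] if pos.shape[0] == 1 else cont

    def in_bounds(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(idx)
        ok = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)
        return ok[0] if ok.shape[0] == 1 else ok

    def label_at(self, pos: np.ndarray) -> int:
        """Label at the voxel containing a mm position (OUTSIDE if off-grid)."""
        idx = np.atleast_2d(self.world_to_voxel(pos))[0]
        if not np.all((idx >= 0) & (idx < np.array(self.shape))):
            return OUTSIDE
        return int(self.labels[tuple(idx)])

    # -- masks and areas --------------------------------------------------

    @property
    def area_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids >= FIRST_AREA_LABEL]

    def area_mask(self, area: int) -> np.ndarray:
        if area not in self.area_ids:
            raise KeyError(f"area {area} not present in template")
        return self.labels == area

    @property
    def gray_mask(self) -> np.ndarray:
        return self.labels >= FIRST_AREA_LABEL

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels >= WHITE

    def gray_volume(self, area: int | None = None) -> float:
        """Gray-matter volume in mm^3, of one area or of the whole cortex."""
        vv = float(np.prod(self.voxel_size))
        mask = self.gray_mask if area is None else self.area_mask(area)
        return float(mask.sum()) * vv

    # -- nearest-structure queries ---------------------------------------

    def _ensure_area_tree(self) -> None:
        if self._area_tree is None:
            idx = np.argwhere(self.gray_mask)
            self._area_points = self.voxel_to_world(idx)
            self._area_labels_flat = self.labels[tuple(idx.T)]
            self._area_tree = cKDTree(self._area_points)

    def nearest_area_voxel(self, pos: np.ndarray) -> tuple[int, float]:
        """(area label, mm distance) of the nearest gray-matter voxel center."""
        self._ensure_area_tree()
        dist, i = self._area_tree.query(np.asarray(pos, dtype=float))
        return int(self._area_labels_flat[i]), float(dist)

    def _ensure_mid_tree(self) -> None:
        if self._mid_tree is None:
            if self.midthickness.shape[0] == 0:
                raise ValueError("template has an empty mid-thickness surface")
            self._mid_tree = cKDTree(self.midthickness)

    def nearest_midthickness(self, pos: np.ndarray) -> tuple[int, np.ndarray]:
        """Index and mm coordinate of the nearest mid-thickness point.

        Ties (within 1e-9 mm) are broken toward the lowest vertex index so the
        projection is deterministic.
        """
        self._ensure_mid_tree()
        pos = np.asarray(pos, dtype=float)
        k = min(4, self.midthickness.shape[0])
        dist, idx = self._mid_tree.query(pos, k=k)
        dist = np.atleast_1d(dist)
        idx = np.atleast_1d(idx)
        tied = idx[dist <= dist[0] + 1e-9]
        best = int(tied.min())
        return best, self.midthickness[best].copy()


@dataclass
class Injection:
    """One retrograde-tracer deposit."""

    id: str
    tracer: str
    center: np.ndarray  # mm
    assigned_area: int
    volume: float  # mm^3
    exclusion_radius: float  # mm
    percent_by_area: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.exclusion_radius < 0:
            raise ValueError("exclusion_radius must be >= 0")
        if self.tracer not in TRACERS:
            raise ValueError(f"unknown tracer {self.tracer!r}; expected one of {TRACERS}")
        if self.percent_by_area:
            total = sum(self.percent_by_area.values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError("percent_by_area must sum to 1 over touched areas")

    @property
    def fully_contained(self) -> bool:
        """True when the whole deposit sits inside a single cytoarchitectural area."""
        if not self.percent_by_area:
            return True
        return max(self.percent_by_area.values()) >= 1.0 - 1e-9


def validate_cell_table(cells: pd.DataFrame, known_areas: np.ndarray | None = None) -> pd.DataFrame:
    """Validate and normalize a cell table; raises on malformed rows."""
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    out = cells[CELL_COLUMNS].copy()
    for col in ("x_mm", "y_mm", "z_mm"):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            raise ValueError(
                f"non-numeric or NaN coordinate in column {col!r}, first bad row "
                f"{int(np.flatnonzero(bad.to_numpy())[0])}"
            )
        out[col] = vals.astype(float)
    lam = out["lamina"].astype(str)
    bad = ~lam.isin(list(LAMINA_TOKENS))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"unknown lamina token {lam.iloc[row]!r} in row {row}")
    out["lamina"] = lam
    out["area"] = pd.to_numeric(out["area"], errors="raise").astype(int)
    if known_areas is not None:
        unknown = set(out["area"]) - set(int(a) for a in known_areas)
        if unknown:
            raise ValueError(f"cell table references unknown areas: {sorted(unknown)}")
    return out


def cells_xyz(cells: pd.DataFrame) -> np.ndarray:
    """(N, 3) mm coordinate array of a cell table."""
    return cells[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
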