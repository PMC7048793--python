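"""Readers and writers for the pipeline's on-disk formats.

Label volumes travel as NIfTI-1 integer images (the affine is
authoritative; anisotropic voxels such as the 40 x 500 x 40 um atlas
template are honored per axis).  Cell tables, injections, matrices and
per-pair QC go to UTF-8 comma-separated files with mandatory headers.
Every writer can attach a JSON provenance sidecar carrying the config
hash, seed and package version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .template import Injection, TemplateVolume, validate_cell_table

__all__ = [
    "RunConfig",
    "read_cell_table",
    "write_cell_table",
    "read_injections",
    "write_injections",
    "read_label_volume",
    "write_label_volume",
    "write_matrix_csv",
    "write_provenance",
]


@dataclass
class RunConfig:
    """End-to-end run settings (phantom + analysis + output paths)."""

    out_dir: str = "marmoconn_out"
    seed: int = 0
    n_areas: int = 8
    grid_shape: tuple[int, int, int] = (80, 80, 80)
    voxel_size: tuple[float, float, float] = (0.25, 0.25, 0.25)
    cells_per_injection: int = 2000
    decay_length: float = 3.0
    f_wm: float = 1.0
    f_gm: float = 0.05
    primary_set: str = "default"
    local_mm: float = 4.0
    distant_mm: float = 8.0
    ratio_sweep: tuple[float, ...] = ()
    verbosity: int = 1

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("grid_shape", "voxel_size", "ratio_sweep"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_provenance(path, config: RunConfig | dict, extra: dict | None = None) -> None:
    from . import __version__

    payload = {
        "package": "marmoconn",
        "version": __version__,
        "config": asdict(config) if isinstance(config, RunConfig) else dict(config),
    }
    if isinstance(config, RunConfig):
        payload["seed"] = config.seed
        payload["config_hash"] = config.config_hash()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=list) + "\n")


# -- cell tables ------------------------------------------------------------


def write_cell_table(cells: pd.DataFrame, path) -> None:
    validate_cell_table(cells).to_csv(path, index=False)


def read_cell_table(path, tpl: TemplateVolume | None = None,
                    column_map: dict[str, str] | None = None,
                    mirror_x: bool = False) -> pd.DataFrame:
    """Validated cell table from CSV.

    ``column_map`` renames external-source columns onto the package schema
    (portal exports name columns differently across releases).
    ``mirror_x`` flips the x coordinate for left-hemisphere imports.
    """
    raw = pd.read_csv(path)
    if column_map:
        raw = raw.rename(columns=column_map)
    known = tpl.area_ids if tpl is not None else None
    cells = validate_cell_table(raw, known_areas=known)
    if cells["injection_id"].isna().any():
        raise ValueError("cell table has rows without an injection id")
    if mirror_x:
        cells["x_mm"] = -cells["x_mm"]
    return cells


# -- injections -------------------------------------------------------------

_INJ_COLUMNS = ["id", "tracer", "x_mm", "y_mm", "z_mm", "assigned_area",
                "volume_mm3", "exclusion_radius_mm", "percent_by_area"]


def write_injections(injections: list[Injection], path) -> None:
    rows = []
    for inj in injections:
        rows.append(
            {
                "id": inj.id,
                "tracer": inj.tracer,
                "x_mm": inj.center[0],
                "y_mm": inj.center[1],
                "z_mm": inj.center[2],
                "assigned_area": inj.assigned_area,
                "volume_mm3": inj.volume,
                "exclusion_radius_mm": inj.exclusion_radius,
                "percent_by_area": json.dumps(
                    {str(k): v for k, v in inj.percent_by_area.items()}
                ),
            }
        )
    pd.DataFrame(rows, columns=_INJ_COLUMNS).to_csv(path, index=False)


def read_injections(path) -> list[Injection]:
    df = pd.read_csv(path)
    missing = [c for c in _INJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"injection table missing columns: {missing}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate injection id {dup!r}")
    out = []
    for _, row in df.iterrows():
        pct = {int(k): float(v) for k, v in json.loads(row["percent_by_area"]).items()}
        out.append(
            Injection(
                id=str(row["id"]),
                tracer=str(row["tracer"]),
                center=np.array([row["x_mm"], row["y_mm"], row["z_mm"]], dtype=float),
                assigned_area=int(row["assigned_area"]),
                volume=float(row["volume_mm3"]),
                exclusion_radius=float(row["exclusion_radius_mm"]),
                percent_by_area=pct,
            )
        )
    return out


# -- label volumes ----------------------------------------------------------


def write_label_volume(tpl: TemplateVolume, path, area_names_path=None,
                       lamina_path=None, midthickness_path=None) -> None:
    """TemplateVolume as NIfTI label image (+ optional companions)."""
    img = nib.Nifti1Image(tpl.labels.astype(np.int32), tpl.affine)
    nib.save(img, str(path))
    if area_names_path is not None:
        names = tpl.area_names or {int(a): str(a) for a in tpl.area_ids}
        Path(area_names_path).write_text(
            json.dumps({str(k): v for k, v in names.items()}, indent=2) + "\n"
        )
    if lamina_path is not None:
        nib.save(nib.Nifti1Image(tpl.lamina.astype(np.uint8), tpl.affine), str(lamina_path))
    if midthickness_path is not None:
        pd.DataFrame(tpl.midthickness, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
            midthickness_path, index=False
        )


def read_label_volume(path, lamina_path=None, midthickness_path=None,
                      area_names_path=None) -> TemplateVolume:
    """TemplateVolume from a NIfTI-1 integer label image."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError("label volume must hold integer codes")
        data = np.round(data).astype(np.int32)
    affine = np.asarray(img.affine, dtype=float)
    if affine.shape != (4, 4) or not np.isfinite(affine).all():
        raise ValueError("label volume has no usable affine")
    voxel_size = tuple(float(v) for v in img.header.get_zooms()[:3])
    if lamina_path is not None:
        lam = np.asanyarray(nib.load(str(lamina_path)).dataobj).astype(np.uint8)
    else:
        lam = np.zeros(data.shape, dtype=np.uint8)
    if midthickness_path is not None:
        mid = pd.read_csv(midthickness_path)[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
    else:
        mid = np.empty((0, 3))
    names = None
    if area_names_path is not None:
        names = {int(k): v for k, v in json.loads(Path(area_names_path).read_text()).items()}
    return TemplateVolume(
        labels=data.astype(np.int32), lamina=lam, voxel_size=voxel_size,
        affine=affine, midthickness=mid, area_names=names,
    )


# -- matrices ---------------------------------------------------------------


def write_matrix_csv(matrix: pd.DataFrame, path, intrinsic_sentinel: bool = True) -> None:
    """Connectivity matrix CSV: rows = source areas, columns = injected areas;
    empty cell = projection not detected, 'intrinsic' on the diagonal."""
    out = matrix.copy().astype(object)
    if intrinsic_sentinel:
        for a in out.index:
            if a in out.columns:
                out.loc[a, a] = "intrinsic"
    out.index.name = "source_area"
    out.to_csv(path, na_rep="")


def read_matrix_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df = df.replace("intrinsic", np.nan)
    df.columns = [int(c) if str(c).isdigit() else c for c in df.columns]
    return df.astype(float)
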