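"""Connectivity quantification: FLNe, SLN, aggregation and matrix ordering.

For an injection into area A, the strength of the projection from area B is
the fraction of labeled neurons, extrinsic:

    FLNe(B -> A) = N(B -> A) / (N(all -> A) - N(A -> A))

i.e. intrinsic (within-area) cells are removed from both numerator pool and
denominator.  The laminar-origin index is the supragranular fraction:

    SLN(B -> A) = N_supra(B -> A) / N(B -> A)

SLN is undefined (NaN) for zero-count projections and for source areas
without a visible layer 4 (in the marmoset atlas: entorhinal and piriform
cortex, the amygdalopiriform transition area and area 29 subdivisions).

Across multiple injections into the same area, FLNe is averaged
arithmetically with unobserved projections counted as 0, while SLN is
re-computed from supra/infra counts pooled over the injections in which
the projection was observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .template import TemplateVolume, UnassignableError

__all__ = [
    "assign_area",
    "count_cells",
    "compute_flne",
    "compute_sln",
    "aggregate_by_area",
    "cluster_order",
    "ConnectivityMatrices",
]

#: Atlas area names whose cells carry no supra/infra assignment (no layer 4).
NO_LAYER4_AREAS = ("Ent", "Pir", "APir", "A29a", "A29b", "A29c")


def assign_area(position, tpl: TemplateVolume, tolerance: float = 0.5) -> int:
    """Area label at a mm position, or the nearest area within ``tolerance``.

    Mirrors the rule used for mapped cells: the containing voxel decides;
    points falling in white matter or just outside the parcellation are
    snapped to the nearest labeled voxel if it is no farther than the
    tolerance (mm).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    label = tpl.label_at(position)
    if label >= 2:
        return int(label)
    area, dist = tpl.nearest_area_voxel(position)
    if dist > tolerance:
        raise UnassignableError(
            f"no cortical area within {tolerance} mm of {np.asarray(position)}"
        )
    return int(area)


def count_cells(cells: pd.DataFrame, injection_id: str | None = None) -> pd.Series:
    """Labeled-cell counts per source area for one injection's table."""
    sub = cells if injection_id is None else cells[cells["injection_id"] == injection_id]
    return sub.groupby("area").size().astype(int)


def compute_flne(cells: pd.DataFrame, injection) -> pd.Series:
    """Extrinsic fraction-of-labeled-neurons vector for one injection.

    Index: source area ids (injected area excluded).  Sums to 1.
    """
    counts = count_cells(cells, injection.id)
    extrinsic = counts.drop(labels=[injection.assigned_area], errors="ignore")
    total = extrinsic.sum()
    if total == 0:
        raise ValueError(
            f"injection {injection.id}: no extrinsic labeled cells, FLNe undefined"
        )
    return (extrinsic / total).astype(float)


def compute_sln(cells: pd.DataFrame, injection,
                no_layer4: set[int] | None = None) -> pd.Series:
    """Supragranular-fraction vector for one injection (NaN where undefined)."""
    sub = cells[cells["injection_id"] == injection.id]
    no_layer4 = no_layer4 or set()
    out = {}
    for area, grp in sub.groupby("area"):
        if int(area) == int(injection.assigned_area):
            continue
        if int(area) in no_layer4:
            out[int(area)] = np.nan
            continue
        supra = int((grp["lamina"] == "supra").sum())
        infra = int((grp["lamina"] == "infra").sum())
        denom = supra + infra
        out[int(area)] = supra / denom if denom > 0 else np.nan
    return pd.Series(out, dtype=float)


@dataclass
class ConnectivityMatrices:
    """Per-area and per-injection connectivity tables (source x target).

    Rows are source areas, columns injected (target) areas — the layout of
    the published matrices.  NaN marks a projection not observed in any
    injection; the diagonal (intrinsic) is NaN in FLNe/SLN by construction.
    """

    counts: pd.DataFrame
    flne: pd.DataFrame
    sln: pd.DataFrame
    observed: pd.DataFrame
    per_injection_flne: dict[str, pd.Series] = field(default_factory=dict)
    per_injection_sln: dict[str, pd.Series] = field(default_factory=dict)
    per_injection_counts: dict[str, pd.Series] = field(default_factory=dict)
    injection_targets: dict[str, int] = field(default_factory=dict)


def aggregate_by_area(cells: pd.DataFrame, injections,
                      no_layer4: set[int] | None = None,
                      source_areas=None,
                      unobserved_as_zero: bool = True) -> ConnectivityMatrices:
    """Build count/FLNe/SLN matrices from per-injection tables.

    FLNe for a target area is the arithmetic mean over all its injections,
    with projections not observed in a given injection contributing 0
    (set ``unobserved_as_zero=False`` to average over observing injections
    only).  SLN pools supra/infra counts over the injections in which the
    projection was observed before taking the ratio.
    """
    no_layer4 = no_layer4 or set()
    per_flne: dict[str, pd.Series] = {}
    per_sln: dict[str, pd.Series] = {}
    per_counts: dict[str, pd.Series] = {}
    targets: dict[str, int] = {}
    for inj in injections:
        per_counts[inj.id] = count_cells(cells, inj.id)
        per_flne[inj.id] = compute_flne(cells, inj)
        per_sln[inj.id] = compute_sln(cells, inj, no_layer4=no_layer4)
        targets[inj.id] = int(inj.assigned_area)

    target_areas = sorted(set(targets.values()))
    if source_areas is None:
        source_areas = sorted(
            set().union(*(set(c.index) for c in per_counts.values())) | set(target_areas)
        )
    source_areas = [int(a) for a in source_areas]

    flne = pd.DataFrame(np.nan, index=source_areas, columns=target_areas, dtype=float)
    sln = pd.DataFrame(np.nan, index=source_areas, columns=target_areas, dtype=float)
    counts = pd.DataFrame(0, index=source_areas, columns=target_areas, dtype=int)
    observed = pd.DataFrame(False, index=source_areas, columns=target_areas, dtype=bool)

    for tgt in target_areas:
        ids = [i for i, a in targets.items() if a == tgt]
        # counts: summed over injections (intrinsic included, for reference)
        for i in ids:
            add = per_counts[i].reindex(source_areas).fillna(0).astype(int)
            counts[tgt] = counts[tgt] + add
        for src in source_areas:
            if src == tgt:
                continue
            vals = [per_flne[i].get(src, np.nan) for i in ids]
            seen = [v for v in vals if not np.isnan(v)]
            if not seen:
                continue
            observed.loc[src, tgt] = True
            if unobserved_as_zero:
                flne.loc[src, tgt] = float(np.mean([0.0 if np.isnan(v) else v for v in vals]))
            else:
                flne.loc[src, tgt] = float(np.mean(seen))
            if src in no_layer4:
                continue
            supra_tot = 0
            infra_tot = 0
            for i in ids:
                sub = cells[(cells["injection_id"] == i) & (cells["area"] == src)]
                if len(sub) == 0:
                    continue  # pool only injections observing the projection
                supra_tot += int((sub["lamina"] == "supra").sum())
                infra_tot += int((sub["lamina"] == "infra").sum())
            if supra_tot + infra_tot > 0:
                sln.loc[src, tgt] = supra_tot / (supra_tot + infra_tot)
    return ConnectivityMatrices(
        counts=counts, flne=flne, sln=sln, observed=observed,
        per_injection_flne=per_flne, per_injection_sln=per_sln,
        per_injection_counts=per_counts, injection_targets=targets,
    )


def cluster_order(matrix: pd.DataFrame, floor: float = 1e-6) -> list:
    """Area ordering from agglomerative clustering of connectivity profiles.

    Average linkage on the correlation distance between log10(FLNe + floor)
    source profiles; areas with similar connectivity end up adjacent.
    Deterministic for a given matrix.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least two areas to order")
    x = np.log10(matrix.fillna(0.0).to_numpy(dtype=float) + floor)
    # rows with zero variance make correlation distance undefined; nudge them
    sd = x.std(axis=1)
    x[sd == 0] += np.linspace(0, 1e-9, x.shape[1])
    dist = pdist(x, metric="correlation")
    dist = np.clip(dist, 0.0, None)
    link = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(link)
    labels = [matrix.index[i] for i in order]
    return [x.item() if hasattr(x, "item") else x for x in labels]
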