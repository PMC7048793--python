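"""Synthetic brain phantom: labeled volume, injections and cell tables.

The phantom is a spherical-shell "cortex" (gray matter of a stated
thickness) wrapped around a white-matter core, partitioned into contiguous
areas by spherical Voronoi sectors.  Its virtue is analytic geometry: the
mid-thickness surface sits at the shell's radial midpoint and the laminar
split (supra/infra) at the same midpoint stands in for layer 4.

Cell tables are drawn from the same statistical structure the downstream
analyses assume: for an injection into area A, the expected number of
labeled cells in source area B is proportional to

    pair_weights[A, B] * exp(-d(A, B) / lambda) * V_B

where d is the *wiring* distance between the areas (module ``wiring``, so
generator and analysis share one metric), lambda a decay length in mm, and
V_B the source's gray volume (cells fall uniformly in source gray matter,
so the per-area count scales with volume).  Intrinsic (within-area) cells
use ``intrinsic_weight`` in place of the distance kernel.  Each extrinsic
cell is supragranular with probability ``supra_fraction[A, B]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import wiring
from .template import (
    FIRST_AREA_LABEL,
    LAMINA_INFRA,
    LAMINA_SUPRA,
    WHITE,
    DegenerateGeometryError,
    Injection,
    TemplateVolume,
    TRACERS,
)

__all__ = [
    "PhantomConfig",
    "build_template",
    "place_injections",
    "simulate_cells",
    "expected_source_distribution",
]


@dataclass
class PhantomConfig:
    """Parameters of the synthetic brain and its planted connectivity.

    Defaults give an 80^3 grid at 0.25 mm (20 mm cube), a 2 mm-thick
    cortical shell of outer radius 8 mm split into 8 areas, a 3 mm
    connection decay length, and ~2000 cells per injection.  Exclusion
    radii are drawn uniformly from 0.1-1.1 mm, the range observed for
    injection-halo exclusion zones in retrograde tracer material.
    """

    grid_shape: tuple[int, int, int] = (80, 80, 80)
    voxel_size: tuple[float, float, float] = (0.25, 0.25, 0.25)
    n_areas: int = 8
    cortex_thickness: float = 2.0  # mm
    outer_radius: float = 8.0  # mm
    decay_length: float = 3.0  # mm, lambda of the distance kernel
    pair_weights: np.ndarray | None = None  # (n_areas, n_areas), rows = target
    supra_fraction: float | np.ndarray = 0.5
    intrinsic_weight: float = 1.0
    cells_per_injection: int = 2000
    exclusion_radius_range: tuple[float, float] = (0.1, 1.1)  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_areas < 2:
            raise ValueError("n_areas must be >= 2")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be > 0")
        if self.intrinsic_weight < 0:
            raise ValueError("intrinsic_weight must be >= 0")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be > 0")
        sf = np.asarray(self.supra_fraction, dtype=float)
        if np.any(sf < 0) or np.any(sf > 1):
            raise ValueError("supra_fraction must lie in [0, 1]")
        if self.pair_weights is not None:
            w = np.asarray(self.pair_weights, dtype=float)
            if w.shape != (self.n_areas, self.n_areas):
                raise ValueError("pair_weights must be (n_areas, n_areas)")
            if np.any(w < 0):
                raise ValueError("pair_weights must be nonnegative")
        if not (0 <= self.exclusion_radius_range[0] <= self.exclusion_radius_range[1]):
            raise ValueError("invalid exclusion_radius_range")

    # -- planted-parameter accessors -------------------------------------

    def resolved_pair_weights(self) -> np.ndarray:
        """Planted relative projection strengths (rows = target area index).

        When unset, log-normal weights (sigma = 1) are drawn from the config
        seed, mimicking the heavy-tailed spread of projection strengths.
        """
        if self.pair_weights is not None:
            return np.asarray(self.pair_weights, dtype=float)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 119]))
        return rng.lognormal(mean=0.0, sigma=1.0, size=(self.n_areas, self.n_areas))

    def supra_fraction_matrix(self) -> np.ndarray:
        sf = np.asarray(self.supra_fraction, dtype=float)
        if sf.ndim == 0:
            return np.full((self.n_areas, self.n_areas), float(sf))
        if sf.shape != (self.n_areas, self.n_areas):
            raise ValueError("supra_fraction matrix must be (n_areas, n_areas)")
        return sf


def _fibonacci_directions(n: int) -> np.ndarray:
    """n well-spread unit vectors (golden-spiral points on the sphere)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def build_template(config: PhantomConfig) -> TemplateVolume:
    """Deterministic labeled shell-cortex template from a config."""
    vs = np.asarray(config.voxel_size, dtype=float)
    if config.cortex_thickness < 2 * float(vs.min()):
        raise DegenerateGeometryError(
            f"cortex thickness {config.cortex_thickness} mm spans fewer than two "
            f"voxels at voxel size {tuple(vs)}"
        )
    shape = np.asarray(config.grid_shape, dtype=int)
    origin = -(shape - 1) / 2.0 * vs  # grid centered on the mm origin
    idx = np.indices(tuple(shape), dtype=float)
    coords = np.stack([idx[a] * vs[a] + origin[a] for a in range(3)], axis=-1)
    r = np.linalg.norm(coords, axis=-1)

    r_out = float(config.outer_radius)
    r_in = r_out - float(config.cortex_thickness)
    if r_in <= 0:
        raise DegenerateGeometryError("cortex thickness exceeds the outer radius")
    if r_out > float((shape * vs).min()) / 2.0:
        raise DegenerateGeometryError("outer radius does not fit inside the grid")

    labels = np.zeros(tuple(shape), dtype=np.int32)
    labels[r < r_in] = WHITE
    shell = (r >= r_in) & (r < r_out)

    # contiguous sectors: nearest of n well-spread directions
    dirs = _fibonacci_directions(config.n_areas)
    sh = coords[shell]
    with np.errstate(invalid="ignore"):
        unit = sh / np.linalg.norm(sh, axis=1, keepdims=True)
    sector = np.argmax(unit @ dirs.T, axis=1)
    labels[shell] = FIRST_AREA_LABEL + sector.astype(np.int32)

    lamina = np.zeros(tuple(shape), dtype=np.uint8)
    mid_r = 0.5 * (r_in + r_out)
    lamina[shell & (r >= mid_r)] = LAMINA_SUPRA  # outer half: closer to pia
    lamina[shell & (r < mid_r)] = LAMINA_INFRA

    # mid-thickness surface: centers of gray voxels straddling the mid radius
    half = 0.5 * float(vs.min())
    midmask = shell & (np.abs(r - mid_r) <= half)
    mid_pts = coords[midmask]

    affine = np.eye(4)
    affine[:3, :3] = np.diag(vs)
    affine[:3, 3] = origin
    return TemplateVolume(
        labels=labels,
        lamina=lamina,
        voxel_size=tuple(vs),
        affine=affine,
        midthickness=mid_pts,
        area_names={int(FIRST_AREA_LABEL + k): f"S{k + 1}" for k in range(config.n_areas)},
    )


def place_injections(tpl: TemplateVolume, areas, config: PhantomConfig,
                     tracers=None) -> list[Injection]:
    """One injection per requested area at a random gray voxel of that area.

    The assigned area is re-read from the label at the barycenter voxel (the
    placement rule used for real deposits); the exclusion radius is drawn
    uniformly from the configured range.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    known = set(int(a) for a in tpl.area_ids)
    out: list[Injection] = []
    lo, hi = config.exclusion_radius_range
    for i, a in enumerate(areas):
        a = int(a)
        if a not in known:
            raise KeyError(f"area {a} absent from template")
        vox = np.argwhere(tpl.labels == a)
        center = tpl.voxel_to_world(vox[rng.integers(len(vox))])
        r_ex = float(rng.uniform(lo, hi))
        r_core = 0.5 * r_ex  # deposit core inside the halo exclusion zone
        volume = 4.0 / 3.0 * np.pi * r_core**3
        assigned = tpl.label_at(center)
        pct = _percent_by_area(tpl, center, r_core)
        tracer = tracers[i] if tracers is not None else TRACERS[i % len(TRACERS)]
        out.append(
            Injection(
                id=f"INJ{i:03d}-{tracer}",
                tracer=tracer,
                center=center,
                assigned_area=int(assigned),
                volume=volume,
                exclusion_radius=r_ex,
                percent_by_area=pct,
            )
        )
    return out


def _percent_by_area(tpl: TemplateVolume, center: np.ndarray, radius: float) -> dict[int, float]:
    """Fractions of area-labeled voxels of a ball around the deposit center."""
    vs = np.asarray(tpl.voxel_size)
    half = np.ceil(radius / vs).astype(int) + 1
    c = np.atleast_2d(tpl.world_to_voxel(center))[0]
    lo = np.maximum(c - half, 0)
    hi = np.minimum(c + half + 1, np.array(tpl.shape))
    sub = tpl.labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    grid = np.indices(sub.shape, dtype=float)
    pos = np.stack(
        [grid[a] + lo[a] for a in range(3)], axis=-1
    ) * vs + tpl.origin
    inside = np.linalg.norm(pos - center, axis=-1) <= max(radius, float(vs.max()) / 2)
    touched = sub[inside]
    touched = touched[touched >= FIRST_AREA_LABEL]
    if touched.size == 0:
        return {int(tpl.label_at(center)): 1.0}
    ids, counts = np.unique(touched, return_counts=True)
    total = counts.sum()
    return {int(i): float(cnt) / float(total) for i, cnt in zip(ids, counts)}


def expected_source_distribution(config: PhantomConfig, tpl: TemplateVolume,
                                 target_area: int,
                                 dmat: wiring.DistanceMatrix) -> pd.Series:
    """Planted probability that a labeled cell falls in each source area.

    This is the closed-form expectation the generator samples from and the
    reference that recovery tests compare estimated FLNe/connectivity
    distances against.
    """
    areas = [int(a) for a in tpl.area_ids]
    w = config.resolved_pair_weights()
    ti = areas.index(int(target_area))
    lam = config.decay_length
    probs = {}
    for sj, b in enumerate(areas):
        vol = tpl.gray_volume(b)
        if b == target_area:
            probs[b] = config.intrinsic_weight * vol
        else:
            d = dmat.lookup(int(target_area), b)
            probs[b] = w[ti, sj] * np.exp(-d / lam) * vol
    s = pd.Series(probs, dtype=float)
    total = s.sum()
    if total <= 0:
        raise ValueError("all planted weights are zero for this injection")
    return s / total


def simulate_cells(tpl: TemplateVolume, injections: list[Injection],
                   config: PhantomConfig,
                   dmat: wiring.DistanceMatrix | None = None) -> pd.DataFrame:
    """Labeled-cell table for a set of injections (fully seed-reproducible).

    For each injection, ``cells_per_injection`` cells are split across
    source areas by a multinomial draw from the planted distribution, then
    placed uniformly in the source's supra- or infragranular gray matter
    according to the per-pair supragranular probability.
    """
    if dmat is None:
        dmat = wiring.pairwise_area_distances(tpl)
    sf = config.supra_fraction_matrix()
    areas = [int(a) for a in tpl.area_ids]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    vs = np.asarray(tpl.voxel_size)

    vox_by_area_lam: dict[tuple[int, int], np.ndarray] = {}
    for a in areas:
        m = tpl.labels == a
        vox_by_area_lam[(a, LAMINA_SUPRA)] = np.argwhere(m & (tpl.lamina == LAMINA_SUPRA))
        vox_by_area_lam[(a, LAMINA_INFRA)] = np.argwhere(m & (tpl.lamina == LAMINA_INFRA))

    rows = []
    for inj in injections:
        probs = expected_source_distribution(config, tpl, inj.assigned_area, dmat)
        counts = rng.multinomial(config.cells_per_injection, probs.to_numpy())
        ti = areas.index(int(inj.assigned_area))
        for b, n_b in zip(probs.index, counts):
            if n_b == 0:
                continue
            sj = areas.index(int(b))
            n_supra = rng.binomial(n_b, sf[ti, sj])
            for lam_code, n_lam in ((LAMINA_SUPRA, n_supra), (LAMINA_INFRA, n_b - n_supra)):
                if n_lam == 0:
                    continue
                pool = vox_by_area_lam[(int(b), lam_code)]
                if len(pool) == 0:  # degenerate tiny area: fall back to any lamina
                    pool = np.argwhere(tpl.labels == int(b))
                pick = pool[rng.integers(len(pool), size=n_lam)]
                jitter = rng.uniform(-0.5, 0.5, size=(n_lam, 3)) * vs
                pos = pick * vs + tpl.origin + jitter
                for p in pos:
                    rows.append(
                        (inj.id, inj.tracer, p[0], p[1], p[2], int(b),
                         "supra" if lam_code == LAMINA_SUPRA else "infra")
                    )
    cells = pd.DataFrame(
        rows, columns=["injection_id", "tracer", "x_mm", "y_mm", "z_mm", "area", "lamina"]
    )
    return cells


def make_phantom(config: PhantomConfig | None = None, injection_areas=None):
    """Convenience: (template, injections, cells, distance matrix) in one call."""
    config = config or PhantomConfig()
    tpl = build_template(config)
    if injection_areas is None:
        injection_areas = list(tpl.area_ids)
    inj = place_injections(tpl, injection_areas, config)
    dmat = wiring.pairwise_area_distances(tpl)
    cells = simulate_cells(tpl, inj, config, dmat=dmat)
    return tpl, inj, cells, dmat
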