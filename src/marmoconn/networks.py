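"""Local-versus-distant connectivity across functional cortical networks.

Per injection, labeled cells within 4 mm of the injection center count as
local afferents and cells farther than 8 mm as distant; cells between the
thresholds belong to neither class.  The per-injection statistic is the
ratio of the local fraction to the distant fraction, compared across
functional networks of areas (primary sensorimotor, higher-order
somatomotor, visuomotor integration, and the two putative default-mode
homologs) with a tie-corrected Kruskal-Wallis H test followed by Dunn's
pairwise rank comparisons (Holm-adjusted by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import wiring
from .template import Injection, TemplateVolume, cells_xyz

__all__ = [
    "NetworkTable",
    "default_networks",
    "RatioRecord",
    "local_distant_ratio",
    "compare_networks",
    "NetworkComparison",
]

LOCAL_MM = 4.0
DISTANT_MM = 8.0


@dataclass
class NetworkTable:
    """Disjoint named groups of areas (functional networks)."""

    networks: dict[str, list]

    def __post_init__(self) -> None:
        if not self.networks:
            raise ValueError("network table must be nonempty")
        seen: set = set()
        for name, areas in self.networks.items():
            if not areas:
                raise ValueError(f"network {name!r} has no areas")
            dup = seen & set(areas)
            if dup:
                raise ValueError(f"areas assigned to multiple networks: {sorted(dup)}")
            seen |= set(areas)

    def network_of(self, area) -> str | None:
        for name, areas in self.networks.items():
            if area in areas:
                return name
        return None


def default_networks() -> NetworkTable:
    """The five marmoset functional networks (atlas area names)."""
    with resources.files("marmoconn.data").joinpath("networks_default.json").open() as f:
        return NetworkTable(json.load(f))


@dataclass
class RatioRecord:
    """Local/distant afferent composition of one injection."""

    injection_id: str
    network: str | None
    n_cells: int
    frac_local: float
    frac_distant: float
    ratio: float  # inf when no distant cells
    local_mm: float = LOCAL_MM
    distant_mm: float = DISTANT_MM

    def __post_init__(self) -> None:
        if self.frac_local + self.frac_distant > 1 + 1e-12:
            raise ValueError("local and distant fractions exceed 1")


def local_distant_ratio(inj: Injection, cells: pd.DataFrame,
                        tpl: TemplateVolume | None = None,
                        cost: wiring.CostField | None = None,
                        metric: str = "wiring",
                        local_mm: float = LOCAL_MM,
                        distant_mm: float = DISTANT_MM,
                        network: str | None = None) -> RatioRecord:
    """Fractions of labeled cells within ``local_mm`` / beyond ``distant_mm``
    of the injection center, and their ratio.

    ``metric='wiring'`` (default) measures simulated-tract lengths through
    the cost field; ``metric='euclidean'`` uses straight-line distances.
    """
    if local_mm >= distant_mm:
        raise ValueError("local threshold must be below the distant threshold")
    sub = cells[cells["injection_id"] == inj.id]
    if len(sub) == 0:
        raise ValueError(f"injection {inj.id}: no labeled cells")
    pos = cells_xyz(sub)
    if metric == "euclidean":
        d = np.linalg.norm(pos - inj.center, axis=1)
    elif metric == "wiring":
        if cost is None:
            if tpl is None:
                raise ValueError("wiring metric needs a template or cost field")
            cost = wiring.build_cost_field(tpl)
        d = wiring.distances_from_point(cost, inj.center, pos)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    n = len(d)
    frac_local = float(np.sum(d <= local_mm)) / n
    frac_distant = float(np.sum(d > distant_mm)) / n
    ratio = frac_local / frac_distant if frac_distant > 0 else np.inf
    return RatioRecord(
        injection_id=inj.id, network=network, n_cells=n,
        frac_local=frac_local, frac_distant=frac_distant, ratio=ratio,
        local_mm=local_mm, distant_mm=distant_mm,
    )


@dataclass
class NetworkComparison:
    """Kruskal-Wallis + Dunn report over network groups."""

    H: float
    p: float
    groups: dict[str, int]  # network -> sample size used
    dunn: pd.DataFrame      # pairwise z, p, p_adj, significance tier
    excluded_infinite: int
    excluded_networks: list[str]


def _dunn_pairwise(values: list[np.ndarray], names: list[str],
                   adjust: str = "holm") -> pd.DataFrame:
    """Dunn's post-hoc z-tests on pooled ranks with tie correction."""
    pooled = np.concatenate(values)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term for the rank-variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1)) if n > 1 else 0.0
    mean_ranks = []
    sizes = []
    start = 0
    for v in values:
        k = len(v)
        mean_ranks.append(float(np.mean(ranks[start:start + k])))
        sizes.append(k)
        start += k
    rows = []
    for i in range(len(values)):
        for j in range(i + 1, len(values)):
            se = np.sqrt(
                (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2 * stats.norm.sf(abs(z))
            rows.append({"group_a": names[i], "group_b": names[j], "z": z, "p": p})
    out = pd.DataFrame(rows)
    if adjust == "holm":
        out["p_adj"] = multipletests(out["p"], method="holm")[1]
    elif adjust == "none":
        out["p_adj"] = out["p"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    out["tier"] = pd.cut(
        out["p_adj"], [-np.inf, 1e-3, 1e-2, 0.05, np.inf],
        labels=["***", "**", "*", "ns"],
    ).astype(str)
    return out


def compare_networks(records: list[RatioRecord], table: NetworkTable | None = None,
                     adjust: str = "holm", min_per_group: int = 2) -> NetworkComparison:
    """Rank-based comparison of local/distant ratios across networks.

    Records with infinite ratio (no distant cells) are dropped with an
    audit count; networks with fewer than ``min_per_group`` usable records
    are excluded with a warning.
    """
    by_net: dict[str, list[float]] = {}
    n_inf = 0
    for r in records:
        if r.network is None:
            continue
        if not np.isfinite(r.ratio):
            n_inf += 1
            continue
        by_net.setdefault(r.network, []).append(r.ratio)
    excluded = [k for k, v in by_net.items() if len(v) < min_per_group]
    for k in excluded:
        warnings.warn(f"network {k!r} excluded: fewer than {min_per_group} injections")
        del by_net[k]
    if len(by_net) < 2:
        raise ValueError("need at least two networks with enough injections")
    names = sorted(by_net)
    values = [np.asarray(by_net[k], dtype=float) for k in names]
    H, p = stats.kruskal(*values)
    dunn = _dunn_pairwise(values, names, adjust=adjust)
    return NetworkComparison(
        H=float(H), p=float(p),
        groups={k: len(v) for k, v in zip(names, values)},
        dunn=dunn, excluded_infinite=n_inf, excluded_networks=excluded,
    )
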