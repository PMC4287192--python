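"""Consensus framework mapping across biparental populations.

Anchor markers segregating in two or more populations are merged by pooling
recombinant/non-recombinant meiosis counts on the *meiotic* scale (RIL
observed counts are shrunk through the inverse Haldane-Waddington expansion
first). Population heterogeneity of recombination rate is screened with a
2 x m contingency chi-square; populations with excessive heterogeneity
(P < 0.001) are excluded one at a time, largest standardized residual
first. The pooled two-point estimates drive grouping/ordering exactly as in
single-population mapping, and population-unique markers are projected onto
the framework by linear interpolation between their two nearest anchors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedEstimateError, ValidationError
from . import linkage
from .linkage import LinkageGroup, ril_expand, ril_invert, two_point_lod

__all__ = [
    "PopPairCounts",
    "PooledPairEstimate",
    "ConsensusGroup",
    "ConsensusMap",
    "test_heterogeneity",
    "pool_pair",
    "pool_all_pairs",
    "build_framework",
    "interpolate_unique",
    "collinearity",
    "summarize_map",
    "cm_per_marker",
    "length_excess_pct",
]


# ---------------------------------------------------------------------------
# per-population counts and pooling


@dataclass(frozen=True)
class PopPairCounts:
    """One population's evidence on one marker pair."""

    population: str
    k: int  # observed recombinant lines
    n: int  # informative meioses
    population_type: str = "RIL"

    def meiotic(self) -> tuple[float, float]:
        """(recombinant count, total) on the meiotic scale.

        DH counts are already meiotic; RIL observed fractions are shrunk
        through r = R/(2(1-R)) and re-expressed as expected counts.
        """
        if self.n == 0:
            return 0.0, 0.0
        if self.population_type == "DH":
            return float(self.k), float(self.n)
        r = ril_invert(self.k / self.n)
        return r * self.n, float(self.n)


@dataclass(frozen=True)
class PooledPairEstimate:
    marker_a: str
    marker_b: str
    per_population: tuple[PopPairCounts, ...]
    r: float
    n: float  # pooled meioses over included populations
    lod: float
    het_chi2: float
    het_df: int
    het_p: float
    excluded: tuple[str, ...] = ()

    @property
    def included(self) -> tuple[PopPairCounts, ...]:
        out = set(self.excluded)
        return tuple(c for c in self.per_population if c.population not in out)


def test_heterogeneity(counts: list[PopPairCounts]) -> tuple[float, int, float]:
    """2 x m contingency chi-square of meiotic recombinant proportions.

    Returns (chi2, df, P) with df = m - 1. Requires >= 2 populations with
    informative meioses.
    """
    rows = [c.meiotic() for c in counts if c.n > 0]
    if len(rows) < 2:
        raise UndefinedEstimateError("heterogeneity test needs >= 2 populations with data")
    k = np.array([r[0] for r in rows])
    n = np.array([r[1] for r in rows])
    p = k.sum() / n.sum()
    if p <= 0 or p >= 1:
        return 0.0, len(rows) - 1, 1.0
    exp_k = n * p
    exp_nk = n * (1 - p)
    chi2 = float((((k - exp_k) ** 2) / exp_k).sum() + (((n - k - exp_nk) ** 2) / exp_nk).sum())
    df = len(rows) - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def _standardized_residuals(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Max |adjusted standardized Pearson residual| per population row."""
    total = n.sum()
    p = k.sum() / total
    res = np.zeros(len(k))
    for j, (obs, col_p) in enumerate([(k, p), (n - k, 1 - p)]):
        e = n * col_p
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = np.sqrt(e * (1 - col_p) * (1 - n / total))
            r = np.where(denom > 0, (obs - e) / denom, 0.0)
        res = np.maximum(res, np.abs(r))
    return res


def pool_pair(
    marker_a: str,
    marker_b: str,
    counts: list[PopPairCounts],
    heterogeneity_alpha: float = 0.001,
) -> PooledPairEstimate:
    """Pool one marker pair's meioses across populations.

    If the heterogeneity test rejects at ``heterogeneity_alpha``, the
    population with the largest standardized residual is dropped, repeatedly,
    until homogeneity is restored or a single population remains. The pooled
    meiotic r is sum(k)/sum(n) over included populations and the LOD is the
    sum of per-population LODs evaluated at the pooled rate (re-expanded to
    each population's observed scale).
    """
    usable = [c for c in counts if c.n > 0]
    if not usable:
        raise UndefinedEstimateError(f"no meioses for pair ({marker_a}, {marker_b})")
    included = list(usable)
    excluded: list[str] = []
    chi2, df, p = (0.0, 0, 1.0)
    if len(included) >= 2:
        chi2, df, p = test_heterogeneity(included)
        while p < heterogeneity_alpha and len(included) > 1:
            mk = np.array([c.meiotic()[0] for c in included])
            mn = np.array([c.meiotic()[1] for c in included])
            worst = int(np.argmax(_standardized_residuals(mk, mn)))
            excluded.append(included.pop(worst).population)
            if len(included) >= 2:
                _, _, p = test_heterogeneity(included)
            else:
                p = 1.0

    mk = np.array([c.meiotic()[0] for c in included])
    mn = np.array([c.meiotic()[1] for c in included])
    r = float(mk.sum() / mn.sum())
    lod = 0.0
    for c in included:
        R = ril_expand(r) if c.population_type == "RIL" else r
        R = min(max(R, 1e-12), 1 - 1e-12)
        lod += float(two_point_lod(c.k, c.n, R))
    return PooledPairEstimate(
        marker_a, marker_b, tuple(usable), r, float(mn.sum()), lod, chi2, df, p,
        tuple(excluded),
    )


def pool_all_pairs(
    populations: dict[str, "linkage.SegregationMatrix"],
    markers: list[str] | None = None,
    heterogeneity_alpha: float = 0.001,
) -> pd.DataFrame:
    """Pooled two-point estimates for every marker pair shared by >= 1 population.

    Returns a pair table (marker_a, marker_b, r, lod, n, het_p, n_pops,
    excluded) compatible with :func:`durmap.linkage.group_markers` and
    :func:`durmap.linkage.order_markers`.
    """
    per_pop = {}
    for name, seg in populations.items():
        tab = linkage.estimate_all_pairs(seg)
        for row in tab.itertuples(index=False):
            key = (row.marker_a, row.marker_b) if row.marker_a < row.marker_b else (row.marker_b, row.marker_a)
            per_pop.setdefault(key, []).append(
                PopPairCounts(name, int(row.k), int(row.n), seg.population_type)
            )
    keep = set(markers) if markers is not None else None
    rows = []
    for (a, b), counts in sorted(per_pop.items()):
        if keep is not None and (a not in keep or b not in keep):
            continue
        est = pool_pair(a, b, counts, heterogeneity_alpha)
        rows.append(
            (a, b, est.r, est.lod, est.n, est.het_p, len(est.included), "|".join(est.excluded))
        )
    return pd.DataFrame(
        rows, columns=["marker_a", "marker_b", "r", "lod", "n", "het_p", "n_pops", "excluded"]
    )


# ---------------------------------------------------------------------------
# consensus map container


@dataclass(frozen=True)
class ConsensusGroup:
    name: str
    markers: tuple[str, ...]
    positions: np.ndarray
    status: tuple[str, ...]  # "framework" | "interpolated" per marker
    sources: tuple[tuple[str, ...], ...]  # populations carrying each marker

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "markers", tuple(self.markers))
        object.__setattr__(self, "status", tuple(self.status))
        object.__setattr__(self, "sources", tuple(tuple(s) for s in self.sources))
        if not (len(self.markers) == len(pos) == len(self.status) == len(self.sources)):
            raise ValidationError("consensus group field lengths differ")
        if len(pos) > 1 and np.any(np.diff(pos) < -1e-9):
            raise ValidationError("positions must be non-decreasing")

    @property
    def length_cM(self) -> float:
        return float(self.positions[-1] - self.positions[0]) if len(self.positions) else 0.0

    def position_of(self, marker: str) -> float:
        return float(self.positions[self.markers.index(marker)])


@dataclass(frozen=True)
class ConsensusMap:
    groups: tuple[ConsensusGroup, ...]

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))

    @property
    def markers(self) -> list[str]:
        return [m for g in self.groups for m in g.markers]

    def group_of(self, marker: str) -> ConsensusGroup:
        for g in self.groups:
            if marker in g.markers:
                return g
        raise ValidationError(f"marker {marker!r} not on consensus map")

    def position_of(self, marker: str) -> float:
        return self.group_of(marker).position_of(marker)

    def positions_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for m, p, s, src in zip(g.markers, g.positions, g.status, g.sources):
                rows.append((m, g.name, float(p), s, "|".join(src)))
        return pd.DataFrame(rows, columns=["marker", "group", "cM", "status", "sources"])


# ---------------------------------------------------------------------------
# framework construction


def build_framework(
    pooled_pairs: pd.DataFrame,
    anchor_sources: dict[str, tuple[str, ...]] | None = None,
    lod_min: float = 3.0,
    max_r: float = 0.3,
) -> tuple[ConsensusMap, pd.DataFrame]:
    """Group and order anchor markers on pooled estimates.

    Markers whose pooled pairs never reach the linkage thresholds split into
    separate groups (the 1A1/1A2-style situation). Returns the framework
    consensus map plus a per-group report: marker count, length, cM/marker,
    mean +/- sd of the adjacent-pair two-point LOD.
    """
    markers = sorted(set(pooled_pairs["marker_a"]) | set(pooled_pairs["marker_b"]))
    groups = linkage.group_markers(pooled_pairs, lod_min=lod_min, max_r=max_r, markers=markers)
    lod_lookup = {
        (min(a, b), max(a, b)): l
        for a, b, l in pooled_pairs[["marker_a", "marker_b", "lod"]].itertuples(index=False)
    }
    cgroups, rows = [], []
    for g in groups:
        ordered, pos = linkage.order_markers(g, pooled_pairs)
        name = ordered[0]
        src = tuple(
            tuple(anchor_sources.get(m, ())) if anchor_sources else () for m in ordered
        )
        cgroups.append(
            ConsensusGroup(name, tuple(ordered), pos, ("framework",) * len(ordered), src)
        )
        adj = [
            lod_lookup.get((min(x, y), max(x, y)), np.nan)
            for x, y in zip(ordered[:-1], ordered[1:])
        ]
        length = float(pos[-1]) if len(pos) else 0.0
        rows.append(
            (
                name,
                len(ordered),
                round(length, 2),
                round(length / len(ordered), 2) if ordered else 0.0,
                float(np.nanmean(adj)) if adj else np.nan,
                float(np.nanstd(adj)) if adj else np.nan,
            )
        )
    report = pd.DataFrame(
        rows, columns=["group", "n_markers", "length_cM", "cM_per_marker", "mean_adj_lod", "sd_adj_lod"]
    )
    cgroups.sort(key=lambda g: g.name)
    return ConsensusMap(tuple(cgroups)), report


# ---------------------------------------------------------------------------
# interpolation of unique markers


def _project(m: float, anchors_comp: np.ndarray, anchors_cons: np.ndarray) -> float:
    """Project a component position through the anchor scale.

    Between two anchors: linear interpolation. Beyond the terminal anchors:
    the scale of the two nearest anchors is extended linearly.
    """
    i = int(np.searchsorted(anchors_comp, m))
    if i == 0:
        a1, a2 = 0, 1
    elif i >= len(anchors_comp):
        a1, a2 = len(anchors_comp) - 2, len(anchors_comp) - 1
    else:
        a1, a2 = i - 1, i
    c1, c2 = anchors_comp[a1], anchors_comp[a2]
    C1, C2 = anchors_cons[a1], anchors_cons[a2]
    if c2 == c1:
        return float(C1)
    return float(C1 + (m - c1) / (c2 - c1) * (C2 - C1))


def interpolate_unique(
    component_map: LinkageGroup,
    framework: ConsensusMap,
    source: str = "",
) -> tuple[pd.DataFrame, list[str]]:
    """Project a component group's unique markers onto the framework.

    The component group must share >= 2 anchors with a single framework
    group; markers in component segments are positioned by linear scaling
    between (or linear extension beyond) their two nearest anchors. Returns
    (projections, unplaceable): projections has columns marker, group,
    cM, source.
    """
    shared_by_group: dict[str, list[str]] = {}
    fw_markers = set(framework.markers)
    for m in component_map.markers:
        if m in fw_markers:
            shared_by_group.setdefault(framework.group_of(m).name, []).append(m)
    if not shared_by_group:
        return pd.DataFrame(columns=["marker", "group", "cM", "source"]), [
            m for m in component_map.markers
        ]
    # the framework group sharing the most anchors hosts the projection
    target_name = max(shared_by_group, key=lambda g: (len(shared_by_group[g]), g))
    anchors = shared_by_group[target_name]
    unique = [m for m in component_map.markers if m not in fw_markers]
    if len(anchors) < 2:
        return pd.DataFrame(columns=["marker", "group", "cM", "source"]), unique
    target = framework.group_of(anchors[0])
    comp_pos = np.array([component_map.position_of(m) for m in anchors])
    cons_pos = np.array([target.position_of(m) for m in anchors])
    order = np.argsort(comp_pos)
    comp_pos, cons_pos = comp_pos[order], cons_pos[order]
    rows = [
        (m, target.name, _project(component_map.position_of(m), comp_pos, cons_pos), source)
        for m in unique
    ]
    return pd.DataFrame(rows, columns=["marker", "group", "cM", "source"]), []


def add_interpolated(framework: ConsensusMap, projections: pd.DataFrame) -> ConsensusMap:
    """Insert projected markers into the framework map.

    Markers tied at the same consensus position keep source-map input order,
    then name. Each group is shifted so its first marker sits at 0 when
    extensions push positions below the framework origin.
    """
    by_group: dict[str, list[tuple[str, float, str]]] = {}
    for i, row in enumerate(projections.itertuples(index=False)):
        by_group.setdefault(row.group, []).append((row.marker, float(row.cM), i))
    new_groups = []
    for g in framework.groups:
        entries = [
            (m, float(p), s, src)
            for m, p, s, src in zip(g.markers, g.positions, g.status, g.sources)
        ]
        for m, p, i in by_group.get(g.name, []):
            entries.append((m, p, "interpolated", ()))
        # stable sort: position, then framework before interpolated at ties,
        # then projection input order (encoded implicitly), then name
        entries.sort(key=lambda e: (e[1], e[2] == "interpolated", e[0]))
        pos = np.array([e[1] for e in entries])
        pos = pos - pos[0]
        new_groups.append(
            ConsensusGroup(
                g.name,
                tuple(e[0] for e in entries),
                pos,
                tuple(e[2] for e in entries),
                tuple(e[3] for e in entries),
            )
        )
    return ConsensusMap(tuple(new_groups))


# ---------------------------------------------------------------------------
# collinearity and summaries


def collinearity(
    component_map: LinkageGroup, consensus_group: ConsensusGroup
) -> tuple[float, float, int]:
    """(Spearman rho, OLS r-squared, n shared) between component and consensus.

    Orientation is resolved by taking the sign of rho: the component scale
    is flipped when that increases the rank correlation. Both statistics are
    computed on the shared markers' positions.
    """
    shared = [m for m in component_map.markers if m in consensus_group.markers]
    if len(shared) < 3:
        raise UndefinedEstimateError("collinearity needs >= 3 shared markers")
    x = np.array([component_map.position_of(m) for m in shared])
    y = np.array([consensus_group.position_of(m) for m in shared])
    rho = stats.spearmanr(x, y).statistic
    if rho < 0:
        x = -x
        rho = stats.spearmanr(x, y).statistic
    if np.std(x) == 0 or np.std(y) == 0:
        return float(rho), 1.0, len(shared)
    r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return float(rho), r2, len(shared)


def cm_per_marker(total_cM: float, n_markers: int) -> float:
    """Average inter-marker distance: total length / total marker count."""
    if n_markers <= 0:
        raise ValidationError("need >= 1 marker")
    return total_cM / n_markers


def length_excess_pct(length_cM: float, reference_cM: float) -> float:
    """Percent length excess of a map over a reference map."""
    if reference_cM <= 0:
        raise ValidationError("reference length must be positive")
    return 100.0 * (length_cM - reference_cM) / reference_cM


def summarize_map(cmap: ConsensusMap) -> pd.DataFrame:
    """Per-group and total marker counts, lengths and cM/marker by class."""
    rows = []
    for g in cmap.groups:
        n_fw = sum(s == "framework" for s in g.status)
        n_ip = sum(s == "interpolated" for s in g.status)
        n = len(g.markers)
        rows.append(
            (g.name, n_fw, n_ip, n, round(g.length_cM, 2),
             round(g.length_cM / n, 2) if n else 0.0)
        )
    df = pd.DataFrame(
        rows,
        columns=["group", "n_framework", "n_interpolated", "n_markers", "length_cM", "cM_per_marker"],
    )
    total_n = int(df["n_markers"].sum())
    total_len = float(df["length_cM"].sum())
    total = pd.DataFrame(
        [
            (
                "TOTAL",
                int(df["n_framework"].sum()),
                int(df["n_interpolated"].sum()),
                total_n,
                round(total_len, 2),
                round(cm_per_marker(total_len, total_n), 2) if total_n else 0.0,
            )
        ],
        columns=df.columns,
    )
    return pd.concat([df, total], ignore_index=True)
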