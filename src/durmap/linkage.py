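"""Single-population linkage mapping for inbred biparental populations.

Builds a genetic map from a marker x line segregation matrix of a RIL
(recombinant inbred line) or DH (doubled haploid) population: quality
filtering, two-point recombination/LOD estimation, transitive grouping,
marker ordering by two-point composite likelihood, singleton (double
crossover) correction and map assembly with Haldane distances.

Genotype coding: calls are ``0`` (parent A allele), ``1`` (parent B allele)
and ``-1`` (missing). DH lines carry one meiotic gamete each, so the
observed recombinant fraction equals the meiotic fraction r. For selfed
F-infinity RILs the observed fraction is expanded, R = 2r / (1 + 2r)
(Haldane-Waddington), and two-point estimates invert this before mapping.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyResultError, UndefinedEstimateError, ValidationError

MISSING = -1

__all__ = [
    "MISSING",
    "SegregationMatrix",
    "PairEstimate",
    "LinkageGroup",
    "MapParams",
    "haldane_cM",
    "haldane_r",
    "ril_expand",
    "ril_invert",
    "two_point_lod",
    "filter_markers",
    "estimate_pair",
    "estimate_all_pairs",
    "group_markers",
    "order_markers",
    "order_group",
    "correct_singletons",
    "build_component_map",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class SegregationMatrix:
    """Genotype calls of one biparental inbred population.

    Parameters
    ----------
    markers, lines
        Row and column labels; markers must be unique.
    calls
        ``(n_markers, n_lines)`` int8 array of {0, 1, -1}.
    population_type
        ``"RIL"`` or ``"DH"``.
    """

    markers: tuple[str, ...]
    lines: tuple[str, ...]
    calls: np.ndarray
    population_type: str

    def __post_init__(self):
        calls = np.asarray(self.calls, dtype=np.int8)
        object.__setattr__(self, "calls", calls)
        object.__setattr__(self, "markers", tuple(self.markers))
        object.__setattr__(self, "lines", tuple(self.lines))
        if self.population_type not in ("RIL", "DH"):
            raise ValidationError(
                f"unsupported population type {self.population_type!r}"
            )
        if calls.shape != (len(self.markers), len(self.lines)):
            raise ValidationError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.markers)} markers x {len(self.lines)} lines"
            )
        if len(set(self.markers)) != len(self.markers):
            dup = sorted({m for m in self.markers if self.markers.count(m) > 1})
            raise ValidationError(f"duplicate marker names: {dup}")
        if not np.isin(calls, (0, 1, MISSING)).all():
            raise ValidationError("calls must be 0, 1 or -1 (missing)")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def marker_index(self, name: str) -> int:
        try:
            return self.markers.index(name)
        except ValueError:
            raise ValidationError(f"marker {name!r} not in matrix") from None

    def subset(self, markers: list[str]) -> "SegregationMatrix":
        idx = [self.marker_index(m) for m in markers]
        return replace(self, markers=tuple(markers), calls=self.calls[idx])


@dataclass(frozen=True)
class PairEstimate:
    """Two-point estimate for one marker pair."""

    marker_a: str
    marker_b: str
    k: int  # observed recombinant lines
    n: int  # informative meioses (lines non-missing at both markers)
    R: float  # observed recombinant fraction k/n
    r: float  # meiotic recombination fraction
    lod: float

    def __post_init__(self):
        if not 0 <= self.k <= self.n:
            raise ValidationError("need 0 <= k <= n")


@dataclass(frozen=True)
class LinkageGroup:
    """Ordered markers with cumulative Haldane positions (cM), first at 0."""

    name: str
    markers: tuple[str, ...]
    positions: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "markers", tuple(self.markers))
        if len(self.markers) != len(pos):
            raise ValidationError("markers and positions length mismatch")
        if len(pos) and abs(pos[0]) > 1e-9:
            raise ValidationError("first position must be 0")
        if len(pos) > 1 and np.any(np.diff(pos) < -1e-9):
            raise ValidationError("positions must be non-decreasing")

    @property
    def length_cM(self) -> float:
        return float(self.positions[-1] - self.positions[0]) if len(self.positions) else 0.0

    def position_of(self, marker: str) -> float:
        return float(self.positions[self.markers.index(marker)])


# ---------------------------------------------------------------------------
# mapping function and RIL expansion


def haldane_cM(r) -> float | np.ndarray:
    """Haldane map distance d = -50 ln(1 - 2r), in cM, for r in [0, 0.5)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValidationError("haldane_cM requires 0 <= r < 0.5")
    out = -50.0 * np.log1p(-2.0 * r)
    return float(out) if out.ndim == 0 else out


def haldane_r(d_cM) -> float | np.ndarray:
    """Inverse Haldane function r = (1 - exp(-2 d/100)) / 2 for d >= 0 cM."""
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValidationError("distances must be >= 0")
    out = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(out) if out.ndim == 0 else out


def ril_expand(r) -> float | np.ndarray:
    """Meiotic r -> observed fraction in selfed F-infinity RILs: R = 2r/(1+2r)."""
    r = np.asarray(r, dtype=float)
    out = 2.0 * r / (1.0 + 2.0 * r)
    return float(out) if out.ndim == 0 else out


def ril_invert(R) -> float | np.ndarray:
    """Observed RIL fraction -> meiotic r = R / (2(1-R)), capped at 0.5."""
    R = np.asarray(R, dtype=float)
    out = np.where(R >= 0.5, R / np.maximum(2.0 * (1.0 - R), 1e-300), R / (2.0 * (1.0 - R)))
    out = np.minimum(out, 0.5)
    return float(out) if out.ndim == 0 else out


def two_point_lod(k, n, R) -> float | np.ndarray:
    """LOD of linkage at fraction ``R`` against the null R = 0.5.

    LOD = k log10 R + (n-k) log10(1-R) - n log10(0.5), with 0 log 0 := 0.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    R = np.asarray(R, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log10(np.maximum(R, 1e-300)), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log10(np.maximum(1.0 - R, 1e-300)), 0.0)
    out = t1 + t2 - n * np.log10(0.5)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# filtering


def filter_markers(
    seg: SegregationMatrix,
    max_missing: float = 0.15,
    distortion_p: float = 1e-4,
) -> tuple[SegregationMatrix, pd.DataFrame]:
    """Drop low-quality markers and report why.

    A marker is removed when its missing-call fraction exceeds ``max_missing``
    or when a 1 df chi-square test of the expected 1:1 segregation (on
    non-missing calls) gives P below ``distortion_p``.
    """
    if not (0 < max_missing < 1 and 0 < distortion_p < 1):
        raise ValidationError("thresholds must lie in (0, 1)")
    rows = []
    keep = []
    for i, m in enumerate(seg.markers):
        calls = seg.calls[i]
        n_missing = int((calls == MISSING).sum())
        frac_missing = n_missing / seg.n_lines
        if frac_missing > max_missing:
            rows.append((m, "missing", frac_missing, np.nan))
            continue
        a = int((calls == 0).sum())
        b = int((calls == 1).sum())
        if a + b == 0:
            rows.append((m, "missing", frac_missing, np.nan))
            continue
        chi2 = (a - b) ** 2 / (a + b)
        p = float(stats.chi2.sf(chi2, df=1))
        if p < distortion_p:
            rows.append((m, "distortion", frac_missing, p))
            continue
        keep.append(m)
    report = pd.DataFrame(rows, columns=["marker", "reason", "missing_fraction", "distortion_p"])
    if not keep:
        raise EmptyResultError("no markers left after filtering")
    return seg.subset(keep), report


# ---------------------------------------------------------------------------
# two-point estimation


def estimate_pair(seg: SegregationMatrix, marker_a: str, marker_b: str) -> PairEstimate:
    """Two-point recombination estimate between two markers.

    The observed fraction R = k/n is computed on pairwise-complete lines;
    for DH populations r = R, for RILs r inverts the Haldane-Waddington
    expansion. The LOD is evaluated at the estimate itself.
    """
    ia, ib = seg.marker_index(marker_a), seg.marker_index(marker_b)
    ca, cb = seg.calls[ia], seg.calls[ib]
    ok = (ca != MISSING) & (cb != MISSING)
    n = int(ok.sum())
    if n == 0:
        raise UndefinedEstimateError(
            f"no informative meioses for pair ({marker_a}, {marker_b})"
        )
    k = int((ca[ok] != cb[ok]).sum())
    R = k / n
    r = ril_invert(R) if seg.population_type == "RIL" else min(R, 0.5)
    return PairEstimate(marker_a, marker_b, k, n, R, float(r), float(two_point_lod(k, n, R)))


def estimate_all_pairs(seg: SegregationMatrix) -> pd.DataFrame:
    """Vectorized two-point estimates for every marker pair.

    Returns a DataFrame with one row per unordered pair: k, n, R, r, lod.
    Pairs with zero informative meioses are omitted.
    """
    A = ((seg.calls == 0)).astype(np.float64)
    B = ((seg.calls == 1)).astype(np.float64)
    V = A + B  # non-missing indicator
    n = V @ V.T
    k = A @ B.T + B @ A.T
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(n > 0, k / np.maximum(n, 1), np.nan)
    if seg.population_type == "RIL":
        r = ril_invert(np.nan_to_num(R, nan=0.5))
    else:
        r = np.minimum(np.nan_to_num(R, nan=0.5), 0.5)
    lod = two_point_lod(k, n, np.clip(np.nan_to_num(R, nan=0.5), 0.0, 1.0))
    iu, ju = np.triu_indices(seg.n_markers, 1)
    ok = n[iu, ju] > 0
    iu, ju = iu[ok], ju[ok]
    names = np.asarray(seg.markers)
    return pd.DataFrame(
        {
            "marker_a": names[iu],
            "marker_b": names[ju],
            "k": k[iu, ju].astype(int),
            "n": n[iu, ju].astype(int),
            "R": R[iu, ju],
            "r": r[iu, ju],
            "lod": lod[iu, ju],
        }
    )


# ---------------------------------------------------------------------------
# grouping


def group_markers(
    pair_estimates: pd.DataFrame,
    lod_min: float = 6.0,
    max_r: float | None = None,
    markers: list[str] | None = None,
) -> list[list[str]]:
    """Partition markers by single-linkage transitive closure of linked pairs.

    A pair links two markers when its LOD >= ``lod_min`` (and, if ``max_r``
    is given, its meiotic r <= ``max_r`` as well — the relaxed re-grouping
    rule). Groups are sorted and implicitly named by their lowest member.
    """
    g = nx.Graph()
    if markers is not None:
        g.add_nodes_from(markers)
    g.add_nodes_from(pair_estimates["marker_a"])
    g.add_nodes_from(pair_estimates["marker_b"])
    sel = pair_estimates["lod"] >= lod_min
    if max_r is not None:
        sel &= pair_estimates["r"] <= max_r
    for a, b in pair_estimates.loc[sel, ["marker_a", "marker_b"]].itertuples(index=False):
        g.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: c[0])


# ---------------------------------------------------------------------------
# ordering


def _pair_matrices(pairs: pd.DataFrame, markers: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Dense (distance_cM, lod) matrices for ``markers`` from a pair table."""
    idx = {m: i for i, m in enumerate(markers)}
    p = len(markers)
    dist = np.full((p, p), np.nan)
    lod = np.zeros((p, p))
    cap = 0.49999  # r at/above 0.5 carries no linkage information
    for a, b, r, l in pairs[["marker_a", "marker_b", "r", "lod"]].itertuples(index=False):
        if a in idx and b in idx:
            i, j = idx[a], idx[b]
            d = haldane_cM(min(float(r), cap))
            dist[i, j] = dist[j, i] = d
            lod[i, j] = lod[j, i] = float(l)
    np.fill_diagonal(dist, 0.0)
    # unestimated pairs are treated as unlinked (large distance)
    big = 2.0 * haldane_cM(cap)
    dist = np.where(np.isnan(dist), big, dist)
    return dist, lod


def _path_cost(order: np.ndarray, dist: np.ndarray) -> float:
    return float(dist[order[:-1], order[1:]].sum())


def _two_opt(order: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Path 2-opt (segment reversal) until no improving move remains."""
    order = order.copy()
    p = len(order)
    improved = True
    while improved:
        improved = False
        for i in range(p - 1):
            for j in range(i + 1, p):
                # reversing order[i..j] changes only the two boundary edges
                before = 0.0
                after = 0.0
                if i > 0:
                    before += dist[order[i - 1], order[i]]
                    after += dist[order[i - 1], order[j]]
                if j < p - 1:
                    before += dist[order[j], order[j + 1]]
                    after += dist[order[i], order[j + 1]]
                if after < before - 1e-12:
                    order[i : j + 1] = order[i : j + 1][::-1]
                    improved = True
    return order


def _ripple(order: np.ndarray, dist: np.ndarray, window: int = 4) -> tuple[np.ndarray, bool]:
    """Sliding-window exhaustive re-permutation; returns (order, improved?)."""
    order = order.copy()
    p = len(order)
    improved_any = False
    for start in range(0, max(p - window, 0) + 1):
        seg = order[start : start + window]
        best = seg.copy()
        best_cost = None
        for perm in itertools.permutations(seg):
            cand = order.copy()
            cand[start : start + window] = perm
            c = _path_cost(cand, dist)
            if best_cost is None or c < best_cost - 1e-12:
                best_cost = c
                best = np.array(perm)
        if not np.array_equal(best, seg):
            if best_cost < _path_cost(order, dist) - 1e-12:
                order[start : start + window] = best
                improved_any = True
    return order, improved_any


def order_markers(markers: list[str], pairs: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Order markers to minimize the summed adjacent Haldane distances.

    Equivalent to maximizing the two-point composite likelihood of adjacent
    pairs. Greedy insertion seeded from the highest-LOD pair, then 2-opt and
    sliding-window (size 4) ripple improvement until neither helps. Returns
    the canonically oriented order and cumulative cM positions (first = 0).
    Ties break on the lexicographically smallest marker name.
    """
    markers = sorted(markers)
    p = len(markers)
    if p == 1:
        return markers, np.array([0.0])
    dist, lod = _pair_matrices(pairs, markers)
    if p == 2:
        order = np.array([0, 1])
    else:
        # seed: highest-LOD pair (ties -> smallest indices, i.e. names)
        iu, ju = np.triu_indices(p, 1)
        best = np.lexsort((ju, iu, -lod[iu, ju]))[0]
        order = [int(iu[best]), int(ju[best])]
        placed = set(order)
        while len(order) < p:
            remaining = [i for i in range(p) if i not in placed]
            # next marker: strongest linkage to anything placed
            cand = max(remaining, key=lambda i: (lod[i, order].max(), -i))
            best_pos, best_cost = 0, None
            for pos in range(len(order) + 1):
                trial = np.array(order[:pos] + [cand] + order[pos:])
                c = _path_cost(trial, dist)
                if best_cost is None or c < best_cost - 1e-12:
                    best_cost, best_pos = c, pos
            order.insert(best_pos, cand)
            placed.add(cand)
        order = np.array(order)
        order = _two_opt(order, dist)
        improved = True
        while improved:
            order, improved = _ripple(order, dist, window=4)
            if improved:
                order = _two_opt(order, dist)
    # canonical orientation: alphabetically smaller end marker first
    if markers[order[-1]] < markers[order[0]]:
        order = order[::-1]
    pos = np.concatenate([[0.0], np.cumsum(dist[order[:-1], order[1:]])])
    return [markers[i] for i in order], pos


def order_group(seg: SegregationMatrix, group: list[str], name: str | None = None) -> LinkageGroup:
    """Order one linkage group from a population's segregation data."""
    if len(group) < 1:
        raise ValidationError("empty group")
    sub = seg.subset(sorted(group))
    pairs = estimate_all_pairs(sub)
    ordered, pos = order_markers(list(sub.markers), pairs)
    return LinkageGroup(name or min(group), tuple(ordered), pos)


# ---------------------------------------------------------------------------
# singleton correction


def correct_singletons(
    seg: SegregationMatrix, linkage_group: LinkageGroup, window_cM: float = 5.0
) -> tuple[SegregationMatrix, int]:
    """Blank single-marker double crossovers within a tight map window.

    For each line, a non-missing call that disagrees with both immediate
    flanking calls — when the flanks agree with each other and each lies
    within ``window_cM`` of the focal marker — is set to missing (never
    flipped). All hits are detected on the original data, so a second pass
    is a no-op. Returns the cleaned matrix and the number of blanked calls.
    """
    idx = [seg.marker_index(m) for m in linkage_group.markers]
    calls = seg.calls[idx]  # ordered view (copy via fancy indexing)
    pos = linkage_group.positions
    n_corrected = 0
    mask = np.zeros_like(calls, dtype=bool)
    for i in range(1, len(idx) - 1):
        if pos[i] - pos[i - 1] > window_cM or pos[i + 1] - pos[i] > window_cM:
            continue
        left, mid, right = calls[i - 1], calls[i], calls[i + 1]
        hit = (
            (mid != MISSING)
            & (left != MISSING)
            & (right != MISSING)
            & (left == right)
            & (mid != left)
        )
        mask[i] |= hit
    n_corrected = int(mask.sum())
    new_calls = seg.calls.copy()
    ordered = new_calls[idx]
    ordered[mask] = MISSING
    new_calls[idx] = ordered
    return replace(seg, calls=new_calls), n_corrected


# ---------------------------------------------------------------------------
# full single-population pipeline


@dataclass(frozen=True)
class MapParams:
    """Thresholds of the single-map pipeline (defaults = published protocol)."""

    max_missing: float = 0.15
    distortion_p: float = 1e-4
    lod_group: float = 6.0
    lod_merge: float = 3.0
    max_r_merge: float = 0.3
    singleton_window_ril: float = 5.0
    singleton_window_dh: float = 10.0


@dataclass(frozen=True)
class ComponentMapResult:
    groups: list[LinkageGroup]
    filter_report: pd.DataFrame = field(repr=False)
    n_singletons_corrected: int = 0

    @property
    def n_markers(self) -> int:
        return sum(len(g.markers) for g in self.groups)

    @property
    def total_cM(self) -> float:
        return float(sum(g.length_cM for g in self.groups))

    @property
    def cm_per_marker(self) -> float:
        return self.total_cM / self.n_markers if self.n_markers else 0.0

    def summary(self) -> pd.DataFrame:
        rows = [
            (g.name, len(g.markers), round(g.length_cM, 2),
             round(g.length_cM / len(g.markers), 2) if len(g.markers) else 0.0)
            for g in self.groups
        ]
        return pd.DataFrame(rows, columns=["group", "n_markers", "length_cM", "cM_per_marker"])


def build_component_map(seg: SegregationMatrix, params: MapParams = MapParams()) -> ComponentMapResult:
    """Full single-population mapping pipeline.

    filter -> two-point estimates -> grouping (stringent LOD) -> ordering ->
    singleton correction -> re-estimate/re-order -> final relaxed merge
    (r <= 0.3, LOD >= 3) and re-ordering of merged groups.
    """
    window = (
        params.singleton_window_dh
        if seg.population_type == "DH"
        else params.singleton_window_ril
    )
    filtered, report = filter_markers(seg, params.max_missing, params.distortion_p)
    pairs = estimate_all_pairs(filtered)
    groups = group_markers(pairs, lod_min=params.lod_group, markers=list(filtered.markers))
    ordered = [order_group(filtered, g) for g in groups if len(g) >= 1]

    cleaned = filtered
    n_corr = 0
    for lg in ordered:
        if len(lg.markers) >= 3:
            cleaned, c = correct_singletons(cleaned, lg, window)
            n_corr += c

    pairs2 = estimate_all_pairs(cleaned)
    merged = group_markers(
        pairs2,
        lod_min=params.lod_merge,
        max_r=params.max_r_merge,
        markers=list(cleaned.markers),
    )
    final = [order_group(cleaned, g) for g in merged]
    final.sort(key=lambda g: g.name)
    return ComponentMapResult(final, report, n_corr)
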