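"""Linkage disequilibrium on the inbred panel and Sved decay modelling.

Pairwise r-squared and D' are computed between mapped loci on
pairwise-complete haploid calls; multi-allelic loci are biallelified
(each allele against the pool of the others) and a locus pair is summarized
by the maximum over allele-pair combinations. Decay of syntenic LD with
genetic distance c (Morgans) follows the drift expectation

    E[r2 - 1/n] = 1 / (alpha + k Ne c),        k = 4 for autosomes,

whose parameters (alpha, beta = k Ne) are fitted by nonlinear least
squares; 1/n adjusts for the finite chromosome sample (n accessions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import UndefinedEstimateError, ValidationError
from .consensus import ConsensusMap
from .panel import MISSING, PanelData

__all__ = [
    "LDPair",
    "SvedFit",
    "biallelic_columns",
    "pairwise_ld",
    "bin_by_distance",
    "fit_sved",
    "predict_r2",
    "distance_at",
    "background_threshold",
    "count_ld_blocks",
    "TABLE5_BINS",
]


@dataclass(frozen=True)
class LDPair:
    marker_a: str
    marker_b: str
    same_group: bool
    distance_cM: float  # NaN for non-syntenic pairs
    r2: float
    dprime: float
    n: int  # haplotypes (pairwise-complete accessions)


@dataclass(frozen=True)
class SvedFit:
    alpha: float
    beta: float
    k: float
    n: int  # chromosome sample size used in the 1/n adjustment
    rss: float
    n_pairs: int
    model_r2: float

    def __post_init__(self):
        if self.alpha <= 0 or self.beta < 0:
            raise ValidationError("need alpha > 0 and beta >= 0")

    @property
    def ne(self) -> float:
        return self.beta / self.k


# ---------------------------------------------------------------------------
# pairwise LD


def biallelic_columns(panel: PanelData, maf_min: float = 0.10) -> dict[str, list[int]]:
    """Alleles per locus whose allele-vs-rest split has MAF >= ``maf_min``."""
    out: dict[str, list[int]] = {}
    for j, locus in enumerate(panel.loci):
        calls = panel.calls[:, j]
        ok = calls[calls != MISSING]
        if ok.size == 0:
            continue
        vals, counts = np.unique(ok, return_counts=True)
        freqs = counts / ok.size
        alleles = [int(v) for v, f in zip(vals, freqs) if min(f, 1 - f) >= maf_min]
        if alleles:
            out[locus] = alleles
    return out


def _pair_ld(xa: np.ndarray, xb: np.ndarray) -> tuple[float, float, int]:
    """(r2, D', n) of two binary haploid vectors with missing = -1."""
    ok = (xa >= 0) & (xb >= 0)
    n = int(ok.sum())
    if n == 0:
        return np.nan, np.nan, 0
    a, b = xa[ok].astype(float), xb[ok].astype(float)
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return np.nan, np.nan, n
    pab = (a * b).mean()
    D = pab - pa * pb
    r2 = D * D / (pa * (1 - pa) * pb * (1 - pb))
    if D >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dprime = abs(D) / dmax if dmax > 0 else np.nan
    return float(r2), float(dprime), n


def pairwise_ld(
    panel: PanelData,
    consensus_map: ConsensusMap,
    maf_min: float = 0.10,
    include_nonsyntenic: bool = True,
    dprime_weighted: bool = False,
) -> list[LDPair]:
    """Locus-pair LD for all mapped loci passing the MAF filter.

    Multi-allelic loci contribute one binary split per qualifying allele;
    the locus-pair r2 (and by default D') is the maximum over allele-pair
    combinations. With ``dprime_weighted`` D' is instead the
    allele-frequency-weighted average, the multi-allelic D' convention.
    Monomorphic-after-filtering loci are excluded.
    """
    placed = {}
    for g in consensus_map.groups:
        for m, p in zip(g.markers, g.positions):
            placed[m] = (g.name, float(p))
    cols = biallelic_columns(panel, maf_min)
    loci = [l for l in panel.loci if l in cols and l in placed]
    binary: dict[str, list[tuple[np.ndarray, float]]] = {}
    for locus in loci:
        calls = panel.calls[:, panel.locus_index(locus)]
        entries = []
        for allele in cols[locus]:
            x = np.where(calls == MISSING, -1, (calls == allele).astype(np.int8))
            ok = x >= 0
            entries.append((x, float(x[ok].mean()) if ok.any() else 0.0))
        binary[locus] = entries
    out: list[LDPair] = []
    for i in range(len(loci)):
        gi, pi = placed[loci[i]]
        for j in range(i + 1, len(loci)):
            gj, pj = placed[loci[j]]
            same = gi == gj
            if not same and not include_nonsyntenic:
                continue
            best_r2, best_dp, best_n = -1.0, np.nan, 0
            wsum, wtot = 0.0, 0.0
            for xa, fa in binary[loci[i]]:
                for xb, fb in binary[loci[j]]:
                    r2, dp, n = _pair_ld(xa, xb)
                    if np.isnan(r2):
                        continue
                    if r2 > best_r2:
                        best_r2, best_dp, best_n = r2, dp, n
                    if not np.isnan(dp):
                        w = fa * fb
                        wsum += w * dp
                        wtot += w
            if best_r2 < 0:
                continue
            dprime = wsum / wtot if (dprime_weighted and wtot > 0) else best_dp
            out.append(
                LDPair(
                    loci[i],
                    loci[j],
                    same,
                    abs(pi - pj) if same else np.nan,
                    best_r2,
                    float(dprime),
                    best_n,
                )
            )
    return out


def ld_frame(pairs: list[LDPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker_a": [p.marker_a for p in pairs],
            "marker_b": [p.marker_b for p in pairs],
            "same_group": [p.same_group for p in pairs],
            "distance_cM": [p.distance_cM for p in pairs],
            "r2": [p.r2 for p in pairs],
            "dprime": [p.dprime for p in pairs],
            "n": [p.n for p in pairs],
        }
    )


# ---------------------------------------------------------------------------
# distance-binned decay table

# printed-class layout: the zero class is exact, the rest are half-open (lo, hi]
TABLE5_BINS: list[tuple[str, float, float]] = [
    ("0", 0.0, 0.0),
    ("0-0.5", 0.0, 0.5),
    ("0.5-1.0", 0.5, 1.0),
    ("1.0-5.0", 1.0, 5.0),
    ("5.1-10.0", 5.0, 10.0),
    ("10.1-20.0", 10.0, 20.0),
    ("20.1-30.0", 20.0, 30.0),
    ("30.1-40.0", 30.0, 40.0),
    ("40.1-50.0", 40.0, 50.0),
    (">50", 50.0, np.inf),
]


def bin_by_distance(pairs: list[LDPair]) -> pd.DataFrame:
    """Mean r2/D' of syntenic pairs by map-distance class.

    Completely linked pairs (distance exactly 0 cM) form their own class;
    remaining classes are half-open intervals matching the printed layout.
    Counts conserve the number of syntenic input pairs.
    """
    syntenic = [p for p in pairs if p.same_group and not np.isnan(p.distance_cM)]
    rows = []
    for label, lo, hi in TABLE5_BINS:
        if lo == hi:
            sel = [p for p in syntenic if p.distance_cM == 0.0]
        else:
            sel = [p for p in syntenic if lo < p.distance_cM <= hi]
        if not sel and not syntenic:
            continue
        rows.append(
            (
                label,
                len(sel),
                float(np.mean([p.r2 for p in sel])) if sel else np.nan,
                float(np.mean([p.dprime for p in sel])) if sel else np.nan,
            )
        )
    return pd.DataFrame(rows, columns=["class", "count", "mean_r2", "mean_dprime"])


# ---------------------------------------------------------------------------
# Sved decay model


def fit_sved(
    pairs: list[LDPair],
    n: int,
    k: float = 4.0,
    fit_alpha: bool = True,
    min_pairs: int = 20,
) -> SvedFit:
    """Fit E[r2 - 1/n] = 1/(alpha + beta c) to syntenic pairs (c in Morgans).

    Iterative least squares from the start (alpha=1, beta=40); with
    ``fit_alpha=False`` alpha is fixed at 1 (the no-mutation form) and only
    beta is estimated. Ne = beta / k.
    """
    syn = [p for p in pairs if p.same_group and not np.isnan(p.distance_cM)]
    if len(syn) < min_pairs:
        raise UndefinedEstimateError(f"need >= {min_pairs} syntenic pairs, got {len(syn)}")
    c = np.array([p.distance_cM for p in syn]) / 100.0
    y = np.array([p.r2 for p in syn]) - 1.0 / n

    if fit_alpha:
        def resid(theta):
            a, b = theta
            return y - 1.0 / (a + b * c)
        res = optimize.least_squares(
            resid, x0=[1.0, 40.0], bounds=([1e-9, 0.0], [np.inf, np.inf])
        )
        alpha, beta = res.x
    else:
        def resid(theta):
            return y - 1.0 / (1.0 + theta[0] * c)
        res = optimize.least_squares(resid, x0=[40.0], bounds=([0.0], [np.inf]))
        alpha, beta = 1.0, res.x[0]
    if not res.success:
        raise UndefinedEstimateError(f"Sved fit did not converge: {res.message}")
    rss = float(np.sum(res.fun**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    model_r2 = 1.0 - rss / tss if tss > 0 else np.nan
    return SvedFit(float(alpha), float(beta), k, n, rss, len(syn), model_r2)


def predict_r2(fit: SvedFit, c_morgans: float) -> float:
    """Expected r2 at genetic distance c (Morgans): 1/(alpha + beta c) + 1/n."""
    if c_morgans < 0:
        raise ValidationError("distance must be >= 0")
    return 1.0 / (fit.alpha + fit.beta * c_morgans) + 1.0 / fit.n


def distance_at(fit: SvedFit, target_r2: float) -> float:
    """Genetic distance (cM) where the fitted decay curve crosses ``target_r2``.

    Analytic inverse c = (1/(target - 1/n) - alpha)/beta, valid only between
    the background asymptote 1/n and the prediction at c = 0.
    """
    lo = 1.0 / fit.n
    hi = predict_r2(fit, 0.0)
    if not lo < target_r2 <= hi:
        raise ValidationError(
            f"target r2 {target_r2} outside attainable range ({lo:.4g}, {hi:.4g}]"
        )
    if fit.beta == 0:
        raise UndefinedEstimateError("beta = 0: the curve never declines")
    c = (1.0 / (target_r2 - lo) - fit.alpha) / fit.beta
    return 100.0 * c


# ---------------------------------------------------------------------------
# background LD and blocks


def background_threshold(
    pairs: list[LDPair], min_cM: float = 50.0, percentile: float = 95.0, min_pairs: int = 100
) -> float:
    """Empirical percentile of background r2.

    Background pairs are non-syntenic or at map distance >= ``min_cM``;
    the percentile uses linear interpolation.
    """
    bg = [
        p.r2
        for p in pairs
        if (not p.same_group) or (not np.isnan(p.distance_cM) and p.distance_cM >= min_cM)
    ]
    if len(bg) < min_pairs:
        raise UndefinedEstimateError(f"need >= {min_pairs} background pairs, got {len(bg)}")
    return float(np.percentile(bg, percentile))


def count_ld_blocks(
    consensus_map: ConsensusMap,
    pairs: list[LDPair],
    r2_block: float = 0.3,
    markers: set[str] | None = None,
) -> tuple[int, dict[str, int]]:
    """Count genome-wide unique linkage blocks along the map order.

    Scanning each group in order, adjacent markers join the same block when
    their r2 >= ``r2_block``; a missing adjacent estimate is a block
    boundary. ``markers`` restricts the scan (e.g. to panel-genotyped loci).
    Returns (n_blocks, marker -> block id).
    """
    lut = {}
    for p in pairs:
        lut[(p.marker_a, p.marker_b)] = p.r2
        lut[(p.marker_b, p.marker_a)] = p.r2
    known = {m for pair in lut for m in pair}
    assignment: dict[str, int] = {}
    block = 0
    for g in consensus_map.groups:
        scan = [
            m
            for m in g.markers
            if (markers is None or m in markers) and m in known
        ]
        prev = None
        for m in scan:
            if prev is None or lut.get((prev, m), -1.0) < r2_block:
                block += 1
            assignment[m] = block
            prev = m
    return block, assignment
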