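"""Subpopulation differentiation on the inbred panel.

One-level AMOVA with the pairwise-difference distance (number of
mismatching haploid calls between two accessions), overall and pairwise
FST with permutation significance, a per-locus differentiation scan across
all subpopulation pairs, classification of recurring differentiation
patterns, and polymorphism-information-content (PIC) profiles along the
map.

Variance components follow the standard one-level AMOVA expectations for
haploid data: sigma2_within = MSD(within); sigma2_among =
(MSD(among) - MSD(within)) / n', with n' the weighted average
subpopulation size. Negative components are floored at zero and
FST = sigma2_among / (sigma2_among + sigma2_within).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .consensus import ConsensusMap
from .panel import MISSING, PanelData

__all__ = [
    "AmovaResult",
    "FstScanRecord",
    "pairwise_distance_matrix",
    "amova",
    "pairwise_fst",
    "locus_fst_scan",
    "classify_pattern",
    "pic",
    "pic_scan",
    "ROLES",
]

#: canonical subpopulation roles of the five-lineage design
ROLES = ("dryland", "temperate", "italian_early", "mid", "late")


@dataclass(frozen=True)
class AmovaResult:
    ssd_among: float
    ssd_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    fst: float
    pct_among: float
    pct_within: float
    p_value: float
    n_permutations: int


@dataclass(frozen=True)
class FstScanRecord:
    locus: str
    pair_fst: dict = field(default_factory=dict)  # (labelA, labelB) -> FST
    pair_p: dict = field(default_factory=dict)
    significant: frozenset = frozenset()  # pairs with P <= alpha
    pattern: str = "none"


# ---------------------------------------------------------------------------
# distances and sums of squares


def pairwise_distance_matrix(panel: PanelData) -> np.ndarray:
    """Accession x accession count of mismatching calls (pairwise-complete)."""
    n, L = panel.n_accessions, panel.n_loci
    D = np.zeros((n, n))
    for j in range(L):
        col = panel.calls[:, j]
        ok = col != MISSING
        both = np.outer(ok, ok)
        diff = col[:, None] != col[None, :]
        D += np.where(both, diff, 0.0)
    return D


def _check_design(panel: PanelData, design: pd.Series) -> pd.Series:
    if set(design.index) != set(panel.accessions):
        raise ValidationError("design must label every accession exactly")
    design = design.loc[list(panel.accessions)]
    sizes = design.value_counts()
    if (sizes >= 2).sum() < 2:
        raise ValidationError("need >= 2 subpopulations with >= 2 members")
    return design


def _amova_components(
    D: np.ndarray, groups: np.ndarray
) -> tuple[float, float, float, float, int, int, float]:
    """(sigma2_among, sigma2_within, ssd_among, ssd_within, df_a, df_w, raw_fst).

    ``raw_fst`` is the unfloored statistic used for permutation comparison;
    the reported components floor negative estimates at zero.
    """
    N = len(groups)
    labels = np.unique(groups)
    P = len(labels)
    iu = np.triu_indices(N, 1)
    ssd_total = D[iu].sum() / N
    ssd_within = 0.0
    sizes = []
    for lab in labels:
        idx = np.flatnonzero(groups == lab)
        sizes.append(len(idx))
        if len(idx) > 1:
            sub = D[np.ix_(idx, idx)]
            ssd_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ssd_among = ssd_total - ssd_within
    sizes = np.array(sizes, dtype=float)
    df_a, df_w = P - 1, N - P
    ms_w = ssd_within / df_w if df_w > 0 else 0.0
    n_prime = (N - (sizes**2).sum() / N) / df_a
    ms_a = ssd_among / df_a
    sigma_w = max(ms_w, 0.0)
    sigma_a_raw = (ms_a - ms_w) / n_prime
    sigma_a = max(sigma_a_raw, 0.0)
    raw_tot = sigma_a_raw + ms_w
    raw_fst = sigma_a_raw / raw_tot if raw_tot != 0 else 0.0
    return sigma_a, sigma_w, ssd_among, ssd_within, df_a, df_w, raw_fst


def amova(
    panel: PanelData,
    design: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> AmovaResult:
    """One-level AMOVA of the panel by subpopulation.

    Significance is assessed by permuting accessions across subpopulations
    (``n_perm`` label permutations); P is the fraction of permuted FST
    values at least as large as the observed one (add-one corrected).
    """
    design = _check_design(panel, design)
    D = pairwise_distance_matrix(panel)
    groups = design.to_numpy()
    sa, sw, ssd_a, ssd_w, df_a, df_w, raw_obs = _amova_components(D, groups)
    tot = sa + sw
    fst = sa / tot if tot > 0 else np.nan
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        *_, raw_perm = _amova_components(D, perm)
        if raw_perm >= raw_obs - 1e-15:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1) if n_perm > 0 else np.nan
    return AmovaResult(
        ssd_a, ssd_w, df_a, df_w, sa, sw, float(fst),
        100.0 * sa / tot if tot > 0 else np.nan,
        100.0 * sw / tot if tot > 0 else np.nan,
        float(p), n_perm,
    )


def pairwise_fst(
    panel: PanelData, design: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subpopulation-pair FST and pairwise-difference statistics.

    Returns (fst, distances): ``fst`` is the symmetric subpop x subpop FST
    matrix; ``distances`` holds, per pair, the mean between-population
    pairwise difference pi_XY, the within means pi_X and pi_Y, and the
    net distance pi_XY - (pi_X + pi_Y)/2. Subpopulations with a single
    member are excluded (a warning-style note would be moot here: they
    simply cannot contribute a within-group variance).
    """
    design = _check_design(panel, design)
    D = pairwise_distance_matrix(panel)
    groups = design.to_numpy()
    labels = [lab for lab in np.unique(groups) if (groups == lab).sum() >= 2]
    fst = pd.DataFrame(np.nan, index=labels, columns=labels)
    rows = []
    for i, la in enumerate(labels):
        fst.loc[la, la] = 0.0
        for lb in labels[i + 1 :]:
            ia = np.flatnonzero(groups == la)
            ib = np.flatnonzero(groups == lb)
            idx = np.concatenate([ia, ib])
            sub_groups = np.array([la] * len(ia) + [lb] * len(ib))
            sa, sw, *_ = _amova_components(D[np.ix_(idx, idx)], sub_groups)
            tot = sa + sw
            f = sa / tot if tot > 0 else np.nan
            fst.loc[la, lb] = fst.loc[lb, la] = f
            pi_between = float(D[np.ix_(ia, ib)].mean())
            pi_a = float(D[np.ix_(ia, ia)][np.triu_indices(len(ia), 1)].mean())
            pi_b = float(D[np.ix_(ib, ib)][np.triu_indices(len(ib), 1)].mean())
            rows.append(
                (la, lb, f, pi_between, pi_a, pi_b, pi_between - (pi_a + pi_b) / 2.0)
            )
    distances = pd.DataFrame(
        rows, columns=["pop_a", "pop_b", "fst", "pi_between", "pi_a", "pi_b", "corrected"]
    )
    return fst, distances


# ---------------------------------------------------------------------------
# per-locus scan


def _locus_fst_from_counts(c1: np.ndarray, c2: np.ndarray) -> tuple[float, float]:
    """(floored FST, unfloored permutation statistic) from allele counts."""
    n1, n2 = c1.sum(), c2.sum()
    N = n1 + n2
    if n1 < 2 or n2 < 2:
        return np.nan, np.nan
    C = c1 + c2
    ssd_t = (N * N - (C.astype(float) ** 2).sum()) / (2.0 * N)
    ssd_w = (n1 * n1 - (c1.astype(float) ** 2).sum()) / (2.0 * n1) + (
        n2 * n2 - (c2.astype(float) ** 2).sum()
    ) / (2.0 * n2)
    ssd_a = ssd_t - ssd_w
    df_w = N - 2
    ms_w = ssd_w / df_w
    n_prime = N - (n1 * n1 + n2 * n2) / N
    sigma_w = max(ms_w, 0.0)
    sigma_a_raw = (ssd_a - ms_w) / n_prime
    sigma_a = max(sigma_a_raw, 0.0)
    tot = sigma_a + sigma_w
    raw_tot = sigma_a_raw + ms_w
    raw = sigma_a_raw / raw_tot if raw_tot != 0 else 0.0
    return (sigma_a / tot if tot > 0 else np.nan), raw


def _locus_pair_test(
    a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Observed FST and permutation P for one locus and one subpop pair."""
    a = a[a != MISSING]
    b = b[b != MISSING]
    if len(a) < 2 or len(b) < 2:
        return np.nan, np.nan
    pooled = np.concatenate([a, b])
    alleles = np.unique(pooled)
    if len(alleles) < 2:
        return np.nan, np.nan  # monomorphic: undefined, non-significant
    remap = {v: i for i, v in enumerate(alleles)}
    pooled_i = np.vectorize(remap.get)(pooled)
    k = len(alleles)
    one_hot = np.eye(k, dtype=np.int32)[pooled_i]  # (N, k)
    n1 = len(a)
    obs, obs_raw = _locus_fst_from_counts(one_hot[:n1].sum(0), one_hot[n1:].sum(0))
    if n_perm <= 0 or np.isnan(obs):
        return obs, np.nan
    # vectorized label permutations: random subsets of size n1
    order = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
    sel = order[:, :n1]
    c1 = one_hot[sel].sum(axis=1)  # (n_perm, k)
    ctot = one_hot.sum(0)[None, :]
    c2 = ctot - c1
    N = len(pooled)
    n2 = N - n1
    ssd_t = (N * N - (ctot.astype(float) ** 2).sum(axis=1)) / (2.0 * N)
    ssd_w = (n1 * n1 - (c1.astype(float) ** 2).sum(axis=1)) / (2.0 * n1) + (
        n2 * n2 - (c2.astype(float) ** 2).sum(axis=1)
    ) / (2.0 * n2)
    ssd_a = ssd_t - ssd_w
    ms_w = ssd_w / (N - 2)
    n_prime = N - (n1 * n1 + n2 * n2) / N
    sigma_a_raw = (ssd_a - ms_w) / n_prime
    raw_tot = sigma_a_raw + ms_w
    perm_raw = np.where(raw_tot != 0, sigma_a_raw / np.where(raw_tot == 0, 1.0, raw_tot), 0.0)
    p = (np.sum(perm_raw >= obs_raw - 1e-15) + 1) / (n_perm + 1)
    return obs, float(p)


def locus_fst_scan(
    panel: PanelData,
    design: pd.Series,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    roles: dict[str, str] | None = None,
) -> list[FstScanRecord]:
    """Per-locus FST for every subpopulation pair, with permutation P.

    Loci monomorphic in a pair are recorded as undefined and
    non-significant for that pair. When ``roles`` maps subpopulation labels
    to the five canonical roles, each record is also pattern-classified.
    """
    design = _check_design(panel, design)
    groups = design.to_numpy()
    labels = sorted(lab for lab in np.unique(groups) if (groups == lab).sum() >= 2)
    if len(labels) < 2:
        raise ValidationError("need >= 2 usable subpopulations")
    rng = np.random.default_rng(seed)
    members = {lab: np.flatnonzero(groups == lab) for lab in labels}
    records = []
    for j, locus in enumerate(panel.loci):
        col = panel.calls[:, j]
        pair_fst, pair_p, sig = {}, {}, set()
        for ia, la in enumerate(labels):
            for lb in labels[ia + 1 :]:
                f, p = _locus_pair_test(col[members[la]], col[members[lb]], n_perm, rng)
                pair_fst[(la, lb)] = f
                pair_p[(la, lb)] = p
                if not np.isnan(p) and p <= alpha:
                    sig.add((la, lb))
        rec = FstScanRecord(locus, pair_fst, pair_p, frozenset(sig))
        if roles is not None:
            rec = FstScanRecord(
                locus, pair_fst, pair_p, frozenset(sig), classify_pattern(frozenset(sig), roles)
            )
        records.append(rec)
    return records


def classify_pattern(significant: frozenset, roles: dict[str, str]) -> str:
    """Assign a differentiation pattern from the significant-pair set.

    With five subpopulations in the canonical roles (dryland, temperate,
    italian_early, mid, late):

    * pattern 1 — >= 7 of the 10 possible pairs significant;
    * pattern 2 — >= 3 of the 4 dryland-involving pairs significant;
    * pattern 3 — >= 3 of the 4 pairs {temperate, italian_early} x
      {mid, late} significant;
    * otherwise none. Precedence 1 > 2 > 3.
    """
    if set(roles.values()) != set(ROLES):
        raise ValidationError(f"roles must cover exactly {ROLES}")
    by_role = {r: lab for lab, r in roles.items()}
    sig = {frozenset(p) for p in significant}

    def pair(r1, r2):
        return frozenset((by_role[r1], by_role[r2]))

    if len(sig) >= 7:
        return "1"
    dry = [pair("dryland", r) for r in ROLES if r != "dryland"]
    if sum(p in sig for p in dry) >= 3:
        return "2"
    cross = [pair(a, b) for a in ("temperate", "italian_early") for b in ("mid", "late")]
    if sum(p in sig for p in cross) >= 3:
        return "3"
    return "none"


# ---------------------------------------------------------------------------
# polymorphism information content


def pic(frequencies: np.ndarray) -> tuple[float, float]:
    """(PIC, standardized PIC) from allele frequencies.

    PIC = 1 - sum(p_i^2); the standardized form divides by the
    equifrequency maximum 1 - 1/k for the k observed alleles (monomorphic
    loci score 0).
    """
    f = np.asarray(frequencies, dtype=float)
    f = f[f > 0]
    k = len(f)
    raw = 1.0 - float((f**2).sum())
    if k <= 1:
        return 0.0, 0.0
    return raw, raw / (1.0 - 1.0 / k)


def pic_scan(panel: PanelData, consensus_map: ConsensusMap, window: int = 3) -> pd.DataFrame:
    """Per-locus PIC along the map plus a sliding-window mean.

    The window mean averages the standardized PIC of ``window`` consecutive
    mapped markers (centered; truncated at group ends). Unmapped panel loci
    are skipped.
    """
    placed = {}
    for g in consensus_map.groups:
        for m, p in zip(g.markers, g.positions):
            placed[m] = (g.name, float(p))
    rows = []
    for j, locus in enumerate(panel.loci):
        if locus not in placed:
            continue
        col = panel.calls[:, j]
        ok = col[col != MISSING]
        if ok.size == 0:
            raw = std = 0.0
        else:
            _, counts = np.unique(ok, return_counts=True)
            raw, std = pic(counts / ok.size)
        grp, pos = placed[locus]
        rows.append((locus, grp, pos, raw, std))
    df = pd.DataFrame(rows, columns=["locus", "group", "cM", "pic", "pic_std"])
    df = df.sort_values(["group", "cM"], kind="stable").reset_index(drop=True)
    half = window // 2
    means = np.full(len(df), np.nan)
    for grp, sub in df.groupby("group"):
        vals = sub["pic_std"].to_numpy()
        for i in range(len(vals)):
            lo, hi = max(0, i - half), min(len(vals), i + half + 1)
            means[sub.index[i]] = vals[lo:hi].mean()
    df["window_mean"] = means
    return df
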