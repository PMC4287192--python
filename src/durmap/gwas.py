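"""Q+K mixed-linear-model association mapping for multi-environment traits.

The scan fits, per biallelified marker,

    y = mu + Q nu + covariates + marker b + u + e,   u ~ N(0, sigma_g^2 K)

with K an identity-by-state kinship matrix and Q population-structure
covariates. Variance components are estimated once by exact REML on the
null model through a spectral decomposition of K (so with K = I the scan
collapses exactly to ordinary least squares); each marker is then tested
by a generalized-least-squares F-test at those components. Genome-wide
significance divides the experiment-wise alpha by the number of
independent LD blocks, and significant markers are grouped into QTL
regions whose confidence interval pads the member span by 2.2 cM per side
(singletons span 4.4 cM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import UndefinedEstimateError, ValidationError
from .consensus import ConsensusMap
from .panel import MISSING, PanelData

__all__ = [
    "Thresholds",
    "QTLRegion",
    "biallelify",
    "ibs_kinship",
    "adjusted_means",
    "broad_sense_h2",
    "MLMModel",
    "fit_mlm_null",
    "mlm_scan",
    "scan_environments",
    "significance_thresholds",
    "declare_qtl_regions",
    "multi_qtl_r2",
]


# ---------------------------------------------------------------------------
# marker coding and kinship


def biallelify(
    panel: PanelData, maf_min: float = 0.10
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Binary marker matrix: one 0/1 column per qualifying allele.

    Multi-allelic (SSR-like) loci are tested allele-vs-pool-of-others, one
    column per allele with MAF >= ``maf_min`` (named ``locus.allele``);
    dominant (DArT-like) loci contribute their single presence/absence
    column when it meets the MAF bound. Missing calls become NaN. Returns
    (matrix, column -> source locus provenance map).
    """
    cols: dict[str, np.ndarray] = {}
    provenance: dict[str, str] = {}
    for j, locus in enumerate(panel.loci):
        calls = panel.calls[:, j]
        ok = calls != MISSING
        if not ok.any():
            continue
        vals, counts = np.unique(calls[ok], return_counts=True)
        freqs = counts / ok.sum()
        qualifying = [int(v) for v, f in zip(vals, freqs) if min(f, 1 - f) >= maf_min]
        if not qualifying:
            continue
        if panel.locus_types[j] == "DArT":
            allele = qualifying[-1]  # presence state
            x = np.where(ok, (calls == allele).astype(float), np.nan)
            name = locus
            cols[name] = x
            provenance[name] = locus
        else:
            for allele in qualifying:
                x = np.where(ok, (calls == allele).astype(float), np.nan)
                name = f"{locus}.{allele}"
                cols[name] = x
                provenance[name] = locus
    if not cols:
        raise UndefinedEstimateError("no marker columns pass the MAF filter")
    mat = pd.DataFrame(cols, index=list(panel.accessions))
    return mat, provenance


def ibs_kinship(binary_panel: pd.DataFrame | PanelData) -> pd.DataFrame:
    """Identity-by-state kinship: fraction of matching calls per pair.

    Accepts the biallelified matrix or the raw panel; matching is counted
    over pairwise-complete loci. Diagonal is 1; a pair sharing zero loci is
    an error.
    """
    if isinstance(binary_panel, PanelData):
        X = np.where(binary_panel.calls == MISSING, np.nan, binary_panel.calls).astype(float)
        index = list(binary_panel.accessions)
    else:
        X = binary_panel.to_numpy(dtype=float)
        index = list(binary_panel.index)
    n = X.shape[0]
    if n < 2:
        raise ValidationError("need >= 2 accessions")
    K = np.empty((n, n))
    valid = ~np.isnan(X)
    for i in range(n):
        both = valid[i] & valid
        same = (X[i] == X) & both
        shared = both.sum(axis=1)
        if (shared == 0).any():
            j = int(np.flatnonzero(shared == 0)[0])
            raise UndefinedEstimateError(
                f"accessions {index[i]} and {index[j]} share no genotyped loci"
            )
        K[i] = same.sum(axis=1) / shared
    np.fill_diagonal(K, 1.0)
    return pd.DataFrame(K, index=index, columns=index)


# ---------------------------------------------------------------------------
# phenotypes


def adjusted_means(
    phenotypes: pd.DataFrame, macro_areas: dict[str, str] | None = None
) -> pd.DataFrame:
    """Accession x macro-area means of environment-centered values.

    Each environment's mean (over the accessions observed there) is
    subtracted before averaging within macro-area, removing additive
    environment offsets. ``macro_areas`` maps environment -> area and
    defaults to the table's ``macro_area`` column. An area with no data is
    an error; an accession absent from an area yields NaN.
    """
    df = phenotypes.copy()
    if macro_areas is not None:
        df["macro_area"] = df["environment"].map(macro_areas)
    if "macro_area" not in df or df["macro_area"].isna().any():
        raise ValidationError("every environment needs a macro-area")
    df["centered"] = df["value"] - df.groupby("environment")["value"].transform("mean")
    wide = df.pivot_table(index="accession", columns="macro_area", values="centered", aggfunc="mean")
    for area in df["macro_area"].unique():
        if area not in wide.columns or wide[area].isna().all():
            raise ValidationError(f"macro-area {area!r} has no data")
    return wide


def broad_sense_h2(phenotypes: pd.DataFrame) -> float:
    """Broad-sense heritability on environment means.

    h2 = sigma2_G / (sigma2_G + sigma2_e / n) for n environments, with
    variance components from a one-way random-effects ANOVA of
    environment-centered values (accession as the random factor).
    Accessions missing any environment are dropped to keep the design
    balanced.
    """
    envs = phenotypes["environment"].unique()
    n_env = len(envs)
    if n_env < 2:
        raise UndefinedEstimateError("heritability needs >= 2 environments")
    df = phenotypes.copy()
    df["centered"] = df["value"] - df.groupby("environment")["value"].transform("mean")
    wide = df.pivot_table(index="accession", columns="environment", values="centered").dropna()
    Y = wide.to_numpy()
    a = Y.shape[0]
    if a < 2:
        raise UndefinedEstimateError("heritability needs >= 2 complete accessions")
    grand = Y.mean()
    acc_means = Y.mean(axis=1)
    ms_g = n_env * ((acc_means - grand) ** 2).sum() / (a - 1)
    ms_e = ((Y - acc_means[:, None]) ** 2).sum() / (a * (n_env - 1))
    sigma_e = ms_e
    sigma_g = max((ms_g - ms_e) / n_env, 0.0)
    denom = sigma_g + sigma_e / n_env
    return float(sigma_g / denom) if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# mixed linear model


@dataclass(frozen=True)
class MLMModel:
    """Null-model state reused across markers (P3D)."""

    accessions: tuple[str, ...]
    y_rot: np.ndarray  # U'y
    x0_rot: np.ndarray  # U'X0
    u: np.ndarray  # eigenvectors of K
    weights: np.ndarray  # 1/(eigenvalue + delta)
    delta: float
    rss0: float
    tss: float  # weighted total SS around the GLS grand mean


def _reml_delta(y_rot: np.ndarray, x_rot: np.ndarray, eigvals: np.ndarray) -> float:
    """Maximize the restricted likelihood over delta = sigma_e^2/sigma_g^2."""
    n, p = x_rot.shape

    def neg_restricted_ll(log_delta: float) -> float:
        delta = 10.0**log_delta
        w = 1.0 / (eigvals + delta)
        sw = np.sqrt(w)
        xw = x_rot * sw[:, None]
        yw = y_rot * sw
        beta, *_ = np.linalg.lstsq(xw, yw, rcond=None)
        rss = float(np.sum((yw - xw @ beta) ** 2))
        xtx = xw.T @ xw
        sign, logdet_x = np.linalg.slogdet(xtx)
        if sign <= 0:
            return np.inf
        return (
            (n - p) * np.log(rss / (n - p))
            + np.sum(np.log(eigvals + delta))
            + logdet_x
        )

    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(-6.0, 6.0), method="bounded")
    return float(10.0**res.x)


def fit_mlm_null(
    y: pd.Series,
    Q: pd.DataFrame | None = None,
    K: pd.DataFrame | None = None,
    covariates: pd.DataFrame | None = None,
) -> MLMModel:
    """Fit the marker-free Q+K model and freeze its variance components.

    One Q column is dropped against the intercept for identifiability.
    With K = None (identity) the transformed model is exactly OLS.
    """
    y = y.dropna()
    acc = list(y.index)
    n = len(acc)
    if n < 3:
        raise ValidationError("need >= 3 phenotyped accessions")
    parts = [np.ones((n, 1))]
    if Q is not None and Q.shape[1] > 0:
        q = Q.loc[acc].to_numpy(dtype=float)
        parts.append(q[:, :-1])  # drop one column against the intercept
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.loc[acc].to_numpy(dtype=float)
        cov = np.where(np.isnan(cov), np.nanmean(cov, axis=0), cov)
        parts.append(cov)
    X0 = np.concatenate(parts, axis=1)
    if K is None:
        eigvals = np.ones(n)
        U = np.eye(n)
    else:
        Km = K.loc[acc, acc].to_numpy(dtype=float)
        Km = 0.5 * (Km + Km.T)
        eigvals, U = np.linalg.eigh(Km)
        eigvals = np.maximum(eigvals, 0.0)
    y_rot = U.T @ y.to_numpy(dtype=float)
    x0_rot = U.T @ X0
    if np.allclose(eigvals, eigvals[0]):
        delta = 1.0  # V proportional to I: the split is irrelevant
    else:
        delta = _reml_delta(y_rot, x0_rot, eigvals)
    w = 1.0 / (eigvals + delta)
    sw = np.sqrt(w)
    xw = x0_rot * sw[:, None]
    yw = y_rot * sw
    beta, *_ = np.linalg.lstsq(xw, yw, rcond=None)
    rss0 = float(np.sum((yw - xw @ beta) ** 2))
    ones_w = sw  # rotated intercept column times sqrt weights
    mu = float(ones_w @ yw / (ones_w @ ones_w))
    tss = float(np.sum((yw - mu * ones_w) ** 2))
    return MLMModel(tuple(acc), y_rot, x0_rot, U, w, delta, rss0, tss)


def mlm_scan(
    y: pd.Series,
    markers: pd.DataFrame,
    Q: pd.DataFrame | None = None,
    K: pd.DataFrame | None = None,
    covariate_markers: list[str] | None = None,
) -> pd.DataFrame:
    """Per-marker GLS F-tests under the frozen Q+K variance components.

    Marker columns listed in ``covariate_markers`` enter the null design
    (the two-pass conditioning on major-locus markers); missing marker
    calls are mean-imputed. A marker collinear with the null design yields
    F = 0, P = 1 and a diagnostic flag. Returns columns: marker, effect,
    f_stat, p, r2, df, note.
    """
    covariate_markers = list(covariate_markers or [])
    covariates = markers[covariate_markers] if covariate_markers else None
    model = fit_mlm_null(y, Q, K, covariates)
    acc = list(model.accessions)
    sw = np.sqrt(model.weights)
    xw0 = model.x0_rot * sw[:, None]
    yw = model.y_rot * sw
    n, p0 = xw0.shape
    rows = []
    M = markers.loc[acc]
    for name in markers.columns:
        x = M[name].to_numpy(dtype=float)
        if np.isnan(x).all():
            rows.append((name, np.nan, np.nan, np.nan, np.nan, np.nan, "all-missing"))
            continue
        x = np.where(np.isnan(x), np.nanmean(x), x)
        if np.ptp(x) == 0:
            rows.append((name, np.nan, np.nan, np.nan, np.nan, np.nan, "monomorphic"))
            continue
        xr = (model.u.T @ x) * sw
        X = np.concatenate([xw0, xr[:, None]], axis=1)
        beta, _, rank, _ = np.linalg.lstsq(X, yw, rcond=None)
        rss1 = float(np.sum((yw - X @ beta) ** 2))
        note = ""
        if rank < p0 + 1:
            note = "collinear-with-null"
        df2 = n - (p0 + 1)
        if df2 <= 0:
            raise ValidationError("not enough residual degrees of freedom")
        num = max(model.rss0 - rss1, 0.0)
        f = (num / 1.0) / (rss1 / df2) if rss1 > 0 else np.inf
        if note == "collinear-with-null":
            f = 0.0
        pval = float(stats.f.sf(f, 1, df2)) if np.isfinite(f) else 0.0
        r2 = num / model.tss if model.tss > 0 else np.nan
        rows.append((name, float(beta[-1]), float(f), pval, float(r2), df2, note))
    return pd.DataFrame(rows, columns=["marker", "effect", "f_stat", "p", "r2", "df", "note"])


def scan_environments(
    phenotypes: pd.DataFrame,
    markers: pd.DataFrame,
    Q: pd.DataFrame | None = None,
    K: pd.DataFrame | None = None,
    covariate_markers: list[str] | None = None,
    scope_column: str = "macro_area",
) -> pd.DataFrame:
    """Run the MLM scan per scope (macro-area adjusted means or environment).

    For ``scope_column="macro_area"`` the response is the adjusted mean per
    area; for ``"environment"`` it is the centered value per trial. Returns
    the concatenated per-scope association tables with a ``scope`` column.
    """
    out = []
    if scope_column == "macro_area":
        wide = adjusted_means(phenotypes)
        scopes = list(wide.columns)
        get = lambda s: wide[s].dropna()
    elif scope_column == "environment":
        df = phenotypes.copy()
        df["centered"] = df["value"] - df.groupby("environment")["value"].transform("mean")
        scopes = list(df["environment"].unique())
        get = lambda s: df[df["environment"] == s].set_index("accession")["centered"]
    else:
        raise ValidationError("scope_column must be 'macro_area' or 'environment'")
    for scope in scopes:
        res = mlm_scan(get(scope), markers, Q, K, covariate_markers)
        res.insert(0, "scope", scope)
        out.append(res)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# thresholds and QTL regions


@dataclass(frozen=True)
class Thresholds:
    experiment_wise: float  # Bonferroni over LD blocks
    marker_wise: float


def significance_thresholds(
    ld_block_count: int, alpha_exp: float = 0.05, alpha_marker: float = 0.01
) -> Thresholds:
    """Experiment-wise threshold = alpha_exp / number of independent LD blocks."""
    if ld_block_count < 1:
        raise ValidationError("block count must be >= 1")
    return Thresholds(alpha_exp / ld_block_count, alpha_marker)


@dataclass(frozen=True)
class QTLRegion:
    name: str
    group: str
    representative: str  # peak-P marker column
    members: tuple[str, ...]  # member marker columns
    interval_cM: tuple[float, float]  # significance interval (member span)
    ci_cM: tuple[float, float]  # interval padded by ci_pad per side
    peak_p: float
    area_p: dict
    area_r2: dict
    n_significant_envs: int = 0

    @property
    def ci_width(self) -> float:
        return self.ci_cM[1] - self.ci_cM[0]


def declare_qtl_regions(
    results: pd.DataFrame,
    consensus_map: ConsensusMap,
    ld_pairs,
    provenance: dict[str, str] | None = None,
    alpha_marker: float = 0.01,
    block_r2: float = 0.3,
    ci_pad: float = 2.2,
    env_results: pd.DataFrame | None = None,
    env_alpha: float = 0.05,
) -> list[QTLRegion]:
    """Group significant markers into QTL regions with LD-padded intervals.

    A marker qualifies with P <= ``alpha_marker`` in at least one macro-area
    scope of ``results``. Qualifying markers on the same linkage group merge
    into one region when consecutive (in map order) and mutually in LD at
    r2 >= ``block_r2``; the region's significance interval is its members'
    cM span and the confidence interval pads it by ``ci_pad`` per side, so a
    singleton's CI is 2 * ci_pad wide. ``env_results`` (per-environment
    scan) feeds the count of single environments with P <= ``env_alpha``
    for the representative marker.
    """
    provenance = provenance or {}
    lut = {}
    for p in ld_pairs:
        lut[(p.marker_a, p.marker_b)] = p.r2
        lut[(p.marker_b, p.marker_a)] = p.r2
    sig = results[results["p"] <= alpha_marker]
    if sig.empty:
        return []
    best = sig.loc[sig.groupby("marker")["p"].idxmin()]

    def locate(col: str):
        locus = provenance.get(col, col)
        try:
            g = consensus_map.group_of(locus)
        except Exception:
            return None
        return g.name, g.position_of(locus), locus

    entries = []
    for row in best.itertuples(index=False):
        loc = locate(row.marker)
        if loc is None:
            continue
        entries.append((loc[0], loc[1], row.marker, loc[2], row.p))
    entries.sort(key=lambda e: (e[0], e[1], e[2]))

    regions: list[list[tuple]] = []
    for e in entries:
        if regions and regions[-1][-1][0] == e[0]:
            prev = regions[-1][-1]
            r2 = lut.get((prev[3], e[3]), -1.0)
            if r2 >= block_r2:
                regions[-1].append(e)
                continue
        regions.append([e])

    out = []
    res_by_marker = {
        m: dict(zip(sub["scope"], zip(sub["p"], sub["r2"])))
        for m, sub in results.groupby("marker")
    }
    for i, members in enumerate(regions, start=1):
        group = members[0][0]
        cols = tuple(m[2] for m in members)
        positions = [m[1] for m in members]
        lo, hi = min(positions), max(positions)
        peak = min(members, key=lambda m: m[4])
        scope_stats = res_by_marker.get(peak[2], {})
        area_p = {s: ps[0] for s, ps in scope_stats.items()}
        area_r2 = {s: ps[1] for s, ps in scope_stats.items()}
        n_env = 0
        if env_results is not None:
            sub = env_results[env_results["marker"] == peak[2]]
            n_env = int((sub["p"] <= env_alpha).sum())
        out.append(
            QTLRegion(
                f"QTL{i:02d}", group, peak[2], cols,
                (lo, hi), (lo - ci_pad, hi + ci_pad),
                float(peak[4]), area_p, area_r2, n_env,
            )
        )
    return out


def multi_qtl_r2(y: pd.Series, representative_markers: pd.DataFrame) -> float:
    """Joint OLS R-squared of all QTL-representative markers.

    Collinear columns are pruned (rank-revealing QR via lstsq) with no
    effect on the fitted subspace; missing marker calls are mean-imputed.
    """
    if representative_markers.shape[1] < 1:
        raise ValidationError("need >= 1 marker")
    y = y.dropna()
    X = representative_markers.loc[y.index].to_numpy(dtype=float)
    col_means = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_means, X)
    X = np.concatenate([np.ones((len(y), 1)), X], axis=1)
    yv = y.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    rss = float(np.sum((yv - X @ beta) ** 2))
    tss = float(np.sum((yv - yv.mean()) ** 2))
    if tss == 0:
        return 0.0
    return 1.0 - rss / tss
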