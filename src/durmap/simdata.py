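"""Synthetic inputs with the statistical structure the pipeline assumes.

Everything downstream of this module (linkage maps, consensus merging, LD,
differentiation, association) is exercised on data generated here, because
the study material it emulates — biparental RIL/DH segregation matrices and
an elite inbred diversity panel — is not publicly deposited.

The meiosis model is Haldane (no crossover interference): the per-interval
crossover probability between adjacent markers d cM apart is
r = (1 - exp(-2d/100))/2. DH lines carry single gametes; selfed F-infinity
RIL genomes are Markov mosaics with per-interval switch probability
R = 2r/(1+2r) (Haldane-Waddington expansion). The diversity panel is built
by random union of gametes within subpopulations at small effective size,
which generates linkage disequilibrium that decays with map distance, plus
optional admixture between subpopulation gene pools.

All generators take explicit seeds; identical seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .linkage import MISSING, SegregationMatrix, haldane_r, ril_expand
from .panel import PanelData

__all__ = [
    "TrueGroup",
    "TrueMap",
    "SimConfig",
    "PanelConfig",
    "MajorLocus",
    "PhenoConfig",
    "simulate_true_map",
    "simulate_gametes",
    "simulate_population",
    "simulate_anchor_design",
    "simulate_panel",
    "simulate_heading_date",
]


# ---------------------------------------------------------------------------
# ground-truth map


@dataclass(frozen=True)
class TrueGroup:
    name: str
    markers: tuple[str, ...]
    positions: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "markers", tuple(self.markers))
        if len(pos) != len(self.markers):
            raise ValidationError("markers/positions length mismatch")
        if len(pos) and abs(pos[0]) > 1e-12:
            raise ValidationError("first position must be 0")
        if np.any(np.diff(pos) <= 0):
            raise ValidationError("positions must be strictly increasing")


@dataclass(frozen=True)
class TrueMap:
    """Simulated ground truth: ordered markers with cM positions per group."""

    groups: tuple[TrueGroup, ...]

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        names = [m for g in self.groups for m in g.markers]
        if len(set(names)) != len(names):
            raise ValidationError("marker names must be unique map-wide")

    @property
    def markers(self) -> list[str]:
        return [m for g in self.groups for m in g.markers]

    @property
    def n_markers(self) -> int:
        return sum(len(g.markers) for g in self.groups)

    def group_of(self, marker: str) -> TrueGroup:
        for g in self.groups:
            if marker in g.markers:
                return g
        raise ValidationError(f"marker {marker!r} not in map")

    def position_of(self, marker: str) -> float:
        g = self.group_of(marker)
        return float(g.positions[g.markers.index(marker)])


def simulate_true_map(
    n_groups: int,
    group_length_cM: float,
    n_markers_per_group: int,
    seed: int,
    force_endpoints: bool = True,
) -> TrueMap:
    """Draw a ground-truth map: uniform marker positions, sorted, first at 0.

    With ``force_endpoints`` (default) the first and last markers of each
    group sit exactly at 0 and at ``group_length_cM``.
    """
    if n_groups < 1 or n_markers_per_group < 2:
        raise ValidationError("need >= 1 group and >= 2 markers per group")
    if group_length_cM <= 0:
        raise ValidationError("group length must be positive")
    rng = np.random.default_rng(seed)
    groups = []
    for gi in range(n_groups):
        pos = np.sort(rng.uniform(0.0, group_length_cM, size=n_markers_per_group))
        if force_endpoints:
            pos[0], pos[-1] = 0.0, group_length_cM
        else:
            pos -= pos[0]
        # enforce strict increase (coincident draws nudged apart)
        for i in range(1, len(pos)):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1e-6
        markers = tuple(f"G{gi + 1}M{j + 1:03d}" for j in range(n_markers_per_group))
        groups.append(TrueGroup(f"LG{gi + 1}", markers, pos))
    return TrueMap(tuple(groups))


# ---------------------------------------------------------------------------
# meiosis and biparental populations


def _mosaic(n: int, switch_probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """n haploid genomes over m = len(switch_probs)+1 markers: 0/1 origins.

    The first marker's origin is Bernoulli(1/2); each subsequent interval
    switches origin independently with its own probability (Markov chain,
    i.e. no interference).
    """
    m = len(switch_probs) + 1
    start = rng.integers(0, 2, size=(n, 1))
    switches = rng.random((n, m - 1)) < switch_probs
    return (start + np.concatenate([np.zeros((n, 1), dtype=int), np.cumsum(switches, axis=1)], axis=1)) % 2


def simulate_gametes(true_map: TrueMap, n: int, seed: int) -> np.ndarray:
    """Parental-origin haplotypes of ``n`` independent meioses.

    Returns an (n, n_markers) 0/1 array ordered as ``true_map.markers``.
    Adjacent markers recombine with the inverse-Haldane probability of their
    cM distance; groups are independent (r = 1/2 between groups).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    blocks = []
    for g in true_map.groups:
        r = haldane_r(np.diff(g.positions))
        blocks.append(_mosaic(n, r, rng))
    return np.concatenate(blocks, axis=1)


@dataclass(frozen=True)
class SimConfig:
    """Biparental-population generator settings (seed is mandatory)."""

    pop_type: str = "RIL"
    n_lines: int = 200
    missing_rate: float = 0.05
    error_rate: float = 0.005
    distortion: dict = field(default_factory=dict)  # marker -> expected allele-A freq
    seed: int = 0

    def __post_init__(self):
        if self.pop_type not in ("RIL", "DH"):
            raise ValidationError(f"unsupported population type {self.pop_type!r}")
        if not (0 <= self.missing_rate < 1 and 0 <= self.error_rate < 1):
            raise ValidationError("rates must lie in [0, 1)")
        if self.n_lines < 1:
            raise ValidationError("n_lines must be >= 1")
        for m, p in self.distortion.items():
            if not 0 < p < 1:
                raise ValidationError(f"distortion ratio for {m!r} must be in (0, 1)")


def simulate_population(true_map: TrueMap, config: SimConfig) -> SegregationMatrix:
    """Simulate one RIL or DH population on the true map.

    DH lines are single gametes (observed fraction = meiotic r); RIL genomes
    are mosaics whose adjacent-marker switch probability is the
    Haldane-Waddington expansion R = 2r/(1+2r). Segregation distortion,
    genotyping error and missing data are then layered on.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_lines
    blocks = []
    for g in true_map.groups:
        r = haldane_r(np.diff(g.positions))
        switch = ril_expand(r) if config.pop_type == "RIL" else r
        blocks.append(_mosaic(n, switch, rng))
    calls = np.concatenate(blocks, axis=1).T.astype(np.int8)  # markers x lines

    markers = true_map.markers
    if config.distortion:
        for m, p in config.distortion.items():
            i = markers.index(m)
            row = calls[i]
            if p >= 0.5:  # bias toward allele A (0)
                flip = (row == 1) & (rng.random(n) < (2 * p - 1))
                row[flip] = 0
            else:
                flip = (row == 0) & (rng.random(n) < (1 - 2 * p))
                row[flip] = 1
    if config.error_rate > 0:
        err = rng.random(calls.shape) < config.error_rate
        calls[err] = 1 - calls[err]
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = MISSING

    lines = tuple(f"L{i + 1:04d}" for i in range(n))
    return SegregationMatrix(tuple(markers), lines, calls, config.pop_type)


def simulate_anchor_design(
    true_map: TrueMap, n_pops: int, anchor_fraction: float, seed: int
) -> dict[str, list[str]]:
    """Split the map's markers into per-population genotyping panels.

    A per-group anchor subset (fraction ``anchor_fraction`` of markers, at
    least 2) is shared by all populations; the remaining unique markers are
    partitioned randomly, one population each. Every marker ends up in at
    least one population and every anchor in at least two.
    """
    if not 0 < anchor_fraction <= 1:
        raise ValidationError("anchor_fraction must lie in (0, 1]")
    if n_pops < 2:
        raise ValidationError("need >= 2 populations")
    rng = np.random.default_rng(seed)
    pops = {f"pop{i + 1}": [] for i in range(n_pops)}
    for g in true_map.groups:
        m = len(g.markers)
        n_anchor = int(round(anchor_fraction * m))
        if n_anchor < 2:
            raise ValidationError(
                f"anchor set for group {g.name} would have {n_anchor} < 2 markers"
            )
        anchor_idx = np.sort(rng.choice(m, size=n_anchor, replace=False))
        anchors = [g.markers[i] for i in anchor_idx]
        unique = [mk for mk in g.markers if mk not in set(anchors)]
        for p in pops.values():
            p.extend(anchors)
        for mk in unique:
            pops[f"pop{rng.integers(0, n_pops) + 1}"].append(mk)
    order = {mk: i for i, mk in enumerate(true_map.markers)}
    return {name: sorted(mks, key=order.__getitem__) for name, mks in pops.items()}


# ---------------------------------------------------------------------------
# diversity panel


@dataclass(frozen=True)
class PanelConfig:
    """Diversity-panel generator settings.

    Defaults emulate the published panel: five breeding-lineage
    subpopulations of 11/55/26/56/35 inbred accessions (183 total), drift at
    effective size 20 per subpopulation with 10% admixture — an island-model
    regime whose equilibrium differentiation is FST ~ 1/(1 + 2 Ne m) ~ 0.2.
    ``ne=None`` means an effectively infinite gene pool (no drift-induced
    LD or divergence).
    """

    subpop_sizes: tuple[int, ...] = (11, 55, 26, 56, 35)
    ne: int | None = 20
    generations: int = 8
    admixture: float = 0.1
    ssr_fraction: float = 0.35
    max_ssr_alleles: int = 4
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if len(self.subpop_sizes) < 1 or any(s < 1 for s in self.subpop_sizes):
            raise ValidationError("subpop sizes must be positive")
        if self.ne is not None and self.ne < 2:
            raise ValidationError("Ne must be >= 2 (or None for infinite)")
        if not 0 <= self.admixture < 1:
            raise ValidationError("admixture must lie in [0, 1)")
        if self.generations < 0:
            raise ValidationError("generations must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must lie in [0, 1)")

    @property
    def n_subpops(self) -> int:
        return len(self.subpop_sizes)


def _founder_frequencies(true_map: TrueMap, config: PanelConfig, rng) -> tuple[list[np.ndarray], list[str]]:
    """Per-locus global allele frequencies and locus types."""
    freqs, types = [], []
    for _ in true_map.markers:
        if rng.random() < config.ssr_fraction:
            k = int(rng.integers(2, config.max_ssr_alleles + 1))
            freqs.append(rng.dirichlet(np.ones(k)))
            types.append("SSR")
        else:
            p = rng.uniform(0.15, 0.85)
            freqs.append(np.array([p, 1 - p]))
            types.append("DArT")
    return freqs, types


def _draw_founders(n: int, freqs: list[np.ndarray], rng) -> np.ndarray:
    calls = np.empty((n, len(freqs)), dtype=np.int16)
    for j, f in enumerate(freqs):
        calls[:, j] = rng.choice(len(f), size=n, p=f)
    return calls


def _recombine(parent_a: np.ndarray, parent_b: np.ndarray, origins: np.ndarray) -> np.ndarray:
    return np.where(origins == 0, parent_a, parent_b)


def simulate_panel(true_map: TrueMap, config: PanelConfig) -> PanelData:
    """Simulate an inbred diversity panel on the true map.

    Founders are drawn per subpopulation from shared global allele
    frequencies (linkage equilibrium); each drift generation replaces the
    subpopulation with Ne offspring obtained by random union of gametes
    (each offspring is one recombinant gamete of two parents, i.e. fully
    inbred haploid coding). With probability ``admixture`` a parent is drawn
    from the whole metapopulation instead of the home subpopulation.
    Realized ancestry fractions are tracked through the pedigree and
    returned as the Q matrix.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    freqs, types = _founder_frequencies(true_map, config, rng)
    n_sub = config.n_subpops

    # per-interval meiotic switch probabilities across the whole genome
    switch = []
    for gi, g in enumerate(true_map.groups):
        if gi > 0:
            switch.append(np.array([0.5]))  # free recombination between groups
        switch.append(haldane_r(np.diff(g.positions)))
    switch = np.concatenate(switch) if switch else np.empty(0)

    ne = config.ne
    pool_n = ne if ne is not None else max(200, 2 * max(config.subpop_sizes))
    genomes = [_draw_founders(pool_n, freqs, rng) for _ in range(n_sub)]
    ancestry = [np.eye(n_sub)[np.full(pool_n, s)] for s in range(n_sub)]

    def offspring(home: int, count: int) -> tuple[np.ndarray, np.ndarray]:
        geno = np.empty((count, len(true_map.markers)), dtype=np.int16)
        anc = np.empty((count, n_sub))
        for i in range(count):
            pops_of_parents = []
            parents = []
            for _ in range(2):
                src = home
                if config.admixture > 0 and rng.random() < config.admixture:
                    src = int(rng.integers(0, n_sub))
                idx = int(rng.integers(0, len(genomes[src])))
                parents.append((src, idx))
                pops_of_parents.append(src)
            (sa, ia), (sb, ib) = parents
            origins = _mosaic(1, switch, rng)[0]
            geno[i] = _recombine(genomes[sa][ia], genomes[sb][ib], origins)
            anc[i] = 0.5 * (ancestry[sa][ia] + ancestry[sb][ib])
        return geno, anc

    if ne is not None:
        for _ in range(config.generations):
            new_g, new_a = [], []
            for s in range(n_sub):
                g, a = offspring(s, ne)
                new_g.append(g)
                new_a.append(a)
            genomes, ancestry = new_g, new_a

    # final accession draw (one more random-union round per subpopulation,
    # so panels larger than Ne are possible)
    acc_calls, acc_anc, labels = [], [], []
    for s, size in enumerate(config.subpop_sizes):
        if ne is None or config.generations == 0:
            g = _draw_founders(size, freqs, rng)
            a = np.eye(n_sub)[np.full(size, s)]
        else:
            g, a = offspring(s, size)
        acc_calls.append(g)
        acc_anc.append(a)
        labels.extend([f"S{s + 1}"] * size)
    calls = np.concatenate(acc_calls)
    anc = np.concatenate(acc_anc)

    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = -1

    accessions = tuple(f"acc{i + 1:03d}" for i in range(calls.shape[0]))
    subpops = pd.Series(labels, index=list(accessions), name="subpop")
    q = pd.DataFrame(anc, index=list(accessions), columns=[f"S{s + 1}" for s in range(n_sub)])
    return PanelData(accessions, tuple(true_map.markers), calls, tuple(types), subpops, q)


# ---------------------------------------------------------------------------
# multi-environment phenotype


@dataclass(frozen=True)
class MajorLocus:
    """A large-effect locus whose effect scales with environment latitude.

    ``pole="north"`` makes the effect grow with latitude from the southern
    edge of the trial network; ``pole="south"`` the reverse. Two major loci
    with opposite poles emulate the sign-opposed latitude responses of the
    two photoperiod-response homoeologs.
    """

    marker: str
    slope: float
    pole: str = "north"

    def __post_init__(self):
        if self.pole not in ("north", "south"):
            raise ValidationError("pole must be 'north' or 'south'")


@dataclass(frozen=True)
class PhenoConfig:
    """Multi-environment heading-date generator settings.

    27 trial environments spanning latitudes 19-45 degrees N, grouped into 5
    macro-areas by latitude, mirror the published trial network. Effects are
    in days; ``env_sd`` is the within-environment residual SD and
    ``env_offset_sd`` the between-environment mean shift removed later by
    environment centering.
    """

    qtl_effects: dict = field(default_factory=dict)  # marker -> additive effect (days)
    major_loci: tuple[MajorLocus, ...] = ()
    n_envs: int = 27
    n_areas: int = 5
    lat_range: tuple[float, float] = (19.0, 45.0)
    env_sd: float = 2.0
    env_offset_sd: float = 5.0
    base: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.n_envs < 1 or self.n_areas < 1:
            raise ValidationError("need >= 1 environment and macro-area")


def simulate_heading_date(panel: PanelData, config: PhenoConfig) -> pd.DataFrame:
    """Simulate a long-format phenotype table (accession x environment).

    value = base + env offset + sum of QTL effects + latitude-scaled major
    locus effects + iid environment noise. A QTL/major-locus carrier is an
    accession whose call at the marker is allele 0. Columns: accession,
    environment, macro_area, latitude, value.
    """
    for m in list(config.qtl_effects) + [ml.marker for ml in config.major_loci]:
        if m not in panel.loci:
            raise ValidationError(f"effect assigned to absent marker {m!r}")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    lats = np.sort(rng.uniform(*config.lat_range, size=config.n_envs))[::-1]
    env_names = [f"env{e + 1:02d}" for e in range(config.n_envs)]
    # macro-areas by decreasing latitude, sizes as equal as possible
    bounds = np.array_split(np.arange(config.n_envs), config.n_areas)
    area_of = {}
    for ai, idxs in enumerate(bounds):
        for i in idxs:
            area_of[env_names[i]] = f"area{ai + 1}"
    offsets = rng.normal(0.0, config.env_offset_sd, size=config.n_envs)

    n_acc = panel.n_accessions
    genetic = np.full(n_acc, config.base)
    for m, eff in config.qtl_effects.items():
        genetic = genetic + eff * (panel.locus_calls(m) == 0)

    lo, hi = min(config.lat_range), max(config.lat_range)
    rows = []
    for e, env in enumerate(env_names):
        val = genetic + offsets[e]
        for ml in config.major_loci:
            scale = (lats[e] - lo) / 10.0 if ml.pole == "north" else (hi - lats[e]) / 10.0
            val = val + ml.slope * scale * (panel.locus_calls(ml.marker) == 0)
        val = val + rng.normal(0.0, config.env_sd, size=n_acc)
        rows.append(
            pd.DataFrame(
                {
                    "accession": list(panel.accessions),
                    "environment": env,
                    "macro_area": area_of[env],
                    "latitude": round(float(lats[e]), 2),
                    "value": val,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
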