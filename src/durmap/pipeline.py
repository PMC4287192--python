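"""End-to-end pipeline on simulated (or user-supplied) inputs.

Chains every stage — simulation, single-population mapping, consensus
framework construction and interpolation, LD decay, differentiation
scanning and Q+K association mapping — under a single root seed, and
writes every report file. Mostly a thin composition of the stage modules;
useful programmatically (:func:`run_pipeline`) and from the CLI.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus, diversity, gwas, io, ld, linkage, simdata
from .config import PipelineConfig

__all__ = ["PipelineResult", "simulate_inputs", "run_pipeline"]


@dataclass
class PipelineResult:
    true_map: simdata.TrueMap
    populations: dict
    component_maps: dict
    framework: consensus.ConsensusMap
    framework_report: pd.DataFrame
    consensus_map: consensus.ConsensusMap
    map_summary: pd.DataFrame
    collinearity: pd.DataFrame
    panel: object
    phenotypes: pd.DataFrame
    ld_pairs: list
    ld_bins: pd.DataFrame
    sved: ld.SvedFit
    background_r2: float
    n_blocks: int
    amova: diversity.AmovaResult
    pairwise_fst: pd.DataFrame
    fst_records: list
    pic: pd.DataFrame
    associations: pd.DataFrame
    env_associations: pd.DataFrame
    thresholds: gwas.Thresholds
    qtl_regions: list
    joint_r2: float
    log: dict = field(default_factory=dict)


def _child_seeds(root: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31 derived from the root seed."""
    ss = np.random.SeedSequence(root)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def simulate_inputs(config: PipelineConfig):
    """Generate the full synthetic study: maps, populations, panel, phenotypes."""
    cfg = config.sim
    seeds = _child_seeds(config.seed, 8 + cfg.n_pops)
    true_map = simdata.simulate_true_map(
        cfg.n_groups, cfg.group_length_cM, cfg.n_markers_per_group, seed=seeds[0]
    )
    design = simdata.simulate_anchor_design(true_map, cfg.n_pops, cfg.anchor_fraction, seed=seeds[1])
    populations = {}
    for i, (name, markers) in enumerate(sorted(design.items())):
        sim = simdata.SimConfig(
            pop_type=cfg.pop_type,
            n_lines=cfg.n_lines,
            missing_rate=cfg.missing_rate,
            error_rate=cfg.error_rate,
            seed=seeds[8 + i],
        )
        populations[name] = simdata.simulate_population(true_map, sim).subset(markers)
    panel_cfg = simdata.PanelConfig(
        subpop_sizes=tuple(cfg.subpop_sizes),
        ne=cfg.ne,
        generations=cfg.generations,
        admixture=cfg.admixture,
        seed=seeds[2],
    )
    panel = simdata.simulate_panel(true_map, panel_cfg)
    rng = np.random.default_rng(seeds[3])
    loci = list(true_map.markers)
    qtl = list(rng.choice(loci, size=min(cfg.n_qtl + 2, len(loci)), replace=False))
    majors = (
        simdata.MajorLocus(qtl[0], cfg.major_slope, "north"),
        simdata.MajorLocus(qtl[1], cfg.major_slope * 0.75, "south"),
    )
    effects = {
        m: cfg.qtl_effect * (0.5 + 0.5 * rng.random()) * rng.choice([-1, 1])
        for m in qtl[2:]
    }
    pheno_cfg = simdata.PhenoConfig(
        qtl_effects=effects,
        major_loci=majors,
        n_envs=cfg.n_envs,
        n_areas=cfg.n_areas,
        env_sd=cfg.env_sd,
        seed=seeds[4],
    )
    phenotypes = simdata.simulate_heading_date(panel, pheno_cfg)
    truth = {"qtl_effects": effects, "major_loci": [m.marker for m in majors]}
    return true_map, design, populations, panel, phenotypes, truth


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage on a simulated study and (optionally) write reports."""
    t0 = time.time()
    true_map, design, populations, panel, phenotypes, truth = simulate_inputs(config)

    # single-population maps
    component_maps = {
        name: linkage.build_component_map(seg, config.map_params)
        for name, seg in populations.items()
    }

    # anchors: markers genotyped in >= 2 populations
    counts: dict[str, int] = {}
    for markers in design.values():
        for m in markers:
            counts[m] = counts.get(m, 0) + 1
    anchors = sorted(m for m, c in counts.items() if c >= 2)
    anchor_sources = {
        m: tuple(sorted(p for p, mk in design.items() if m in mk)) for m in anchors
    }
    pooled = consensus.pool_all_pairs(
        populations, markers=anchors, heterogeneity_alpha=config.heterogeneity_alpha
    )
    framework, framework_report = consensus.build_framework(
        pooled, anchor_sources, lod_min=config.map_params.lod_merge,
        max_r=config.map_params.max_r_merge,
    )

    # interpolate population-unique markers from each component map
    projections = []
    placed = set(framework.markers)
    for name, result in sorted(component_maps.items()):
        for lg in result.groups:
            proj, _ = consensus.interpolate_unique(lg, framework, source=name)
            if len(proj):
                proj = proj[~proj["marker"].isin(placed)]
                placed.update(proj["marker"])
                projections.append(proj)
    cmap = consensus.add_interpolated(
        framework, pd.concat(projections, ignore_index=True) if projections else
        pd.DataFrame(columns=["marker", "group", "cM", "source"])
    )
    map_summary = consensus.summarize_map(cmap)

    coll_rows = []
    for name, result in sorted(component_maps.items()):
        for lg in result.groups:
            try:
                grp = cmap.group_of(lg.markers[0])
                rho, r2, n_shared = consensus.collinearity(lg, grp)
                coll_rows.append((name, grp.name, n_shared, rho, r2))
            except Exception:
                continue
    coll = pd.DataFrame(coll_rows, columns=["population", "group", "n_shared", "rho", "r2"])

    # LD
    pairs = ld.pairwise_ld(panel, cmap, maf_min=config.ld.maf_min)
    bins = ld.bin_by_distance(pairs)
    sved = ld.fit_sved(pairs, n=panel.n_accessions, k=config.ld.k, fit_alpha=config.ld.fit_alpha)
    background = ld.background_threshold(
        pairs, min_cM=config.ld.background_min_cM,
        percentile=config.ld.background_percentile, min_pairs=20,
    )
    n_blocks, _ = ld.count_ld_blocks(cmap, pairs, r2_block=config.ld.r2_block)

    # diversity
    d_seeds = _child_seeds(config.seed + 1, 2)
    amova_res = diversity.amova(panel, panel.subpops, n_perm=config.diversity.n_perm, seed=d_seeds[0])
    fst_matrix, _ = diversity.pairwise_fst(panel, panel.subpops)
    roles = dict(zip(sorted(panel.subpops.unique()), diversity.ROLES))
    fst_records = diversity.locus_fst_scan(
        panel, panel.subpops, alpha=config.diversity.alpha,
        n_perm=config.diversity.n_perm, seed=d_seeds[1], roles=roles,
    )
    pic_table = diversity.pic_scan(panel, cmap)

    # association
    markers, provenance = gwas.biallelify(panel, maf_min=config.gwas.maf_min)
    K = gwas.ibs_kinship(markers)
    Q = panel.q_matrix
    covars = [
        c for c in markers.columns
        if provenance[c] in truth["major_loci"]
    ][: config.gwas.n_covariate_majors]
    associations = gwas.scan_environments(phenotypes, markers, Q, K, covars, "macro_area")
    env_associations = gwas.scan_environments(phenotypes, markers, Q, K, covars, "environment")
    thresholds = gwas.significance_thresholds(
        n_blocks, config.gwas.alpha_exp, config.gwas.alpha_marker
    )
    regions = gwas.declare_qtl_regions(
        associations, cmap, pairs, provenance,
        alpha_marker=thresholds.marker_wise, block_r2=config.ld.r2_block,
        ci_pad=config.gwas.ci_pad, env_results=env_associations,
    )
    reps = [r.representative for r in regions]
    y_overall = gwas.adjusted_means(phenotypes).mean(axis=1)
    joint = gwas.multi_qtl_r2(y_overall, markers[reps + covars]) if reps or covars else 0.0

    log = {
        "seed": config.seed,
        "n_markers_true": true_map.n_markers,
        "n_populations": len(populations),
        "n_anchors": len(anchors),
        "framework_markers": sum(len(g.markers) for g in framework.groups),
        "consensus_markers": sum(len(g.markers) for g in cmap.groups),
        "n_ld_pairs": len(pairs),
        "sved_alpha": sved.alpha,
        "sved_ne": sved.ne,
        "background_r2": background,
        "n_ld_blocks": n_blocks,
        "amova_fst": amova_res.fst,
        "experiment_wise_p": thresholds.experiment_wise,
        "n_qtl_regions": len(regions),
        "joint_r2": joint,
        "params": config.to_dict(),
        "wall_time_s": None,
    }

    result = PipelineResult(
        true_map, populations, component_maps, framework, framework_report, cmap,
        map_summary, coll, panel, phenotypes, pairs, bins, sved, background, n_blocks,
        amova_res, fst_matrix, fst_records, pic_table, associations, env_associations,
        thresholds, regions, joint, log,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, seg in populations.items():
            io.write_segregation(seg, outdir / f"segregation_{name}.tsv")
        for name, res in component_maps.items():
            io.write_map(res.groups, outdir / f"map_{name}.tsv")
        io.write_consensus_map(cmap, outdir / "consensus_map.tsv")
        io.write_panel(panel, outdir / "panel.tsv", outdir / "panel_meta.csv")
        io.write_phenotypes(phenotypes, outdir / "phenotypes.csv")
        io.write_report(map_summary, outdir / "map_summary.csv")
        io.write_report(coll, outdir / "collinearity.csv")
        io.write_report(framework_report, outdir / "framework_groups.csv")
        io.write_report(ld.ld_frame(pairs), outdir / "ld_pairs.csv")
        io.write_report(bins, outdir / "ld_distance_classes.csv")
        io.write_report(pic_table, outdir / "pic_scan.csv")
        io.write_report(associations, outdir / "associations_macro_areas.csv")
        io.write_report(env_associations, outdir / "associations_environments.csv")
        scan_rows = []
        for rec in fst_records:
            row = {"locus": rec.locus, "pattern": rec.pattern}
            for pair, f in rec.pair_fst.items():
                row[f"fst_{pair[0]}_{pair[1]}"] = f
                row[f"p_{pair[0]}_{pair[1]}"] = rec.pair_p[pair]
            scan_rows.append(row)
        io.write_report(pd.DataFrame(scan_rows), outdir / "fst_scan.csv")
        qtl_rows = [
            {
                "region": r.name, "group": r.group, "representative": r.representative,
                "n_members": len(r.members), "interval_lo": round(r.interval_cM[0], 2),
                "interval_hi": round(r.interval_cM[1], 2), "ci_lo": round(r.ci_cM[0], 2),
                "ci_hi": round(r.ci_cM[1], 2), "peak_p": r.peak_p,
                "n_significant_envs": r.n_significant_envs,
            }
            for r in regions
        ]
        io.write_report(pd.DataFrame(qtl_rows), outdir / "qtl_regions.csv")
        sved_report = {
            "alpha": sved.alpha, "beta": sved.beta, "k": sved.k, "ne": sved.ne,
            "n": sved.n, "rss": sved.rss, "n_pairs": sved.n_pairs,
            "model_r2": sved.model_r2, "background_threshold": background,
            "n_ld_blocks": n_blocks,
        }
        (outdir / "sved_fit.json").write_text(json.dumps(sved_report, indent=2))
        log["wall_time_s"] = round(time.time() - t0, 2)
        (outdir / "pipeline_log.json").write_text(json.dumps(log, indent=2, default=str))
    else:
        log["wall_time_s"] = round(time.time() - t0, 2)
    return result
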