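"""Linkage-disequilibrium decay in a structured inbred panel.

Simulates a 183-accession panel (five subpopulations, drift at Ne = 20
with admixture) on a known map, computes pairwise r2 / D' for all mapped
loci, summarizes LD by the printed distance classes, fits the Sved drift
expectation E[r2 - 1/n] = 1/(alpha + 4 Ne c), and derives the background
threshold and the number of independent LD blocks used later for the
association Bonferroni correction.
"""

from durmap import consensus, ld, simdata

true_map = simdata.simulate_true_map(3, 120.0, 25, seed=5)
panel = simdata.simulate_panel(true_map, simdata.PanelConfig(seed=6))

# loci are already on the true map; express it as a consensus-map container
cmap = consensus.ConsensusMap(
    tuple(
        consensus.ConsensusGroup(
            g.name, g.markers, g.positions,
            ("framework",) * len(g.markers), ((),) * len(g.markers),
        )
        for g in true_map.groups
    )
)

pairs = ld.pairwise_ld(panel, cmap, maf_min=0.10)
print(f"{len(pairs)} marker pairs ({sum(p.same_group for p in pairs)} syntenic)")
print(ld.bin_by_distance(pairs).to_string(index=False))

fit = ld.fit_sved(pairs, n=panel.n_accessions)
print(f"Sved fit: alpha={fit.alpha:.2f}  Ne={fit.ne:.1f}  model R2={fit.model_r2:.2f}")
r2_at_zero = ld.predict_r2(fit, 0.0)
print(f"expected r2 at 0 cM: {r2_at_zero:.2f}")
# the half-value decline of the fitted curve (the 0.3 reference threshold
# only applies when the curve starts above it)
half = 0.5 * (r2_at_zero + 1.0 / fit.n)
target = 0.3 if r2_at_zero > 0.3 else half
print(f"distance where r2 falls to {target:.3f}: {ld.distance_at(fit, target):.2f} cM")
print(f"background r2 (95th pct, pairs >= 50 cM apart): "
      f"{ld.background_threshold(pairs, min_pairs=20):.3f}")
n_blocks, _ = ld.count_ld_blocks(cmap, pairs, r2_block=0.3)
print(f"independent LD blocks at r2 >= 0.3: {n_blocks}")
# Mean r2 should fall monotonically across distance classes; the fitted Ne
# reflects the simulated drift size, and the block count sets the
# experiment-wise significance threshold (0.05 / n_blocks) for the scan.
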