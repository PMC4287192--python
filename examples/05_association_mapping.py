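"""Q+K mixed-model association mapping for a multi-environment trait.

Runs the complete association chain on one simulated study: biallelified
marker matrix, IBS kinship, adjusted means per macro-environmental area,
broad-sense heritability, the Q+K mixed-linear-model scan with major-locus
covariates, LD-block Bonferroni thresholds, QTL-region declaration with
2.2 cM confidence-interval padding, and the joint R2 of all
QTL-representative markers.
"""

from durmap import gwas, ld
from durmap.config import PipelineConfig
from durmap.pipeline import run_pipeline, simulate_inputs

cfg = PipelineConfig(seed=11)
res = run_pipeline(cfg)

h2 = gwas.broad_sense_h2(res.phenotypes)
print(f"broad-sense h2 across environments: {h2:.2f}")
print(f"LD blocks: {res.n_blocks} -> experiment-wise threshold "
      f"P <= {res.thresholds.experiment_wise:.2e} (alpha 0.05)")

sig = res.associations[res.associations["p"] <= res.thresholds.marker_wise]
print(f"{len(sig)} marker x area records at marker-wise P <= 0.01")
print(f"{len(res.qtl_regions)} QTL regions declared:")
for r in res.qtl_regions:
    print(f"  {r.name} {r.group} rep={r.representative} "
          f"CI [{r.ci_cM[0]:.1f}, {r.ci_cM[1]:.1f}] cM "
          f"peak P={r.peak_p:.2e} envs P<=0.05: {r.n_significant_envs}")
print(f"joint R2 of representative markers: {res.joint_r2:.2f}")
# Each region's confidence interval pads the member span by 2.2 cM per
# side (singletons: 4.4 cM total); the joint R2 approximates the genetic
# variance captured by the declared regions plus major-locus covariates.
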