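"""Voxel-wise group comparison with a known focal atrophy effect.

Simulates 30 controls and 30 patients whose GCIPL carries a -5 um disc
of atrophy, registers everyone to the common target space, fits the
voxel-wise GLM (group + age + sex + per-voxel retinal thickness),
applies BH-FDR and the 9-voxel cluster-extent filter, and prints the
recovered cluster together with the percentage-change map inside it.
"""

import numpy as np

from octvbm import (
    EffectSpec,
    GLMSpec,
    ScanGeometry,
    TemplateSpec,
    cluster_table,
    cohort_stacks,
    fovea_exclusion_mask,
    make_cohort,
    percentage_change_map,
    template_target,
    voxelwise_glm,
)

spec = TemplateSpec(geometry=ScanGeometry().crop_columns(128))
fovea = spec.resolved_fovea()
disc = EffectSpec(layer="GCIPL", shape="disc", delta_um=-5.0,
                  center=(fovea[0], fovea[1] + 25), radius=8.0)

cohort = make_cohort(spec, [("HC", 30, []), ("MS", 30, [disc])],
                     jitter_rows=1, jitter_cols=5, seed=11)
target = template_target(spec)
stacks = cohort_stacks(cohort, register=True, target=target)
fmask = fovea_exclusion_mask(target, radius_um=500.0)

sms = voxelwise_glm(stacks["GCIPL"], stacks["Retina"], GLMSpec(), fmask)
print(f"significant voxels after FDR + cluster filter: "
      f"{sms.n_significant}")
print(cluster_table(sms).to_string(index=False))

g = stacks["GCIPL"]
hc = g.subset(np.flatnonzero((g.covariates["group"] == "HC").values))
ms = g.subset(np.flatnonzero((g.covariates["group"] == "MS").values))
pct = percentage_change_map(ms, hc)
disc_mask = cohort.effect_masks["MS"]["GCIPL"]
print(f"mean percent change inside the injected disc: "
      f"{np.nanmean(pct[disc_mask]):.1f} %")

# The cluster table localizes the atrophy (centroid, extent, peak t) and
# its mean difference recovers the injected -5 um; the percentage map
# expresses it relative to the control baseline.
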