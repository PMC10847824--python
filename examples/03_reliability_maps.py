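"""Voxel-wise test-retest reliability on same-day repeated scans.

Simulates 10 healthy subjects scanned twice with known variance
components, computes per-voxel Sw, CV and ICC maps, and runs the paired
comparison between sessions, which should flag nothing after the
multiplicity correction.
"""

import numpy as np

from octvbm import (
    ScanGeometry,
    TemplateSpec,
    make_retest,
    reliability_maps,
    retest_paired_test,
)

spec = TemplateSpec(geometry=ScanGeometry().crop_columns(128))
stack = make_retest(spec, n_subjects=10, between_sd_um=5.0,
                    within_sd_um=1.5, seed=3)

maps = reliability_maps(stack)
print(f"mean Sw  : {maps.summary['mean_sw_um']:.2f} um")
print(f"mean CV  : {maps.summary['mean_cv_pct']:.2f} %")
print(f"mean ICC : {maps.summary['mean_icc']:.3f} "
      f"({maps.classification})")

sms = retest_paired_test(stack)
print(f"voxels significant in session-1 vs session-2 paired test: "
      f"{int(sms.sig.sum())}")

# Sw sits at the simulated within-session noise; the ICC reflects the
# ratio of between-subject to total variance; and the paired test stays
# clean because the two sessions differ only by measurement noise.
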