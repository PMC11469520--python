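"""Predict candidate pharmacophore features in a synthetic binding pocket.

Builds a pocket with four planted interaction sites (each backed by a
complementary protein group), evaluates the per-class confidence field on
a 0.5 Å grid, and runs the full extraction pipeline: binarize, label
26-connected components, pick the top-confidence point per nearby
complementary group, and merge points by 1.5 Å average-linkage clustering.
"""

import numpy as np

from qpharm.extraction import extract_features
from qpharm.synth import SyntheticPocketSpec, make_pocket

pocket = make_pocket(SyntheticPocketSpec(n_sites=4, seed=7))
features = extract_features(pocket.oracle, pocket.protein, pocket.spec.box)

print(f"planted {len(pocket.features)} sites, extracted {len(features)} features\n")
print(f"{'class':<18}{'extracted (Å)':<28}{'planted (Å)':<28}{'error'}")
truth = {int(f.cls): f.position for f in pocket.features}
for f in features:
    err = np.linalg.norm(f.position - truth[int(f.cls)])
    print(f"{f.cls.name:<18}{np.round(f.position, 2)!s:<28}"
          f"{np.round(truth[int(f.cls)], 2)!s:<28}{err:.2f} Å")

print("\nEach extracted feature is a cluster centroid of grid points where")
print("the predictor fired near a complementary protein group; errors well")
print("under the 0.5 Å grid diagonal mean the sites were localized cleanly.")
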