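"""PCA clustering of a best-fit ensemble and the sedimentation cross-check.

Takes a quick screened ensemble, strips glycans, superposes on the Fc,
clusters the conformations by PCA + k-means, and predicts sedimentation
coefficients with the convex-hull method.
"""

import numpy as np

import igsas
from igsas.models import lattice_ellipsoid

truth = igsas.make_ground_truth("igg3_like", seed=3)
library = igsas.run_tamc(truth.model, n_moves=600, seed=5)
expt = igsas.simulate_curve(truth, igsas.xray_noise(0.01, seed=8))
screen = igsas.screen_library(library, expt, n_select=60)

models = [igsas.strip_glycans(library.model(int(i))) for i in screen.top_ids]
aligned, rmsd = igsas.superpose(models, models[0], "FC")
print(f"superposed {len(aligned)} models on the Fc "
      f"(RMSD up to {rmsd.max():.2f} nm)")

pca = igsas.pca_cluster(aligned, k=5, seed=0)
print(f"PC1-3 capture {pca.variance_captured_3:.1f}% of the variance")
for g, c in sorted(pca.centroids.items()):
    size = int(np.sum(pca.groups == g))
    print(f"  group {g}: {size} models, centroid model index {c}")

tips = [igsas.fab_tip_separation(m) for m in aligned]
print(f"Fab tip separations: {np.mean(tips):.1f} +- {np.std(tips):.1f} nm")

# hydrodynamics: the elongated antibody sediments slower than a compact
# sphere of the same 158-kDa mass
sphere = lattice_ellipsoid((3.0, 3.0, 3.0), 0.25)
from igsas.models import BeadModel
compact = BeadModel(sphere, np.arange(1, len(sphere) + 1),
                    np.array(["A"] * len(sphere), dtype=object),
                    np.array(["UNK"] * len(sphere), dtype=object),
                    np.array(["FAB1"] * len(sphere), dtype=object))
s_compact = igsas.hull_s_estimate(compact, mass=158100.0, vbar=0.776)
s_ext = igsas.hull_s_estimate(library.model(int(screen.top_ids[0])),
                              mass=158100.0, vbar=0.776)
print(f"s(compact sphere) = {s_compact.s:.2f} S, "
      f"s(extended antibody) = {s_ext.s:.2f} S, "
      f"f/f0 = {s_ext.frictional_ratio:.2f}")

# standardizing an observed s value from the measured buffer to water/20C
buffer_lw = igsas.SolventConditions(20.0, 1.00578, 0.010190, 0.776)
print(f"s20,w correction factor for the light-water buffer: "
      f"{igsas.s20w_standardize(1.0, buffer_lw):.4f}")
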