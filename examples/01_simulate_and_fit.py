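"""Simulate one gene on a two-cell-type landscape and fit the mixture model.

Builds a 2,000-spot section with two spatially clustered cell types, draws
a smooth ground-truth maternal-probability surface for cell type 1 (cell
type 2 stays balanced at p = 0.5), samples 2,000 allele-resolved UMIs with
overdispersion 0.1, and fits the beta-binomial mixture model with a 5-df
thin-plate spline per cell type.
"""

import numpy as np

from asemap.fitter import fit_gene, make_design
from asemap.simulate import evaluate_fit, gen_landscape, gen_truth_surface, sample_counts

coords, weights = gen_landscape(S=2000, K=2, layout="blobs", seed=7)
truth = gen_truth_surface(coords, weights, k=5, coef_scale=1.0,
                          ase_cell_type="ct1", seed=8)
counts = sample_counts(truth, total_umi=2000, phi=0.1, seed=9)

design = make_design(counts, "g1", weights=weights, covariates=truth.basis,
                     shared_spline=False)
fit = fit_gene(design)
r, rmse = evaluate_fit(fit, truth)

print(f"usable spots (n > 0): {design.S}")
print(f"converged: {fit.converged} after {fit.n_iterations} Newton iterations")
print(f"estimated overdispersion phi: {fit.phi_hat:.3f} (truth 0.1)")
print(f"surface correlation with truth r = {r:.3f}; coefficient RMSE = {rmse:.2f}")
print("cell-type intercepts (logit scale):",
      np.round(fit.beta_hat[:2], 3), "(truth: 0, 0)")
# r near 1 means the fitted 2D maternal-probability surface reproduces the
# simulated spatial ASE pattern despite the cell-type mixing at each spot.
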