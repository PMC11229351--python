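# Methods

## Model

For gene *j* at spot *i*, maternal allele-resolved UMI counts are modeled
as `Y_ij ~ BetaBinomial(p_ij, N_ij, phi_j)`, parameterized by the mean
maternal probability and a gene-level overdispersion: the underlying Beta
has `a = p (1-phi)/phi`, `b = (1-p)(1-phi)/phi`. As phi → 0 the
distribution tends to the binomial (implemented exactly, not by limit);
as phi → 1 it tends to all-or-none allelic sampling, the spatial analogue
of transcriptional bursting. `p = 0` or `1` is the degenerate point mass.
Below `phi = 1e-12` the binomial branch is used: the difference is
O(phi·n²), far below float precision, and the log-gamma path would
overflow.

The mean is a cell-type mixture of inverse-logit predictors,
`p_i = sum_k alpha_ik expit(eta_ik)`, with `eta_ik` linear in an
intercept per cell type plus covariates (a thin-plate spline design in
non-parametric mode). Covariate coefficients can be shared across cell
types or cell-type-specific; the parameter layout is K intercepts
followed by the covariate block(s). The shares `alpha` are precomputed
from deconvolution proportions and cell-type expression rates; spots with
a zero denominator (no expressing cell type present) have an undefined
conditional probability and are excluded from the gene's likelihood
rather than erroring. Cell types whose total share over expressing spots
falls below a floor (default 1.0 — less than one expected transcript's
worth of contribution) are dropped from that gene's parameter set for
identifiability and the remaining shares renormalized; drops are recorded
on the fit.

## Fitting

Per-gene maximum likelihood. The score and observed information in beta
are analytic: with `u_k = alpha_k sigma'(eta_k)` the derivative of `p`
chains through the mixture, and the log-pmf derivatives in `p` are
digamma/trigamma expressions (the Beta parameters a and b sum to a
constant in p, which keeps them short). Linear predictors are clipped to
±15 inside the expit — complete separation (an all-maternal gene)
otherwise diverges — and a clipping event is reported as a separation
warning.

The beta-step maximizes the quadratic model of the log-likelihood inside
a trust region: eigendecomposition of the negated Hessian plus a
bisection on the Levenberg shift solves the constrained subproblem; steps
with achieved/predicted improvement ratio > 0.1 are accepted, the radius
halves below 0.25 and doubles (capped at 1e3) above 0.75 when the step
was radius-limited. Iteration stops when the gradient norm falls below
1e-6, the accepted improvement falls below 1e-8, or after 200 iterations.
The phi-step is bounded scalar maximization on [1e-6, 1-1e-6] with beta
fixed; beta- and phi-steps alternate (at most 50 rounds) until the joint
log-likelihood changes by less than 1e-8. Whether to fix phi first or
alternate was an open design choice; alternation is monotone in the
likelihood and exploits the parameterization's separability.
Initialization: beta = 0 (all cell types at p = 0.5, the global null) and
a method-of-moments phi clipped to bounds. When every usable spot has
n = 1 the likelihood is flat in phi (flagged; a single transcript carries
no overdispersion information). The Wald covariance is the inverse
observed information in beta at the optimum with phi treated as fixed;
non-positive-definite information is ridged with the smallest power-of-two
multiple of 1e-8 that admits a Cholesky factorization, and the ridge is
recorded. Genes are independent, so the driver parallelizes over genes
with results identical for any worker count.

## Spline basis

The 2D smoother is a low-rank thin-plate regression spline. Coordinates
are standardized (centered, scaled by root-mean-square distance; the
constants are stored and undone transparently at evaluation). The radial
kernel `r² log r` on pairwise distances is eigendecomposed and truncated
to the k−3 leading directions by |eigenvalue|; the linear null-space
terms (x1, x2) are retained; the constant is absorbed by centering each
column over the training spots, since the model supplies its own
intercept. That yields L = k − 1 columns whose span contains linear
functions of the coordinates. Columns are scaled to unit RMS so the
kernel and linear directions carry coefficients on a common scale (pure
column scaling; the span, fitted values, and tests are unchanged).
Out-of-sample evaluation uses the Nystrom extension of the eigenvectors,
which reproduces the stored design exactly at the training coordinates.
Eigenvector signs are fixed by forcing the largest-magnitude component
positive, making construction deterministic. No penalization is applied:
fits use fixed degrees of freedom (k = 5 default for testing, k = 15 for
visualization). Only the constant is absorbed, not the linear terms; the
convention is documented here because external constructions differ.
Exact numerical equality with any external spline implementation is not a
goal; agreement is asserted at the level of fitted probability surfaces
on simulations.

## Hypothesis testing

Overall bias and within-cell-type bias use Wald statistics
(estimate/standard error against a standard normal) on the intercepts;
the likelihood-ratio test is reserved for the multi-coefficient spatial
alternatives, referred to chi-square with df = L (statistics are floored
at 0; flooring is a warning and indicates an optimizer defect if
frequent). Overdispersion is re-estimated in every model, including the
intercept-only null. Direction calls require both significance and a
margin on the probability scale: maternal only if p̂ > 0.6, paternal only
if p̂ < 0.4 — a significant gene inside [0.4, 0.6] gets no direction and
is not counted in a bias row. BH correction is applied within each test
category, and within cell type for the within-cell-type categories,
matching how the summary table is stratified (configurable). The
within-cell-type spatial test defaults to spline coefficients shared
across cell types with cell-type-specific intercepts (df = L); an option
fits cell-type-specific spline blocks and tests each cell type's block
with df = L. Both conventions are kept because either reading of the
model is defensible; the shared form is the default.

## Surfaces and confidence intervals

Surfaces evaluate the fitted predictor on arbitrary grids. Pointwise
variance comes from the delta method through the mixture mean; intervals
are built on the logit scale and mapped through expit, so they respect
[0, 1] — for a single-predictor surface this is exactly
`expit(eta ± z·se(eta))`. Intervals are pointwise, not simultaneous, and
labeled as such. "Overall" surfaces weight the cell-type expits by the
fit's spot-averaged mixture shares; named-cell-type surfaces take that
cell type's expit directly. Grid points outside the tissue are masked by
a Delaunay-based concave hull (triangles with circumradius above 4x the
median nearest-neighbor spacing are discarded) to avoid extrapolation
artifacts.

## Simulation framework

The generator emulates the structure that drives estimability in real
spot data: spots uniform on the unit square; cell-type weights from soft
vertical bands, a softmax of smooth random bump fields ("blobs" —
clustered types with broad vs. narrow footprints), or exactly uniform
shares; ground-truth surfaces as random linear combinations of the 5-df
basis with N(0, coef_scale²) coefficients (coef_scale = 1 by default,
giving logit-scale patterns of roughly ±2; the distribution of the
coefficients was an open choice and zero-mean normal is the documented
one) assigned to one cell type, the others balanced; a gene's total UMI
budget allocated over spots by a multinomial proportional to expected
expression; and maternal counts drawn beta-binomially. It does not
emulate platform chemistry, segmentation error, or deconvolution error —
weights are known exactly to the fitter — so passing tests demonstrate
correctness of estimation and inference under the model, not robustness
to upstream misestimation.

Study-scale defaults mirror the validation design: S = 2,000 spots, K = 2
cell types, phi = 0.1, UMI bins {100–500, 500–1,000, 1,000–10,000},
surfaces at k = 5. Performance is summarized by the Pearson correlation
between fitted and true probability surfaces at the spot locations and
the RMSE of logit-scale coefficients aligned by cell type and basis
column. Reduced problem sizes used elsewhere (e.g. 600-spot examples,
1,500-spot coverage runs at 20 replicates, 50-replicate recovery grids)
are chosen to keep each study a few minutes on one core while leaving the
Monte-Carlo margins comfortable.

## Numerical choices and degenerate inputs

- Containers validate 0 ≤ Y ≤ N entry-wise and reject duplicate or
  missing identifiers; loading intersects spot sets rather than
  zero-filling.
- Gene filters: a gene is testable overall with ≥ 128 expressing spots
  (2^7; the validation shows correlations are still usably positive in
  the 100–500 UMI range), and per cell type with ≥ 128 expressing spots
  whose weight for that cell type is at least 0.5 (majority presence —
  the presence threshold is configurable; 0 reduces the rule to the
  overall filter).
- Merged pseudo-genes (e.g. a chromosome-wide profile) sum Y and N over
  the member genes per spot; count totals are conserved exactly.
- Random streams: every grid replicate draws three child seeds from a
  spawned SeedSequence, so tables are reproducible and independent of
  execution order.

## Known limitations

- The mixture weights are treated as known; uncertainty from upstream
  deconvolution and DE estimation is not propagated.
- The mixture-of-expits likelihood is non-concave in general; the
  trust-region iteration is monotone but global optimality is only
  verified against multi-start search on small instances.
- Smooth bases cannot represent sharp allelic boundaries; a thin
  structure (e.g. a one-cell-wide biallelic band) will be smoothed into
  its neighborhood.
- Wald intervals treat phi as fixed at its estimate; the cross
  information between beta and phi is ignored.
- Serial-section registration is out of scope; coordinates are assumed
  pre-registered.
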