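# asemap

Allele-specific expression (ASE) mapping for spatial transcriptomics.

In a diploid tissue section profiled with a spot-based technology
(Slide-seq, Visium), each measurement spot can source transcripts from
several cells — and several cell types — at once, and the allele-resolved
UMI counts per spot are sparse and overdispersed. `asemap` estimates, for
each gene, the probability *p* that a transcript comes from the maternal
allele, as a smooth function of 2D position and of the cell types mixed at
each spot, and tests whether allelic imbalance is constant, cell-type
specific, or spatially patterned. Typical uses are mapping X-chromosome
inactivation across a section, separating cell-type-driven from
within-cell-type spatial ASE, and screening for imprinted or
XCI-escaping genes.

## Model

Maternal counts at spot *i* for gene *j* follow a beta-binomial in
mean/overdispersion form:

    Y_ij ~ BetaBinomial(p_ij, N_ij, phi_j)
    p_ij = sum_k alpha_ijk * expit( beta_{0,k,j} + sum_l beta_{l,k,j} gamma_il )

where `N_ij` is the total allele-resolved count, `phi_j` in [0, 1) is a
gene-level overdispersion (phi → 0 recovers the binomial; high phi captures
burst-like monoallelic sampling), and the mean is a mixture over cell
types *k* of inverse-logit linear predictors. The mixture shares

    alpha_ijk = w_ik * mu_ijk / sum_k w_ik * mu_ijk

combine per-spot cell-type proportions `w` (from an upstream deconvolution
tool) with cell-type expression rates `mu` (from an upstream cell-type DE
tool); with no rate estimates, alpha reduces to `w`. Covariates `gamma`
are arbitrary; the non-parametric mode uses a low-rank 2D thin-plate
regression spline basis (k = 5 degrees of freedom for testing, k = 15 for
high-resolution maps). Each gene is fitted independently by trust-region
Newton maximum likelihood with analytic gradient and Hessian, alternating
with bounded scalar estimation of `phi`.

Four hypothesis categories are tested per gene — overall bias, within
cell-type bias (Wald tests; a significant gene is called maternal only if
p̂ > 0.6, paternal only if p̂ < 0.4), overall spatial pattern, and within
cell-type spatial pattern (likelihood-ratio tests against the matching
intercept model) — with Benjamini–Hochberg correction per category and
significance at q < 0.01. Genes are tallied into a seven-row taxonomy in
which "no significant ASE" is exclusive.

## Worked example

`examples/01_simulate_and_fit.py` simulates one gene on a 2,000-spot
landscape with two spatially clustered cell types — cell type 1 carries a
smooth spatial ASE surface, cell type 2 is balanced — samples 2,000
allele-resolved UMIs with overdispersion 0.1, and fits the mixture model:

```
usable spots (n > 0): 1291
converged: True after 14 Newton iterations
estimated overdispersion phi: 0.049 (truth 0.1)
surface correlation with truth r = 0.961; coefficient RMSE = 2.89
cell-type intercepts (logit scale): [ 0.264 -0.123] (truth: 0, 0)
```

The correlation r = 0.96 says the fitted 2D maternal-probability surface
recovers the simulated spatial pattern despite every spot being a
cell-type mixture; the intercepts stay near 0 (p = 0.5), correctly
attributing no constant bias to either cell type. The other examples show
the hypothesis-testing battery with its summary table, high-resolution
surface maps with confidence-interval cross-sections, and a small
parameter-recovery study.

A thin CLI wraps the same library calls:

```sh
asemap simulate --outdir bundle --spots 2000 --total-umi 2000 --seed 7
asemap fit bundle --weights bundle/weights.csv --rates bundle/rates.csv
asemap test bundle --min-nonzero 128
asemap surface bundle --gene g1 --k 15
```

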