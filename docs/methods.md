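# Methods

## The prediction model

For individual $i$ with clinical outcome $Y_i$ (continuous or binary),
adjusting covariates $X_i \in \mathbb{R}^r$ (age, sex, lab values, …) and
TCR beta-chain repertoire $R_i = \{(a_{ij}, w_{ij})\}_{j=1}^{m_i}$ (unique
CDR3 amino-acid sequences with clonal abundances), the package fits the
semi-parametric model

$$E[Y_i] = \pi\bigl(\beta_0 + X_i^\top\beta + Z_i^\top\gamma + h(R_i)\bigr),$$

where $\pi$ is the identity (continuous) or logistic (binary) link.  The
repertoire enters twice:

* **Extracted features** $Z_i$: abundance-weighted counts of amino-acid
  k-mers aggregated over all CDR3s of the repertoire, column-scaled by the
  0.75 quantile.  $\gamma$ carries an L1 penalty, so the fitted model names
  a small set of predictive k-mers.
* **Hidden features** $h(\cdot)$: an element of the RKHS generated by a
  repertoire-homology kernel.  The homology between two repertoires is the
  abundance-weighted best-match alignment score

  $$k(R_i, R_{i'}) = \frac{\sum_j w_{ij}\max_{j'} s(a_{ij}, a_{i'j'})
                        + \sum_{j'} w_{i'j'}\max_j s(a_{ij}, a_{i'j'})}
                       {\sum_j w_{ij} + \sum_{j'} w_{i'j'}},$$

  with $s(a,b)$ the global (Needleman–Wunsch, affine-gap) alignment score
  under BLOSUM62 or PAM250, self-normalized as
  $S(a,b)/\sqrt{S(a,a)S(b,b)}$ so that $s(a,a)=1$ and $k(R,R)=1$.  By the
  representer theorem $h(R_i) = K_i^\top\alpha$ for the $n\times n$ kernel
  matrix $K$, with a quadratic penalty $\alpha^\top K \alpha$.

Note that the homology is a *weighted average* of best-match similarities:
it is invariant to rescaling both repertoires' abundances by a common
constant, but not to rescaling one side only.

## Estimation

Fitting alternates two exact sub-steps until the training loss (MSE for
continuous, cross-entropy for binary) changes by less than `eps`
(default 1e-4, at most `max_iter` = 20 iterations):

1. **Partially penalized (weighted) lasso.**  The kernel-adjusted response
   $Y - K\alpha$ (or the IRLS working response
   $\Delta + (Y-\pi(\Delta))/[\pi(\Delta)(1-\pi(\Delta))]$ with weights
   $\nu = \pi(1-\pi)$, $\pi$ clipped to $[10^{-8}, 1-10^{-8}]$) is
   regressed on $[X, Z^{(t-1)}]$ with the penalty on $\gamma$ only.
   Because the intercept and $X$ are never penalized, the problem is
   solved exactly by projecting the penalized block onto the
   orthocomplement of the unpenalized block and running coordinate-descent
   lasso on the projected design.  Features with zero coefficients are
   dropped and never re-enter, so the support is non-increasing.  For the
   binary path the quadratic surrogate is calibrated so that its fixed
   point minimizes the penalized log-likelihood at the stated λ (the
   working-response subproblem carries 2λ on the sum-of-squares scale);
   this makes the zero-kernel special case agree coefficient-for-
   coefficient with a direct L1-penalized logistic fit at the same λ.
2. **Closed-form kernel update.**  With the parametric part fixed,
   $\alpha = (\lambda^{(t)} I + K)^{-1}(\text{residual})$ for the
   continuous outcome and
   $\alpha = (\lambda^{(t)} I + \Omega^{1/2}K)^{-1}\Omega^{1/2}(\cdot)$
   for the binary one ($\Omega = \mathrm{diag}(\nu)$), with the
   data-driven penalty $\lambda^{(t)} = (p^{(t)} + r + 1)/n$.

**Low-rank kernel basis.**  The α update is computed in the kernel's
leading eigenbasis: eigenvalues above `kernel_eigen_floor` (default 2)
times the average eigenvalue $\mathrm{tr}(K)/n$.  Two reasons.  First,
PSD-truncated kernels have a null space in which α is unidentified — the
training fit $h = K\alpha$ never sees those components — but the raw
cross-kernel rows used to score *new* individuals are not orthogonal to
them, so a full-space solve leaks residual/λ noise into predictions (we
observed an order-of-magnitude variance inflation of the predicted hidden
effect).  Second, with $\lambda^{(t)} \approx 0.1$ and kernel eigenvalues
up to $O(n/4)$, the full-rank update can interpolate the working response,
starving the feature-selection step: the support then ratchets to zero
while the training loss goes to its floor.  The leading eigenspace (the
components carrying genuine between-individual structure) removes both
degeneracies; `kernel_eigen_floor=0` restores the literal full-rank
closed form, which on positive-definite kernels is what the unit tests
compare against a generic numerical minimizer.

**Penalty selection.**  λ on γ is chosen once by 10-fold cross-validation
on the first-iteration penalized regression and held fixed.  For the
binary path the initialization itself is penalized, so CV would be
circular; instead an unpenalized covariate-only logistic pre-fit supplies
the working response and weights for a weighted LassoCV, and the chosen λ
is then used throughout (including the initialization).

**Binary step-3 operator.**  The matrix
$(\lambda I + \Omega^{1/2}K)$ as printed is non-symmetric; a symmetrized
variant $(\lambda I + \Omega^{1/2}K\Omega^{1/2})$ is available via
`symmetrized_alpha_update=True`.  Both are solved in the same low-rank
basis.  The binary loss trace records the cross-entropy at the iteration's
*working* linear predictor (the step-1 quantity), so it lags the
coefficient update by one iteration.

**Prediction.**  A new individual is scored as
$\beta_0 + X^\top\beta + Z^\top\gamma + K_{\text{new}}^\top\alpha$, where
$Z$ contains only the selected k-mers (rebuilt from the new repertoire and
divided by the stored training scale factors; absent k-mers score 0) and
$K_{\text{new}}$ is the raw (unprojected) cross homology against the
training repertoires.  Binary models return the logistic probability and
the 0.5-thresholded class.

## Feature pipeline

`build_feature_matrix` counts all contiguous k-mers (k = 3 by default;
1 ≤ k ≤ 10), each occurrence weighted by clonal abundance (a flag turns
weighting off).  `quantile_scale` divides each column by its 0.75 quantile
(type-7/linear interpolation; over all entries by default, over non-zero
entries for sparse real-data matrices), falling back to the column max and
then to 1 for degenerate columns, and records the factors.
`prevalence_filter` keeps columns non-zero in ≥ 5% of individuals.
`sis_screen` keeps the d = ⌊n/(2 ln n)⌋ columns with the largest absolute
Pearson correlation with the outcome (ties lexicographic, zero-variance
columns last).  Marginal screening can mask jointly identifiable,
compositionally coupled columns (usage shares are negatively correlated by
construction), so screening is best reserved for the penalized baselines
it was described with; the kernel model runs fine on the
prevalence-filtered matrix directly.

## Filtering conventions

Clones with abundance < 2, or containing any character outside the 20
standard amino-acid letters, are removed; individuals with fewer than two
remaining unique sequences are dropped.  Cohorts are aligned by the
intersection of repertoire and complete-covariate individuals, ordered
lexicographically by id; that canonical order indexes every matrix.
Abundances are treated as positive integer counts on input; the kernel
and entropy formulas accept real weights.

## Alignment scoring

Gap penalties default to 10 (open, charged on the first gap residue) and 1
(extend).  The scoring engine is a numba-compiled Gotoh dynamic program
driven in batch over the union of unique sequences, so each unique
sequence pair is aligned exactly once per kernel computation; unit tests
verify exact score equality with Biopython's `PairwiseAligner` on random
peptide pairs under both substitution matrices.  Unnormalized raw scores
are available (`normalize=False`) for users matching other homology
conventions.

## Synthetic cohorts

The generator produces CDR3-like beta-chain repertoires so that every
stage runs without external sequencing data.  It emulates the three
structural features of real repertoires that the method actually consumes:

* **Conserved V/J motifs.**  Every clone starts with one of six 3-letter
  V motifs (CAS, CGS, …) and ends with one of six J motifs (QYF, EQF, …),
  drawn from individual-specific usage proportions
  (Dirichlet, concentration 1.6 per segment).  Motif k-mers are therefore
  the most frequent k-mers, present in essentially every individual —
  dense, properly quantile-scalable columns whose variance reflects
  usage differences, the synthetic analogue of the conserved-region
  k-mers that dominate real repertoires.
* **Public clonotype families.**  Latent archetypes (HLA/exposure groups)
  own slices of a public-sequence library organised as convergent motif
  families (3 ancestor interiors per archetype plus 0–2-point mutants).
  An individual draws 55% of its clones from its archetype's library.
  V/J motifs are assigned to library sequences cyclically, so all
  archetypes share the same motif composition: archetype identity lives in
  the alignment-visible interiors (giving the kernel its block/low-rank
  structure) and not in the k-mer counts — the hidden-effect channel is
  deliberately not readable from the extracted features, which is the
  premise that makes a kernel term worth having.
* **Clonal expansion.**  Abundances follow a Zipf(1.5) law floored at 2
  and capped (default 100; the uncapped law has infinite variance, which
  makes mean-squared errors meaningless).

Defaults: 1,000 individuals, 10–60 clones, CDR3 length 8–20.  The
desk-scale pool used by the tests and the acceptance script
(`DESK_POOL_SPEC`: 800 individuals, 15–25 clones, lengths 9–14,
abundance cap 20) keeps each replicate's kernel computation in seconds;
the heavy public sharing also keeps the union of unique sequences small.

What the generator does **not** reproduce: realistic repertoire depths
(thousands of clones), V(D)J recombination statistics, nucleotide-level
convergence, length/position-dependent residue usage, or batch effects.
Passing benchmarks on this pool show that the estimator recovers the
structure it models — not that it will attain any particular accuracy on
real cohorts.

## Outcome generation and benchmark

Given a pool, each replicate samples n_train + n_test repertoires without
replacement, builds the joint scaled Z and the joint homology kernel, and
draws

$$\eta = \beta_0 + \beta_1 X_1 + Z_c\gamma + h,\qquad
  h \sim N(0, \tau K_{\text{proj}}),$$

with $\beta_0 = 2$, $\beta_1 = -1$, $X_1 \sim N(0,1)$, the six most
frequent k-mers as causal features ($\gamma_j \sim c_0\,U(-1,1)$), and
$\tau = 5$.  "Most frequent" is ranked by raw (pre-scaling) column sums:
post-scaling sums rank by the mean-to-quantile ratio, which selects sparse
tail-heavy columns rather than frequent k-mers (a flag restores the
post-scaling ranking).  Continuous outcomes add N(0,1) noise; binary
outcomes are Bernoulli(logistic(η)), and (X, γ, h, Y) are redrawn —
keeping the sampled repertoires and kernel — until the case proportion
lies in (0.3, 0.7).  K is built jointly over train+test because the
hidden effect must exist on the test side for evaluation.

`run_benchmark` fits, per replicate: the covariate-only GLM, lasso/ridge
on the SIS-screened features with unpenalized covariates, and the kernel
model under BLOSUM62 and PAM250 (training block of the kernel
PSD-projected; raw test×train block for prediction), and reports
classification error and Mann–Whitney AUC (binary) or MSE (continuous),
per replicate and averaged.  Everything is deterministic given the seed.

## Numerical choices

* Quantile: type-7 (linear interpolation), the numpy default.
* PSD projection: hard truncation of negative eigenvalues (the
  Frobenius-nearest PSD matrix); count and magnitude recorded.
* Logistic probabilities clipped to $[10^{-8}, 1-10^{-8}]$ before forming
  working responses; step-halving guards the rare non-decreasing IRLS
  step.  Near-separation at very small n with a weak fixed penalty can
  still saturate the working response — choose λ by CV in that regime.
* Lasso solutions satisfy the KKT subgradient conditions at the returned
  λ (tested); the projection identity used for partial penalization is
  exact, not approximate.
* Loss traces are recorded per iteration; non-monotone traces are
  possible (the alternating scheme has no descent guarantee on the
  training loss alone) and are logged, not raised.
* Ties in SIS ranking and in causal-feature ranking break
  lexicographically by k-mer, making every pipeline stage reproducible.

## Known limitations

* The alternating estimator has no global-optimality guarantee; the
  never-re-enter support rule makes it sensitive to the first-iteration λ.
* The kernel's predictive value depends entirely on between-individual
  homology structure; on exchangeable cohorts (no shared clonotype
  families) the hidden-effect term cannot help and adds a little variance.
* Survival outcomes, multi-kernel learning, and coefficient inference are
  out of scope; gapped or reduced-alphabet k-mers are not implemented,
  but arbitrary named non-negative features can be appended to a
  `FeatureMatrix`.
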