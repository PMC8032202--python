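# Methods

## Model and procedure

Each data point x_i is observed through m feature vectors f_1(x_i), …,
f_m(x_i) of length d (marker patches of an ROI, sensor readouts of an
object).  Stage 1 builds the complete feature graph with Gaussian weights
W_i(k,l) = exp(−‖f_k − f_l‖²/2ε) — the diagonal is kept at 1 (self-loops),
which the degree identity P(k,k) = 1/D(k,k) and the DKS/SSD relation rely
on — and takes the steady-state distribution (SSD) of the random walk
P_i = D_i⁻¹W_i as the signature.  Since W_i is symmetric, the SSD is the
normalized degree vector and costs O(m²d), no eigendecomposition.  Stage 2
applies diffusion maps to the signatures with a Gaussian kernel on squared
l1 distances; l1 is the default because the total variation between two
SSDs (probability vectors) is an l1 distance, so kernel neighborhoods
respect the statistically meaningful metric.  l2 and an unsquared-distance
variant are exposed for ablation.

Eigendecompositions go through the symmetric conjugate D^{−1/2}WD^{−1/2},
which guarantees a real spectrum; right/left eigenvectors of P follow by
degree rescaling, and in the global stage they are normalized so that the
trivial right eigenvector is the constant 1 and the first left eigenvector
is the stationary law.  Each eigenvector is oriented so its
largest-magnitude entry is positive, making outputs reproducible.  With
that scaling, Euclidean distances between embedding rows at full rank
equal the diffusion distance D_t, which the test suite verifies to 1e−6.

## Kernel scales

ε multiplies the squared distance in the exponent, so it is a
squared-distance scale.  `default_epsilon` uses the median of pairwise
*squared* Euclidean distances of one bundle; the batch helper
`pooled_median_epsilon` pools the pairwise distances of all bundles so
that every data point is measured at one common scale, which keeps
signatures comparable across points.  The global scale ε′ defaults to the
median of squared pairwise l1 distances.  Multiscale SSDs (one row per ε)
are supported; small ε emphasizes local feature clusters, large ε drives
the SSD to the uniform vector (verified to 1e−4 at ε = 10⁶ × data scale).

## Dimension selection

The embedding dimension is chosen by a permutation null adapted from the
Jackstraw idea: independently permute each signature coordinate across
points, rebuild the kernel at the observed ε′, and record the absolute
eigenvalues; after s shuffles (default 100, seeded), observed eigenvalues
are accepted from the second one upward while λ(x) ≥ max over shuffles of
|λ*(x)| (ties pass, compared per index), and the count of consecutive
acceptances is returned, excluding the trivial first eigenvector.  Column
permutation preserves every marginal while destroying the joint geometry,
so i.i.d.-noise signatures yield l ≤ 2 in essentially all seeded runs
while clustered signatures keep their cluster dimensions.  An alternative
null that permutes entries within rows of the kernel matrix itself is
available (`permutation_scope="kernel-rows"`), but it is a much weaker
null — any genuine kernel geometry beats it at every index — and is kept
only for comparison.

## Statistical theory

The theory module models a point's features as one draw of an
md-dimensional Gaussian: block mean (μ_j repeated d times) and covariance
with blocks σ_{k,l}·I_d, diagonal σ_j.  All its ε values are per-pixel
scales; a sampled bundle with patch dimension d corresponds to kernel
scale d·ε.  Definitions: heterogeneity h(j) = (μ_j − ⟨μ⟩)/μ_j, weighted
heterogeneity g(j) = μ_j − ⟨μ⟩.  A zero μ_j is an error, not a
convention — h divides by it.

First-order Taylor expansion of the kernel around large ε gives the
closed-form mean SSD implemented here:

    π(j) = 1/(2m) + [ε − (g²(j) + σ_j) + 2⟨Σ_{j,·}⟩ − ⟨Σ⟩]
                    / [2εm − 2m(⟨g²⟩ + ⟨σ⟩ − ⟨Σ⟩)]

with ⟨Σ_{j,·}⟩ the mean of row j of the m×m covariance matrix (diagonal
included) and ⟨Σ⟩ its grand mean.  The sign of the covariance terms is
forced by the expansion: a feature that co-varies positively with the rest
sits closer to them, so its degree and steady-state mass *increase*.  With
independent features the expression reduces to the diagonal-only form up
to O(1/m) self-terms.  The expansion's denominator must be positive
(ε > ⟨g²⟩ + ⟨σ⟩ − ⟨Σ⟩); below that the function raises.

The Monte-Carlo check of this formula uses a feature-exchangeable
demonstrator: balanced two-level means (±amp around a base), equal
variances with small per-feature perturbations, uniform cross-covariance.
Exchangeability makes the terms the first-order expansion neglects common
across features, where they cancel in the SSD normalization; the
per-feature variance perturbations then give the formula genuine
non-uniform structure to predict (resolved at ~5–15 Monte-Carlo standard
errors by 10⁴ bundles of dimension 10×50) while the residual bias stays
within the 3-standard-error band.  In generic, non-exchangeable parameter
regimes the first-order formula's per-coordinate bias at ε = 10⟨g²⟩ is an
order of magnitude larger than the Monte-Carlo resolution; the formula is
a structural approximation there, not a numerically exact one.

Total-variation machinery: the univariate TV is computed by adaptive
quadrature over ±10 standard deviations; the two-term closed-form bound
takes the model's variance units and scales the mean gap by the larger
standard deviation and the variance gap by the larger variance — the only
unit-consistent reading that dominates the quadrature TV on its admissible
set |σ₁−σ₂|/σ_max ≤ 2/3 (0 violations in 5000 random admissible pairs;
either pure-unit reading is violated on a third of them).  The SSD
separation of the two hypotheses is reported as the full l1 sum of the
closed-form mean SSD difference (so it lives in [0, 2]); a simplified
common-denominator form is returned alongside and agrees with the full
value when the two hypotheses share their mean weighted heterogeneity and
mean covariance.  Joint-Gaussian TV for the MAP comparison is estimated by
Monte Carlo as P₁(log p₁ > log p₂) − P₂(log p₁ > log p₂) with a binomial
standard error.

Demonstrator instances for the discrimination propositions are
constructed, not fitted: the covariance-only instance correlates different
feature pairs under each hypothesis with identical marginals; the
lower-bound instance balances variance and heterogeneity patterns so the
premises hold — feature 0 has equal means and a variance gap, the
patterned features satisfy the mean-product premise, and ε sits midway
between the expansion's validity edge and the premise ceiling.  Its means
use a large sum with a small difference so the joint Gaussian TV stays
clearly below 1 (≈0.85 at patch dimension 2) and the comparison against
the SSD separation (≈1.3–1.5) is non-trivial.

## Simulations

The sensor and region positions of the localization scenarios are only
shown graphically in the source material, so the package fixes its own
seeded geometry:

* **sim1** — region centers are a seeded-rotated regular tetrahedron
  (pairwise angles ≈109.5°, satisfying the ≥60° separation constraint);
  points are uniform in spherical caps of angular radius 0.3.  Four
  sensors sit at radius 1.5 on the axes opposite each region (each is
  equidistant from three regions and singles out the fourth by a
  near-zero signal), jittered by 0.05; the fifth sensor sits at the
  centroid of the other four, i.e. near the sphere's center, where it is
  nearly equidistant from everything and uninformative alone.  This makes
  the contrast structural: every single sensor confuses at least three
  regions (10-fold SVM accuracy ≤ ~47% in practice), while the joint SSD
  profile identifies all four (≥85% mean over seeds).
* **sim2** — 12 sensors on a seeded in-plane arc (azimuth ±0.4 rad) of
  radius 1.2 with 0.002 off-plane jitter; the two regions are mirror
  images through the sensor plane, so every per-sensor marginal is
  distributionally identical across regions (per-sensor two-sample KS
  tests reject at the nominal 1% rate).  Cross-covariances |N(0, 0.5)| are
  drawn once per scenario per region; a point's 12d-dimensional covariance
  (blocks σ_{k,l}I_d, diagonal σ_j(x)²) is sampled via the 12×12 matrix's
  Cholesky factor against d i.i.d. columns, after eigenvalue clipping to
  the PSD cone.  The close-arc geometry keeps every variance well above
  the cross-covariance scale, so clipping is almost never active and the
  mirrored-marginal symmetry survives; it also gives the empirical
  group-mean heterogeneity and covariance statistics large norms, making
  the two assumption-check ratios small (~0.05 and ~0.0003).  The price is
  that the covariance signal is faint relative to the variances, so
  SSD-based classification of sim2 is modest (~55%) rather than dramatic.
* **sim3** — as sim2 but sensors are pushed ±0.35 off-plane except
  sensors 1 and 7, which are projected exactly into the mirror plane;
  only those two have matched marginals, and removing them leaves
  classification accuracy unchanged or slightly improved.

The observation noise scale is 20·exp(−‖x−s‖²) (squared Euclidean
distance in the exponent, no denominator) with d = 100 coordinates per
sensor; both are overridable.

The synthetic multiplexed image plants 32 bright 10×10 indicator blobs on
a 224×224 zero background, with six marker channels that are zero outside
the blobs; inside a blob, marker pixels are correlated Gaussians
(baseline 5, sd 1) whose correlated pair — (0,1) or (2,3), ρ = 0.95 —
depends on the blob's class, with identical marginals, and the last two
marker channels have 20% of their blob pixels zeroed to emulate
sparse-expression markers.  This is exactly the structure the theory says
only the SSD can detect, and the end-to-end pipeline (extract → SSD →
embed → SVM) recovers the planted classes at ≥90% across seeds.

## IMC preprocessing

Per channel: optional 3×3 median filter (reflected borders, so constant
regions pass through; intended for dense-expression datasets), then a
z-score whose mean and standard deviation come from the *nonzero* pixels
only — zeros are structural background in IMC — with every pixel passed
through the same affine map.  An all-zero channel is left unchanged with a
warning; a zero spread clamps the divisor to 1.  ROI selection convolves
the (preprocessed, switchable to raw) indicator channel with a constant
b×b kernel over fully-inside windows via summed-area tables, takes the
row-major-first argmax, zeroes the selected region and — by default —
hard-excludes any window overlapping a selected one; zeroing alone is
available as `exclusion="zeroing"` since it is the literal reading of the
selection scheme, but it can still pick a straddling window when the
surround is bright.  Patches are flattened row-major into bundles.

## Evaluation

Leave-one-subject-out removes all of a subject's points from training;
the subject score averages the held-out hard predictions (decision-score
averaging is available) and ties at exactly 0.5 are called positive.
Accuracy, the confusion matrix and the AUC are subject-level.  Stratified
k-fold (falling back to plain shuffled folds when stratification is
impossible, e.g. leave-one-out) reports per-class accuracies.  The RBF
SVM defaults to C = 1 with scikit-learn's scale gamma; a random forest is
available, and the protocol is classifier-agnostic.

## Problem sizes and numerical choices

The test and acceptance runs use the generators' study-scale defaults
(800-point/5-sensor sim1, 400-point/12-sensor sim2, 10⁴ Monte-Carlo
bundles for the closed-form check, 2×10⁴ samples per joint-TV trial, 50
seeded proposition instances, 3 synthetic-image seeds); the whole suite
completes in well under a minute of numerical work per block.  Row sums
of transition matrices are validated to 1e−10; spectral reconstruction of
P and P² to 1e−8; negative eigenvalues under non-integer DKS powers are
clamped to zero (sign-safe integer powers otherwise); WKS excludes
eigenvalues with 1 − λ ≤ 1e−12 from the log and defaults its bandwidth to
a seventh of the log-spectral range; eigenvalue ties in the permutation
test pass with a 1e−12 roundoff guard.

## Limitations

The clinical IMC cohorts behind the original application are not publicly
deposited, so nothing here validates the method on real tissue: the
synthetic multiplexed images emulate blob-shaped, covariance-coded ROIs
with stationary statistics and cannot stand in for real marker biology,
spillover, or tissue morphology.  The closed-form mean SSD is first-order
in 1/ε and quantitatively accurate only near feature-exchangeable regimes
(see above).  Simulation geometry is this package's own design; only the
qualitative contrasts (joint-vs-single-sensor, covariance-only
detectability, symmetric-marginal indistinguishability) are claimed, not
any particular printed accuracy.  No out-of-sample extension of the
embedding is provided, and directed-graph signatures are out of scope.
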