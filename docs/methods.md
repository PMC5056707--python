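# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the design decisions behind
`gsikit`. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Data model

A baseline is a genotype matrix (individuals × loci, each cell the
number of copies of a designated A allele, −1 = missing) plus a
hierarchy: individual → site → river → (region, assignment unit). The
unit map is a partition of rivers, initially the identity, refined by
the unit-definition stage. All frequency-based statistics run off an
`AlleleCountTable` of per-group allele counts; heterozygote and
genotyped-individual counts are carried alongside because the
Weir–Cockerham components need observed heterozygosity, not just allele
frequencies. Missing genotypes remove both gene copies, so group gene
counts are always even. Genepop is the interchange format (3-digit
allele codes, `000000` missing, one site per POP block); a sidecar YAML
carries the site→river→region structure, river adjacency, locus classes
(SNP vs MSV-3) and allele orientation, none of which Genepop can
express.

## Quality control

* **Call rate**: loci with call rate strictly below 0.90 (configurable)
  are discarded. Both locus classes (SNP and MSV-3) are eligible; the
  class never enters any computation and is reported descriptively only.
* **Hardy–Weinberg**: per site-locus, the exact conditional test — the
  probability of the heterozygote count h given the allele counts is
  n! 2^h n_A! n_B! / (n_AA! n_AB! n_BB! (2n)!), and the two-sided p sums
  all outcomes no more probable than the observed one (the standard
  exact-HWE convention). Monomorphic site-loci carry no information and
  contribute p = 1 rather than being dropped, keeping the degrees of
  freedom comparable across sites; they are flagged. Per site, the
  per-locus p-values are combined with Fisher's method (X² = −2Σln p,
  df = 2k); across sites, the combined p-values get a Holm (sequential
  Bonferroni) adjustment. Combining within site before adjusting across
  sites gives one equilibrium measure per site, which is the decision
  actually taken (flag/remove a site).

## Structure

* **Nei's D_A** between site allele-frequency profiles:
  1 − (1/L) Σ_l Σ_a √(x y), computed from observed (maximum-likelihood)
  frequencies; loci with no genes in either group are excluded. D_A is
  not a metric — the triangle inequality can fail — so the ordination
  below may produce negative eigenvalues.
* **PCoA**: classical Torgerson scaling (double-centre −D²/2,
  eigendecompose, scale eigenvectors by √eigenvalue). Negative
  eigenvalues are reported but never embedded.
* **Outlier sites**: flagged when their distance from the
  coordinate-wise median on the first two axes exceeds
  median + 3×MAD. This mechanizes what is normally a visual call on the
  ordination plot; flagged sites are reported, not removed — the
  pipeline excludes them from ranking but returns them for evaluation,
  and a manual list overrides the rule. Borderline sites may be decided
  differently than an expert eye would.
* **Regional clusters**: k-means (20 restarts, seeded) on the top
  principal components of the mean-imputed, centred genotype matrix
  (imputation is for PCA only, never for likelihoods; the default
  number of PCs explains 90% of variance). BIC(k) = n·ln(WSS_k/n) +
  k·ln(n); the chosen k is the smallest whose BIC gain to k+1 falls
  below 5% of the scan's BIC range — a deterministic stand-in for the
  visual elbow, overridable with an explicit k.

## Panel selection

Per-locus Weir–Cockerham (1984) θ̂ = a/(a+b+c) from the standard
variance components; multi-locus θ is the ratio of sums Σa/Σ(a+b+c),
the standard way to combine loci. Ranking pools the sites of a river
into one sample (ranking is "at the river level"; a 3-level
site-within-river estimator would be a natural extension and the
hierarchy is retained to permit it). Negative single-locus estimates
are kept and simply rank last; ties break by locus id so ranking is
reproducible. Default panel sizes are 12, 24, 96, 192, 288, 384, 480
(multiples/subsets of a 96-well genotyping format); panels are nested.

The **outlier-locus screen** (for the neutral-only variant) is
deliberately simple: trim the top and bottom 5% of θ, take the trimmed
mean as the neutral F̄_ST, treat θ(r−1)/F̄ as χ²(r−1), and flag loci
with Benjamini–Hochberg q < 0.05. It is not a reimplementation of the
MCMC/likelihood outlier packages; it exists so the neutral-only
pipeline rerun (identical workflow minus flagged loci) is exercisable.

## Assignment

Rannala–Mountain compound-Dirichlet genotype probabilities with
per-allele prior 1/k (k = 2), which handles zero reference counts
without ad-hoc constants and reduces to (3/8, 1/4, 3/8) at n = 0.
Scores are normalized over **all** baseline sites first (0–100 scale)
and then summed within river/unit — normalizing over rivers instead
would be a one-line switch but summation after site-level normalization
is the behaviour implemented and tested. The cut-off (default 80)
applies to the best unit score. Likelihoods are computed in log space
with max-subtraction, so no panel size underflows to NaN; exact ties
(within 1e−9) are flagged and broken by unit id.

Evaluators enforce leave-out discipline structurally: the hold-out
evaluator requires training and hold-out sets to be disjoint, and
two-fold CV assigns each half against counts from the other half only.
The two-fold split is stratified by site (an unstratified split can
empty a small site from one half, leaving site-level likelihoods
undefined); with odd site sizes the extra fish alternates halves across
repeats. The Monte-Carlo exclusion test (simulate genotypes from the
unit's posterior-mean frequencies, p = fraction of simulated
log-likelihoods ≤ observed) is diagnostic output only and never gates
assignment.

## Unit definition

Each iteration: rank loci on the current units (training set), evaluate
every unit with both methods at the working panel size, then decide per
unit — keep (both ≥ 0.80), merge (both < 0.80), or case-by-case
(exactly one ≥ 0.80). Merges go to the admissible partner with the
largest reciprocal-misassignment weight, where weight(u,v) averages
(mis(u→v)+mis(v→u))/(fish from u + fish from v) over the two methods on
cut-off-filtered tables; admissible means same regional cluster,
preferring adjacent units when any exist. The case-by-case arm is
mechanized with a margin: keep if the failing estimate is within 0.05
of the threshold, else merge — and every such decision is emitted to
the ledger and overridable via config, because this arm models a
judgement call. "Reciprocal misassignment" has no canonical formula;
the symmetric rate above is this package's operationalization. A
sub-threshold unit with no admissible partner is kept and flagged
"isolated". Multiple merge requests in one iteration resolve by
union-find; merged units are renamed to the '+'-joined sorted list of
member rivers. The loop terminates at a fixed point (unit count is
non-increasing, so at most one iteration per river); the ledger alone
replays to the final partition, which the tests assert bit-exactly.

## Mixed-stock analysis

Conditional-ML EM from a uniform start: responsibilities
r_mu ∝ π_u L_u(g_m) with L from HWE at the unit's posterior-mean
frequencies (x+½)/(n+1), π updated as the mean responsibility, stopping
at max|Δπ| < 1e−8 (≤ 5000 iterations). The log-likelihood is monotone
by construction and asserted in tests. Fish with zero likelihood in
every unit (possible when a frequency is exactly 0 or 1) are excluded
with a warning.

Replicate simulations draw unit frequencies from Beta(x_A+½, x_B+½),
regenerate a baseline of the same gene counts from one draw (alleles
are independent under HWE, so allele counts are Binomial(n, f);
heterozygote counts are not tracked because mixture likelihoods need
frequencies only), and generate mixture genotypes from an independent
second draw — removing the bias of scoring a mixture against
frequencies fitted to its own genotypes. Exact resampling schemes vary
between packages; the independent-double-draw Dirichlet/Beta variant is
this package's definition. CIs are 2.5/97.5 percentiles over
replicates; the SE of the mean is reported alongside. Defaults: 1000
replicates; 200 fish per 100% simulation; 1000 fish per fishery
simulation.

## Synthetic data

The generator emulates the sampling design of a national salmonid
baseline: regions containing rivers containing sites, with ~10–32 fish
per site, and Balding–Nichols differentiation at each level (F = 0
copies the parent frequency exactly, so the hierarchy is exactly
nested). Defaults — the "demo18" scenario used throughout the tests —
are 6 regions × 3 rivers × 2 sites × 24 fish, 300 loci, F_region =
0.03, F_river = 0.03, F_site = 0.005, ancestral frequencies uniform on
(0.1, 0.9), 2% missingness, 16% MSV-3 loci. These values were chosen
once to produce the qualitative regime of a strong river-level
baseline: near-zero differentiation between sites of a river, modest
differentiation between rivers and regions, and assignment accuracy
that climbs steeply with panel size. The generator draws no linkage,
no selection, no migration and no family structure, so passing tests
demonstrate correct behaviour of the estimators under their own
assumptions — not robustness to LD, sib-groups or ascertainment bias in
real baselines. `identical_river_pairs` forces chosen same-region river
pairs to share frequencies, planting known-mergeable units for the
unit-definition tests. River adjacency defaults to a chain within each
region as a geographic stand-in.

Mixture simulation draws origins Multinomial(n, π) and genotypes
Binomial(2, unit frequency), recording the realized composition.

## Problem sizes and determinism

The test suite and acceptance script run everything at desk scale: the
demo18 baseline (864 fish, 300 loci), 100 replicates for the mixture
simulations, 500 replicates × 500 simulations for exclusion-test
calibration, and a 6-river baseline for the unit-definition checks —
sizes chosen so the whole suite completes in well under a minute per
heavy stage while leaving the Monte-Carlo assertions comfortable
margins. Every stochastic operation takes an explicit seed;
the pipeline derives per-stage seeds from one master seed via hashed
seed sequences, and a rerun under the same seed is byte-identical
(asserted in tests).

## Known limitations

* The WC estimator here is 2-level (populations = rivers or units);
  sites are pooled within rivers for ranking.
* The outlier-locus screen is a calibrated simplification, not a
  replacement for dedicated outlier software.
* The exclusion test simulates from posterior-mean frequencies rather
  than integrating over frequency uncertainty; at small reference
  samples its null distribution is only approximately uniform (the
  calibration test runs at n = 50 reference individuals).
* D_A-based outlier flagging and the BIC elbow are deterministic
  stand-ins for judgment calls; both accept manual overrides.
* The EM estimator conditions on baseline frequencies; full Bayesian
  mixture estimation (MCMC over π and frequencies) is out of scope.
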