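# gsikit

Genetic stock identification (GSI) from SNP baselines: locus QC,
F<sub>ST</sub>-ranked panel selection, Bayesian individual assignment,
iterative definition of assignment units, and simulation-based
mixed-stock analysis.

`gsikit` is aimed at fishery geneticists who hold a hierarchical
reference baseline — diploid biallelic SNP genotypes for individuals
sampled at **sites**, nested in **rivers**, nested in **regions** — and
want to know (a) which subset of loci best discriminates stocks, (b) how
accurately individuals can be assigned back to rivers or groups of
rivers, and (c) how well the composition of a mixed-stock fishery sample
can be estimated. A hierarchical baseline simulator with known structure
makes every stage testable end to end without any real data.

## The methods at the core

**Individual assignment.** The genotype likelihood is the
Rannala–Mountain compound-Dirichlet predictive with a per-allele prior of
1/2: for a locus with reference gene counts (x_A, x_B), n = x_A + x_B,

    P(AA) = (x_A + ½)(x_A + 3/2) / ((n+1)(n+2))
    P(AB) = 2 (x_A + ½)(x_B + ½) / ((n+1)(n+2))

multiplied across loci. Each fish is scored against every baseline
*site*; likelihoods are normalized to a 0–100 scale across sites and
then **summed within river/unit**, so a river sampled at several sites
is not penalized for spreading its likelihood across them. A score
cut-off (default 80) decides whether the fish counts as assigned.

**Panel selection.** Per-locus Weir–Cockerham θ̂ = a/(a+b+c) at the
river (or unit) level ranks loci by discriminatory power; nested panels
of the top 12, 24, 96, 192, 288, 384 and 480 loci are evaluated with a
hold-out/training split (6 fish per site held out) and two-fold
cross-validation (10 repeats, N = 20 estimates per unit).

**Assignment units.** Rivers whose precision ("proportion correctly
assigned": of the fish assigned *to* a unit, the fraction truly from it)
reaches 80% with **both** evaluators are kept as units; rivers failing
both are merged with their strongest reciprocal-misassignment partner
within the same regional k-means cluster (preferring geographic
neighbours); one-sided failures are case-by-case with a margin rule and
manual overrides. The loop re-ranks loci on each new partition and runs
to a fixed point, with every decision logged to a replayable ledger.

**Mixed-stock analysis.** Stock proportions of a mixture sample are
estimated by conditional maximum likelihood (EM with baseline allele
frequencies held fixed). Simulation replicates propagate baseline
uncertainty by drawing unit frequencies from the Beta posterior of the
observed counts, regenerating a baseline of the same gene counts from
one draw and generating mixture genotypes from an independent second
draw. Both 100% (single-unit) and realistic fishery mixtures are
supported, with percentile 95% CIs and SEs over replicates.

**Simulator.** The baseline generator is the Balding–Nichols F-model
applied at each hierarchy level: child frequency ~ Beta(p(1−F)/F,
(1−p)(1−F)/F) around parent frequency p, genotypes Binomial(2, site
frequency).

## Worked example

```python
import gsikit as g

cfg = g.SimConfig(n_regions=2, rivers_per_region=3, sites_per_river=2,
                  fish_per_site=20, n_loci=150, f_region=0.05,
                  f_river=0.15, f_site=0.002, seed=7)
gm, hierarchy, loci = g.simulate_baseline(cfg)

theta = g.wc_theta_per_locus(g.counts_by_group(gm, hierarchy, "river"))
ranked = g.rank_and_select(theta, sizes=(12, 24, 96))
print("top locus:", ranked.table.iloc[0]["locus_id"],
      "theta = %.3f" % ranked.table.iloc[0]["theta"])

train, hold = g.holdout_split(gm, hierarchy, per_site_holdout=6, seed=1)
ct = g.evaluate_holdout(train, hold, hierarchy, ranked.panel(96), cutoff=80)
print(ct.metrics.round(3))
```

prints

```
top locus: locus0123 theta = 0.492
         n_fish  n_assigned_in  proportion_assigned  proportion_correct
unit
river01      12             12                  1.0                 1.0
...
river06      12             12                  1.0                 1.0
```

i.e. all 72 held-out fish pass the cut-off and every river reaches 100%
precision at these (strongly differentiated, F_river = 0.15) conditions.
A mixed-stock run on the same baseline:

```python
counts = g.counts_by_group(gm, hierarchy, "unit")
summary = g.sim_fishery(counts, {u: 1/6 for u in counts.groups},
                        B=50, mix_size=500, seed=2)
print(summary.table.round(3))
```

```
         truth   mean     lo     hi     se
unit
river01  0.167  0.165  0.135  0.206  0.003
river02  0.167  0.164  0.142  0.202  0.002
...
```

— the estimated proportions recover the simulated truth (1/6 per river)
within narrow CIs.

The same workflow is available from the shell: `gsikit simulate`,
`gsikit qc`, `gsikit structure`, `gsikit panel`, `gsikit evaluate`,
`gsikit units`, `gsikit mix`, and `gsikit run` for the whole pipeline;
see `gsikit --help`.

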