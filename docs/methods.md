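# Methods

This note documents the models, defaults and numerical conventions behind
each stage of the pipeline, and what the synthetic-data tests do and do not
demonstrate about real cohorts.

## Triplet calling

The sponge signature is operationalized with sample Pearson correlations
(ddof-1 convention; p-values from the two-sided t approximation with n−2
degrees of freedom; constant expression rows are dropped up front with a
logged count, since their correlations are undefined).

**Positive threshold.** The lncRNA–mRNA cutoff is by default the 99th
percentile of the *exhaustive* all-pairs correlation distribution, computed
as one dense matrix product over row-standardized matrices. A fixed absolute
cutoff (e.g. 0.33) can be supplied instead. The percentile rule adapts to
cohort size: with pure-noise pairs the 99th percentile sits near
2.33/√n, so larger cohorts get tighter thresholds automatically.

**Shared-miRNA rule.** A candidate needs at least `min_shared` (default 1)
miRNAs that target both molecules in the validated catalogs *and* are
measured in the miRNA expression layer; unmeasured catalog miRNAs cannot be
scored and are ignored. The parameter is exposed because "shares a common
miRNA" is sometimes read as "shares at least two" in the literature; the
functional rule below needs only one negative mediator either way.

**Negativity rule.** Default `p05`: a shared miRNA certifies a candidate as
functional when r < 0 with two-sided p < 0.05 against *both* the lncRNA and
the mRNA. At large n a sign-only rule admits arbitrarily faint negative
correlations, so the significance gate is the default; `sign` mode (r < 0
only) is provided for small cohorts where p < 0.05 is unattainable.
The retained shared-miRNA set of a functional triplet is pruned to the
mediators that pass.

**Edge semantics.** By default the network carries only the miRNA-mediated
edges (miRNA–mRNA, miRNA–lncRNA) of each functional triplet, which makes
inferred networks star-like around mediators; an explicit flag adds the
direct lncRNA–mRNA ceRNA edge, which creates triangles and is the mode used
when clustering-based statistics of the inferred network are of interest.
Duplicate edges collapse and accumulate triplet provenance.

**Condition-specific networks** re-run the *entire* procedure (threshold →
candidates → functional → assembly) independently on each clinical subgroup
(≥3 samples; smaller groups are skipped with a warning), so each condition's
threshold reflects its own correlation distribution and conditions are
mutually independent by construction.

## Topology and null models

- CC is the mean local clustering coefficient; degree-0/1 nodes contribute 0.
- CPL averages shortest-path lengths over *connected ordered pairs only*, so
  disconnected networks get a finite value. The diameter is the largest
  finite eccentricity; the radius is computed within the largest component
  (some network tools report radius 1 on disconnected graphs by treating
  infinite eccentricities as absent; we do not reproduce that convention).
- Heterogeneity is the coefficient of variation of the degree sequence
  (population SD / mean).
- Betweenness uses the standard 2/((N−1)(N−2)) normalization; closeness uses
  the component-size-scaled (Wasserman–Faust) form so values are comparable
  across components.

**Degree-preserving randomization** performs `10·E` attempted double-edge
swaps (a standard mixing heuristic for edge-swap MCMC), rejecting swaps that
would create self-loops, duplicate edges or — when `respect_classes` is on,
the default for typed ceRNA networks — edges whose class pairing never
occurs in the original network, so null networks remain consistent with the
bipartite-like structure of miRNA-mediated graphs. Both modes are exposed
because published analyses rarely state whether their nulls respected node
types. The degree sequence is preserved exactly; a graph admitting no valid
swap (e.g. a triangle) is returned unchanged with a warning.

**Empirical p** is one-sided with the add-one correction,
p = (#{null > observed} + 1)/(R + 1), never exactly 0 at finite R; a
`less` direction is available for metrics (like CPL in clustered networks)
where the observed value exceeds the null. The small-world index
σ = (CC/CC_r)/(CPL/CPL_r) uses the null-ensemble means and requires all four
quantities positive; for zero-clustering networks it is undefined and the
CLI records NaN.

## Hubs, MCODE, enrichment

**Hubs.** Per molecular class, the top `fraction` (default 5%) of nodes by
degree on the full heterogeneous network; the target count is the nearest
integer with halves rounded up — the unique rule consistent with selecting
5, 8 and 40 hubs from classes of 97, 150 and 798, and 10/8/7 from 204/162/139.
Ties at the cutoff degree break lexicographically by id (documented,
deterministic).

**MCODE.** Vertex weight = k × density of the highest k-core of the closed
neighborhood (vertices below the degree cutoff, default 2, weigh 0).
Complexes grow breadth-first from the highest-weight unused seed, admitting
unused neighbors with weight ≥ (1 − node_score_cutoff)·seed weight (default
cutoff 0.2) up to a depth limit; post-processing discards complexes lacking
a 2-core and, with haircut on (default), trims each complex to its 2-core;
fluff is off by default. Scores are density × size; parameters default to
the widely used Cytoscape-plugin values since module mining is
parameter-sensitive and published runs rarely state deviations.

**Enrichment** is the upper-tail hypergeometric probability P(X ≥ k) with
N = |universe|, K = |set ∩ universe|, n = |selection|; fold enrichment is
the plain ratio (k/n)/(K/N) (no EASE-style adjustment). Benjamini–Hochberg
q-values are optional on multi-set queries. The universe is always explicit
— network nodes for topology-driven questions, all measured molecules for
cohort-level questions.

**Guilt-by-association** annotates an lncRNA from the mRNA nodes within
network distance 2 (one hop through a mediating miRNA) — or its direct mRNA
neighbors when ceRNA edges are present — ranking annotation sets by
ascending enrichment p; the top set is the inferred function.

## Survival analysis

**Risk model.** Weights come from a multivariate Cox proportional-hazards
fit of the signature lncRNAs against overall survival (lifelines; Efron tie
handling, lifelines' native method — with continuous survival times ties are
rare and Efron is the more accurate approximation where they occur). The
score is the exact linear combination Σ Wᵢ·Expᵢ; the cutoff is the training
cohort's median score (even n: midpoint of the central pair), and samples
exactly at the cutoff go to the *low*-risk group, so an odd cohort of
distinct scores splits (n−1)/2 high vs (n+1)/2 low (401 → 200/201).

**Kaplan–Meier / log-rank.** Product-limit curves per group; median OS is
the earliest time the curve reaches ≤ 0.5 (undefined, with a warning, when
it never does); the group difference is the two-sided log-rank chi-square
(1 df for two groups); the "5-year survival rate" is the KM estimate at 60
months. For two groups a univariate Cox fit on the group indicator supplies
the hazard ratio with a Wald 95% CI.

**Covariate tables.** Univariate fits per covariate plus one joint
multivariate fit; categorical covariates enter as dummies against fixed
reference levels (stage II, grade G1/G2, residual disease 0–10 mm);
univariate fits use all samples non-missing for that covariate, the
multivariate fit uses complete cases; non-converging covariates (e.g. under
separation) are flagged, not fatal.

**Time-dependent ROC** uses the Kaplan–Meier-based
cumulative-cases/dynamic-controls estimator: at each score threshold c,
sens(c) = (1 − S(t|X>c))·P(X>c)/(1 − S(t)) and
spec(c) = S(t|X≤c)·P(X≤c)/S(t), with AUC by trapezoid integrating the curve
in threshold order (re-sorting by FPR is numerically fragile when many
thresholds share a false-positive rate). With no censoring the estimator
reduces exactly to the empirical AUC. The default horizon is 60 months.

**Stratified analysis** dichotomizes at the *global* cutoff within each
stratum (age ≤65/>65, pooled-stage groupings, etc.) and reruns the KM
comparison per stratum.

**Unsupervised split.** Samples are clustered agglomeratively on per-gene
z-scored signature expression (Euclidean distance, complete linkage — the
common heatmap default; both configurable) and the dendrogram is cut at its
root, yielding exactly two nonempty groups.

## Synthetic cohorts

For each planted triplet a latent miRNA activity vector m ~ N(0, 1) per
sample drives the miRNA row (m + noise) and the planted lncRNA and mRNA rows
(−c·m + noise, coupling c ∈ (0,1]), giving the sponge signature: positive
lncRNA–mRNA correlation ≈ c²/(c² + σ²) and negative miRNA arms. Background
rows are i.i.d. noise. Interaction catalogs contain the planted pairs plus
decoys attached to *background molecules only*, so ground truth is
unambiguous. Survival is exponential proportional hazards with linear
predictor Σ β·Exp over planted lncRNAs (exponential baseline for closed-form
sampling; any PH-consistent generator serves for recovery tests) and
independent exponential censoring. All randomness flows from one integer
seed through a single generator stream; child seeds for pipeline stages
derive from `spawn_seeds`.

Defaults describe a desk-scale ovarian-cancer-like cohort: 200 patients,
30/60/120 molecules per class, 12 planted triplets with 2 shared miRNAs
each, coupling 0.9 with noise SD 0.35 (planted |r| ≈ 0.85–0.9, far above the
99th-percentile background threshold ≈ 0.17), 300 decoy interactions, stage
mix II/III/IV = 0.15/0.70/0.15 (advanced-stage-dominated, as in
high-grade serous cohorts), survival on a months scale (baseline hazard
0.02/month, ~3-year median; censoring rate 0.008/month, roughly a third of
patients censored), and planted Cox coefficients (+0.8, −0.8, +0.5, −0.5)
on four planted lncRNAs. Stage-restricted triplets (coupled only within one
stage's samples) are available for testing condition-specific inference.

**What passing tests show — and don't.** The generator matches the
*assumptions* of the inference (linear coupling, Gaussian noise, exact
proportional hazards, catalogs that contain the true mediators). Recovery
of ≥90% of planted triplets with ≤10% false calls therefore demonstrates
correctness of the implementation under its own model, not robustness to
exon-array probe effects, batch structure, non-linear regulation, heavy-tailed
expression, incomplete or biased interaction catalogs, or miRNA target
multiplicity — none of which are emulated.

## Problem sizes

Test and acceptance runs use desk-scale instances chosen to make every
check exhaustive or near-exhaustive: brute-force triplet equivalence up to
50×50×20 molecules, topology and MCODE oracles on graphs up to 50 nodes,
exact rational hypergeometric arithmetic up to N=50, 1000-replicate null
ensembles on inferred networks of ~50 nodes, and Cox recovery/coverage on
cohorts of 150–401 patients across 20–100 seeds.

## Known limitations

- Identifiers are opaque strings; no symbol/accession normalization.
- Partial-correlation or conditional-mutual-information ceRNA scores are out
  of scope; the correlation-sign filter is the method.
- Cox fitting is unpenalized; separation or strong collinearity among
  signature genes surfaces as a convergence error rather than being
  regularized away.
- The KM-based ROC estimator is not guaranteed monotone under heavy
  censoring (a known property of this estimator family).
- Weighted-network statistics, spectral properties and visualization are not
  provided; networks export to GraphML for external tools.
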