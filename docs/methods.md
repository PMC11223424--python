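# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical conventions, and the design choices that were genuinely open.

## Diversity estimators

Alpha indices operate on a single sample's count vector. Shannon entropy
H = −Σ pᵢ ln pᵢ uses the natural log by default (a `log_base` switch is
provided); Pielou evenness is H / ln S_obs and therefore requires at least
two observed taxa. Simpson is reported in the Gini-Simpson form 1 − Σ pᵢ²
(the complementary convention is a one-liner away; the choice is documented
because sources often leave it implicit). Chao1 is the bias-corrected
estimator S_obs + F₁(F₁−1)/(2(F₂+1)); ACE uses the conventional
rare/abundant cutoff of 10 with the squared coefficient of variation floored
at 0, and is reported as undefined (NaN) in the degenerate case where every
rare taxon is a singleton. Chao1 and ACE are computed by scikit-bio; all six
indices are cross-checked against independent closed-form evaluation in the
test suite.

Rarefaction subsamples each sample **without replacement** to the target
depth via the multivariate hypergeometric distribution (one seeded draw;
multi-draw averaging is deliberately not the default). Samples below the
target depth are dropped and logged, never up-sampled. The pipeline default
depth is 16,864 reads.

## PCoA and PERMANOVA

PCoA is classical scaling: Gower-center −D²/2, eigendecompose, build
coordinates from positive eigenvalues scaled by √λ. Negative eigenvalues
(non-Euclidean input such as Bray-Curtis) are reported in the result rather
than silently dropped; proportions explained are taken over the positive
spectrum.

PERMANOVA is the one-way pseudo-F on the distance matrix:
SS_total = Σ_{i<j} d²ᵢⱼ / N, SS_within = Σ_groups Σ_{i<j∈g} d²ᵢⱼ / n_g,
F = (SS_between/(a−1)) / (SS_within/(N−a)). Labels are permuted freely
(tissues treated as independent groups; a paired design is handled elsewhere
by the Wilcoxon path). When the design admits no more distinct label
assignments than the permutation budget — the two-group case with
C(N, n₁) ≤ B — the permutation distribution is enumerated exactly and the
p-value is the exact tail fraction #{F ≥ F_obs}/#assignments (so two tight
4+4 clouds attain the distribution's minimum, 1/35). Otherwise B Monte-Carlo
permutations give p = (c+1)/(B+1). With B = 199 the null rejection
probability at α = 0.05 is exactly 10/200; the test suite verifies type-I
calibration over 500 null simulations.

## Rank tests

Mann-Whitney uses exact enumeration when min(n) ≤ 8 and the pooled data are
tie-free, else the normal approximation with tie and continuity corrections.
The exact path matches full enumeration to machine precision. The
approximation at very small samples (8+8) is accurate to a few hundredths
in the mid-range of p — an inherent limit of the normal approximation at 16
observations, which the tests assert at its measured accuracy rather than
pretending better. Wilcoxon signed-rank drops zero differences (Wilcoxon
convention) and is exact for n ≤ 15 without ties in |d|. Spearman uses
mid-ranks with the t-distribution p-value and pairwise-complete missing-data
handling; the reported n is always the count actually used.

## Discriminant taxa (LDA effect size)

Per feature: (1) a Kruskal-Wallis screen at α = 0.05; (2) over 30 bootstrap
rounds, two-thirds of each class is subsampled, a one-discriminant LDA is
fitted on the surviving features with abundances scaled to sum 100,000 per
sample, and the per-feature effect is
0.5·(|class-mean difference along the discriminant, back-projected through
the unit-normalized coefficient| + |raw class-mean difference|). The score
is log₁₀(mean effect + 1); a feature passes when it survived the screen and
the score meets the threshold (boundary inclusive, default 3.5). With only
two classes the subclass (within-class) stage of the original procedure is
vacuous and is omitted. Rounds whose subsample leaves a class with fewer
than two members, or a singular fit, are skipped and logged.

A threshold of 3.5 on this scale corresponds to an absolute between-class
difference of roughly 3% of the community — deliberately stringent. At the
reference synthetic conditions (below) no single genus reaches it, because
planted per-genus differences are ~1% absolute; the planted-effect
validation therefore uses the stated stronger design (one genus at 10× in
one class, n = 50/50, depth 20k), which passes with the correct direction
in ≥95% of runs.

## CAG construction

Genus filter: mean relative abundance strictly > 0.1% **within TT and
within NT** (the conjunctive reading; `either_group` and `overall` modes are
exposed because the criterion is stated ambiguously in the field).

Genus dissimilarity: d = 1 − Spearman ρ between genus abundance profiles
across all samples jointly (a Bray-Curtis mode over loading-normalized
genus profiles is selectable). Correlation-based clustering is the default
for the genus level, Bray-Curtis for the sample level — the two stages of
the analysis traditionally use different geometries.

Ward linkage is implemented in the **ward.D2** convention: the
Lance-Williams recurrence on squared dissimilarities,
d²(k, i∪j) = ((nᵢ+n_k)d²(k,i) + (nⱼ+n_k)d²(k,j) − n_k d²(i,j)) / (nᵢ+nⱼ+n_k),
with heights √cost. This matters on non-Euclidean input, where ward.D1
yields different trees. Ties are broken toward the pair containing the
lowest leaf index, making dendrograms bit-reproducible; the tests verify
merge-for-merge equality with an independent centroid-identity
recomputation on 100 random instances. Note that on an exact ultrametric,
ward.D2 reproduces the topology but its upper merge heights exceed the
ultrametric levels (costs scale with cluster size) — a property, not a bug,
shared by every ward.D2 implementation.

Cutting at k = 4 defines the CAGs (k is a config default, not estimated; a
silhouette diagnostic may be added by users but never overrides them).
CAG profiles are **raw sums** of member-genus relative abundances, not
renormalized, so printed medians stay on the same percent scale as
per-genus abundances. Samples are clustered on Bray-Curtis between CAG
profiles and cut at g = 6.

The exclusion step re-runs the tissue contrasts and the CAG-CAG Spearman
matrix after dropping one sample group. The automatic choice ("the group
whose mean CAG1 share of the profile total exceeds 90%") encodes the
"predominantly one CAG" reading as an explicit, overridable heuristic; if
no group qualifies the step is skipped and recorded as such.

## Clinical associations

Computed on tumor samples only. Binary variables get Mann-Whitney with
per-level medians in percent; categorical variables with ≥3 levels get
Kruskal-Wallis (2-level inputs delegate to the binary path); numeric tumor
markers get Spearman correlations. Missing values are excluded pairwise and
counted. Raw p-values drive the significance flag at 0.05 — matching how
such tables are conventionally read — with BH-adjusted values reported in
an adjacent column; variables with fewer than two observed levels in the
cohort at hand are skipped rather than failing the run.

## Synthetic-data model

For patient p, block c, tissue t the latent block factor is

    z[p,c,t] = exp(μ_c + log m[c,t] + σ·u[p,c] + σ_ε·ε[g,p,t])

with u[p,c] ~ N(0,1) shared by both tissues of a patient and all member
genera, tissue multipliers m (normal tissue ≡ 1), and per-genus noise
σ_ε = σ√((1−ρ)/ρ) so the within-block log-scale correlation is ρ. At ρ = 0
the shared term is dropped and σ_ε = σ (the finite-variance no-structure
limit). Each member genus carries a fixed log-normal loading; background
genera are independent log-normals; counts are multinomial at a uniform
random depth. Identical seeds give bit-identical datasets.

Reference conditions (the generator defaults, frozen at design time):
250 patients × 2 tissues; blocks 14/12/11/10 named with the published
membership labels; ρ = 0.8, σ = 0.6; multipliers (1, 3, 0.4, 0.6); baseline
log-intensities (3.0, 0.5, 1.5, 0.5) making block 1 dominant (~70% of the
community, mirroring the dominant-cluster phenomenon in real cohorts);
loading sd 0.4; 20 background genera at log-mean −2.5 ± 1.2 with sample sd
1.2; depths uniform on [10 000, 50 000]. The background placement was chosen
so that all 47 structured genera clear the 0.1% filter while background
mostly sits below it (~3–6 genera pass per replicate as clutter), matching
a cohort that retained exactly its 47 member genera. When background is
made abundant instead, compositional closure against the dominant block
binds the background genera into a coherent fifth cluster and a k = 4 cut
merges the two weakest blocks — a real failure mode of correlation-based
CAG construction worth knowing about.

Clinical links: the binary microsatellite-like feature is
Bernoulli(logistic(−2.9 + 1.0·z₂)) on the standardized log block-2 tumor
factor (prevalence ≈ 7%, the cohort's 17/247 imbalance); the CA199-like
marker is linear in the standardized log block-4 tumor factor with slope
2·sin(π·ρ_s/6) for a target Spearman ρ_s = 0.17 (the bivariate-normal
identity), plus independent Gaussian noise.

What the generator does **not** emulate: zero inflation beyond what the
multinomial induces, phylogenetic relatedness between genera, over-dispersed
(e.g. Dirichlet-multinomial) count noise, batch effects, or within-patient
tissue contamination. Passing tests therefore demonstrate that the pipeline
recovers the co-abundance structure it is designed for, not that it is
robust to every artifact of real amplicon data.

## Pipeline and determinism

Stage order: simulate-or-load → rarefy → alpha contrasts → Bray-Curtis /
PCoA / PERMANOVA → discriminant taxa → CAG model → sample groups → tissue
contrasts → exclusion re-analysis → clinical associations. Stage seeds are
derived from the master seed by fixed spawn keys, so any stage can be rerun
in isolation and two runs with the same master seed produce byte-identical
report payloads (the echoed output path is the only field that can differ).
The report is schema-versioned JSON plus TSVs re-loadable by the I/O layer;
dendrograms are exported as Newick with branch lengths equal to
parent-minus-child merge heights.

Problem sizes used by the validation studies — 500 null simulations for
PERMANOVA calibration (B = 199, 24 samples), 100 random instances (n ≤ 8)
for the Ward cross-check, 50 replicates of the reference design for CAG
recovery, 50 runs for the planted discriminant genus, 200 replicates each
for the clinical-association studies — were chosen to make Monte-Carlo
error small relative to the bands being checked while keeping a full
validation run in the tens of seconds.

## Known limitations

- The genus filter applies to mean abundance only; prevalence-based filters
  are not implemented.
- k and g are user choices; no internal model selection is performed.
- The discriminant procedure is a faithful reimplementation of the
  screen + bootstrap-LDA idea, not a bit-for-bit port of any particular
  server implementation; parity is behavioral (planted effects recovered at
  the stated threshold).
- PERMANOVA offers free permutation only in the pipeline; the paired
  (within-patient) permutation scheme exists as an analysis choice for
  users but is not the default, since the primary contrast treats tissues
  as independent groups.
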