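# Methods

This note documents the models, the numerical choices, and what the
synthetic data generator does and does not emulate. It states no
empirical result that the test suite or the acceptance script does not
itself compute.

## The synthetic study

`synthpop` generates a complete study — VCF, sample metadata, monthly
climate normals, impact annotation, truth JSON — emulating a wild-vine
sampling design: mother plants on a NW→SE transect with elevation
decreasing along it, two demes at the transect ends with admixed
mothers in a central band, and four open-pollinated offspring genotyped
per mother.

**Genetic model.** Deme allele frequencies follow Balding–Nichols:
p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral frequency
p ~ U(0.05, 0.95) with F = `fst_target`. An admixed mother's maternal
frequency is w·p₁ + (1−w)·p₂ with w ~ U(0.3, 0.7). Each offspring is
one Mendelian maternal gamete plus one pollen gamete drawn from the
*local* pool — the deme frequency, or the zone average
(p₁ + p₂)/2 in the admixed band. The zone-average pollen pool matters:
a mother-specific pollen pool would make broods more correlated than
half-sibs, distorting every downstream variance calculation.

**Environmental loci.** `n_env_loci` common loci (ancestral frequency
in (0.25, 0.75)) receive a logit shift `env_effect · sign · z` in the
local frequency, with z the standardized elevation of the mother's
site. Effect signs are random; the truth set records locus ids and
signed effects.

**Defaults as the stated world.** 78 mothers × 4 offspring subsampled
to 286 genotyped plants; F target 0.03; 40 % of mothers admixed;
elevations spanning 722–2295 m; impact-class proportions
0.75 % HIGH / 17 % MODERATE / 17 % LOW / 65.25 % MODIFIER. Two values
the design leaves open were fixed once on realism grounds:
`missing_rate = 0.2` (GBS data typically carry 10–40 % missing calls)
and mean genotype depth 12 (consistent with depth filters at min 3 and
mean ≥ 5 leaving most calls intact).

**What the generator does *not* emulate.** Loci are drawn
independently — there is no within-chromosome linkage — so
distance-dependent LD decay is absent from synthetic data and the
Hill–Weir fit on it correctly reports the decay distance at its search
bound. Decay-fit correctness is instead established by
self-consistency: pairs simulated from the Hill–Weir expectation with
known ρ recover ρ within 1 %. Sequencing errors, allele dropout and
reference bias are likewise not modeled; a green test on synthetic
data establishes the statistics and their wiring, not robustness to
those artifacts.

## Ancestry inference

STRUCTURE-style Bayesian sampling is replaced by maximum-likelihood
admixture estimation under the same generative model
(π_il = Σ_k q_ik p_kl, binomial log-likelihood over non-missing
genotypes, block EM with multiplicative updates). EM guarantees a
monotone log-likelihood, which the tests assert per iteration.
Frequencies are clipped to [10⁻⁶, 1−10⁻⁶] for numerical safety.

**Choice of K.** ΔK = mean|L(K+1) − 2L(K) + L(K−1)| / sd(L(K)) over
≥ 2 (default 3) seeded replicates per K; sd = 0 leaves ΔK undefined at
that K rather than dividing by zero. A practical caveat found during
development: *under-converged* replicates at the true K scatter across
local optima, inflating sd(L(K)) and deflating ΔK exactly where the
signal is. Convergence settings (max_iter ≈ 400, tol ≈ 10⁻³ at a few
thousand markers) matter more for model choice than for the membership
estimates themselves — the analogue of running the sampler's burn-in
long enough.

**Memberships.** Max membership strictly above 0.8 assigns a
subpopulation; otherwise admixed. With weak differentiation
(F_ST ≈ 0.03) and a few thousand markers the admixed group is large —
the expected behavior, since memberships shrink toward uniform as
per-locus information falls.

**Clustering.** Rogers' distance reduces, for diallelic loci coded by
dosage halves x ∈ {0, ½, 1}, to the mean |x−y| over shared loci;
UPGMA is hand-rolled for a deterministic lexicographic tie-break and
cross-checked against average linkage; k-means runs on the top
genotype PCs with the Lloyd algorithm (the Hartigan–Wong variant is
not available in the installed stack; the objective optimized is the
same within-cluster SS) and the elbow is made reproducible as the
max-second-difference of the mean within-SS curve, with the curve
exported for by-eye judgment.

## Population genetics

* **F_ST** — Weir & Cockerham (1984) a/b/c components per locus,
  ratio-of-sums combination; loci monomorphic in the pooled sample are
  skipped; small negative estimates are legitimate.
* **Intrapopulation F** — drift-from-pooled,
  mean (p_k − p̄)²/(p̄(1−p̄)); there is no single textbook estimator
  for a cluster-specific F from labels alone, so the Balding–Nichols
  sense is used and documented. Note that with exactly two equal-sized
  clusters the statistic is identical for both by construction.
* **LD** — composite (Burrows-type) r² from unphased dosages,
  pairwise-complete; the Hill–Weir expectation with its sample-size
  correction term is fitted by nonlinear least squares in log ρ, and
  d₀.₂ solved by bisection, flagged when the fitted curve never
  crosses 0.2 inside the search bracket.
* **Mantel** — Spearman on upper-triangle entries, one-sided
  (greater), p = (1 + #{ρ_perm ≥ ρ_obs})/(1 + n_perm); the smallest
  attainable p is therefore 1/(n_perm+1), e.g. 10⁻⁴ at 9999
  permutations. Genetic distances are averaged to mother-plant level
  before testing so each family contributes one unit.

## Genetic load

P_del = (minor alleles carried at non-missing HIGH SNPs) /
(2 × non-missing MODERATE∪HIGH SNPs). The denominator reads "number
of alleles × 2" as *total alleles carried* at those SNPs — the only
parse that keeps P_del a per-individual proportion; the alternative
(×4) parse sits behind `allele_count_times_two`. The minor allele is
fixed once from the whole retained sample (REF is major on an exact
0.5 tie) so the statistic is comparable across individuals. Group
comparison is one-way ANOVA plus Tukey HSD; groups under 3 individuals
are excluded with a note.

## Climate indices

Monthly normals are expanded to days by replication (the effective
resolution of gridded monthly climate products). Windows: GST/GSR
Apr–Oct, GST49/GSR49 Apr–Sep, RRSPR Apr–Jul, HYB Apr–Aug (classical
Branas window; configurable), Huglin Apr–Sep with the stepwise
day-length coefficient (1.00 below 40°, then 1.02…1.06 to 50°;
latitudes above 50° error unless extrapolation is enabled) and
negative daily terms floored at zero. The dryness index starts from a
200 mm reserve at end-March and iterates
W = min(w₀, W + P − k·PET − Es) with k = 0.1 (Apr), 0.3 (May),
0.5 (Jun–Sep) and Es = (PET/N)(1−k)·min(P/5, N); W may go negative.
The correlation screen drops the longer-window member of pairs with
|r| ≥ 0.99 (never reducing the set below the PCA minimum of three),
and the environmental PCA runs on standardized columns — the indices
mix °C, mm and products thereof — with elevation excluded because it
is a field measurement, not an interpolated product.

## The association scan

Per marker: trait ~ intercept + structure covariates (K−1 membership
columns) + pseudo-QTNs + marker, F-test on the marker term, vectorized
through a QR residual projector. Pseudo-QTNs in LD (r² ≥ 0.7) with the
tested marker — and the marker itself when it is one — are dropped
from that marker's covariate block.

**Pseudo-QTN selection.** Markers sorted by ascending p, greedily
LD-pruned, retained count chosen by minimum BIC of
trait ~ covariates + top-m over m = 0..n/10. Two selection-aware
guards are the package's defaults:

* the set stays empty unless min p < 0.01/L — naive BIC after a
  best-of-L search otherwise always admits the top chance marker
  (the best of 2000 null markers explains ~5 % of variance, which BIC
  at n ≈ 300 rewards);
* a candidate must itself clear 0.05/L — markers carrying only
  polygenic or family-structure signal (nominal p ~ 10⁻³–10⁻⁵ in
  confounded designs) otherwise stack into the covariate block and
  re-emerge as spurious "hits".

Iteration stops when the pseudo-QTN set repeats; on a cycle the scan
is re-run once with the adopted set so reported p-values are always
conditioned on the returned set. Significance uses 0.05/n and 0.01/n
with n the tested marker count; genomic inflation is reported as the
median-χ² λ.

**Known limitation — the half-sib design effect.** Offspring inherit
their mother's site environment, so the trait is constant within
families while half-sibs are ~0.25 genetically correlated. This
inflates single-marker statistics by ≈ 1 + (mean sibs − 1)·0.25 ≈ 1.7
and cannot be fully absorbed by the structure covariate plus
pseudo-QTN conditioning (a kinship random effect is deliberately out
of scope). In practice the scans remain well calibrated on
unstructured nulls (the test suite verifies family-wise error at the
Bonferroni level) but show λ ≈ 1.2–1.4 on family-structured traits
and produce on the order of 0–2 marginal family-drift hits per three
scans at the 0.05/n threshold. One acceptance check
(`test_hits_only_at_planted_loci`) is accordingly expected to fail on
some worlds; it is kept at face value rather than weakened.

**Power calibration.** For recovery experiments the planted cline
steepness is set by `calibrate_env_effect_empirical`, which simulates
probe loci under the generator's own transmission model, applies the
missingness and major-allele fill, computes the partial correlation of
imputed dosage with the covariate given true ancestry, and converts it
to power at the Bonferroni level with the design-effect-corrected
sample size. The closed-form `calibrate_env_effect` is the first-order
version of the same calculation; it ignores logistic saturation,
imputation shrinkage and cline/ancestry alignment and therefore
understates the required steepness by roughly two- to three-fold in
this design. Neither routine looks at scan output.

## Pipeline and determinism

`pipeline.run_all` drives all stages from one declarative config;
every stage writes plain-text tables and the manifest records the
seed, parameters, input hashes and output hashes. All randomness —
simulation, EM initialization, k-means restarts, Mantel permutations,
scan internals — derives from the single config seed, so reruns are
byte-identical, which the tests assert via the manifest hashes.
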