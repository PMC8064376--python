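# Methods

This note documents the statistical model behind peepkit, the design of its
synthetic-trial generator, the parameter defaults and why they were chosen,
and the known limitations — in particular, which recovery properties the
default study conditions can and cannot support.

## The analysis model

**Paired differential expression.** Within each arm, per-subject deltas
Δ_s = x_s(post) − x_s(pre) are tested per gene with a one-sample two-sided
t-test (df = n_pairs − 1). Genes with zero delta variance are flagged and
assigned p = 1; genes with any missing value are excluded up front with a
logged count, because small-sample t statistics and SDs are undefined for
them. Benjamini–Hochberg q-values are computed and reported, but the
treatment-unique panel is gated on the *nominal* p ≤ α (default 0.05): the
panel concept is a screening set feeding an individual-level analysis, not a
final inference, and the downstream profile statistics do their own error
control via the |z| ≥ 2 call.

**Placebo-concordance filter.** A gene significant in both arms whose mean
delta has the same sign in both is attributed to placebo / repeat-sampling
effects and removed. Genes significant in both arms with *opposite* signs
are retained. Both arms use the same nominal α by default (configurable).

**Perturbation profiles.** For each treated subject, each panel gene is
scored as z = (x_post − μ_ref)/σ_ref, where μ_ref and σ_ref are the sample
mean and SD (ddof = 1) of the gene across reference samples. Calls are
inclusive at |z| ≥ 2. Three reference choices are provided because the
methodology is legitimately described both against the placebo group and
against the pre-treatment population: `control_post` (default, n = 14 under
the default design), `control_all` (placebo pre + post pooled, n = 28) and
`case_pre` (treated-arm baselines, n = 10). With n reference samples the
exact null exceedance of the call is 2·P(t_{n−1} > 2/√(1 + 1/n)):
0.0746 at n = 14, 0.0597 at n = 28, 0.0889 at n = 10. No t-correction is
applied — the score is the plain z the method defines — but this inflation
is why calibration checks use the pooled control reference, which is valid
whenever no systematic pre→post placebo shift is present.

**Stratification and clustering.** FEV₁ percent change is
100·(post − pre)/pre. Strata: strong > 20; weak closed on [5, 10] (a ≥ 5 %
change counts as a response, so the 5 % boundary belongs to weak); non < 5;
the gap 10 < change ≤ 20 receives an explicit `intermediate` label rather
than a silent merge, since the emulated trial happened not to populate it.
Profiles are clustered with average linkage (UPGMA) on Euclidean distances
between z-vectors via scipy; merge order is scipy's deterministic order for
the given input (ties between equal distances — measure zero for continuous
profiles — follow scipy's internal candidate order). Agreement with strata
is the adjusted Rand index of a maxclust cut at user-chosen k.

**Over-representation.** One-sided upper-tail hypergeometric test per gene
set, sets intersected with the universe first, BH across the collection.
The universe is the PEEP panel — exactly the genes eligible to be called —
not the whole transcriptome; conditioning on a larger universe would
anti-conservatively inflate enrichment. "Significantly affected" means
q ≤ 0.05 (configurable); a set significant in exactly one stratum (within a
direction) is reported as unique to that stratum. An external enrichment
web service is deliberately not used: the in-repo hypergeometric test keeps
the pipeline reproducible offline.

**Network proximity.** The closest-distance statistic of network medicine:
for source set S and target set T, d(S→T) = mean over s ∈ S of the minimum
hop distance to any t ∈ T. The definition is directed; a gene in both sets
contributes 0; unmapped and unreachable genes are excluded from the mean
and counted in the result. Distances are unweighted hops even when the edge
list carries weights (weights are parsed and kept as metadata). Optional
significance uses a degree-binned permutation null: random source sets with
the observed set's log₂-degree-bin profile, z = (d_obs − mean_null)/sd_null.
A disease module is the largest connected component of a gene set's induced
subgraph, ties broken toward the lexicographically smallest member set.

**Baseline-table check.** Welch's two-sample t from summary statistics
(mean, SD, n per arm) with Welch–Satterthwaite df, applied to the bundled
baseline characteristics of the emulated trial's arms (ages, lung function,
airway inflammation markers, symptom scores; some rows have reduced n where
the measurement was unavailable for some subjects).

## The synthetic-trial generator

Expression is simulated directly on the normalized log scale — the analysis
consumes "normalized data" whose upstream protocol is unspecified, so
raw-count simulation plus normalization is out of scope and the Gaussian
log-scale model is an explicit assumption:

x[g, (s,t)] = μ_g + b_s + effect[g,s,t] + ε,
μ_g ~ N(8, 2), b_s ~ N(0, subject_sd), ε ~ N(0, noise_sd).

Defaults: 10 treated / 14 placebo subjects, one pre and one post sample
each; 2000 genes; 50 module genes at module_effect = −3; 30 placebo-drift
genes at placebo_effect = +2.5; noise_sd = 1, subject_sd = 0.5;
strata fractions (0.2, 0.3, 0.5) → 2 strong / 3 weak / 5 non-responders
by largest-remainder apportionment (a positive fraction that would receive
zero subjects is an error).

Choices worth flagging:

* **Effect units.** module_effect and placebo_effect are in units of the
  *total* between-sample SD, √(noise_sd² + subject_sd²) — the scale on
  which the perturbation z is defined, so a −3 plant has expected z = −3
  against the control reference by construction.
* **Stratum amplitudes** are monotone in clinical response: strong × 1,
  weak × 1/3, non-responder × 0. This creates the graded profile-similarity
  structure the clustering stage is meant to display.
* **Placebo drift** shifts post samples of *both* arms with the same sign,
  giving the concordance filter true positives. The 2.5 SD default comes
  from an a-priori power calculation: the drift must be detectable in both
  arms — including the 10-pair treated arm, where the paired-t
  noncentrality at 2.5 SD with √2-SD delta noise is ≈ 5.6, i.e. miss
  probability < 10⁻⁴ — so that "every planted placebo gene is removed" is
  the expected behavior rather than a coin flip.
* **FEV₁ changes** are drawn uniformly inside each stratum's interval with
  a margin from the boundaries (strong U(22, 40), weak U(5.5, 9.5), non and
  placebo subjects U(−4, 4)); the 10–20 % intermediate band is unpopulated,
  matching the emulated trial.
* **Network.** A preferential-attachment core over the non-planted genes;
  the module as a hub-and-spokes star densified with random intra-module
  edges (density 0.2 — functional modules are locally dense, and without
  densification any strict subset of the star is edgeless, making disease
  modules degenerate); target-family genes attached to the hub (every
  module gene within 2 hops of the target set); one bridge edge from the
  hub into the core, which keeps unrelated genes strictly farther from the
  target family. Coverage defaults to the full gene universe, as real
  functional interaction networks cover essentially the whole measured
  transcriptome; partial coverage silently shrinks proximity means to the
  few mapped genes.
* **Gene sets.** The first GMT entry is exactly the planted module; the
  rest are uniform random draws from the universe.

Everything is a deterministic function of the design seed.

What the generator does **not** emulate: count-level noise and
normalization artifacts, batch effects, mean–variance coupling, correlated
co-expression outside the planted module, missing samples, and any
alias/namespace mapping between gene identifiers. Passing tests therefore
demonstrate correctness of the *statistics* under a clean Gaussian world,
not robustness to real RNA-seq pathologies.

## Power at the default study conditions — what is and is not recoverable

The default conditions pin the arm-level power almost completely, and some
recovery properties one might hope for are mathematically out of reach:

* **Panel recall of module genes is ~0.23, not ≈ 1.** With stratum
  amplitudes (1, 1/3, 0) over 2/3/5 subjects, a module gene's per-subject
  deltas have mean 0.3·|e| but carry between-stratum heterogeneity with
  sample SD ≈ 0.40·|e| (ddof = 1). Even with *zero* residual noise the
  paired t is 0.3·|e|·√10 / (0.40·|e|) ≈ 2.38, barely above the df = 9
  critical value 2.26; with the actual √2-SD delta noise at |e| = 3 the
  noncentrality is ≈ 1.5 and per-gene power ≈ 0.25. This is a property of
  the response heterogeneity itself — a t-test over an arm where half the
  subjects do not respond — and no realistic noise level changes it.
* **Shared-call coverage of the module is bounded by panel recall**
  (measured ≈ 0.16), and the per-subject module down-call probability at a
  −3 SD plant is itself capped near Φ(1) ≈ 0.84, because the subject's own
  residual contributes unit variance to z.
* **Clustering cannot fully separate weak from non-responders.** Weak
  profiles differ from non-responder profiles by ~1 z-unit on the dozen
  module genes that survive the panel, against a noise floor of ~100 panel
  genes with unit z-variance; a flat cut at k = 3 recovers the strata only
  partially (ARI ≈ 0.25 on average). The strong pair, with ~3 z-units of
  separation, is usually isolated correctly.
* **What does work, robustly:** complete removal of planted placebo genes;
  the planted pathway as the top enrichment of the strong stratum's shared
  repressed genes (20/20 trials), unique to that stratum in ~95 % of
  trials (occasionally the *weak* stratum also reaches significance — a
  faithful outcome, since weak responders carry a real 1/3-amplitude
  effect); and the proximity ordering strong-shared → target <
  non-responder → target in 20/20 trials. For the proximity comparison the
  non-responder gene set is the *union* of non-responder down-calls: their
  intersection is empty by design (heterogeneous response is the point),
  so the union is the meaningful "genes of non-responders".

## Numerical and I/O choices

* TSV writers emit %.17g floats and readers parse with round-trip
  precision, so write → read is bit-exact; all tables carry the run's
  configuration hash in `#`-comment headers.
* BH adjustment is statsmodels' step-up; hypergeometric tails are scipy's;
  both are cross-checked in the test suite against brute-force
  enumerations, as are linkage heights (O(n³) UPGMA) and hop distances
  (Floyd–Warshall).
* Problem sizes in tests and in the acceptance script — 2000 genes,
  24 subjects, 20 replicate trials — are the generator's default study
  conditions; each full replicate takes well under a second.

## Known limitations

* The plain z-score is anti-conservative for small reference panels (see
  the exact rates above); a t-quantile or empirical-null correction is
  deliberately not applied, to keep the score as defined.
* No moderated-variance (limma-style) DE, no covariate adjustment, no
  consensus clustering, no diffusion-based proximity — all out of scope.
* Gene identifiers are treated as opaque strings; target families that mix
  aliases (e.g. non-standard symbols) must be resolved by the user before
  they are supplied as a target list.
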