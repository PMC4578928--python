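# Methods

This note records the models, conventions and numerical choices behind
`mtpopgen`, and what the synthetic-data tests do and do not demonstrate.

## Data model

The unit of analysis is the **haplotype dataset**: an aligned matrix of
mtDNA sequences collapsed to unique haplotypes with per-population
individual counts.  Under the default `gap_policy="exclude_sites"` every
alignment column containing `-`, `N` or `?` in *any* sequence is masked
before haplotype identity and before all per-site statistics (complete
deletion).  This makes collapsing order-independent and reproducible; the
cost is that a handful of gapped columns are dropped globally.  The
alternative `treat_as_state` keeps gaps as a fifth state.  Ambiguity codes
other than `N` are rejected rather than silently resolved — in clean
population data they almost always indicate an upstream base-calling
problem.

Two statistics deliberately use a *different* missing-data rule: K2P
distances use pairwise deletion (each pair compared over the sites where
both carry an unambiguous base), matching the convention of the
tree/distance programs this module emulates, and nucleotide diversity
offers `deletion="pairwise"` behind a flag because the common desktop
programs disagree here.

## Diversity

Hd = n/(n−1)(1 − Σp²) with sampling variance per Nei (1987) eq. 8.12;
π is the frequency-weighted mean proportion of differing retained sites
over all C(n,2) individual pairs, with variance per Nei (1987) eq. 10.9
(which includes both the sampling-of-sites and sampling-of-individuals
terms).  The unscaled mean pairwise difference π̂ = π·L is the quantity
reused by Tajima's D, Fu's Fs and the mismatch machinery, so the
cross-module identity mean(mismatch distribution) = π̂ holds exactly and is
asserted in the tests.

## K2P distances and lineage means

d = −½ln(1−2P−Q) − ¼ln(1−2Q), with P and Q the transition and transversion
proportions over comparable sites.  When 1−2P−Q ≤ 0 or 1−2Q ≤ 0 the
distance is undefined (saturation) and an error is raised rather than a
clamped value returned.  Between-lineage means average over all cross pairs,
each haplotype counted once by default (`by_haplotype`); individual-count
weighting is available for sensitivity.  Standard errors come from a site
bootstrap: alignment columns resampled with replacement, the *same* columns
for every pair within a replicate, SE = sd over replicates.  The bootstrap
is seeded and bit-reproducible.

## AMOVA

Haplotypic AMOVA partitions squared inter-individual distances — the
number of differing retained sites, i.e. squared Euclidean distance in the
usual molecular-variance convention — into among-group, among-population
and within-population components using the unequal-sample-size
expected-mean-square coefficients of Excoffier, Smouse & Quattro (1992).
Negative variance components are reported as estimated, flagged, never
truncated.  Each fixation index has its own permutation scheme: F_ST
permutes individuals among populations ignoring groups, F_SC within their
group, F_CT permutes whole populations among groups; p = (#{null ≥ obs}+1)/(R+1)
with R = 1000 by default.  With few populations per group the F_CT
permutation space is small, so its p-values are coarse — an inherent
property of the design, not an implementation limit.  A custom
haplotype-level squared-distance matrix (e.g. K2P-based) may be supplied.

## Mantel isolation-by-distance

r is the Pearson correlation over lower-triangle entries of the genetic
(pairwise Φ_ST) and great-circle (haversine, R = 6371 km) matrices; the
null simultaneously permutes rows and columns of one matrix.  Both tails
are always reported, because the directional convention differs between
programs; the headline p is the positive-association tail.  For n ≤ 7 all
n! relabelings are enumerated and the p-value is exact.  A `log_km`
transform of geographic distance is available.

## Neutrality tests

Tajima's D uses the 1989 constants (a₁…e₂); S counts segregating retained
sites, π̂ is the frequency-weighted mean pairwise difference.  Fu's Fs uses
S′ = P(K ≥ k_obs | θ = π̂, n) under the Ewens sampling distribution, with
unsigned Stirling numbers of the first kind computed once per n by the
recursion |s(n+1,k)| = n|s(n,k)| + |s(n,k−1)| carried entirely in log
space — exact enough at n ≈ 200 where naive integers would be astronomically
large and naive floats would overflow.  k_obs is the number of distinct
haplotypes in the subset.

Significance is by simulation of constant-size coalescent genealogies
(lower tail, matching the "significantly negative under expansion"
reading): for D the null is conditioned on the observed S (mutations placed
multinomially on branches in proportion to length), for Fs on θ = π̂
(Poisson mutations at rate θ/2 per lineage).  Conditioning on S versus on θ
is a genuine fork between desktop programs; conditioned-on-S is the default
for D and both are exposed through the same machinery.  Replicates without
polymorphism score +∞ (never "as extreme as" a finite observation).

## Mismatch distributions and expansion dating

Under sudden expansion (θ₀ → θ₁ at mutation-scaled time τ = 2ut) the
pairwise-difference distribution has the closed form

    F_j = F̂_j(θ₁)·γreg(j+1, τ(1+θ₁)/θ₁) + e^(−τ/θ₁) Σ_{i≤j} Pois(i; τ)·F̂_{j−i}(θ₀)

with F̂_j(θ) = θ^j/(1+θ)^{j+1} the stationary distribution — the first term
is pairs coalescing after the expansion, the second pairs predating it.
This is the standard sudden-expansion expectation written as an exact
mixture (regularised incomplete gamma instead of a truncated series), and
is evaluated in log space so large j and θ are safe.

Fitting minimises the SSD between observed and expected frequencies by
bounded least squares over (τ, θ₀, θ₁), with eight deterministic multistarts
jittered around moment-based initial values; ties break by lowest SSD then
lowest τ.  Expected mass above the largest observed class is pooled into
that class so both distributions sum to one.  θ₁ can be pinned at a ceiling
(1e5) when free estimation is unstable, and the fit records that choice.
Harpending's raggedness r = Σ_{i=1}^{d+1}(x_i − x_{i−1})² (with x_{d+1}=0)
is a statistic of the *observed* distribution.  Goodness-of-fit p-values
come from a parametric bootstrap: coalescent samples simulated under the
fitted parameters (infinite-sites, reduced directly to mismatch
distributions), each refit, p = fraction with SSD (raggedness) ≥ observed.
Fit failures in replicates are counted and reported, not dropped silently.

Expansion time: t = τ/(2u) with u = μ·k mutations per sequence per
generation.  **Rate convention**: published per-site rates for mtDNA are
frequently *pairwise divergence* rates (substitutions accumulating along
both lineages); under the default `pairwise_divergence` the per-lineage
rate is μ/2 before scaling by k.  This is the convention that makes the
canonical τ = 2.695 / 0.957%·site⁻¹·Myr⁻¹ / k = 1151 example date to
0.245 Ma; `per_lineage` is available when the rate is already one-sided.
Generation time defaults to 1 year.  The same τ = 0.516 inputs give
0.047 Ma, which the tests assert as computed (a nearby rounded figure in
circulation is not reproducible under any convention tried).

## Statistical-parsimony networks

Haplotypes are joined by a minimum-spanning forest (deterministic Kruskal;
ties by step count then lexical order) using only connections at or below
the parsimony limit.  Multi-step edges pass through inferred unsampled
intermediates (materialised in the GraphML export).  Non-tree edges that
could replace a tree edge of equal weight are reported as ambiguity loops
and left unresolved — classical loop resolution uses frequency and
geographic criteria that need human judgement.  The connection limit uses a
documented Jukes–Cantor multiple-hits estimator,
P(j) = exp(−(L·d_JC(j/L) − j)), the largest j with P(j) ≥ 0.95; the
original TCS constants are not fully published, so the limit is exposed as
an override wherever it is consumed (for L = 1151 this estimator gives 9
steps; legacy software reports other values).  Root scores are an explicit
heuristic — frequency × (1 + degree), normalised per subnetwork — a
surrogate for outgroup-free rooting, not a probability model.

## Synthetic data

Generators use the standard coalescent (msprime ancestry) with finite-sites
HKY mutations, κ = 4 and base frequencies A/C/G/T = 0.302/0.302/0.108/0.288
(an mtDNA-like deficit of G), so K2P correction and saturation behaviour
are genuinely exercised.  Time is mutation-scaled with u = 1 mutation per
sequence per generation: θ equals the expected pairwise difference count
(haploid population size θ/2) and a sudden size change at τ sits at
generation τ/2, matching the mismatch module's τ = 2ut convention so
recovery tests close the loop.  Matrix mutation models emit a fraction of
silent events (parent state redrawn); the per-site event rate is scaled up
by 1/(1−silent fraction) so one *state-changing* mutation per sequence per
generation is realised.  Structured datasets place lineage founders
divergence_steps apart at lineage-private sites (transition with
probability κ/(κ+2)) and hang an independent per-population coalescent off
each founder; coordinates sit on a configurable lattice for IBD testing.

What this does *not* emulate: migration and gene flow between populations,
recombination (appropriate for mtDNA), selection, rate variation among
sites, sequencing error, and uneven real-world sampling.  Passing tests
therefore demonstrate statistical correctness of the estimators under the
stated models, not robustness to every property of field data.

Problem sizes used by the test suite and acceptance script (parameter
recovery over 200 replicates at n = 50, θ₀ = 0.5, θ₁ = 50, τ = 3;
calibration over 300–500 constant-model replicates at n = 30, θ = 3;
three-lineage structured datasets of 36–48 individuals) were chosen as the
smallest designs at which the relevant expectations are statistically
resolvable.

## Pipeline

Stages run in a fixed order with per-stage seeds derived from one master
seed; every table carries a provenance header (version, seed, config hash)
and the JSON manifest suffices to re-run any stage.  Lineage assignment is
an input (lineages are usually tree-derived); the built-in single-linkage
K2P clustering at a user threshold is labelled a surrogate in the manifest.

## Known limitations

- AMOVA p-values are permutation-based and inherit the coarseness of small
  permutation spaces (few populations per group).
- Fu's Fs p-values condition on θ = π̂, ignoring uncertainty in π̂ itself,
  as is conventional.
- The sudden-expansion SSD test has limited power against mixtures of a
  few moderately diverged lineages; strongly bimodal mismatch
  distributions are rejected, weakly bimodal ones often are not.
- The connection-limit estimator is a documented approximation; published
  network figures built with other constants are reproduced by forcing
  their limit, not by re-deriving it.
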