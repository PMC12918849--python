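# Methods

`phylodeco` reimplements, as a tested library, the computational workflow of
a phylogenomic study of a small Andean plant radiation (~17 species spanning
0–3900 m of elevation): attributing cytonuclear discordance to incomplete
lineage sorting (ILS) versus gene flow, concordance statistics, target-capture
locus triage, phylogenetically structured trait–environment models, continuous
ancestral reconstruction, and DEC biogeography. All stages run end-to-end on
synthetic data whose statistical structure matches what the analyses assume;
this note records the models, the defaults and why, and what the synthetic
experiments do and do not demonstrate.

## Multispecies coalescent simulation

Gene trees are simulated by the censored coalescent: within a species-tree
branch carrying *k* gene lineages, waiting times are Exp(k(k−1)/2) in
coalescent units (2N generations); uncoalesced lineages pass rootward and
coalesce to a single lineage above the root. The 3-taxon closed form — the
concordant rooted triplet has probability 1 − (2/3)e^(−t) for an internal
branch of t coalescent units, and each discordant triplet (1/3)e^(−t) — is the
primary correctness oracle.

A species network is the base tree plus reticulation edges, each identified by
the tip clades under its recipient and donor edges, an attachment time, and an
inheritance probability γ ∈ (0,1). During simulation, every gene lineage on
the recipient edge at the reticulation time independently jumps to the donor
edge with probability γ. When a single lineage enters the reticulation, this
is equivalent to the two-pass mixture (simulate on the minor-resolved tree
with probability γ, else on the major tree), which is the independent oracle
used in tests.

Defaults: one sample per species (matching one-accession-per-species designs);
terminal branch lengths are used as given, since with one sample per species
they do not affect topology (an override constant is available for
multi-sample designs, whose terminal lengths the user must supply).
Ultrametricity is required to a relative tolerance of 1e−6 (Newick round-off).

**γ estimation** inverts the simulator: topology frequencies are precomputed
on a γ grid (default 50 points on [0.01, 0.99], 2000 simulations per point,
per-point seeds fixed by the global seed), and γ̂ minimizes the L2 distance
between observed and grid frequencies; the CI is a multinomial bootstrap over
observed trees. With 2000 observed gene trees on a 4-taxon network the
estimator recovers a planted γ = 0.25 within ±0.07 in well over 90% of
replicates.

## Discordance attribution and concordance

`clade_support` scores each rooted clade of a reference tree against a tree
set: the denominator counts trees containing the whole clade plus at least one
outside taxon (prune-then-test), matching standard concordance-summary
behavior for incompletely sampled gene trees. Attribution is a strict
threshold: a clade is "ILS-consistent" only when its frequency in MSC-null
simulations *exceeds* 0.9; at or below, it is "conflict-beyond-ILS". The
threshold comparison is deliberately strict at the boundary.

`gene_concordance_factor` works on unrooted bipartitions: a gene tree is
decisive for a branch when, on each side of the branch, at least two of the
adjacent subtree groups retain taxa; gCF is the percentage of decisive trees
containing the bipartition. For complete tree sets and clades whose complement
is also a clade, gCF/100 equals clade support.

`embedding_fraction` roots each gene tree on the first present outgroup taxon,
finds the smallest clade spanning one group (e.g. the focal genus), and
reports the fractions of eligible trees in which ≥1, respectively all, members
of a second group (e.g. the sister genus) fall inside — the direct tally used
to quantify intergeneric admixture in gene-tree surveys.

## Locus triage

The bait-design screen collapses branches with ultrafast-bootstrap support
below 70 into polytomies (unlabeled internal branches count as support 0 by
default — conservative, configurable), then classifies each locus on the
collapsed tree: *unresolved* if nothing survives, *informative* if strictly
more than 4 surviving nodes have support ≥ 90. Pairwise divergence is the
p-distance over comparable columns (gap/ambiguity columns excluded), and the
divergence screen is inclusive at 0.15. Selected loci are the
informative-and-divergent intersection. Counting strong nodes after collapse
is the only reading under which "unresolved" trees can exist, since collapse
precedes assessment in the screening workflow.

## Trait–environment models

pPCA uses the GLS ancestral mean a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X and the evolutionary
covariance R = (X−1a)ᵀC⁻¹(X−1a)/(n−1), with scores (X−1a)V in the original
trait space; C = I recovers ordinary PCA. Traits are z-scored before PCA by
default (raw-unit analysis is available by skipping `standardize`).

The phylogenetic mixed model y = Xβ + b + e is fit by ML (not REML, so AIC is
comparable across fixed-effect structures). Under the phylogenetic random
effect ("P"), b ~ N(0, σ²_b·C̃) with C̃ scaled to unit maximum diagonal so
σ²_b and σ²_e share a scale; β is profiled by GLS and the likelihood is
maximized over the mixing proportion h = σ²_b/(σ²_b+σ²_e) ∈ [0,1]. Under the
iid species effect ("NP") with one observation per species, σ²_b and σ²_e are
confounded, so the fit collapses to OLS with a single residual variance —
reported openly rather than hidden.

Backward elimination starts from the full elevation × precipitation ×
temperature interaction model and removes, at each step, the removable term
(marginality respected) whose removal most lowers AIC, stopping when no
removal lowers AIC. With n near the parameter count the full model is
near-saturated; a warning advises cross-validation. k-fold CV (k = 3 or 4)
partitions species by a seeded shuffle; held-out species are predicted from
fixed effects plus, under P, the conditional Brownian expectation of their
random effect given the training species. Note that AIC stepwise retains
spurious terms at roughly the χ²₁ > 2 rate per term (~16%), so pure-noise
data select the intercept-only model in only a minority of runs; this is a
property of AIC selection itself, which is why the CV check exists.

The P-vs-NP choice uses a boundary likelihood-ratio test with
p = 0.5·P(χ²₁ ≥ LR) (p = 0.5 exactly at LR = 0), choosing P iff p < 0.5 —
a deliberately permissive cutoff that admits any detectable phylogenetic
structure. At small n this choice has limited power: even for pure-Brownian
data at n = 17, roughly 9% of draws genuinely have their ML variance mix at
ĥ = 0 (verified against a direct multivariate-normal likelihood), so
high-power checks of the choice rule are run at n = 50.

Likelihood R² is 1 − exp(−(2/n)(ℓ_full − ℓ_reduced)); total R² reduces to the
intercept-only OLS model, partial R² refits without the focal term. Multiple
tests are adjusted by Benjamini–Yekutieli (statsmodels), whose hand-evaluated
step-up formula is kept as an independent oracle in the tests.

Wald 95% CIs from the ML fit undercover slightly at n = 17 (empirically ~90%
for the elevation slope on the packaged tree) — the familiar small-sample
behavior of ML variance estimates; REML-based intervals would be wider but
would break the AIC comparisons this pipeline is built around.

## Ancestral reconstruction

Continuous characters (elevation, PC scores) and geographic centroids evolve
by Brownian motion. The ML state at an internal node equals the GLS
phylogenetic mean under the tree re-rooted at that node; re-rooted covariances
are computed from patristic distances, and the root estimate is
(1ᵀC⁻¹1)⁻¹1ᵀC⁻¹x with variance σ̂²(1ᵀC⁻¹1)⁻¹. Latitude and longitude are
reconstructed independently with no spherical correction: over the continental
extent of one radiation the lat/lon plane is effectively Euclidean and avoids
periodicity artifacts. Species centroids are arithmetic means of occurrence
coordinates (southern latitudes negative); record exclusion is a data flag,
not a hard-coded rule, and coordinate deduplication is off by default.

## DEC biogeography

Ranges are subsets of A discrete areas (2^A − 1 observable states plus an
internal null range). Anagenesis: gain of area a at rate d·|r| (equal
dispersal multipliers), loss of any occupied area at rate e; single-area
ranges pass to the absorbing null range. Cladogenesis enumerates ordered
daughter pairs — sympatric duplication, subset sympatry, single-area
vicariance — with equal weights, plus founder-event jumps with weight j
(j = 0 is plain DEC); probabilities are the normalized weights, verified
against a brute-force enumeration oracle. The likelihood is Felsenstein
pruning with expm(Q·t) branch transitions and a flat prior over non-null root
states (a range-size-weighted alternative is provided). ML fitting uses
multi-start Nelder–Mead on log rates; AIC uses k = 2 (DEC) or 3 (DEC+J). No
maximum range size is imposed by default — A ≤ 7 keeps at most 127 observable
states, which dense matrix exponentials handle comfortably.

Stochastic mapping samples the root state from prior × conditional
likelihood, cladogenetic events and branch endpoint states from their
conditional distributions, and branch histories conditional on endpoints by
rejection sampling (50 retries) with an exact uniformization fallback. A
dispersal gain of area b by range r credits 1/|r| to every (a∈r)→b cell —
a symmetric attribution that sums to one event per gain; cladogenetic jumps
are credited the same way.

The forward simulator shares the anagenetic rates and cladogenetic weights
with the likelihood and logs every dispersal event. In the recovery
experiment the forward root range is drawn from the same flat prior the
mapping assumes: with a mismatched (fixed) root, reverse-dispersal cells are
systematically over-mapped, which is a prior artifact rather than a sampler
error. Under matched priors, mean mapped counts agree with forward truth
within ±30% on all well-populated cells (≥5 events summed over 20 datasets
of 16 tips, 3 areas, d = 0.25, e = 0.02, 50 maps each).

## Synthetic data and the packaged fixture

Every generator is a pure function of a `ScenarioConfig` and a single seed,
expanded into fixed per-generator substreams
(`SeedSequence(seed, spawn_key=(stream,))`) so adding a generator never
perturbs existing outputs. Ground truths (trait coefficients, true centroids,
dispersal event logs, planted supports and divergences) are returned — and
written as JSON sidecars — so recovery tests never read simulator internals.

Defaults describe the emulated system: 17 species, crown age 5.6 (time units
treated as Myr), birth 0.4 / death 0.02 per Myr (E[N] ≈ 17 at the crown age);
elevation Brownian with rate 2.5×10⁵ m²/Myr from a 2000 m root, clamped to
[0, 3900] m (clamping, not reflection — the boundary values are biologically
meaningful); temperature = 24 °C − 5.5 °C/km lapse + 1 °C noise;
log-precipitation Brownian around 500 mm/yr; ten quantitative traits with
per-SD environmental slopes (compact growth at elevation: negative slopes)
plus Brownian deviations, and two ordinal (0/1/2) traits from thresholded
latent Brownian characters; occurrence centroids drift from (−21.9°, −64.8°)
at (2.0, 1.0) deg²/Myr with 30 records per species at 0.3° dispersion; seven
habitat areas with DEC rates d = 0.25, e = 0.02 per Myr. Locus generation
plants per-node supports (a strong/weak two-class mixture) and mutates exactly
round(target·L) sites of an ungapped reference, so realized p-distance is
within 0.5/L of target; sequences are a two-taxon JC-style pair only, since
the divergence screen is pairwise — no tree-wide sequence evolution is
attempted.

The packaged 17-tip fixture is a synthetic stand-in: its six-clade structure
(clade F = brevispicata + meziana + seramisiana sister to the rest, then E,
then D), crown age, and elevation gradient follow the published qualitative
description of the system, but branch lengths and all attached data are
simulated. Passing tests demonstrate internal statistical consistency of the
pipeline under its assumed models (Brownian traits, MSC gene trees, DEC
ranges) — they do not validate the models against real data, and real
datasets bring missingness, sampling bias, and model misspecification that
the generators deliberately omit.

## Numerical choices

Ultrametricity tolerance 1e−6 (relative); PMM mixing proportion optimized by
bounded Brent with boundary candidates checked explicitly; singular
phylogenetic covariances (zero-length branches) raise with jitter advice
rather than being silently regularized; expm results cached per branch
length; DEC optimization runs 3 seeded Nelder–Mead starts on log-rates;
stochastic-map rejection budget 50 before the uniformization fallback
(truncated at 500 uniformized jumps, mass ≥ 0.9999). Problem sizes in the
test-suite experiments (50 000 coalescent replicates for closed-form checks,
100 × 2000 trees for γ recovery, 500 mixed-model simulations, 20 × 50
stochastic maps) were chosen to give the comparisons 3-SE resolution at
desk scale.

## Known limitations

Network simulation assumes reticulations are sparse enough that lineage
jumps are independent; no continuous-migration model. The NP random effect
is only meaningful with replicate observations per species. DEC omits
time-stratified dispersal matrices and DIVA/BAYAREA-like cladogenesis
families. The γ estimator is a simulation-matching heuristic, not a
pseudolikelihood network-inference engine, and inherits grid resolution
(±1 grid step) into its precision.
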