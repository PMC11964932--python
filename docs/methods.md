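# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package, in the order the pipeline runs them.

## Network data model

A metabolic network is a list of compartment-tagged metabolites and
reactions with signed stoichiometry, flux bounds (mmol·period⁻¹ on a
consistent scale within a model), a flat gene-association set, a subsystem
label and a provenance tag (`colon`, `liver`, `brain`, `microbiome`,
`exchange`, `diet`). Gene associations are membership sets, not boolean
GPR trees: every downstream use maps genes to the reactions they are
associated with, which needs only membership. Default bounds where a
source states none are ±1000 (reversible) or [0, 1000] — the conventional
genome-scale convention.

Three dialects are supported. The TSV dialect (three hand-editable files:
metabolites, reactions with `met:coef;…` stoichiometry and `g1|g2` genes,
and a small JSON sidecar for the objective and maps) exists for fixtures;
JSON is the pipeline's working format; SBML Level 3 + FBC goes through
cobra. Floats are serialized with `repr`, so load∘save round-trips are
bit-exact.

**Microbiome merging.** Per-species models are pooled into one reaction
space. Reaction identity for deduplication is exact stoichiometry after
normalizing coefficients by the gcd of their absolute values (computed on
rationals), so scaled duplicates collapse. Orientation is part of the
identity: two species contributing the same chemistry written in opposite
directions are kept as separate reactions, because silently flipping one
species' bounds could change its feasible directions. When duplicates
disagree only on bounds, the widest bounds are kept and the conflict
logged. A species→reaction membership map is retained and also serves as
the reaction-contribution matrix for metagenome abundances.

**Exchange splitting.** Reversible exchange/diet reactions are split into
irreversible forward (`[0, ub]`) and backward (`[0, −lb]`, negated
stoichiometry) twins with a recorded pairing map. All variability analyses
block the opposing twin when scoring a direction, so a futile
import/export cycle can never masquerade as usable flux range.

## LP engine

All programs run through scipy's HiGHS. Feasibility tolerance is 1e-9 and
the activity / energy-cycle threshold 1e-6, standard for double-precision
genome-scale LP. FVA is implemented as sequential per-reaction LPs; the
contract is per-reaction independence, so execution order is free.
`fraction_of_optimum = 0` imposes no objective constraint — the
metaorganism analyses run without growth optimization because adult tissue
replicates negligibly. Flux minimization uses the split-variable
formulation (`v = p − q`, `p, q ≥ 0`) solved with the dual simplex so the
returned solution is basic (a vertex), which is what the EFM sampler needs.

Energy-generating cycles are detected by closing every single-metabolite
inflow (uptake and diet) and maximizing each ATP-dissipation reaction; an
optimum above 1e-6 is a cycle, and the reported support is that of a
flux-minimized witness at the fixed dissipation flux (the witness choice
is this package's own definition; alternatives would report supersets).

## Synthetic study

The generators emulate a five-group aging cohort — ages {2, 9, 15, 24, 30}
months with 10/10/10/10/12 animals — and fix all structural ground truth:

- **Organs** are 15–40-reaction, flux-consistent networks with glucose /
  oxygen / amino-acid uptake, glycolysis, respiration, lactate
  fermentation, protein synthesis and ATP maintenance; the liver adds bile
  acid synthesis, the brain sphingolipid synthesis, and the colon a
  six-step butyrate oxidation chain whose genes are the planted
  aging-repressed module. Butyrate is deliberately absent from the diet,
  making colonic butyrate uptake the planted microbiome-dependent exchange
  and dietary glucose the planted host-autonomous control.
- **Bacteria** realize ecological strategies: a fermenter/donor grows on
  glucose and obligatorily secretes butyrate, a recipient grows only on
  the byproduct, a competitor consumes glucose silently, an independent
  uses a private substrate, an exploiter needs both glucose and the
  byproduct; `requires`/`secretes` knobs build reciprocal (mutualistic)
  pairs. Six constructed pairs realize the six interaction types.
- **Expression** is negative-binomial with dispersion 0.2 and log-normal
  baseline means; planted genes change by 2^(±effect·age/10), i.e. the
  effect size is a log2 fold change per 10 months (default 1). Batches add
  a multiplicative log-normal factor (σ = 0.3). **Abundances** are
  log-normal with the same age-trend parameterization, normalized to sum
  one per sample.
- **Diet**: glucose 10 mmol/day (50% absorbed), amino acids 5 (80%),
  oxygen 40 (blood), fibre 8 (0% — all to the lumen), on a 3.5 g/day food
  basis.

What the generators do *not* emulate: taxonomic realism, sequencing noise,
gene-length variation within the simulated counts, compositional
covariance between taxa, and genome-scale network size. Passing tests
therefore demonstrate algorithmic correctness and statistical calibration
at toy scale, not biological generalization.

## Metamodel assembly

Organ copies are prefixed `<organ>__`; lumen/blood pool metabolites are
unprefixed `<met>_<env>`. Each boundary exchange becomes explicit
irreversible secretion (`…__sec`, organ→pool) and uptake (`…__upt`) links,
paired for opposing-direction blocking. The colon touches lumen and blood,
liver and brain blood only, the microbiome lumen only. Brain uptake links
are only created for whitelist metabolites; bloodstream directionality is
encoded as per-link irreversibility (a layout option can restrict an organ
to uptake-only or secretion-only), not as a quantitative transport model.
Each pool metabolite gets a closed dietary inflow — opened by the diet
step to `mmol/day·absorbed` (blood) and `mmol/day·(1−absorbed)` (lumen),
an exact conservation identity — and an open outflow (faecal/urinary
loss; these outflows also serve as the blood-outflow core reactions that
stand in for the unmodelled kidney).

Energy-cycle resolution iterates detection→correction: within a cycle's
witness support, the reversible non-boundary reaction with the largest ATP
gain in its witness direction is made irreversible against that direction.
The rule is logged and overridable; residual cycles after `max_iter` raise.

## Context extraction

Expression preprocessing: FPKM, removal of genes with any zero-count
sample or mean FPKM < 0.1, log2; an externally batch-corrected matrix can
be substituted via a hook (batch correction itself is out of scope).

Core derivation clusters rows by the chi-square distance between their
log-value histograms (shared bin grid over the pooled range, bin count
2·(⌈log2(#samples·#groups)⌉+1)), complete linkage, cut at k clusters
(defaults: 39 for expression, 15 for reaction abundances; a Jaccard
stability search over a k grid with tolerance 0.05 is provided). Each
cluster's activity threshold is its 25th percentile across samples; the
bin scheme and percentile are declared defaults of this package, exposed
in the API. A row active in a sample contributes its mapped reactions to
that sample's core set. Thresholds are monotone: lowering one never
shrinks a core set.

FASTCC is implemented as an exact variability sweep — a reaction is kept
iff it can carry |flux| ≥ ε (default 1e-4) — which at this package's
scale is affordable and exactly characterizes the maximal consistent
subnetwork. FASTCORE follows the published LP7/LP10 alternation with
bound flipping for reversible cores; non-activatable core reactions are
returned in an excluded list rather than failing. Because the greedy
alternation can strand redundant reactions, extraction optionally
post-processes the result: a redundancy prune (drop any non-core reaction
whose removal keeps the subnetwork consistent) and, for networks of ≤ 16
reactions, an exact minimum-cardinality search via a small mixed-integer
program (one steady-state vector per core reaction, big-M selection
binaries on non-core reactions, orientation binaries for reversible
cores). The MILP is exact but exponential in the worst case, so it is
gated to toy scale; cohort-scale extraction uses plain FASTCORE, whose
output is near-minimal.

## Dependency analysis

FVA over all host organ↔environment links, without growth optimization,
opposing twins blocked; repeated with **all** microbiome reactions blocked
jointly. A link with positive full range is dependent when the blocked
range falls below 10% of it; zero-range links are labelled independent
(undefined ratio) and logged. The joint reading of "blocking microbiome
reactions" was chosen over one-at-a-time blocking (which remains available
as an option) because the dependency criterion is phrased against the
microbiome as a whole. Per metabolite and organ, dependent uptakes and
secretions are counted across samples; |net| strictly above the threshold
(20% of the cohort, i.e. 10 of 52; ⌈0.2·n⌉ otherwise) assigns
microbiota→host or host→microbiota. Display filtering (net ≥ 35 colon,
≥ 12 brain/liver) is a separate plotting threshold.

## EFM sampling and modules

Modes through an indicator are sampled by fixing its flux to 1 (scale-free
for support identification; capped at the indicator's maximum when that is
smaller), minimizing a randomly re-weighted L1 norm (weights uniform on
[0.5, 1.5]), and taking the support of the basic optimum. Elementarity is
verified exactly: the nullspace of S restricted to the support must be
one-dimensional, nonzero on the support, and sign-compatible with
irreversibilities. Non-elementary supports are repaired by re-minimizing
within their own support with fresh weights; a repeating non-elementary
support is discarded. Supports are deduplicated as frozen reaction-id
sets, so the sampling target counts distinct modes; stopping is at 10,000
distinct modes, a draw cap, or a 200 s wall-clock budget per indicator.
Results are independent of any parallel execution order because each
indicator is seeded separately.

Frequencies are per-animal fractions of an indicator's modes containing
each reaction, averaged over animals that sampled the indicator. Modules
are the reactions at frequency ≥ 0.2 per indicator (host and microbiome
members both count); ≥ 20 microbial members marks microbiome dependence.
Aging regulation is a one-sided Fisher test per module and direction
against the tissue-wide reaction background, flagged at P ≤ 0.01; for the
synthetic cohorts the aging gene sets themselves come from a Spearman/BH
screen of expression against age (externally derived sets can be supplied
instead). Subsystem-pair enrichment tests each (host subsystem, microbiome
subsystem) pair's ≥ 0.5-frequency interactions against the matrix-wide
rate, BH-corrected.

## Community ecology

Community FBA uses balanced-growth coupling, `v_bio,i = aᵢ·μ` with
abundances normalized to one, a shared diet-bounded pool, and a subsequent
flux minimization at the fixed optimum for species fluxes and reaction
activities. Growth is monotone in every diet bound, and the coupled μ is
bounded by the sum of individual growths.

Pairwise classification compares each species' single growth (alone on
the full environment) with its co-growth. Co-growth is the max-min fair
point of the joint model: first maximize the smaller growth rate m, then
each species' rate is its maximum given the partner keeps ≥ m. This
formulation was chosen after the natural alternative — equal-abundance
balanced coupling — provably cannot express competition (halving each
population halves its demand, so a shared resource never binds), and
selfish single-species optimization never expresses it either (the
partner simply abstains). Max-min reproduces all six canonical sign
patterns on the constructed pairs. Relative growth changes use a 1e-6
relative tolerance with a 1e-9 floor for non-growers; asymmetric types are
reported beneficiary-first (unaffected-first for amensalism). Pipeline
communities include the species at ≥ 5% relative abundance in a sample,
so compositional age trends translate into interaction-frequency trends.

## Association statistics

Partial Spearman: rank-transform rows, residualize the ranks on the
(ranked) covariates plus intercept by least squares, Pearson on the
residuals, t-distributed p with df = n − 2 − #covariates. With no
covariates this reduces to plain Spearman to machine precision. The
default pair filter is BH FDR ≤ 0.1 and |ρ| ≥ 0.55, stratified by sign;
covariates are age always and batch where a tissue's design has one.
Hypergeometric enrichment uses the upper-tail `P[X ≥ k]` ("observed − 1")
convention, reports terms with ≥ 3 overlapping features at FDR ≤ 0.05, and
signed summaries are −log10(FDR) (capped at 300), negated for negative
strata, summed within provided grouping tables. Age-group ratio
comparisons use Yates-corrected chi-squared on consecutive groups with
Bonferroni correction.

## Numerical and degenerate-input choices

Solver jitter on degenerate FVA ranges (vmin marginally above vmax) is
midpoint-collapsed. Constant rows are excluded from correlation and
regression with a log entry; zero-FDR values are capped before logs;
empty correlation inputs yield empty, well-typed frames. Cluster
singletons fall back to the global median threshold. EFM sampling of a
blocked indicator returns an empty sample with a warning rather than
failing.

## Benchmarks and problem sizes

`metaorg.benchmarks` (driven by `scripts/acceptance.py` and the test
suite) validates against independent oracles: exhaustive polytope-vertex
enumeration (50 random ≤ 8-reaction networks), exhaustive minimal
consistent-superset search (10 random toys), complete brute-force EFM
enumeration (two fixtures, ≤ 500 draws), the six constructed species
pairs over three seeds, planted dependency recovery over 10 samples,
aging-module recovery over 50 simulation replicates at n = 50 samples
with 1 log2FC/10 months (plus 50 null replicates), exact combinatorial
checks of the statistics with 1000 label permutations for type-I
calibration, and the conservation identities. These sizes were chosen so
each benchmark is exhaustive or well-powered while the whole battery
completes in well under a minute each.

## Known limitations

- Toy-scale networks: no thermodynamics, no GPR logic, no metabolite
  mass/charge balancing, coarse stoichiometry.
- The bloodstream layout approximates directional transport as per-link
  irreversibility; there is no quantitative inter-organ transport model.
- FASTCC-by-FVA and the exact MILP extraction do not scale to
  genome-sized networks; at that scale the published approximate
  algorithms are the intended path.
- The community-FBA coupling and the pairwise max-min co-growth are this
  package's declared formulations of under-specified published
  procedures; alternatives (e.g. joint-sum co-growth) would change
  borderline classifications.
- Aging gene sets derived by rank correlation stand in for a full
  differential-expression pipeline; real cohorts should supply externally
  derived sets.
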