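# Methods

## Validity semantics

A covariate set C suffices to control confounding of the effect of exposure
A on outcome Y when the counterfactual outcomes are independent of the
exposure within strata of C (Y_a ⊥ A | C), in which case
E[Y₁ − Y₀ | c] = E[Y | A=1, c] − E[Y | A=0, c].  That counterfactual
condition is not graphically checkable as stated, so the toolkit adopts
Pearl's backdoor criterion as its operational validity test: S is valid iff
(i) no member of S is a descendant of A and (ii) S blocks every backdoor
path from A to Y.  The more permissive generalized adjustment criterion is
deliberately out of scope: all selection criteria here restrict candidates
to pre-exposure (non-descendant) covariates, a regime in which the two
criteria coincide.

d-separation is decided by moralized-ancestral-graph reachability: restrict
to the ancestors of {x, y} ∪ Z, moralize (marry co-parents, drop
directions), delete Z, and test connectivity.  This formulation was chosen
for transparency; the test suite checks it exhaustively against two
independent routes — a from-scratch path-enumeration blocker and
`networkx.is_d_separator` — over every labelled DAG on up to 4 nodes and
over large seeded samples of 5–6-node DAGs (all node pairs × all
conditioning sets).  Full enumeration of labelled DAGs beyond 4 nodes
(≈3.8 M at 6 nodes) is not attempted; the sampled check is the package's
own reading of "exhaustive at small size".

Open backdoor paths reported in verdicts come from explicit trail
enumeration, which doubles as the engine of `all_valid_subsets` (capped at
12 measured covariates = 4096 subsets; the cap is configurable and
enforced with an error, not a truncation).

## Selection criteria

* **Pretreatment**: all measured non-descendants of A (or, with wave
  indices, all covariates from waves before the exposure wave).  Fails on
  the M-structure: the collider L is pre-exposure yet adjusting for it
  opens A–U1–L–U2–Y.
* **Common cause**: covariates causing both A and Y.  Safe but
  conservative; on the structure U→A, U→C, C→Y it refuses C although
  adjusting for C is exactly what removes the bias.
* **Disjunctive cause**: pre-exposure covariates causing A or Y or both.
  Its sufficiency property — if any valid measured subset exists, the
  disjunctive set is valid — is asserted as a property test and as an
  acceptance rate over 1000 random pre-exposure diagrams (100 % required).
  The property presumes candidates are non-descendants of A; the random-DAG
  generator enforces that regime by topological placement.
* **Modified disjunctive cause**: the disjunctive set minus known
  instruments plus proxies of unmeasured common causes.  Both modifications
  require explicit annotation flags and are never inferred from a diagram:
  "known to be an instrument" and "proxy of a common cause" are claims
  about latent structure that measured-variable data cannot certify.

**Unknown causal status** ("don't know whether it causes A or Y") is
included by default under the disjunctive criterion — the criterion's whole
point is robustness under partial knowledge, and a covariate that might be
a cause belongs in the safe set.  `unknown_policy="exclude"` is available
for sensitivity analysis.  The common-cause criterion, by contrast, demands
positive knowledge of both links.

**Timing filter**: with multi-wave data, only covariates from the wave
immediately before the exposure wave are kept by default (`max_lag=1`;
`max_lag=None` keeps all strictly earlier waves).  Same-wave covariates are
dropped with a machine-readable `possible_mediator` warning: measured
simultaneously with the exposure, confounding and mediation cannot be
distinguished.  A prior-wave measurement of the exposure itself is kept
when present.

## Linear-SEM bias algebra

Every node is a linear function of its parents plus independent Gaussian
noise; Σ = (I−B)⁻¹ Ω (I−B)⁻ᵀ.  The true total effect is entry
(Y, A) of (I−B)⁻¹ (the path-product sum); the adjusted coefficient for set
S solves the normal equations on the {A} ∪ S submatrix of Σ.  All headline
quantities are computed from Σ exactly — sampling exists only for
Monte-Carlo cross-validation (3-standard-error bands) and to feed the
data-driven selectors.  Bias is signed as estimated minus true; "zero bias
for valid sets" is asserted at 1e−10 (1e−8 across random SEMs, where
condition numbers vary).  An ill-conditioned regressor submatrix raises
with the condition number rather than returning garbage (guard at 1e12).

Canonical all-ones parameterizations give hand-checkable anchors:
M-structure coef(∅)=1, coef({L})=0.8; latent-confounder-with-measured-child
structure coef(∅)=1.5, coef({C})=1.0; instrument structure bias(∅)=1/3,
bias({Z})=1/2, amplification (a²+b²+σ_A²)/(b²+σ_A²)=3/2; proxy structure
bias(∅)=1/2, bias({C1})=1/3.  Directionality — |bias({Z})|>|bias(∅)| and
|bias({C1})|<|bias(∅)| — is asserted over 500 random parameterizations with
coefficient magnitudes in [0.3, 1.5] (random sign, unit variances).  The
proxy result is a property of the linear-Gaussian family; proxy adjustment
is *not* guaranteed to reduce bias in general (e.g. differential or
coarsened proxies), which is documented here rather than asserted, and no
counterexample structure is shipped.

The non-collapsibility computation is a separate closed-form logistic
calculation, not a nonlinear SEM: with randomized A and binary C,
conditional OR = exp(β_A) and the marginal OR mixes stratum risks over C.
For β_A, β_C ≠ 0 the marginal OR lies strictly between 1 and the
conditional OR, verified over a parameter grid.

## Data-driven selectors

Backward and forward selection judge "covariate ⟂ outcome | exposure ∪
current set" through a pluggable backend: a Fisher-z partial-correlation
test (default α = 0.05, adequate for the Gaussian data the SEM sampler
produces) or a population d-separation oracle.  The oracle backend realizes
the faithful regime exactly, which isolates the procedures' structural
properties from test error: under it, both procedures provably preserve
sufficiency of the full candidate set, asserted at 100 % over 500+ random
diagrams whose full measured set is valid.  Greedy loops process candidates
in input order and act on the first eligible one, so results are
deterministic and order-dependent by design.  At fixed α the sample-mode
selection agrees with the oracle with frequency approaching 1−α, not 1 (an
α-sized false-retention rate never vanishes); the large-n consistency check
therefore runs at α = 0.01 and asserts ≥95 % agreement over 200 replicates
at n = 10⁵.

Change-in-estimate retains a covariate iff the relative change in the
exposure coefficient, |(β_with − β_without)/β_without|, strictly exceeds
the threshold (default 0.10), with β_without computed excluding only the
covariate under test.  On the odds-ratio scale the procedure is computed
but tagged with a non-collapsibility warning, and the suite demonstrates
the failure: in a simulated randomized trial the OR-scale rule flags the
(non-confounding) prognostic covariate while the risk-difference scale does
not.

HDPS prioritization scores each binary covariate by the Bross-type
multiplier (p₁(RR−1)+1)/(p₀(RR−1)+1), built from its prevalence among
exposed (p₁) and unexposed (p₀) and its risk ratio with the outcome, ranks
by |log score|, and selects the top fraction (default 10 %) plus any
forced-in covariates.  Zero cells get a 0.5 continuity correction and are
flagged.  The exact transform behind published HDPS implementations is not
uniquely pinned down in the literature this mirrors; the Bross reading is
this package's documented interpretation.  Unlike backward/forward
selection, the ranking is one-covariate-at-a-time and carries no
sufficiency guarantee.

Split-sample estimation selects on a seeded random half and fits OLS on
the other half; the conventional standard error is then valid because
selection and estimation are independent.  All non-split procedures attach
a machine-readable `post_selection_inference` warning; no post-selection
correction is implemented.

## Synthetic instances

Random diagrams draw a random topological order with latents and measured
covariates placed before A and Y last, so measured covariates are
pre-exposure by construction — the regime every criterion here assumes.
Edges appear independently with probability p (default 0.3, spanning sparse
to moderately dense epidemiological diagrams); default sizes (≤6 measured,
≤3 latent) keep exhaustive subset enumeration cheap.  Random SEM
coefficients have magnitude uniform in [0.3, 1.5] with random sign and unit
variances: bounded away from zero so that exact cancellations (unfaithful
parameterizations) are measure-zero, a guard spot-checked by verifying that
zero population partial correlation coincides with d-separation across 100
random instances at 1e−8.

These generators exercise structural properties; they do not mimic real
covariate data (no nonlinearity, no non-Gaussian noise, no measurement
error beyond the explicit proxy structure, no missingness, no realistic
graph topologies).  Passing tests therefore certify the algebra and the
procedures' structural guarantees, not performance on any particular
applied dataset.

## Problem sizes and numerical choices

The test and acceptance workloads use: exhaustive d-separation checks on
all labelled 4-node DAGs plus 250 sampled 5–6-node DAGs; 1000 diagrams for
the disjunctive sufficiency rate; 500 for the greedy-selection sufficiency
rates and for each bias-direction rate; n = 10⁵ rows for Monte-Carlo
cross-checks (3-SE bands) and the randomized-trial demonstration.  Exact
assertions use 1e−10; cross-SEM zero-bias checks 1e−8.  Tie-breaking is
lexicographic everywhere (path lists, subset enumeration, rationale
ordering) so all outputs are deterministic given a seed.

## Known limitations

No identification machinery beyond covariate adjustment (no front-door, no
instrumental-variable estimation — instruments appear only as variables to
exclude); no cyclic or chain graphs; no latent-variable *learning* of
causal status; no nonlinear or non-Gaussian SEM engine; no hazard-ratio
analogue of the non-collapsibility computation; no survival outcomes; no
post-selection inference corrections beyond the split-sample design.
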