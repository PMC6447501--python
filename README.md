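# confsel

A toolkit for **principled confounder selection** in observational studies.
Given an exposure A, an outcome Y and a pool of candidate covariates, which
ones should go into the adjustment set?  `confsel` answers that question at
three levels of available knowledge, and quantifies what goes wrong when the
answer is wrong:

1. **Full causal diagram known** — d-separation and Pearl's backdoor
   criterion decide validity exactly: a covariate set S is sufficient iff no
   member of S is a descendant of A and every backdoor path (a path from A
   to Y starting with an edge into A) is blocked given S.
2. **Only per-covariate knowledge** ("is it a cause of A? of Y?") — the
   pretreatment, common-cause and disjunctive-cause criteria, and the
   **modified disjunctive cause criterion**: select every pre-exposure
   covariate that causes the exposure or the outcome or both, *exclude*
   covariates known to be instruments, *include* measured proxies of
   unmeasured common causes.  The disjunctive set has the key property that
   whenever *any* subset of the measured covariates suffices to control
   confounding, the disjunctive set suffices too.
3. **Data only** — backward/forward selection on conditional independence,
   the 10 % change-in-estimate rule, split-sample estimation, and
   HDPS-style one-at-a-time bias prioritization, each with its documented
   failure modes.

The quantitative engine is a linear-Gaussian structural equation model over
the diagram: with edge coefficients B and exogenous variances Ω the implied
covariance is Σ = (I−B)⁻¹ Ω (I−B)⁻ᵀ, from which the population regression
coefficient of A for any adjustment set — and hence its confounding bias —
is computed in closed form.  The canonical pathologies are built in as named
structures: collider adjustment (M-bias), bias amplification by adjusting
for an instrument (Z-bias), partial bias removal by a proxy confounder, and
odds-ratio non-collapsibility.

## Worked example

The M-bias structure: latent U1 causes A and a measured covariate L; latent
U2 causes L and Y; A→Y with unit effect.  L is pre-exposure, so the
pretreatment criterion selects it — and adjusting for it *creates* bias:

```text
$ confsel demo mbias
[bias_report]
true_effect: 1
sets:
  - members=[], coefficient=1, bias=0, backdoor_valid=True
  - members=[L], coefficient=0.8, bias=-0.2, backdoor_valid=False
amplification: None
reduction: None
```

Unadjusted, the regression of Y on A recovers the true effect 1 exactly;
adjusting for the collider L opens the path A–U1–L–U2–Y and drags the
coefficient to 0.8 (bias −0.2).  The disjunctive cause criterion leaves L
out, because L causes neither A nor Y.

The modified disjunctive cause criterion on an annotation table
(a pharmacoepidemiology-flavoured example):

```text
$ confsel select --criterion modified_disjunctive --annotations ann.csv
[selection_result]
criterion: modified_disjunctive
selected:
  - ses_proxy
  - smoking
excluded_instruments:
  - prescriber_pref
included_proxies:
  - ses_proxy
```

`smoking` (a cause of exposure and outcome) is selected; `prescriber_pref`
is a known instrument and is excluded — adjusting for it would amplify any
residual unmeasured confounding (at the all-ones parameterization of the
instrument structure, bias grows from 1/3 to 1/2, a factor of 1.5); the
socioeconomic-status proxy is pulled in because it absorbs part of the bias
from the unmeasured common cause it measures (1/2 → 1/3 at unit parameters).

Non-collapsibility, the reason change-in-estimate selection cannot be
trusted on the odds-ratio scale:

```text
$ confsel demo collapsibility
conditional OR: 2.7183
marginal OR: 2.2300
the marginal OR is attenuated toward 1 with no confounding present
```

With a randomized exposure and a prognostic binary covariate
(logit P(Y=1) = −1 + A + 2C, P(C=1) = ½), the covariate-conditional odds
ratio is e ≈ 2.72 while the marginal odds ratio is 2.23: a >10 % "change in
estimate" with no confounding whatsoever.

Other entry points: `confsel check --dag FILE --set C1,C2` (backdoor verdict
with open paths), `confsel sets --dag FILE --minimal` (enumerate valid
sets), `confsel statselect --method backward|forward|cie|hdps|split` (data
driven selection), `confsel gen` (canned or random diagrams, SEM specs and
sampled datasets).  The same operations are available as a Python API
(`confsel.is_valid_adjustment_set`, `confsel.disjunctive_cause_criterion`,
`confsel.bias_report`, …).

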