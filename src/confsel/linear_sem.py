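"""Exact bias algebra for adjustment sets under linear-Gaussian SEMs.

Each node V equals a linear combination of its parents plus independent
Gaussian noise: V = Σ_p B[V,p]·p + ε_V, ε_V ~ N(0, ω_V).  Collecting the
edge coefficients in B and the noise variances in the diagonal Ω, the
implied covariance of the joint distribution is

    Σ = (I − B)⁻¹ Ω (I − B)⁻ᵀ

All population quantities — the true total effect of the exposure, the
coefficient of the exposure in a least-squares regression of the outcome on
{exposure} ∪ S, and hence the confounding bias of any adjustment set S — are
computed exactly from Σ, never by sampling.  Sampling exists only for
Monte-Carlo cross-validation and to feed the data-driven selectors.

A closed-form logistic computation demonstrates odds-ratio
non-collapsibility: with a randomized exposure and a prognostic binary
covariate, the covariate-conditional OR exp(β_A) and the marginal OR
(obtained by mixing stratum risks over the covariate) genuinely differ,
even though there is no confounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from .dag_core import CausalDAG, is_valid_adjustment_set

__all__ = [
    "LinearSEM",
    "BiasReport",
    "SetBias",
    "implied_covariance",
    "true_total_effect",
    "adjusted_coefficient",
    "bias_report",
    "sample_dataset",
    "noncollapsibility_demo",
]

_COND_LIMIT = 1e12  # condition-number guard for the normal equations


@dataclass(frozen=True)
class LinearSEM:
    """A CausalDAG equipped with edge coefficients and exogenous variances.

    ``coefficients`` must cover exactly the DAG's edges; ``variances`` must
    be positive for every node.  Intercepts are fixed at zero — they shift
    means, which none of the covariance-based quantities depend on.
    """

    dag: CausalDAG
    coefficients: Mapping[Tuple[str, str], float]
    variances: Mapping[str, float]

    def __post_init__(self):
        got, want = set(self.coefficients), set(self.dag.edges)
        if got != want:
            raise ValueError(
                f"coefficients must cover exactly the DAG edges; "
                f"missing={sorted(want - got)}, extra={sorted(got - want)}"
            )
        if set(self.variances) != set(self.dag.nodes):
            raise ValueError("variances must cover exactly the DAG nodes")
        bad = [v for v, w in self.variances.items() if not w > 0]
        if bad:
            raise ValueError(f"exogenous variances must be positive: {sorted(bad)}")

    @property
    def node_order(self) -> list[str]:
        return sorted(self.dag.nodes)

    def matrices(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(B, Ω, node order) with B[head, tail] = edge coefficient."""
        order = self.node_order
        idx = {v: i for i, v in enumerate(order)}
        n = len(order)
        B = np.zeros((n, n))
        for (tail, head), c in self.coefficients.items():
            B[idx[head], idx[tail]] = c
        omega = np.diag([self.variances[v] for v in order])
        return B, omega, order

    @classmethod
    def with_unit_parameters(cls, dag: CausalDAG, coefficient: float = 1.0) -> "LinearSEM":
        """All edge coefficients equal (default 1), unit variances."""
        return cls(
            dag=dag,
            coefficients={e: coefficient for e in dag.edges},
            variances={v: 1.0 for v in dag.nodes},
        )


@dataclass(frozen=True)
class SetBias:
    """Bias diagnostics for one adjustment set."""

    members: FrozenSet[str]
    coefficient: float
    bias: float  # estimated minus true
    backdoor_valid: bool


@dataclass(frozen=True)
class BiasReport:
    """True effect plus per-set regression coefficients and biases.

    ``amplification`` is bias(set)/bias(∅) for sets that *increase* |bias|
    (the instrument / Z-bias phenomenon); ``reduction`` is the same ratio
    for sets that shrink it (proxy adjustment).  Ratios are only defined
    when the unadjusted analysis is itself biased.
    """

    true_effect: float
    sets: Tuple[SetBias, ...]
    amplification: Optional[float] = None
    reduction: Optional[float] = None

    def bias_of(self, members: Iterable[str]) -> float:
        key = frozenset(members)
        for s in self.sets:
            if s.members == key:
                return s.bias
        raise KeyError(f"no entry for set {sorted(key)}")


def implied_covariance(sem: LinearSEM) -> pd.DataFrame:
    """Exact covariance Σ = (I−B)⁻¹ Ω (I−B)⁻ᵀ, indexed by node name."""
    B, omega, order = sem.matrices()
    eye = np.eye(len(order))
    # (I - B) is unit lower-triangular in topological order: always invertible
    inv = np.linalg.inv(eye - B)
    sigma = inv @ omega @ inv.T
    sigma = (sigma + sigma.T) / 2.0
    assert np.all(np.linalg.eigvalsh(sigma) > 0), "implied covariance not PD"
    return pd.DataFrame(sigma, index=order, columns=order)


def true_total_effect(sem: LinearSEM) -> float:
    """Total causal effect of exposure on outcome.

    Equals the sum over directed exposure→…→outcome paths of the products of
    edge coefficients, i.e. entry (outcome, exposure) of (I−B)⁻¹.
    """
    B, _, order = sem.matrices()
    inv = np.linalg.inv(np.eye(len(order)) - B)
    i, j = order.index(sem.dag.outcome), order.index(sem.dag.exposure)
    return float(inv[i, j])


def adjusted_coefficient(sem: LinearSEM, s: Iterable[str] = ()) -> float:
    """Population OLS coefficient of the exposure, adjusting for set ``s``.

    Solves the normal equations on the (exposure ∪ s) submatrix of the
    implied covariance — exact, no sampling.  Raises a numerical error when
    the submatrix is ill-conditioned.
    """
    members = sorted(set(s))
    for m in members:
        if m not in sem.dag.measured_covariates:
            raise ValueError(f"{m!r} is not a measured covariate")
    sigma = implied_covariance(sem)
    regressors = [sem.dag.exposure] + members
    gram = sigma.loc[regressors, regressors].to_numpy()
    cond = np.linalg.cond(gram)
    if cond > _COND_LIMIT:
        raise np.linalg.LinAlgError(
            f"regressor covariance ill-conditioned (cond={cond:.3g})"
        )
    rhs = sigma.loc[regressors, sem.dag.outcome].to_numpy()
    beta = np.linalg.solve(gram, rhs)
    return float(beta[0])


def bias_report(sem: LinearSEM, sets: Sequence[Iterable[str]]) -> BiasReport:
    """Per-set bias (estimated − true), in input order.

    When the unadjusted set ∅ is among the requested sets and is biased,
    ratio diagnostics are emitted: the amplification factor bias(S)/bias(∅)
    for the first set that enlarges |bias| (Z-bias) and the reduction factor
    for the first set that shrinks it (proxy adjustment).
    """
    tau = true_total_effect(sem)
    entries = []
    for raw in sets:
        members = frozenset(raw)
        coef = adjusted_coefficient(sem, members)
        verdict = is_valid_adjustment_set(sem.dag, members)
        entries.append(
            SetBias(
                members=members,
                coefficient=coef,
                bias=coef - tau,
                backdoor_valid=bool(verdict),
            )
        )
    amplification = reduction = None
    null = next((e for e in entries if not e.members), None)
    if null is not None and abs(null.bias) > 1e-12:
        for e in entries:
            if not e.members:
                continue
            ratio = e.bias / null.bias
            if abs(e.bias) > abs(null.bias) and amplification is None:
                amplification = ratio
            elif abs(e.bias) < abs(null.bias) and reduction is None:
                reduction = ratio
    return BiasReport(
        true_effect=tau,
        sets=tuple(entries),
        amplification=amplification,
        reduction=reduction,
    )


def sample_dataset(sem: LinearSEM, n: int, seed: int = 0) -> pd.DataFrame:
    """Draw ``n`` i.i.d. rows from the SEM, node-by-node in topological order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    g = sem.dag.to_networkx()
    order = list(nx.lexicographical_topological_sort(g))
    data: Dict[str, np.ndarray] = {}
    for v in order:
        col = rng.normal(0.0, np.sqrt(sem.variances[v]), size=n)
        for p in sorted(g.predecessors(v)):
            col = col + sem.coefficients[(p, v)] * data[p]
        data[v] = col
    return pd.DataFrame({v: data[v] for v in sem.node_order})


def noncollapsibility_demo(
    beta0: float, betaA: float, betaC: float, pC: float
) -> tuple[float, float]:
    """Conditional vs marginal odds ratio in a randomized design.

    Exposure A ∈ {0,1} is randomized independently of a binary covariate C
    with prevalence ``pC``; the outcome follows
    logit P(Y=1 | A, C) = β₀ + β_A·A + β_C·C.

    Returns ``(conditional OR, marginal OR)``: the conditional OR is
    exp(β_A); the marginal OR mixes the stratum-specific risks over C,

        p_a = (1−pC)·expit(β₀ + β_A·a) + pC·expit(β₀ + β_A·a + β_C),

    and forms [p₁/(1−p₁)] / [p₀/(1−p₀)].  With β_C ≠ 0 and β_A ≠ 0 the
    marginal OR is attenuated toward 1 relative to the conditional OR —
    a true change on the OR scale with no confounding present.
    """
    if not 0 <= pC <= 1:
        raise ValueError("pC must be a probability")
    conditional = float(np.exp(betaA))
    risks = []
    for a in (0, 1):
        risk = (1 - pC) * expit(beta0 + betaA * a) + pC * expit(beta0 + betaA * a + betaC)
        risks.append(float(risk))
    p0, p1 = risks
    marginal = (p1 / (1 - p1)) / (p0 / (1 - p0))
    return conditional, float(marginal)
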