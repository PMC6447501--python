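"""Generators for canonical bias structures and random test instances.

The five canned diagrams are the textbook confounding structures:

* ``fig1`` — the classic confounder triangle: measured C causes both A and Y.
* ``fig2`` — M-bias: a measured collider L between two latent causes U1
  (of A) and U2 (of Y); adjusting for L opens the path.
* ``fig3`` — a measured mediator-of-a-latent-confounder: U→A, U→C, C→Y;
  C is not a common cause yet blocks the backdoor path.
* ``fig4`` — Z-bias: an instrument Z→A alongside latent confounding U;
  adjusting for Z amplifies the residual bias.
* ``fig5`` — proxy confounding: measured C1 is a noisy child of the latent
  common cause U; adjusting for C1 partially removes the bias.

Random DAGs are drawn over a topological order with latents and measured
covariates placed before the exposure and the outcome last, so every measured
covariate is pre-exposure — the regime the selection criteria assume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dag_core import CausalDAG

__all__ = ["FIGURES", "DagGenSpec", "make_figure_dag", "random_dag", "random_sem"]


_FIGURE_SPECS = {
    "fig1": dict(
        edges=[("C", "A"), ("C", "Y"), ("A", "Y")],
        latent=[],
    ),
    "fig2": dict(
        edges=[("U1", "A"), ("U1", "L"), ("U2", "L"), ("U2", "Y"), ("A", "Y")],
        latent=["U1", "U2"],
    ),
    "fig3": dict(
        edges=[("U", "A"), ("U", "C"), ("C", "Y"), ("A", "Y")],
        latent=["U"],
    ),
    "fig4": dict(
        edges=[("Z", "A"), ("U", "A"), ("U", "Y"), ("A", "Y")],
        latent=["U"],
    ),
    "fig5": dict(
        edges=[("U", "A"), ("U", "Y"), ("U", "C1"), ("A", "Y")],
        latent=["U"],
    ),
}

FIGURES = tuple(sorted(_FIGURE_SPECS))


def make_figure_dag(which: str) -> CausalDAG:
    """Build one of the five canonical structures (``fig1`` … ``fig5``)."""
    try:
        spec = _FIGURE_SPECS[which]
    except KeyError:
        raise ValueError(f"unknown figure {which!r}; choose from {FIGURES}") from None
    nodes = {"A", "Y"} | {v for e in spec["edges"] for v in e}
    return CausalDAG(
        nodes=nodes,
        edges=spec["edges"],
        exposure="A",
        outcome="Y",
        latent=spec["latent"],
    )


@dataclass(frozen=True)
class DagGenSpec:
    """Parameters for the random-DAG generator.

    ``require_pre_exposure`` forces every measured covariate to be a
    non-descendant of the exposure (by topological placement).  Instances
    intended for exhaustive subset enumeration should keep
    ``n_measured + n_latent`` ≤ 10.
    """

    n_measured: int = 4
    n_latent: int = 2
    edge_probability: float = 0.3
    require_pre_exposure: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_measured < 0 or self.n_latent < 0:
            raise ValueError("covariate counts must be non-negative")
        if not 0 < self.edge_probability < 1:
            raise ValueError("edge_probability must lie strictly in (0, 1)")


def random_dag(spec: DagGenSpec) -> CausalDAG:
    """Draw a random acyclic diagram per ``spec``, reproducibly by seed.

    Edges are oriented along a random topological order in which latents and
    measured covariates precede the exposure and the outcome comes last; each
    forward pair receives an edge independently with ``edge_probability``
    (including the direct A→Y edge).
    """
    rng = np.random.default_rng(spec.seed)
    measured = [f"C{i}" for i in range(1, spec.n_measured + 1)]
    latent = [f"U{i}" for i in range(1, spec.n_latent + 1)]
    pre = measured + latent
    rng.shuffle(pre)
    if spec.require_pre_exposure:
        order = pre + ["A", "Y"]
    else:
        # measured covariates may land after the exposure
        order = latent + ["A"] + measured
        rng.shuffle(order)
        order.append("Y")
    edges = [
        (order[i], order[j])
        for i in range(len(order))
        for j in range(i + 1, len(order))
        if rng.random() < spec.edge_probability
    ]
    return CausalDAG(
        nodes=set(order),
        edges=edges,
        exposure="A",
        outcome="Y",
        latent=latent,
    )


def random_sem(
    dag: CausalDAG,
    coefficient_range: tuple[float, float] = (0.3, 1.5),
    seed: int = 0,
):
    """Random linear-SEM parameterization of ``dag``.

    Edge-coefficient magnitudes are drawn uniformly from
    ``coefficient_range`` with random sign; exogenous variances are 1.
    Keeping magnitudes bounded away from zero makes exact (unfaithful)
    cancellations measure-zero and numerically improbable, so population
    partial correlations track d-separation on generated instances.
    """
    from .linear_sem import LinearSEM

    lo, hi = coefficient_range
    if lo <= 0:
        raise ValueError("coefficient magnitudes must be bounded away from zero")
    rng = np.random.default_rng(seed)
    coeffs = {}
    for edge in sorted(dag.edges):
        mag = rng.uniform(lo, hi)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        coeffs[edge] = sign * mag
    variances = {v: 1.0 for v in dag.nodes}
    return LinearSEM(dag=dag, coefficients=coeffs, variances=variances)
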