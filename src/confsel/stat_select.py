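"""Data-driven covariate-selection procedures and their failure modes.

Implements the classical statistical selectors — backward and forward
selection on conditional (in)dependence with the outcome, the 10 %
change-in-estimate rule, a split-sample estimator, and HDPS-style
one-at-a-time bias prioritization — with a pluggable conditional-independence
backend:

* **sample mode** — Fisher-z partial-correlation test at level α on a
  rectangular dataset (adequate for linear-Gaussian data);
* **oracle mode** — population d-separation queries against a known DAG,
  isolating the *procedure's* properties from finite-sample test error.

The oracle backend is exactly the faithful regime: conditional independence
holds iff the diagram implies it.  Under it, backward selection started from
a sufficient candidate set always returns a sufficient set, and so does
forward selection — the guarantee evaporates once p-values make the calls.

None of the non-split procedures adjusts inference for selection; their
outputs therefore carry a machine-readable post-selection warning record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dag_core import CausalDAG, d_separated

__all__ = [
    "CITestBackend",
    "SelectionRun",
    "HdpsRow",
    "HdpsRanking",
    "InsufficientSampleError",
    "POST_SELECTION_WARNING",
    "backward_select",
    "forward_select",
    "change_in_estimate_select",
    "hdps_score",
    "hdps_rank",
    "split_sample_estimate",
]

POST_SELECTION_WARNING = (
    "post_selection_inference",
    "covariates were selected on the same data used for estimation; naive "
    "standard errors and confidence intervals after selection are not valid",
)

NONCOLLAPSIBILITY_WARNING = (
    "noncollapsibility",
    "change-in-estimate on the odds-ratio scale conflates confounding with "
    "non-collapsibility: marginal and conditional odds ratios differ even "
    "without confounding",
)


class InsufficientSampleError(ValueError):
    """Not enough rows to fit the requested model."""


@dataclass(frozen=True)
class CITestBackend:
    """Conditional-independence backend for the greedy selectors.

    Exactly one of ``data`` (sample mode: Fisher-z partial correlation at
    level ``alpha``) or ``dag`` (oracle mode: population d-separation) must
    be supplied.
    """

    data: Optional[pd.DataFrame] = None
    dag: Optional[CausalDAG] = None
    alpha: float = 0.05

    def __post_init__(self):
        if (self.data is None) == (self.dag is None):
            raise ValueError("supply exactly one of data= (sample) or dag= (oracle)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def mode(self) -> str:
        return "oracle" if self.dag is not None else "sample"

    def independent(self, x: str, y: str, given: Iterable[str]) -> bool:
        """True iff x ⟂ y | given, by the backend's lights."""
        z = sorted(set(given))
        if self.dag is not None:
            return d_separated(self.dag, x, y, z)
        return not self._fisher_z_dependent(x, y, z)

    def _fisher_z_dependent(self, x: str, y: str, z: list[str]) -> bool:
        df = self.data
        cols = [x, y] + z
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise KeyError(f"columns absent from data: {missing}")
        n = len(df)
        if n <= len(z) + 3:
            raise InsufficientSampleError(
                f"n={n} too small for a partial correlation given {len(z)} covariates"
            )
        r = _partial_correlation(df, x, y, z)
        r = min(max(r, -1 + 1e-15), 1 - 1e-15)
        zstat = 0.5 * math.log((1 + r) / (1 - r)) * math.sqrt(n - len(z) - 3)
        pval = 2 * stats.norm.sf(abs(zstat))
        return pval < self.alpha


def _partial_correlation(df: pd.DataFrame, x: str, y: str, z: list[str]) -> float:
    sub = df[[x, y] + z].to_numpy()
    cov = np.cov(sub, rowvar=False)
    cov = np.atleast_2d(cov)
    prec = np.linalg.pinv(cov)
    return float(-prec[0, 1] / math.sqrt(prec[0, 0] * prec[1, 1]))


@dataclass(frozen=True)
class SelectionRun:
    """Result of one data-driven selection procedure."""

    method: str
    selected: Tuple[str, ...]
    trace: Tuple[str, ...] = ()
    warnings: Tuple[tuple, ...] = ()


def _resolve_backend(
    source: Union[pd.DataFrame, CITestBackend, CausalDAG],
    outcome: str,
    exposure: str,
    alpha: float,
) -> CITestBackend:
    if isinstance(source, CITestBackend):
        return source
    if isinstance(source, CausalDAG):
        return CITestBackend(dag=source, alpha=alpha)
    return CITestBackend(data=source, alpha=alpha)


def _check_candidates(covariates, exposure, outcome):
    cset = set(covariates)
    if len(cset) != len(list(covariates)):
        raise ValueError("duplicate covariates in candidate list")
    if exposure in cset or outcome in cset:
        raise ValueError("candidate covariates must exclude exposure and outcome")


def backward_select(
    source: Union[pd.DataFrame, CITestBackend, CausalDAG],
    covariates: Sequence[str],
    exposure: str = "A",
    outcome: str = "Y",
    alpha: float = 0.05,
) -> SelectionRun:
    """Backward elimination on conditional independence with the outcome.

    Starts from the full candidate set and repeatedly removes the first
    covariate (input order) judged independent of the outcome given the
    exposure and the remaining covariates, until a fixed point.  If the full
    candidate set suffices to control confounding and every independence
    call is decided correctly, the surviving set suffices too.
    """
    _check_candidates(covariates, exposure, outcome)
    backend = _resolve_backend(source, outcome, exposure, alpha)
    if backend.mode == "sample" and len(backend.data) <= len(covariates) + 2:
        raise InsufficientSampleError(
            f"n={len(backend.data)} rows cannot support {len(covariates)} covariates"
        )
    current = list(covariates)
    trace = []
    changed = True
    while changed:
        changed = False
        for c in list(current):
            rest = [v for v in current if v != c]
            if backend.independent(c, outcome, [exposure] + rest):
                current.remove(c)
                trace.append(f"drop {c}: independent of {outcome} given "
                             f"{{{exposure}}} ∪ {rest}")
                changed = True
                break
    return SelectionRun(
        method="backward",
        selected=tuple(current),
        trace=tuple(trace),
        warnings=(POST_SELECTION_WARNING,),
    )


def forward_select(
    source: Union[pd.DataFrame, CITestBackend, CausalDAG],
    covariates: Sequence[str],
    exposure: str = "A",
    outcome: str = "Y",
    alpha: float = 0.05,
) -> SelectionRun:
    """Forward inclusion on conditional dependence with the outcome.

    Starts from the empty set and, at each stage, adds the first remaining
    covariate (input order) associated with the outcome given the exposure
    and the covariates already selected; stops when every remaining
    covariate tests independent.  The sufficiency guarantee additionally
    requires faithfulness — the oracle backend is exactly that regime.
    """
    _check_candidates(covariates, exposure, outcome)
    backend = _resolve_backend(source, outcome, exposure, alpha)
    if backend.mode == "sample" and len(backend.data) <= len(covariates) + 2:
        raise InsufficientSampleError(
            f"n={len(backend.data)} rows cannot support {len(covariates)} covariates"
        )
    selected: list[str] = []
    remaining = list(covariates)
    trace = []
    progress = True
    while progress:
        progress = False
        for c in remaining:
            if not backend.independent(c, outcome, [exposure] + selected):
                selected.append(c)
                remaining.remove(c)
                trace.append(f"add {c}: associated with {outcome} given "
                             f"{{{exposure}}} ∪ {selected[:-1]}")
                progress = True
                break
    return SelectionRun(
        method="forward",
        selected=tuple(selected),
        trace=tuple(trace),
        warnings=(POST_SELECTION_WARNING,),
    )


def _exposure_coefficient(
    data: pd.DataFrame, exposure: str, outcome: str, covs: Sequence[str], scale: str
) -> float:
    X = sm.add_constant(data[[exposure] + list(covs)], has_constant="add")
    if scale == "or":
        fit = sm.Logit(data[outcome], X).fit(disp=0)
    else:
        fit = sm.OLS(data[outcome], X).fit()
    return float(fit.params[exposure])


def change_in_estimate_select(
    data: pd.DataFrame,
    covariates: Sequence[str],
    exposure: str = "A",
    outcome: str = "Y",
    threshold: float = 0.10,
    scale: str = "difference",
) -> SelectionRun:
    """Retain covariates whose removal shifts the exposure coefficient > threshold.

    Backward-style loop: the drop decision compares the exposure coefficient
    with the current set against the coefficient with the covariate under
    test removed; the covariate is retained iff the relative change
    |(β_with − β_without)/β_without| strictly exceeds ``threshold``.

    ``scale="difference"`` (default) uses linear regression; ``scale="or"``
    uses logistic regression on the log-odds-ratio scale and attaches a
    non-collapsibility warning — on that scale the rule can flag a covariate
    in a perfectly randomized design.  ``threshold=math.inf`` degenerates to
    "never retain".
    """
    _check_candidates(covariates, exposure, outcome)
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    if scale not in ("difference", "or"):
        raise ValueError("scale must be 'difference' or 'or'")
    warnings = [POST_SELECTION_WARNING]
    if scale == "or":
        warnings.append(NONCOLLAPSIBILITY_WARNING)
    current = list(covariates)
    trace = []
    changed = True
    while changed:
        changed = False
        for c in list(current):
            rest = [v for v in current if v != c]
            beta_with = _exposure_coefficient(data, exposure, outcome, current, scale)
            beta_without = _exposure_coefficient(data, exposure, outcome, rest, scale)
            if beta_without == 0.0:
                rel = math.inf if beta_with != beta_without else 0.0
            else:
                rel = abs((beta_with - beta_without) / beta_without)
            if not rel > threshold:
                current.remove(c)
                trace.append(f"drop {c}: relative change {rel:.4f} <= {threshold}")
                changed = True
                break
            trace.append(f"keep {c}: relative change {rel:.4f} > {threshold}")
    return SelectionRun(
        method="change_in_estimate",
        selected=tuple(current),
        trace=tuple(trace),
        warnings=tuple(warnings),
    )


# ---------------------------------------------------------------------------
# HDPS-style one-at-a-time bias prioritization


@dataclass(frozen=True)
class HdpsRow:
    covariate: str
    p_exposed: float
    p_unexposed: float
    risk_ratio: float
    score: float  # Bross-type approximate-bias multiplier
    corrected: bool = False  # continuity correction applied


@dataclass(frozen=True)
class HdpsRanking:
    """Covariates ranked by approximate one-at-a-time confounding bias."""

    rows: Tuple[HdpsRow, ...]  # sorted by |log score| descending
    selected: Tuple[str, ...]
    fraction: float
    forced_in: Tuple[str, ...] = ()


def hdps_score(p_exposed: float, p_unexposed: float, risk_ratio: float) -> float:
    """Bross-type multiplicative bias of ignoring one binary confounder.

    score = (p₁(RR−1)+1) / (p₀(RR−1)+1), where p₁/p₀ are the covariate's
    prevalences among exposed/unexposed and RR its risk ratio with the
    outcome.  Equals 1 when the prevalences agree or when RR = 1.
    """
    if not (0 <= p_exposed <= 1 and 0 <= p_unexposed <= 1):
        raise ValueError("prevalences must lie in [0, 1]")
    if not risk_ratio > 0:
        raise ValueError("risk ratio must be positive")
    return (p_exposed * (risk_ratio - 1) + 1) / (p_unexposed * (risk_ratio - 1) + 1)


def _binary_check(series: pd.Series, name: str) -> None:
    vals = set(pd.unique(series))
    if not vals <= {0, 1}:
        raise ValueError(f"{name} must be coded 0/1; saw values {sorted(vals)[:5]}")


def hdps_rank(
    data: pd.DataFrame,
    binary_covariates: Sequence[str],
    exposure: str = "A",
    outcome: str = "Y",
    fraction: float = 0.10,
    forced_in: Sequence[str] = (),
) -> HdpsRanking:
    """Rank binary covariates by approximate bias; select the top fraction.

    For each covariate the prevalence among exposed and unexposed and the
    covariate-outcome risk ratio are estimated from the data; the Bross
    multiplier combines them and covariates are ordered by |log score|.
    ceil(fraction × #ranked) covariates are selected, plus any forced-in
    covariates (e.g. core demographics).  Zero cells in the prevalence or
    risk-ratio estimates receive a 0.5 continuity correction and are
    flagged on the affected row.
    """
    _check_candidates(binary_covariates, exposure, outcome)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    _binary_check(data[exposure], exposure)
    _binary_check(data[outcome], outcome)
    a = data[exposure].to_numpy()
    y = data[outcome].to_numpy()
    rows = []
    for c in binary_covariates:
        _binary_check(data[c], c)
        cv = data[c].to_numpy()
        corrected = False
        n1, n0 = (a == 1).sum(), (a == 0).sum()
        k1, k0 = cv[a == 1].sum(), cv[a == 0].sum()
        yc1_n, yc0_n = (cv == 1).sum(), (cv == 0).sum()
        yc1_k, yc0_k = y[cv == 1].sum(), y[cv == 0].sum()
        cells = [n1, n0, yc1_n, yc0_n]
        zeroish = (
            min(cells) == 0
            or k1 in (0, n1)
            or k0 in (0, n0)
            or yc1_k in (0, yc1_n)
            or yc0_k in (0, yc0_n)
        )
        if zeroish:
            corrected = True
            p1 = (k1 + 0.5) / (n1 + 1.0) if n1 else 0.5
            p0 = (k0 + 0.5) / (n0 + 1.0) if n0 else 0.5
            r1 = (yc1_k + 0.5) / (yc1_n + 1.0) if yc1_n else 0.5
            r0 = (yc0_k + 0.5) / (yc0_n + 1.0) if yc0_n else 0.5
        else:
            p1, p0 = k1 / n1, k0 / n0
            r1, r0 = yc1_k / yc1_n, yc0_k / yc0_n
        rr = r1 / r0
        rows.append(
            HdpsRow(
                covariate=c,
                p_exposed=float(p1),
                p_unexposed=float(p0),
                risk_ratio=float(rr),
                score=hdps_score(p1, p0, rr),
                corrected=corrected,
            )
        )
    rows.sort(key=lambda r: (-abs(math.log(r.score)), r.covariate))
    n_select = math.ceil(fraction * len(rows)) if rows else 0
    picked = [r.covariate for r in rows[:n_select]]
    for f in forced_in:
        if f not in picked:
            picked.append(f)
    return HdpsRanking(
        rows=tuple(rows),
        selected=tuple(picked),
        fraction=fraction,
        forced_in=tuple(forced_in),
    )


def split_sample_estimate(
    data: pd.DataFrame,
    selector: Callable[[pd.DataFrame], Sequence[str]],
    exposure: str = "A",
    outcome: str = "Y",
    seed: int = 0,
) -> tuple[Tuple[str, ...], float, float]:
    """Select on one random half of the data, estimate on the other.

    ``selector`` maps a DataFrame to a covariate list; the final model is an
    ordinary linear regression of the outcome on the exposure plus the
    selected covariates, fitted on the held-out half.  Because selection and
    estimation use disjoint data, the conventional standard error of the
    exposure coefficient is valid — at the price of half the sample.

    Returns (selected covariates, exposure-effect estimate, standard error).
    """
    n = len(data)
    if n < 20:
        raise InsufficientSampleError(f"split-sample needs n >= 20, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half = n // 2
    select_df = data.iloc[perm[:half]].reset_index(drop=True)
    fit_df = data.iloc[perm[half:]].reset_index(drop=True)
    selected = tuple(selector(select_df))
    if len(selected) + 2 >= len(fit_df):
        raise InsufficientSampleError(
            f"{len(selected)} selected covariates exceed the held-out half's "
            f"degrees of freedom (n={len(fit_df)})"
        )
    X = sm.add_constant(fit_df[[exposure] + list(selected)], has_constant="add")
    fit = sm.OLS(fit_df[outcome], X).fit()
    return selected, float(fit.params[exposure]), float(fit.bse[exposure])
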