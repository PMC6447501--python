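"""Confounder-selection criteria based on substantive causal knowledge.

Four criteria of increasing discrimination are provided, each usable either
on a full :class:`~confsel.dag_core.CausalDAG` (when the complete diagram is
known) or on per-covariate annotations (when only "is it a cause of the
exposure / of the outcome?" knowledge is available):

* **pretreatment** — adjust for everything measured before the exposure.
  Liberal; can adjust for a collider and *introduce* bias (M-bias).
* **common cause** — adjust only for covariates causing both exposure and
  outcome.  Conservative; can miss a covariate that would have sufficed.
* **disjunctive cause** — adjust for covariates causing the exposure *or*
  the outcome (or both).  Whenever any subset of the measured covariates
  suffices to control confounding, the disjunctive set suffices too.
* **modified disjunctive cause** — the disjunctive set, minus covariates
  known to be instruments (to avoid bias amplification), plus measured
  proxies of unmeasured common causes (to absorb part of their bias).

A wave-based timing filter supports multi-wave cohort designs where a
covariate measured contemporaneously with the exposure may be a mediator:
only covariates from a wave strictly prior to the exposure wave are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Optional, Sequence, Union

from .dag_core import CausalDAG, ancestors, descendants

__all__ = [
    "CovariateAnnotation",
    "SelectionResult",
    "AnnotationError",
    "pretreatment_criterion",
    "common_cause_criterion",
    "disjunctive_cause_criterion",
    "modified_disjunctive_criterion",
    "timing_filter",
    "annotations_from_dag",
]

THREE_VALUED = ("yes", "no", "unknown")


class AnnotationError(ValueError):
    """An annotation table is inconsistent or missing required fields."""


@dataclass(frozen=True)
class CovariateAnnotation:
    """Substantive causal knowledge about one measured covariate.

    ``causes_exposure`` / ``causes_outcome`` are three-valued ("yes" / "no" /
    "unknown") because in practice causal status is often uncertain.
    ``known_instrument`` requires positive knowledge that the covariate
    causes the exposure and is unrelated to the outcome except through it;
    ``proxy_of_common_cause`` flags a noisy measurement of an *unmeasured*
    common cause.  ``wave`` is an optional measurement-occasion index for the
    timing filter.
    """

    covariate: str
    causes_exposure: str = "unknown"
    causes_outcome: str = "unknown"
    known_instrument: bool = False
    proxy_of_common_cause: bool = False
    wave: Optional[int] = None

    def __post_init__(self):
        for fieldname in ("causes_exposure", "causes_outcome"):
            if getattr(self, fieldname) not in THREE_VALUED:
                raise AnnotationError(
                    f"{fieldname} must be one of {THREE_VALUED}, "
                    f"got {getattr(self, fieldname)!r} for {self.covariate!r}"
                )
        if self.known_instrument and not (
            self.causes_exposure == "yes" and self.causes_outcome == "no"
        ):
            raise AnnotationError(
                f"{self.covariate!r}: an instrument must have causes_exposure=yes "
                "and causes_outcome=no"
            )
        if self.wave is not None and self.wave < 0:
            raise AnnotationError(f"{self.covariate!r}: wave must be >= 0")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of applying a selection criterion.

    ``rationale`` maps each considered covariate to a one-line explanation of
    why it was selected or not; ``excluded_instruments`` and
    ``included_proxies`` record the two modifications of the modified
    disjunctive criterion.
    """

    criterion: str
    selected: FrozenSet[str]
    excluded_instruments: FrozenSet[str] = frozenset()
    included_proxies: FrozenSet[str] = frozenset()
    rationale: tuple = ()
    warnings: tuple = ()

    def __post_init__(self):
        if self.excluded_instruments & self.selected:
            raise ValueError("excluded instruments cannot also be selected")
        if not self.included_proxies <= self.selected:
            raise ValueError("included proxies must be a subset of the selection")


Annotations = Sequence[CovariateAnnotation]
DagOrAnnotations = Union[CausalDAG, Annotations]


def annotations_from_dag(dag: CausalDAG) -> list[CovariateAnnotation]:
    """Derive per-covariate cause-of-exposure/outcome flags from a full DAG.

    "Cause of X" means ancestor of X via at least one directed path.  Latent
    ancestry does not make a measured covariate a cause.  Instrument and
    proxy flags are never inferred from the graph — that knowledge must be
    asserted explicitly.
    """
    anc_a = ancestors(dag, dag.exposure)
    anc_y = ancestors(dag, dag.outcome)
    out = []
    for c in sorted(dag.measured_covariates):
        out.append(
            CovariateAnnotation(
                covariate=c,
                causes_exposure="yes" if c in anc_a else "no",
                causes_outcome="yes" if c in anc_y else "no",
            )
        )
    return out


def _as_annotations(source: DagOrAnnotations) -> list[CovariateAnnotation]:
    if isinstance(source, CausalDAG):
        return annotations_from_dag(source)
    return list(source)


def _is_pre_exposure(dag: CausalDAG, c: str) -> bool:
    return c not in descendants(dag, dag.exposure)


def pretreatment_criterion(
    source: DagOrAnnotations, exposure_wave: Optional[int] = None
) -> SelectionResult:
    """Select every covariate measured prior to the exposure.

    DAG mode selects all measured non-descendants of the exposure.
    Annotation mode with ``exposure_wave`` selects covariates from strictly
    earlier waves; without waves, every covariate is taken to be available
    pre-exposure and is selected.
    """
    rationale = []
    if isinstance(source, CausalDAG):
        selected = set()
        for c in sorted(source.measured_covariates):
            if _is_pre_exposure(source, c):
                selected.add(c)
                rationale.append(f"{c}: non-descendant of exposure -> selected")
            else:
                rationale.append(f"{c}: descendant of exposure -> excluded")
    else:
        anns = list(source)
        selected = set()
        for a in sorted(anns, key=lambda a: a.covariate):
            if exposure_wave is None:
                selected.add(a.covariate)
                rationale.append(f"{a.covariate}: pre-exposure covariate -> selected")
            else:
                if a.wave is None:
                    raise AnnotationError(
                        f"{a.covariate!r} lacks a wave index but exposure_wave was given"
                    )
                if a.wave < exposure_wave:
                    selected.add(a.covariate)
                    rationale.append(
                        f"{a.covariate}: wave {a.wave} < exposure wave {exposure_wave} -> selected"
                    )
                else:
                    rationale.append(
                        f"{a.covariate}: wave {a.wave} >= exposure wave {exposure_wave} -> excluded"
                    )
    return SelectionResult(
        criterion="pretreatment",
        selected=frozenset(selected),
        rationale=tuple(rationale),
    )


def common_cause_criterion(source: DagOrAnnotations) -> SelectionResult:
    """Select covariates that cause both the exposure and the outcome.

    Unknown causal status counts as "not established", so unknowns are not
    selected — the criterion demands positive knowledge of both links.
    """
    rationale = []
    selected = set()
    if isinstance(source, CausalDAG):
        dag = source
        anc_a, anc_y = ancestors(dag, dag.exposure), ancestors(dag, dag.outcome)
        for c in sorted(dag.measured_covariates):
            if c in anc_a and c in anc_y and _is_pre_exposure(dag, c):
                selected.add(c)
                rationale.append(f"{c}: common cause of exposure and outcome -> selected")
            else:
                rationale.append(f"{c}: not a common cause -> excluded")
    else:
        for a in sorted(source, key=lambda a: a.covariate):
            if a.causes_exposure == "yes" and a.causes_outcome == "yes":
                selected.add(a.covariate)
                rationale.append(
                    f"{a.covariate}: causes exposure and outcome -> selected"
                )
            else:
                rationale.append(f"{a.covariate}: not a known common cause -> excluded")
    return SelectionResult(
        criterion="common_cause",
        selected=frozenset(selected),
        rationale=tuple(rationale),
    )


def disjunctive_cause_criterion(
    source: DagOrAnnotations, unknown_policy: str = "include"
) -> SelectionResult:
    """Select covariates that cause the exposure, the outcome, or both.

    ``unknown_policy`` controls annotation mode when both causal flags are
    "unknown": ``"include"`` (default) keeps the covariate — the criterion's
    point is robustness under partial knowledge — while ``"exclude"`` drops
    it.  In DAG mode causal status is always determined by the graph.
    """
    if unknown_policy not in ("include", "exclude"):
        raise ValueError("unknown_policy must be 'include' or 'exclude'")
    rationale = []
    selected = set()
    if isinstance(source, CausalDAG):
        dag = source
        anc_a, anc_y = ancestors(dag, dag.exposure), ancestors(dag, dag.outcome)
        for c in sorted(dag.measured_covariates):
            if not _is_pre_exposure(dag, c):
                rationale.append(f"{c}: descendant of exposure -> excluded")
            elif c in anc_a or c in anc_y:
                selected.add(c)
                which = "exposure" if c in anc_a else "outcome"
                if c in anc_a and c in anc_y:
                    which = "exposure and outcome"
                rationale.append(f"{c}: cause of {which} -> selected")
            else:
                rationale.append(f"{c}: causes neither exposure nor outcome -> excluded")
    else:
        for a in sorted(source, key=lambda a: a.covariate):
            causes_any = a.causes_exposure == "yes" or a.causes_outcome == "yes"
            has_unknown = "unknown" in (a.causes_exposure, a.causes_outcome)
            if causes_any:
                selected.add(a.covariate)
                rationale.append(f"{a.covariate}: cause of exposure or outcome -> selected")
            elif has_unknown and unknown_policy == "include":
                selected.add(a.covariate)
                rationale.append(
                    f"{a.covariate}: causal status unknown -> selected (include-by-default)"
                )
            else:
                rationale.append(
                    f"{a.covariate}: causes neither exposure nor outcome -> excluded"
                )
    return SelectionResult(
        criterion="disjunctive",
        selected=frozenset(selected),
        rationale=tuple(rationale),
    )


def modified_disjunctive_criterion(
    annotations: Annotations, unknown_policy: str = "include"
) -> SelectionResult:
    """The disjunctive set, minus known instruments, plus common-cause proxies.

    Operates on annotations only: the two modifications rest on knowledge
    ("known to be an instrument", "proxy for an unmeasured common cause")
    that a DAG over measured variables cannot certify.
    """
    anns = list(annotations)
    if not anns:
        raise AnnotationError("modified disjunctive criterion requires annotations")
    contradictory = [
        a.covariate for a in anns if a.known_instrument and a.proxy_of_common_cause
    ]
    if contradictory:
        raise AnnotationError(
            f"covariate(s) flagged both instrument and proxy: {sorted(contradictory)}"
        )
    base = disjunctive_cause_criterion(anns, unknown_policy=unknown_policy)
    selected = set(base.selected)
    excluded_instruments, included_proxies = set(), set()
    rationale = list(base.rationale)
    for a in sorted(anns, key=lambda a: a.covariate):
        if a.known_instrument and a.covariate in selected:
            selected.discard(a.covariate)
            excluded_instruments.add(a.covariate)
            rationale.append(
                f"{a.covariate}: known instrument -> excluded (bias amplification risk)"
            )
        if a.proxy_of_common_cause and a.covariate not in selected:
            selected.add(a.covariate)
            included_proxies.add(a.covariate)
            rationale.append(
                f"{a.covariate}: proxy of unmeasured common cause -> included"
            )
    return SelectionResult(
        criterion="modified_disjunctive",
        selected=frozenset(selected),
        excluded_instruments=frozenset(excluded_instruments),
        included_proxies=frozenset(included_proxies),
        rationale=tuple(rationale),
    )


def timing_filter(
    annotations: Annotations,
    exposure_wave: int,
    max_lag: Optional[int] = 1,
    exposure_name: Optional[str] = None,
) -> tuple[list[CovariateAnnotation], tuple]:
    """Keep covariates measured in wave(s) prior to the exposure wave.

    By default only the immediately prior wave (``max_lag=1``) is kept;
    ``max_lag=None`` keeps all strictly earlier waves.  Covariates measured
    in the exposure wave itself are dropped as possible mediators.  A prior
    measurement of the exposure itself (``exposure_name``) is kept when
    present, to further rule out confounding by prior exposure.

    Returns the surviving annotations and a tuple of warning records.
    """
    anns = list(annotations)
    warnings = []
    missing = [a.covariate for a in anns if a.wave is None]
    if missing:
        raise AnnotationError(f"covariates lack wave indices: {sorted(missing)}")
    if exposure_wave == 0 and anns:
        warnings.append(
            ("no_prior_wave", "exposure is at wave 0; no earlier wave exists")
        )
    earliest = exposure_wave - max_lag if max_lag is not None else 0
    kept = []
    for a in anns:
        if a.covariate == exposure_name and a.wave < exposure_wave:
            kept.append(a)
            continue
        if earliest <= a.wave <= exposure_wave - 1:
            kept.append(a)
        elif a.wave >= exposure_wave:
            warnings.append(
                (
                    "possible_mediator",
                    f"{a.covariate}: measured at/after the exposure wave; "
                    "cannot distinguish confounder from mediator",
                )
            )
    return kept, tuple(warnings)
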