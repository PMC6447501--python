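"""Plain-text formats: the DAG dialect, TSV edge lists, annotation tables,
SEM spec files, and JSON/text report rendering.

The DAG dialect is dagitty-flavoured::

    dag {
      A [exposure]
      Y [outcome]
      U [latent]     # unmeasured
      U -> A
      A -> Y
    }

Whitespace-insensitive; ``#`` starts a comment; role tags are optional for
plain covariates.  ``parse_dag_text`` and ``serialize_dag`` round-trip up to
whitespace.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict
from typing import Iterable, Optional

import pandas as pd
import yaml

from .criteria import AnnotationError, CovariateAnnotation, SelectionResult
from .dag_core import CausalDAG
from .linear_sem import BiasReport, LinearSEM
from .stat_select import HdpsRanking, SelectionRun

__all__ = [
    "DagSyntaxError",
    "parse_dag_text",
    "serialize_dag",
    "read_edge_list",
    "read_annotations",
    "write_annotations",
    "read_sem_spec",
    "write_sem_spec",
    "render_report",
]

REPORT_SCHEMA_VERSION = 1

_ROLES = ("exposure", "outcome", "latent")


class DagSyntaxError(ValueError):
    """Malformed DAG text; carries the 1-based line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(f"{message}{where}")


_TOKEN_RE = re.compile(r"->|[\[\]]|[^\s\[\]{};]+")


def _tokenize_body(text: str) -> list[tuple[int, str]]:
    """(line number, token) pairs from inside the single ``dag { ... }`` block."""
    tokens: list[tuple[int, str]] = []
    inside = closed = saw_open = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0]
        for chunk in re.split(r"([{}])", line):
            if chunk == "{":
                if inside or closed:
                    raise DagSyntaxError("unexpected '{'", lineno)
                inside = saw_open = True
            elif chunk == "}":
                if not inside:
                    raise DagSyntaxError("unexpected '}'", lineno)
                inside, closed = False, True
            elif inside:
                tokens.extend((lineno, t) for t in _TOKEN_RE.findall(chunk))
            else:
                stray = chunk.strip()
                if stray and stray != "dag" and not closed:
                    raise DagSyntaxError(f"text outside dag block: {stray!r}", lineno)
    if not saw_open or inside:
        raise DagSyntaxError("no complete 'dag { ... }' block found")
    return tokens


def parse_dag_text(text: str) -> CausalDAG:
    """Parse the ``dag { ... }`` dialect into a CausalDAG."""
    toks = _tokenize_body(text)
    nodes: dict[str, Optional[str]] = {}
    edges: list[tuple[str, str]] = []
    i = 0

    def _name_at(j: int) -> str:
        if j >= len(toks) or toks[j][1] in ("->", "[", "]"):
            lineno = toks[min(j, len(toks) - 1)][0] if toks else None
            raise DagSyntaxError("expected a node name", lineno)
        return toks[j][1]

    while i < len(toks):
        lineno, tok = toks[i]
        name = _name_at(i)
        i += 1
        role = None
        if i < len(toks) and toks[i][1] == "[":
            if i + 2 >= len(toks) or toks[i + 2][1] != "]":
                raise DagSyntaxError("unclosed role tag", toks[i][0])
            role = toks[i + 1][1]
            if role not in _ROLES:
                raise DagSyntaxError(f"unknown role tag [{role}]", toks[i][0])
            i += 3
        if i < len(toks) and toks[i][1] == "->":
            if role is not None:
                raise DagSyntaxError("role tags are not allowed inside edges", lineno)
            chain = [name]
            while i < len(toks) and toks[i][1] == "->":
                i += 1
                chain.append(_name_at(i))
                i += 1
            for tail, head in zip(chain, chain[1:]):
                if tail == head:
                    raise DagSyntaxError(f"self-loop {tail!r} -> {head!r}", lineno)
                if (tail, head) in edges:
                    raise DagSyntaxError(f"duplicate edge {tail!r} -> {head!r}", lineno)
                edges.append((tail, head))
                nodes.setdefault(tail, None)
                nodes.setdefault(head, None)
        else:
            if name in nodes and nodes[name] is not None and role is not None:
                raise DagSyntaxError(f"duplicate role declaration for {name!r}", lineno)
            nodes[name] = nodes.get(name) or role
    exposure = [n for n, r in nodes.items() if r == "exposure"]
    outcome = [n for n, r in nodes.items() if r == "outcome"]
    if len(exposure) != 1 or len(outcome) != 1:
        raise DagSyntaxError(
            f"need exactly one [exposure] and one [outcome] node; "
            f"found {len(exposure)} and {len(outcome)}"
        )
    latent = [n for n, r in nodes.items() if r == "latent"]
    return CausalDAG(
        nodes=set(nodes),
        edges=edges,
        exposure=exposure[0],
        outcome=outcome[0],
        latent=latent,
    )


def serialize_dag(dag: CausalDAG) -> str:
    """Write a CausalDAG in the dialect; parse ∘ serialize is the identity."""
    lines = ["dag {"]
    lines.append(f"  {dag.exposure} [exposure]")
    lines.append(f"  {dag.outcome} [outcome]")
    for v in sorted(dag.latent):
        lines.append(f"  {v} [latent]")
    for v in sorted(dag.measured_covariates):
        lines.append(f"  {v}")
    for tail, head in sorted(dag.edges):
        lines.append(f"  {tail} -> {head}")
    lines.append("}")
    return "\n".join(lines) + "\n"


def read_edge_list(
    edges_path: str, roles_path: Optional[str] = None
) -> CausalDAG:
    """TSV edge list (columns tail, head) plus a roles sidecar (node, role)."""
    edf = pd.read_csv(edges_path, sep="\t", header=0)
    if edf.shape[1] < 2:
        raise DagSyntaxError("edge list needs two columns (tail, head)")
    edges = [(str(t), str(h)) for t, h in edf.iloc[:, :2].itertuples(index=False)]
    roles: dict[str, str] = {}
    if roles_path is not None:
        rdf = pd.read_csv(roles_path, sep="\t", header=0)
        for node, role in rdf.iloc[:, :2].itertuples(index=False):
            role = str(role)
            if role not in _ROLES:
                raise DagSyntaxError(f"unknown role {role!r} for node {node!r}")
            roles[str(node)] = role
    exposure = [n for n, r in roles.items() if r == "exposure"]
    outcome = [n for n, r in roles.items() if r == "outcome"]
    if len(exposure) != 1 or len(outcome) != 1:
        raise DagSyntaxError("roles sidecar must name exactly one exposure and one outcome")
    nodes = {v for e in edges for v in e} | set(roles)
    return CausalDAG(
        nodes=nodes,
        edges=edges,
        exposure=exposure[0],
        outcome=outcome[0],
        latent=[n for n, r in roles.items() if r == "latent"],
    )


_BOOLS = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def read_annotations(path: str) -> list[CovariateAnnotation]:
    """Read a delimited covariate-annotation table.

    Header: covariate, causes_exposure, causes_outcome, known_instrument,
    proxy_of_common_cause, wave.  Delimiter sniffed from {',', tab}.
    """
    df = pd.read_csv(path, sep=None, engine="python", skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    required = {"covariate", "causes_exposure", "causes_outcome"}
    if not required <= set(df.columns):
        raise AnnotationError(
            f"annotation table must have columns {sorted(required)}; got {list(df.columns)}"
        )
    out = []
    for row in df.to_dict(orient="records"):
        wave = row.get("wave")
        if wave is None or (isinstance(wave, float) and pd.isna(wave)) or wave == "":
            wave = None
        else:
            wave = int(wave)
        out.append(
            CovariateAnnotation(
                covariate=str(row["covariate"]).strip(),
                causes_exposure=str(row["causes_exposure"]).strip().lower(),
                causes_outcome=str(row["causes_outcome"]).strip().lower(),
                known_instrument=_parse_bool(row.get("known_instrument", False)),
                proxy_of_common_cause=_parse_bool(row.get("proxy_of_common_cause", False)),
                wave=wave,
            )
        )
    return out


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return False
    s = str(v).strip().lower()
    if s in _BOOLS:
        return _BOOLS[s]
    raise AnnotationError(f"cannot parse boolean {v!r}")


def write_annotations(annotations: Iterable[CovariateAnnotation], path: str) -> None:
    rows = [asdict(a) for a in annotations]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sem_spec(path: str) -> LinearSEM:
    """YAML SEM spec: roles plus per-edge coefficients and per-node variances.

    ::

        exposure: A
        outcome: Y
        latent: [U]
        edges:
          - {from: U, to: A, coef: 1.0}
          - {from: A, to: Y, coef: 1.0}
        variances: {A: 1.0, Y: 1.0, U: 1.0}
    """
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    edges, coeffs = [], {}
    for e in spec["edges"]:
        edge = (str(e["from"]), str(e["to"]))
        edges.append(edge)
        coeffs[edge] = float(e.get("coef", 1.0))
    variances = {str(k): float(v) for k, v in spec.get("variances", {}).items()}
    nodes = {v for e in edges for v in e} | set(variances)
    nodes |= {spec["exposure"], spec["outcome"]}
    for v in nodes:
        variances.setdefault(v, 1.0)
    dag = CausalDAG(
        nodes=nodes,
        edges=edges,
        exposure=str(spec["exposure"]),
        outcome=str(spec["outcome"]),
        latent=[str(v) for v in spec.get("latent", [])],
    )
    return LinearSEM(dag=dag, coefficients=coeffs, variances=variances)


def write_sem_spec(sem: LinearSEM, path: str) -> None:
    spec = {
        "exposure": sem.dag.exposure,
        "outcome": sem.dag.outcome,
        "latent": sorted(sem.dag.latent),
        "edges": [
            {"from": t, "to": h, "coef": float(c)}
            for (t, h), c in sorted(sem.coefficients.items())
        ],
        "variances": {v: float(sem.variances[v]) for v in sorted(sem.variances)},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(spec, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Report rendering


def _result_to_dict(result) -> dict:
    if isinstance(result, SelectionResult):
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "kind": "selection_result",
            "criterion": result.criterion,
            "selected": sorted(result.selected),
            "excluded_instruments": sorted(result.excluded_instruments),
            "included_proxies": sorted(result.included_proxies),
            "rationale": list(result.rationale),
            "warnings": [list(w) for w in result.warnings],
        }
    if isinstance(result, SelectionRun):
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "kind": "selection_run",
            "method": result.method,
            "selected": list(result.selected),
            "trace": list(result.trace),
            "warnings": [list(w) for w in result.warnings],
        }
    if isinstance(result, BiasReport):
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "kind": "bias_report",
            "true_effect": result.true_effect,
            "sets": [
                {
                    "members": sorted(s.members),
                    "coefficient": s.coefficient,
                    "bias": s.bias,
                    "backdoor_valid": s.backdoor_valid,
                }
                for s in result.sets
            ],
            "amplification": result.amplification,
            "reduction": result.reduction,
        }
    if isinstance(result, HdpsRanking):
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "kind": "hdps_ranking",
            "fraction": result.fraction,
            "forced_in": list(result.forced_in),
            "selected": list(result.selected),
            "rows": [asdict(r) for r in result.rows],
        }
    raise TypeError(f"cannot render object of type {type(result).__name__}")


def render_report(result, format: str = "text") -> str:
    """Render a result object as deterministic JSON or readable text."""
    doc = _result_to_dict(result)
    if format == "json":
        return json.dumps(doc, indent=2, sort_keys=False)
    if format != "text":
        raise ValueError("format must be 'text' or 'json'")
    lines = [f"[{doc['kind']}]"]
    for key, val in doc.items():
        if key in ("schema_version", "kind"):
            continue
        if isinstance(val, list) and val and isinstance(val[0], dict):
            lines.append(f"{key}:")
            for item in val:
                lines.append("  - " + ", ".join(f"{k}={_fmt(v)}" for k, v in item.items()))
        elif isinstance(val, list):
            lines.append(f"{key}:")
            for item in val:
                lines.append(f"  - {_fmt(item)}")
        else:
            lines.append(f"{key}: {_fmt(val)}")
    return "\n".join(lines) + "\n"


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(str(x) for x in v) + "]"
    return str(v)
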