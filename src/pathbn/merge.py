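"""Mixture-model merge of per-platform parameter contrasts.

Each platform j contributes its significant contrast beta*(j) as a normal
component with mean mu_j (the contrast estimate) and variance var_j (its
squared standard error); platforms where the parameter was not significant
contribute a zero-mean, zero-variance component.  Components are weighted by
platform subject counts, p_j = N_j / sum_j N_j, and the merged parameter is
summarized by its mixture moments

    mu_f  = sum_j p_j mu_j
    var_f = sum_j p_j (var_j + mu_j^2) - mu_f^2

and the standardized score mu* = mu_f / sqrt(var_f), whose sign classifies a
node as up/downregulated and an edge as increasing/decreasing biological
function.  Parameters significant on no platform are omitted (an all-zero
mixture carries no evidence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .estimate import ParameterKey
from .difftest import ParameterContrast
from .pathway import PathwayGraph

__all__ = [
    "PlatformWeights",
    "FinalParameter",
    "DegenerateScoreError",
    "platform_weights",
    "merge_parameter",
    "merge_contrasts",
    "standardized_score",
    "classify_sign",
    "rank_parameters",
    "extrema_table",
    "finals_to_frame",
    "finals_to_graph",
]


@dataclass(frozen=True)
class PlatformWeights:
    """Subject-count mixture weights p_j = N_j / sum N_j."""

    counts: dict[str, int]
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("at least one platform required")
        for j, n in self.counts.items():
            if n < 1:
                raise ValueError(f"platform {j!r} has non-positive count {n}")
        total = sum(self.counts.values())
        object.__setattr__(
            self, "weights", {j: n / total for j, n in sorted(self.counts.items())}
        )

    @property
    def platforms(self) -> list[str]:
        return sorted(self.counts)

    def __getitem__(self, platform: str) -> float:
        return self.weights[platform]


def platform_weights(counts: dict[str, int]) -> PlatformWeights:
    return PlatformWeights(dict(counts))


class DegenerateScoreError(ValueError):
    """Raised when a zero-variance mixture cannot be standardized."""


@dataclass
class FinalParameter:
    """Mixture-merged final parameter with standardized score."""

    key: ParameterKey
    pathway_id: str
    mu_f: float
    var_f: float
    mu_star: float | None
    sign_class: str
    contributing_platforms: tuple[str, ...]


def classify_sign(kind: str, mu_star: float) -> str:
    if mu_star == 0:
        return "no net change"
    if kind == "node":
        return "upregulated" if mu_star > 0 else "downregulated"
    return "increasing function" if mu_star > 0 else "decreasing function"


def merge_parameter(
    key: ParameterKey,
    per_platform: dict[str, tuple[float, float, bool]],
    w: PlatformWeights,
    pathway_id: str = "",
) -> FinalParameter | None:
    """Merge one parameter's per-platform (mu, var, significant) triples.

    Non-significant (or untested) platforms enter with mu = var = 0; if the
    parameter is significant nowhere, None is returned.  A zero-variance
    mixture with nonzero mean (a single exact-fit component) is reported with
    mu_star = None and var_f = 0 rather than an infinite score.
    """
    contributing = []
    mu_f = 0.0
    second_moment = 0.0
    for j in w.platforms:
        mu_j, var_j, sig = per_platform.get(j, (0.0, 0.0, False))
        if var_j < 0:
            raise ValueError(f"negative variance for platform {j!r}")
        if not sig:
            continue
        contributing.append(j)
        mu_f += w[j] * mu_j
        second_moment += w[j] * (var_j + mu_j**2)
    if not contributing:
        return None
    var_f = second_moment - mu_f**2
    # Jensen: E[m^2] >= (E m)^2 for sub-probability weights too
    assert var_f > -1e-12, f"impossible negative mixture variance {var_f}"
    var_f = max(var_f, 0.0)
    if var_f > 0:
        mu_star = mu_f / math.sqrt(var_f)
        sign_class = classify_sign(key.kind, mu_star)
    else:
        mu_star = None
        sign_class = "degenerate"
    return FinalParameter(
        key=key,
        pathway_id=pathway_id,
        mu_f=mu_f,
        var_f=var_f,
        mu_star=mu_star,
        sign_class=sign_class,
        contributing_platforms=tuple(contributing),
    )


def standardized_score(fp: FinalParameter) -> float:
    """mu_f / sqrt(var_f); raises on a degenerate zero-variance mixture."""
    if fp.var_f <= 0:
        raise DegenerateScoreError(
            f"{fp.key}: zero mixture variance, score undefined"
        )
    return fp.mu_f / math.sqrt(fp.var_f)


def merge_contrasts(
    contrasts: list[ParameterContrast], w: PlatformWeights
) -> list[FinalParameter]:
    """Merge FDR-annotated contrasts (one pathway) across platforms."""
    if any(c.significant is None for c in contrasts):
        raise ValueError("contrasts must carry significance flags (apply_fdr)")
    pathways = {c.pathway_id for c in contrasts}
    if len(pathways) > 1:
        raise ValueError(f"merge_contrasts expects one pathway, got {sorted(pathways)}")
    pathway_id = pathways.pop() if pathways else ""
    table: dict[ParameterKey, dict[str, tuple[float, float, bool]]] = {}
    for c in contrasts:
        table.setdefault(c.key, {})[c.platform_id] = (
            c.beta_star,
            c.se_star**2,
            bool(c.significant),
        )
    finals = []
    for key in sorted(table):
        fp = merge_parameter(key, table[key], w, pathway_id=pathway_id)
        if fp is not None:
            finals.append(fp)
    return finals


def _sort_key(fp: FinalParameter):
    return (fp.key.kind, fp.key.child, fp.key.parent or "")


def rank_parameters(
    finals: list[FinalParameter], k: int = 3
) -> dict[str, list[FinalParameter]]:
    """Top/bottom-k nodes and edges by mu*; ties broken lexicographically.

    Degenerate (scoreless) parameters are excluded from ranking.
    """
    out: dict[str, list[FinalParameter]] = {}
    for kind, label in (("node", "nodes"), ("edge", "edges")):
        scored = [f for f in finals if f.key.kind == kind and f.mu_star is not None]
        asc = sorted(scored, key=lambda f: (f.mu_star, _sort_key(f)))
        out[f"{label}_down"] = asc[:k]
        out[f"{label}_up"] = sorted(
            scored, key=lambda f: (-f.mu_star, _sort_key(f))
        )[:k]
    return out


def extrema_table(finals: list[FinalParameter]) -> pd.DataFrame:
    """Min/max mu* for nodes and edges (the summary range of final scores)."""
    rows = []
    for kind in ("node", "edge"):
        scores = [f.mu_star for f in finals if f.key.kind == kind and f.mu_star is not None]
        rows.append(
            {
                "type": kind,
                "min_mu_star": min(scores) if scores else float("nan"),
                "max_mu_star": max(scores) if scores else float("nan"),
                "n": len(scores),
            }
        )
    return pd.DataFrame(rows, columns=["type", "min_mu_star", "max_mu_star", "n"])


def finals_to_frame(finals: list[FinalParameter]) -> pd.DataFrame:
    rows = []
    for f in sorted(finals, key=_sort_key):
        rows.append(
            {
                "pathway_id": f.pathway_id,
                "type": f.key.kind,
                "child": f.key.child,
                "parent": f.key.parent if f.key.parent is not None else "NA",
                "mu_f": f.mu_f,
                "var_f": f.var_f,
                "mu_star": f.mu_star if f.mu_star is not None else float("nan"),
                "sign_class": f.sign_class,
                "platforms": ",".join(f.contributing_platforms),
            }
        )
    cols = [
        "pathway_id", "type", "child", "parent",
        "mu_f", "var_f", "mu_star", "sign_class", "platforms",
    ]
    return pd.DataFrame(rows, columns=cols)


def finals_to_graph(pg: PathwayGraph, finals: list[FinalParameter]) -> nx.DiGraph:
    """Annotate the pathway graph with final scores for GraphML export.

    Nodes carry mu_star (color scale) and abs_mu_star (size scale); edges
    carry mu_star; parameters never significant carry 0 and significant=False.
    """
    g = nx.DiGraph(pathway_id=pg.pathway_id)
    node_scores = {
        f.key.child: f for f in finals if f.key.kind == "node"
    }
    edge_scores = {
        (f.key.parent, f.key.child): f for f in finals if f.key.kind == "edge"
    }
    for n in pg.nodes:
        f = node_scores.get(n)
        score = f.mu_star if f is not None and f.mu_star is not None else 0.0
        g.add_node(
            n,
            mu_star=float(score),
            abs_mu_star=abs(float(score)),
            sign_class=f.sign_class if f is not None else "not significant",
            significant=f is not None,
        )
    for p, c in pg.edges:
        f = edge_scores.get((p, c))
        score = f.mu_star if f is not None and f.mu_star is not None else 0.0
        g.add_edge(
            p,
            c,
            mu_star=float(score),
            sign_class=f.sign_class if f is not None else "not significant",
            significant=f is not None,
            relation=pg.relation(p, c),
        )
    return g
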