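"""Per-group training of a pathway-structured Bayesian network.

Each gene's expression is modeled as an ordinary-least-squares regression on
its pathway parents: Y = beta0 + sum_k beta_k X_k + eps.  The intercept beta0
is the node parameter (the gene's expression level in that group), the parent
coefficients are the edge parameters, and their sampling covariance is
sigma^2 (X'X)^-1, so every parameter carries an estimate, a standard error
and residual degrees of freedom for downstream contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pathway import PathwayGraph
from .normalize import MergedPlatformDataset

__all__ = [
    "ParameterKey",
    "FittedNodeModel",
    "FittedNetwork",
    "NodeUnestimableError",
    "fit_node_regression",
    "fit_network",
    "network_to_frame",
]

_RANK_TOL = 1e-8


@dataclass(frozen=True, order=True)
class ParameterKey:
    """Identity of one network parameter: a node (intercept of ``child``) or
    an edge (coefficient of ``parent`` in ``child``'s model)."""

    kind: str  # "node" | "edge"
    child: str
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("node", "edge"):
            raise ValueError(f"kind must be node/edge, got {self.kind!r}")
        if (self.kind == "edge") != (self.parent is not None):
            raise ValueError("edge keys need a parent; node keys must not have one")

    def __str__(self) -> str:
        if self.kind == "node":
            return f"node:{self.child}"
        return f"edge:{self.parent}->{self.child}"


class NodeUnestimableError(ValueError):
    """Raised when a node regression has no residual degrees of freedom."""


@dataclass
class FittedNodeModel:
    """OLS fit of one gene on its (kept) parents.

    ``cov_beta`` is sigma2_hat * (X'X)^-1 over [intercept, parents];
    ``dropped_parents`` lists collinear columns removed deterministically
    (later lexicographic parent dropped first).
    """

    child: str
    parents: tuple[str, ...]
    beta0: float
    betas: np.ndarray
    sigma2_hat: float
    cov_beta: np.ndarray
    df_resid: int
    n: int
    dropped_parents: tuple[str, ...] = ()

    @property
    def se_beta0(self) -> float:
        return float(np.sqrt(self.cov_beta[0, 0]))

    def se_beta(self, k: int) -> float:
        return float(np.sqrt(self.cov_beta[k + 1, k + 1]))

    def parameters(self) -> dict[ParameterKey, tuple[float, float, int]]:
        """Map parameter key -> (estimate, se, df_resid)."""
        out = {
            ParameterKey("node", self.child): (self.beta0, self.se_beta0, self.df_resid)
        }
        for k, parent in enumerate(self.parents):
            out[ParameterKey("edge", self.child, parent)] = (
                float(self.betas[k]),
                self.se_beta(k),
                self.df_resid,
            )
        return out


def fit_node_regression(
    y: np.ndarray,
    X: np.ndarray | None,
    parents: tuple[str, ...] = (),
    child: str = "y",
) -> FittedNodeModel:
    """OLS of ``y`` on an intercept plus parent columns ``X``.

    Collinear columns are dropped greedily in parent order (so of two
    collinear parents the lexicographically later one is dropped, parents
    being supplied in lexicographic order).  Raises
    :class:`NodeUnestimableError` when n <= number of retained columns.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X is None or (hasattr(X, "size") and np.size(X) == 0):
        X = np.empty((n, 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError(f"y has {n} rows but X has {X.shape[0]}")
    if len(parents) != X.shape[1]:
        raise ValueError("parents must name every column of X")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError(f"non-finite values in regression data for {child!r}")

    design = np.column_stack([np.ones(n), X])
    # greedy Gram-Schmidt rank filter: keep a column only if it adds rank
    keep: list[int] = []
    basis = np.empty((n, 0))
    dropped: list[str] = []
    for j in range(design.shape[1]):
        v = design[:, j]
        r = v - basis @ (basis.T @ v)
        norm = np.linalg.norm(r)
        if norm > _RANK_TOL * max(np.linalg.norm(v), 1.0):
            keep.append(j)
            basis = np.column_stack([basis, r / norm])
        elif j > 0:
            dropped.append(parents[j - 1])
    D = design[:, keep]
    p = D.shape[1]
    if n <= p:
        raise NodeUnestimableError(
            f"node {child!r}: n={n} <= p={p}, no residual degrees of freedom"
        )

    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    df_resid = n - p
    sigma2 = float(resid @ resid) / df_resid
    cov = sigma2 * np.linalg.inv(D.T @ D)

    kept_parents = tuple(parents[j - 1] for j in keep if j > 0)
    return FittedNodeModel(
        child=child,
        parents=kept_parents,
        beta0=float(beta[0]),
        betas=np.asarray(beta[1:], dtype=float),
        sigma2_hat=sigma2,
        cov_beta=cov,
        df_resid=df_resid,
        n=n,
        dropped_parents=tuple(dropped),
    )


@dataclass
class FittedNetwork:
    """One group's trained network on one platform: a FittedNodeModel per
    estimable gene, plus genes skipped (with reasons) and parents excluded
    because they were absent from the expression matrix."""

    pathway_id: str
    group: str
    platform_id: str
    node_models: dict[str, FittedNodeModel] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    missing_parents: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def parameters(self) -> dict[ParameterKey, tuple[float, float, int]]:
        out: dict[ParameterKey, tuple[float, float, int]] = {}
        for gene in sorted(self.node_models):
            out.update(self.node_models[gene].parameters())
        return out


def fit_network(
    g: PathwayGraph,
    m: MergedPlatformDataset | pd.DataFrame,
    group: str | None = None,
    platform_id: str | None = None,
) -> FittedNetwork:
    """Fit every estimable pathway gene on one group's expression columns.

    Genes absent from the matrix are skipped ("missing gene"); absent parents
    are excluded from that node's design and recorded; nodes with no residual
    degrees of freedom are skipped ("insufficient samples").  Iteration is in
    topological order with lexicographic ties, so output is deterministic.
    """
    if isinstance(m, MergedPlatformDataset):
        if group is None:
            raise ValueError("group is required with a MergedPlatformDataset")
        mat = m.group_matrix(group)
        platform_id = platform_id or m.platform_id
        if mat.shape[1] == 0:
            raise ValueError(f"no samples for group {group!r} on {platform_id}")
    else:
        mat = m
        group = group or "all"
        platform_id = platform_id or "unknown"
        if mat.shape[1] == 0:
            raise ValueError(f"no samples for group {group!r}")

    net = FittedNetwork(g.pathway_id, group, platform_id)
    present = set(mat.index)
    data = {gene: mat.loc[gene].to_numpy(dtype=float) for gene in g.nodes if gene in present}
    for gene in g.topological_order():
        if gene not in present:
            net.skipped[gene] = "missing gene"
            continue
        parents_all = g.parents_of(gene)
        parents = tuple(p for p in parents_all if p in present)
        absent = tuple(p for p in parents_all if p not in present)
        if absent:
            net.missing_parents[gene] = absent
        X = (
            np.column_stack([data[p] for p in parents])
            if parents
            else np.empty((len(data[gene]), 0))
        )
        try:
            net.node_models[gene] = fit_node_regression(
                data[gene], X, parents, child=gene
            )
        except NodeUnestimableError:
            net.skipped[gene] = "insufficient samples"
    return net


def network_to_frame(net: FittedNetwork) -> pd.DataFrame:
    """One row per parameter: estimate, se, df — the serialization schema."""
    rows = []
    for key, (est, se, df) in net.parameters().items():
        rows.append(
            {
                "pathway_id": net.pathway_id,
                "platform_id": net.platform_id,
                "group": net.group,
                "type": key.kind,
                "child": key.child,
                "parent": key.parent if key.parent is not None else "NA",
                "estimate": est,
                "se": se,
                "df": df,
            }
        )
    return pd.DataFrame(rows)
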