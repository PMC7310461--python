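"""Case-vs-control contrasts of network parameters with FDR control.

For each parameter estimable in both groups the difference
beta* = beta_case - beta_control is tested with a Welch-type Wald contrast:
t = beta* / sqrt(se_case^2 + se_control^2), with Welch-Satterthwaite degrees
of freedom, two-sided p from the t distribution, and Benjamini-Hochberg FDR
within each (pathway, platform) family over nodes and edges jointly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimate import FittedNetwork, ParameterKey

__all__ = [
    "ParameterContrast",
    "contrast_parameter",
    "contrast_networks",
    "bh_fdr",
    "apply_fdr",
    "significant_set",
    "count_significant",
    "contrasts_to_frame",
]


@dataclass
class ParameterContrast:
    """One parameter's case-minus-control difference on one platform."""

    key: ParameterKey
    pathway_id: str
    platform_id: str
    beta_star: float
    se_star: float
    t_stat: float
    df: float
    p_value: float
    fdr: float | None = None
    significant: bool | None = None


def contrast_parameter(
    case: tuple[float, float, float],
    control: tuple[float, float, float],
) -> tuple[float, float, float, float, float]:
    """Welch contrast of two (estimate, se, df) triples.

    Returns (beta_star, se_star, t, df, p).  Degenerate zero-SE inputs (exact
    fits) give t=0, p=1 when the estimates agree and p=0 otherwise.
    """
    est_s, se_s, df_s = case
    est_h, se_h, df_h = control
    if not all(map(math.isfinite, (est_s, se_s, est_h, se_h))):
        raise ValueError("contrast requires finite estimates and SEs")
    beta_star = est_s - est_h
    se_star = math.sqrt(se_s**2 + se_h**2)
    if se_star == 0.0:
        if beta_star == 0.0:
            return beta_star, se_star, 0.0, float(df_s + df_h), 1.0
        return beta_star, se_star, math.copysign(math.inf, beta_star), float(df_s + df_h), 0.0
    t = beta_star / se_star
    df = se_star**4 / (se_s**4 / df_s + se_h**4 / df_h)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return beta_star, se_star, t, df, min(p, 1.0)


def contrast_networks(
    case: FittedNetwork, control: FittedNetwork
) -> tuple[list[ParameterContrast], list[ParameterKey]]:
    """Contrast every parameter shared by both groups' fitted networks.

    Parameters estimable in only one group are untestable and returned
    separately; they never enter the FDR family.
    """
    if (case.pathway_id, case.platform_id) != (control.pathway_id, control.platform_id):
        raise ValueError("case/control networks must share pathway and platform")
    ps, ph = case.parameters(), control.parameters()
    shared = sorted(set(ps) & set(ph))
    untestable = sorted(set(ps) ^ set(ph))
    out = []
    for key in shared:
        beta_star, se_star, t, df, p = contrast_parameter(ps[key], ph[key])
        out.append(
            ParameterContrast(
                key=key,
                pathway_id=case.pathway_id,
                platform_id=case.platform_id,
                beta_star=beta_star,
                se_star=se_star,
                t_stat=t,
                df=df,
                p_value=p,
            )
        )
    return out, untestable


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_fdr(contrasts: list[ParameterContrast], alpha: float = 0.05) -> None:
    """Fill fdr/significant in place, treating ``contrasts`` as one family."""
    if not contrasts:
        return
    adj = bh_fdr(np.array([c.p_value for c in contrasts]))
    for c, q in zip(contrasts, adj):
        c.fdr = float(q)
        c.significant = bool(q < alpha)


def significant_set(
    contrasts: list[ParameterContrast], alpha: float = 0.05
) -> list[ParameterContrast]:
    """Contrasts with FDR below ``alpha`` (fdr must be populated)."""
    if any(c.fdr is None for c in contrasts):
        raise ValueError("apply_fdr before filtering")
    return [c for c in contrasts if c.fdr < alpha]


def count_significant(contrasts: list[ParameterContrast], alpha: float = 0.05) -> pd.DataFrame:
    """Significant node/edge counts by pathway x platform."""
    rows: dict[tuple[str, str], dict[str, int]] = {}
    for c in contrasts:
        cell = rows.setdefault(
            (c.pathway_id, c.platform_id), {"nodes": 0, "edges": 0}
        )
        if c.fdr is not None and c.fdr < alpha:
            cell["nodes" if c.key.kind == "node" else "edges"] += 1
    out = [
        {"pathway_id": pw, "platform_id": pl, **counts}
        for (pw, pl), counts in sorted(rows.items())
    ]
    return pd.DataFrame(out, columns=["pathway_id", "platform_id", "nodes", "edges"])


def contrasts_to_frame(contrasts: list[ParameterContrast]) -> pd.DataFrame:
    rows = []
    for c in contrasts:
        rows.append(
            {
                "pathway_id": c.pathway_id,
                "platform_id": c.platform_id,
                "type": c.key.kind,
                "child": c.key.child,
                "parent": c.key.parent if c.key.parent is not None else "NA",
                "beta_star": c.beta_star,
                "se": c.se_star,
                "t": c.t_stat,
                "df": c.df,
                "p": c.p_value,
                "fdr": c.fdr,
                "significant": c.significant,
            }
        )
    cols = [
        "pathway_id", "platform_id", "type", "child", "parent",
        "beta_star", "se", "t", "df", "p", "fdr", "significant",
    ]
    return pd.DataFrame(rows, columns=cols)
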