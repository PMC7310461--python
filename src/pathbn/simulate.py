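"""Synthetic multi-platform expression studies with known ground truth.

Data are drawn from the exact generative model the estimation stage assumes:
a linear-Gaussian structural equation model on a pathway DAG (each gene =
intercept + weighted parents + homoscedastic Gaussian noise), with
group-specific node/edge parameters, per-dataset linear location/scale batch
effects (the class parametric ComBat removes), and per-platform gene
dropout.  Effect sizes are calibrated in units of the analytic standard
error of the case-minus-control contrast, so "a 3-SE effect" means the same
thing at any sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .estimate import ParameterKey
from .normalize import ExpressionDataset
from .pathway import PathwayGraph, parse_sif, to_sif

__all__ = [
    "GroundTruth",
    "DatasetDesign",
    "StudyDesign",
    "StudyBundle",
    "simulate_sem",
    "apply_batch_and_dropout",
    "generate_study",
    "write_study",
    "default_pathway",
    "make_ground_truth",
    "default_study_design",
    "analytic_moments",
    "contrast_se",
]

GROUPS = ("case", "control")


# -- ground truth ---------------------------------------------------------

@dataclass
class GroundTruth:
    """Group-specific SEM parameters on a pathway DAG.

    node_params / edge_params map group -> {gene: beta0} / {(parent, child):
    beta}; noise_sd maps gene -> residual sd; perturbed lists (key,
    direction) for every parameter whose case value differs from control.
    """

    pathway: PathwayGraph
    node_params: dict[str, dict[str, float]]
    edge_params: dict[str, dict[tuple[str, str], float]]
    noise_sd: dict[str, float]
    perturbed: list[tuple[ParameterKey, int]] = field(default_factory=list)
    injected: list[tuple[ParameterKey, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        genes, edges = set(self.pathway.nodes), set(self.pathway.edges)
        for grp in GROUPS:
            if set(self.node_params[grp]) != genes:
                raise ValueError(f"{grp} node params must cover every gene")
            if set(self.edge_params[grp]) != edges:
                raise ValueError(f"{grp} edge params must cover every edge")
        if any(sd <= 0 for sd in self.noise_sd.values()):
            raise ValueError("noise_sd must be positive")

    def truth_frame(self) -> pd.DataFrame:
        """Every parameter once: group values, perturbed flag (case value
        differs from control), direction of the difference."""
        rows = []
        for gene in self.pathway.nodes:
            key = ParameterKey("node", gene)
            rows.append((key, self.node_params["control"][gene], self.node_params["case"][gene]))
        for p, c in self.pathway.edges:
            key = ParameterKey("edge", c, p)
            rows.append((key, self.edge_params["control"][(p, c)], self.edge_params["case"][(p, c)]))
        return pd.DataFrame(
            [
                {
                    "type": key.kind,
                    "child": key.child,
                    "parent": key.parent if key.parent is not None else "NA",
                    "control_value": ctl,
                    "case_value": cas,
                    "perturbed": cas != ctl,
                    "direction": int(np.sign(cas - ctl)),
                }
                for key, ctl, cas in rows
            ]
        )


def analytic_moments(gt: GroundTruth, group: str) -> tuple[pd.Series, pd.DataFrame]:
    """Exact SEM mean vector and covariance: m = (I-B)^-1 b0,
    Sigma = (I-B)^-1 D (I-B)^-T, with B[child, parent] the edge weights."""
    genes = gt.pathway.nodes
    idx = {g: i for i, g in enumerate(genes)}
    k = len(genes)
    B = np.zeros((k, k))
    for (p, c), beta in gt.edge_params[group].items():
        B[idx[c], idx[p]] = beta
    b0 = np.array([gt.node_params[group][g] for g in genes])
    D = np.diag([gt.noise_sd[g] ** 2 for g in genes])
    Ainv = np.linalg.inv(np.eye(k) - B)
    mean = Ainv @ b0
    cov = Ainv @ D @ Ainv.T
    return (
        pd.Series(mean, index=genes),
        pd.DataFrame(cov, index=genes, columns=genes),
    )


def _coef_se(gt: GroundTruth, group: str, key: ParameterKey, n: int) -> float:
    """Asymptotic OLS standard error of one coefficient at sample size n,
    from the analytic design second-moment matrix."""
    mean, cov = analytic_moments(gt, group)
    parents = gt.pathway.parents_of(key.child)
    m = mean[parents].to_numpy() if parents else np.empty(0)
    S = cov.loc[parents, parents].to_numpy() if parents else np.empty((0, 0))
    p = len(parents)
    M = np.empty((p + 1, p + 1))
    M[0, 0] = 1.0
    M[0, 1:] = m
    M[1:, 0] = m
    M[1:, 1:] = S + np.outer(m, m)
    Minv = np.linalg.inv(M)
    if key.kind == "node":
        j = 0
    else:
        j = 1 + parents.index(key.parent)
    sigma2 = gt.noise_sd[key.child] ** 2
    return float(np.sqrt(sigma2 * Minv[j, j] / n))


def contrast_se(gt: GroundTruth, key: ParameterKey, n_case: int, n_control: int) -> float:
    """Analytic SE of the case-minus-control contrast for one parameter."""
    return float(
        np.sqrt(
            _coef_se(gt, "case", key, n_case) ** 2
            + _coef_se(gt, "control", key, n_control) ** 2
        )
    )


# -- SEM sampling ---------------------------------------------------------

def simulate_sem(
    gt: GroundTruth,
    group: str,
    n: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw n samples from the linear-Gaussian SEM (genes x samples).

    Genes are sampled in topological order: roots ~ N(beta0, sigma^2),
    children = beta0 + sum_k beta_k parent_k + N(0, sigma^2).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = gt.pathway.topological_order()  # raises on cyclic input
    values: dict[str, np.ndarray] = {}
    b0 = gt.node_params[group]
    bete = gt.edge_params[group]
    for gene in order:
        x = b0[gene] + gt.noise_sd[gene] * rng.standard_normal(n)
        for p in gt.pathway.parents_of(gene):
            x = x + bete[(p, gene)] * values[p]
        values[gene] = x
    genes = gt.pathway.nodes
    return pd.DataFrame(np.vstack([values[g] for g in genes]), index=genes)


# -- study design ---------------------------------------------------------

@dataclass(frozen=True)
class DatasetDesign:
    """One dataset's sample sizes and batch-effect parameters.

    Per-gene additive shifts are drawn N(shift, shift_sd^2) and multiplicative
    scales N(scale, scale_sd^2) — the location/scale class ComBat models.
    """

    dataset_id: str
    platform_id: str
    n_case: int
    n_control: int
    shift: float = 0.0
    shift_sd: float = 0.0
    scale: float = 1.0
    scale_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError(
                f"dataset {self.dataset_id}: need >=2 samples per group"
            )


@dataclass(frozen=True)
class StudyDesign:
    """Multi-platform study layout: datasets, per-platform dropout, seed.

    ``background_genes`` non-pathway genes (identical distribution in both
    groups) pad every dataset so quantile normalization and the empirical-
    Bayes shrinkage of the batch adjustment operate at array-like gene
    counts, as they do on real microarrays where pathway genes are a tiny
    subset of the measured features.
    """

    datasets: tuple[DatasetDesign, ...]
    dropout: dict[str, tuple[str, ...]] = field(default_factory=dict)
    seed: int = 0
    background_genes: int = 1000

    def __post_init__(self) -> None:
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate dataset ids: {ids}")

    @property
    def platforms(self) -> list[str]:
        return sorted({d.platform_id for d in self.datasets})

    def platform_subjects(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for d in self.datasets:
            out[d.platform_id] = out.get(d.platform_id, 0) + d.n_case + d.n_control
        return out


@dataclass
class StudyBundle:
    """A generated study: datasets, the truth table, and its provenance."""

    datasets: list[ExpressionDataset]
    truth: pd.DataFrame
    ground_truth: GroundTruth
    design: StudyDesign


def apply_batch_and_dropout(
    d: ExpressionDataset,
    dd: DatasetDesign,
    dropout_genes: tuple[str, ...] = (),
    rng: np.random.Generator | None = None,
) -> ExpressionDataset:
    """Apply the dataset's per-gene location/scale batch effect, then drop
    the platform's dropout genes.  x -> scale_g * x + shift_g."""
    rng = rng or np.random.default_rng(0)
    genes = d.matrix.index
    shift = dd.shift + dd.shift_sd * rng.standard_normal(len(genes))
    scale = dd.scale + dd.scale_sd * rng.standard_normal(len(genes))
    mat = d.matrix.mul(scale, axis=0).add(shift, axis=0)
    present_drop = [g for g in dropout_genes if g in mat.index]
    if present_drop:
        mat = mat.drop(index=present_drop)
    return replace(d, matrix=mat)


def generate_study(gt: GroundTruth, design: StudyDesign) -> StudyBundle:
    """Simulate every dataset of the design with one seeded RNG.

    The identifiability precondition n > max in-degree + 1 is enforced per
    group per dataset, so every generated study is estimable by construction.
    """
    max_indeg = max(
        (len(gt.pathway.parents_of(g)) for g in gt.pathway.nodes), default=0
    )
    for dd in design.datasets:
        if min(dd.n_case, dd.n_control) <= max_indeg + 1:
            raise ValueError(
                f"dataset {dd.dataset_id}: group size must exceed max "
                f"in-degree + 1 = {max_indeg + 1}"
            )
    rng = np.random.default_rng(design.seed)
    nbg = design.background_genes
    bg_names = [f"BG{i + 1:04d}" for i in range(nbg)]
    # background gene means and spreads are heterogeneous, as on real arrays,
    # so pathway genes (whose variance grows along the cascade) do not sit in
    # the collective tails where rank-based normalization compresses values;
    # fixed per study, not per batch
    bg_means = rng.uniform(3.0, 12.0, size=nbg)
    bg_sds = rng.uniform(0.5, 2.5, size=nbg)
    datasets = []
    for dd in design.datasets:
        blocks, metas = [], []
        for group, n in (("case", dd.n_case), ("control", dd.n_control)):
            block = simulate_sem(gt, group, n, rng)
            tag = "S" if group == "case" else "H"
            cols = [f"{dd.dataset_id}.{tag}{i + 1}" for i in range(n)]
            block.columns = cols
            if nbg:
                bg = pd.DataFrame(
                    bg_means[:, None] + bg_sds[:, None] * rng.standard_normal((nbg, n)),
                    index=bg_names,
                    columns=cols,
                )
                block = pd.concat([block, bg], axis=0)
            blocks.append(block)
            metas.append(pd.DataFrame({"group": group}, index=cols))
        raw = ExpressionDataset(
            dataset_id=dd.dataset_id,
            platform_id=dd.platform_id,
            matrix=pd.concat(blocks, axis=1),
            sample_meta=pd.concat(metas, axis=0),
        )
        datasets.append(
            apply_batch_and_dropout(
                raw, dd, design.dropout.get(dd.platform_id, ()), rng
            )
        )
    return StudyBundle(datasets, gt.truth_frame(), gt, design)


def write_study(bundle: StudyBundle, out_dir) -> dict[str, str]:
    """Write expression TSVs, sample metadata, pathway SIF and the truth
    table; returns the path map.  Output is deterministic per seed."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    metas = []
    for d in bundle.datasets:
        p = out / f"{d.dataset_id}.tsv"
        d.matrix.to_csv(p, sep="\t", index_label="gene_id", float_format="%.8g")
        paths[d.dataset_id] = str(p)
        meta = d.sample_meta.copy()
        meta["dataset_id"] = d.dataset_id
        meta["platform_id"] = d.platform_id
        metas.append(meta)
    meta_all = pd.concat(metas, axis=0)
    meta_path = out / "samples.tsv"
    meta_all.to_csv(meta_path, sep="\t", index_label="sample_id")
    paths["samples"] = str(meta_path)
    sif_path = out / f"{bundle.ground_truth.pathway.pathway_id}.sif"
    sif_path.write_text(to_sif(bundle.ground_truth.pathway))
    paths["pathway"] = str(sif_path)
    truth_path = out / "truth.tsv"
    bundle.truth.to_csv(truth_path, sep="\t", index=False, float_format="%.8g")
    paths["truth"] = str(truth_path)
    manifest = {
        "datasets": [
            {
                "dataset_id": d.dataset_id,
                "platform_id": d.platform_id,
                "n_case": d.n_case,
                "n_control": d.n_control,
            }
            for d in bundle.design.datasets
        ]
    }
    man_path = out / "manifest.yaml"
    man_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    paths["manifest"] = str(man_path)
    return paths


# -- default study conditions --------------------------------------------

_DEFAULT_SIF = """\
CD3E\tactivation\tLCK
CD3E\tactivation\tZAP70
LCK\tactivation\tZAP70
ZAP70\tactivation\tLAT
LAT\tactivation\tPLCG1
PLCG1\tactivation\tPRKCQ
PLCG1\tactivation\tNFATC1
PRKCQ\tactivation\tMAP2K1
MAP2K1\tactivation\tMAPK1
MAPK1\tactivation\tFOS
MAPK1\tactivation\tJUN
FOS\tactivation\tIL2
JUN\tactivation\tIL2
NFATC1\tactivation\tIL2
"""


def default_pathway() -> PathwayGraph:
    """12-gene, 14-edge DAG shaped like a receptor-signaling cascade."""
    return parse_sif(_DEFAULT_SIF, pathway_id="tcr_mini")


def make_ground_truth(
    pathway: PathwayGraph | None = None,
    n_perturbed_edges: int = 5,
    n_perturbed_nodes: int = 5,
    effect_se: float = 3.0,
    extra_edge_se: float | None = None,
    n_per_group: int = 80,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> GroundTruth:
    """Build a ground truth with effects calibrated in contrast-SE units.

    Control marginal means emulate log2 microarray levels (5..9); edge
    weights are moderate (|beta| in [0.4, 0.8], random sign).  The requested
    numbers of node and edge parameters are shifted in the case group by
    effect_se standard errors of their contrast at n_per_group subjects per
    group per platform, with random directions; ``extra_edge_se`` optionally
    perturbs one additional edge more strongly (a designated strongest hit).

    Edge perturbations model rewiring at constant expression level: the
    child's intercept is compensated by -delta * E[parent], so marginal
    expression stays in the microarray band (a naked coefficient shift of
    ~0.5 with a parent near 7 would move the child by several log2 units, a
    fold change real arrays do not show).  The compensatory intercept
    changes are genuine case/control node-parameter differences and are
    listed in ``perturbed``; ``injected`` holds only the deliberately
    injected effect-size-calibrated parameters.
    """
    pathway = pathway or default_pathway()
    if not pathway.is_acyclic():
        raise ValueError("ground truth requires an acyclic pathway")
    rng = np.random.default_rng(seed)
    genes, edges = pathway.nodes, pathway.edges

    control_edges = {
        e: float(rng.choice([-1, 1]) * rng.uniform(0.4, 0.8)) for e in edges
    }
    # intercepts are chosen so every gene's marginal mean lands in the
    # log2-microarray band (5..9) whatever the topology: beta0 = target mean
    # minus the parent contribution, computed in topological order
    target_mean = {g: float(rng.uniform(5.0, 9.0)) for g in genes}
    control_nodes: dict[str, float] = {}
    marg_mean: dict[str, float] = {}
    for g in pathway.topological_order():
        contrib = sum(
            control_edges[(p, g)] * marg_mean[p] for p in pathway.parents_of(g)
        )
        control_nodes[g] = target_mean[g] - contrib
        marg_mean[g] = target_mean[g]
    sds = {g: noise_sd for g in genes}
    gt = GroundTruth(
        pathway=pathway,
        node_params={"case": dict(control_nodes), "control": control_nodes},
        edge_params={"case": dict(control_edges), "control": control_edges},
        noise_sd=sds,
    )

    if n_perturbed_edges > len(edges) or n_perturbed_nodes > len(genes):
        raise ValueError("more perturbations requested than parameters exist")
    edge_pick = [edges[i] for i in rng.choice(len(edges), n_perturbed_edges, replace=False)]
    if extra_edge_se is not None:
        remaining = [e for e in edges if e not in edge_pick]
        if not remaining:
            raise ValueError("no unperturbed edge left for the strong effect")
        strong_edge = remaining[int(rng.integers(len(remaining)))]
    else:
        strong_edge = None
    # node perturbations avoid children of perturbed edges so that injected
    # directions stay unambiguous (edge rewiring compensates the child's
    # intercept, see below)
    edge_children = {c for _, c in edge_pick} | (
        {strong_edge[1]} if strong_edge else set()
    )
    node_candidates = [g for g in genes if g not in edge_children]
    if n_perturbed_nodes > len(node_candidates):
        raise ValueError("not enough genes left for node perturbations")
    node_pick = [
        node_candidates[i]
        for i in rng.choice(len(node_candidates), n_perturbed_nodes, replace=False)
    ]

    injected: list[tuple[ParameterKey, int]] = []

    def perturb_edge(p: str, c: str, k_se: float) -> None:
        """Rewire the p->c coupling at constant expression level: shift the
        edge weight by k_se contrast-SEs and compensate the child's
        intercept by -delta * E[parent] so the child's marginal mean (and
        everything downstream) stays in the microarray band."""
        key = ParameterKey("edge", c, p)
        direction = int(rng.choice([-1, 1]))
        delta = direction * k_se * contrast_se(gt, key, n_per_group, n_per_group)
        case_mean, _ = analytic_moments(gt, "case")
        gt.edge_params["case"][(p, c)] += delta
        gt.node_params["case"][c] -= delta * float(case_mean[p])
        injected.append((key, direction))

    for p, c in edge_pick:
        perturb_edge(p, c, effect_se)
    if strong_edge is not None:
        perturb_edge(*strong_edge, extra_edge_se)
    for g in node_pick:
        key = ParameterKey("node", g)
        direction = int(rng.choice([-1, 1]))
        delta = direction * effect_se * contrast_se(gt, key, n_per_group, n_per_group)
        gt.node_params["case"][g] = control_nodes[g] + delta
        injected.append((key, direction))

    gt.injected = injected
    perturbed: list[tuple[ParameterKey, int]] = []
    for g in genes:
        diff = gt.node_params["case"][g] - gt.node_params["control"][g]
        if diff != 0:
            perturbed.append((ParameterKey("node", g), int(np.sign(diff))))
    for p, c in edges:
        diff = gt.edge_params["case"][(p, c)] - gt.edge_params["control"][(p, c)]
        if diff != 0:
            perturbed.append((ParameterKey("edge", c, p), int(np.sign(diff))))
    gt.perturbed = perturbed
    return gt


def default_study_design(
    n_case: int = 40,
    n_control: int = 40,
    seed: int = 0,
    dropout: dict[str, tuple[str, ...]] | None = None,
) -> StudyDesign:
    """Three platforms x two datasets each, with distinct batch effects.

    Mirrors the six-dataset / three-platform layout of a multi-cohort
    microarray study; n_case/n_control are per dataset, so each platform has
    twice as many subjects per group.
    """
    shifts = {"A1": 1.2, "A2": -0.8, "I1": 0.6, "I2": -1.0, "H1": 0.9, "H2": -0.5}
    datasets = tuple(
        DatasetDesign(
            dataset_id=f"DS{tag}",
            platform_id=tag[0],
            n_case=n_case,
            n_control=n_control,
            shift=shift,
            shift_sd=0.3,
            scale=1.0,
            scale_sd=0.05,
        )
        for tag, shift in shifts.items()
    )
    if dropout is None:
        # a sink gene: its absence removes parameters from one platform
        # without misspecifying any other gene's regression there
        dropout = {"I": ("IL2",)}
    return StudyDesign(datasets=datasets, dropout=dropout, seed=seed)
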