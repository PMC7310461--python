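"""Cross-platform normalization (CPN) of multi-dataset expression studies.

Datasets sharing a platform are quantile-normalized individually, merged on
the intersection of their gene sets (columns concatenated, with a lost-gene
report per member dataset), and batch-adjusted with a parametric
empirical-Bayes location/scale model (ComBat), optionally protecting the
case/control contrast with a group covariate.  Numeric QC summaries
(per-sample quartiles, top principal components, PC1~batch R^2) replace the
usual boxplot/PCA figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "MergedPlatformDataset",
    "QCReport",
    "quantile_normalize",
    "quantile_normalize_frame",
    "merge_platform",
    "combat_adjust",
    "qc_summary",
    "collapse_probes",
]

GROUPS = ("case", "control")


def _check_meta(matrix: pd.DataFrame, sample_meta: pd.DataFrame) -> None:
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate sample ids in matrix")
    if list(matrix.columns) != list(sample_meta.index):
        raise ValueError("matrix columns and sample_meta index must align")
    if "group" not in sample_meta.columns:
        raise ValueError("sample_meta requires a 'group' column")
    bad = set(sample_meta["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")


@dataclass
class ExpressionDataset:
    """One expression dataset: genes x samples log-scale matrix + metadata.

    ``sample_meta`` is indexed by sample_id with a ``group`` column
    ("case"/"control").
    """

    dataset_id: str
    platform_id: str
    matrix: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.matrix.shape[0] < 1 or self.matrix.shape[1] < 2:
            raise ValueError(
                f"dataset {self.dataset_id}: need >=1 gene and >=2 samples, "
                f"got shape {self.matrix.shape}"
            )
        _check_meta(self.matrix, self.sample_meta)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def group_counts(self) -> dict[str, int]:
        vc = self.sample_meta["group"].value_counts()
        return {g: int(vc.get(g, 0)) for g in GROUPS}


@dataclass
class MergedPlatformDataset:
    """Per-platform merge: gene intersection x concatenated samples.

    ``sample_meta`` carries group and dataset_id (the batch label) per sample;
    ``lost_gene_report`` holds, per member dataset, its original gene count
    and the fraction lost to the intersection.
    """

    platform_id: str
    matrix: pd.DataFrame
    sample_meta: pd.DataFrame
    lost_gene_report: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        _check_meta(self.matrix, self.sample_meta)
        if "dataset_id" not in self.sample_meta.columns:
            raise ValueError("merged sample_meta requires a 'dataset_id' column")

    @property
    def batches(self) -> list[str]:
        return sorted(self.sample_meta["dataset_id"].unique())

    def group_matrix(self, group: str) -> pd.DataFrame:
        keep = self.sample_meta.index[self.sample_meta["group"] == group]
        return self.matrix[keep]


# -- quantile normalization ----------------------------------------------

def quantile_normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to their common mean distribution.

    After normalization every column, when sorted, equals the across-column
    mean of sorted columns; ties within a column receive the mean of the
    reference values at the tied ranks (limma's normalizeQuantiles
    convention).  A single-column frame is returned unchanged.
    """
    vals = df.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        rows, cols = np.nonzero(~np.isfinite(vals))
        cells = [(df.index[r], df.columns[c]) for r, c in zip(rows[:10], cols[:10])]
        raise ValueError(f"non-finite expression values at {cells}")
    n, k = vals.shape
    order = np.argsort(vals, axis=0, kind="mergesort")
    ref = np.take_along_axis(vals, order, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(k):
        oj = order[:, j]
        sorted_col = vals[oj, j]
        starts = np.flatnonzero(np.r_[True, np.diff(sorted_col) != 0])
        counts = np.diff(np.r_[starts, n])
        means = np.add.reduceat(ref, starts) / counts
        out[oj, j] = np.repeat(means, counts)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def quantile_normalize(d: ExpressionDataset) -> ExpressionDataset:
    """Quantile-normalize a dataset's matrix; labels are unchanged."""
    return replace(d, matrix=quantile_normalize_frame(d.matrix))


def collapse_probes(matrix: pd.DataFrame, probe_to_gene: dict[str, str]) -> pd.DataFrame:
    """Collapse many-probes-per-gene rows, keeping the highest-mean probe.

    Probes absent from the map are dropped. The winning probe per gene is
    deterministic: highest mean intensity, ties broken by probe id.
    """
    mapped = matrix.loc[matrix.index.isin(probe_to_gene)]
    genes = pd.Series({p: probe_to_gene[p] for p in mapped.index})
    means = mapped.mean(axis=1)
    rank = pd.DataFrame({"gene": genes, "mean": means, "probe": mapped.index})
    winners = (
        rank.sort_values(["gene", "mean", "probe"], ascending=[True, False, True])
        .drop_duplicates("gene")["probe"]
    )
    out = mapped.loc[winners]
    out.index = [probe_to_gene[p] for p in out.index]
    return out.sort_index()


# -- merging --------------------------------------------------------------

def merge_platform(datasets: list[ExpressionDataset]) -> MergedPlatformDataset:
    """Merge same-platform datasets on the intersection of their gene sets."""
    if not datasets:
        raise ValueError("merge_platform requires >=1 dataset")
    platforms = {d.platform_id for d in datasets}
    if len(platforms) != 1:
        raise ValueError(f"mixed platform_ids in merge: {sorted(platforms)}")
    ids = [d.dataset_id for d in datasets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate dataset_ids in merge: {ids}")

    shared: set[str] = set(datasets[0].matrix.index)
    for d in datasets[1:]:
        shared &= set(d.matrix.index)
    if not shared:
        raise ValueError("empty gene intersection across datasets")
    genes = sorted(shared)

    blocks, metas, report = [], [], []
    for d in datasets:
        blocks.append(d.matrix.loc[genes])
        meta = d.sample_meta.copy()
        meta["dataset_id"] = d.dataset_id
        metas.append(meta)
        n_genes = d.matrix.shape[0]
        report.append(
            {
                "dataset_id": d.dataset_id,
                "n_genes": n_genes,
                "n_shared": len(genes),
                "lost_fraction": 1.0 - len(genes) / n_genes,
            }
        )
    matrix = pd.concat(blocks, axis=1)
    sample_meta = pd.concat(metas, axis=0)
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate sample ids across merged datasets")
    return MergedPlatformDataset(
        platform_id=datasets[0].platform_id,
        matrix=matrix,
        sample_meta=sample_meta,
        lost_gene_report=pd.DataFrame(report).set_index("dataset_id"),
    )


# -- ComBat ---------------------------------------------------------------

def _eb_fit_batch(
    z_batch: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    t2: float,
    a_prior: float,
    b_prior: float,
    conv: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative empirical-Bayes shrinkage of one batch's per-gene effects."""
    n = z_batch.shape[1]
    g_old, d_old = gamma_hat.copy(), delta_hat.copy()
    for _ in range(max_iter):
        g_new = (n * t2 * gamma_hat + d_old * gamma_bar) / (n * t2 + d_old)
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n / 2 + a_prior - 1)
        change = max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max())
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_adjust(
    m: MergedPlatformDataset,
    preserve_group: bool = True,
    conv: float = 1e-4,
    max_iter: int = 1000,
    allow_single_batch: bool = False,
) -> MergedPlatformDataset:
    """Parametric empirical-Bayes batch adjustment (ComBat).

    Per gene, expression is standardized against a grand model (batch
    indicators plus, when ``preserve_group`` is set, a case/control
    covariate whose effect is retained); per-batch location (gamma) and scale
    (delta^2) effects are shrunk toward normal / inverse-gamma priors whose
    hyperparameters come from method-of-moments fits across genes; the
    shrinkage iteration stops when the largest absolute parameter change
    drops below ``conv``.  Adjusted data are back-transformed to the original
    scale; shape and labels are unchanged.

    Zero-variance genes pass through unadjusted with a warning.  A single
    batch is an error unless ``allow_single_batch`` bypasses validation, in
    which case the data are returned unchanged (nothing to adjust).
    """
    meta = m.sample_meta
    batches = m.batches
    if len(batches) < 2:
        if allow_single_batch:
            return replace(m, matrix=m.matrix.copy())
        raise ValueError("ComBat requires >=2 batches (dataset_ids)")
    masks = [(meta["dataset_id"] == b).to_numpy() for b in batches]
    sizes = [int(mask.sum()) for mask in masks]
    small = [b for b, s in zip(batches, sizes) if s < 2]
    if small:
        raise ValueError(
            f"batches with a single sample: {small}; merge them into another "
            "batch or exclude them before ComBat"
        )

    X = m.matrix.to_numpy(dtype=float)
    n_array = X.shape[1]

    active = X.var(axis=1) > 0
    design_cols = [mask.astype(float) for mask in masks]
    if preserve_group:
        grp = (meta["group"] == "case").to_numpy(dtype=float)
        if 0 < grp.sum() < n_array:  # both groups present
            design_cols.append(grp)
    design = np.column_stack(design_cols)
    nb = len(batches)

    Y = X[active]
    beta_hat, *_ = np.linalg.lstsq(design, Y.T, rcond=None)
    resid = Y.T - design @ beta_hat
    var_pooled = (resid**2).mean(axis=0)
    degenerate = var_pooled <= 0
    if degenerate.any() or not active.all():
        n_bad = int(degenerate.sum() + (~active).sum())
        warnings.warn(
            f"{n_bad} zero-variance gene(s) passed through ComBat unadjusted",
            stacklevel=2,
        )
    keep = ~degenerate
    Y, beta_hat, var_pooled = Y[keep], beta_hat[:, keep], var_pooled[keep]
    idx_active = np.flatnonzero(active)[keep]

    grand = (np.asarray(sizes) / n_array) @ beta_hat[:nb]
    stand_mean = np.tile(grand[:, None], (1, n_array))
    if design.shape[1] > nb:
        stand_mean += (design[:, nb:] @ beta_hat[nb:]).T
    Z = (Y - stand_mean) / np.sqrt(var_pooled)[:, None]

    n_genes = Z.shape[0]
    Z_adj = np.empty_like(Z)
    for mask, size in zip(masks, sizes):
        zb = Z[:, mask]
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)
        if n_genes >= 2 and gamma_hat.var(ddof=1) > 0 and delta_hat.var(ddof=1) > 0:
            gamma_bar = float(gamma_hat.mean())
            t2 = float(gamma_hat.var(ddof=1))
            dm, ds2 = float(delta_hat.mean()), float(delta_hat.var(ddof=1))
            a_prior = (2 * ds2 + dm**2) / ds2
            b_prior = (dm * ds2 + dm**3) / ds2
            gamma_star, delta_star = _eb_fit_batch(
                zb, gamma_hat, delta_hat, gamma_bar, t2, a_prior, b_prior, conv, max_iter
            )
        else:  # too few genes to estimate hyperpriors: no shrinkage
            gamma_star, delta_star = gamma_hat, delta_hat
        Z_adj[:, mask] = (zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out = X.copy()
    out[idx_active] = Z_adj * np.sqrt(var_pooled)[:, None] + stand_mean
    return replace(
        m, matrix=pd.DataFrame(out, index=m.matrix.index, columns=m.matrix.columns)
    )


# -- QC -------------------------------------------------------------------

@dataclass
class QCReport:
    """Numeric stand-in for the usual before/after boxplot + PCA figures."""

    sample_quartiles: pd.DataFrame  # q25/median/q75 per sample
    pc_scores: pd.DataFrame  # PC1, PC2 per sample
    pc1_var_frac: float  # fraction of variance on PC1
    pc1_batch_r2: float  # R^2 of PC1 ~ batch (dataset_id)
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "pc1_var_frac": self.pc1_var_frac,
            "pc1_batch_r2": self.pc1_batch_r2,
            "degenerate": self.degenerate,
            "sample_quartiles": self.sample_quartiles.to_dict(orient="index"),
            "pc_scores": self.pc_scores.to_dict(orient="index"),
        }


def qc_summary(m: MergedPlatformDataset) -> QCReport:
    """Per-sample quartiles plus top-2 PCs and the PC1~batch R^2."""
    vals = m.matrix.to_numpy(dtype=float)
    q = np.percentile(vals, [25, 50, 75], axis=0)
    quartiles = pd.DataFrame(
        q.T, index=m.matrix.columns, columns=["q25", "median", "q75"]
    )
    centered = vals.T - vals.mean(axis=1)  # samples x genes
    total_var = (centered**2).sum()
    if total_var <= 0:
        zeros = pd.DataFrame(
            0.0, index=m.matrix.columns, columns=["PC1", "PC2"]
        )
        return QCReport(quartiles, zeros, 0.0, 0.0, degenerate=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :2] * s[:2]
    if scores.shape[1] < 2:
        scores = np.column_stack([scores, np.zeros(len(scores))])
    pc = pd.DataFrame(scores, index=m.matrix.columns, columns=["PC1", "PC2"])
    pc1 = pc["PC1"].to_numpy()
    grand = pc1.mean()
    ss_tot = ((pc1 - grand) ** 2).sum()
    ss_between = 0.0
    for b in m.batches:
        sel = (m.sample_meta["dataset_id"] == b).to_numpy()
        ss_between += sel.sum() * (pc1[sel].mean() - grand) ** 2
    r2 = float(ss_between / ss_tot) if ss_tot > 0 else 0.0
    return QCReport(
        quartiles, pc, float(s[0] ** 2 / (s**2).sum()), r2, degenerate=False
    )
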