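"""Study manifests: per-dataset sample counts and the platform arithmetic.

The manifest is the bookkeeping table of a multi-cohort study — one row per
dataset with its platform and case/control counts.  Platform subject totals
N_j derived here are exactly the quantities that weight the mixture merge
(p_j = N_j / sum N_j).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import yaml

from .merge import PlatformWeights, platform_weights

__all__ = ["StudyManifest", "load_manifest"]

_REQUIRED = ("dataset_id", "platform_id", "n_case", "n_control")


@dataclass
class StudyManifest:
    """Validated manifest with derived platform totals."""

    table: pd.DataFrame  # columns: dataset_id, platform_id, n_case, n_control

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _REQUIRED if c not in t.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if t["dataset_id"].duplicated().any():
            dupes = t.loc[t["dataset_id"].duplicated(), "dataset_id"].tolist()
            raise ValueError(f"duplicate dataset_id rows: {dupes}")
        for _, row in t.iterrows():
            for col in ("n_case", "n_control"):
                n = row[col]
                if not float(n).is_integer() or n <= 0:
                    raise ValueError(
                        f"dataset {row['dataset_id']!r}: {col}={n!r} must be a "
                        "positive integer"
                    )

    @property
    def total_cases(self) -> int:
        return int(self.table["n_case"].sum())

    @property
    def total_controls(self) -> int:
        return int(self.table["n_control"].sum())

    def platform_subjects(self) -> dict[str, int]:
        """N_j = sum over member datasets of (n_case + n_control)."""
        subj = self.table["n_case"] + self.table["n_control"]
        return {
            str(k): int(v)
            for k, v in subj.groupby(self.table["platform_id"]).sum().items()
        }

    def weights(self) -> PlatformWeights:
        return platform_weights(self.platform_subjects())


def load_manifest(source) -> StudyManifest:
    """Load a manifest from YAML text, a path, or a parsed mapping.

    Expected shape: ``datasets: [{dataset_id, platform_id, n_case,
    n_control}, ...]``.  Errors name the offending row.
    """
    if isinstance(source, dict):
        doc = source
    else:
        text = source
        if hasattr(source, "read_text"):
            text = source.read_text()
        elif isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml")):
            from pathlib import Path

            text = Path(source).read_text()
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "datasets" not in doc:
        raise ValueError("manifest YAML must contain a 'datasets' list")
    rows = []
    for i, row in enumerate(doc["datasets"]):
        missing = [c for c in _REQUIRED if c not in row]
        if missing:
            raise ValueError(f"manifest row {i} ({row.get('dataset_id', '?')}): missing {missing}")
        rows.append({c: row[c] for c in _REQUIRED})
    return StudyManifest(pd.DataFrame(rows, columns=list(_REQUIRED)))
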