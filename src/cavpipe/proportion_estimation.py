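"""Marker-based relative cell-type proportion proxies for bulk samples.

For each cell type present in a tissue, the per-sample trimmed mean of its
marker genes (on log2(TPM+1)) serves as a reference profile; markers whose
Pearson correlation with that reference exceeds 0.33 are kept as
*informative*, and the final score is the trimmed mean over informative
markers only.  Scores are relative abundances in arbitrary (log) units,
never normalized to a simplex — they are used solely as regression
predictors downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix
from .marker_discovery import CellTypeMarkerCatalog

__all__ = [
    "ProportionConfig",
    "ProportionTable",
    "trimmed_mean",
    "select_informative_markers",
    "estimate_proportions",
]


@dataclass(frozen=True)
class ProportionConfig:
    trim_fraction: float = 0.05  # removed from *each* tail
    informative_r_threshold: float = 0.33
    min_informative_markers: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.trim_fraction <= 0.25:
            raise ValueError("trim_fraction must lie in [0, 0.25]")
        if not -1.0 <= self.informative_r_threshold <= 1.0:
            raise ValueError("informative_r_threshold must lie in [-1, 1]")
        if self.min_informative_markers < 1:
            raise ValueError("min_informative_markers must be >= 1")


@dataclass
class ProportionTable:
    scores: pd.DataFrame  # sample x cell type
    informative_markers: dict[str, list[str]]
    excluded_cell_types: dict[str, str] = field(default_factory=dict)


def trimmed_mean(values: np.ndarray, trim_fraction: float) -> float:
    """Mean after dropping floor(trim_fraction * n) values from each tail.

    When n is too small for the floor to remove anything, this is the
    plain mean.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot take the trimmed mean of an empty vector")
    k = int(np.floor(trim_fraction * v.size))
    if k == 0:
        return float(v.mean())
    v = np.sort(v)
    return float(v[k : v.size - k].mean())


def _trimmed_mean_rows(mat: np.ndarray, trim_fraction: float) -> np.ndarray:
    """Row-wise trimmed mean of a 2-D array (rows = samples)."""
    n = mat.shape[1]
    k = int(np.floor(trim_fraction * n))
    if k == 0:
        return mat.mean(axis=1)
    s = np.sort(mat, axis=1)
    return s[:, k : n - k].mean(axis=1)


def _log2_tpm(expr: ExpressionMatrix) -> pd.DataFrame:
    if expr.unit == "logTPM":
        return expr.values
    return np.log2(expr.values + 1.0)


def select_informative_markers(
    expr: ExpressionMatrix,
    markers: list[str],
    config: ProportionConfig = ProportionConfig(),
) -> tuple[list[str], np.ndarray]:
    """Filter a marker list down to the genes tracking their joint reference.

    The reference is the per-sample trimmed mean of all candidate markers
    on log2(TPM+1); a marker is informative if its Pearson r with the
    reference across samples exceeds the threshold (strict).
    Returns the surviving markers and the reference profile.
    """
    present = [g for g in markers if g in expr.gene_ids]
    if not present:
        raise ValueError("none of the markers are present in the expression matrix")
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples to correlate markers")
    log_expr = _log2_tpm(expr).loc[present]  # markers x samples
    mat = log_expr.to_numpy().T  # samples x markers
    reference = _trimmed_mean_rows(mat, config.trim_fraction)
    kept = []
    ref_c = reference - reference.mean()
    ref_ss = float(ref_c @ ref_c)
    for j, gene in enumerate(present):
        x = mat[:, j] - mat[:, j].mean()
        denom = np.sqrt(float(x @ x) * ref_ss)
        r = float(x @ ref_c) / denom if denom > 0 else 0.0
        if r > config.informative_r_threshold:
            kept.append(gene)
    return kept, reference


def estimate_proportions(
    expr: ExpressionMatrix,
    catalog: CellTypeMarkerCatalog,
    tissue: str,
    config: ProportionConfig = ProportionConfig(),
    candidate_cell_types: list[str] | None = None,
) -> ProportionTable:
    """Score every estimable cell type of a tissue across its bulk samples.

    Candidate cell types default to those the catalog detected in the
    tissue (or, for tissues without single-nucleus data, all consensus
    cell types — pass them via ``candidate_cell_types``).  A cell type is
    excluded, with a recorded reason, when no marker is present in the
    matrix or fewer than ``min_informative_markers`` markers survive the
    correlation filter.
    """
    sub = expr.subset_tissue(tissue) if tissue in set(expr.tissues()) else expr
    if sub.n_samples < 3:
        raise ValueError(f"tissue {tissue!r} has fewer than 3 samples")
    if candidate_cell_types is None:
        candidate_cell_types = list(catalog.detected_in) if tissue not in catalog.per_tissue else list(
            catalog.per_tissue[tissue]
        )
    log_expr = _log2_tpm(sub)
    scores: dict[str, np.ndarray] = {}
    informative: dict[str, list[str]] = {}
    excluded: dict[str, str] = {}
    for ct in candidate_cell_types:
        markers = catalog.consensus.get(ct, [])
        present = [g for g in markers if g in sub.gene_ids]
        if not present:
            excluded[ct] = "no consensus markers present in expression matrix"
            continue
        kept, _ = select_informative_markers(sub, present, config)
        if len(kept) < config.min_informative_markers:
            excluded[ct] = (
                f"only {len(kept)} informative markers "
                f"(< {config.min_informative_markers})"
            )
            continue
        mat = log_expr.loc[kept].to_numpy().T  # samples x informative markers
        scores[ct] = _trimmed_mean_rows(mat, config.trim_fraction)
        informative[ct] = kept
    if not scores:
        raise ValueError(f"tissue {tissue!r}: no estimable cell types ({excluded})")
    table = pd.DataFrame(scores, index=sub.sample_ids)
    return ProportionTable(scores=table, informative_markers=informative, excluded_cell_types=excluded)
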