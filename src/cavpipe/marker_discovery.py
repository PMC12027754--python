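"""Cell-type marker discovery from single-nucleus counts.

Markers are found per tissue by a one-vs-rest Wilcoxon rank-sum test on
pooled cells (all donors pooled to raise per-type cell counts), with
Bonferroni adjustment over the genes tested within each cell-type
comparison and retention of positive markers only.  Cell types observed in
several tissues get a consensus list: a gene is a consensus marker if it
was flagged in at least half of the tissues where the cell type was
detected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneSetCollection, SingleNucleusDataset

__all__ = [
    "MarkerTestResult",
    "CellTypeMarkerCatalog",
    "wilcoxon_markers",
    "marker_statistics",
    "discover_markers",
    "consensus_markers",
    "classify_gene_status",
]

#: Largest per-group size for which the exact rank-sum null is used; above
#: this the tie-corrected normal approximation with continuity correction.
EXACT_MAX_N = 20


@dataclass
class MarkerTestResult:
    """Full per-gene test table for one tissue (both directions retained)."""

    tissue: str
    table: pd.DataFrame  # gene, cell_type, effect_direction, p_raw, p_adjusted

    def positive_markers(self, alpha: float = 0.05) -> dict[str, list[str]]:
        t = self.table
        hit = t[(t["effect_direction"] == "positive") & (t["p_adjusted"] < alpha)]
        out: dict[str, list[str]] = {ct: [] for ct in t["cell_type"].unique()}
        for ct, grp in hit.groupby("cell_type", observed=True):
            out[ct] = grp["gene"].tolist()
        return out

    def negative_markers(self, alpha: float = 0.05) -> dict[str, list[str]]:
        t = self.table
        hit = t[(t["effect_direction"] == "negative") & (t["p_adjusted"] < alpha)]
        out: dict[str, list[str]] = {ct: [] for ct in t["cell_type"].unique()}
        for ct, grp in hit.groupby("cell_type", observed=True):
            out[ct] = grp["gene"].tolist()
        return out


@dataclass
class CellTypeMarkerCatalog:
    """Per-tissue and consensus marker lists per cell type."""

    per_tissue: dict[str, dict[str, list[str]]]
    consensus: dict[str, list[str]]
    detected_in: dict[str, list[str]]
    negative_per_tissue: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    universe: list[str] | None = None  # gene ids seen during discovery

    def to_gmt(self) -> GeneSetCollection:
        sets = {ct: genes for ct, genes in self.consensus.items() if genes}
        return GeneSetCollection(sets, {ct: {"kind": "cell_type_markers"} for ct in sets})


def _rank_sum_pvalues(in_group: np.ndarray, rest: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p per gene (columns); exact null for small groups.

    Constant genes (identical value in every pooled cell) get p = 1: there
    is no evidence of any shift, and the tie-corrected variance degenerates.
    """
    n1, n2 = in_group.shape[0], rest.shape[0]
    method = "exact" if max(n1, n2) <= EXACT_MAX_N else "asymptotic"
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(
            in_group, rest, axis=0, alternative="two-sided", method=method,
            use_continuity=True,
        )
    p = np.asarray(res.pvalue, dtype=float)
    pooled = np.vstack([in_group, rest])
    constant = pooled.max(axis=0) == pooled.min(axis=0)
    p = np.where(constant | ~np.isfinite(p), 1.0, p)
    return np.minimum(p, 1.0)


def marker_statistics(
    data: SingleNucleusDataset,
    tissue: str,
    min_cells: int = 3,
    min_frac_expressed: float = 0.10,
) -> MarkerTestResult:
    """One-vs-rest rank-sum statistics for every cell type in one tissue.

    Genes enter a comparison only if detected (count > 0) in at least
    ``min_frac_expressed`` of the in-type cells; Bonferroni m is the number
    of genes actually tested within that comparison.
    """
    sub = data.subset_tissue(tissue)
    if sub.n_cells == 0:
        raise ValueError(f"tissue {tissue!r} has no cells")
    labels = sub.cell_annotations["cell_type"]
    counts = labels.value_counts()
    present = [ct for ct, c in counts.items() if c >= min_cells]
    if len(present) < 2:
        raise ValueError(
            f"tissue {tissue!r}: no reference population "
            f"(needs >=2 cell types with >={min_cells} cells)"
        )
    X = np.asarray(sub.counts.todense(), dtype=float)
    rows = []
    for ct in present:
        mask = (labels == ct).to_numpy()
        in_grp, rest = X[mask], X[~mask]
        detected_frac = (in_grp > 0).mean(axis=0)
        tested = detected_frac >= min_frac_expressed
        if not tested.any():
            continue
        p_raw = _rank_sum_pvalues(in_grp[:, tested], rest[:, tested])
        m = int(tested.sum())
        p_adj = np.minimum(1.0, m * p_raw)
        direction = np.where(
            in_grp[:, tested].mean(axis=0) > rest[:, tested].mean(axis=0),
            "positive",
            "negative",
        )
        genes = data.gene_ids[tested]
        rows.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "cell_type": ct,
                    "tissue": tissue,
                    "effect_direction": direction,
                    "p_raw": p_raw,
                    "p_adjusted": p_adj,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    return MarkerTestResult(tissue=tissue, table=table)


def wilcoxon_markers(
    data: SingleNucleusDataset,
    tissue: str,
    alpha: float = 0.05,
    min_cells: int = 3,
    min_frac_expressed: float = 0.10,
) -> pd.DataFrame:
    """Significant positive markers for one tissue (records table).

    Returns the rows of :func:`marker_statistics` with positive direction
    and Bonferroni-adjusted p below ``alpha``.
    """
    res = marker_statistics(data, tissue, min_cells=min_cells, min_frac_expressed=min_frac_expressed)
    t = res.table
    return t[(t["effect_direction"] == "positive") & (t["p_adjusted"] < alpha)].reset_index(drop=True)


def discover_markers(
    data: SingleNucleusDataset,
    alpha: float = 0.05,
    min_cells: int = 3,
    min_frac_expressed: float = 0.10,
) -> CellTypeMarkerCatalog:
    """Run per-tissue discovery on every tissue, then build the consensus."""
    per_tissue: dict[str, dict[str, list[str]]] = {}
    negative: dict[str, dict[str, list[str]]] = {}
    for tissue in data.cell_annotations["tissue"].unique():
        res = marker_statistics(
            data, tissue, min_cells=min_cells, min_frac_expressed=min_frac_expressed
        )
        per_tissue[tissue] = res.positive_markers(alpha)
        negative[tissue] = res.negative_markers(alpha)
    catalog = consensus_markers(per_tissue)
    catalog.negative_per_tissue = negative
    catalog.universe = list(data.gene_ids)
    return catalog


def consensus_markers(per_tissue: dict[str, dict[str, list[str]]]) -> CellTypeMarkerCatalog:
    """Cross-tissue consensus: marker in >= half of the detecting tissues.

    A cell type counts as detected in every tissue whose catalog lists it
    (even with an empty marker list).  The threshold is ceil(n/2), i.e.
    2-of-4 and 2-of-3 qualify, 1-of-3 does not; a cell type seen in a
    single tissue inherits that tissue's markers.
    """
    if not per_tissue:
        raise ValueError("need at least one per-tissue catalog")
    detected_in: dict[str, list[str]] = {}
    votes: dict[str, dict[str, int]] = {}
    for tissue, ct_map in per_tissue.items():
        for ct, genes in ct_map.items():
            detected_in.setdefault(ct, []).append(tissue)
            bucket = votes.setdefault(ct, {})
            for g in dict.fromkeys(genes):
                bucket[g] = bucket.get(g, 0) + 1
    consensus: dict[str, list[str]] = {}
    for ct, tissues in detected_in.items():
        need = math.ceil(len(tissues) / 2)
        consensus[ct] = sorted(g for g, v in votes.get(ct, {}).items() if v >= need)
    return CellTypeMarkerCatalog(
        per_tissue={t: {ct: list(dict.fromkeys(g)) for ct, g in m.items()} for t, m in per_tissue.items()},
        consensus=consensus,
        detected_in=detected_in,
    )


def classify_gene_status(
    gene: str, catalog: CellTypeMarkerCatalog, tissue: str
) -> dict[str, str]:
    """Per-cell-type status of one gene in one tissue.

    ``positive_marker`` if the gene is a consensus marker of the cell type,
    ``negative_marker`` if it was significantly depleted in that cell type
    in this tissue's negative-direction pass, else ``neither``.
    """
    if tissue not in catalog.per_tissue:
        raise KeyError(f"tissue {tissue!r} not in catalog")
    if catalog.universe is not None:
        known = set(catalog.universe)
    else:
        known = set()
        for source in (catalog.per_tissue, catalog.negative_per_tissue):
            for ct_map in source.values():
                for genes in ct_map.values():
                    known.update(genes)
        for genes in catalog.consensus.values():
            known.update(genes)
    if gene not in known:
        raise KeyError(f"gene {gene!r} unknown to the catalog")
    out: dict[str, str] = {}
    negatives = catalog.negative_per_tissue.get(tissue, {})
    for ct in catalog.per_tissue[tissue]:
        if gene in catalog.consensus.get(ct, []):
            out[ct] = "positive_marker"
        elif gene in negatives.get(ct, []):
            out[ct] = "negative_marker"
        else:
            out[ct] = "neither"
    return out
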