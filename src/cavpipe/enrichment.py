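"""Pre-ranked gene-set enrichment of correlation vectors.

First level: genes ranked by their tissue-specific correlation with CAV1
are scanned with the weighted Kolmogorov-Smirnov running-sum statistic
(hit increments proportional to |r|^p, miss decrements 1/(N-k)); p-values
come from a gene-label permutation null (random same-size sets), are
signed one-sided within the sign class, and are BH-adjusted across the
sets tested in a tissue.

Second level: ChIP-style target datasets are themselves ranked by their
first-level NES, and each transcriptional regulator's datasets form a set
in a second pre-ranked scan, yielding a Gene Set Rank Statistic (GSRS)
per regulator with a dataset-label permutation p.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection
from .marker_discovery import CellTypeMarkerCatalog
from .tscv import TSCV

__all__ = [
    "rank_from_tscv",
    "gsea_es",
    "gsea_permutation",
    "preranked_gsea",
    "meta_enrichment_gsrs",
    "celltype_enrichment",
    "summarize_enrichment",
]

MIN_SET_SIZE = 5
MAX_SET_SIZE = 2000


def rank_from_tscv(tscv: TSCV, min_genes: int = 100) -> pd.Series:
    """Genes sorted by correlation, descending; missing removed.

    Ties break by gene id so the ranking is invariant to input order.
    """
    r = tscv.r.dropna()
    if len(r) < min_genes:
        raise ValueError(f"only {len(r)} non-missing genes (< {min_genes})")
    df = pd.DataFrame({"stat": r}).sort_index(kind="stable")
    df = df.sort_values("stat", ascending=False, kind="stable")
    return df["stat"]


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------


def gsea_es(
    ranked: pd.Series, gene_set: list[str], weight_p: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS running sum for one set; returns (ES, profile, leading edge).

    ES is the extremum of the running sum; when the positive and negative
    extrema tie in magnitude exactly, the positive one is reported.
    """
    members = set(gene_set) & set(ranked.index)
    if not members:
        raise ValueError("gene set has no overlap with the ranked universe")
    N = len(ranked)
    k = len(members)
    if k >= N:
        raise ValueError("gene set covers the whole universe")
    is_hit = ranked.index.isin(members)
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight_p
    w_hit = np.where(is_hit, w, 0.0)
    total = w_hit.sum()
    if total == 0:  # all member stats exactly zero: flat hit weights
        w_hit = is_hit.astype(float)
        total = float(k)
    inc = w_hit / total
    dec = np.where(is_hit, 0.0, 1.0 / (N - k))
    running = np.cumsum(inc - dec)
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    es = float(running[i_max]) if running[i_max] >= -running[i_min] else float(running[i_min])
    if es >= 0:
        leading = [g for g, h in zip(ranked.index[: i_max + 1], is_hit[: i_max + 1]) if h]
    else:
        leading = [g for g, h in zip(ranked.index[i_min:], is_hit[i_min:]) if h]
    return es, running, leading


def _es_batch(w: np.ndarray, positions: np.ndarray, N: int) -> np.ndarray:
    """ES for many same-size index sets, evaluated only at hit positions.

    ``w`` is the |stat|^p weight vector over the ranked universe;
    ``positions`` is (B, k), each row the sorted 0-based ranks of a set.
    """
    B, k = positions.shape
    dec = 1.0 / (N - k)
    wp = w[positions]
    tot = wp.sum(axis=1, keepdims=True)
    flat = tot[:, 0] == 0
    if flat.any():
        wp[flat] = 1.0
        tot[flat] = float(k)
    H = np.cumsum(wp, axis=1) / tot
    m = np.arange(1, k + 1)
    after = H - (positions + 1 - m) * dec
    before = (H - wp / tot) - (positions - (m - 1)) * dec
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


# ---------------------------------------------------------------------------
# Permutation p-values
# ---------------------------------------------------------------------------


def preranked_gsea(
    ranked: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    min_size: int = MIN_SET_SIZE,
    max_size: int = MAX_SET_SIZE,
) -> pd.DataFrame:
    """Permutation-based enrichment of many sets against one ranking.

    The null draws random gene-label sets of matched size; the p-value is
    one-sided within the observed sign class,
    ``(1 + #{same-sign |ES_null| >= |ES|}) / (1 + n_same_sign)``, and NES
    divides ES by the mean |ES_null| of that sign class.  Sets with no
    overlap (or out-of-bounds size after intersection) are flagged
    untestable and excluded from the BH universe.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    N = len(ranked)
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight_p
    null_cache: dict[int, np.ndarray] = {}

    def null_es(k: int) -> np.ndarray:
        if k not in null_cache:
            keys = rng.random((n_perm, N))
            pos = np.sort(np.argpartition(keys, k - 1, axis=1)[:, :k], axis=1)
            null_cache[k] = _es_batch(w, pos, N)
        return null_cache[k]

    rows = []
    universe = set(ranked.index)
    for name, members in sets.items():
        overlap = sorted(set(members) & universe)
        k = len(overlap)
        if k == 0 or k < min_size or k > max_size or k >= N:
            rows.append(
                {
                    "set_name": name, "size": k, "ES": np.nan, "NES": np.nan,
                    "p": np.nan, "p_adjusted": np.nan, "direction": 0,
                    "leading_edge": [], "testable": False,
                }
            )
            continue
        es, _, leading = gsea_es(ranked, overlap, weight_p=weight_p)
        null = null_es(k)
        same = null >= 0 if es >= 0 else null < 0
        n_same = int(same.sum())
        exceed = int((np.abs(null[same]) >= abs(es)).sum())
        p = (1 + exceed) / (1 + n_same)
        denom = np.abs(null[same]).mean() if n_same else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        rows.append(
            {
                "set_name": name, "size": k, "ES": es, "NES": nes, "p": p,
                "p_adjusted": np.nan, "direction": int(np.sign(es)),
                "leading_edge": leading, "testable": True,
            }
        )
    out = pd.DataFrame(rows)
    testable = out["testable"].to_numpy()
    if testable.any():
        out.loc[testable, "p_adjusted"] = multipletests(
            out.loc[testable, "p"].to_numpy(), method="fdr_bh"
        )[1]
    return out


def gsea_permutation(
    ranked: pd.Series,
    sets: GeneSetCollection | dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Enrichment of a gene-set collection against one ranked list."""
    mapping = sets.sets if isinstance(sets, GeneSetCollection) else sets
    return preranked_gsea(ranked, mapping, n_perm=n_perm, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# Meta-enrichment (GSRS)
# ---------------------------------------------------------------------------


def meta_enrichment_gsrs(
    first_level: pd.DataFrame,
    regulator_map: dict[str, str],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Second-level enrichment summarizing redundant target datasets.

    Datasets become the ranked universe (ordered by first-level NES) and
    each regulator's member datasets form a set; the resulting ES is the
    regulator's Gene Set Rank Statistic (GSRS) with a dataset-label
    permutation p, BH-adjusted across regulators.  Regulators with no
    tested dataset are omitted.
    """
    tested = first_level[first_level["testable"] & first_level["NES"].notna()]
    if len(tested) < 2:
        raise ValueError("need first-level results for at least two datasets")
    stats = pd.Series(
        tested["NES"].to_numpy(dtype=float), index=tested["set_name"].to_numpy()
    )
    stats = stats[~stats.index.duplicated()]
    ranked = stats.sort_index(kind="stable").sort_values(ascending=False, kind="stable")
    groups: dict[str, list[str]] = {}
    for ds, reg in regulator_map.items():
        if ds in ranked.index:
            groups.setdefault(reg, []).append(ds)
    res = preranked_gsea(
        ranked, groups, n_perm=n_perm, seed=seed, min_size=1, max_size=len(ranked) - 1
    )
    res = res.rename(columns={"set_name": "regulator", "ES": "GSRS"})
    res["member_datasets"] = res["regulator"].map(lambda r: groups.get(r, []))
    return res.drop(columns=["leading_edge"])


# ---------------------------------------------------------------------------
# Cell-type marker enrichment
# ---------------------------------------------------------------------------


def celltype_enrichment(
    tscv: TSCV,
    catalog: CellTypeMarkerCatalog,
    n_perm: int = 1000,
    seed: int = 0,
    min_genes: int = 100,
) -> pd.DataFrame:
    """Enrichment of consensus cell-type marker sets in one tissue's TSCV.

    Adds the target gene's own marker status per cell type (positive
    consensus marker / negative marker in this tissue / neither), the
    annotation used to flag cell types that express the target themselves.
    """
    ranked = rank_from_tscv(tscv, min_genes=min_genes)
    sets = {ct: genes for ct, genes in catalog.consensus.items() if genes}
    if not sets:
        raise ValueError("catalog has no non-empty consensus marker sets")
    res = preranked_gsea(ranked, sets, n_perm=n_perm, seed=seed)
    negatives = catalog.negative_per_tissue.get(tscv.tissue, {})
    status = []
    for ct in res["set_name"]:
        if tscv.target in catalog.consensus.get(ct, []):
            status.append("positive_marker")
        elif tscv.target in negatives.get(ct, []):
            status.append("negative_marker")
        else:
            status.append("neither")
    res = res.rename(columns={"set_name": "cell_type"})
    res["target_marker_status"] = status
    res["tissue"] = tscv.tissue
    return res


# ---------------------------------------------------------------------------
# Cross-tissue summaries
# ---------------------------------------------------------------------------


def summarize_enrichment(
    results: pd.DataFrame, min_tissues: int = 1, alpha: float = 0.05
) -> dict:
    """Signed significance counts per set across tissues.

    ``results`` is the concatenation of per-tissue enrichment tables (a
    ``tissue`` column plus the usual ES/NES/p_adjusted columns).  Returns
    per-set positive/negative significant-tissue counts, the fraction of
    tested sets significant in at least one tissue, and a heatmap-ready
    long table restricted to sets significant in >= ``min_tissues``.
    """
    name_col = "set_name" if "set_name" in results.columns else "cell_type"
    tested = results[results["testable"]]
    sig = tested[tested["p_adjusted"] < alpha]
    counts = (
        sig.assign(sign=np.where(sig["ES"] > 0, "positive", "negative"))
        .pivot_table(index=name_col, columns="sign", values="tissue", aggfunc="nunique", fill_value=0)
        .reindex(columns=["positive", "negative"], fill_value=0)
    )
    counts = counts.reindex(tested[name_col].unique(), fill_value=0).astype(int)
    n_tested_sets = tested[name_col].nunique()
    coverage = counts.sum(axis=1).gt(0).sum() / n_tested_sets if n_tested_sets else np.nan
    total = counts.sum(axis=1)
    keep = total[total >= min_tissues].index
    long = tested[tested[name_col].isin(keep)][
        [c for c in ("tissue", name_col, "ES", "NES", "p", "p_adjusted", "direction") if c in tested.columns]
    ].reset_index(drop=True)
    if long.empty and min_tissues > results["tissue"].nunique():
        import warnings

        warnings.warn(
            f"min_tissues={min_tissues} exceeds the {results['tissue'].nunique()} analyzed tissues",
            stacklevel=2,
        )
    return {"counts": counts, "coverage_fraction": float(coverage), "long_table": long}
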