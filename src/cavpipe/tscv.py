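"""Tissue-specific correlation vectors (TSCVs) around a target gene.

Per tissue: genes are kept when they reach 4 TPM in strictly more than 5%
of the tissue's samples, samples are TMM-normalized (trimmed mean of
M-values against a 75th-percentile reference), expression is
log2(TPM/factor + 1) transformed, and every surviving gene is Pearson-
correlated with the target gene (CAV1).  The per-tissue vectors assemble
into a tissues x genes matrix in which genes not expressed in a tissue
stay *missing* (never zero), and tissues are compared by classical
(Torgerson) multidimensional scaling on correlation distances computed
over pairwise-complete genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix

__all__ = [
    "TSCV",
    "TSCVMatrix",
    "MDSEmbedding",
    "filter_genes",
    "tmm_factors",
    "normalize_log2",
    "compute_tscv",
    "build_tissue_tscv",
    "assemble_tscv_matrix",
    "zero_filled_export",
    "classical_mds",
    "mds_embed",
]

MIN_SAMPLES = 25


@dataclass
class TSCV:
    tissue: str
    r: pd.Series  # gene -> Pearson r with the target, NaN allowed
    n_samples: int
    target: str = "CAV1"


@dataclass
class TSCVMatrix:
    """Tissues x genes correlation matrix with missing-aware semantics."""

    R: pd.DataFrame
    provenance: dict = field(default_factory=dict)


@dataclass
class MDSEmbedding:
    coordinates: pd.DataFrame  # tissue -> dim1, dim2
    eigenvalues: np.ndarray
    explained_fraction: float


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------


def filter_genes(
    expr: ExpressionMatrix, min_tpm: float = 4.0, min_frac: float = 0.05
) -> ExpressionMatrix:
    """Keep genes reaching ``min_tpm`` in strictly more than ``min_frac``
    of the samples (a gene at the threshold TPM counts; a gene hitting it
    in exactly 5% of samples does not)."""
    if expr.unit != "TPM":
        raise ValueError("gene filter operates on TPM matrices")
    vals = expr.values.to_numpy()
    frac = (vals >= min_tpm).mean(axis=1)
    keep = frac > min_frac
    if not keep.any():
        raise ValueError("no gene passes the expression filter")
    return expr.with_values(expr.values.loc[keep], unit="TPM")


def tmm_factors(
    expr: ExpressionMatrix,
    log_ratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per sample.

    The reference is the sample whose 75th percentile of library-
    normalized values sits closest to the mean of those percentiles.  For
    every sample, M (log2 ratio to the reference) and A (average log2
    abundance) are computed on depth-normalized values over genes positive
    in both; the upper and lower ``log_ratio_trim`` of M and
    ``abs_expr_trim`` of A are discarded, and the factor is 2 to the
    precision-weighted mean of the surviving M values.  Factors are
    rescaled to geometric mean 1.
    """
    vals = expr.values.to_numpy(dtype=float)
    lib = vals.sum(axis=0)
    if (lib <= 0).any():
        bad = expr.sample_ids[lib <= 0].tolist()
        raise ValueError(f"samples with all-zero values: {bad}")
    norm = vals / lib
    f75 = np.quantile(norm, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref, lib_ref = vals[:, ref_idx], lib[ref_idx]

    factors = np.ones(expr.n_samples)
    for j in range(expr.n_samples):
        if j == ref_idx:
            continue
        obs, lib_obs = vals[:, j], lib[j]
        ok = (obs > 0) & (ref > 0)
        if not ok.any():
            continue
        o, r = obs[ok], ref[ok]
        M = np.log2((o / lib_obs) / (r / lib_ref))
        A = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
        finite = np.isfinite(M) & np.isfinite(A)
        M, A, o, r = M[finite], A[finite], o[finite], r[finite]
        if M.size == 0 or np.max(np.abs(M)) < 1e-6:
            continue
        n = M.size
        lo_m, hi_m = np.floor(n * log_ratio_trim) + 1, n - np.floor(n * log_ratio_trim)
        lo_a, hi_a = np.floor(n * abs_expr_trim) + 1, n - np.floor(n * abs_expr_trim)
        rank_m = pd.Series(M).rank().to_numpy()
        rank_a = pd.Series(A).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            continue
        # inverse asymptotic (binomial) variance of M as weights
        w = 1.0 / ((lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r))
        factors[j] = 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=expr.sample_ids, name="tmm_factor")


def normalize_log2(expr: ExpressionMatrix, factors: pd.Series) -> ExpressionMatrix:
    """log2(TPM / factor + 1) with per-sample TMM factors; unit -> logTPM."""
    scaled = expr.values / factors.loc[expr.sample_ids]
    return expr.with_values(np.log2(scaled + 1.0), unit="logTPM")


# ---------------------------------------------------------------------------
# Correlation vectors
# ---------------------------------------------------------------------------


def compute_tscv(expr_log: ExpressionMatrix, tissue: str, target: str = "CAV1") -> TSCV:
    """Pearson correlation of every gene with the target on log2 values."""
    if expr_log.unit != "logTPM":
        raise ValueError("compute_tscv expects log-normalized expression")
    if expr_log.n_samples < MIN_SAMPLES:
        raise ValueError(
            f"tissue {tissue!r} has {expr_log.n_samples} samples (< {MIN_SAMPLES})"
        )
    if target not in expr_log.gene_ids:
        raise ValueError(f"target {target!r} was filtered out in tissue {tissue!r}")
    X = expr_log.values.to_numpy(dtype=float)
    t = X[expr_log.gene_ids.get_loc(target)]
    tc = t - t.mean()
    t_ss = float(tc @ tc)
    Xc = X - X.mean(axis=1, keepdims=True)
    num = Xc @ tc
    denom = np.sqrt((Xc * Xc).sum(axis=1) * t_ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / denom
    r = pd.Series(r, index=expr_log.gene_ids, name=tissue)
    r[target] = 1.0  # exact by definition; avoids rounding in the self-term
    return TSCV(tissue=tissue, r=r, n_samples=expr_log.n_samples, target=target)


def build_tissue_tscv(
    expr: ExpressionMatrix,
    tissue: str,
    target: str = "CAV1",
    min_tpm: float = 4.0,
    min_frac: float = 0.05,
) -> TSCV:
    """Filter -> TMM -> log2 -> correlate, for one tissue's TPM submatrix."""
    sub = expr.subset_tissue(tissue)
    if sub.n_samples < MIN_SAMPLES:
        raise ValueError(f"tissue {tissue!r} has {sub.n_samples} samples (< {MIN_SAMPLES})")
    filtered = filter_genes(sub, min_tpm=min_tpm, min_frac=min_frac)
    factors = tmm_factors(filtered)
    logged = normalize_log2(filtered, factors)
    return compute_tscv(logged, tissue, target=target)


def assemble_tscv_matrix(tscvs: list[TSCV]) -> TSCVMatrix:
    """Union-of-genes tissues x genes matrix; unexpressed genes stay NaN."""
    if len(tscvs) < 2:
        raise ValueError("need at least two TSCVs to assemble a matrix")
    names = [t.tissue for t in tscvs]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate tissue labels: {dup}")
    for t in tscvs:
        if t.n_samples < MIN_SAMPLES:
            raise ValueError(f"tissue {t.tissue!r} below the {MIN_SAMPLES}-sample floor")
    R = pd.DataFrame({t.tissue: t.r for t in tscvs}).T
    R.index.name = "tissue"
    return TSCVMatrix(R=R, provenance={"n_samples": {t.tissue: t.n_samples for t in tscvs}})


def zero_filled_export(matrix: TSCVMatrix) -> pd.DataFrame:
    """Explicit NA->0 copy for downstream matrix algebra.

    Absence of expression is *not* evidence of zero correlation; this
    export exists only for algorithms that require a complete matrix, and
    is deliberately the single place where missing values become zeros.
    """
    return matrix.R.fillna(0.0)


# ---------------------------------------------------------------------------
# Classical MDS
# ---------------------------------------------------------------------------


def _correlation_distance(R: pd.DataFrame, min_overlap: int) -> np.ndarray:
    T = R.shape[0]
    D = np.zeros((T, T))
    vals = R.to_numpy(dtype=float)
    for i in range(T):
        for j in range(i + 1, T):
            ok = np.isfinite(vals[i]) & np.isfinite(vals[j])
            if ok.sum() < min_overlap:
                raise ValueError(
                    f"tissues {R.index[i]!r} and {R.index[j]!r} share only "
                    f"{int(ok.sum())} genes (< {min_overlap})"
                )
            x, y = vals[i, ok], vals[j, ok]
            xc, yc = x - x.mean(), y - y.mean()
            denom = np.sqrt((xc @ xc) * (yc @ yc))
            r = (xc @ yc) / denom if denom > 0 else 0.0
            D[i, j] = D[j, i] = 1.0 - r
    return D


def classical_mds(D: np.ndarray, dims: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson scaling of a symmetric distance matrix.

    Double-centers the squared distances, eigendecomposes, and returns the
    top-``dims`` coordinates (eigenvectors scaled by sqrt eigenvalue) plus
    the full eigenvalue spectrum.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals[:dims], 0.0, None)
    return evecs[:, :dims] * np.sqrt(pos), evals


def mds_embed(matrix: TSCVMatrix, dims: int = 2, min_overlap: int = 500) -> MDSEmbedding:
    """Classical (Torgerson) MDS of tissues on 1 - Pearson distances.

    Distances use pairwise-complete genes; the squared-distance matrix is
    double-centered and the top eigenvectors, scaled by the square root of
    their eigenvalues, give the coordinates.  The embedding is unique up
    to rotation/reflection.
    """
    D = _correlation_distance(matrix.R, min_overlap)
    coords, evals = classical_mds(D, dims=dims)
    pos = np.clip(evals[:dims], 0.0, None)
    total = np.sum(np.clip(evals, 0.0, None))
    explained = float(pos.sum() / total) if total > 0 else 0.0
    df = pd.DataFrame(
        coords, index=matrix.R.index, columns=[f"dim{i + 1}" for i in range(dims)]
    )
    return MDSEmbedding(coordinates=df, eigenvalues=evals, explained_fraction=explained)
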