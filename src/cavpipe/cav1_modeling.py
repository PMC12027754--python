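"""Per-tissue linear-model ladder for CAV1 expression.

Three nested model sets predict log2(TPM) of a target gene (CAV1 by
default) within each tissue:

* **set 1** — ordinary least squares on the publicly available sample
  covariates (RIN, autolysis score, ischemic time, age decade, sex,
  terminal-phase context);
* **set 2** — the same covariates plus marker-derived relative cell-type
  proportion scores; collinearity is handled by an elastic-net feature
  selection step, and the selected predictors are refit by OLS;
* **set 3** — the full covariate table (extended phenotypes included):
  columns above 5% missingness are dropped, the remainder imputed by
  chained equations, then elastic-net selection and an OLS refit.

Significance of a variable within a tissue is a two-sided t-test for
numeric predictors and a partial F-test over the (selected) dummy columns
for categorical ones.  Cross-tissue significance counts per variable give
the model-ladder summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.model_selection import RepeatedKFold
from sklearn.tree import DecisionTreeClassifier

from .io_formats import ExpressionMatrix
from .proportion_estimation import ProportionTable

__all__ = [
    "ElasticNetConfig",
    "ModelFit",
    "SignificanceSummary",
    "SET1_VARIABLES",
    "DEATH_RELATED_VARIABLES",
    "build_design",
    "fit_ols",
    "elastic_net_select",
    "impute_missing",
    "run_model_set",
    "summarize_significance",
]

MIN_SAMPLES_PER_TISSUE = 25

#: Publicly available covariates entering model set 1.
SET1_VARIABLES = ["SMRIN", "SMATSSCR", "SMTSISCH", "AGE_GROUP", "SEX", "terminal_phase"]

#: Variables counted as "death-related" in the cross-tissue summary.
DEATH_RELATED_VARIABLES = [
    "terminal_phase",
    "death_manner",
    "death_place",
    "cohort",
    "ventilator_flag",
]


@dataclass(frozen=True)
class ElasticNetConfig:
    """Hyperparameter grids and CV layout for the selection step.

    The penalty follows the conventional scaled objective
    ``(1/2n)·RSS + lam·[(1-alpha)·||b||²/2 + alpha·||b||₁]``, so ``alpha``
    mixes lasso (1) and ridge (0) and ``lam`` sets the overall strength.
    Grids are restricted to alpha in [0.4, 0.6] and lam in [0.05, 0.2]
    (enforced elastic-net behaviour with a guaranteed positive penalty)
    unless ``enforce_ranges`` is lifted.
    """

    alpha_grid: tuple[float, ...] = (0.4, 0.5, 0.6)
    lambda_grid: tuple[float, ...] = (0.05, 0.1, 0.15, 0.2)
    cv_folds: int = 10
    cv_repeats: int = 5
    seed: int = 0
    enforce_ranges: bool = True

    def __post_init__(self) -> None:
        if self.enforce_ranges:
            if not all(0.4 <= a <= 0.6 for a in self.alpha_grid):
                raise ValueError("alpha_grid must lie within [0.4, 0.6]")
            if not all(0.05 <= l <= 0.2 for l in self.lambda_grid):
                raise ValueError("lambda_grid must lie within [0.05, 0.2]")


@dataclass
class ModelFit:
    """One tissue's fitted model with per-variable significance."""

    coefficients: pd.Series
    p_values: pd.Series  # per design column
    variable_p_values: pd.Series  # per original variable (factor F-tests)
    residuals: np.ndarray
    r_squared: float
    n: int
    selected_features: list[str]
    provenance: dict = field(default_factory=dict)


@dataclass
class SignificanceSummary:
    """Variable x model-set tissue counts at p < 0.05 (NaN = absent)."""

    counts: pd.DataFrame
    n_tissues: dict[str, int]


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


def build_design(
    table: pd.DataFrame,
    variables: list[str],
    age_as_rank: bool = True,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expand a covariate table into a numeric design matrix.

    Ordered categoricals become their integer rank when ``age_as_rank``;
    unordered categoricals one-hot encode with the first level dropped.
    Zero-variance columns are removed.  Returns the matrix and a map from
    each source variable to its design columns.
    """
    cols: dict[str, pd.Series] = {}
    groups: dict[str, list[str]] = {}
    for var in variables:
        s = table[var]
        if isinstance(s.dtype, pd.CategoricalDtype):
            if s.cat.ordered and age_as_rank:
                cols[var] = pd.Series(s.cat.codes.astype(float), index=s.index)
                groups[var] = [var]
            else:
                dummies = pd.get_dummies(s, prefix=var, drop_first=True, dtype=float)
                groups[var] = list(dummies.columns)
                for c in dummies.columns:
                    cols[c] = dummies[c]
        else:
            cols[var] = pd.to_numeric(s, errors="raise").astype(float)
            groups[var] = [var]
    X = pd.DataFrame(cols, index=table.index)
    keep = X.columns[X.std(ddof=0) > 0]
    X = X[keep]
    groups = {v: [c for c in g if c in X.columns] for v, g in groups.items()}
    groups = {v: g for v, g in groups.items() if g}
    return X, groups


# ---------------------------------------------------------------------------
# OLS with classical t / partial-F inference
# ---------------------------------------------------------------------------


def fit_ols(
    y: pd.Series,
    X: pd.DataFrame,
    var_groups: dict[str, list[str]] | None = None,
) -> ModelFit:
    """Ordinary least squares with an intercept and classical inference."""
    if var_groups is None:
        var_groups = {c: [c] for c in X.columns}
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p+1 (n={n}, p={p})")
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # name the columns involved in the dependency for the error message
        bad = []
        base = Xc[["const"]].to_numpy()
        for c in X.columns:
            trial = np.column_stack([base, Xc[c].to_numpy()])
            if np.linalg.matrix_rank(trial) < trial.shape[1]:
                bad.append(c)
        raise ValueError(f"design matrix is rank deficient; collinear columns include {bad or list(X.columns)}")
    res = sm.OLS(y.astype(float), Xc).fit()
    var_p = {}
    for var, g in var_groups.items():
        present = [c for c in g if c in X.columns]
        if not present:
            continue
        if len(present) == 1:
            var_p[var] = float(res.pvalues[present[0]])
        else:
            contrast = np.zeros((len(present), Xc.shape[1]))
            for i, c in enumerate(present):
                contrast[i, Xc.columns.get_loc(c)] = 1.0
            var_p[var] = float(res.f_test(contrast).pvalue)
    return ModelFit(
        coefficients=res.params,
        p_values=res.pvalues,
        variable_p_values=pd.Series(var_p),
        residuals=np.asarray(res.resid),
        r_squared=float(res.rsquared),
        n=n,
        selected_features=list(X.columns),
    )


# ---------------------------------------------------------------------------
# Elastic-net feature selection
# ---------------------------------------------------------------------------


def elastic_net_fit(
    y: pd.Series | np.ndarray,
    X: pd.DataFrame | np.ndarray,
    alpha: float,
    lam: float,
) -> np.ndarray:
    """Elastic-net coefficients at fixed hyperparameters.

    Predictors are standardized to zero mean / unit variance and the
    response centered before penalization; returned coefficients are on
    the standardized scale.  In an orthonormal design this reduces
    coordinate-wise to ``S(b_ols, lam*alpha) / (1 + lam*(1-alpha))`` with
    ``S`` the soft-threshold operator.
    """
    Xs = np.asarray(X, dtype=float)
    mu, sd = Xs.mean(axis=0), Xs.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xs - mu) / sd
    yc = np.asarray(y, dtype=float)
    yc = yc - yc.mean()
    model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False, max_iter=100000, tol=1e-10)
    model.fit(Xs, yc)
    return model.coef_.copy()


def elastic_net_select(
    y: pd.Series,
    X: pd.DataFrame,
    cfg: ElasticNetConfig = ElasticNetConfig(),
) -> tuple[list[str], tuple[float, float]]:
    """Select predictors by elastic net on standardized columns.

    Hyperparameters are chosen by minimum mean CV mean-squared error over
    a 10-fold layout repeated 5 times; the model is then refit on all
    samples and every predictor with a nonzero coefficient is selected.
    Returns the selected column names and the chosen ``(alpha, lam)``.
    """
    n = len(y)
    if n < cfg.cv_folds:
        raise ValueError(f"n={n} below cv_folds={cfg.cv_folds}")
    Xs = X.to_numpy(dtype=float)
    mu, sd = Xs.mean(axis=0), Xs.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xs - mu) / sd
    yc = y.to_numpy(dtype=float)
    yc = yc - yc.mean()

    splits = list(
        RepeatedKFold(
            n_splits=cfg.cv_folds, n_repeats=cfg.cv_repeats, random_state=cfg.seed
        ).split(Xs)
    )
    best: tuple[float, float, float] | None = None  # (mse, alpha, lam)
    for alpha in cfg.alpha_grid:
        for lam in cfg.lambda_grid:
            model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True, max_iter=5000)
            errs = []
            for tr, te in splits:
                model.fit(Xs[tr], yc[tr])
                pred = model.predict(Xs[te])
                errs.append(float(np.mean((yc[te] - pred) ** 2)))
            mse = float(np.mean(errs))
            if best is None or mse < best[0]:
                best = (mse, alpha, lam)
    _, alpha, lam = best
    final = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True, max_iter=50000)
    final.fit(Xs, yc)
    selected = [c for c, b in zip(X.columns, final.coef_) if b != 0.0]
    return selected, (alpha, lam)


# ---------------------------------------------------------------------------
# Chained-equation imputation
# ---------------------------------------------------------------------------


def _encode_predictors(table: pd.DataFrame, exclude: str) -> np.ndarray:
    parts = []
    for col in table.columns:
        if col == exclude:
            continue
        s = table[col]
        if isinstance(s.dtype, pd.CategoricalDtype):
            parts.append(pd.get_dummies(s, prefix=col, dtype=float).to_numpy())
        else:
            parts.append(s.to_numpy(dtype=float)[:, None])
    return np.hstack(parts) if parts else np.zeros((len(table), 0))


def impute_missing(
    table: pd.DataFrame,
    max_missing: float = 0.05,
    max_iter: int = 10,
    seed: int = 0,
    pmm_donors: int = 5,
) -> tuple[pd.DataFrame, list[str]]:
    """Chained-equation imputation of a typed covariate table.

    Columns missing in more than ``max_missing`` of rows are dropped (and
    returned).  The rest are initialized with mean/mode and then swept up
    to ``max_iter`` times: numeric columns are regressed on all other
    columns and imputed by predictive mean matching against the closest
    observed predictions (``pmm_donors`` donors), categorical columns by a
    classification tree.  Fully deterministic under ``seed``.
    """
    frac = table.isna().mean()
    dropped = list(frac.index[frac > max_missing])
    work = table.drop(columns=dropped).copy()
    if work.shape[1] == 0:
        raise ValueError("all columns exceeded the missingness threshold")
    missing_cols = [c for c in work.columns if work[c].isna().any()]
    if not missing_cols:
        return work, dropped
    rng = np.random.default_rng(seed)
    masks = {c: work[c].isna().to_numpy() for c in missing_cols}
    for c in missing_cols:
        s = work[c]
        if isinstance(s.dtype, pd.CategoricalDtype):
            work[c] = s.fillna(s.mode().iloc[0])
        else:
            work[c] = s.fillna(s.mean())
    # visit in order of increasing missingness, as chained-equation
    # implementations conventionally do
    order = sorted(missing_cols, key=lambda c: masks[c].sum())
    for _ in range(max_iter):
        for c in order:
            mask = masks[c]
            Xp = _encode_predictors(work, exclude=c)
            obs, mis = ~mask, mask
            s = work[c]
            if isinstance(s.dtype, pd.CategoricalDtype):
                clf = DecisionTreeClassifier(max_depth=4, random_state=seed)
                clf.fit(Xp[obs], s.to_numpy()[obs])
                pred = clf.predict(Xp[mis])
                vals = s.to_numpy(copy=True)
                vals[mis] = pred
                work[c] = pd.Categorical(vals, categories=s.cat.categories, ordered=s.cat.ordered)
            else:
                reg = LinearRegression()
                y_obs = s.to_numpy(dtype=float)[obs]
                reg.fit(Xp[obs], y_obs)
                pred_obs = reg.predict(Xp[obs])
                pred_mis = reg.predict(Xp[mis])
                vals = s.to_numpy(dtype=float, copy=True)
                # predictive mean matching: donate an observed value whose
                # prediction is among the closest to the missing row's
                for i, pm in zip(np.flatnonzero(mis), pred_mis):
                    d = np.abs(pred_obs - pm)
                    donors = np.argpartition(d, min(pmm_donors, d.size) - 1)[:pmm_donors]
                    vals[i] = y_obs[rng.choice(donors)]
                work[c] = vals
    return work, dropped


# ---------------------------------------------------------------------------
# Model-set orchestration
# ---------------------------------------------------------------------------


def _response(expr: ExpressionMatrix, target_gene: str, sample_ids: pd.Index) -> pd.Series:
    if target_gene not in expr.gene_ids:
        raise KeyError(f"target gene {target_gene!r} not in expression matrix")
    tpm = expr.values.loc[target_gene, sample_ids]
    if (tpm <= 0).any():
        raise ValueError(f"{target_gene} has non-positive TPM in some samples; cannot take log2")
    return np.log2(tpm.astype(float))


def run_model_set(
    expr: ExpressionMatrix,
    proportions: dict[str, ProportionTable] | None,
    set_id: str,
    cfg: ElasticNetConfig = ElasticNetConfig(),
    target_gene: str = "CAV1",
    annotations: pd.DataFrame | None = None,
    impute_seed: int = 0,
) -> dict[str, ModelFit]:
    """Fit one model set in every tissue with at least 25 samples.

    ``proportions`` maps tissue to its :class:`ProportionTable` (required
    for sets 2 and 3).  Tissues below the sample floor are skipped and
    recorded in each fit's provenance is the chosen hyperparameters and
    any dropped covariate columns.
    """
    if set_id not in {"set1", "set2", "set3"}:
        raise ValueError("set_id must be one of set1/set2/set3")
    if set_id in {"set2", "set3"} and proportions is None:
        raise ValueError(f"{set_id} requires proportion tables")
    ann = annotations if annotations is not None else expr.sample_annotations
    fits: dict[str, ModelFit] = {}
    for tissue, n_t in expr.tissues().value_counts().items():
        if n_t < MIN_SAMPLES_PER_TISSUE:
            continue
        ids = expr.sample_annotations.index[expr.tissues() == tissue]
        table = ann.loc[ids]
        y = _response(expr, target_gene, ids)
        if set_id == "set3":
            covars = [c for c in table.columns if c != "tissue"]
            table, dropped = impute_missing(table[covars], seed=impute_seed)
            variables = list(table.columns)
        else:
            variables = [v for v in SET1_VARIABLES if v in table.columns]
            table = table[variables].dropna()
            dropped = []
            y = y.loc[table.index]
        X, groups = build_design(table, variables)
        if set_id in {"set2", "set3"}:
            if tissue not in proportions:
                continue
            prop = proportions[tissue].scores.loc[X.index]
            prop = prop.rename(columns=lambda ct: f"prop_{ct}")
            for c in prop.columns:
                X[c] = prop[c]
                groups[c] = [c]
            selected, (a, l) = elastic_net_select(y, X, cfg)
            prov = {
                "alpha": a,
                "lambda": l,
                "dropped_columns": dropped,
                "candidate_variables": list(groups),
            }
            if not selected:
                fit = ModelFit(
                    coefficients=pd.Series({"const": float(y.mean())}),
                    p_values=pd.Series(dtype=float),
                    variable_p_values=pd.Series(dtype=float),
                    residuals=(y - y.mean()).to_numpy(),
                    r_squared=0.0,
                    n=len(y),
                    selected_features=[],
                    provenance={**prov, "intercept_only": True},
                )
                fits[tissue] = fit
                continue
            Xsel = X[selected]
            gsel = {v: [c for c in g if c in selected] for v, g in groups.items()}
            gsel = {v: g for v, g in gsel.items() if g}
            fit = fit_ols(y, Xsel, gsel)
            fit.selected_features = selected
            fit.provenance = prov
        else:
            fit = fit_ols(y, X, groups)
            fit.provenance = {"dropped_columns": dropped, "candidate_variables": list(groups)}
        fits[tissue] = fit
    if not fits:
        raise ValueError("no tissue reached the 25-sample floor")
    return fits


def summarize_significance(
    fits_by_set: dict[str, dict[str, ModelFit]],
    alpha: float = 0.05,
    death_related: list[str] = DEATH_RELATED_VARIABLES,
) -> SignificanceSummary:
    """Cross-tissue significance counts per variable and model set.

    A variable's count is the number of tissues where its (factor-level)
    p-value is below ``alpha``; a variable that was a selection candidate
    but ended unselected counts as not significant in that tissue.  The
    death-related variables are also aggregated into one group, counted
    when any member is significant.  Variables absent from a model set
    (never candidates) are NaN, not zero.
    """
    all_vars: list[str] = []
    for fits in fits_by_set.values():
        for fit in fits.values():
            for v in fit.provenance.get("candidate_variables", fit.variable_p_values.index):
                if v not in all_vars:
                    all_vars.append(v)
    counts = pd.DataFrame(index=all_vars + ["death_related"], columns=list(fits_by_set), dtype=float)
    n_tissues = {}
    for set_id, fits in fits_by_set.items():
        n_tissues[set_id] = len(fits)
        present: set[str] = set()
        for fit in fits.values():
            present.update(fit.provenance.get("candidate_variables", fit.variable_p_values.index))
        for v in all_vars:
            if v not in present:
                counts.loc[v, set_id] = np.nan
                continue
            counts.loc[v, set_id] = sum(
                1
                for fit in fits.values()
                if v in fit.variable_p_values.index and fit.variable_p_values[v] < alpha
            )
        counts.loc["death_related", set_id] = sum(
            1
            for fit in fits.values()
            if any(
                fit.variable_p_values.get(v, 1.0) < alpha
                for v in death_related
            )
        )
    return SignificanceSummary(counts=counts, n_tissues=n_tissues)
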