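"""Synthetic multi-tissue expression data with a known causal structure.

The generator emulates the features of a post-mortem multi-tissue cohort
that the downstream analysis relies on:

* bulk TPM matrices are proportion-weighted mixtures of cell-type
  expression profiles with multiplicative log-normal noise;
* single-nucleus counts are Poisson draws around the same profiles;
* donor covariates follow a causal DAG in which the *terminal phase* of
  death (a five-level Hardy-scale-like context) shifts RNA quality (RIN),
  ischemic time and cell-type composition, composition drives CAV1, and
  RIN is additionally coupled to composition — so that RIN acts as a proxy
  for cell-type proportions while having no direct effect on CAV1.

Every stochastic quantity is drawn from a named substream of the config
seed, so identical configs are bitwise-reproducible, and the full ground
truth (proportions, marker map, covariates, realized CAV1 effects) is
returned for recovery tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse

from .io_formats import (
    AGE_GROUP_LEVELS,
    ExpressionMatrix,
    GeneSetCollection,
    SingleNucleusDataset,
)

__all__ = [
    "DagEffects",
    "GeneratorConfig",
    "GroundTruth",
    "TERMINAL_PHASES",
    "TERMINAL_PHASE_SHIFT",
    "substream",
    "generate_cell_profiles",
    "generate_donor_covariates",
    "generate_mixture_proportions",
    "synthesize_bulk_tpm",
    "synthesize_snrna_counts",
    "generate_gene_sets",
    "generate_dataset",
]

#: Five-level terminal-phase context: death on a ventilator plus the four
#: Hardy-scale points from sudden violent death to slow death after illness.
TERMINAL_PHASES = ["ventilator", "violent_fast", "fast_natural", "intermediate", "slow"]

#: Ordinal severity score per category used to scale DAG effects.
TERMINAL_PHASE_SHIFT = {
    "ventilator": 1.0,
    "violent_fast": 0.5,
    "fast_natural": 0.0,
    "intermediate": -0.5,
    "slow": -1.0,
}

_PHASE_PROBS = np.array([0.30, 0.15, 0.20, 0.20, 0.15])

CELL_TYPE_POOL = [
    "endothelial",
    "fibroblast",
    "immune",
    "epithelial",
    "adipocyte",
    "neuronal",
    "muscle",
    "pericyte",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible RNG substream derived from a single global seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass(frozen=True)
class DagEffects:
    """Effect sizes on the causal graph linking death context to CAV1.

    ``tp_*`` effects scale with the terminal-phase severity score;
    ``rin_composition`` couples RIN to the (log2) CAV1-positive cell share,
    reproducing the quality-as-composition-proxy confound. The direct
    RIN -> CAV1 path is structurally zero.
    """

    tp_to_proportions: float = 0.9  # logit shift of CAV1-positive cell types
    tp_to_rin: float = 0.2  # RIN units per severity unit
    tp_to_ischemic: float = -120.0  # minutes per severity unit
    tp_to_cav1: float = 0.5  # direct log2-TPM shift per severity unit
    proportions_to_cav1: float = 1.0  # extra log2 CAV1 per log2 positive-share
    rin_composition: float = 0.4  # RIN units per centered log2 positive-share

    def zeroed(self) -> "DagEffects":
        return DagEffects(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a modest desk-scale cohort: a handful of tissues with
    ~120 samples each, a few hundred genes, 15 markers per cell type at an
    8-fold expression ratio, and log-normal bulk noise with sd 0.2 (natural
    log scale).
    """

    n_tissues: int = 5
    samples_per_tissue: int = 120
    n_genes: int = 300
    markers_per_cell_type: int = 15
    marker_fold: float = 8.0
    cell_types_per_tissue: dict[str, list[str]] | None = None
    cav1_positive_cell_types: tuple[str, ...] = ("endothelial", "fibroblast")
    dirichlet_concentration: Mapping[str, float] | float = 10.0
    dag_effects: DagEffects = field(default_factory=DagEffects)
    noise_sd: float = 0.2
    cav1_rate: float = 20.0
    snrna_library_size: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_types_per_tissue is None:
            self.cell_types_per_tissue = self._default_tissue_map()
        for tissue, types in self.cell_types_per_tissue.items():
            if len(types) < 2:
                raise ValueError(f"tissue {tissue!r} must have >=2 cell types")
        pool = self.all_cell_types()
        if self.markers_per_cell_type * len(pool) + 1 > self.n_genes:
            raise ValueError(
                f"{self.markers_per_cell_type} markers x {len(pool)} cell types "
                f"exceed the {self.n_genes}-gene universe"
            )
        for eff in vars(self.dag_effects).values():
            if not np.isfinite(eff):
                raise ValueError("all DAG effect sizes must be finite")

    def _default_tissue_map(self) -> dict[str, list[str]]:
        # every tissue carries endothelial + immune; two more rotate through
        # the pool so cell types recur across tissues (consensus is testable)
        extras = [ct for ct in CELL_TYPE_POOL if ct not in ("endothelial", "immune")]
        out = {}
        for i in range(self.n_tissues):
            name = f"tissue_{i + 1:02d}"
            out[name] = ["endothelial", "immune", extras[i % len(extras)], extras[(i + 1) % len(extras)]]
        return out

    def all_cell_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for types in self.cell_types_per_tissue.values():
            for ct in types:
                seen.setdefault(ct)
        return list(seen)

    def tissues(self) -> list[str]:
        return list(self.cell_types_per_tissue)

    def concentration(self, cell_type: str) -> float:
        if isinstance(self.dirichlet_concentration, Mapping):
            return float(self.dirichlet_concentration[cell_type])
        return float(self.dirichlet_concentration)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    true_proportions: pd.DataFrame  # sample x cell type, rows on the simplex
    true_marker_map: dict[str, list[str]]
    true_covariates: pd.DataFrame
    cav1_effect_path: pd.Series  # realized per-sample direct+composition log2 shift


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------


def gene_universe(config: GeneratorConfig) -> tuple[pd.Index, dict[str, list[str]]]:
    """Gene ids plus the planted marker map; CAV1 appears exactly once."""
    cell_types = config.all_cell_types()
    genes = ["CAV1"]
    marker_map: dict[str, list[str]] = {}
    k = config.markers_per_cell_type
    for j, ct in enumerate(cell_types):
        marker_map[ct] = [f"MK_{ct.upper()}_{i + 1:03d}" for i in range(k)]
        genes.extend(marker_map[ct])
    n_bg = config.n_genes - len(genes)
    genes.extend(f"BG_{i + 1:04d}" for i in range(n_bg))
    return pd.Index(genes, name="gene"), marker_map


def generate_cell_profiles(config: GeneratorConfig) -> pd.DataFrame:
    """Cell-type x gene expression-rate matrix.

    Each cell type expresses its own markers at ``marker_fold`` times the
    gene's background rate; CAV1 is high only in the configured
    CAV1-positive cell types and essentially absent elsewhere.
    """
    rng = substream(config.seed, "profiles")
    genes, marker_map = gene_universe(config)
    cell_types = config.all_cell_types()
    base = rng.lognormal(mean=0.0, sigma=0.5, size=len(genes))
    rates = np.tile(base, (len(cell_types), 1))
    prof = pd.DataFrame(rates, index=pd.Index(cell_types, name="cell_type"), columns=genes)
    for ct, markers in marker_map.items():
        prof.loc[ct, markers] = prof.loc[ct, markers] * config.marker_fold
    prof["CAV1"] = 0.01
    for ct in config.cav1_positive_cell_types:
        if ct in prof.index:
            prof.loc[ct, "CAV1"] = config.cav1_rate
    return prof


# ---------------------------------------------------------------------------
# Covariates (DAG roots and quality variables)
# ---------------------------------------------------------------------------


def generate_donor_covariates(
    config: GeneratorConfig, n: int, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-sample covariates downstream of the latent terminal phase.

    RIN and ischemic time get category-dependent means via the DAG effects;
    the composition coupling of RIN is applied later, once proportions are
    drawn.  Extended phenotypes (death manner/place, cohort, ventilator
    flag, anthropometrics with sporadic missingness) are included for the
    full-covariate model set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng if rng is not None else substream(config.seed, "covariates")
    eff = config.dag_effects
    phase = rng.choice(TERMINAL_PHASES, size=n, p=_PHASE_PROBS)
    shift = np.array([TERMINAL_PHASE_SHIFT[p] for p in phase])
    rin = 7.5 + eff.tp_to_rin * shift + rng.normal(0.0, 0.45, size=n)
    ischemic = 480.0 + eff.tp_to_ischemic * shift + rng.normal(0.0, 90.0, size=n)
    autolysis = rng.choice([0.0, 1.0, 2.0, 3.0], size=n, p=[0.35, 0.35, 0.2, 0.1])
    age = rng.choice(AGE_GROUP_LEVELS, size=n, p=[0.08, 0.12, 0.2, 0.25, 0.25, 0.1])
    sex = rng.choice(["male", "female"], size=n)
    paxgene = rng.normal(300.0, 60.0, size=n)

    # extended phenotypes, all nuisance: death descriptors echo the terminal
    # phase with classification noise, anthropometrics are independent
    flip = rng.random(n) < 0.15
    death_manner = np.where(
        np.isin(phase, ["violent_fast"]) ^ flip, "accident", "natural"
    )
    death_place = np.where((shift >= 0.5) ^ (rng.random(n) < 0.2), "hospital", "home")
    cohort = np.where((shift >= 1.0) ^ (rng.random(n) < 0.2), "organ_donor", "postmortem")
    ventilator_flag = np.where((phase == "ventilator") ^ (rng.random(n) < 0.1), "yes", "no")
    bmi = rng.normal(27.0, 4.0, size=n)
    height = rng.normal(170.0, 9.0, size=n)

    table = pd.DataFrame(
        {
            "terminal_phase": pd.Categorical(phase, categories=TERMINAL_PHASES),
            "SMRIN": rin,
            "SMTSISCH": ischemic,
            "SMATSSCR": autolysis,
            "AGE_GROUP": pd.Categorical(age, categories=AGE_GROUP_LEVELS, ordered=True),
            "SEX": pd.Categorical(sex),
            "SMPAXTIME": paxgene,
            "death_manner": pd.Categorical(death_manner),
            "death_place": pd.Categorical(death_place),
            "cohort": pd.Categorical(cohort),
            "ventilator_flag": pd.Categorical(ventilator_flag),
            "BMI": bmi,
            "HEIGHT": height,
        },
        index=pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample"),
    )
    # sparse missingness (~3%) on anthropometrics; one column above the 5%
    # exclusion threshold to exercise the drop rule
    for col, rate in (("BMI", 0.03), ("HEIGHT", 0.03)):
        table.loc[rng.random(n) < rate, col] = np.nan
    mh = rng.normal(0.0, 1.0, size=n)
    mh[rng.random(n) < 0.08] = np.nan
    table["medical_history_score"] = mh
    return table


# ---------------------------------------------------------------------------
# Mixture proportions
# ---------------------------------------------------------------------------


def generate_mixture_proportions(
    config: GeneratorConfig,
    covariates: pd.DataFrame,
    tissue: str,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample x cell-type Dirichlet proportions for one tissue.

    Terminal-phase severity shifts the log-concentration (logit-scale mean)
    of the CAV1-positive cell types before the Dirichlet draw, so closure
    to the simplex is exact by construction.
    """
    rng = rng if rng is not None else substream(config.seed, f"proportions:{tissue}")
    cell_types = config.cell_types_per_tissue[tissue]
    log_alpha = np.log([config.concentration(ct) for ct in cell_types])
    shift = covariates["terminal_phase"].map(TERMINAL_PHASE_SHIFT).to_numpy(dtype=float)
    pos = np.array([ct in config.cav1_positive_cell_types for ct in cell_types])
    rows = np.empty((len(covariates), len(cell_types)))
    for i, s in enumerate(shift):
        la = log_alpha + np.where(pos, config.dag_effects.tp_to_proportions * s, 0.0)
        rows[i] = rng.dirichlet(np.exp(la))
    return pd.DataFrame(rows, index=covariates.index, columns=cell_types)


# ---------------------------------------------------------------------------
# Bulk synthesis
# ---------------------------------------------------------------------------


def _positive_share(config: GeneratorConfig, proportions: pd.DataFrame) -> np.ndarray:
    cols = [ct for ct in proportions.columns if ct in config.cav1_positive_cell_types]
    if not cols:
        return np.full(len(proportions), np.nan)
    return proportions[cols].sum(axis=1).to_numpy()


def synthesize_bulk_tpm(
    profiles: pd.DataFrame,
    proportions: pd.DataFrame,
    config: GeneratorConfig,
    covariates: pd.DataFrame,
    tissue: str,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Mix cell-type profiles into bulk TPM for one tissue.

    Sample expression is the proportion-weighted sum of profiles, rescaled
    so columns sum to 1e6, then hit by multiplicative log-normal noise
    (which is allowed to break the exact 1e6 column sum).  CAV1 receives,
    on top of its mixture share, the direct composition and terminal-phase
    paths of the DAG.  RIN is coupled to the realized composition here,
    completing the proxy confound.
    """
    if not set(proportions.columns) <= set(profiles.index):
        missing = set(proportions.columns) - set(profiles.index)
        raise ValueError(f"proportions reference unknown cell types: {sorted(missing)}")
    rng = rng if rng is not None else substream(config.seed, f"bulk:{tissue}")
    eff = config.dag_effects
    genes = profiles.columns
    P = proportions.to_numpy()  # samples x cell types
    F = profiles.loc[proportions.columns].to_numpy()  # cell types x genes
    mix = P @ F  # samples x genes

    cav1_idx = genes.get_loc("CAV1")
    share = _positive_share(config, proportions)
    shift = covariates["terminal_phase"].map(TERMINAL_PHASE_SHIFT).to_numpy(dtype=float)
    extra = np.zeros(len(proportions))
    if np.isfinite(share).all() and share.min() > 0:
        log_share = np.log2(share)
        extra = eff.proportions_to_cav1 * (log_share - log_share.mean())
    extra = extra + eff.tp_to_cav1 * shift
    mix[:, cav1_idx] *= 2.0 ** extra

    tpm = mix / mix.sum(axis=1, keepdims=True) * 1e6
    if config.noise_sd > 0:
        tpm = tpm * rng.lognormal(0.0, config.noise_sd, size=tpm.shape)

    cov = covariates.copy()
    if np.isfinite(share).all() and share.min() > 0:
        log_share = np.log2(share)
        cov["SMRIN"] = cov["SMRIN"] + eff.rin_composition * (log_share - log_share.mean())
    cov.insert(0, "tissue", tissue)

    values = pd.DataFrame(tpm.T, index=genes, columns=proportions.index)
    expr = ExpressionMatrix(values, cov, unit="TPM")
    _, marker_map = gene_universe(config)
    truth = GroundTruth(
        true_proportions=proportions.copy(),
        true_marker_map={ct: list(m) for ct, m in marker_map.items()},
        true_covariates=cov,
        cav1_effect_path=pd.Series(extra, index=proportions.index, name="cav1_log2_shift"),
    )
    return expr, truth


# ---------------------------------------------------------------------------
# Single-nucleus synthesis
# ---------------------------------------------------------------------------


def synthesize_snrna_counts(
    profiles: pd.DataFrame,
    config: GeneratorConfig,
    cells_per_type: int = 100,
    tissues: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> SingleNucleusDataset:
    """Poisson single-nucleus counts around each cell type's profile."""
    if cells_per_type < 10:
        raise ValueError("cells_per_type must be >= 10")
    rng = rng if rng is not None else substream(config.seed, "snrna")
    tissues = list(tissues) if tissues is not None else config.tissues()
    blocks, ann_rows, cell_ids = [], [], []
    for tissue in tissues:
        for ct in config.cell_types_per_tissue[tissue]:
            rates = profiles.loc[ct].to_numpy()
            lam = rates / rates.sum() * config.snrna_library_size
            counts = rng.poisson(lam, size=(cells_per_type, len(lam)))
            blocks.append(scipy.sparse.csr_matrix(counts))
            for i in range(cells_per_type):
                cell_ids.append(f"{tissue}:{ct}:{i + 1:04d}")
                ann_rows.append({"tissue": tissue, "donor": f"D{(i % 4) + 1}", "cell_type": ct})
    ann = pd.DataFrame(ann_rows, index=pd.Index(cell_ids, name="cell"))
    return SingleNucleusDataset(scipy.sparse.vstack(blocks).tocsr(), ann, profiles.columns)


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


def generate_gene_sets(
    config: GeneratorConfig,
    truth: GroundTruth,
    n_null_pathways: int = 20,
    null_set_size: int = 30,
    n_null_regulators: int = 8,
    datasets_per_regulator: int = 3,
    rng: np.random.Generator | None = None,
) -> tuple[GeneSetCollection, GeneSetCollection]:
    """Pathway-like and regulator-target-like gene sets with planted signal.

    The planted pathway collects the markers of the CAV1-positive cell
    types (genes that co-vary with CAV1 in bulk mixtures); null pathways
    are random draws from the universe.  The planted regulator ``TFpos``
    owns several partially overlapping target datasets drawn from the same
    co-varying pool; null regulators own random datasets.
    """
    rng = rng if rng is not None else substream(config.seed, "gene_sets")
    genes, _ = gene_universe(config)
    universe = [g for g in genes if g != "CAV1"]
    positive_pool = [
        g
        for ct in config.cav1_positive_cell_types
        for g in truth.true_marker_map.get(ct, [])
    ]

    pathways: dict[str, list[str]] = {"PATHWAY_CAV1_POSITIVE": list(positive_pool)}
    for i in range(n_null_pathways):
        pathways[f"PATHWAY_NULL_{i + 1:02d}"] = list(
            rng.choice(universe, size=min(null_set_size, len(universe)), replace=False)
        )
    pathway_sets = GeneSetCollection(pathways)

    reg_sets: dict[str, list[str]] = {}
    reg_meta: dict[str, dict] = {}
    n_keep = max(2, int(round(0.6 * len(positive_pool))))
    for d in range(datasets_per_regulator):
        name = f"TFpos_dataset_{d + 1}"
        reg_sets[name] = list(rng.choice(positive_pool, size=n_keep, replace=False))
        reg_meta[name] = {"regulator": "TFpos"}
    for r in range(n_null_regulators):
        label = f"TFnull{r + 1:02d}"
        for d in range(datasets_per_regulator):
            name = f"{label}_dataset_{d + 1}"
            reg_sets[name] = list(rng.choice(universe, size=null_set_size, replace=False))
            reg_meta[name] = {"regulator": label}
    return pathway_sets, GeneSetCollection(reg_sets, reg_meta)


# ---------------------------------------------------------------------------
# Whole-cohort orchestration
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    bulk: ExpressionMatrix  # all tissues, column-concatenated
    truth_by_tissue: dict[str, GroundTruth]
    snrna: SingleNucleusDataset
    profiles: pd.DataFrame
    pathway_sets: GeneSetCollection
    regulator_sets: GeneSetCollection


def generate_dataset(config: GeneratorConfig, cells_per_type: int = 100) -> SyntheticCohort:
    """Generate bulk, single-nucleus and gene-set data for every tissue."""
    profiles = generate_cell_profiles(config)
    exprs, truths = [], {}
    for tissue in config.tissues():
        cov = generate_donor_covariates(
            config, config.samples_per_tissue, substream(config.seed, f"covariates:{tissue}")
        )
        cov.index = pd.Index(
            [f"{tissue}-{s}" for s in cov.index], name="sample"
        )
        props = generate_mixture_proportions(config, cov, tissue)
        expr, truth = synthesize_bulk_tpm(profiles, props, config, cov, tissue)
        exprs.append(expr)
        truths[tissue] = truth
    values = pd.concat([e.values for e in exprs], axis=1)
    annotations = pd.concat([e.sample_annotations for e in exprs], axis=0)
    bulk = ExpressionMatrix(values, annotations, unit="TPM")
    snrna = synthesize_snrna_counts(profiles, config, cells_per_type=cells_per_type)
    any_truth = next(iter(truths.values()))
    pathway_sets, regulator_sets = generate_gene_sets(config, any_truth)
    return SyntheticCohort(bulk, truths, snrna, profiles, pathway_sets, regulator_sets)
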