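"""End-to-end orchestration: simulate -> markers -> proportions -> models
-> correlation vectors -> enrichment, under one YAML config and one seed.

Stages communicate only through serialized artifacts in the output
directory; a JSON manifest records parameters, per-stage seeds and the
SHA-256 of every artifact, so a rerun with the same config reproduces the
manifest bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cav1_modeling import ElasticNetConfig, run_model_set, summarize_significance
from .enrichment import (
    celltype_enrichment,
    gsea_permutation,
    meta_enrichment_gsrs,
    rank_from_tscv,
    summarize_enrichment,
)
from .io_formats import write_gct, write_gmt, write_snrna
from .marker_discovery import discover_markers
from .proportion_estimation import ProportionConfig, estimate_proportions
from .synthetic_gtex import DagEffects, GeneratorConfig, generate_dataset, substream
from .tscv import MIN_SAMPLES, assemble_tscv_matrix, build_tissue_tscv, mds_embed

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

STAGES = ["simulate", "markers", "proportions", "models", "tscv", "enrichment"]

_TOP_KEYS = {
    "seed",
    "stages",
    "tissue_subset",
    "generator",
    "proportion",
    "elastic_net",
    "tscv",
    "enrichment",
    "override_paper_ranges",
}


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    tissue_subset: list[str] | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    proportion: ProportionConfig = field(default_factory=ProportionConfig)
    elastic_net: ElasticNetConfig = field(default_factory=ElasticNetConfig)
    tscv_min_tpm: float = 4.0
    tscv_min_frac: float = 0.05
    mds_min_overlap: int = 50
    n_perm: int = 500
    cells_per_type: int = 100


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and normalize a YAML pipeline config.

    Unknown keys are rejected by name; the elastic-net grids must stay in
    the enforced alpha [0.4, 0.6] / lambda [0.05, 0.2] windows unless
    ``override_paper_ranges: true`` is set.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("pipeline config must be a YAML mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    seed = int(raw.get("seed", 0))
    override = bool(raw.get("override_paper_ranges", False))

    gen_kwargs = dict(raw.get("generator", {}))
    cells_per_type = int(gen_kwargs.pop("cells_per_type", 100))
    if "dag_effects" in gen_kwargs:
        gen_kwargs["dag_effects"] = DagEffects(**gen_kwargs["dag_effects"])
    gen_kwargs.setdefault("seed", seed)
    generator = GeneratorConfig(**gen_kwargs)

    en_kwargs = dict(raw.get("elastic_net", {}))
    en_kwargs.setdefault("seed", seed)
    for key in ("alpha_grid", "lambda_grid"):
        if key in en_kwargs:
            en_kwargs[key] = tuple(float(x) for x in en_kwargs[key])
    try:
        elastic = ElasticNetConfig(**en_kwargs, enforce_ranges=not override)
    except ValueError as exc:
        raise ValueError(
            f"{exc}; the enforced windows are alpha in [0.4, 0.6] and "
            "lambda in [0.05, 0.2] (set override_paper_ranges to lift them)"
        ) from None

    prop = ProportionConfig(**raw.get("proportion", {}))
    tscv_opts = raw.get("tscv", {})
    enr_opts = raw.get("enrichment", {})
    stages = raw.get("stages", list(STAGES))
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    return PipelineConfig(
        seed=seed,
        stages=list(stages),
        tissue_subset=raw.get("tissue_subset"),
        generator=generator,
        proportion=prop,
        elastic_net=elastic,
        tscv_min_tpm=float(tscv_opts.get("min_tpm", 4.0)),
        tscv_min_frac=float(tscv_opts.get("min_frac", 0.05)),
        mds_min_overlap=int(tscv_opts.get("min_overlap", 50)),
        n_perm=int(enr_opts.get("n_perm", 500)),
        cells_per_type=cells_per_type,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


class _Log:
    def __init__(self, path: Path | None):
        self.fh = path.open("a") if path else None

    def __call__(self, stage: str, level: str, message: str) -> None:
        rec = json.dumps({"ts": round(time.time(), 3), "stage": stage, "level": level, "message": message})
        if self.fh:
            self.fh.write(rec + "\n")
        print(rec, file=sys.stderr)

    def close(self) -> None:
        if self.fh:
            self.fh.close()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the configured stages, returning (and writing) the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _Log(outdir / "pipeline.log.jsonl")
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": config.stages,
        "parameters": {
            "generator": dataclasses.asdict(config.generator),
            "proportion": dataclasses.asdict(config.proportion),
            "elastic_net": dataclasses.asdict(config.elastic_net),
            "tscv": {
                "min_tpm": config.tscv_min_tpm,
                "min_frac": config.tscv_min_frac,
                "min_overlap": config.mds_min_overlap,
            },
            "n_perm": config.n_perm,
        },
        "artifacts": {},
    }

    def register(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path.relative_to(outdir)), "sha256": _sha256(path)}

    try:
        cohort = None
        if "simulate" in config.stages:
            log("simulate", "info", "generating synthetic cohort")
            cohort = generate_dataset(config.generator, cells_per_type=config.cells_per_type)
            write_gct(cohort.bulk, outdir / "bulk_tpm.gct")
            cohort.bulk.sample_annotations.to_csv(outdir / "sample_annotations.tsv", sep="\t")
            write_snrna(
                cohort.snrna,
                outdir / "snrna_counts.mtx",
                outdir / "snrna_cells.tsv",
                outdir / "snrna_genes.tsv",
            )
            write_gmt(cohort.pathway_sets, outdir / "pathway_sets.gmt")
            write_gmt(cohort.regulator_sets, outdir / "regulator_sets.gmt")
            truth = pd.concat(
                [t.true_proportions for t in cohort.truth_by_tissue.values()], axis=0
            )
            _write_tsv(truth, outdir / "true_proportions.tsv")
            for name in (
                "bulk_tpm.gct",
                "sample_annotations.tsv",
                "snrna_counts.mtx",
                "snrna_cells.tsv",
                "snrna_genes.tsv",
                "pathway_sets.gmt",
                "regulator_sets.gmt",
                "true_proportions.tsv",
            ):
                register(name, outdir / name)
        if cohort is None:
            raise RuntimeError("downstream stages require the simulate stage in this build")

        tissues = config.tissue_subset or config.generator.tissues()
        missing = [t for t in tissues if t not in config.generator.tissues()]
        if missing:
            raise FileNotFoundError(f"tissue subset references unknown tissues: {missing}")

        catalog = None
        if "markers" in config.stages:
            log("markers", "info", "discovering cell-type markers")
            catalog = discover_markers(cohort.snrna)
            write_gmt(catalog.to_gmt(), outdir / "consensus_markers.gmt")
            register("consensus_markers.gmt", outdir / "consensus_markers.gmt")

        proportions = None
        if "proportions" in config.stages:
            log("proportions", "info", "estimating relative cell-type proportions")
            proportions = {
                t: estimate_proportions(cohort.bulk, catalog, t, config.proportion)
                for t in tissues
            }
            scores = pd.concat([p.scores for p in proportions.values()], axis=0)
            _write_tsv(scores, outdir / "proportion_scores.tsv")
            register("proportion_scores.tsv", outdir / "proportion_scores.tsv")

        if "models" in config.stages:
            log("models", "info", "fitting the three model sets")
            fits = {
                "set1": run_model_set(cohort.bulk, None, "set1", config.elastic_net),
                "set2": run_model_set(cohort.bulk, proportions, "set2", config.elastic_net),
                "set3": run_model_set(
                    cohort.bulk, proportions, "set3", config.elastic_net, impute_seed=config.seed
                ),
            }
            summary = summarize_significance(fits)
            _write_tsv(summary.counts, outdir / "significance_counts.tsv")
            register("significance_counts.tsv", outdir / "significance_counts.tsv")
            rows = []
            for set_id, per_tissue in fits.items():
                for tissue, fit in per_tissue.items():
                    for var, p in fit.variable_p_values.items():
                        rows.append(
                            {"model_set": set_id, "tissue": tissue, "variable": var, "p": p}
                        )
            _write_tsv(pd.DataFrame(rows).set_index("model_set"), outdir / "model_pvalues.tsv")
            register("model_pvalues.tsv", outdir / "model_pvalues.tsv")

        matrix = None
        if "tscv" in config.stages:
            log("tscv", "info", "building correlation vectors and MDS")
            vectors = [
                build_tissue_tscv(
                    cohort.bulk, t, min_tpm=config.tscv_min_tpm, min_frac=config.tscv_min_frac
                )
                for t in tissues
                if (cohort.bulk.tissues() == t).sum() >= MIN_SAMPLES
            ]
            matrix = assemble_tscv_matrix(vectors)
            _write_tsv(matrix.R, outdir / "tscv_matrix.tsv")
            register("tscv_matrix.tsv", outdir / "tscv_matrix.tsv")
            embedding = mds_embed(matrix, min_overlap=config.mds_min_overlap)
            _write_tsv(embedding.coordinates, outdir / "mds_embedding.tsv")
            register("mds_embedding.tsv", outdir / "mds_embedding.tsv")
            manifest["tscv"] = {t.tissue: t.n_samples for t in vectors}

        if "enrichment" in config.stages:
            if matrix is None:
                raise RuntimeError("the enrichment stage requires the tscv stage")
            log("enrichment", "info", "running first- and second-level enrichment")
            regulator_map = {
                name: meta["regulator"]
                for name, meta in cohort.regulator_sets.metadata.items()
            }
            pathway_rows, gsrs_rows, ct_rows = [], [], []
            for tissue in matrix.R.index:
                tv = [v for v in vectors if v.tissue == tissue][0]
                ranked = rank_from_tscv(tv, min_genes=50)
                seed_t = int(substream(config.seed, f"enrich:{tissue}").integers(2**31))
                res = gsea_permutation(
                    ranked, cohort.pathway_sets, n_perm=config.n_perm, seed=seed_t
                )
                res["tissue"] = tissue
                pathway_rows.append(res)
                reg = gsea_permutation(
                    ranked, cohort.regulator_sets, n_perm=config.n_perm, seed=seed_t
                )
                gsrs = meta_enrichment_gsrs(reg, regulator_map, n_perm=config.n_perm, seed=seed_t)
                gsrs["tissue"] = tissue
                gsrs_rows.append(gsrs)
                if catalog is not None:
                    ct = celltype_enrichment(
                        tv, catalog, n_perm=config.n_perm, seed=seed_t, min_genes=50
                    )
                    ct_rows.append(ct)
            pathways = pd.concat(pathway_rows, ignore_index=True).drop(columns=["leading_edge"])
            _write_tsv(pathways.set_index("tissue"), outdir / "pathway_enrichment.tsv")
            register("pathway_enrichment.tsv", outdir / "pathway_enrichment.tsv")
            gsrs_all = pd.concat(gsrs_rows, ignore_index=True)
            gsrs_all["member_datasets"] = gsrs_all["member_datasets"].map(",".join)
            _write_tsv(gsrs_all.set_index("tissue"), outdir / "regulator_gsrs.tsv")
            register("regulator_gsrs.tsv", outdir / "regulator_gsrs.tsv")
            if ct_rows:
                ct_all = pd.concat(ct_rows, ignore_index=True).drop(columns=["leading_edge"])
                _write_tsv(ct_all.set_index("tissue"), outdir / "celltype_enrichment.tsv")
                register("celltype_enrichment.tsv", outdir / "celltype_enrichment.tsv")
            summary = summarize_enrichment(pathways)
            _write_tsv(summary["counts"], outdir / "pathway_counts.tsv")
            register("pathway_counts.tsv", outdir / "pathway_counts.tsv")
            manifest["coverage_fraction"] = summary["coverage_fraction"]
    except Exception as exc:
        log("pipeline", "error", f"aborted: {exc}")
        (outdir / "manifest.partial.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        log.close()
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log("pipeline", "info", "completed")
    log.close()
    return manifest
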