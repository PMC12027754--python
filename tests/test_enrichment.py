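import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cavpipe.enrichment import (
    celltype_enrichment,
    gsea_es,
    meta_enrichment_gsrs,
    preranked_gsea,
    rank_from_tscv,
    summarize_enrichment,
)
from cavpipe.marker_discovery import CellTypeMarkerCatalog
from cavpipe.tscv import TSCV


def naive_es(ranked: pd.Series, members: set, p: float = 1.0) -> float:
    """Independent running-sum implementation: explicit loop, no shortcuts."""
    stats_ = ranked.to_numpy(dtype=float)
    hits = [g in members for g in ranked.index]
    total = sum(abs(s) ** p for s, h in zip(stats_, hits) if h)
    n_miss = len(ranked) - sum(hits)
    running, profile = 0.0, []
    for s, h in zip(stats_, hits):
        if h:
            running += abs(s) ** p / total if total > 0 else 1.0 / sum(hits)
        else:
            running -= 1.0 / n_miss
        profile.append(running)
    hi, lo = max(profile), min(profile)
    return hi if hi >= -lo else lo  # positive wins an exact-magnitude tie


def make_tscv(genes, values, tissue="t1", target="CAV1"):
    return TSCV(tissue=tissue, r=pd.Series(values, index=genes), n_samples=30, target=target)


class TestRanking:
    def _tscv(self):
        genes = [f"g{i:03d}" for i in range(120)] + ["CAV1"]
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.uniform(-0.9, 0.9, 120), [1.0]])
        vals[5] = vals[6] = 0.25  # exact tie
        return make_tscv(genes, vals)

    def test_target_ranks_first(self):
        ranked = rank_from_tscv(self._tscv())
        assert ranked.index[0] == "CAV1"

    def test_ties_break_by_gene_id(self):
        ranked = rank_from_tscv(self._tscv())
        tied = [g for g in ranked.index if ranked[g] == 0.25]
        assert tied == sorted(tied)

    def test_input_order_invariance(self):
        t = self._tscv()
        shuffled = TSCV(tissue=t.tissue, r=t.r.sample(frac=1, random_state=1), n_samples=30)
        pd.testing.assert_series_equal(rank_from_tscv(t), rank_from_tscv(shuffled))

    def test_floor_enforced(self):
        with pytest.raises(ValueError, match="non-missing"):
            rank_from_tscv(make_tscv(["CAV1", "a"], [1.0, 0.5]))


class TestEnrichmentScore:
    def test_hand_traced_six_gene_toy(self):
        # stats 6..1, set = top two genes; increments |s|/sum at hits,
        # -1/4 at misses; peak after the second hit = 1.0 - 0 misses seen
        ranked = pd.Series([6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
                           index=["a", "b", "c", "d", "e", "f"])
        es, running, leading = gsea_es(ranked, ["a", "b"])
        assert es == pytest.approx(1.0, abs=1e-12)
        assert leading == ["a", "b"]
        np.testing.assert_allclose(running[:2], [6 / 11, 1.0], atol=1e-12)

    def test_bottom_clustered_set_scores_negative(self):
        ranked = pd.Series(np.arange(10, 0, -1, dtype=float),
                           index=[f"g{i}" for i in range(10)])
        es, _, _ = gsea_es(ranked, ["g8", "g9"])
        assert es < 0

    def test_matches_naive_oracle_on_small_universes(self):
        rng = np.random.default_rng(1)
        for trial in range(50):
            N = rng.integers(6, 13)
            stats_ = np.sort(rng.uniform(-1, 1, N))[::-1]
            ranked = pd.Series(stats_, index=[f"g{i}" for i in range(N)])
            k = int(rng.integers(1, N - 1))
            members = set(rng.choice(ranked.index, size=k, replace=False))
            es, _, _ = gsea_es(ranked, sorted(members))
            assert es == pytest.approx(naive_es(ranked, members), abs=1e-12)

    def test_reversed_symmetric_ranking_negates_es(self):
        vals = np.array([0.9, 0.6, 0.3, -0.3, -0.6, -0.9])
        ranked = pd.Series(vals, index=list("abcdef"))
        rev = pd.Series(vals, index=list("fedcba")).sort_values(ascending=False)
        set_ = ["a", "b"]
        es_fwd, _, _ = gsea_es(ranked, set_)
        es_rev, _, _ = gsea_es(rev, set_)
        assert es_fwd == pytest.approx(-es_rev, abs=1e-12)

    def test_no_overlap_rejected(self):
        ranked = pd.Series([1.0, 0.5], index=["a", "b"])
        with pytest.raises(ValueError, match="no overlap"):
            gsea_es(ranked, ["zzz"])


class TestPermutation:
    def test_exhaustive_small_universe_oracle(self):
        # p for a size-3 set in a 10-gene universe vs enumeration of all
        # C(10,3)=120 possible sets, within 3 Monte-Carlo SE
        rng = np.random.default_rng(2)
        ranked = pd.Series(np.sort(rng.uniform(-1, 1, 10))[::-1],
                           index=[f"g{i}" for i in range(10)])
        members = ["g0", "g3", "g7"]
        n_perm = 100_000
        res = preranked_gsea(ranked, {"s": members}, n_perm=n_perm, seed=0, min_size=1)
        es_obs = res["ES"].iloc[0]
        all_es = np.array([
            naive_es(ranked, set(c)) for c in itertools.combinations(ranked.index, 3)
        ])
        same = all_es >= 0 if es_obs >= 0 else all_es < 0
        p_exact = (np.abs(all_es[same]) >= abs(es_obs)).mean()
        p_got = res["p"].iloc[0]
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm) + 2.0 / n_perm
        assert abs(p_got - p_exact) < 3 * se + 2e-4

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        pvals = []
        for rep in range(120):
            ranked = pd.Series(
                np.sort(rng.normal(size=60))[::-1], index=[f"g{i}" for i in range(60)]
            )
            members = list(rng.choice(ranked.index, size=8, replace=False))
            res = preranked_gsea(ranked, {"s": members}, n_perm=400, seed=rep)
            pvals.append(res["p"].iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_null_bh_discovery_rate_bounded(self):
        # under a null generator, BH at 0.05 rarely fires
        rng = np.random.default_rng(4)
        rates = []
        for rep in range(50):
            ranked = pd.Series(
                np.sort(rng.normal(size=80))[::-1], index=[f"g{i}" for i in range(80)]
            )
            sets = {
                f"s{j}": list(rng.choice(ranked.index, size=10, replace=False))
                for j in range(12)
            }
            res = preranked_gsea(ranked, sets, n_perm=200, seed=rep)
            rates.append((res["p_adjusted"] < 0.05).mean())
        assert np.mean(rates) <= 0.05

    def test_untestable_sets_flagged_and_excluded_from_bh(self):
        ranked = pd.Series(np.linspace(1, -1, 40), index=[f"g{i}" for i in range(40)])
        sets = {"ok": [f"g{i}" for i in range(0, 12)], "gone": ["zz1", "zz2"]}
        res = preranked_gsea(ranked, sets, n_perm=200, seed=0).set_index("set_name")
        assert not res.loc["gone", "testable"]
        assert np.isnan(res.loc["gone", "p_adjusted"])
        assert res.loc["ok", "testable"]

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        ranked = pd.Series(np.sort(rng.normal(size=50))[::-1],
                           index=[f"g{i}" for i in range(50)])
        sets = {"s": [f"g{i}" for i in range(10)]}
        r1 = preranked_gsea(ranked, sets, n_perm=300, seed=9)
        r2 = preranked_gsea(ranked, sets, n_perm=300, seed=9)
        pd.testing.assert_frame_equal(r1, r2)


class TestMetaEnrichment:
    def _first_level(self, nes_by_dataset):
        return pd.DataFrame(
            {
                "set_name": list(nes_by_dataset),
                "NES": list(nes_by_dataset.values()),
                "testable": True,
            }
        )

    def test_top_ranked_datasets_give_maximal_gsrs(self):
        nes = {f"d{i}": float(v) for i, v in enumerate(np.linspace(3, -3, 12))}
        reg_map = {"d0": "TOP", "d1": "TOP", "d2": "TOP"}
        reg_map.update({f"d{i}": f"null{i}" for i in range(3, 12)})
        res = meta_enrichment_gsrs(self._first_level(nes), reg_map, n_perm=300, seed=0)
        res = res.set_index("regulator")
        assert res.loc["TOP", "GSRS"] == res["GSRS"].max()
        assert res.loc["TOP", "GSRS"] > 0

    def test_single_dataset_regulators_preserve_nes_order(self):
        rng = np.random.default_rng(6)
        nes = {f"d{i}": float(v) for i, v in enumerate(rng.normal(size=10))}
        reg_map = {ds: f"R_{ds}" for ds in nes}
        res = meta_enrichment_gsrs(self._first_level(nes), reg_map, n_perm=200, seed=0)
        by_gsrs = res.sort_values("GSRS", ascending=False)["regulator"].tolist()
        by_nes = [f"R_{ds}" for ds in sorted(nes, key=nes.get, reverse=True)]
        assert by_gsrs == by_nes

    def test_mid_ranked_singleton_not_significant(self):
        nes = {f"d{i}": float(v) for i, v in enumerate(np.linspace(2, -2, 11))}
        reg_map = {ds: ("MID" if ds == "d5" else f"r{ds}") for ds in nes}
        res = meta_enrichment_gsrs(self._first_level(nes), reg_map, n_perm=500, seed=1)
        row = res.set_index("regulator").loc["MID"]
        assert row["p"] > 0.05


class TestCellTypeEnrichment:
    def _catalog(self, consensus, negatives=None):
        return CellTypeMarkerCatalog(
            per_tissue={"t1": {ct: list(g) for ct, g in consensus.items()}},
            consensus={ct: list(g) for ct, g in consensus.items()},
            detected_in={ct: ["t1"] for ct in consensus},
            negative_per_tissue={"t1": negatives or {}},
        )

    def _tscv(self, n=150, top_genes=("e0", "e1", "e2", "e3", "e4", "e5")):
        rng = np.random.default_rng(7)
        genes = list(top_genes) + [f"b{i}" for i in range(n)] + ["CAV1"]
        vals = np.concatenate([
            rng.uniform(0.6, 0.95, len(top_genes)), rng.uniform(-0.5, 0.5, n), [1.0]
        ])
        return make_tscv(genes, vals)

    def test_covarying_markers_positively_enriched(self):
        tscv = self._tscv()
        catalog = self._catalog({"endothelial": ["e0", "e1", "e2", "e3", "e4", "e5"]})
        res = celltype_enrichment(tscv, catalog, n_perm=500, seed=0)
        row = res.set_index("cell_type").loc["endothelial"]
        assert row["ES"] > 0 and row["p_adjusted"] < 0.05

    def test_absent_cell_type_untestable(self):
        tscv = self._tscv()
        catalog = self._catalog({
            "endothelial": ["e0", "e1", "e2", "e3", "e4", "e5"],
            "ghost": ["nope1", "nope2", "nope3", "nope4", "nope5"],
        })
        res = celltype_enrichment(tscv, catalog, n_perm=200, seed=0).set_index("cell_type")
        assert not res.loc["ghost", "testable"]

    def test_positive_enrichment_with_negative_marker_status(self):
        # markers of a cell type that does NOT express the target can still
        # co-vary with it; status annotation must distinguish the two facts
        tscv = self._tscv()
        catalog = self._catalog(
            {"immune": ["e0", "e1", "e2", "e3", "e4", "e5"]},
            negatives={"immune": ["CAV1"]},
        )
        res = celltype_enrichment(tscv, catalog, n_perm=500, seed=0).set_index("cell_type")
        assert res.loc["immune", "ES"] > 0
        assert res.loc["immune", "target_marker_status"] == "negative_marker"


class TestSummaries:
    def _results(self):
        rows = []
        for tissue in ("t1", "t2", "t3", "t4", "t5"):
            for name, p, es in (("hot", 0.01, 0.5), ("cold", 0.5, -0.2)):
                rows.append({
                    "tissue": tissue, "set_name": name, "ES": es, "NES": es * 2,
                    "p": p, "p_adjusted": p if tissue != "t4" else 0.9,
                    "direction": int(np.sign(es)), "testable": True,
                })
        return pd.DataFrame(rows)

    def test_counts_and_coverage_match_recount(self):
        res = self._results()
        summary = summarize_enrichment(res)
        assert summary["counts"].loc["hot", "positive"] == 4  # t4 not significant
        assert summary["counts"].loc["cold", "negative"] == 0
        # brute-force recount of the coverage fraction
        sig_sets = res[(res["p_adjusted"] < 0.05)]["set_name"].nunique()
        assert summary["coverage_fraction"] == pytest.approx(sig_sets / 2)

    def test_min_tissue_filter_warns_when_unreachable(self):
        with pytest.warns(UserWarning, match="exceeds"):
            summary = summarize_enrichment(self._results(), min_tissues=25)
        assert summary["long_table"].empty
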