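import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cavpipe.tscv import (
    TSCV,
    assemble_tscv_matrix,
    build_tissue_tscv,
    classical_mds,
    compute_tscv,
    filter_genes,
    mds_embed,
    normalize_log2,
    tmm_factors,
    zero_filled_export,
)
from conftest import make_expression


class TestGeneFilter:
    def test_threshold_edge_cases(self):
        n = 100
        rows = np.zeros((3, n))
        rows[0, :6] = 4.0  # 4 TPM in 6% of samples -> kept
        rows[1, :] = 3.9  # never reaches 4 TPM -> dropped
        rows[2, :5] = 100.0  # high but in exactly 5% -> dropped (strict >)
        expr = make_expression(rows + 0.0, genes=["kept", "low", "boundary"])
        # keep one always-expressed gene so the result is non-empty anyway
        out = filter_genes(expr, min_tpm=4.0, min_frac=0.05)
        assert list(out.gene_ids) == ["kept"]

    def test_empty_result_rejected(self):
        expr = make_expression(np.full((2, 10), 1.0))
        with pytest.raises(ValueError, match="no gene passes"):
            filter_genes(expr)


class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        col = np.random.default_rng(0).uniform(1, 100, size=30)
        expr = make_expression(np.tile(col[:, None], (1, 4)))
        np.testing.assert_allclose(tmm_factors(expr).to_numpy(), 1.0, atol=1e-12)

    def test_pure_depth_scaling_gives_unit_factor(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(1, 500, size=50)
        mat = np.column_stack([base, base * 2.0, base * 0.5])
        factors = tmm_factors(make_expression(mat))
        np.testing.assert_allclose(factors.to_numpy(), 1.0, atol=1e-9)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(2)
        mat = rng.lognormal(2, 1, size=(80, 6))
        factors = tmm_factors(make_expression(mat))
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_sample_rejected(self):
        mat = np.ones((5, 3))
        mat[:, 1] = 0
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(make_expression(mat))

    def test_matches_edger_reference(self, tmp_path):
        # independent oracle: edgeR's calcNormFactors on the same counts
        rng = np.random.default_rng(7)
        counts = rng.poisson(
            rng.lognormal(3, 1, size=(60, 1)) * np.array([1, 2, 0.7, 1.5]), size=(60, 4)
        ).astype(float)
        np.savetxt(tmp_path / "counts.tsv", counts, delimiter="\t")
        ours = tmm_factors(make_expression(counts)).to_numpy()
        script = (
            'suppressMessages(library(edgeR));'
            f'x <- as.matrix(read.table("{tmp_path}/counts.tsv"));'
            'cat(calcNormFactors(x, method="TMM"), sep="\\n")'
        )
        res = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, timeout=300)
        assert res.returncode == 0, res.stderr[-300:]
        theirs = np.array([float(v) for v in res.stdout.split()])
        np.testing.assert_allclose(ours, theirs, atol=1e-6)


class TestNormalizeLog2:
    def test_values_and_monotonicity(self):
        expr = make_expression(np.array([[3.0, 0.0], [7.0, 1.0]]))
        factors = pd.Series([1.0, 1.0], index=expr.sample_ids)
        out = normalize_log2(expr, factors)
        assert out.unit == "logTPM"
        assert out.values.iloc[0, 0] == pytest.approx(2.0)  # log2(3+1)
        assert out.values.iloc[0, 1] == 0.0
        assert (np.diff(out.values.to_numpy(), axis=0) > 0).all()


def pearson_brute(x, y):
    """The explicit sum formula, evaluated term by term."""
    xb, yb = np.mean(x), np.mean(y)
    num = sum((xi - xb) * (yi - yb) for xi, yi in zip(x, y))
    den = np.sqrt(sum((xi - xb) ** 2 for xi in x)) * np.sqrt(sum((yi - yb) ** 2 for yi in y))
    return num / den


class TestComputeTscv:
    def _logged(self, mat, genes=None):
        return make_expression(mat, genes=genes, unit="logTPM")

    def test_self_correlation_is_exactly_one(self):
        rng = np.random.default_rng(0)
        expr = self._logged(rng.uniform(0, 8, size=(5, 30)), genes=["CAV1", "a", "b", "c", "d"])
        res = compute_tscv(expr, "t")
        assert res.r["CAV1"] == pytest.approx(1.0, abs=1e-12)

    def test_negated_gene_gives_minus_one(self):
        rng = np.random.default_rng(1)
        cav1 = rng.uniform(0, 8, size=40)
        mat = np.vstack([cav1, 10.0 - cav1])
        res = compute_tscv(self._logged(mat, genes=["CAV1", "anti"]), "t")
        assert res.r["anti"] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_sum_formula_on_random_fixtures(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            mat = rng.uniform(0, 10, size=(6, 28))
            expr = self._logged(mat, genes=["CAV1", "g1", "g2", "g3", "g4", "g5"])
            res = compute_tscv(expr, "t")
            for j, g in enumerate(expr.gene_ids):
                assert res.r[g] == pytest.approx(pearson_brute(mat[j], mat[0]), abs=1e-12)

    def test_sample_floor_enforced(self):
        expr = self._logged(np.random.default_rng(3).uniform(0, 8, size=(3, 21)),
                            genes=["CAV1", "a", "b"])
        with pytest.raises(ValueError, match="21 samples"):
            compute_tscv(expr, "bladder")

    def test_permutation_null_matches_theory(self):
        # shuffling the target's sample labels makes r follow the exact
        # null: t = r sqrt((n-2)/(1-r^2)) ~ t_{n-2}; its survival p is U(0,1)
        rng = np.random.default_rng(4)
        n = 30
        gene = rng.normal(size=n)
        cav1 = rng.normal(size=n)
        rs = []
        for _ in range(1000):
            perm = rng.permutation(cav1)
            rs.append(np.corrcoef(gene, perm)[0, 1])
        rs = np.array(rs)
        t = rs * np.sqrt((n - 2) / (1 - rs**2))
        pvals = stats.t.sf(t, df=n - 2)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestMatrixAssembly:
    def _tscv(self, tissue, genes, vals, n=30):
        return TSCV(tissue=tissue, r=pd.Series(vals, index=genes), n_samples=n)

    def test_union_with_missing_preserved(self, tmp_path):
        m = assemble_tscv_matrix([
            self._tscv("A", ["CAV1", "g1"], [1.0, 0.5]),
            self._tscv("B", ["CAV1", "g2"], [1.0, -0.2]),
        ])
        assert np.isnan(m.R.loc["B", "g1"])
        path = tmp_path / "m.tsv"
        m.R.to_csv(path, sep="\t")
        back = pd.read_csv(path, sep="\t", index_col=0)
        assert np.isnan(back.loc["B", "g1"])
        assert back.loc["A", "g1"] == 0.5

    def test_small_tissue_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            assemble_tscv_matrix([
                self._tscv("A", ["CAV1"], [1.0]),
                self._tscv("bladder", ["CAV1"], [1.0], n=21),
            ])

    def test_duplicate_tissue_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            assemble_tscv_matrix([
                self._tscv("A", ["CAV1"], [1.0]),
                self._tscv("A", ["CAV1"], [1.0]),
            ])

    def test_zero_fill_is_explicit_and_isolated(self):
        m = assemble_tscv_matrix([
            self._tscv("A", ["CAV1", "g1"], [1.0, 0.5]),
            self._tscv("B", ["CAV1", "g2"], [1.0, -0.2]),
        ])
        filled = zero_filled_export(m)
        assert filled.loc["B", "g1"] == 0.0
        assert np.isnan(m.R.loc["B", "g1"])  # original untouched


def procrustes_rmse(X, Y):
    """RMSE after optimal translation/rotation/reflection (no scaling)."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    U, _, Vt = np.linalg.svd(Xc.T @ Yc)
    R = U @ Vt
    return float(np.sqrt(np.mean((Xc @ R - Yc) ** 2)))


class TestMds:
    def test_three_point_closed_form(self):
        # distances {AB=0 is degenerate; use AB=1, AC=1, BC=1}? isosceles
        # case from the documented example: d(A,B)=0 -> coincident points,
        # d to C = 1 for both
        D = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        coords, _ = classical_mds(D)
        assert np.linalg.norm(coords[0] - coords[1]) == pytest.approx(0.0, abs=1e-8)
        assert np.linalg.norm(coords[0] - coords[2]) == pytest.approx(1.0, abs=1e-8)

    def test_planted_configuration_recovered(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 2))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        coords, evals = classical_mds(D)
        assert procrustes_rmse(pts, coords) < 0.05
        # 2D-realizable distances: embedding reproduces them exactly
        Dhat = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(Dhat, D, atol=1e-8)

    def test_identical_tscvs_coincide(self):
        r = pd.Series(np.random.default_rng(6).uniform(-1, 1, 600))
        tscvs = [TSCV(tissue=t, r=r.copy(), n_samples=30) for t in ("A", "B", "C")]
        emb = mds_embed(assemble_tscv_matrix(tscvs), min_overlap=100)
        span = emb.coordinates.max() - emb.coordinates.min()
        assert (span.abs() < 1e-6).all()

    def test_low_overlap_pair_named(self):
        g1 = [f"g{i}" for i in range(200)]
        g2 = [f"h{i}" for i in range(200)]
        rng = np.random.default_rng(7)
        tscvs = [
            TSCV(tissue="A", r=pd.Series(rng.uniform(-1, 1, 200), index=g1), n_samples=30),
            TSCV(tissue="B", r=pd.Series(rng.uniform(-1, 1, 200), index=g2), n_samples=30),
        ]
        with pytest.raises(ValueError, match="'A' and 'B'"):
            mds_embed(assemble_tscv_matrix(tscvs), min_overlap=50)


def test_end_to_end_tissue_vector(small_cohort):
    cfg, cohort = small_cohort
    tissue = cfg.tissues()[0]
    vec = build_tissue_tscv(cohort.bulk, tissue)
    assert vec.r["CAV1"] == pytest.approx(1.0, abs=1e-12)
    # markers of the CAV1-positive cell types co-vary with CAV1
    pos_markers = [g for g in vec.r.index if g.startswith("MK_ENDOTHELIAL")]
    assert np.nanmean(vec.r[pos_markers]) > 0.3
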