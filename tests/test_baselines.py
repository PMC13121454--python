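import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm, rankdata

from sctwas import (
    CellCountMatrix,
    NormalizedGReXRegressor,
    PseudobulkDataset,
    an_normalize,
    inverse_normal_transform,
    na_normalize,
    tmm_factors,
)
from sctwas.data import SctwasError
from sctwas.grex import fit_weighted_elastic_net


def _pb(counts):
    counts = np.asarray(counts)
    return PseudobulkDataset(
        counts=counts,
        gene_ids=np.array([f"g{j}" for j in range(counts.shape[1])]),
        individuals=np.array([f"I{i}" for i in range(counts.shape[0])]),
        depth=counts.sum(axis=1).astype(float),
        cell_type="T",
        n_cells=np.ones(counts.shape[0], int),
    )


class TestINT:
    def test_three_values(self):
        out = inverse_normal_transform([3.0, 1.0, 2.0])
        assert out == pytest.approx([0.9674, -0.9674, 0.0], abs=5e-5)

    def test_affine_invariance(self, rng):
        v = rng.standard_normal(25)
        assert np.array_equal(inverse_normal_transform(v),
                              inverse_normal_transform(3.5 * v + 2.0))

    def test_tie_average_rank(self):
        out = inverse_normal_transform([1.0, 1.0, 2.0, 3.0])
        assert out[0] == out[1]                  # tied values share the average rank
        assert out[0] == pytest.approx(norm.ppf((1.5 - 0.5) / 4))

    def test_too_short_errors(self):
        with pytest.raises(SctwasError):
            inverse_normal_transform([1.0, 2.0])

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=40, unique=True))
    def test_output_is_quantile_multiset(self, values):
        """Tie-free INT output is exactly the quantile set Phi^-1((r-0.5)/n)."""
        out = inverse_normal_transform(values)
        n = len(values)
        expected = norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        assert np.allclose(np.sort(out), expected)
        assert abs(out.mean() - expected.mean()) < 1e-10


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        pb = _pb(np.tile([100, 200, 50, 400, 30, 220], (4, 1)))
        assert np.array_equal(tmm_factors(pb), np.ones(4))

    def test_geometric_mean_one(self, rng):
        pb = _pb(rng.poisson(50, size=(6, 100)) + 1)
        f = tmm_factors(pb)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-10)

    def test_global_scaling_invariance(self, rng):
        counts = rng.poisson(80, size=(5, 60)) + 1
        assert np.allclose(tmm_factors(_pb(counts)), tmm_factors(_pb(3 * counts)))

    def test_two_sample_hand_worked(self):
        # 6 genes, both samples expressed everywhere; m=6 with a 0.3 M-trim
        # keeps M-ranks 2..5 (drops the extreme two); the 0.05 A-trim keeps all
        c1 = np.array([100, 200, 300, 400, 500, 500], float)
        c2 = np.array([80, 250, 270, 600, 800, 1000], float)
        pb = _pb(np.vstack([c1, c2]))
        lib1, lib2 = c1.sum(), c2.sum()
        # reference = sample 0 (f75/depth ties, first index wins)
        r1, r2 = c2 / lib2, c1 / lib1
        M = np.log2(r1 / r2)
        A = 0.5 * np.log2(r1 * r2)
        v = (lib2 - c2) / (lib2 * c2) + (lib1 - c1) / (lib1 * c1)
        keep = np.argsort(M)[1:-1]               # drop smallest and largest M
        f = 2.0 ** (np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep]))
        expected = np.array([1 / np.sqrt(f), np.sqrt(f)])  # geo-mean rescale
        assert np.allclose(tmm_factors(pb), expected, atol=1e-8)

    def test_matches_edger(self, tmp_path, rng):
        """Independent oracle: Bioconductor edgeR's calcNormFactors."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        counts = rng.poisson(rng.uniform(1, 60, size=(1, 120)),
                             size=(8, 120))
        np.savetxt(tmp_path / "counts.tsv", counts.T, fmt="%d", delimiter="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            'suppressMessages(library(edgeR))\n'
            f'x <- as.matrix(read.table("{tmp_path}/counts.tsv"))\n'
            'f <- calcNormFactors(x, method="TMM")\n'
            'cat(sprintf("%.12f", f), sep="\\n")\n')
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        ref = np.array([float(v) for v in out.stdout.split()])
        assert np.allclose(tmm_factors(_pb(counts)), ref, atol=1e-6)


class TestNAPipeline:
    def _cells(self, counts, individuals):
        counts = np.asarray(counts)
        return CellCountMatrix(
            counts=counts,
            gene_ids=np.array([f"g{j}" for j in range(counts.shape[1])]),
            cell_individual=np.asarray(individuals),
            cell_type=np.repeat("T", counts.shape[0]),
            cell_depth=counts.sum(axis=1),
        )

    def test_single_cell_cpm_log(self):
        # depth 100, count 10 -> CPM 1e5 -> log1p = ln(100001); with 3
        # individuals the INT maps the ranked means onto the quantile set
        cells = self._cells([[10, 90], [5, 95], [20, 80]], ["I0", "I1", "I2"])
        logcpm = np.log1p(10 / 100 * 1e6)
        assert logcpm == pytest.approx(np.log(100001))
        out = na_normalize(cells, "T")
        # aggregated means order g0: I1 < I0 < I2 -> INT quantiles
        q = norm.ppf((np.array([2, 1, 3]) - 0.5) / 3)
        assert np.allclose(out.gene_values("g0"), q)

    def test_two_identical_cells_equal_one(self):
        one = self._cells([[10, 90], [5, 95], [20, 80]], ["I0", "I1", "I2"])
        two = self._cells([[10, 90], [10, 90], [5, 95], [5, 95], [20, 80],
                           [20, 80]], ["I0", "I0", "I1", "I1", "I2", "I2"])
        assert np.allclose(na_normalize(one, "T").values,
                           na_normalize(two, "T").values)


class TestANPipeline:
    def test_four_sample_hand_pipeline(self):
        counts = np.array([[100, 200, 300, 400],
                           [110, 190, 310, 390],
                           [90, 210, 290, 410],
                           [105, 195, 305, 395]], float)
        pb = _pb(counts)
        out = an_normalize(pb)
        factors = tmm_factors(pb)
        eff = pb.depth * factors
        logcpm = np.log1p(counts / eff[:, None] * 1e6)
        expected = np.column_stack(
            [inverse_normal_transform(logcpm[:, j]) for j in range(4)])
        assert np.allclose(out.values, expected)
        assert out.recipe == "AN"

    def test_gene_scaling_preserves_rank_order(self, rng):
        counts = rng.poisson(100, size=(6, 10)) + 1
        base = an_normalize(_pb(counts))
        scaled = counts.copy()
        scaled[:, 3] *= 2
        out = an_normalize(_pb(scaled))
        assert np.array_equal(rankdata(base.values[:, 3]),
                              rankdata(out.values[:, 3]))

    def test_agrees_with_na_for_single_cells_unit_factors(self, rng):
        """AN == NA when each individual has one cell and TMM factors are 1."""
        counts = np.tile(rng.poisson(50, size=10) + 1, (5, 1))
        counts = counts + np.arange(5)[:, None] * 0   # identical rows -> factors 1
        cells = CellCountMatrix(
            counts=counts, gene_ids=np.array([f"g{j}" for j in range(10)]),
            cell_individual=np.array([f"I{i}" for i in range(5)]),
            cell_type=np.repeat("T", 5), cell_depth=counts.sum(axis=1))
        from sctwas import aggregate_pseudobulk
        pb = aggregate_pseudobulk(cells, "T")
        na = na_normalize(cells, "T")
        an = an_normalize(pb)
        assert np.allclose(na.values, an.values)


class TestStandardElasticNet:
    def test_infinite_penalty_gives_covariate_ols(self, rng):
        n = 50
        G = rng.standard_normal((n, 6))
        x = rng.standard_normal(n)
        est = NormalizedGReXRegressor().fit(G, x, lam=1e12)
        assert np.all(est.beta_ == 0)
        assert est.gamma_[0] == pytest.approx(x.mean(), rel=1e-8)

    def test_lambda_zero_matches_ols(self, rng):
        n, p = 60, 5
        G = rng.standard_normal((n, p))
        x = G @ rng.standard_normal(p) + rng.standard_normal(n)
        est = NormalizedGReXRegressor(standardize=False).fit(G, x, lam=0.0)
        A = np.column_stack([G, np.ones(n)])
        ref = np.linalg.lstsq(A, x, rcond=None)[0]
        got = np.concatenate([est.beta_, est.gamma_])
        assert np.allclose(got, ref, rtol=1e-6, atol=1e-8)

    def test_reduces_to_weighted_fit_with_unit_weights(self, rng):
        n, p = 40, 4
        G = rng.standard_normal((n, p))
        x = G @ rng.standard_normal(p) + rng.standard_normal(n)
        est = NormalizedGReXRegressor().fit(G, x, lam=2.0)
        beta, gamma = fit_weighted_elastic_net(
            x, np.ones(n), G, None, np.ones(n), lam=2.0)
        assert np.allclose(est.beta_, beta)
        assert np.allclose(est.gamma_, gamma)
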