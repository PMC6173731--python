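"""Logicle transform, batch correction, PCA and group statistics."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from clonotrace.indexsort import (
    batch_correct,
    biexponential,
    estimate_logicle_params,
    group_tests,
    logicle,
    median_shift,
    pca_markers,
    transform_table,
)


# ---------------------------------------------------------------------------
# logicle
# ---------------------------------------------------------------------------


class TestLogicleParams:
    def test_w_from_negative_percentile(self):
        # r = -150 is the only negative event, T = 262144
        x = np.array([262144.0, -150.0, 10.0])
        p = estimate_logicle_params(x, m=4.5)
        assert p.T == 262144.0
        assert p.M == 4.5
        assert p.A == 0.0
        assert p.W == pytest.approx((4.5 - np.log10(262144 / 150)) / 2, abs=1e-12)

    def test_w_at_published_decades(self):
        x = np.array([262144.0, -150.0, 10.0])
        p = estimate_logicle_params(x, m=5.1)
        assert p.W == pytest.approx((5.1 - np.log10(262144 / 150)) / 2, abs=1e-12)

    def test_no_negative_events_gives_zero_w(self):
        p = estimate_logicle_params(np.array([5.0, 100.0, 1000.0]), m=4.5)
        assert p.W == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            estimate_logicle_params(np.array([-5.0, -1.0]), m=4.5)
        with pytest.raises(ValueError):
            estimate_logicle_params(np.array([1.0, 2.0]), m=-1)


@pytest.fixture(scope="module")
def params():
    return estimate_logicle_params(np.array([262144.0, -150.0, 10.0]), m=5.1)


class TestLogicleTransform:

    def test_top_of_scale_maps_to_full_decades(self, params):
        assert logicle(params.T, params) == pytest.approx(params.M, abs=1e-3)

    def test_zero_maps_to_w(self, params):
        assert logicle(0.0, params) == pytest.approx(params.W, abs=1e-10)

    @pytest.mark.parametrize("x", [-100.0, 10.0, 1e4])
    def test_round_trip(self, params, x):
        y = logicle(x, params)
        assert biexponential(y, params) == pytest.approx(x, rel=1e-8, abs=1e-8)

    def test_strictly_increasing(self, params):
        xs = np.linspace(-145.0, params.T, 400)
        ys = logicle(xs, params)
        assert np.all(np.diff(ys) > 0)

    def test_out_of_range_errors(self, params):
        with pytest.raises(ValueError):
            logicle(params.T * 10, params)

    def test_round_trip_many_random_values(self, params):
        rng = np.random.default_rng(3)
        lo = biexponential(0.0, params)
        x = rng.uniform(lo, params.T, size=2000)
        y = logicle(x, params)
        back = biexponential(y, params)
        assert np.max(np.abs(back - x) / np.maximum(1.0, np.abs(x))) <= 1e-8

    def test_transform_table_clamps_and_appends_columns(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"M1": np.concatenate([rng.normal(0, 50, 50),
                                                 rng.lognormal(5, 1, 50)])})
        out = transform_table(df, ["M1"], m=5.1)
        assert "M1.lgcl" in out
        assert np.all(np.isfinite(out["M1.lgcl"]))


# ---------------------------------------------------------------------------
# batch correction
# ---------------------------------------------------------------------------


class TestBatchCorrect:
    def test_single_batch_is_identity(self, rng):
        X = rng.normal(0, 1, (40, 6))
        assert np.abs(batch_correct(X, ["a"] * 40) - X).max() <= 1e-10

    def test_batch_of_one_errors(self, rng):
        X = rng.normal(0, 1, (5, 3))
        with pytest.raises(ValueError):
            batch_correct(X, ["a", "a", "a", "a", "b"])

    def test_nonfinite_errors(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0], [1.0, 2.0], [0.0, 1.0]])
        with pytest.raises(ValueError):
            batch_correct(X, ["a", "a", "b", "b"])

    def test_removes_planted_location_scale_effects(self):
        """Per-feature batch shifts/scales are removed while grand means
        are preserved exactly."""
        rng = np.random.default_rng(5)
        shifts = rng.normal(2.0, 0.8, 20)
        scales = rng.uniform(0.7, 1.5, 20)
        A = rng.normal(0, 1, (500, 20))
        B = rng.normal(0, 1, (500, 20)) * scales + shifts
        X = np.vstack([A, B])
        batches = ["a"] * 500 + ["b"] * 500
        Y = batch_correct(X, batches)
        dmean = np.abs(Y[:500].mean(0) - Y[500:].mean(0))
        assert (dmean < 0.05).mean() >= 0.95
        assert np.abs(Y.mean(0) - X.mean(0)).max() <= 1e-6

    def test_zero_variance_feature_passes_through(self, rng):
        X = rng.normal(0, 1, (40, 3))
        X[:, 1] = 7.0
        Y = batch_correct(X, ["a"] * 20 + ["b"] * 20)
        assert np.all(Y[:, 1] == 7.0)

    def test_matches_bioconductor_sva_combat(self, tmp_path):
        """Dual-route check: the EB adjustment agrees with sva::ComBat to
        numerical precision after feature centring (this implementation
        recentres grand means exactly; sva does not)."""
        rscript = shutil.which("Rscript")
        assert rscript is not None, "Rscript expected on PATH in this environment"
        rng = np.random.default_rng(42)
        shifts = rng.normal(1.5, 0.7, 8)
        scales = rng.uniform(0.8, 1.4, 8)
        A = rng.normal(0, 1, (60, 8))
        B = rng.normal(0, 1, (60, 8)) * scales + shifts
        X = np.vstack([A, B])
        np.savetxt(tmp_path / "in.csv", X, delimiter=",")
        script = tmp_path / "combat.R"
        script.write_text(
            'suppressMessages(library(sva))\n'
            f'X <- as.matrix(read.csv("{tmp_path}/in.csv", header=FALSE))\n'
            'Y <- t(ComBat(dat=t(X), batch=c(rep("a",60), rep("b",60))))\n'
            f'write.table(Y, "{tmp_path}/out.csv", sep=",", row.names=FALSE, col.names=FALSE)\n'
        )
        subprocess.run([rscript, str(script)], check=True, capture_output=True)
        R = np.loadtxt(tmp_path / "out.csv", delimiter=",")
        Y = batch_correct(X, ["a"] * 60 + ["b"] * 60)
        assert np.abs((Y - Y.mean(0)) - (R - R.mean(0))).max() <= 1e-6


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


class TestPCA:
    def test_loadings_orthonormal(self, rng):
        r = pca_markers(rng.normal(0, 1, (50, 6)))
        assert np.abs(r.loadings.T @ r.loadings - np.eye(6)).max() <= 1e-8

    def test_data_on_a_line(self, rng):
        X = rng.normal(0, 1, (100, 1)) @ np.array([[1.0, 1.0]])
        r = pca_markers(X)
        assert r.variance_explained[0] == pytest.approx(1.0, abs=1e-12)
        assert r.loadings[:, 0] == pytest.approx(np.full(2, 1 / np.sqrt(2)), abs=1e-8)

    def test_total_variance_conserved(self, rng):
        X = rng.normal(0, 2, (80, 5))
        r = pca_markers(X)
        comp_var = (r.scores**2).sum(axis=0)
        assert comp_var.sum() == pytest.approx(((X - X.mean(0)) ** 2).sum(), rel=1e-10)

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(0, 1, (30, 4))
        r = pca_markers(X)
        rec = r.scores @ r.loadings.T + X.mean(axis=0)
        assert np.abs(rec - X).max() <= 1e-8

    def test_sign_convention(self, rng):
        r = pca_markers(rng.normal(0, 1, (40, 5)))
        for j in range(5):
            col = r.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_too_few_cells_errors(self):
        with pytest.raises(ValueError):
            pca_markers(np.ones((1, 3)))


def test_pc1_polarity_on_simulated_gradient(default_sim):
    """After normalization, CLEC9A and CD34 load PC1 with opposite signs
    (the anti-correlated differentiation gradient)."""
    table = default_sim.table
    markers = [c for c in table.columns if c not in ("cell_id", "well", "sort_batch")]
    norm = transform_table(table, markers, m=5.1)
    cols = [m + ".lgcl" for m in markers]
    X = batch_correct(norm[cols].to_numpy(), norm["sort_batch"].to_numpy())
    r = pca_markers(X, markers=markers)
    load = dict(zip(markers, r.loadings[:, 0]))
    assert load["CLEC9A"] * load["CD34"] < 0


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


class TestMedianShift:
    def test_identical_groups(self, rng):
        x = rng.normal(5, 1, 100)
        assert median_shift(x, x) == 0.0

    @pytest.mark.parametrize("ma, mb, expected", [(140, 100, 40.0), (87, 100, -13.0)])
    def test_arithmetic(self, ma, mb, expected):
        assert median_shift([ma], [mb]) == pytest.approx(expected)

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError):
            median_shift([1.0], [0.0])


class TestGroupTests:
    def test_kruskal_identical_groups(self):
        res = group_tests([1.0] * 10, ["a"] * 5 + ["b"] * 5, design="kruskal")
        assert res["statistic"] == 0.0
        assert "pairwise" in res

    def test_fisher_matches_hypergeometric_enumeration(self):
        """Two-sided exact p equals the sum over all tables with the same
        margins whose probability does not exceed the observed one."""
        table = [[13, 6], [0, 6]]
        res = group_tests(table, None, design="fisher")
        row1, _ = 19, 6
        col1 = 13
        N = 25
        p_obs = stats.hypergeom.pmf(13, N, row1, col1)
        p_two = sum(
            p
            for a in range(max(0, col1 - 6), min(row1, col1) + 1)
            if (p := stats.hypergeom.pmf(a, N, row1, col1)) <= p_obs * (1 + 1e-9)
        )
        assert res["p"] == pytest.approx(p_two, rel=1e-9)

    def test_separated_groups_agree_with_permutation_oracle(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)
        values = np.concatenate([a, b])
        labels = np.array(["a"] * 50 + ["b"] * 50)
        res = group_tests(values, labels, design="mannwhitney")
        assert res["p"] < 1e-3
        # permutation oracle on the difference of means
        obs = abs(a.mean() - b.mean())
        perm = 0
        for _ in range(10_000):
            sh = rng.permutation(values)
            perm += abs(sh[:50].mean() - sh[50:].mean()) >= obs
        assert (perm + 1) / 10_001 < 1e-3

    def test_kruskal_pairwise_flags_the_separated_pair(self, rng):
        values = np.concatenate(
            [rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(4, 1, 30)]
        )
        labels = np.repeat(["a", "b", "c"], 30)
        res = group_tests(values, labels, design="kruskal")
        pw = res["pairwise"].set_index(["group_1", "group_2"])
        assert pw.loc[("a", "c"), "p_adjusted"] < 0.01
        assert pw.loc[("a", "b"), "p_adjusted"] > 0.05

    def test_anova_and_paired_t_dispatch(self, rng):
        a = rng.normal(0, 1, 20)
        res = group_tests(
            np.concatenate([a, a + 2]), ["x"] * 20 + ["y"] * 20, design="anova"
        )
        assert res["p"] < 1e-4
        res2 = group_tests(
            np.concatenate([a, a + 1]), ["x"] * 20 + ["y"] * 20, design="paired_t"
        )
        assert res2["p"] < 1e-6

    def test_errors(self):
        with pytest.raises(ValueError):
            group_tests([1.0, 2.0], ["a", "a"], design="kruskal")
        with pytest.raises(ValueError):
            group_tests([[1, 2, 3], [1, 2, 3]], None, design="fisher")
        with pytest.raises(ValueError):
            group_tests([1.0, 2.0], ["a", "b"], design="unknown")


# ---------------------------------------------------------------------------
# property: logicle monotone + invertible on random parameterizations
# ---------------------------------------------------------------------------


@settings(max_examples=25, deadline=None)
@given(
    m=st.floats(min_value=3.5, max_value=6.0),
    r=st.floats(min_value=-5000.0, max_value=-10.0),
    t_exp=st.floats(min_value=4.0, max_value=6.0),
)
def test_logicle_monotone_invertible_property(m, r, t_exp):
    T = 10.0**t_exp
    params = estimate_logicle_params(np.array([T, r, 10.0]), m=m)
    lo = biexponential(0.0, params)
    xs = np.linspace(lo, T, 60)
    ys = logicle(xs, params)
    assert np.all(np.diff(ys) > 0)
    back = biexponential(ys, params)
    assert np.max(np.abs(back - xs) / np.maximum(1.0, np.abs(xs))) <= 1e-8
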