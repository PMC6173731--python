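"""Cell QC thresholds, size factors and spike-in-anchored HVG selection."""

import numpy as np
import pandas as pd
import pytest

from clonotrace.scqc import (
    CountsMatrix,
    batch_correct_expression,
    qc_filter,
    select_hvgs,
    size_factors,
)
from clonotrace.synthetic import CountsSimConfig, simulate_counts


def small_matrix(counts, meta=None, **kw):
    return CountsMatrix.from_counts(pd.DataFrame(counts), cell_meta=meta, **kw)


class TestQCFilter:
    def test_threshold_rules(self):
        meta = pd.DataFrame(
            {
                "total_reads": [1e6, 3e5, 1e6, 1e6],
                "reads_in_genes": [1.5e5, 2.5e5, 5e5, 5e5],
            },
            index=["low_reads", "ok", "high_mito", "ok2"],
        )
        counts = pd.DataFrame(
            np.array([[100, 100, 100, 100], [10, 10, 400, 10]]),
            index=["G1", "MT-1"],
            columns=meta.index,
        )
        qc = qc_filter(CountsMatrix.from_counts(counts, cell_meta=meta))
        assert qc.kept_cells == ["ok", "ok2"]
        assert set(qc.dropped_cells) == {"low_reads", "high_mito"}

    def test_exact_agreement_with_direct_rule(self, counts_sim):
        """The filter is a pure threshold function: agrees cell-by-cell
        with a one-line reimplementation."""
        matrix, _ = counts_sim
        thr = 1e5  # exercise both sides of the threshold on this fixture
        qc = qc_filter(matrix, min_gene_reads=thr)
        meta = matrix.cell_meta
        mito = matrix.counts.loc[matrix.is_mito].sum()
        nuclear = matrix.counts.loc[~matrix.is_mito & ~matrix.is_spikein].sum()
        expected = (
            (meta["reads_in_genes"] > thr)
            & (meta["reads_in_genes"] / meta["total_reads"] > 0.20)
            & (mito / (mito + nuclear) < 0.20)
        )
        assert qc.kept_cells == list(meta.index[expected])

    def test_detected_genes_criterion_switch(self, counts_sim):
        matrix, _ = counts_sim
        qc = qc_filter(matrix, mapping_criterion="detected_genes",
                       min_mapping_fraction=0.5)
        endo = matrix.endogenous
        detected = (endo > 0).sum() / endo.shape[0]
        mask = pd.Index(qc.kept_cells)
        assert (detected[mask] > 0.5).all()

    def test_missing_metadata_errors(self):
        m = small_matrix({"c1": [1, 2], "c2": [3, 4]}, meta=pd.DataFrame(index=["c1", "c2"]))
        with pytest.raises(ValueError):
            qc_filter(m)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = small_matrix(np.tile(np.arange(1, 11)[:, None], (1, 4)))
        assert np.allclose(size_factors(m), 1.0)

    def test_doubled_column_factor_ratio_is_exactly_two(self):
        counts = np.tile(np.arange(1, 11)[:, None], (1, 4))
        counts[:, 2] = counts[:, 2] * 2
        sf = size_factors(small_matrix(counts))
        assert sf.iloc[2] / sf.iloc[0] == pytest.approx(2.0, rel=1e-12)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0, rel=1e-12)

    def test_spikeins_excluded_from_reference(self):
        genes = ["G1", "G2", "ERCC-1"]
        base = pd.DataFrame(
            [[10, 10], [20, 20], [100, 1]], index=genes, columns=["c1", "c2"]
        )
        sf = size_factors(CountsMatrix.from_counts(base))
        # endogenous rows are identical across cells -> unit factors even
        # though the spike-in row is wildly unbalanced
        assert np.allclose(sf, 1.0)

    def test_scaling_equivariance(self):
        """Scaling one cell's counts by c multiplies its factor relative
        to every other cell by exactly c."""
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(100, 6)) + 1
        m1 = small_matrix(counts)
        scaled = counts.astype(float).copy()
        scaled[:, 3] *= 3.0
        m2 = small_matrix(scaled)
        s1, s2 = size_factors(m1), size_factors(m2)
        ratio1 = s1.iloc[3] / s1.iloc[0]
        ratio2 = s2.iloc[3] / s2.iloc[0]
        assert ratio2 == pytest.approx(3.0 * ratio1, rel=1e-12)

    def test_no_reference_gene_errors(self):
        m = small_matrix(np.array([[0, 5], [5, 0]]))
        with pytest.raises(ValueError):
            size_factors(m)


class TestSelectHVGs:
    def quad_cv(self, log_mean):
        # known technical-noise curve: log10 CV = 0.05*lm^2 - 0.6*lm + 0.1
        # (low enough that 5x the curve CV still keeps all values positive)
        return 0.05 * log_mean**2 - 0.6 * log_mean + 0.1

    def exact_matrix(self, n_cols=10):
        """Spike-ins placed exactly on the quadratic; one endogenous gene
        at 5x the curve's CV."""
        rows, index = [], []
        for i, mu in enumerate(np.logspace(1.2, 3.5, 12)):
            cv = 10 ** self.quad_cv(np.log10(mu))
            delta = cv * np.sqrt((n_cols - 1) / n_cols)
            row = mu * (1 + delta * np.tile([1.0, -1.0], n_cols // 2))
            rows.append(row)
            index.append(f"ERCC-{i}")
        mu_g = 100.0
        cv_g = 5 * 10 ** self.quad_cv(np.log10(mu_g))
        delta = cv_g * np.sqrt((n_cols - 1) / n_cols)
        rows.append(mu_g * (1 + delta * np.tile([1.0, -1.0], n_cols // 2)))
        index.append("GENE-HOT")
        rows.append(np.full(n_cols, 50.0))  # zero-CV gene, never flagged
        index.append("GENE-FLAT")
        df = pd.DataFrame(rows, index=index)
        return CountsMatrix.from_counts(df)

    def test_planted_gene_above_exact_quadratic(self):
        m = self.exact_matrix()
        res = select_hvgs(m, pd.Series(1.0, index=m.counts.columns))
        assert res.hvg_genes == ["GENE-HOT"]
        # the fitted quadratic reproduces the construction
        assert res.coefficients == pytest.approx([0.05, -0.6, 0.1], abs=1e-8)

    def test_too_few_qualifying_spikeins_errors(self):
        m = self.exact_matrix()
        with pytest.raises(ValueError):
            select_hvgs(m, pd.Series(1.0, index=m.counts.columns), mean_for_fit=1e6)

    def test_margin_monotonically_shrinks_the_set(self, counts_sim):
        matrix, _ = counts_sim
        sf = size_factors(matrix)
        sets = [
            set(select_hvgs(matrix, sf, margin=m).hvg_genes)
            for m in (0.0, 0.05, 0.15, 0.4)
        ]
        for bigger, smaller in zip(sets, sets[1:]):
            assert smaller <= bigger

    def test_planted_hvgs_recovered(self, counts_sim):
        matrix, truth = counts_sim
        res = select_hvgs(matrix, size_factors(matrix))
        planted = set(truth["is_hvg"][truth["is_hvg"]].index)
        recovered = planted & set(res.hvg_genes)
        assert len(recovered) / len(planted) >= 0.9

    def test_spikein_above_curve_rate_near_half_at_zero_margin(self, counts_sim):
        """With margin 0, fit-window spike-ins straddle their own fitted
        curve at roughly the 50% rate the margin implies."""
        matrix, _ = counts_sim
        res = select_hvgs(matrix, size_factors(matrix))
        tab = res.table
        fitted = tab[tab.is_spikein & (tab["mean"] > 10) & tab.log10_cv.notna()]
        assert 0.25 <= fitted["above_curve"].mean() <= 0.75

    def test_every_hvg_lies_above_prediction(self, counts_sim):
        matrix, _ = counts_sim
        res = select_hvgs(matrix, size_factors(matrix), margin=0.1)
        tab = res.table.loc[res.hvg_genes]
        assert (tab["log10_cv"] > tab["predicted_log10_cv"] + 0.1).all()


class TestBatchCorrectExpression:
    def test_single_batch_identity(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(5, 1, (20, 10)))
        out = batch_correct_expression(X, ["a"] * 10)
        assert np.abs(out.to_numpy() - X.to_numpy()).max() <= 1e-10

    def test_planted_shift_removed(self):
        rng = np.random.default_rng(1)
        shift_g = rng.normal(0.0, 2.0, 200)
        A = rng.normal(5, 1, (200, 100))
        B = rng.normal(5, 1, (200, 100)) + shift_g[:, None]
        X = pd.DataFrame(np.hstack([A, B]))
        out = batch_correct_expression(X, ["b1"] * 100 + ["b2"] * 100)
        dm = np.abs(out.iloc[:, :100].mean(1) - out.iloc[:, 100:].mean(1))
        assert (dm < 0.05).mean() >= 0.95

    def test_low_count_genes_pass_through(self):
        X = pd.DataFrame(np.zeros((3, 10)))
        X.iloc[1] = np.arange(10) * 0.1  # total > 1 -> adjusted
        X.iloc[2, 0] = 0.5               # total <= 1 -> untouched
        out = batch_correct_expression(X, ["a"] * 5 + ["b"] * 5)
        assert (out.iloc[0] == 0).all()
        assert out.iloc[2, 0] == 0.5


class TestSimulateCounts:
    def test_seeded_reproducibility(self):
        a, _ = simulate_counts(CountsSimConfig(seed=3, n_genes=200, n_cells=30))
        b, _ = simulate_counts(CountsSimConfig(seed=3, n_genes=200, n_cells=30))
        assert a.counts.equals(b.counts)

    def test_spikein_row_means_within_sampling_error(self):
        cfg = CountsSimConfig(seed=5, n_cells=500, n_genes=300)
        m, truth = simulate_counts(cfg)
        spikes = m.counts.loc[m.is_spikein]
        bad = 0
        for g in spikes.index:
            mu = truth["spike_means"][g]
            phi = cfg.dispersion_a / mu + cfg.dispersion_b
            se = np.sqrt((mu + phi * mu**2) / cfg.n_cells)
            bad += abs(spikes.loc[g].mean() - mu) > 3 * se
        assert bad <= max(1, int(0.01 * len(spikes)))  # ~3-sigma exceptions

    def test_mito_fraction_near_configured(self):
        cfg = CountsSimConfig(seed=6, mito_fraction=0.08)
        m, _ = simulate_counts(cfg)
        frac = m.counts.loc[m.is_mito].sum().sum() / m.endogenous.sum().sum()
        assert abs(frac - 0.08) <= 0.02

    def test_truth_record_complete(self, counts_sim):
        matrix, truth = counts_sim
        for key in ("gene_means", "is_hvg", "spike_means", "depth", "batch"):
            assert key in truth
        assert len(truth["depth"]) == matrix.counts.shape[1]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CountsSimConfig(mito_fraction=1.5)
        with pytest.raises(ValueError):
            CountsSimConfig(dispersion_b=0.0)

    def test_spikeins_never_mito(self, counts_sim):
        matrix, _ = counts_sim
        assert not (matrix.is_spikein & matrix.is_mito).any()
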