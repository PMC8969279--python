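"""Size factors, dispersion, the NB likelihood-ratio test, and selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riddmap import deu
from riddmap.deu import fold_change, select_candidates, size_factors
from riddmap.deu import test_bin as lr_test_bin
from riddmap.simulate import ExonCountMatrix
from riddmap.annotation import ExonBin


def _matrix(counts_dict, gene="g1", chrom="chr1"):
    counts = pd.DataFrame(counts_dict)
    bins = [
        ExonBin(bin_id=i, gene_ids=(gene,), chrom=chrom, start=100 * k, end=100 * (k + 1),
                strand="+")
        for k, i in enumerate(counts.index)
    ]
    conds = {s: ("mock" if s.startswith("mock") else "ire1") for s in counts.columns}
    return ExonCountMatrix(counts=counts, conditions=conds, bins=bins)


class TestSizeFactors:
    def test_identical_samples(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        np.testing.assert_allclose(size_factors(counts), [1.0, 1.0])

    def test_proportional_columns_recover_ratio(self):
        # closed form: B = 2A everywhere -> ratios (2^-1/2, 2^1/2) at gmean 1
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = size_factors(counts)
        np.testing.assert_allclose(sf, [2**-0.5, 2**0.5])
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            size_factors(pd.DataFrame({"a": [0, 0], "b": [0, 0]}))

    def test_fallback_without_all_positive_bin(self, caplog):
        counts = pd.DataFrame({"a": [10, 0], "b": [0, 10]})
        with caplog.at_level("WARNING"):
            sf = size_factors(counts)
        np.testing.assert_allclose(sf, [1.0, 1.0])
        assert "falling back" in caplog.text


class TestDispersion:
    def test_equal_replicates_give_zero(self):
        m = _matrix({"mock_1": [100, 50], "mock_2": [100, 50],
                     "ire1_1": [100, 50], "ire1_2": [100, 50]})
        assert (deu.estimate_dispersions(m) == 0).all()

    def test_poisson_boundary_gives_zero(self):
        # within-condition variance equal to the mean: alpha-hat = 0
        m = _matrix({"mock_1": [90, 50], "mock_2": [110, 50],
                     "ire1_1": [90, 50], "ire1_2": [110, 50]})
        norm = m.counts  # size factors are 1 here by symmetry
        mu = norm[["mock_1", "mock_2"]].mean(axis=1)
        s2 = norm[["mock_1", "mock_2"]].var(axis=1, ddof=1)
        assert s2.iloc[0] > mu.iloc[0]  # sanity: this row is over-dispersed
        m2 = _matrix({"mock_1": [100, 50], "mock_2": [100, 50],
                      "ire1_1": [100, 50], "ire1_2": [100, 50]})
        assert deu.estimate_dispersions(m2).iloc[0] == 0.0

    def test_monte_carlo_recovery(self):
        """NB data with alpha=0.1, 200 bins x 6 replicates: the mean
        method-of-moments estimate lands within 25% of the truth."""
        rng = np.random.default_rng(21)
        alpha, mu = 0.1, 500.0
        r = 1 / alpha
        draws = rng.negative_binomial(r, r / (r + mu), size=(200, 6))
        counts = pd.DataFrame(
            draws, index=[f"b{i}" for i in range(200)],
            columns=["mock_1", "mock_2", "mock_3", "ire1_1", "ire1_2", "ire1_3"],
        )
        bins = [ExonBin(bin_id=f"b{i}", gene_ids=(f"g{i}",), chrom="c", start=i * 10,
                        end=i * 10 + 5, strand="+") for i in range(200)]
        m = ExonCountMatrix(
            counts=counts,
            conditions={s: ("mock" if s.startswith("mock") else "ire1") for s in counts},
            bins=bins,
        )
        est = deu.estimate_dispersions(m, sf=pd.Series(1.0, index=counts.columns))
        assert abs(est.mean() - alpha) / alpha < 0.25


def g_test_2x2(table):
    """Closed-form G statistic of independence on a 2x2 table (the oracle)."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    g = 0.0
    for i in range(2):
        for j in range(2):
            e = table[i].sum() * table[:, j].sum() / total
            if table[i, j] > 0:
                g += 2 * table[i, j] * np.log(table[i, j] / e)
    return g


class TestLikelihoodRatio:
    conditions = np.array(["mock", "mock", "mock", "ire1", "ire1", "ire1"])
    sf = np.ones(6)

    def test_identical_conditions_give_zero(self):
        y_bin = np.array([100, 100, 100, 100, 100, 100])
        y_rest = np.array([400, 400, 400, 400, 400, 400])
        res = lr_test_bin(y_bin, y_rest, self.conditions, 0.0, self.sf)
        assert res.lr_stat <= 1e-6
        assert res.p == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_poisson_limit_equals_g_test(self, seed):
        """With alpha=0 and equal size factors the LR reduces to the G test
        of independence on the collapsed (bin/rest x condition) table."""
        rng = np.random.default_rng(seed)
        y_bin = rng.integers(10, 500, size=6).astype(float)
        y_rest = rng.integers(100, 2000, size=6).astype(float)
        res = lr_test_bin(y_bin, y_rest, self.conditions, 0.0, self.sf)
        mock = self.conditions == "mock"
        table = [
            [y_bin[mock].sum(), y_bin[~mock].sum()],
            [y_rest[mock].sum(), y_rest[~mock].sum()],
        ]
        assert res.lr_stat == pytest.approx(g_test_2x2(table), abs=1e-6)

    def test_planted_depletion_is_detected(self):
        # strong usage loss in treated samples at high depth
        y_bin = np.array([5000, 5100, 4900, 500, 520, 480])
        y_rest = np.array([20000, 20400, 19600, 20000, 20800, 19200])
        res = lr_test_bin(y_bin, y_rest, self.conditions, 0.05, self.sf)
        assert res.p < 1e-6

    def test_nb_shrinks_statistic_versus_poisson(self):
        y_bin = np.array([520, 480, 510, 430, 400, 380])
        y_rest = np.array([2000, 2050, 1940, 2010, 1980, 2060])
        lr_pois = lr_test_bin(y_bin, y_rest, self.conditions, 0.0, self.sf).lr_stat
        lr_nb = lr_test_bin(y_bin, y_rest, self.conditions, 0.1, self.sf).lr_stat
        assert 0 < lr_nb < lr_pois

    def test_all_zero_bin(self):
        res = lr_test_bin(np.zeros(6), np.full(6, 100.0), self.conditions, 0.0, self.sf)
        assert res.p == 1.0

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            lr_test_bin(np.ones(3), np.ones(3), np.array(["mock", "ire1", "ire1"]), 0.0,
                     np.ones(3))


class TestFoldChange:
    def test_worked_example(self):
        # usage 0.2 (mock) vs 0.05 (ire1): odds ratio 0.2105 -> fc -4.75
        assert fold_change(0.2, 0.05) == pytest.approx(-4.75, abs=0.0001)

    def test_equal_usage_is_plus_one(self):
        assert fold_change(0.3, 0.3) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_swap_antisymmetry(self, u1, u2):
        a = fold_change(u1, u2)
        b = fold_change(u2, u1)
        assert abs(a) == pytest.approx(abs(b), rel=1e-9)
        if abs(a) > 1:
            assert np.sign(a) == -np.sign(b)

    def test_degenerate_usage_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 0.5)


class TestBhAndSelection:
    def test_bh_monotone_and_at_least_p(self, null_deu_results):
        tested = null_deu_results[null_deu_results["testable"]].sort_values("p")
        assert (tested["fdr"] >= tested["p"] - 1e-12).all()
        assert (np.diff(tested["fdr"]) >= -1e-12).all()

    def _results(self):
        return pd.DataFrame(
            {
                "bin_id": ["b1", "b2", "b3", "b4"],
                "gene_id": ["ATM", "IRF4", "CUL5", "EDGE"],
                "fc": [-34.9, -1.59, -2.05, -2.0],
                "fdr": [1e-6, 1e-6, 1e-3, 1e-3],
                "testable": [True] * 4,
                "ambiguous": [False] * 4,
            }
        )

    def test_strong_fc_selected_and_ranked_first(self):
        out = select_candidates(self._results())
        assert out["gene_id"].iloc[0] == "ATM"
        assert out[out["gene_id"] == "ATM"]["best_fc"].iloc[0] == -34.9

    def test_weak_fc_excluded_without_override(self):
        out = select_candidates(self._results())
        assert "IRF4" not in set(out["gene_id"])

    def test_override_appends_and_flags(self):
        out = select_candidates(self._results(), override=("IRF4",))
        row = out[out["gene_id"] == "IRF4"]
        assert len(row) == 1 and bool(row["override"].iloc[0])
        assert out.index[-1] == out.index.max()  # appended at the end
        assert out["gene_id"].iloc[-1] == "IRF4"

    def test_exact_threshold_excluded(self):
        out = select_candidates(self._results())
        assert "EDGE" not in set(out["gene_id"])  # fc == -2.0: strict inequality
        assert "CUL5" in set(out["gene_id"])

    def test_empty_results(self):
        empty = self._results().iloc[0:0]
        assert len(select_candidates(empty)) == 0

    def test_threshold_monotonicity(self):
        strict = set(select_candidates(self._results(), fc_max=-2.0)["gene_id"])
        loose = set(select_candidates(self._results(), fc_max=-1.5)["gene_id"])
        assert strict <= loose


class TestTypeIError:
    def test_null_simulation_calibrated(self, null_deu_results):
        """Null data (no cleavage): the p < 0.05 fraction stays inside the
        99% binomial band around 0.05."""
        tested = null_deu_results[null_deu_results["testable"]]
        n = len(tested)
        assert n >= 500
        frac = (tested["p"] < 0.05).mean()
        half = 2.576 * np.sqrt(0.05 * 0.95 / n)
        assert 0.05 - half <= frac <= 0.05 + half
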