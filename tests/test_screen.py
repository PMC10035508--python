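"""Regulator correlation screen and tumor sign-concordance filter."""

import math

import numpy as np
import pandas as pd
import pytest

from splicescreen import (
    ExpressionMatrix, PanelConfig, RegulatorScreen, concordance_filter,
    gen_multitissue_panel, screen_junction_regulators,
)
from splicescreen.simulate import INCLUSION_JUNCTION, TARGET_GENE


def _expr(values, genes=None, samples=None, normalized=True):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"R{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values, normalized=normalized)


def _usage(values, samples=None):
    samples = samples or [f"s{i}" for i in range(len(values))]
    return pd.Series(np.asarray(values, dtype=float), index=samples)


class TestPearsonScreen:
    def test_self_correlation_rank_one(self):
        u = _usage([0.1, 0.3, 0.5, 0.7, 0.2])
        e = _expr([u.to_numpy(), [5, 5, 4, 6, 5]], genes=["SELF", "FLAT"])
        res = RegulatorScreen(e, u).fit()
        row = res.table.set_index("rbp").loc["SELF"]
        assert row["r"] == pytest.approx(1.0)
        assert row["rank"] == 1

    def test_negation_gives_minus_one(self):
        u = _usage([0.1, 0.3, 0.5, 0.7])
        e = _expr([1.0 - u.to_numpy()], genes=["NEG"])
        res = RegulatorScreen(e, u).fit()
        assert res.table["r"].iloc[0] == pytest.approx(-1.0)
        assert res.table["sign"].iloc[0] == "-"

    def test_closed_form_oracle_five_points(self):
        """r and p from the explicit Pearson/t formulas on a 5-point set."""
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        # independent brute-force evaluation
        xc, yc = x - x.mean(), y - y.mean()
        r_exp = (xc * yc).sum() / math.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        n = 5
        t = r_exp * math.sqrt((n - 2) / (1 - r_exp ** 2))
        from scipy.stats import t as tdist
        p_exp = 2 * tdist.sf(abs(t), df=n - 2)

        res = RegulatorScreen(_expr([x], genes=["A"]), _usage(y)).fit()
        assert res.table["r"].iloc[0] == pytest.approx(r_exp, rel=1e-12)
        assert res.table["p"].iloc[0] == pytest.approx(p_exp, rel=1e-9)

    def test_tie_break_by_p_then_symbol(self):
        u = _usage([0.1, 0.2, 0.4, 0.8, 0.9])
        x = u.to_numpy()
        e = _expr([x, 1.0 - x, 2 * x], genes=["ZZZ", "MMM", "AAA"])
        res = RegulatorScreen(e, u).fit()
        # all |r| = 1, all p equal -> lexicographic symbol order
        assert res.table["rbp"].tolist() == ["AAA", "MMM", "ZZZ"]

    def test_zero_variance_untestable(self):
        u = _usage([0.1, 0.5, 0.9])
        e = _expr([[4, 4, 4]], genes=["CONST"])
        res = RegulatorScreen(e, u).fit()
        assert res.table.empty
        assert res.untestable == [("CONST", "zero variance")]

    def test_too_few_pairs_untestable(self):
        u = _usage([0.1, np.nan, np.nan, 0.5])
        e = _expr([[1, 2, 3, 4]], genes=["A"])
        res = RegulatorScreen(e, u).fit()
        assert res.untestable[0][0] == "A"

    def test_permutation_and_scale_invariance(self, rng):
        u = _usage(rng.uniform(0, 1, 20))
        x = rng.lognormal(3, 1, 20)
        res1 = RegulatorScreen(_expr([x], genes=["A"]), u).fit()
        perm = rng.permutation(20)
        res2 = RegulatorScreen(
            _expr([x[perm]], genes=["A"], samples=[f"s{i}" for i in perm]), u
        ).fit()
        res3 = RegulatorScreen(_expr([x * 1234.5], genes=["A"]), u).fit()
        assert res1.table["r"].iloc[0] == pytest.approx(res2.table["r"].iloc[0])
        assert res1.table["r"].iloc[0] == pytest.approx(res3.table["r"].iloc[0])

    def test_rank_permutation_invariant(self):
        res = RegulatorScreen(
            _expr([[1, 2, 3, 5], [4, 3, 2, 1.5]], genes=["A", "B"]),
            _usage([0.1, 0.2, 0.3, 0.4])).fit()
        assert sorted(res.table["rank"]) == [1, 2]
        assert (res.table["r"].abs().diff().dropna() <= 1e-15).all() or \
            res.table["r"].abs().is_monotonic_decreasing


class TestTopK:
    @pytest.fixture
    def results(self):
        u = _usage(np.linspace(0.1, 0.9, 10))
        vals = np.vstack([np.linspace(0.1, 0.9, 10) + 0.05 * np.sin(np.arange(10) + k)
                          for k in range(5)])
        return RegulatorScreen(_expr(vals), u).fit()

    def test_k_equals_n_identity(self, results):
        pd.testing.assert_frame_equal(results.top(5), results.table)

    def test_k_larger_returns_all_with_warning(self, results):
        assert len(results.top(50)) == 5

    def test_k_below_one_error(self, results):
        with pytest.raises(ValueError):
            results.top(0)


class TestRecovery:
    def test_planted_repressor_found(self):
        """PTBP1-like planted repressor (slope -1.5) ranks in the top 10 of
        50 RBPs across seeded replicates."""
        hits = 0
        for seed in range(5):
            cfg = PanelConfig(n_tissues=10, samples_per_tissue=30, n_rbps=50,
                              regulator_slope=-1.5, seed=seed)
            jcm, expr, attrs, truth = gen_multitissue_panel(cfg)
            res = screen_junction_regulators(jcm, expr, INCLUSION_JUNCTION,
                                             exclude_genes=(TARGET_GENE,))
            hits += res.rank_of(truth["regulator"]) <= 10
        assert hits == 5

    def test_null_panel_no_strong_correlation(self):
        """With slope 0 the regulator shows only noise-level correlation."""
        cfg = PanelConfig(n_tissues=10, samples_per_tissue=30, n_rbps=20,
                          regulator_slope=0.0, seed=11)
        jcm, expr, attrs, truth = gen_multitissue_panel(cfg)
        res = screen_junction_regulators(jcm, expr, INCLUSION_JUNCTION,
                                         exclude_genes=(TARGET_GENE,))
        r = res.table.set_index("rbp").loc[truth["regulator"], "r"]
        assert abs(r) < 0.2


class TestConcordance:
    def _tumor(self, hi_vals, lo_vals, gene="X"):
        n_hi, n_lo = len(hi_vals), len(lo_vals)
        samples = [f"h{i}" for i in range(n_hi)] + [f"l{i}" for i in range(n_lo)]
        groups = pd.Series(["high"] * n_hi + ["low"] * n_lo, index=samples)
        expr = _expr([list(hi_vals) + list(lo_vals)], genes=[gene],
                     samples=samples)
        return expr, groups

    def _cand(self, gene, sign):
        return pd.DataFrame({"rbp": [gene], "r": [0.9 if sign == "+" else -0.9],
                             "p": [1e-4], "n": [30], "sign": [sign], "rank": [1]})

    def test_repressor_lower_in_high_psi_is_concordant(self):
        expr, groups = self._tumor([1, 2, 1.5, 1.2, 0.8], [9, 10, 11, 12, 9.5])
        v = concordance_filter(self._cand("X", "-"), expr, groups)[0]
        assert v.tumor_de_sign == "lower_in_highPSI"
        assert v.concordant

    def test_sfrs9_pattern_rejected(self):
        """Negative cross-tissue correlation but HIGHER tumor expression in
        the high-PSI group: the discordant pattern fails the filter."""
        expr, groups = self._tumor([9, 10, 11, 12, 9.5], [1, 2, 1.5, 1.2, 0.8])
        v = concordance_filter(self._cand("X", "-"), expr, groups)[0]
        assert v.tumor_de_sign == "higher_in_highPSI"
        assert not v.concordant

    def test_enhancer_higher_is_concordant(self):
        expr, groups = self._tumor([9, 10, 11, 12, 9.5], [1, 2, 1.5, 1.2, 0.8])
        v = concordance_filter(self._cand("X", "+"), expr, groups)[0]
        assert v.concordant

    def test_nonsignificant_is_not_concordant(self):
        expr, groups = self._tumor([5, 6, 5.5, 6.2], [5.1, 6.1, 5.4, 6.3])
        v = concordance_filter(self._cand("X", "-"), expr, groups)[0]
        assert v.tumor_de_sign == "ns"
        assert not v.concordant

    def test_small_group_is_error(self):
        expr, groups = self._tumor([1], [2, 3, 4])
        with pytest.raises(ValueError, match=">=2"):
            concordance_filter(self._cand("X", "-"), expr, groups)

    def test_planted_concordant_vs_discordant(self, rng):
        """One planted concordant and one planted discordant candidate:
        exactly the concordant one passes."""
        n = 30
        samples = [f"t{i}" for i in range(2 * n)]
        groups = pd.Series(["high"] * n + ["low"] * n, index=samples)
        conc = np.concatenate([rng.lognormal(1.0, 0.3, n),
                               rng.lognormal(2.0, 0.3, n)])  # lower in high
        disc = np.concatenate([rng.lognormal(2.0, 0.3, n),
                               rng.lognormal(1.0, 0.3, n)])  # higher in high
        expr = _expr([conc, disc], genes=["CONC", "DISC"], samples=samples)
        cands = pd.DataFrame({
            "rbp": ["CONC", "DISC"], "r": [-0.8, -0.8], "p": [1e-5, 1e-5],
            "n": [60, 60], "sign": ["-", "-"], "rank": [1, 2]})
        verdicts = {v.rbp: v.concordant
                    for v in concordance_filter(cands, expr, groups)}
        assert verdicts == {"CONC": True, "DISC": False}
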