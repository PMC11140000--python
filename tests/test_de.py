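import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import bh_stepup_by_hand, mc_conditional_p
from ticktx.de import (DEResult, bh_fdr, call_de, estimate_dispersion,
                       exact_nb_test, norm_factors)
from ticktx.design import build_design


class TestNormFactors:
    def test_identical_libraries_all_one(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 1000, 200)
        df = pd.DataFrame({"a": col, "b": col, "c": col})
        assert np.allclose(norm_factors(df), 1.0)

    def test_pure_depth_difference_absorbed(self):
        rng = np.random.default_rng(1)
        col = rng.integers(10, 1000, 500)
        df = pd.DataFrame({"a": col, "b": 2 * col, "c": col})
        f = norm_factors(df)
        # a doubled library gets exactly twice the scaling factor, so
        # dividing counts by the factors equalizes the libraries
        assert f["b"] / f["a"] == pytest.approx(2.0, abs=1e-9)
        assert f["c"] / f["a"] == pytest.approx(1.0, abs=1e-9)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.integers(0, 500, size=(300, 6)),
                          columns=list("abcdef"))
        f = norm_factors(df)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0)

    def test_all_zero_library_rejected(self):
        df = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError):
            norm_factors(df)


class TestDispersion:
    def _design(self):
        return build_design(["s"], ["A", "B"], 3)

    def test_poisson_counts_give_near_zero(self):
        rng = np.random.default_rng(3)
        mu = rng.uniform(50, 500, 500)
        counts = pd.DataFrame(rng.poisson(np.outer(mu, np.ones(6))),
                              columns=self._design().library_ids)
        assert estimate_dispersion(counts, self._design()) < 0.05

    def test_nb_counts_recover_dispersion(self):
        rng = np.random.default_rng(4)
        mu = rng.uniform(50, 500, 500)
        r = 1 / 0.2
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + np.outer(mu, np.ones(6)))),
            columns=self._design().library_ids)
        phi = estimate_dispersion(counts, self._design())
        assert 0.1 <= phi <= 0.3

    def test_constant_counts_give_zero(self):
        counts = pd.DataFrame(7, index=range(20),
                              columns=self._design().library_ids)
        assert estimate_dispersion(counts, self._design()) == 0.0


class TestExactTest:
    def test_identical_groups_null(self):
        lfc, p = exact_nb_test([10, 12, 11], [10, 12, 11], phi=0.1)
        assert lfc == 0.0 and p == 1.0

    def test_zero_total(self):
        lfc, p = exact_nb_test([0, 0, 0], [0, 0, 0], phi=0.1)
        assert (lfc, p) == (0.0, 1.0)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            exact_nb_test([1], [1], phi=-0.1)

    def test_swapping_groups_negates_lfc_and_preserves_p(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.integers(0, 300, 3)
            b = rng.integers(0, 300, 3)
            l1, p1 = exact_nb_test(a, b, phi=0.2)
            l2, p2 = exact_nb_test(b, a, phi=0.2)
            assert l1 == pytest.approx(-l2)
            assert p1 == pytest.approx(p2)

    def test_poisson_limit_matches_conditional_binomial_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            n_a, n_b = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            a = int(rng.integers(0, 200))
            b = int(rng.integers(0, 200))
            if a + b == 0:
                continue
            _, p = exact_nb_test([a] + [0] * (n_a - 1), [b] + [0] * (n_b - 1),
                                 phi=0.0)
            total = a + b
            x = np.arange(total + 1)
            pmf = stats.binom.pmf(x, total, n_a / (n_a + n_b))
            expected = pmf[pmf <= pmf[a] * (1 + 1e-12)].sum()
            assert p == pytest.approx(min(1.0, expected), rel=1e-9)

    @pytest.mark.parametrize("a,b,phi", [(90, 25, 0.15), (40, 70, 0.4)])
    def test_matches_monte_carlo_conditional_oracle(self, a, b, phi):
        counts_a = [a // 3, a // 3, a - 2 * (a // 3)]
        counts_b = [b // 3, b // 3, b - 2 * (b // 3)]
        _, p = exact_nb_test(counts_a, counts_b, phi=phi)
        p_hat, se = mc_conditional_p(a, b, 3, 3, phi, n_draws=100_000, seed=1)
        assert abs(p - p_hat) <= 3 * se + 1e-9


class TestBH:
    def test_worked_stepup_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_equal_pvalues_unchanged(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_single_pvalue(self):
        assert bh_fdr([0.123])[0] == pytest.approx(0.123)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_literal_stepup_and_dominates_p(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, 50)
        q = bh_fdr(p)
        assert np.allclose(q, bh_stepup_by_hand(p))
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()  # monotone in sorted-p order
        assert (q >= p - 1e-12).all()


class TestCallDe:
    def _res(self, lfc, p):
        return DEResult("c", "s", "A", "B", lfc, p)

    def test_boundary_inclusive_lfc_and_strict_fdr(self):
        (r,) = call_de([self._res(2.0, 0.049)], 2.0, 0.05)
        assert r.significant and r.direction == "up"

    def test_large_lfc_bad_fdr_not_significant(self):
        (r,) = call_de([self._res(5.0, 0.2)], 2.0, 0.05)
        assert not r.significant and r.direction == "ns"

    def test_strong_downregulation(self):
        (r,) = call_de([self._res(-3.0, 0.001)], 2.0, 0.05)
        assert r.significant and r.direction == "down"

    def test_fdr_threshold_is_strict(self):
        (r,) = call_de([self._res(3.0, 0.05)], 2.0, 0.05)
        assert not r.significant


def test_recall_decreases_with_dispersion():
    """Planted fold changes are recalled less often as biological noise grows
    (checked in expectation over replicate count simulations)."""
    from ticktx.params import PipelineParams
    from ticktx.de import run_contrasts

    design = build_design(["s"], ["UF", "FED6h"], 3)
    params = PipelineParams()
    contrasts = (("UF", "FED6h"),)

    def recall(phi, seed):
        rng = np.random.default_rng(seed)
        n_de, n_flat = 60, 300  # mostly-null background keeps normalization honest
        mu_a = np.concatenate([rng.uniform(15, 40, n_de),
                               rng.uniform(50, 400, n_flat)])
        mu_b = mu_a.copy()
        mu_b[:n_de] *= 16.0
        mu = np.column_stack([np.repeat(mu_a[:, None], 3, axis=1),
                              np.repeat(mu_b[:, None], 3, axis=1)])
        r = 1 / phi
        counts = pd.DataFrame(rng.negative_binomial(r, r / (r + mu)),
                              columns=design.library_ids,
                              index=[f"g{i}" for i in range(n_de + n_flat)])
        table = run_contrasts(counts, design, params, contrasts)
        sig = table.set_index("cds_id")["significant"]
        return sig.loc[[f"g{i}" for i in range(n_de)]].mean()

    low = np.mean([recall(0.05, s) for s in range(20)])
    high = np.mean([recall(0.9, s) for s in range(20)])
    assert low > high
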