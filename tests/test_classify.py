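"""Nine-region probabilities, assignment rules, FDR and count tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from jointeb import (
    LABELS,
    RegionGrid,
    ValidationError,
    assign,
    build_grid,
    category_table,
    fdr,
    region_probs,
)
from jointeb.classify import UNASSIGNED, category_counts
from jointeb.posterior import DiffPosterior


def diffp(mean, cov, gene="g"):
    return DiffPosterior(gene, np.asarray(mean, float), np.asarray(cov, float))


class TestBuildGrid:
    def test_two_point_sd(self):
        diffs = [diffp([-1, -1], np.eye(2), "a"), diffp([1, 1], np.eye(2), "b")]
        grid = build_grid(diffs, c_mult=1.5)
        assert grid.t_ge == pytest.approx(1.5 * np.sqrt(2))
        assert grid.t_m == pytest.approx(1.5 * np.sqrt(2))

    def test_zero_c_mult_rejected(self):
        with pytest.raises(ValidationError, match="c_mult"):
            RegionGrid(c_mult=0.0, sd_ge=1.0, sd_m=1.0)

    def test_constant_means_rejected(self):
        diffs = [diffp([1, 1], np.eye(2), "a"), diffp([1, 1], np.eye(2), "b")]
        with pytest.raises(ValidationError, match="constant"):
            build_grid(diffs)

    def test_sampling_sd(self):
        rng = np.random.default_rng(0)
        means = rng.normal(0.0, 2.0, size=(20_000, 2))
        diffs = [diffp(m, np.eye(2), f"g{i}") for i, m in enumerate(means)]
        grid = build_grid(diffs, c_mult=1.0)
        assert grid.sd_ge == pytest.approx(2.0, rel=0.02)
        assert grid.sd_m == pytest.approx(2.0, rel=0.02)


class TestRegionProbs:
    def test_huge_thresholds_concentrate_center(self):
        grid = RegionGrid(c_mult=1.0, sd_ge=100.0, sd_m=100.0)
        p = region_probs(diffp([0, 0], np.eye(2)), grid)
        assert p[LABELS.index("NG/NM")] > 1 - 1e-10

    def test_independence_factorization(self):
        """Diagonal covariance: 9-vector equals the outer product of the two
        univariate 3-bin probabilities."""
        grid = RegionGrid(c_mult=1.5, sd_ge=0.8, sd_m=0.6)
        mean, var = np.array([0.4, -0.7]), np.array([0.9, 1.4])
        p = region_probs(diffp(mean, np.diag(var)), grid)
        uni = []
        for axis, t in enumerate((grid.t_ge, grid.t_m)):
            sd = np.sqrt(var[axis])
            lo = norm.cdf(-t, mean[axis], sd)
            mid = norm.cdf(t, mean[axis], sd) - lo
            uni.append(np.array([lo, mid, 1 - lo - mid]))
        expected = np.outer(uni[0], uni[1]).reshape(-1)
        assert np.max(np.abs(p - expected)) < 1e-7

    def test_correlated_case_matches_monte_carlo(self):
        grid = RegionGrid(c_mult=1.5, sd_ge=0.5, sd_m=0.5)
        cov = np.array([[1.0, 0.6], [0.6, 1.0]])
        mean = np.array([0.3, -0.2])
        p = region_probs(diffp(mean, cov), grid)
        rng = np.random.default_rng(1)
        n = 200_000
        draws = rng.multivariate_normal(mean, cov, size=n)
        ix = np.searchsorted([-grid.t_ge, grid.t_ge], draws[:, 0], side="right")
        iy = np.searchsorted([-grid.t_m, grid.t_m], draws[:, 1], side="right")
        counts = np.bincount(ix * 3 + iy, minlength=9) / n
        se = np.sqrt(p * (1 - p) / n)  # binomial SE at the analytic probability
        assert np.all(np.abs(p - counts) <= 3 * se + 1e-8)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        mx=st.floats(-3, 3), my=st.floats(-3, 3),
        v1=st.floats(0.1, 4), v2=st.floats(0.1, 4), r=st.floats(-0.9, 0.9),
    )
    def test_probabilities_partition_unity(self, mx, my, v1, v2, r):
        cov = np.array([[v1, r * np.sqrt(v1 * v2)], [r * np.sqrt(v1 * v2), v2]])
        grid = RegionGrid(c_mult=1.5, sd_ge=1.0, sd_m=1.0)
        p = region_probs(diffp([mx, my], cov), grid)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)


class TestAssign:
    def test_dominant_category_assigned_above_cutoff(self):
        p = np.full(9, 0.025)
        p[LABELS.index("NG/HO")] = 0.8
        [call] = assign(["CDH3-like"], p, rule="0.6")
        assert call.assigned == "NG/HO"
        assert call.max_prob == pytest.approx(0.8)

    def test_below_cutoff_unassigned(self):
        p = np.full(9, 0.45 / 8)
        p[3] = 0.55
        [call] = assign(["g"], p, rule="0.6")
        assert call.assigned == UNASSIGNED

    def test_uniform_tie_break_first_label(self):
        p = np.full(9, 1.0 / 9)
        [call] = assign(["g"], p, rule="max")
        assert call.assigned == LABELS[0] == "DN/HO"

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValidationError):
            assign(["g"], np.full(9, 1 / 9), rule="0.5")


class TestFdr:
    def make_calls(self, ps, category="UP/HO"):
        k = LABELS.index(category)
        calls = []
        for i, p in enumerate(ps):
            probs = np.full(9, (1 - p) / 8)
            probs[k] = p
            calls += assign([f"g{i}"], probs, rule="max")
        return calls

    def test_perfect_calls_zero_fdr(self):
        rep = fdr(self.make_calls([1.0, 1.0, 1.0]), "UP/HO", kappa=0.5)
        assert rep.n_selected == 3
        assert rep.fdr_hat == 0.0

    def test_hand_evaluation(self):
        rep = fdr(self.make_calls([0.9, 0.8, 0.7]), "UP/HO", kappa=0.75)
        assert rep.n_selected == 2
        assert rep.d_kappa == pytest.approx(0.3)
        assert rep.fdr_hat == pytest.approx(0.15)

    def test_empty_selection_undefined(self):
        rep = fdr(self.make_calls([0.9, 0.8]), "UP/HO", kappa=1.0)
        assert rep.n_selected == 0
        assert rep.fdr_hat is None

    def test_kappa_monotonicity(self):
        calls = self.make_calls(np.linspace(0.3, 0.99, 40))
        prev_n, prev_d = np.inf, np.inf
        for kappa in (0.4, 0.6, 0.8, 0.95):
            rep = fdr(calls, "UP/HO", kappa)
            assert rep.n_selected <= prev_n
            assert rep.d_kappa <= prev_d + 1e-12
            prev_n, prev_d = rep.n_selected, rep.d_kappa

    def test_fdr_bound_invariant(self):
        rep = fdr(self.make_calls([0.92, 0.95, 0.99]), "UP/HO", kappa=0.9)
        assert 0 <= rep.fdr_hat <= 1 - 0.9 + 1e-12


class TestCategoryTable:
    def test_all_center_bookkeeping(self):
        p = np.zeros(9)
        p[LABELS.index("NG/NM")] = 1.0
        genes = ["a", "b", "c"]
        calls = {r: assign(genes, np.tile(p, (3, 1)), r) for r in ("max", "0.6", "0.7")}
        table = category_table(calls)
        assert table.loc["NM", "NG"] == "3/3/3"
        assert table.loc["HO", "DN"] == "0/0/0"

    def test_cutoff_drops_one(self):
        p = np.full(9, 0.35 / 8)
        p[LABELS.index("UP/HR")] = 0.65
        calls = {r: assign(["g"], p, r) for r in ("max", "0.6", "0.7")}
        assert category_table(calls).loc["HR", "UP"] == "1/1/0"

    def test_counts_match_enumeration(self):
        rng = np.random.default_rng(3)
        probs = rng.dirichlet(np.ones(9) * 0.3, size=200)
        genes = [f"g{i}" for i in range(200)]
        calls = {r: assign(genes, probs, r) for r in ("max", "0.6", "0.7")}
        counts = category_counts(calls["0.6"])
        for label in LABELS:
            e, m = label.split("/")
            expected = sum(
                1
                for row in probs
                if row.max() >= 0.6 and LABELS[int(np.argmax(row))] == label
            )
            assert counts.loc[m, e] == expected

    def test_mismatched_gene_sets_rejected(self):
        p = np.full(9, 1 / 9)
        calls = {
            "max": assign(["a"], p, "max"),
            "0.6": assign(["b"], p, "0.6"),
        }
        with pytest.raises(ValidationError):
            category_table(calls)
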