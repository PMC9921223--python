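import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connectomotif import (
    DegenerateInputError,
    DomainError,
    UsageError,
    bonferroni,
    connectionwise_group_test,
    mann_whitney_u,
    spearman,
)

from conftest import make_cohort


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman([1, 2, 3], [6, 5, 4])
        assert rho == pytest.approx(-1.0)

    def test_rank_difference_formula_example(self):
        # rho = 1 - 6 * sum d^2 / (n (n^2-1)) = 1 - 6*4/(5*24) = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        x = rng.standard_normal(6)
        y = rng.standard_normal(6)
        rho, p = spearman(x, y)
        # brute-force oracle: enumerate all orderings of y
        from scipy.stats import rankdata
        rx, ry = rankdata(x), rankdata(y)
        rxc = rx - rx.mean()
        obs = abs(np.dot(rxc, ry - ry.mean()))
        hits = total = 0
        for perm in itertools.permutations(range(6)):
            ryp = ry[list(perm)]
            if abs(np.dot(rxc, ryp - ryp.mean())) >= obs - 1e-12:
                hits += 1
            total += 1
        assert p == pytest.approx(hits / total)

    def test_large_n_uses_t_approximation(self, rng):
        from scipy.stats import spearmanr
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        rho, p = spearman(x, y)
        ref = spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_symmetry(self, rng):
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        assert spearman(x, y) == spearman(y, x)

    @given(st.integers(1, 4))
    @settings(max_examples=4, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(15)
        y = rng.standard_normal(15)
        rho1, p1 = spearman(x, y)
        rho2, p2 = spearman(np.exp(x), y**3 + 5 * y)
        assert rho1 == pytest.approx(rho2)
        assert p1 == pytest.approx(p2)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_rejected(self):
        with pytest.raises(UsageError):
            spearman([1, 2], [3, 4])

    def test_null_type_i_rate_within_binomial_ci(self):
        rng = np.random.default_rng(1234)
        n_sims, n = 2000, 20
        false_pos = 0
        for _ in range(n_sims):
            _, p = spearman(rng.standard_normal(n), rng.standard_normal(n))
            false_pos += p < 0.05
        from scipy.stats import binomtest
        ci = binomtest(false_pos, n_sims, 0.05).proportion_ci(0.95)
        assert ci.low <= 0.05 <= ci.high


class TestMannWhitney:
    def test_complete_separation(self):
        U, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert U == 0.0

    def test_identical_samples_give_half_product(self):
        U, _ = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert U == pytest.approx(4.5)

    def test_exact_p_matches_enumeration_oracle(self):
        x, y = np.array([1.0, 3.0]), np.array([2.0, 4.0])
        U, p = mann_whitney_u(x, y)
        # enumerate all C(4,2)=6 rank assignments for the first sample
        pooled = np.sort(np.concatenate([x, y]))
        obs_u = U
        us = []
        for combo in itertools.combinations(range(4), 2):
            r = np.array(combo) + 1
            us.append(r.sum() - 2 * 3 / 2)
        us = np.array(us)
        p_oracle = 2 * min((us <= obs_u).mean(), (us >= obs_u).mean())
        assert p == pytest.approx(min(1.0, p_oracle))

    def test_u_statistics_sum_to_product(self, rng):
        x = rng.standard_normal(8)
        y = rng.standard_normal(11)
        Ux, _ = mann_whitney_u(x, y)
        Uy, _ = mann_whitney_u(y, x)
        assert Ux + Uy == pytest.approx(8 * 11)

    def test_empty_sample_rejected(self):
        with pytest.raises(UsageError):
            mann_whitney_u([], [1.0])

    def test_tied_large_samples_use_tie_corrected_approximation(self, rng):
        from scipy.stats import mannwhitneyu
        x = rng.integers(0, 5, size=25).astype(float)
        y = rng.integers(0, 5, size=25).astype(float)
        U, p = mann_whitney_u(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert (U, p) == (ref.statistic, ref.pvalue)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expect", [(0.001, 28, 0.028), (0.01, 56, 0.56), (0.05, 28, 1.0)]
    )
    def test_examples(self, p, m, expect):
        assert bonferroni(p, m) == pytest.approx(expect)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            bonferroni(1.2, 3)
        with pytest.raises(DomainError):
            bonferroni(0.5, 0)

    @given(p=st.floats(0, 1), m=st.integers(1, 100000))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_and_capped(self, p, m):
        out = bonferroni(p, m)
        assert 0 <= out <= 1
        assert out >= bonferroni(p, max(1, m - 1)) or out == 1.0
        assert out >= p


class TestConnectionwise:
    def _cohort(self, rng, shift_pair=None, shift=0.0, n_subj=12, d=8):
        labels = [f"r{i}" for i in range(d)]
        vals = {}
        for i in range(n_subj):
            base = rng.uniform(10, 20, size=(d, d))
            for scan in ("a", "b"):
                v = base + rng.normal(0, 1.0, size=(d, d))
                v = np.clip(v, 0, None)
                if scan == "b" and shift_pair is not None:
                    r, c = shift_pair
                    v[r, c] += shift
                    v[c, r] += shift
                vals[(f"s{i:02d}", scan)] = v
        return make_cohort(vals, labels)

    def test_identical_scans_flag_nothing(self, rng):
        labels = [f"r{i}" for i in range(8)]
        vals = {}
        for i in range(10):
            v = rng.uniform(5, 30, size=(8, 8))
            vals[(f"s{i}", "a")] = v
            vals[(f"s{i}", "b")] = v.copy()
        cohort = make_cohort(vals, labels)
        table = connectionwise_group_test(cohort, "a", "b")
        assert int(table["significant"].sum()) == 0
        assert table.attrs["family_size"] == 28

    def test_planted_shift_detected_exactly(self, rng):
        # one connection shifted by ~10 pooled SDs in every subject's scan b
        cohort = self._cohort(rng, shift_pair=(0, 1), shift=15.0)
        table = connectionwise_group_test(cohort, "a", "b")
        sig = table[table["significant"]]
        assert len(sig) == 1
        assert {sig.iloc[0]["source"], sig.iloc[0]["target"]} == {"r0", "r1"}

    def test_null_familywise_error_controlled(self):
        # 100 null cohorts: corrected tests should flag a connection in at
        # most a binomially-plausible fraction of them
        from scipy.stats import binomtest
        flagged = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cohort = self._cohort(rng, n_subj=8, d=6)
            table = connectionwise_group_test(cohort, "a", "b")
            flagged += int(table["significant"].any())
        assert binomtest(flagged, 100, 0.05, alternative="greater").pvalue > 0.05

    def test_paired_variant_runs(self, rng):
        cohort = self._cohort(rng, shift_pair=(2, 3), shift=15.0)
        table = connectionwise_group_test(cohort, "a", "b", paired=True)
        sig = table[table["significant"]]
        assert len(sig) >= 1
        assert table.attrs["test"] == "wilcoxon_paired"

    def test_few_subjects_warns_but_computes(self, rng):
        cohort = self._cohort(rng, n_subj=2, d=5)
        with pytest.warns(UserWarning, match="power"):
            table = connectionwise_group_test(cohort, "a", "b")
        assert len(table) == 10
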