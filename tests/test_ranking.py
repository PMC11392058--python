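"""Log transform, ANOVA, Tukey HSD and the compact letter display."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nanosites import ranking


class TestLogTransform:
    def test_unit_values(self):
        out, excl = ranking.log_transform({"a": [1, 1, 1]})
        np.testing.assert_allclose(out["a"], [0, 0, 0])
        assert excl == []

    def test_closed_form(self):
        out, _ = ranking.log_transform({"a": [np.e, np.e**2]})
        np.testing.assert_allclose(out["a"], [1.0, 2.0])

    def test_zero_replicate_dropped_with_flag(self):
        out, excl = ranking.log_transform({"a": [1.0, 0.0, 2.0]})
        assert out["a"].size == 2
        assert excl[0].reason == "non-positive replicates dropped"

    def test_all_nonpositive_excluded(self):
        out, excl = ranking.log_transform({"a": [0.0, -1.0]})
        assert "a" not in out
        assert excl[0].reason == "no positive replicates"


class TestAnova:
    def test_identical_groups(self):
        f, p = ranking.one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert f == 0.0
        assert p == 1.0

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(5)
        groups = {f"g{i}": rng.normal(i, 1.0, size=4) for i in range(4)}
        f, p = ranking.one_way_anova(groups)
        ref = stats.f_oneway(*groups.values())
        assert f == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(8)
        groups = {
            "lo": rng.normal(0.0, 0.1, 3),
            "hi": rng.normal(10.0, 0.1, 3),
        }
        _, p = ranking.one_way_anova(groups)
        assert p < 1e-4

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        groups = {f"g{i}": rng.normal(i, 1.0, 3) for i in range(3)}
        f1, _ = ranking.one_way_anova(groups)
        f2, _ = ranking.one_way_anova(dict(reversed(groups.items())))
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n = 1"):
            ranking.one_way_anova({"a": [1.0], "b": [1, 2]})


class TestTukey:
    def test_identical_groups_all_p_near_one(self):
        p = ranking.tukey_hsd({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        off_diag = p.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.all(off_diag >= 0.999)

    def test_only_separated_group_significant(self):
        rng = np.random.default_rng(12)
        groups = {
            "a": rng.normal(0, 0.1, 3),
            "b": rng.normal(0, 0.1, 3),
            "c": rng.normal(10, 0.1, 3),
        }
        p = ranking.tukey_hsd(groups)
        assert p.loc["a", "b"] >= 0.05
        assert p.loc["a", "c"] < 0.05
        assert p.loc["b", "c"] < 0.05

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(13)
        groups = {f"g{i}": rng.normal(i, 1.0, 3) for i in range(4)}
        p = ranking.tukey_hsd(groups)
        np.testing.assert_allclose(p.to_numpy(), p.to_numpy().T)
        np.testing.assert_allclose(np.diag(p.to_numpy()), 1.0)

    def test_matches_statsmodels_oracle(self):
        """Independent route: statsmodels' pairwise Tukey HSD."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(14)
        groups = {f"g{i}": rng.normal(0.5 * i, 1.0, 5) for i in range(4)}
        ours = ranking.tukey_hsd(groups)
        values = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [len(v) for v in groups.values()])
        ref = pairwise_tukeyhsd(values, labels, alpha=0.05)
        for (g1, g2), pval in zip(
            itertools.combinations(groups, 2), ref.pvalues
        ):
            assert ours.loc[g1, g2] == pytest.approx(pval, abs=1e-6)


class TestCompactLetters:
    def make_p(self, ids, sig_pairs):
        p = pd.DataFrame(1.0, index=ids, columns=ids)
        for i, j in sig_pairs:
            p.loc[i, j] = p.loc[j, i] = 0.01
        return p

    def test_no_differences_single_letter(self):
        ids = list("abcd")
        letters, n = ranking.compact_letters(self.make_p(ids, []), {i: 0.0 for i in ids})
        assert n == 1
        assert len({letters[i] for i in ids}) == 1

    def test_all_different_one_letter_each(self):
        ids = list("abc")
        p = self.make_p(ids, itertools.combinations(ids, 2))
        letters, n = ranking.compact_letters(p, {"a": 3.0, "b": 2.0, "c": 1.0})
        assert n == 3
        assert letters == {"a": "a", "b": "b", "c": "c"}

    def test_three_tier_fixture(self):
        rng = np.random.default_rng(15)
        groups = {
            "hi": np.log(100.0) + rng.normal(0, 0.1, 3),
            "mid": np.log(10.0) + rng.normal(0, 0.1, 3),
            "lo": np.log(1.0) + rng.normal(0, 0.1, 3),
        }
        p = ranking.tukey_hsd(groups)
        means = {k: float(np.mean(v)) for k, v in groups.items()}
        letters, n = ranking.compact_letters(p, means)
        assert n == 3
        assert ranking.check_letters_consistent(letters, p)
        assert letters["hi"] == "a"  # letters ordered by descending mean

    def test_display_consistent_on_random_panels(self):
        """Brute-force oracle: letters must encode the pairwise matrix for
        arbitrary Tukey outcomes."""
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            k = int(rng.integers(3, 7))
            groups = {
                f"g{i}": rng.normal(rng.uniform(0, 3), 0.5, 3) for i in range(k)
            }
            p = ranking.tukey_hsd(groups)
            means = {g: float(np.mean(v)) for g, v in groups.items()}
            letters, _ = ranking.compact_letters(p, means)
            assert ranking.check_letters_consistent(letters, p), f"seed {seed}"


class TestRankSamples:
    def three_tier_groups(self, scale=1.0, seed=16):
        rng = np.random.default_rng(seed)
        return {
            "hi1": scale * 100.0 * np.exp(rng.normal(0, 0.2, 3)),
            "hi2": scale * 100.0 * np.exp(rng.normal(0, 0.2, 3)),
            "mid": scale * 10.0 * np.exp(rng.normal(0, 0.2, 3)),
            "lo": scale * 1.0 * np.exp(rng.normal(0, 0.2, 3)),
        }

    def test_three_categories(self):
        res = ranking.rank_samples(self.three_tier_groups())
        assert res.n_categories == 3
        assert res.letters["hi1"] == res.letters["hi2"] == "a"

    def test_scale_invariance_of_letters(self):
        r1 = ranking.rank_samples(self.three_tier_groups(scale=1.0))
        r2 = ranking.rank_samples(self.three_tier_groups(scale=137.0))
        assert r1.letters == r2.letters
        assert r1.f_statistic == pytest.approx(r2.f_statistic, rel=1e-9)

    def test_exclusions_recorded(self):
        groups = self.three_tier_groups()
        groups["bad"] = np.array([0.0, -1.0, 0.0])
        res = ranking.rank_samples(groups, exclude=["hi2"])
        assert "hi2" not in res.letters
        assert "bad" not in res.letters
        reasons = {e.sample_id: e.reason for e in res.excluded}
        assert reasons["hi2"] == "excluded by caller"
        assert reasons["bad"] == "no positive replicates"
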