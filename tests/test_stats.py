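"""Repeated-measures ANOVA and the accuracy mixed model."""

import numpy as np
import pandas as pd
import pytest

from activegaze.errors import InvalidInputError, MissingDesignError
from activegaze.simulate import generate_design
from activegaze.stats import (
    fit_accuracy_model,
    learning_blocks,
    rm_anova,
    rm_anova_nway,
)


def _long(values: np.ndarray, factor_name="f") -> pd.DataFrame:
    """(m subjects x k levels) cell-mean matrix to long format."""
    m, k = values.shape
    rows = []
    for i in range(m):
        for j in range(k):
            rows.append({"subject_id": f"S{i}", factor_name: f"L{j}", "dv": values[i, j]})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_hand_built_table_matches_manual_ss_oracle(self):
        """3 subjects x 2 levels: F from an independent sums-of-squares
        decomposition computed by hand."""
        y = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 5.0]])
        res = rm_anova(_long(y), "dv", "f")
        grand = y.mean()
        ss_f = 3 * np.sum((y.mean(axis=0) - grand) ** 2)
        resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0) + grand
        ss_e = np.sum(resid**2)
        f_expected = (ss_f / 1) / (ss_e / 2)
        assert res.statistic == pytest.approx(f_expected, abs=1e-9)
        assert (res.df_num, res.df_den) == (1, 2)

    def test_matches_pingouin_on_random_data(self, rng):
        pingouin = pytest.importorskip("pingouin")
        y = rng.normal(size=(10, 4))
        df = _long(y)
        res = rm_anova(df, "dv", "f")
        pg = pingouin.rm_anova(data=df, dv="dv", within="f", subject="subject_id")
        assert res.statistic == pytest.approx(float(pg["F"].iloc[0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(pg["p_unc"].iloc[0]), abs=1e-12)

    def test_df_contract_three_levels_47_subjects(self):
        rng = np.random.default_rng(8)
        res = rm_anova(_long(rng.normal(size=(47, 3))), "dv", "f")
        assert (res.df_num, res.df_den) == (2, 92)

    def test_invariant_to_subject_relabeling_and_level_permutation(self, rng):
        y = rng.normal(size=(8, 3))
        base = rm_anova(_long(y), "dv", "f").statistic
        perm = rm_anova(_long(y[:, [2, 0, 1]][::-1]), "dv", "f").statistic
        assert perm == pytest.approx(base, rel=1e-12)

    def test_location_invariance(self, rng):
        y = rng.normal(size=(6, 3))
        a = rm_anova(_long(y), "dv", "f").statistic
        b = rm_anova(_long(y + 17.3), "dv", "f").statistic
        assert a == pytest.approx(b, rel=1e-9)

    def test_aggregates_trials_to_cell_means_first(self, rng):
        """Duplicated trials per cell must not inflate the F statistic."""
        y = rng.normal(size=(5, 3))
        df1 = _long(y)
        df2 = pd.concat([df1, df1], ignore_index=True)
        assert rm_anova(df2, "dv", "f").statistic == pytest.approx(
            rm_anova(df1, "dv", "f").statistic, rel=1e-12
        )

    def test_missing_cell_raises(self):
        df = _long(np.ones((3, 2)) + np.arange(6).reshape(3, 2))
        df = df[~((df.subject_id == "S0") & (df.f == "L1"))]
        with pytest.raises(MissingDesignError):
            rm_anova(df, "dv", "f")

    def test_type_one_error_calibrated(self):
        """Null simulations reject at about the nominal 5% rate."""
        rejections = 0
        n_sim = 200
        for s in range(n_sim):
            r = np.random.default_rng(3000 + s)
            res = rm_anova(_long(r.normal(size=(12, 3))), "dv", "f")
            rejections += int(res.significant)
        # binomial 99% CI around 0.05 with n=200
        assert 2 <= rejections <= 20


class TestRmAnovaNway:
    def test_two_way_main_effects_match_one_way_dfs(self, rng):
        m = 12
        rows = []
        for i in range(m):
            for a in range(3):
                for b in range(2):
                    rows.append(
                        {"subject_id": f"S{i}", "A": f"a{a}", "B": f"b{b}",
                         "dv": rng.normal()}
                    )
        df = pd.DataFrame(rows)
        results = {r.effect: r for r in rm_anova_nway(df, "dv", ["A", "B"])}
        assert (results["A"].df_num, results["A"].df_den) == (2, 22)
        assert (results["B"].df_num, results["B"].df_den) == (1, 11)
        assert "A x B" in results

    def test_incomplete_grid_raises(self, rng):
        rows = [
            {"subject_id": f"S{i}", "A": f"a{a}", "B": f"b{b}", "dv": rng.normal()}
            for i in range(4)
            for a in range(2)
            for b in range(2)
            if not (i == 0 and a == 1 and b == 1)
        ]
        with pytest.raises(MissingDesignError):
            rm_anova_nway(pd.DataFrame(rows), "dv", ["A", "B"])


class TestLearningBlocks:
    def test_block_boundaries(self):
        assert learning_blocks([1])[0] == 1
        assert learning_blocks([3])[0] == 1
        assert learning_blocks([4])[0] == 2
        assert learning_blocks([18])[0] == 6

    def test_block_factor_yields_printed_dfs(self):
        """Blocking 18 trials into 6 blocks over 47 subjects gives the
        (5, 230) denominator reported for every learning effect."""
        design = generate_design(47, 18, seed=4)
        rng = np.random.default_rng(4)
        design["dv"] = rng.normal(size=len(design))
        design["block"] = learning_blocks(design["trial_index"].to_numpy())
        res = rm_anova(design, "dv", "block")
        assert (res.df_num, res.df_den) == (5, 230)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            learning_blocks([0])
        with pytest.raises(InvalidInputError):
            learning_blocks([19])


class TestAccuracyModel:
    def test_constant_response_flags_separation(self):
        design = generate_design(6, 18, seed=5)
        design["correct"] = True
        with pytest.warns(UserWarning, match="separation"):
            results = fit_accuracy_model(design)
        assert all(r.warning for r in results)

    def test_injected_sameness_effect_recovers_positive_sign(self):
        """Odds ratio 3 on sameness: the fitted coefficient is positive."""
        hits = 0
        for s in range(10):
            design = generate_design(47, 18, seed=600 + s)
            r = np.random.default_rng(700 + s)
            eta = np.log(9.0) + np.log(3.0) * design["same"].to_numpy()
            p = 1 / (1 + np.exp(-eta))
            design["correct"] = r.uniform(size=len(design)) < p
            results = fit_accuracy_model(design, factors=["same"])
            coef = results[0].meta["coef"]["same[True]"]
            hits += int(coef > 0)
        assert hits >= 9

    def test_subject_variance_recovered(self):
        """A strong subject random intercept is estimated as clearly
        non-zero."""
        design = generate_design(47, 18, seed=42)
        r = np.random.default_rng(43)
        subj_eff = {s: r.normal(0, 1.0) for s in design["subject_id"].unique()}
        eta = 2.0 + design["subject_id"].map(subj_eff).to_numpy()
        design["correct"] = r.uniform(size=len(design)) < 1 / (1 + np.exp(-eta))
        results = fit_accuracy_model(design, factors=["same"])
        assert results[0].meta["sigma_subject"] > 0.4
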