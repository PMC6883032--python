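"""ANOVA, Tukey HSD letters, partial correlation, and the CAR~RSLR model."""

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tidalcarbon.errors import ValidationError
from tidalcarbon.stats import (
    fit_car_rslr,
    oneway_anova,
    partial_r,
    pearson_r,
    tukey_hsd,
)


def anova_oracle(groups):
    """Brute-force between/within sum-of-squares decomposition."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    pooled = np.concatenate(arrays)
    grand = pooled.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1 = len(arrays) - 1
    df2 = pooled.size - len(arrays)
    return (ss_between / df1) / (ss_within / df2)


class TestOnewayAnova:
    def test_identical_groups_give_zero_f(self):
        res = oneway_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_matches_sum_of_squares_oracle(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 5))
            groups = {f"g{i}": rng.normal(rng.uniform(-2, 2), 1.0, int(rng.integers(3, 12))) for i in range(k)}
            res = oneway_anova(groups)
            assert res.F == pytest.approx(anova_oracle(groups), rel=1e-10)

    def test_location_shift_invariance(self, rng):
        groups = {"a": rng.normal(0, 1, 8), "b": rng.normal(1, 1, 8)}
        shifted = {k: v + 123.4 for k, v in groups.items()}
        assert oneway_anova(groups).F == pytest.approx(oneway_anova(shifted).F, rel=1e-10)

    def test_all_identical_values_degenerate(self):
        with pytest.raises(ValidationError):
            oneway_anova({"a": [5.0, 5.0], "b": [5.0, 5.0, 5.0]})

    def test_anova_p_matches_permutation_oracle(self, rng):
        """F-test p agrees with a label-permutation null on normal data."""
        groups = {
            "a": rng.normal(0.0, 1.0, 12),
            "b": rng.normal(0.8, 1.0, 12),
            "c": rng.normal(0.3, 1.0, 12),
        }
        res = oneway_anova(groups)
        pooled = np.concatenate(list(groups.values()))
        sizes = [len(v) for v in groups.values()]
        count = 0
        n_perm = 20_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            f_perm = anova_oracle({f"g{i}": p for i, p in enumerate(parts)})
            count += f_perm >= res.F
        p_perm = (count + 1) / (n_perm + 1)
        assert res.p == pytest.approx(p_perm, abs=0.02)


def tukey_r_oracle(groups):
    """Adjusted pairwise p-values from R's aov + TukeyHSD (base stats)."""
    with tempfile.TemporaryDirectory() as td:
        data = pd.DataFrame(
            [(g, v) for g, vals in groups.items() for v in vals], columns=["group", "value"]
        )
        csv = Path(td) / "groups.csv"
        out = Path(td) / "tukey.csv"
        data.to_csv(csv, index=False)
        script = (
            f"d <- read.csv('{csv}'); d$group <- factor(d$group);"
            f"t <- TukeyHSD(aov(value ~ group, data=d))$group;"
            f"write.csv(data.frame(pair=rownames(t), p=t[,'p adj']), '{out}', row.names=FALSE)"
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        res = pd.read_csv(out)
    return {frozenset(pair.split("-")): p for pair, p in zip(res["pair"], res["p"])}


class TestTukeyHsd:
    def test_identical_groups_share_one_letter(self):
        pairs, letters = tukey_hsd({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [1.0, 2, 3, 4]})
        assert not pairs["significant"].any()
        assert len(set(letters.values())) == 1

    def test_separated_groups_get_distinct_letters(self, rng):
        pairs, letters = tukey_hsd(
            {"lo": rng.normal(0, 1, 10), "hi": rng.normal(100, 1, 10)}
        )
        assert pairs["significant"].all()
        assert set(letters["lo"]).isdisjoint(set(letters["hi"]))

    def test_letters_encode_significance_exactly(self, rng):
        groups = {
            "a": rng.normal(0, 1, 9),
            "b": rng.normal(1.2, 1, 14),
            "c": rng.normal(3.5, 1, 7),
            "d": rng.normal(3.6, 1, 11),
        }
        pairs, letters = tukey_hsd(groups)
        for row in pairs.itertuples():
            shared = set(letters[row.group_a]) & set(letters[row.group_b])
            assert bool(shared) == (not row.significant)

    def test_pairwise_p_matches_r_tukeyhsd(self, rng):
        """Adjusted p-values agree with R's aov/TukeyHSD on unbalanced groups."""
        groups = {
            "a": rng.normal(0.0, 1.0, 8),
            "b": rng.normal(1.0, 1.0, 13),
            "c": rng.normal(0.5, 1.0, 10),
        }
        oracle = tukey_r_oracle(groups)
        pairs, _ = tukey_hsd(groups)
        for row in pairs.itertuples():
            assert row.p_adj == pytest.approx(oracle[frozenset({row.group_a, row.group_b})], abs=1e-6)


class TestCorrelations:
    def test_perfect_linear_relation(self, rng):
        x = rng.normal(0, 1, 30)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_partial_reduces_to_pearson_for_orthogonal_control(self, rng):
        x = rng.normal(0, 1, 40)
        y = 0.5 * x + rng.normal(0, 1, 40)
        z = rng.normal(0, 1, 40)
        # project out x and y so the control is exactly uncorrelated with both
        basis = np.column_stack([np.ones(40), x, y])
        z_orth = z - basis @ np.linalg.lstsq(basis, z, rcond=None)[0]
        r_partial, _ = partial_r(x, y, z_orth)
        r_plain, _ = pearson_r(x, y)
        assert r_partial == pytest.approx(r_plain, abs=1e-12)

    def test_partial_matches_residual_regression_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, 50)
            z = rng.normal(0, 1, 50)
            y = 0.4 * x + 0.7 * z + rng.normal(0, 1, 50)
            r, _ = partial_r(x, y, z)
            # oracle: correlate OLS residuals of x|z and y|z
            zc = np.column_stack([np.ones(50), z])
            rx = x - zc @ np.linalg.lstsq(zc, x, rcond=None)[0]
            ry = y - zc @ np.linalg.lstsq(zc, y, rcond=None)[0]
            expected = float(np.corrcoef(rx, ry)[0, 1])
            assert r == pytest.approx(expected, abs=1e-10)

    @given(st.integers(0, 2**31 - 1))
    def test_partial_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        x, y, z = rng.normal(0, 1, (3, 20))
        r_xy, _ = partial_r(x, y, z)
        r_yx, _ = partial_r(y, x, z)
        assert r_xy == pytest.approx(r_yx, abs=1e-12)
        assert -1.0 <= r_xy <= 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def make_model_frame(car, rslr, sources):
    return pd.DataFrame({"car_gC_m2_yr": car, "rslr_mm_yr": rslr, "source_id": sources})


class TestFitCarRslr:
    def test_exact_proportional_relation(self):
        rslr = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        df = make_model_frame(30.0 * rslr, rslr, ["s1", "s1", "s2", "s2", "s3", "s3"])
        for mode in ("ols", "cluster_robust"):
            model = fit_car_rslr(df, fit_mode=mode)
            assert model.slope == pytest.approx(30.0, abs=1e-9)
            assert model.intercept == pytest.approx(0.0, abs=1e-8)

    def test_random_intercept_recovers_slope(self, rng):
        sources = np.repeat([f"s{i}" for i in range(20)], 8)
        rslr = rng.uniform(1, 9, sources.size)
        intercepts = dict(zip([f"s{i}" for i in range(20)], rng.normal(0, 30, 20)))
        car = 100 + 25 * rslr + np.array([intercepts[s] for s in sources]) + rng.normal(0, 20, sources.size)
        model = fit_car_rslr(make_model_frame(car, rslr, sources), fit_mode="random_intercept")
        assert model.fit_mode == "random_intercept"
        assert model.slope == pytest.approx(25.0, abs=3 * model.slope_se)

    def test_ols_slope_is_cov_over_var(self, rng):
        rslr = rng.uniform(0, 10, 60)
        car = 50 + 18 * rslr + rng.normal(0, 40, 60)
        model = fit_car_rslr(make_model_frame(car, rslr, ["s"] * 60), fit_mode="ols")
        expected = np.cov(car, rslr, ddof=1)[0, 1] / np.var(rslr, ddof=1)
        assert model.slope == pytest.approx(expected, rel=1e-12)

    def test_duplication_leaves_ols_slope_unchanged(self, rng):
        rslr = rng.uniform(0, 10, 25)
        car = 30 + 20 * rslr + rng.normal(0, 10, 25)
        df = make_model_frame(car, rslr, ["s"] * 25)
        doubled = pd.concat([df, df], ignore_index=True)
        assert fit_car_rslr(df, "ols").slope == pytest.approx(fit_car_rslr(doubled, "ols").slope, rel=1e-12)

    def test_constant_rslr_unidentifiable(self):
        df = make_model_frame([1.0, 2.0, 3.0], [5.0, 5.0, 5.0], ["a", "b", "c"])
        with pytest.raises(ValidationError):
            fit_car_rslr(df, "ols")

    def test_cluster_robust_se_exceeds_ols_under_clustering(self, rng):
        """Strong within-source correlation inflates clustered SEs."""
        sources = np.repeat([f"s{i}" for i in range(15)], 10)
        rslr_by_source = dict(zip([f"s{i}" for i in range(15)], rng.uniform(1, 9, 15)))
        rslr = np.array([rslr_by_source[s] for s in sources]) + rng.normal(0, 0.05, sources.size)
        source_noise = dict(zip([f"s{i}" for i in range(15)], rng.normal(0, 60, 15)))
        car = 100 + 20 * rslr + np.array([source_noise[s] for s in sources]) + rng.normal(0, 5, sources.size)
        df = make_model_frame(car, rslr, sources)
        se_ols = fit_car_rslr(df, "ols").slope_se
        se_cluster = fit_car_rslr(df, "cluster_robust").slope_se
        assert se_cluster > se_ols
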