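"""Factor analysis, MTSI distances, selection gains, factor contributions."""

import numpy as np
import pandas as pd
import pytest

from vernstab.mtsi import factor_analysis, factor_contributions, mtsi, selection_gain


def _trait_matrix(rng, n=12, p=6, blocks=None):
    if blocks is None:
        return pd.DataFrame(
            rng.normal(size=(n, p)),
            index=[f"g{i}" for i in range(n)],
            columns=[f"t{j}" for j in range(p)],
        )
    cols = {}
    for b, size in enumerate(blocks):
        base = rng.normal(size=n)
        for j in range(size):
            cols[f"b{b}t{j}"] = base + rng.normal(scale=1e-6, size=n)
    return pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])


class TestFactorAnalysis:
    def test_communality_plus_uniqueness_is_one(self, rng):
        model = factor_analysis(_trait_matrix(rng))
        total = model.communality + model.uniqueness
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_rotation_preserves_communality(self, rng):
        """Varimax rotates loadings but leaves each trait's communality."""
        X = _trait_matrix(rng)
        model = factor_analysis(X)
        R = np.corrcoef(X.to_numpy(), rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(R)
        order = np.argsort(eigvals)[::-1]
        f = model.loadings.shape[1]
        L0 = eigvecs[:, order[:f]] * np.sqrt(eigvals[order[:f]])
        assert np.allclose(
            (model.loadings**2).sum(axis=1), (L0**2).sum(axis=1), atol=1e-8
        )

    def test_two_correlated_blocks_give_two_factors(self, rng):
        X = _trait_matrix(rng, blocks=(3, 3))
        model = factor_analysis(X)
        assert model.loadings.shape[1] == 2
        assert model.cumulative_pct[-1] > 99.0

    def test_uncorrelated_traits_have_unit_eigenvalues(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(4000, 6)), columns=list("abcdef"))
        model = factor_analysis(X)
        assert np.abs(model.eigenvalues - 1.0).max() < 0.15

    def test_constant_column_rejected(self, rng):
        X = _trait_matrix(rng)
        X["t0"] = 5.0
        with pytest.raises(ValueError, match="constant"):
            factor_analysis(X)

    def test_too_few_traits(self, rng):
        with pytest.raises(ValueError, match="3 traits"):
            factor_analysis(_trait_matrix(rng, p=2))


class TestMtsi:
    def test_genotype_at_ideal_has_zero_index(self, rng):
        X = _trait_matrix(rng)
        X.iloc[0] = X.max(axis=0) + 0.0  # dominate every trait
        X.iloc[0] += 0.5
        model = factor_analysis(X)
        goals = {t: "increase" for t in X.columns}
        result = mtsi(model, goals)
        assert result.mtsi.iloc[0] == pytest.approx(0.0, abs=1e-8)
        assert result.ranking[0] == X.index[0]

    def test_single_factor_reduces_to_absolute_gap(self, rng):
        X = _trait_matrix(rng, blocks=(3,))
        model = factor_analysis(X)
        assert model.scores.shape[1] == 1
        goals = {t: "increase" for t in X.columns}
        result = mtsi(model, goals)
        gaps = (model.scores.iloc[:, 0] - result.ideal_scores.iloc[0]).abs()
        assert np.allclose(result.mtsi, gaps, atol=1e-10)

    def test_matches_bruteforce_distance(self, rng):
        X = _trait_matrix(rng, n=5, p=3)
        model = factor_analysis(X)
        goals = dict.fromkeys(X.columns, "increase")
        result = mtsi(model, goals)
        for g in X.index:
            d = np.sqrt(
                ((model.scores.loc[g] - result.ideal_scores) ** 2).sum()
            )
            assert result.mtsi[g] == pytest.approx(d, abs=1e-10)

    def test_order_invariance(self, rng):
        X = _trait_matrix(rng)
        goals = dict.fromkeys(X.columns, "increase")
        base = mtsi(factor_analysis(X), goals).mtsi
        perm = X.iloc[::-1, ::-1]
        other = mtsi(factor_analysis(perm), goals).mtsi
        assert np.allclose(other.reindex(base.index), base, atol=1e-8)

    def test_selection_size(self, rng):
        X = _trait_matrix(rng)
        result = mtsi(factor_analysis(X), dict.fromkeys(X.columns, "increase"), pressure=0.25)
        assert len(result.selected) == 3


class TestSelectionGain:
    @staticmethod
    def _result(rng, pressure=0.25):
        X = _trait_matrix(rng)
        model = factor_analysis(X)
        return X, mtsi(model, dict.fromkeys(X.columns, "increase"), pressure=pressure)

    def test_zero_differential_when_selection_equals_grand_mean(self, rng):
        X, result = self._result(rng)
        flat = X.copy()
        flat[:] = 1.0 + np.arange(len(X.columns))  # same mean everywhere
        gains = selection_gain(result, flat, dict.fromkeys(X.columns, 0.5),
                               dict.fromkeys(X.columns, "increase"))
        assert np.allclose(gains["SD_pct"], 0.0, atol=1e-10)

    def test_sd_equals_direct_mean_arithmetic(self, rng):
        X, result = self._result(rng)
        means = X.abs() + 1.0
        gains = selection_gain(result, means, dict.fromkeys(X.columns, 0.8),
                               dict.fromkeys(X.columns, "increase"))
        for t in X.columns:
            sd = 100 * (means.loc[result.selected, t].mean() - means[t].mean()) / means[t].mean()
            assert gains.loc[t, "SD_pct"] == pytest.approx(sd, abs=1e-10)

    def test_sg_is_sd_times_h2_exactly(self, rng):
        X, result = self._result(rng)
        h2 = {t: 0.3 + 0.1 * i for i, t in enumerate(X.columns)}
        gains = selection_gain(result, X.abs() + 1.0, h2, dict.fromkeys(X.columns, "increase"))
        assert np.allclose(gains["SG_pct"], gains["SD_pct"] * gains["h2"], atol=1e-12)


class TestFactorContributions:
    def test_shares_sum_to_one(self, rng):
        X = _trait_matrix(rng)
        model = factor_analysis(X)
        result = mtsi(model, dict.fromkeys(X.columns, "increase"))
        contrib = factor_contributions(result, model)
        sums = contrib.drop(columns="degenerate").sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-10)

    def test_equal_gaps_split_evenly(self, rng):
        X = _trait_matrix(rng)
        model = factor_analysis(X)
        result = mtsi(model, dict.fromkeys(X.columns, "increase"))
        f = model.scores.shape[1]
        model.scores.iloc[0] = result.ideal_scores + 1.0  # equal gap on every factor
        contrib = factor_contributions(result, model)
        assert np.allclose(contrib.drop(columns="degenerate").iloc[0], 1.0 / f, atol=1e-10)

    def test_degenerate_genotype_uniform_with_flag(self, rng):
        X = _trait_matrix(rng)
        model = factor_analysis(X)
        result = mtsi(model, dict.fromkeys(X.columns, "increase"))
        model.scores.iloc[0] = result.ideal_scores.to_numpy()
        contrib = factor_contributions(result, model)
        f = model.scores.shape[1]
        assert contrib["degenerate"].iloc[0]
        assert np.allclose(contrib.drop(columns="degenerate").iloc[0], 1.0 / f)
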