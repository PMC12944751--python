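"""AMMI decomposition, Gollob tests, WAASB / WAASBY and biplot quadrants."""

import numpy as np
import pandas as pd
import pytest

from vernstab.ammi import (
    ammi_decompose,
    double_center,
    quadrant_classify,
    waasb,
    waasby,
)
from vernstab.lmm import fit_met_lmm, ge_blup_matrix
from vernstab.synthetic import SyntheticConfig, gen_met_trials


def _cell_means(seed=11, **kw):
    df, _ = gen_met_trials(SyntheticConfig(seed=seed, **kw))
    return df.groupby(["genotype", "environment"], observed=True)["value"].mean().unstack()


@pytest.fixture(scope="module")
def decomposition():
    return ammi_decompose(_cell_means(), ms_error=3.0, replicates=4, df_error=198)


class TestAmmiDecompose:
    def test_gollob_dfs_12x6(self, decomposition):
        assert list(decomposition.table["df"]) == [15, 13, 11, 9, 7]

    def test_explained_sums_to_100(self, decomposition):
        assert decomposition.explained.sum() == pytest.approx(100.0, abs=1e-6)
        assert decomposition.table["cumulative_pct"].iloc[-1] == pytest.approx(100.0, abs=1e-6)

    def test_double_centering(self, decomposition):
        inter = decomposition.interaction.to_numpy()
        assert np.abs(inter.mean(axis=0)).max() < 1e-10
        assert np.abs(inter.mean(axis=1)).max() < 1e-10

    def test_rank_one_interaction_gives_ep1_100(self):
        cfg = SyntheticConfig(seed=2, gei_rank=1, sigma2_res=0.0, sigma2_block=0.0)
        cell = _cell_means(seed=2, gei_rank=1, sigma2_res=0.0, sigma2_block=0.0)
        dec = ammi_decompose(cell, ms_error=1.0, replicates=cfg.n_blocks)
        assert dec.explained[0] == pytest.approx(100.0, abs=1e-8)

    def test_component_ss_match_truncation_oracle(self, rng):
        """Each component SS equals the drop in reconstruction SS it causes."""
        m = pd.DataFrame(rng.normal(size=(4, 3)))
        dec = ammi_decompose(m, ms_error=1.0, replicates=1)
        inter = dec.interaction.to_numpy()
        u, s, vt = np.linalg.svd(inter)
        for k in range(len(dec.singular_values)):
            approx_k = (u[:, :k] * s[:k]) @ vt[:k]
            approx_k1 = (u[:, : k + 1] * s[: k + 1]) @ vt[: k + 1]
            drop = np.sum((inter - approx_k) ** 2) - np.sum((inter - approx_k1) ** 2)
            assert dec.table["ss"].iloc[k] == pytest.approx(drop, abs=1e-8)

    def test_ss_sum_equals_interaction_ss(self, decomposition):
        total = 4 * np.sum(decomposition.interaction.to_numpy() ** 2)
        assert decomposition.table["ss"].sum() == pytest.approx(total, rel=1e-8)

    def test_missing_cells_rejected(self):
        cell = _cell_means()
        cell.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            ammi_decompose(cell, 1.0, 4)


class TestWaasb:
    def test_single_component_reduces_to_abs_score(self):
        scores = pd.DataFrame({"IPC1": [3.0, -2.0, 0.5]}, index=list("abc"))
        out = waasb(scores, np.array([100.0]))
        assert list(out) == [3.0, 2.0, 0.5]

    def test_hand_arithmetic_two_components(self):
        scores = pd.DataFrame({"IPC1": [3.0], "IPC2": [-1.0]}, index=["g"])
        assert waasb(scores, np.array([50.0, 50.0]))["g"] == pytest.approx(2.0)

    def test_matches_naive_loop(self, decomposition):
        scores, ep = decomposition.genotype_scores, decomposition.explained
        out = waasb(scores, ep)
        for gen in scores.index:
            naive = sum(abs(scores.loc[gen, f"IPC{k+1}"]) * ep[k] for k in range(len(ep)))
            assert out[gen] == pytest.approx(naive / ep.sum(), abs=1e-10)

    def test_sign_flip_invariance(self, decomposition):
        scores, ep = decomposition.genotype_scores.copy(), decomposition.explained
        flipped = scores.copy()
        flipped["IPC2"] *= -1
        pd.testing.assert_series_equal(waasb(scores, ep), waasb(flipped, ep))

    def test_zero_weights_rejected(self):
        scores = pd.DataFrame({"IPC1": [1.0]})
        with pytest.raises(ValueError):
            waasb(scores, np.array([0.0]))

    def test_blup_waasb_approaches_fixed_waas_without_noise(self):
        """With vanishing residual noise shrinkage disappears."""
        cfg = SyntheticConfig(seed=4, sigma2_res=1e-6, sigma2_block=0.0)
        df, _ = gen_met_trials(cfg)
        cell = df.groupby(["genotype", "environment"], observed=True)["value"].mean().unstack()
        _, blups = fit_met_lmm(df, "value")
        dec_fixed = ammi_decompose(cell, 1.0, 4)
        dec_blup = ammi_decompose(ge_blup_matrix(blups), 1.0, 4)
        w_fixed = waasb(dec_fixed.genotype_scores, dec_fixed.explained)
        w_blup = waasb(dec_blup.genotype_scores, dec_blup.explained).reindex(w_fixed.index)
        rel = np.abs(w_blup - w_fixed) / np.abs(w_fixed)
        assert rel.max() < 0.01


class TestWaasby:
    def test_double_maximum_scores_100(self):
        yld = pd.Series({"a": 10.0, "b": 8.0, "c": 6.0})
        w = pd.Series({"a": 0.1, "b": 0.5, "c": 0.9})
        out = waasby(yld, w)
        assert out.loc["a", "WAASBY"] == pytest.approx(100.0)

    def test_stability_weight_zero_collapses_to_yield_ranking(self, rng):
        yld = pd.Series(rng.uniform(5, 15, 8), index=[f"g{i}" for i in range(8)])
        w = pd.Series(rng.uniform(0, 1, 8), index=yld.index)
        out = waasby(yld, w, theta_y=50.0, theta_s=0.0)
        assert list(out.index) == list(yld.sort_values(ascending=False).index)

    def test_hand_computed_rescaling(self):
        yld = pd.Series({"a": 10.0, "b": 20.0, "c": 15.0, "d": 12.0})
        w = pd.Series({"a": 2.0, "b": 1.0, "c": 4.0, "d": 3.0})
        out = waasby(yld, w)
        # rG(c) = 100*(15-10)/10 = 50; rW(c) = 100*(4-4)/3 = 0
        assert out.loc["c", "rG"] == pytest.approx(50.0)
        assert out.loc["c", "rW"] == pytest.approx(0.0)
        assert out.loc["c", "WAASBY"] == pytest.approx(25.0)

    def test_degenerate_range_flagged(self):
        yld = pd.Series({"a": 10.0, "b": 10.0})
        w = pd.Series({"a": 1.0, "b": 2.0})
        out = waasby(yld, w)
        assert (out["rG"] == 100.0).all()


class TestQuadrants:
    def test_high_yield_low_waasb_is_iv(self):
        yld = pd.Series({"a": 11.0, "b": 9.0})
        w = pd.Series({"a": 0.5, "b": 1.5})
        out = quadrant_classify(yld, w)
        assert out["a"] == "IV" and out["b"] == "I"

    def test_boundary_point_goes_to_favourable_side(self):
        yld = pd.Series({"a": 10.0, "b": 10.0})
        w = pd.Series({"a": 1.0, "b": 1.0})
        out = quadrant_classify(yld, w)
        assert (out == "IV").all()

    def test_partition_counts(self, rng):
        yld = pd.Series(rng.normal(10, 2, 12))
        w = pd.Series(rng.uniform(0, 2, 12))
        out = quadrant_classify(yld, w)
        assert out.isin(["I", "II", "III", "IV"]).all() and len(out) == 12
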