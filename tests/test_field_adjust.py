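import numpy as np
import pandas as pd
import pytest

from phenogs.field_adjust import (
    RankDeficiencyError,
    estimate_variance_components,
    fit_adjusted_means,
)
from phenogs.io_formats import TrialTable, ValidationError

from conftest import augmented_trial, balanced_trial


def four_plot_trial():
    """Two blocks, one shared check, one entry in each block."""
    return TrialTable(pd.DataFrame({
        "entry_id": ["C@1", "C@2", "X", "Y"],
        "environment_id": ["E1"] * 4,
        "block_id": ["B1", "B2", "B1", "B2"],
        "is_check": [True, True, False, False],
        "check_id": ["C", "C", "", ""],
        "value": [5.0, 7.0, 10.0, 10.0],
    }))


class TestBlue:
    def test_single_block_blue_is_raw_value(self):
        t = TrialTable(pd.DataFrame({
            "entry_id": ["C@1", "X", "Y"], "environment_id": ["E1"] * 3,
            "block_id": ["B1"] * 3, "is_check": [True, False, False],
            "check_id": ["C", "", ""], "value": [5.0, 8.0, 9.5],
        }))
        m = fit_adjusted_means(t, "BLUE_single_env")
        assert m.values["X"] == pytest.approx(8.0)
        assert m.values["Y"] == pytest.approx(9.5)

    def test_two_block_check_adjustment(self):
        # check 5 in B1, 7 in B2 -> B2 sits 2 higher; X and Y both read 10,
        # so the adjusted difference X - Y must be exactly 2
        m = fit_adjusted_means(four_plot_trial(), "BLUE_single_env")
        assert m.values["X"] - m.values["Y"] == pytest.approx(2.0, abs=1e-10)

    def test_matches_ols_oracle_on_balanced_instance(self):
        # fully replicated single-env layout: the BLUE must equal the OLS
        # solution of the explicit genotype + block model (normal equations)
        rng = np.random.default_rng(11)
        genos, blocks = [f"G{i}" for i in range(5)], ["B1", "B2", "B3"]
        rows = [(g, "E1", b, False, "", 3 + i * 0.5 + j * 0.2 + rng.normal(0, 0.3))
                for i, g in enumerate(genos) for j, b in enumerate(blocks)]
        # one check so augmented validation passes
        rows += [("C@" + b, "E1", b, True, "C", 4 + j * 0.2 + rng.normal(0, 0.3))
                 for j, b in enumerate(blocks)]
        t = TrialTable(pd.DataFrame(rows, columns=[
            "entry_id", "environment_id", "block_id", "is_check", "check_id", "value"]))
        m = fit_adjusted_means(t, "BLUE_single_env")
        # oracle: solve y = geno one-hot + sum-to-zero blocks by normal equations
        df = t.data
        labels = np.where(df.is_check, "chk", df.entry_id)
        levels = list(dict.fromkeys(labels))
        G = (labels[:, None] == np.array(levels)[None, :]).astype(float)
        Bc = np.zeros((len(df), 2))
        for j, b in enumerate(blocks[:-1]):
            Bc[(df.block_id == b).to_numpy(), j] = 1
            Bc[(df.block_id == blocks[-1]).to_numpy(), j] = -1
        A = np.hstack([G, Bc])
        coef = np.linalg.solve(A.T @ A, A.T @ df.value.to_numpy())
        oracle = dict(zip(levels, coef[: len(levels)]))
        for g in genos:
            assert m.values[g] == pytest.approx(oracle[g], abs=1e-8)

    def test_block_constant_shift_leaves_contrasts_invariant(self):
        t = four_plot_trial()
        m0 = fit_adjusted_means(t, "BLUE_single_env")
        shifted = t.data.copy()
        shifted.loc[shifted.block_id == "B2", "value"] += 11.0
        m1 = fit_adjusted_means(TrialTable(shifted), "BLUE_single_env")
        assert (m1.values["X"] - m1.values["Y"]
                == pytest.approx(m0.values["X"] - m0.values["Y"], abs=1e-9))

    def test_block_without_check_is_inestimable(self):
        df = four_plot_trial().data
        df = df[~((df.block_id == "B2") & df.is_check)]
        with pytest.raises((ValidationError, RankDeficiencyError)):
            fit_adjusted_means(TrialTable(df), "BLUE_single_env")

    def test_multi_environment_rejected_in_blue_mode(self):
        t, _ = augmented_trial(n_entries=10, n_env=2)
        with pytest.raises(ValidationError):
            fit_adjusted_means(t, "BLUE_single_env")


class TestBlup:
    def test_shrinkage_toward_mean(self):
        t, _ = augmented_trial(n_entries=50, n_env=3, seed=5)
        m = fit_adjusted_means(t, "BLUP_combined")
        raw = t.data[~t.data.is_check].groupby("entry_id")["value"].mean()
        assert m.values.var() <= raw.var()

    def test_blups_track_true_genetic_values(self):
        t, gv = augmented_trial(n_entries=120, n_env=4, seed=7)
        m = fit_adjusted_means(t, "BLUP_combined")
        r = np.corrcoef(m.values.loc[gv.index], gv)[0, 1]
        assert r > 0.6

    def test_near_zero_genetic_variance_gives_full_shrinkage(self):
        # every entry shares the same true value: entry BLUPs collapse to
        # (nearly) the grand entry mean
        t, _ = augmented_trial(n_entries=40, n_env=3, s2g=1e-12, seed=9)
        m = fit_adjusted_means(t, "BLUP_combined")
        assert m.values.std() < 0.05 * t.data.value.std()

    def test_single_environment_rejected(self):
        t, _ = augmented_trial(n_entries=10, n_env=1)
        with pytest.raises(ValidationError):
            fit_adjusted_means(t, "BLUP_combined")


class TestVarianceComponents:
    def test_matches_anova_ems_oracle_on_balanced_data(self):
        t = balanced_trial(n_geno=80, n_env=4, n_rep=2, seed=1)
        vc = estimate_variance_components(t)
        df = t.data
        cell = df.groupby(["entry_id", "environment_id"])["value"].mean().unstack()
        g_n, e_n, r_n = cell.shape[0], cell.shape[1], 2
        # residual MS adjusted for replicate (block-within-env) effects
        sse, dof = 0.0, 0
        for _, sub in df.groupby("environment_id"):
            piv = sub.pivot(index="entry_id", columns="block_id", values="value")
            res = (piv - piv.mean(axis=1).to_numpy()[:, None]
                   - piv.mean(axis=0).to_numpy()[None, :] + piv.to_numpy().mean())
            sse += (res.to_numpy() ** 2).sum()
            dof += (piv.shape[0] - 1) * (piv.shape[1] - 1)
        mse = sse / dof
        gm = cell.to_numpy().mean()
        ms_g = e_n * r_n * ((cell.mean(axis=1) - gm) ** 2).sum() / (g_n - 1)
        resid = (cell - cell.mean(axis=1).to_numpy()[:, None]
                 - cell.mean(axis=0).to_numpy()[None, :] + gm)
        ms_ge = r_n * (resid.to_numpy() ** 2).sum() / ((g_n - 1) * (e_n - 1))
        assert vc.sigma2_G == pytest.approx((ms_g - ms_ge) / (e_n * r_n), abs=1e-6)
        assert vc.sigma2_GEI == pytest.approx((ms_ge - mse) / r_n, abs=1e-6)
        assert vc.sigma2_eps == pytest.approx(mse, abs=1e-6)

    def test_monte_carlo_recovery_within_15_percent(self):
        est = np.array([
            [vc.sigma2_G, vc.sigma2_GEI, vc.sigma2_eps]
            for seed in (2, 3, 4, 5)
            for vc in [estimate_variance_components(balanced_trial(
                n_geno=500, n_env=4, n_rep=2,
                s2g=1.0, s2ge=0.5, s2e=2.0, seed=seed))]
        ]).mean(axis=0)
        assert est[0] == pytest.approx(1.0, rel=0.15)
        assert est[1] == pytest.approx(0.5, rel=0.15)
        assert est[2] == pytest.approx(2.0, rel=0.15)

    def test_no_genetic_signal_estimates_zero_variance(self):
        # responses depend only on environment: sigma2_G hits the boundary
        rows = [(f"G{i}", f"E{e}", "B1", False, "", float(e))
                for i in range(20) for e in range(3)]
        t = TrialTable(pd.DataFrame(rows, columns=[
            "entry_id", "environment_id", "block_id", "is_check", "check_id", "value"]))
        vc = estimate_variance_components(t)
        assert vc.sigma2_G == 0.0

    def test_single_environment_gei_not_estimable(self):
        t = balanced_trial(n_geno=30, n_env=1, n_rep=3)
        vc = estimate_variance_components(t)
        assert not vc.gei_estimable
        assert np.isnan(vc.sigma2_GEI)
        assert vc.sigma2_G > 0

    def test_constant_response_rejected(self):
        rows = [(f"G{i}", "E1", "B1", False, "", 1.0) for i in range(5)]
        t = TrialTable(pd.DataFrame(rows, columns=[
            "entry_id", "environment_id", "block_id", "is_check", "check_id", "value"]))
        with pytest.raises(ValidationError):
            estimate_variance_components(t)

    def test_permutation_invariance(self):
        t, _ = augmented_trial(n_entries=30, n_env=2, seed=13)
        vc0 = estimate_variance_components(t)
        shuffled = TrialTable(
            t.data.sample(frac=1.0, random_state=4).reset_index(drop=True))
        vc1 = estimate_variance_components(shuffled)
        assert vc1.sigma2_G == pytest.approx(vc0.sigma2_G, abs=1e-8)
        assert vc1.sigma2_eps == pytest.approx(vc0.sigma2_eps, abs=1e-8)
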