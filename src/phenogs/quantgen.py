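"""Falconer indirect-selection statistics for a secondary trait vs. yield.

For a secondary trait x (a spectral index at one growth stage) and the
target trait y (grain yield), indirect selection is summarized by:

* broad-sense heritability  H2 = s2_G / (s2_G + s2_GEI/n + s2_eps/(n r))
* genetic correlation       r_G = Cov_g(x, y) / sqrt(s2_gx * s2_gy)
* response to selection     R  = sqrt(H2_x) * sigma_gx
* correlated response       CR = sqrt(H2_x) * r_G * sigma_gy
* relative efficiency       RE = CR_x / R_y

RE > 1 means selecting on the secondary trait advances yield faster than
selecting on yield itself. The identity RE = r_G * sqrt(H2_x / H2_y) holds
exactly by construction (selection intensities cancel in the ratio).

The genetic covariance is obtained with the pairwise-sums trick
Cov_g(x, y) = [s2_G(x + y) - s2_G(x) - s2_G(y)] / 2, reusing the univariate
REML engine on the sum trait; exact for balanced data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .field_adjust import (
    VarianceComponents,
    estimate_variance_components,
    fit_adjusted_means,
)
from .io_formats import TrialTable, ValidationError


class UndefinedStatisticError(ValueError):
    pass


@dataclass
class IndirectSelectionStats:
    """One trait x stage row of the indirect-selection report."""

    trait: str
    stage: str
    H2_x: float
    H2_y: float
    mean_x: float
    r_P: float
    r_G: float
    sigma_gx: float
    sigma_gy: float
    R_x: float
    R_y: float
    CR_x: float
    RE: float
    r_G_clipped: bool = False


def broad_sense_heritability(vc: VarianceComponents) -> float:
    """Entry-mean broad-sense heritability from variance components."""
    s2g = vc.sigma2_G
    s2ge = 0.0 if not vc.gei_estimable else vc.sigma2_GEI
    denom = s2g + s2ge / vc.n_env + vc.sigma2_eps / (vc.n_env * vc.n_rep)
    if denom == 0:
        raise UndefinedStatisticError("all variance components are zero")
    return s2g / denom


def _sum_trait(trial_x: TrialTable, trial_y: TrialTable) -> TrialTable:
    kx = trial_x.data.set_index(["entry_id", "environment_id", "block_id"])
    ky = trial_y.data.set_index(["entry_id", "environment_id", "block_id"])
    common = kx.index.intersection(ky.index)
    if common.empty:
        raise ValidationError("traits share no (entry, environment, block) plots")
    merged = kx.loc[common].copy()
    merged["value"] = kx.loc[common, "value"] + ky.loc[common, "value"]
    out = merged.reset_index()
    return TrialTable(out, response=f"{trial_x.response}+{trial_y.response}")


def _align_plots(trial_x: TrialTable, trial_y: TrialTable) -> tuple[TrialTable, TrialTable]:
    kx = trial_x.data.set_index(["entry_id", "environment_id", "block_id"])
    ky = trial_y.data.set_index(["entry_id", "environment_id", "block_id"])
    common = kx.index.intersection(ky.index)
    tx = TrialTable(kx.loc[common].reset_index(), response=trial_x.response)
    ty = TrialTable(ky.loc[common].reset_index(), response=trial_y.response)
    return tx, ty


def genetic_covariance(trial_x: TrialTable, trial_y: TrialTable):
    """Genotypic covariance between two traits on shared plots.

    Returns ``(cov_g, var_gx, var_gy)`` where each genotypic variance comes
    from a univariate REML fit and the covariance from the REML fit of the
    plot-wise sum trait.
    """
    tx, ty = _align_plots(trial_x, trial_y)
    shared_envs = set(tx.environments) & set(ty.environments)
    if len(shared_envs) < 2:
        raise ValidationError("genetic covariance needs >= 2 shared environments")
    vx = estimate_variance_components(tx).sigma2_G
    vy = estimate_variance_components(ty).sigma2_G
    vs = estimate_variance_components(_sum_trait(tx, ty)).sigma2_G
    cov = 0.5 * (vs - vx - vy)
    return cov, vx, vy


def genetic_correlation(cov_g: float, var_gx: float, var_gy: float,
                        clip: bool = True) -> tuple[float, bool]:
    """r_G = Cov_g / sqrt(var_gx * var_gy); returns (value, clipped_flag)."""
    if var_gx <= 0 or var_gy <= 0:
        raise UndefinedStatisticError("genetic correlation undefined: nonpositive variance")
    r = cov_g / np.sqrt(var_gx * var_gy)
    clipped = abs(r) > 1
    if clipped and clip:
        r = float(np.clip(r, -1.0, 1.0))
    return float(r), bool(clipped)


def response_to_selection(H2_x: float, sigma_gx: float) -> float:
    """R = sqrt(H2) * genotypic SD (selection intensity normalized out)."""
    if not (0 <= H2_x <= 1) or sigma_gx < 0:
        raise UndefinedStatisticError("need H2 in [0,1] and sigma_gx >= 0")
    return float(np.sqrt(H2_x) * sigma_gx)


def correlated_response(H2_x: float, r_G: float, sigma_gy: float) -> float:
    """CR = sqrt(H2_x) * r_G * sigma_gy; sign follows r_G."""
    if not (0 <= H2_x <= 1) or not (-1 <= r_G <= 1) or sigma_gy < 0:
        raise UndefinedStatisticError("invalid inputs to correlated response")
    return float(np.sqrt(H2_x) * r_G * sigma_gy)


def relative_efficiency(CR_x: float, R_y: float) -> float:
    """RE = CR_x / R_y; RE > 1 flags superior indirect selection."""
    if R_y == 0:
        raise UndefinedStatisticError("relative efficiency undefined: R_y = 0")
    return float(CR_x / R_y)


def phenotypic_correlation(trial_x: TrialTable, trial_y: TrialTable) -> float:
    """Pearson correlation of per-environment entry BLUEs, pooled across envs."""
    pairs = []
    for env in sorted(set(trial_x.environments) & set(trial_y.environments)):
        bx = fit_adjusted_means(trial_x.subset_environment(env), "BLUE_single_env").values
        by = fit_adjusted_means(trial_y.subset_environment(env), "BLUE_single_env").values
        common = bx.index.intersection(by.index)
        pairs.append(pd.DataFrame({"x": bx.loc[common], "y": by.loc[common]}))
    pooled = pd.concat(pairs)
    if len(pooled) < 3:
        raise UndefinedStatisticError("too few paired values for phenotypic correlation")
    return float(np.corrcoef(pooled["x"], pooled["y"])[0, 1])


def indirect_selection_report(trials: dict, yield_trial: TrialTable) -> pd.DataFrame:
    """Indirect-selection summary, one row per (trait, stage).

    ``trials`` maps (trait_name, stage) -> TrialTable of that index. Rows
    whose components fail are flagged (NaNs + note), not dropped.
    """
    vcy = estimate_variance_components(yield_trial)
    H2_y = broad_sense_heritability(vcy)
    sigma_gy = float(np.sqrt(vcy.sigma2_G))
    R_y = response_to_selection(H2_y, sigma_gy)
    yield_entries = set(yield_trial.entries)
    rows = []
    for (trait, stage), tx in sorted(trials.items()):
        if not (set(tx.entries) & yield_entries):
            raise ValidationError(f"no shared entries between {trait}/{stage} and yield")
        try:
            vcx = estimate_variance_components(tx)
            H2_x = broad_sense_heritability(vcx)
            cov, vgx, vgy = genetic_covariance(tx, yield_trial)
            r_G, clipped = genetic_correlation(cov, vgx, vgy)
            r_P = phenotypic_correlation(tx, yield_trial)
            sigma_gx = float(np.sqrt(vgx))
            R_x = response_to_selection(H2_x, sigma_gx)
            # CR uses the same sigma_gy as R_y so that RE = r_G*sqrt(H2x/H2y)
            # holds exactly, not only when the aligned and full yield fits agree
            CR_x = correlated_response(H2_x, r_G, sigma_gy)
            RE = relative_efficiency(CR_x, R_y)
            stats = IndirectSelectionStats(
                trait=trait, stage=stage, H2_x=H2_x, H2_y=H2_y,
                mean_x=float(tx.data["value"].mean()), r_P=r_P, r_G=r_G,
                sigma_gx=sigma_gx, sigma_gy=sigma_gy, R_x=R_x, R_y=R_y,
                CR_x=CR_x, RE=RE, r_G_clipped=clipped,
            )
            rows.append(vars(stats) | {"note": ""})
        except (UndefinedStatisticError, ValidationError) as exc:
            rows.append({"trait": trait, "stage": stage, "H2_y": H2_y, "R_y": R_y,
                         "note": str(exc)})
    cols = ["trait", "stage", "H2_x", "mean_x", "r_P", "r_G", "R_x", "CR_x", "RE",
            "H2_y", "R_y", "sigma_gx", "sigma_gy", "r_G_clipped", "note"]
    return pd.DataFrame(rows).reindex(columns=cols)
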