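"""Augmented-design adjustment and variance components for field trials.

An augmented block design replicates a handful of check cultivars in every
block while each test entry appears once per environment. Block (and
environment) effects are therefore estimated from the checks and used to
adjust the un-replicated entries:

* ``BLUE_single_env`` — all effects fixed, one environment: ordinary least
  squares on genotype-identity + block terms; the entry BLUE is the entry's
  value at the average block (sum-to-zero block convention).
* ``BLUP_combined`` — across environments: entry effects (and their
  interaction with environment) are random and REML-estimated, shrinking
  entries toward the mean; environment, block-within-environment, and the
  check structure are nuisance terms.

The same REML engine yields the variance components
(sigma2_G, sigma2_GEI, sigma2_eps) that feed broad-sense heritability
H2 = sigma2_G / (sigma2_G + sigma2_GEI/n + sigma2_eps/(n*r)).

Implementation notes: the marginal covariance is block-diagonal by entry
(checks carry no random effect), so each REML likelihood evaluation costs
only small dense solves grouped by replication pattern. The optimizer is
bounded quasi-Newton on log-variance scale with a method-of-moments start
plus fixed alternative starts; tolerance 1e-8 on the log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .io_formats import TrialTable, ValidationError

_LOG_BOUND = 30.0  # bounds on log(variance / scale): effectively (0, inf)
_BIG = 1e30


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the best-found values."""

    def __init__(self, msg, best=None, grad_norm=None):
        super().__init__(msg)
        self.best = best
        self.grad_norm = grad_norm


class RankDeficiencyError(ValueError):
    pass


@dataclass
class VarianceComponents:
    """REML variance components from a multi-environment trial."""

    sigma2_G: float
    sigma2_GEI: float
    sigma2_eps: float
    n_env: int
    n_rep: float
    gei_estimable: bool = True
    loglik: float = np.nan
    converged: bool = True

    def __post_init__(self):
        for name in ("sigma2_G", "sigma2_eps"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.gei_estimable and self.sigma2_GEI < 0:
            raise ValidationError("sigma2_GEI must be >= 0")
        if self.n_env < 1 or self.n_rep < 1:
            raise ValidationError("n_env and n_rep must be >= 1")


@dataclass
class AdjustedMeans:
    """Per-entry adjusted genotype values for one response."""

    response: str
    mode: str  # BLUE_single_env | BLUP_combined
    environments: list
    values: pd.Series  # index: entry_id
    sigma2_eps: float = np.nan
    converged: bool = True
    components: VarianceComponents | None = None


# ---------------------------------------------------------------------------
# design-matrix assembly
# ---------------------------------------------------------------------------


def _dummies(labels, drop_first=False) -> tuple[np.ndarray, list]:
    levels = list(dict.fromkeys(labels))
    use = levels[1:] if drop_first else levels
    cols = np.stack([(np.asarray(labels, dtype=object) == lv).astype(float) for lv in use],
                    axis=1) if use else np.zeros((len(labels), 0))
    return cols, use


def _nuisance_design(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Fixed nuisance design: intercept, environment, block(env), check x env."""
    n = len(df)
    cols = [np.ones((n, 1))]
    names = ["intercept"]
    envs = list(dict.fromkeys(df["environment_id"]))
    if len(envs) > 1:
        X_e, lv = _dummies(df["environment_id"].to_numpy(), drop_first=True)
        cols.append(X_e)
        names += [f"env[{v}]" for v in lv]
    # blocks nested in environment, first block per env dropped
    for e in envs:
        m = (df["environment_id"] == e).to_numpy()
        blocks = df.loc[m, "block_id"].to_numpy()
        lv = list(dict.fromkeys(blocks))[1:]
        for b in lv:
            c = np.zeros((n, 1))
            c[m & (df["block_id"] == b).to_numpy(), 0] = 1.0
            cols.append(c)
            names.append(f"block[{e}:{b}]")
    # check-identity cell dummies (check x environment)
    chk = df["is_check"].to_numpy()
    if chk.any():
        cells = df.loc[chk, ["check_id", "environment_id"]].astype(str).agg(":".join, axis=1)
        for cell in dict.fromkeys(cells):
            c = np.zeros((n, 1))
            idx = np.zeros(n, dtype=bool)
            idx[np.flatnonzero(chk)[(cells == cell).to_numpy()]] = True
            c[idx, 0] = 1.0
            cols.append(c)
            names.append(f"check[{cell}]")
    X = np.concatenate(cols, axis=1)
    return X, names


def _reduce_rank(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop linearly dependent columns (pivoted QR), keeping earlier columns."""
    from scipy.linalg import qr

    if X.shape[1] == 0:
        return X, names
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 1.0)
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    return X[:, keep], [names[k] for k in keep]


# ---------------------------------------------------------------------------
# REML core
# ---------------------------------------------------------------------------


class _RemlProblem:
    """Pre-grouped sufficient structures for fast REML evaluations.

    Random effects: entry genotype (G) and entry genotype x environment
    (GE). Entries are grouped by replication signature (plots per
    environment cell) so each group shares one small covariance block
    B = s2G * J + s2GE * blockdiag(J_cell) + s2e * I.
    """

    def __init__(self, trial: TrialTable, with_gei: bool):
        df = trial.data.copy()
        df = df[np.isfinite(df["value"].to_numpy(dtype=float))]
        # canonical record order makes every estimate exactly invariant to
        # the order rows arrived in (summation order and all)
        df = df.sort_values(
            ["is_check", "entry_id", "check_id", "environment_id", "block_id"],
            kind="stable").reset_index(drop=True)
        if df.empty:
            raise ValidationError("no non-missing responses")
        self.df = df
        self.with_gei = with_gei
        X, names = _nuisance_design(df)
        X, names = _reduce_rank(X, names)
        self.X, self.names = X, names
        self.y = df["value"].to_numpy(dtype=float)
        self.n, self.p = X.shape

        entry_rows = ~df["is_check"].to_numpy()
        self.check_rows = np.flatnonzero(~entry_rows)
        # group entry rows by genotype, sorted by environment within genotype
        groups: dict[tuple, list[tuple[object, np.ndarray]]] = {}
        sub = df.loc[entry_rows]
        for gid, gdf in sub.groupby("entry_id", sort=True):
            gdf = gdf.sort_values("environment_id", kind="stable")
            cells = gdf.groupby("environment_id", sort=True).size()
            sig = tuple(cells.tolist())
            groups.setdefault(sig, []).append((gid, gdf.index.to_numpy()))
        self.groups = []
        for sig, members in groups.items():
            idx = np.stack([rows for _, rows in members])  # (g, n_i)
            gids = [gid for gid, _ in members]
            # GE incidence pattern: records sharing an env cell
            C = _blockdiag_ones(sig)
            n_i = C.shape[0]
            J = np.ones((n_i, n_i))
            grp = {"sig": sig, "gids": gids, "idx": idx, "J": J, "C": C,
                   "Xg": X[idx], "yg": self.y[idx]}
            # one plot per env cell: B = a*J + d*I is compound-symmetric, so
            # X'B^-1 X reduces to two precomputed p x p sufficient statistics
            grp["cs"] = bool(np.array_equal(C, np.eye(n_i)))
            if grp["cs"]:
                Xg, yg = grp["Xg"], grp["yg"]
                s = Xg.sum(axis=1)                      # (g, p)
                sy = yg.sum(axis=1)                     # (g,)
                grp["T_XX"] = np.einsum("gip,giq->pq", Xg, Xg)
                grp["T_SS"] = s.T @ s
                grp["T_Xy"] = np.einsum("gi,gip->p", yg, Xg)
                grp["T_Sy"] = s.T @ sy
                grp["T_yy"] = float(np.einsum("gi,gi->", yg, yg))
                grp["T_syy"] = float(sy @ sy)
            self.groups.append(grp)
        # check plots carry no random effect: their part of V is s2e * I
        if self.check_rows.size:
            Xc, yc = X[self.check_rows], self.y[self.check_rows]
            self._chk = (Xc.T @ Xc, Xc.T @ yc, float(yc @ yc))
        self.scale = max(np.var(self.y), 1e-12)

    def loglik(self, theta: np.ndarray) -> float:
        """REML log-likelihood (up to constant) at log-variance vector theta."""
        out = self._assemble(theta)
        if out is None:
            return -_BIG  # infeasible covariance: finite penalty keeps
                          # numerical gradients well defined
        XtViX, XtViy, ytViy, logdetV = out
        sign, logdetC = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -_BIG
        beta = np.linalg.solve(XtViX, XtViy)
        quad = ytViy - XtViy @ beta
        return -0.5 * (logdetV + logdetC + quad)

    def _variances(self, theta):
        if self.with_gei:
            s2g, s2ge, s2e = np.exp(theta) * self.scale
        else:
            s2g, s2e = np.exp(theta) * self.scale
            s2ge = 0.0
        return s2g, s2ge, s2e

    def _assemble(self, theta):
        s2g, s2ge, s2e = self._variances(theta)
        XtViX = np.zeros((self.p, self.p))
        XtViy = np.zeros(self.p)
        ytViy = 0.0
        logdetV = 0.0
        for grp in self.groups:
            n_i = grp["J"].shape[0]
            n_grp = grp["idx"].shape[0]
            if grp["cs"]:
                a, d = s2g, s2ge + s2e
                if d <= 0 or d + a * n_i <= 0:
                    return None
                c1 = 1.0 / d
                c2 = a / (d * (d + a * n_i))
                XtViX += c1 * grp["T_XX"] - c2 * grp["T_SS"]
                XtViy += c1 * grp["T_Xy"] - c2 * grp["T_Sy"]
                ytViy += c1 * grp["T_yy"] - c2 * grp["T_syy"]
                logdetV += n_grp * ((n_i - 1) * np.log(d) + np.log(d + a * n_i))
            else:
                B = s2g * grp["J"] + s2ge * grp["C"] + s2e * np.eye(n_i)
                try:
                    L = np.linalg.cholesky(B)
                except np.linalg.LinAlgError:
                    return None
                Binv = np.linalg.inv(B)
                logdetV += 2.0 * np.log(np.diag(L)).sum() * n_grp
                Xg, yg = grp["Xg"], grp["yg"]
                BX = np.einsum("ij,gjp->gip", Binv, Xg)
                XtViX += np.einsum("gip,giq->pq", BX, Xg)
                By = yg @ Binv
                XtViy += np.einsum("gi,gip->p", By, Xg)
                ytViy += float(np.einsum("gi,gi->", By, yg))
        if self.check_rows.size:
            CXX, CXy, Cyy = self._chk
            XtViX += CXX / s2e
            XtViy += CXy / s2e
            ytViy += Cyy / s2e
            logdetV += self.check_rows.size * np.log(s2e)
        return XtViX, XtViy, ytViy, logdetV

    def gls(self, theta):
        out = self._assemble(theta)
        XtViX, XtViy, _, _ = out
        return np.linalg.solve(XtViX, XtViy)

    def entry_blups(self, theta) -> pd.Series:
        s2g, s2ge, s2e = self._variances(theta)
        beta = self.gls(theta)
        resid = self.y - self.X @ beta
        vals, gids = [], []
        for grp in self.groups:
            B = s2g * grp["J"] + s2ge * grp["C"] + s2e * np.eye(grp["J"].shape[0])
            Binv = np.linalg.inv(B)
            rg = resid[grp["idx"]]  # (g, n_i)
            # BLUP(g_i) = s2g * 1' B^{-1} r_i
            blup = s2g * (rg @ Binv).sum(axis=1)
            vals.extend(blup.tolist())
            gids.extend(grp["gids"])
        return pd.Series(vals, index=gids).sort_index()


def _blockdiag_ones(sig: tuple) -> np.ndarray:
    n = sum(sig)
    C = np.zeros((n, n))
    start = 0
    for r in sig:
        C[start:start + r, start:start + r] = 1.0
        start += r
    return C


def _mom_starts(prob: _RemlProblem) -> list[np.ndarray]:
    """Method-of-moments and fallback starting points on log-variance scale."""
    df = prob.df
    entry = df[~df["is_check"]]
    piv = entry.pivot_table(index="entry_id", columns="environment_id",
                            values="value", aggfunc="mean")
    line_means = piv.mean(axis=1)
    within = piv.sub(piv.mean(axis=0), axis=1).sub(line_means - line_means.mean(), axis=0)
    n_env = max(piv.shape[1], 1)
    between = float(line_means.var()) if len(line_means) > 1 else prob.scale
    inter = float(np.nanvar(within.to_numpy())) if piv.shape[1] > 1 else prob.scale
    s2e0 = prob.scale * 0.5
    checks = df[df["is_check"]]
    if len(checks) > 1:
        wv = checks.groupby(["check_id", "environment_id"])["value"].var().dropna()
        if len(wv):
            s2e0 = max(float(wv.mean()), 1e-3 * prob.scale)
    s2ge0 = max(inter - s2e0, 0.05 * prob.scale)
    s2g0 = max(between - (s2ge0 + s2e0) / n_env, 0.05 * prob.scale)
    starts = []
    if prob.with_gei:
        starts.append(np.log(np.array([s2g0, s2ge0, s2e0]) / prob.scale))
        starts.append(np.log(np.array([0.4, 0.2, 0.4])))
        starts.append(np.log(np.array([0.05, 0.05, 0.9])))
    else:
        starts.append(np.log(np.array([max(between, 0.05 * prob.scale), s2e0]) / prob.scale))
        starts.append(np.log(np.array([0.5, 0.5])))
    return [np.clip(s, -_LOG_BOUND + 1, _LOG_BOUND - 1) for s in starts]


def _optimize_reml(prob: _RemlProblem) -> tuple[np.ndarray, float, bool]:
    best_theta, best_ll, ok = None, -np.inf, False
    for x0 in _mom_starts(prob):
        res = minimize(
            lambda t: -prob.loglik(t),
            x0,
            method="L-BFGS-B",
            bounds=[(-_LOG_BOUND, _LOG_BOUND)] * len(x0),
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        if -res.fun > best_ll:
            best_ll, best_theta, ok = -res.fun, res.x, bool(res.success)
    if best_theta is None or not np.isfinite(best_ll):
        raise ConvergenceError("REML optimization failed from every start", best=best_theta)
    # derivative-free polish: the surface is flat near the optimum and
    # quasi-Newton alone stops a little short of full parameter precision
    res = minimize(lambda t: -prob.loglik(t), best_theta, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    if -res.fun >= best_ll:
        best_ll, best_theta = -res.fun, res.x
    return best_theta, best_ll, ok


def _snap(v: float, scale: float) -> float:
    """Variances driven to the boundary report exactly 0."""
    return 0.0 if v < 1e-8 * scale else float(v)


def estimate_variance_components(trial: TrialTable) -> VarianceComponents:
    """REML estimates of (sigma2_G, sigma2_GEI, sigma2_eps).

    Genotype and genotype-by-environment effects are random; environment,
    block-within-environment, and the check structure are fixed nuisance.
    With a single environment the GEI component is not estimable and is
    reported as NaN with ``gei_estimable=False``. Deterministic given data.
    """
    vals = trial.data["value"].to_numpy(dtype=float)
    if np.nanstd(vals) == 0:
        raise ValidationError("response is constant; variance components undefined")
    envs = trial.environments
    with_gei = len(envs) >= 2
    prob = _RemlProblem(trial, with_gei=with_gei)
    theta, ll, ok = _optimize_reml(prob)
    s2g, s2ge, s2e = prob._variances(theta)
    n_rep = _mean_check_reps(trial)
    return VarianceComponents(
        sigma2_G=_snap(s2g, prob.scale),
        sigma2_GEI=_snap(s2ge, prob.scale) if with_gei else float("nan"),
        sigma2_eps=_snap(s2e, prob.scale),
        n_env=len(envs),
        n_rep=n_rep,
        gei_estimable=with_gei,
        loglik=ll,
        converged=ok,
    )


def _mean_check_reps(trial: TrialTable) -> float:
    """Replications per environment: entries are unreplicated in an
    augmented design, so r = 1 unless genotypes are actually replicated."""
    entry = trial.data[~trial.data["is_check"]]
    reps = entry.groupby(["entry_id", "environment_id"]).size()
    return float(max(reps.mean(), 1.0)) if len(reps) else 1.0


# ---------------------------------------------------------------------------
# adjusted means
# ---------------------------------------------------------------------------


def fit_adjusted_means(trial: TrialTable, mode: str) -> AdjustedMeans:
    """Adjusted genotype means: per-environment BLUEs or combined BLUPs."""
    if mode == "BLUE_single_env":
        return _fit_blue(trial)
    if mode == "BLUP_combined":
        return _fit_blup(trial)
    raise ValueError(f"unknown mode {mode!r}")


def _fit_blue(trial: TrialTable) -> AdjustedMeans:
    envs = trial.environments
    if len(envs) != 1:
        raise ValidationError(f"BLUE mode needs a single environment, got {envs}")
    df = trial.data.copy()
    df = df[np.isfinite(df["value"].to_numpy(dtype=float))]
    df = df.sort_values(["is_check", "entry_id", "check_id", "block_id"],
                        kind="stable").reset_index(drop=True)
    n_blocks = df["block_id"].nunique()
    if n_blocks > 1:
        trial_nonmiss = TrialTable(df.copy(), response=trial.response, units=trial.units)
        trial_nonmiss.validate_blocks_have_checks()
    # genotype identity: entries by entry_id, checks by check_id
    geno = np.where(df["is_check"], "chk:" + df["check_id"], "ent:" + df["entry_id"])
    G, geno_levels = _dummies(geno)
    blocks = df["block_id"].to_numpy()
    block_levels = list(dict.fromkeys(blocks))
    # sum-to-zero block contrasts (last block is -1 in every contrast column)
    Bc = np.zeros((len(df), max(len(block_levels) - 1, 0)))
    for j, b in enumerate(block_levels[:-1]):
        Bc[blocks == b, j] = 1.0
        Bc[blocks == block_levels[-1], j] = -1.0
    X = np.concatenate([G, Bc], axis=1)
    y = df["value"].to_numpy(dtype=float)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise RankDeficiencyError(
            "singular BLUE design: genotype and block terms are confounded "
            f"(rank {rank} < {X.shape[1]} columns); every block needs a shared check"
        )
    resid = y - X @ coef
    dof = max(len(y) - X.shape[1], 1)
    s2e = float(resid @ resid / dof)
    values = {}
    for lv, c in zip(geno_levels, coef[: len(geno_levels)]):
        if lv.startswith("ent:"):
            values[lv[4:]] = float(c)
    return AdjustedMeans(
        response=trial.response,
        mode="BLUE_single_env",
        environments=envs,
        values=pd.Series(values).sort_index(),
        sigma2_eps=s2e,
    )


def _fit_blup(trial: TrialTable) -> AdjustedMeans:
    envs = trial.environments
    if len(envs) < 2:
        raise ValidationError("BLUP_combined needs >= 2 environments")
    vc = estimate_variance_components(trial)
    prob = _RemlProblem(trial, with_gei=True)
    theta = np.log(np.array([
        max(vc.sigma2_G, 1e-12 * prob.scale),
        max(vc.sigma2_GEI, 1e-12 * prob.scale),
        max(vc.sigma2_eps, 1e-12 * prob.scale),
    ]) / prob.scale)
    blups = prob.entry_blups(theta)
    beta = prob.gls(theta)
    entry_rows = ~prob.df["is_check"].to_numpy()
    mu = float((prob.X[entry_rows] @ beta).mean())
    return AdjustedMeans(
        response=trial.response,
        mode="BLUP_combined",
        environments=envs,
        values=(blups + mu).sort_index(),
        sigma2_eps=vc.sigma2_eps,
        converged=vc.converged,
        components=vc,
    )
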