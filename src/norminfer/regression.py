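"""Bayesian hierarchical linear regression of judgments on model posteriors.

The linking model regresses each participant's condition-mean judgmental
posterior ``y`` on the model-derived posterior ``x``:

    y_ij = (b0 + u0_j) + (b1 + u1_j) x_ij + e_ij,
    (u0_j, u1_j) ~ N(0, Sigma_p),   e_ij ~ N(0, sigma^2),

with a correlated random intercept and slope per participant and, for the
more rigorous robustness variant, an additional crossed random intercept and
slope per condition.  Priors are weakly informative: Normal(0, 2.5) on the
population intercept and slope (predictor and response both live on [0, 1]),
half-Normal(0, 1) on every standard deviation, and a uniform prior on each
intercept-slope correlation.

Sampling integrates the random effects out analytically (the marginal
likelihood of each group is multivariate normal) and explores the remaining
low-dimensional hyperparameter posterior with an affine-invariant ensemble
sampler (emcee), one independent ensemble per chain.  Random effects are then
re-drawn exactly from their Gaussian conditional for every retained draw,
which yields the per-observation log-likelihoods needed for LOO-based model
comparison.

Reported quantities follow the field's conventions: the slope's posterior
mean ``beta``, its 95% credible interval (equal-tailed or HDI), the posterior
mass ``Pr(beta > 0)``, the standardized effect size ``delta_t`` (slope over
the square root of the summed variance components) and the split-Rhat
convergence diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import optimize

import emcee

__all__ = [
    "RegressionInput",
    "RegressionResult",
    "ConvergenceWarning",
    "fit_hierarchical",
    "delta_t",
    "rhat",
    "summarize",
]

_LOG2PI = np.log(2.0 * np.pi)
_MIN_LOG_SD = np.log(1e-5)
_MAX_LOG_SD = np.log(10.0)


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class RegressionInput:
    """Aligned arrays for one regression fit; groups may be unbalanced."""

    x: np.ndarray
    y: np.ndarray
    participant: np.ndarray
    condition: np.ndarray | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.participant = np.asarray(self.participant)
        if self.condition is not None:
            self.condition = np.asarray(self.condition)
        n = len(self.x)
        if len(self.y) != n or len(self.participant) != n:
            raise ValueError("x, y and participant must have equal length")
        if self.condition is not None and len(self.condition) != n:
            raise ValueError("condition must align with x and y")
        if np.unique(self.participant).size < 2:
            raise ValueError("need at least 2 participants")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        x_col: str,
        y_col: str = "posterior_norm",
        participant_col: str = "participant",
        condition_col: str | None = None,
    ) -> "RegressionInput":
        return cls(
            x=frame[x_col].to_numpy(),
            y=frame[y_col].to_numpy(),
            participant=frame[participant_col].to_numpy(),
            condition=frame[condition_col].to_numpy() if condition_col else None,
        )


@dataclass
class RegressionResult:
    """Posterior draws and derived summaries of one hierarchical fit."""

    param_names: list[str]
    draws: dict[str, np.ndarray]          # name -> (chains, n_draws), natural scale
    pointwise_loglik: np.ndarray          # (chains, n_draws, n_obs)
    rhat: dict[str, float]
    n_obs: int
    groupings: list[str] = field(default_factory=lambda: ["participant"])
    converged: bool = True

    @property
    def beta_draws(self) -> np.ndarray:
        return self.draws["beta"]

    @property
    def beta_mean(self) -> float:
        return float(self.beta_draws.mean())

    def cri_95(self, kind: str = "equal_tailed") -> tuple[float, float]:
        flat = self.beta_draws.ravel()
        if kind == "equal_tailed":
            lo, hi = np.quantile(flat, [0.025, 0.975])
        elif kind == "hdi":
            import arviz as az

            lo, hi = az.hdi(flat, hdi_prob=0.95)
        else:
            raise ValueError("kind must be 'equal_tailed' or 'hdi'")
        return float(lo), float(hi)

    @property
    def pr_beta_gt_0(self) -> float:
        return float((self.beta_draws > 0).mean())

    @property
    def variance_components(self) -> dict[str, float]:
        """Posterior-mean variances of every random term plus the residual."""
        comps = {}
        for name, d in self.draws.items():
            if name.startswith("sd_"):
                comps[name.replace("sd_", "var_")] = float((d**2).mean())
        return comps

    @property
    def delta_t(self) -> float:
        return delta_t(self)


def delta_t(result: RegressionResult) -> float:
    """Standardized slope: beta over the root of the summed variance components.

    Computed per posterior draw and averaged; the variance components are all
    random-effect variances plus the residual variance.
    """
    total = np.zeros_like(result.beta_draws)
    for name, d in result.draws.items():
        if name.startswith("sd_"):
            total += d**2
    if np.all(total == 0):
        raise ZeroDivisionError("total variance is zero")
    return float((result.beta_draws / np.sqrt(total)).mean())


def rhat(chains: np.ndarray) -> float:
    """Split-Rhat convergence statistic for one scalar parameter.

    ``chains`` is (n_chains, n_draws); each chain is split in half so within-
    chain drift also inflates the statistic.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least 2 chains of draws")
    n = chains.shape[1]
    if n < 4:
        raise ValueError("chains too short to split")
    half = n // 2
    halves = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = halves.shape
    chain_means = halves.mean(axis=1)
    B = n * chain_means.var(ddof=1)
    W = halves.var(axis=1, ddof=1).mean()
    if W == 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


# ---------------------------------------------------------------------------
# Marginalized mixed-model log posterior
# ---------------------------------------------------------------------------

class _MixedModel:
    """Marginal log-posterior over (intercept, beta, RE sds/corr, residual sd)."""

    def __init__(self, data: RegressionInput):
        self.crossed = data.condition is not None
        order = np.argsort(data.participant, kind="stable")
        self.x = data.x[order]
        self.y = data.y[order]
        self.n = len(self.x)
        self.U = np.column_stack([np.ones(self.n), self.x])  # (n, 2)

        self.p_ids, self.p_idx = np.unique(data.participant[order], return_inverse=True)
        self.n_p = len(self.p_ids)
        if self.crossed:
            self.c_ids, self.c_idx = np.unique(data.condition[order], return_inverse=True)
            self.n_c = len(self.c_ids)
            self.same_p = self.p_idx[:, None] == self.p_idx[None, :]
            self.same_c = self.c_idx[:, None] == self.c_idx[None, :]
            self.param_names = [
                "intercept",
                "beta",
                "sd_participant_intercept",
                "sd_participant_slope",
                "corr_participant",
                "sd_condition_intercept",
                "sd_condition_slope",
                "corr_condition",
                "sd_residual",
            ]
        else:
            # Group observations by participant; batch groups of equal size.
            sizes = np.bincount(self.p_idx)
            self.size_classes = []
            for g in np.unique(sizes):
                groups = np.flatnonzero(sizes == g)
                rows = np.stack(
                    [np.flatnonzero(self.p_idx == j) for j in groups]
                )  # (m, g)
                self.size_classes.append((int(g), rows, self.U[rows]))  # U: (m, g, 2)
            self.param_names = [
                "intercept",
                "beta",
                "sd_participant_intercept",
                "sd_participant_slope",
                "corr_participant",
                "sd_residual",
            ]
        self.ndim = len(self.param_names)

    # -- parameterization: sds on log scale, correlations via atanh ---------

    def to_natural(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        theta = np.atleast_2d(theta)
        out: dict[str, np.ndarray] = {}
        for i, name in enumerate(self.param_names):
            col = theta[..., i]
            if name.startswith("sd_"):
                out[name] = np.exp(col)
            elif name.startswith("corr_"):
                out[name] = np.tanh(col)
            else:
                out[name] = col
        return out

    @staticmethod
    def _cov2(sd0, sd1, rho):
        W = np.broadcast_shapes(np.shape(sd0), np.shape(sd1), np.shape(rho))
        S = np.empty((*W, 2, 2))
        S[..., 0, 0] = sd0**2
        S[..., 1, 1] = sd1**2
        S[..., 0, 1] = S[..., 1, 0] = rho * sd0 * sd1
        return S

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        lp = np.zeros(theta.shape[0])
        for i, name in enumerate(self.param_names):
            col = theta[:, i]
            if name.startswith("sd_"):
                bad = (col < _MIN_LOG_SD) | (col > _MAX_LOG_SD)
                sd = np.exp(col)
                lp += np.where(bad, -np.inf, -0.5 * sd**2 + col)  # half-N(0,1) + Jacobian
            elif name.startswith("corr_"):
                rho = np.tanh(col)
                with np.errstate(divide="ignore"):
                    lp += np.log1p(-(rho**2))  # uniform(-1,1) + tanh Jacobian
            else:
                lp += -0.5 * (col / 2.5) ** 2
        return lp

    def log_likelihood(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        nat = self.to_natural(theta)
        W = theta.shape[0]
        resid = self.y[None, :] - (
            nat["intercept"][:, None] + nat["beta"][:, None] * self.x[None, :]
        )
        sigma2 = nat["sd_residual"] ** 2
        Sp = self._cov2(
            nat["sd_participant_intercept"],
            nat["sd_participant_slope"],
            nat["corr_participant"],
        )
        ll = np.zeros(W)
        if self.crossed:
            Sc = self._cov2(
                nat["sd_condition_intercept"],
                nat["sd_condition_slope"],
                nat["corr_condition"],
            )
            Mp = np.einsum("ia,wab,jb->wij", self.U, Sp, self.U)
            Mc = np.einsum("ia,wab,jb->wij", self.U, Sc, self.U)
            V = Mp * self.same_p + Mc * self.same_c
            V[:, np.arange(self.n), np.arange(self.n)] += sigma2[:, None]
            L, ok = _chol(V)
            sol = np.linalg.solve(L, resid[..., None])[..., 0]
            ll = -0.5 * (
                (sol**2).sum(axis=-1)
                + 2.0 * np.log(np.diagonal(L, axis1=-2, axis2=-1)).sum(axis=-1)
                + self.n * _LOG2PI
            )
            ll[~ok] = -np.inf
            return ll
        for g, rows, Ug in self.size_classes:
            V = np.einsum("mga,wab,mhb->wmgh", Ug, Sp, Ug)
            V[..., np.arange(g), np.arange(g)] += sigma2[:, None, None]
            L, ok = _chol(V)
            r = resid[:, rows]  # (W, m, g)
            sol = np.linalg.solve(L, r[..., None])[..., 0]
            ll += np.where(
                ok.all(axis=-1),
                -0.5
                * (
                    (sol**2).sum(axis=(-2, -1))
                    + 2.0 * np.log(np.diagonal(L, axis1=-2, axis2=-1)).sum(axis=(-2, -1))
                    + rows.size * _LOG2PI
                ),
                -np.inf,
            )
        return ll

    def log_posterior(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        lp = self.log_prior(theta)
        out = np.full(theta.shape[0], -np.inf)
        finite = np.isfinite(lp)
        if finite.any():
            out[finite] = lp[finite] + self.log_likelihood(theta[finite])
        return out


def _chol(V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched Cholesky that flags (rather than raises on) non-PD matrices."""
    diag = np.diagonal(V, axis1=-2, axis2=-1)
    ok = np.isfinite(V).all(axis=(-2, -1)) & (diag > 0).all(axis=-1)
    safe = np.where(ok[..., None, None], V, np.eye(V.shape[-1]))
    try:
        L = np.linalg.cholesky(safe)
    except np.linalg.LinAlgError:
        # Fall back element-wise only in the rare indefinite case.
        flat = safe.reshape(-1, *safe.shape[-2:])
        okf = ok.reshape(-1).copy()
        L = np.empty_like(flat)
        for i, M in enumerate(flat):
            try:
                L[i] = np.linalg.cholesky(M)
            except np.linalg.LinAlgError:
                L[i] = np.eye(M.shape[-1])
                okf[i] = False
        L = L.reshape(safe.shape)
        ok = okf.reshape(ok.shape)
    return L, ok


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _map_estimate(model: _MixedModel) -> np.ndarray:
    X = np.column_stack([np.ones(model.n), model.x])
    coef, *_ = np.linalg.lstsq(X, model.y, rcond=None)
    resid_sd = max(float(np.std(model.y - X @ coef)), 1e-3)
    start = []
    for name in model.param_names:
        if name == "intercept":
            start.append(coef[0])
        elif name == "beta":
            start.append(coef[1])
        elif name.startswith("sd_residual"):
            start.append(np.log(resid_sd))
        elif name.startswith("sd_"):
            start.append(np.log(max(resid_sd, 0.05)))
        else:
            start.append(0.0)
    start = np.array(start)

    def neg(theta):
        return -float(model.log_posterior(theta[None, :])[0])

    res = optimize.minimize(neg, start, method="Nelder-Mead",
                            options={"maxiter": 1500, "xatol": 1e-5, "fatol": 1e-5})
    return res.x if np.isfinite(res.fun) else start


def _sample_random_effects_and_loglik(
    model: _MixedModel, draws: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Exact conditional draw of all random effects per retained posterior draw,
    returning the (n_draws, n_obs) pointwise log-likelihood matrix."""
    nat = model.to_natural(draws)
    D = draws.shape[0]

    # Dense random-effects design Z (n, q): participant blocks then condition.
    blocks = [(model.p_idx, model.n_p, "participant")]
    if model.crossed:
        blocks.append((model.c_idx, model.n_c, "condition"))
    q = 2 * sum(nb for _, nb, _ in blocks)
    Z = np.zeros((model.n, q))
    offset = 0
    for idx, nb, _ in blocks:
        Z[np.arange(model.n), offset + 2 * idx] = 1.0
        Z[np.arange(model.n), offset + 2 * idx + 1] = model.x
        offset += 2 * nb

    resid = model.y[None, :] - (
        nat["intercept"][:, None] + nat["beta"][:, None] * model.x[None, :]
    )
    sigma2 = nat["sd_residual"] ** 2
    loglik = np.empty((D, model.n))
    ZtZ = Z.T @ Z
    chunk = 256
    for s in range(0, D, chunk):
        e = min(s + chunk, D)
        m = e - s
        Ginv = np.zeros((m, q, q))
        offset = 0
        for _, nb, label in blocks:
            S = model._cov2(
                nat[f"sd_{label}_intercept"][s:e],
                nat[f"sd_{label}_slope"][s:e],
                nat[f"corr_{label}"][s:e],
            )
            Sinv = np.linalg.inv(S)
            for j in range(nb):
                Ginv[:, offset + 2 * j : offset + 2 * j + 2,
                     offset + 2 * j : offset + 2 * j + 2] = Sinv
            offset += 2 * nb
        A = ZtZ[None, :, :] / sigma2[s:e, None, None] + Ginv
        b = (resid[s:e] @ Z) / sigma2[s:e, None]
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, b[..., None])[..., 0]
        xi = rng.standard_normal((m, q))
        # u = mean + L^{-T} xi has covariance A^{-1}.
        u = mean + np.linalg.solve(np.swapaxes(L, -1, -2), xi[..., None])[..., 0]
        res_u = resid[s:e] - u @ Z.T
        loglik[s:e] = (
            -0.5 * (res_u**2) / sigma2[s:e, None]
            - 0.5 * np.log(sigma2[s:e, None])
            - 0.5 * _LOG2PI
        )
    return loglik


def fit_hierarchical(
    data: RegressionInput | pd.DataFrame,
    chains: int = 2,
    iterations: int = 10_000,
    warmup: int = 2_000,
    seed: int | None = None,
    condition_random_effect: bool = False,
    n_walkers: int = 24,
    x_col: str | None = None,
    y_col: str = "posterior_norm",
) -> RegressionResult:
    """Fit the hierarchical regression by ensemble MCMC on the marginal model.

    ``chains`` independent ensembles are run; ``iterations`` and ``warmup``
    count draws per chain, so each chain contributes ``iterations - warmup``
    retained posterior draws.  With ``condition_random_effect=True`` the
    crossed condition intercept/slope terms are added (the robustness
    variant).  Reproducible given ``seed``.
    """
    if isinstance(data, pd.DataFrame):
        if x_col is None:
            raise ValueError("x_col is required when passing a DataFrame")
        data = RegressionInput.from_frame(
            data,
            x_col=x_col,
            y_col=y_col,
            condition_col="condition" if condition_random_effect else None,
        )
    elif condition_random_effect and data.condition is None:
        raise ValueError("condition labels required for the condition random effect")
    if not condition_random_effect:
        data = RegressionInput(data.x, data.y, data.participant, None)
    if iterations <= warmup:
        raise ValueError("iterations must exceed warmup")

    model = _MixedModel(data)
    n_walkers = max(n_walkers, 2 * model.ndim + 2)
    n_keep = iterations - warmup
    warm_steps = max(200, -(-warmup // n_walkers))
    samp_steps = max(300, -(-n_keep // n_walkers))

    theta_map = _map_estimate(model)
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    chain_seeds = ss.spawn(chains + 1)
    re_rng = np.random.default_rng(chain_seeds[-1])

    all_draws = []
    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        p0 = theta_map[None, :] + 0.05 * rng.standard_normal((n_walkers, model.ndim))
        lp0 = model.log_posterior(p0)
        for i in np.flatnonzero(~np.isfinite(lp0)):
            for _ in range(100):
                cand = theta_map + 0.01 * rng.standard_normal(model.ndim)
                if np.isfinite(model.log_posterior(cand[None, :])[0]):
                    p0[i] = cand
                    break
        sampler = emcee.EnsembleSampler(
            n_walkers,
            model.ndim,
            model.log_posterior,
            vectorize=True,
            moves=[
                (emcee.moves.DEMove(), 0.8),
                (emcee.moves.DESnookerMove(), 0.2),
            ],
        )
        sampler.random_state = np.random.RandomState(
            int(chain_seeds[c].generate_state(1)[0])
        ).get_state()
        state = sampler.run_mcmc(p0, warm_steps, skip_initial_state_check=True)
        sampler.reset()
        sampler.run_mcmc(state, samp_steps, skip_initial_state_check=True)
        flat = sampler.get_chain().reshape(samp_steps * n_walkers, model.ndim)
        keep_idx = np.linspace(0, len(flat) - 1, n_keep).astype(int)
        all_draws.append(flat[keep_idx])
    theta = np.stack(all_draws)  # (chains, n_keep, ndim)

    draws: dict[str, np.ndarray] = {}
    nat = model.to_natural(theta.reshape(-1, model.ndim))
    for name in model.param_names:
        draws[name] = nat[name].reshape(chains, n_keep)

    rhats = {name: rhat(draws[name]) for name in model.param_names}
    converged = all(v <= 1.05 for v in rhats.values())
    if not converged:
        bad = {k: round(v, 3) for k, v in rhats.items() if v > 1.05}
        warnings.warn(
            f"hierarchical fit may not have converged; split-Rhat > 1.05 for {bad}",
            ConvergenceWarning,
        )

    loglik = _sample_random_effects_and_loglik(
        model, theta.reshape(-1, model.ndim), re_rng
    ).reshape(chains, n_keep, model.n)

    return RegressionResult(
        param_names=model.param_names,
        draws=draws,
        pointwise_loglik=loglik,
        rhat=rhats,
        n_obs=model.n,
        groupings=["participant", "condition"] if model.crossed else ["participant"],
        converged=converged,
    )


def summarize(result: RegressionResult, interval: str = "equal_tailed") -> pd.Series:
    """One report row: beta, 95% interval, Pr(beta>0) in %, delta_t, max Rhat."""
    lo, hi = result.cri_95("hdi" if interval == "hdi" else "equal_tailed")
    return pd.Series(
        {
            "beta": result.beta_mean,
            "cri_lower": lo,
            "cri_upper": hi,
            "pr_beta_gt_0": round(100.0 * result.pr_beta_gt_0, 2),
            "delta_t": result.delta_t,
            "rhat_max": max(result.rhat.values()),
            "converged": result.converged,
        }
    )
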