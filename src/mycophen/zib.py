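"""Zero-inflated binomial presence/detection model for fruiting censuses.

The response for survey ``i`` and species group ``j`` is the number of
distinct species detected, ``D[i,j]``, out of the ``N[j]`` species of the
group ever observed.  Each species is modelled as an independent
presence/detection pair: it truly fruits with probability ``p[i,j]`` and, if
fruiting, is found with probability ``d``.  Summing over the group's species
gives the binomial hierarchy

    X[i,j] ~ Binomial(N[j], p[i,j])        (latent fruiting species)
    D[i,j] ~ Binomial(X[i,j], d)           (detected among fruiting)

with ``logit p[i,j] = alpha[j] + sum_k beta[j,k] x[i,k]`` on standardized
climate covariates.  Failure to detect a species is thus a mixture of true
absence and overlooked presence — the zero inflation.

Fitting is Bayesian: vague Normal(0, 1e6) priors on the regression scale, a
flat Beta(1,1) prior on each detection probability, and a
Metropolis-within-Gibbs sampler that alternates (1) exact Gibbs imputation of
``X`` from its shifted-binomial full conditional, (2) a conjugate Beta update
of the detection probabilities, and (3) adaptive random-walk Metropolis on
each group's ``(alpha, beta)`` block.  Convergence is checked with the
Gelman-Rubin potential scale reduction factor over multiple chains.

Usage follows the Model/Results convention::

    model = ZIBModel(detections, covariates)
    res = model.fit(ZIBConfig.desk(seed=1))
    res.summary()
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import binom

from .io import CovariateTable, DetectionMatrix

__all__ = [
    "ZIBConfig",
    "ZIBModel",
    "ZIBResults",
    "LatentConditional",
    "presence_prob",
    "marginal_loglik",
    "latent_conditional",
    "sample_posterior",
    "summarize_posterior",
    "gelman_rubin",
]

_DETECTION_STRUCTURES = ("per_survey_shared", "per_survey_per_group",
                         "constant", "fixed_known")


@dataclass(frozen=True)
class ZIBConfig:
    """Sampler configuration.

    Defaults mirror the full-scale analysis (3 chains of 400,000 iterations,
    100,000 burn-in, thinning every 40th draw, Normal(0, 1e6) priors);
    :meth:`desk` gives a small-scale configuration suitable for tests and
    simulation studies.
    """

    n_chains: int = 3
    n_iter: int = 400_000
    thin: int = 40
    burn_in: int = 100_000
    prior_mean: float = 0.0
    prior_variance: float = 1_000_000.0
    detection_structure: str = "per_survey_shared"
    fixed_d: float | np.ndarray = 1.0
    seed: int = 0
    adapt_target_acceptance: float = 0.3
    rhat_threshold: float = 1.1
    init_scale: float = 1.0
    proposal_scale: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_variance <= 0:
            raise ValueError("prior_variance must be positive")
        if not (0 < self.adapt_target_acceptance < 1):
            raise ValueError("adapt_target_acceptance must be in (0,1)")
        if self.detection_structure not in _DETECTION_STRUCTURES:
            raise ValueError(
                f"detection_structure must be one of {_DETECTION_STRUCTURES}")

    @property
    def n_retained(self) -> int:
        """Retained draws per chain: burn-in discarded first, then thinned."""
        return (self.n_iter - self.burn_in) // self.thin

    @classmethod
    def desk(cls, **kwargs) -> "ZIBConfig":
        """Small-scale settings: 3 chains x 5,000 iterations, 1,000 burn-in,
        thin 4 (1,000 retained draws per chain)."""
        base = dict(n_chains=3, n_iter=5_000, thin=4, burn_in=1_000)
        base.update(kwargs)
        return cls(**base)


# ---------------------------------------------------------------------------
# model primitives

def presence_prob(alpha: float, beta: np.ndarray, x: np.ndarray) -> float:
    """Fruiting probability on the logistic scale: expit(alpha + beta.x).

    Overflow-safe; saturates smoothly toward 0/1 without producing NaN.
    """
    beta = np.asarray(beta, dtype=float)
    x = np.asarray(x, dtype=float)
    if beta.shape != x.shape:
        raise ValueError("beta and x must have the same length")
    return float(expit(alpha + beta @ x))


def marginal_loglik(D, N, p, d):
    """Log-likelihood of the detected count with the latent count summed out.

    A species is detected iff it fruits (prob p) and is then found (prob d),
    independently across the group's species, so marginally
    ``D ~ Binomial(N, p*d)``.  Broadcasts over array arguments.
    """
    D = np.asarray(D)
    N = np.asarray(N)
    if np.any(D > N) or np.any(D < 0):
        raise ValueError("require 0 <= D <= N")
    return binom.logpmf(D, N, np.asarray(p) * np.asarray(d))


@dataclass(frozen=True)
class LatentConditional:
    """Full conditional of the latent fruiting count X given D.

    ``X = D + Z`` with ``Z ~ Binomial(N - D, q)`` where
    ``q = p(1-d) / (1 - p d)`` — among the ``N - D`` undetected species, each
    was present-but-missed with probability q.  Support is {D, ..., N}.
    """

    D: int
    N: int
    q: float

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.D, self.N + 1)

    def pmf(self, x) -> np.ndarray:
        x = np.asarray(x)
        out = binom.pmf(x - self.D, self.N - self.D, self.q)
        return np.where((x >= self.D) & (x <= self.N), out, 0.0)

    def mean(self) -> float:
        return self.D + (self.N - self.D) * self.q

    def rvs(self, rng: np.random.Generator, size=None):
        return self.D + rng.binomial(self.N - self.D, self.q, size=size)


def latent_conditional(D: int, N: int, p: float, d: float) -> LatentConditional:
    """Distribution of the latent fruiting count given the detected count."""
    if not (0 <= D <= N):
        raise ValueError("require 0 <= D <= N")
    pd_ = p * d
    if pd_ >= 1.0:
        if D < N:
            raise ValueError("p*d = 1 with D < N is impossible data")
        return LatentConditional(D=D, N=N, q=0.0)
    q = p * (1.0 - d) / (1.0 - pd_)
    return LatentConditional(D=D, N=N, q=float(q))


def gelman_rubin(chains: Sequence[np.ndarray]) -> float:
    """Potential scale reduction factor (Brooks-Gelman corrected form).

    ``chains`` is a list of >= 2 equal-length draw sequences.  Two or more
    identical constant chains return 1.0 by convention (the 0/0 case).
    """
    arr = np.asarray([np.asarray(c, dtype=float) for c in chains])
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two chains")
    m, n = arr.shape
    if n < 2:
        raise ValueError("need at least two draws per chain")
    W = arr.var(axis=1, ddof=1).mean()
    B = n * arr.mean(axis=1).var(ddof=0) * m / (m - 1)
    if W == 0.0:
        return 1.0 if B == 0.0 else math.inf
    v_hat = (n - 1) / n * W + B / n
    r2 = (m + 1) / m * v_hat / W - (n - 1) / (m * n)
    return float(np.sqrt(max(r2, 0.0)))


def _rhat_columns(draws: np.ndarray) -> np.ndarray:
    """Vectorized PSRF for draws shaped (chains, draws, params)."""
    m, n, p = draws.shape
    W = draws.var(axis=1, ddof=1).mean(axis=0)
    B = n * draws.mean(axis=1).var(axis=0, ddof=0) * m / (m - 1)
    out = np.empty(p)
    zero = W == 0.0
    out[zero] = np.where(B[zero] == 0.0, 1.0, np.inf)
    nz = ~zero
    v_hat = (n - 1) / n * W[nz] + B[nz] / n
    r2 = (m + 1) / m * v_hat / W[nz] - (n - 1) / (m * n)
    out[nz] = np.sqrt(np.maximum(r2, 0.0))
    return out


# ---------------------------------------------------------------------------
# model / results

class ZIBModel:
    """Zero-inflated binomial presence/detection model bound to census data.

    Parameters
    ----------
    detections
        Survey x group matrix of detected species counts with group totals.
    covariates
        Standardized covariate table aligned on the same surveys, or None for
        an intercept-only model.
    """

    def __init__(self, detections: DetectionMatrix,
                 covariates: CovariateTable | None = None):
        self.data = detections
        self.covariates = covariates
        if covariates is not None:
            if covariates.n_surveys != detections.n_surveys:
                raise ValueError("detections and covariates differ in surveys")
            self.exog = np.asarray(covariates.x, dtype=float)
            self.exog_names = list(covariates.names)
        else:
            self.exog = np.empty((detections.n_surveys, 0))
            self.exog_names = []
        self._A = np.column_stack(
            [np.ones(detections.n_surveys), self.exog])

    @classmethod
    def from_tables(cls, surveys, species, climate, grouping: str = "by_guild",
                    genera=None, windows=None) -> "ZIBModel":
        """Build the model directly from parsed input tables."""
        from . import io as _io
        kw = {} if windows is None else {"windows": windows}
        matrix = _io.build_detection_matrix(surveys, species, grouping=grouping,
                                            genera=genera)
        cov = _io.build_covariates(surveys, climate, **kw)
        return cls(matrix, cov)

    # -- likelihood pieces ---------------------------------------------------

    def loglike(self, alpha: np.ndarray, beta: np.ndarray, d) -> float:
        """Marginal log-likelihood (latent counts summed out)."""
        theta = np.column_stack([np.asarray(alpha, float),
                                 np.atleast_2d(beta)])
        p = expit(self._A @ theta.T)
        d_mat = self._broadcast_d(d)
        ll = marginal_loglik(self.data.D, self.data.N[None, :], p, d_mat)
        return float(ll.sum())

    def _broadcast_d(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        n, J = self.data.D.shape
        if d.ndim == 0:
            return np.broadcast_to(d, (n, J))
        if d.shape == (n,):
            return np.broadcast_to(d[:, None], (n, J))
        if d.shape == (n, J):
            return d
        raise ValueError(f"cannot broadcast detection values of shape {d.shape}")

    # -- sampling ------------------------------------------------------------

    def fit(self, config: ZIBConfig | None = None) -> "ZIBResults":
        """Run the Metropolis-within-Gibbs sampler and summarize the draws."""
        config = config or ZIBConfig()
        D = self.data.D
        N = self.data.N
        n, J = D.shape
        P = self._A.shape[1]  # intercept + covariates
        n_ret = config.n_retained
        struct = config.detection_structure

        if struct == "per_survey_shared":
            d_shape: tuple[int, ...] = (n,)
        elif struct == "per_survey_per_group":
            d_shape = (n, J)
        elif struct == "constant":
            d_shape = ()
        else:  # fixed_known
            d_shape = np.shape(np.asarray(config.fixed_d, dtype=float))

        alpha_draws = np.empty((config.n_chains, n_ret, J))
        beta_draws = np.empty((config.n_chains, n_ret, J, P - 1))
        d_draws = (None if struct == "fixed_known"
                   else np.empty((config.n_chains, n_ret) + d_shape))

        for chain in range(config.n_chains):
            self._run_chain(chain, config, alpha_draws, beta_draws, d_draws)

        return ZIBResults(model=self, config=config,
                          alpha_draws=alpha_draws, beta_draws=beta_draws,
                          d_draws=d_draws)

    def _run_chain(self, chain: int, cfg: ZIBConfig,
                   alpha_out: np.ndarray, beta_out: np.ndarray,
                   d_out: np.ndarray | None) -> None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, chain]))
        D = self.data.D
        N = self.data.N
        A = self._A
        n, J = D.shape
        P = A.shape[1]
        struct = cfg.detection_structure
        prior_var = cfg.prior_variance
        prior_mean = cfg.prior_mean

        # overdispersed start: regression block ~ Normal(0, init_scale^2)
        theta = rng.normal(0.0, cfg.init_scale, size=(J, P))
        X = D.copy()
        if struct == "fixed_known":
            d_cur = self._broadcast_d(cfg.fixed_d)
        elif struct == "constant":
            d_cur = np.float64(0.9)
        else:
            d_cur = np.full((n,) if struct == "per_survey_shared" else (n, J),
                            0.9)

        eta = A @ theta.T
        lp = self._block_logpost(theta, eta, X, N, prior_mean, prior_var)
        if not np.all(np.isfinite(lp)):
            raise RuntimeError("non-finite log-posterior at initialization")

        scales = np.full(J, cfg.proposal_scale)
        acc = np.zeros(J)
        batch = 50
        undetected = N[None, :] - D

        keep = 0
        for it in range(cfg.n_iter):
            p = expit(eta)
            d_mat = d_cur if (struct in ("per_survey_per_group", "fixed_known")
                              and np.ndim(d_cur) == 2) \
                else self._broadcast_d(d_cur)
            # 1) Gibbs imputation of latent fruiting counts
            pd_ = np.clip(p * d_mat, None, 1.0 - 1e-12)
            q = np.clip(p * (1.0 - d_mat) / (1.0 - pd_), 0.0, 1.0)
            X = D + rng.binomial(undetected, q)

            # 2) conjugate Beta(1,1) detection update over cells sharing a d
            miss = X - D
            if struct == "per_survey_shared":
                d_cur = rng.beta(1.0 + D.sum(axis=1), 1.0 + miss.sum(axis=1))
            elif struct == "per_survey_per_group":
                d_cur = rng.beta(1.0 + D, 1.0 + miss)
            elif struct == "constant":
                d_cur = rng.beta(1.0 + D.sum(), 1.0 + miss.sum())

            # 3) adaptive random-walk Metropolis on each group's block
            lp = self._block_logpost(theta, eta, X, N, prior_mean, prior_var)
            prop = theta + scales[:, None] * rng.standard_normal((J, P))
            eta_prop = A @ prop.T
            lp_prop = self._block_logpost(prop, eta_prop, X, N,
                                          prior_mean, prior_var)
            accept = np.log(rng.random(J)) < lp_prop - lp
            theta[accept] = prop[accept]
            eta[:, accept] = eta_prop[:, accept]
            acc += accept

            if it < cfg.burn_in and (it + 1) % batch == 0:
                rate = acc / batch
                scales *= np.exp(0.5 * (rate - cfg.adapt_target_acceptance))
                acc[:] = 0.0
            elif it == cfg.burn_in:
                acc[:] = 0.0  # adaptation frozen from here on

            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == cfg.thin - 1:
                alpha_out[chain, keep] = theta[:, 0]
                beta_out[chain, keep] = theta[:, 1:]
                if d_out is not None:
                    d_out[chain, keep] = d_cur
                keep += 1

    @staticmethod
    def _block_logpost(theta: np.ndarray, eta: np.ndarray, X: np.ndarray,
                       N: np.ndarray, prior_mean: float,
                       prior_var: float) -> np.ndarray:
        """Per-group log-posterior of the regression block given X.

        Binomial(X; N, expit(eta)) likelihood up to the X-only combinatorial
        constant, plus the Normal prior.
        """
        ll = (X * eta - N[None, :] * np.logaddexp(0.0, eta)).sum(axis=0)
        dev = theta - prior_mean
        return ll - 0.5 * (dev * dev).sum(axis=1) / prior_var


@dataclass
class ZIBResults:
    """Posterior draws, convergence diagnostics and coefficient summaries."""

    model: ZIBModel
    config: ZIBConfig
    alpha_draws: np.ndarray          # (chains, draws, groups)
    beta_draws: np.ndarray           # (chains, draws, groups, covariates)
    d_draws: np.ndarray | None       # (chains, draws, ...) or None if fixed
    _summary: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def groups(self) -> list[str]:
        return self.model.data.groups

    @property
    def exog_names(self) -> list[str]:
        return self.model.exog_names

    def _scalar_draws(self) -> tuple[list[str], np.ndarray]:
        """All scalar parameters as (names, draws(chains, n, params))."""
        m, n, J = self.alpha_draws.shape
        K = self.beta_draws.shape[3]
        cols = [self.alpha_draws.reshape(m, n, J),
                self.beta_draws.reshape(m, n, J * K)]
        names = [f"alpha[{g}]" for g in self.groups]
        names += [f"beta[{g},{c}]" for g in self.groups
                  for c in self.exog_names]
        if self.d_draws is not None:
            flat = self.d_draws.reshape(m, n, -1)
            cols.append(flat)
            if flat.shape[2] == 1:
                names.append("d")
            elif self.d_draws.ndim == 3:
                names += [f"d[{i}]" for i in range(flat.shape[2])]
            else:
                names += [f"d[{i},{g}]" for i in range(self.d_draws.shape[2])
                          for g in self.groups]
        return names, np.concatenate(cols, axis=2)

    @property
    def rhat(self) -> pd.Series:
        names, draws = self._scalar_draws()
        return pd.Series(_rhat_columns(draws), index=names, name="rhat")

    @property
    def max_rhat(self) -> float:
        return float(self.rhat.max())

    @property
    def converged(self) -> bool:
        return self.max_rhat < self.config.rhat_threshold

    def summary(self) -> pd.DataFrame:
        """Coefficient table: posterior mean, 95%/99% equal-tailed credible
        intervals, Gelman-Rubin Rhat and interval-excludes-zero flags.

        Rows cover each group's intercept and covariate coefficients.
        """
        if self._summary is not None:
            return self._summary
        rhat = self.rhat
        rows = []
        for j, g in enumerate(self.groups):
            pooled = self.alpha_draws[:, :, j].ravel()
            rows.append(self._summ_row(g, "intercept", pooled,
                                       rhat[f"alpha[{g}]"]))
            for k, c in enumerate(self.exog_names):
                pooled = self.beta_draws[:, :, j, k].ravel()
                rows.append(self._summ_row(g, c, pooled,
                                           rhat[f"beta[{g},{c}]"]))
        self._summary = pd.DataFrame(rows)
        return self._summary

    @staticmethod
    def _summ_row(group: str, name: str, draws: np.ndarray,
                  rhat: float) -> dict:
        lo95, hi95 = np.percentile(draws, [2.5, 97.5])
        lo99, hi99 = np.percentile(draws, [0.5, 99.5])
        return {
            "group": group, "covariate": name,
            "mean": draws.mean(),
            "ci95_lo": lo95, "ci95_hi": hi95,
            "ci99_lo": lo99, "ci99_hi": hi99,
            "rhat": rhat,
            "sig95": bool(lo95 > 0 or hi95 < 0),
            "sig99": bool(lo99 > 0 or hi99 < 0),
        }

    def beta_interval(self, group: str, covariate: str,
                      level: float = 0.95) -> tuple[float, float]:
        j = self.groups.index(group)
        k = self.exog_names.index(covariate)
        pooled = self.beta_draws[:, :, j, k].ravel()
        tail = 100 * (1 - level) / 2
        lo, hi = np.percentile(pooled, [tail, 100 - tail])
        return float(lo), float(hi)

    def draws_frame(self) -> pd.DataFrame:
        """All retained draws, one row per (chain, draw), one column per
        scalar parameter — the exportable posterior sample."""
        names, draws = self._scalar_draws()
        m, n, p = draws.shape
        out = pd.DataFrame(draws.reshape(m * n, p), columns=names)
        out.insert(0, "chain", np.repeat(np.arange(m), n))
        out.insert(1, "draw", np.tile(np.arange(n), m))
        return out

    def save(self, draws_path: str | Path, summary_path: str | Path) -> None:
        self.draws_frame().to_csv(draws_path, index=False)
        self.summary().to_csv(summary_path, index=False)


def sample_posterior(matrix: DetectionMatrix,
                     covariates: CovariateTable | None,
                     config: ZIBConfig) -> ZIBResults:
    """Functional entry point: fit the ZIB model to a detection matrix."""
    return ZIBModel(matrix, covariates).fit(config)


def summarize_posterior(results: ZIBResults) -> pd.DataFrame:
    """Coefficient table with credible intervals and significance flags."""
    return results.summary()
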