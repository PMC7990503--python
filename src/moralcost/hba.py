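"""Hierarchical Bayesian estimation of the social-utility choice models.

Every model is fit with the same hierarchy: each subject's raw parameter
vector z_s (one entry per utility parameter plus the softmax temperature)
is drawn from independent group-level normals, z_sk ~ Normal(mu_k,
sigma_k), and mapped to its bounded support through a probit squashing,

    param = lower + (upper - lower) * Phi(z),

with utilities on [-20, 20] and tau on [0, 10]. Priors: mu_k ~ Normal(0, 1)
and sigma_k ~ half-Normal(1) on the raw scale. All group- and
individual-level parameters are estimated jointly by Hamiltonian Monte
Carlo on the non-centered parameterization (subject standard effects,
group means, group log-sds), with adapted diagonal mass and step size,
jittered trajectory lengths, and an extra exact Metropolis move along the
tau-utility scale ridge; see :func:`_sample_chains`.

Because each model's subjective value is linear in its utility parameters
(see :mod:`moralcost.models`), the per-trial likelihood is a Bernoulli
logit in tau * (offset + X @ u), and its gradient with respect to all
parameters is a handful of segment sums.

Convergence is assessed with split R-hat and models are compared by LOOIC
from Pareto-smoothed importance-sampling leave-one-out (both via arviz),
with the pointwise unit being the trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, logsumexp, ndtr, ndtri
from sklearn.base import BaseEstimator

from . import models

__all__ = [
    "MCMCConfig",
    "PRESETS",
    "FitResult",
    "HierarchicalChoiceModel",
    "fit_model",
    "compare_models",
    "check_convergence",
]


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 4
    warmup: int = 2000
    iterations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.chains < 1 or self.warmup < 1 or self.iterations < 1:
            raise ValueError("chains, warmup and iterations must be positive")


#: "paper" mirrors the reproduction defaults (4 chains, 1000 post-warmup
#: iterations after 2000 warmup); "test" is the reduced desk-scale preset
#: (the warmup stays at 1000 because step-size/mass adaptation needs it);
#: "acceptance" keeps 4 chains with the reduced schedule.
PRESETS: dict[str, MCMCConfig] = {
    "paper": MCMCConfig(chains=4, warmup=2000, iterations=1000),
    "test": MCMCConfig(chains=2, warmup=1000, iterations=500),
    "acceptance": MCMCConfig(chains=4, warmup=1000, iterations=500),
}

_RW_TARGET = 0.44  # canonical optimal acceptance for 1-d random-walk MH


def _as_config(mcmc) -> MCMCConfig:
    if mcmc is None:
        return PRESETS["paper"]
    if isinstance(mcmc, MCMCConfig):
        return mcmc
    if isinstance(mcmc, str):
        try:
            return PRESETS[mcmc]
        except KeyError:
            raise KeyError(f"unknown MCMC preset {mcmc!r}; have {sorted(PRESETS)}")
    if isinstance(mcmc, dict):
        return MCMCConfig(**mcmc)
    raise TypeError(f"cannot interpret MCMC config {mcmc!r}")


def _bounds_arrays(spec: models.ModelSpec):
    names = spec.all_parameter_names
    lo = np.array([spec.bounds[p][0] for p in names])
    hi = np.array([spec.bounds[p][1] for p in names])
    return names, lo, hi


@dataclass
class FitResult:
    """Posterior draws and summaries of one hierarchical fit."""

    model_id: int
    parameter_names: tuple[str, ...]  # includes "tau" (last)
    subject_ids: tuple[str, ...]
    config: MCMCConfig
    #: constrained individual parameters, (chains, draws, subjects, params)
    subject_draws: np.ndarray
    #: group-level location mapped to the constrained scale, (chains, draws, params)
    group_mean_draws: np.ndarray
    #: raw-scale group sds, (chains, draws, params)
    group_sd_draws: np.ndarray
    #: pointwise log-likelihood, (chains, draws, trials), trial order = input
    log_lik: np.ndarray
    rhat: pd.Series
    n_trials: int = 0
    _loo: object | None = field(default=None, repr=False)

    @property
    def n_draws(self) -> int:
        return self.subject_draws.shape[0] * self.subject_draws.shape[1]

    @property
    def individual_means(self) -> pd.DataFrame:
        """Posterior mean of each subject's constrained parameters."""
        m = self.subject_draws.mean(axis=(0, 1))
        return pd.DataFrame(m, index=list(self.subject_ids), columns=list(self.parameter_names))

    @property
    def group_means(self) -> pd.Series:
        return pd.Series(
            self.group_mean_draws.mean(axis=(0, 1)), index=list(self.parameter_names)
        )

    @property
    def max_rhat(self) -> float:
        return float(self.rhat.max())

    @property
    def loo(self):
        """arviz PSIS-LOO result (computed on first access)."""
        if self._loo is None:
            idata = az.from_dict(
                posterior={"mu": self.group_mean_draws},
                log_likelihood={"choice": self.log_lik},
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self._loo = az.loo(idata, pointwise=True)
        return self._loo

    @property
    def looic(self) -> float:
        """-2 * elpd from PSIS-LOO.

        PSIS returns NaN for observations whose log-likelihood is
        numerically constant across draws (importance weights with zero
        variance, e.g. trials every plausible parameter accepts with
        probability ~1); for those the leave-one-out density equals the
        ordinary log predictive density, which is substituted.
        """
        loo_i = np.asarray(self.loo.loo_i.values, dtype=float)
        bad = ~np.isfinite(loo_i)
        if bad.any():
            ll = self.log_lik.astype(np.float64).reshape(-1, self.log_lik.shape[-1])
            lpd = logsumexp(ll[:, bad], axis=0) - np.log(ll.shape[0])
            loo_i[bad] = lpd
        return float(-2.0 * loo_i.sum())

    def flat_subject_draws(self) -> np.ndarray:
        """(total draws, subjects, params) constrained draws."""
        c, d, s, k = self.subject_draws.shape
        return self.subject_draws.reshape(c * d, s, k)


def _prepare(dataset: pd.DataFrame, spec: models.ModelSpec):
    if "choice" not in dataset.columns:
        raise ValueError("dataset must carry a 'choice' column (0/1)")
    subjects = list(dict.fromkeys(dataset["subject_id"]))
    if len(subjects) < 2:
        raise ValueError("hierarchical fit needs at least 2 subjects")
    y = dataset["choice"].to_numpy(float)
    if np.any(~np.isin(y, (0.0, 1.0))):
        raise ValueError("choice column must be 0/1")

    subj_codes = pd.Categorical(dataset["subject_id"], categories=subjects).codes
    order = np.argsort(subj_codes, kind="stable")  # group trials by subject
    inv_order = np.argsort(order)
    offset, X = models.delta_sv_design(spec, dataset)
    offset = offset[order]
    X = X[order]
    sign = (2.0 * y - 1.0)[order]
    subj_idx = np.asarray(subj_codes)[order]
    starts = np.searchsorted(subj_idx, np.arange(len(subjects)))

    var = dataset.groupby("subject_id", observed=True)["choice"].var()
    flat = var[var == 0].index.tolist()
    if flat:
        warnings.warn(
            f"subjects with zero choice variance: {flat}; the hierarchy will "
            "shrink their parameters toward the group mean",
            stacklevel=3,
        )
    return subjects, offset, X, sign, subj_idx, starts, inv_order


def _sample_chains(spec, offset, X, sign, subj_idx, starts, n_subj, config, seed):
    """Run all chains of the MCMC, vectorized over chains.

    The state is the non-centered parameterization: per-subject standard
    effects zt (subject raw parameter = mu + sigma * zt), group means mu
    and group log-sds ls, all updated jointly by Hamiltonian Monte Carlo
    with a diagonal mass matrix and step size adapted during warmup. The
    non-centered hierarchy plus joint gradient updates is what lets the
    sampler move through the hierarchical funnel (sigma near zero) and the
    correlated subject-level directions that defeat random-walk schemes.

    On top of HMC, one cheap exact "scale-ridge" Metropolis move per
    iteration rescales every subject's utilities by a common factor 1/c
    and tau by c (models whose dSV offset is zero leave every logit, hence
    the whole likelihood, unchanged under this map), carrying the group
    locations along. Only the priors and the probit-transform Jacobian
    enter its acceptance ratio.

    Returns post-warmup draws of the raw subject parameters z, mu and
    sigma, each with a leading (chains, draws) shape.
    """
    names, lo, hi = _bounds_arrays(spec)
    K = len(names)
    S = n_subj
    C = config.chains
    width = hi - lo
    y01 = (sign + 1.0) / 2.0
    sqrt2pi = np.sqrt(2.0 * np.pi)
    rng = np.random.default_rng(seed)

    zt = rng.normal(0.0, 1.0, size=(C, S, K))
    mu = rng.normal(0.0, 0.5, size=(C, K))
    ls = rng.normal(-1.0, 0.3, size=(C, K))  # log group sds

    def u_grad(zt, mu, ls):
        """Potential (C,), its gradients, and the raw z, per chain."""
        sig = np.exp(ls)
        z = mu[:, None, :] + sig[:, None, :] * zt
        phi = np.exp(-0.5 * z**2) / sqrt2pi
        u = lo + width * ndtr(z)
        delta = offset + np.einsum("nk,cnk->cn", X, u[:, subj_idx, :-1])
        logit = u[:, subj_idx, -1] * delta
        ll = log_expit(sign * logit).sum(axis=1)
        resid = y01 - expit(logit)  # d loglik / d logit, (C, N)
        gu = np.empty((C, S, K))
        w = resid * u[:, subj_idx, -1]
        for k in range(K - 1):
            gu[:, :, k] = np.add.reduceat(w * X[:, k], starts, axis=1)
        gu[:, :, -1] = np.add.reduceat(resid * delta, starts, axis=1)
        dudz = width * phi  # (C, S, K)
        pot = (
            -ll
            + 0.5 * (zt**2).sum(axis=(1, 2))
            + 0.5 * (mu**2).sum(axis=1)
            + (0.5 * sig**2 - ls).sum(axis=1)
        )
        g_common = -gu * dudz  # d(-loglik)/dz
        g_zt = g_common * sig[:, None, :] + zt
        g_mu = g_common.sum(axis=1) + mu
        g_ls = (g_common * zt).sum(axis=1) * sig + sig**2 - 1.0
        return pot, g_zt, g_mu, g_ls, z, u

    D = S * K + 2 * K

    def flat(a_zt, a_mu, a_ls):
        return np.concatenate(
            [a_zt.reshape(C, S * K), a_mu, a_ls], axis=1
        )

    def split(th):
        return (
            th[:, : S * K].reshape(C, S, K),
            th[:, S * K : S * K + K],
            th[:, S * K + K :],
        )

    def pot_grad(th):
        a_zt, a_mu, a_ls = split(th)
        pot, g_zt, g_mu, g_ls, z, u = u_grad(a_zt, a_mu, a_ls)
        return pot, flat(g_zt, g_mu, g_ls), z, u

    th = flat(zt, mu, ls)
    inv_mass = np.full((C, D), 0.01)
    log_eps = np.full(C, np.log(0.01))
    max_leap = 64  # trajectory length jittered uniformly up to this
    wf_mean = th.copy()
    wf_m2 = np.zeros((C, D))
    wf_n = 0
    log_step_gridge = np.log(0.05)
    ridge_ok = bool(np.all(offset == 0.0))

    n_iter = config.warmup + config.iterations
    keep_z = np.empty((config.iterations, C, S, K))
    keep_mu = np.empty((config.iterations, C, K))
    keep_sigma = np.empty((config.iterations, C, K))

    # move each chain near its posterior mode first (plain gradient descent
    # with per-chain backtracking); random inits can start with saturated
    # logits whose huge gradients would defeat step-size adaptation
    pot, grad, z_raw, u = pot_grad(th)
    lr = np.full(C, 1e-6)
    for _ in range(150):
        th_try = th - lr[:, None] * grad
        pot_try, grad_try, _, _ = pot_grad(th_try)
        better = np.isfinite(pot_try) & (pot_try < pot)
        th = np.where(better[:, None], th_try, th)
        pot = np.where(better, pot_try, pot)
        grad = np.where(better[:, None], grad_try, grad)
        lr = np.where(better, lr * 1.5, lr * 0.5)

    mass_window_start = max(1, int(0.3 * config.warmup))
    for it in range(n_iter):
        adapt = it < config.warmup
        gamma = (it + 1) ** -0.6

        # ---- joint HMC update ----
        n_leap = int(rng.integers(max_leap // 4, max_leap + 1))
        eps = (np.exp(log_eps) * (0.9 + 0.2 * rng.random(C)))[:, None]
        mass = 1.0 / inv_mass
        p = rng.standard_normal((C, D)) * np.sqrt(mass)
        h0 = pot + 0.5 * (p**2 * inv_mass).sum(axis=1)
        th_c, grad_c = th, grad
        p = p - 0.5 * eps * grad_c
        for step in range(n_leap):
            th_c = th_c + eps * p * inv_mass
            pot_c, grad_c, z_c, u_c = pot_grad(th_c)
            p = p - (eps if step < n_leap - 1 else 0.5 * eps) * grad_c
        h1 = pot_c + 0.5 * (p**2 * inv_mass).sum(axis=1)
        d_h = np.where(np.isfinite(h1), h1 - h0, np.inf)
        acc_p = np.exp(np.minimum(0.0, -d_h))
        acc = rng.random(C) < acc_p
        th = np.where(acc[:, None], th_c, th)
        pot = np.where(acc, pot_c, pot)
        grad = np.where(acc[:, None], grad_c, grad)
        if adapt:
            log_eps += 2.0 * gamma * (acc_p - 0.85)
            if it == mass_window_start:
                # restart the variance estimator once chains are in the
                # typical set, so early transient draws don't skew the mass
                wf_mean = th.copy()
                wf_m2 = np.zeros((C, D))
                wf_n = 0
            wf_n += 1
            dv = th - wf_mean
            wf_mean += dv / wf_n
            wf_m2 += dv * (th - wf_mean)
            if wf_n >= 50 and it % 25 == 0:
                inv_mass = np.clip(wf_m2 / (wf_n - 1), 1e-6, 100.0)

        # ---- exact group-scale ridge move ----
        if ridge_ok:
            zt, mu, ls = split(th)
            sig = np.exp(ls)
            z = mu[:, None, :] + sig[:, None, :] * zt
            u = lo + width * ndtr(z)
            eps_g = np.exp(log_step_gridge) * rng.standard_normal(C)
            c_g = np.exp(eps_g)
            u_new = np.empty_like(u)
            u_new[:, :, :-1] = u[:, :, :-1] / c_g[:, None, None]
            u_new[:, :, -1] = u[:, :, -1] * c_g[:, None]
            loc = lo + width * ndtr(mu)
            loc_new = loc.copy()
            loc_new[:, :-1] /= c_g[:, None]
            loc_new[:, -1] *= c_g
            frac_z = (u_new - lo) / width
            frac_m = (loc_new - lo) / width
            with np.errstate(divide="ignore", invalid="ignore"):
                z_new = ndtri(frac_z)
                mu_new = ndtri(frac_m)
            valid = (
                np.all((frac_z > 0.0) & (frac_z < 1.0), axis=(1, 2))
                & np.all((frac_m > 0.0) & (frac_m < 1.0), axis=1)
                & np.all(np.isfinite(z_new), axis=(1, 2))
            )
            prior_diff = (
                -0.5
                * (
                    ((z_new - mu_new[:, None, :]) / sig[:, None, :]) ** 2
                    - ((z - mu[:, None, :]) / sig[:, None, :]) ** 2
                ).sum(axis=(1, 2))
                - 0.5 * (mu_new**2 - mu**2).sum(axis=1)
            )
            log_jac = (S + 1) * (2 - K) * eps_g + 0.5 * (
                (z_new**2 - z**2).sum(axis=(1, 2)) + (mu_new**2 - mu**2).sum(axis=1)
            )
            lp = np.where(valid, prior_diff + log_jac, -np.inf)
            acc_g = np.log(rng.random(C)) < lp
            if acc_g.any():
                zt_new = (z_new - mu_new[:, None, :]) / sig[:, None, :]
                zt = np.where(acc_g[:, None, None], zt_new, zt)
                mu = np.where(acc_g[:, None], mu_new, mu)
                th = flat(zt, mu, ls)
                pot, grad, z_raw, u = pot_grad(th)
            if adapt:
                log_step_gridge += gamma * (acc_g.astype(float).mean() - _RW_TARGET)

        if it >= config.warmup:
            j = it - config.warmup
            a_zt, a_mu, a_ls = split(th)
            a_sig = np.exp(a_ls)
            keep_z[j] = a_mu[:, None, :] + a_sig[:, None, :] * a_zt
            keep_mu[j] = a_mu
            keep_sigma[j] = a_sig

    # (iterations, C, ...) -> (C, iterations, ...)
    return (
        np.moveaxis(keep_z, 0, 1),
        np.moveaxis(keep_mu, 0, 1),
        np.moveaxis(keep_sigma, 0, 1),
    )


def fit_model(
    dataset: pd.DataFrame,
    model_id: int | str | models.ModelSpec = 5,
    mcmc: MCMCConfig | str | dict | None = None,
) -> FitResult:
    """Fit one utility model hierarchically by MCMC.

    Parameters
    ----------
    dataset : trial table with ``choice`` (0/1) recorded on every row.
    model_id : utility model (1-7, name, or ModelSpec).
    mcmc : MCMCConfig, preset name ("paper" | "test"), or dict.

    Returns a :class:`FitResult` with constrained posterior draws,
    individual posterior means, split R-hat per parameter, and the
    pointwise log-likelihood needed for LOOIC.
    """
    spec = models.get_model(model_id)
    config = _as_config(mcmc)
    subjects, offset, X, sign, subj_idx, starts, inv_order = _prepare(dataset, spec)
    names, lo, hi = _bounds_arrays(spec)
    S, K = len(subjects), len(names)
    width = hi - lo

    z, mu, sigma = _sample_chains(
        spec, offset, X, sign, subj_idx, starts, S, config, config.seed
    )  # (C, D, S, K), (C, D, K), (C, D, K)

    subject_draws = lo + width * ndtr(z)
    group_mean_draws = lo + width * ndtr(mu)

    # pointwise log-likelihood per draw, trial axis in the input row order
    C, D = z.shape[:2]
    n = len(dataset)
    log_lik = np.empty((C, D, n), dtype=np.float32)
    for c in range(C):
        for d in range(D):
            u = subject_draws[c, d]
            delta = offset + np.einsum("nk,nk->n", X, u[subj_idx, :-1])
            logit = u[subj_idx, -1] * delta
            log_lik[c, d] = log_expit(sign * logit)[inv_order]

    rhat = _rhat_table(subject_draws, group_mean_draws, sigma, names, subjects)

    return FitResult(
        model_id=spec.model_id,
        parameter_names=names,
        subject_ids=tuple(subjects),
        config=config,
        subject_draws=subject_draws,
        group_mean_draws=group_mean_draws,
        group_sd_draws=sigma,
        log_lik=log_lik,
        rhat=rhat,
        n_trials=n,
    )


def _rhat_table(subject_draws, group_mean_draws, sigma_draws, names, subjects):
    """Split R-hat for every monitored parameter, as a flat Series."""
    ds = az.from_dict(
        posterior={
            "mu": group_mean_draws,
            "sigma": sigma_draws,
            "subject": subject_draws,
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = az.rhat(ds)
    out = {}
    for i, p in enumerate(names):
        out[f"mu[{p}]"] = float(r["mu"].values[i])
        out[f"sigma[{p}]"] = float(r["sigma"].values[i])
    for si, s in enumerate(subjects):
        for ki, p in enumerate(names):
            out[f"{p}[{s}]"] = float(r["subject"].values[si, ki])
    return pd.Series(out, name="rhat")


def check_convergence(fit: FitResult, threshold: float = 1.1) -> dict:
    """Gelman-Rubin split-R-hat report: pass iff max R-hat <= threshold."""
    if fit.config.chains < 2:
        raise ValueError("R-hat needs at least 2 chains")
    worst = fit.rhat.idxmax()
    return {
        "max_rhat": fit.max_rhat,
        "worst_parameter": worst,
        "threshold": threshold,
        "passed": bool(fit.max_rhat <= threshold),
        "n_parameters": int(fit.rhat.size),
    }


#: LOOIC differences at least this large are conventionally decisive.
DECISIVE_DELTA = 10.0


def compare_models(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fitted models by LOOIC (lower is better).

    All fits must be of the same dataset (equal trial counts). The returned
    table carries each model's LOOIC, the difference to the best model, and
    whether that difference is decisive (>= 10).
    """
    if not fits:
        raise ValueError("no fits to compare")
    n = {f.n_trials for f in fits}
    if len(n) != 1:
        raise ValueError(f"fits cover different trial counts: {sorted(n)}")
    rows = [
        {"model_id": f.model_id, "looic": f.looic, "max_rhat": f.max_rhat} for f in fits
    ]
    tab = pd.DataFrame(rows).sort_values("looic", ignore_index=True)
    tab["delta_looic"] = tab["looic"] - tab["looic"].iloc[0]
    tab["decisive"] = tab["delta_looic"] >= DECISIVE_DELTA
    tab["winner"] = tab.index == 0
    return tab


class HierarchicalChoiceModel(BaseEstimator):
    """sklearn-style estimator wrapping the hierarchical MCMC fit.

    Parameters
    ----------
    model : int | str
        Utility model id (1-7) or registry name.
    chains, warmup, iterations, seed : MCMC settings.
    preset : optional preset name overriding the explicit settings
        ("paper" or "test").

    Fitted attributes
    -----------------
    result_ : FitResult
    individual_means_ : DataFrame (subjects x parameters)
    group_means_ : Series
    rhat_ : Series; looic_ : float; n_subjects_ : int
    """

    def __init__(
        self,
        model: int | str = 5,
        chains: int = 4,
        warmup: int = 2000,
        iterations: int = 1000,
        seed: int = 0,
        preset: str | None = None,
    ):
        self.model = model
        self.chains = chains
        self.warmup = warmup
        self.iterations = iterations
        self.seed = seed
        self.preset = preset

    def _config(self) -> MCMCConfig:
        if self.preset is not None:
            return replace(PRESETS[self.preset], seed=self.seed)
        return MCMCConfig(
            chains=self.chains,
            warmup=self.warmup,
            iterations=self.iterations,
            seed=self.seed,
        )

    def fit(self, X: pd.DataFrame, y=None):
        """Fit the model to a choice table (``y`` is ignored; the choices
        live in X's ``choice`` column)."""
        self.result_ = fit_model(X, self.model, self._config())
        self.individual_means_ = self.result_.individual_means
        self.group_means_ = self.result_.group_means
        self.rhat_ = self.result_.rhat
        self.looic_ = self.result_.looic
        self.n_subjects_ = len(self.result_.subject_ids)
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Acceptance probability per row from individual posterior means."""
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        spec = models.get_model(self.model)
        offset, xd = models.delta_sv_design(spec, X)
        means = self.individual_means_
        unknown = set(X["subject_id"]) - set(means.index)
        if unknown:
            raise ValueError(f"subjects not seen in fit: {sorted(unknown)[:5]}")
        pm = means.loc[X["subject_id"]].to_numpy()
        u, tau = pm[:, :-1], pm[:, -1]
        return np.asarray(
            models.accept_probability(tau, offset + np.einsum("nk,nk->n", xd, u), 0.0)
        )

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Most probable choice per row (1 = accept)."""
        return (self.predict_proba(X) >= 0.5).astype(int)

    def simulate(self, X: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
        """Simulate a choice table from the individual posterior means."""
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        params = {
            s: self.individual_means_.loc[s].to_dict() for s in self.result_.subject_ids
        }
        return models.simulate_choices(X, self.model, params, seed=seed)
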