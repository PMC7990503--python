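"""Parameter recovery and posterior predictive checks for fitted models.

Recovery: simulate one choice dataset per subject from the individual-level
posterior means of a fit, refit the same model with the same settings, and
correlate generating vs recovered individual posterior means per parameter.

PPC: regenerate choices from the joint posterior on the actual trial
sequences and compare per-subject per-condition predicted acceptance
proportions with the observed ones (Pearson r across subjects, one r per
condition). The within-sample variant conditions on the full fit; the
out-of-sample variant fits run 1 only and predicts run 2 from the
individual posterior means.

Predicted proportions can be computed by draw-wise Bernoulli simulation
(the fidelity path) or as the posterior-averaged analytic expectation of
the softmax acceptance probability (the default: identical in the
infinite-replication limit, faster and lower variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import pearsonr

from . import models
from .hba import FitResult, MCMCConfig, fit_model
from .task import CONDITIONS

__all__ = [
    "RecoveryReport",
    "PPCReport",
    "parameter_recovery",
    "ppc_within",
    "ppc_out_of_sample",
]


@dataclass
class RecoveryReport:
    """Per-parameter generating-vs-recovered correlations."""

    correlations: pd.Series
    generating: pd.DataFrame
    recovered: pd.DataFrame
    degenerate: list[str] = field(default_factory=list)
    seed: int = 0

    @property
    def min_r(self) -> float:
        return float(self.correlations.min())


@dataclass
class PPCReport:
    """Predicted vs actual per-condition acceptance, across subjects."""

    mode: str  # "within" | "out_of_sample"
    predicted: pd.DataFrame  # subjects x conditions
    actual: pd.DataFrame  # subjects x conditions
    correlations: pd.Series  # Pearson r per condition
    p_values: pd.Series

    @property
    def min_r(self) -> float:
        return float(self.correlations.min())


def _condition_of(df: pd.DataFrame) -> pd.Series:
    return df["scenario"].str[0] + df["conduct"].str[0]


def _acceptance_by_condition(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
    d = df[["subject_id"]].copy()
    d["condition"] = _condition_of(df).to_numpy()
    d["v"] = df[value_col].to_numpy()
    wide = d.pivot_table(index="subject_id", columns="condition", values="v", sort=False)
    return wide[[c for c in CONDITIONS if c in wide.columns]]


def parameter_recovery(
    fit: FitResult,
    design: pd.DataFrame,
    seed: int = 0,
    mcmc: MCMCConfig | str | dict | None = None,
) -> RecoveryReport:
    """Simulate from the fit's individual posterior means and refit.

    ``design`` is the trial table the simulation runs on (typically the one
    the fit used, without choices). ``mcmc`` defaults to the fit's own
    configuration. Parameters with (near-)zero variance across subjects in
    the generating values are reported as degenerate and get r = NaN.
    """
    gen = fit.individual_means
    params = {s: gen.loc[s].to_dict() for s in fit.subject_ids}
    sim = models.simulate_choices(design, fit.model_id, params, seed=seed)
    refit = fit_model(sim, fit.model_id, mcmc if mcmc is not None else fit.config)
    rec = refit.individual_means.loc[gen.index]

    corrs, degenerate = {}, []
    for p in fit.parameter_names:
        g, r = gen[p].to_numpy(), rec[p].to_numpy()
        if np.std(g) < 1e-12 or np.std(r) < 1e-12:
            degenerate.append(p)
            corrs[p] = np.nan
        else:
            corrs[p] = float(np.corrcoef(g, r)[0, 1])
    if degenerate:
        warnings.warn(
            f"recovery correlation undefined for zero-variance parameters: {degenerate}",
            stacklevel=2,
        )
    return RecoveryReport(
        correlations=pd.Series(corrs, name="recovery_r"),
        generating=gen,
        recovered=rec,
        degenerate=degenerate,
        seed=seed,
    )


def _predicted_acceptance(
    fit: FitResult,
    design: pd.DataFrame,
    n_reps: int,
    seed: int,
    method: str,
) -> pd.DataFrame:
    """Posterior-predictive acceptance proportion per subject x condition."""
    spec = models.get_model(fit.model_id)
    offset, x = models.delta_sv_design(spec, design)
    draws = fit.flat_subject_draws()  # (n_draws, S, K)
    n_draws = draws.shape[0]
    if n_reps > n_draws:
        warnings.warn(
            f"n_reps={n_reps} exceeds available draws ({n_draws}); clipping",
            stacklevel=3,
        )
        n_reps = n_draws
    rng = np.random.default_rng(seed)
    take = rng.choice(n_draws, size=n_reps, replace=False)

    sub_order = {s: i for i, s in enumerate(fit.subject_ids)}
    row_sub = design["subject_id"].map(sub_order).to_numpy()

    acc = np.zeros(len(design))
    for d in take:
        u = draws[d]  # (S, K)
        logit = u[row_sub, -1] * (offset + np.einsum("nk,nk->n", x, u[row_sub, :-1]))
        p = expit(logit)
        if method == "simulate":
            acc += rng.random(len(design)) < p
        else:
            acc += p
    out = design[["subject_id", "scenario", "conduct"]].copy()
    out["p_accept"] = acc / n_reps
    return _acceptance_by_condition(out, "p_accept")


def _ppc_report(pred: pd.DataFrame, actual: pd.DataFrame, mode: str) -> PPCReport:
    actual = actual.loc[pred.index, pred.columns]
    corrs, pvals = {}, {}
    for c in pred.columns:
        r, p = pearsonr(pred[c], actual[c])
        corrs[c], pvals[c] = float(r), float(p)
    return PPCReport(
        mode=mode,
        predicted=pred,
        actual=actual,
        correlations=pd.Series(corrs, name="ppc_r"),
        p_values=pd.Series(pvals, name="p"),
    )


def ppc_within(
    fit: FitResult,
    dataset: pd.DataFrame,
    n_reps: int = 200,
    seed: int = 0,
    method: str = "analytic",
) -> PPCReport:
    """Within-sample PPC: predict the fitted dataset from its own posterior.

    ``method`` is "analytic" (average the softmax acceptance probability
    over ``n_reps`` posterior draws) or "simulate" (draw Bernoulli choices
    per draw, the draw-wise fidelity path).
    """
    if method not in ("analytic", "simulate"):
        raise ValueError("method must be 'analytic' or 'simulate'")
    pred = _predicted_acceptance(fit, dataset, n_reps, seed, method)
    actual = _acceptance_by_condition(dataset, "choice")
    return _ppc_report(pred, actual, "within")


def ppc_out_of_sample(
    dataset: pd.DataFrame,
    model_id: int | str = 5,
    mcmc: MCMCConfig | str | dict | None = None,
    seed: int = 0,
    n_sim: int = 1,
) -> PPCReport:
    """Out-of-sample PPC: fit run 1, predict run 2 from posterior means.

    Simulates ``n_sim`` independent run-2 datasets from each subject's
    individual-level posterior mean (default one) and compares predicted
    to actual run-2 acceptance per condition.
    """
    if "run" not in dataset.columns:
        raise ValueError("dataset has no 'run' column")
    runs = set(dataset["run"])
    if runs != {1, 2}:
        raise ValueError(f"expected runs {{1, 2}}, got {sorted(runs)}")
    run1 = dataset[dataset["run"] == 1].reset_index(drop=True)
    run2 = dataset[dataset["run"] == 2].reset_index(drop=True)

    fit = fit_model(run1, model_id, mcmc)
    params = {s: fit.individual_means.loc[s].to_dict() for s in fit.subject_ids}
    acc = np.zeros(len(run2))
    for i in range(n_sim):
        sim = models.simulate_choices(run2, model_id, params, seed=seed + i)
        acc += sim["choice"].to_numpy()
    pred_tab = run2[["subject_id", "scenario", "conduct"]].copy()
    pred_tab["p_accept"] = acc / n_sim
    pred = _acceptance_by_condition(pred_tab, "p_accept")
    actual = _acceptance_by_condition(run2, "choice")
    return _ppc_report(pred, actual, "out_of_sample")
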