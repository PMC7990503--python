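"""Social-utility choice models for the bribe-taking task.

Seven competing utility functions assign a subjective value (SV) to
accepting or rejecting an offer; a softmax with inverse temperature tau
maps the SV difference to an acceptance probability.

* Model 1: weighted payoffs for proposer and power-holder, with a moral
  cost theta that devalues the power-holder's own payoff on Bribe trials
  (conniving with fraud).
* Model 2: adds gamma * |p_P - p_PH|, an aversion to absolute payoff
  inequity in the offer.
* Model 3: adds delta, an extra conniving cost in the Dyad scenario.
* Model 4: Models 2 + 3 combined.
* Model 5 (the winning model): like Model 2 plus omega * q * p_T in the
  Dyad scenario — the power-holder values the third party's payoff, so
  accepting a bribe that strips the third party carries an explicit moral
  cost of harming.
* Models 6-7: Fehr-Schmidt inequity aversion with condition-specific
  (Model 6) or agent-and-condition-specific (Model 7) alpha/beta; Model 7's
  Dyad form averages the proposer and third-party inequity terms with
  weight 0.5.

Every SV is linear in the utility parameters given the trial, so each model
is represented internally by a per-trial design vector ``x`` and offset
``c`` with ``SV = c + x . u``; this powers the vectorized likelihood and
the MCMC sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from .task import Trial

UTILITY_BOUNDS = (-20.0, 20.0)
TAU_BOUNDS = (0.0, 10.0)


@dataclass(frozen=True)
class ModelSpec:
    """Identity and parameter layout of one utility model."""

    model_id: int
    name: str
    parameter_names: tuple[str, ...]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        b = {p: UTILITY_BOUNDS for p in self.parameter_names}
        b["tau"] = TAU_BOUNDS
        object.__setattr__(self, "bounds", b)

    @property
    def all_parameter_names(self) -> tuple[str, ...]:
        """Utility parameters plus the softmax temperature."""
        return self.parameter_names + ("tau",)


_M67_ALPHAS = ("alpha_SC", "alpha_SB", "alpha_DC", "alpha_DB")
_M67_BETAS = ("beta_SC", "beta_SB", "beta_DC", "beta_DB")

MODELS: dict[int, ModelSpec] = {
    1: ModelSpec(1, "conniving-cost", ("beta_P", "beta_PH", "theta")),
    2: ModelSpec(2, "conniving-inequity", ("beta_P", "beta_PH", "theta", "gamma")),
    3: ModelSpec(3, "conniving-dyad-cost", ("beta_P", "beta_PH", "theta", "delta")),
    4: ModelSpec(
        4, "conniving-dyad-inequity", ("beta_P", "beta_PH", "theta", "delta", "gamma")
    ),
    5: ModelSpec(
        5, "third-party-harm", ("beta_P", "beta_PH", "theta", "omega", "gamma")
    ),
    6: ModelSpec(6, "fehr-schmidt", _M67_ALPHAS + _M67_BETAS),
    7: ModelSpec(
        7,
        "fehr-schmidt-three-person",
        (
            "alpha_SC",
            "alpha_SB",
            "beta_SC",
            "beta_SB",
            "alpha_P_DC",
            "beta_P_DC",
            "alpha_T_DB",
            "beta_T_DB",
        ),
    ),
}
MODELS_BY_NAME = {m.name: m for m in MODELS.values()}


def get_model(model: int | str | ModelSpec) -> ModelSpec:
    if isinstance(model, ModelSpec):
        return model
    if isinstance(model, str) and model in MODELS_BY_NAME:
        return MODELS_BY_NAME[model]
    try:
        return MODELS[int(model)]
    except (KeyError, ValueError, TypeError):
        raise KeyError(f"unknown model {model!r}; ids 1-7 or names {sorted(MODELS_BY_NAME)}")


def _trial_arrays(df: pd.DataFrame):
    r = df["reported_payoff"].to_numpy(float)
    o = df["offer_amount"].to_numpy(float)
    q = (df["conduct"] == "Bribe").to_numpy(float)
    dyad = (df["scenario"] == "Dyad").to_numpy(float)
    return r, o, q, dyad


def _choice_payoffs(df: pd.DataFrame, choice: str):
    """Vectorized payoffs_for_choice; p_T is 0 on Solo rows."""
    r, o, q, dyad = _trial_arrays(df)
    if choice == "accept":
        return r - o, o, dyad * (100.0 - r), q, dyad
    p_t = dyad * np.where(q == 1.0, r, 100.0 - r)
    return np.zeros_like(r), np.zeros_like(o), p_t, q, dyad


def _sv_terms(model_id: int, p_p, p_ph, p_t, q, dyad):
    """Per-trial offset and design vector so that SV = offset + X @ u."""
    n = p_p.shape[0]
    spec = MODELS[model_id]
    cols: dict[str, np.ndarray] = {}
    offset = np.zeros(n)
    if model_id in (1, 2, 3, 4, 5):
        cols["beta_P"] = p_p
        cols["beta_PH"] = p_ph
        cols["theta"] = -q * p_ph
        if model_id in (3, 4):
            cols["delta"] = -q * p_ph * dyad
        if model_id == 5:
            cols["omega"] = q * p_t * dyad
        if model_id in (2, 4, 5):
            cols["gamma"] = np.abs(p_p - p_ph)
    elif model_id == 6:
        offset = p_ph.copy()
        dis = np.maximum(p_p - p_ph, 0.0)  # disadvantageous inequity
        adv = np.maximum(p_ph - p_p, 0.0)
        cond = {
            "SC": (1 - dyad) * (1 - q),
            "SB": (1 - dyad) * q,
            "DC": dyad * (1 - q),
            "DB": dyad * q,
        }
        for c, mask in cond.items():
            cols[f"alpha_{c}"] = -mask * dis
            cols[f"beta_{c}"] = -mask * adv
    elif model_id == 7:
        offset = p_ph.copy()
        dis_p = np.maximum(p_p - p_ph, 0.0)
        adv_p = np.maximum(p_ph - p_p, 0.0)
        dis_t = np.maximum(p_t - p_ph, 0.0)
        adv_t = np.maximum(p_ph - p_t, 0.0)
        solo = 1 - dyad
        cols["alpha_SC"] = -solo * (1 - q) * dis_p
        cols["alpha_SB"] = -solo * q * dis_p
        cols["beta_SC"] = -solo * (1 - q) * adv_p
        cols["beta_SB"] = -solo * q * adv_p
        # Dyad: both agents' inequity terms, each weighted 0.5; the proposer
        # terms carry the DC-labelled parameters and the third-party terms
        # the DB-labelled ones, in both Dyad conditions.
        cols["alpha_P_DC"] = -0.5 * dyad * dis_p
        cols["beta_P_DC"] = -0.5 * dyad * adv_p
        cols["alpha_T_DB"] = -0.5 * dyad * dis_t
        cols["beta_T_DB"] = -0.5 * dyad * adv_t
    else:  # pragma: no cover - guarded by get_model
        raise KeyError(model_id)
    X = np.column_stack([cols[p] for p in spec.parameter_names])
    return offset, X


def sv_design(model: int | str | ModelSpec, df: pd.DataFrame, choice: str):
    """Offset and design matrix of the chosen option's SV for each row."""
    spec = get_model(model)
    if choice not in ("accept", "reject"):
        raise ValueError(f"choice must be 'accept' or 'reject', got {choice!r}")
    return _sv_terms(spec.model_id, *_choice_payoffs(df, choice))


def delta_sv_design(model: int | str | ModelSpec, df: pd.DataFrame):
    """Design of SV(accept) - SV(reject): ``dSV = offset + X @ u``."""
    off_a, x_a = sv_design(model, df, "accept")
    off_r, x_r = sv_design(model, df, "reject")
    return off_a - off_r, x_a - x_r


def _params_to_vector(spec: ModelSpec, params: dict) -> np.ndarray:
    try:
        u = np.array([float(params[p]) for p in spec.parameter_names])
    except KeyError as e:
        raise KeyError(f"parameter {e.args[0]!r} missing for model {spec.model_id}")
    lo, hi = UTILITY_BOUNDS
    if np.any(u < lo) or np.any(u > hi):
        raise ValueError(f"utility parameters out of bounds {UTILITY_BOUNDS}")
    return u


def subjective_value(
    model: int | str | ModelSpec, params: dict, trial: Trial, choice: str
) -> float:
    """SV of the chosen option under one model and parameter vector."""
    spec = get_model(model)
    u = _params_to_vector(spec, params)
    df = pd.DataFrame(
        [
            {
                "reported_payoff": trial.reported_payoff,
                "offer_amount": trial.offer_amount,
                "conduct": trial.conduct,
                "scenario": trial.scenario,
            }
        ]
    )
    offset, x = sv_design(spec, df, choice)
    return float(offset[0] + x[0] @ u)


def accept_probability(tau, sv_accept, sv_reject):
    """Softmax probability of accepting: ``expit(tau * (SV_a - SV_r))``.

    Computed in log-sum-exp form (via expit) so that |tau * SV| in the
    thousands neither overflows nor underflows.
    """
    tau = np.asarray(tau, float)
    if np.any(tau < TAU_BOUNDS[0]) or np.any(tau > TAU_BOUNDS[1]):
        raise ValueError(f"tau out of bounds {TAU_BOUNDS}")
    return expit(tau * (np.asarray(sv_accept, float) - np.asarray(sv_reject, float)))


def log_likelihood(
    dataset: pd.DataFrame, model: int | str | ModelSpec, params: dict
) -> np.ndarray:
    """Per-trial log-probability of the recorded choices under ``params``.

    ``dataset`` must carry a ``choice`` column (1 = accept, 0 = reject).
    A single parameter vector (including ``tau``) applies to every row.
    """
    spec = get_model(model)
    if "choice" not in dataset.columns:
        raise ValueError("dataset has no 'choice' column")
    y = dataset["choice"].to_numpy(float)
    if np.any(~np.isin(y, (0.0, 1.0))):
        raise ValueError("choice column must be 0/1")
    u = _params_to_vector(spec, params)
    tau = float(params["tau"])
    if not TAU_BOUNDS[0] <= tau <= TAU_BOUNDS[1]:
        raise ValueError(f"tau out of bounds {TAU_BOUNDS}")
    offset, x = delta_sv_design(spec, dataset)
    logit = tau * (offset + x @ u)
    if np.any(~np.isfinite(logit)):
        raise ValueError("non-finite SV encountered (NaN payoffs?)")
    sign = 2.0 * y - 1.0
    return log_expit(sign * logit)


def simulate_choices(
    design: pd.DataFrame,
    model: int | str | ModelSpec,
    params_by_subject: dict[str, dict] | list[dict],
    seed: int,
) -> pd.DataFrame:
    """Draw Bernoulli choices for every trial of a multi-subject design.

    ``params_by_subject`` maps subject_id to a parameter dict (including
    ``tau``), or is a list aligned with the subjects in order of first
    appearance. Returns a copy of ``design`` with a ``choice`` column.
    """
    spec = get_model(model)
    subjects = list(dict.fromkeys(design["subject_id"]))
    if isinstance(params_by_subject, list):
        if len(params_by_subject) != len(subjects):
            raise ValueError(
                f"got {len(params_by_subject)} parameter vectors for "
                f"{len(subjects)} subjects"
            )
        params_by_subject = dict(zip(subjects, params_by_subject))
    missing = [s for s in subjects if s not in params_by_subject]
    if missing:
        raise ValueError(f"no parameters for subjects {missing[:5]}")

    rng = np.random.default_rng(seed)
    out = design.copy()
    offset, x = delta_sv_design(spec, design)
    p = np.empty(len(design))
    for s in subjects:
        mask = (design["subject_id"] == s).to_numpy()
        pv = params_by_subject[s]
        u = _params_to_vector(spec, pv)
        tau = float(pv["tau"])
        p[mask] = expit(tau * (offset[mask] + x[mask] @ u))
    out["choice"] = (rng.random(len(design)) < p).astype(int)
    return out


def export_bounds() -> dict:
    """Parameter bounds per model, JSON-serializable."""
    return {
        m.model_id: {"name": m.name, "bounds": {k: list(v) for k, v in m.bounds.items()}}
        for m in MODELS.values()
    }
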