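"""Synthetic study generator: subject parameters, choices, neural patterns.

Emulates the study conditions end to end so that every downstream stage
(hierarchical fitting, model comparison, recovery, posterior predictive
checks, similarity/decoding) runs without any external data: 39 subjects,
144 trials each (36 offers x 4 conditions over 2 runs of 72), choices
generated from the winning third-party-harm model with individual
parameters drawn from normal distributions matching the reported group
means/SDs, and subject x voxel "contrast" matrices with plantable condition
effects and inter-subject behavior-brain coupling.

The neural patterns are pure stand-ins for extracted ROI contrast values:
no hemodynamics and no spatial smoothness, only the similarity/decoding
structure that the analyses consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import models, task

#: Group-level posterior means and SDs of the winning model's parameters,
#: used as the default generating population.
DEFAULT_POPULATION_PARAMS: dict[str, tuple[float, float]] = {
    "beta_P": (-0.88, 2.48),
    "beta_PH": (16.02, 2.47),
    "theta": (5.94, 4.28),
    "omega": (0.97, 0.82),
    "gamma": (-2.35, 2.23),
}

#: The softmax temperature is not reported; with the group-mean utilities a
#: fixed tau of 0.01 reproduces condition-wise acceptance rates in the
#: observed 60-85% band (see the calibration test).
DEFAULT_TAU = 0.01

DEFAULT_N_SUBJECTS = 39


@dataclass(frozen=True)
class PopulationSpec:
    """Generating population for a synthetic choice study."""

    n_subjects: int = DEFAULT_N_SUBJECTS
    params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_POPULATION_PARAMS)
    )
    tau: float | tuple[float, float] = DEFAULT_TAU
    model_id: int = 5
    seed: int = 0


@dataclass(frozen=True)
class PatternSpec:
    """Generating process for synthetic subject x voxel contrast maps.

    Each subject's Bribe / Control map is built from a subject-specific
    shared component (controls cross-condition pattern correlation), a
    population-level condition-effect direction (+/- half the effect in the
    two maps), a behavior-coupling component that embeds the subject's
    z-scored (theta, omega) into two fixed voxel directions, and iid
    Gaussian noise.
    """

    n_subjects: int = DEFAULT_N_SUBJECTS
    n_voxels: int = 200
    condition_effect: float = 1.0
    shared_signal: float = 1.0
    behavior_coupling: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0


@dataclass(frozen=True)
class PatternMatrix:
    """Subjects x voxels contrast values for one condition within one ROI."""

    subject_ids: tuple[str, ...]
    values: np.ndarray
    roi_label: str = ""
    contrast_label: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != len(self.subject_ids):
            raise ValueError("values must be (n_subjects, n_voxels)")
        if v.shape[1] < 2:
            raise ValueError("need at least 2 voxels")
        if np.any(~np.isfinite(v)):
            raise ValueError("pattern matrix contains non-finite values")
        object.__setattr__(self, "values", v)


def draw_population(spec: PopulationSpec) -> list[dict]:
    """Draw one parameter dict per subject from the group-level normals.

    Draws are independent across parameters and subjects and truncated
    (clipped) to the model bounds; tau is fixed (scalar spec) or drawn from
    a normal (mean, sd) truncated to [0, 10].
    """
    mspec = models.get_model(spec.model_id)
    unknown = set(spec.params) - set(mspec.parameter_names)
    if unknown:
        raise ValueError(f"parameters {sorted(unknown)} not in model {mspec.model_id}")
    if any(sd < 0 for _, sd in spec.params.values()):
        raise ValueError("population sds must be >= 0")
    if spec.n_subjects < 2:
        warnings.warn(
            "fewer than 2 subjects: downstream correlation analyses are undefined",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    lo, hi = models.UTILITY_BOUNDS
    out = []
    for _ in range(spec.n_subjects):
        pv = {}
        for name in mspec.parameter_names:
            m, sd = spec.params.get(name, (0.0, 0.0))
            pv[name] = float(np.clip(rng.normal(m, sd), lo, hi))
        if isinstance(spec.tau, tuple):
            tm, tsd = spec.tau
            pv["tau"] = float(np.clip(rng.normal(tm, tsd), *models.TAU_BOUNDS))
        else:
            pv["tau"] = float(spec.tau)
        out.append(pv)
    return out


def generate_choice_study(
    pop_spec: PopulationSpec | None = None,
    model_id: int | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Full synthetic study: trial design plus simulated choices.

    Returns the choice table and the generating per-subject parameters.
    ``seed`` (defaults to ``pop_spec.seed``) drives the design split, the
    parameter draws and the choice simulation through independent streams.
    """
    spec = pop_spec or PopulationSpec()
    if model_id is not None:
        spec = replace(spec, model_id=model_id)
    if seed is not None:
        spec = replace(spec, seed=seed)
    s_design, s_pop, s_choice = np.random.SeedSequence(spec.seed).spawn(3)

    offers = task.build_offer_set()
    design = task.expand_design(
        offers, spec.n_subjects, seed=int(s_design.generate_state(1)[0] % 2**31)
    )
    params = draw_population(replace(spec, seed=int(s_pop.generate_state(1)[0] % 2**31)))
    data = models.simulate_choices(
        design, spec.model_id, params, seed=int(s_choice.generate_state(1)[0] % 2**31)
    )
    return data, params


def generate_patterns(
    spec: PatternSpec, params: list[dict]
) -> tuple[PatternMatrix, PatternMatrix, dict]:
    """Synthetic Bribe / Control contrast maps with plantable structure.

    ``params`` supplies each subject's (theta, omega); with
    ``behavior_coupling`` > 0 the Bribe-minus-Control pattern difference
    embeds the z-scored (theta, omega), so inter-subject pattern distance
    tracks parameter distance. Returns the two matrices and a ground-truth
    record of the planted components.
    """
    if len(params) != spec.n_subjects:
        raise ValueError(
            f"got {len(params)} parameter vectors for n_subjects={spec.n_subjects}"
        )
    if spec.n_voxels < 2:
        raise ValueError("n_voxels must be >= 2")
    rng = np.random.default_rng(spec.seed)
    n, v = spec.n_subjects, spec.n_voxels

    theta = np.array([p["theta"] for p in params])
    omega = np.array([p["omega"] for p in params])

    def _z(x):
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    cond_dir = rng.standard_normal(v) / np.sqrt(v)
    embed_dirs = rng.standard_normal((2, v)) / np.sqrt(v)
    shared = spec.shared_signal * rng.standard_normal((n, v))
    coupling = spec.behavior_coupling * (
        np.outer(_z(theta), embed_dirs[0]) + np.outer(_z(omega), embed_dirs[1])
    )
    half_effect = 0.5 * spec.condition_effect * cond_dir
    noise_a = spec.noise_sd * rng.standard_normal((n, v))
    noise_b = spec.noise_sd * rng.standard_normal((n, v))

    bribe = shared + half_effect + 0.5 * coupling + noise_a
    control = shared - half_effect - 0.5 * coupling + noise_b

    ids = tuple(f"sub{i + 1:03d}" for i in range(n))
    truth = {
        "condition_direction": cond_dir,
        "embedding_directions": embed_dirs,
        "theta": theta,
        "omega": omega,
        "spec": spec,
    }
    return (
        PatternMatrix(ids, bribe, roi_label="synthetic", contrast_label="Bribe"),
        PatternMatrix(ids, control, roi_label="synthetic", contrast_label="Control"),
        truth,
    )


def acceptance_rates(data: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-condition acceptance proportions (long format)."""
    d = data.copy()
    d["condition"] = d["scenario"].str[0] + d["conduct"].str[0]
    g = (
        d.groupby(["subject_id", "condition"], observed=True)["choice"]
        .mean()
        .rename("acceptance")
        .reset_index()
    )
    return g
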