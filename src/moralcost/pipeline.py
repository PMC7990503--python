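"""End-to-end pipeline configuration and orchestration.

A PipelineConfig captures every seed and setting needed to regenerate a
run; ``run_pipeline`` executes design -> simulate (or load) -> fit ->
compare -> recover -> PPC -> similarity/decoding and archives each stage's
outputs (delimited tables + JSON reports embedding the configuration).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import hba, io, models, similarity, synth, validation

log = logging.getLogger("moralcost")


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str = "moralcost_run"
    choices_path: str | None = None  # load instead of simulate when set
    model_ids: tuple[int, ...] = (5,)
    fit_model_id: int = 5
    preset: str = "test"  # "paper" | "test" | "acceptance"
    seed: int = 0
    n_subjects: int = synth.DEFAULT_N_SUBJECTS
    tau: float = synth.DEFAULT_TAU
    n_voxels: int = 200
    condition_effect: float = 1.0
    shared_signal: float = 1.0
    behavior_coupling: float = 0.5
    noise_sd: float = 1.0
    n_perm: int = 5000
    ppc_reps: int = 4000
    run_neural: bool = True
    run_recovery: bool = True
    run_ppc: bool = True

    def __post_init__(self):
        if self.preset not in hba.PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; have {sorted(hba.PRESETS)}")
        bad = [m for m in self.model_ids if m not in models.MODELS]
        if bad:
            raise ValueError(f"unknown model ids {bad}; registry has 1-7")
        if self.fit_model_id not in models.MODELS:
            raise ValueError(f"unknown model id {self.fit_model_id}")

    @property
    def mcmc(self) -> hba.MCMCConfig:
        return replace(hba.PRESETS[self.preset], seed=self.seed)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


#: reduced settings suitable for smoke runs and the test preset
TEST_OVERRIDES = dict(n_perm=200, ppc_reps=200)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all requested stages; returns a summary dict (also archived).

    Stage failures abort with the stage name; outputs written before the
    failure are retained in the archive directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": asdict(config), "config_hash": config.config_hash()}
    stage = "design/simulate"
    try:
        if config.choices_path:
            data, report = io.validate_choice_table(config.choices_path)
            params = None
            log.info("loaded %d trials from %s", len(data), config.choices_path)
        else:
            pop = synth.PopulationSpec(
                n_subjects=config.n_subjects, tau=config.tau, seed=config.seed
            )
            data, params = synth.generate_choice_study(pop)
            _, report = io.validate_choice_table(data)
            log.info("simulated %d trials for %d subjects", len(data), config.n_subjects)
        io.write_table(data, out / "choices.csv")
        summary["validation"] = report
        rates = synth.acceptance_rates(data)
        io.write_table(rates, out / "acceptance_rates.csv")
        summary["acceptance_by_condition"] = (
            rates.groupby("condition")["acceptance"].mean().round(4).to_dict()
        )

        stage = "fit"
        fits = {}
        for m in config.model_ids:
            log.info("fitting model %d (%s preset)", m, config.preset)
            fits[m] = hba.fit_model(data, m, config.mcmc)
            io.save_fit(fits[m], out / f"fit_model{m}")
        fit = fits.get(config.fit_model_id) or hba.fit_model(
            data, config.fit_model_id, config.mcmc
        )
        summary["max_rhat"] = {m: f.max_rhat for m, f in fits.items()}

        stage = "compare"
        if len(fits) > 1:
            comparison = hba.compare_models(list(fits.values()))
            io.write_table(comparison, out / "model_comparison.csv")
            summary["winner"] = int(comparison.loc[0, "model_id"])

        if config.run_recovery:
            stage = "recover"
            rec = validation.parameter_recovery(
                fit, data.drop(columns=["choice"]), seed=config.seed + 1
            )
            io.write_json(
                {"correlations": rec.correlations, "degenerate": rec.degenerate},
                out / "recovery.json",
            )
            summary["recovery_r"] = rec.correlations.round(4).to_dict()

        if config.run_ppc:
            stage = "ppc"
            within = validation.ppc_within(
                fit, data, n_reps=config.ppc_reps, seed=config.seed + 2
            )
            oos = validation.ppc_out_of_sample(
                data, config.fit_model_id, config.mcmc, seed=config.seed + 3
            )
            io.write_json(
                {
                    "within_r": within.correlations,
                    "out_of_sample_r": oos.correlations,
                },
                out / "ppc.json",
            )
            summary["ppc_within_r"] = within.correlations.round(4).to_dict()
            summary["ppc_out_of_sample_r"] = oos.correlations.round(4).to_dict()

        if config.run_neural:
            stage = "neural"
            means = fit.individual_means
            theta = means["theta"].to_numpy()
            omega = means["omega"].to_numpy()
            if params is not None:  # synthetic: plant coupling with the true values
                theta = np.array([p["theta"] for p in params])
                omega = np.array([p["omega"] for p in params])
            pspec = synth.PatternSpec(
                n_subjects=len(means),
                n_voxels=config.n_voxels,
                condition_effect=config.condition_effect,
                shared_signal=config.shared_signal,
                behavior_coupling=config.behavior_coupling,
                noise_sd=config.noise_sd,
                seed=config.seed + 4,
            )
            plist = [{"theta": t, "omega": o} for t, o in zip(theta, omega)]
            pat_a, pat_b = synth.generate_patterns(pspec, plist)[:2]
            io.write_patterns(pat_a, out / "patterns_bribe.csv")
            io.write_patterns(pat_b, out / "patterns_control.csv")
            contrast = synth.PatternMatrix(
                pat_a.subject_ids,
                pat_a.values - pat_b.values,
                roi_label=pat_a.roi_label,
                contrast_label="Bribe-Control",
            )
            prdm = similarity.parameter_rdm(theta, omega, subject_ids=pat_a.subject_ids)
            nrdm = similarity.neural_rdm(contrast)
            io.write_rdm(prdm, out / "rdm_parameters.csv")
            io.write_rdm(nrdm, out / "rdm_neural.csv")
            rsa = similarity.isrsa(prdm, nrdm, n_perm=config.n_perm, seed=config.seed + 5)
            sim_res = similarity.pattern_similarity(
                pat_a, pat_b, n_perm=config.n_perm, seed=config.seed + 6
            )
            dec = similarity.loso_decode(
                pat_a, pat_b, n_perm=min(config.n_perm, 500), seed=config.seed + 7
            )
            summary["isrsa"] = {"rho": round(rsa["rho"], 4), "p": rsa["p"]}
            summary["pattern_similarity"] = {
                "mean_r": round(sim_res["mean_r"], 4),
                "p": sim_res["p"],
            }
            summary["decoding"] = {
                "accuracy": dec["forced_choice_accuracy"],
                "auc": round(dec["auc"], 4),
                "p": dec["p"],
            }
            io.write_json(
                {
                    "isrsa": summary["isrsa"],
                    "pattern_similarity": summary["pattern_similarity"],
                    "decoding": summary["decoding"],
                },
                out / "neural_similarity.json",
            )
    except Exception as e:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    io.write_json(summary, out / "summary.json")
    return summary
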