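"""Readers, writers and table validation binding the pipeline stages.

All interchange formats are plain delimited text with a header row, plus
JSON for structured reports: choice tables (one row per trial), pattern
matrices (first column ``subject_id``, remaining columns voxel values) and
RDMs (square table with subject ids as header and index).
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import task
from .synth import PatternMatrix

REQUIRED_CHOICE_COLUMNS = [
    "subject_id",
    "run",
    "scenario",
    "conduct",
    "reported_payoff",
    "offer_amount",
]


def read_table(path) -> pd.DataFrame:
    """Read a delimited text table, sniffing comma vs tab."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)


def validate_choice_table(path_or_df) -> tuple[pd.DataFrame, dict]:
    """Validate a choice table; returns (dataset, report).

    Schema and payoff invariants raise; softer issues (subjects missing a
    choice type in some condition, missing choices) are reported but the
    subjects are not dropped.
    """
    df = read_table(path_or_df) if not isinstance(path_or_df, pd.DataFrame) else path_or_df
    missing = [c for c in REQUIRED_CHOICE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"choice table missing columns: {missing}")
    task.validate_trial_table(df)

    report: dict = {"n_subjects": df["subject_id"].nunique(), "n_trials": len(df)}
    cond = df["scenario"].str[0] + df["conduct"].str[0]
    counts = (
        df.assign(condition=cond)
        .groupby(["subject_id", "condition"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    report["trials_per_condition"] = counts.to_dict()

    if "choice" in df.columns:
        bad = df["choice"].isna() | ~df["choice"].isin([0, 1])
        report["n_missing_choice"] = int(bad.sum())
        one_sided = (
            df.assign(condition=cond)
            .groupby(["subject_id", "condition"], observed=True)["choice"]
            .agg(lambda s: s.nunique() < 2)
        )
        flagged = sorted(one_sided[one_sided].index.get_level_values(0).unique())
        # mirrors the exclusion note for choice-specific analyses: flagged,
        # never dropped
        report["subjects_missing_choice_type"] = flagged
    else:
        report["n_missing_choice"] = len(df)
    return df, report


def read_patterns(path, roi_label: str = "", contrast_label: str = "") -> PatternMatrix:
    df = read_table(path)
    if df.columns[0] != "subject_id":
        raise ValueError("pattern matrix file must start with a subject_id column")
    ids = tuple(str(s) for s in df["subject_id"])
    return PatternMatrix(
        ids,
        df.iloc[:, 1:].to_numpy(float),
        roi_label=roi_label,
        contrast_label=contrast_label,
    )


def write_patterns(patterns: PatternMatrix, path) -> None:
    cols = [f"v{i + 1}" for i in range(patterns.values.shape[1])]
    df = pd.DataFrame(patterns.values, columns=cols)
    df.insert(0, "subject_id", list(patterns.subject_ids))
    write_table(df, path)


def write_rdm(rdm, path) -> None:
    df = pd.DataFrame(rdm.matrix, index=list(rdm.subject_ids), columns=list(rdm.subject_ids))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path)


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if is_dataclass(o) and not isinstance(o, type):
            return asdict(o)
        if isinstance(o, pd.Series):
            return o.to_dict()
        if isinstance(o, pd.DataFrame):
            return o.to_dict()
        return super().default(o)


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_Encoder) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def save_fit(fit, directory) -> None:
    """Archive a FitResult: draws as .npy-free delimited text + JSON metadata.

    Subject draws are flattened to a (chain, draw, subject, parameter) long
    table; group draws to (chain, draw, parameter) tables.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    C, D, S, K = fit.subject_draws.shape
    meta = {
        "model_id": fit.model_id,
        "parameter_names": list(fit.parameter_names),
        "subject_ids": list(fit.subject_ids),
        "config": asdict(fit.config),
        "rhat": fit.rhat.to_dict(),
        "max_rhat": fit.max_rhat,
        "looic": fit.looic,
        "n_trials": fit.n_trials,
        "shape": [C, D, S, K],
    }
    write_json(meta, d / "meta.json")
    fit.individual_means.rename_axis("subject_id").reset_index().to_csv(
        d / "individual_means.csv", index=False
    )
    gm = pd.DataFrame(
        fit.group_mean_draws.reshape(C * D, K), columns=list(fit.parameter_names)
    )
    gm.to_csv(d / "group_mean_draws.csv", index=False)
    gs = pd.DataFrame(
        fit.group_sd_draws.reshape(C * D, K), columns=list(fit.parameter_names)
    )
    gs.to_csv(d / "group_sd_draws.csv", index=False)
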