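"""Per-trial, per-modality labels derived from a sampled sequence.

For every modality a trial is a *standard* (intensity repeats), a *deviant*
(intensity alternates) or the run-initial *first* stimulus.  Deviants carry a
train length (number of standard repetitions since the previous deviant) and
its bin; every transition additionally carries a cross-modal predictability
label comparing the realized transition's probability across the two
contexts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from rovebold.markov import MODALITIES, ConditionSetting, CONDITIONS
from rovebold.sequences import ISI_SECONDS, STIM_DURATION_SECONDS, SequenceRun, Session

__all__ = [
    "TRAIN_BINS",
    "label_roles",
    "compute_train_lengths",
    "train_bin",
    "label_predictability",
    "annotate_run",
    "build_event_table",
    "validate_event_table",
    "write_schema_json",
]

#: the six train-length categories, in order; bin index = position in this tuple
TRAIN_BINS = ("1", "2", "3", "4-5", "6-8", ">8")


def train_bin(length: int) -> str:
    """Map a positive train length to its category."""
    if length < 1:
        raise ValueError(f"train length must be >= 1, got {length}")
    if length <= 3:
        return str(length)
    if length <= 5:
        return "4-5"
    if length <= 8:
        return "6-8"
    return ">8"


def train_bin_index(length: int) -> int:
    return TRAIN_BINS.index(train_bin(length))


def label_roles(observations: np.ndarray) -> np.ndarray:
    """Roles for a single modality's binary intensity sequence.

    Trial 0 is ``first``; trial t>0 is ``deviant`` iff the intensity differs
    from trial t-1, else ``standard``.
    """
    obs = np.asarray(observations)
    if obs.ndim != 1 or obs.shape[0] < 1:
        raise ValueError("observations must be a non-empty 1-D array")
    roles = np.empty(obs.shape[0], dtype="<U8")
    roles[0] = "first"
    changed = obs[1:] != obs[:-1]
    roles[1:] = np.where(changed, "deviant", "standard")
    return roles


def compute_train_lengths(roles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Train length and first-train flag per trial (NaN off deviants).

    For each deviant the train length is the number of standard trials since
    the previous deviant, or since trial 0 for the run's first train (flagged,
    so downstream analyses can exclude trains whose start was not observed).
    A deviant immediately following another deviant would have length 0 and
    stays unbinned (cannot occur on constrained sampler output).
    """
    roles = np.asarray(roles)
    n = roles.shape[0]
    lengths = np.full(n, np.nan)
    first_train = np.zeros(n, dtype=bool)
    prev_deviant: int | None = None
    for t in range(n):
        if roles[t] != "deviant":
            continue
        start = 0 if prev_deviant is None else prev_deviant
        lengths[t] = t - start - 1
        first_train[t] = prev_deviant is None
        prev_deviant = t
    return lengths, first_train


def label_predictability(
    states: np.ndarray, condition: ConditionSetting | str
) -> np.ndarray:
    """Predictability of each realized transition, per trial x modality.

    A transition (change or repetition) of modality m at trial t under
    context c (congruency of the other two modalities at t-1) is *predicted*
    when its conditional probability under c exceeds the probability of the
    same transition type under the opposite context, *mispredicted* when
    lower, *unpredictable* when equal.  Trial 0 has no transition -> ``n/a``.
    """
    if isinstance(condition, str):
        condition = CONDITIONS[condition]
    from rovebold.markov import states_to_obs

    obs = states_to_obs(np.asarray(states))
    n = obs.shape[0]
    out = np.full((n, 3), "n/a", dtype="<U13")
    p_cc, p_ci = condition.p_change_congruent, condition.p_change_incongruent
    prev, cur = obs[:-1], obs[1:]
    for m in MODALITIES:
        k = m.value
        others = [mm.value for mm in MODALITIES if mm is not m]
        congruent = prev[:, others[0]] == prev[:, others[1]]
        changed = prev[:, k] != cur[:, k]
        # probability of the realized transition type in this vs other context
        p_here = np.where(
            changed,
            np.where(congruent, p_cc, p_ci),
            np.where(congruent, 1 - p_cc, 1 - p_ci),
        )
        p_other = np.where(
            changed,
            np.where(congruent, p_ci, p_cc),
            np.where(congruent, 1 - p_ci, 1 - p_cc),
        )
        lab = np.where(
            np.isclose(p_here, p_other),
            "unpredictable",
            np.where(p_here > p_other, "predicted", "mispredicted"),
        )
        out[1:, k] = lab
    return out


_PREDICTABILITY_CODE = {"mispredicted": 1.0, "predicted": -1.0, "unpredictable": 0.0, "n/a": 0.0}

EVENT_COLUMNS = [
    "onset",
    "duration",
    "run",
    "condition",
    "trial",
    "modality",
    "intensity",
    "role",
    "context",
    "train_length",
    "train_bin",
    "first_train",
    "predictability",
    "mod_intensity",
    "mod_mismatch",
    "mod_predictability",
    "is_catch",
    "catch_query",
]


def annotate_run(
    run: SequenceRun,
    condition: ConditionSetting | str | None = None,
    run_index: int = 1,
    include_first_train: bool = True,
    predictability_scope: str = "all",
) -> pd.DataFrame:
    """Full annotation of one run as a long-format event table.

    One row per trial x modality.  ``include_first_train=False`` drops the
    train bin of each modality's first deviant (whose train head is trial 0).
    ``predictability_scope="deviants_only"`` zeroes the predictability
    modulator on standards.
    """
    if condition is None:
        condition = CONDITIONS[run.condition_id]
    elif isinstance(condition, str):
        condition = CONDITIONS[condition]
    if predictability_scope not in ("all", "deviants_only"):
        raise ValueError("predictability_scope must be 'all' or 'deviants_only'")

    obs = run.observations
    n = run.n_trials
    pred = label_predictability(run.states, condition)
    catch = dict(run.catch_trials)
    records: list[dict] = []
    for m in MODALITIES:
        k = m.value
        roles = label_roles(obs[:, k])
        lengths, first_flags = compute_train_lengths(roles)
        others = [mm.value for mm in MODALITIES if mm is not m]
        for t in range(n):
            role = roles[t]
            context = "n/a"
            if t > 0:
                context = (
                    "congruent"
                    if obs[t - 1, others[0]] == obs[t - 1, others[1]]
                    else "incongruent"
                )
            length = lengths[t]
            binned = (
                not np.isnan(length)
                and length >= 1
                and (include_first_train or not first_flags[t])
            )
            p_lab = pred[t, k]
            mod_pred = _PREDICTABILITY_CODE[p_lab]
            if predictability_scope == "deviants_only" and role != "deviant":
                mod_pred = 0.0
            records.append(
                {
                    "onset": round(t * ISI_SECONDS, 4),
                    "duration": STIM_DURATION_SECONDS,
                    "run": run_index,
                    "condition": condition.id,
                    "trial": t,
                    "modality": m.name,
                    "intensity": "high" if obs[t, k] else "low",
                    "role": role,
                    "context": context,
                    "train_length": length if binned else np.nan,
                    "train_bin": train_bin(int(length)) if binned else "n/a",
                    "first_train": bool(first_flags[t]),
                    "predictability": p_lab,
                    "mod_intensity": 0.0 if t == 0 else (1.0 if obs[t, k] else -1.0),
                    "mod_mismatch": 0.0
                    if t == 0
                    else (1.0 if role == "deviant" else -1.0),
                    "mod_predictability": 0.0 if t == 0 else mod_pred,
                    "is_catch": t in catch,
                    "catch_query": catch.get(t, "n/a"),
                }
            )
    df = pd.DataFrame.from_records(records, columns=EVENT_COLUMNS)
    return df.sort_values(["trial", "modality"], kind="stable").reset_index(drop=True)


def build_event_table(session: Session, **kwargs) -> pd.DataFrame:
    """Annotate all runs of a session into one event table."""
    frames = [
        annotate_run(run, run_index=r, **kwargs)
        for r, run in enumerate(session.runs, start=1)
    ]
    df = pd.concat(frames, ignore_index=True)
    validate_event_table(df)
    return df


_SCHEMA = {
    "columns": EVENT_COLUMNS,
    "dtypes": {
        "onset": "float",
        "duration": "float",
        "run": "int",
        "trial": "int",
        "train_length": "float (NaN when undefined)",
    },
    "categorical": {
        "condition": ["C1", "C2", "C3"],
        "modality": ["A", "S", "V"],
        "intensity": ["low", "high"],
        "role": ["first", "standard", "deviant"],
        "context": ["congruent", "incongruent", "n/a"],
        "train_bin": list(TRAIN_BINS) + ["n/a"],
        "predictability": ["predicted", "mispredicted", "unpredictable", "n/a"],
        "catch_query": ["A", "S", "V", "n/a"],
    },
    "modulators": {
        "mod_intensity": "+1 high, -1 low, 0 at trial 0",
        "mod_mismatch": "+1 deviant, -1 standard, 0 at trial 0",
        "mod_predictability": "+1 mispredicted, -1 predicted, 0 unpredictable / trial 0",
    },
}


def validate_event_table(df: pd.DataFrame) -> None:
    """Raise ValueError on schema violations."""
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    for col, allowed in _SCHEMA["categorical"].items():
        bad = set(df[col].astype(str).unique()) - set(allowed)
        if bad:
            raise ValueError(f"column {col!r} has illegal values: {sorted(bad)}")
    for col in ("mod_intensity", "mod_mismatch", "mod_predictability"):
        if not df[col].isin([-1.0, 0.0, 1.0]).all():
            raise ValueError(f"modulator column {col!r} must be in {{-1, 0, 1}}")


def write_schema_json(path: str | Path) -> None:
    Path(path).write_text(json.dumps(_SCHEMA, indent=2) + "\n")


def write_events_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV dump of an annotated event table."""
    df.to_csv(path, sep="\t", index=False, na_rep="n/a", float_format="%.4f")
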