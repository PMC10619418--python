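"""Constrained sampling and validation of tri-modal roving sequences.

A run is a 400-trial realization of the condition's Markov chain with a
minimum-one-repetition constraint (a modality that just changed intensity may
not change again on the next transition).  Runs are accepted only if their
empirical change statistics stay within configured tolerances of the nominal
probabilities; sessions bundle six runs with per-run conditions and catch
trials.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from rovebold.markov import (
    CONDITIONS,
    MODALITIES,
    ConditionSetting,
    Modality,
    TransitionMatrix,
    build_transition_matrix,
    states_to_obs,
)

__all__ = [
    "ToleranceSpec",
    "SequenceRun",
    "Session",
    "SequenceStats",
    "ValidationReport",
    "SamplingError",
    "sample_run",
    "compute_stats",
    "validate_stats",
    "sample_valid_run",
    "place_catch_trials",
    "build_session",
    "write_events_tsv",
]

ISI_SECONDS = 1.75
STIM_DURATION_SECONDS = 0.1


class SamplingError(RuntimeError):
    """Raised when constrained sampling or validated resampling gives up."""

    def __init__(self, message: str, best_report: "ValidationReport | None" = None):
        super().__init__(message)
        self.best_report = best_report


@dataclass(frozen=True)
class ToleranceSpec:
    """Acceptance tolerances for empirical sequence statistics.

    ``conditional_tol`` bounds the deviation of the context-conditional change
    probabilities, ``overall_tol`` the deviation of the overall change
    probability and of the high-intensity proportion from 0.5.

    ``pool_modalities`` controls whether statistics are pooled over the three
    modalities before checking (default) or checked per modality; at n=400 the
    per-modality conditional check at +/-0.005 has a vanishing per-draw
    acceptance probability, so pooling is the practical default.
    ``difference_mode`` switches the conditional check to the
    congruent-minus-incongruent difference instead of each conditional.
    """

    conditional_tol: float = 0.005
    overall_tol: float = 0.025
    unit: str = "run"  # statistics pooled per run (default) or per session
    pool_modalities: bool = True
    difference_mode: bool = False


@dataclass
class SequenceRun:
    """One sampled tri-modal sequence plus catch-trial placement."""

    condition_id: str
    seed: int | None
    states: np.ndarray
    catch_trials: list[tuple[int, str]] = field(default_factory=list)
    attempts: int = 1

    @property
    def n_trials(self) -> int:
        return int(self.states.shape[0])

    @property
    def observations(self) -> np.ndarray:
        """(n_trials, 3) binary intensity array in modality order A, S, V."""
        return states_to_obs(self.states)


@dataclass
class Session:
    """Six runs with condition assignment, derived deterministically from a seed."""

    participant_id: str
    master_seed: int
    runs: list[SequenceRun]
    condition_assignment: list[str]
    tolerance: ToleranceSpec

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def sample_run(
    matrix: TransitionMatrix,
    n_trials: int = 400,
    rng: np.random.Generator | None = None,
    enforce_min_repetition: bool = True,
    rejection_scope: str = "same",
    max_redraws: int = 1000,
) -> SequenceRun:
    """Sample one sequence from the chain with the min-one-repetition rule.

    The initial state is uniform over the 8 states.  When
    ``enforce_min_repetition`` is on, a proposed transition that changes a
    modality which changed on the immediately preceding transition is rejected
    and redrawn (``rejection_scope="same"``); with scope ``"any"`` every
    change proposal following any change is rejected (stricter variant).

    Raises
    ------
    SamplingError
        If a single trial needs more than ``max_redraws`` redraws.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    if rejection_scope not in ("same", "any"):
        raise ValueError("rejection_scope must be 'same' or 'any'")
    rng = np.random.default_rng() if rng is None else rng

    cum = np.cumsum(matrix.entries, axis=1)
    cum[:, -1] = 1.0  # guard against fp undershoot
    cum_rows = [row.tolist() for row in cum]

    states = np.empty(n_trials, dtype=np.int8)
    s = int(rng.integers(8))
    states[0] = s
    prev_changed_bits = 0  # XOR mask of the previous transition (0 = repetition)
    for t in range(1, n_trials):
        row = cum_rows[s]
        for attempt in range(max_redraws):
            u = rng.random()
            proposal = bisect_right(row, u)
            diff = s ^ proposal
            if enforce_min_repetition and diff and prev_changed_bits:
                if rejection_scope == "any" or diff == prev_changed_bits:
                    continue  # redraw
            break
        else:
            raise SamplingError(
                f"trial {t}: exceeded {max_redraws} redraws from state {s}"
            )
        prev_changed_bits = diff
        s = proposal
        states[t] = s
    return SequenceRun(condition_id=matrix.condition.id, seed=None, states=states)


@dataclass
class SequenceStats:
    """Empirical transition statistics of one or more pooled runs.

    ``change_counts``/``context_counts`` are (3, 2) arrays indexed by modality
    (A, S, V) and context (0=congruent, 1=incongruent).  ``high_counts`` and
    ``trial_counts`` are per-modality totals over all trials.  Conditional
    probabilities for empty context cells are NaN (undefined), never 0.
    """

    change_counts: np.ndarray
    context_counts: np.ndarray
    high_counts: np.ndarray
    trial_counts: np.ndarray

    def _safe_div(self, num, den):
        num = np.asarray(num, dtype=float)
        den = np.asarray(den, dtype=float)
        out = np.full(np.broadcast_shapes(num.shape, den.shape), np.nan)
        np.divide(num, den, out=out, where=den > 0)
        return out

    # --- per-modality statistics (arrays of length 3, order A, S, V) ---
    @property
    def p_change_given_congruent(self) -> np.ndarray:
        return self._safe_div(self.change_counts[:, 0], self.context_counts[:, 0])

    @property
    def p_change_given_incongruent(self) -> np.ndarray:
        return self._safe_div(self.change_counts[:, 1], self.context_counts[:, 1])

    @property
    def p_change_overall(self) -> np.ndarray:
        return self._safe_div(
            self.change_counts.sum(axis=1), self.context_counts.sum(axis=1)
        )

    @property
    def p_high(self) -> np.ndarray:
        return self._safe_div(self.high_counts, self.trial_counts)

    # --- pooled over modalities (scalars) ---
    def pooled(self, which: str) -> float:
        if which == "change_given_congruent":
            return float(
                self._safe_div(
                    self.change_counts[:, 0].sum(), self.context_counts[:, 0].sum()
                )
            )
        if which == "change_given_incongruent":
            return float(
                self._safe_div(
                    self.change_counts[:, 1].sum(), self.context_counts[:, 1].sum()
                )
            )
        if which == "change_overall":
            return float(
                self._safe_div(self.change_counts.sum(), self.context_counts.sum())
            )
        if which == "p_high":
            return float(self._safe_div(self.high_counts.sum(), self.trial_counts.sum()))
        raise ValueError(f"unknown statistic {which!r}")


def compute_stats(runs: SequenceRun | list[SequenceRun]) -> SequenceStats:
    """Empirical statistics over the transitions of one run or pooled runs.

    Transitions are t-1 -> t for t >= 2 (trial 0 has no transition); the
    context for each modality is read from the state at t-1.
    """
    if isinstance(runs, SequenceRun):
        runs = [runs]
    change_counts = np.zeros((3, 2), dtype=np.int64)
    context_counts = np.zeros((3, 2), dtype=np.int64)
    high_counts = np.zeros(3, dtype=np.int64)
    trial_counts = np.zeros(3, dtype=np.int64)
    for run in runs:
        obs = run.observations
        if obs.shape[0] < 2:
            raise ValueError("need at least 2 trials to compute transition stats")
        prev, cur = obs[:-1], obs[1:]
        changes = prev != cur  # (n-1, 3)
        for m in MODALITIES:
            k = m.value
            others = [mm.value for mm in MODALITIES if mm is not m]
            congruent = prev[:, others[0]] == prev[:, others[1]]  # (n-1,)
            for ctx, mask in ((0, congruent), (1, ~congruent)):
                context_counts[k, ctx] += int(mask.sum())
                change_counts[k, ctx] += int(changes[mask, k].sum())
        high_counts += obs.sum(axis=0)
        trial_counts += obs.shape[0]
    return SequenceStats(change_counts, context_counts, high_counts, trial_counts)


@dataclass
class Check:
    name: str
    value: float
    nominal: float
    tol: float

    @property
    def passed(self) -> bool:
        return np.isfinite(self.value) and abs(self.value - self.nominal) <= self.tol


@dataclass
class ValidationReport:
    checks: list[Check]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    @property
    def worst_excess(self) -> float:
        """Largest deviation-over-tolerance ratio (for best-so-far reporting)."""
        vals = [
            abs(c.value - c.nominal) / c.tol if np.isfinite(c.value) else np.inf
            for c in self.checks
        ]
        return max(vals) if vals else 0.0

    def to_dict(self) -> dict:
        return {
            c.name: {
                "value": c.value,
                "nominal": c.nominal,
                "tol": c.tol,
                "passed": c.passed,
            }
            for c in self.checks
        }


def validate_stats(
    stats: SequenceStats,
    condition: ConditionSetting,
    tol: ToleranceSpec | None = None,
) -> ValidationReport:
    """Check empirical statistics against the condition's nominal probabilities.

    Nominal conditionals come from the configured condition; the nominal
    overall change probability is the matrix-implied stationary marginal
    ``(p_cc + p_ci) / 2``; the nominal high-intensity proportion is 0.5.
    """
    tol = ToleranceSpec() if tol is None else tol
    checks: list[Check] = []
    p_cc, p_ci = condition.p_change_congruent, condition.p_change_incongruent
    if tol.pool_modalities:
        cong = stats.pooled("change_given_congruent")
        incong = stats.pooled("change_given_incongruent")
        if tol.difference_mode:
            checks.append(
                Check("cond_difference", cong - incong, p_cc - p_ci, tol.conditional_tol)
            )
        else:
            checks.append(Check("change|congruent", cong, p_cc, tol.conditional_tol))
            checks.append(
                Check("change|incongruent", incong, p_ci, tol.conditional_tol)
            )
        checks.append(
            Check(
                "change_overall",
                stats.pooled("change_overall"),
                condition.marginal_change,
                tol.overall_tol,
            )
        )
        checks.append(Check("p_high", stats.pooled("p_high"), 0.5, tol.overall_tol))
    else:
        cong = stats.p_change_given_congruent
        incong = stats.p_change_given_incongruent
        overall = stats.p_change_overall
        p_high = stats.p_high
        for m in MODALITIES:
            k = m.value
            if tol.difference_mode:
                checks.append(
                    Check(
                        f"cond_difference[{m.name}]",
                        cong[k] - incong[k],
                        p_cc - p_ci,
                        tol.conditional_tol,
                    )
                )
            else:
                checks.append(
                    Check(f"change|congruent[{m.name}]", cong[k], p_cc, tol.conditional_tol)
                )
                checks.append(
                    Check(
                        f"change|incongruent[{m.name}]",
                        incong[k],
                        p_ci,
                        tol.conditional_tol,
                    )
                )
            checks.append(
                Check(
                    f"change_overall[{m.name}]",
                    overall[k],
                    condition.marginal_change,
                    tol.overall_tol,
                )
            )
            checks.append(Check(f"p_high[{m.name}]", p_high[k], 0.5, tol.overall_tol))
    return ValidationReport(checks)


def sample_valid_run(
    condition: ConditionSetting | str,
    n_trials: int = 400,
    tol: ToleranceSpec | None = None,
    rng: np.random.Generator | None = None,
    max_attempts: int = 10_000,
    matrix: TransitionMatrix | None = None,
) -> SequenceRun:
    """Resample runs until one passes :func:`validate_stats`.

    Returns the first accepted run with its attempt count recorded; raises
    :class:`SamplingError` carrying the best-so-far report if ``max_attempts``
    is exhausted.
    """
    if isinstance(condition, str):
        condition = CONDITIONS[condition]
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    tol = ToleranceSpec() if tol is None else tol
    rng = np.random.default_rng() if rng is None else rng
    if matrix is None:
        matrix = build_transition_matrix(condition)
    best: ValidationReport | None = None
    for attempt in range(1, max_attempts + 1):
        run = sample_run(matrix, n_trials=n_trials, rng=rng)
        report = validate_stats(compute_stats(run), condition, tol)
        if report.passed:
            run.attempts = attempt
            return run
        if best is None or report.worst_excess < best.worst_excess:
            best = report
    raise SamplingError(
        f"no valid {condition.id} run in {max_attempts} attempts", best_report=best
    )


_CATCH_LETTER = {"A": "A", "S": "T", "V": "V"}  # T = "tactile" query for S


def place_catch_trials(
    n_trials: int = 400, n_catch: int = 6, rng: np.random.Generator | None = None
) -> list[tuple[int, str]]:
    """Place catch trials: unique indices in [1, n_trials), balanced queries.

    Queried modalities cycle through A, S, V as evenly as ``n_catch`` allows
    (2/2/2 for the default six), then the pairing is shuffled.
    """
    if n_catch >= n_trials:
        raise ValueError("n_catch must be smaller than n_trials")
    rng = np.random.default_rng() if rng is None else rng
    indices = rng.choice(np.arange(1, n_trials), size=n_catch, replace=False)
    modalities = [MODALITIES[i % 3].name for i in range(n_catch)]
    rng.shuffle(modalities)
    return sorted(zip((int(i) for i in indices), modalities))


def build_session(
    master_seed: int,
    conditions: list[str] | None = None,
    n_runs: int = 6,
    n_trials: int = 400,
    n_catch: int = 6,
    tol: ToleranceSpec | None = None,
    max_attempts: int = 10_000,
    participant_id: str = "sub-01",
) -> Session:
    """Assemble a session of validated runs with catch trials.

    Per-run seeds derive deterministically from ``master_seed`` via seed
    spawning, so identical inputs give identical sessions.  ``conditions``
    lists a condition id per run; ``None`` assigns conditions uniformly at
    random.
    """
    tol = ToleranceSpec() if tol is None else tol
    ss = np.random.SeedSequence(master_seed)
    assign_ss, *run_seeds = ss.spawn(n_runs + 1)
    if conditions is None:
        assign_rng = np.random.default_rng(assign_ss)
        conditions = [
            list(CONDITIONS)[int(i)] for i in assign_rng.integers(0, 3, size=n_runs)
        ]
    elif len(conditions) != n_runs:
        raise ValueError("conditions must list one condition per run")
    runs: list[SequenceRun] = []
    matrices = {cid: build_transition_matrix(CONDITIONS[cid]) for cid in set(conditions)}
    for r, cid in enumerate(conditions):
        rng = np.random.default_rng(run_seeds[r])
        run = sample_valid_run(
            CONDITIONS[cid],
            n_trials=n_trials,
            tol=tol,
            rng=rng,
            max_attempts=max_attempts,
            matrix=matrices[cid],
        )
        run.seed = master_seed
        run.catch_trials = place_catch_trials(n_trials, n_catch, rng)
        runs.append(run)
    return Session(
        participant_id=participant_id,
        master_seed=master_seed,
        runs=runs,
        condition_assignment=list(conditions),
        tolerance=tol,
    )


def write_events_tsv(session: Session, path: str | Path) -> None:
    """Write a long-format events table: one row per trial x modality.

    Columns: onset (s), duration, run, condition, modality, intensity,
    is_catch, catch_query.  Onsets restart at 0 within each run.
    """
    lines = [
        "onset\tduration\trun\tcondition\tmodality\tintensity\tis_catch\tcatch_query"
    ]
    for r, run in enumerate(session.runs, start=1):
        catch = dict(run.catch_trials)
        obs = run.observations
        for t in range(run.n_trials):
            is_catch = t in catch
            query = catch.get(t, "n/a")
            for m in MODALITIES:
                intensity = "high" if obs[t, m.value] else "low"
                lines.append(
                    f"{t * ISI_SECONDS:.2f}\t{STIM_DURATION_SECONDS:.2f}\t{r}\t"
                    f"{run.condition_id}\t{m.name}\t{intensity}\t"
                    f"{int(is_catch)}\t{query}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_session_json(session: Session, path: str | Path) -> None:
    """Provenance log: seed, assignment, tolerances, attempt counts."""
    payload = {
        "participant_id": session.participant_id,
        "master_seed": session.master_seed,
        "condition_assignment": session.condition_assignment,
        "tolerance": {
            "conditional_tol": session.tolerance.conditional_tol,
            "overall_tol": session.tolerance.overall_tol,
            "unit": session.tolerance.unit,
            "pool_modalities": session.tolerance.pool_modalities,
            "difference_mode": session.tolerance.difference_mode,
        },
        "runs": [
            {
                "condition": run.condition_id,
                "n_trials": run.n_trials,
                "attempts": run.attempts,
                "catch_trials": [[i, m] for i, m in run.catch_trials],
            }
            for run in session.runs
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
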