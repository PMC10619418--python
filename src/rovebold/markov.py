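"""Cross-modally conditioned 8-state transition model for tri-modal roving sequences.

Each trial presents one binary-intensity stimulus (low/high) in each of three
modalities — auditory (A), somatosensory (S) and visual (V).  The joint
stimulus pattern is one of 8 states.  From one trial to the next at most one
modality may change intensity; the probability of that change depends on
whether the *other two* modalities were congruent (same intensity) or
incongruent on the source trial.  A condition setting fixes the two
conditional change probabilities.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Modality",
    "MODALITIES",
    "ConditionSetting",
    "CONDITIONS",
    "TransitionMatrix",
    "encode_state",
    "decode_state",
    "context_congruency",
    "build_transition_matrix",
    "stationary_distribution",
    "StationaryResult",
    "N_STATES",
]

N_STATES = 8

#: bit weight of each modality in the state index (A is the most significant)
_BIT_WEIGHT = {"A": 4, "S": 2, "V": 1}


class Modality(enum.Enum):
    """The three stimulus modalities, in fixed encoding order (A, S, V)."""

    A = 0  # auditory
    S = 1  # somatosensory
    V = 2  # visual

    @property
    def bit(self) -> int:
        """Bit weight of this modality in the state index."""
        return _BIT_WEIGHT[self.name]


MODALITIES = (Modality.A, Modality.S, Modality.V)


def encode_state(obs: tuple[int, int, int]) -> int:
    """Encode a tri-modal observation triple ``(o_A, o_S, o_V)`` as a state index.

    The convention is ``index = 4*o_A + 2*o_S + o_V``.
    """
    o_a, o_s, o_v = obs
    for o in (o_a, o_s, o_v):
        if o not in (0, 1):
            raise ValueError(f"observation components must be 0 or 1, got {obs!r}")
    return 4 * o_a + 2 * o_s + o_v


def decode_state(index: int) -> tuple[int, int, int]:
    """Decode a state index 0-7 into the observation triple ``(o_A, o_S, o_V)``."""
    if not 0 <= index <= 7:
        raise ValueError(f"state index must be in 0..7, got {index}")
    return ((index >> 2) & 1, (index >> 1) & 1, index & 1)


# state (n,) -> (n, 3) observation array; vectorized decode used throughout
def states_to_obs(states: np.ndarray) -> np.ndarray:
    """Vectorized :func:`decode_state`: (n,) int array -> (n, 3) binary array."""
    states = np.asarray(states)
    return np.stack([(states >> 2) & 1, (states >> 1) & 1, states & 1], axis=-1)


def context_congruency(state: int, modality: Modality) -> str:
    """Congruency of the two modalities *other than* ``modality`` in ``state``.

    Returns ``"congruent"`` when both carry the same intensity, else
    ``"incongruent"``.
    """
    obs = decode_state(state)
    others = [obs[m.value] for m in MODALITIES if m is not modality]
    return "congruent" if others[0] == others[1] else "incongruent"


@dataclass(frozen=True)
class ConditionSetting:
    """Conditional single-modality change probabilities for one condition.

    Parameters
    ----------
    id :
        Condition label (``C1``, ``C2``, ``C3`` for the defaults).
    p_change_congruent :
        Probability that a modality changes intensity when the other two
        modalities were congruent on the previous trial.
    p_change_incongruent :
        Change probability under the incongruent context.
    """

    id: str
    p_change_congruent: float
    p_change_incongruent: float

    def __post_init__(self) -> None:
        pc, pi = self.p_change_congruent, self.p_change_incongruent
        if not (0.0 <= pc <= 1.0 and 0.0 <= pi <= 1.0):
            raise ValueError(f"{self.id}: probabilities must lie in [0, 1]")
        # all-congruent rows carry 3*p_cc change mass; mixed rows p_cc + 2*p_ci
        if 3.0 * max(pc, pi) > 1.0 + 1e-12 or pc + 2.0 * pi > 1.0 + 1e-12:
            raise ValueError(
                f"{self.id}: infeasible change probabilities "
                f"(p_cc={pc}, p_ci={pi}); some row would exceed total mass 1"
            )

    def p_change(self, context: str) -> float:
        if context == "congruent":
            return self.p_change_congruent
        if context == "incongruent":
            return self.p_change_incongruent
        raise ValueError(f"unknown context {context!r}")

    @property
    def marginal_change(self) -> float:
        """Per-modality change probability under the uniform stationary law."""
        return 0.5 * (self.p_change_congruent + self.p_change_incongruent)


CONDITIONS: dict[str, ConditionSetting] = {
    "C1": ConditionSetting("C1", 0.15, 0.025),
    "C2": ConditionSetting("C2", 0.025, 0.15),
    "C3": ConditionSetting("C3", 0.0875, 0.0875),
}


@dataclass
class TransitionMatrix:
    """8x8 row-stochastic matrix for one condition setting.

    Entries for transitions differing in two or more modalities are exactly
    zero; single-modality changes carry the context-conditional probability;
    the diagonal absorbs the remaining mass.
    """

    condition: ConditionSetting
    entries: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.shape != (N_STATES, N_STATES):
            raise ValueError("transition matrix must be 8x8")
        rows = self.entries.sum(axis=1)
        bad = np.nonzero(np.abs(rows - 1.0) > 1e-12)[0]
        if bad.size:
            raise ValueError(f"rows {bad.tolist()} do not sum to 1")

    def __getitem__(self, key):
        return self.entries[key]

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV with state indices as header and row labels."""
        path = Path(path)
        header = "state\t" + "\t".join(str(j) for j in range(N_STATES))
        lines = [header]
        for i in range(N_STATES):
            lines.append(
                str(i) + "\t" + "\t".join(format(v, ".17g") for v in self.entries[i])
            )
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, condition: ConditionSetting) -> "TransitionMatrix":
        rows = []
        for line in Path(path).read_text().strip().splitlines()[1:]:
            rows.append([float(v) for v in line.split("\t")[1:]])
        return cls(condition=condition, entries=np.asarray(rows))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "condition": {
                "id": self.condition.id,
                "p_change_congruent": self.condition.p_change_congruent,
                "p_change_incongruent": self.condition.p_change_incongruent,
            },
            "entries": self.entries.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TransitionMatrix":
        payload = json.loads(Path(path).read_text())
        cond = ConditionSetting(**payload["condition"])
        return cls(condition=cond, entries=np.asarray(payload["entries"]))


def build_transition_matrix(condition: ConditionSetting) -> TransitionMatrix:
    """Build the 8x8 transition matrix implied by a condition setting.

    For each source state the three single-modality neighbours receive the
    change probability conditional on the congruency of the *other two*
    modalities in the source state; multi-modality changes are exactly 0; the
    diagonal is the complement of the row's change mass.
    """
    P = np.zeros((N_STATES, N_STATES))
    for s in range(N_STATES):
        change_mass = 0.0
        for m in MODALITIES:
            t = s ^ m.bit  # flip exactly this modality
            p = condition.p_change(context_congruency(s, m))
            P[s, t] = p
            change_mass += p
        if change_mass > 1.0 + 1e-12:
            raise ValueError(
                f"row {s}: change mass {change_mass} exceeds 1 for condition "
                f"{condition.id}"
            )
        P[s, s] = 1.0 - change_mass
    return TransitionMatrix(condition=condition, entries=P)


@dataclass
class StationaryResult:
    """Stationary distribution of a transition matrix with uniqueness flag."""

    distribution: np.ndarray
    unique: bool


def stationary_distribution(
    matrix: TransitionMatrix | np.ndarray, tol: float = 1e-10
) -> StationaryResult:
    """Stationary distribution pi with ``pi @ P = pi``.

    Solved as the left null space of ``P - I``.  When the eigenvalue 1 has
    multiplicity greater than one (reducible chain) the result is flagged
    non-unique and one valid stationary vector is returned.
    """
    P = matrix.entries if isinstance(matrix, TransitionMatrix) else np.asarray(matrix)
    vals, vecs = np.linalg.eig(P.T)
    close = np.abs(vals - 1.0) < 1e-8
    if not close.any():
        raise np.linalg.LinAlgError("no eigenvalue 1 found; matrix not stochastic?")
    idx = np.nonzero(close)[0]
    v = np.real(vecs[:, idx[0]])
    pi = v / v.sum()
    if np.any(pi < -tol):
        raise np.linalg.LinAlgError("stationary vector has negative components")
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    resid = np.abs(pi @ P - pi).max()
    if resid > tol:
        raise np.linalg.LinAlgError(f"stationary residual {resid} exceeds {tol}")
    return StationaryResult(distribution=pi, unique=idx.size == 1)


def flip_permutation() -> np.ndarray:
    """Permutation matrix of the global low<->high relabeling (state s -> 7-s)."""
    Pi = np.zeros((N_STATES, N_STATES))
    for s in range(N_STATES):
        Pi[s, 7 - s] = 1.0
    return Pi
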