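"""N-back task sequences, response keys, and behavioral scoring.

The task presents a stream of letters; the subject judges whether the
current letter matches the one shown ``n`` positions earlier (YES/NO).
A 1-back block serves as the low-workload condition and a 2-back block
as the high-workload condition.  The two experiment stimulus sets were
designed so that their correct response sequences are identical, which
removes motor-response differences between conditions.

Behavioral measures:

* reaction time (RT) — seconds between letter onset and the response;
* accuracy rate (AR) — correct responses over scoreable responses.

The first ``n`` stimuli of a block are unscoreable (there is nothing to
compare against) and are excluded from AR's denominator.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import AlignmentError, GenerationError, InvalidInputError

__all__ = [
    "TaskConfig",
    "LetterSequence",
    "ResponseKey",
    "TrialRecord",
    "BehavioralSummary",
    "derive_response_key",
    "generate_sequence",
    "score_block",
    "assign_orders",
    "LOW_WORKLOAD_LETTERS",
    "HIGH_WORKLOAD_LETTERS",
    "TRAINING_LETTERS",
    "DISTRIBUTED_RESPONSE_KEY",
    "CONDITION_N_LEVEL",
]

#: Experiment stimulus sets (low = 1-back, high = 2-back).
LOW_WORKLOAD_LETTERS = "DAABEEDRRODHHRDSSELDD"
HIGH_WORKLOAD_LETTERS = "BAEAAEASHSAELEOBBBOSHS"

#: Training stimulus sets by n level (excluded from analysis).
TRAINING_LETTERS = {1: "EEIPP", 2: "OSOMLI"}

#: Response key distributed with the original stimulus set.  It does NOT
#: equal the key derived from the printed letters; both experiment blocks
#: independently derive the same key (the design intent), so the letters
#: are treated as authoritative.  Kept for documentation, never used for
#: scoring.
DISTRIBUTED_RESPONSE_KEY = "YNNNYNNNYNNNYNNYNNYN"

#: Block condition label -> n level.
CONDITION_N_LEVEL = {"low": 1, "high": 2}


@dataclass(frozen=True)
class TaskConfig:
    """Timing and stimulus parameters of one N-back session.

    Defaults reproduce the reference protocol: 3,000 ms stimulus
    timeout, 1–2 s inter-stimulus interval, 5 s rest between blocks,
    and a 10 s eyes-open rest before the first block.
    """

    n_level: int = 1
    stimulus_timeout_ms: float = 3000.0
    inter_stimulus_interval_s: tuple[float, float] = (1.0, 2.0)
    rest_between_blocks_s: float = 5.0
    rest_eyes_open_s: float = 10.0
    alphabet: str = string.ascii_uppercase

    def __post_init__(self) -> None:
        if self.n_level < 1:
            raise InvalidInputError("n_level must be >= 1")
        if self.stimulus_timeout_ms <= 0:
            raise InvalidInputError("stimulus_timeout_ms must be positive")
        lo, hi = self.inter_stimulus_interval_s
        if lo > hi or lo < 0:
            raise InvalidInputError("inter-stimulus interval range invalid")
        if not self.alphabet or not all(
            c in string.ascii_uppercase for c in self.alphabet
        ):
            raise InvalidInputError("alphabet must be non-empty uppercase letters")

    @property
    def stimulus_timeout_s(self) -> float:
        return self.stimulus_timeout_ms / 1000.0


@dataclass(frozen=True)
class LetterSequence:
    letters: str
    block_label: str = "low"
    n_level: int = 1

    def __post_init__(self) -> None:
        _check_letters(self.letters)

    def __len__(self) -> int:
        return len(self.letters)


@dataclass(frozen=True)
class ResponseKey:
    """Ordered Y/N match flags, one per scoreable stimulus."""

    entries: str

    def __post_init__(self) -> None:
        if any(c not in "YN" for c in self.entries):
            raise InvalidInputError("response key entries must be Y or N")

    def __len__(self) -> int:
        return len(self.entries)

    def __str__(self) -> str:
        return self.entries


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus presentation with its behavioral outcome.

    ``correct`` is ``None`` exactly when the stimulus is unscoreable
    (one of the first ``n_level`` letters of a block).  Timed-out
    scoreable trials have ``response_ts is None``, ``choice == "none"``
    and ``correct is False``.
    """

    participant_id: int
    block_label: str
    n_level: int
    trial_index: int
    letter: str
    onset_ts: float
    response_ts: Optional[float]
    choice: str  # {"match", "nonmatch", "none"}
    correct: Optional[bool]

    @property
    def rt(self) -> Optional[float]:
        """Reaction time in seconds (None for timeouts/unscoreable)."""
        if self.response_ts is None:
            return None
        return self.response_ts - self.onset_ts

    @property
    def scoreable(self) -> bool:
        return self.trial_index >= self.n_level


@dataclass(frozen=True)
class BehavioralSummary:
    """Per-block RT values and accuracy rate (AR)."""

    participant_id: int
    block_label: str
    rt_values: tuple[float, ...]
    n_correct: int
    n_scoreable: int

    @property
    def accuracy_rate(self) -> float:
        return self.n_correct / self.n_scoreable


def _check_letters(letters: str) -> None:
    if any(c not in string.ascii_uppercase for c in letters):
        bad = sorted({c for c in letters if c not in string.ascii_uppercase})
        raise InvalidInputError(f"non-letter symbols in sequence: {bad!r}")


def derive_response_key(sequence: str | LetterSequence, n_level: int) -> ResponseKey:
    """Apply the n-back rule to a letter sequence.

    Entry ``i`` is ``Y`` iff the letter at scoreable position ``i``
    equals the letter ``n_level`` positions earlier.  The key has
    ``max(0, len(sequence) - n_level)`` entries.
    """
    letters = sequence.letters if isinstance(sequence, LetterSequence) else sequence
    _check_letters(letters)
    if n_level < 1:
        raise InvalidInputError("n_level must be >= 1")
    entries = "".join(
        "Y" if letters[i] == letters[i - n_level] else "N"
        for i in range(n_level, len(letters))
    )
    return ResponseKey(entries)


def generate_sequence(
    config: TaskConfig, target_key: ResponseKey | str, seed: int
) -> LetterSequence:
    """Construct a letter sequence whose derived key equals ``target_key``.

    Deterministic given ``seed``.  Raises :class:`GenerationError` when
    the alphabet cannot realize the key (e.g. a single-letter alphabet
    with any ``N`` entry).
    """
    key = str(target_key)
    if not key:
        raise InvalidInputError("target_key must be nonempty")
    n = config.n_level
    rng = np.random.default_rng(seed)
    alphabet = sorted(set(config.alphabet))
    letters: list[str] = [alphabet[int(rng.integers(len(alphabet)))] for _ in range(n)]
    for i, flag in enumerate(key):
        anchor = letters[i]  # letter n positions before the new one
        if flag == "Y":
            letters.append(anchor)
        else:
            choices = [c for c in alphabet if c != anchor]
            if not choices:
                raise GenerationError(
                    "alphabet cannot produce a nonmatch: every letter equals "
                    f"{anchor!r}"
                )
            letters.append(choices[int(rng.integers(len(choices)))])
    seq = LetterSequence(
        "".join(letters),
        block_label="low" if n == 1 else "high",
        n_level=n,
    )
    assert str(derive_response_key(seq, n)) == key
    return seq


def score_block(
    trials: Sequence[TrialRecord],
    key: ResponseKey | str,
    config: TaskConfig | None = None,
) -> BehavioralSummary:
    """Score one block of trials against its response key.

    ``trials`` may include the leading unscoreable stimuli or only the
    scoreable ones; in either case the number of scoreable trials must
    equal the key length.  Timed-out trials count as incorrect and
    contribute no RT.
    """
    key = str(key)
    trials = list(trials)
    if any(
        trials[i].onset_ts >= trials[i + 1].onset_ts for i in range(len(trials) - 1)
    ):
        raise InvalidInputError("trials must be ordered by onset")
    scoreable = [t for t in trials if t.scoreable]
    if len(scoreable) != len(key):
        raise AlignmentError(
            f"scoreable trial count {len(scoreable)} != key length {len(key)}"
        )
    timeout_s = (config or TaskConfig()).stimulus_timeout_s
    rts: list[float] = []
    n_correct = 0
    for trial, flag in zip(scoreable, key):
        if trial.response_ts is None or trial.choice == "none":
            continue  # timeout: incorrect, no RT
        rt = trial.response_ts - trial.onset_ts
        if not 0.0 < rt <= timeout_s:
            raise InvalidInputError(
                f"trial {trial.trial_index}: rt {rt:.3f}s outside (0, "
                f"{timeout_s:g}]"
            )
        rts.append(rt)
        expected = "match" if flag == "Y" else "nonmatch"
        if trial.choice == expected:
            n_correct += 1
    first = trials[0]
    return BehavioralSummary(
        participant_id=first.participant_id,
        block_label=first.block_label,
        rt_values=tuple(rts),
        n_correct=n_correct,
        n_scoreable=len(key),
    )


def assign_orders(participant_ids: Sequence[int]) -> dict[int, str]:
    """Counterbalance block orders by participant-ID parity.

    Odd IDs run Order1 (low then high workload); even IDs run Order2
    (high then low).
    """
    if len(participant_ids) == 0:
        raise InvalidInputError("participant_ids must be nonempty")
    return {
        pid: ("Order1" if pid % 2 == 1 else "Order2") for pid in participant_ids
    }
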