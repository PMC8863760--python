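"""Trial sequencing for the two classical numerosity paradigms.

*Habituation/dishabituation*: one numerosity is presented repeatedly with a
different exemplar on every trial (so every continuous property changes
while the number stays constant), then a novel numerosity is shown.

*Simultaneous dual choice*: two stimulus sets differing in numerosity are
shown side by side on every trial, with the left/right assignment
counterbalanced across the session (|#left - #right| <= 1).

The sequencer is display-agnostic: it emits an ordered, fully determined
trial table that any presentation layer (or a printed protocol) can
execute, and exports/parses it as CSV so the realized session can be
archived next to the stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "StimulusSetRef",
    "TrialTiming",
    "Trial",
    "TrialSequence",
    "SessionLog",
    "build_habituation",
    "build_dual_choice",
    "export_log",
    "load_log",
    "set_ref_from_file",
]

MAX_SETS = 4


@dataclass(frozen=True)
class StimulusSetRef:
    """A named pool of exemplar stimuli sharing one numerosity."""

    name: str
    numerosity: int
    exemplars: tuple[str, ...]

    def __post_init__(self):
        if not self.exemplars:
            raise InvalidParameterError(f"stimulus set {self.name!r} has no exemplars")
        if self.numerosity < 1:
            raise InvalidParameterError("numerosity must be >= 1")


def set_ref_from_file(sset, name: str | None = None) -> StimulusSetRef:
    """Build a set reference from a loaded :class:`StimulusSetFile`."""
    exemplars = tuple(f"{sset.name}_{i:04d}" for i in range(len(sset.arrays)))
    return StimulusSetRef(
        name=name or sset.name,
        numerosity=sset.arrays[0].n,
        exemplars=exemplars,
    )


@dataclass(frozen=True)
class TrialTiming:
    presentation_s: float = 2.0
    pause_s: float = 1.0
    advance: str = "timed"  # timed | keyboard

    def __post_init__(self):
        if self.advance not in ("timed", "keyboard"):
            raise InvalidParameterError(f"unknown advance mode {self.advance!r}")


@dataclass(frozen=True)
class Trial:
    index: int
    phase: str  # habituation | dishabituation | choice
    stimuli: tuple[str, ...]  # exemplar id(s); (left, right) for dual choice
    sets: tuple[str, ...]  # set name per stimulus
    side_of_first: str | None  # 'left'/'right' for dual choice, else None
    presentation_s: float
    pause_s: float
    advance: str


@dataclass
class TrialSequence:
    paradigm: str
    trials: list[Trial]
    sets: dict[str, StimulusSetRef]
    seed: int

    def __post_init__(self):
        if len(self.sets) > MAX_SETS:
            raise InvalidParameterError(f"at most {MAX_SETS} stimulus sets per sequence")


@dataclass
class SessionLog:
    """Realized presentation record: one entry per executed trial."""

    paradigm: str
    records: list[dict] = field(default_factory=list)


def _exemplar_stream(set_ref: StimulusSetRef, rng: np.random.Generator):
    """Yield exemplars without replacement, reshuffling when exhausted."""
    while True:
        order = rng.permutation(len(set_ref.exemplars))
        for i in order:
            yield set_ref.exemplars[i]


def build_habituation(
    hab_set: StimulusSetRef,
    dishab_set: StimulusSetRef,
    n_hab_trials: int,
    n_dishab_trials: int,
    timing: TrialTiming = TrialTiming(),
    seed: int = 0,
) -> TrialSequence:
    """Habituation trials on one numerosity, then dishabituation on a novel one.

    Exemplars are sampled without replacement within a cycle so the
    continuous properties change on every trial while the numerosity stays
    fixed throughout the habituation phase.
    """
    if hab_set.numerosity == dishab_set.numerosity:
        raise InvalidParameterError(
            "dishabituation must present a novel numerosity, got "
            f"{hab_set.numerosity} vs {dishab_set.numerosity}"
        )
    if n_hab_trials < 1 or n_dishab_trials < 0:
        raise InvalidParameterError("need n_hab_trials >= 1 and n_dishab_trials >= 0")
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    hab_stream = _exemplar_stream(hab_set, rng)
    dishab_stream = _exemplar_stream(dishab_set, rng)
    for i in range(n_hab_trials + n_dishab_trials):
        phase = "habituation" if i < n_hab_trials else "dishabituation"
        src, stream = (
            (hab_set, hab_stream) if phase == "habituation" else (dishab_set, dishab_stream)
        )
        trials.append(
            Trial(
                index=i,
                phase=phase,
                stimuli=(next(stream),),
                sets=(src.name,),
                side_of_first=None,
                presentation_s=timing.presentation_s,
                pause_s=timing.pause_s,
                advance=timing.advance,
            )
        )
    return TrialSequence(
        paradigm="habituation_dishabituation",
        trials=trials,
        sets={hab_set.name: hab_set, dishab_set.name: dishab_set},
        seed=seed,
    )


def build_dual_choice(
    set_a: StimulusSetRef,
    set_b: StimulusSetRef,
    n_trials: int,
    timing: TrialTiming = TrialTiming(),
    seed: int = 0,
) -> TrialSequence:
    """Side-by-side comparison trials with counterbalanced side assignment."""
    if n_trials < 1:
        raise InvalidParameterError("need at least one trial")
    rng = np.random.default_rng(seed)
    n_left = n_trials // 2
    sides = np.array(["left"] * n_left + ["right"] * (n_trials - n_left))
    rng.shuffle(sides)
    a_stream = _exemplar_stream(set_a, rng)
    b_stream = _exemplar_stream(set_b, rng)
    trials = []
    for i in range(n_trials):
        ex_a, ex_b = next(a_stream), next(b_stream)
        side_a = str(sides[i])
        stimuli = (ex_a, ex_b) if side_a == "left" else (ex_b, ex_a)
        sets = (
            (set_a.name, set_b.name) if side_a == "left" else (set_b.name, set_a.name)
        )
        trials.append(
            Trial(
                index=i,
                phase="choice",
                stimuli=stimuli,
                sets=sets,
                side_of_first=side_a,
                presentation_s=timing.presentation_s,
                pause_s=timing.pause_s,
                advance=timing.advance,
            )
        )
    return TrialSequence(
        paradigm="dual_choice",
        trials=trials,
        sets={set_a.name: set_a, set_b.name: set_b},
        seed=seed,
    )


def _sequence_frame(seq: TrialSequence) -> pd.DataFrame:
    rows = []
    for t in seq.trials:
        rows.append(
            {
                "trial": t.index,
                "phase": t.phase,
                "stimulus_left": t.stimuli[0],
                "stimulus_right": t.stimuli[1] if len(t.stimuli) > 1 else "",
                "set_left": t.sets[0],
                "set_right": t.sets[1] if len(t.sets) > 1 else "",
                "side_of_first": t.side_of_first or "",
                "presentation_s": t.presentation_s,
                "pause_s": t.pause_s,
                "advance": t.advance,
            }
        )
    return pd.DataFrame(rows)


def export_log(seq_or_log: TrialSequence | SessionLog, path: str | Path) -> Path:
    """Write a trial sequence or realized session log as a CSV table."""
    path = Path(path)
    if isinstance(seq_or_log, SessionLog):
        if not seq_or_log.records:
            raise InvalidParameterError("cannot export an empty session log")
        pd.DataFrame(seq_or_log.records).to_csv(path, index=False)
        return path
    if not seq_or_log.trials:
        raise InvalidParameterError("cannot export an empty trial sequence")
    _sequence_frame(seq_or_log).to_csv(path, index=False)
    return path


def load_log(path: str | Path) -> pd.DataFrame:
    """Parse an exported trial table back into a DataFrame."""
    df = pd.read_csv(path, keep_default_na=False)
    if df.empty:
        raise InvalidParameterError("empty trial table")
    return df
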