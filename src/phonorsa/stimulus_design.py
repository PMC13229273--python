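"""Word set, factorial condition space, and constrained trial-sequence generation.

The paradigm presents eight consonant-vowel-consonant (CVC) words in two
stimulus types per group (hearing: visual speech + auditory speech; deaf:
visual speech + dynamic text), each in two forms (speakers or fonts) and two
exemplars.  A run is a fixed-length sequence of 3.95 s trials: 128 stimulus
trials (every unique stimulus twice, permuted in two blocks of 64), 10 null
trials, and 16 target + 16 decision trials implementing an occasional
one-back two-alternative forced-choice task.

Trial sequences are pseudorandom subject to the published structural
constraints: no lexical word on two consecutive stimulus-bearing trials,
decision trials immediately after their target, null trials spread out with
index gaps in [8, 26] (mean ~17), and target/decision pairs spread with gaps
in [7, 14] (mean ~11).  Over a four-run session each of the 64 unique stimuli
serves as target exactly once, balanced per run over words, forms and
exemplars within each stimulus type.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Position",
    "Phoneme",
    "WordItem",
    "Condition",
    "Stimulus",
    "Trial",
    "RunSequence",
    "ParadigmSpec",
    "SequenceConstraintError",
    "build_word_set",
    "shared_phoneme_count",
    "enumerate_conditions",
    "build_stimulus_set",
    "generate_run_sequence",
    "generate_session",
    "design_summary",
    "validate_run",
    "validate_session",
    "events_table",
]


class Position(str, Enum):
    INITIAL = "initial"
    VOWEL = "vowel"
    FINAL = "final"


TRIAL_DURATION = 3.95  # seconds; one sparse-sampling volume per trial
ACQUISITION_TIME = 2.45  # seconds of EPI readout at the start of each trial
STIMULUS_ONSET_DELAY = 2.50  # stimulus starts 50 ms after readout offset

#: closed phoneme inventory of the eight-word set
INITIALS = ("b", "r")
VOWELS = ("i:", "u:")
FINALS = ("m", "t", "l", "f")

#: orthography -> (initial, vowel, final) positional transcription
_TRANSCRIPTIONS = {
    "beam": ("b", "i:", "m"),
    "beat": ("b", "i:", "t"),
    "boom": ("b", "u:", "m"),
    "boot": ("b", "u:", "t"),
    "real": ("r", "i:", "l"),
    "reef": ("r", "i:", "f"),
    "rule": ("r", "u:", "l"),
    "roof": ("r", "u:", "f"),
}

#: per-stimulus-type duration ranges in seconds (min, max of the recorded sets)
DURATION_RANGES = {
    "visual_speech": (1.040, 1.360),
    "auditory_speech": (0.558, 0.972),
    "dynamic_text": (1.000, 1.320),
}

STIMULUS_TYPES_BY_GROUP = {
    "hearing": ("visual_speech", "auditory_speech"),
    "deaf": ("visual_speech", "dynamic_text"),
}


@dataclass(frozen=True)
class Phoneme:
    label: str
    position: Position

    def __post_init__(self):
        valid = {
            Position.INITIAL: INITIALS,
            Position.VOWEL: VOWELS,
            Position.FINAL: FINALS,
        }[Position(self.position)]
        if self.label not in valid:
            raise ValueError(
                f"phoneme {self.label!r} not valid at position {self.position}"
            )


@dataclass(frozen=True)
class WordItem:
    orthography: str
    phonemes: tuple[Phoneme, Phoneme, Phoneme]

    @property
    def labels(self) -> tuple[str, str, str]:
        return tuple(p.label for p in self.phonemes)

    def phoneme_at(self, position: Position | str) -> str:
        idx = [Position.INITIAL, Position.VOWEL, Position.FINAL].index(
            Position(position)
        )
        return self.phonemes[idx].label


@dataclass(frozen=True)
class Condition:
    word: WordItem
    stimulus_type: str
    form: str  # "A" or "B" (speaker or font)

    @property
    def label(self) -> str:
        return f"{self.word.orthography}_{self.stimulus_type}_{self.form}"


@dataclass(frozen=True)
class Stimulus:
    condition: Condition
    exemplar: int  # 1 or 2
    duration: float = 1.0  # seconds, fixed per stimulus across repetitions

    @property
    def label(self) -> str:
        return f"{self.condition.label}_ex{self.exemplar}"


@dataclass(frozen=True)
class Trial:
    kind: str  # stimulus | null | target | decision
    index: int
    stimulus: Stimulus | None = None

    def __post_init__(self):
        has_stim = self.stimulus is not None
        if has_stim != (self.kind in ("stimulus", "target")):
            raise ValueError(f"trial kind {self.kind} stimulus mismatch")

    @property
    def onset(self) -> float:
        return self.index * TRIAL_DURATION


@dataclass(frozen=True)
class RunSequence:
    trials: tuple[Trial, ...]
    run_index: int
    seed: int

    def indices_of(self, kind: str) -> list[int]:
        return [t.index for t in self.trials if t.kind == kind]


@dataclass(frozen=True)
class ParadigmSpec:
    """Structural parameters of one scanning run and session.

    Gap parameters reproduce the published spacing summaries; they are the
    sampler's targets, not post-hoc observations.
    """

    group: str = "hearing"
    n_runs: int = 4
    trial_duration: float = TRIAL_DURATION
    n_stimulus: int = 128
    n_null: int = 10
    n_target: int = 16
    n_decision: int = 16
    null_gap_mean: float = 17.0
    null_gap_sd: float = 3.0
    null_gap_min: int = 8
    null_gap_max: int = 26
    target_gap_mean: float = 11.0
    target_gap_sd: float = 2.0
    target_gap_min: int = 7
    target_gap_max: int = 14

    def __post_init__(self):
        if self.group not in STIMULUS_TYPES_BY_GROUP:
            raise ValueError(f"unknown group {self.group!r}")

    @property
    def stimulus_types(self) -> tuple[str, str]:
        return STIMULUS_TYPES_BY_GROUP[self.group]

    @property
    def n_trials(self) -> int:
        return self.n_stimulus + self.n_null + self.n_target + self.n_decision

    def to_config(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_config(cls, cfg: dict) -> "ParadigmSpec":
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in cfg.items() if k in names})


class SequenceConstraintError(RuntimeError):
    """A sequence constraint could not be satisfied within the attempt budget."""


def build_word_set() -> list[WordItem]:
    """Return the eight CVC words with positional phoneme transcriptions.

    Initial consonant and vowel are fully crossed; the final consonant is
    nested within the initial (b-words end in m/t, r-words in l/f), so any
    b-word and r-word share at most the vowel.
    """
    words = []
    for orth, (ini, vow, fin) in _TRANSCRIPTIONS.items():
        words.append(
            WordItem(
                orth,
                (
                    Phoneme(ini, Position.INITIAL),
                    Phoneme(vow, Position.VOWEL),
                    Phoneme(fin, Position.FINAL),
                ),
            )
        )
    return words


def shared_phoneme_count(w1: WordItem, w2: WordItem) -> int:
    """Number of positions (0..3) at which two CVC words carry the same phoneme."""
    return sum(a == b for a, b in zip(w1.labels, w2.labels))


def enumerate_conditions(spec: ParadigmSpec) -> list[Condition]:
    """The 32 conditions in canonical order: word-major, then type, then form.

    Index of (word w, type t, form f) is ``4*w + 2*t + f`` with words in the
    fixed published order and types in group order (visual speech first).
    """
    conditions = []
    for word in build_word_set():
        for stype in spec.stimulus_types:
            for form in ("A", "B"):
                conditions.append(Condition(word, stype, form))
    return conditions


def build_stimulus_set(spec: ParadigmSpec, rng: np.random.Generator) -> list[Stimulus]:
    """All 64 unique stimuli with durations drawn once from the recorded ranges."""
    stimuli = []
    for cond in enumerate_conditions(spec):
        lo, hi = DURATION_RANGES[cond.stimulus_type]
        for exemplar in (1, 2):
            dur = float(np.round(rng.uniform(lo, hi), 3))
            stimuli.append(Stimulus(cond, exemplar, dur))
    return stimuli


# ---------------------------------------------------------------------------
# sequence generation


def _truncated_gaps(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: int, hi: int
) -> np.ndarray:
    """n integer gaps ~ round(Normal(mean, sd)) rejection-sampled into [lo, hi]."""
    out = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        draw = np.rint(rng.normal(mean, sd, size=2 * (n - filled))).astype(int)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _word_of(stim: Stimulus) -> str:
    return stim.condition.word.orthography


def _no_adjacent_shuffle(
    items: list[Stimulus], rng: np.random.Generator, max_attempts: int = 2000
) -> list[Stimulus]:
    """Permutation of items with no equal lexical word on adjacent slots.

    Shuffle then repair by swapping each offending slot with a random slot
    that removes the violation without creating a new one.
    """
    order = list(rng.permutation(len(items)))
    seq = [items[i] for i in order]
    n = len(seq)
    for _ in range(max_attempts):
        bad = [i for i in range(1, n) if _word_of(seq[i]) == _word_of(seq[i - 1])]
        if not bad:
            return seq
        i = bad[int(rng.integers(len(bad)))]
        for j in rng.permutation(n):
            j = int(j)
            if abs(j - i) < 1:
                continue
            wi, wj = _word_of(seq[i]), _word_of(seq[j])
            # swapping seq[i] <-> seq[j] must fix i and not break around j
            ok_i = all(
                wj != _word_of(seq[k]) for k in (i - 1, i + 1) if 0 <= k < n and k != j
            )
            ok_j = all(
                wi != _word_of(seq[k]) for k in (j - 1, j + 1) if 0 <= k < n and k != i
            )
            if ok_i and ok_j:
                seq[i], seq[j] = seq[j], seq[i]
                break
    raise SequenceConstraintError(
        "could not produce a no-adjacent-word stimulus permutation"
    )


def _random_latin_square(rng: np.random.Generator, symbols: list) -> np.ndarray:
    """4x4 Latin square via randomized cyclic square (rows/cols/symbols permuted)."""
    n = len(symbols)
    base = (np.arange(n)[:, None] + np.arange(n)[None, :]) % n
    base = base[rng.permutation(n)][:, rng.permutation(n)]
    sym = [symbols[i] for i in rng.permutation(n)]
    return np.array([[sym[base[i, j]] for j in range(n)] for i in range(n)], dtype=object)


def _session_target_assignment(
    spec: ParadigmSpec, stimuli: list[Stimulus], rng: np.random.Generator
) -> list[list[Stimulus]]:
    """Partition the 64 stimuli into per-run target lists.

    Per run and stimulus type: all 8 words once each, forms 4+4, exemplars
    4+4; across runs every unique stimulus is a target exactly once.  Built
    from stacked 4x4 Latin squares over the (form, exemplar) cells so the
    balance holds by construction.
    """
    by_key = {(s.condition.label, s.exemplar): s for s in stimuli}
    words = [w.orthography for w in build_word_set()]
    cells = [("A", 1), ("A", 2), ("B", 1), ("B", 2)]
    per_run: list[list[Stimulus]] = [[] for _ in range(spec.n_runs)]
    for stype in spec.stimulus_types:
        # rows = 8 words (two stacked Latin squares), cols = 4 runs
        square = np.concatenate(
            [_random_latin_square(rng, cells), _random_latin_square(rng, cells)]
        )
        square = square[rng.permutation(8)]
        for wi, word in enumerate(words):
            for run in range(spec.n_runs):
                form, exemplar = square[wi, run]
                stim = by_key[(f"{word}_{stype}_{form}", exemplar)]
                per_run[run].append(stim)
    for run in range(spec.n_runs):
        rng.shuffle(per_run[run])
    return per_run


def _sample_special_slots(
    spec: ParadigmSpec, rng: np.random.Generator, max_attempts: int = 1000
) -> tuple[list[int], list[int]]:
    """Null indices and target indices satisfying the spacing constraints."""
    n = spec.n_trials
    for _ in range(max_attempts):
        gaps = _truncated_gaps(
            rng,
            spec.n_null - 1,
            spec.null_gap_mean,
            spec.null_gap_sd,
            spec.null_gap_min,
            spec.null_gap_max,
        )
        nulls = np.concatenate([[0], np.cumsum(gaps)])  # first null = run-start rest
        if nulls[-1] >= n:
            continue
        null_set = set(int(i) for i in nulls)
        t0 = int(rng.integers(2, 9))
        tgaps = _truncated_gaps(
            rng,
            spec.n_target - 1,
            spec.target_gap_mean,
            spec.target_gap_sd,
            spec.target_gap_min,
            spec.target_gap_max,
        )
        targets = t0 + np.concatenate([[0], np.cumsum(tgaps)])
        if targets[-1] + 1 >= n:
            continue
        special = set()
        collision = False
        for t in targets:
            t = int(t)
            if t in null_set or t + 1 in null_set or t in special or t + 1 in special:
                collision = True
                break
            special.update((t, t + 1))
        if collision:
            continue
        return sorted(null_set), [int(t) for t in targets]
    raise SequenceConstraintError(
        "could not place null and target/decision trials under the spacing "
        "constraints (null gaps "
        f"[{spec.null_gap_min},{spec.null_gap_max}], target gaps "
        f"[{spec.target_gap_min},{spec.target_gap_max}])"
    )


def _order_targets(
    targets: list[Stimulus],
    target_slots: list[int],
    trial_words: dict[int, str],
    rng: np.random.Generator,
    max_attempts: int = 500,
) -> list[Stimulus]:
    """Order run targets so no target repeats the word of the preceding trial."""
    for _ in range(max_attempts):
        order = [targets[int(i)] for i in rng.permutation(len(targets))]
        ok = all(
            trial_words.get(slot - 1) != _word_of(stim)
            for slot, stim in zip(target_slots, order)
        )
        if ok:
            return order
    raise SequenceConstraintError("could not order target stimuli without word repeats")


def generate_run_sequence(
    spec: ParadigmSpec,
    run_index: int,
    seed: int,
    *,
    stimulus_set: list[Stimulus] | None = None,
    run_targets: list[Stimulus] | None = None,
) -> RunSequence:
    """Generate one constrained 170-trial run.

    Standalone use draws the stimulus set and a balanced target sample from
    ``seed``; :func:`generate_session` passes both in so that targets cover
    all 64 stimuli across the session.
    """
    rng = np.random.default_rng(seed)
    if stimulus_set is None:
        stimulus_set = build_stimulus_set(spec, rng)
    if run_targets is None:
        # balanced standalone sample: one Latin-square column's worth
        run_targets = _session_target_assignment(spec, stimulus_set, rng)[0]
    if len(run_targets) != spec.n_target:
        raise ValueError(f"expected {spec.n_target} targets, got {len(run_targets)}")

    nulls, target_slots = _sample_special_slots(spec, rng)
    special = set(nulls) | set(target_slots) | {t + 1 for t in target_slots}
    stim_slots = [i for i in range(spec.n_trials) if i not in special]
    if len(stim_slots) != spec.n_stimulus:
        raise SequenceConstraintError("slot accounting failed")  # pragma: no cover

    # two no-adjacent blocks; re-shuffle both if the boundary clashes
    for _ in range(200):
        block1 = _no_adjacent_shuffle(list(stimulus_set), rng)
        block2 = _no_adjacent_shuffle(list(stimulus_set), rng)
        if _word_of(block1[-1]) != _word_of(block2[0]):
            break
    else:  # pragma: no cover
        raise SequenceConstraintError("block boundary word repeat")
    stim_order = block1 + block2

    # adjacency across inserted nulls/targets: the word constraint applies to
    # consecutive trial indices; a null or decision trial breaks adjacency, a
    # target trial does not (it presents a stimulus).
    trial_words: dict[int, str] = {
        slot: _word_of(stim) for slot, stim in zip(stim_slots, stim_order)
    }
    target_order = _order_targets(run_targets, target_slots, trial_words, rng)
    for slot, stim in zip(target_slots, target_order):
        trial_words[slot] = _word_of(stim)
    # targets may also precede a stimulus trial at slot+2 only via the decision
    # trial, which breaks adjacency; nothing more to check.

    trials: list[Trial] = []
    stim_iter = iter(stim_order)
    tgt_iter = iter(target_order)
    decision_slots = {t + 1 for t in target_slots}
    null_set = set(nulls)
    tgt_slots = set(target_slots)
    for i in range(spec.n_trials):
        if i in null_set:
            trials.append(Trial("null", i))
        elif i in tgt_slots:
            trials.append(Trial("target", i, next(tgt_iter)))
        elif i in decision_slots:
            trials.append(Trial("decision", i))
        else:
            trials.append(Trial("stimulus", i, next(stim_iter)))
    run = RunSequence(tuple(trials), run_index, seed)
    validate_run(run, spec)
    return run


def generate_session(spec: ParadigmSpec, seed: int) -> list[RunSequence]:
    """Generate the four runs of one session with session-level target coverage."""
    rng = np.random.default_rng(seed)
    stimuli = build_stimulus_set(spec, rng)
    per_run_targets = _session_target_assignment(spec, stimuli, rng)
    run_seeds = rng.integers(0, 2**31 - 1, size=spec.n_runs)
    runs = [
        generate_run_sequence(
            spec,
            r + 1,
            int(run_seeds[r]),
            stimulus_set=stimuli,
            run_targets=per_run_targets[r],
        )
        for r in range(spec.n_runs)
    ]
    validate_session(runs, spec)
    return runs


# ---------------------------------------------------------------------------
# validation and summaries


def validate_run(run: RunSequence, spec: ParadigmSpec) -> None:
    """Re-check every run invariant independently of the generator internals."""
    trials = run.trials
    if len(trials) != spec.n_trials:
        raise AssertionError(f"run has {len(trials)} trials, expected {spec.n_trials}")
    counts = {k: sum(t.kind == k for t in trials) for k in
              ("stimulus", "null", "target", "decision")}
    expected = {
        "stimulus": spec.n_stimulus,
        "null": spec.n_null,
        "target": spec.n_target,
        "decision": spec.n_decision,
    }
    if counts != expected:
        raise AssertionError(f"trial composition {counts} != {expected}")
    for t in trials:
        if t.kind == "decision" and trials[t.index - 1].kind != "target":
            raise AssertionError(f"decision at {t.index} does not follow a target")
    # no same lexical word on consecutive stimulus-bearing trials
    for a, b in zip(trials[:-1], trials[1:]):
        if a.stimulus is not None and b.stimulus is not None:
            if _word_of(a.stimulus) == _word_of(b.stimulus):
                raise AssertionError(
                    f"word {_word_of(a.stimulus)!r} repeated at trials "
                    f"{a.index},{b.index}"
                )
    # two blocks of 64 covering each unique stimulus exactly once
    stim_labels = [t.stimulus.label for t in trials if t.kind == "stimulus"]
    half = spec.n_stimulus // 2
    for block in (stim_labels[:half], stim_labels[half:]):
        if len(set(block)) != half:
            raise AssertionError("a stimulus block does not cover each stimulus once")
    # spacing constraints
    nulls = run.indices_of("null")
    gaps = np.diff(nulls)
    if gaps.size and (gaps.min() < spec.null_gap_min or gaps.max() > spec.null_gap_max):
        raise AssertionError(f"null gaps {gaps} outside bounds")
    tgts = run.indices_of("target")
    tgaps = np.diff(tgts)
    if tgaps.size and (
        tgaps.min() < spec.target_gap_min or tgaps.max() > spec.target_gap_max
    ):
        raise AssertionError(f"target gaps {tgaps} outside bounds")


def validate_session(runs: Sequence[RunSequence], spec: ParadigmSpec) -> None:
    """Session-level invariants: full unique-target coverage, per-run balance."""
    for run in runs:
        validate_run(run, spec)
    all_targets = [
        t.stimulus.label for run in runs for t in run.trials if t.kind == "target"
    ]
    if len(set(all_targets)) != 64 or len(all_targets) != 64:
        raise AssertionError("session targets do not cover the 64 stimuli once each")
    for run in runs:
        tgt = [t.stimulus for t in run.trials if t.kind == "target"]
        for stype in spec.stimulus_types:
            sub = [s for s in tgt if s.condition.stimulus_type == stype]
            if len(sub) != 8:
                raise AssertionError(f"run targets not 8 per type ({stype})")
            if len({s.condition.word.orthography for s in sub}) != 8:
                raise AssertionError("run targets do not cover all 8 words per type")
            if sum(s.condition.form == "A" for s in sub) != 4:
                raise AssertionError("run targets unbalanced over forms")
            if sum(s.exemplar == 1 for s in sub) != 4:
                raise AssertionError("run targets unbalanced over exemplars")


def design_summary(run: RunSequence) -> dict:
    """Counts and spacing statistics of one run (on trial indices)."""
    counts = {
        k: sum(t.kind == k for t in run.trials)
        for k in ("stimulus", "null", "target", "decision")
    }
    null_gaps = np.diff(run.indices_of("null"))
    target_gaps = np.diff(run.indices_of("target"))

    def _stats(g: np.ndarray) -> dict:
        if g.size == 0:
            return {"min": None, "max": None, "mean": None, "sd": None}
        return {
            "min": int(g.min()),
            "max": int(g.max()),
            "mean": float(g.mean()),
            "sd": float(g.std(ddof=1)) if g.size > 1 else 0.0,
        }

    return {
        "n_trials": len(run.trials),
        "counts": counts,
        "decision_stimulus_ratio": counts["decision"] / counts["stimulus"],
        "null_gaps": null_gaps.tolist(),
        "null_gap_stats": _stats(null_gaps),
        "target_gaps": target_gaps.tolist(),
        "target_gap_stats": _stats(target_gaps),
    }


def events_table(run: RunSequence, spec: ParadigmSpec) -> pd.DataFrame:
    """BIDS-events-style table for one run (tab-separated on disk).

    Stimulus onsets fall in the silent gap, 2.5 s after trial start (50 ms
    after readout offset).  Decision trials contribute a cue event and a
    button event 0.8 s later.
    """
    rows = []
    for t in run.trials:
        base = t.onset + STIMULUS_ONSET_DELAY
        if t.kind in ("stimulus", "target"):
            s = t.stimulus
            rows.append(
                dict(
                    onset=round(base, 3),
                    duration=s.duration,
                    trial_type=(s.condition.label if t.kind == "stimulus"
                                else f"target_{s.condition.stimulus_type}"),
                    word=s.condition.word.orthography,
                    stimulus_type=s.condition.stimulus_type,
                    form=s.condition.form,
                    exemplar=s.exemplar,
                    kind=t.kind,
                )
            )
        elif t.kind == "decision":
            rows.append(
                dict(onset=round(base, 3), duration=1.5, trial_type="decision_cue",
                     word="n/a", stimulus_type="n/a", form="n/a", exemplar=0,
                     kind="decision")
            )
            rows.append(
                dict(onset=round(base + 0.8, 3), duration=0.0, trial_type="button",
                     word="n/a", stimulus_type="n/a", form="n/a", exemplar=0,
                     kind="button")
            )
    return pd.DataFrame(rows).sort_values("onset").reset_index(drop=True)
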