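"""Theoretical dissimilarity models and pair-subset masks.

Three word-level models over the 32-condition space:

* **Shared Phonemes** — dissimilarity ``3 - #shared positional phonemes``
  between the two conditions' words; evaluated over all pairs.
* **Sublexical** (Shared Phonemes given Lexical) — identical predictions, but
  every pair whose two conditions carry the same lexical word (any form, any
  stimulus type) is excluded from evaluation, removing identity-driven fit.
* **Lexical** — 0 for same-word pairs, 1 otherwise: each word maximally and
  equally dissimilar to every other word.

Position models (initial / vowel / final) predict 0 when the two words share
the phoneme at that position and 1 otherwise, with same-word pairs excluded.

Model predictions use small integers; only their ranks matter because fits
are assessed with Kendall tau-a.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimulus_design import Condition, Position, shared_phoneme_count

__all__ = [
    "PairMask",
    "ModelRDM",
    "shared_phonemes_model",
    "sublexical_model",
    "lexical_model",
    "position_model",
    "partition_mask",
    "RELATIONS",
]

RELATIONS = (
    "within_type_any",
    "across_type",
    "across_form_within_type",
    "same_form_within_type",
)


@dataclass(frozen=True)
class PairMask:
    """Symmetric boolean indicator over unordered condition pairs (no self-pairs)."""

    conditions: tuple[Condition, ...]
    indicator: np.ndarray  # (n, n) bool, symmetric, zero diagonal

    def __post_init__(self):
        ind = self.indicator
        if ind.shape != (len(self.conditions),) * 2:
            raise ValueError("indicator shape does not match condition count")
        if not np.array_equal(ind, ind.T) or ind.diagonal().any():
            raise ValueError("mask must be symmetric with empty diagonal")

    @property
    def n_pairs(self) -> int:
        return int(np.triu(self.indicator, 1).sum())

    def pair_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle (i, j) indices of selected pairs, i < j."""
        return np.nonzero(np.triu(self.indicator, 1))

    def intersect(self, other: "PairMask") -> "PairMask":
        return PairMask(self.conditions, self.indicator & other.indicator)


@dataclass(frozen=True)
class ModelRDM:
    """Predicted dissimilarity per condition pair plus its evaluation mask."""

    name: str
    conditions: tuple[Condition, ...]
    predictions: np.ndarray  # (n, n) float, symmetric, zero diagonal
    mask: PairMask

    def __post_init__(self):
        p = self.predictions
        if not np.array_equal(p, p.T):
            raise ValueError("predictions must be symmetric")
        if not np.isfinite(p).all() or (p < 0).any():
            raise ValueError("predictions must be finite and nonnegative")

    def masked_vector(self, mask: PairMask | None = None) -> np.ndarray:
        """Predictions over the selected pairs (upper triangle order)."""
        m = self.mask if mask is None else self.mask.intersect(mask)
        i, j = m.pair_indices()
        return self.predictions[i, j]

    def to_frame(self) -> pd.DataFrame:
        """Square export with NaN outside the evaluation mask."""
        out = self.predictions.astype(float).copy()
        out[~self.mask.indicator] = np.nan
        labels = [c.label for c in self.conditions]
        return pd.DataFrame(out, index=labels, columns=labels)


def _all_pairs_mask(conditions: tuple[Condition, ...]) -> np.ndarray:
    n = len(conditions)
    return ~np.eye(n, dtype=bool)


def _same_word(conditions) -> np.ndarray:
    words = np.array([c.word.orthography for c in conditions])
    return words[:, None] == words[None, :]


def shared_phonemes_model(conditions) -> ModelRDM:
    conditions = tuple(conditions)
    n = len(conditions)
    pred = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            pred[i, j] = 3 - shared_phoneme_count(
                conditions[i].word, conditions[j].word
            )
    mask = PairMask(conditions, _all_pairs_mask(conditions))
    return ModelRDM("shared_phonemes", conditions, pred, mask)


def sublexical_model(conditions) -> ModelRDM:
    base = shared_phonemes_model(conditions)
    keep = _all_pairs_mask(base.conditions) & ~_same_word(base.conditions)
    return ModelRDM(
        "sublexical", base.conditions, base.predictions,
        PairMask(base.conditions, keep),
    )


def lexical_model(conditions) -> ModelRDM:
    conditions = tuple(conditions)
    pred = (~_same_word(conditions)).astype(float)
    mask = PairMask(conditions, _all_pairs_mask(conditions))
    return ModelRDM("lexical", conditions, pred, mask)


def position_model(conditions, position: Position | str) -> ModelRDM:
    position = Position(position)
    conditions = tuple(conditions)
    phon = np.array([c.word.phoneme_at(position) for c in conditions])
    pred = (phon[:, None] != phon[None, :]).astype(float)
    keep = _all_pairs_mask(conditions) & ~_same_word(conditions)
    return ModelRDM(
        f"position_{position.value}", conditions, pred, PairMask(conditions, keep)
    )


def partition_mask(conditions, relation: str, stimulus_type: str | None = None) -> PairMask:
    """Pair subset selector by stimulus-type relation.

    relation:
      * ``"within_type"`` (requires ``stimulus_type``) — both conditions of
        that type;
      * ``"within_type_any"`` — both conditions of the same type (either);
      * ``"across_type"`` — the two conditions differ in type;
      * ``"across_form_within_type"`` / ``"same_form_within_type"`` — within
        same type, split by form agreement.
    """
    conditions = tuple(conditions)
    types = np.array([c.stimulus_type for c in conditions])
    forms = np.array([c.form for c in conditions])
    same_type = types[:, None] == types[None, :]
    same_form = forms[:, None] == forms[None, :]
    off = _all_pairs_mask(conditions)
    if relation == "within_type":
        if stimulus_type is None:
            raise ValueError("within_type relation needs a stimulus_type")
        sel = (types == stimulus_type)
        ind = off & sel[:, None] & sel[None, :]
    elif relation == "within_type_any":
        ind = off & same_type
    elif relation == "across_type":
        ind = off & ~same_type
    elif relation == "across_form_within_type":
        ind = off & same_type & ~same_form
    elif relation == "same_form_within_type":
        ind = off & same_type & same_form
    else:
        raise ValueError(f"unknown relation {relation!r}")
    return PairMask(conditions, ind)
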