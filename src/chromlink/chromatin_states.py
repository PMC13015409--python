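"""Enhancer chromatin-state classification, activation switching, CRE
assembly, and the chromatin-state-count selection curve.

Enhancer states follow the standard three-mark convention:

===========  =========================================
state        marks
===========  =========================================
active       H3K27ac present, H3K27me3 absent
poised       H3K4me1 and H3K27me3 present
primed       H3K4me1 only (no H3K27ac, no H3K27me3)
inactive     anything else
===========  =========================================

Conflicts are resolved by the precedence order
poised > active > primed > inactive.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import GenomicInterval, IntervalIndex, merge_intervals, sort_intervals

__all__ = [
    "ENHANCER_STATES",
    "EnhancerElement",
    "EmissionMatrix",
    "classify_enhancer_state",
    "classify_enhancers",
    "assemble_cres",
    "model_selection_curve",
]

ENHANCER_STATES = ("active", "primed", "poised", "inactive")
_STATE_MARKS = frozenset({"H3K27ac", "H3K4me1", "H3K27me3"})
_NON_ACTIVE = frozenset({"primed", "poised", "inactive"})


@dataclass(frozen=True)
class EnhancerElement:
    interval: GenomicInterval
    state_control: str
    state_treated: str

    @property
    def switch(self) -> str:
        c, t = self.state_control, self.state_treated
        if c == "active" and t == "active":
            return "stays_active"
        if c in _NON_ACTIVE and t == "active":
            return "activated"
        if c == "active" and t in _NON_ACTIVE:
            return "deactivated"
        return "stays_nonactive"


@dataclass
class EmissionMatrix:
    """Per-state mark-emission probabilities of a chromatin-state model."""

    n_states: int
    marks: list[str]
    emissions: np.ndarray  # n_states x n_marks, values in [0, 1]

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=float)
        if self.emissions.shape != (self.n_states, len(self.marks)):
            raise ValueError("emission matrix shape mismatch")
        if ((self.emissions < 0) | (self.emissions > 1)).any():
            raise ValueError("emissions must lie in [0, 1]")


def classify_enhancer_state(marks_present: Iterable[str]) -> str:
    """Map the set of overlapping histone marks to an enhancer state."""
    marks = set(marks_present)
    unknown = marks - _STATE_MARKS
    if unknown:
        raise ValueError(f"unknown mark(s) for state classification: {sorted(unknown)}")
    if "H3K4me1" in marks and "H3K27me3" in marks:
        return "poised"
    if "H3K27ac" in marks and "H3K27me3" not in marks:
        return "active"
    if "H3K4me1" in marks and not marks & {"H3K27ac", "H3K27me3"}:
        return "primed"
    return "inactive"


def classify_enhancers(
    enhancers: Sequence[GenomicInterval],
    peaks_by_condition: Mapping[str, Mapping[str, Sequence[GenomicInterval]]],
    control: str = "control",
    treated: str = "dex",
    classifier=classify_enhancer_state,
) -> list[EnhancerElement]:
    """Assign per-condition enhancer states from consensus mark peaks.

    ``peaks_by_condition[condition][mark]`` holds consensus peaks; a
    mark is "present" at an enhancer when any of its peaks overlaps the
    enhancer by >= 1 bp.  ``classifier`` maps a mark set to a state
    label and can be swapped for a custom scheme.
    """
    indexes = {
        cond: {
            mark: IntervalIndex(ivs)
            for mark, ivs in marks.items()
            if mark in _STATE_MARKS
        }
        for cond, marks in peaks_by_condition.items()
    }
    out = []
    for enh in sort_intervals(enhancers):
        states = {}
        for cond in (control, treated):
            present = {
                mark
                for mark, idx in indexes.get(cond, {}).items()
                if idx.any_overlap(enh)
            }
            states[cond] = classifier(present)
        out.append(EnhancerElement(enh, states[control], states[treated]))
    return out


def assemble_cres(
    segments: Sequence[tuple[GenomicInterval, str]]
) -> list[GenomicInterval]:
    """Union-merge promoter- and enhancer-labeled state segments into
    cis-regulatory elements; book-ended segments merge."""
    allowed = {"promoter", "enhancer"}
    bad = {lab for _, lab in segments} - allowed
    if bad:
        raise ValueError(f"assemble_cres: unexpected segment label(s) {sorted(bad)}")
    return merge_intervals([iv for iv, _ in segments], gap=0)


def _best_match_corr(row: np.ndarray, candidates: np.ndarray) -> float:
    """Max Pearson correlation of ``row`` against candidate rows;
    zero-variance pairs contribute correlation 0 (with a warning)."""
    if np.std(row) == 0:
        warnings.warn("constant emission row: correlation defined as 0")
        return 0.0
    best = -np.inf
    for cand in candidates:
        if np.std(cand) == 0:
            warnings.warn("constant emission row: correlation defined as 0")
            r = 0.0
        else:
            r = float(np.corrcoef(row, cand)[0, 1])
        best = max(best, r)
    return best


def load_emission_models(directory) -> list[EmissionMatrix]:
    """Read ``model_<k>.tsv`` emission matrices (state x mark) from a
    directory, ordered by state count."""
    import pandas as pd
    from pathlib import Path

    models = []
    for path in Path(directory).glob("model_*.tsv"):
        k = int(path.stem.split("_")[1])
        df = pd.read_csv(path, sep="\t", index_col=0)
        models.append(EmissionMatrix(k, list(df.columns), df.to_numpy()))
    models.sort(key=lambda m: m.n_states)
    return models


def model_selection_curve(
    models: Sequence[EmissionMatrix], epsilon: float = 0.01
) -> tuple[list[float], int]:
    """Score each state-count model by similarity to the next-larger
    model, and pick the state count where the curve plateaus.

    For each model except the last, every state's emission row is
    correlated (Pearson) against all rows of the next model and the
    best match kept; the model's score is the mean of those maxima.
    The selected state count is the first model whose successor score
    gain falls below ``epsilon`` (the curve has stopped improving); if
    the curve never plateaus the last scored model is selected.
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    counts = [m.n_states for m in models]
    if counts != sorted(set(counts)):
        raise ValueError("models must have strictly increasing n_states")
    mark_orders = {tuple(m.marks) for m in models}
    if len(mark_orders) > 1:
        raise ValueError("models must share an identical mark ordering")

    scores = []
    for cur, nxt in zip(models, models[1:]):
        per_state = [
            _best_match_corr(cur.emissions[i], nxt.emissions)
            for i in range(cur.n_states)
        ]
        scores.append(float(np.mean(per_state)))

    selected = counts[len(scores) - 1]
    for i in range(len(scores) - 1):
        if scores[i + 1] - scores[i] < epsilon:
            selected = counts[i]
            break
    return scores, selected
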