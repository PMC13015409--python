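"""A/B compartment window classification, between-condition shift
detection, and the per-mark signal-change one-sample t-test.

Compartment scores arrive as fixed-width bedGraph windows (default
50 kb) per condition; positive scores are euchromatic A, negative
heterochromatic B.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import GenomicInterval, sort_intervals

__all__ = [
    "CompartmentWindow",
    "SignalShiftResult",
    "classify_windows",
    "detect_shifts",
    "signal_shift_test",
]


@dataclass
class CompartmentWindow:
    interval: GenomicInterval
    score_control: Optional[float] = None
    score_treated: Optional[float] = None
    class_control: Optional[str] = None
    class_treated: Optional[str] = None
    shift: str = "none"


@dataclass(frozen=True)
class SignalShiftResult:
    mark: str
    direction: str
    n_windows: int
    mean_delta: float
    t_statistic: float
    p_value: float


def _classify_scores(scores: Sequence[float]) -> list[str]:
    """Sign-based A/B classes; exact zeros take the majority class of
    their immediate neighbours, defaulting to B (with a warning)."""
    classes = []
    for i, s in enumerate(scores):
        if s > 0:
            classes.append("A")
        elif s < 0:
            classes.append("B")
        else:
            neighbours = [
                scores[j]
                for j in (i - 1, i + 1)
                if 0 <= j < len(scores) and scores[j] != 0
            ]
            votes_a = sum(1 for v in neighbours if v > 0)
            votes_b = sum(1 for v in neighbours if v < 0)
            cls = "A" if votes_a > votes_b else "B"
            warnings.warn(
                f"compartment score exactly 0 at window {i}: classified {cls}"
            )
            classes.append(cls)
    return classes


def classify_windows(score_track: Sequence[GenomicInterval]) -> list[CompartmentWindow]:
    """Classify one condition's score track into A/B windows."""
    track = sort_intervals(score_track)
    for a, b in zip(track, track[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(f"overlapping track records at {a} / {b}")
    scores = [iv.score or 0.0 for iv in track]
    classes = _classify_scores(scores)
    return [
        CompartmentWindow(iv, score_control=s, class_control=c)
        for iv, s, c in zip(track, scores, classes)
    ]


def detect_shifts(
    control_track: Sequence[GenomicInterval],
    treated_track: Sequence[GenomicInterval],
    method: str = "delta_threshold",
    delta: float = 0.3,
    flags: Optional[dict[tuple[str, int, int], str]] = None,
) -> list[CompartmentWindow]:
    """Flag windows with compartment shifts between conditions.

    ``delta_threshold`` mode flags |score_treated - score_control| >=
    ``delta`` with direction = sign of the change; ``external_flags``
    mode consumes a mapping (chrom, start, end) -> direction emitted by
    an upstream compartment-change caller.
    """
    control = sort_intervals(control_track)
    treated = sort_intervals(treated_track)
    ckeys = [(iv.chrom, iv.start, iv.end) for iv in control]
    tkeys = [(iv.chrom, iv.start, iv.end) for iv in treated]
    if ckeys != tkeys:
        raise ValueError("window sets differ between conditions")
    c_scores = [iv.score or 0.0 for iv in control]
    t_scores = [iv.score or 0.0 for iv in treated]
    c_classes = _classify_scores(c_scores)
    t_classes = _classify_scores(t_scores)
    windows = []
    for iv, key, sc, st, cc, ct in zip(
        control, ckeys, c_scores, t_scores, c_classes, t_classes
    ):
        w = CompartmentWindow(
            GenomicInterval(iv.chrom, iv.start, iv.end),
            score_control=sc,
            score_treated=st,
            class_control=cc,
            class_treated=ct,
        )
        if method == "external_flags":
            if flags is None:
                raise ValueError("external_flags mode requires a flags mapping")
            w.shift = flags.get(key, "none")
        elif method == "delta_threshold":
            d = st - sc
            if abs(d) >= delta:
                w.shift = "toward_A" if d > 0 else "toward_B"
        else:
            raise ValueError(f"unknown shift-detection method {method!r}")
        windows.append(w)
    return windows


def signal_shift_test(
    deltas: Sequence[float], mark: str, direction: str
) -> SignalShiftResult:
    """One-sample two-sided t-test of per-window signal changes vs 0.

    ``deltas`` are precomputed per-window mean signal changes for one
    mark, restricted to windows shifting in one direction; t =
    mean / (sd / sqrt(n)) with the n-1 sample standard deviation and
    n-1 degrees of freedom.
    """
    x = np.asarray(deltas, dtype=float)
    if x.size < 2:
        raise ValueError("signal_shift_test needs >= 2 windows")
    if np.std(x, ddof=1) == 0:
        raise ValueError("degenerate variance: all deltas identical")
    t, p = stats.ttest_1samp(x, 0.0)
    return SignalShiftResult(
        mark=mark,
        direction=direction,
        n_windows=int(x.size),
        mean_delta=float(x.mean()),
        t_statistic=float(t),
        p_value=float(p),
    )
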