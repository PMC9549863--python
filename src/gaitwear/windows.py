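"""Sliding-window segmentation, majority labels, and task label mapping.

Windows are 128 samples (2.56 s at 50 Hz) with a 64-sample hop, 0-based
half-open ``[start, start + length)``; a trailing partial window is
discarded. Each window takes the modal per-sample label; ties break to
the label whose first occurrence in the window is earliest. Windows whose
majority label is a transition class are kept out of training sets but
retained for evaluation, where a transition from class A to B counts as
correct if the model predicts either A or B.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable, Sequence

import numpy as np

from .recordings import (ACTIVITY_CLASSES, LABEL_VOCABULARY,
                         TRANSITION_CLASSES, TRANSITION_PAIRS)

DEFAULT_WINDOW = 128
DEFAULT_HOP = 64

TASKS = ("gait", "gait_posture")

#: Task label sets (fixed class order used for confusion matrices).
TASK_CLASSES = {
    "gait": ("gait", "no_gait"),
    "gait_posture": ACTIVITY_CLASSES,
}

_GAIT_MAP = {"walking": "gait", "stairs": "gait",
             "lying": "no_gait", "sitting": "no_gait", "standing": "no_gait"}


@dataclasses.dataclass
class LabeledWindow:
    """One fixed-length window with its majority label.

    ``adjoining_pair`` is set only for transition windows and names the two
    flanking activity classes (directionless). ``dominant_adjacent`` is the
    flanking class occupying more samples of the window — used to attribute
    an incorrectly classified transition window to a true class when
    building confusion matrices.
    """

    start: int
    length: int
    majority_label: str
    is_transition: bool
    subject_id: str
    adjoining_pair: tuple[str, str] | None = None
    dominant_adjacent: str | None = None

    def __post_init__(self) -> None:
        if self.majority_label not in LABEL_VOCABULARY:
            raise ValueError(f"unknown label {self.majority_label!r}")
        if self.is_transition != (self.majority_label in TRANSITION_CLASSES):
            raise ValueError("is_transition inconsistent with majority_label")
        if self.is_transition and self.adjoining_pair is None:
            raise ValueError("transition window requires adjoining_pair")
        if not self.is_transition and self.adjoining_pair is not None:
            raise ValueError("non-transition window must not set adjoining_pair")


def segment(n_samples: int, window: int = DEFAULT_WINDOW,
            hop: int = DEFAULT_HOP) -> list[int]:
    """Start indices of all full windows: 0, hop, 2*hop, ...

    Returns ``floor((n - window)/hop) + 1`` starts when ``n >= window``,
    else an empty list.
    """
    if window <= 0 or not 0 < hop <= window:
        raise ValueError("require window > 0 and 0 < hop <= window")
    if n_samples < window:
        return []
    return list(range(0, n_samples - window + 1, hop))


def majority_label(window_labels: Sequence[str]) -> str:
    """Modal label; ties break to earliest first occurrence in the window."""
    if len(window_labels) == 0:
        raise ValueError("empty label window")
    counts = Counter(window_labels)
    best = max(counts.values())
    candidates = [lab for lab, c in counts.items() if c == best]
    if len(candidates) == 1:
        return candidates[0]
    first_idx = {lab: list(window_labels).index(lab) for lab in candidates}
    return min(candidates, key=first_idx.get)


def make_windows(labels: Sequence[str], subject_id: str,
                 window: int = DEFAULT_WINDOW, hop: int = DEFAULT_HOP
                 ) -> list[LabeledWindow]:
    """Segment a label track into LabeledWindows with majority labels."""
    labels = np.asarray(labels, dtype=object)
    out: list[LabeledWindow] = []
    for start in segment(len(labels), window, hop):
        chunk = labels[start:start + window]
        maj = majority_label(chunk)
        is_tr = maj in TRANSITION_CLASSES
        pair = TRANSITION_PAIRS[maj] if is_tr else None
        dominant = None
        if is_tr:
            a, b = pair
            ca = int(np.sum(chunk == a))
            cb = int(np.sum(chunk == b))
            dominant = a if ca >= cb else b
        out.append(LabeledWindow(start=start, length=window,
                                 majority_label=maj, is_transition=is_tr,
                                 subject_id=subject_id,
                                 adjoining_pair=pair,
                                 dominant_adjacent=dominant))
    return out


def map_task_labels(label: str, task: str) -> str:
    """Map an 8-class label into a task's label space.

    Gait task: walking/stairs -> "gait", postures -> "no_gait"; transition
    labels keep their transition status (their adjoining pair is mapped via
    :func:`map_adjoining_pair`). Gait-and-posture task: identity.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if label in TRANSITION_CLASSES:
        return label
    if label not in ACTIVITY_CLASSES:
        raise ValueError(f"unknown label {label!r}")
    if task == "gait":
        return _GAIT_MAP[label]
    return label


def map_adjoining_pair(pair: tuple[str, str], task: str) -> tuple[str, str]:
    """Map a transition window's flanking classes into the task space.

    Under the gait task this makes trans_stand_walk accept any prediction
    (pair becomes (no_gait, gait)) while the posture-posture transitions
    accept only "no_gait" — the literal consequence of the A-or-B rule.
    """
    return (map_task_labels(pair[0], task), map_task_labels(pair[1], task))


def split_train_eval(windows: Iterable[LabeledWindow]
                     ) -> tuple[list[LabeledWindow], list[LabeledWindow]]:
    """Training set drops transition windows; evaluation keeps everything."""
    windows = list(windows)
    train = [w for w in windows if not w.is_transition]
    if not train:
        raise ValueError("no trainable windows: all windows are transitions")
    return train, windows
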