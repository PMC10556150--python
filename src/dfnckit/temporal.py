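"""Temporal properties of state label sequences.

Three per-subject summaries of a window-level state sequence:

* mean dwell time — average length (in windows) of maximal runs of a state;
* fraction of time — proportion of windows assigned to a state;
* number of transitions — count of window-to-window state changes.

Subjects who never visit a state get dwell time 0 by default (they are
kept in group contrasts with a zero, matching degrees of freedom that
include all subjects); ``absent_as_nan=True`` switches to missing-value
semantics for sensitivity analyses. Dwell time is stored in window
units; seconds are a reporting conversion (windows x step x TR), never
the stored value.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _check_labels(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("label sequence is empty")
    if (labels < 1).any():
        raise ValueError("state labels must be 1-based positive integers")
    return labels


def _run_lengths(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(state, length) of each maximal run, in order."""
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [labels.size]))
    return labels[starts], ends - starts


def mean_dwell_time(
    labels, state: int, n_states: int | None = None, absent_as_nan: bool = False
) -> float:
    """Average run length of ``state``; 0.0 (or NaN) if never visited."""
    labels = _check_labels(labels)
    k = n_states if n_states is not None else int(labels.max())
    if not 1 <= state <= k:
        raise ValueError(f"unknown state label {state} (valid: 1..{k})")
    run_states, run_lens = _run_lengths(labels)
    lens = run_lens[run_states == state]
    if lens.size == 0:
        return float("nan") if absent_as_nan else 0.0
    return float(lens.mean())


def fraction_time(labels, state: int) -> float:
    """Proportion of windows spent in ``state``, in [0, 1]."""
    labels = _check_labels(labels)
    return float(np.count_nonzero(labels == state) / labels.size)


def n_transitions(labels) -> int:
    """Number of indices t with label[t] != label[t-1]."""
    labels = _check_labels(labels)
    return int(np.count_nonzero(np.diff(labels) != 0))


@dataclass
class TemporalProfile:
    subject_id: str
    dwell: np.ndarray      # per state, window units
    fraction: np.ndarray   # per state, sums to 1
    transitions: int

    @property
    def n_states(self) -> int:
        return self.dwell.size


def temporal_profile(
    labels, subject_id: str, n_states: int, absent_as_nan: bool = False
) -> TemporalProfile:
    labels = _check_labels(labels)
    if labels.max() > n_states:
        raise ValueError("labels exceed declared number of states")
    dwell = np.array(
        [mean_dwell_time(labels, s, n_states, absent_as_nan) for s in range(1, n_states + 1)]
    )
    frac = np.array([fraction_time(labels, s) for s in range(1, n_states + 1)])
    return TemporalProfile(subject_id, dwell, frac, n_transitions(labels))


def profiles_table(
    label_sequences: dict[str, np.ndarray],
    groups: dict[str, str],
    n_states: int,
    absent_as_nan: bool = False,
) -> pd.DataFrame:
    """One row per subject: subject_id, group, dwell_s*, frac_s*, n_transitions."""
    rows = []
    for sid, labels in label_sequences.items():
        p = temporal_profile(labels, sid, n_states, absent_as_nan)
        row: dict = {"subject_id": sid, "group": groups[sid]}
        for s in range(n_states):
            row[f"dwell_s{s + 1}"] = p.dwell[s]
        for s in range(n_states):
            row[f"frac_s{s + 1}"] = p.fraction[s]
        row["n_transitions"] = p.transitions
        rows.append(row)
    return pd.DataFrame(rows)
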