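"""Trial-level trajectory measures and predictive/reactive classification.

Two distances are computed from the cursor position at the end of the
750-ms inter-stimulus interval (just before stimulus onset):

* **initial distance to next** — Euclidean distance to the upcoming target's
  center; 0 under a perfect predictive movement.
* **initial distance from previous** — axis-max (Chebyshev) distance from the
  previous target's center, max(|dx|, |dy|); large whenever the cursor has
  committed to *some* other target, correct or not.  A Euclidean variant is
  available via ``metric="euclidean"``.

A trial is **predictive** when distance-from-previous >= 275 px (inclusive),
and a predictive trial is **correct** when distance-to-next <= 100 px
(inclusive).  Trial 1 has no previous target and is excluded from
classification (but kept for RT analyses).  The 48 trials aggregate into
eight 6-trial blocks; each block's excess score is the number of predictive
trials minus the number of correct ones, an index of prediction preceding
accurate knowledge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .cohort import Layout, ParticipantRecord, TrialRecord

PREDICTIVE_THRESHOLD_PX = 275.0
CORRECT_THRESHOLD_PX = 100.0
BLOCK_SIZE = 6

Metric = Literal["chebyshev", "euclidean"]


class MissingISIData(ValueError):
    """No cursor samples available in a trial's ISI window."""


@dataclass(frozen=True)
class TrialFeatures:
    trial: int
    dist_to_next: float
    dist_from_prev: float | None  # None for trial 1
    label: Literal["predictive", "reactive"] | None
    correct: bool | None
    rt_ms: float


@dataclass(frozen=True)
class BlockSummary:
    block: int  # 1-8
    prop_predictive: float  # multiple of 1/6
    excess_score: int  # predictive minus correct, 0-6


def isi_end_position(trial: TrialRecord) -> tuple[float, float]:
    """Cursor position at the 750-ms mark (largest sample time <= onset).

    If jitter leaves the onset between two samples, interpolate linearly; if
    all samples precede the onset, the last one is used.
    """
    t = np.asarray(trial.isi_t, dtype=float)
    if t.size == 0:
        raise MissingISIData(f"trial {trial.index}: no ISI samples")
    onset = trial.onset_ms
    before = np.flatnonzero(t <= onset)
    if before.size == 0:
        raise MissingISIData(f"trial {trial.index}: no ISI sample at or before onset")
    i = before[-1]
    if t[i] == onset or i == t.size - 1:
        return float(trial.isi_x[i]), float(trial.isi_y[i])
    # straddling samples: interpolate to the onset instant
    frac = (onset - t[i]) / (t[i + 1] - t[i])
    x = trial.isi_x[i] + frac * (trial.isi_x[i + 1] - trial.isi_x[i])
    y = trial.isi_y[i] + frac * (trial.isi_y[i + 1] - trial.isi_y[i])
    return float(x), float(y)


def initial_distance_to_next(pos: tuple[float, float], next_center: tuple[float, float]) -> float:
    """Euclidean distance from the ISI-end cursor to the upcoming target."""
    dx = pos[0] - next_center[0]
    dy = pos[1] - next_center[1]
    return float(np.hypot(dx, dy))


def initial_distance_from_previous(
    pos: tuple[float, float],
    prev_center: tuple[float, float],
    metric: Metric = "chebyshev",
) -> float:
    """Axis-max (default) or Euclidean distance from the previous target."""
    dx = abs(pos[0] - prev_center[0])
    dy = abs(pos[1] - prev_center[1])
    if metric == "chebyshev":
        return float(max(dx, dy))
    if metric == "euclidean":
        return float(np.hypot(dx, dy))
    raise ValueError(f"unknown metric: {metric!r}")


def classify_trial(
    dist_from_prev: float,
    dist_to_next: float,
    predictive_threshold: float = PREDICTIVE_THRESHOLD_PX,
    correct_threshold: float = CORRECT_THRESHOLD_PX,
) -> tuple[str, bool]:
    """Label a trial predictive/reactive and flag correct predictions."""
    predictive = dist_from_prev >= predictive_threshold
    correct = bool(predictive and dist_to_next <= correct_threshold)
    return ("predictive" if predictive else "reactive"), correct


def participant_features(
    participant: ParticipantRecord,
    layout: Layout | None = None,
    metric: Metric = "chebyshev",
    predictive_threshold: float = PREDICTIVE_THRESHOLD_PX,
    correct_threshold: float = CORRECT_THRESHOLD_PX,
) -> list[TrialFeatures]:
    """Per-trial features for one participant; trial 1 is left unclassified."""
    layout = layout or Layout()
    feats: list[TrialFeatures] = []
    prev_symbol: int | None = None
    for tr in participant.trials:
        pos = isi_end_position(tr)
        next_center = tuple(layout.center_of(tr.symbol))
        d_next = initial_distance_to_next(pos, next_center)
        if prev_symbol is None:
            feats.append(TrialFeatures(tr.index, d_next, None, None, None, tr.rt_ms))
        else:
            prev_center = tuple(layout.center_of(prev_symbol))
            d_prev = initial_distance_from_previous(pos, prev_center, metric)
            label, correct = classify_trial(
                d_prev, d_next, predictive_threshold, correct_threshold
            )
            feats.append(TrialFeatures(tr.index, d_next, d_prev, label, correct, tr.rt_ms))
        prev_symbol = tr.symbol
    return feats


def block_summaries(feats: list[TrialFeatures], block_size: int = BLOCK_SIZE) -> list[BlockSummary]:
    """Aggregate 48 classified trials into 8 consecutive 6-trial blocks.

    Trial 1 (unclassified) counts as reactive for the block proportion, as a
    trial with no overt movement away from a previous target cannot be a
    wager.
    """
    if len(feats) != 48:
        raise ValueError(f"shape-error: expected 48 trials, got {len(feats)}")
    out = []
    for b in range(len(feats) // block_size):
        chunk = feats[b * block_size : (b + 1) * block_size]
        n_pred = sum(1 for f in chunk if f.label == "predictive")
        n_corr = sum(1 for f in chunk if f.correct)
        out.append(
            BlockSummary(block=b + 1, prop_predictive=n_pred / block_size,
                         excess_score=n_pred - n_corr)
        )
    return out


def features_table(
    cohort: list[ParticipantRecord],
    layout: Layout | None = None,
    metric: Metric = "chebyshev",
    predictive_threshold: float = PREDICTIVE_THRESHOLD_PX,
    correct_threshold: float = CORRECT_THRESHOLD_PX,
) -> pd.DataFrame:
    """Long-format per-trial feature table for a whole cohort.

    Columns: participant_id, sequence_id, trial, rt_ms, dist_to_next,
    dist_from_prev, label, correct.
    """
    rows = []
    for p in cohort:
        for f in participant_features(p, layout, metric, predictive_threshold, correct_threshold):
            rows.append(
                (p.id, p.sequence_id, f.trial, f.rt_ms, f.dist_to_next,
                 f.dist_from_prev, f.label, f.correct)
            )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "sequence_id", "trial", "rt_ms",
                 "dist_to_next", "dist_from_prev", "label", "correct"],
    )


def blocks_table(cohort: list[ParticipantRecord], **kwargs) -> pd.DataFrame:
    """Per-participant block summaries: proportion predictive and excess score."""
    rows = []
    for p in cohort:
        feats = participant_features(p, **kwargs)
        for b in block_summaries(feats):
            rows.append((p.id, p.sequence_id, b.block, b.prop_predictive, b.excess_score))
    return pd.DataFrame(
        rows, columns=["participant_id", "sequence_id", "block",
                       "prop_predictive", "excess_score"]
    )


def predictive_proportion_final_blocks(blocks: pd.DataFrame, n_blocks: int = 2) -> pd.Series:
    """Per-participant predictive proportion over the last ``n_blocks`` blocks."""
    last = blocks["block"].max()
    sel = blocks[blocks["block"] > last - n_blocks]
    return sel.groupby("participant_id")["prop_predictive"].mean()
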