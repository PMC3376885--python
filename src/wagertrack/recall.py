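"""Scoring of the 24-click recall output.

Two scores per participant:

* **recall regularity** — the same redundancy G used for training sequences,
  applied to the 24 recalled positions (unobserved symbols contribute zero
  entropy).
* **match percent** — a cross-recurrence alignment score against the 48-item
  training sequence: build the 48x24 cross-recurrence matrix (cell (i, j) is
  1 iff training[i] == recall[j]) and take the best diagonal, i.e.

      match = 100 * max_{d in 0..24} (1/24) * sum_j [training[j+d] == recall[j]]

  Negative lags (recall leading training) are excluded by default.  A
  normalized longest-common-subsequence variant is available for sensitivity
  analysis (``method="lcs"``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sequences import RegularityScore, SymbolSequence, redundancy_G


def recall_regularity(recall: SymbolSequence) -> RegularityScore:
    """Redundancy G of a 24-item recall sequence."""
    return redundancy_G(recall)


def match_score(
    training: SymbolSequence,
    recall: SymbolSequence,
    method: str = "diagonal",
    include_negative_lags: bool = False,
) -> float:
    """Percent match between recall and training, in [0, 100].

    ``method="diagonal"`` (default): best single-diagonal cross-recurrence
    alignment, denominator 24.  ``method="lcs"``: longest common subsequence
    length divided by 24.
    """
    t = np.asarray(training.items)
    r = np.asarray(recall.items)
    if method == "lcs":
        return 100.0 * _lcs_length(t, r) / len(r)
    if method != "diagonal":
        raise ValueError(f"unknown method: {method!r}")
    n_t, n_r = len(t), len(r)
    lags = range(-(n_r - 1) if include_negative_lags else 0, n_t - n_r + 1)
    best = 0
    for d in lags:
        lo = max(0, -d)
        hi = min(n_r, n_t - d)
        if hi <= lo:
            continue
        best = max(best, int((t[lo + d : hi + d] == r[lo:hi]).sum()))
    return 100.0 * best / n_r


def _lcs_length(a: np.ndarray, b: np.ndarray) -> int:
    prev = np.zeros(len(b) + 1, dtype=int)
    for x in a:
        cur = prev.copy()
        for j, y in enumerate(b, start=1):
            cur[j] = prev[j - 1] + 1 if x == y else max(cur[j - 1], prev[j])
        prev = cur
    return int(prev[-1])


def score_cohort(
    participants,
    blocks: pd.DataFrame,
    method: str = "diagonal",
) -> pd.DataFrame:
    """Per-participant recall scores joined with the covariates the analyses use.

    Columns: participant_id, sequence_id, training_G, recall_G, match_percent,
    pred_prop_final (predictive proportion over the last two blocks),
    awareness, flagged (True when recall is missing; excluded downstream).
    """
    from .features import predictive_proportion_final_blocks

    pred_final = predictive_proportion_final_blocks(blocks, n_blocks=2)
    rows = []
    for p in participants:
        has_recall = p.recall is not None and len(p.recall) > 0
        train_G = redundancy_G(p.sequence).G
        rows.append(
            {
                "participant_id": p.id,
                "sequence_id": p.sequence_id,
                "training_G": train_G,
                "recall_G": recall_regularity(p.recall).G if has_recall else np.nan,
                "match_percent": match_score(p.sequence, p.recall, method=method)
                if has_recall
                else np.nan,
                "pred_prop_final": pred_final.get(p.id, np.nan),
                "awareness": p.awareness,
                "flagged": not has_recall,
            }
        )
    return pd.DataFrame(rows)
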