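"""Flat CSV schemas for cohorts and round-trip readers.

Three files describe a cohort:

* ``events.csv`` — participant_id, trial, symbol, onset_ms, click_ms
* ``samples.csv`` — participant_id, trial, t_ms, x, y (the ISI stream
  preceding that trial's onset)
* ``participants.csv`` — id, sequence_id, sequence, awareness, recall
  (sequences as dash-separated strings)

UTF-8, header row, period decimal separator.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ParticipantRecord, TrialRecord
from .sequences import SymbolSequence

EVENT_COLUMNS = ["participant_id", "trial", "symbol", "onset_ms", "click_ms"]
SAMPLE_COLUMNS = ["participant_id", "trial", "t_ms", "x", "y"]
PARTICIPANT_COLUMNS = ["id", "sequence_id", "sequence", "awareness", "recall"]


def cohort_frames(cohort: list[ParticipantRecord]) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Flatten a cohort into (events, samples, participants) DataFrames."""
    ev_rows, sm_chunks, pp_rows = [], [], []
    for p in cohort:
        for tr in p.trials:
            ev_rows.append((p.id, tr.index, tr.symbol, tr.onset_ms, tr.click_ms))
            sm_chunks.append(
                pd.DataFrame(
                    {
                        "participant_id": p.id,
                        "trial": tr.index,
                        "t_ms": tr.isi_t,
                        "x": tr.isi_x,
                        "y": tr.isi_y,
                    }
                )
            )
        pp_rows.append(
            (p.id, p.sequence_id, p.sequence.to_string(), p.awareness, p.recall.to_string())
        )
    events = pd.DataFrame(ev_rows, columns=EVENT_COLUMNS)
    samples = pd.concat(sm_chunks, ignore_index=True) if sm_chunks else pd.DataFrame(columns=SAMPLE_COLUMNS)
    participants = pd.DataFrame(pp_rows, columns=PARTICIPANT_COLUMNS)
    return events, samples, participants


def write_cohort(cohort: list[ParticipantRecord], out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events, samples, participants = cohort_frames(cohort)
    paths = {
        "events": out / "events.csv",
        "samples": out / "samples.csv",
        "participants": out / "participants.csv",
    }
    events.to_csv(paths["events"], index=False)
    samples.to_csv(paths["samples"], index=False)
    participants.to_csv(paths["participants"], index=False)
    return paths


def read_cohort(in_dir: str | Path) -> list[ParticipantRecord]:
    """Rebuild in-memory participant records from the three CSVs."""
    in_dir = Path(in_dir)
    events = pd.read_csv(in_dir / "events.csv")
    samples = pd.read_csv(in_dir / "samples.csv")
    participants = pd.read_csv(in_dir / "participants.csv")
    sm_grouped = {k: g for k, g in samples.groupby(["participant_id", "trial"], sort=False)}
    cohort = []
    for _, prow in participants.iterrows():
        pid = prow["id"]
        trials = []
        for _, erow in events[events["participant_id"] == pid].sort_values("trial").iterrows():
            g = sm_grouped.get((pid, erow["trial"]))
            trials.append(
                TrialRecord(
                    index=int(erow["trial"]),
                    symbol=int(erow["symbol"]),
                    onset_ms=float(erow["onset_ms"]),
                    click_ms=float(erow["click_ms"]),
                    isi_t=g["t_ms"].to_numpy() if g is not None else np.array([]),
                    isi_x=g["x"].to_numpy() if g is not None else np.array([]),
                    isi_y=g["y"].to_numpy() if g is not None else np.array([]),
                )
            )
        cohort.append(
            ParticipantRecord(
                id=pid,
                sequence_id=prow["sequence_id"],
                sequence=SymbolSequence.from_string(prow["sequence"], role="training"),
                trials=trials,
                recall=SymbolSequence.from_string(prow["recall"], role="recall"),
                awareness=float(prow["awareness"]),
                predictive_mode=None,
            )
        )
    return cohort
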