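"""Synthetic cohort simulator for the cursor-tracking sequence-learning task.

Each simulated participant performs a 48-trial serial reaction time task on a
500x500-px canvas with four circular targets in a 2x2 grid.  Stimuli follow an
assigned training sequence with a 750-ms inter-stimulus interval (ISI) between
a click and the next onset; the cursor is sampled at ~40 Hz throughout.

The agent keeps additively-smoothed first-order transition counts over the
observed symbols.  During each ISI it behaves in one of two modes:

* **reactive** — it waits at the just-clicked target or (with probability
  ``centering_propensity``) moves to the canvas center, the equidistant
  "readying" position;
* **predictive** — it wagers: it commits a straight movement toward an
  expected target.  The wagered target is drawn by probability matching from
  the agent's smoothed successor distribution (sharpened by
  ``guess_sharpness``; large values recover a pure argmax with uniform tie
  breaking).  Early wagers are therefore often *incorrect* — prediction
  precedes accurate knowledge — and sharpen as evidence accumulates.

The agent enters predictive mode once its maximum successor probability
reaches ``wager_threshold`` and tends to stay there (``wager_stickiness``).
Movement is straight-line at ``motor_speed`` with isotropic per-sample noise.

Reaction time is emergent, not injected: click latency combines a base
latency, travel time proportional to the cursor-to-target distance at onset,
and an expectancy facilitation proportional to the agent's internal
probability of the symbol that actually appeared.  The last term makes
RT facilitation with sequence regularity arise even in agents that never
wager (implicit learning without overt prediction).

After training the agent free-generates a 24-item recall sequence from its
learned transition table, and reports pattern awareness on a 100-400 scale
as a noisy logistic function of its late-training predictive proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .sequences import SymbolSequence, validate_sequence, ALPHABET

ISI_MS = 750.0
SAMPLE_PERIOD_MS = 25.0  # ~40 Hz
CANVAS = 500.0


@dataclass(frozen=True)
class Layout:
    """Canvas geometry: four targets in a 2x2 grid, labels 1-4 in reading order.

    Targets sit near the corners so that any between-target movement exceeds
    the 275-px axis-max predictive threshold while a move to center (165 px)
    does not.
    """

    canvas: float = CANVAS
    target_radius: float = 17.5
    target_centers: tuple[tuple[float, float], ...] = (
        (85.0, 85.0),
        (415.0, 85.0),
        (85.0, 415.0),
        (415.0, 415.0),
    )

    def __post_init__(self) -> None:
        for x, y in self.target_centers:
            if not (self.target_radius <= x <= self.canvas - self.target_radius):
                raise ValueError("target circle extends outside canvas (x)")
            if not (self.target_radius <= y <= self.canvas - self.target_radius):
                raise ValueError("target circle extends outside canvas (y)")
        pts = np.asarray(self.target_centers)
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.linalg.norm(pts[i] - pts[j]) <= 2 * self.target_radius:
                    raise ValueError("target circles overlap")

    def center_of(self, symbol: int) -> np.ndarray:
        return np.asarray(self.target_centers[symbol - 1], dtype=float)

    @property
    def canvas_center(self) -> np.ndarray:
        return np.array([self.canvas / 2.0, self.canvas / 2.0])


#: Sentinel wager threshold that can never be reached: disables wagering.
NEVER = 1.01


@dataclass
class AgentParams:
    """Behavioral parameters of the simulated participant.

    wager_threshold : max successor probability at which the agent commits to
        predictive movements (set to :data:`NEVER` to disable wagering).
    wager_stickiness : probability of staying predictive once entered.
    centering_propensity : probability a reactive ISI moves to canvas center
        rather than waiting at the previous target.
    motor_speed : cursor speed, px/s.
    motor_noise_sd : isotropic per-sample positional jitter, px.
    base_latency_ms, latency_noise_sd_ms : reaction-time intercept and noise.
    expectancy_gain_ms : RT facilitation at internal probability 1 vs. chance.
    smoothing_pseudocount : additive smoothing of internal transition counts.
    guess_sharpness : exponent on the successor distribution when drawing a
        wagered target; 1 = probability matching, ``inf``-like values = argmax.
    awareness_slope, awareness_offset : logistic link from late predictive
        proportion to the 100-400 awareness scale.
    awareness_noise_sd : Gaussian noise on the awareness report.
    """

    wager_threshold: float = 0.75
    wager_stickiness: float = 0.95
    centering_propensity: float = 0.5
    motor_speed: float = 700.0
    motor_noise_sd: float = 8.0
    base_latency_ms: float = 250.0
    latency_noise_sd_ms: float = 30.0
    expectancy_gain_ms: float = 120.0
    smoothing_pseudocount: float = 0.1
    guess_sharpness: float = 1.0
    awareness_slope: float = 5.0
    awareness_offset: float = -2.5
    awareness_noise_sd: float = 150.0

    def validate(self) -> None:
        probs = {
            "wager_stickiness": self.wager_stickiness,
            "centering_propensity": self.centering_propensity,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"config-error: {name}={p} outside [0,1]")
        if not 0.0 < self.wager_threshold <= NEVER:
            raise ValueError("config-error: wager_threshold outside (0, 1.01]")
        for name in ("motor_speed", "motor_noise_sd", "latency_noise_sd_ms",
                     "awareness_noise_sd", "smoothing_pseudocount"):
            if getattr(self, name) < 0:
                raise ValueError(f"config-error: {name} must be non-negative")
        if self.motor_speed <= 0:
            raise ValueError("config-error: motor_speed must be positive")
        if self.guess_sharpness <= 0:
            raise ValueError("config-error: guess_sharpness must be positive")


@dataclass
class TrialRecord:
    """One stimulus event with the cursor stream of its preceding ISI."""

    index: int  # 1-48
    symbol: int  # 1-4
    onset_ms: float
    click_ms: float
    isi_t: np.ndarray  # sample times, ms
    isi_x: np.ndarray
    isi_y: np.ndarray

    @property
    def rt_ms(self) -> float:
        return self.click_ms - self.onset_ms


@dataclass
class ParticipantRecord:
    id: str
    sequence_id: str
    sequence: SymbolSequence
    trials: list[TrialRecord]
    recall: SymbolSequence
    awareness: float
    predictive_mode: np.ndarray = field(default=None)  # agent-internal per-trial flags


def _isi_samples(rng: np.random.Generator, t0: float) -> np.ndarray:
    """Sample times covering [t0, t0 + 750) at ~40 Hz with bounded jitter."""
    n = int(ISI_MS // SAMPLE_PERIOD_MS)
    base = t0 + np.arange(n) * SAMPLE_PERIOD_MS
    jitter = rng.uniform(-2.0, 2.0, size=n)
    jitter[0] = abs(jitter[0])  # keep first sample inside the ISI
    t = base + jitter
    return np.maximum.accumulate(t)  # strictly increasing up to float ties


def _move_path(
    start: np.ndarray,
    goal: np.ndarray,
    t: np.ndarray,
    t0: float,
    speed: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Straight-line positions at sample times, capped at the goal, plus noise."""
    vec = goal - start
    dist = float(np.linalg.norm(vec))
    elapsed_s = (t - t0) / 1000.0
    travelled = np.minimum(elapsed_s * speed, dist)
    if dist > 0:
        pos = start[None, :] + (travelled / dist)[:, None] * vec[None, :]
    else:
        pos = np.repeat(start[None, :], len(t), axis=0)
    if noise_sd > 0:
        pos = pos + rng.normal(0.0, noise_sd, size=pos.shape)
    return np.clip(pos, 0.0, CANVAS)


def simulate_participant(
    seq: SymbolSequence,
    params: AgentParams | None = None,
    layout: Layout | None = None,
    seed: int | np.random.Generator = 0,
    participant_id: str = "p0",
    sequence_id: str = "seq",
) -> ParticipantRecord:
    """Simulate one participant on a training sequence.

    Deterministic for a fixed seed.  See the module docstring for the
    behavioral model.
    """
    params = params or AgentParams()
    layout = layout or Layout()
    params.validate()
    report = validate_sequence(seq, "training")
    if not report.passed:
        raise ValueError(f"invalid training sequence: {report.violations}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    alpha = params.smoothing_pseudocount
    counts = np.zeros((4, 4))
    predictive = False
    pred_flags = np.zeros(len(seq), dtype=bool)

    trials: list[TrialRecord] = []
    cursor = layout.canvas_center.copy()
    t_clock = 0.0
    prev_symbol: int | None = None

    for idx, symbol in enumerate(seq.items, start=1):
        # --- ISI preceding this onset: plan and move ---------------------
        isi_t = _isi_samples(rng, t_clock)
        if prev_symbol is None:
            goal = layout.canvas_center  # pre-experiment: cursor rests at center
            pred_flags_this = False
        else:
            row = counts[prev_symbol - 1] + alpha
            probs = row / row.sum()
            p_max = float(probs.max())
            if predictive:
                predictive = rng.random() < params.wager_stickiness or p_max >= params.wager_threshold
            if not predictive and p_max >= params.wager_threshold:
                predictive = True
            pred_flags_this = predictive
            if predictive:
                # wager: probability-matched draw over the other three targets
                # (the task never repeats a position, so the previous one is out)
                w = probs.copy()
                w[prev_symbol - 1] = 0.0
                w = (w / w.max()) ** params.guess_sharpness
                guess = int(rng.choice(ALPHABET, p=w / w.sum()))
                goal = layout.center_of(guess)
            elif rng.random() < params.centering_propensity:
                goal = layout.canvas_center
            else:
                goal = layout.center_of(prev_symbol)
        pred_flags[idx - 1] = pred_flags_this
        pos = _move_path(cursor, goal, isi_t, t_clock, params.motor_speed,
                         params.motor_noise_sd, rng)
        cursor = pos[-1].copy()

        onset = t_clock + ISI_MS
        target = layout.center_of(symbol)

        # --- expectancy of the observed symbol (before updating counts) --
        if prev_symbol is not None:
            row = counts[prev_symbol - 1] + alpha
            p_obs = float(row[symbol - 1] / row.sum())
            counts[prev_symbol - 1, symbol - 1] += 1.0
        else:
            p_obs = 0.25

        # --- click latency ------------------------------------------------
        dist_at_onset = float(np.linalg.norm(cursor - target))
        latency = (
            params.base_latency_ms
            + dist_at_onset / params.motor_speed * 1000.0
            - params.expectancy_gain_ms * (p_obs - 0.25)
            + rng.normal(0.0, params.latency_noise_sd_ms)
        )
        click = onset + max(latency, 0.0)
        trials.append(
            TrialRecord(index=idx, symbol=symbol, onset_ms=onset, click_ms=click,
                        isi_t=isi_t, isi_x=pos[:, 0], isi_y=pos[:, 1])
        )
        cursor = target + (rng.normal(0.0, params.motor_noise_sd / 2, size=2)
                           if params.motor_noise_sd > 0 else 0.0)
        t_clock = click
        prev_symbol = symbol

    # --- recall: free generation from the learned table ------------------
    recall_items = []
    current = int(rng.integers(1, 5))
    recall_items.append(current)
    for _ in range(23):
        row = counts[current - 1] + alpha
        current = int(rng.choice(ALPHABET, p=row / row.sum()))
        recall_items.append(current)
    recall = SymbolSequence(tuple(recall_items), role="recall")

    # --- awareness: logistic in the final-two-block predictive proportion -
    p_pred = float(pred_flags[-12:].mean())
    z = params.awareness_slope * p_pred + params.awareness_offset
    aware = 100.0 + 300.0 / (1.0 + math.exp(-z)) + rng.normal(0.0, params.awareness_noise_sd)
    aware = float(np.clip(aware, 100.0, 400.0))

    return ParticipantRecord(
        id=participant_id,
        sequence_id=sequence_id,
        sequence=seq,
        trials=trials,
        recall=recall,
        awareness=aware,
        predictive_mode=pred_flags,
    )


def simulate_cohort(
    sequences: Sequence[SymbolSequence],
    n_per_sequence: int = 13,
    params: AgentParams | None = None,
    layout: Layout | None = None,
    seed: int = 0,
    sequence_ids: Sequence[str] | None = None,
) -> list[ParticipantRecord]:
    """Simulate ``n_per_sequence`` independent participants per sequence.

    Participants receive independent child seeds from a single seed sequence,
    so the cohort is reproducible as a whole.
    """
    if n_per_sequence < 0:
        raise ValueError("n_per_sequence must be >= 0")
    if sequence_ids is None:
        sequence_ids = [f"s{i}" for i in range(len(sequences))]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(sequences) * n_per_sequence)
    cohort: list[ParticipantRecord] = []
    k = 0
    for sid, seq in zip(sequence_ids, sequences):
        for j in range(n_per_sequence):
            rng = np.random.default_rng(children[k])
            cohort.append(
                simulate_participant(
                    seq, params=params, layout=layout, seed=rng,
                    participant_id=f"{sid}_p{j}", sequence_id=sid,
                )
            )
            k += 1
    return cohort


def default_params() -> AgentParams:
    return AgentParams()


def params_to_dict(params: AgentParams) -> dict:
    return asdict(params)
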