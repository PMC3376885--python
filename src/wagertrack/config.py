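"""Pipeline configuration: task constants, agent parameters, analysis switches.

Defaults mirror the task design: 275-px predictive threshold, 100-px correct
threshold, 6-trial blocks, 750-ms ISI, awareness cutoff at the scale
midpoint (250, "somewhat patterned").
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import AgentParams, Layout
from .stats import SOMEWHAT_PATTERNED


@dataclass
class PipelineConfig:
    seed: int = 42
    n_per_sequence: int = 13
    agent: AgentParams = field(default_factory=AgentParams)
    layout: Layout = field(default_factory=Layout)
    predictive_threshold_px: float = 275.0
    correct_threshold_px: float = 100.0
    block_size: int = 6
    awareness_cutoff: float = SOMEWHAT_PATTERNED
    distance_metric: str = "chebyshev"  # or "euclidean"
    match_method: str = "diagonal"  # or "lcs"
    out_dir: str = "results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["layout"]["target_centers"] = [list(c) for c in d["layout"]["target_centers"]]
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML/JSON file plus keyword overrides.

    Unknown keys raise a config-error naming the key.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"config-error: unknown key(s): {sorted(unknown)}")
    if "agent" in data and isinstance(data["agent"], dict):
        agent_known = {f.name for f in dataclasses.fields(AgentParams)}
        bad = set(data["agent"]) - agent_known
        if bad:
            raise ValueError(f"config-error: unknown agent key(s): {sorted(bad)}")
        data["agent"] = AgentParams(**data["agent"])
    if "layout" in data and isinstance(data["layout"], dict):
        lay = dict(data["layout"])
        if "target_centers" in lay:
            lay["target_centers"] = tuple(tuple(c) for c in lay["target_centers"])
        data["layout"] = Layout(**lay)
    cfg = PipelineConfig(**data)
    cfg.agent.validate()
    return cfg
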