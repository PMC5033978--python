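"""Structured run configuration: YAML round-trip and validation.

A RunConfig aggregates the protocol counts, the physics, the learner and
the analysis settings, plus the seed and cohort size.  Its defaults
reproduce the standard protocol constants: 617 post-familiarization trials
in 22 blocks, 30-trial assessment blocks, 18 field trials per adaptation
block, 192 familiarization trials, a 15 N s/m curl gain, a 5000 N/m /
30 N s/m channel, a 350-450 ms success window, 2.25 cm onset and 0.75 cm
end thresholds, and a 1 cm curved-cursor deviation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .decayfit import AnalysisConfig
from .protocol import ProtocolConfig
from .simulate import (ChannelParams, CohortConfig, ControllerParams,
                       FieldParams, GROUPS, LearnerParams)


@dataclass
class RunConfig:
    """Everything one end-to-end run needs."""

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    field_params: FieldParams = field(default_factory=FieldParams)
    channel: ChannelParams = field(default_factory=ChannelParams)
    controller: ControllerParams = field(default_factory=ControllerParams)
    learner: LearnerParams = field(default_factory=LearnerParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    groups: tuple = GROUPS
    n_per_group: int = 15
    seed: int = 0
    mode: str = "fast"

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            protocol=self.protocol, field_params=self.field_params,
            channel=self.channel, controller=self.controller,
            learner=self.learner, groups=tuple(self.groups),
            n_per_group=self.n_per_group,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(self.groups)
        d["protocol"]["expected_total"] = self.protocol.expected_total
        d["analysis"]["fit_blocks"] = list(self.analysis.fit_blocks)
        d["analysis"]["b_bounds"] = list(self.analysis.b_bounds)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        sections = {
            "protocol": ProtocolConfig, "field_params": FieldParams,
            "channel": ChannelParams, "controller": ControllerParams,
            "learner": LearnerParams, "analysis": AnalysisConfig,
        }
        for name, klass in sections.items():
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = klass(**kwargs[name])
        if "groups" in kwargs:
            kwargs["groups"] = tuple(kwargs["groups"])
        if isinstance(kwargs.get("analysis"), AnalysisConfig):
            a = kwargs["analysis"]
            a.fit_blocks = tuple(a.fit_blocks)
            a.b_bounds = tuple(a.b_bounds)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violated invariants (empty iff the config is valid)."""
    v: list[str] = []
    p = config.protocol
    for name in ("familiarization_trials", "n1_null_trials", "n_ff_blocks",
                 "ff_trials_per_block", "n_ec_blocks", "ec_block_trials",
                 "n2_null_trials"):
        if getattr(p, name) <= 0:
            v.append(f"protocol.{name}: must be positive")
    for name in ("n1_iec_trials", "iec_per_ff_block", "n2_iec_trials"):
        if getattr(p, name) < 0:
            v.append(f"protocol.{name}: must be non-negative")
    if p.iec_per_ff_block >= p.ff_trials_per_block:
        v.append("protocol.iec_per_ff_block: must be fewer than the host block's field trials")
    if p.expected_total is not None:
        computed = (p.n1_null_trials + p.n1_iec_trials
                    + p.n_ff_blocks * (p.ff_trials_per_block + p.iec_per_ff_block)
                    + p.n_ec_blocks * p.ec_block_trials
                    + p.n2_null_trials + p.n2_iec_trials)
        if computed != p.expected_total:
            v.append(f"protocol: block counts sum to {computed}, "
                     f"expected_total is {p.expected_total}")

    if config.field_params.g_field <= 0:
        v.append("field_params.g_field: must be positive")
    if config.channel.stiffness < 0:
        v.append("channel.stiffness: must be non-negative")
    if config.channel.damping < 0:
        v.append("channel.damping: must be non-negative")

    c = config.controller
    if c.mass <= 0:
        v.append("controller.mass: must be positive")
    if c.target_movement_time_ms <= 0:
        v.append("controller.target_movement_time_ms: must be positive")

    le = config.learner
    if not (0 < le.retention_fast < le.retention_slow < 1):
        v.append("learner: need 0 < retention_fast < retention_slow < 1")
    if not (le.learn_fast > le.learn_slow > 0):
        v.append("learner: need learn_fast > learn_slow > 0")
    for g in config.groups:
        if g not in le.clamp_error_gain:
            v.append(f"learner.clamp_error_gain: missing entry for group {g!r}")
    if any(g < 0 for g in le.clamp_error_gain.values()):
        v.append("learner.clamp_error_gain: gains must be non-negative")

    a = config.analysis
    if a.subsample_k <= 0:
        v.append("analysis.subsample_k: must be positive")
    if a.subsample_k > config.n_per_group:
        v.append("analysis.subsample_k: cannot exceed n_per_group")
    if a.permutation_rule not in ("two-sided", "one-sided"):
        v.append("analysis.permutation_rule: must be 'two-sided' or 'one-sided'")
    if config.n_per_group <= 0:
        v.append("n_per_group: must be positive")
    if config.mode not in ("fast", "trajectory"):
        v.append("mode: must be 'fast' or 'trajectory'")
    return v
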