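"""Trial schedule for a force-field adaptation experiment with error-clamp probes.

The session alternates adaptation blocks and assessment blocks: after a
null-field familiarization period and a null-field baseline block (N1), the
participant alternates force-field blocks (FF1..FF10) with error-clamp
assessment blocks (EC1..EC9), then washes out in a second null block (N2)
before a final recall probe (EC10).  A small number of error-clamp trials are
additionally interspersed ("IEC") at unpredictable positions inside the
baseline and force-field blocks to probe adaptation mid-learning.

Phases
------
FAM  familiarization reach, no perturbation
N    null-field trial (baseline or washout)
FF   velocity-dependent curl-field trial
EC   error-clamp trial inside an assessment block
IEC  error-clamp trial interspersed inside an N or FF block
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

PHASES = ("FAM", "N", "FF", "EC", "IEC")
FEEDBACK_CONDITIONS = ("arc", "cursor", "augmented")

#: IEC positions may not fall on the first trials of their host block, so that
#: block-entry behavior is always probed under the block's own field.
IEC_EXCLUDED_LEAD = 3


class ScheduleError(ValueError):
    """Raised when a protocol configuration cannot produce a valid schedule."""


@dataclass
class ProtocolConfig:
    """Counts defining the session layout.

    Defaults reproduce the standard session: 192 familiarization trials, then
    617 trials in 22 blocks (N1 of 72 incl. 6 interspersed clamps, ten
    force-field blocks of 18 FF + 2 interspersed clamps, ten error-clamp
    blocks of 30, and a 45-trial washout before the recall probe).
    """

    familiarization_trials: int = 192
    n1_null_trials: int = 66
    n1_iec_trials: int = 6
    n_ff_blocks: int = 10
    ff_trials_per_block: int = 18
    iec_per_ff_block: int = 2
    n_ec_blocks: int = 10
    ec_block_trials: int = 30
    n2_null_trials: int = 45
    n2_iec_trials: int = 0
    #: If set, schedule construction fails unless the post-familiarization
    #: trial count matches exactly.
    expected_total: int | None = 617
    expected_blocks: int | None = 22
    #: Seed for the placement of interspersed clamp trials.  Kept separate
    #: from the cohort seed so that noise realizations can vary while the
    #: schedule stays fixed.
    iec_seed: int = 7


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial."""

    global_index: int          # 1-based, counted from the first familiarization trial
    phase: str                 # one of PHASES
    block_label: str           # "FAM", "N1", "FF3", "EC9", ...
    within_block_index: int    # 1-based position inside the block
    feedback: str              # group-level rendering condition for EC/IEC trials

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ScheduleError(f"unknown phase {self.phase!r}")
        if self.feedback not in FEEDBACK_CONDITIONS:
            raise ScheduleError(f"unknown feedback condition {self.feedback!r}")

    @property
    def is_channel(self) -> bool:
        return self.phase in ("EC", "IEC")


@dataclass
class Schedule:
    """Ordered experiment plan for one participant."""

    trials: list[TrialSpec]
    config_digest: str = ""

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def post_familiarization_trials(self) -> int:
        return sum(1 for t in self.trials if t.phase != "FAM")

    @property
    def block_labels(self) -> list[str]:
        """Block labels in order of first occurrence, familiarization excluded."""
        labels: list[str] = []
        for t in self.trials:
            if t.block_label != "FAM" and (not labels or labels[-1] != t.block_label):
                labels.append(t.block_label)
        return labels

    @property
    def n_blocks(self) -> int:
        return len(self.block_labels)

    def block(self, label: str) -> list[TrialSpec]:
        return [t for t in self.trials if t.block_label == label]

    def validate(self, config: ProtocolConfig | None = None) -> None:
        """Check structural invariants; raise ScheduleError on violation."""
        prev_label = None
        expected_within = 1
        for i, t in enumerate(self.trials, start=1):
            if t.global_index != i:
                raise ScheduleError(f"global_index not contiguous at trial {i}")
            if t.block_label != prev_label:
                prev_label = t.block_label
                expected_within = 1
            if t.within_block_index != expected_within:
                raise ScheduleError(
                    f"within_block_index not contiguous in block {t.block_label}"
                )
            expected_within += 1
            if t.phase == "IEC" and t.block_label.startswith("EC"):
                raise ScheduleError("IEC trial inside an assessment EC block")
            if t.phase == "EC" and not t.block_label.startswith("EC"):
                raise ScheduleError("EC trial outside an assessment EC block")
        if config is not None:
            total = self.post_familiarization_trials
            if config.expected_total is not None and total != config.expected_total:
                raise ScheduleError(
                    f"post-familiarization trial count {total} != configured "
                    f"total {config.expected_total}"
                )
            if config.expected_blocks is not None and self.n_blocks != config.expected_blocks:
                raise ScheduleError(
                    f"block count {self.n_blocks} != configured "
                    f"{config.expected_blocks}"
                )
            for label in self.block_labels:
                if label.startswith("EC") and len(self.block(label)) != config.ec_block_trials:
                    raise ScheduleError(
                        f"assessment block {label} has {len(self.block(label))} "
                        f"trials, expected {config.ec_block_trials}"
                    )

    # -- serialization --------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "global_index": [t.global_index for t in self.trials],
                "phase": [t.phase for t in self.trials],
                "block_label": [t.block_label for t in self.trials],
                "within_block_index": [t.within_block_index for t in self.trials],
                "feedback": [t.feedback for t in self.trials],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, config_digest: str = "") -> "Schedule":
        trials = [
            TrialSpec(
                global_index=int(r.global_index),
                phase=str(r.phase),
                block_label=str(r.block_label),
                within_block_index=int(r.within_block_index),
                feedback=str(r.feedback),
            )
            for r in frame.itertuples(index=False)
        ]
        return cls(trials=trials, config_digest=config_digest)

    @classmethod
    def read_csv(cls, path, config_digest: str = "") -> "Schedule":
        return cls.from_frame(pd.read_csv(path), config_digest=config_digest)


def config_digest(config: ProtocolConfig) -> str:
    """Stable short token identifying a protocol configuration."""
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def place_iec(host_block_length: int, n_iec: int, rng: np.random.Generator) -> list[int]:
    """Pick within-block positions (1-based) for interspersed clamp trials.

    Positions are unique, sorted, and never within the first
    ``IEC_EXCLUDED_LEAD`` trials of the block, so that entry into each block
    is always performed under the block's nominal field.
    """
    if n_iec < 0:
        raise ScheduleError("n_iec must be non-negative")
    if n_iec == 0:
        return []
    if n_iec >= host_block_length:
        raise ScheduleError(
            f"cannot place {n_iec} interspersed clamp trials in a block of "
            f"{host_block_length} trials"
        )
    candidates = np.arange(IEC_EXCLUDED_LEAD + 1, host_block_length + 1)
    if n_iec > candidates.size:
        raise ScheduleError(
            f"cannot place {n_iec} interspersed clamp trials outside the "
            f"first {IEC_EXCLUDED_LEAD} trials of a {host_block_length}-trial block"
        )
    chosen = rng.choice(candidates, size=n_iec, replace=False)
    return sorted(int(p) for p in chosen)


def _host_block(label: str, base_phase: str, n_base: int, n_iec: int,
                rng: np.random.Generator) -> list[tuple[str, str]]:
    """Expand one N or FF block (with interspersed clamps) into (phase, label) pairs."""
    length = n_base + n_iec
    iec_positions = set(place_iec(length, n_iec, rng))
    return [
        ("IEC" if pos in iec_positions else base_phase, label)
        for pos in range(1, length + 1)
    ]


def build_schedule(config: ProtocolConfig | None = None,
                   feedback: str = "cursor") -> Schedule:
    """Build the default alternating schedule.

    Block order: FAM, N1, (FF_i, EC_i) for i = 1..n-1, FF_n, N2, EC_n — the
    last assessment block is the recall probe that follows the washout.
    Deterministic given the configuration (interspersed-clamp placement is
    driven by ``config.iec_seed``).
    """
    config = config or ProtocolConfig()
    for name in ("familiarization_trials", "n1_null_trials", "n_ff_blocks",
                 "ff_trials_per_block", "n_ec_blocks", "ec_block_trials",
                 "n2_null_trials"):
        if getattr(config, name) <= 0:
            raise ScheduleError(f"protocol count {name} must be positive")
    if config.n_ec_blocks < 2:
        raise ScheduleError("need at least one assessment block plus the recall probe")

    rng = np.random.default_rng(config.iec_seed)
    plan: list[tuple[str, str]] = []
    plan += [("FAM", "FAM")] * config.familiarization_trials
    plan += _host_block("N1", "N", config.n1_null_trials, config.n1_iec_trials, rng)
    for i in range(1, config.n_ff_blocks + 1):
        plan += _host_block(f"FF{i}", "FF", config.ff_trials_per_block,
                            config.iec_per_ff_block, rng)
        if i < config.n_ec_blocks:
            plan += [("EC", f"EC{i}")] * config.ec_block_trials
    plan += _host_block("N2", "N", config.n2_null_trials, config.n2_iec_trials, rng)
    plan += [("EC", f"EC{config.n_ec_blocks}")] * config.ec_block_trials

    trials: list[TrialSpec] = []
    within = 0
    prev_label = None
    for gi, (phase, label) in enumerate(plan, start=1):
        within = 1 if label != prev_label else within + 1
        prev_label = label
        trials.append(TrialSpec(gi, phase, label, within, feedback))

    schedule = Schedule(trials=trials, config_digest=config_digest(config))
    schedule.validate(config)
    return schedule


# Name used in the interface contract of downstream modules.
build_default_schedule = build_schedule
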