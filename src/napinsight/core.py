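"""Core data containers shared across the simulation and analysis layers.

The containers mirror the objects of a nap-intervention insight study:
trial-wise behaviour on a random-dot motion/colour task (``SessionData``),
a multichannel nap EEG recording (``Recording``) and its 30-s sleep-stage
annotation (``Hypnogram``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: AASM stage codes ordered by sleep depth.
STAGE_ORDER = {"W": 0, "N1": 1, "N2": 2, "N3": 3}

#: Motion-coherence levels of the task, as fractions of coherently moving dots.
COHERENCE_LEVELS = (0.05, 0.23, 0.41, 0.59, 0.76, 1.00)

#: The three easiest (least noisy) coherence levels, used by the learning filter.
EASY_COHERENCES = (0.41, 0.59, 0.76)

#: Diagonal motion directions mapped to the left response key.
LEFT_DIRECTIONS = ("NW", "SE")
RIGHT_DIRECTIONS = ("NE", "SW")


@dataclass(frozen=True)
class TrialRecord:
    """A single task trial with its stimulus attributes and outcome."""

    block: int
    trial_index: int  # 1-based position in the 900-trial session
    coherence: float
    colour: str  # "orange" | "purple"
    direction: str  # "NW" | "NE" | "SW" | "SE"
    response: str  # "left" | "right" | "" (schedule only)
    correct: bool
    rt_ms: float
    colour_predictive: bool = False
    instructed: bool = False


@dataclass
class SessionData:
    """One subject's 900-trial session with the standard phase markers.

    The hidden colour rule becomes active at ``colour_onset_trial`` (trial
    351, mid block 4), the nap break separates trials 400 and 401, and the
    final block (9) is performed under explicit colour instruction.
    """

    trials: list[TrialRecord]
    subject_id: str = ""
    colour_onset_trial: int = 351
    nap_boundary_trial: int = 400
    instruction_block: int = 9

    def __post_init__(self) -> None:
        if len(self.trials) == 0:
            raise ValueError("SessionData requires at least one trial")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": [t.block for t in self.trials],
                "trial": [t.trial_index for t in self.trials],
                "coherence": [t.coherence for t in self.trials],
                "colour": [t.colour for t in self.trials],
                "direction": [t.direction for t in self.trials],
                "response": [t.response for t in self.trials],
                "correct": [int(t.correct) for t in self.trials],
                "rt_ms": [t.rt_ms for t in self.trials],
            }
        )

    def accuracy(
        self,
        coherence: float | None = None,
        blocks: Sequence[int] | None = None,
        trial_range: tuple[int, int] | None = None,
    ) -> float:
        """Proportion correct over an optional coherence/block/trial filter.

        ``trial_range`` bounds are inclusive. Returns NaN if no trial matches.
        """
        sel = []
        for t in self.trials:
            if coherence is not None and not np.isclose(t.coherence, coherence):
                continue
            if blocks is not None and t.block not in blocks:
                continue
            if trial_range is not None and not (
                trial_range[0] <= t.trial_index <= trial_range[1]
            ):
                continue
            sel.append(t.correct)
        if not sel:
            return float("nan")
        return float(np.mean(sel))


@dataclass
class Hypnogram:
    """Sleep-stage labels in consecutive 30-s scoring epochs."""

    epoch_labels: list[str]
    epoch_length: float = 30.0

    def __post_init__(self) -> None:
        bad = set(self.epoch_labels) - set(STAGE_ORDER)
        if bad:
            raise ValueError(f"unknown stage codes: {sorted(bad)}")

    @property
    def duration(self) -> float:
        return len(self.epoch_labels) * self.epoch_length

    def deepest_stage(self) -> str:
        return max(self.epoch_labels, key=STAGE_ORDER.__getitem__)

    def count(self, stage: str) -> int:
        return sum(1 for s in self.epoch_labels if s == stage)

    def minutes(self, stage: str) -> float:
        return self.count(stage) * self.epoch_length / 60.0

    def group_label(self) -> str:
        """Vigilance group under the scoring convention of nap studies.

        No N1/N2/N3 epoch -> "Wake"; N1 but nothing deeper -> "N1";
        any N2 (or N3) epoch -> "N2".
        """
        deepest = self.deepest_stage()
        if deepest == "W":
            return "Wake"
        if deepest == "N1":
            return "N1"
        return "N2"


@dataclass
class Recording:
    """Multichannel EEG samples in microvolts."""

    samples: np.ndarray  # (n_channels, n_times)
    sampling_rate: float
    channel_names: list[str]
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, times) array")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match samples rows")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.channel_names.index(name)]


@dataclass
class Subject:
    """Bundle of one simulated (or ingested) participant's data."""

    subject_id: str
    group: str  # "Wake" | "N1" | "N2"
    session: SessionData
    hypnogram: Hypnogram | None = None
    recording: Recording | None = None
    truth: dict = field(default_factory=dict)  # simulator ground truth, if any
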