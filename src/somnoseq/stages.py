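"""Sleep-stage vocabulary and the hypnogram container.

The five AASM stages are ordered W < N1 < N2 < N3 < R; this ordinal
order is used everywhere an index is needed (confusion-matrix axes,
softmax output columns, argmax tie-breaking).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

EPOCH_SECONDS = 30.0


class Stage(IntEnum):
    """A scorable sleep stage; the integer value is its ordinal index."""

    W = 0
    N1 = 1
    N2 = 2
    N3 = 3
    R = 4

    def __str__(self) -> str:  # tokens as written in hypnogram files
        return self.name


#: Sentinel for epochs without a manual score.  Exists only at I/O
#: boundaries (recording margins); never inside an analysis-ready
#: :class:`Hypnogram`.
UNSCORED = -1

N_STAGES = 5
STAGE_NAMES = tuple(s.name for s in Stage)

_TOKEN_TO_CODE = {s.name: int(s) for s in Stage}
_TOKEN_TO_CODE.update({"?": UNSCORED, "U": UNSCORED, "UNSCORED": UNSCORED})


def parse_stage_token(token: str) -> int:
    """Map a text token to a stage code (``UNSCORED`` allowed)."""
    try:
        return _TOKEN_TO_CODE[token.strip().upper()]
    except KeyError:
        raise ValueError(f"unknown sleep-stage token {token!r}") from None


@dataclass
class Hypnogram:
    """Ordered stage labels on the fixed 30-s epoch grid.

    Parameters
    ----------
    codes
        Integer stage codes, one per 30-s epoch, in ordinal order
        W=0 .. R=4.  All codes must be scorable (no ``UNSCORED``).
    source_id
        Identifier of the scorer or model that produced the labels.
    """

    codes: np.ndarray
    source_id: str = ""
    epoch_duration_s: float = EPOCH_SECONDS

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 1 or len(self.codes) < 1:
            raise ValueError("hypnogram must hold at least one epoch")
        if self.epoch_duration_s != EPOCH_SECONDS:
            raise ValueError("epoch duration is fixed at 30 s")
        bad = (self.codes < 0) | (self.codes >= N_STAGES)
        if bad.any():
            raise ValueError(
                f"non-scorable stage code at epoch {int(np.flatnonzero(bad)[0])}"
            )

    @classmethod
    def from_stages(cls, stages: Iterable[Stage | str], source_id: str = "") -> "Hypnogram":
        codes = [parse_stage_token(s) if isinstance(s, str) else int(s) for s in stages]
        return cls(np.asarray(codes), source_id=source_id)

    def __len__(self) -> int:
        return len(self.codes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return np.array_equal(self.codes, other.codes)

    @property
    def stages(self) -> list[Stage]:
        return [Stage(c) for c in self.codes]

    @property
    def duration_s(self) -> float:
        return len(self) * self.epoch_duration_s

    def counts(self) -> np.ndarray:
        """Per-stage epoch counts, length 5, ordinal order."""
        return np.bincount(self.codes, minlength=N_STAGES)

    def proportions(self) -> np.ndarray:
        return self.counts() / len(self)


@dataclass
class SignalChannel:
    """One bipolar derivation: label, sampling rate, samples in microvolts."""

    derivation: str
    sampling_rate_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"non-finite samples in {self.derivation}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate_hz


#: The montage the classifier consumes: frontal EEG, EOG, chin EMG.
REQUIRED_DERIVATIONS = ("F4-M1", "E1-M2", "Chin1-Chin2")


@dataclass
class PsgRecording:
    """A multichannel PSG recording plus subject metadata.

    ``metadata`` carries the recruitment group flag (``"SDB"`` or
    ``"control"``), the apnea–hypopnea index ``ahi`` (events/h), and
    optionally ``sex`` / ``age``.
    """

    id: str
    channels: dict[str, SignalChannel]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rates = {c.sampling_rate_hz for c in self.channels.values()}
        if len(rates) > 1:
            raise ValueError(f"channels of {self.id} have mixed sampling rates: {rates}")
        lengths = {len(c.samples) for c in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError(f"channels of {self.id} have unequal lengths: {lengths}")

    @property
    def sampling_rate_hz(self) -> float:
        return next(iter(self.channels.values())).sampling_rate_hz

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())).samples)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel_matrix(self, order: Sequence[str] = REQUIRED_DERIVATIONS) -> np.ndarray:
        """Stack channels as an (n_samples, n_channels) array in ``order``."""
        return np.stack([self.channels[d].samples for d in order], axis=1)
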