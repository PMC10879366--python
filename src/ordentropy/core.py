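"""Core data containers shared across the pipeline.

The pipeline operates on four-channel EEG (frontal Fp1/Fp2, parietal P3/P4)
recorded around anesthesia induction and emergence.  Two clinical events
anchor the analysis: loss of responsiveness (LoR), when the patient stops
squeezing the investigator's hand on command during induction, and return
of responsiveness (RoR), when they resume during emergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

REQUIRED_CHANNELS = ("Fp1", "Fp2", "P3", "P4")


class ConfigurationError(ValueError):
    """Raised when a configuration violates one of its invariants."""


class DataError(ValueError):
    """Raised when input data violates a contract (shape, rate, finiteness)."""


@dataclass
class EegRecording:
    """Multichannel raw EEG: a channels x time sample matrix in microvolts.

    ``start_time_s`` is the time of the first sample.  ``settled_from_s``,
    when set, marks the earliest time at which the signal is free of filter
    startup transients; analysis windows must not start before it.
    """

    channel_labels: list[str]
    fs: float
    samples: np.ndarray
    start_time_s: float = 0.0
    settled_from_s: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise DataError(
                f"{len(self.channel_labels)} labels but "
                f"{self.samples.shape[0]} sample rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise DataError(f"duplicate channel labels: {self.channel_labels}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel by label (case-insensitive match)."""
        for i, lab in enumerate(self.channel_labels):
            if lab.lower() == label.lower():
                return self.samples[i]
        raise DataError(
            f"channel {label!r} not found; available: {self.channel_labels}"
        )

    def require_channels(self, labels=REQUIRED_CHANNELS) -> None:
        have = {lab.lower() for lab in self.channel_labels}
        missing = [lab for lab in labels if lab.lower() not in have]
        if missing:
            raise DataError(
                f"missing channel(s) {missing}; available: {self.channel_labels}"
            )


@dataclass
class EventAnnotations:
    """Per-recording LoR/RoR event times, in recording time coordinates."""

    patient_id: str
    lor_s: float
    ror_s: float

    def __post_init__(self) -> None:
        if not self.lor_s < self.ror_s:
            raise DataError(
                f"patient {self.patient_id}: lor_s ({self.lor_s}) must be "
                f"< ror_s ({self.ror_s})"
            )

    def check_within(self, recording: EegRecording) -> None:
        t0 = recording.start_time_s
        t1 = t0 + recording.duration_s
        if not (t0 < self.lor_s and self.ror_s < t1):
            raise DataError(
                f"patient {self.patient_id}: events ({self.lor_s}, {self.ror_s}) "
                f"outside recording extent [{t0}, {t1}]"
            )
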