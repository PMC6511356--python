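"""Adventitious respiratory sound classes and their acoustic definitions.

Four phenomenon classes are modeled. Wheezes and rhonchi are continuous
("musical") sounds: a wheeze is a tonal sound with fundamental frequency
roughly between 100 Hz and 1 kHz lasting more than 80 ms; a rhonchus is a
periodic, snoring-like sound with fundamental below 300 Hz lasting more than
100 ms.  Crackles are short explosive broadband transients: fine crackles
last about 5 ms, coarse crackles about 15 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Canonical class order used by every frames-by-classes matrix in the package.
CLASSES = ("wheeze", "rhonchus", "fine_crackle", "coarse_crackle")

#: Optional fifth model output for interference/noise detection.
NOISE_CLASS = "noise"

#: Duration of one analysis frame in seconds (the raster grid).
FRAME_HOP_S = 0.010


class ConstraintViolation(ValueError):
    """An event violates the acoustic definition of its phenomenon class."""


@dataclass(frozen=True)
class PhenomenonSpec:
    """Acoustic envelope of one phenomenon class.

    Parameters
    ----------
    class_name:
        One of :data:`CLASSES`.
    f0_range:
        Fundamental-frequency interval in Hz for tonal classes; for crackles
        the emphasis band of the transient.
    min_duration:
        Hard lower bound on event duration in seconds (0 = unconstrained).
    default_duration_range:
        Interval the corpus generator samples event durations from, seconds.
    """

    class_name: str
    f0_range: tuple[float, float]
    min_duration: float
    default_duration_range: tuple[float, float]

    @property
    def tonal(self) -> bool:
        return self.class_name in ("wheeze", "rhonchus")


WHEEZE = PhenomenonSpec("wheeze", (100.0, 1000.0), 0.080, (0.20, 1.00))
RHONCHUS = PhenomenonSpec("rhonchus", (80.0, 300.0), 0.100, (0.30, 1.20))
FINE_CRACKLE = PhenomenonSpec("fine_crackle", (500.0, 1500.0), 0.0, (0.005, 0.005))
COARSE_CRACKLE = PhenomenonSpec("coarse_crackle", (200.0, 700.0), 0.0, (0.015, 0.015))

SPECS: dict[str, PhenomenonSpec] = {
    s.class_name: s for s in (WHEEZE, RHONCHUS, FINE_CRACKLE, COARSE_CRACKLE)
}

#: Minimum event duration, per class, applied when decoding detector output.
#: Tonal classes reuse their definitional bounds; crackles keep one frame
#: because 5-15 ms is below the 10 ms grid.
MIN_EVENT_DURATION_S = {
    "wheeze": 0.080,
    "rhonchus": 0.100,
    "fine_crackle": 0.010,
    "coarse_crackle": 0.010,
    NOISE_CLASS: 0.010,
}


@dataclass
class PhenomenonEvent:
    """One adventitious-sound interval ``[onset, offset)`` in seconds."""

    class_name: str
    onset: float
    offset: float
    f0: Optional[float] = None
    amplitude: float = 1.0

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def validate(self) -> "PhenomenonEvent":
        if self.class_name not in SPECS:
            raise ConstraintViolation(f"unknown phenomenon class {self.class_name!r}")
        spec = SPECS[self.class_name]
        if not self.offset > self.onset:
            raise ConstraintViolation(
                f"{self.class_name}: offset ({self.offset}) must exceed onset ({self.onset})"
            )
        if self.duration < spec.min_duration - 1e-9:
            raise ConstraintViolation(
                f"{self.class_name} events must last >= {spec.min_duration * 1000:.0f} ms, "
                f"got {self.duration * 1000:.1f} ms"
            )
        if spec.tonal and self.f0 is not None:
            lo, hi = spec.f0_range
            if not lo <= self.f0 <= hi:
                raise ConstraintViolation(
                    f"{self.class_name} fundamental {self.f0:.1f} Hz outside [{lo}, {hi}] Hz"
                )
        return self


@dataclass(frozen=True)
class RecordingLabels:
    """Recording-level presence/absence of each phenomenon class."""

    wheeze: bool = False
    rhonchus: bool = False
    fine_crackle: bool = False
    coarse_crackle: bool = False

    def __getitem__(self, class_name: str) -> bool:
        if class_name not in CLASSES:
            raise KeyError(class_name)
        return getattr(self, class_name)

    def as_dict(self) -> dict[str, bool]:
        return {c: getattr(self, c) for c in CLASSES}

    def as_tuple(self) -> tuple[bool, ...]:
        return tuple(getattr(self, c) for c in CLASSES)

    @classmethod
    def from_dict(cls, d) -> "RecordingLabels":
        return cls(**{c: bool(d[c]) for c in CLASSES})

    @property
    def any_pathology(self) -> bool:
        return any(self.as_tuple())
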