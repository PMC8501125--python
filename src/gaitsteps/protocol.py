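"""Treadmill protocol description: ordered constant-speed stages.

A protocol is a sequence of speed stages (km/h) with durations in seconds.
Time is 0-based from the start of the recording and stage intervals are
half-open ``[start, end)``.  Stages may carry a ground-truth step count
(video-counted in a lab study, simulator-planted here).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = ["ProtocolSegment", "ProtocolSpec"]


@dataclass(frozen=True)
class ProtocolSegment:
    """One constant-speed stage; ``true_steps`` is optional ground truth."""

    speed_kmh: float
    start_s: float
    end_s: float
    true_steps: int | None = None

    def __post_init__(self):
        if self.speed_kmh <= 0:
            raise ValueError(f"speed must be positive, got {self.speed_kmh}")
        if not self.end_s > self.start_s:
            raise ValueError(
                f"segment must have positive duration: [{self.start_s}, {self.end_s})"
            )
        if self.true_steps is not None and self.true_steps < 0:
            raise ValueError("true_steps cannot be negative")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def with_true_steps(self, n: int) -> "ProtocolSegment":
        return dataclasses.replace(self, true_steps=int(n))

    def to_dict(self) -> dict:
        d = {"speed_kmh": self.speed_kmh, "start_s": self.start_s, "end_s": self.end_s}
        if self.true_steps is not None:
            d["true_steps"] = self.true_steps
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSegment":
        return cls(
            speed_kmh=float(d["speed_kmh"]),
            start_s=float(d["start_s"]),
            end_s=float(d["end_s"]),
            true_steps=int(d["true_steps"]) if d.get("true_steps") is not None else None,
        )


@dataclass(frozen=True)
class ProtocolSpec:
    """An ordered, non-overlapping list of stages plus a cohort label."""

    segments: tuple[ProtocolSegment, ...]
    label: str = ""

    def __post_init__(self):
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("protocol needs at least one segment")
        for a, b in zip(segs, segs[1:]):
            if b.start_s < a.end_s:
                raise ValueError(
                    f"segments overlap or are out of order at t={b.start_s} s"
                )

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def total_duration_s(self) -> float:
        return self.segments[-1].end_s - self.segments[0].start_s

    @property
    def speeds(self) -> tuple[float, ...]:
        return tuple(s.speed_kmh for s in self.segments)

    @classmethod
    def from_speeds(
        cls, speeds, segment_duration_s: float = 240.0, label: str = ""
    ) -> "ProtocolSpec":
        """Contiguous equal-duration stages starting at t = 0.

        The study-style default is 4-minute stages; a 20-min routine is five
        stages, the 24-min variant six.
        """
        segs = [
            ProtocolSegment(float(v), i * segment_duration_s, (i + 1) * segment_duration_s)
            for i, v in enumerate(speeds)
        ]
        return cls(tuple(segs), label=label)

    def to_dict(self) -> dict:
        return {"label": self.label, "segments": [s.to_dict() for s in self.segments]}

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        return cls(
            tuple(ProtocolSegment.from_dict(s) for s in d["segments"]),
            label=d.get("label", ""),
        )
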