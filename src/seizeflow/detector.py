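"""Real-time alert criterion on the biomarker stream.

An alert is raised when, among the last N analysis windows, at least n have
epileptic content above the threshold T.  With the defaults [N, n, T] =
[7, 6, 0.4] at 1.5 s windows this means: of the past 10.5 s, at least 9 s
carry an epileptic charge above 0.4.

During warm-up (fewer than N windows seen so far) the criterion is
evaluated on the available buffer, so an event is possible as soon as n
samples exceed T; set ``strict_warmup=True`` to require a full buffer.

After an alert the detector is refractory: no new event is emitted while
the criterion remains continuously satisfied, nor before a configurable
dead time (default 40 windows = 60 s) has elapsed — both conditions must
clear.  This suppresses repeated alerts within a single seizure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: half-width of the stored per-event context, in windows
CONTEXT_HALFSPAN = 25


@dataclass(frozen=True)
class DetectionParams:
    """The [N, n, T] alert criterion parameters."""

    N: int = 7
    n: int = 6
    T: float = 0.4

    def __post_init__(self) -> None:
        if not (1 <= self.n <= self.N):
            raise ValueError(f"need 1 <= n <= N, got n={self.n}, N={self.N}")
        if not (0 < self.T < 1):
            raise ValueError(f"threshold must be in (0, 1), got {self.T}")


DEFAULT_PARAMS = DetectionParams()


@dataclass
class EventRecord:
    """A detected alert with its stored +-25 window context.

    ``biomarker_context`` and ``flow_context`` are filled as windows arrive;
    entries are NaN / None until available.  Labels: TC (true seizure), FP
    (false positive), test (deliberate imitation), unvalidated.
    """

    event_id: int
    trigger_window: int
    trigger_time: float
    biomarker_context: np.ndarray = field(
        default_factory=lambda: np.full(2 * CONTEXT_HALFSPAN + 1, np.nan)
    )
    flow_context: list = field(
        default_factory=lambda: [None] * (2 * CONTEXT_HALFSPAN + 1)
    )
    label: str = "unvalidated"
    label_source: str = "none"

    def context_slot(self, window_index: int) -> int | None:
        off = window_index - self.trigger_window + CONTEXT_HALFSPAN
        if 0 <= off < 2 * CONTEXT_HALFSPAN + 1:
            return off
        return None

    def biomarker_at(self, offset: int) -> float:
        """Biomarker value at trigger_window + offset."""
        return float(self.biomarker_context[offset + CONTEXT_HALFSPAN])

    def flow_at(self, offset: int):
        """Stored per-window flow values at trigger_window + offset."""
        return self.flow_context[offset + CONTEXT_HALFSPAN]

    def context_complete(self, halfspan: int = 20) -> bool:
        lo, hi = CONTEXT_HALFSPAN - halfspan, CONTEXT_HALFSPAN + halfspan
        return all(v is not None for v in self.flow_context[lo : hi + 1])


class Detector:
    """Stateful online detector; feed biomarker samples in window order."""

    def __init__(
        self,
        params: DetectionParams = DEFAULT_PARAMS,
        window_seconds: float = 1.5,
        dead_time: int = 40,
        strict_warmup: bool = False,
    ):
        self.params = params
        self.window_seconds = window_seconds
        self.dead_time = dead_time
        self.strict_warmup = strict_warmup
        self._buffer: list[float] = []
        self._last_index: int | None = None
        self._next_id = 0
        self._last_trigger: int | None = None
        self._criterion_broken = True  # since the last trigger

    def step(self, window_index: int, e_value: float) -> EventRecord | None:
        """Consume one biomarker sample; return an event if one triggers."""
        if self._last_index is not None and window_index <= self._last_index:
            raise ValueError(
                f"window index {window_index} not after {self._last_index}"
            )
        self._last_index = window_index

        self._buffer.append(float(e_value))
        if len(self._buffer) > self.params.N:
            self._buffer.pop(0)

        count = sum(v > self.params.T for v in self._buffer)
        satisfied = count >= self.params.n
        if self.strict_warmup and len(self._buffer) < self.params.N:
            satisfied = False

        if not satisfied:
            self._criterion_broken = True
            return None
        if self._last_trigger is not None:
            dead = window_index < self._last_trigger + self.dead_time
            if dead or not self._criterion_broken:
                return None
        self._last_trigger = window_index
        self._criterion_broken = False
        event = EventRecord(
            event_id=self._next_id,
            trigger_window=window_index,
            trigger_time=window_index * self.window_seconds,
        )
        self._next_id += 1
        return event


def detect_offline(
    e_series: np.ndarray,
    params: DetectionParams = DEFAULT_PARAMS,
    window_seconds: float = 1.5,
    dead_time: int = 40,
    strict_warmup: bool = False,
    first_window: int = 0,
) -> list[EventRecord]:
    """Run the online rule over a complete biomarker series.

    Produces the identical event set to feeding :meth:`Detector.step`
    sample by sample, and fills each event's biomarker context from the
    series.
    """
    e_series = np.asarray(e_series, dtype=float)
    det = Detector(params, window_seconds=window_seconds,
                   dead_time=dead_time, strict_warmup=strict_warmup)
    events: list[EventRecord] = []
    for i, v in enumerate(e_series):
        ev = det.step(first_window + i, v)
        if ev is not None:
            events.append(ev)
    for ev in events:
        q0 = ev.trigger_window - first_window
        for off in range(-CONTEXT_HALFSPAN, CONTEXT_HALFSPAN + 1):
            i = q0 + off
            if 0 <= i < len(e_series):
                ev.biomarker_context[off + CONTEXT_HALFSPAN] = e_series[i]
    return events
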