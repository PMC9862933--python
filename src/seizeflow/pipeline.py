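"""Acquisition-cycle orchestration, event logging, metrics, adaptation loops.

The processing chain per 36-frame acquisition cycle is:

    frames -> 2x2 block average -> affine group velocities -> Gabor window
    spectrum -> epileptic content E -> normalized biomarker E_check ->
    [N, n, T] detector step

Detected events are logged with their +-25 window biomarker and flow
context.  Three adaptation modes exist: ``off`` (rigid parameters),
``supervised`` (an operator labels events; optimization runs on the
operator-validated seizures) and ``unsupervised`` (after every
``min_events`` new events the clustering validator labels them and the
optimizer runs on the events it accepted — no human in the loop, and no
raw video is read after flow extraction).

Alerts are dispatched to a pluggable sink only inside the configured daily
schedule; events outside the schedule are still logged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import adapt as adapt_mod
from . import clustering, flow, wavelets
from .detector import (
    CONTEXT_HALFSPAN,
    DetectionParams,
    Detector,
    EventRecord,
)
from .synth import SyntheticTrial


class BankConfig(BaseModel):
    f_min: float = 0.5
    f_max: float = 12.0
    K: int = 200
    cycles: float = 1.5


class PipelineConfig(BaseModel):
    """Validated configuration of the whole detection pipeline."""

    fps: float = 24.0
    frames_per_window: int = 36
    band: tuple[float, float] = (2.0, 7.0)
    N: int = 7
    n: int = 6
    T: float = 0.4
    dead_time: int = 40  # windows
    lam: float = Field(default=flow.DEFAULT_LAMBDA, description="flow regularization")
    bank: BankConfig = Field(default_factory=BankConfig)
    e0_seed: int = 12345
    e0_reps: int = 200
    adaptation: Literal["off", "supervised", "unsupervised"] = "off"
    min_events: int = 10
    max_events: int = 50
    eps: float = 0.5
    alert_schedule: tuple[float, float] = (0.0, 24.0)  # hours of day

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        DetectionParams(self.N, self.n, self.T)  # validates the triple
        fa, fb = self.band
        wavelets.FrequencyBand(fa, fb)
        if not (0 < self.frames_per_window):
            raise ValueError("frames_per_window must be positive")
        if self.bank.f_max > self.fps / 2:
            raise ValueError("bank f_max must not exceed Nyquist")
        return self

    @property
    def window_seconds(self) -> float:
        return self.frames_per_window / self.fps

    @property
    def detection_params(self) -> DetectionParams:
        return DetectionParams(self.N, self.n, self.T)

    def make_bank(self) -> wavelets.GaborBank:
        return wavelets.build_bank(self.bank.f_min, self.bank.f_max,
                                   self.bank.K, self.fps, self.bank.cycles)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


@dataclass
class RunResult:
    events: list[EventRecord]
    config: PipelineConfig
    biomarker: np.ndarray  # E_check per window
    adaptations: list  # OptimizationResult per adaptation pass
    alerts: list[int]  # window indices at which an alert was dispatched

    def biomarker_to_csv(self, path) -> None:
        pd.DataFrame({
            "window": np.arange(len(self.biomarker)),
            "time_s": np.arange(len(self.biomarker)) * self.config.window_seconds,
            "E_check": self.biomarker,
        }).to_csv(path, index=False)


def _iter_window_rates(source, config: PipelineConfig):
    """Yield (window_index, (fpw-1, 6) rate array) per acquisition cycle."""
    fpw = config.frames_per_window
    if isinstance(source, SyntheticTrial):
        frames = source.frames
    elif isinstance(source, np.ndarray):
        frames = source
    elif isinstance(source, (str, Path)):
        frames = load_frames(source)
    else:
        raise TypeError(f"unsupported source type {type(source)!r}")
    n_windows = len(frames) // fpw
    for q in range(n_windows):
        window = flow.FrameWindow(frames[q * fpw : (q + 1) * fpw], fps=config.fps,
                                  window_index=q, frames_per_window=fpw)
        yield q, flow.process_window(window, lam=config.lam).values


def _iter_window_rates_from_stream(rates: np.ndarray, config: PipelineConfig):
    """Window a raw group-velocity stream (one sample per frame pair).

    Window q covers frames [q*fpw, (q+1)*fpw); its fpw-1 within-window rate
    samples start at index q*fpw.  The boundary pair between adjacent
    windows is dropped — cycles are processed independently.
    """
    fpw = config.frames_per_window
    n_windows = (len(rates) + 1) // fpw
    for q in range(n_windows):
        yield q, np.asarray(rates[q * fpw : q * fpw + fpw - 1], dtype=float)


def load_frames(path) -> np.ndarray:
    """Load a frame directory (numbered PNG/JPEG) or a video file."""
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")
        )
        if not files:
            raise FileNotFoundError(f"no image frames in {path}")
        frames = np.stack([iio.imread(p) for p in files])
    else:
        frames = iio.imread(path)
    frames = frames.astype(float)
    if frames.max() > 1.5:
        frames /= 255.0
    if frames.ndim == 3:  # grayscale -> replicate channels
        frames = np.repeat(frames[..., None], 3, axis=-1)
    return frames


def run(
    source,
    config: PipelineConfig | None = None,
    rates: np.ndarray | None = None,
    alert_sink: Callable[[EventRecord], None] | None = None,
    start_hour: float = 0.0,
) -> RunResult:
    """Process a source end to end and return the event log.

    ``source`` may be a :class:`SyntheticTrial`, a frame array, or a path
    to a frame directory / video file.  Alternatively pass ``rates`` (a
    pre-extracted group-velocity stream, one 6-vector per frame pair) to
    skip video processing entirely.
    """
    config = config or PipelineConfig()
    bank = config.make_bank()
    band = wavelets.FrequencyBand(*config.band)
    n_samples = config.frames_per_window - 1
    e0 = wavelets.noise_baseline(band, bank, n_reps=config.e0_reps,
                                 seed=config.e0_seed, n_samples=n_samples)
    detector = Detector(config.detection_params,
                        window_seconds=config.window_seconds,
                        dead_time=config.dead_time)

    if rates is not None:
        window_iter = _iter_window_rates_from_stream(rates, config)
    else:
        window_iter = _iter_window_rates(source, config)

    ring: list[tuple[int, float, np.ndarray]] = []  # (q, E_check, flow values)
    events: list[EventRecord] = []
    pending: list[EventRecord] = []
    biomarker: list[float] = []
    adaptations: list = []
    alerts: list[int] = []
    last_adapted = 0

    for q, values in window_iter:
        spec = wavelets.spectrum_of_values(values, bank)
        E = wavelets.epileptic_content(spec, band)
        e_check = wavelets.normalized_biomarker(E, e0)
        biomarker.append(e_check)

        ring.append((q, e_check, values))
        if len(ring) > 2 * CONTEXT_HALFSPAN + 1:
            ring.pop(0)

        event = detector.step(q, e_check)
        if event is not None:
            event.event_id = len(events)
            events.append(event)
            pending.append(event)
            hour = (start_hour + q * config.window_seconds / 3600.0) % 24.0
            lo, hi = config.alert_schedule
            in_schedule = lo <= hour < hi if lo <= hi else (hour >= lo or hour < hi)
            if in_schedule:
                alerts.append(q)
                if alert_sink is not None:
                    alert_sink(event)

        # back- and forward-fill event contexts from the ring buffer
        for ev in list(pending):
            for rq, re, rv in ring:
                slot = ev.context_slot(rq)
                if slot is not None and ev.flow_context[slot] is None:
                    ev.biomarker_context[slot] = re
                    ev.flow_context[slot] = rv
            if ev.context_slot(q) is None and q > ev.trigger_window:
                pending.remove(ev)

        if (
            config.adaptation == "unsupervised"
            and len(events) - last_adapted >= config.min_events
            and not pending
        ):
            result = _unsupervised_pass(events, bank, config)
            if result is not None:
                adaptations.append(result)
                band = result.band
                e0 = wavelets.noise_baseline(band, bank, n_reps=config.e0_reps,
                                             seed=config.e0_seed,
                                             n_samples=n_samples)
                detector.params = result.params
            last_adapted = len(events)

    return RunResult(events=events, config=config,
                     biomarker=np.asarray(biomarker),
                     adaptations=adaptations, alerts=alerts)


def _unsupervised_pass(events, bank, config):
    """Cluster-label all events, then optimize on the accepted seizures."""
    usable = [ev for ev in events if ev.context_complete(clustering.SIGNATURE_HALFSPAN)]
    if len(usable) < 3:
        return None
    sigs = [clustering.signature(ev) for ev in usable]
    result = clustering.classify(sigs, eps=config.eps)
    for ev, is_seiz in zip(usable, result.Q):
        if ev.label_source != "operator":  # operator labels always win
            ev.label = "TC" if is_seiz else "FP"
            ev.label_source = "clustering"
    seizures = [ev for ev in usable if ev.label == "TC"]
    if len(seizures) < config.min_events:
        return None
    try:
        return adapt_mod.adapt(seizures, bank, min_events=config.min_events,
                               max_events=config.max_events,
                               e0_seed=config.e0_seed, e0_reps=config.e0_reps)
    except ValueError:
        return None


# ---------------------------------------------------------------- event log


def events_to_frame(events: list[EventRecord], config: PipelineConfig | None = None
                    ) -> pd.DataFrame:
    config = config or PipelineConfig()
    return pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "trigger_window": [e.trigger_window for e in events],
            "trigger_time_s": [e.trigger_time for e in events],
            "N": config.N,
            "n": config.n,
            "T": config.T,
            "band_fa": config.band[0],
            "band_fb": config.band[1],
            "label": [e.label for e in events],
            "label_source": [e.label_source for e in events],
        }
    )


def save_event_log(events: list[EventRecord], csv_path,
                   config: PipelineConfig | None = None) -> None:
    """CSV log plus a JSON sidecar holding the per-event context arrays."""
    csv_path = Path(csv_path)
    events_to_frame(events, config).to_csv(csv_path, index=False)
    sidecar = {}
    for ev in events:
        sidecar[str(ev.event_id)] = {
            "trigger_window": ev.trigger_window,
            "biomarker_context": [
                None if np.isnan(v) else float(v) for v in ev.biomarker_context
            ],
            "flow_context": [
                None if f is None else np.asarray(f).tolist() for f in ev.flow_context
            ],
        }
    csv_path.with_suffix(".context.json").write_text(json.dumps(sidecar))


def load_event_log(csv_path) -> list[EventRecord]:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    side = {}
    sidecar_path = csv_path.with_suffix(".context.json")
    if sidecar_path.exists():
        side = json.loads(sidecar_path.read_text())
    events = []
    for _, row in df.iterrows():
        ev = EventRecord(
            event_id=int(row.event_id),
            trigger_window=int(row.trigger_window),
            trigger_time=float(row.trigger_time_s),
            label=row.label,
            label_source=row.label_source,
        )
        ctx = side.get(str(ev.event_id))
        if ctx:
            ev.biomarker_context = np.array(
                [np.nan if v is None else v for v in ctx["biomarker_context"]]
            )
            ev.flow_context = [
                None if f is None else np.asarray(f) for f in ctx["flow_context"]
            ]
        events.append(ev)
    return events


def validate_events(events: list[EventRecord], labels: dict[int, str]
                    ) -> list[EventRecord]:
    """Apply operator labels; they override any clustering label.

    Events labelled ``test`` are excluded from training sets downstream.
    """
    by_id = {e.event_id: e for e in events}
    for event_id, label in labels.items():
        if event_id not in by_id:
            raise KeyError(f"unknown event id {event_id}")
        if label not in ("TC", "FP", "test"):
            raise ValueError(f"unknown label {label!r}")
        by_id[event_id].label = label
        by_id[event_id].label_source = "operator"
    return events


def training_events(events: list[EventRecord]) -> list[EventRecord]:
    """Validated true seizures usable for adaptation (tests excluded)."""
    return [e for e in events if e.label == "TC"]


# ------------------------------------------------------------------ metrics


@dataclass
class TrialMetrics:
    """Detection and classifier performance summary.

    ``specificity_pct`` follows the clinical convention used for this
    system: true detections over all validated detections — what is
    conventionally called precision / positive predictive value.  Test
    events are excluded from every rate.
    """

    n_true: int
    n_false: int
    n_tests: int
    n_unvalidated: int
    specificity_pct: float
    fp_per_day: float
    classifier_accuracy_pct: float | None = None
    classifier_sensitivity_pct: float | None = None

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def compute_metrics(
    events: list[EventRecord],
    observation_days: float,
    operator_labels: dict[int, str] | None = None,
) -> TrialMetrics:
    """Summary metrics from a labelled event log.

    When both clustering and operator labels exist, the classifier
    accuracy/sensitivity compare the clustering decision against the
    operator's (tests excluded).
    """
    n_true = sum(e.label == "TC" for e in events)
    n_false = sum(e.label == "FP" for e in events)
    n_tests = sum(e.label == "test" for e in events)
    n_unval = sum(e.label == "unvalidated" for e in events)
    validated = n_true + n_false
    spec = 100.0 * n_true / validated if validated else 0.0
    fp_rate = n_false / observation_days if observation_days > 0 else 0.0

    acc = sens = None
    if operator_labels:
        pairs = [
            (operator_labels[e.event_id], e.label)
            for e in events
            if e.event_id in operator_labels
            and e.label_source == "clustering"
            and operator_labels[e.event_id] in ("TC", "FP")
        ]
        if pairs:
            acc = 100.0 * sum(o == c for o, c in pairs) / len(pairs)
            tc = [(o, c) for o, c in pairs if o == "TC"]
            if tc:
                sens = 100.0 * sum(c == "TC" for _, c in tc) / len(tc)
    return TrialMetrics(
        n_true=n_true, n_false=n_false, n_tests=n_tests, n_unvalidated=n_unval,
        specificity_pct=spec, fp_per_day=fp_rate,
        classifier_accuracy_pct=acc, classifier_sensitivity_pct=sens,
    )


def metrics_from_counts(n_true: int, n_false: int,
                        observation_days: float = 0.0) -> TrialMetrics:
    """Metrics arithmetic from bare validated counts (no event objects)."""
    ev = []
    for i in range(n_true):
        ev.append(EventRecord(i, i, 0.0, label="TC", label_source="operator"))
    for i in range(n_false):
        ev.append(EventRecord(n_true + i, n_true + i, 0.0, label="FP",
                              label_source="operator"))
    return compute_metrics(ev, observation_days)
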