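"""Synthetic fixtures: a fixed-frame-rate camera watching a textured scene.

The generator emulates the motion structure the detector assumes, with
known ground truth:

* **seizure** segments — sustained (20-60 s) sinusoidal oscillation of one
  or more affine rate channels in the clonic band (2-7 Hz), the target
  class;
* **normal** segments — smooth low-frequency movement, a band-limited
  (< 1 Hz) random walk of the rates;
* **tremor** segments — brief (2-5 s) oscillation bursts at clonic-like
  frequencies, hard negatives that share the seizure's spectral content but
  not its duration;
* **quiet** baseline — no motion.

A :class:`MotionProgram` holds the per-frame 6-vector of group rates (units
1/s in normalized centred coordinates, matching the flow estimator's
convention) plus the segment annotations.  :func:`render_sequence` warps a
textured pattern by the cumulative affine transform implied by integrating
those rates and adds Gaussian sensor noise; the imposed rates are returned
as ground truth.  For fast tests the rate stream can be used directly,
skipping rendering and flow estimation.

Not emulated: bodies, bedding occlusion, infrared night mode, auto-exposure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .detector import CONTEXT_HALFSPAN, EventRecord
from .flow import GROUP_NAMES, GroupVelocitySeries, rates_to_matrices

SEGMENT_KINDS = ("quiet", "normal", "seizure", "tremor")

#: per-frame displacement cap, fraction of the normalized half-width:
#: single-step flow linearization breaks beyond small displacements
MAX_STEP_FRACTION = 0.2  # 10% of image width = 0.2 normalized units


@dataclass(frozen=True)
class Segment:
    start: float  # seconds
    end: float
    kind: str
    oscillation_frequency: float = 0.0  # Hz
    amplitude: float = 0.0  # rate amplitude, 1/s


@dataclass
class MotionProgram:
    """Per-frame affine rate schedule with segment annotations."""

    duration: float
    fps: float
    rates: np.ndarray  # (n_frames, 6)
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        n = int(round(self.duration * self.fps))
        if self.rates.shape != (n, 6):
            raise ValueError(f"rates must have shape ({n}, 6)")
        prev_end = -np.inf
        for seg in sorted(self.segments, key=lambda s: s.start):
            if seg.kind not in SEGMENT_KINDS:
                raise ValueError(f"unknown segment kind {seg.kind!r}")
            if seg.start < 0 or seg.end > self.duration or seg.start >= seg.end:
                raise ValueError(f"segment outside [0, duration]: {seg}")
            if seg.start < prev_end:
                raise ValueError("segments overlap")
            if seg.oscillation_frequency >= self.fps / 2:
                raise ValueError("oscillation frequency above Nyquist")
            prev_end = seg.end
        step = np.abs(self.rates).max() / self.fps if len(self.rates) else 0.0
        if step > MAX_STEP_FRACTION:
            raise ValueError(
                f"per-frame displacement {step:.3f} exceeds the linearization "
                f"cap {MAX_STEP_FRACTION}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.rates)

    def truth_events(self, kinds=("seizure",)) -> list[tuple[float, float, str]]:
        return [(s.start, s.end, s.kind) for s in self.segments if s.kind in kinds]

    def truth_series(self) -> GroupVelocitySeries:
        """Imposed rates as a ground-truth series (n_frames - 1 samples)."""
        n = self.n_frames - 1
        times = (np.arange(n) + 0.5) / self.fps
        return GroupVelocitySeries(times, self.rates[:n], fps=self.fps)


@dataclass
class SyntheticTrial:
    frames: np.ndarray  # (n_frames, H, W, 3) float32 in [0, 1]
    fps: float
    truth_events: list[tuple[float, float, str]]
    truth_rates: GroupVelocitySeries
    program: MotionProgram

    def write_frames(self, directory) -> None:
        """PNG frame directory with a JSON ground-truth sidecar."""
        import imageio.v3 as iio

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(self.frames):
            iio.imwrite(directory / f"frame_{i:06d}.png",
                        (np.clip(frame, 0, 1) * 255).astype(np.uint8))
        sidecar = {
            "fps": self.fps,
            "truth_events": [list(e) for e in self.truth_events],
        }
        (directory / "truth.json").write_text(json.dumps(sidecar, indent=2))
        self.truth_rates.to_csv(directory / "truth_rates.csv")


def make_textured_pattern(seed: int, height: int = 240, width: int = 320) -> np.ndarray:
    """Broadband random texture, one independent field per RGB channel.

    Smoothed Gaussian noise rescaled to [0, 1]; deterministic given seed.
    """
    if height < 32 or width < 32:
        raise ValueError("pattern must be at least 32x32")
    rng = np.random.default_rng(seed)
    img = np.empty((height, width, 3))
    for c in range(3):
        noise = ndimage.gaussian_filter(rng.standard_normal((height, width)), sigma=2.0)
        lo, hi = noise.min(), noise.max()
        img[..., c] = (noise - lo) / (hi - lo)
    return img


def render_sequence(
    pattern: np.ndarray,
    program: MotionProgram,
    noise_sd: float = 0.01,
    seed: int = 0,
    max_outside: float = 0.3,
) -> SyntheticTrial:
    """Render a frame sequence by integrating the program's affine rates.

    Each frame samples the pattern through the inverse of the cumulative
    forward transform (bilinear interpolation, reflection padding — no
    black borders that would create spurious gradients), then i.i.d.
    Gaussian pixel noise is added.  Fails if the cumulative transform would
    map more than ``max_outside`` of the frame outside the pattern.
    """
    pattern = np.asarray(pattern, dtype=float)
    h, w = pattern.shape[:2]
    n = program.n_frames
    dt = 1.0 / program.fps
    rng = np.random.default_rng(seed)

    # pixel <-> normalized coordinate maps (x along width)
    sx, sy = (w - 1) / 2.0, (h - 1) / 2.0
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    xn = (cols - sx) / sx
    yn = (rows - sy) / sy
    # coarse grid for the out-of-frame check
    xc = xn[:: max(1, h // 16), :: max(1, w // 16)].ravel()
    yc = yn[:: max(1, h // 16), :: max(1, w // 16)].ravel()

    A = np.eye(2)  # cumulative forward transform: x_t = A x_0 + b
    b = np.zeros(2)
    frames = np.empty((n, h, w, 3), dtype=np.float32)
    for t in range(n):
        Ainv = np.linalg.inv(A)
        # source position of each output pixel, in normalized coordinates
        src_x = Ainv[0, 0] * (xn - b[0]) + Ainv[0, 1] * (yn - b[1])
        src_y = Ainv[1, 0] * (xn - b[0]) + Ainv[1, 1] * (yn - b[1])
        cx = Ainv[0, 0] * (xc - b[0]) + Ainv[0, 1] * (yc - b[1])
        cy = Ainv[1, 0] * (xc - b[0]) + Ainv[1, 1] * (yc - b[1])
        outside = np.mean((np.abs(cx) > 1) | (np.abs(cy) > 1))
        if outside > max_outside:
            raise ValueError(
                f"cumulative transform maps {outside:.0%} of frame {t} outside "
                "the pattern; fixture unusable"
            )
        coords = np.stack([src_y * sy + sy, src_x * sx + sx])
        for c in range(3):
            frames[t, ..., c] = ndimage.map_coordinates(
                pattern[..., c], coords, order=1, mode="reflect"
            )
        if noise_sd > 0:
            frames[t] += rng.normal(0.0, noise_sd, size=(h, w, 3)).astype(np.float32)
            np.clip(frames[t], 0.0, 1.0, out=frames[t])
        if t < n - 1:
            M, tau = rates_to_matrices(program.rates[t])
            S = np.eye(2) + dt * M
            A = S @ A
            b = S @ b + dt * tau
    return SyntheticTrial(
        frames=frames,
        fps=program.fps,
        truth_events=program.truth_events(kinds=SEGMENT_KINDS),
        truth_rates=program.truth_series(),
        program=program,
    )


def _sinusoid_burst(n: int, fps: float, freq: float, amplitude: float,
                    phase: float, taper: float = 0.5) -> np.ndarray:
    """Sinusoidal rate burst with cosine-tapered onset/offset (taper in s)."""
    t = np.arange(n) / fps
    env = np.ones(n)
    k = int(taper * fps)
    if k > 0 and n > 2 * k:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
        env[:k] = ramp
        env[-k:] = ramp[::-1]
    return amplitude * env * np.sin(2 * np.pi * freq * t + phase)


def make_trial_program(
    seed: int,
    duration: float = 600.0,
    n_seizures: int = 2,
    n_normal: int = 5,
    n_tremor: int = 5,
    fps: float = 24.0,
    seizure_freq_range: tuple[float, float] = (2.0, 7.0),
    seizure_amplitude: float = 0.6,
    normal_amplitude: float = 0.3,
    tremor_amplitude: float = 0.6,
    min_gap: float = 30.0,
) -> MotionProgram:
    """Randomly scheduled trial with annotated seizure/normal/tremor segments.

    Seizures are 20-60 s sinusoidal oscillations of the two translation
    channels at a frequency drawn from ``seizure_freq_range``; normal
    movements are 10-20 s band-limited (< 1 Hz) random walks; tremors are
    2-5 s oscillation bursts.  Segments are separated by at least
    ``min_gap`` seconds of quiet.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    durations = (
        [float(rng.uniform(20, 60)) for _ in range(n_seizures)]
        + [float(rng.uniform(10, 20)) for _ in range(n_normal)]
        + [float(rng.uniform(2, 5)) for _ in range(n_tremor)]
    )
    kinds = ["seizure"] * n_seizures + ["normal"] * n_normal + ["tremor"] * n_tremor
    order = rng.permutation(len(kinds))
    total = sum(durations) + min_gap * (len(kinds) + 1)
    if total > duration:
        raise ValueError(
            f"cannot place events: need {total:.0f} s, trial lasts {duration:.0f} s"
        )
    slack = duration - total
    gaps = rng.dirichlet(np.ones(len(kinds) + 1)) * slack + min_gap

    n_frames = int(round(duration * fps))
    rates = np.zeros((n_frames, 6))
    segments: list[Segment] = []
    t = 0.0
    for pos, idx in enumerate(order):
        t += gaps[pos]
        start, seg_dur = t, durations[idx]
        kind = kinds[idx]
        i0 = int(round(start * fps))
        i1 = min(n_frames, int(round((start + seg_dur) * fps)))
        m = i1 - i0
        freq = 0.0
        if kind == "seizure":
            freq = float(rng.uniform(*seizure_freq_range))
            for ch, amp in ((0, seizure_amplitude), (1, 0.5 * seizure_amplitude)):
                rates[i0:i1, ch] += _sinusoid_burst(
                    m, fps, freq, amp, phase=rng.uniform(0, 2 * np.pi)
                )
        elif kind == "tremor":
            freq = float(rng.uniform(*seizure_freq_range))
            rates[i0:i1, 0] += _sinusoid_burst(
                m, fps, freq, tremor_amplitude, phase=rng.uniform(0, 2 * np.pi),
                taper=0.3,
            )
        elif kind == "normal":
            # smooth sub-1-Hz wander: band-limited position trajectory,
            # differentiated to rates, so the scene never drifts off frame
            sigma = fps / (2 * np.pi * 0.5)  # ~0.5 Hz cutoff
            for ch in (0, 1):
                pos = ndimage.gaussian_filter1d(rng.standard_normal(m), sigma)
                env = np.ones(m)
                k = int(fps)  # 1 s taper so the segment starts/ends at rest
                if m > 2 * k > 0:
                    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
                    env[:k], env[-k:] = ramp, ramp[::-1]
                pos *= env
                rate = np.gradient(pos) * fps
                rms = np.sqrt(np.mean(rate**2))
                if rms > 0:
                    scale = normal_amplitude / rms
                    # keep the scene in frame: cap the position excursion
                    peak = np.abs(pos).max()
                    if peak > 0:
                        scale = min(scale, 0.15 / peak)
                    rate *= scale
                rates[i0:i1, ch] += rate
        segments.append(Segment(start, start + seg_dur, kind, freq,
                                seizure_amplitude if kind == "seizure" else 0.0))
        t += seg_dur
    return MotionProgram(duration=duration, fps=fps, rates=rates, segments=segments)


# ------------------------------------------------- synthetic event contexts
#
# Pre-built detected-event records with fully populated flow context, for
# studying the clustering validator and the adaptive optimizer without
# running video through the detector.  The quiet-scene flow-noise floor
# (0.003 1/s) is calibrated to what the flow estimator returns for a static
# textured scene with 1%-of-range sensor noise.

EVENT_FLOW_NOISE = 0.003  # 1/s, per-channel rate noise in quiet windows


def _context_window(rng, freq, amplitude, channels, fps=24.0, n_samples=35,
                    noise_sd=EVENT_FLOW_NOISE):
    values = rng.normal(0.0, noise_sd, (n_samples, 6))
    if freq is not None:
        t = np.arange(n_samples) / fps
        for ch, weight in channels:
            values[:, ch] += weight * amplitude * np.sin(
                2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi)
            )
    return values


def make_seizure_event(
    event_id: int,
    seed: int,
    freq: float = 4.0,
    amplitude: float = 0.6,
    onset_offset: int = -6,
    end_offset: int = 20,
) -> EventRecord:
    """Synthetic tonic-clonic event: one long, stereotyped convulsion.

    The clonic oscillation at ``freq`` spans context windows
    ``onset_offset``..``end_offset`` relative to the trigger — by default a
    ~40 s convulsion with the alert raised ~9 s after onset, as the [7, 6,
    0.4] criterion would.  Amplitude jitters +-10% across events; phases are
    random per window.
    """
    rng = np.random.default_rng(seed)
    event = EventRecord(event_id, trigger_window=100, trigger_time=150.0)
    amp = amplitude * rng.uniform(0.9, 1.1)
    channels = ((0, 1.0), (1, 0.5))
    for slot in range(2 * CONTEXT_HALFSPAN + 1):
        off = slot - CONTEXT_HALFSPAN
        active = onset_offset <= off <= end_offset
        event.flow_context[slot] = _context_window(
            rng, freq if active else None, amp, channels
        )
    return event


def make_false_event(event_id: int, seed: int) -> EventRecord:
    """Synthetic false detection: a succession of short convulsive movements.

    Emulates the dominant false-positive source in long-term monitoring of
    this population: irregular trains of brief motor paroxysms that are not
    tonic-clonic seizures.  Each event draws its own oscillation frequency,
    amplitude, channel mix and burst schedule (2-4 bursts of 3-7.5 s, the
    last ending at the trigger), so false events are heterogeneous both
    against seizures and among themselves.
    """
    rng = np.random.default_rng(seed)
    event = EventRecord(event_id, trigger_window=100, trigger_time=150.0)
    freq = float(rng.uniform(2.2, 6.8))
    amp = float(rng.uniform(0.15, 1.5))
    channels = [
        (int(c), float(rng.uniform(0.3, 1.0)))
        for c in rng.choice(6, size=rng.integers(1, 3), replace=False)
    ]
    active: set[int] = set()
    pos = 2
    for _ in range(int(rng.integers(2, 5))):
        width = int(rng.integers(2, 5))
        active.update(range(pos - width + 1, pos + 1))
        pos -= width + int(rng.integers(2, 8))
    for slot in range(2 * CONTEXT_HALFSPAN + 1):
        off = slot - CONTEXT_HALFSPAN
        event.flow_context[slot] = _context_window(
            rng, freq if off in active else None, amp, channels
        )
    return event
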