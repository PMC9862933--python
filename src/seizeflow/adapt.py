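"""Personalized adaptation of the frequency band and detection parameters.

Two learning layers operate on the accumulated set of validated seizure
events, using only stored flow context (never raw video):

1. Frequency-band selection.  The frequency mean-subtracted wavelet
   spectrum is averaged over 26 windows around each seizure (10 before the
   trigger through 15 after, trigger included) and over events, with a
   penalty for across-event variability:

       K(f) = M(f) / (|M(f)| + SD(f))

   where M is the across-event mean and SD the across-event standard
   deviation of the per-event averages.  The new band is the contiguous
   frequency run around the peak of K where K exceeds 10% of its maximum.

2. Detection-parameter optimization.  For every candidate (T, N) the
   filling number n(T, N) is the minimum, over training seizures, of the
   count of super-threshold windows among the N windows ending at the
   trigger.  Maximizing the cost C(T, N) = T * (2 n(T, N) - N) and adopting
   n = n(T, N) guarantees that every training seizure would still be
   detected under the new parameters (the preservation guarantee, asserted
   after every optimization).

After a band change, event biomarkers are recomputed from the stored flow
context so the filling numbers always reflect the current band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detector import CONTEXT_HALFSPAN, DetectionParams, EventRecord, detect_offline
from .wavelets import (
    FrequencyBand,
    GaborBank,
    epileptic_content,
    noise_baseline,
    normalized_biomarker,
    spectrum_of_values,
)

#: window span around the trigger used for the spectral average
SPECTRUM_OFFSETS = range(-10, 16)

DEFAULT_T_GRID = np.round(np.arange(0.05, 0.951, 0.01), 10)
DEFAULT_N_GRID = np.arange(2, 16)


@dataclass
class CorrectedSpectrum:
    """Across-event seizure spectrum K(f), variability-penalized, |K| <= 1."""

    frequencies: np.ndarray
    values: np.ndarray
    n_events_used: int

    def __post_init__(self) -> None:
        if np.any(np.abs(self.values) > 1 + 1e-12):
            raise ValueError("|K| must not exceed 1")


@dataclass
class OptimizationResult:
    band: FrequencyBand
    params: DetectionParams
    cost_surface: pd.DataFrame  # index T, columns N
    n_events_used: int

    def cost_to_csv(self, path) -> None:
        self.cost_surface.to_csv(path)


def corrected_spectrum(events: list[EventRecord], bank: GaborBank) -> CorrectedSpectrum:
    """Variability-penalized mean seizure spectrum over validated events.

    Events missing any of the 26 context windows are skipped with a
    warning; at least two usable events are required.
    """
    per_event = []
    for ev in events:
        flows = [ev.flow_at(off) for off in SPECTRUM_OFFSETS]
        if any(f is None for f in flows):
            warnings.warn(f"event {ev.event_id}: incomplete spectral context, skipped")
            continue
        specs = np.array([spectrum_of_values(f, bank).values for f in flows])
        tilde = specs - specs.mean(axis=1, keepdims=True)  # subtract frequency mean
        per_event.append(tilde.mean(axis=0))
    if len(per_event) < 2:
        raise ValueError("need at least two events with full spectral context")
    per_event = np.array(per_event)
    M = per_event.mean(axis=0)
    SD = per_event.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(np.abs(M) + SD > 0, M / (np.abs(M) + SD), 0.0)
    return CorrectedSpectrum(bank.frequencies, K, n_events_used=len(per_event))


def select_band(spectrum: CorrectedSpectrum, rel_threshold: float = 0.1) -> FrequencyBand:
    """Contiguous band around the peak of K where K > rel_threshold * max K.

    If several disjoint super-threshold runs exist, the one containing the
    global maximum wins.
    """
    K = spectrum.values
    kmax = K.max()
    if kmax <= 0:
        raise ValueError("corrected spectrum has no positive peak (no seizure signature)")
    above = K / kmax > rel_threshold
    peak = int(np.argmax(K))
    lo = peak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak
    while hi < len(K) - 1 and above[hi + 1]:
        hi += 1
    return FrequencyBand(float(spectrum.frequencies[lo]), float(spectrum.frequencies[hi]))


def recompute_biomarkers(
    events: list[EventRecord],
    bank: GaborBank,
    band: FrequencyBand,
    e0: float | None = None,
    e0_seed: int = 12345,
    e0_reps: int = 200,
) -> list[np.ndarray]:
    """Per-event biomarker traces over the stored context, under ``band``.

    Returns one array per event, indexed like the event context
    (offsets -25..+25 relative to the trigger); NaN where flow context is
    missing.  Recomputing from flow (rather than reusing stored biomarker
    values) keeps the traces consistent with the current band.
    """
    if e0 is None:
        e0 = noise_baseline(band, bank, n_reps=e0_reps, seed=e0_seed)
    traces = []
    for ev in events:
        trace = np.full(2 * CONTEXT_HALFSPAN + 1, np.nan)
        for slot, flow in enumerate(ev.flow_context):
            if flow is not None:
                E = epileptic_content(spectrum_of_values(flow, bank), band)
                trace[slot] = normalized_biomarker(E, e0)
        traces.append(trace)
    return traces


def filling_number(T: float, N: int, traces: list[np.ndarray]) -> int:
    """Minimum super-threshold count in the N windows ending at the trigger.

    ``traces`` are context-indexed biomarker arrays from
    :func:`recompute_biomarkers`.  The N-window span ends at the trigger
    window, matching the online rule's look-back.
    """
    if N > CONTEXT_HALFSPAN + 1:
        raise ValueError(f"N={N} exceeds stored context depth {CONTEXT_HALFSPAN + 1}")
    counts = []
    for trace in traces:
        span = trace[CONTEXT_HALFSPAN - N + 1 : CONTEXT_HALFSPAN + 1]
        if np.any(np.isnan(span)):
            raise ValueError("event context incomplete over the N-window span")
        counts.append(int(np.sum(span > T)))
    return min(counts)


def optimize_params(
    events: list[EventRecord],
    bank: GaborBank,
    band: FrequencyBand,
    T_grid: np.ndarray = DEFAULT_T_GRID,
    N_grid: np.ndarray = DEFAULT_N_GRID,
    min_events: int = 10,
    max_events: int = 50,
    e0: float | None = None,
    e0_seed: int = 12345,
    e0_reps: int = 200,
) -> OptimizationResult:
    """Grid-search [T, N, n] maximizing C(T, N) = T (2 n(T, N) - N).

    Requires at least ``min_events`` validated seizures; only the most
    recent ``max_events`` are used (older events may reflect stale
    conditions).  Ties are broken by larger T, then smaller N.  Cells with
    filling number 0 are excluded (they cannot guarantee preservation).
    The preservation guarantee is asserted before returning.
    """
    if len(events) < min_events:
        raise ValueError(
            f"need at least {min_events} validated seizure events, have {len(events)}"
        )
    events = sorted(events, key=lambda e: e.trigger_window)[-max_events:]
    traces = recompute_biomarkers(events, bank, band, e0=e0,
                                  e0_seed=e0_seed, e0_reps=e0_reps)
    usable = [t for t in traces
              if not np.any(np.isnan(t[CONTEXT_HALFSPAN - int(max(N_grid)) + 1:
                                       CONTEXT_HALFSPAN + 1]))]
    if len(usable) < len(traces):
        warnings.warn(f"{len(traces) - len(usable)} events lack full context; skipped")
    if len(usable) < min_events:
        raise ValueError("too few events with complete context")
    return optimize_from_traces(usable, band, T_grid=T_grid, N_grid=N_grid)


def optimize_from_traces(
    traces: list[np.ndarray],
    band: FrequencyBand,
    T_grid: np.ndarray = DEFAULT_T_GRID,
    N_grid: np.ndarray = DEFAULT_N_GRID,
) -> OptimizationResult:
    """Grid search over context-indexed biomarker traces (numeric core)."""
    cost = np.full((len(T_grid), len(N_grid)), -np.inf)
    n_of = np.zeros_like(cost, dtype=int)
    for i, T in enumerate(T_grid):
        for j, N in enumerate(N_grid):
            n = filling_number(float(T), int(N), traces)
            n_of[i, j] = n
            if n >= 1:
                cost[i, j] = T * (2 * n - N)
    if not np.any(np.isfinite(cost)):
        raise ValueError("no (T, N) cell preserves all training seizures")

    best = np.argwhere(cost == cost.max())
    # ties: larger T, then smaller N
    best = sorted(best, key=lambda ij: (-T_grid[ij[0]], N_grid[ij[1]]))[0]
    i, j = int(best[0]), int(best[1])
    params = DetectionParams(N=int(N_grid[j]), n=int(n_of[i, j]), T=float(T_grid[i]))

    for trace in traces:  # preservation guarantee (hard assertion)
        span = trace[: CONTEXT_HALFSPAN + 1]
        span = span[~np.isnan(span)]
        if not detect_offline(span, params):
            raise AssertionError(
                "optimization produced parameters that would miss a training seizure"
            )
    surface = pd.DataFrame(cost, index=T_grid, columns=N_grid)
    surface.index.name = "T"
    surface.columns.name = "N"
    return OptimizationResult(band=band, params=params, cost_surface=surface,
                              n_events_used=len(traces))


def adapt(
    events: list[EventRecord],
    bank: GaborBank,
    min_events: int = 10,
    max_events: int = 50,
    rel_threshold: float = 0.1,
    **kwargs,
) -> OptimizationResult:
    """Full adaptation pass: band selection, then parameter optimization."""
    if len(events) < min_events:
        raise ValueError(
            f"need at least {min_events} validated seizure events, have {len(events)}"
        )
    K = corrected_spectrum(events, bank)
    band = select_band(K, rel_threshold=rel_threshold)
    return optimize_params(events, bank, band, min_events=min_events,
                           max_events=max_events, **kwargs)
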