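"""Unsupervised retrospective validation of detected events.

Convulsive seizures are compulsive and therefore stereotyped: their motion
traces resemble each other far more than arbitrary false alarms do.  Each
detected event is summarized by its flow-energy signature — the per-window,
channel-averaged standard deviation of the group velocities over the 41
windows centred on the trigger (20 before, 20 after):

    P(q) = < std_t V_g(t) >_g

Signatures are compared with a lag-minimized, normalized L1 distance

    D_ij = min_tau  sum_q |P_i(q+tau) - P_j(q)| / sum_q |P_i(q+tau) + P_j(q)|

which is bounded in [0, 1], symmetric, and invariant to a common positive
rescaling.  An event is labelled a seizure when its mean distance to all
other recorded events falls below a threshold eps (0.5 by default — the
expected distance between unrelated random signatures — or 0.45 for a more
conservative rule).  The classifier reads only flow-derived signatures:
neither the detection parameters nor the frequency band enter it, and no
raw video is required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detector import EventRecord

#: windows kept on each side of the trigger for the signature
SIGNATURE_HALFSPAN = 20

#: default lag search range, windows
DEFAULT_TAU_MAX = 10

EPS_DEFAULT = 0.5
EPS_CONSERVATIVE = 0.45


@dataclass
class EventSignature:
    """Flow-energy trace P(q) of one event over 41 context windows."""

    event_id: int
    P: np.ndarray  # (41,) non-negative

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if len(self.P) != 2 * SIGNATURE_HALFSPAN + 1:
            raise ValueError(f"signature must span {2 * SIGNATURE_HALFSPAN + 1} windows")
        if np.any(self.P < 0):
            raise ValueError("window energies must be non-negative")


@dataclass
class ClusterResult:
    event_ids: list[int]
    distances: np.ndarray  # (M, M)
    C: np.ndarray  # (M,) mean distance to the other events
    Q: np.ndarray  # (M,) bool, True = classified as seizure
    eps: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"event_id": self.event_ids, "mean_distance": self.C, "is_seizure": self.Q}
        )

    def distances_to_csv(self, path) -> None:
        pd.DataFrame(self.distances, index=self.event_ids,
                     columns=self.event_ids).to_csv(path)


def window_energy(values: np.ndarray) -> float:
    """Channel-averaged temporal standard deviation of one window's rates."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two samples per window")
    return float(values.std(axis=0, ddof=0).mean())


def signature(event: EventRecord) -> EventSignature:
    """Flow-energy signature from an event's stored +-20 window context."""
    from .detector import CONTEXT_HALFSPAN

    P = np.empty(2 * SIGNATURE_HALFSPAN + 1)
    for i, off in enumerate(range(-SIGNATURE_HALFSPAN, SIGNATURE_HALFSPAN + 1)):
        flow = event.flow_context[off + CONTEXT_HALFSPAN]
        if flow is None:
            raise ValueError(f"event {event.event_id}: incomplete flow context")
        P[i] = window_energy(flow)
    return EventSignature(event.event_id, P)


def pairwise_distance(
    sig_i: EventSignature | np.ndarray,
    sig_j: EventSignature | np.ndarray,
    tau_max: int = DEFAULT_TAU_MAX,
) -> float:
    """Lag-minimized normalized L1 distance between two signatures.

    For each integer lag in [-tau_max, tau_max] the sums run over the
    overlapping index range of the shifted pair; the minimum over lags is
    returned.  A pair of all-zero signatures is defined as distance 0
    (identical signals).
    """
    pi = sig_i.P if isinstance(sig_i, EventSignature) else np.asarray(sig_i, float)
    pj = sig_j.P if isinstance(sig_j, EventSignature) else np.asarray(sig_j, float)
    if len(pi) != len(pj):
        raise ValueError("signatures must have equal length")
    if not pi.any() and not pj.any():
        warnings.warn("both signatures are all-zero; distance defined as 0")
        return 0.0
    L = len(pi)
    best = 1.0
    for tau in range(-tau_max, tau_max + 1):
        # overlap: indices q with 0 <= q < L and 0 <= q + tau < L
        lo, hi = max(0, -tau), min(L, L - tau)
        if hi <= lo:
            continue
        a = pi[lo + tau : hi + tau]
        b = pj[lo:hi]
        den = np.abs(a + b).sum()
        if den == 0:
            continue  # silent overlap carries no evidence
        best = min(best, np.abs(a - b).sum() / den)
    return float(best)


def distance_matrix(
    signatures: list[EventSignature], tau_max: int = DEFAULT_TAU_MAX
) -> np.ndarray:
    M = len(signatures)
    D = np.zeros((M, M))
    for i in range(M):
        for j in range(i + 1, M):
            D[i, j] = D[j, i] = pairwise_distance(signatures[i], signatures[j], tau_max)
    return D


def classify(
    signatures: list[EventSignature],
    eps: float = EPS_DEFAULT,
    tau_max: int = DEFAULT_TAU_MAX,
) -> ClusterResult:
    """Label each event by its mean lag-minimized distance to all others.

    Requires at least three events — with fewer, the mean distance to "the
    rest" is not a meaningful clustering quantity.
    """
    if len(signatures) < 3:
        raise ValueError("need at least three events to cluster")
    D = distance_matrix(signatures, tau_max=tau_max)
    M = len(signatures)
    C = D.sum(axis=1) / (M - 1)
    Q = C <= eps
    return ClusterResult(
        event_ids=[s.event_id for s in signatures], distances=D, C=C, Q=Q, eps=eps
    )
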