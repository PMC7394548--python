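"""Template-based miniature-event detection and evoked-amplitude measurement.

Miniature EPSPs are found by a matched filter: the trace is cross-correlated
with the unit-peak difference-of-exponentials event kernel, the correlation
score is thresholded at a multiple of a robust (MAD-based) noise SD, and
local score maxima separated by at least a refractory interval become events.
Amplitudes are measured baseline-to-peak, with the baseline taken as the
median of the 10 ms preceding the event onset. Windows around stimulus times
are excluded so evoked responses are never counted as minis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .errors import DomainError
from .params import TraceSpec
from .simulate import event_kernel

BASELINE_MS = 10.0  # pre-event window for the local baseline median


@dataclass(frozen=True)
class DetectedEvent:
    time: float  # s, at the event peak
    amplitude: float  # mV, baseline-to-peak
    kind: str  # "mini" or "evoked"


def _check_trace(time: np.ndarray, voltage: np.ndarray) -> float:
    if len(time) == 0:
        raise DomainError("empty trace")
    dt = np.diff(time)
    if len(dt) and (dt.max() - dt.min()) > 1e-6 * dt.mean():
        raise DomainError("non-uniform sampling in trace")
    return float(dt.mean()) if len(dt) else 1.0


def detect_minis(
    time: np.ndarray,
    voltage: np.ndarray,
    spec: TraceSpec | None = None,
    threshold_sd: float = 3.5,
    refractory_ms: float = 5.0,
    stimulus_times: Sequence[float] = (),
    exclusion_ms: float = 100.0,
) -> list[DetectedEvent]:
    """Detect miniature events with a matched filter.

    Parameters
    ----------
    time, voltage : arrays
        Uniformly sampled trace (s, mV).
    spec : TraceSpec, optional
        Supplies the kernel time constants and sampling rate; defaults match
        the simulator defaults (1 ms rise, 8 ms decay).
    threshold_sd : float
        Detection threshold as a multiple of the robust noise SD of the
        matched-filter score (MAD-based, so large events do not inflate it).
    refractory_ms : float
        Minimum separation between detected events.
    stimulus_times, exclusion_ms :
        Events within ``exclusion_ms`` of a stimulus are discarded.
    """
    time = np.asarray(time, dtype=float)
    voltage = np.asarray(voltage, dtype=float)
    dt = _check_trace(time, voltage)
    if threshold_sd <= 0:
        raise DomainError("threshold_sd must be > 0")
    fs = 1.0 / dt
    if spec is None:
        spec = TraceSpec(sampling_rate=fs, duration=time[-1] + dt)
    kernel = event_kernel(
        TraceSpec(
            sampling_rate=fs,
            duration=time[-1] + dt,
            rise_tau=spec.rise_tau,
            decay_tau=spec.decay_tau,
        )
    )
    if len(voltage) <= len(kernel):
        raise DomainError("trace shorter than detection kernel")

    k = kernel - kernel.mean()
    k /= np.sqrt(np.sum(k**2))
    # score[i] = correlation of the kernel with the trace starting at i (onset)
    score = signal.fftconvolve(voltage, k[::-1], mode="valid")

    mad = np.median(np.abs(score - np.median(score)))
    noise_sd = 1.4826 * mad
    scale = np.abs(score).max()
    if scale == 0:
        return []
    if noise_sd < 1e-9 * scale:
        # effectively noise-free: keep peaks within 1e-4 of the largest match
        noise_sd = 1e-4 * scale

    refractory = max(int(round(refractory_ms / 1000.0 * fs)), 1)
    onsets, _ = signal.find_peaks(
        score, height=threshold_sd * noise_sd, distance=refractory
    )

    kpeak = int(np.argmax(kernel))
    base_n = max(int(round(BASELINE_MS / 1000.0 * fs)), 1)
    events: list[DetectedEvent] = []
    for i in onsets:
        peak = i + kpeak
        if peak >= len(voltage):
            continue
        t_ev = time[i]  # onset time, comparable to planted event times
        if any(abs(t_ev - s) <= exclusion_ms / 1000.0 for s in stimulus_times):
            continue
        lo = max(i - base_n, 0)
        baseline = np.median(voltage[lo:i]) if i > lo else 0.0
        amplitude = float(voltage[peak] - baseline)
        if amplitude <= 0:  # a template match inside a downward noise dip
            continue
        events.append(
            DetectedEvent(time=float(t_ev), amplitude=amplitude, kind="mini")
        )
    return events


def measure_evoked(
    time: np.ndarray,
    voltage: np.ndarray,
    stimulus_times: Sequence[float],
    window_ms: float = 50.0,
) -> list[DetectedEvent]:
    """Measure one evoked amplitude per stimulus.

    Amplitude is the maximum voltage within ``window_ms`` after the stimulus
    minus the median of the 10 ms preceding it.
    """
    time = np.asarray(time, dtype=float)
    voltage = np.asarray(voltage, dtype=float)
    dt = _check_trace(time, voltage)
    fs = 1.0 / dt
    stims = sorted(float(s) for s in stimulus_times)
    for s in stims:
        if not (time[0] <= s <= time[-1]):
            raise DomainError(f"stimulus time {s} s outside trace span")
    for a, b in zip(stims, stims[1:]):
        if b - a < window_ms / 1000.0:
            raise DomainError("overlapping evoked measurement windows")

    win_n = max(int(round(window_ms / 1000.0 * fs)), 1)
    base_n = max(int(round(BASELINE_MS / 1000.0 * fs)), 1)
    events = []
    for s in stims:
        i0 = int(np.searchsorted(time, s))
        lo = max(i0 - base_n, 0)
        baseline = np.median(voltage[lo:i0]) if i0 > lo else 0.0
        seg = voltage[i0 : min(i0 + win_n, len(voltage))]
        ipk = int(np.argmax(seg))
        events.append(
            DetectedEvent(
                time=float(time[i0 + ipk]),
                amplitude=float(seg[ipk] - baseline),
                kind="evoked",
            )
        )
    return events


def events_to_frame(events: Sequence[DetectedEvent]) -> pd.DataFrame:
    """Event list as the standard CSV layout ``time_s,amplitude_mV,kind``."""
    return pd.DataFrame(
        [(e.time, e.amplitude, e.kind) for e in events],
        columns=["time_s", "amplitude_mV", "kind"],
    )


def match_events(
    detected: Sequence[DetectedEvent],
    truth: pd.DataFrame,
    tolerance_s: float = 0.005,
) -> tuple[int, int, int]:
    """Greedy one-to-one match of detected events to a ground-truth table.

    Returns ``(true_positives, false_positives, false_negatives)``; used for
    F1 scoring against the simulator's planted events.
    """
    truth_times = list(truth["time_s"])
    used = [False] * len(truth_times)
    tp = 0
    for e in sorted(detected, key=lambda e: e.time):
        best, best_d = -1, tolerance_s
        for j, t in enumerate(truth_times):
            if not used[j] and abs(e.time - t) <= best_d:
                best, best_d = j, abs(e.time - t)
        if best >= 0:
            used[best] = True
            tp += 1
    return tp, len(detected) - tp, len(truth_times) - tp


__all__ = [
    "DetectedEvent",
    "detect_minis",
    "measure_evoked",
    "events_to_frame",
    "match_events",
]
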