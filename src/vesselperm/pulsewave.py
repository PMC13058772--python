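"""Parametric arterial pulse-wave synthesis and stepper-motor scheduling.

The flow waveform mimics an arterial pulse: a half-cosine upstroke from the
baseline flow to the systolic peak, a half-cosine decay back to baseline,
and a raised-cosine dicrotic notch — the brief dip and secondary crest that
aortic valve closure stamps on arterial waveforms — subtracted from the
decay.  Each period ends with a flat diastolic gap.  Every knob of the pump
firmware is a field of :class:`PulseParams`: flow direction, baseline and
systolic amplitudes, time to systolic peak, pulse duration, gap between
pulses, and the onset, duration and depth of the notch.

The default cycle is one beat per second (a 60 beats/min cardiac rhythm).

Note the double crest exists only when the notch releases faster than the
decay envelope falls, i.e. roughly ``notch_depth * pi / t_notch_dur >
|d(amplitude)/dt| / amplitude`` at the notch; with the default timing this
means depths of about 0.3 and above.  Shallower notches produce a shoulder,
not a second maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import argrelmax, find_peaks

__all__ = [
    "PulseParams",
    "StepSchedule",
    "waveform",
    "schedule_steps",
    "waveform_metrics",
]

#: one second expressed in minutes, for readability of the defaults
_SEC = 1.0 / 60.0


@dataclass(frozen=True)
class PulseParams:
    """Pump waveform parameters.  All times in minutes, flows in µL/min."""

    direction: int = 1
    Q_base: float = 10.0
    Q_sys: float = 100.0
    t_rise: float = 0.15 * _SEC
    t_pulse: float = 0.6 * _SEC
    t_between: float = 0.4 * _SEC
    t_notch_onset: float = 0.35 * _SEC
    t_notch_dur: float = 0.1 * _SEC
    notch_depth: float = 0.4
    sample_rate: float = 6000.0  # samples per minute (100 Hz)

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if self.Q_base < 0 or self.Q_sys <= self.Q_base:
            raise ValueError("require Q_sys > Q_base >= 0")
        if not 0.0 < self.t_rise < self.t_pulse:
            raise ValueError("require 0 < t_rise < t_pulse")
        if not (
            self.t_rise < self.t_notch_onset
            and self.t_notch_onset + self.t_notch_dur <= self.t_pulse
        ):
            raise ValueError(
                "notch must lie within the decay: "
                "t_rise < t_notch_onset and notch end <= t_pulse"
            )
        if self.t_notch_dur <= 0:
            raise ValueError("t_notch_dur must be positive")
        if not 0.0 <= self.notch_depth < 1.0:
            raise ValueError("notch_depth must be in [0, 1)")
        if self.t_between < 0 or self.sample_rate <= 0:
            raise ValueError("t_between >= 0 and sample_rate > 0 required")

    @property
    def period(self) -> float:
        return self.t_pulse + self.t_between

    @property
    def samples_per_period(self) -> int:
        return int(round(self.period * self.sample_rate))


@dataclass
class StepSchedule:
    """Discretized motor drive: step counts per sample and volume ledger."""

    ul_per_step: float
    steps: np.ndarray  # nonnegative integer steps emitted at each sample
    volume_ul: np.ndarray  # exact cumulative commanded volume

    @property
    def total_steps(self) -> int:
        return int(self.steps.sum())


def waveform(params: PulseParams, n_periods: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Sampled flow series over ``n_periods`` beats.

    Returns ``(t_min, Q_ul_min)``; the series is signed by
    ``params.direction`` and continuous across segment joins.
    """
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    n = params.samples_per_period
    t = np.arange(n) / params.sample_rate
    Q = np.full(n, float(params.Q_base))
    amp_full = params.Q_sys - params.Q_base

    up = t < params.t_rise
    Q[up] = params.Q_base + amp_full * (1 - np.cos(np.pi * t[up] / params.t_rise)) / 2

    dec = (t >= params.t_rise) & (t < params.t_pulse)
    phase = (t[dec] - params.t_rise) / (params.t_pulse - params.t_rise)
    amp = amp_full * (1 + np.cos(np.pi * phase)) / 2
    t_c = params.t_notch_onset + params.t_notch_dur / 2
    dip = np.zeros_like(amp)
    inside = np.abs(t[dec] - t_c) <= params.t_notch_dur / 2
    dip[inside] = (
        params.notch_depth
        * (1 + np.cos(2 * np.pi * (t[dec][inside] - t_c) / params.t_notch_dur))
        / 2
    )
    Q[dec] = params.Q_base + amp * (1 - dip)

    Q = np.tile(Q, n_periods) * params.direction
    t_all = np.arange(n * n_periods) / params.sample_rate
    return t_all, Q


def schedule_steps(
    flow_ul_min: np.ndarray, sample_rate: float, ul_per_step: float
) -> StepSchedule:
    """Convert a flow-magnitude series into integer motor steps per sample.

    Volume is accumulated exactly (one sample spans ``1 / sample_rate``
    minutes) and whole steps are emitted as the accumulator crosses step
    volumes, carrying the remainder; the commanded volume therefore never
    lags the requested volume by more than one step volume.
    """
    flow = np.asarray(flow_ul_min, dtype=float)
    if ul_per_step <= 0:
        raise ValueError("ul_per_step must be positive")
    if (flow < 0).any():
        raise ValueError(
            "flow magnitudes must be nonnegative; handle direction separately"
        )
    vol = np.cumsum(flow / sample_rate)
    emitted = np.floor(vol / ul_per_step).astype(np.int64)
    steps = np.diff(emitted, prepend=0)
    return StepSchedule(ul_per_step=ul_per_step, steps=steps, volume_ul=vol)


def waveform_metrics(series: np.ndarray, sample_rate: float) -> dict[str, float]:
    """Recover pulse rate, peak flow and notch features from a flow trace.

    The dominant (systolic) maxima are found by prominence; the pulse rate
    is the reciprocal of their median spacing.  Within each beat the notch
    is located as the local-minimum / secondary-maximum pair following the
    systolic peak, and its depth is reported relative to the local
    amplitude above the trace's baseline (minimum).
    """
    q = np.asarray(series, dtype=float)
    if len(q) < 4:
        raise ValueError("series too short")
    q = np.abs(q)
    span = q.max() - q.min()
    if span <= 0:
        raise ValueError("flat series: no periodicity to measure")
    peaks, _ = find_peaks(q, prominence=0.5 * span)
    if len(peaks) < 2:
        raise ValueError("fewer than two systolic peaks: no periodicity")
    spacing = float(np.median(np.diff(peaks)))
    pulse_rate = sample_rate / spacing
    peak_flow = float(np.median(q[peaks]))
    base = float(q.min())

    # notch features from the beat after the first full systolic peak
    notch_onsets, notch_depths = [], []
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        seg = q[p0:p1]
        maxima = argrelmax(seg)[0]
        maxima = maxima[maxima > 0]
        if len(maxima) == 0:
            continue
        sec = maxima[np.argmax(seg[maxima])]
        trough = int(np.argmin(seg[:sec]))
        local_amp = seg[trough:sec + 1].max() - base
        if local_amp <= 0:
            continue
        notch_onsets.append(trough / sample_rate)
        notch_depths.append((seg[sec] - seg[trough]) / local_amp)
    return {
        "pulse_rate_per_min": pulse_rate,
        "peak_flow": peak_flow,
        "notch_onset_est": float(np.median(notch_onsets)) if notch_onsets else np.nan,
        "notch_depth_est": float(np.median(notch_depths)) if notch_depths else 0.0,
    }
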