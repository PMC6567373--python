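"""Gait features of the 7-meter walk.

Heel strikes are detected from the low-pass-filtered vertical acceleration
of the lumbar sensor; the 19 gait measures are temporal (duration, cadence
and its variability), smoothness (per-step normalized jerk), regularity
(step/stride autocorrelation peaks), amplitude (RMS, range per axis) and
bilateral coordination (phase coordination index, PCI).  Gait speed is the
walked distance over the test duration and is reported alongside the
health-related measures rather than inside the 19-measure set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.integrate import trapezoid

from .recording import ImuRecording, resample_uniform

GAIT_FEATURE_NAMES = [
    "Total duration", "Cadence", "SD Cadence",
    "NJS AP", "NJS ML", "NJS V",
    "PCI",
    "Range A AP", "Range A ML", "Range A V",
    "RMS A AP", "RMS A ML", "RMS A V",
    "Step Reg AP", "Step Reg ML", "Step Reg V",
    "Stride Reg AP", "Stride Reg ML", "Stride Reg V",
]

GAIT_JERK_MEASURES = ["NJS AP", "NJS ML", "NJS V"]


class InsufficientStepsError(ValueError):
    """Raised when fewer heel strikes are detected than the analysis needs."""


@dataclass
class StepEvents:
    """Detected heel-strike times and the step structure derived from them.

    The alternating strikes are split into two interleaved series (the two
    legs); the series with the longer mean step time is labelled *long*.
    ``long_starts_first`` records whether the long-step series begins at
    the first strike, which fixes the pairing used by the PCI phase.
    """

    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        if self.times.size < 4:
            raise InsufficientStepsError(
                f"need >= 4 heel strikes, got {self.times.size}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("heel-strike times must be strictly increasing")

    @property
    def step_times(self) -> np.ndarray:
        return np.diff(self.times)

    @property
    def n_steps(self) -> int:
        return self.times.size - 1

    @property
    def window(self) -> tuple[float, float]:
        """Gait phase: first to last heel strike."""
        return float(self.times[0]), float(self.times[-1])

    @property
    def long_starts_first(self) -> bool:
        st = self.step_times
        return st[0::2].mean() >= st[1::2].mean()

    @property
    def hs_long(self) -> np.ndarray:
        """Strikes *initiating* the longer steps."""
        return self.times[0::2] if self.long_starts_first else self.times[1::2]

    @property
    def hs_short(self) -> np.ndarray:
        return self.times[1::2] if self.long_starts_first else self.times[0::2]

    @property
    def mean_step_time(self) -> float:
        return float(self.step_times.mean())


def detect_heel_strikes(rec: ImuRecording, rate: float = 100.0,
                        lowpass_hz: float = 10.0,
                        min_separation_s: float = 0.3) -> StepEvents:
    """Detect heel strikes by peak picking on low-passed vertical acceleration.

    The vertical axis is low-pass filtered (zero-phase Butterworth), mean
    removed, and peaks at least ``min_separation_s`` apart are kept if they
    exceed half the median candidate peak height (adaptive threshold).
    """
    if rec.test_label != "7MW":
        raise ValueError(f"expected a 7MW recording, got {rec.test_label!r}")
    sig = resample_uniform(rec, rate)
    v = sig["acc_v"] - sig["acc_v"].mean()
    sos = sps.butter(4, lowpass_hz, btype="lowpass", fs=rate, output="sos")
    v = sps.sosfiltfilt(sos, v)
    dist = max(1, int(round(min_separation_s * rate)))
    idx, props = sps.find_peaks(v, distance=dist, height=0.0)
    if idx.size < 4:
        raise InsufficientStepsError(
            f"detected {idx.size} candidate heel strikes; need >= 4")
    thr = 0.5 * np.median(props["peak_heights"])
    idx = idx[v[idx] >= thr]
    if idx.size < 4:
        raise InsufficientStepsError(
            f"detected {idx.size} heel strikes above threshold; need >= 4")
    return StepEvents(times=idx / rate)


def cadence_features(ev: StepEvents) -> dict[str, float]:
    """Cadence (steps/min) over the gait phase, its per-step SD, and duration.

    Per-step cadence is 60 / step_time; its standard deviation (ddof=1)
    is the cadence-variability measure.
    """
    t0, t1 = ev.window
    duration = t1 - t0
    cadence = 60.0 * ev.n_steps / duration
    per_step = 60.0 / ev.step_times
    sd = float(per_step.std(ddof=1)) if per_step.size > 1 else 0.0
    return {"Cadence": cadence, "SD_Cadence": sd, "Duration": duration}


def _unbiased_autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    """A(n) = 1/(N-n) * sum s_i s_{i+n}, normalized by A(0), for n = 0..max_lag."""
    x = np.asarray(x, float)
    n = x.size
    max_lag = min(max_lag, n - 1)
    full = np.correlate(x, x, mode="full")[n - 1:n + max_lag]
    counts = n - np.arange(max_lag + 1)
    a = full / counts
    return a / a[0]


def regularity(x: np.ndarray, rate: float, ev: StepEvents) -> dict[str, float]:
    """Step and stride regularity of one acceleration axis.

    The unbiased autocorrelation of the mean-removed signal is normalized
    by lag zero; step regularity is its maximum within 0.5-1.5x the mean
    step lag (first dominant period), stride regularity the maximum within
    0.5-1.5x the mean stride lag (second dominant period).  Values are
    bounded in [-1, 1] and invariant to amplitude scaling.
    """
    x = np.asarray(x, float) - np.mean(x)
    step_lag = ev.mean_step_time * rate
    stride_lag = 2.0 * step_lag
    hi = int(np.ceil(1.5 * stride_lag))
    a = _unbiased_autocorr(x, hi)

    def window_peak(center: float) -> float:
        lo = max(1, int(np.floor(0.5 * center)))
        hi_ = min(a.size - 1, int(np.ceil(1.5 * center)))
        if hi_ < lo:
            return float("nan")
        # the unbiased estimator can overshoot 1 slightly at nonzero lag on
        # near-periodic signals; a correlation coefficient stays in [-1, 1]
        return float(np.clip(a[lo:hi_ + 1].max(), -1.0, 1.0))

    return {"StepReg": window_peak(step_lag), "StrideReg": window_peak(stride_lag)}


def phase_coordination_index(ev: StepEvents) -> float:
    """PCI: variability plus inaccuracy of the left-right stepping phase.

    Each stride (long-step strike to the next) spans 360 degrees; the phase
    of the intervening short-step strike is
    phi_i = 360 * (hs_S,i - hs_L,i) / (hs_L,i+1 - hs_L,i).
    PCI = 100 * SD(phi)/mean(phi) + 100 * mean(|phi - 180|) / 180,
    zero only for perfectly alternating, perfectly consistent gait.
    """
    hs_l, hs_s = ev.hs_long, ev.hs_short
    if not ev.long_starts_first:
        # short-series strike precedes each long strike; pair with next long
        hs_s = hs_s[1:] if hs_s[0] < hs_l[0] else hs_s
    n_strides = min(hs_l.size - 1, hs_s.size)
    if n_strides < 2:
        raise InsufficientStepsError("need >= 3 strides for PCI")
    phi = 360.0 * (hs_s[:n_strides] - hs_l[:n_strides]) / np.diff(hs_l)[:n_strides]
    phase_cv = 100.0 * phi.std(ddof=0) / phi.mean()
    return float(phase_cv + 100.0 * np.mean(np.abs(phi - 180.0)) / 180.0)


def gait_jerk(x: np.ndarray, rate: float, ev: StepEvents) -> float:
    """Mean per-step normalized jerk score of one acceleration axis.

    For each step (between consecutive heel strikes)
    NJS = sqrt(T^5 / 2 * integral(da/dt)^2 dt) with T the step duration;
    the feature is the mean over all steps.
    """
    x = np.asarray(x, float)
    dt = 1.0 / rate
    jerk = np.gradient(x, dt)
    vals = []
    for t0, t1 in zip(ev.times[:-1], ev.times[1:]):
        i0, i1 = int(round(t0 * rate)), int(round(t1 * rate))
        if i1 - i0 < 2:
            continue
        T = (i1 - i0) * dt
        vals.append(np.sqrt(T ** 5 / 2.0 * trapezoid(jerk[i0:i1 + 1] ** 2, dx=dt)))
    return float(np.mean(vals))


def gait_speed(duration_s: float, distance_m: float = 7.0) -> float:
    """Distance covered divided by the time taken, m/s."""
    return distance_m / duration_s


def extract_gait_features(rec: ImuRecording, rate: float = 100.0,
                          distance_m: float = 7.0) -> pd.Series:
    """Extract the 19 gait measures from one 7-meter-walk recording.

    RMS/Range are computed on the mean-removed acceleration within the gait
    phase (first to last heel strike).  The returned series carries
    ``gait_speed`` and the device-measured duration in ``.attrs``.
    """
    ev = detect_heel_strikes(rec, rate)
    sig = resample_uniform(rec, rate)
    cad = cadence_features(ev)
    t0, t1 = ev.window
    i0, i1 = int(round(t0 * rate)), int(round(t1 * rate)) + 1
    out: dict[str, float] = {
        "Total duration": cad["Duration"],
        "Cadence": cad["Cadence"],
        "SD Cadence": cad["SD_Cadence"],
        "PCI": phase_coordination_index(ev),
    }
    for ax in ("ap", "ml", "v"):
        a = sig[f"acc_{ax}"]
        w = a[i0:i1] - a[i0:i1].mean()
        axu = ax.upper()
        out[f"RMS A {axu}"] = float(np.sqrt(np.mean(w ** 2)))
        out[f"Range A {axu}"] = float(w.max() - w.min())
        out[f"NJS {axu}"] = gait_jerk(a - a.mean(), rate, ev)
        reg = regularity(a[i0:i1], rate, ev)
        out[f"Step Reg {axu}"] = reg["StepReg"]
        out[f"Stride Reg {axu}"] = reg["StrideReg"]
    s = pd.Series(out, name=rec.meta.get("subject")).reindex(GAIT_FEATURE_NAMES)
    s.attrs["gait_speed"] = gait_speed(cad["Duration"], distance_m)
    s.attrs["device_duration_s"] = cad["Duration"]
    s.attrs["stopwatch_s"] = rec.meta.get("stopwatch_s")
    return s
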