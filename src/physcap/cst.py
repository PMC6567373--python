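"""Five-times chair-stand segmentation and features.

The test is segmented into its ten postural transitions (five sit-to-stand,
Sts, and five stand-to-sit, stS) from the medio-lateral angular velocity,
with the antero-posterior acceleration polarity disambiguating the two
kinds.  The 31 measures pool per-repetition statistics: transition
durations (mean, SD), per-axis normalized jerk of the acceleration, and
RMS/Range of acceleration (three axes) and angular velocity (AP, ML).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.integrate import trapezoid

from .recording import ACC_RANGE, ImuRecording, resample_uniform

CST_FEATURE_NAMES = [
    "Total Duration",
    "Duration Sts", "SD Duration Sts",
    "Sts JS AP", "Sts JS ML", "Sts JS V",
    "Sts A RMS AP", "Sts A RMS ML", "Sts A RMS V",
    "Sts A Range AP", "Sts A Range ML", "Sts A Range V",
    "Sts G RMS AP", "Sts G RMS ML",
    "Sts G Range AP", "Sts G Range ML",
    "Duration stS", "SD Duration stS",
    "stS JS AP", "stS JS ML", "stS JS V",
    "stS A RMS AP", "stS A RMS ML", "stS A RMS V",
    "stS A Range AP", "stS A Range ML", "stS A Range V",
    "stS G RMS AP", "stS G RMS ML",
    "stS G Range AP", "stS G Range ML",
]

CST_JERK_MEASURES = ["Sts JS AP", "Sts JS ML", "Sts JS V",
                     "stS JS AP", "stS JS ML", "stS JS V"]


class IncompleteTestError(ValueError):
    """Raised when fewer than the required 5 + 5 transitions are detected."""


class NoTransitionsError(ValueError):
    """Raised when no postural transition can be located at all."""


@dataclass
class TransitionSegmentation:
    """Ordered, non-overlapping transition phases of a chair-stand test.

    Each phase is ``(kind, start_s, end_s)`` with kind in {"Sts", "stS"};
    kinds alternate starting with a sit-to-stand.
    """

    phases: list[tuple[str, float, float]]

    def __post_init__(self):
        prev_end = -np.inf
        for i, (kind, start, end) in enumerate(self.phases):
            if kind not in ("Sts", "stS"):
                raise ValueError(f"unknown phase kind {kind!r}")
            if end - start <= 0.2:
                raise ValueError("every phase must last more than 0.2 s")
            if start < prev_end:
                raise ValueError("phases must be non-overlapping and ordered")
            expected = "Sts" if i % 2 == 0 else "stS"
            if kind != expected:
                raise ValueError("kinds must alternate starting with Sts")
            prev_end = end

    def of_kind(self, kind: str) -> list[tuple[float, float]]:
        return [(s, e) for k, s, e in self.phases if k == kind]

    @property
    def n_cycles(self) -> int:
        return len(self.of_kind("Sts"))

    @property
    def total_duration(self) -> float:
        return self.phases[-1][2] - self.phases[0][1]


def segment_transitions(rec: ImuRecording, rate: float = 100.0,
                        lowpass_hz: float = 1.5,
                        rel_threshold: float = 0.10,
                        min_peak_dps: float = 10.0,
                        n_cycles: int = 5) -> TransitionSegmentation:
    """Locate the 5 + 5 postural transitions of a complete chair-stand test.

    The ML angular velocity is low-pass filtered (zero-phase Butterworth at
    ``lowpass_hz``); each contiguous region where its magnitude exceeds
    ``rel_threshold`` times the maximum is one transition burst, with
    boundaries at the threshold crossings.  The first burst is classified
    Sts or stS from the sign of the AP acceleration at burst onset (a
    sit-to-stand starts with a forward trunk lean, positive AP), and kinds
    alternate from there; a subject starts the test seated.
    """
    if rec.test_label != "CST":
        raise ValueError(f"expected a CST recording, got {rec.test_label!r}")
    if rec.gyro is None:
        raise ValueError("chair-stand segmentation requires the gyroscope")
    sig = resample_uniform(rec, rate)
    w = sig["gyro_ml"] - sig["gyro_ml"].mean()
    sos = sps.butter(4, lowpass_hz, btype="lowpass", fs=rate, output="sos")
    w = sps.sosfiltfilt(sos, w)
    mag = np.abs(w)
    if mag.max() < min_peak_dps:
        # a genuine postural transition rotates the pelvis by tens of deg/s
        raise NoTransitionsError(
            f"peak |omega_ML| {mag.max():.1f} deg/s below {min_peak_dps}; "
            "no postural transition present")
    thr = rel_threshold * mag.max()
    above = mag > thr
    if not above.any() or thr <= 0:
        raise NoTransitionsError("no angular-velocity bursts found")
    # contiguous runs of `above`
    run_starts = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8))))
                                == 1)
    run_ends = np.flatnonzero(np.diff(np.concatenate((above.view(np.int8), [0])))
                              == -1)
    bursts = [(s / rate, e / rate) for s, e in zip(run_starts, run_ends)
              if (e - s) / rate > 0.2]
    if not bursts:
        raise NoTransitionsError("no burst longer than 0.2 s")
    if len(bursts) < 2 * n_cycles:
        raise IncompleteTestError(
            f"detected {len(bursts)} transitions; a complete test has {2 * n_cycles}")
    bursts = bursts[:2 * n_cycles]
    ap = sig["acc_ap"] - sig["acc_ap"].mean()
    s0, e0 = bursts[0]
    i0, i1 = int(s0 * rate), int(s0 * rate + (e0 - s0) * rate / 3) + 1
    first_kind = "Sts" if ap[i0:i1].mean() > 0 else "stS"
    if first_kind != "Sts":
        raise IncompleteTestError(
            "first detected transition looks like a stand-to-sit; "
            "the test must start seated")
    phases = [("Sts" if i % 2 == 0 else "stS", s, e)
              for i, (s, e) in enumerate(bursts)]
    return TransitionSegmentation(phases=phases)


def _segment_stats(x: np.ndarray, rate: float,
                   spans: list[tuple[float, float]]) -> tuple[float, float]:
    """Per-repetition RMS (about the segment mean) and Range, averaged."""
    rms, rng = [], []
    for t0, t1 in spans:
        seg = x[int(round(t0 * rate)):int(round(t1 * rate)) + 1]
        seg = seg - seg.mean()
        rms.append(np.sqrt(np.mean(seg ** 2)))
        rng.append(seg.max() - seg.min())
    return float(np.mean(rms)), float(np.mean(rng))


def _segment_njs(x: np.ndarray, rate: float,
                 spans: list[tuple[float, float]]) -> float:
    """Mean over repetitions of sqrt(T^5/2 * integral(da/dt)^2 dt)."""
    dt = 1.0 / rate
    jerk = np.gradient(np.asarray(x, float), dt)
    vals = []
    for t0, t1 in spans:
        i0, i1 = int(round(t0 * rate)), int(round(t1 * rate))
        T = (i1 - i0) * dt
        vals.append(np.sqrt(T ** 5 / 2.0 * trapezoid(jerk[i0:i1 + 1] ** 2, dx=dt)))
    return float(np.mean(vals))


def extract_cst_features(rec: ImuRecording,
                         seg: TransitionSegmentation | None = None,
                         rate: float = 100.0) -> pd.Series:
    """Extract the 31 chair-stand measures.

    Statistics are computed within each repetition and then averaged across
    the five repetitions of each kind.  Acceleration samples beyond the
    +-2 g sensor range (the sitting impact) are winsorized at the range
    limit before feature computation.
    """
    if seg is None:
        seg = segment_transitions(rec, rate)
    sig = resample_uniform(rec, rate)
    acc = {ax: np.clip(sig[f"acc_{ax}"], -ACC_RANGE, ACC_RANGE)
           for ax in ("ap", "ml", "v")}
    gyro = {ax: sig[f"gyro_{ax}"] for ax in ("ap", "ml")}
    out: dict[str, float] = {"Total Duration": seg.total_duration}
    for kind in ("Sts", "stS"):
        spans = seg.of_kind(kind)
        durs = np.array([e - s for s, e in spans])
        out[f"Duration {kind}"] = float(durs.mean())
        out[f"SD Duration {kind}"] = float(durs.std(ddof=1)) if durs.size > 1 else 0.0
        for ax in ("ap", "ml", "v"):
            axu = ax.upper()
            a = acc[ax] - acc[ax].mean()
            out[f"{kind} JS {axu}"] = _segment_njs(a, rate, spans)
            rms, rng = _segment_stats(acc[ax], rate, spans)
            out[f"{kind} A RMS {axu}"] = rms
            out[f"{kind} A Range {axu}"] = rng
        for ax in ("ap", "ml"):
            axu = ax.upper()
            rms, rng = _segment_stats(gyro[ax], rate, spans)
            out[f"{kind} G RMS {axu}"] = rms
            out[f"{kind} G Range {axu}"] = rng
    return pd.Series(out, name=rec.meta.get("subject")).reindex(CST_FEATURE_NAMES)
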