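"""Lumbar-IMU recording model and signal conditioning.

A single functional test (quiet stand, 7-meter walk or five-times chair
stand) is represented as an :class:`ImuRecording`: tri-axial acceleration
(and, for the chair stand, angular velocity) sampled at a nominal 100 Hz
with per-sample nanosecond timestamps.  Because consumer devices do not
sample uniformly, every analysis starts by interpolating onto an exactly
uniform grid (:func:`resample_uniform`).  The module also provides the two
conditioning primitives shared by the feature extractors: a band-limited
Welch power-spectral-density estimate with spectral moments
(:func:`band_limited_psd`) and a drift-suppressed double integration of
horizontal acceleration into an estimate of center-of-mass displacement
(:func:`estimate_displacement`).

Axis convention: AP (antero-posterior), ML (medio-lateral), V (vertical).
Acceleration is in m/s^2, angular velocity in deg/s.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

#: standard gravity, m/s^2 per g
G = 9.80665

#: accelerometer full-scale range of the phones used for this protocol (+-2 g)
ACC_RANGE = 2.0 * G

AXES = ("ap", "ml", "v")
TEST_LABELS = ("QS", "7MW", "CST")

SIGNAL_CSV_COLUMNS = ["t_ns", "acc_ap", "acc_ml", "acc_v",
                      "gyro_ap", "gyro_ml", "gyro_v"]


class InvalidRecordingError(ValueError):
    """Raised when a recording violates its structural invariants."""


class TooShortError(ValueError):
    """Raised when a recording is too short for the requested operation."""


@dataclass
class ImuRecording:
    """Raw tri-axial inertial stream of one functional test.

    Parameters
    ----------
    test_label : {"QS", "7MW", "CST"}
    t_ns : ndarray of int64
        Per-sample timestamps in nanoseconds, strictly increasing.
    acc : ndarray, shape (n, 3)
        Acceleration in m/s^2, columns ordered (AP, ML, V).
    gyro : ndarray, shape (n, 3), optional
        Angular velocity in deg/s, same column order.  May be ``None``
        for tests that do not use the gyroscope (QS, 7MW).
    meta : dict
        Free-form metadata: ``subject``, ``stopwatch_s`` (manually timed
        duration), and generator-planted ground truth such as ``events``
        (heel-strike times) or ``phases`` (transition boundaries).
    """

    test_label: str
    t_ns: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t_ns = np.asarray(self.t_ns, dtype=np.int64)
        self.acc = np.atleast_2d(np.asarray(self.acc, dtype=float))
        if self.test_label not in TEST_LABELS:
            raise InvalidRecordingError(
                f"unknown test label {self.test_label!r}; expected one of {TEST_LABELS}")
        if self.t_ns.size < 2:
            raise InvalidRecordingError("recording needs at least 2 samples")
        if np.any(np.diff(self.t_ns) <= 0):
            raise InvalidRecordingError("timestamps must be strictly increasing")
        if self.acc.shape != (self.t_ns.size, 3):
            raise InvalidRecordingError(
                f"acc must be (n, 3) with one row per timestamp; got {self.acc.shape}")
        if self.gyro is not None:
            self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
            if self.gyro.shape != self.acc.shape:
                raise InvalidRecordingError("gyro must match acc sample count")

    @property
    def n_samples(self) -> int:
        return self.t_ns.size

    @property
    def t_s(self) -> np.ndarray:
        """Timestamps in seconds relative to the first sample."""
        return (self.t_ns - self.t_ns[0]) / 1e9

    @property
    def duration_s(self) -> float:
        return float((self.t_ns[-1] - self.t_ns[0]) / 1e9)

    @property
    def clipped_mask(self) -> np.ndarray:
        """Boolean (n, 3) mask of samples at/beyond the +-2 g sensor range.

        Saturation is flagged, not rejected: at the lower back it is limited
        to a few samples around the sitting impact of the chair-stand test.
        """
        return np.abs(self.acc) >= ACC_RANGE

    # ---------------------------------------------------------------- I/O

    def to_csv(self, path: str | Path) -> None:
        """Write the signal CSV (header ``t_ns,acc_ap,...,gyro_v``)."""
        df = pd.DataFrame({"t_ns": self.t_ns})
        for j, ax in enumerate(AXES):
            df[f"acc_{ax}"] = self.acc[:, j]
        if self.gyro is not None:
            for j, ax in enumerate(AXES):
                df[f"gyro_{ax}"] = self.gyro[:, j]
        df.to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase, test_label: str,
                 acc_unit: str = "m/s^2", meta: dict | None = None) -> "ImuRecording":
        """Read a signal CSV.  Missing gyroscope columns are allowed.

        ``acc_unit`` may be ``"m/s^2"`` (default) or ``"g"``; values are
        always stored internally in m/s^2.
        """
        df = pd.read_csv(path)
        if "t_ns" not in df.columns:
            raise InvalidRecordingError("signal CSV must contain a t_ns column")
        scale = G if acc_unit == "g" else 1.0
        if acc_unit not in ("g", "m/s^2"):
            raise ValueError(f"acc_unit must be 'g' or 'm/s^2', got {acc_unit!r}")
        acc = df[[f"acc_{ax}" for ax in AXES]].to_numpy() * scale
        gyro_cols = [f"gyro_{ax}" for ax in AXES]
        gyro = df[gyro_cols].to_numpy() if all(c in df.columns for c in gyro_cols) else None
        return cls(test_label, df["t_ns"].to_numpy(), acc, gyro, meta=dict(meta or {}))


@dataclass
class UniformSignal:
    """Named channels on a uniform time grid."""

    rate: float
    channels: dict[str, np.ndarray]

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("all channels must have equal length")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    @property
    def n(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        """Span T = (N - 1) / rate in seconds."""
        return (self.n - 1) / self.rate

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n) / self.rate


@dataclass
class PsdEstimate:
    """One-sided band-limited PSD with spectral moments.

    ``psd`` is a power spectral density (signal units squared per Hz) on the
    retained grid ``f`` (frequencies below the low cut excluded).  Moments
    are integrals over the retained band, so ``mu0`` equals the total power
    ``tp`` and approximates the time-domain variance of the band-limited
    signal (Parseval).
    """

    f: np.ndarray
    psd: np.ndarray
    df: float

    def __post_init__(self):
        self.f = np.asarray(self.f, float)
        self.psd = np.asarray(self.psd, float)
        if self.f.size and (np.any(np.diff(self.f) <= 0) or self.f[0] < 0):
            raise ValueError("frequency grid must be non-negative and increasing")
        if np.any(self.psd < 0):
            raise ValueError("PSD must be non-negative")

    @property
    def mu0(self) -> float:
        return float(np.sum(self.psd) * self.df)

    tp = mu0

    @property
    def mu1(self) -> float:
        return float(np.sum(self.f * self.psd) * self.df)

    @property
    def mu2(self) -> float:
        return float(np.sum(self.f ** 2 * self.psd) * self.df)


def resample_uniform(rec: ImuRecording, rate: float = 100.0) -> UniformSignal:
    """Interpolate a recording onto the uniform grid ``t0 + k / rate``.

    Piecewise-linear interpolation against the absolute nanosecond
    timestamps; the grid covers [t0, t_end].  Idempotent on input that is
    already uniform at the requested rate.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    t = rec.t_s
    if t[-1] < 2.0 / rate:
        raise TooShortError(
            f"recording spans {t[-1]:.4f} s; need at least {2.0 / rate:.4f} s at {rate} Hz")
    n_out = int(np.floor(t[-1] * rate + 1e-9)) + 1
    grid = np.arange(n_out) / rate
    channels: dict[str, np.ndarray] = {}
    for j, ax in enumerate(AXES):
        channels[f"acc_{ax}"] = np.interp(grid, t, rec.acc[:, j])
    if rec.gyro is not None:
        for j, ax in enumerate(AXES):
            channels[f"gyro_{ax}"] = np.interp(grid, t, rec.gyro[:, j])
    return UniformSignal(rate=rate, channels=channels)


#: minimum series length for a PSD estimate
PSD_MIN_SAMPLES = 256


def band_limited_psd(x: np.ndarray, rate: float, low_cut: float = 0.15,
                     seg_seconds: float = 20.0) -> PsdEstimate:
    """Welch PSD restricted to frequencies at or above ``low_cut``.

    Hann window, 50 % overlap, per-segment mean removal.  The segment
    length (default 20 s, capped at the series length) keeps the frequency
    resolution at or below 0.05 Hz so the 0.15 Hz floor is resolvable on a
    30 s quiet-stand record.
    """
    x = np.asarray(x, float)
    if x.size < PSD_MIN_SAMPLES:
        raise TooShortError(
            f"series has {x.size} samples; PSD estimation needs at least {PSD_MIN_SAMPLES}")
    nperseg = min(x.size, int(round(seg_seconds * rate)))
    f, psd = sps.welch(x, fs=rate, window="hann", nperseg=nperseg,
                       noverlap=nperseg // 2, detrend="constant")
    df = f[1] - f[0]
    keep = f >= low_cut
    return PsdEstimate(f=f[keep], psd=psd[keep], df=float(df))


def _highpass(x: np.ndarray, rate: float, corner: float) -> np.ndarray:
    # Gustafsson initial conditions: a plain zero-phase pass of a 0.15 Hz
    # corner rings for seconds at the record edges, which would leak into
    # every displacement-based sway measure
    b, a = sps.butter(4, corner, btype="highpass", fs=rate)
    return sps.filtfilt(b, a, x, method="gust")


def estimate_displacement(acc_ap: np.ndarray, acc_ml: np.ndarray, rate: float,
                          corner: float = 0.15,
                          taper_s: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Estimate planar center-of-mass displacement from horizontal acceleration.

    Drift-suppressing double integration: zero-phase 4th-order Butterworth
    high-pass at ``corner`` Hz applied to the acceleration, trapezoidal
    integration to velocity, re-high-pass, integration to displacement,
    re-high-pass; finally the first/last ``taper_s`` seconds are faded with
    a half-cosine to remove edge transients.  Output series are zero-mean.

    The 0.15 Hz corner matches the spectral floor of the sway analysis:
    postural content below it is indistinguishable from integration drift.
    """
    out = []
    for a in (acc_ap, acc_ml):
        a = np.asarray(a, float)
        a = _highpass(a - a.mean(), rate, corner)
        v = cumulative_trapezoid(a, dx=1.0 / rate, initial=0.0)
        # remove the integration constant/trend before high-passing: a large
        # DC or linear component would otherwise ring at the record edges
        v = _highpass(sps.detrend(v, type="linear"), rate, corner)
        d = cumulative_trapezoid(v, dx=1.0 / rate, initial=0.0)
        d = _highpass(sps.detrend(d, type="linear"), rate, corner)
        n_tap = min(int(round(taper_s * rate)), d.size // 2)
        if n_tap > 0:
            w = 0.5 * (1 - np.cos(np.pi * np.arange(n_tap) / n_tap))
            d[:n_tap] *= w
            d[-n_tap:] *= w[::-1]
        out.append(d - d.mean())
    return out[0], out[1]
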