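"""Quiet-stand postural-sway features.

Computes the 23 sway measures of the 30 s eyes-closed quiet stand from the
lumbar accelerometer: per-axis (AP, ML) spectral descriptors (CF, F50, F95,
FD, SE), time-domain dispersion (RMS, Range) and jerkiness (NJS) of the
acceleration, and trajectory measures of the estimated center-of-mass
displacement (sway path, mean velocity, sway area, 95 % confidence ellipse
area).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid

from .recording import (ImuRecording, PsdEstimate, band_limited_psd,
                        estimate_displacement, resample_uniform)

#: chi-square 0.95 quantile with 2 degrees of freedom (95 % confidence ellipse)
CHI2_95_DF2 = 5.991

#: canonical names of the 23 quiet-stand measures (matching the loading fixtures)
QS_FEATURE_NAMES = [
    "CF AP", "F50 AP", "F95 AP", "FD AP", "SE AP",
    "RMS A AP", "Range A AP", "NJS AP",
    "CF ML", "F50 ML", "F95 ML", "FD ML", "SE ML",
    "RMS A ML", "Range A ML", "NJS ML",
    "SP AP DISPL", "SP ML DISPL", "SP Planar DISPL",
    "MV AP DISPL", "MV ML DISPL", "SA DISPL", "EA DISPL",
]

#: quiet-stand measures that are jerk scores (log-transformed before EFA)
QS_JERK_MEASURES = ["NJS AP", "NJS ML"]


class UndefinedSpectrumError(ValueError):
    """Raised when spectral features are requested for a zero-power spectrum."""


def spectral_features(psd: PsdEstimate) -> dict[str, float]:
    """Spectral sway descriptors from a band-limited PSD.

    CF = sqrt(mu2/mu0) (centroidal frequency); F50/F95 = smallest grid
    frequency at which cumulative power reaches 50 %/95 % of the total;
    FD = sqrt(1 - mu1^2/(mu0*mu2)) (0 for a pure sinusoid, grows with
    bandwidth); SE = normalized power-spectrum entropy in [0, 1].
    """
    tp = psd.mu0
    if psd.f.size < 2 or tp <= 0:
        raise UndefinedSpectrumError("total power is zero; spectral features undefined")
    cf = float(np.sqrt(psd.mu2 / psd.mu0))
    cum = np.cumsum(psd.psd) * psd.df
    f50 = float(psd.f[np.searchsorted(cum, 0.50 * tp)])
    f95 = float(psd.f[np.searchsorted(cum, 0.95 * tp)])
    fd = float(np.sqrt(max(0.0, 1.0 - psd.mu1 ** 2 / (psd.mu0 * psd.mu2))))
    p = psd.psd * psd.df / tp
    nz = p[p > 0]
    se = float(-(nz * np.log(nz)).sum() / np.log(p.size))
    return {"CF": cf, "F50": f50, "F95": f95, "FD": fd, "SE": se}


def sway_time_features(x: np.ndarray, rate: float) -> dict[str, float]:
    """RMS, Range and normalized jerk score of one acceleration axis.

    NJS = sqrt(T^5 / (2 SP^2) * integral(da/dt)^2 dt) where SP is the
    one-dimensional path length of the same acceleration component
    (sum of absolute increments) and da/dt uses central differences.
    A constant signal has SP = 0 and its NJS is returned as NaN.
    """
    x = np.asarray(x, float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    dt = 1.0 / rate
    T = (x.size - 1) * dt
    rms = float(np.sqrt(np.mean((x - x.mean()) ** 2)))
    rng = float(x.max() - x.min())
    sp = float(np.sum(np.abs(np.diff(x))))
    if sp == 0.0:
        return {"RMS": rms, "Range": rng, "NJS": float("nan")}
    jerk = np.gradient(x, dt)
    njs = float(np.sqrt(T ** 5 / (2.0 * sp ** 2) * trapezoid(jerk ** 2, dx=dt)))
    return {"RMS": rms, "Range": rng, "NJS": njs}


def displacement_features(d_ap: np.ndarray, d_ml: np.ndarray,
                          T: float) -> dict[str, float]:
    """Trajectory measures of the planar sway displacement.

    Sway path per axis is the sum of absolute increments; the planar sway
    path sums Euclidean step lengths.  Mean velocity is SP/T per axis.
    Sway area is the triangle sum swept about the mean point; the ellipse
    area is pi * chi2(0.95, 2) * sqrt(det cov), the area of the 95 %
    confidence ellipse of the (AP, ML) point cloud.
    """
    d_ap = np.asarray(d_ap, float)
    d_ml = np.asarray(d_ml, float)
    if d_ap.size != d_ml.size:
        raise ValueError("AP and ML displacement series must have equal length")
    sp_ap = float(np.sum(np.abs(np.diff(d_ap))))
    sp_ml = float(np.sum(np.abs(np.diff(d_ml))))
    sp_planar = float(np.sum(np.hypot(np.diff(d_ap), np.diff(d_ml))))
    m_ap, m_ml = d_ap.mean(), d_ml.mean()
    a_ap, a_ml = d_ap - m_ap, d_ml - m_ml
    sa = float(0.5 * np.sum(np.abs(a_ap[1:] * a_ml[:-1] - a_ap[:-1] * a_ml[1:])))
    cov = np.cov(d_ap, d_ml)
    ea = float(np.pi * CHI2_95_DF2 * np.sqrt(max(0.0, np.linalg.det(cov))))
    return {"SP_AP": sp_ap, "SP_ML": sp_ml, "SP_planar": sp_planar,
            "MV_AP": sp_ap / T, "MV_ML": sp_ml / T, "SA": sa, "EA": ea}


def extract_qs_features(rec: ImuRecording, rate: float = 100.0,
                        low_cut: float = 0.15,
                        min_duration_s: float = 20.0) -> pd.Series:
    """Extract the 23 quiet-stand measures from one recording.

    The recording is resampled to a uniform grid; spectral and time-domain
    measures are computed on the mean-removed AP and ML acceleration, and
    trajectory measures on the estimated center-of-mass displacement.
    """
    if rec.test_label != "QS":
        raise ValueError(f"expected a QS recording, got {rec.test_label!r}")
    if rec.duration_s < min_duration_s:
        raise ValueError(
            f"QS recording lasts {rec.duration_s:.1f} s; need >= {min_duration_s} s")
    sig = resample_uniform(rec, rate)
    out: dict[str, float] = {}
    for ax in ("ap", "ml"):
        a = sig[f"acc_{ax}"]
        a = a - a.mean()
        spec = spectral_features(band_limited_psd(a, rate, low_cut=low_cut))
        axu = ax.upper()
        out[f"CF {axu}"] = spec["CF"]
        out[f"F50 {axu}"] = spec["F50"]
        out[f"F95 {axu}"] = spec["F95"]
        out[f"FD {axu}"] = spec["FD"]
        out[f"SE {axu}"] = spec["SE"]
        tdom = sway_time_features(a, rate)
        out[f"RMS A {axu}"] = tdom["RMS"]
        out[f"Range A {axu}"] = tdom["Range"]
        out[f"NJS {axu}"] = tdom["NJS"]
    d_ap, d_ml = estimate_displacement(sig["acc_ap"], sig["acc_ml"], rate,
                                       corner=low_cut)
    disp = displacement_features(d_ap, d_ml, sig.duration)
    out["SP AP DISPL"] = disp["SP_AP"]
    out["SP ML DISPL"] = disp["SP_ML"]
    out["SP Planar DISPL"] = disp["SP_planar"]
    out["MV AP DISPL"] = disp["MV_AP"]
    out["MV ML DISPL"] = disp["MV_ML"]
    out["SA DISPL"] = disp["SA"]
    out["EA DISPL"] = disp["EA"]
    return pd.Series(out, name=rec.meta.get("subject")).reindex(QS_FEATURE_NAMES)
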