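"""Synthetic inputs for every stage of the pipeline.

No public accession exists for the original cohort's smartphone recordings,
so this module generates every input the analysis needs:

* per-test IMU recordings with planted ground truth — band-limited sway for
  the quiet stand, a walk with planted heel strikes and controllable
  asymmetry/variability, and a five-cycle chair stand with planted
  transition boundaries;
* factor-structured feature matrices drawn from the common factor model
  ``X = F L' + E diag(sqrt(psi))`` with the published per-test loading
  matrices shipped as fixtures;
* a cohort table of health-related measures whose default means and SDs
  follow the published demographic/functional profile of the study
  population.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import G, ImuRecording

__all__ = [
    "SyntheticFactorSpec", "GaitSimParams", "load_loading_matrix",
    "simulate_feature_matrix", "generate_qs_recording",
    "generate_walk_recording", "generate_cst_recording",
    "generate_cohort_table", "COHORT_COLUMNS",
]

#: uniqueness floor keeping the model covariance positive definite even for
#: measures whose published communality approaches 1
UNIQUENESS_FLOOR = 0.05

_FIXTURES = {"qs": "loadings_qs.csv", "7mw": "loadings_7mw.csv",
             "cst": "loadings_cst.csv"}

#: study subgroup sizes per test (subjects completing each test)
SUBGROUP_SIZES = {"qs": 204, "7mw": 201, "cst": 173}


def load_loading_matrix(test: str) -> pd.DataFrame:
    """Published varimax loading matrix for one test ("qs", "7mw" or "cst").

    Rows are measure names (matching the feature extractors), columns the
    per-test factors (QS1..QS4, 7MW1..7MW5, CST1..CST6).
    """
    try:
        fname = _FIXTURES[test.lower()]
    except KeyError:
        raise ValueError(f"unknown test {test!r}; expected one of {sorted(_FIXTURES)}")
    with resources.files("physcap.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, index_col=0)


@dataclass
class SyntheticFactorSpec:
    """Common-factor generative model for a feature matrix.

    ``loadings`` is the p x k loading matrix; uniquenesses are
    ``max(1 - communality, floor)`` so the implied covariance
    ``L L' + diag(psi)`` stays positive definite.
    """

    loadings: pd.DataFrame
    n: int
    floor: float = UNIQUENESS_FLOOR

    def __post_init__(self):
        if self.floor <= 0:
            raise ValueError("uniqueness floor must be positive")
        if self.n <= 0:
            raise ValueError("need a positive number of subjects")

    @property
    def uniquenesses(self) -> np.ndarray:
        L = self.loadings.to_numpy()
        return np.maximum(1.0 - (L ** 2).sum(axis=1), self.floor)

    @property
    def implied_covariance(self) -> np.ndarray:
        L = self.loadings.to_numpy()
        return L @ L.T + np.diag(self.uniquenesses)

    @classmethod
    def for_test(cls, test: str, n: int | None = None,
                 floor: float = UNIQUENESS_FLOOR) -> "SyntheticFactorSpec":
        """Spec built from the shipped loading fixture of one test, at the
        study's subgroup size unless ``n`` is given."""
        return cls(loadings=load_loading_matrix(test),
                   n=n if n is not None else SUBGROUP_SIZES[test.lower()],
                   floor=floor)


def simulate_feature_matrix(spec: SyntheticFactorSpec,
                            seed: int | np.random.Generator | None = None,
                            return_factors: bool = False):
    """Draw a subjects x measures table from the common factor model.

    ``X = F L' + E diag(sqrt(psi))`` with latent factors F and unique
    errors E independent standard normal; columns have mean ~0 and
    variance ~1 (exactly 1 in expectation up to the uniqueness floor).
    """
    rng = np.random.default_rng(seed)
    L = spec.loadings.to_numpy()
    p, k = L.shape
    F = rng.standard_normal((spec.n, k))
    E = rng.standard_normal((spec.n, p))
    X = F @ L.T + E * np.sqrt(spec.uniquenesses)
    idx = pd.Index([f"s{i:04d}" for i in range(spec.n)], name="subject")
    table = pd.DataFrame(X, index=idx, columns=spec.loadings.index)
    if return_factors:
        return table, pd.DataFrame(F, index=idx, columns=spec.loadings.columns)
    return table


# --------------------------------------------------------------------------
# IMU recording generators
# --------------------------------------------------------------------------

def _timestamps(n: int, rate: float, rng: np.random.Generator,
                jitter_ms: float) -> np.ndarray:
    """Strictly increasing nanosecond timestamps, nominally 1/rate apart.

    Non-zero jitter emulates the non-real-time sampling of a phone OS.
    """
    dt = np.full(n - 1, 1.0 / rate)
    if jitter_ms > 0:
        dt = dt + rng.normal(0.0, jitter_ms * 1e-3, size=n - 1)
        dt = np.maximum(dt, 0.2 / rate)
    t = np.concatenate(([0.0], np.cumsum(dt)))
    return np.round(t * 1e9).astype(np.int64)


def _band_limited_noise(n: int, rate: float, band: tuple[float, float],
                        rms: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise band-passed to ``band`` and scaled to an exact RMS."""
    if rms == 0.0:
        return np.zeros(n)
    x = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, x)
    x = x - x.mean()
    return x * (rms / np.sqrt(np.mean(x ** 2)))


def generate_qs_recording(rms_ap: float = 0.08, rms_ml: float = 0.06,
                          band: tuple[float, float] = (0.2, 2.0),
                          duration_s: float = 30.0, rate: float = 100.0,
                          seed: int | np.random.Generator | None = None,
                          jitter_ms: float = 1.0,
                          subject: str | None = None) -> ImuRecording:
    """30 s quiet-stand recording: band-limited Gaussian sway acceleration.

    AP and ML channels are zero-mean noise confined to ``band`` with the
    requested per-axis RMS (exact on the generated samples); the vertical
    channel sits at gravity plus small wide-band noise.  Defaults emulate
    the sway magnitude of community-dwelling older adults.
    """
    if rms_ap < 0 or rms_ml < 0:
        raise ValueError("sway RMS must be non-negative")
    if duration_s <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate)) + 1
    t_ns = _timestamps(n, rate, rng, jitter_ms)
    acc = np.empty((n, 3))
    acc[:, 0] = _band_limited_noise(n, rate, band, rms_ap, rng)
    acc[:, 1] = _band_limited_noise(n, rate, band, rms_ml, rng)
    acc[:, 2] = G + rng.normal(0.0, 0.01, n)
    return ImuRecording("QS", t_ns, acc,
                        meta={"subject": subject, "band": band,
                              "rms_ap": rms_ap, "rms_ml": rms_ml})


@dataclass
class GaitSimParams:
    """Planted gait structure for the walk generator.

    cadence in steps/min; ``asymmetry`` >= 1 is the long/short step-time
    ratio; ``step_cv`` the coefficient of variation of step times;
    amplitudes are the per-axis heel-strike impulse sizes in m/s^2.
    Defaults approximate an older adult walking 7 m at a comfortable pace.
    """

    cadence: float = 110.0
    asymmetry: float = 1.0
    step_cv: float = 0.0
    amp_v: float = 1.2
    amp_ap: float = 0.6
    amp_ml: float = 0.3
    n_steps: int = 14
    lead_in_s: float = 1.0

    def __post_init__(self):
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")
        if self.asymmetry < 1:
            raise ValueError("asymmetry ratio must be >= 1")
        if self.step_cv < 0:
            raise ValueError("step-time CV must be >= 0")


#: default smartphone-minus-stopwatch duration offset (s): mean and SD of the
#: paired differences used when emulating the manually timed duration
STOPWATCH_OFFSET = {"7MW": (1.37, 0.995), "CST": (2.925, 1.558)}


def generate_walk_recording(params: GaitSimParams | None = None,
                            rate: float = 100.0,
                            seed: int | np.random.Generator | None = None,
                            jitter_ms: float = 1.0,
                            subject: str | None = None) -> ImuRecording:
    """7-meter-walk recording with planted heel strikes.

    Step times alternate long/short according to the asymmetry ratio and
    are perturbed multiplicatively by the step-time CV; each heel strike
    plants a half-sine impulse on the V and AP axes on top of a
    cadence-locked oscillation, and the ML axis oscillates at the stride
    frequency (trunk sway alternates side to side).  Planted strike times
    are returned in ``meta["events"]`` and an emulated stopwatch duration
    in ``meta["stopwatch_s"]``.
    """
    params = params or GaitSimParams()
    rng = np.random.default_rng(seed)
    base = 60.0 / params.cadence
    r = params.asymmetry
    t_long, t_short = 2 * base * r / (1 + r), 2 * base / (1 + r)
    steps = np.where(np.arange(params.n_steps) % 2 == 0, t_long, t_short)
    if params.step_cv > 0:
        steps = steps * np.maximum(0.2, 1 + params.step_cv
                                   * rng.standard_normal(params.n_steps))
    events = params.lead_in_s + np.concatenate(([0.0], np.cumsum(steps)))
    total = events[-1] + params.lead_in_s
    n = int(round(total * rate)) + 1
    # waveforms are evaluated at the actual (jittered) sample times so the
    # planted event metadata stays exact in recording time
    t_ns = _timestamps(n, rate, rng, jitter_ms)
    t = t_ns / 1e9
    step_hz = params.cadence / 60.0
    acc = np.zeros((n, 3))
    walking = (t >= events[0] - 0.3) & (t <= events[-1] + 0.3)
    # background oscillation phase-locked to the first strike so its maxima
    # fall near the planted strikes (vertical acceleration peaks at contact)
    tau = t - events[0]
    acc[:, 0] += 0.25 * params.amp_ap * np.cos(2 * np.pi * step_hz * tau) * walking
    acc[:, 2] += 0.25 * params.amp_v * np.cos(2 * np.pi * step_hz * tau) * walking
    acc[:, 1] += 0.8 * params.amp_ml * np.cos(np.pi * step_hz * tau) * walking
    width = 0.14  # impulse duration, s; centered on the planted strike time
    for i, ev in enumerate(events):
        mask = (t >= ev - width / 2) & (t < ev + width / 2)
        lobe = np.sin(np.pi * (t[mask] - ev + width / 2) / width)
        side = 1.0 if i % 2 == 0 else -1.0
        scale = 1.0 if i % 2 == 0 else 1.0 / r  # stride periodicity for r > 1
        acc[mask, 2] += params.amp_v * scale * lobe
        acc[mask, 0] += params.amp_ap * scale * lobe
        acc[mask, 1] += 0.4 * params.amp_ml * side * lobe
    acc[:, 2] += G
    acc += rng.normal(0.0, 0.02, acc.shape)
    dur = events[-1] - events[0]
    mu, sd = STOPWATCH_OFFSET["7MW"]
    stopwatch = dur - rng.normal(mu, sd)
    return ImuRecording("7MW", t_ns, acc,
                        meta={"subject": subject, "events": events,
                              "stopwatch_s": float(max(stopwatch, 0.5 * dur)),
                              "params": params})


def generate_cst_recording(n_cycles: int = 5, sts_dur: float = 1.2,
                           sts_dur_sd: float = 0.0, sts_dur_sts: float = 1.4,
                           amplitudes: dict | None = None,
                           tremor: float = 0.0,
                           rate: float = 100.0,
                           seed: int | np.random.Generator | None = None,
                           jitter_ms: float = 1.0,
                           subject: str | None = None) -> ImuRecording:
    """Five-cycle chair-stand recording with planted phase boundaries.

    Each cycle is a sit-to-stand burst (duration ``sts_dur`` +- the SD),
    a standing pause, a stand-to-sit burst (``sts_dur_sts``), and a seated
    pause.  Transitions appear as half-sine bursts on the ML angular
    velocity; the AP acceleration carries a biphasic lobe whose initial
    polarity distinguishes the two kinds (forward lean first when rising).
    Planted boundaries are in ``meta["phases"]``.
    """
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    amplitudes = {"gyro_ml": 60.0, "acc_ap": 1.5, "acc_v": 2.0,
                  **(amplitudes or {})}
    rng = np.random.default_rng(seed)
    pause = 0.6
    phases: list[tuple[str, float, float]] = []
    cursor = 1.0
    for _ in range(n_cycles):
        d1 = max(0.3, sts_dur + (sts_dur_sd and rng.normal(0.0, sts_dur_sd)))
        phases.append(("Sts", cursor, cursor + d1))
        cursor += d1 + pause
        d2 = max(0.3, sts_dur_sts + (sts_dur_sd and rng.normal(0.0, sts_dur_sd)))
        phases.append(("stS", cursor, cursor + d2))
        cursor += d2 + pause
    total = cursor + 0.5
    n = int(round(total * rate)) + 1
    t_ns = _timestamps(n, rate, rng, jitter_ms)
    t = t_ns / 1e9
    acc = np.zeros((n, 3))
    gyro = np.zeros((n, 3))
    for kind, s, e in phases:
        mask = (t >= s) & (t < e)
        u = (t[mask] - s) / (e - s)
        sign = 1.0 if kind == "Sts" else -1.0
        gyro[mask, 1] += sign * amplitudes["gyro_ml"] * np.sin(np.pi * u)
        acc[mask, 0] += sign * amplitudes["acc_ap"] * np.sin(2 * np.pi * u)
        acc[mask, 2] += amplitudes["acc_v"] * np.sin(np.pi * u) * sign
        if tremor > 0:
            # high-frequency ripple during the movement: an un-smooth
            # transition at unchanged amplitude and duration
            ripple = tremor * np.sin(2 * np.pi * 8.0 * (t[mask] - s))
            ripple *= np.sin(np.pi * u)  # fade in/out within the burst
            acc[mask, 0] += ripple
            acc[mask, 2] += ripple
    acc[:, 2] += G
    acc += rng.normal(0.0, 0.02, acc.shape)
    gyro += rng.normal(0.0, 0.5, gyro.shape)
    dur = phases[-1][2] - phases[0][1]
    mu, sd = STOPWATCH_OFFSET["CST"]
    stopwatch = dur - rng.normal(mu, sd)
    return ImuRecording("CST", t_ns, acc, gyro,
                        meta={"subject": subject, "phases": phases,
                              "stopwatch_s": float(max(stopwatch, 0.5 * dur))})


# --------------------------------------------------------------------------
# Cohort table
# --------------------------------------------------------------------------

COHORT_COLUMNS = ["Age", "Gender", "Weight", "Height", "MMSE", "NM", "IADL",
                  "FALL", "FALL_history", "CES-D", "PA", "SPPB", "HAND",
                  "PWR", "TMTA", "GaitSpeed"]

#: default (mean, SD) of the continuous health-related measures, matching the
#: published total-population profile
COHORT_NORMALS = {
    "Age": (80.90, 6.37),
    "Weight": (69.60, 13.30),
    "Height": (159.72, 9.53),
    "MMSE": (27.25, 1.77),
    "CES-D": (12.8, 8.3),      # implies ~35 % at or above the 16-point cut
    "PA": (2.91, 1.01),
    "SPPB": (8.72, 3.18),
    "HAND": (26.98, 9.26),
    "PWR": (88.69, 51.28),
    "TMTA": (78.37, 43.94),
    "GaitSpeed": (1.11, 0.26),
}

#: Poisson rates for count measures, chosen to match the published
#: exceedance fractions (>=4 medications 56 %, IADL >=1 38 %, falls >=2 5-6 %)
COHORT_POISSON = {"NM": 4.0, "IADL": 0.478, "FALL": 0.355, "FALL_history": 0.40}

#: fraction of females in the population (Gender coded 1 = female)
FEMALE_FRACTION = 0.54

#: published plausibility ranges used for validation warnings
COHORT_RANGES = {"MMSE": (0, 30), "IADL": (0, 8), "CES-D": (0, 60),
                 "PA": (1, 7), "SPPB": (0, 12)}


def generate_cohort_table(n: int,
                          seed: int | np.random.Generator | None = None,
                          means: dict | None = None, sds: dict | None = None,
                          planted: dict | None = None) -> pd.DataFrame:
    """Cohort of health-related measures and covariates.

    Continuous measures are Gaussian with the published means/SDs (override
    via ``means``/``sds``); count measures are Poisson; Gender is Bernoulli
    (1 = female).  ``planted`` maps a column name to
    ``({predictor: coefficient, ...}, noise_sd)`` and overwrites that
    column with a known linear dependence for regression-recovery tests.
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    rng = np.random.default_rng(seed)
    cols = {}
    for name, (mu, sd) in COHORT_NORMALS.items():
        mu = (means or {}).get(name, mu)
        sd = (sds or {}).get(name, sd)
        cols[name] = rng.normal(mu, sd, n)
    for name, lam in COHORT_POISSON.items():
        cols[name] = rng.poisson((means or {}).get(name, lam), n).astype(float)
    cols["Gender"] = rng.binomial(1, FEMALE_FRACTION, n).astype(float)
    idx = pd.Index([f"s{i:04d}" for i in range(n)], name="subject")
    df = pd.DataFrame(cols, index=idx)[COHORT_COLUMNS]
    for outcome, (coefs, noise_sd) in (planted or {}).items():
        y = rng.normal(0.0, noise_sd, n)
        for pred, beta in coefs.items():
            y = y + beta * df[pred].to_numpy()
        df[outcome] = y
    return df


def validate_cohort(df: pd.DataFrame) -> list[str]:
    """Return plausibility warnings (values outside published ranges)."""
    warnings = []
    for name, (lo, hi) in COHORT_RANGES.items():
        if name in df.columns:
            bad = ((df[name] < lo) | (df[name] > hi)).sum()
            if bad:
                warnings.append(f"{name}: {bad} value(s) outside [{lo}, {hi}]")
    return warnings
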