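"""Pipeline orchestration, configuration and percentile-based reporting.

:func:`run_pipeline` executes the whole analysis — simulate inputs,
extract or simulate feature tables, fit one factor model per test, score
subjects, run the construct-validity statistics and duration agreement,
and write a per-subject radar profile — deterministically from a config
mapping and a seed.  :func:`radar_profile` computes the numeric content of
the radar plots: each domain score expressed as an empirical percentile of
the reference population, with the interquartile band and an extreme flag.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cst import extract_cst_features
from .factor import FactorModel
from .gait import extract_gait_features
from .qs import extract_qs_features
from .synthetic import (SUBGROUP_SIZES, GaitSimParams, SyntheticFactorSpec,
                        generate_cohort_table, generate_cst_recording,
                        generate_qs_recording, generate_walk_recording,
                        simulate_feature_matrix)
from .validity import association_matrix, bland_altman

__all__ = ["radar_profile", "percentile_rank", "run_pipeline",
           "default_config", "load_config"]

TESTS = ("qs", "7mw", "cst")
_FLOAT_FMT = "%.10g"


def percentile_rank(value: float, reference: np.ndarray) -> float:
    """Empirical percentile of ``value`` within ``reference``.

    Linear interpolation between order statistics at plotting positions
    (i - 0.5)/n, clamped to [0, 100]; the reference median maps to 50.
    """
    ref = np.sort(np.asarray(reference, float))
    n = ref.size
    if n == 0:
        raise ValueError("empty reference distribution")
    pos = 100.0 * (np.arange(1, n + 1) - 0.5) / n
    return float(np.clip(np.interp(value, ref, pos,
                                   left=0.0, right=100.0), 0.0, 100.0))


def radar_profile(subject_scores: pd.Series,
                  reference_scores: pd.DataFrame) -> pd.DataFrame:
    """Numeric radar-plot profile of one subject against a reference cohort.

    For every domain: the subject's score, the reference median and
    quartiles, the subject's percentile rank, and an ``extreme`` flag set
    when the rank leaves the interquartile band (above the 75th or below
    the 25th percentile).
    """
    rows = []
    for domain in subject_scores.index:
        ref = reference_scores[domain].dropna().to_numpy()
        rank = percentile_rank(float(subject_scores[domain]), ref)
        rows.append({
            "domain": domain,
            "score": float(subject_scores[domain]),
            "reference_median": float(np.median(ref)),
            "p25": float(np.percentile(ref, 25)),
            "p75": float(np.percentile(ref, 75)),
            "percentile_rank": rank,
            "extreme": bool(rank > 75.0 or rank < 25.0),
        })
    return pd.DataFrame(rows).set_index("domain")


def default_config() -> dict:
    """Pipeline defaults: the study's subgroup sizes and thresholds."""
    return {
        "seed": 0,
        "mode": "recovery",          # "recovery" (fixture-based) or "sensor"
        "tests": list(TESTS),
        "n_subjects": dict(SUBGROUP_SIZES),
        "sensor_n_subjects": 30,     # per-test cohort in sensor mode
        "cohort_n": 304,
        "loading_threshold": 0.5,
        "min_variance": 0.70,
        "p_threshold": 0.05,
        "pa_iter": 100,
        "pa_quantile": 0.95,
        "bland_altman_n": 30,
        "radar_subject": "s0000",
        "distance_m": 7.0,
    }


def load_config(path: str | Path | None) -> dict:
    """Defaults overridden by a YAML config file (key: value mapping)."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError("config file must contain a mapping")
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _domain_labels(test: str, k: int) -> dict[str, str]:
    prefix = test.upper().replace("MW", "MW")
    return {f"F{j + 1}": f"{test.upper()}{j + 1}" for j in range(k)}


def _sensor_feature_table(test: str, n: int, rng: np.random.Generator,
                          distance_m: float) -> pd.DataFrame:
    """Feature table obtained by generating and extracting one recording
    per subject, with between-subject parameter variation."""
    rows = {}
    for i in range(n):
        sid = f"s{i:04d}"
        if test == "qs":
            rec = generate_qs_recording(
                rms_ap=float(rng.uniform(0.04, 0.14)),
                rms_ml=float(rng.uniform(0.03, 0.11)),
                seed=rng, subject=sid)
            rows[sid] = extract_qs_features(rec)
        elif test == "7mw":
            params = GaitSimParams(
                cadence=float(rng.uniform(95, 125)),
                asymmetry=float(rng.uniform(1.0, 1.25)),
                step_cv=float(rng.uniform(0.0, 0.08)),
                amp_v=float(rng.uniform(0.8, 1.6)))
            rec = generate_walk_recording(params, seed=rng, subject=sid)
            rows[sid] = extract_gait_features(rec, distance_m=distance_m)
        else:
            rec = generate_cst_recording(
                sts_dur=float(rng.uniform(0.9, 1.6)),
                sts_dur_sd=float(rng.uniform(0.02, 0.12)),
                sts_dur_sts=float(rng.uniform(1.0, 1.8)),
                seed=rng, subject=sid)
            rows[sid] = extract_cst_features(rec)
    table = pd.DataFrame(rows).T
    table.index.name = "subject"
    return table


def run_pipeline(out_dir: str | Path, config: dict | str | Path | None = None,
                 seed: int | None = None) -> dict:
    """Run simulate -> extract/simulate features -> EFA -> scores ->
    validity -> report, writing all artifacts under ``out_dir``.

    Fully reproducible: identical config and seed give byte-identical CSV
    outputs.  Returns a manifest dict (also written as ``manifest.json``)
    with per-stage record counts and artifact paths.
    """
    cfg = load_config(config) if not isinstance(config, dict) else \
        {**default_config(), **config}
    if seed is not None:
        cfg["seed"] = seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(cfg["seed"])
    stage_seeds = {name: s for name, s in zip(
        ("features", "pa", "cohort", "agreement"), root_ss.spawn(4))}
    manifest: dict = {"version": __version__, "seed": cfg["seed"],
                      "mode": cfg["mode"], "python": sys.version.split()[0],
                      "stages": {}, "artifacts": {}}

    def save(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, float_format=_FLOAT_FMT, **kw)
        manifest["artifacts"][name] = str(path)

    # ---- feature tables -------------------------------------------------
    feat_rng = np.random.default_rng(stage_seeds["features"])
    tables: dict[str, pd.DataFrame] = {}
    for test in cfg["tests"]:
        if cfg["mode"] == "recovery":
            spec = SyntheticFactorSpec.for_test(test, n=cfg["n_subjects"][test])
            tables[test] = simulate_feature_matrix(spec, seed=feat_rng)
        elif cfg["mode"] == "sensor":
            tables[test] = _sensor_feature_table(
                test, cfg["sensor_n_subjects"], feat_rng, cfg["distance_m"])
        else:
            raise ValueError(f"unknown mode {cfg['mode']!r}")
        save(tables[test], f"features_{test}.csv")
        manifest["stages"][f"features_{test}"] = tables[test].shape

    # ---- one EFA per test ----------------------------------------------
    pa_rng = np.random.default_rng(stage_seeds["pa"])
    all_scores = []
    domains_per_test = {}
    for test in cfg["tests"]:
        # fixture-simulated tables are already on the standardized
        # post-preprocessing scale; only sensor-extracted jerk is logged
        jerk = [] if cfg["mode"] == "recovery" else None
        model = FactorModel(tables[test], jerk_measures=jerk)
        res = model.fit(threshold=cfg["loading_threshold"],
                        min_variance=cfg["min_variance"],
                        seed=pa_rng, pa_iter=cfg["pa_iter"],
                        pa_quantile=cfg["pa_quantile"])
        res.rename_factors(_domain_labels(test, res.n_factors))
        save(res.loading_table(), f"loadings_{test}.csv")
        save(res.scores, f"scores_{test}.csv")
        save(res.assignment.to_frame(), f"assignment_{test}.csv")
        manifest["stages"][f"efa_{test}"] = {
            "n_factors": res.n_factors,
            "cumulative_variance": round(res.cumulative_variance, 4),
            "meets_min_variance": res.meets_variance(),
            "n_assigned": res.n_assigned,
        }
        all_scores.append(res.scores)
        domains_per_test[test] = list(res.scores.columns)

    domains = pd.concat(all_scores, axis=1)
    save(domains, "domains.csv")

    # ---- construct validity --------------------------------------------
    cohort = generate_cohort_table(cfg["cohort_n"],
                                   seed=np.random.default_rng(
                                       stage_seeds["cohort"]))
    save(cohort, "cohort.csv")
    for adjusted, name in ((False, "associations_unadjusted.csv"),
                           (True, "associations_adjusted.csv")):
        assoc = association_matrix(domains, cohort, adjusted=adjusted,
                                   alpha=cfg["p_threshold"])
        save(assoc, name, index=False)
        manifest["stages"][name] = len(assoc)

    # ---- duration agreement (device vs stopwatch) ----------------------
    agr_rng = np.random.default_rng(stage_seeds["agreement"])
    ba_rows = []
    n_ba = cfg["bland_altman_n"]
    for label, gen, device_duration in (
        ("7MW", lambda r: generate_walk_recording(seed=r),
         lambda rec: extract_gait_features(rec).attrs["device_duration_s"]),
        ("CST", lambda r: generate_cst_recording(sts_dur_sd=0.08, seed=r),
         lambda rec: extract_cst_features(rec)["Total Duration"]),
    ):
        device, ref = [], []
        for _ in range(n_ba):
            rec = gen(agr_rng)
            device.append(device_duration(rec))
            ref.append(rec.meta["stopwatch_s"])
        ba = bland_altman(np.array(device), np.array(ref))
        ba_rows.append({"test": label, "bias_s": ba.bias, "sd_s": ba.sd,
                        "loa_lower_s": ba.loa_lower, "loa_upper_s": ba.loa_upper,
                        "n": n_ba})
    save(pd.DataFrame(ba_rows), "bland_altman.csv", index=False)

    # ---- radar report ---------------------------------------------------
    subject = cfg["radar_subject"]
    if subject in domains.index:
        profile = radar_profile(domains.loc[subject].dropna(),
                                domains)
        save(profile, f"radar_{subject}.csv")
        manifest["stages"]["radar"] = subject

    manifest["n_domains_total"] = int(domains.shape[1])
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    manifest["artifacts"]["manifest.json"] = str(out / "manifest.json")
    return manifest


def plot_radar(profile: pd.DataFrame, ax=None):
    """Optional cosmetic radar plot of a :func:`radar_profile` table."""
    import matplotlib.pyplot as plt

    domains = profile.index.tolist()
    angles = np.linspace(0, 2 * np.pi, len(domains), endpoint=False)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    for col, style in (("percentile_rank", "-o"),):
        vals = profile[col].to_numpy()
        ax.plot(np.concatenate([angles, angles[:1]]),
                np.concatenate([vals, vals[:1]]), style)
    ax.fill_between(np.linspace(0, 2 * np.pi, 200), 75, 100, alpha=0.2,
                    color="gray")
    ax.fill_between(np.linspace(0, 2 * np.pi, 200), 0, 25, alpha=0.2,
                    color="gray")
    ax.set_xticks(angles)
    ax.set_xticklabels(domains)
    ax.set_ylim(0, 100)
    return ax
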