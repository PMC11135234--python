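"""End-to-end pipeline: read (or simulate) -> preprocess -> survey -> knee.

Driven by a flat configuration mapping (or TOML file).  Every source of
randomness derives from the single ``seed`` key, which is recorded in the
report, so a report re-run with the same configuration is byte-identical.
Per-stage timings go to the logger, not the report, to keep reports
deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
import tomllib
from dataclasses import replace
from pathlib import Path
from typing import Any

from . import __version__
from .cv import DEFAULT_CV_SPEC, HoldoutScheme, select_rank_press
from .errors import ConfigError
from .io import PreprocessConfig, preprocess, read_matrix
from .knee import select_rank
from .nmf import AlgorithmSpec
from .simulate import SimulationSpec, simulate_catalog
from .survey import run_survey

__all__ = ["run_pipeline", "load_config"]

logger = logging.getLogger("uiknmf")

SCHEMA_VERSION = 1

_KNOWN_KEYS = {
    "input", "format", "simulate", "sim_processes", "sim_genomes", "sim_scale",
    "sim_noise", "ranks", "n_run", "algorithm", "theta", "seed",
    "log_transform", "pseudo_count", "min_total_count", "normalize_samples",
    "normalize_mode", "variance_filter_keep", "cv", "cv_fraction", "cv_repeats",
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a flat TOML configuration file."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _parse_ranks(spec: Any) -> list[int]:
    if isinstance(spec, str):
        if ":" not in spec:
            raise ConfigError(f"ranks string must look like 'A:B', got {spec!r}")
        lo, hi = spec.split(":", 1)
        try:
            lo_i, hi_i = int(lo), int(hi)
        except ValueError as exc:
            raise ConfigError(f"non-integer rank bound in {spec!r}") from exc
        if hi_i < lo_i:
            raise ConfigError(f"empty rank range {spec!r}")
        return list(range(lo_i, hi_i + 1))
    try:
        ranks = [int(r) for r in spec]
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid ranks {spec!r}") from exc
    if len(ranks) < 4:
        raise ConfigError(f"knee detection needs >= 4 candidate ranks, got {ranks}")
    if any(b <= a for a, b in zip(ranks, ranks[1:])):
        raise ConfigError(f"ranks must be strictly increasing, got {ranks}")
    return ranks


def _nan_to_none(xs: list[float]) -> list[float | None]:
    return [None if math.isnan(x) else x for x in xs]


def run_pipeline(config: dict[str, Any] | str | Path, out: str | Path | None = None) -> dict:
    """Run the configured pipeline and return (optionally write) the report.

    The report is a plain JSON-serializable dict: input shape, algorithm,
    rank grid, RSS and cophenetic curves, knee estimate and selected rank,
    plus the PRESS curve when cross-validation is enabled.  Undefined
    cophenetic values appear as null.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")

    ranks = _parse_ranks(config.get("ranks", "2:15"))
    seed = int(config.get("seed", 0))
    n_run = int(config.get("n_run", 10))
    algo = AlgorithmSpec(
        name=str(config.get("algorithm", "brunet")),
        theta=float(config.get("theta", 0.5)),
        seed=seed,
    )
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    logger.info("pipeline: uiknmf %s, seed %d, config digest %s", __version__, seed, digest)

    t0 = time.perf_counter()
    if config.get("simulate", False):
        sim = SimulationSpec(
            n_processes=int(config.get("sim_processes", 10)),
            n_genomes=int(config.get("sim_genomes", 100)),
            exposure_scale=float(config.get("sim_scale", 1000.0)),
            poisson_noise=bool(config.get("sim_noise", True)),
            seed=seed,
        )
        V = simulate_catalog(sim).to_target_matrix()
        source = f"simulated catalog (P={sim.n_processes}, G={sim.n_genomes})"
    elif "input" in config:
        V = read_matrix(config["input"], format=config.get("format"))
        source = str(config["input"])
    else:
        raise ConfigError("configuration needs either 'input' or 'simulate = true'")
    logger.info("pipeline: loaded %s with shape %s in %.2fs", source, V.shape, time.perf_counter() - t0)

    pre = PreprocessConfig(
        log_transform=bool(config.get("log_transform", False)),
        pseudo_count=float(config.get("pseudo_count", 1.0)),
        min_total_count=float(config.get("min_total_count", 0.0)),
        normalize_samples=bool(config.get("normalize_samples", False)),
        normalize_mode=str(config.get("normalize_mode", "divide")),
        variance_filter_keep=(
            int(config["variance_filter_keep"]) if config.get("variance_filter_keep") else None
        ),
    )
    V = preprocess(V, pre)

    if ranks[-1] > min(V.shape):
        raise ConfigError(
            f"rank grid up to {ranks[-1]} invalid for matrix of shape {V.shape}"
        )

    t1 = time.perf_counter()
    survey = run_survey(V, ranks, n_run=n_run, spec=algo)
    logger.info("pipeline: survey over %d ranks in %.2fs", len(ranks), time.perf_counter() - t1)
    knee = select_rank(survey)

    report: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "uiknmf_version": __version__,
        "seed": seed,
        "config_digest": digest,
        "source": source,
        "shape": list(V.shape),
        "algorithm": algo.name,
        "theta": algo.theta if algo.name == "nsnmf" else None,
        "n_run": n_run,
        "ranks": survey.ranks,
        "rss_curve": survey.rss_curve,
        "cophenetic_curve": _nan_to_none(survey.cophenetic_curve),
        "curve_type": [knee.curve_type.convexity, knee.curve_type.trend],
        "knee_start": knee.knee_start,
        "knee_end": knee.knee_end,
        "selected_rank": knee.selected,
    }

    if config.get("cv", False):
        scheme = HoldoutScheme(
            fraction=float(config.get("cv_fraction", 0.05)),
            n_repeats=int(config.get("cv_repeats", 5)),
            seed=seed,
        )
        t2 = time.perf_counter()
        pr = select_rank_press(V, ranks, scheme=scheme, spec=replace(DEFAULT_CV_SPEC, seed=seed))
        logger.info("pipeline: PRESS over %d ranks in %.2fs", len(ranks), time.perf_counter() - t2)
        report["press_curve"] = pr.press_curve
        report["press_optimal_rank"] = pr.optimal

    if out is not None:
        Path(out).write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
    return report
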