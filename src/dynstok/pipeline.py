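"""End-to-end orchestration of simulation/estimation/evaluation experiments.

An experiment runs ``n_realizations`` seeded repetitions of:
draw a surrogate network -> simulate trials -> (optionally) corrupt with
observation noise and/or spatial mixing -> estimate tvMVAR coefficients with
each configured filter -> compute PDC -> score ROC AUC against the
ground-truth PDC.  Results are collected into a flat AUC table and a JSON
manifest (configuration, seed, versions) that suffices to reproduce every
output.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .evaluate import ground_truth_pdc, roc_auc
from .kalman import KfConfig, kf_filter
from .simulate import (
    SimulationConfig,
    add_observation_noise,
    apply_spatial_mixing,
    generate_surrogate_model,
    random_grid_positions,
    simulate_trials,
)
from .spectral import default_frequency_grid, pdc
from .stok import StokConfig, stok_filter

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Config-driven experiment description.

    ``filters`` maps a name to a spec dict: ``{"method": "kf", "c": 0.02}``
    or ``{"method": "stok", "b": 0.05, "theta": 0.99}`` (optionally
    ``fixed_c``).  ``snr_levels``/``mixing_sigmas`` entries of ``None`` mean
    the corresponding corruption is skipped.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    order: int = 6
    filters: dict = field(
        default_factory=lambda: {
            "kf": {"method": "kf", "c": 0.02},
            "stok": {"method": "stok", "b": 0.05, "theta": 0.99},
        }
    )
    fmin: float = 1.0
    fmax: float = 100.0
    df: float = 1.0
    gt_rule: str = "greater_than_zero"
    snr_levels: list = field(default_factory=lambda: [None])
    mixing_sigmas: list = field(default_factory=lambda: [None])
    n_realizations: int = 1
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", {})
        if isinstance(sim, dict):
            sim = SimulationConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()})
        return cls(simulation=sim, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def to_dict(self) -> dict:
        out = asdict(self)
        return out


def _run_filter(Y, name: str, spec: dict, order: int):
    method = spec.get("method", name)
    if method == "kf":
        return kf_filter(Y, KfConfig(order=order, c=spec.get("c", 0.02)))
    if method == "stok":
        return stok_filter(
            Y,
            StokConfig(
                order=order,
                b=spec.get("b", 0.05),
                theta=spec.get("theta", 0.99),
                fixed_c=spec.get("fixed_c"),
            ),
        )
    raise ValueError(f"unknown filter method {method!r} for {name!r}")


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the experiment; return (and optionally write) the results bundle.

    The bundle holds ``auc_table`` (one row per realization x condition x
    filter) and ``manifest``.  With ``out_dir`` set, writes ``auc.csv`` and
    ``manifest.json`` there.
    """
    freqs = default_frequency_grid(config.simulation.fs, config.fmin, config.fmax, config.df)
    rows: list[dict] = []
    for r in range(config.n_realizations):
        seed = (config.seed + 10_000 * r) % (2**31 - 1)
        sim_cfg = SimulationConfig(**{**asdict(config.simulation), "seed": seed})
        try:
            model = generate_surrogate_model(sim_cfg)
            Y_clean = simulate_trials(
                model, sim_cfg.n_trials, trial_corr=sim_cfg.trial_corr, seed=seed + 1
            )
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"simulation failed at realization {r}: {exc}") from exc
        gt = ground_truth_pdc(model, freqs)
        for snr in config.snr_levels:
            for sigma in config.mixing_sigmas:
                Y = Y_clean
                if snr is not None:
                    Y = add_observation_noise(Y, snr, seed=seed + 2)
                if sigma is not None:
                    positions = random_grid_positions(sim_cfg.d, seed=seed + 3)
                    Y = apply_spatial_mixing(Y, positions, sigma)
                for name, spec in config.filters.items():
                    try:
                        est = _run_filter(Y, name, spec, config.order)
                        score = roc_auc(gt, pdc(est, freqs), gt_rule=config.gt_rule)
                    except Exception as exc:  # noqa: BLE001
                        raise RuntimeError(
                            f"stage '{name}' failed at realization {r} "
                            f"(snr={snr}, sigma={sigma}): {exc}"
                        ) from exc
                    logger.info(
                        "realization %d snr=%s sigma=%s %s: AUC=%.4f", r, snr, sigma, name, score.auc
                    )
                    rows.append(
                        {
                            "realization": r,
                            "snr": snr,
                            "mixing_sigma": sigma,
                            "filter": name,
                            "auc": score.auc,
                        }
                    )
    manifest = _manifest(config)
    bundle = {"auc_table": rows, "manifest": manifest}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "auc.csv", "w", newline="") as f:
            writer = csv.DictWriter(f, fieldnames=["realization", "snr", "mixing_sigma", "filter", "auc"])
            writer.writeheader()
            writer.writerows(rows)
        with open(out_dir / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, default=str)
    return bundle


def _manifest(config: ExperimentConfig) -> dict:
    cfg = config.to_dict()
    digest = hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    return {
        "config": cfg,
        "config_hash": digest,
        "seed": config.seed,
        "versions": {
            "dynstok": __version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
    }


def mean_auc(rows: list[dict], filter_name: str) -> float:
    """Mean AUC across the table for one filter."""
    vals = [row["auc"] for row in rows if row["filter"] == filter_name]
    if not vals:
        raise ValueError(f"no AUC rows for filter {filter_name!r}")
    return float(np.mean(vals))
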