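"""Run configuration: defaults, validation and YAML/JSON loading.

Every default equals the published model value where one exists; everything
else is an explicit package choice documented in the methods note.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "DEFAULTS", "load_config"]


DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "outputs",
    "log_level": "INFO",
    "synthetic": {
        "n_odours": 110,
        "n_orns": 24,
        "mean_rate": 30.0,      # Hz
        "shape": 0.7,
        "zero_fraction": 0.2,
        "n_samples": 220,       # paired tables (222 also used in the study)
        "n_odours_paired": 7,
        "mu_n": -2.0,
        "sigma_n": 0.0,
    },
    "model": {
        "M": 2000,
        "n_pn": 24,
        "r_max": 165.0,
        "m": 10.63,
        "sigma_t": 12.0,
        "exponent": 1.5,
        "norm_const": 190.0,
        "claw_mu": 6.0,
        "claw_sigma": 1.7,
        "claw_min": 2,
        "claw_max": 11,
        "weight_mu": -0.0507,
        "weight_sigma": 0.3527,
        "theta_cv": 0.26,
        "n_trials": 30,
        "target_full": 0.10,
        "target_blocked": 0.20,
        "tune_tol": 0.002,
        "eq_tol": 0.02,
        "activity_eps": 0.0,
    },
    "plasticity": {
        "n_instances": 20,
        "grid_step": 0.05,
        "g_w_range": [0.0, 1.2],
        "g_alpha_range": [0.0, 1.2],
        "g_theta_range": [0.8, 2.0],
        "axes": ["g_w", "g_alpha"],
    },
    "stats": {
        "n_sims": 1000,
        "steps": 150,
        "n_sim_per_step": 10,
        "fit_init_mu": -1.0,
        "fit_init_sigma": 0.25,
        "smooth_width": 0.2,        # s
        "target_frame_time": 0.018,  # s
    },
}


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run."""

    seed: int = 0
    output_dir: str = "outputs"
    log_level: str = "INFO"
    synthetic: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS["synthetic"]))
    model: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS["model"]))
    plasticity: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS["plasticity"]))
    stats: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS["stats"]))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "log_level": self.log_level,
            "synthetic": copy.deepcopy(self.synthetic),
            "model": copy.deepcopy(self.model),
            "plasticity": copy.deepcopy(self.plasticity),
            "stats": copy.deepcopy(self.stats),
        }


def _check_keys(user: dict, defaults: dict, path: str = "") -> None:
    for key, value in user.items():
        where = f"{path}{key}"
        if key not in defaults:
            valid = ", ".join(sorted(defaults))
            raise KeyError(f"unknown config key {where!r}; valid keys: {valid}")
        default = defaults[key]
        if isinstance(default, dict):
            if not isinstance(value, dict):
                raise TypeError(f"config key {where!r} must be a mapping")
            _check_keys(value, default, where + ".")
        elif default is not None and value is not None:
            if isinstance(default, bool) != isinstance(value, bool):
                raise TypeError(f"config key {where!r} expects {type(default).__name__}")
            if isinstance(default, (int, float)) and not isinstance(value, (int, float)):
                raise TypeError(f"config key {where!r} expects a number")
            if isinstance(default, str) and not isinstance(value, str):
                raise TypeError(f"config key {where!r} expects a string")
            if isinstance(default, list) and not isinstance(value, list):
                raise TypeError(f"config key {where!r} expects a list")


def _merge(user: dict, defaults: dict) -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        if isinstance(defaults.get(key), dict) and isinstance(value, dict):
            out[key] = _merge(value, defaults[key])
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML/JSON config file, apply defaults and validate keys.

    An absent or empty file yields all defaults. Unknown keys raise KeyError
    listing the valid keys; type mismatches raise TypeError. YAML parse
    errors propagate with line information.
    """
    user: dict = {}
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise TypeError("config file must contain a mapping at top level")
    _check_keys(user, DEFAULTS)
    merged = _merge(user, DEFAULTS)
    return RunConfig(
        seed=merged["seed"],
        output_dir=merged["output_dir"],
        log_level=merged["log_level"],
        synthetic=merged["synthetic"],
        model=merged["model"],
        plasticity=merged["plasticity"],
        stats=merged["stats"],
    )


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved config alongside outputs (JSON)."""
    Path(path).write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
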