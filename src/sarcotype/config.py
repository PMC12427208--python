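"""Pipeline configuration: one namespace per stage, validated strictly.

Unknown keys are rejected (typos should fail loudly, not silently fall back
to defaults). Every run persists the fully resolved config next to its
artifacts so results can be reproduced bit-identically.
"""

from __future__ import annotations

import copy

import yaml


class ConfigError(ValueError):
    pass


DEFAULTS = {
    "seed": 0,
    "outdir": "sarcotype_out",
    "log_level": "INFO",
    "cohorts": {
        # each cohort is either {"synthetic": {CohortConfig overrides}} or
        # {"counts": <tsv path>, "clinical": <csv path>}
        "discovery": {"synthetic": {"seed": 7}},
        "validation": {"synthetic": {"seed": 13}},
    },
    "preprocess": {
        "min_cpm": 1.0,
        "min_fraction": 0.2,
        "keep_fraction": 0.55,
    },
    "discover": {
        "kmin": 2,
        "kmax": 8,
        "n_resamples": 1000,
        "item_fraction": 0.8,
        "metric": "pearson",
        "method": "average",
        "selector": "elbow",
    },
    "signatures": {
        "q_threshold": 0.05,
        "lfc_threshold": 0.0,
    },
    "classify": {
        "alpha": 0.25,
        "n_perm": 1000,
        "threshold": 0.05,
        "require_sign_concordance": False,
        "context_gmt": None,
    },
    "survival": {
        "time_col": "os_months",
        "event_col": "os_event",
        "extra_covariates": ["age_years"],
    },
    "benchmark": {
        "risk_col": "risk_score_5yOS",
        "risk_threshold": 0.60,
        "grouping": "C1-vs-rest",
    },
}

_SYNTHETIC_KEYS = {
    "n_samples", "n_subtypes", "subtype_proportions", "n_genes",
    "markers_per_subtype_per_direction", "log2_effect", "nb_dispersion",
    "libsize_log_mean", "libsize_log_sd", "hazards_per_month",
    "admin_censor_months", "dropout_rate_per_month", "recurrence_hazard_ratio",
    "risk_score_noise_sd", "seed",
}


def _check_keys(given: dict, allowed, path: str) -> None:
    unknown = set(given) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown config key(s) at {path}: {sorted(unknown)}")


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    _check_keys(overrides, defaults, path or "<root>")
    out = copy.deepcopy(defaults)
    for key, val in overrides.items():
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge(defaults[key], val, f"{path}.{key}".lstrip("."))
        else:
            out[key] = copy.deepcopy(val)
    return out


def resolve_config(overrides: dict = None) -> dict:
    """Merge user overrides into the defaults, rejecting unknown keys."""
    overrides = overrides or {}
    _check_keys(overrides, DEFAULTS, "<root>")
    out = copy.deepcopy(DEFAULTS)
    for key, val in overrides.items():
        if key == "cohorts":
            _check_keys(val, {"discovery", "validation"}, "cohorts")
            for which, spec in val.items():
                _validate_cohort_spec(spec, f"cohorts.{which}")
                out["cohorts"][which] = copy.deepcopy(spec)
        elif isinstance(DEFAULTS[key], dict) and isinstance(val, dict):
            out[key] = _merge(DEFAULTS[key], val, key)
        else:
            out[key] = copy.deepcopy(val)
    disc = out["discover"]
    if disc["kmax"] < disc["kmin"]:
        raise ConfigError("discover.kmax must be >= discover.kmin")
    return out


def _validate_cohort_spec(spec: dict, path: str) -> None:
    if not isinstance(spec, dict):
        raise ConfigError(f"{path} must be a mapping")
    if "synthetic" in spec:
        _check_keys(spec, {"synthetic"}, path)
        _check_keys(spec["synthetic"], _SYNTHETIC_KEYS, f"{path}.synthetic")
    else:
        _check_keys(spec, {"counts", "clinical"}, path)
        if "counts" not in spec:
            raise ConfigError(f"{path}: need either 'synthetic' or 'counts'")


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    return resolve_config(raw)


def dump_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
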