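"""Structured (YAML) configuration for simulation and analysis.

A config file holds up to three top-level mappings, all optional:

``cohort:``
    any field of :class:`~t2titrate.cohort.CohortConfig` (sample size,
    biomarker distribution parameters, latent-class fractions, dynamics);
``trial:``
    any field of :class:`~t2titrate.conduct.TrialConfig` except ``cohort``
    (allocation ratio, block size, adherence probabilities, withdrawal);
``ladder:``
    a list of ``[ics_ug_day, ocs_mg_day]`` pairs replacing the default
    treatment ladder.

Unknown keys raise, so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .cohort import CohortConfig
from .conduct import TrialConfig
from .ladder import Ladder

__all__ = ["load_config", "config_hash", "dump_config"]


def _check_keys(section: str, given: dict, cls) -> None:
    allowed = {f.name for f in dataclasses.fields(cls) if f.init}
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown {section} config keys: {sorted(unknown)}")


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> TrialConfig:
    """Build a :class:`TrialConfig` from a YAML file and/or override dict."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw = {**raw, **overrides}
    cohort_kw = dict(raw.get("cohort", {}))
    trial_kw = dict(raw.get("trial", {}))
    if "ratio" in trial_kw:
        trial_kw["ratio"] = tuple(trial_kw["ratio"])
    ladder_spec = raw.get("ladder")
    _check_keys("cohort", cohort_kw, CohortConfig)
    _check_keys("trial", trial_kw, TrialConfig)
    if ladder_spec is not None:
        cohort_kw["ladder"] = Ladder([tuple(step) for step in ladder_spec])
    cohort = CohortConfig(**cohort_kw)
    return TrialConfig(cohort=cohort, **trial_kw)


def dump_config(config: TrialConfig) -> dict:
    """A plain-dict view of a config (ladder as dose-pair list)."""
    cohort = dataclasses.asdict(config.cohort)
    ladder = cohort.pop("ladder")
    cohort.pop("feno_mu", None)
    cohort.pop("feno_sigma", None)
    cohort.pop("eos_mu", None)
    cohort.pop("eos_sigma", None)
    trial = {
        f.name: getattr(config, f.name)
        for f in dataclasses.fields(config)
        if f.name != "cohort"
    }
    return {
        "cohort": cohort,
        "trial": trial,
        "ladder": [list(step) for step in config.cohort.ladder.steps],
    }


def config_hash(config: TrialConfig) -> str:
    """Deterministic digest of a configuration."""
    payload = json.dumps(dump_config(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()
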