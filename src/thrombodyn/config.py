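"""Rate-constant configuration files (YAML/JSON).

The kinetic constants are configuration, not fitted quantities: analyses
echo the constants they were run with, and the shipped defaults are
documented placeholders meant to be re-calibrated against a reference
plasma before quantitative use on real data.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .inactivation import RateConstants

__all__ = ["load_rate_constants", "save_rate_constants", "default_rate_constants"]

CONFIG_VERSION = 1
_FIELDS = ("k_at", "k_a2m", "k_ms", "fibrinogen_slope_at", "fibrinogen_slope_a2m")


def default_rate_constants() -> RateConstants:
    """The packaged default constants (see ``data/rate_constants.yaml``)."""
    with resources.files("thrombodyn").joinpath("data/rate_constants.yaml").open() as fh:
        return _from_mapping(yaml.safe_load(fh))


def _from_mapping(doc: dict) -> RateConstants:
    if "rate_constants" in doc:
        doc = doc["rate_constants"]
    unknown = set(doc) - set(_FIELDS) - {"version", "comment"}
    if unknown:
        raise ValueError(f"unknown rate-constant fields: {sorted(unknown)}")
    kwargs = {f: float(doc[f]) for f in _FIELDS if f in doc}
    return RateConstants(**kwargs)


def load_rate_constants(path: str | Path) -> RateConstants:
    """Load constants from a YAML (or JSON, a YAML subset) config file."""
    with Path(path).open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping of rate constants")
    return _from_mapping(doc)


def save_rate_constants(k: RateConstants, path: str | Path) -> Path:
    path = Path(path)
    doc = {"version": CONFIG_VERSION, "rate_constants": k.as_dict()}
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path
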