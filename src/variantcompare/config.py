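"""Flat key-value runtime configuration.

A YAML file of flat, namespaced keys, e.g.::

    rarity.f_min: 1.0e-4
    rarity.s_min: 0.05
    layout.gap_fraction: 0.2
    layout.ring_order: parent1,parent2,child1,child2

Nested mappings are also accepted and flattened with dots. Precedence is
resolved by the caller: command-line flags > config file > defaults.
"""

from __future__ import annotations

import yaml

from .errors import ConfigError

__all__ = ["load_config", "KNOWN_KEYS"]

KNOWN_KEYS = frozenset(
    {
        "rarity.f_min",
        "rarity.s_min",
        "layout.gap_fraction",
        "layout.ring_order",
    }
)


def _flatten(mapping: dict, prefix: str = "") -> dict:
    flat: dict = {}
    for key, value in mapping.items():
        full = f"{prefix}{key}"
        if isinstance(value, dict):
            flat.update(_flatten(value, f"{full}."))
        else:
            flat[full] = value
    return flat


def load_config(path: str) -> dict:
    """Load and flatten a YAML config file; unknown keys are rejected."""
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid config file {path}: {exc}") from None
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise ConfigError(f"config file {path} must be a key-value mapping")
    flat = _flatten(doc)
    unknown = set(flat) - KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    return flat
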