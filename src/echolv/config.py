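"""Strict TOML configuration handling.

Unknown keys are rejected outright: a typo in a scientific parameter must be
an error, never a silently ignored default.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import tomllib
from pathlib import Path
from typing import Any, TypeVar

__all__ = ["load_toml", "apply_section", "write_resolved_config"]

T = TypeVar("T")


def load_toml(path: str | Path) -> dict[str, Any]:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def apply_section(instance: T, section: dict[str, Any]) -> T:
    """Return a copy of a (frozen) dataclass with the section's keys applied.

    Nested dataclass fields accept nested tables; list values are coerced to
    tuples for tuple-typed fields.  Unknown keys raise ValueError.
    """
    names = {f.name: f for f in dataclasses.fields(instance)}
    unknown = set(section) - set(names)
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} for "
            f"{type(instance).__name__}; valid keys: {sorted(names)}")
    updates: dict[str, Any] = {}
    for key, value in section.items():
        current = getattr(instance, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            updates[key] = apply_section(current, value)
        elif isinstance(current, tuple) and isinstance(value, list):
            updates[key] = tuple(value)
        else:
            updates[key] = value
    return dataclasses.replace(instance, **updates)


def write_resolved_config(out_dir: str | Path, name: str, payload: dict[str, Any]) -> None:
    """Drop a resolved-config copy plus a version stamp into an output directory."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = {
        "echolv_version": __version__,
        "python": sys.version.split()[0],
        **payload,
    }

    def default(o: Any):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    (out / name).write_text(json.dumps(doc, indent=2, default=default) + "\n")
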