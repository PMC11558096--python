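"""Flat ``key = value`` configuration files.

Values are parsed as JSON scalars/arrays when possible, else kept as
strings; ``#`` starts a comment.  Keys are dotted paths such as
``field.frequency_hz`` or ``clinical.threshold_ng_ml``.
"""

from __future__ import annotations

import json
from pathlib import Path

__all__ = ["parse_config", "load_config"]


def parse_config(text: str) -> dict:
    config: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        try:
            config[key] = json.loads(value)
        except json.JSONDecodeError:
            config[key] = value
    return config


def load_config(path: str | Path) -> dict:
    return parse_config(Path(path).read_text())
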