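"""Key-value config loading (YAML superset: JSON files parse too)."""

from __future__ import annotations

from pathlib import Path

import yaml


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    return data
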