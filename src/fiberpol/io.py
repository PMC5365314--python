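"""CSV/YAML reading and writing with provenance headers.

CSV dialect: UTF-8, comma separator, mandatory header row, '.' decimal,
pCa as a positive decimal.  Every file written here carries ``#``-prefixed
comment lines recording the package version, the seed (when given) and a
SHA-256 hash of the configuration in force, so re-running a stage with the
same config and seed is byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__

__all__ = ["config_hash", "write_csv", "read_csv", "load_yaml"]


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a JSON-serializable configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


def write_csv(
    df: pd.DataFrame,
    path,
    config: Optional[dict] = None,
    seed: Optional[int] = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = [f"# fiberpol_version={__version__}"]
    if seed is not None:
        header.append(f"# seed={seed}")
    if config is not None:
        header.append(f"# config_sha256={config_hash(config)}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def load_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data
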