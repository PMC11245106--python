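"""Table I/O with reproducibility metadata.

Every table the pipeline writes carries a small metadata block as
leading ``#`` comment lines (package version, seed, configuration
hash), so any output can be traced to the exact invocation that
produced it.  Readers skip comment lines.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["config_hash", "write_table", "read_table", "write_json", "sample_table"]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _metadata_lines(seed, config: dict | None) -> list[str]:
    lines = [f"# gamrec {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config is not None:
        lines.append(f"# config_hash={config_hash(config)}")
    return lines


def write_table(df: pd.DataFrame, path, seed=None, config: dict | None = None) -> None:
    """TSV with '#' metadata block and a header line; deterministic order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _metadata_lines(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json(obj: dict, path, seed=None, config: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"gamrec_version": __version__}
    if seed is not None:
        meta["seed"] = seed
    if config is not None:
        meta["config_hash"] = config_hash(config)
    with open(path, "w") as fh:
        json.dump({"metadata": meta, **obj}, fh, indent=2, default=float)
        fh.write("\n")


def sample_table() -> pd.DataFrame:
    """The packaged per-sample event-count fixture (sperm and control)."""
    with resources.files("gamrec.data").joinpath("sample_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
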