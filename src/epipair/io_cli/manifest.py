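"""Deterministic result writing with a machine-readable run manifest."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from epipair.io_cli.config import PipelineConfig

MANIFEST_NAME = "manifest.json"


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    overwrite: bool = False,
) -> dict:
    """Write named tables as TSVs plus a JSON manifest.

    Column order is preserved as given; a manifest records file names, row
    counts and the config hash. Refuses to write over a manifest from a
    different configuration unless ``overwrite`` is set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    cfg_hash = config.hash()

    manifest_path = out_dir / MANIFEST_NAME
    if manifest_path.exists():
        existing = json.loads(manifest_path.read_text())
        if existing.get("config_hash") != cfg_hash and not overwrite:
            raise FileExistsError(
                f"{manifest_path} was written with config hash "
                f"{existing.get('config_hash')}, current is {cfg_hash}; "
                "pass overwrite=True to replace"
            )

    entries = []
    for name in sorted(tables):
        df = tables[name]
        fname = f"{name}.tsv"
        df.to_csv(out_dir / fname, sep="\t", index=False)
        entries.append({"name": name, "file": fname, "rows": int(len(df))})

    manifest = {"config_hash": cfg_hash, "tables": entries}
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
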