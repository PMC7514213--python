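"""Deterministic TSV output and run manifests.

Floats are written with 12 significant digits; log-domain zeros serialize as
the literal token ``-inf``.  Two runs with identical config and seed produce
byte-identical files.
"""
from __future__ import annotations

import datetime
import json
import math
from pathlib import Path
from typing import Iterable, Sequence


def _fmt(value) -> str:
    if isinstance(value, float):
        if math.isinf(value):
            return "-inf" if value < 0 else "inf"
        if math.isnan(value):
            return "nan"
        return format(value, ".12g")
    return str(value)


def write_table(rows: Iterable[Sequence], columns: Sequence[str], path) -> Path:
    """Write rows as a TSV with header; deterministic row order is the caller's."""
    path = Path(path)
    rows = list(rows)
    for row in rows:
        if len(row) != len(columns):
            raise ValueError(
                f"row of length {len(row)} does not match {len(columns)} columns"
            )
    lines = ["\t".join(columns)]
    lines.extend("\t".join(_fmt(v) for v in row) for row in rows)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_table(path):
    """Read a TSV written by write_table back into (columns, rows of floats/str)."""
    lines = Path(path).read_text().splitlines()
    columns = lines[0].split("\t")
    rows = []
    for line in lines[1:]:
        row = []
        for tok in line.split("\t"):
            try:
                row.append(float(tok))
            except ValueError:
                row.append(tok)
        rows.append(row)
    return columns, rows


def write_manifest(
    out_dir, command: str, config: dict, seed, outputs: Sequence[str]
) -> Path:
    """One manifest per CLI run: command, resolved config, seed, outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "package_version": __version__,
        "outputs": sorted(str(o) for o in outputs),
        "written_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
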