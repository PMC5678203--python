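"""Result serialization: CSV tables with provenance headers + JSON sidecars.

Every table is written as RFC-4180 CSV preceded by ``#``-prefixed metadata
lines (the JSON-encoded run configuration), with a full JSON sidecar next to
it.  Writing is deterministic: the same result object always produces
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd

from .metapopulation import MetapopRun
from .sweeps import MapResult


def _metadata_lines(metadata: dict[str, Any]) -> str:
    return "".join(f"# {key}: {json.dumps(value, sort_keys=True)}\n"
                   for key, value in sorted(metadata.items()))


def metapop_table(run: MetapopRun) -> pd.DataFrame:
    """Flatten a metapopulation trajectory into one row per round."""
    rows = []
    for st in run.states:
        row: dict[str, Any] = {"round": st.round, "total_size": st.total_size}
        for v, q in enumerate(st.frequencies):
            row[f"freq_{v}"] = q
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(result: MapResult | MetapopRun | pd.DataFrame, path: str | Path,
                  metadata: dict[str, Any] | None = None) -> tuple[Path, Path]:
    """Write a result as CSV + JSON sidecar; returns both paths."""
    path = Path(path)
    if isinstance(result, MapResult):
        table, meta = result.table, dict(result.metadata)
    elif isinstance(result, MetapopRun):
        table = metapop_table(result)
        meta = {"kind": "metapop_run", "converged": result.converged,
                "rounds": result.states[-1].round}
    else:
        table, meta = result, {}
    if metadata:
        meta.update(metadata)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(_metadata_lines(meta))
        table.to_csv(fh, index=False)
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump({"metadata": meta,
                   "columns": list(table.columns),
                   "n_rows": int(len(table))}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path, sidecar


def read_results(path: str | Path) -> MapResult:
    """Read back a CSV written by :func:`write_results`."""
    path = Path(path)
    metadata: dict[str, Any] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("# "):
                break
            skip += 1
            key, _, raw = line[2:].partition(": ")
            metadata[key] = json.loads(raw)
    table = pd.read_csv(path, skiprows=skip)
    return MapResult(table=table, metadata=metadata)
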