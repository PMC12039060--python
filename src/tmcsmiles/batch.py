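"""Batch conversion with per-complex failure accounting.

A manifest is a TSV with rows ``id<TAB>xyz_path<TAB>charge`` (a header
line is optional).  Each row is converted independently; unreadable
rows are counted as ``FAILED:input`` and the run continues.  Output is
a two-column TSV ``id<TAB>SMILES|FAILED:stage`` written in sorted id
order, so re-running with the same config reproduces it byte for byte.
Runs are resumable: ids already present in the output file are skipped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .assembly import xyz_to_smiles
from .config import PipelineConfig, DEFAULT_CONFIG

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    statuses: dict[str, str] = field(default_factory=dict)  # id -> OK|FAILED:stage
    counts: dict[str, int] = field(default_factory=dict)
    config_snapshot: dict = field(default_factory=dict)
    tool_version: str = __version__

    @property
    def n_inputs(self) -> int:
        return len(self.statuses)

    @property
    def n_ok(self) -> int:
        return sum(1 for v in self.statuses.values() if v == "OK")

    def to_json(self) -> str:
        return json.dumps(
            {
                "tool_version": self.tool_version,
                "counts": self.counts,
                "statuses": self.statuses,
                "config": self.config_snapshot,
            },
            indent=1,
            sort_keys=True,
        )


def read_manifest(path) -> list[tuple[str, Path, int]]:
    rows = []
    base = Path(path).parent
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] in ("id", "name") and len(rows) == 0:
            continue
        if len(parts) < 3:
            rows.append((parts[0] if parts else raw, None, None))
            continue
        try:
            q = int(parts[2])
        except ValueError:
            rows.append((parts[0], None, None))
            continue
        p = Path(parts[1])
        rows.append((parts[0], p if p.is_absolute() else base / p, q))
    return rows


def run_batch(
    manifest,
    out_path,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> RunReport:
    """Convert every manifest row; write the id→SMILES TSV; return report."""
    rows = read_manifest(manifest) if not isinstance(manifest, list) else manifest
    out_path = Path(out_path)
    done: dict[str, str] = {}
    if out_path.exists():  # resume
        for line in out_path.read_text().splitlines():
            if "\t" in line:
                k, v = line.split("\t", 1)
                done[k] = v
    report = RunReport(config_snapshot=config.snapshot())
    results: dict[str, str] = {}
    for key, path, q in sorted(rows, key=lambda r: r[0]):
        if key in done:
            results[key] = done[key]
            report.statuses[key] = "OK" if not done[key].startswith("FAILED") else done[key]
            continue
        if path is None or q is None or not Path(path).exists():
            results[key] = "FAILED:input"
            report.statuses[key] = "FAILED:input"
            continue
        try:
            r = xyz_to_smiles(Path(path).read_text(), q, config)
        except Exception as exc:  # never abort the batch
            logger.error("unexpected error for %s: %s", key, exc)
            r = None
        if r is not None and r.ok:
            results[key] = r.smiles
            report.statuses[key] = "OK"
        else:
            stage = r.failure_stage if r is not None else "internal"
            results[key] = f"FAILED:{stage}"
            report.statuses[key] = f"FAILED:{stage}"
    for status in report.statuses.values():
        bucket = "OK" if status == "OK" else status
        report.counts[bucket] = report.counts.get(bucket, 0) + 1
    out_path.write_text(
        "".join(f"{k}\t{results[k]}\n" for k in sorted(results))
    )
    return report
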