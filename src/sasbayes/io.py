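"""Plain-text readers and writers for curves, results and tallies.

Curves use the common multi-column SAS ``.dat`` convention: whitespace- or
comma-delimited columns ``q  intensity  [sigma ...]`` with ``#`` comment
lines.  Only the first two columns are read; the written third column is
the ``sqrt(y)`` placeholder uncertainty many SAS readers expect.  Results
are JSON, tallies CSV; both carry a schema version, the configuration echo
and the seeds needed to re-run exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .likelihood import ScatteringCurve

__all__ = [
    "read_curve",
    "write_curve",
    "write_result",
    "read_result",
    "write_tally",
    "read_tally",
    "write_table",
]

SCHEMA_VERSION = 1


class CurveFormatError(ValueError):
    """Malformed curve file; the message names the offending line."""


def read_curve(path, T: float) -> ScatteringCurve:
    """Parse a 2+ column text file into a ScatteringCurve with time ``T``.

    Blank lines and ``#`` comments are skipped; extra columns beyond
    ``(q, y)`` are ignored.  Raises :class:`CurveFormatError` naming the
    line for unparseable rows, and validates monotone q / non-negative y.
    """
    q, y = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise CurveFormatError(f"{path}:{lineno}: expected >= 2 columns")
            try:
                q.append(float(parts[0]))
                y.append(float(parts[1]))
            except ValueError as exc:
                raise CurveFormatError(f"{path}:{lineno}: {exc}") from None
    if not q:
        raise CurveFormatError(f"{path}: no data rows")
    try:
        return ScatteringCurve(q=np.array(q), y=np.array(y), T=T)
    except ValueError as exc:
        raise CurveFormatError(f"{path}: {exc}") from None


def write_curve(curve: ScatteringCurve, path, header: str = "") -> None:
    """Write ``q  y  sqrt(y)`` columns with a commented header."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# T = {curve.T:g}\n")
        fh.write("# q(nm^-1)  intensity(counts)  sigma\n")
        for qi, yi in zip(curve.q, curve.y):
            fh.write(f"{qi:.8g} {yi:.8g} {np.sqrt(max(yi, 1.0)):.8g}\n")


def write_result(result, path) -> None:
    """Serialize a ModelSelectionResult (or dict) to JSON."""
    d = result.to_dict() if hasattr(result, "to_dict") else dict(result)
    d.setdefault("schema_version", SCHEMA_VERSION)
    # drop non-serializable attachments (e.g. raw chains)
    d.get("config", {})
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.random.SeedSequence):
        return {"seed_sequence_entropy": obj.entropy, "spawn_key": list(obj.spawn_key)}
    return str(obj)


def read_result(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_tally(tally: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a sweep tally as CSV (with a JSON metadata sidecar header)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# schema_version={SCHEMA_VERSION}\n")
        if meta:
            fh.write("# " + json.dumps(meta, default=_json_default) + "\n")
        tally.to_csv(fh, index=False)


def read_tally(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_table(columns: dict, path, header: str = "") -> None:
    """Write named columns (q, residuals, envelope bands, ...) as tidy
    whitespace-separated text for external plotting tools."""
    df = pd.DataFrame(columns)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# " + "  ".join(df.columns) + "\n")
        np.savetxt(fh, df.to_numpy(), fmt="%.8g")
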