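"""Table readers and report writers shared by the command-line pipelines.

Energy tables are delimited text (comma or tab, auto-detected) with the
header columns ``system, subsystem, family, X, component, cp_flavor,
unit, energy``; unknown columns are preserved as per-record metadata.
Reports are written as JSON or CSV at full precision, or as markdown
tables rounded to the two-to-three decimals customary for kcal/mol
reporting.  Outputs are deterministic: the same inputs produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .schemes import EnergyRecord

__all__ = ["read_energy_table", "records_to_frame", "write_report"]

MANDATORY = ("system", "subsystem", "family", "X", "component", "cp_flavor", "unit", "energy")


def read_energy_table(path, dialect: str | None = None) -> list:
    """Read and validate an energy table into :class:`EnergyRecord` rows.

    ``dialect`` forces ``","`` or ``"\\t"``; by default the separator is
    sniffed.  Extra columns land in a ``meta`` dict attached to each
    record (as attribute ``meta``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = {"csv": ",", "tsv": "\t", ",": ",", "\t": "\t"}.get(dialect, None)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in MANDATORY]
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        d = dict(zip(df.columns, row))
        try:
            x = int(d["X"])
        except (TypeError, ValueError):
            raise ValueError(f"row {row_no}: X must be an integer, got {d['X']!r}")
        try:
            energy = float(d["energy"])
        except (TypeError, ValueError):
            raise ValueError(f"row {row_no}: non-numeric energy {d['energy']!r}")
        try:
            rec = EnergyRecord(
                system=str(d["system"]),
                subsystem=str(d["subsystem"]),
                family=str(d["family"]),
                X=x,
                component=str(d["component"]),
                cp_flavor=str(d["cp_flavor"]),
                energy=energy,
                unit=str(d["unit"]),
            )
        except ValueError as exc:
            raise ValueError(f"row {row_no}: {exc}") from None
        if extra:
            object.__setattr__(rec, "meta", {c: d[c] for c in extra})
        records.append(rec)
    return records


def records_to_frame(records: Sequence[EnergyRecord]) -> pd.DataFrame:
    """Records back to a table with the canonical column order."""
    return pd.DataFrame(
        [
            {
                "system": r.system,
                "subsystem": r.subsystem,
                "family": r.family,
                "X": r.X,
                "component": r.component,
                "cp_flavor": r.cp_flavor,
                "unit": r.unit,
                "energy": r.energy,
            }
            for r in records
        ],
        columns=list(MANDATORY),
    )


def _jsonable(obj):
    if hasattr(obj, "as_dict"):
        return _jsonable(obj.as_dict())
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def _markdown_table(rows: list) -> str:
    if not rows:
        raise ValueError("results must be nonempty")
    cols = list(rows[0].keys())
    def fmt(v):
        if isinstance(v, float):
            return f"{v:.3f}"
        return str(v)
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for r in rows:
        lines.append("| " + " | ".join(fmt(r.get(c, "")) for c in cols) + " |")
    return "\n".join(lines) + "\n"


def write_report(results, path, format: str = "json") -> None:
    """Write result objects deterministically as json, csv or markdown.

    ``results`` is a dict, a result object with ``as_dict``, or a list of
    either.  JSON/CSV carry full precision; markdown rounds to 3 decimals.
    """
    path = Path(path)
    data = _jsonable(results)
    if format == "json":
        text = json.dumps(data, indent=2, sort_keys=False) + "\n"
    elif format in ("csv", "markdown"):
        rows = data if isinstance(data, list) else [data]
        flat = []
        for r in rows:
            if not isinstance(r, dict):
                raise ValueError("csv/markdown output needs dict-like results")
            flat.append({k: v for k, v in r.items() if not isinstance(v, (dict, list))})
        if format == "csv":
            text = pd.DataFrame(flat).to_csv(index=False)
        else:
            text = _markdown_table(flat)
    else:
        raise ValueError("format must be json, csv or markdown")
    path.write_text(text)
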