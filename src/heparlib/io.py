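"""File readers/writers and run configuration.

Peak lists travel as CSV with a required ``ppm_h`` column and optional
``ppm_c`` and ``j_hz`` columns.  Reports are written as TSV (ppm to two
decimals, Da to one decimal, matching the precision the values are
quoted at) or as JSON at full precision.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .assignment import AssignmentConfig, Peak, PeakList
from .enzymes import PlannerConfig


class PeakListFormatError(ValueError):
    pass


def read_peaklist(path: str | Path) -> PeakList:
    """Read a peak-list CSV (columns ppm_h[, ppm_c, j_hz]).

    Malformed rows are reported with their line number; duplicate rows
    (after rounding shifts to 0.001 ppm) are rejected as transcription
    errors.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise PeakListFormatError(f"{path}: {exc}") from exc
    if "ppm_h" not in df.columns:
        raise PeakListFormatError(f"{path}: missing required column 'ppm_h'")
    peaks = []
    seen = set()
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            h = float(row["ppm_h"])
            c = float(row["ppm_c"]) if "ppm_c" in df.columns and pd.notna(
                row["ppm_c"]) else None
            j = float(row["j_hz"]) if "j_hz" in df.columns and pd.notna(
                row["j_hz"]) else None
            peak = Peak(h, c, j)
        except (TypeError, ValueError) as exc:
            raise PeakListFormatError(f"{path}:{line}: {exc}") from exc
        key = (round(h, 3), None if c is None else round(c, 3), j)
        if key in seen:
            raise PeakListFormatError(
                f"{path}:{line}: duplicate peak row {key}")
        seen.add(key)
        peaks.append(peak)
    if not peaks:
        raise PeakListFormatError(f"{path}: no peaks")
    return PeakList(tuple(peaks))


def _fmt(value, kind: str) -> str:
    if value is None:
        return ""
    if kind == "ppm":
        return f"{value:.2f}"
    if kind == "da":
        return f"{value:.1f}"
    return str(value)


def write_report(rows: list[dict], path: str | Path | None,
                 fmt: str = "tsv", number_kinds: dict[str, str] | None = None
                 ) -> str:
    """Serialize report rows; returns the text (and writes it if a path
    is given).  TSV applies display rounding; JSON keeps full precision."""
    number_kinds = number_kinds or {}
    if fmt == "json":
        text = json.dumps(rows, indent=2, default=str) + "\n"
    elif fmt == "tsv":
        if not rows:
            text = ""
        else:
            cols = list(rows[0])
            lines = ["\t".join(cols)]
            for row in rows:
                lines.append("\t".join(
                    _fmt(row.get(c), number_kinds.get(c, ""))
                    for c in cols))
            text = "\n".join(lines) + "\n"
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    if path is not None:
        Path(path).write_text(text)
    return text


@dataclass(frozen=True)
class RunConfig:
    """Configuration surface of the command-line interface.

    Defaults reproduce the packaged model table and rule flags.
    """

    shift_table: str | None = None      # path override for the model table
    assignment: AssignmentConfig = field(default_factory=AssignmentConfig)
    planner: PlannerConfig = field(default_factory=PlannerConfig)
    output_format: str = "tsv"          # tsv | json
    log_level: str = "INFO"


def load_run_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; missing keys keep their defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    if "shift_table" in data:
        kwargs["shift_table"] = data["shift_table"]
    if "assignment" in data:
        kwargs["assignment"] = AssignmentConfig(**data["assignment"])
    if "planner" in data:
        kwargs["planner"] = PlannerConfig(**data["planner"])
    for key in ("output_format", "log_level"):
        if key in data:
            kwargs[key] = data[key]
    return RunConfig(**kwargs)


def route_to_dict(route) -> dict:
    """JSON-ready form of a planner route."""
    from .glycans import format_sequence
    return {
        "start": format_sequence(route.start),
        "end": format_sequence(route.end),
        "n_steps": len(route.steps),
        "steps": [
            {"action": s.action, "donor": s.donor, "sites": list(s.sites)}
            for s in route.steps
        ],
    }


def dataclass_row(obj) -> dict:
    return dataclasses.asdict(obj)
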