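"""Rendering of validation and stability results to plain text, plus
provenance metadata embedded in every report."""

from __future__ import annotations

import hashlib
import json
from typing import Any

import pandas as pd

from . import __version__
from .validation import ValidationReport

__all__ = [
    "provenance",
    "render_validation_text",
    "render_stability_text",
    "stability_table_to_json",
    "content_hash",
]


def provenance(config: dict[str, Any]) -> dict[str, Any]:
    cfg = json.dumps(config, sort_keys=True, default=str)
    return {
        "package": "stabval",
        "version": __version__,
        "config": config,
        "config_sha256": hashlib.sha256(cfg.encode()).hexdigest(),
    }


def content_hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def _fmt(v: Any, nd: int = 2) -> str:
    if isinstance(v, float):
        return f"{v:.{nd}f}"
    return str(v)


def render_validation_text(report: ValidationReport) -> str:
    """Human-readable table: one line per check with value, criterion and
    verdict."""
    lines = ["Validation summary", "=" * 70]
    for section in report.sections:
        lines.append(f"\n[{section.name}]  ->  {'PASS' if section.passed else 'FAIL'}")
        for name, check in section.checks.items():
            verdict = "pass" if check.passed else "FAIL"
            lines.append(f"  {name:<28} {_fmt(check.value, 4):>14}   "
                         f"{check.criterion:<38} {verdict}")
        extras = {k: v for k, v in section.values.items()
                  if isinstance(v, (int, float, str))}
        if extras:
            rendered = ", ".join(f"{k}={_fmt(v, 4)}" for k, v in extras.items())
            lines.append(f"  values: {rendered}")
    lines.append("")
    lines.append(f"Overall: {'PASS' if report.passed else 'FAIL'}")
    return "\n".join(lines)


def render_stability_text(table: pd.DataFrame) -> str:
    """Stability table with the rate in x10^-3 1/h and t90/recovery at two
    decimals (full precision is retained in the CSV/JSON outputs)."""
    lines = ["Stability summary", "=" * 94]
    header = (f"{'sample':<8}{'condition':<14}{'T(degC)':>8}"
              f"{'KA(x1e-3/h)':>14}{'t90(h)':>10}{'r2':>8}{'rec(%)':>9}  note")
    lines.append(header)
    lines.append("-" * 94)
    for row in table.itertuples():
        lines.append(
            f"{row.sample_id:<8}{row.condition:<14}{row.temperature_c:>8.0f}"
            f"{row.ka_e3_per_h:>14.2f}{row.t90_h:>10.2f}{row.r2:>8.2f}"
            f"{row.recovery_last_pct:>9.2f}  {row.note}")
    return "\n".join(lines)


def stability_table_to_json(table: pd.DataFrame, config: dict[str, Any]) -> str:
    payload = {
        "provenance": provenance(config),
        "rows": table.to_dict(orient="records"),
    }
    return json.dumps(payload, default=str, indent=2)
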