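"""Findings and QA/QC reports.

A :class:`Finding` is one detected issue; a :class:`QAQCReport` is the
ordered, serializable collection of findings for one pipeline stage with a
per-check and overall status.  JSON is the canonical serialization (the
text rendering is derived from it), and reports embed the tool version,
the configuration snapshot and input digests for provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import IntEnum
from typing import Any, Iterable, Optional

from . import __version__


class Severity(IntEnum):
    """Ordered severity scale; a report's overall status is the maximum."""

    PASS = 0
    SKIPPED = 1
    WARNING = 2
    ACTION_REQUIRED = 3

    def __str__(self) -> str:  # serialized form
        return self.name


_SUGGESTED_ACTION = {
    Severity.PASS: "no action needed",
    Severity.SKIPPED: "provide the missing inputs if available",
    Severity.WARNING: "review the flagged period and confirm or correct",
    Severity.ACTION_REQUIRED: "correct the data and resubmit",
}


@dataclass(frozen=True)
class Finding:
    """One detected issue from a QA/QC check."""

    check: str
    code: str
    severity: Severity
    variables: tuple[str, ...] = ()
    span_start: Optional[str] = None  # YYYYMMDDHHMM
    span_end: Optional[str] = None
    metrics: dict = field(default_factory=dict)
    message: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["severity"] = self.severity.name
        d["variables"] = list(self.variables)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Finding":
        return cls(
            check=d["check"], code=d["code"], severity=Severity[d["severity"]],
            variables=tuple(d.get("variables", ())),
            span_start=d.get("span_start"), span_end=d.get("span_end"),
            metrics=d.get("metrics", {}), message=d.get("message", ""),
        )


def skipped(check: str, reason: str) -> Finding:
    """A SKIPPED marker finding: the check could not run (not pass, not fail)."""
    return Finding(check=check, code="SKIPPED", severity=Severity.SKIPPED,
                   message=reason)


def _finding_sort_key(order: list[str]):
    rank = {name: i for i, name in enumerate(order)}

    def key(f: Finding):
        return (rank.get(f.check, len(order)), -int(f.severity),
                f.span_start or "", f.code, f.variables)

    return key


@dataclass
class QAQCReport:
    """Ordered findings plus per-check and overall status for one stage."""

    site_id: str
    stage: str  # FORMAT | DATA
    checks: list[str]
    findings: list[Finding]
    config: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    version: str = __version__

    def check_status(self, check: str) -> Severity:
        sev = [f.severity for f in self.findings if f.check == check]
        return max(sev, default=Severity.PASS)

    @property
    def per_check_status(self) -> dict[str, str]:
        return {c: self.check_status(c).name for c in self.checks}

    @property
    def overall_status(self) -> Severity:
        statuses = [self.check_status(c) for c in self.checks]
        return max(statuses, default=Severity.PASS)

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "stage": self.stage,
            "version": self.version,
            "overall_status": self.overall_status.name,
            "per_check_status": self.per_check_status,
            "checks": list(self.checks),
            "findings": [f.to_dict() for f in self.findings],
            "config": self.config,
            "input_digests": self.input_digests,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True,
                          default=_json_default) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "QAQCReport":
        d = json.loads(text)
        return cls(
            site_id=d["site_id"], stage=d["stage"], checks=list(d["checks"]),
            findings=[Finding.from_dict(fd) for fd in d["findings"]],
            config=d.get("config", {}), input_digests=d.get("input_digests", {}),
            version=d.get("version", __version__),
        )


def _json_default(obj: Any):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def assemble_report(
    findings: Iterable[Finding],
    stage: str,
    site_id: str,
    checks: list[str],
    config: Optional[dict] = None,
    input_digests: Optional[dict] = None,
) -> QAQCReport:
    """Group and order findings into a report.

    Findings are ordered by check (pipeline order), then severity
    (descending), then time span.  Every SKIPPED check keeps its marker
    finding so the report states *why* a check did not run.
    """
    ordered = sorted(findings, key=_finding_sort_key(checks))
    return QAQCReport(
        site_id=site_id, stage=stage, checks=list(checks), findings=ordered,
        config=dict(config or {}), input_digests=dict(input_digests or {}),
    )


def render_text(report: QAQCReport) -> str:
    """Deterministic plain-text rendering: one summary line per check, one
    block per finding with span, metrics and a suggested action."""
    lines: list[str] = []
    lines.append(f"QA/QC report  stage={report.stage}  site={report.site_id}  "
                 f"tool=fluxqaqc {report.version}")
    lines.append(f"Overall status: {report.overall_status.name}")
    lines.append("")
    lines.append("Per-check summary:")
    for check in report.checks:
        n = sum(1 for f in report.findings
                if f.check == check and f.severity > Severity.PASS)
        lines.append(f"  {check:24s} {report.check_status(check).name:16s}"
                     f" findings={n}")
    lines.append("")
    real = [f for f in report.findings]
    if not real:
        lines.append("No findings.")
    for f in real:
        span = ""
        if f.span_start and f.span_end:
            span = f"  span {f.span_start}-{f.span_end}"
        lines.append(f"[{f.severity.name}] {f.check} / {f.code}"
                     + (f"  vars={','.join(f.variables)}" if f.variables else "")
                     + span)
        if f.message:
            lines.append(f"    {f.message}")
        if f.metrics:
            parts = ", ".join(f"{k}={_fmt_metric(v)}" for k, v in sorted(f.metrics.items()))
            lines.append(f"    metrics: {parts}")
        lines.append(f"    action: {_SUGGESTED_ACTION[f.severity]}")
    return "\n".join(lines) + "\n"


def _fmt_metric(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)
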