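"""Format QA/QC: FP-In compliance assessment with one autocorrection pass.

The flow mirrors a submission pipeline: read the file, diagnose format
issues, make exactly one automatic correction attempt for the fixable ones
(filling skipped intervals with the missing sentinel, typographic variable
renames, delimiter normalization, end-timestamp recomputation), re-check,
and report an overall status:

* ``PASS``  — no findings at all,
* ``FIXED`` — findings found and all of them fixed automatically,
* ``FAIL``  — at least one finding could not be fixed.

Autocorrection is conservative: every data value present in the input
survives unchanged; only rows of missing values are inserted and labels /
timestamps normalized.  Semantic renames (e.g. ``NEE`` -> ``FC``) are never
attempted — only typographic (case-fold) fixes against the registry.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .fp_format import (
    FPTable, ParseDiagnostic, SiteMetadata, TIMESTAMP_START, TIMESTAMP_END,
    format_timestamp, parse_variable_name, read_fp_file,
)
from .registry import VariableRegistry

FORMAT_CODES = (
    "BAD_FILENAME", "BAD_TIMESTAMP_FORMAT", "NONMONOTONIC_TIME",
    "SKIPPED_INTERVALS", "DUPLICATE_ROWS", "BAD_VARIABLE_NAME",
    "MISSING_MANDATORY", "NON_NUMERIC_CELL", "WRONG_DELIMITER",
)

#: accepted filename convention: SITEID_RES_START_END.csv (RES: HH or HR)
_FILENAME_RE = re.compile(r"^[A-Za-z]{2}-[A-Za-z0-9]{2,4}_(HH|HR)_\d{12}_\d{12}\.csv$")


@dataclass(frozen=True)
class FormatFinding:
    """One format-compliance issue; ``fixed`` implies ``fixable``."""

    code: str
    message: str
    row: Optional[int] = None
    column: Optional[str] = None
    fixable: bool = False
    fixed: bool = False
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fixed and not self.fixable:
            raise ValueError("a finding cannot be fixed but not fixable")
        if self.code not in FORMAT_CODES + ("FATAL",):
            raise ValueError(f"unknown format finding code {self.code}")

    def to_dict(self) -> dict:
        return {
            "code": self.code, "message": self.message, "row": self.row,
            "column": self.column, "fixable": self.fixable, "fixed": self.fixed,
            "detail": dict(self.detail),
        }


@dataclass
class FormatReport:
    """Outcome of one Format QA/QC run."""

    status: str  # PASS | FIXED | FAIL
    findings: list[FormatFinding]
    input_digest: str = ""
    filename: str = ""
    site_id: str = ""
    table: Optional[FPTable] = None  # corrected table when status != FAIL-at-read

    def to_dict(self) -> dict:
        return {
            "stage": "FORMAT",
            "site_id": self.site_id,
            "filename": self.filename,
            "status": self.status,
            "input_digest": self.input_digest,
            "findings": [f.to_dict() for f in self.findings],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def render_text(self) -> str:
        lines = [f"Format QA/QC report  site={self.site_id}  file={self.filename}",
                 f"Status: {self.status}", ""]
        if not self.findings:
            lines.append("No format issues found.")
        for f in self.findings:
            loc = ""
            if f.row is not None:
                loc += f" row={f.row}"
            if f.column is not None:
                loc += f" col={f.column}"
            state = "fixed" if f.fixed else ("fixable" if f.fixable else "not fixable")
            lines.append(f"[{f.code}]{loc} ({state}) {f.message}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# checks
# ---------------------------------------------------------------------------

def check_structure(table: FPTable, diagnostics: list[ParseDiagnostic]
                    ) -> list[FormatFinding]:
    """Findings for the time axis and cell-level parse diagnostics."""
    findings: list[FormatFinding] = []

    for d in diagnostics:
        if d.code == "WRONG_DELIMITER":
            findings.append(FormatFinding("WRONG_DELIMITER", d.message, fixable=True))
        elif d.code == "NON_NUMERIC_CELL":
            findings.append(FormatFinding("NON_NUMERIC_CELL", d.message,
                                          row=d.row, column=d.column, fixable=True))
        elif d.code == "BAD_TIMESTAMP_FORMAT":
            findings.append(FormatFinding("BAD_TIMESTAMP_FORMAT", d.message,
                                          row=d.row, column=d.column, fixable=False))
        elif d.code == "DUPLICATE_COLUMN":
            findings.append(FormatFinding("BAD_VARIABLE_NAME", d.message,
                                          column=d.column, fixable=False))

    start, end = table.start, table.end
    if start.hasnans or end.hasnans:
        return findings  # axis checks need parseable timestamps

    step = pd.Timedelta(minutes=table.resolution_minutes)

    bad_end = (end - start) != step
    if bad_end.any():
        n = int(bad_end.sum())
        findings.append(FormatFinding(
            "BAD_TIMESTAMP_FORMAT",
            f"TIMESTAMP_END - TIMESTAMP_START != {table.resolution_minutes} min "
            f"for {n} rows", fixable=True,
            detail={"n_rows": n, "fix": "recompute_end"}))

    dup_mask = start.duplicated(keep=False)
    if dup_mask.any():
        findings.append(FormatFinding(
            "DUPLICATE_ROWS",
            f"{int(start.duplicated().sum())} duplicated start timestamps",
            fixable=False))

    unique_sorted = not dup_mask.any()
    diffs = np.diff(start.asi8)
    if len(start) > 1 and not (diffs > 0).all():
        findings.append(FormatFinding(
            "NONMONOTONIC_TIME", "start timestamps are not strictly increasing",
            fixable=unique_sorted, detail={"fix": "sort"}))

    # skipped intervals, evaluated on the sorted unique axis
    if unique_sorted or not dup_mask.any():
        s = start.sort_values()
        gaps = np.diff(s.asi8) // (60 * 10**9)
        res = table.resolution_minutes
        for i in np.nonzero(gaps > res)[0]:
            n_missing = int(gaps[i] // res) - 1
            if gaps[i] % res != 0:
                findings.append(FormatFinding(
                    "BAD_TIMESTAMP_FORMAT",
                    f"gap after {format_timestamp(s[i])} is not a multiple of the "
                    f"{res}-min resolution", fixable=False))
                continue
            findings.append(FormatFinding(
                "SKIPPED_INTERVALS",
                f"{n_missing} skipped interval(s) after {format_timestamp(s[i])}",
                fixable=True,
                detail={"n_missing": n_missing,
                        "gap_start": format_timestamp(s[i] + pd.Timedelta(minutes=res)),
                        "gap_end": format_timestamp(s[i + 1])}))
    return findings


def check_filename(filename: str) -> list[FormatFinding]:
    """Non-fatal filename-convention check (SITEID_RES_START_END.csv)."""
    name = Path(filename).name
    if _FILENAME_RE.match(name):
        return []
    return [FormatFinding(
        "BAD_FILENAME",
        f"filename {name!r} does not follow SITEID_RES_START_END.csv; "
        "accepted as-is and a canonical name recorded",
        fixable=True, detail={"fix": "canonical_name"})]


def _rename_candidate(label: str, registry: VariableRegistry) -> Optional[str]:
    """Unambiguous typographic (case-fold) rename for a label, or None."""
    try:
        var = parse_variable_name(label)
    except ValueError:
        return None
    matches = [b for b in registry.bases() if b.casefold() == var.base.casefold()]
    if len(matches) != 1:
        return None
    canonical = replace(var, base=matches[0], warnings=()).label
    return canonical if canonical != label else None


def check_variables(table: FPTable, registry: Optional[VariableRegistry] = None
                    ) -> list[FormatFinding]:
    """Findings for the variable labels and the minimum-variable rule.

    The minimum variables are the paired timestamps and one carbon flux
    (an ``FC`` or ``FCH4`` base, any qualifiers).
    """
    registry = registry or VariableRegistry.default()
    findings: list[FormatFinding] = []
    bases: list[str] = []
    renames_seen: dict[str, list[str]] = {}

    for label in table.columns:
        try:
            var = parse_variable_name(label)
        except ValueError as exc:
            findings.append(FormatFinding("BAD_VARIABLE_NAME", str(exc),
                                          column=label, fixable=False))
            continue
        bases.append(var.base.upper())
        candidate = _rename_candidate(label, registry)
        if candidate is not None:
            renames_seen.setdefault(candidate, []).append(label)
        elif var.warnings:
            findings.append(FormatFinding(
                "BAD_VARIABLE_NAME", "; ".join(var.warnings),
                column=label, fixable=False))

    for canonical, labels in sorted(renames_seen.items()):
        ambiguous = len(labels) > 1 or canonical in table.columns
        for label in labels:
            if ambiguous:
                findings.append(FormatFinding(
                    "BAD_VARIABLE_NAME",
                    f"label {label!r} matches {canonical!r} after case-fold but the "
                    "rename would be ambiguous", column=label, fixable=False))
            else:
                findings.append(FormatFinding(
                    "BAD_VARIABLE_NAME",
                    f"label {label!r} should be {canonical!r}", column=label,
                    fixable=True, detail={"rename_to": canonical}))

    if not any(b in ("FC", "FCH4") for b in bases):
        findings.append(FormatFinding(
            "MISSING_MANDATORY",
            "no carbon flux variable (FC or FCH4) present", fixable=False))
    return findings


# ---------------------------------------------------------------------------
# autocorrection
# ---------------------------------------------------------------------------

def autocorrect(table: FPTable, findings: list[FormatFinding]
                ) -> tuple[FPTable, list[FormatFinding]]:
    """Apply exactly one correction pass for the fixable findings.

    Data values are never altered; unfixable findings are returned
    untouched.  The operation is idempotent: a second pass on the corrected
    table diagnoses nothing fixable.
    """
    t = table.copy()
    out: list[FormatFinding] = []

    def fix(f: FormatFinding) -> FormatFinding:
        return replace(f, fixed=True)

    # order matters: renames / end recompute / sort / gap fill
    for f in findings:
        if f.code in ("WRONG_DELIMITER", "NON_NUMERIC_CELL", "BAD_FILENAME") and f.fixable:
            # normalization already happened at read (delimiter, cell -> missing);
            # the filename convention is advisory
            out.append(fix(f))
        elif f.code == "BAD_VARIABLE_NAME" and f.fixable:
            target = f.detail.get("rename_to")
            if target and f.column in t.data.columns and target not in t.data.columns:
                t.data = t.data.rename(columns={f.column: target})
                out.append(fix(f))
            else:
                out.append(f)
        elif f.code == "BAD_TIMESTAMP_FORMAT" and f.fixable \
                and f.detail.get("fix") == "recompute_end":
            t.end = t.start + pd.Timedelta(minutes=t.resolution_minutes)
            out.append(fix(f))
        else:
            out.append(f)

    findings = out
    out = []
    sort_ok = any(f.code == "NONMONOTONIC_TIME" and f.fixable for f in findings)
    if sort_ok:
        order = np.argsort(t.start.asi8, kind="stable")
        t = FPTable(t.start[order], t.end[order], t.data.iloc[order],
                    t.resolution_minutes, t.site_id)
    for f in findings:
        if f.code == "NONMONOTONIC_TIME" and f.fixable:
            out.append(fix(f))
        else:
            out.append(f)
    findings = out

    gap_findings = [f for f in findings if f.code == "SKIPPED_INTERVALS" and f.fixable]
    axis_clean = (not t.start.hasnans and not t.start.duplicated().any()
                  and (np.diff(t.start.asi8) > 0).all() if len(t) > 1 else True)
    if gap_findings and axis_clean:
        step = pd.Timedelta(minutes=t.resolution_minutes)
        full = pd.date_range(t.start[0], t.start[-1], freq=step)
        data = t.data.set_index(t.start).reindex(full).reset_index(drop=True)
        t = FPTable(full, full + step, data, t.resolution_minutes, t.site_id)
        findings = [fix(f) if (f.code == "SKIPPED_INTERVALS" and f.fixable) else f
                    for f in findings]
    return t, findings


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_format_qaqc(
    path: Union[str, Path],
    site_meta: Optional[SiteMetadata] = None,
    registry: Optional[VariableRegistry] = None,
) -> FormatReport:
    """Read -> check -> (one) autocorrect -> re-check -> status."""
    path = Path(path)
    registry = registry or VariableRegistry.default()
    site_id = site_meta.site_id if site_meta else ""
    try:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
    except OSError:
        digest = ""

    table, diags = read_fp_file(path, registry=registry, site_id=site_id)
    if table is None:
        fatal = [FormatFinding("FATAL", d.message, fixable=False)
                 for d in diags if d.fatal] or \
                [FormatFinding("FATAL", "file could not be parsed", fixable=False)]
        return FormatReport("FAIL", fatal, input_digest=digest,
                            filename=path.name, site_id=site_id)

    findings = (check_filename(path.name)
                + check_structure(table, diags)
                + check_variables(table, registry))
    if not findings:
        return FormatReport("PASS", [], input_digest=digest,
                            filename=path.name, site_id=site_id, table=table)

    corrected, after_fix = autocorrect(table, findings)
    fixed = [f for f in after_fix if f.fixed]
    # re-check the corrected table; anything remaining is unfixed
    residual = [f for f in check_structure(corrected, []) + check_variables(corrected, registry)
                if not f.fixed]
    # unfixable parse-level findings (bad timestamps) do not reappear from
    # check_structure on the corrected table, carry them over explicitly
    carried = [f for f in after_fix
               if not f.fixed and f.code in ("BAD_TIMESTAMP_FORMAT", "NON_NUMERIC_CELL")
               and f.row is not None]
    residual = carried + residual
    final = fixed + residual
    status = "FAIL" if residual else "FIXED"
    return FormatReport(status, final, input_digest=digest,
                        filename=path.name, site_id=site_id, table=corrected)
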