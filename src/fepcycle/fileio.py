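"""Readers and writers for lambda-window sample files and result records.

Two on-disk dialects carry per-window energy-difference samples:

TSV dialect (read/write)
    ``#T <kelvin>`` once at the top, then per window a ``#WINDOW <lam_i>
    <lam_next>`` header followed by data rows ``<step>\\t<dU>`` with dU in
    kcal/mol.  Byte-stable: writing the same run twice produces identical
    files.

NAMD-style fepout dialect (read only)
    Window boundaries come from lines starting ``#NEW FEP WINDOW:`` (the
    two lambda values are parsed from that line); samples come from lines
    starting ``FepEnergy:``, whose 7th whitespace-separated numeric field
    is the energy difference dE.  All other fields are ignored as opaque.

Malformed lines are collected with their line numbers and reported
together, rather than aborting at the first problem.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .estimators import FreeEnergyEstimate
from .toy_alchemy import FEPRun, LambdaWindow

__all__ = ["read_windows", "write_windows", "write_result_json", "FormatError"]


class FormatError(ValueError):
    """A window-sample file violates its dialect."""


def write_windows(run: FEPRun, path: str | Path, dialect: str = "tsv") -> Path:
    """Write a run in the TSV window dialect (deterministic byte layout)."""
    if dialect != "tsv":
        raise ValueError(f"only the 'tsv' dialect is writable, got {dialect!r}")
    path = Path(path)
    lines = [f"#T {float(run.T)!r}", f"#DIRECTION {run.direction}"]
    for w in run.windows:
        lines.append(f"#WINDOW {float(w.lam_i)!r} {float(w.lam_next)!r}")
        for step, du in enumerate(w.samples_dU):
            lines.append(f"{step}\t{float(du)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def _finish_window(pending, windows, T):
    lam_i, lam_next, samples, seed = pending
    if not samples:
        raise FormatError(f"window ({lam_i}, {lam_next}) holds no samples")
    windows.append(LambdaWindow(lam_i, lam_next, np.asarray(samples), T, seed))


def _read_tsv(lines: list[str]) -> tuple[list[LambdaWindow], str, float, list]:
    T = None
    direction = None
    windows: list[LambdaWindow] = []
    pending = None
    bad: list[tuple[int, str]] = []
    for ln, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#T "):
            T = float(line.split()[1])
        elif line.startswith("#DIRECTION "):
            direction = line.split()[1]
        elif line.startswith("#WINDOW "):
            if T is None:
                raise FormatError(f"line {ln}: #WINDOW before #T header")
            if pending is not None:
                _finish_window(pending, windows, T)
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"line {ln}: malformed #WINDOW header {line!r}")
            pending = (float(parts[1]), float(parts[2]), [], 0)
        elif line.startswith("#"):
            continue  # unknown comment lines are permitted
        else:
            if pending is None:
                bad.append((ln, "data row outside any window"))
                continue
            parts = line.split("\t")
            try:
                pending[2].append(float(parts[1]))
            except (IndexError, ValueError):
                bad.append((ln, f"malformed data row {line!r}"))
    if pending is not None:
        _finish_window(pending, windows, T)
    if direction is None and windows:
        direction = "forward" if windows[0].lam_i < windows[0].lam_next else "backward"
    return windows, direction, T, bad


_FEPOUT_WINDOW_RE = re.compile(
    r"#NEW FEP WINDOW:.*?LAMBDA\s+SET\s+TO\s+([0-9.eE+-]+)\s+LAMBDA2\s+([0-9.eE+-]+)",
)
_FEPOUT_WINDOW_FALLBACK_RE = re.compile(r"#NEW FEP WINDOW:[^0-9]*([0-9.eE+-]+)\s+([0-9.eE+-]+)")


def _read_fepout(lines: list[str]) -> tuple[list[LambdaWindow], str, float, list]:
    T = None
    windows: list[LambdaWindow] = []
    pending = None
    bad: list[tuple[int, str]] = []
    for ln, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if line.startswith("#NEW FEP WINDOW:"):
            m = _FEPOUT_WINDOW_RE.search(line) or _FEPOUT_WINDOW_FALLBACK_RE.search(line)
            if not m:
                raise FormatError(f"line {ln}: cannot parse lambda values from {line!r}")
            if pending is not None:
                _finish_window(pending, windows, T if T is not None else 300.0)
            pending = (float(m.group(1)), float(m.group(2)), [], 0)
        elif line.startswith("FepEnergy:"):
            if pending is None:
                bad.append((ln, "FepEnergy record outside any window"))
                continue
            fields = line.split()
            # layout: FepEnergy: step elec0 elec1 vdw0 vdw1 dE dE_avg temp dG
            if len(fields) < 7:
                bad.append((ln, f"short FepEnergy record ({len(fields)} fields)"))
                continue
            try:
                pending[2].append(float(fields[6]))
                if T is None and len(fields) >= 9:
                    T = float(fields[8])
            except ValueError:
                bad.append((ln, f"non-numeric FepEnergy record {line!r}"))
    if pending is not None:
        _finish_window(pending, windows, T if T is not None else 300.0)
    if T is None:
        T = 300.0
    direction = None
    if windows:
        direction = "forward" if windows[0].lam_i < windows[0].lam_next else "backward"
    return windows, direction, T, bad


def read_windows(path: str | Path, dialect: str = "tsv") -> FEPRun:
    """Parse a window-sample file into an :class:`FEPRun`.

    Raises :class:`FormatError` for zero windows, a non-monotone lambda
    sequence, or any malformed lines (reported with line numbers).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if dialect == "tsv":
        windows, direction, T, bad = _read_tsv(lines)
    elif dialect in ("namd_fepout", "fepout"):
        windows, direction, T, bad = _read_fepout(lines)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected tsv or namd_fepout")

    if bad:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in bad[:10])
        raise FormatError(f"{len(bad)} malformed line(s) in {path}: {detail}")
    if not windows:
        raise FormatError(f"zero windows in {path}")
    lams = [w.lam_i for w in windows] + [windows[-1].lam_next]
    diffs = np.diff(lams)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise FormatError(f"non-monotone lambda sequence in {path}: {lams}")
    return FEPRun(windows=windows, direction=direction, system=None, T=T)


def write_result_json(estimate: FreeEnergyEstimate, path: str | Path) -> Path:
    """Write a machine-readable free-energy result record."""
    path = Path(path)
    record = {
        "value_kcal_mol": estimate.value,
        "stderr_kcal_mol": estimate.stderr,
        "method": estimate.method,
        "T_K": estimate.T,
        "n_bootstrap": estimate.n_bootstrap,
        "per_window": [
            {"lam_i": a, "lam_next": b, "dG": g, "stderr": s}
            for a, b, g, s in estimate.per_window
        ],
    }
    path.write_text(json.dumps(record, indent=2) + "\n")
    return path
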