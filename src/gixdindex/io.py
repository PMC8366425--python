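"""Peak-list readers and solution-report writers.

Peak files hold one reflection per row: q_xy in the first column, q_z in the
second, in A^-1 with dot decimal separation.  A row with q_xy = 0 is the
specular peak; its presence selects the specular indexing route.  Supported
dialects are .xlsx (first sheet, no header) and .csv (optional header
``q_xy,q_z``).  Reports are written as a solutions table plus an indexing
table, either as a CSV pair or as one workbook with two sheets.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .peaks import PeakList
from .specular import Solution

__all__ = ["read_peaks", "write_peaks", "write_report", "read_report"]

_CSV_HEADER = ("q_xy", "q_z")

SOLUTION_COLUMNS = [
    "a",
    "b",
    "c",
    "alpha",
    "beta",
    "gamma",
    "u",
    "v",
    "w",
    "psi",
    "phi",
    "V",
    "dq_xy",
    "dq_z",
    "dq_xyz",
    "dq_spec",
]

INDEXING_COLUMNS = ["solution", "q_xy", "q_z", "h", "k", "l", "d_xy", "d_z", "d_xyz"]


class PeakFileError(ValueError):
    """A peak file failed validation; the message names the offending cell."""


def _rows_from_xlsx(path: Path) -> list[tuple[object, object, int]]:
    import openpyxl

    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    ws = wb.worksheets[0]
    rows = []
    for r, row in enumerate(ws.iter_rows(values_only=True), start=1):
        if row is None or all(v is None for v in row):
            continue
        vals = [v for v in row]
        rows.append((vals[0] if len(vals) > 0 else None, vals[1] if len(vals) > 1 else None, r))
    wb.close()
    return rows


def _rows_from_csv(path: Path) -> list[tuple[object, object, int]]:
    rows = []
    with open(path, newline="") as fh:
        for r, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.replace(";", ",").split(",")]
            if r == 1 and tuple(p.lower() for p in parts[:2]) == _CSV_HEADER:
                continue
            rows.append((parts[0] if parts else None, parts[1] if len(parts) > 1 else None, r))
    return rows


def read_peaks(path: str | Path) -> PeakList:
    """Read a peak file; rows with q_xy = 0 are specular.

    Raises :class:`PeakFileError` naming the row and column for non-numeric
    cells, negative q_xy, or an empty file.  The returned list preserves the
    file's row order; whether a specular peak is present determines which
    indexing route applies.
    """
    path = Path(path)
    if not path.exists():
        raise PeakFileError(f"{path}: file not found")
    suffix = path.suffix.lower()
    if suffix == ".xls":
        raise PeakFileError(
            f"{path}: legacy binary .xls is not supported; save as .xlsx or .csv"
        )
    if suffix == ".xlsx":
        raw = _rows_from_xlsx(path)
    elif suffix in (".csv", ".txt", ".dat"):
        raw = _rows_from_csv(path)
    else:
        raise PeakFileError(f"{path}: unsupported peak-file extension {suffix!r}")

    if not raw:
        raise PeakFileError(f"{path}: no peak rows found")
    rows: list[tuple[float, float]] = []
    for v_xy, v_z, r in raw:
        vals = []
        for col, v in zip(("q_xy", "q_z"), (v_xy, v_z)):
            try:
                x = float(v)
            except (TypeError, ValueError):
                raise PeakFileError(f"{path}: row {r}, column {col}: non-numeric value {v!r}")
            if not math.isfinite(x):
                raise PeakFileError(f"{path}: row {r}, column {col}: non-finite value {v!r}")
            vals.append(x)
        if vals[0] < 0:
            raise PeakFileError(f"{path}: row {r}, column q_xy: negative value {vals[0]}")
        rows.append((vals[0], vals[1]))
    return PeakList.from_rows(rows)


def write_peaks(peaks: PeakList, path: str | Path) -> None:
    """Write a peak list in the same dialects the reader accepts."""
    path = Path(path)
    rows = [(p.q_xy, p.q_z) for p in peaks.gixd]
    if peaks.specular is not None:
        rows.append((0.0, peaks.specular.q_z))
    if path.suffix.lower() == ".xlsx":
        df = pd.DataFrame(rows)
        df.to_excel(path, header=False, index=False)
    else:
        with open(path, "w", newline="") as fh:
            fh.write("q_xy,q_z\n")
            for x, z in rows:
                fh.write(f"{_fmt(x, 6)},{_fmt(z, 6)}\n")


def _fmt(x: float, sig: int) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return f"{x:.{sig}g}"


def _solution_frames(solutions: list[Solution]) -> tuple[pd.DataFrame, pd.DataFrame]:
    sol_rows = []
    idx_rows = []
    for i, sol in enumerate(solutions, start=1):
        c = sol.cell
        plane = sol.plane.indices if sol.plane is not None else (None, None, None)
        ori = sol.orientation
        sol_rows.append(
            {
                "solution": i,
                "a": _fmt(c.a, 6),
                "b": _fmt(c.b, 6),
                "c": _fmt(c.c, 6),
                "alpha": _fmt(c.alpha, 6),
                "beta": _fmt(c.beta, 6),
                "gamma": _fmt(c.gamma, 6),
                "u": "" if plane[0] is None else plane[0],
                "v": "" if plane[1] is None else plane[1],
                "w": "" if plane[2] is None else plane[2],
                "psi": "" if ori is None else _fmt(ori.psi, 6),
                "phi": "" if ori is None else _fmt(ori.phi, 6),
                "V": _fmt(sol.volume, 6),
                "dq_xy": _fmt(sol.errors.dq_xy, 4),
                "dq_z": _fmt(sol.errors.dq_z, 4),
                "dq_xyz": _fmt(sol.errors.dq_xyz, 4),
                "dq_spec": "" if sol.errors.dq_spec is None else _fmt(sol.errors.dq_spec, 4),
            }
        )
        for ip in sol.indexed:
            idx_rows.append(
                {
                    "solution": i,
                    "q_xy": _fmt(ip.peak.q_xy, 6),
                    "q_z": _fmt(ip.peak.q_z, 6),
                    "h": ip.hkl.h,
                    "k": ip.hkl.k,
                    "l": ip.hkl.l,
                    "d_xy": _fmt(ip.d_xy, 4),
                    "d_z": _fmt(ip.d_z, 4),
                    "d_xyz": _fmt(ip.d_xyz, 4),
                }
            )
    sol_df = pd.DataFrame(sol_rows, columns=["solution"] + SOLUTION_COLUMNS)
    idx_df = pd.DataFrame(idx_rows, columns=INDEXING_COLUMNS)
    return sol_df, idx_df


def write_report(solutions: list[Solution], path: str | Path, fmt: str | None = None) -> list[Path]:
    """Write the solution report; returns the written file paths.

    CSV output produces ``<stem>_solutions.csv`` and ``<stem>_indexing.csv``;
    xlsx output produces one workbook with sheets "solutions" and "indexing".
    Column order and float formatting (6 significant digits for lattice
    parameters, 4 for RMSDs) are fixed, so identical solution lists yield
    byte-identical files.
    """
    path = Path(path)
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() == ".xlsx" else "csv"
    sol_df, idx_df = _solution_frames(solutions)
    if fmt == "xlsx":
        out = path if path.suffix.lower() == ".xlsx" else path.with_suffix(".xlsx")
        with pd.ExcelWriter(out, engine="openpyxl") as writer:
            sol_df.to_excel(writer, sheet_name="solutions", index=False)
            idx_df.to_excel(writer, sheet_name="indexing", index=False)
        return [out]
    stem = path.with_suffix("")
    sol_path = Path(f"{stem}_solutions.csv")
    idx_path = Path(f"{stem}_indexing.csv")
    sol_df.to_csv(sol_path, index=False, lineterminator="\n")
    idx_df.to_csv(idx_path, index=False, lineterminator="\n")
    return [sol_path, idx_path]


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a solutions table (CSV file or xlsx 'solutions' sheet)."""
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        return pd.read_excel(path, sheet_name="solutions")
    return pd.read_csv(path)
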