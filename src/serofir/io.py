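"""Reading and writing spectral datasets.

Two on-disk formats are supported, both plain text and round-trippable:

* **wide CSV** — first column ``wavenumber``, one column per spectrum named
  by its ``spectrum_id``, plus a companion metadata TSV keyed by column name
  (columns: spectrum_id, subject_id, group, batch, replicate);
* **JCAMP-DX** — one labelled block per spectrum (compound multi-block files
  accepted), ``XYDATA=(X++(Y..Y))`` or ``XYPOINTS=(XY..XY)`` dialects, AFFN
  numbers plus SQZ/DIF/DUP compressed ordinates.  Other compression schemes
  are rejected with a clear error.

Whatever the file order, the in-memory grid is normalised to ascending
wavenumbers; storage written by this module is always ascending too, so
reading twice never re-reverses anything.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import META_COLUMNS, SpectralDataset

__all__ = ["read_dataset", "write_dataset", "SpectralIOError"]


class SpectralIOError(ValueError):
    """Raised when a spectral file cannot be parsed or written."""


# ---------------------------------------------------------------------------
# wide CSV + metadata TSV
# ---------------------------------------------------------------------------

def _metadata_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".meta.tsv")


def _read_wide_csv(path: Path) -> SpectralDataset:
    try:
        table = pd.read_csv(path)
    except ValueError as exc:
        raise SpectralIOError(f"cannot parse {path}: {exc}") from exc
    if table.shape[1] < 2:
        raise SpectralIOError(f"{path}: need a wavenumber column plus >= 1 spectrum")
    for col in table.columns:
        if not np.issubdtype(table[col].dtype, np.number):
            bad = table[col][pd.to_numeric(table[col], errors="coerce").isna()]
            raise SpectralIOError(
                f"{path}: non-numeric cell in column {col!r} at row "
                f"{bad.index[0] if len(bad) else '?'}"
            )
    grid = table.iloc[:, 0].to_numpy(dtype=float)
    intens = table.iloc[:, 1:].to_numpy(dtype=float).T
    ids = list(table.columns[1:])
    if grid.size >= 2 and grid[0] > grid[-1]:  # descending storage
        grid = grid[::-1].copy()
        intens = intens[:, ::-1].copy()

    meta_path = _metadata_path(path)
    if not meta_path.exists():
        raise SpectralIOError(f"metadata file {meta_path} not found")
    meta = pd.read_csv(meta_path, sep="\t", dtype={c: str for c in META_COLUMNS[:-1]})
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise SpectralIOError(f"{meta_path}: missing metadata columns {missing_cols}")
    meta = meta.set_index("spectrum_id", drop=False)
    orphans = [sid for sid in ids if sid not in meta.index]
    if orphans:
        raise SpectralIOError(
            f"{path}: spectra with no metadata row: {orphans}"
        )
    meta = meta.loc[ids].reset_index(drop=True)
    meta["replicate"] = meta["replicate"].astype(int)
    return SpectralDataset(wavenumbers=grid, intensities=intens, metadata=meta)


def _write_wide_csv(dataset: SpectralDataset, path: Path) -> list[Path]:
    cols = {"wavenumber": dataset.wavenumbers}
    for i, sid in enumerate(dataset.metadata["spectrum_id"]):
        cols[str(sid)] = dataset.intensities[i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")
    meta_path = _metadata_path(path)
    dataset.metadata[list(META_COLUMNS)].to_csv(meta_path, sep="\t", index=False)
    return [path, meta_path]


# ---------------------------------------------------------------------------
# JCAMP-DX
# ---------------------------------------------------------------------------

_SQZ = {c: v for v, c in zip(range(10), "@ABCDEFGHI")}
_SQZ.update({c: -v for v, c in zip(range(1, 10), "abcdefghi")})
_DIF = {c: v for v, c in zip(range(10), "%JKLMNOPQR")}
_DIF.update({c: -v for v, c in zip(range(1, 10), "jklmnopqr")})
# DUP digits 1-9; a DUP count n means the previous token occurs n times total.
_DUP = {c: v for v, c in zip(range(1, 10), "STUVWXYZs")}

_TOKEN_RE = re.compile(r"[@A-Ia-i%J-Rj-rS-Zs+\-]?[0-9.]*(?:[eE][+\-]?[0-9]+)?")


def _decode_ydata(line_tokens: list[str], prev: float | None):
    """Decode one XYDATA line's y tokens (after the leading x).

    Returns (values, last_value, line_ended_in_dif); ``prev`` carries the
    last ordinate across lines so DIF deltas chain correctly.
    """
    values: list[float] = []
    last = prev
    last_was_dif = False
    for tok in line_tokens:
        head = tok[0]
        if head in _SQZ:
            v = float(_SQZ[head]) if len(tok) == 1 else float(
                f"{'-' if _SQZ[head] < 0 else ''}{abs(_SQZ[head])}{tok[1:]}"
            )
            last_was_dif = False
        elif head in _DIF:
            if last is None:
                raise SpectralIOError("DIF token with no previous ordinate")
            d = float(_DIF[head]) if len(tok) == 1 else float(
                f"{'-' if _DIF[head] < 0 else ''}{abs(_DIF[head])}{tok[1:]}"
            )
            v = last + d
            last_was_dif = True
        elif head in _DUP:
            raise SpectralIOError("DUP token not expanded before decoding")
        else:
            v = float(tok)
            last_was_dif = False
        values.append(v)
        last = v
    return values, last, last_was_dif


def _decode_line(line: str, state: dict) -> None:
    """Decode one ``x y y y ...`` data line into state['x'], state['y']."""
    raw_tokens = [t for t in _TOKEN_RE.findall(line) if t]
    if not raw_tokens:
        return
    # Expand DUP tokens first (they repeat the previous token literally).
    tokens: list[str] = []
    for tok in raw_tokens:
        head = tok[0]
        if head in _DUP:
            count = int(f"{_DUP[head]}{tok[1:]}")
            if not tokens:
                raise SpectralIOError("DUP token with nothing to repeat")
            tokens.extend([tokens[-1]] * (count - 1))
        else:
            tokens.append(tok)
    try:
        x = float(tokens[0])
    except ValueError as exc:
        raise SpectralIOError(f"bad abscissa in line {line!r}") from exc
    ys, last, ended_dif = _decode_ydata(tokens[1:], state.get("last_y"))
    if state.get("in_dif", False) and ys:
        # previous line ended in DIF mode: first ordinate is an x-check value
        expected = state["last_y"]
        if abs(ys[0] - expected) > 1e-6 * max(1.0, abs(expected)):
            raise SpectralIOError(
                f"DIF checkpoint mismatch: {ys[0]} vs {expected}"
            )
        ys = ys[1:]
    state.setdefault("xs", []).append(x)
    state.setdefault("ys_per_line", []).append(ys)
    state["last_y"] = last
    state["in_dif"] = ended_dif


def _parse_block(lines: list[str], source: str) -> tuple[np.ndarray, np.ndarray, dict]:
    labels: dict[str, str] = {}
    data_lines: list[str] = []
    mode = None
    for raw in lines:
        line = raw.split("$$")[0].rstrip()
        if not line.strip():
            continue
        if line.startswith("##"):
            label, _, value = line[2:].partition("=")
            label = label.strip().upper().replace(" ", "")
            value = value.strip()
            if label == "XYDATA":
                if "X++" not in value.replace(" ", ""):
                    raise SpectralIOError(
                        f"{source}: unsupported XYDATA form {value!r}"
                    )
                mode = "xydata"
            elif label == "XYPOINTS":
                mode = "xypoints"
            elif label == "END":
                break
            else:
                labels[label] = value
        elif mode is not None:
            data_lines.append(line)
    if mode is None:
        raise SpectralIOError(f"{source}: block has no XYDATA/XYPOINTS section")

    xfactor = float(labels.get("XFACTOR", "1"))
    yfactor = float(labels.get("YFACTOR", "1"))

    if mode == "xypoints":
        xs, ys = [], []
        for line in data_lines:
            for pair in re.split(r";", line):
                pair = pair.strip()
                if not pair:
                    continue
                parts = re.split(r"[,\s]+", pair)
                if len(parts) != 2:
                    raise SpectralIOError(f"{source}: bad XY pair {pair!r}")
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
        x = np.asarray(xs) * xfactor
        y = np.asarray(ys) * yfactor
    else:
        state: dict = {}
        for line in data_lines:
            _decode_line(line, state)
        ys = [v for line_ys in state.get("ys_per_line", []) for v in line_ys]
        n = len(ys)
        if n == 0:
            raise SpectralIOError(f"{source}: empty XYDATA block")
        firstx = float(labels.get("FIRSTX", state["xs"][0] * xfactor))
        lastx = float(labels.get("LASTX", firstx))
        npoints = int(float(labels.get("NPOINTS", n)))
        if npoints != n:
            raise SpectralIOError(
                f"{source}: NPOINTS={npoints} but {n} ordinates decoded"
            )
        x = np.linspace(firstx, lastx, n)
        y = np.asarray(ys, dtype=float) * yfactor

    if x.size >= 2 and x[0] > x[-1]:
        x = x[::-1].copy()
        y = y[::-1].copy()
    if np.any(np.diff(x) <= 0):
        raise SpectralIOError(f"{source}: abscissae not strictly monotone")
    meta = {
        "spectrum_id": labels.get("TITLE", source),
        "subject_id": labels.get("$SUBJECTID", labels.get("TITLE", source)),
        "group": labels.get("$GROUP", ""),
        "batch": labels.get("$BATCH", "b0"),
        "replicate": int(float(labels.get("$REPLICATE", "0"))),
    }
    return x, y, meta


def _read_jcamp(path: Path) -> SpectralDataset:
    text = Path(path).read_text()
    blocks: list[list[str]] = []
    current: list[str] | None = None
    for line in text.splitlines():
        if line.strip().upper().startswith("##TITLE"):
            if current:
                blocks.append(current)
            current = []
        if current is not None:
            current.append(line)
            if line.strip().upper().startswith("##END"):
                blocks.append(current)
                current = None
    if current:
        blocks.append(current)
    if not blocks:
        raise SpectralIOError(f"{path}: no JCAMP-DX blocks found")
    grid = None
    rows, metas = [], []
    for bi, block in enumerate(blocks):
        x, y, meta = _parse_block(block, f"{path}[block {bi}]")
        if grid is None:
            grid = x
        elif x.shape != grid.shape or not np.allclose(x, grid, rtol=1e-9, atol=1e-9):
            raise SpectralIOError(
                f"grid mismatch: block {bi} ({meta['spectrum_id']!r}) differs "
                f"from block 0"
            )
        rows.append(y)
        metas.append(meta)
    return SpectralDataset(
        wavenumbers=grid,
        intensities=np.vstack(rows),
        metadata=pd.DataFrame(metas),
    )


def _write_jcamp(dataset: SpectralDataset, path: Path) -> list[Path]:
    lines: list[str] = []
    grid = dataset.wavenumbers
    for i in range(dataset.n_spectra):
        row = dataset.metadata.iloc[i]
        y = dataset.intensities[i]
        lines += [
            f"##TITLE={row['spectrum_id']}",
            "##JCAMP-DX=4.24",
            "##DATA TYPE=INFRARED SPECTRUM",
            "##XUNITS=1/CM",
            "##YUNITS=ABSORBANCE",
            f"##$SUBJECTID={row['subject_id']}",
            f"##$GROUP={row['group']}",
            f"##$BATCH={row['batch']}",
            f"##$REPLICATE={int(row['replicate'])}",
            "##XFACTOR=1",
            "##YFACTOR=1",
            f"##FIRSTX={grid[0]:.10g}",
            f"##LASTX={grid[-1]:.10g}",
            f"##NPOINTS={grid.size}",
            "##XYDATA=(X++(Y..Y))",
        ]
        for start in range(0, grid.size, 6):
            chunk = y[start : start + 6]
            lines.append(
                f"{grid[start]:.10g} " + " ".join(f"{v:.10g}" for v in chunk)
            )
        lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")
    return [Path(path)]


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

_FORMATS = {"wide-csv", "jcamp-dx"}


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in _FORMATS:
            raise SpectralIOError(f"unknown format {format!r}; choose from {sorted(_FORMATS)}")
        return format
    if path.suffix.lower() in {".jdx", ".dx", ".jcm"}:
        return "jcamp-dx"
    return "wide-csv"


def read_dataset(path, format: str | None = None) -> SpectralDataset:
    """Read a dataset from wide CSV (+ metadata TSV) or JCAMP-DX."""
    path = Path(path)
    if not path.exists():
        raise SpectralIOError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    return _read_wide_csv(path) if fmt == "wide-csv" else _read_jcamp(path)


def write_dataset(dataset: SpectralDataset, path, format: str | None = None) -> list[Path]:
    """Write a dataset; returns the list of files written.

    Numeric text carries >= 9 significant digits so a round trip is exact to
    representation precision.  Refuses to write an empty dataset.
    """
    if dataset.n_spectra == 0:
        raise SpectralIOError("refusing to write a dataset with zero spectra")
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    return (
        _write_wide_csv(dataset, path) if fmt == "wide-csv" else _write_jcamp(dataset, path)
    )
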