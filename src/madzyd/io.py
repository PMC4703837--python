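"""Readers and writers for the plain-text formats the pipeline touches.

BED and BED-like tables are 0-based half-open on disk and in memory.
Tabular files with a header are tab-separated; the header must contain
``scaffold``/``chrom``, ``start`` and ``end`` columns, and any further
columns (counts, signal, labels) are carried through untouched.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, TSSRecord

_COORD_ALIASES = {"chrom": "scaffold", "chr": "scaffold", "#scaffold": "scaffold"}


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, path, line_number: int, message: str):
        self.path = str(path)
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


def _validate_coords(df: pd.DataFrame, path, strict: bool):
    bad = (df["end"] <= df["start"]) | (df["start"] < 0)
    n_bad = int(bad.sum())
    if n_bad:
        line = int(df.index[bad][0]) + 1
        if strict:
            raise ParseError(path, line, "end <= start or negative start")
        df = df[~bad]
    return df, n_bad


def read_peaks(path, strict: bool = True) -> pd.DataFrame:
    """Read peaks from BED (headerless) or a tabular file with header.

    Returns a coordinate-sorted DataFrame with at least columns
    ``scaffold``, ``start``, ``end``; a headerless BED contributes ``name``
    and ``score`` when present. In strict mode any malformed line raises
    :class:`ParseError` naming the line; in tolerant mode bad lines are
    dropped and counted in ``df.attrs['n_skipped']``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first:
        return pd.DataFrame(columns=["scaffold", "start", "end"])
    has_header = any(
        tok in _COORD_ALIASES or tok == "scaffold"
        for tok in first.rstrip("\n").split("\t")
    )
    n_skipped = 0
    if has_header:
        df = pd.read_csv(path, sep="\t")
        df = df.rename(columns=_COORD_ALIASES)
        for col in ("scaffold", "start", "end"):
            if col not in df.columns:
                raise ParseError(path, 1, f"missing required column {col!r}")
        df.index = pd.RangeIndex(1, len(df) + 1)  # header occupies line 1
    else:
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    if strict:
                        raise ParseError(path, i, "fewer than 3 BED fields")
                    n_skipped += 1
                    continue
                try:
                    row = {
                        "scaffold": fields[0],
                        "start": int(fields[1]),
                        "end": int(fields[2]),
                    }
                except ValueError:
                    if strict:
                        raise ParseError(path, i, "non-integer coordinate")
                    n_skipped += 1
                    continue
                if len(fields) > 3:
                    row["name"] = fields[3]
                if len(fields) > 4:
                    row["score"] = float(fields[4])
                if len(fields) > 5:
                    row["strand"] = fields[5]
                rows.append((i, row))
        df = pd.DataFrame([r for _, r in rows], index=[i - 1 for i, _ in rows])
        if df.empty:
            df = pd.DataFrame(columns=["scaffold", "start", "end"])
    df, n_bad = _validate_coords(df, path, strict)
    n_skipped += n_bad
    df = df.sort_values(["scaffold", "start", "end"], kind="mergesort")
    df = df.reset_index(drop=True)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df.attrs["n_skipped"] = n_skipped
    return df


def write_peaks(df: pd.DataFrame, path) -> None:
    """Write a peak table as tab-separated text with header (lossless)."""
    df.to_csv(path, sep="\t", index=False)


def peaks_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    strands = df["strand"] if "strand" in df.columns else ["."] * len(df)
    return [
        GenomicInterval(s, int(a), int(b), st if st in "+-" else ".")
        for s, a, b, st in zip(df["scaffold"], df["start"], df["end"], strands)
    ]


def intervals_to_frame(intervals) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scaffold": [iv.scaffold for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
        }
    )


def read_tss_table(path) -> list[TSSRecord]:
    """TSV with header gene_id, scaffold, tss, strand -> TSSRecord list."""
    df = pd.read_csv(path, sep="\t").rename(columns=_COORD_ALIASES)
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r}: one canonical TSS per gene")
    return [
        TSSRecord(str(r.gene_id), str(r.scaffold), int(r.tss), str(r.strand))
        for r in df.itertuples()
    ]


def write_tss_table(records, path) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "scaffold": [r.scaffold for r in records],
            "tss": [r.tss for r in records],
            "strand": [r.strand for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_bedgraph(path) -> pd.DataFrame:
    """Headerless bedGraph: scaffold, start, end, value."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["scaffold", "start", "end", "value"],
        comment="#",
    )
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["scaffold", "start", "end", "value"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_segmentation(path) -> pd.DataFrame:
    """BED4 chromatin-state segmentation: scaffold, start, end, state."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["scaffold", "start", "end", "state"],
        comment="#",
    )
    return df


def write_segmentation(df: pd.DataFrame, path) -> None:
    df[["scaffold", "start", "end", "state"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_matrix(path) -> pd.DataFrame:
    """TSV matrix with row ids in the first column and a header row."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, fixed indentation, trailing newline."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def dumps_json(obj) -> str:
    return json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n"
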