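"""Readers and writers for the plain-text formats the pipeline exchanges.

All tables are tab-separated with a header line and no quoting. Coordinates
are 1-based inclusive internally; BED exports convert to 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

FRAGMENT_COLUMNS = ["tumor_id", "chrom", "position", "ligation_point", "orientation"]
INSERTION_COLUMNS = ["tumor_id", "chrom", "position", "orientation", "lp_count", "read_count"]
TUMOR_COLUMNS = ["tumor_id", "strain", "genotype"]


class FormatError(ValueError):
    """A malformed row in an input table; carries the 1-based file line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


def _first_bad_line(mask: pd.Series) -> int:
    # +2: one for the header line, one for 0- vs 1-based row index
    return int(mask.idxmax()) + 2


def _check(df: pd.DataFrame, mask: pd.Series, what: str) -> None:
    if mask.any():
        raise FormatError(f"invalid {what}", line=_first_bad_line(mask))


def write_fragments(fragments: pd.DataFrame, path: str | Path) -> None:
    fragments.to_csv(path, sep="\t", index=False, columns=FRAGMENT_COLUMNS)


def read_fragments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"tumor_id": str, "chrom": str, "orientation": str})
    missing = set(FRAGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"fragment table missing columns: {sorted(missing)}")
    df = df[FRAGMENT_COLUMNS].reset_index(drop=True)
    _check(df, df["position"] < 1, "position (must be >= 1)")
    _check(df, df["ligation_point"] < 1, "ligation_point (must be >= 1)")
    _check(df, df["ligation_point"] == df["position"], "ligation_point (equals position)")
    _check(df, ~df["orientation"].isin(["+", "-"]), "orientation (must be + or -)")
    df["position"] = df["position"].astype("int64")
    df["ligation_point"] = df["ligation_point"].astype("int64")
    return df


def write_insertions(insertions: pd.DataFrame, path: str | Path) -> None:
    insertions.to_csv(path, sep="\t", index=False, columns=INSERTION_COLUMNS)


def read_insertions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"tumor_id": str, "chrom": str, "orientation": str})
    missing = set(INSERTION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"insertion table missing columns: {sorted(missing)}")
    df = df[INSERTION_COLUMNS].reset_index(drop=True)
    _check(df, df["position"] < 1, "position (must be >= 1)")
    _check(df, df["lp_count"] < 1, "lp_count (must be >= 1)")
    _check(df, df["lp_count"] > df["read_count"], "lp_count (exceeds read_count)")
    return df


def insertions_to_bed6(insertions: pd.DataFrame) -> pd.DataFrame:
    """Single-base BED6 intervals; score = lp_count, name = tumor_id."""
    return pd.DataFrame(
        {
            "chrom": insertions["chrom"],
            "start": insertions["position"] - 1,
            "end": insertions["position"],
            "name": insertions["tumor_id"],
            "score": insertions["lp_count"],
            "strand": insertions["orientation"],
        }
    )


def write_tumor_table(tumors: pd.DataFrame, path: str | Path) -> None:
    tumors.to_csv(path, sep="\t", index=False, columns=TUMOR_COLUMNS)


def read_tumor_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(TUMOR_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"tumor table missing columns: {sorted(missing)}")
    return df[TUMOR_COLUMNS]


def write_chrom_sizes(names, lengths, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(names, lengths):
            fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.split("\t")
            if len(parts) != 2:
                raise FormatError("chrom.sizes rows need exactly name<TAB>length", line=i)
            name, length = parts[0].strip(), parts[1].strip()
            try:
                sizes[name] = int(length)
            except ValueError as exc:
                raise FormatError(f"bad chromosome length {length!r}", line=i) from exc
    return sizes


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read gene intervals from BED (>=4 cols) or minimal GFF3.

    Returns a frame with columns chrom, start, end (1-based inclusive),
    strand, name.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if path.suffix.lower() in {".gff", ".gff3"} or len(fields) == 9:
                if len(fields) != 9:
                    raise FormatError("GFF3 rows need 9 fields", line=i)
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                name = attrs.get("Name") or attrs.get("gene_name") or attrs.get("ID", "")
                rows.append((fields[0], int(fields[3]), int(fields[4]), fields[6], name))
            else:
                if len(fields) < 4:
                    raise FormatError("BED rows need at least 4 fields", line=i)
                strand = fields[5] if len(fields) >= 6 else "+"
                # BED is 0-based half-open
                rows.append((fields[0], int(fields[1]) + 1, int(fields[2]), strand, fields[3]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "name"])


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
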