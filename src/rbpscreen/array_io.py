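"""Reading and writing GenePix Results (GPR) scans in the ATF 1.0 dialect.

A GPR file is an Axon Text Format table: an ``ATF`` magic line, a line with
the optional-header-record and data-column counts, a block of optional
``"Key=Value"`` records, a column-header row, and one tab-delimited row per
spotted feature.  This module exposes each scan as an :class:`ArrayScan`
whose ``spots`` table is a pandas DataFrame — one row per spotted feature,
with grid position (block/row/column, 1-based per GPR convention), feature
identity, the 635 nm foreground and local-background median intensities
(F635, B635), the scanner quality flag, and a control marker.

Positive-control features (anti-IgG, fluorophore-conjugated albumin and the
like on commercial protein arrays) are recognised by configurable
case-insensitive glob patterns matched against the feature ID and Name;
their exact nomenclature varies between array lots, hence the pattern list
is user-overridable rather than hard-wired.
"""

from __future__ import annotations

import fnmatch
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, GPRFormatError

logger = logging.getLogger(__name__)

#: Spot columns every ArrayScan carries, in file order.
SPOT_COLUMNS = [
    "block",
    "row",
    "column",
    "protein_id",
    "protein_name",
    "f635",
    "b635",
    "flag",
    "is_control",
]

#: Case-insensitive glob patterns marking positive-control / non-protein
#: features on commercial protein arrays. Overridable per call or via config.
DEFAULT_CONTROL_PATTERNS = [
    "*control*",
    "*anti-*",
    "*igg*",
    "*alexa*",
    "*cy3*",
    "*cy5*",
    "*bsa*",
    "*buffer*",
    "*empty*",
    "*blank*",
    "*gst*",
    "*v5*",
    "*biotin*",
    "*calmodulin*",
]

# Canonical name -> accepted header aliases (lower-cased, unquoted).
_COLUMN_ALIASES: Mapping[str, tuple[str, ...]] = {
    "block": ("block",),
    "row": ("row",),
    "column": ("column", "col"),
    "protein_id": ("id",),
    "protein_name": ("name",),
    "f635": ("f635 median", "f635median"),
    "b635": ("b635 median", "b635median"),
    "flag": ("flags", "flag"),
}

_NUMERIC_FIELDS = ("block", "row", "column", "f635", "b635", "flag")


@dataclass(frozen=True)
class SpotRecord:
    """One spotted feature from a scan."""

    block: int
    row: int
    column: int
    protein_id: str
    protein_name: str
    f635: float
    b635: float
    flag: int = 0
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.block < 1 or self.row < 1 or self.column < 1:
            raise ValueError("spot coordinates are 1-based positive integers")
        if not (np.isfinite(self.f635) and np.isfinite(self.b635)):
            raise ValueError("intensities must be finite")
        if self.f635 < 0 or self.b635 < 0:
            raise ValueError("intensities must be non-negative")


@dataclass
class ArrayScan:
    """A parsed microarray scan: metadata plus a per-spot DataFrame.

    ``spots`` has one row per feature with the columns in
    :data:`SPOT_COLUMNS`. ``strand`` is ``None`` until the scan is assigned
    to an incubation ("sense" or "antisense"); hit calling requires it.
    """

    scan_id: str
    spots: pd.DataFrame
    rna_id: str = ""
    strand: str | None = None
    n_blocks: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.spots.columns]
        if missing:
            raise ValueError(f"spots table lacks columns: {missing}")
        if self.strand is not None and self.strand not in ("sense", "antisense"):
            raise ValueError(f"strand must be 'sense' or 'antisense', got {self.strand!r}")
        if not self.n_blocks:
            self.n_blocks = int(self.spots["block"].max()) if len(self.spots) else 0
        dup = self.spots.duplicated(subset=["block", "row", "column"])
        if dup.any():
            where = self.spots.loc[dup, ["block", "row", "column"]].iloc[0]
            raise GPRFormatError(
                f"duplicate spot coordinate (block={where.block}, "
                f"row={where.row}, column={where.column}) in scan {self.scan_id!r}"
            )

    def __len__(self) -> int:
        return len(self.spots)

    def iter_spots(self) -> Iterable[SpotRecord]:
        """Yield spots as :class:`SpotRecord` objects, in table order."""
        for t in self.spots.itertuples(index=False):
            yield SpotRecord(
                block=int(t.block),
                row=int(t.row),
                column=int(t.column),
                protein_id=str(t.protein_id),
                protein_name=str(t.protein_name),
                f635=float(t.f635),
                b635=float(t.b635),
                flag=int(t.flag),
                is_control=bool(t.is_control),
            )


def scan_from_spots(
    spot_records: Sequence[SpotRecord],
    scan_id: str = "",
    rna_id: str = "",
    strand: str | None = None,
) -> ArrayScan:
    """Build an :class:`ArrayScan` from individual spot records."""
    df = pd.DataFrame(
        [
            (s.block, s.row, s.column, s.protein_id, s.protein_name,
             s.f635, s.b635, s.flag, s.is_control)
            for s in spot_records
        ],
        columns=SPOT_COLUMNS,
    )
    return ArrayScan(scan_id=scan_id, spots=df, rna_id=rna_id, strand=strand)


def _unquote(text: str) -> str:
    text = text.strip()
    if len(text) >= 2 and text[0] == '"' and text[-1] == '"':
        return text[1:-1]
    return text


def match_controls(ids: pd.Series, names: pd.Series,
                   patterns: Sequence[str]) -> pd.Series:
    """Boolean mask: feature ID or Name matches any control glob pattern."""
    if not len(patterns):
        return pd.Series(False, index=ids.index)
    regex = "|".join(fnmatch.translate(p.lower()) for p in patterns)
    compiled = re.compile(regex)
    def hit(s: pd.Series) -> pd.Series:
        return s.astype(str).str.lower().str.match(compiled).fillna(False)
    return (hit(ids) | hit(names)).astype(bool)


def read_gpr(
    path: str | Path,
    control_patterns: Sequence[str] | None = None,
) -> ArrayScan:
    """Parse a GenePix Results file into an :class:`ArrayScan`.

    Accepts both ``ATF\\t1.0`` and ``ATF 1.0`` magic lines and quoted or
    unquoted fields; column-name matching is case-insensitive. Flagged spots
    are retained here (exclusion happens at aggregation time so filtering is
    auditable).

    Raises
    ------
    GPRFormatError
        Missing magic/required column, non-numeric intensity (reported with
        its data-row number), negative or non-finite intensity, or duplicate
        (block, row, column).
    """
    path = Path(path)
    if control_patterns is None:
        control_patterns = DEFAULT_CONTROL_PATTERNS

    with path.open("r", encoding="utf-8") as fh:
        magic = fh.readline().rstrip("\r\n")
        if not re.fullmatch(r'"?ATF"?[\t ]+"?1\.0"?\s*', magic + " "):
            raise GPRFormatError(f"{path.name}: not an ATF 1.0 file (first line {magic!r})")
        counts = fh.readline().split()
        if len(counts) < 2:
            raise GPRFormatError(f"{path.name}: malformed ATF count line")
        try:
            n_header = int(counts[0])
        except ValueError as exc:
            raise GPRFormatError(f"{path.name}: malformed ATF count line") from exc
        metadata: dict[str, str] = {}
        for _ in range(n_header):
            rec = _unquote(fh.readline().rstrip("\r\n"))
            if "=" in rec:
                key, _, value = rec.partition("=")
                metadata[key.strip()] = value.strip()
        header_line = fh.readline().rstrip("\r\n")
        if not header_line:
            raise GPRFormatError(f"{path.name}: missing column header row")
        raw_columns = [_unquote(c) for c in header_line.split("\t")]
        table = pd.read_csv(
            fh, sep="\t", header=None, names=raw_columns, dtype=str,
            quotechar='"', skip_blank_lines=True, engine="python",
        )

    lower = {c.lower(): c for c in raw_columns}
    selected: dict[str, str] = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                selected[canonical] = lower[alias]
                break
        else:
            pretty = {"f635": "F635 Median", "b635": "B635 Median",
                      "protein_id": "ID", "protein_name": "Name",
                      "flag": "Flags"}.get(canonical, canonical.capitalize())
            raise GPRFormatError(f"{path.name}: required column {pretty!r} not found")

    df = pd.DataFrame({k: table[v] for k, v in selected.items()})
    df["protein_id"] = df["protein_id"].map(lambda s: _unquote(str(s)))
    df["protein_name"] = df["protein_name"].map(lambda s: _unquote(str(s)))

    for col in _NUMERIC_FIELDS:
        try:
            # per-element float() is correctly rounded, so written values
            # round-trip bit-exactly (pd.to_numeric's fast path is not)
            df[col] = df[col].to_numpy().astype(np.float64)
        except (ValueError, TypeError):
            numeric = pd.to_numeric(df[col], errors="coerce")
            rownum = int(np.flatnonzero(numeric.isna())[0]) + 1
            raise GPRFormatError(
                f"{path.name}: non-numeric value {df[col].iloc[rownum - 1]!r} "
                f"in column {col!r} at data row {rownum}"
            ) from None
    for col in ("block", "row", "column", "flag"):
        df[col] = df[col].astype(int)
    for col in ("f635", "b635"):
        vals = df[col].to_numpy(float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            rownum = int(np.flatnonzero(~(np.isfinite(vals) & (vals >= 0)))[0]) + 1
            raise GPRFormatError(
                f"{path.name}: negative or non-finite {col} at data row {rownum}"
            )

    df["is_control"] = match_controls(df["protein_id"], df["protein_name"],
                                      control_patterns)
    df = df[SPOT_COLUMNS]

    n_blocks = int(metadata.get("BlockCount", 0) or 0)
    return ArrayScan(
        scan_id=path.stem,
        spots=df.reset_index(drop=True),
        rna_id=metadata.get("RNA", ""),
        strand=metadata.get("Strand") or None,
        n_blocks=n_blocks,
        metadata=metadata,
    )


def _format_number(x: float) -> str:
    # integers print without a decimal point; everything else uses Python's
    # shortest round-tripping repr so read(write(scan)) is bit-exact
    xf = float(x)
    if xf.is_integer() and abs(xf) < 1e15:
        return str(int(xf))
    return repr(xf)


def write_gpr(scan: ArrayScan, path: str | Path) -> None:
    """Write a scan as a GPR/ATF 1.0 file.

    The required columns round-trip bit-exactly through :func:`read_gpr`.
    """
    path = Path(path)
    meta = dict(scan.metadata)
    meta.setdefault("Type", "GenePix Results 3")
    meta.setdefault("BlockCount", str(scan.n_blocks))
    if scan.rna_id:
        meta.setdefault("RNA", scan.rna_id)
    if scan.strand:
        meta.setdefault("Strand", scan.strand)

    header = ["Block", "Row", "Column", "ID", "Name",
              "F635 Median", "B635 Median", "Flags"]
    lines = ["ATF\t1.0", f"{len(meta)}\t{len(header)}"]
    lines += [f'"{k}={v}"' for k, v in meta.items()]
    lines.append("\t".join(f'"{h}"' if " " in h else h for h in header))
    for t in scan.spots.itertuples(index=False):
        lines.append("\t".join([
            str(int(t.block)), str(int(t.row)), str(int(t.column)),
            f'"{t.protein_id}"', f'"{t.protein_name}"',
            _format_number(t.f635), _format_number(t.b635), str(int(t.flag)),
        ]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def pair_duplicates(scan: ArrayScan) -> dict[str, list[SpotRecord]]:
    """Group non-control spots by protein, in (block, row, column) order.

    Every protein is expected twice (the duplicate-spot array design);
    proteins with any other spot count are reported at warning level and
    kept with whatever spots they have — the aggregation step simply uses
    fewer replicates.

    Raises
    ------
    EmptyInputError
        If the scan contains no non-control protein spots.
    """
    spots = scan.spots
    noncontrol = spots.loc[~spots["is_control"]]
    if noncontrol.empty:
        raise EmptyInputError(f"scan {scan.scan_id!r} has no non-control protein spots")
    ordered = noncontrol.sort_values(["block", "row", "column"], kind="mergesort")
    out: dict[str, list[SpotRecord]] = {}
    for t in ordered.itertuples(index=False):
        out.setdefault(str(t.protein_id), []).append(SpotRecord(
            block=int(t.block), row=int(t.row), column=int(t.column),
            protein_id=str(t.protein_id), protein_name=str(t.protein_name),
            f635=float(t.f635), b635=float(t.b635), flag=int(t.flag),
            is_control=False,
        ))
    singletons = sorted(pid for pid, ss in out.items() if len(ss) != 2)
    if singletons:
        logger.warning(
            "scan %s: %d protein(s) without exactly 2 spots: %s",
            scan.scan_id, len(singletons), ", ".join(singletons[:20]),
        )
    return out
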