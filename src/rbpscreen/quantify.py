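"""Per-spot signal-over-background ratios, duplicate aggregation, Z-scores.

The quantification unit is the ratio F635/B635: foreground over local
background at the 635 nm (Cy5) wavelength. Non-binding proteins sit near a
ratio of 1; RNA-bound features are elevated. Per protein, the ratios of the
duplicate spots are summarised by their arithmetic mean and their minimum
(the minimum is what the dual-threshold hit filter tests, so one bad
duplicate vetoes a call). Z-scores standardise the per-protein mean ratios
against the global mean and sample (n-1) standard deviation over all
non-control proteins on the same array; control features are engineered
bright and are excluded so they cannot inflate the spread.

Two routes are provided: :func:`aggregate_protein` / :func:`global_zscores`
operate on explicit records, and :func:`quantify_scan` is the vectorised
whole-array path the pipeline uses; they agree exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .array_io import ArrayScan, SpotRecord
from .errors import (
    DegenerateBackgroundError,
    DegenerateDistributionError,
    EmptyInputError,
    InsufficientDataError,
)

logger = logging.getLogger(__name__)

#: Columns of the table produced by :func:`quantify_scan`.
STAT_COLUMNS = ["ratio_spot1", "ratio_spot2", "n_spots",
                "mean_ratio", "min_ratio", "zscore"]


@dataclass(frozen=True)
class ProteinStat:
    """Duplicate-spot summary for one protein on one array."""

    protein_id: str
    ratios: tuple[float, ...]
    mean_ratio: float
    min_ratio: float
    zscore: float | None = None

    def __post_init__(self) -> None:
        if self.min_ratio > self.mean_ratio + 1e-12:
            raise ValueError("min_ratio cannot exceed mean_ratio")


def spot_ratio(f635: float, b635: float) -> float:
    """Signal-over-background ratio F635/B635 for one spot.

    Raises :class:`DegenerateBackgroundError` when ``b635 <= 0`` — the ratio
    is undefined and the spot must be excluded (with a report) upstream.
    """
    if b635 <= 0:
        raise DegenerateBackgroundError(
            f"background intensity must be positive, got {b635!r}"
        )
    return float(f635) / float(b635)


def usable(spot: SpotRecord) -> bool:
    """A spot contributes to aggregation iff unflagged and with positive background."""
    return spot.flag >= 0 and spot.b635 > 0


def aggregate_protein(spots: Sequence[SpotRecord]) -> ProteinStat:
    """Summarise the duplicate spots of one protein (Z-score left unset).

    Flagged spots (``flag < 0``) and spots with non-positive background are
    skipped; at least one usable spot is required.
    """
    if not spots:
        raise EmptyInputError("no spots supplied")
    pid = spots[0].protein_id
    ratios = tuple(
        spot_ratio(s.f635, s.b635) for s in spots if usable(s)
    )
    if not ratios:
        raise EmptyInputError(f"protein {pid!r}: no usable spots (all flagged or zero background)")
    return ProteinStat(
        protein_id=pid,
        ratios=ratios,
        mean_ratio=float(np.mean(ratios)),
        min_ratio=float(np.min(ratios)),
    )


def global_zscores(stats: Iterable[ProteinStat]) -> list[ProteinStat]:
    """Standardise mean ratios to Z-scores across all proteins given.

    Z = (mean_ratio − μ) / s with μ the global mean and s the sample (n−1)
    standard deviation of per-protein mean ratios. By construction the
    returned Z-scores have mean 0 and sample SD 1.
    """
    stats = list(stats)
    if len(stats) < 2:
        raise InsufficientDataError("Z-scores require at least 2 proteins")
    means = np.array([s.mean_ratio for s in stats], dtype=float)
    mu = means.mean()
    sd = means.std(ddof=1)
    if sd == 0:
        raise DegenerateDistributionError(
            "all mean ratios identical: Z-scores undefined"
        )
    z = (means - mu) / sd
    return [replace(s, zscore=float(zi)) for s, zi in zip(stats, z)]


def quantify_scan(scan: ArrayScan, with_zscores: bool = True) -> pd.DataFrame:
    """Quantify every non-control protein on a scan (vectorised).

    Returns a DataFrame indexed by ``protein_id`` (ascending) with columns
    ``n_spots`` (usable spots), ``mean_ratio``, ``min_ratio`` and ``zscore``.
    Flagged spots, zero-background spots and fully-dropped proteins are
    reported via logging so the filtering is auditable.
    """
    spots = scan.spots
    noncontrol = spots.loc[~spots["is_control"]]
    if noncontrol.empty:
        raise EmptyInputError(f"scan {scan.scan_id!r} has no non-control protein spots")

    ok = (noncontrol["flag"].to_numpy() >= 0) & (noncontrol["b635"].to_numpy() > 0)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("scan %s: excluded %d flagged/zero-background spot(s)",
                    scan.scan_id, n_excluded)
    use = noncontrol.loc[ok]
    if use.empty:
        raise EmptyInputError(f"scan {scan.scan_id!r}: no usable spots after flag/background filter")

    use = use.sort_values(["block", "row", "column"], kind="mergesort")
    ratio = use["f635"].to_numpy(float) / use["b635"].to_numpy(float)
    per_spot = pd.DataFrame({"protein_id": use["protein_id"].to_numpy(),
                             "ratio": ratio})
    grouped = (
        per_spot.groupby("protein_id", sort=True)["ratio"]
        .agg(n_spots="size", mean_ratio="mean", min_ratio="min")
    )
    # per-duplicate ratios in grid order, for the TSV export
    per_spot["pos"] = per_spot.groupby("protein_id").cumcount()
    wide = per_spot.loc[per_spot["pos"] < 2].pivot(
        index="protein_id", columns="pos", values="ratio")
    grouped["ratio_spot1"] = wide[0] if 0 in wide.columns else np.nan
    grouped["ratio_spot2"] = wide[1] if 1 in wide.columns else np.nan
    dropped = sorted(set(noncontrol["protein_id"]) - set(grouped.index))
    if dropped:
        logger.warning("scan %s: dropped %d protein(s) with zero usable spots: %s",
                       scan.scan_id, len(dropped), ", ".join(dropped[:20]))

    out = grouped.copy()
    out["n_spots"] = out["n_spots"].astype(int)
    if with_zscores:
        means = out["mean_ratio"].to_numpy(float)
        if len(means) < 2:
            raise InsufficientDataError("Z-scores require at least 2 proteins")
        sd = means.std(ddof=1)
        if sd == 0:
            raise DegenerateDistributionError(
                f"scan {scan.scan_id!r}: all mean ratios identical, Z undefined"
            )
        out["zscore"] = (means - means.mean()) / sd
    else:
        out["zscore"] = np.nan
    return out[STAT_COLUMNS]


def stats_to_records(table: pd.DataFrame) -> list[ProteinStat]:
    """Convert a :func:`quantify_scan` table to :class:`ProteinStat` records."""
    return [
        ProteinStat(
            protein_id=str(pid),
            ratios=tuple(float(r) for r in (row.ratio_spot1, row.ratio_spot2)
                         if pd.notna(r)),
            mean_ratio=float(row.mean_ratio),
            min_ratio=float(row.min_ratio),
            zscore=None if pd.isna(row.zscore) else float(row.zscore),
        )
        for pid, row in table.iterrows()
    ]


def write_stats_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Export a quantification table as TSV (protein_id + stat columns)."""
    table.to_csv(path, sep="\t", index_label="protein_id",
                 float_format="%.10g")
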