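"""Hit calling, antisense subtraction, interaction matrix and clustering.

A protein is a significant binder of an RNA when *both* duplicate spots are
at least ``fold_min`` (default 2.5) over local background — i.e. the
minimum duplicate ratio passes — *and* the per-protein mean ratio lies at
least ``z_min`` (default 3.0) standard deviations above the array's global
mean. Both comparisons are inclusive. Sequence-nonspecific binders are
removed by subtracting each locus's antisense hit set from its sense hit
set; the surviving sense-specific calls across all probed RNAs form a
binary proteins x RNAs interaction matrix. "Common binders" are proteins
significant in at least ``min_frac`` (default 75%) of all incubations,
counting every sense and antisense scan as a trial.

Matrix rows/columns are clustered agglomeratively (Jaccard distance on the
binary profiles, average linkage) purely for display ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .errors import EmptyInputError, PairingError, ParameterError
from .quantify import ProteinStat

__all__ = [
    "HitTable",
    "InteractionMatrix",
    "call_hits",
    "sense_specific",
    "build_matrix",
    "common_binders",
    "cluster_matrix",
]


@dataclass
class HitTable:
    """Significant proteins for one RNA incubation, with thresholds used.

    ``stats`` holds one row per hit (index protein_id, columns at least
    mean_ratio / min_ratio / zscore); ``hits`` is the protein-id set.
    """

    rna_id: str
    strand: str
    stats: pd.DataFrame
    z_min: float
    fold_min: float

    def __post_init__(self) -> None:
        if self.strand not in ("sense", "antisense"):
            raise ValueError(f"strand must be 'sense' or 'antisense', got {self.strand!r}")
        bad = (self.stats["zscore"] < self.z_min) | (self.stats["min_ratio"] < self.fold_min)
        if bad.any():
            raise ValueError("HitTable rows must satisfy the recorded thresholds")

    @property
    def hits(self) -> frozenset[str]:
        return frozenset(self.stats.index.astype(str))

    def __len__(self) -> int:
        return len(self.stats)


@dataclass
class InteractionMatrix:
    """Binary proteins x RNAs matrix of sense-specific interactions.

    ``values`` is a 0/1 DataFrame (rows = proteins with >= 1 interaction,
    lexicographic; columns = RNA ids in input order). ``row_order`` /
    ``col_order`` are permutations set by :func:`cluster_matrix`.
    """

    values: pd.DataFrame
    row_order: list[int] | None = field(default=None)
    col_order: list[int] | None = field(default=None)

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index.astype(str))

    @property
    def rnas(self) -> list[str]:
        return list(self.values.columns.astype(str))

    @property
    def n_interactions(self) -> int:
        return int(self.values.to_numpy().sum())

    def ordered(self) -> pd.DataFrame:
        """The matrix with clustering order applied (identity if unset)."""
        df = self.values
        if self.row_order is not None:
            df = df.iloc[self.row_order]
        if self.col_order is not None:
            df = df.iloc[:, self.col_order]
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="protein_id")


def _as_stats_frame(stats) -> pd.DataFrame:
    if isinstance(stats, pd.DataFrame):
        df = stats
    else:
        records: Iterable[ProteinStat] = stats
        df = pd.DataFrame(
            [(s.protein_id, s.mean_ratio, s.min_ratio, s.zscore) for s in records],
            columns=["protein_id", "mean_ratio", "min_ratio", "zscore"],
        ).set_index("protein_id")
    if df["zscore"].isna().any():
        raise ValueError("Z-scores must be set before hit calling")
    return df


def call_hits(
    stats,
    z_min: float = 3.0,
    fold_min: float = 2.5,
    rna_id: str = "",
    strand: str = "sense",
) -> HitTable:
    """Apply the dual significance filter to per-protein statistics.

    ``stats`` is either a :func:`~rbpscreen.quantify.quantify_scan` table or
    an iterable of :class:`~rbpscreen.quantify.ProteinStat` with Z-scores
    set. A protein is a hit iff ``min_ratio >= fold_min`` (every duplicate
    spot passes the fold cutoff) and ``zscore >= z_min``; both inclusive.
    """
    if z_min <= 0 or fold_min <= 0:
        raise ParameterError(
            f"thresholds must be positive (z_min={z_min}, fold_min={fold_min})"
        )
    df = _as_stats_frame(stats)
    mask = (df["min_ratio"] >= fold_min) & (df["zscore"] >= z_min)
    return HitTable(
        rna_id=rna_id,
        strand=strand,
        stats=df.loc[mask].sort_index(),
        z_min=float(z_min),
        fold_min=float(fold_min),
    )


def sense_specific(sense: HitTable, antisense: HitTable) -> HitTable:
    """Remove sequence-nonspecific binders: sense hits minus antisense hits."""
    if sense.rna_id != antisense.rna_id:
        raise PairingError(
            f"locus mismatch: sense {sense.rna_id!r} vs antisense {antisense.rna_id!r}"
        )
    if sense.strand != "sense" or antisense.strand != "antisense":
        raise PairingError("expected one sense and one antisense table")
    if (sense.z_min, sense.fold_min) != (antisense.z_min, antisense.fold_min):
        raise PairingError("sense and antisense tables were called at different thresholds")
    keep = sorted(sense.hits - antisense.hits)
    return HitTable(
        rna_id=sense.rna_id,
        strand="sense",
        stats=sense.stats.loc[keep],
        z_min=sense.z_min,
        fold_min=sense.fold_min,
    )


def build_matrix(tables: Sequence[HitTable]) -> InteractionMatrix:
    """Assemble sense-specific hit tables into a binary interaction matrix.

    Rows are the union of hit proteins in lexicographic order (the
    deterministic pre-clustering order); columns follow the input table
    order. Proteins with no interaction are never rows, so no all-zero rows
    exist.
    """
    if not tables:
        raise EmptyInputError("no hit tables supplied")
    rnas = [t.rna_id for t in tables]
    if len(set(rnas)) != len(rnas):
        dupes = sorted({r for r in rnas if rnas.count(r) > 1})
        raise ValueError(f"duplicate rna_id across tables: {dupes}")
    proteins = sorted(set().union(*(t.hits for t in tables)))
    values = pd.DataFrame(0, index=pd.Index(proteins, name="protein_id"),
                          columns=rnas, dtype=int)
    for t in tables:
        values.loc[sorted(t.hits), t.rna_id] = 1
    return InteractionMatrix(values=values)


def common_binders(
    tables: Sequence[HitTable],
    min_frac: float = 0.75,
) -> pd.DataFrame:
    """Rank proteins by the percentage of incubations in which they are hits.

    Every table (sense and antisense alike) counts as one trial; the
    denominator is ``len(tables)``. Returns a DataFrame with columns
    ``n_hits`` and ``percent``, keeping proteins with
    ``percent >= 100 * min_frac``, sorted by percent descending then
    protein_id ascending.
    """
    if not tables:
        raise EmptyInputError("no hit tables supplied")
    if not (0 < min_frac <= 1):
        raise ParameterError(f"min_frac must be in (0, 1], got {min_frac}")
    n = len(tables)
    counts: dict[str, int] = {}
    for t in tables:
        for pid in t.hits:
            counts[pid] = counts.get(pid, 0) + 1
    df = pd.DataFrame(
        {"n_hits": pd.Series(counts, dtype=int)},
    )
    df.index.name = "protein_id"
    df["percent"] = 100.0 * df["n_hits"] / n
    df = df.loc[df["percent"] >= 100.0 * min_frac]
    df = df.sort_values(["percent", "protein_id"], ascending=[False, True],
                        kind="mergesort")
    return df


def _cluster_order(profiles: np.ndarray) -> list[int]:
    n = profiles.shape[0]
    if n <= 1:
        return list(range(n))
    dist = pdist(profiles.astype(bool), metric="jaccard")
    tree = linkage(dist, method="average")
    return [int(i) for i in leaves_list(tree)]


def cluster_matrix(matrix: InteractionMatrix) -> InteractionMatrix:
    """Order rows and columns by agglomerative clustering (for display).

    Jaccard distance on the binary profiles with average linkage; input rows
    are already in lexicographic order so equal-profile ties resolve by
    label, and the output is deterministic for identical input.
    """
    if matrix.values.empty:
        raise EmptyInputError("cannot cluster an empty matrix")
    arr = matrix.values.to_numpy()
    return InteractionMatrix(
        values=matrix.values,
        row_order=_cluster_order(arr),
        col_order=_cluster_order(arr.T),
    )


def save_heatmap(matrix: InteractionMatrix, path: str | Path) -> None:
    """Render the (clustered) binary matrix as a simple heat-map image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = matrix.ordered()
    fig, ax = plt.subplots(
        figsize=(max(3, 0.5 * len(df.columns)), max(3, 0.04 * len(df)))
    )
    ax.imshow(df.to_numpy(), aspect="auto", cmap="Greys", interpolation="nearest")
    ax.set_xticks(range(len(df.columns)), df.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_xlabel("RNA")
    ax.set_ylabel(f"{len(df)} proteins")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
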