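"""Replicate concordance, overlap significance, and term enrichment.

All significance here is one-sided over-representation under sampling
without replacement: the probability that at least the observed number of
"marked" proteins lands in a draw of the hit-set size from the finite
universe of spotted proteins — the hypergeometric upper tail, identical to
a one-sided Fisher exact test on the 2x2 table. The same tail probability
serves two roles: the significance of the overlap between two independent
incubations' hit sets, and the enrichment of an annotation term (protein
family domain, GO category...) within a hit set against the spotted-protein
universe. Multiple testing across terms is controlled with the
Benjamini-Hochberg step-up adjustment.

The EASE variant (one observed hit removed before computing the tail) is
available opt-in; it is the conservative score popularised by the DAVID
annotation service.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .array_io import ArrayScan
from .errors import (
    DegenerateDistributionError,
    InsufficientDataError,
    ParameterError,
)
from .quantify import quantify_scan

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationMap",
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "replicate_concordance",
    "overlap_significance",
    "term_enrichment",
    "benjamini_hochberg",
]


@dataclass
class AnnotationMap:
    """Term -> protein-id annotation, e.g. Pfam domains or GO categories.

    ``terms`` maps term_id to the set of annotated protein ids;
    ``term_names`` optionally maps term_id to a human-readable label.
    """

    namespace: str
    terms: dict[str, frozenset[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path, namespace: str = "",
                 labels_path: str | Path | None = None) -> "AnnotationMap":
        """Load from a 2-column TSV (term_id, protein_id), optional label TSV."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["term_id", "protein_id"], dtype=str)
        terms = {
            str(t): frozenset(g["protein_id"].astype(str))
            for t, g in df.groupby("term_id", sort=True)
        }
        names: dict[str, str] = {}
        if labels_path is not None:
            lab = pd.read_csv(labels_path, sep="\t", header=None,
                              names=["term_id", "label"], dtype=str)
            names = dict(zip(lab["term_id"], lab["label"]))
        return cls(namespace=namespace or Path(path).stem, terms=terms,
                   term_names=names)

    def restrict_to(self, universe: frozenset[str] | set[str]) -> tuple["AnnotationMap", frozenset[str]]:
        """Intersect every term with the universe; return (map, unmapped ids)."""
        universe = frozenset(universe)
        unmapped = frozenset().union(*self.terms.values(), frozenset()) - universe
        terms = {t: members & universe for t, members in self.terms.items()}
        if unmapped:
            logger.info("%s: %d annotated protein(s) outside the universe dropped",
                        self.namespace, len(unmapped))
        return AnnotationMap(self.namespace, terms, self.term_names), unmapped


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's enrichment: counts, raw p and BH-adjusted p."""

    term_id: str
    k: int      # hit proteins carrying the term
    K: int      # universe proteins carrying the term
    n: int      # hit-set size
    N: int      # universe size
    p: float
    p_adj: float
    term_name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError("invalid contingency counts")


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n): one-sided over-representation.

    Equivalent to the one-sided Fisher exact p of the 2x2 table
    [[k, K-k], [n-k, N-K-n+k]].
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ParameterError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def replicate_concordance(a: ArrayScan, b: ArrayScan) -> tuple[float, float]:
    """Pearson correlation of per-protein mean ratios between two replicates.

    Computed over all non-control proteins quantifiable in both scans (not
    hits only). Returns ``(r, r_squared)``.
    """
    qa = quantify_scan(a, with_zscores=False)["mean_ratio"]
    qb = quantify_scan(b, with_zscores=False)["mean_ratio"]
    joined = pd.concat([qa, qb], axis=1, join="inner", keys=["a", "b"]).dropna()
    if len(joined) < 3:
        raise InsufficientDataError(
            f"only {len(joined)} shared quantifiable protein(s); need >= 3"
        )
    x = joined["a"].to_numpy(float)
    y = joined["b"].to_numpy(float)
    if x.std() == 0 or y.std() == 0:
        raise DegenerateDistributionError("zero variance in one replicate's ratios")
    r = float(sps.pearsonr(x, y).statistic)
    return r, r * r


def overlap_significance(hits_a: set[str] | frozenset[str],
                         hits_b: set[str] | frozenset[str],
                         universe_n: int) -> float:
    """One-sided Fisher exact p for the overlap of two hit sets.

    The observed overlap is tested against the hypergeometric null of
    drawing ``|hits_b|`` proteins from a universe of ``universe_n`` that
    contains ``|hits_a|`` marked ones: p = P(X >= |overlap|).
    """
    union = set(hits_a) | set(hits_b)
    if universe_n < len(union):
        raise ParameterError(
            f"universe ({universe_n}) smaller than the union of hit sets ({len(union)})"
        )
    k = len(set(hits_a) & set(hits_b))
    return hypergeom_upper_tail(k, universe_n, len(hits_a), len(hits_b))


def term_enrichment(
    hits: set[str] | frozenset[str],
    universe: set[str] | frozenset[str],
    ann: AnnotationMap,
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of annotation terms within a hit set.

    The background is the spotted-protein universe. Per term with K > 0
    universe members, p = P(X >= k) (upper tail); with ``ease=True`` the
    conservative EASE variant replaces k by k-1 (floored at 0). Terms with
    no universe members are skipped with a report. Results are sorted by
    raw p ascending (term_id as tie-break) and carry BH-adjusted p across
    all tested terms.
    """
    hits = frozenset(hits)
    universe = frozenset(universe)
    if not hits <= universe:
        raise ParameterError("hit set must be a subset of the universe")
    restricted, _ = ann.restrict_to(universe)
    N, n = len(universe), len(hits)
    rows = []
    for term_id in sorted(restricted.terms):
        members = restricted.terms[term_id]
        K = len(members)
        if K == 0:
            logger.info("term %s has no universe members; skipped", term_id)
            continue
        k = len(members & hits)
        k_eff = max(k - 1, 0) if ease else k
        p = hypergeom_upper_tail(k_eff, N, K, n) if n else 1.0
        rows.append((term_id, k, K, p))
    if not rows:
        return []
    p_adj = benjamini_hochberg([r[3] for r in rows])
    results = [
        EnrichmentResult(term_id=t, k=k, K=K, n=n, N=N, p=p, p_adj=pa,
                         term_name=ann.term_names.get(t, ""))
        for (t, k, K, p), pa in zip(rows, p_adj)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def benjamini_hochberg(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(list(pvals), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ParameterError("p-values must lie in [0, 1]")
    return [float(x) for x in multipletests(arr, method="fdr_bh")[1]]


def enrichment_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (one row per term) for TSV export."""
    return pd.DataFrame(
        [(r.term_id, r.term_name, r.k, r.K, r.n, r.N, r.p, r.p_adj)
         for r in results],
        columns=["term_id", "term_name", "k", "K", "n", "N", "p", "p_adj"],
    )
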