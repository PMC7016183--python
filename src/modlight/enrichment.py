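"""Enrichment and comparison statistics for predicted gene lists.

Hypergeometric (Fisher) enrichment of a top-ranked gene list against a
disease gene set, Fisher's combined probability across diseases, the exact
binomial comparison test used for embedding/control comparisons, and
closest-gene assignment of SNPs from BED intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "hypergeom_enrichment",
    "fisher_combined",
    "binomial_comparison",
    "closest_gene_map",
    "read_bed",
]


@dataclass
class GeneSet:
    """Named, deduplicated gene collection (insertion order kept)."""

    name: str
    genes: tuple[str, ...]

    def __init__(self, name: str, genes: Iterable[str], description: str = ""):
        self.name = name
        self.description = description
        seen: list[str] = []
        known: set[str] = set()
        for g in genes:
            g = str(g)
            if g not in known:
                known.add(g)
                seen.append(g)
        self.genes = tuple(seen)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


def read_gmt(path) -> list[GeneSet]:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets.append(GeneSet(parts[0], parts[2:], description=parts[1]))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            desc = getattr(gs, "description", "") or "na"
            fh.write("\t".join([gs.name, desc, *gs.genes]) + "\n")


@dataclass
class EnrichmentResult:
    """2×2 overlap test of a top list against a gene set in a universe."""

    k: int            # overlap
    n: int            # top-list size
    K: int            # gene-set size (within universe)
    N: int            # universe size
    p_value: float    # hypergeometric upper tail P(X >= k)
    odds_ratio: float

    @property
    def enrichment_score(self) -> float:
        return -math.log10(self.p_value)


def hypergeom_enrichment(
    top: Sequence[str], gene_set: GeneSet, universe: Sequence[str]
) -> EnrichmentResult:
    """Upper-tail hypergeometric (Fisher) test of the overlap.

    The gene set is intersected with the universe before testing.  The odds
    ratio is the 2×2 cross-product; when a denominator cell is zero a
    Haldane continuity correction of 0.5 is added to every cell.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    top_set = set(top)
    if not top_set:
        raise ValueError("empty top list")
    if not top_set <= uni:
        raise ValueError("top list must be a subset of the universe")
    hits = set(gene_set.genes) & uni
    N, K, n = len(uni), len(hits), len(top_set)
    k = len(top_set & hits)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    a, b, c, d = k, n - k, K - k, N - n - K + k
    if b == 0 or c == 0:
        if a * d == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            odds = (a * d) / (b * c)
        else:
            odds = float("inf")
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(k, n, K, N, p, float(odds))


def fisher_combined(p_values: Sequence[float]) -> float:
    """Fisher's method: -2 sum(ln p) ~ chi-square with 2m df."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    statistic = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(statistic, 2 * p.size))


def binomial_comparison(
    n_success: int,
    n_trials: int,
    tail: str = "geq",
    null_p: float = 0.5,
) -> tuple[float, float]:
    """Exact binomial tail test and simple odds n/(N-n).

    ``geq`` gives P(X >= n_success); ``gt`` gives P(X > n_success).  The
    odds are +inf when every trial succeeds.
    """
    if not 0 <= n_success <= n_trials:
        raise ValueError(f"need 0 <= n_success <= n_trials, got {n_success}/{n_trials}")
    if tail == "geq":
        p = float(stats.binom.sf(n_success - 1, n_trials, null_p))
    elif tail == "gt":
        p = float(stats.binom.sf(n_success, n_trials, null_p))
    else:
        raise ValueError(f"tail must be 'geq' or 'gt', got {tail!r}")
    odds = float("inf") if n_success == n_trials else n_success / (n_trials - n_success)
    return min(p, 1.0), odds


def read_bed(path) -> pd.DataFrame:
    """Browser-style BED (3+ columns, half-open 0-based) into a frame.

    Column 4 (name) defaults to ``chrom:start-end`` when absent.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed coordinates")
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{start}-{end}"
            rows.append((parts[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def closest_gene_map(snps: pd.DataFrame, genes: pd.DataFrame,
                     name: str = "closest_genes") -> GeneSet:
    """Closest gene to each SNP; distance 0 when overlapping, ties kept.

    Inputs are BED-style frames (chrom, start, end, name) with half-open
    0-based coordinates; the gap between [s1, e1) and [s2, e2) is
    max(0, s1 - e2, s2 - e1).  The union of closest genes over all SNPs is
    returned in SNP order.
    """
    for df, label in ((snps, "snps"), (genes, "genes")):
        if not {"chrom", "start", "end", "name"} <= set(df.columns):
            raise ValueError(f"{label} frame needs chrom/start/end/name columns")
    chosen: list[str] = []
    by_chrom = {c: g.reset_index(drop=True) for c, g in genes.groupby("chrom")}
    for snp in snps.itertuples(index=False):
        g = by_chrom.get(snp.chrom)
        if g is None or g.empty:
            continue
        gap = np.maximum(
            0,
            np.maximum(snp.start - g["end"].to_numpy(), g["start"].to_numpy() - snp.end),
        )
        best = gap.min()
        chosen.extend(g["name"].to_numpy()[gap == best])
    return GeneSet(name, chosen)
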