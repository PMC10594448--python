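"""Hypergeometric overrepresentation analysis (ORA) with BH-FDR.

Each gene set is tested for overlap enrichment between a query gene
list (here, the top-ranked target genes) and a reference universe
(a protein-coding reference list).  With N universe genes, m of them in
the set, q in the query and k in both, the p-value is the upper tail
P[X >= k] for X ~ Hypergeometric(N, m, q) — the one-sided Fisher exact
test of the 2x2 overlap table.  FDR is Benjamini-Hochberg, computed per
collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import GeneSet, ValidationError

__all__ = ["ORAResult", "read_gmt", "ora", "bh_fdr", "significant", "GMTParseError"]

logger = logging.getLogger(__name__)


class GMTParseError(ValueError):
    """A GMT line could not be parsed; message carries the line number."""


@dataclass(frozen=True)
class ORAResult:
    """One gene set's overrepresentation test result.

    ``enrichment_ratio`` is (k/q) / (m/N), the observed-over-expected
    overlap.
    """

    set_name: str
    k: int
    m: int
    q: int
    N: int
    p_value: float
    fdr: float
    enrichment_ratio: float


def read_gmt(path) -> List[GeneSet]:
    """Read a GMT file: one tab-separated set per line.

    Fields are set name, description, then one or more genes; duplicate
    genes within a line are dropped, duplicate set names are an error.
    """
    sets: List[GeneSet] = []
    seen: set = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path} line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *genes = fields
            if name in seen:
                raise GMTParseError(f"{path} line {lineno}: duplicate set name {name!r}")
            seen.add(name)
            genes = [g for g in genes if g]
            sets.append(GeneSet(name, desc, frozenset(genes)))
    return sets


def bh_fdr(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p_values: all values must be in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return list(adj)


def ora(
    query: Iterable[str],
    universe: Iterable[str],
    sets: Sequence[GeneSet],
    min_size: int = 5,
    max_size: int = 2000,
) -> List[ORAResult]:
    """Test every gene set for overrepresentation in ``query``.

    Sets are restricted to the universe and filtered to sizes in
    [min_size, max_size]; query genes outside the universe are dropped
    (with a logged count).  Results are sorted by p-value ascending,
    ties by set name; FDR is BH across all tested sets.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValidationError("universe: must be non-empty")
    query_all = set(query)
    query_set = query_all & universe_set
    dropped = len(query_all) - len(query_set)
    if dropped:
        logger.info("ora: dropped %d query genes outside the universe", dropped)
    if not query_set:
        raise ValidationError("query: empty after intersection with universe")
    N, q = len(universe_set), len(query_set)
    rows = []
    for s in sets:
        members = s.genes & universe_set
        m = len(members)
        if not (min_size <= m <= max_size):
            continue
        k = len(members & query_set)
        p = float(hypergeom.sf(k - 1, N, m, q))
        er = (k / q) / (m / N)
        rows.append((s.name, k, m, p, er))
    fdrs = bh_fdr([r[3] for r in rows])
    results = [
        ORAResult(name, k, m, q, N, p, fdr, er)
        for (name, k, m, p, er), fdr in zip(rows, fdrs)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def significant(results: Sequence[ORAResult], fdr_threshold: float = 0.1
                ) -> List[ORAResult]:
    """Rows with fdr strictly below the threshold, order preserved."""
    return [r for r in results if r.fdr < fdr_threshold]


def export_ora(results: Sequence[ORAResult], path) -> None:
    """Write ORA results as CSV."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["set_name", "k", "m", "q", "N", "p_value", "fdr",
                    "enrichment_ratio"])
        for r in results:
            w.writerow([r.set_name, r.k, r.m, r.q, r.N,
                        repr(r.p_value), repr(r.fdr), repr(r.enrichment_ratio)])
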