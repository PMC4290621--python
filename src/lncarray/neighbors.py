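"""Neighbor-gene discovery and term over-representation testing.

Protein-coding genes whose bodies lie within a +/- window (default 10 kb)
of an lncRNA are its neighbors; neighbor gene sets are then tested for
term enrichment with a one-sided hypergeometric test, significant at
raw p < 0.01 with an enrichment ratio of at least 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .core import LncArrayError, TermMapping


@dataclass(frozen=True)
class NeighborPair:
    lncrna_id: str
    gene_id: str
    distance_bp: int


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int
    n: int
    K: int
    N: int
    enrichment: float
    p: float


def find_neighbors(lncrnas, genes, window: int = 10_000):
    """All (lncRNA, gene) pairs whose gene-body gap is <= window bp.

    Strand-agnostic; overlap counts as distance 0 and the bound is
    inclusive (a gap of exactly ``window`` is still a neighbor).
    """
    if window < 0:
        raise LncArrayError("window must be >= 0")
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.interval.start)
    pairs = []
    for lnc in lncrnas:
        for gene in by_chrom.get(lnc.interval.chrom, ()):
            if gene.interval.start > lnc.interval.end + window:
                break
            gap = lnc.interval.gap_to(gene.interval)
            if gap is not None and gap <= window:
                pairs.append(NeighborPair(lnc.transcript_id, gene.gene_id, gap))
    return pairs


def enrich(selected, mapping: TermMapping, p_max: float = 0.01,
           min_enrichment: float = 2.0):
    """Hypergeometric over-representation of each term in ``selected`` genes.

    Returns (significant results, full unfiltered table).  p is the
    upper-tail probability P(X >= k) of drawing k term genes in a sample
    of n from a universe of N containing K term genes; the enrichment
    ratio is (k/n)/(K/N).  No multiple-testing correction is applied (the
    procedure filters on raw p with an enrichment floor).
    """
    selected = set(selected)
    stray = selected - mapping.universe
    if stray:
        raise LncArrayError(f"selected genes outside universe: {sorted(stray)[:5]}")
    N, n = len(mapping.universe), len(selected)
    results = []
    for term, genes in sorted(mapping.terms.items()):
        K = len(genes)
        k = len(selected & genes)
        expected = K / N if N else 0.0
        ratio = (k / n) / expected if (n and expected) else 0.0
        p = float(hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        results.append(EnrichmentResult(term, k, n, K, N, ratio, p))
    results.sort(key=lambda r: (r.p, r.term_id))
    significant = [r for r in results
                   if r.p < p_max and r.enrichment >= min_enrichment]
    return significant, results


def neighbors_to_frame(pairs) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.lncrna_id, p.gene_id, p.distance_bp) for p in pairs],
        columns=["lncrna_id", "gene_id", "distance_bp"])


def enrichment_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.term_id, r.k, r.n, r.K, r.N, r.enrichment, r.p) for r in results],
        columns=["term_id", "k", "n", "K", "N", "enrichment", "p"])
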