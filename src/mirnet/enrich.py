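"""Target-gene mapping and hypergeometric gene-set over-representation.

A file-driven over-representation test: miRNA sets map to their validated
target genes via a packaged or user-supplied target map, and the pooled
genes are tested against named gene sets with the hypergeometric upper
tail, Bonferroni-corrected across the sets tested. The universe defaults
to all genes appearing in the collection; results are flagged significant
at Bonferroni-corrected p ≤ 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

from mirnet.io import GeneSetCollection, TargetMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    p_bonferroni: float
    overlapping_genes: tuple[str, ...]

    @property
    def significant(self) -> bool:
        return self.p_bonferroni <= 0.05


def targets_of(mirnas: set[str], target_map: TargetMap,
               mode: str = "union"):
    """Validated target genes of a miRNA set.

    ``union`` pools genes across miRNAs into one symbol set; ``per_mirna``
    returns a dict preserving the miRNA → genes attribution. miRNAs absent
    from the map are logged and skipped.
    """
    if mode not in ("union", "per_mirna"):
        raise ValueError(f"unknown mode {mode!r}")
    missing = sorted(m for m in mirnas if m not in target_map)
    if missing:
        logger.info("%d miRNA(s) absent from target map: %s",
                    len(missing), ", ".join(missing[:5]))
    present = sorted(m for m in mirnas if m in target_map)
    if mode == "per_mirna":
        return {m: set(target_map[m]) for m in present}
    pooled: set[str] = set()
    for m in present:
        pooled |= target_map[m]
    return pooled


def enrich(query_genes: set[str],
           sets: GeneSetCollection) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query_genes`` in each set.

    For a universe of M genes, a set of K and a query of n drawn genes
    with k overlapping, p = P(X ≥ k) for X ~ Hypergeom(M, K, n).
    Bonferroni multiplies by the number of sets tested (capped at 1).
    Query genes outside the universe are dropped with a warning. Results
    are sorted by p ascending, ties by set name.
    """
    if not query_genes:
        raise ValueError("empty query gene set")
    query = set(query_genes)
    outside = query - sets.universe
    if outside:
        logger.warning("%d query gene(s) outside the universe dropped: %s",
                       len(outside), ", ".join(sorted(outside)[:5]))
        query -= outside
    if not query:
        raise ValueError("no query genes remain inside the universe")
    m_univ = sets.universe_size
    n_query = len(query)
    n_tests = len(sets.sets)
    results = []
    for name, members in sets.sets.items():
        overlap = query & members
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, m_univ, len(members), n_query))
        p = min(1.0, p)
        results.append(EnrichmentResult(
            set_name=name, overlap=k, set_size=len(members),
            query_size=n_query, universe_size=m_univ,
            p_value=p, p_bonferroni=min(1.0, p * n_tests),
            overlapping_genes=tuple(sorted(overlap))))
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def enrichment_to_frame(results: list[EnrichmentResult]):
    import pandas as pd

    rows = [{**{f: getattr(r, f) for f in
                ("set_name", "overlap", "set_size", "query_size",
                 "universe_size", "p_value", "p_bonferroni")},
             "overlapping_genes": ",".join(r.overlapping_genes)}
            for r in results]
    return pd.DataFrame(rows)
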