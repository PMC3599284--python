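"""Hypergeometric overrepresentation of a gene list against a collection.

Used to interpret gene lists produced by external network tools: for each
gene set, the upper-tail probability that a random draw of ``len(gene_list)``
genes from the universe contains at least the observed overlap. Set sizes are
counted within the supplied universe (not the raw GMT) — universe mismatch is
the dominant source of irreproducibility in enrichment statistics, so the
universe is an explicit input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

from .io_formats import GeneSetCollection

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverrepresentationResult:
    set_name: str
    overlap: int
    list_size: int
    set_size_in_universe: int
    universe_size: int
    p_value: float  # P[X >= overlap], overlap included


def hypergeometric_overrepresentation(gene_list, collection: GeneSetCollection,
                                      universe) -> list[OverrepresentationResult]:
    """Upper-tail hypergeometric p-value of each set's overlap with the list.

    Genes in the list absent from the universe are dropped with a warning.
    Results are sorted by p-value ascending, ties broken by set name.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("gene universe is empty")
    query = set(gene_list)
    outside = query - universe_set
    if outside:
        log.warning("dropping %d query gene(s) not in the universe, e.g. %r",
                    len(outside), sorted(outside)[:3])
        query &= universe_set
    n_universe = len(universe_set)
    n_list = len(query)

    results = []
    for s in collection:
        in_universe = s.member_set & universe_set
        k_set = len(in_universe)
        overlap = len(in_universe & query)
        # P[X >= overlap] for X ~ Hypergeom(n_universe, k_set, n_list)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, k_set, n_list))
        p = min(max(p, 0.0), 1.0)
        results.append(OverrepresentationResult(
            set_name=s.name, overlap=overlap, list_size=n_list,
            set_size_in_universe=k_set, universe_size=n_universe, p_value=p))
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results
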