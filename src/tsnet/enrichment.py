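"""Gene-set over-representation analysis of regulatory networks.

Each network's gene list (target genes plus factor genes) is tested against
every set of a collection with a one-sided Fisher's exact test (the
hypergeometric upper tail on the 2x2 overlap table), Benjamini-Hochberg
corrected within the collection. GO-style collections are size-filtered to
10-100 genes per term before testing; pathway-style (KEGG) collections are
used unfiltered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

GO_SIZE_RANGE = (10, 100)
Q_ALPHA = 0.05
GO_P_REPORT = 1e-4


@dataclass
class GeneSetCollection:
    name: str
    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self):
        empty = [n for n, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"collection {self.name}: empty sets {empty}")
        if not self.universe:
            self.universe = set().union(*self.sets.values())


def read_gmt(path, name: str = "", universe: set[str] | None = None) -> GeneSetCollection:
    """GMT: one set per line, tab-separated: name, description, genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return GeneSetCollection(name or str(path), sets, universe or set())


def filter_gene_sets(
    collection: GeneSetCollection,
    min_size: int = GO_SIZE_RANGE[0],
    max_size: int = GO_SIZE_RANGE[1],
) -> GeneSetCollection:
    """Keep sets whose size (within the universe) is in [min_size, max_size]."""
    kept = {}
    for name, genes in collection.sets.items():
        eff = genes & collection.universe
        if min_size <= len(eff) <= max_size:
            kept[name] = eff
    log.info("filter_gene_sets(%s): kept %d / %d sets",
             collection.name, len(kept), len(collection.sets))
    return GeneSetCollection(collection.name, kept, set(collection.universe))


@dataclass
class EnrichmentResult:
    collection: str
    network_id: int | str
    set_name: str
    overlap: int
    network_only: int
    set_only: int
    neither: int
    p_value: float
    q_value: float = float("nan")


def fisher_test(network_genes: set, gene_set: set, universe: set) -> EnrichmentResult:
    """One-sided (over-representation) Fisher's exact test.

    The p-value is the exact hypergeometric upper tail
    P(K >= overlap | N=|universe|, K_set=|set|, n=|network|).
    """
    if not universe:
        raise ValueError("empty universe")
    net = set(network_genes) & universe
    gs = set(gene_set) & universe
    n_univ = len(universe)
    overlap = len(net & gs)
    p = float(hypergeom.sf(overlap - 1, n_univ, len(gs), len(net)))
    return EnrichmentResult(
        collection="", network_id="", set_name="",
        overlap=overlap,
        network_only=len(net) - overlap,
        set_only=len(gs) - overlap,
        neither=n_univ - len(net | gs),
        p_value=min(p, 1.0),
    )


def bh_fdr(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def enrich_networks(
    networks,
    collections: list[GeneSetCollection],
    alpha: float = Q_ALPHA,
    p_report: float = GO_P_REPORT,
) -> pd.DataFrame:
    """All (network, set) tests per collection, BH within collection.

    Flags: ``flagged_q`` for q < alpha (pathway-style reporting) and
    ``flagged_p`` for raw p < 1e-4 (GO-style reporting). Networks sharing no
    genes with a collection's universe are skipped with a warning.
    """
    rows = []
    for coll in collections:
        results: list[EnrichmentResult] = []
        for net in networks:
            genes = set(net.gene_list()) & coll.universe
            if not genes:
                log.warning("enrich_networks: network %s shares no genes with "
                            "collection %s; skipped", net.group_id, coll.name)
                continue
            for set_name in sorted(coll.sets):
                r = fisher_test(genes, coll.sets[set_name], coll.universe)
                r.collection = coll.name
                r.network_id = net.group_id
                r.set_name = set_name
                results.append(r)
        qs = bh_fdr([r.p_value for r in results])
        for r, q in zip(results, qs):
            r.q_value = q
            rows.append(
                {
                    "collection": r.collection,
                    "network_id": r.network_id,
                    "set": r.set_name,
                    "overlap": r.overlap,
                    "network_only": r.network_only,
                    "set_only": r.set_only,
                    "neither": r.neither,
                    "p": r.p_value,
                    "q": r.q_value,
                    "flagged_q": r.q_value < alpha,
                    "flagged_p": r.p_value < p_report,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["collection", "network_id", "set", "overlap", "network_only",
                 "set_only", "neither", "p", "q", "flagged_q", "flagged_p"],
    )
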