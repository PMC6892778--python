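"""Hypergeometric enrichment of sub-pathway gene sets.

Tests whether a sub-pathway's genes overlap a target list (cancer genes,
drug targets) more than chance would allow, given a background universe —
by default the union of genes across the loaded pathway collection, since
target lists are intersected with that universe before testing. The p-value
is the upper tail P(X >= observed overlap) of the hypergeometric
distribution; no multiplicity correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import hypergeom

from .io_formats import GeneList

logger = logging.getLogger("pathcover")


@dataclass(frozen=True)
class EnrichmentResult:
    subpathway_id: str
    list_label: str
    n_subpathway_genes: int
    n_overlap: int
    n_list_in_background: int
    n_background: int
    p: float


def hypergeom_enrichment(
    query, target: GeneList, background: GeneList, subpathway_id: str = ""
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of ``query`` against ``target``.

    Query genes outside the background are dropped with a warning; the
    target is intersected with the background before testing.
    """
    bg = set(background.genes)
    if not bg:
        raise ValueError("background universe is empty")
    query = set(query)
    dropped = query - bg
    if dropped:
        logger.warning("%d query genes outside background dropped", len(dropped))
    q = query & bg
    t = set(target.genes) & bg
    overlap = len(q & t)
    # P(X >= overlap) with population |bg|, successes |t|, draws |q|.
    p = float(hypergeom.sf(overlap - 1, len(bg), len(t), len(q)))
    return EnrichmentResult(
        subpathway_id=subpathway_id,
        list_label=target.label,
        n_subpathway_genes=len(q),
        n_overlap=overlap,
        n_list_in_background=len(t),
        n_background=len(bg),
        p=p,
    )


def enrich_all(
    subpathways: Sequence, lists: Sequence[GeneList], background: GeneList, alpha: float = 0.05
) -> pd.DataFrame:
    """One enrichment row per (sub-pathway, gene list), flagged at p < alpha.

    Accepts common-mode and subtype-mode sub-pathways; the sub-pathway id
    is built from pathway id, component index and, when present, direction.
    """
    rows = []
    for sp in subpathways:
        sp_id = f"{sp.pathway_id}:{sp.component_index}"
        if hasattr(sp, "direction"):
            sp_id += f":{sp.direction}"
        for gl in lists:
            r = hypergeom_enrichment(sp.genes, gl, background, subpathway_id=sp_id)
            rows.append(
                (
                    r.subpathway_id, r.list_label, r.n_overlap, r.n_subpathway_genes,
                    r.n_list_in_background, r.n_background, r.p, r.p < alpha,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subpathway_id", "list_label", "n_overlap", "n_query",
            "n_list", "n_background", "p", "significant",
        ],
    )


def pathway_universe(pathways: Sequence) -> GeneList:
    """Background universe = union of genes across a pathway collection."""
    genes: set[str] = set()
    for pw in pathways:
        genes |= set(pw.genes)
    return GeneList("background", frozenset(genes))
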