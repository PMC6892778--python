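"""Subtype-specific mutated pathways and sub-pathways.

Given two subtype cohorts A and B, pathways with significantly different
mutation frequencies (two-sided Fisher exact test on the 2x2 table of
pathway-mutated vs. not, BH-adjusted) are screened first. Within each
screened pathway, genes are split by the sign of v = f_a - f_b (per-subtype
mutation frequencies): v > 0 genes (G_a) can build A-specific sub-pathways,
v < 0 genes (G_b) B-specific ones; v = 0 genes serve neither. Growth mirrors
the common mode but ranks candidates by the marginal gain Pv in the
coverage difference and retains AT MOST ONE gene whose realized gain is not
positive (and only when one of its neighbors then gains). A sub-pathway is
emitted when its coverage difference reaches the threshold (default 0.25)
with a Fisher exact p < 0.05 on its own 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import fisher_exact

from .common import DiffState, TraceEntry, connected_components, greedy_grow
from .io_formats import MutationProfile, Pathway
from .params import Params
from .significance import bh_adjust, pathway_mutated_samples


@dataclass(frozen=True)
class SubtypePathwayResult:
    pathway_id: str
    name: str
    M_a: int
    M_b: int
    p: float
    q: float


@dataclass(frozen=True)
class SubtypeGenePartition:
    """Per-gene subtype frequencies and the v-sign partition of a component."""

    f_a: dict[str, float]
    f_b: dict[str, float]
    v: dict[str, float]
    G_a: frozenset[str]
    G_b: frozenset[str]


@dataclass(frozen=True)
class SubtypeSubPathway:
    pathway_id: str
    name: str
    component_index: int
    direction: str  # "A" or "B"
    genes: tuple[str, ...]
    coverage_a: float
    coverage_b: float
    diff: float  # coverage_a - coverage_b; positive for A-specific
    fisher_p: float

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def subpathway_fisher_p(
    profile_a: MutationProfile, profile_b: MutationProfile, genes
) -> float:
    """Two-sided Fisher exact p for gene-set mutation status vs subtype."""
    ma = pathway_mutated_samples(profile_a, genes)
    mb = pathway_mutated_samples(profile_b, genes)
    na, nb = profile_a.n_samples, profile_b.n_samples
    return float(fisher_exact([[ma, na - ma], [mb, nb - mb]], alternative="two-sided")[1])


def fisher_pathway_screen(
    profile_a: MutationProfile,
    profile_b: MutationProfile,
    pathways: Sequence[Pathway],
    fdr: float = 0.05,
) -> list[SubtypePathwayResult]:
    """Screen pathways for differential mutation between the subtypes.

    Returns pathways with BH-adjusted q < fdr, sorted by q then id.
    """
    if profile_a.n_samples == 0 or profile_b.n_samples == 0:
        raise ValueError("both subtypes need at least one sample")
    na, nb = profile_a.n_samples, profile_b.n_samples
    stats = []
    for pw in pathways:
        ma = pathway_mutated_samples(profile_a, pw.genes)
        mb = pathway_mutated_samples(profile_b, pw.genes)
        p = float(fisher_exact([[ma, na - ma], [mb, nb - mb]])[1])
        stats.append((pw, ma, mb, p))
    q = bh_adjust([s[3] for s in stats])
    res = [
        SubtypePathwayResult(pw.pathway_id, pw.name, ma, mb, p, float(qi))
        for (pw, ma, mb, p), qi in zip(stats, q)
    ]
    return sorted((r for r in res if r.q < fdr), key=lambda r: (r.q, r.pathway_id))


def partition_genes(
    profile_a: MutationProfile, profile_b: MutationProfile, component
) -> SubtypeGenePartition:
    """Split component genes by the sign of v = f_a - f_b."""
    genes = sorted(set(component))
    fa = profile_a.gene_frequencies().reindex(genes).fillna(0.0)
    fb = profile_b.gene_frequencies().reindex(genes).fillna(0.0)
    v = fa - fb
    return SubtypeGenePartition(
        f_a=fa.to_dict(),
        f_b=fb.to_dict(),
        v=v.to_dict(),
        G_a=frozenset(v.index[v > 0]),
        G_b=frozenset(v.index[v < 0]),
    )


def marginal_diff_gain(
    profile_a: MutationProfile, profile_b: MutationProfile, current, candidate: str
) -> float:
    """Change in (covA - covB), i.e. Pv, from adding ``candidate``. May be negative."""
    current = set(current)
    if candidate in current:
        raise ValueError(f"candidate {candidate!r} already in the gene set")

    def diff(genes):
        ca = profile_a.sample_cover_mask(genes).mean() if genes else 0.0
        cb = profile_b.sample_cover_mask(genes).mean() if genes else 0.0
        return float(ca - cb)

    return diff(current | {candidate}) - diff(current)


def grow_subtype_subpathway(
    component: frozenset[str],
    pathway: Pathway,
    profile_a: MutationProfile,
    profile_b: MutationProfile,
    direction: str,
    params: Params,
    component_index: int = 0,
) -> tuple[SubtypeSubPathway | None, list[TraceEntry]]:
    """Grow one direction-specific sub-pathway on one component.

    ``direction`` "A" seeds at the max-|v| gene of G_a and restricts growth
    to G_a; "B" is computed symmetrically with the subtype roles swapped.
    Emission requires |covA - covB| >= diff_threshold and Fisher p < alpha
    on the final gene set.
    """
    if direction not in ("A", "B"):
        raise ValueError("direction must be 'A' or 'B'")
    if direction == "B":
        sp, trace = grow_subtype_subpathway(
            component, pathway, profile_b, profile_a, "A", params, component_index
        )
        if sp is None:
            return None, trace
        return (
            SubtypeSubPathway(
                sp.pathway_id, sp.name, sp.component_index, "B", sp.genes,
                coverage_a=sp.coverage_b, coverage_b=sp.coverage_a,
                diff=-sp.diff, fisher_p=sp.fisher_p,
            ),
            trace,
        )

    part = partition_genes(profile_a, profile_b, component)
    if not part.G_a:
        return None, []
    seed = min(g for g in part.G_a if part.v[g] == max(part.v[h] for h in part.G_a))
    state = DiffState(profile_a, profile_b)
    members, trace = greedy_grow(
        pathway.to_graph(), set(part.G_a), seed, state,
        non_gain_budget=params.non_gain_budget_subtype,
    )
    cov_a = float(profile_a.sample_cover_mask(members).mean())
    cov_b = float(profile_b.sample_cover_mask(members).mean())
    diff = cov_a - cov_b
    p = subpathway_fisher_p(profile_a, profile_b, members)
    if diff >= params.diff_threshold and p < params.alpha:
        sp = SubtypeSubPathway(
            pathway.pathway_id, pathway.name, component_index, "A",
            tuple(members), cov_a, cov_b, diff, p,
        )
        return sp, trace
    return None, trace


def find_subtype_subpathways(
    profile_a: MutationProfile,
    profile_b: MutationProfile,
    pathways: Sequence[Pathway],
    params: Params | None = None,
) -> list[SubtypeSubPathway]:
    """Both-direction extraction over all components of all given pathways.

    ``pathways`` is normally pre-screened by :func:`fisher_pathway_screen`.
    Results are deduplicated by (pathway_id, direction, gene set) and
    sorted by |diff| descending.
    """
    params = params or Params()
    out: list[SubtypeSubPathway] = []
    seen: set[tuple[str, str, frozenset[str]]] = set()
    for pw in pathways:
        for idx, comp in enumerate(connected_components(pw)):
            for direction in ("A", "B"):
                sp, _ = grow_subtype_subpathway(
                    comp, pw, profile_a, profile_b, direction, params, component_index=idx
                )
                if sp is None:
                    continue
                key = (sp.pathway_id, sp.direction, frozenset(sp.genes))
                if key not in seen:
                    seen.add(key)
                    out.append(sp)
    return sorted(out, key=lambda s: (-abs(s.diff), s.pathway_id, s.direction))


def subtype_table(subpathways: Sequence[SubtypeSubPathway]) -> pd.DataFrame:
    rows = [
        (
            s.pathway_id, s.name, f"{s.direction}-specific", s.n_genes,
            s.coverage_a, s.coverage_b, s.diff, s.fisher_p, ";".join(s.genes),
        )
        for s in subpathways
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "pathway_id", "name", "direction", "n_genes",
            "coverage_A", "coverage_B", "diff", "fisher_p", "genes",
        ],
    )
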