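"""Greedy extraction of common mutated sub-pathways.

A common sub-pathway is a connected subgraph of a pathway's interaction
graph whose member genes' mutations jointly cover at least a threshold
fraction (default 90%) of the cohort, with at least ``min_genes`` genes
(default 5). Growth is greedy: the component gene with the highest cohort
mutation frequency f seeds the sub-pathway; direct neighbors of the seed
frontier are added in descending order of their marginal coverage gain Pf.
Genes whose realized gain at insertion is positive (set GI) stay and become
new seeds; a zero-gain gene (set GN) is kept only if at least one of its own
unvisited neighbors yields a positive gain — those neighbors become new
seeds — and is removed otherwise. Growth stops when the frontier has no
unvisited neighbors left in the component.

The same engine, parameterised by an objective state, also drives the
subtype-differential mode (see :mod:`pathcover.subtype`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import MutationProfile, Pathway
from .params import Params


# ---------------------------------------------------------------------------
# Objective states for the greedy engine
# ---------------------------------------------------------------------------

class CoverageState:
    """Tracks the set of cohort samples covered by the growing gene set."""

    def __init__(self, profile: MutationProfile):
        self._profile = profile
        self._covered = np.zeros(profile.n_samples, dtype=bool)

    def gain(self, gene: str) -> float:
        mask = self._profile.sample_cover_mask([gene])
        return float((mask & ~self._covered).sum()) / self._profile.n_samples

    def add(self, gene: str) -> float:
        g = self.gain(gene)
        self._covered |= self._profile.sample_cover_mask([gene])
        return g

    @property
    def value(self) -> float:
        return float(self._covered.mean())

    def copy(self) -> "CoverageState":
        other = CoverageState.__new__(CoverageState)
        other._profile = self._profile
        other._covered = self._covered.copy()
        return other


class DiffState:
    """Tracks the coverage difference covA - covB of the growing gene set."""

    def __init__(self, profile_a: MutationProfile, profile_b: MutationProfile):
        self._pa, self._pb = profile_a, profile_b
        self._ca = np.zeros(profile_a.n_samples, dtype=bool)
        self._cb = np.zeros(profile_b.n_samples, dtype=bool)

    def gain(self, gene: str) -> float:
        na = (self._pa.sample_cover_mask([gene]) & ~self._ca).sum() / self._pa.n_samples
        nb = (self._pb.sample_cover_mask([gene]) & ~self._cb).sum() / self._pb.n_samples
        return float(na - nb)

    def add(self, gene: str) -> float:
        g = self.gain(gene)
        self._ca |= self._pa.sample_cover_mask([gene])
        self._cb |= self._pb.sample_cover_mask([gene])
        return g

    @property
    def coverage_a(self) -> float:
        return float(self._ca.mean())

    @property
    def coverage_b(self) -> float:
        return float(self._cb.mean())

    @property
    def value(self) -> float:
        return self.coverage_a - self.coverage_b

    def copy(self) -> "DiffState":
        other = DiffState.__new__(DiffState)
        other._pa, other._pb = self._pa, self._pb
        other._ca = self._ca.copy()
        other._cb = self._cb.copy()
        return other


@dataclass(frozen=True)
class TraceEntry:
    gene: str
    gain: float
    kind: str  # seed | GI | GN-retained | GN-rejected


# ---------------------------------------------------------------------------
# Greedy engine
# ---------------------------------------------------------------------------

def greedy_grow(
    graph: nx.Graph,
    allowed: set[str],
    seed: str,
    state,
    non_gain_budget: int | None = None,
) -> tuple[list[str], list[TraceEntry]]:
    """Grow a connected gene set from ``seed`` by marginal objective gain.

    ``allowed`` restricts both frontier candidates and rescue neighbors
    (the whole component in common mode; one direction's gene set in
    subtype mode). ``non_gain_budget`` caps how many retained genes may have
    non-positive realized gain (None = unlimited, the common-mode rule;
    1 is the subtype-mode rule). Every gene is examined at most once.

    Ties in the gain ranking break lexicographically on the gene symbol.
    Returns the retained genes in insertion order plus the full trace,
    including rejected candidates.
    """
    visited = {seed}
    members = [seed]
    trace = [TraceEntry(seed, state.add(seed), "seed")]
    frontier = [seed]
    budget_used = 0

    while frontier:
        candidates = sorted(
            {h for s in frontier for h in graph.neighbors(s) if h in allowed and h not in visited}
        )
        if not candidates:
            break
        # Pf/Pv is computed for every frontier neighbor against the state at
        # the start of the pass; the realized gain at insertion time governs
        # the GI/GN classification.
        ranked = sorted(candidates, key=lambda g: (-state.gain(g), g))
        new_seeds: list[str] = []
        for gene in ranked:
            if gene in visited:
                continue
            visited.add(gene)
            gain = state.gain(gene)
            if gain > 0:
                state.add(gene)
                members.append(gene)
                new_seeds.append(gene)
                trace.append(TraceEntry(gene, gain, "GI"))
                continue
            # GN candidate: retained iff >=1 of its own unvisited neighbors
            # yields a positive gain once the gene itself is (tentatively)
            # in the sub-pathway; those neighbors become new seeds.
            if non_gain_budget is not None and budget_used >= non_gain_budget:
                trace.append(TraceEntry(gene, gain, "GN-rejected"))
                continue
            snapshot = state.copy()
            state.add(gene)
            rescue_nbrs = sorted(
                (h for h in graph.neighbors(gene) if h in allowed and h not in visited),
                key=lambda h: (-state.gain(h), h),
            )
            rescued: list[str] = []
            rescue_trace: list[TraceEntry] = []
            for nbr in rescue_nbrs:
                visited.add(nbr)
                ngain = state.gain(nbr)
                if ngain > 0:
                    state.add(nbr)
                    rescued.append(nbr)
                    rescue_trace.append(TraceEntry(nbr, ngain, "GI"))
                else:
                    rescue_trace.append(TraceEntry(nbr, ngain, "GN-rejected"))
            if rescued:
                members.append(gene)
                members.extend(rescued)
                new_seeds.extend(rescued)
                trace.append(TraceEntry(gene, gain, "GN-retained"))
                trace.extend(rescue_trace)
                budget_used += 1
            else:
                # Roll back the tentative insertion; examined neighbors stay
                # visited (each gene is considered once per component).
                state.__dict__.update(snapshot.__dict__)
                trace.append(TraceEntry(gene, gain, "GN-rejected"))
                trace.extend(rescue_trace)
        frontier = new_seeds

    return members, trace


# ---------------------------------------------------------------------------
# Common-mode operations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubPathway:
    pathway_id: str
    name: str
    component_index: int
    genes: tuple[str, ...]  # insertion order
    coverage: float

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def connected_components(pathway: Pathway) -> list[frozenset[str]]:
    """Maximal connected gene sets of the pathway graph.

    Isolated genes form singleton components. Ordered deterministically by
    the lexicographically smallest member gene.
    """
    comps = [frozenset(c) for c in nx.connected_components(pathway.to_graph())]
    return sorted(comps, key=lambda c: min(c))


def coverage(profile: MutationProfile, genes) -> float:
    """Fraction of samples with >=1 mutated gene among ``genes``."""
    if profile.n_samples == 0:
        raise ValueError("profile has no samples")
    if not set(genes):
        return 0.0
    return float(profile.sample_cover_mask(genes).mean())


def marginal_gain(profile: MutationProfile, current, candidate: str) -> float:
    """Increase in coverage (Pf) from adding ``candidate`` to ``current``."""
    current = set(current)
    if candidate in current:
        raise ValueError(f"candidate {candidate!r} already in the gene set")
    return coverage(profile, current | {candidate}) - coverage(profile, current)


def grow_common_subpathway(
    component: frozenset[str],
    pathway: Pathway,
    profile: MutationProfile,
    params: Params,
    component_index: int = 0,
) -> tuple[SubPathway | None, list[TraceEntry]]:
    """Run the greedy loop on one component; emit iff both gates pass.

    The seed is the component gene with the largest cohort mutation
    frequency (lexicographic tie-break); genes absent from the profile have
    frequency 0 but may still join via GN rescue as connectors.
    """
    if not component:
        raise ValueError("component must be non-empty")
    freqs = profile.gene_frequencies().reindex(sorted(component)).fillna(0.0)
    seed = min(freqs.index[freqs == freqs.max()])
    state = CoverageState(profile)
    members, trace = greedy_grow(pathway.to_graph(), set(component), seed, state)
    cov = coverage(profile, members)
    if cov >= params.coverage_threshold and len(members) >= params.min_genes:
        sp = SubPathway(pathway.pathway_id, pathway.name, component_index, tuple(members), cov)
        return sp, trace
    return None, trace


def find_common_subpathways(
    profile: MutationProfile, pathways: Sequence[Pathway], params: Params | None = None
) -> list[SubPathway]:
    """Extract common sub-pathways from every component of every pathway.

    Results are deduplicated by (pathway_id, gene set) and sorted by
    coverage descending. ``pathways`` is normally the output of the
    significance filter, but any collection is accepted.
    """
    params = params or Params()
    out: list[SubPathway] = []
    seen: set[tuple[str, frozenset[str]]] = set()
    for pw in pathways:
        for idx, comp in enumerate(connected_components(pw)):
            sp, _ = grow_common_subpathway(comp, pw, profile, params, component_index=idx)
            if sp is None:
                continue
            key = (sp.pathway_id, frozenset(sp.genes))
            if key not in seen:
                seen.add(key)
                out.append(sp)
    return sorted(out, key=lambda s: (-s.coverage, s.pathway_id, s.component_index))


def common_table(subpathways: Sequence[SubPathway]) -> pd.DataFrame:
    rows = [
        (s.pathway_id, s.name, s.component_index, s.n_genes, s.coverage, ";".join(s.genes))
        for s in subpathways
    ]
    return pd.DataFrame(
        rows, columns=["pathway_id", "name", "component_index", "n_genes", "coverage", "genes"]
    )
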