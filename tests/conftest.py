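import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pathcover import MutationProfile, Pathway


def make_profile(cover_map: dict[str, list[str]], samples: list[str]) -> MutationProfile:
    """Build a profile from gene -> mutated-sample lists with a fixed roster."""
    genes = sorted(cover_map)
    mat = pd.DataFrame(0, index=pd.Index(genes, name="gene"), columns=samples, dtype=np.int8)
    for g, ss in cover_map.items():
        for s in ss:
            mat.loc[g, s] = 1
    return MutationProfile(mat)


def make_pathway(pid: str, genes, edges) -> Pathway:
    return Pathway(pid, pid, frozenset(genes), frozenset(frozenset(e) for e in edges))


def brute_force_best_coverage(profile: MutationProfile, component, edges) -> float:
    """Best coverage over all connected subsets of a small component."""
    g = nx.Graph()
    g.add_nodes_from(component)
    g.add_edges_from(tuple(sorted(e)) for e in edges if set(e) <= set(component))
    nodes = sorted(component)
    best = 0.0
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if nx.is_connected(g.subgraph(subset)):
                best = max(best, float(profile.sample_cover_mask(subset).mean()))
    return best


def brute_force_best_diff(profile_a, profile_b, component, edges) -> float:
    """Best covA - covB over all connected subsets of a small component."""
    g = nx.Graph()
    g.add_nodes_from(component)
    g.add_edges_from(tuple(sorted(e)) for e in edges if set(e) <= set(component))
    nodes = sorted(component)
    best = -1.0
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if nx.is_connected(g.subgraph(subset)):
                d = float(
                    profile_a.sample_cover_mask(subset).mean()
                    - profile_b.sample_cover_mask(subset).mean()
                )
                best = max(best, d)
    return best


@pytest.fixture
def toy_profile() -> MutationProfile:
    # s1 mutates g1; s2 mutates g2 and g3; s3 mutates nothing
    return make_profile({"g1": ["s1"], "g2": ["s2"], "g3": ["s2"]}, ["s1", "s2", "s3"])


@pytest.fixture
def path_pathway() -> Pathway:
    return make_pathway("P1", ["g1", "g2", "g3"], [("g1", "g2"), ("g2", "g3")])
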