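"""Synthetic cohorts and pathway collections with known planted structure.

Every downstream module is exercised against data whose ground truth is
known exactly: a background gene universe, random pathway gene sets with
Erdos-Renyi interaction graphs, per-sample mutated-gene counts drawn from
an overdispersed negative binomial (real exome cohorts show hypermutator
tails), and two kinds of planted signal —

* a connected gene set whose mutations jointly cover an exact target
  fraction of the cohort (common-mode signal), and
* a connected gene set whose coverage differs between two subtype cohorts
  by an exact target amount (subtype-mode signal).

Planted mutations are assigned round-robin across the planted genes, so
every planted gene covers its own exclusive block of samples and has a
positive marginal gain whenever the greedy search reaches it; an optional
redundant gene receives only already-covered samples to exercise the
zero-gain rescue rule. Background noise never touches planted genes, which
keeps planted coverages exactly auditable on the emitted matrices.

All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneList, MutationProfile, Pathway, SubtypeLabels


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for one synthetic experiment.

    Defaults describe a desk-scale cohort: 200 samples over a 2,000-gene
    universe, ~40 mutated genes per sample on average (per-gene noise
    frequency around 2%), five 30-gene pathways with edge density 0.15,
    a 6-gene planted module at 95% target coverage for common mode and a
    0.40 coverage-difference plant (over a 0.20 base) for subtype mode
    with 200 samples per subtype.
    """

    n_samples: int = 200
    n_background_genes: int = 2000
    n_pathways: int = 5
    pathway_size: int = 30
    edge_density: float = 0.15
    mut_mean: float = 40.0
    mut_shape: float = 8.0  # NB shape; variance = mean + mean^2/shape
    planted_size: int = 6
    common_coverage: float = 0.95
    subtype_diff: float = 0.40
    subtype_base_coverage: float = 0.20
    n_samples_a: int = 200
    n_samples_b: int = 200
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_background_genes, self.n_pathways, self.pathway_size) < 1:
            raise ValueError("sizes must be >= 1")
        if not 0 <= self.edge_density <= 1:
            raise ValueError("edge_density must be in [0, 1]")
        if not 0 < self.common_coverage <= 1:
            raise ValueError("common_coverage must be in (0, 1]")
        if not -1 < self.subtype_diff < 1:
            raise ValueError("subtype_diff must be in (-1, 1)")
        if self.subtype_base_coverage + abs(self.subtype_diff) > 1:
            raise ValueError("base coverage + |diff| exceeds 1: infeasible plant")


@dataclass(frozen=True)
class PathwayDB:
    pathways: list[Pathway]
    background: GeneList
    planted: tuple[str, ...]  # connected gene set inside pathways[0]


def generate_pathway_db(scenario: SyntheticScenario, rng: np.random.Generator) -> PathwayDB:
    """Random pathway collection over a shared background universe.

    Each pathway draws ``pathway_size`` genes uniformly from the background
    and an Erdos-Renyi edge set at ``edge_density``. The first pathway
    hosts the planted module: its first ``planted_size`` drawn genes are
    wired into a path, guaranteeing the planted set induces a connected
    subgraph (extra random edges may also land on it).
    """
    n_bg = scenario.n_background_genes
    bg_genes = [f"BG{i:05d}" for i in range(n_bg)]
    pathways: list[Pathway] = []
    planted: tuple[str, ...] = ()
    for pi in range(scenario.n_pathways):
        size = min(scenario.pathway_size, n_bg)
        members = [bg_genes[i] for i in rng.choice(n_bg, size=size, replace=False)]
        edges: set[frozenset[str]] = set()
        upper = rng.random((size, size))
        for i in range(size):
            for j in range(i + 1, size):
                if upper[i, j] < scenario.edge_density:
                    edges.add(frozenset((members[i], members[j])))
        if pi == 0:
            k = min(scenario.planted_size, size)
            planted = tuple(members[:k])
            for a, b in zip(planted, planted[1:]):
                edges.add(frozenset((a, b)))
        pathways.append(
            Pathway(f"P{pi:03d}", f"synthetic pathway {pi}", frozenset(members), frozenset(edges))
        )
    return PathwayDB(pathways, GeneList("background", frozenset(bg_genes)), planted)


def generate_noise_profile(
    scenario: SyntheticScenario,
    background: GeneList,
    rng: np.random.Generator,
    sample_prefix: str = "S",
    n_samples: int | None = None,
    exclude: Sequence[str] = (),
) -> MutationProfile:
    """Pure-noise cohort: per-sample NB counts, genes uniform w/o replacement.

    ``exclude`` genes (e.g. a planted module) never receive noise mutations
    but still appear as all-zero rows, so planted coverage stays exact.
    """
    n = scenario.n_samples if n_samples is None else n_samples
    genes = sorted(background.genes)
    drawable = [i for i, g in enumerate(genes) if g not in set(exclude)]
    p_nb = scenario.mut_shape / (scenario.mut_shape + scenario.mut_mean)
    counts = rng.negative_binomial(scenario.mut_shape, p_nb, size=n)
    counts = np.minimum(counts, len(drawable))
    mat = np.zeros((len(genes), n), dtype=np.int8)
    drawable_arr = np.asarray(drawable)
    for j in range(n):
        if counts[j]:
            idx = drawable_arr[rng.choice(len(drawable_arr), size=int(counts[j]), replace=False)]
            mat[idx, j] = 1
    samples = [f"{sample_prefix}{j:04d}" for j in range(n)]
    return MutationProfile(pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples))


def _assign_plant(
    matrix: pd.DataFrame,
    genes: Sequence[str],
    n_covered: int,
    rng: np.random.Generator,
    redundant_gene: str | None = None,
) -> None:
    """Round-robin exactly ``n_covered`` samples over ``genes`` (in place)."""
    matrix.loc[list(genes)] = 0
    n = matrix.shape[1]
    covered = rng.choice(n, size=n_covered, replace=False)
    exclusive = [g for g in genes if g != redundant_gene]
    for i, s in enumerate(covered):
        matrix.loc[exclusive[i % len(exclusive)], matrix.columns[s]] = 1
    if redundant_gene is not None and n_covered:
        # The redundant gene mutates only in samples the others already cover,
        # so its marginal coverage gain is exactly zero.
        n_dup = max(1, n_covered // len(genes))
        for s in covered[:n_dup]:
            matrix.loc[redundant_gene, matrix.columns[s]] = 1


def plant_common_signal(
    profile: MutationProfile,
    genes: Sequence[str],
    c: float,
    rng: np.random.Generator,
    redundant_gene: str | None = None,
) -> MutationProfile:
    """Overwrite planted-gene rows so their union covers exactly ceil(c*N) samples."""
    n = profile.n_samples
    if c * n < 1:
        raise ValueError(f"target coverage {c} yields less than one covered sample at N={n}")
    n_covered = math.ceil(c * n)
    if redundant_gene is not None and redundant_gene not in set(genes):
        raise ValueError("redundant_gene must be one of the planted genes")
    mat = profile.matrix.copy()
    _assign_plant(mat, genes, n_covered, rng, redundant_gene)
    return MutationProfile(mat)


def plant_subtype_signal(
    profile_a: MutationProfile,
    profile_b: MutationProfile,
    genes: Sequence[str],
    d: float,
    rng: np.random.Generator,
    base_coverage: float = 0.20,
) -> tuple[MutationProfile, MutationProfile]:
    """Plant a coverage difference of ``d`` (covA - covB) on the planted set.

    The lower subtype sits at ``base_coverage``; the higher at
    ``base_coverage + |d|``. Ceiling effects keep the realized difference
    within 1/min(N_A, N_B) of ``d``.
    """
    if base_coverage + abs(d) > 1 or base_coverage < 0:
        raise ValueError(f"infeasible plant: base {base_coverage}, diff {d}")
    cov_a = base_coverage + d if d >= 0 else base_coverage
    cov_b = base_coverage if d >= 0 else base_coverage - d
    out = []
    for prof, cov in ((profile_a, cov_a), (profile_b, cov_b)):
        mat = prof.matrix.copy()
        n_covered = math.ceil(cov * prof.n_samples)
        _assign_plant(mat, genes, n_covered, rng)
        out.append(MutationProfile(mat))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Whole-scenario builders (used by tests, the CLI and the acceptance script)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommonScenarioData:
    profile: MutationProfile
    pathways: list[Pathway]
    background: GeneList
    planted: tuple[str, ...]


@dataclass(frozen=True)
class SubtypeScenarioData:
    profile_a: MutationProfile
    profile_b: MutationProfile
    pathways: list[Pathway]
    background: GeneList
    planted: tuple[str, ...]
    labels: SubtypeLabels


def simulate_common_scenario(
    scenario: SyntheticScenario, redundant_gene_index: int | None = None
) -> CommonScenarioData:
    """Noise cohort plus a planted common module at the scenario's coverage."""
    rng = np.random.default_rng(scenario.rng_seed)
    db = generate_pathway_db(scenario, rng)
    profile = generate_noise_profile(scenario, db.background, rng, exclude=db.planted)
    redundant = db.planted[redundant_gene_index] if redundant_gene_index is not None else None
    profile = plant_common_signal(
        profile, db.planted, scenario.common_coverage, rng, redundant_gene=redundant
    )
    return CommonScenarioData(profile, db.pathways, db.background, db.planted)


def simulate_subtype_scenario(scenario: SyntheticScenario) -> SubtypeScenarioData:
    """Two subtype cohorts with a planted coverage-difference module."""
    rng = np.random.default_rng(scenario.rng_seed)
    db = generate_pathway_db(scenario, rng)
    prof_a = generate_noise_profile(
        scenario, db.background, rng, sample_prefix="A", n_samples=scenario.n_samples_a,
        exclude=db.planted,
    )
    prof_b = generate_noise_profile(
        scenario, db.background, rng, sample_prefix="B", n_samples=scenario.n_samples_b,
        exclude=db.planted,
    )
    prof_a, prof_b = plant_subtype_signal(
        prof_a, prof_b, db.planted, scenario.subtype_diff, rng,
        base_coverage=scenario.subtype_base_coverage,
    )
    labels = SubtypeLabels(
        {**{s: "A" for s in prof_a.sample_ids}, **{s: "B" for s in prof_b.sample_ids}}
    )
    return SubtypeScenarioData(prof_a, prof_b, db.pathways, db.background, db.planted, labels)


def simulate_null_scenario(scenario: SyntheticScenario) -> CommonScenarioData:
    """Cohort with no planted structure: mutations are pure uniform noise."""
    rng = np.random.default_rng(scenario.rng_seed)
    db = generate_pathway_db(scenario, rng)
    profile = generate_noise_profile(scenario, db.background, rng)
    return CommonScenarioData(profile, db.pathways, db.background, planted=())


def with_seed(scenario: SyntheticScenario, seed: int) -> SyntheticScenario:
    return replace(scenario, rng_seed=int(seed))
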