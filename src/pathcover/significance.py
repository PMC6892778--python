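"""Permutation test for significantly mutated pathways.

A pathway is "mutated" in a sample if at least one of its genes is mutated.
For pathway i the observed statistic is M_i, the number of mutated samples
in the cohort of size N. The null preserves each sample's mutated-gene
count: in every random experiment each sample draws its real number of
mutated genes uniformly without replacement from a background gene universe
(RefSeq-style). All pathways are scored against the same n simulated
cohorts, giving

    p_i = #{experiments r : R_i > M_i} / n

with R_i the simulated mutated-sample count. Ties count as non-exceedance,
exactly as the estimator is defined; an add-one variant is available for
callers who want to avoid p = 0. p-values are BH-adjusted across pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneList, MutationProfile, Pathway

logger = logging.getLogger("pathcover")


@dataclass(frozen=True)
class NullModelSpec:
    """Configuration of the count-preserving random null."""

    background: GeneList
    n_reps: int = 1000
    rng_seed: int | None = None
    add_one: bool = False

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass(frozen=True)
class PathwaySignificanceResult:
    pathway_id: str
    name: str
    n_genes: int
    M: int
    N: int
    p: float
    q: float
    n_reps: int
    exceed_count: int


def pathway_mutated_samples(profile: MutationProfile, genes) -> int:
    """Number of samples with >=1 mutated gene among ``genes`` (M_i).

    Genes absent from the profile contribute nothing; an empty gene set
    covers no samples.
    """
    genes = set(genes)
    if not genes:
        logger.warning("pathway_mutated_samples called with an empty gene set")
        return 0
    return int(profile.sample_cover_mask(genes).sum())


def exceedance_pvalue(M: int, null_counts: Sequence[int], add_one: bool = False) -> tuple[float, int]:
    """Permutation p-value from observed M and simulated counts R_r.

    Returns ``(p, exceed_count)`` where ``exceed_count`` is the number of
    experiments with R_r strictly greater than M.
    """
    null_counts = np.asarray(null_counts)
    if null_counts.size < 1:
        raise ValueError("need at least one null replicate")
    exceed = int((null_counts > M).sum())
    n = null_counts.size
    p = (exceed + 1) / (n + 1) if add_one else exceed / n
    return p, exceed


def _simulate_indicator(
    counts: np.ndarray, n_background: int, rng: np.random.Generator
) -> np.ndarray:
    """One random experiment: a (background x samples) boolean indicator.

    Sample s receives exactly ``counts[s]`` mutated genes drawn uniformly
    without replacement; samples are independent and drawn in fixed order.
    """
    if counts.max(initial=0) > n_background:
        raise ValueError(
            f"a sample has {counts.max()} mutated genes but the background "
            f"universe holds only {n_background}"
        )
    ind = np.zeros((n_background, counts.size), dtype=bool)
    for j, k in enumerate(counts):
        if k:
            ind[rng.choice(n_background, size=int(k), replace=False), j] = True
    return ind


def simulate_null_profile(
    profile: MutationProfile, spec: NullModelSpec, rng: np.random.Generator
) -> MutationProfile:
    """Simulate one count-preserving random cohort over the background universe."""
    bg = sorted(spec.background.genes)
    counts = profile.sample_mutation_counts().to_numpy()
    ind = _simulate_indicator(counts, len(bg), rng)
    return MutationProfile(
        pd.DataFrame(ind.astype(np.int8), index=pd.Index(bg, name="gene"), columns=profile.sample_ids)
    )


def permutation_pvalues(
    profile: MutationProfile, pathways: Sequence[Pathway], spec: NullModelSpec
) -> list[PathwaySignificanceResult]:
    """Run the full permutation test for a pathway collection.

    All pathways are evaluated against the SAME ``n_reps`` simulated cohorts
    (one random cohort per experiment, reused across pathways), so p-values
    are positively correlated across pathways the way the null defines them.
    Deterministic given ``spec.rng_seed``.
    """
    if not pathways:
        raise ValueError("pathways must be non-empty")
    bg = set(spec.background.genes)
    mutated_genes = set(profile.matrix.index[profile.matrix.any(axis=1)])
    extra = mutated_genes - bg
    if extra:
        logger.warning(
            "%d mutated genes absent from the background universe; adding them", len(extra)
        )
        bg |= extra
    bg_list = sorted(bg)
    bg_index = {g: i for i, g in enumerate(bg_list)}

    # Pathway membership over the background, pathways x background (float32
    # so the per-experiment scoring is a single BLAS matmul).
    member = np.zeros((len(pathways), len(bg_list)), dtype=np.float32)
    for i, pw in enumerate(pathways):
        idx = [bg_index[g] for g in pw.genes if g in bg_index]
        member[i, idx] = 1.0

    counts = profile.sample_mutation_counts().to_numpy()
    M = np.array([pathway_mutated_samples(profile, pw.genes) for pw in pathways])

    rng = np.random.default_rng(spec.rng_seed)
    exceed = np.zeros(len(pathways), dtype=np.int64)
    for _ in range(spec.n_reps):
        ind = _simulate_indicator(counts, len(bg_list), rng)
        hits = member @ ind.astype(np.float32)  # pathways x samples mutation counts
        R = (hits > 0).sum(axis=1)
        exceed += R > M

    n = spec.n_reps
    p = (exceed + 1) / (n + 1) if spec.add_one else exceed / n
    q = bh_adjust(p)
    return [
        PathwaySignificanceResult(
            pathway_id=pw.pathway_id,
            name=pw.name,
            n_genes=len(pw.genes),
            M=int(M[i]),
            N=profile.n_samples,
            p=float(p[i]),
            q=float(q[i]),
            n_reps=n,
            exceed_count=int(exceed[i]),
        )
        for i, pw in enumerate(pathways)
    ]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_pathways(
    results: Sequence[PathwaySignificanceResult], fdr: float = 0.05
) -> list[PathwaySignificanceResult]:
    """Pathways with q < fdr, sorted by q then pathway_id."""
    keep = [r for r in results if r.q < fdr]
    return sorted(keep, key=lambda r: (r.q, r.pathway_id))


def significance_table(results: Sequence[PathwaySignificanceResult]) -> pd.DataFrame:
    rows = [
        (r.pathway_id, r.name, r.n_genes, r.M, r.N, r.p, r.q)
        for r in sorted(results, key=lambda r: (r.q, r.pathway_id))
    ]
    return pd.DataFrame(rows, columns=["pathway_id", "name", "n_genes", "M", "N", "p", "q"])
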