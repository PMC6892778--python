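"""Input/output layer: mutation profiles, pathway collections, gene lists.

The central container is :class:`MutationProfile`, a binary gene x sample
indicator matrix. A gene is "mutated" in a sample iff the sample carries at
least one retained somatic variant in that gene; variant multiplicity is
collapsed at read time. Pathways are named gene sets with undirected
gene-gene interaction edges, loaded from a GMT file plus a per-pathway edge
list (SIF-style TSV).

Gene identifiers are matched by exact, case-sensitive string equality; no
alias resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("pathcover")


class FormatError(ValueError):
    """An input file violates its expected format."""


class EmptyInputError(ValueError):
    """An input file is empty or degenerates to an empty dataset."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationProfile:
    """Binary gene x sample somatic-mutation indicator matrix.

    Parameters
    ----------
    matrix
        DataFrame indexed by gene symbol with one column per sample;
        values are 0/1 (int8). Duplicate genes or samples are rejected.
    """

    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates:
            raise FormatError("duplicate gene rows in mutation profile")
        if self.matrix.columns.has_duplicates:
            raise FormatError("duplicate sample columns in mutation profile")
        vals = self.matrix.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise FormatError("mutation indicators must be 0 or 1")
        object.__setattr__(self, "matrix", self.matrix.astype(np.int8))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    # Alias used throughout the statistics code; N is the cohort size.
    N = n_samples

    def gene_frequencies(self) -> pd.Series:
        """Per-gene mutation frequency f = (# mutated samples) / N."""
        if self.n_samples == 0:
            raise EmptyInputError("profile has no samples")
        return self.matrix.mean(axis=1)

    def sample_mutation_counts(self) -> pd.Series:
        """Number of distinct mutated genes per sample."""
        return self.matrix.sum(axis=0)

    def sample_cover_mask(self, genes: Iterable[str]) -> np.ndarray:
        """Boolean mask over samples: True iff >=1 gene of ``genes`` mutated.

        Genes absent from the profile contribute nothing.
        """
        present = self.matrix.index.intersection(pd.Index(set(genes)))
        if len(present) == 0:
            return np.zeros(self.n_samples, dtype=bool)
        return self.matrix.loc[present].to_numpy().any(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "MutationProfile":
        missing = [s for s in sample_ids if s not in self.matrix.columns]
        if missing:
            raise FormatError(f"samples not in profile: {missing[:5]}")
        return MutationProfile(self.matrix.loc[:, list(sample_ids)])

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        sample_ids: Sequence[str],
        gene_ids: Sequence[str] | None = None,
    ) -> "MutationProfile":
        """Build a profile from (gene, sample) mutation pairs.

        ``sample_ids`` fixes the cohort roster so that samples with zero
        retained variants are kept with all-zero columns.
        """
        pairs = list(pairs)
        if gene_ids is None:
            gene_ids = sorted({g for g, _ in pairs})
        mat = pd.DataFrame(
            0, index=pd.Index(gene_ids, name="gene"), columns=list(sample_ids), dtype=np.int8
        )
        for gene, sample in pairs:
            mat.loc[gene, sample] = 1
        return cls(mat)


@dataclass(frozen=True)
class Pathway:
    """Named gene set plus undirected gene-gene interaction edges.

    Edges are stored as frozensets of two member genes; both endpoints must
    belong to ``genes`` and self-loops are disallowed. Genes without any
    edge are legal (isolated nodes of the pathway graph).
    """

    pathway_id: str
    name: str
    genes: frozenset[str]
    edges: frozenset[frozenset[str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise FormatError(f"pathway {self.pathway_id}: self-loop or malformed edge {set(e)}")
            bad = e - self.genes
            if bad:
                raise FormatError(
                    f"pathway {self.pathway_id}: edge endpoint {sorted(bad)} not in gene set"
                )

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g


@dataclass(frozen=True)
class GeneList:
    """Labelled flat gene set (background universe, cancer genes, drug targets)."""

    label: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise EmptyInputError(f"gene list '{self.label}' is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class SubtypeLabels:
    """Sample -> subtype assignment for a two-subtype comparison."""

    assignment: Mapping[str, str]

    def __post_init__(self) -> None:
        tags = set(self.assignment.values())
        if len(tags) != 2:
            raise FormatError(f"expected exactly 2 subtypes, got {sorted(tags)}")

    @property
    def tags(self) -> tuple[str, str]:
        return tuple(sorted(set(self.assignment.values())))  # type: ignore[return-value]

    def samples_of(self, tag: str) -> list[str]:
        return [s for s, t in self.assignment.items() if t == tag]

    def split(self, profile: MutationProfile) -> tuple[MutationProfile, MutationProfile]:
        """Partition a profile into the two subtype cohorts (tag order sorted).

        Every labelled sample must exist in the profile; a mismatch is a hard
        error rather than a silent drop.
        """
        missing = [s for s in self.assignment if s not in set(profile.sample_ids)]
        if missing:
            raise FormatError(f"labelled samples missing from profile: {missing[:5]}")
        a, b = self.tags
        return profile.subset_samples(self.samples_of(a)), profile.subset_samples(self.samples_of(b))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

MAF_GENE_COL = "Hugo_Symbol"
MAF_SAMPLE_COL = "Tumor_Sample_Barcode"
MAF_CLASS_COL = "Variant_Classification"


def read_maf(path: str | Path, exclude_classes: Iterable[str] = ()) -> MutationProfile:
    """Read a MAF-format variant table into a binary mutation profile.

    Every row is counted as a mutation of (Hugo_Symbol, Tumor_Sample_Barcode)
    unless its Variant_Classification is listed in ``exclude_classes``.
    Samples whose variants are all excluded are retained with zero mutations,
    so the cohort size N reflects every sample seen in the file.
    """
    exclude = set(exclude_classes)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"MAF file {path} is empty") from None
    for col in (MAF_GENE_COL, MAF_SAMPLE_COL):
        if col not in df.columns:
            raise FormatError(f"MAF file {path} lacks required column {col!r}")
    if df.empty:
        raise EmptyInputError(f"MAF file {path} has no variant rows")
    samples = list(dict.fromkeys(df[MAF_SAMPLE_COL]))
    if exclude:
        if MAF_CLASS_COL in df.columns:
            df = df[~df[MAF_CLASS_COL].isin(exclude)]
        else:
            logger.warning("exclude_classes given but MAF has no %s column", MAF_CLASS_COL)
    pairs = list(zip(df[MAF_GENE_COL], df[MAF_SAMPLE_COL]))
    return MutationProfile.from_pairs(pairs, sample_ids=samples)


def read_mutation_matrix(path: str | Path) -> MutationProfile:
    """Read a binary gene x sample TSV matrix (genes as rows)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"matrix file {path} is empty") from None
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene rows: {dups[:5]}")
    vals = df.to_numpy()
    if vals.size and not np.isin(vals, (0, 1)).all():
        raise FormatError(f"matrix {path} contains non-binary cells")
    return MutationProfile(df.astype(np.int8))


def write_mutation_matrix(profile: MutationProfile, path: str | Path) -> None:
    profile.matrix.to_csv(path, sep="\t", index_label="gene")


def read_pathways(gmt_path: str | Path, edges_path: str | Path | None = None) -> list[Pathway]:
    """Load a pathway collection from GMT gene sets plus an interaction TSV.

    GMT lines are ``pathway_id <TAB> name <TAB> gene...``; the edge file has
    rows ``pathway_id <TAB> geneA <TAB> geneB``. Edges naming an unknown
    pathway or a gene outside the pathway's set are format errors, reported
    with the offending line number. Reciprocal duplicate rows collapse to a
    single unordered edge.
    """
    gene_sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{gmt_path}:{lineno}: GMT line needs id, name and >=1 gene")
            pid, name, *genes = parts
            if pid in gene_sets:
                raise FormatError(f"{gmt_path}:{lineno}: duplicate pathway id {pid!r}")
            gene_sets[pid] = {g for g in genes if g}
            names[pid] = name
    if not gene_sets:
        raise EmptyInputError(f"GMT file {gmt_path} defines no pathways")

    edges: dict[str, set[frozenset[str]]] = {pid: set() for pid in gene_sets}
    if edges_path is not None:
        with open(edges_path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise FormatError(f"{edges_path}:{lineno}: expected pathway_id, geneA, geneB")
                pid, ga, gb = parts
                if pid not in gene_sets:
                    raise FormatError(f"{edges_path}:{lineno}: unknown pathway id {pid!r}")
                if ga == gb:
                    raise FormatError(f"{edges_path}:{lineno}: self-loop edge on {ga!r}")
                for g in (ga, gb):
                    if g not in gene_sets[pid]:
                        raise FormatError(
                            f"{edges_path}:{lineno}: gene {g!r} not in pathway {pid!r} gene set"
                        )
                edges[pid].add(frozenset((ga, gb)))

    return [
        Pathway(pid, names[pid], frozenset(gene_sets[pid]), frozenset(edges[pid]))
        for pid in gene_sets
    ]


def write_pathways(pathways: Sequence[Pathway], gmt_path: str | Path, edges_path: str | Path) -> None:
    with open(gmt_path, "w") as fh:
        for p in pathways:
            fh.write("\t".join([p.pathway_id, p.name, *sorted(p.genes)]) + "\n")
    with open(edges_path, "w") as fh:
        for p in pathways:
            for e in sorted(tuple(sorted(x)) for x in p.edges):
                fh.write(f"{p.pathway_id}\t{e[0]}\t{e[1]}\n")


def read_gene_list(path: str | Path, label: str = "custom") -> GeneList:
    """Read a one-symbol-per-line gene list; blanks ignored, duplicates collapsed."""
    with open(path) as fh:
        genes = {line.strip() for line in fh if line.strip()}
    if not genes:
        raise EmptyInputError(f"gene list {path} is empty")
    return GeneList(label, frozenset(genes))


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(g + "\n")


def read_subtype_labels(path: str | Path) -> SubtypeLabels:
    """Read a two-column sample<TAB>subtype TSV (no header required)."""
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected sample<TAB>subtype")
            sample, tag = parts
            if sample == "sample" and lineno == 1:  # tolerate a header row
                continue
            if sample in assignment:
                raise FormatError(f"{path}:{lineno}: duplicate sample {sample!r}")
            assignment[sample] = tag
    if not assignment:
        raise EmptyInputError(f"subtype label file {path} is empty")
    return SubtypeLabels(assignment)


def write_subtype_labels(labels: SubtypeLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, t in labels.assignment.items():
            fh.write(f"{s}\t{t}\n")
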