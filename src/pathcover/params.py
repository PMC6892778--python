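"""Tunable parameters for the whole pipeline, with published defaults.

Defaults: 1,000 random experiments for the pathway permutation test; FDR
cutoff 0.05; common sub-pathways must cover >=90% of the cohort with at
least 5 genes; subtype-specific sub-pathways need a coverage difference of
at least 0.25 with a Fisher exact p < 0.05; subtype growth may retain at
most one gene that does not increase the coverage difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class Params:
    n_reps: int = 1000
    fdr: float = 0.05
    coverage_threshold: float = 0.90
    min_genes: int = 5
    diff_threshold: float = 0.25
    alpha: float = 0.05
    rng_seed: int | None = None
    exclude_classes: frozenset[str] = field(default_factory=frozenset)
    non_gain_budget_subtype: int = 1
    # Eq-as-printed estimator can yield p = 0; the add-one variant
    # ((exceed+1)/(n+1)) is available but off by default.
    add_one_pvalue: bool = False

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0 < self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must be in (0, 1]")
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")
        if not 0 < self.diff_threshold < 1:
            raise ValueError("diff_threshold must be in (0, 1)")
        for name in ("fdr", "alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.non_gain_budget_subtype < 0:
            raise ValueError("non_gain_budget_subtype must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exclude_classes"] = sorted(self.exclude_classes)
        return d
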