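"""Evaluation context: a landscape view plus an (optional) error-rate table.

A :class:`Condition` bundles everything needed to score a genotype under one
evolutionary scenario — the genotype-fitness view, the mistranslation table
(``None`` means error-free translation), the expression level ``n`` and the
census population size ``N`` — and memoizes per-genotype fitness moments.
The walk simulator evaluates millions of proposals that revisit the same
genotypes, so this cache is a performance contract; it never changes values.
"""

from __future__ import annotations

from dataclasses import dataclass

from .landscape import GenotypeFitnessView
from .mistranslation import (
    DEFAULT_PRUNE_THRESHOLD,
    FitnessMoments,
    MistranslationTable,
    fitness_moments,
    genotype_mistranslation_rate,
    variant_distribution,
)


@dataclass(frozen=True)
class PopulationParams:
    """Census population size N and proteins produced per cell n."""

    N: int
    n: int = 1

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        if self.n < 1:
            raise ValueError("expression level n must be >= 1")


class Condition:
    """One evolutionary scenario: (landscape view, rate table or None, N, n)."""

    def __init__(self, view: GenotypeFitnessView,
                 table: MistranslationTable | None,
                 params: PopulationParams,
                 prune_threshold: float = DEFAULT_PRUNE_THRESHOLD):
        self.view = view
        self.table = table
        self.params = params
        self.prune_threshold = prune_threshold
        self._moments: dict[str, FitnessMoments] = {}

    @property
    def has_mistranslation(self) -> bool:
        return self.table is not None

    def moments(self, genotype: str) -> FitnessMoments:
        """Cached E(f), Var(f) of a (stop-free) genotype under this condition.

        Without a rate table the encoded fitness is returned with zero
        variance: every protein copy is the encoded peptide.
        """
        cached = self._moments.get(genotype)
        if cached is not None:
            return cached
        if self.table is None:
            m = FitnessMoments(mean=self.view.encoded_fitness(genotype),
                               variance=0.0, n=self.params.n)
        else:
            dist = variant_distribution(genotype, self.table,
                                        self.prune_threshold)
            m = fitness_moments(dist, self.view, self.params.n)
        self._moments[genotype] = m
        return m

    def mean_fitness(self, genotype: str) -> float:
        return self.moments(genotype).mean

    def mistranslation_rate(self, genotype: str) -> float:
        if self.table is None:
            raise ValueError("condition has no mistranslation table")
        return genotype_mistranslation_rate(genotype, self.table)
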