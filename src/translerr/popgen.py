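"""Selection coefficients, mistranslation-adjusted effective population size,
Kimura fixation probabilities and mutation-effect classification.

The chain for a single-nucleotide mutation wt -> mt under one condition:

    s    = E(f_mt) / E(f_wt) - 1
    Ne   = N / (1 + Var(f_wt) / E(f_wt)^2)      (resident moments only)
    u_fix = (1 - exp(-2 Ne s p)) / (1 - exp(-2 Ne s)),  p = 1/N

with a mutation called (nearly) neutral when |s| < 1/(4 Ne). The initial
frequency is 1/N, not 1/Ne: one mutant copy among the N actual individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .condition import Condition, PopulationParams
from .genetic_code import is_synonymous
from .landscape import GenotypeFitnessView
from .mistranslation import MistranslationTable

BENEFICIAL = "beneficial"
NEARLY_NEUTRAL = "nearly_neutral"
DELETERIOUS = "deleterious"

#: below this |2 Ne s| the second-order series of Kimura's formula is used,
#: avoiding 0/0 cancellation; the series is exact to O(x^2).
_NEUTRAL_SWITCH = 1e-8


def selection_coefficient(mean_wt: float, mean_mt: float) -> float:
    """s = E(f_mt)/E(f_wt) - 1; 0 when both means are 0, +inf on "rescue"
    (dead resident, viable mutant — only reachable on degenerate inputs)."""
    if mean_wt < 0 or mean_mt < 0:
        raise ValueError("mean fitness must be nonnegative")
    if mean_wt == 0.0:
        return 0.0 if mean_mt == 0.0 else math.inf
    return mean_mt / mean_wt - 1.0


def effective_population_size(N: int, mean_wt: float, var_wt: float) -> float:
    """Ne = N / (1 + CV^2) with CV^2 = Var(f_wt)/E(f_wt)^2; Ne <= N."""
    if N < 2:
        raise ValueError("population size N must be >= 2")
    if mean_wt <= 0:
        raise ValueError("undefined coefficient of variation: mean fitness 0")
    if var_wt < 0:
        raise ValueError("negative variance")
    return N / (1.0 + var_wt / (mean_wt * mean_wt))


def fixation_probability(Ne: float, s: float, N: int) -> float:
    """Kimura fixation probability of one new mutant copy (p = 1/N).

    Numerics: series for |2 Ne s| < 1e-8; asymptotic branches for large |x|
    where exp over/underflows; result clamped to [0, 1].
    """
    if Ne <= 0:
        raise ValueError("Ne must be positive")
    if N < 2:
        raise ValueError("population size N must be >= 2")
    p = 1.0 / N
    if math.isinf(s):
        return 1.0 if s > 0 else 0.0
    x = 2.0 * Ne * s
    if abs(x) < _NEUTRAL_SWITCH:
        # u = p (1 + x(1-p)/2 + O(x^2)); exact 1/N at s = 0
        u = p * (1.0 + 0.5 * x * (1.0 - p))
    elif x > 700.0:
        u = -math.expm1(-x * p)
    elif x < -700.0:
        # numerator/denominator both explode; u ~ exp(x (1 - p))
        u = math.exp(x * (1.0 - p)) if x * (1.0 - p) > -745.0 else 0.0
    else:
        u = math.expm1(-x * p) / math.expm1(-x)
    return min(1.0, max(0.0, u))


def classify_effect(s: float, Ne: float) -> str:
    """Nearly neutral iff |s| < 1/(4 Ne); otherwise beneficial/deleterious."""
    if Ne <= 0:
        raise ValueError("Ne must be positive")
    if math.isinf(s):
        return BENEFICIAL
    if abs(s) < 1.0 / (4.0 * Ne):
        return NEARLY_NEUTRAL
    return BENEFICIAL if s > 0 else DELETERIOUS


@dataclass(frozen=True)
class MutationEffect:
    """Scored single-nucleotide mutation under one condition."""

    s: float
    effect_class: str
    u_fix: float
    synonymous: bool
    Ne_resident: float
    mean_wt: float
    mean_mt: float


def mutation_effect_under(condition: Condition, wt: str, mt: str) -> MutationEffect:
    """Score the mutation wt -> mt under a prepared :class:`Condition`."""
    syn = is_synonymous(wt, mt, condition.view.code)  # validates distance 1
    mom_wt = condition.moments(wt)
    mom_mt = condition.moments(mt) if _is_sense(condition, mt) else None
    mean_mt = mom_mt.mean if mom_mt is not None else 0.0
    s = selection_coefficient(mom_wt.mean, mean_mt)
    if mom_wt.mean > 0:
        Ne = effective_population_size(condition.params.N, mom_wt.mean,
                                       mom_wt.variance)
        u = fixation_probability(Ne, s, condition.params.N)
        cls = classify_effect(s, Ne)
    else:  # dead resident: rescue convention
        Ne = float(condition.params.N)
        u = 1.0 if math.isinf(s) else 0.0
        cls = BENEFICIAL if math.isinf(s) else NEARLY_NEUTRAL
    return MutationEffect(s=s, effect_class=cls, u_fix=u, synonymous=syn,
                          Ne_resident=Ne, mean_wt=mom_wt.mean, mean_mt=mean_mt)


def _is_sense(condition: Condition, genotype: str) -> bool:
    code = condition.view.code
    return all(not code.is_stop(genotype[i:i + 3])
               for i in range(0, len(genotype), 3))


def mutation_effect(view: GenotypeFitnessView,
                    table: MistranslationTable | None,
                    wt: str, mt: str,
                    params: PopulationParams) -> MutationEffect:
    """Convenience one-shot wrapper around :func:`mutation_effect_under`."""
    return mutation_effect_under(Condition(view, table, params), wt, mt)


def wright_fisher_fixation_estimate(N: int, fitness_wt: float,
                                    fitness_mt: float, replicates: int,
                                    seed: int,
                                    max_generations: int = 1_000_000) -> float:
    """Monte Carlo fixation frequency of one mutant copy under haploid
    Wright–Fisher binomial resampling (validation oracle, not production)."""
    rng = np.random.default_rng(seed)
    if fitness_mt == 0.0:
        return 0.0
    counts = np.ones(replicates, dtype=np.int64)
    active = np.arange(replicates)
    fixed = 0
    for _ in range(max_generations):
        k = counts[active]
        w = k * fitness_mt / (k * fitness_mt + (N - k) * fitness_wt)
        counts[active] = rng.binomial(N, w)
        k = counts[active]
        fixed += int((k == N).sum())
        active = active[(k > 0) & (k < N)]
        if active.size == 0:
            break
    return fixed / replicates
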