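"""Synthetic landscapes and error-rate tables.

The landscape generator is a Rough-Mount-Fuji construction: an additive
component (independent site/amino-acid effects) plus i.i.d. epistatic noise
per peptide. One knob — the ratio of ``epistatic_sd`` to ``additive_weight``
— interpolates between a smooth, single-peaked landscape and a fully rugged
one. Landscapes are normalized to [0, 1] with max 1, a configurable fraction
of peptides set to exact fitness 0 (inviable), and the viable mean matched to
a target by a power transform (which preserves [0, 1], the maximum and all
fitness ranks). The defaults mirror empirical protein landscapes: a low
viable mean (0.08) with a substantial inviable fraction.

The rate generator draws per-(codon, target) error rates log-normally around
a codon-level random effect, emulating the orders-of-magnitude heterogeneity
of measured per-codon mistranslation rates (1e-5 to 1e-2 per amino acid).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize

from .genetic_code import AMINO_ACIDS, GeneticCode, standard_code
from .landscape import PeptideLandscape
from .mistranslation import MistranslationTable

ENUMERATION_BUDGET = 200_000

#: RNG algorithm recorded in generator metadata for cross-platform determinism.
RNG_ALGORITHM = "numpy-PCG64"


@dataclass(frozen=True)
class SyntheticLandscapeSpec:
    L: int = 2
    alphabet_size: int = 20
    additive_weight: float = 1.0
    epistatic_sd: float = 0.3
    lethal_fraction: float = 0.2
    target_mean: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if not (2 <= self.alphabet_size <= 20):
            raise ValueError("alphabet_size must be in [2, 20]")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.additive_weight < 0 or self.epistatic_sd < 0:
            raise ValueError("weights must be nonnegative")
        if not (0.0 <= self.lethal_fraction < 1.0):
            raise ValueError("lethal_fraction must be in [0, 1)")
        if not (0.0 < self.target_mean < 1.0):
            raise ValueError("target_mean must be in (0, 1)")

    def metadata(self) -> dict:
        return {"spec": asdict(self), "rng": RNG_ALGORITHM}


@dataclass(frozen=True)
class SyntheticRateSpec:
    log10_rate_mean: float = -3.5
    log10_rate_sd: float = 0.5
    per_codon_heterogeneity: float = 0.5
    min_rate: float = 1e-5
    max_rate: float = 1e-2
    seed: int = 0

    def __post_init__(self):
        if self.log10_rate_sd < 0 or self.per_codon_heterogeneity < 0:
            raise ValueError("spread parameters must be nonnegative")
        if not (0.0 < self.min_rate <= self.max_rate < 1.0):
            raise ValueError("rate bounds must satisfy 0 < min <= max < 1")

    def metadata(self) -> dict:
        return {"spec": asdict(self), "rng": RNG_ALGORITHM}


def generate_landscape(spec: SyntheticLandscapeSpec) -> PeptideLandscape:
    """Draw a combinatorially complete Rough-Mount-Fuji landscape."""
    alphabet = AMINO_ACIDS[: spec.alphabet_size]
    size = spec.alphabet_size ** spec.L
    if size > ENUMERATION_BUDGET:
        raise ValueError(f"{spec.alphabet_size}^{spec.L} = {size} peptides "
                         f"exceeds the enumeration budget {ENUMERATION_BUDGET}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed]))
    site_effects = rng.standard_normal((spec.L, spec.alphabet_size))
    peptides = ["".join(t) for t in itertools.product(alphabet, repeat=spec.L)]
    idx = {aa: k for k, aa in enumerate(alphabet)}
    additive = np.array([sum(site_effects[i, idx[aa]]
                             for i, aa in enumerate(p)) for p in peptides])
    noise = spec.epistatic_sd * rng.standard_normal(size)
    raw = spec.additive_weight * additive + noise
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        raise ValueError("degenerate landscape: all raw values equal")
    values = (raw - lo) / (hi - lo)
    if spec.lethal_fraction > 0:
        cutoff = np.quantile(values, spec.lethal_fraction)
        values = np.where(values <= cutoff, 0.0, values)
    values = _match_viable_mean(values, spec.target_mean)
    return PeptideLandscape(length=spec.L,
                            fitness=dict(zip(peptides, values.tolist())),
                            alphabet=alphabet)


def _match_viable_mean(values: np.ndarray, target: float) -> np.ndarray:
    """Power-transform viable values so their mean ~ target, keeping max = 1.

    ``v -> v**gamma`` is monotone on [0, 1], fixes 0 and 1, and its viable
    mean decreases continuously in gamma, so a root always exists within the
    bracket unless the target is outside the achievable range (then the
    nearest endpoint is used).
    """
    viable = values > 0
    v = values[viable]
    v = v / v.max()

    def mean_at(gamma: float) -> float:
        return float(np.mean(v ** gamma))

    lo_g, hi_g = 1e-3, 1e3
    if target >= mean_at(lo_g):
        gamma = lo_g
    elif target <= mean_at(hi_g):
        gamma = hi_g
    else:
        gamma = optimize.brentq(lambda g: mean_at(g) - target, lo_g, hi_g)
    out = values.copy()
    out[viable] = v ** gamma
    return out


def generate_rate_table(spec: SyntheticRateSpec,
                        code: GeneticCode | None = None) -> MistranslationTable:
    """Draw per-codon error rates: log10 rate ~ Normal(mean + codon effect,
    sd), clamped to [min_rate, max_rate]."""
    code = code or standard_code()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed]))
    rates: dict[str, dict[str, float]] = {}
    for codon in code.sense_codons:
        cognate = code.codon_to_aa[codon]
        codon_effect = spec.per_codon_heterogeneity * rng.standard_normal()
        row = {}
        for aa in AMINO_ACIDS:
            if aa == cognate:
                continue
            log10 = (spec.log10_rate_mean + codon_effect
                     + spec.log10_rate_sd * rng.standard_normal())
            row[aa] = float(np.clip(10.0 ** log10, spec.min_rate, spec.max_rate))
        rates[codon] = row
    return MistranslationTable(rates, code=code)
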