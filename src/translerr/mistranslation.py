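"""Error-prone translation: per-codon error rates -> protein-variant
distributions -> fitness mean and variance per cell.

The model: each codon ``i`` of a genotype is translated independently, into
its cognate amino acid with probability ``1 - sum(error rates)`` or into one
of the 19 noncognate amino acids at its measured per-codon rate. A protein
variant ``v`` is therefore produced with probability ``q_v = prod_i
P(v_i | codon_i)``. Variants rarer than a prune threshold (default 1e-9) are
dropped and the retained mass renormalized. A cell producing ``n`` protein
copies draws them independently from this distribution (a multinomial with
``n`` trials); each copy contributes its variant's landscape fitness, and
cell fitness is the mean contribution. Hence

    E(f)   = sum_v q_v f_v                      (independent of n)
    Var(f) = (sum_v q_v f_v^2 - E(f)^2) / n     (between-cell variance)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .genetic_code import AMINO_ACIDS, GeneticCode, codons, standard_code
from .landscape import GenotypeFitnessView

DEFAULT_PRUNE_THRESHOLD = 1e-9


class MistranslationTable:
    """Per-codon translation-error probabilities.

    ``rates[codon][aa]`` is the probability that one translation event of
    ``codon`` yields the noncognate amino acid ``aa``. Unmeasured (codon, aa)
    pairs have rate 0 (mass-spectrometry detects only a subset of
    substitutions). The cognate probability of a codon is one minus the sum
    of its error rates.
    """

    def __init__(self, rates: dict[str, dict[str, float]],
                 code: GeneticCode | None = None):
        code = code or standard_code()
        self.code = code
        self.rates: dict[str, dict[str, float]] = {}
        for codon in code.sense_codons:
            self.rates[codon] = {}
        for codon, row in rates.items():
            if codon in code.stop_codons:
                raise ValueError(f"rates listed for stop codon {codon}")
            if codon not in self.rates:
                raise ValueError(f"unknown codon {codon!r}")
            cognate = code.codon_to_aa[codon]
            for aa, rate in row.items():
                if aa == cognate:
                    raise ValueError(
                        f"cognate pair ({codon}, {aa}) listed as an error")
                if aa not in AMINO_ACIDS:
                    raise ValueError(f"unknown amino acid {aa!r}")
                if not (0.0 <= rate < 1.0):
                    raise ValueError(f"rate out of [0, 1): {codon}->{aa}={rate}")
                if rate > 0:
                    self.rates[codon][aa] = float(rate)
        self._cognate_prob = {}
        for codon, row in self.rates.items():
            err = sum(row.values())
            if err >= 1.0:
                raise ValueError(f"error rates of codon {codon} sum to {err} >= 1")
            self._cognate_prob[codon] = 1.0 - err

    @classmethod
    def zero(cls, code: GeneticCode | None = None) -> "MistranslationTable":
        """A table with every error rate 0 (error-free translation)."""
        return cls({}, code=code)

    def cognate_prob(self, codon: str) -> float:
        return self._cognate_prob[codon]

    def error_rates(self, codon: str) -> dict[str, float]:
        return self.rates[codon]

    def codon_distribution(self, codon: str) -> list[tuple[str, float]]:
        """(amino acid, probability) outcomes of one translation of ``codon``,
        cognate first, then error targets alphabetically."""
        cognate = self.code.codon_to_aa[codon]
        out = [(cognate, self._cognate_prob[codon])]
        for aa in sorted(self.rates[codon]):
            out.append((aa, self.rates[codon][aa]))
        return out

    def mean_error_rate(self) -> float:
        """Mean per-codon total error rate over all sense codons."""
        return 1.0 - sum(self._cognate_prob.values()) / len(self._cognate_prob)


def read_rate_table(path: str | Path,
                    code: GeneticCode | None = None) -> MistranslationTable:
    """Read a rate TSV with columns ``codon``, ``amino_acid``, ``rate``."""
    df = pd.read_csv(path, sep="\t",
                     dtype={"codon": str, "amino_acid": str, "rate": float},
                     keep_default_na=False, na_values=[],
                     float_precision="round_trip")
    if not {"codon", "amino_acid", "rate"} <= set(df.columns):
        raise ValueError("rate file must have columns: codon, amino_acid, rate")
    if df.duplicated(["codon", "amino_acid"]).any():
        raise ValueError("duplicate (codon, amino_acid) rows")
    rates: dict[str, dict[str, float]] = {}
    for codon, aa, rate in df[["codon", "amino_acid", "rate"]].itertuples(index=False):
        rates.setdefault(codon.upper().replace("U", "T"), {})[aa] = rate
    return MistranslationTable(rates, code=code)


def write_rate_table(table: MistranslationTable, path: str | Path) -> None:
    rows = [(codon, aa, rate)
            for codon in sorted(table.rates)
            for aa, rate in sorted(table.rates[codon].items())]
    df = pd.DataFrame(rows, columns=["codon", "amino_acid", "rate"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass(frozen=True)
class VariantDistribution:
    """Pruned, renormalized (peptide, probability) pairs from one genotype."""

    entries: tuple[tuple[str, float], ...]
    encoded_peptide: str
    prune_threshold: float

    def probabilities(self) -> dict[str, float]:
        return dict(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def variant_distribution(genotype: str, table: MistranslationTable,
                         prune_threshold: float = DEFAULT_PRUNE_THRESHOLD,
                         ) -> VariantDistribution:
    """Enumerate the protein variants a genotype produces, with probabilities.

    Branch-and-bound over per-codon substitutions: a partial product is
    abandoned once it cannot reach ``prune_threshold`` even if all remaining
    codons take their most likely outcome. The encoded peptide is always
    retained; retained mass is renormalized to 1. Never materializes the
    20^L candidate set.
    """
    if not (0.0 < prune_threshold < 1.0):
        raise ValueError("prune_threshold must be in (0, 1)")
    code = table.code
    codon_list = list(codons(genotype))
    dists = []
    for codon in codon_list:
        if code.is_stop(codon):
            raise ValueError(
                f"stop codon {codon} in genotype: no translation model for "
                "truncated proteins")
        dists.append(table.codon_distribution(codon))
    # suffix_max[i] = max achievable probability product over codons i..L-1
    L = len(dists)
    suffix_max = [1.0] * (L + 1)
    for i in range(L - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] * max(p for _, p in dists[i])
    encoded = "".join(code.codon_to_aa[c] for c in codon_list)

    entries: list[tuple[str, float]] = []
    prefix = [""] * L

    def descend(i: int, prob: float) -> None:
        if i == L:
            entries.append(("".join(prefix), prob))
            return
        for aa, p in dists[i]:
            child = prob * p
            if child * suffix_max[i + 1] < prune_threshold:
                # outcomes are cognate-first then sorted errors, not sorted by
                # probability, so continue scanning the remaining outcomes
                continue
            prefix[i] = aa
            descend(i + 1, child)

    descend(0, 1.0)
    probs = dict(entries)
    if encoded not in probs:  # encoded peptide always retained
        p_enc = 1.0
        for codon in codon_list:
            p_enc *= table.cognate_prob(codon)
        probs[encoded] = p_enc
    total = sum(probs.values())
    normalized = tuple(sorted((pep, p / total) for pep, p in probs.items()))
    return VariantDistribution(entries=normalized, encoded_peptide=encoded,
                               prune_threshold=prune_threshold)


@dataclass(frozen=True)
class FitnessMoments:
    """Expected fitness and between-cell fitness variance at expression n."""

    mean: float
    variance: float
    n: int


def fitness_moments(dist: VariantDistribution, view: GenotypeFitnessView,
                    n: int) -> FitnessMoments:
    """First two moments of cell fitness at expression level ``n``.

    Cell fitness is the mean of n independent per-protein contributions, so
    the mean is n-free and the variance is the single-draw variance over n.
    """
    if n < 1:
        raise ValueError("expression level n must be >= 1")
    mean = 0.0
    second = 0.0
    for peptide, q in dist.entries:
        f = view.peptide_fitness(peptide)
        mean += q * f
        second += q * f * f
    variance = max(0.0, second - mean * mean) / n
    return FitnessMoments(mean=mean, variance=variance, n=n)


def genotype_mistranslation_rate(genotype: str,
                                 table: MistranslationTable) -> float:
    """Probability that a produced protein differs from the encoded peptide.

    Equals ``1 - prod_i cognate_prob(codon_i)``, i.e. one minus the unpruned
    probability of the encoded variant.
    """
    log_p = 0.0
    for codon in codons(genotype):
        if table.code.is_stop(codon):
            raise ValueError(f"stop codon {codon} in genotype")
        log_p += math.log(table.cognate_prob(codon))
    return -math.expm1(log_p)
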