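"""Peptide fitness landscapes and their lift to nucleotide-genotype space.

A :class:`PeptideLandscape` maps every length-L peptide over a given
amino-acid alphabet to a nonnegative fitness (a binding-affinity proxy or a
growth rate; the scale is taken as-is from the input file). The induced
genotype-level landscape is exposed through :class:`GenotypeFitnessView`:
the fitness of a nucleotide genotype is the fitness of its translated
peptide, and stop-containing genotypes have fitness 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_code import (
    AMINO_ACIDS,
    INVIABLE,
    GeneticCode,
    normalize_genotype,
    standard_code,
    translate,
)


@dataclass(frozen=True)
class PeptideLandscape:
    """Combinatorially complete map from length-L peptides to fitness >= 0."""

    length: int
    fitness: dict[str, float]
    alphabet: str = AMINO_ACIDS
    max_fitness: float = field(init=False)
    mean_fitness: float = field(init=False)

    def __post_init__(self):
        values = np.fromiter(self.fitness.values(), dtype=float)
        if values.size == 0:
            raise ValueError("empty landscape")
        if (values < 0).any():
            raise ValueError("negative fitness values")
        object.__setattr__(self, "max_fitness", float(values.max()))
        object.__setattr__(self, "mean_fitness", float(values.mean()))

    def __getitem__(self, peptide: str) -> float:
        return self.fitness[peptide]

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.fitness

    def __len__(self) -> int:
        return len(self.fitness)

    @property
    def peptides(self):
        return self.fitness.keys()

    def viable_values(self) -> np.ndarray:
        """Fitness values of viable peptides (fitness > 0), as an array."""
        v = np.fromiter(self.fitness.values(), dtype=float)
        return v[v > 0]

    @classmethod
    def from_dict(cls, fitness: dict[str, float], alphabet: str = AMINO_ACIDS,
                  missing_policy: str = "error") -> "PeptideLandscape":
        lengths = {len(p) for p in fitness}
        if len(lengths) != 1:
            raise ValueError(f"peptides of differing lengths: {sorted(lengths)}")
        (L,) = lengths
        bad = {p for p in fitness if set(p) - set(alphabet)}
        if bad:
            raise ValueError(f"peptides outside alphabet: {sorted(bad)[:5]}")
        full = {"".join(t) for t in itertools.product(alphabet, repeat=L)}
        missing = full - set(fitness)
        if missing:
            if missing_policy == "error":
                raise ValueError(
                    f"landscape incomplete: {len(missing)} of {len(full)} "
                    f"peptides missing (e.g. {sorted(missing)[:3]})")
            elif missing_policy == "fill-zero":
                fitness = dict(fitness)
                for p in missing:
                    fitness[p] = 0.0
            else:
                raise ValueError(f"unknown missing_policy {missing_policy!r}")
        return cls(length=L, fitness=fitness, alphabet=alphabet)


def read_landscape(path: str | Path, missing_policy: str = "error",
                   alphabet: str = AMINO_ACIDS) -> PeptideLandscape:
    """Read a landscape TSV with header columns ``peptide`` and ``fitness``."""
    # keep_default_na: the peptide "NA" (Asn-Ala) must not parse as missing
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "fitness": float},
                     keep_default_na=False, na_values=[],
                     float_precision="round_trip")
    if not {"peptide", "fitness"} <= set(df.columns):
        raise ValueError("landscape file must have columns: peptide, fitness")
    if df["peptide"].duplicated().any():
        dups = df.loc[df["peptide"].duplicated(), "peptide"].tolist()
        raise ValueError(f"duplicate peptide rows: {dups[:5]}")
    if (df["fitness"] < 0).any():
        raise ValueError("negative fitness values in landscape file")
    fitness = dict(zip(df["peptide"], df["fitness"].astype(float)))
    return PeptideLandscape.from_dict(fitness, alphabet=alphabet,
                                      missing_policy=missing_policy)


def write_landscape(landscape: PeptideLandscape, path: str | Path) -> None:
    """Write a landscape TSV in lexicographic peptide order (reproducible)."""
    rows = sorted(landscape.fitness.items())
    df = pd.DataFrame(rows, columns=["peptide", "fitness"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def phenotypic_neighbors(peptide: str, alphabet: str = AMINO_ACIDS) -> list[str]:
    """The 19L (for the full alphabet) peptides at amino-acid Hamming distance 1.

    Order is deterministic: position-major, alphabetical within a position.
    """
    out = []
    for i, aa in enumerate(peptide):
        for alt in alphabet:
            if alt != aa:
                out.append(peptide[:i] + alt + peptide[i + 1 :])
    return out


class GenotypeFitnessView:
    """Fitness of nucleotide genotypes induced by a peptide landscape.

    ``missing_policy`` governs peptides encodable by the genetic code but
    absent from the landscape (possible with reduced-alphabet landscapes):
    ``"error"`` raises, ``"fill-zero"`` treats them as inviable.
    """

    def __init__(self, landscape: PeptideLandscape,
                 code: GeneticCode | None = None,
                 missing_policy: str = "error"):
        self.landscape = landscape
        self.code = code or standard_code()
        if missing_policy not in ("error", "fill-zero"):
            raise ValueError(f"unknown missing_policy {missing_policy!r}")
        self.missing_policy = missing_policy

    @property
    def genotype_length(self) -> int:
        return 3 * self.landscape.length

    def peptide_fitness(self, peptide: str) -> float:
        try:
            return self.landscape.fitness[peptide]
        except KeyError:
            if self.missing_policy == "fill-zero":
                return 0.0
            raise

    def encoded_fitness(self, genotype: str) -> float:
        """Landscape fitness of the translated peptide; 0 for stop-containing."""
        peptide = translate(genotype, self.code)
        if peptide is INVIABLE:
            return 0.0
        return self.peptide_fitness(peptide)

    def is_viable(self, genotype: str) -> bool:
        return self.encoded_fitness(genotype) > 0

    def all_sense_genotypes(self):
        """Iterate every stop-free genotype of the landscape (4^(3L) scale:
        only use on small L)."""
        for combo in itertools.product(self.code.sense_codons,
                                       repeat=self.landscape.length):
            yield "".join(combo)

    def validate_genotype(self, genotype: str) -> str:
        genotype = normalize_genotype(genotype)
        if len(genotype) != self.genotype_length:
            raise ValueError(
                f"genotype length {len(genotype)} != {self.genotype_length}")
        return genotype
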