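"""Genetic-code machinery and nucleotide-genotype operations.

Genotypes are plain uppercase DNA strings of length ``3*L`` over ``ACGT``.
A genotype whose reading frame contains a stop codon is *inviable*: it stays
a member of genotype space (it can be proposed by mutation) but translates to
the :data:`INVIABLE` marker and is assigned fitness zero downstream.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterator

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Sentinel returned by :func:`translate` for stop-containing genotypes.
INVIABLE = None


class GeneticCode:
    """A codon -> amino-acid map over the 64 DNA codons.

    Parameters
    ----------
    codon_to_aa
        Mapping from each of the 64 codons to a one-letter amino-acid symbol,
        with stop codons absent (they are listed in ``stop_codons``).
    stop_codons
        The codons that terminate translation.
    """

    def __init__(self, codon_to_aa: dict[str, str], stop_codons: frozenset[str]):
        if len(codon_to_aa) + len(stop_codons) != 64:
            raise ValueError("codon table must cover all 64 codons")
        if set(codon_to_aa) & set(stop_codons):
            raise ValueError("stop codons cannot also encode amino acids")
        missing = set(AMINO_ACIDS) - set(codon_to_aa.values())
        if missing:
            raise ValueError(f"amino acids with no codon: {sorted(missing)}")
        self.codon_to_aa = dict(codon_to_aa)
        self.stop_codons = frozenset(stop_codons)
        self.sense_codons = tuple(sorted(codon_to_aa))
        aa_to_codons: dict[str, list[str]] = {}
        for codon, aa in sorted(codon_to_aa.items()):
            aa_to_codons.setdefault(aa, []).append(codon)
        self.aa_to_codons = {aa: tuple(cs) for aa, cs in aa_to_codons.items()}

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard genetic code (Biopython table 1): 61 sense, 3 stop."""
        table = CodonTable.unambiguous_dna_by_id[1]
        return cls(dict(table.forward_table), frozenset(table.stop_codons))

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneticCode({len(self.sense_codons)} sense, {len(self.stop_codons)} stop)"


@lru_cache(maxsize=1)
def standard_code() -> GeneticCode:
    return GeneticCode.standard()


def normalize_genotype(sequence: str) -> str:
    """Canonicalize a nucleotide sequence: uppercase, U -> T, validated."""
    seq = sequence.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"genotype length {len(seq)} not divisible by 3")
    bad = set(seq) - set(NUCLEOTIDES)
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return seq


def codons(genotype: str) -> Iterator[str]:
    for i in range(0, len(genotype), 3):
        yield genotype[i : i + 3]


def translate(genotype: str, code: GeneticCode | None = None) -> str | None:
    """Translate a genotype codon-wise; return :data:`INVIABLE` on any stop."""
    code = code or standard_code()
    genotype = normalize_genotype(genotype)
    peptide = []
    for codon in codons(genotype):
        aa = code.codon_to_aa.get(codon)
        if aa is None:
            return INVIABLE
        peptide.append(aa)
    return "".join(peptide)


def reverse_translate(peptide: str, code: GeneticCode | None = None,
                      choice: int = 0) -> str:
    """One nucleotide encoding of ``peptide`` (codon ``choice`` per residue,
    modulo the residue's codon count; choice 0 gives the alphabetically first).
    """
    code = code or standard_code()
    out = []
    for aa in peptide:
        cs = code.aa_to_codons[aa]
        out.append(cs[choice % len(cs)])
    return "".join(out)


def single_nucleotide_neighbors(genotype: str) -> list[str]:
    """All 9L genotypes at Hamming distance 1, position-major, base-alphabetical."""
    genotype = normalize_genotype(genotype)
    out = []
    for i, base in enumerate(genotype):
        for alt in NUCLEOTIDES:
            if alt != base:
                out.append(genotype[:i] + alt + genotype[i + 1 :])
    return out


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))


def is_synonymous(g1: str, g2: str, code: GeneticCode | None = None) -> bool:
    """True iff the single-nucleotide mutation g1 -> g2 leaves the peptide unchanged.

    Stop-containing genotypes are never synonymous to sense genotypes (and a
    pair of inviable genotypes is not considered synonymous either).
    """
    code = code or standard_code()
    g1 = normalize_genotype(g1)
    g2 = normalize_genotype(g2)
    if hamming(g1, g2) != 1:
        raise ValueError("genotypes must differ at exactly one nucleotide")
    p1 = translate(g1, code)
    p2 = translate(g2, code)
    return p1 is not INVIABLE and p1 == p2
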