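"""Small, fully specified landscape/rate-table fixtures.

Every fixture is deterministic and small enough for exhaustive oracles
(genotype spaces of at most 4^6 sequences). Registry:

``flat``
    L=2, every peptide fitness 1.0, all error rates 0. Walks on it fix at
    the neutral rate; the only non-neutral proposals are stop-creating ones.
``toy-AD``
    L=2 single-peak landscape centred on the peptide "AD" with a hand-set
    rate table under which the genotype GCTGAT ("AD") produces the variant
    "AE" more often than "ED", and "ED" more often than the double
    substitution "DA".
``enumerable-L2``
    Seeded Rough-Mount-Fuji L=2 landscape over all 20 amino acids plus a
    seeded heterogeneous rate table; the workhorse for brute-force checks.
``two-peak``
    L=2 landscape with exactly two fitness peaks ("AC" at 1.0, "WY" at 0.8)
    and all error rates 0.
"""

from __future__ import annotations

import itertools

from .genetic_code import AMINO_ACIDS, GeneticCode, standard_code
from .landscape import PeptideLandscape
from .mistranslation import MistranslationTable
from .synthetic import (
    SyntheticLandscapeSpec,
    SyntheticRateSpec,
    generate_landscape,
    generate_rate_table,
)

FIXTURE_NAMES = ("flat", "toy-AD", "enumerable-L2", "two-peak")


def _all_peptides(L: int = 2) -> list[str]:
    return ["".join(t) for t in itertools.product(AMINO_ACIDS, repeat=L)]


def _flat() -> tuple[PeptideLandscape, MistranslationTable]:
    fitness = {p: 1.0 for p in _all_peptides()}
    return (PeptideLandscape(length=2, fitness=fitness),
            MistranslationTable.zero())


def _toy_ad() -> tuple[PeptideLandscape, MistranslationTable]:
    # smooth single peak at "AD": fitness 1, 0.5 and 0.2 at peptide Hamming
    # distance 0, 1 and 2
    fitness = {}
    for p in _all_peptides():
        d = (p[0] != "A") + (p[1] != "D")
        fitness[p] = (1.0, 0.5, 0.2)[d]
    # GCT (Ala) rarely misreads to E or D; GAT (Asp) misreads to E ten times
    # more often, so from GCTGAT: P("AE") ~ 1e-3 > P("ED") ~ 1e-4 > P("DA") ~ 1e-8
    rates = {
        "GCT": {"E": 1e-4, "D": 1e-4},
        "GAT": {"E": 1e-3, "A": 1e-4},
    }
    return (PeptideLandscape(length=2, fitness=fitness),
            MistranslationTable(rates))


def _enumerable_l2() -> tuple[PeptideLandscape, MistranslationTable]:
    landscape = generate_landscape(SyntheticLandscapeSpec(
        L=2, alphabet_size=20, additive_weight=1.0, epistatic_sd=0.5,
        lethal_fraction=0.2, target_mean=0.08, seed=42))
    table = generate_rate_table(SyntheticRateSpec(seed=7))
    return landscape, table


def _two_peak() -> tuple[PeptideLandscape, MistranslationTable]:
    fitness = {}
    for p in _all_peptides():
        a = ((p[0] == "A") + (p[1] == "C")) / 2.0
        b = ((p[0] == "W") + (p[1] == "Y")) / 2.0
        fitness[p] = max(a * a, 0.8 * b * b)
    return (PeptideLandscape(length=2, fitness=fitness),
            MistranslationTable.zero())


_REGISTRY = {
    "flat": _flat,
    "toy-AD": _toy_ad,
    "enumerable-L2": _enumerable_l2,
    "two-peak": _two_peak,
}


def make_fixture(name: str) -> tuple[PeptideLandscape, MistranslationTable,
                                     GeneticCode]:
    """Instantiate a named fixture; raises KeyError-style error on unknowns."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; known: {sorted(_REGISTRY)}") from None
    landscape, table = factory()
    return landscape, table, standard_code()
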