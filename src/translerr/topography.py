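"""Landscape-level analyses: flattening, neighborhood fitness correlation,
mutation-effect censuses, nearly-neutral-network peak counting and epistasis
classification.

All analyses run under a :class:`~translerr.condition.Condition`; with
``table=None`` they describe the landscape without translation errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .condition import Condition, PopulationParams
from .genetic_code import single_nucleotide_neighbors, translate
from .landscape import GenotypeFitnessView, phenotypic_neighbors
from .mistranslation import MistranslationTable
from .popgen import (
    BENEFICIAL,
    DELETERIOUS,
    NEARLY_NEUTRAL,
    classify_effect,
    effective_population_size,
    mutation_effect_under,
    selection_coefficient,
)

EFFECT_CLASSES = (BENEFICIAL, NEARLY_NEUTRAL, DELETERIOUS)

ADDITIVE = "additive"
MAGNITUDE = "magnitude"
SIMPLE_SIGN = "simple_sign"
RECIPROCAL_SIGN = "reciprocal_sign"


@dataclass(frozen=True)
class FlatteningFit:
    """Least-squares fit of expected fitness with errors on encoded fitness."""

    slope: float
    intercept: float
    r: float
    delta_f: np.ndarray  # per-genotype E(f) - f_encoded


def flattening_fit(genotypes: list[str], view: GenotypeFitnessView,
                   table: MistranslationTable, params: PopulationParams,
                   condition: Condition | None = None) -> FlatteningFit:
    """Regress E(f) under mistranslation on encoded fitness (slope < 1 means
    the landscape is flattened: tops pulled down, valleys pulled up)."""
    if len(genotypes) < 3:
        raise ValueError("need at least 3 genotypes")
    if condition is None:
        condition = Condition(view, table, params)
    x = np.array([view.encoded_fitness(g) for g in genotypes])
    y = np.array([condition.mean_fitness(g) for g in genotypes])
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: encoded fitness is constant")
    fit = stats.linregress(x, y)
    return FlatteningFit(slope=float(fit.slope), intercept=float(fit.intercept),
                         r=float(fit.rvalue), delta_f=y - x)


def neighbor_fitness_means(genotype: str,
                           view: GenotypeFitnessView) -> tuple[float, float]:
    """(mean fitness of the 19L peptide neighbors, mean encoded fitness of the
    9L nucleotide neighbors); stop-creating nucleotide neighbors contribute 0."""
    peptide = translate(genotype, view.code)
    if peptide is None:
        raise ValueError("genotype contains a stop codon")
    phen = np.mean([view.peptide_fitness(p)
                    for p in phenotypic_neighbors(peptide,
                                                  view.landscape.alphabet)])
    gen = np.mean([view.encoded_fitness(g)
                   for g in single_nucleotide_neighbors(genotype)])
    return float(phen), float(gen)


@dataclass
class MutationCensus:
    """Per-pair effect classes under both conditions plus the 3x3 transition
    census (rows: class without mistranslation, columns: with)."""

    records: pd.DataFrame
    census: pd.DataFrame

    def off_diagonal_fraction(self) -> float:
        total = self.census.to_numpy().sum()
        return 1.0 - np.trace(self.census.to_numpy()) / total


def classify_mutation_sample(view: GenotypeFitnessView,
                             table: MistranslationTable | None,
                             pairs: list[tuple[str, str]],
                             params: PopulationParams) -> MutationCensus:
    """Classify each (wt, mt) single-nucleotide pair with and without
    mistranslation and tabulate class transitions and u_fix changes."""
    cond_none = Condition(view, None, params)
    cond_mist = Condition(view, table, params)
    rows = []
    for wt, mt in pairs:
        e0 = mutation_effect_under(cond_none, wt, mt)
        e1 = mutation_effect_under(cond_mist, wt, mt)
        rows.append((wt, mt, e0.synonymous,
                     e0.s, e0.effect_class, e0.u_fix,
                     e1.s, e1.effect_class, e1.u_fix,
                     e1.u_fix - e0.u_fix))
    records = pd.DataFrame(rows, columns=[
        "wt", "mt", "synonymous",
        "s_none", "class_none", "u_fix_none",
        "s_mist", "class_mist", "u_fix_mist", "u_fix_delta"])
    census = pd.crosstab(records["class_none"], records["class_mist"])
    census = census.reindex(index=EFFECT_CLASSES, columns=EFFECT_CLASSES,
                            fill_value=0)
    return MutationCensus(records=records, census=census)


def sample_mutation_pairs(view: GenotypeFitnessView, count: int,
                          seed: int) -> list[tuple[str, str]]:
    """Uniform random (sense genotype, one of its 9L neighbors) pairs."""
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    sense = np.array(view.code.sense_codons)
    pairs = []
    while len(pairs) < count:
        wt = "".join(rng.choice(sense, size=view.landscape.length))
        nbrs = single_nucleotide_neighbors(wt)
        pairs.append((wt, nbrs[int(rng.integers(len(nbrs)))]))
    return pairs


@dataclass(frozen=True)
class NeutralNetwork:
    members: frozenset[str]
    is_peak: bool


def _nearly_neutral_edge(condition: Condition, a: str, b: str) -> bool:
    """Edge iff the mutation is nearly neutral in both directions."""
    ma, mb = condition.moments(a), condition.moments(b)
    if ma.mean <= 0 or mb.mean <= 0:
        return False
    N = condition.params.N
    s_ab = selection_coefficient(ma.mean, mb.mean)
    Ne_a = effective_population_size(N, ma.mean, ma.variance)
    if classify_effect(s_ab, Ne_a) != NEARLY_NEUTRAL:
        return False
    s_ba = selection_coefficient(mb.mean, ma.mean)
    Ne_b = effective_population_size(N, mb.mean, mb.variance)
    return classify_effect(s_ba, Ne_b) == NEARLY_NEUTRAL


def neutral_networks(genotype_set: list[str], view: GenotypeFitnessView,
                     table: MistranslationTable | None,
                     params: PopulationParams,
                     condition: Condition | None = None) -> list[NeutralNetwork]:
    """Connected components of the nearly-neutral graph over ``genotype_set``.

    A component is a fitness peak iff every single-nucleotide neighbor outside
    the component (whether or not it is in ``genotype_set``) is deleterious
    relative to its adjacent member.
    """
    if not genotype_set:
        raise ValueError("empty genotype set")
    if condition is None:
        condition = Condition(view, table, params)
    members = set(genotype_set)
    graph = nx.Graph()
    graph.add_nodes_from(members)
    for g in members:
        for nbr in single_nucleotide_neighbors(g):
            if nbr in members and not graph.has_edge(g, nbr):
                if _nearly_neutral_edge(condition, g, nbr):
                    graph.add_edge(g, nbr)
    networks = []
    code = view.code
    N = condition.params.N
    for comp in nx.connected_components(graph):
        is_peak = True
        for g in comp:
            mg = condition.moments(g)
            if mg.mean <= 0:
                is_peak = False
                break
            Ne_g = effective_population_size(N, mg.mean, mg.variance)
            for nbr in single_nucleotide_neighbors(g):
                if nbr in comp:
                    continue
                if any(code.is_stop(nbr[i:i + 3]) for i in range(0, len(nbr), 3)):
                    continue  # inviable neighbor: strictly lower fitness
                s_out = selection_coefficient(mg.mean,
                                              condition.moments(nbr).mean)
                if classify_effect(s_out, Ne_g) != DELETERIOUS:
                    is_peak = False
                    break
            if not is_peak:
                break
        networks.append(NeutralNetwork(members=frozenset(comp), is_peak=is_peak))
    return networks


def count_peaks_topk(view: GenotypeFitnessView,
                     table: MistranslationTable | None, K: int,
                     params: PopulationParams,
                     condition: Condition | None = None) -> int:
    """Number of peak networks among the K genotypes with highest expected
    fitness under the condition (ties broken lexicographically). Enumerates
    all sense genotypes, so only feasible at small L."""
    if condition is None:
        condition = Condition(view, table, params)
    genotypes = list(view.all_sense_genotypes())
    if K > len(genotypes):
        raise ValueError(f"K={K} exceeds {len(genotypes)} sense genotypes")
    ranked = sorted(genotypes, key=lambda g: (-condition.mean_fitness(g), g))
    top = ranked[:K]
    nets = neutral_networks(top, view, table, params, condition=condition)
    return sum(net.is_peak for net in nets)


def brute_force_peaks(view: GenotypeFitnessView,
                      table: MistranslationTable | None,
                      params: PopulationParams) -> int:
    """Peak count over the whole sense-genotype space (exhaustive oracle)."""
    condition = Condition(view, table, params)
    genotypes = list(view.all_sense_genotypes())
    nets = neutral_networks(genotypes, view, table, params, condition=condition)
    return sum(net.is_peak for net in nets)


@dataclass(frozen=True)
class EpistasisSquare:
    g00: str
    g10: str
    g01: str
    g11: str
    f00: float
    f10: float
    f01: float
    f11: float
    classification: str


def classify_square(f00: float, f10: float, f01: float, f11: float,
                    Ne00: float, Ne01: float, Ne10: float,
                    epsilon_tolerance: float) -> str:
    """Classify one genotype square.

    epsilon = f11 - f10 - f01 + f00 measures deviation from additivity; below
    ``epsilon_tolerance`` the square is additive. Otherwise the effect class
    of each mutation is compared across backgrounds (scored against the
    resident corner's Ne): zero, one or two class changes give magnitude,
    simple sign and reciprocal sign epistasis respectively.
    """
    eps = f11 - f10 - f01 + f00
    if abs(eps) < epsilon_tolerance:
        return ADDITIVE
    cls_a_wt = classify_effect(selection_coefficient(f00, f10), Ne00)
    cls_a_alt = classify_effect(selection_coefficient(f01, f11), Ne01)
    cls_b_wt = classify_effect(selection_coefficient(f00, f01), Ne00)
    cls_b_alt = classify_effect(selection_coefficient(f10, f11), Ne10)
    changed = (cls_a_wt != cls_a_alt) + (cls_b_wt != cls_b_alt)
    if changed == 0:
        return MAGNITUDE
    if changed == 1:
        return SIMPLE_SIGN
    return RECIPROCAL_SIGN


def sample_epistasis_squares(view: GenotypeFitnessView,
                             table: MistranslationTable | None, count: int,
                             params: PopulationParams, seed: int,
                             condition: Condition | None = None,
                             ) -> tuple[list[EpistasisSquare], dict[str, float]]:
    """Sample ``count`` random genotype squares and classify their epistasis.

    A square is a wild type g00, two single-nucleotide mutations at distinct
    nucleotide positions (g10, g01) and the double mutant g11; squares with an
    inviable (dead or stop-containing) corner are redrawn, since ratio-based
    effect classes are undefined there. The additivity tolerance is the drift
    scale of the wild-type corner, |eps| < E(f00)/(4 Ne00).
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if condition is None:
        condition = Condition(view, table, params)
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    sense = np.array(view.code.sense_codons)
    N = params.N
    code = view.code
    squares: list[EpistasisSquare] = []
    max_draws = 1000 * count
    draws = 0
    while len(squares) < count and draws < max_draws:
        draws += 1
        g00 = "".join(rng.choice(sense, size=view.landscape.length))
        length = len(g00)
        i, j = sorted(rng.choice(length, size=2, replace=False))
        alt_i = [b for b in "ACGT" if b != g00[i]][int(rng.integers(3))]
        alt_j = [b for b in "ACGT" if b != g00[j]][int(rng.integers(3))]
        g10 = g00[:i] + alt_i + g00[i + 1 :]
        g01 = g00[:j] + alt_j + g00[j + 1 :]
        g11 = g10[:j] + alt_j + g10[j + 1 :]
        if any(code.is_stop(g[k:k + 3])
               for g in (g10, g01, g11) for k in range(0, length, 3)):
            continue
        moments = {g: condition.moments(g) for g in (g00, g10, g01, g11)}
        if any(m.mean <= 0 for m in moments.values()):
            continue
        Ne = {g: effective_population_size(N, m.mean, m.variance)
              for g, m in moments.items()}
        tol = moments[g00].mean / (4.0 * Ne[g00])
        cls = classify_square(moments[g00].mean, moments[g10].mean,
                              moments[g01].mean, moments[g11].mean,
                              Ne[g00], Ne[g01], Ne[g10], tol)
        squares.append(EpistasisSquare(
            g00=g00, g10=g10, g01=g01, g11=g11,
            f00=moments[g00].mean, f10=moments[g10].mean,
            f01=moments[g01].mean, f11=moments[g11].mean,
            classification=cls))
    if len(squares) < count:
        raise RuntimeError("could not sample enough viable squares")
    fractions = {c: 0.0 for c in
                 (ADDITIVE, MAGNITUDE, SIMPLE_SIGN, RECIPROCAL_SIGN)}
    for sq in squares:
        fractions[sq.classification] += 1.0 / len(squares)
    return squares, fractions
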