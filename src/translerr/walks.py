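"""Origin-fixation adaptive walks in the weak mutation–strong selection regime.

Each walk attempt proposes one of the resident genotype's 9L single-nucleotide
neighbors uniformly at random (stop-creating neighbors included: they have
fitness 0, s = -1 and essentially no chance to fix), scores it under the
configured condition, and fixes it with a single Bernoulli draw at its Kimura
fixation probability. The attempt index is the proxy for evolutionary time.

Replicate r of a run with root seed S uses the RNG stream seeded by
``SeedSequence([S, r])``, so any replicate is reproducible in isolation and
paired conditions can share proposal streams by sharing (S, r).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .condition import Condition, PopulationParams
from .genetic_code import NUCLEOTIDES, single_nucleotide_neighbors
from .landscape import GenotypeFitnessView
from .mistranslation import MistranslationTable, genotype_mistranslation_rate
from .popgen import BENEFICIAL, mutation_effect_under

FULL_SCALE = dict(total_attempts=100_000, replicates=10_000)
DESK_SCALE = dict(total_attempts=10_000, replicates=100)


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of one ensemble of adaptive walks."""

    params: PopulationParams
    table: MistranslationTable | None = None
    total_attempts: int = FULL_SCALE["total_attempts"]
    replicates: int = FULL_SCALE["replicates"]
    start_quantile: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.start_quantile <= 1.0):
            raise ValueError("start_quantile must be in (0, 1]")
        if self.total_attempts < 1 or self.replicates < 1:
            raise ValueError("total_attempts and replicates must be positive")


@dataclass(frozen=True)
class FixationEvent:
    attempt_index: int
    from_genotype: str
    to_genotype: str
    s: float
    synonymous: bool
    fitness_before: float
    fitness_after: float
    mistranslation_rate_after: float  # nan when the walk ran without a table


@dataclass
class WalkRecord:
    start: str
    events: list[FixationEvent] = field(default_factory=list)
    final_genotype: str = ""
    final_fitness: float = 0.0
    final_fitness_fraction: float = 0.0
    start_rate: float = float("nan")  # start mistranslation rate (nan w/o table)
    aborted: bool = False  # resident reached E(f) = 0 (degenerate inputs only)

    @property
    def n_syn_fixed(self) -> int:
        return sum(e.synonymous for e in self.events)

    @property
    def n_nonsyn_fixed(self) -> int:
        return len(self.events) - self.n_syn_fixed


def sample_start_genotypes(view: GenotypeFitnessView, quantile: float,
                           count: int, seed: int) -> list[str]:
    """Sample walk starts among viable genotypes in the bottom fitness quantile.

    Peptides with 0 < fitness <= the ``quantile`` cutoff of the viable-fitness
    distribution are sampled uniformly with replacement; each sampled peptide
    is then assigned one of its synonymous encodings uniformly at random.
    """
    landscape = view.landscape
    viable = sorted(p for p, f in landscape.fitness.items() if f > 0)
    if not viable:
        raise ValueError("landscape has no viable peptides")
    values = np.array([landscape.fitness[p] for p in viable])
    cutoff = np.quantile(values, quantile)
    pool = [p for p, f in zip(viable, values) if f <= cutoff]
    if not pool:
        raise ValueError("no viable peptides at or below the quantile cutoff")
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    starts = []
    for _ in range(count):
        peptide = pool[rng.integers(len(pool))]
        genotype = "".join(
            view.code.aa_to_codons[aa][rng.integers(len(view.code.aa_to_codons[aa]))]
            for aa in peptide)
        starts.append(genotype)
    return starts


def _propose(genotype: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(len(genotype)))
    alt = [b for b in NUCLEOTIDES if b != genotype[pos]][int(rng.integers(3))]
    return genotype[:pos] + alt + genotype[pos + 1 :]


def run_walk(start: str, condition: Condition, total_attempts: int,
             seed: int, replicate: int = 0) -> WalkRecord:
    """One adaptive walk of ``total_attempts`` proposed mutations."""
    start = condition.view.validate_genotype(start)
    if condition.view.encoded_fitness(start) <= 0:
        raise ValueError("walk must start from a viable genotype")
    rng = np.random.default_rng(np.random.SeedSequence([seed, replicate]))
    record = WalkRecord(start=start)
    resident = start
    table = condition.table
    if table is not None:
        record.start_rate = genotype_mistranslation_rate(start, table)
    for attempt in range(total_attempts):
        mutant = _propose(resident, rng)
        effect = mutation_effect_under(condition, resident, mutant)
        if rng.random() < effect.u_fix:
            rate = (genotype_mistranslation_rate(mutant, table)
                    if table is not None else float("nan"))
            record.events.append(FixationEvent(
                attempt_index=attempt, from_genotype=resident,
                to_genotype=mutant, s=effect.s, synonymous=effect.synonymous,
                fitness_before=effect.mean_wt, fitness_after=effect.mean_mt,
                mistranslation_rate_after=rate))
            resident = mutant
            if effect.mean_mt <= 0.0:
                record.aborted = True
                break
    record.final_genotype = resident
    record.final_fitness = condition.mean_fitness(resident)
    record.final_fitness_fraction = (
        record.final_fitness / condition.view.landscape.max_fitness)
    return record


def run_walk_ensemble(view: GenotypeFitnessView, config: WalkConfig,
                      starts: list[str] | None = None,
                      condition: Condition | None = None) -> list[WalkRecord]:
    """Run ``config.replicates`` walks; shared moment cache across replicates."""
    if condition is None:
        condition = Condition(view, config.table, config.params)
    if starts is None:
        starts = sample_start_genotypes(view, config.start_quantile,
                                        config.replicates, config.seed)
    if len(starts) < config.replicates:
        raise ValueError("fewer start genotypes than replicates")
    return [run_walk(starts[r], condition, config.total_attempts,
                     config.seed, replicate=r)
            for r in range(config.replicates)]


def landscape_mean_rate(view: GenotypeFitnessView, table: MistranslationTable,
                        sample_size: int, seed: int) -> float:
    """Mean per-protein mistranslation rate over a random sample of sense
    genotypes (the 100% reference for normalized rate trajectories)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    sense = np.array(view.code.sense_codons)
    total = 0.0
    for _ in range(sample_size):
        g = "".join(rng.choice(sense, size=view.landscape.length))
        total += genotype_mistranslation_rate(g, table)
    return total / sample_size


def posthoc_rates(record: WalkRecord, table: MistranslationTable,
                  mean_rate: float) -> list[tuple[int, float]]:
    """Mistranslation rates the residents of a no-mistranslation walk would
    have had, as (attempt_index, percent-of-landscape-mean) change points.

    The first entry (index 0) is the start genotype; each fixation adds one
    change point at its attempt index.
    """
    if mean_rate <= 0:
        raise ValueError("mean_rate must be positive")
    out = [(0, 100.0 * genotype_mistranslation_rate(record.start, table) / mean_rate)]
    for e in record.events:
        rate = genotype_mistranslation_rate(e.to_genotype, table)
        out.append((e.attempt_index, 100.0 * rate / mean_rate))
    return out


def beneficial_supply(view: GenotypeFitnessView,
                      table: MistranslationTable | None, genotype: str,
                      params: PopulationParams,
                      condition: Condition | None = None) -> int:
    """Number of nonsynonymous single-nucleotide neighbors classified
    beneficial relative to ``genotype`` under the condition."""
    if condition is None:
        condition = Condition(view, table, params)
    count = 0
    for mt in single_nucleotide_neighbors(genotype):
        effect = mutation_effect_under(condition, genotype, mt)
        if not effect.synonymous and effect.effect_class == BENEFICIAL:
            count += 1
    return count


def summarize_walks(records: list[WalkRecord],
                    view: GenotypeFitnessView) -> dict:
    """Ensemble summary: fitness outcomes, fixation counts, syn/nonsyn fitness
    attribution and the rank association between event fitness effect and
    change in mistranslation rate (nan without rate bookkeeping)."""
    if not records:
        raise ValueError("no walk records to summarize")
    frac = np.array([r.final_fitness_fraction for r in records])
    total = np.array([len(r.events) for r in records])
    syn = np.array([r.n_syn_fixed for r in records])
    nonsyn = total - syn
    syn_gain, nonsyn_gain = 0.0, 0.0
    s_values, rate_changes = [], []
    for r in records:
        prev_rate = r.start_rate
        for e in r.events:
            delta = e.fitness_after - e.fitness_before
            if e.synonymous:
                syn_gain += delta
            else:
                nonsyn_gain += delta
            if np.isfinite(e.mistranslation_rate_after) and np.isfinite(prev_rate):
                s_values.append(e.s)
                rate_changes.append(e.mistranslation_rate_after - prev_rate)
            prev_rate = e.mistranslation_rate_after
    if len(s_values) >= 2:
        tau = stats.kendalltau(s_values, rate_changes).statistic
    else:
        tau = float("nan")
    return {
        "replicates": len(records),
        "final_fitness_fraction_mean": float(frac.mean()),
        "final_fitness_fraction_sd": float(frac.std(ddof=0)),
        "fixations_mean": float(total.mean()),
        "fixations_sd": float(total.std(ddof=0)),
        "syn_fixations_mean": float(syn.mean()),
        "syn_fixations_sd": float(syn.std(ddof=0)),
        "nonsyn_fixations_mean": float(nonsyn.mean()),
        "nonsyn_fixations_sd": float(nonsyn.std(ddof=0)),
        "fitness_gain_synonymous": float(syn_gain),
        "fitness_gain_nonsynonymous": float(nonsyn_gain),
        "kendall_tau_s_vs_rate_change": float(tau) if tau is not None else float("nan"),
    }


def events_frame(records: list[WalkRecord]) -> pd.DataFrame:
    """All fixation events across an ensemble, one row per event."""
    rows = []
    for rep, r in enumerate(records):
        for e in r.events:
            rows.append((rep, e.attempt_index, e.from_genotype, e.to_genotype,
                         e.s, e.synonymous, e.fitness_after,
                         e.mistranslation_rate_after))
    return pd.DataFrame(rows, columns=[
        "replicate", "attempt", "from", "to", "s", "synonymous",
        "fitness_after", "mistrans_rate_after"])
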