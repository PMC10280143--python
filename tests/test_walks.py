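import math

import numpy as np
import pytest

from translerr.condition import Condition, PopulationParams
from translerr.genetic_code import single_nucleotide_neighbors, translate
from translerr.landscape import GenotypeFitnessView, PeptideLandscape
from translerr.mistranslation import (
    MistranslationTable,
    genotype_mistranslation_rate,
)
from translerr.walks import (
    WalkConfig,
    beneficial_supply,
    events_frame,
    FixationEvent,
    landscape_mean_rate,
    posthoc_rates,
    run_walk,
    run_walk_ensemble,
    sample_start_genotypes,
    summarize_walks,
    WalkRecord,
)

# fraction of single-nucleotide mutations of a uniform random sense codon
# that create a stop codon: 23 of the 61*9 directed codon mutations
STOP_HIT_FRACTION = 23 / 549


class TestStartSampling:
    def test_bottom_decile_only(self):
        # fitness ladder 0, 0.1, ..., 1.0 over L=1 peptides (rest 0)
        ladder = dict(zip("ACDEFGHIKLM", [i / 10 for i in range(11)]))
        fitness = {aa: ladder.get(aa, 0.0) for aa in "ACDEFGHIKLMNPQRSTVWY"}
        view = GenotypeFitnessView(PeptideLandscape(length=1, fitness=fitness))
        starts = sample_start_genotypes(view, quantile=0.10, count=200, seed=4)
        peptides = {translate(g) for g in starts}
        assert peptides == {"C"}  # lowest viable decile: fitness 0.1 only
        assert all(view.encoded_fitness(g) > 0 for g in starts)

    def test_quantile_one_excludes_inviable(self, enumerable):
        _, _, _, view = enumerable
        starts = sample_start_genotypes(view, quantile=1.0, count=100, seed=1)
        assert all(view.encoded_fitness(g) > 0 for g in starts)

    def test_deterministic_per_seed(self, enumerable):
        _, _, _, view = enumerable
        a = sample_start_genotypes(view, 0.10, 50, seed=9)
        b = sample_start_genotypes(view, 0.10, 50, seed=9)
        assert a == b


class TestRunWalk:
    def test_reproducible_event_streams(self, enumerable):
        _, table, _, view = enumerable
        params = PopulationParams(N=10**6, n=1)
        cond1 = Condition(view, table, params)
        cond2 = Condition(view, table, params)
        start = sample_start_genotypes(view, 0.10, 1, seed=2)[0]
        r1 = run_walk(start, cond1, 1500, seed=3, replicate=0)
        r2 = run_walk(start, cond2, 1500, seed=3, replicate=0)
        assert r1.events == r2.events
        assert r1.final_genotype == r2.final_genotype

    def test_requires_viable_start(self, enumerable):
        _, table, _, view = enumerable
        cond = Condition(view, table, PopulationParams(N=1000))
        dead = next(g for g in view.all_sense_genotypes()
                    if view.encoded_fitness(g) == 0)
        with pytest.raises(ValueError, match="viable"):
            run_walk(dead, cond, 10, seed=0)

    def test_no_mistranslation_synonymous_events_are_neutral(self, enumerable):
        _, _, _, view = enumerable
        params = PopulationParams(N=100, n=1)  # small N: plenty of fixations
        cfg = WalkConfig(params=params, table=None, total_attempts=2000,
                         replicates=10, seed=6)
        for record in run_walk_ensemble(view, cfg):
            for e in record.events:
                if e.synonymous:
                    assert e.s == 0.0

    def test_zero_table_walks_identical_to_none(self, enumerable):
        _, _, _, view = enumerable
        params = PopulationParams(N=1000, n=1)
        cfg_none = WalkConfig(params=params, table=None, total_attempts=1000,
                              replicates=5, seed=8)
        cfg_zero = WalkConfig(params=params, table=MistranslationTable.zero(),
                              total_attempts=1000, replicates=5, seed=8)
        recs_none = run_walk_ensemble(view, cfg_none)
        recs_zero = run_walk_ensemble(view, cfg_zero)
        for a, b in zip(recs_none, recs_zero):
            assert a.start == b.start
            assert [(e.attempt_index, e.to_genotype, e.s) for e in a.events] \
                == [(e.attempt_index, e.to_genotype, e.s) for e in b.events]

    def test_neutral_fixation_rate_on_flat_fixture(self, flat):
        """On the flat landscape every sense proposal is neutral, so the
        fixation count is Binomial(attempts, (1 - stop_fraction)/N)."""
        _, _, _, view = flat
        N = 50
        attempts, walks = 400, 300
        cfg = WalkConfig(params=PopulationParams(N=N), table=None,
                         total_attempts=attempts, replicates=walks, seed=12)
        records = run_walk_ensemble(view, cfg)
        counts = np.array([len(r.events) for r in records])
        p = (1 - STOP_HIT_FRACTION) / N
        mean, var = attempts * p, attempts * p * (1 - p)
        se_mean = math.sqrt(var / walks)
        assert abs(counts.mean() - mean) < 3 * se_mean


class TestPosthocRates:
    def test_no_fixation_constant_series(self, enumerable):
        _, table, _, view = enumerable
        start = sample_start_genotypes(view, 0.10, 1, seed=5)[0]
        record = WalkRecord(start=start)
        mean_rate = landscape_mean_rate(view, table, 200, seed=5)
        series = posthoc_rates(record, table, mean_rate)
        assert len(series) == 1
        assert series[0][0] == 0

    def test_uniform_table_normalizes_to_100(self, flat):
        _, _, _, view = flat
        code = view.code
        # every codon has 19 identical error rates -> identical genotype rates
        uniform = MistranslationTable(
            {c: {aa: 1e-4 for aa in "ACDEFGHIKLMNPQRSTVWY"
                 if aa != code.codon_to_aa[c]}
             for c in code.sense_codons})
        mean_rate = landscape_mean_rate(view, uniform, 50, seed=1)
        record = WalkRecord(start="GCTGAT")
        series = posthoc_rates(record, uniform, mean_rate)
        assert series[0][1] == pytest.approx(100.0)

    def test_matches_direct_recomputation(self, enumerable):
        _, table, _, view = enumerable
        params = PopulationParams(N=1000, n=1)
        cfg = WalkConfig(params=params, table=None, total_attempts=500,
                         replicates=1, seed=3)
        record = run_walk_ensemble(view, cfg)[0]
        mean_rate = landscape_mean_rate(view, table, 200, seed=3)
        series = posthoc_rates(record, table, mean_rate)
        genotypes = [record.start] + [e.to_genotype for e in record.events]
        for (_, pct), g in zip(series, genotypes):
            direct = 100 * genotype_mistranslation_rate(g, table) / mean_rate
            assert pct == pytest.approx(direct, rel=1e-12)


class TestBeneficialSupply:
    def test_zero_at_global_peak(self, two_peak):
        _, _, _, view = two_peak
        params = PopulationParams(N=10**6)
        peak = "GCTTGT"  # encodes "AC", the global optimum
        assert view.encoded_fitness(peak) == 1.0
        assert beneficial_supply(view, None, peak, params) == 0

    def test_hand_enumeration_l1(self):
        fitness = {aa: (0.9 if aa == "C" else 0.1)
                   for aa in "ACDEFGHIKLMNPQRSTVWY"}
        view = GenotypeFitnessView(PeptideLandscape(length=1, fitness=fitness))
        params = PopulationParams(N=10**6)
        # TGT (Cys) is the optimum; from TAT (Tyr) the neighbors include TGT
        count = 0
        for nbr in single_nucleotide_neighbors("TAT"):
            pep = translate(nbr)
            if pep is not None and pep != "Y" and fitness[pep] > 0.1:
                count += 1
        assert beneficial_supply(view, None, "TAT", params) == count
        assert count == 1  # only TAT->TGT is beneficial

    def test_bounded_by_neighborhood(self, enumerable):
        _, table, _, view = enumerable
        params = PopulationParams(N=10**6)
        g = "GCTGAT"
        assert 0 <= beneficial_supply(view, table, g, params) <= 18


class TestSummaries:
    def test_attribution_telescopes(self, enumerable):
        _, table, _, view = enumerable
        params = PopulationParams(N=10**4, n=1)
        cfg = WalkConfig(params=params, table=table, total_attempts=1000,
                         replicates=3, seed=10)
        records = run_walk_ensemble(view, cfg)
        summary = summarize_walks(records, view)
        cond = Condition(view, table, params)
        total_gain = sum(cond.mean_fitness(r.final_genotype)
                         - cond.mean_fitness(r.start) for r in records)
        assert (summary["fitness_gain_synonymous"]
                + summary["fitness_gain_nonsynonymous"]) == pytest.approx(
                    total_gain, abs=1e-9)

    def test_syn_fraction_and_counts(self):
        events = [
            FixationEvent(1, "A", "B", 0.1, False, 0.1, 0.2, 1e-3),
            FixationEvent(5, "B", "C", 0.0, True, 0.2, 0.2, 9e-4),
            FixationEvent(9, "C", "D", 0.2, False, 0.2, 0.3, 8e-4),
        ]
        record = WalkRecord(start="A", events=events, final_genotype="D",
                            final_fitness=0.3, final_fitness_fraction=0.3,
                            start_rate=1.1e-3)
        assert record.n_syn_fixed == 1
        assert record.n_nonsyn_fixed == 2

    def test_perfectly_anticorrelated_tau(self, enumerable):
        view = enumerable[3]
        # strictly larger s paired with strictly larger rate *decrease*
        events = [FixationEvent(i, "x", "y", s, False, 0.1, 0.1, rate)
                  for i, (s, rate) in enumerate(
                      [(0.1, 4.9e-3), (0.2, 4.7e-3),
                       (0.3, 4.4e-3), (0.4, 4.0e-3)])]
        record = WalkRecord(start="x", events=events, final_genotype="y",
                            start_rate=5e-3)
        summary = summarize_walks([record], view)
        assert summary["kendall_tau_s_vs_rate_change"] == pytest.approx(-1.0)

    def test_empty_input_rejected(self, enumerable):
        with pytest.raises(ValueError):
            summarize_walks([], enumerable[3])


def test_events_frame_columns(enumerable):
    _, table, _, view = enumerable
    cfg = WalkConfig(params=PopulationParams(N=10**4), table=table,
                     total_attempts=500, replicates=2, seed=1)
    df = events_frame(run_walk_ensemble(view, cfg))
    assert list(df.columns) == ["replicate", "attempt", "from", "to", "s",
                                "synonymous", "fitness_after",
                                "mistrans_rate_after"]
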