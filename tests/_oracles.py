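"""Independent brute-force oracles used to validate the production code.

These deliberately share no code paths with the package internals: variant
distributions are enumerated over the full outcome product, moments are
estimated by multinomial Monte Carlo, peaks by exhaustive neighborhood
comparison.
"""

import itertools

import numpy as np

from translerr.genetic_code import codons, single_nucleotide_neighbors


def brute_force_variants(genotype, table, prune_threshold=None):
    """All protein variants of a genotype by full product enumeration.

    Returns dict peptide -> probability; pruned (then renormalized) when a
    threshold is given, always keeping the encoded peptide.
    """
    outcome_lists = [table.codon_distribution(c) for c in codons(genotype)]
    encoded = "".join(table.code.codon_to_aa[c] for c in codons(genotype))
    probs = {}
    for combo in itertools.product(*outcome_lists):
        peptide = "".join(aa for aa, _ in combo)
        p = 1.0
        for _, q in combo:
            p *= q
        probs[peptide] = probs.get(peptide, 0.0) + p
    if prune_threshold is not None:
        probs = {pep: p for pep, p in probs.items()
                 if p >= prune_threshold or pep == encoded}
        total = sum(probs.values())
        probs = {pep: p / total for pep, p in probs.items()}
    return probs


def monte_carlo_moments(dist, view, n, draws, seed):
    """Mean/variance of cell fitness by direct multinomial sampling.

    Returns (mean, variance, se_mean, se_var) with standard errors estimated
    from the sample.
    """
    rng = np.random.default_rng(seed)
    q = np.array([p for _, p in dist.entries])
    f = np.array([view.peptide_fitness(pep) for pep, _ in dist.entries])
    # sampling per-protein variant indices is equivalent to the multinomial
    # count vector but avoids a draws x categories matrix
    idx = rng.choice(len(q), size=(draws, n), p=q)
    cell_fitness = f[idx].mean(axis=1)
    mean = cell_fitness.mean()
    var = cell_fitness.var(ddof=1)
    se_mean = cell_fitness.std(ddof=1) / np.sqrt(draws)
    # SE of the sample variance via fourth central moment
    m4 = np.mean((cell_fitness - mean) ** 4)
    se_var = np.sqrt(max(m4 - var**2, 0.0) / draws)
    return mean, var, se_mean, se_var


def exhaustive_peak_count(view, table, params, prune_threshold=1e-9):
    """Peak count over the full sense-genotype space, written from scratch.

    Uses its own variant enumeration, moment sums, union-find components and
    peak test; shares only the elementary definitions with the package.
    """
    code = view.code
    L = view.landscape.length

    sense = ["".join(c) for c in itertools.product(code.sense_codons, repeat=L)]
    moments = {}
    for g in sense:
        if table is None:
            mean, var = view.encoded_fitness(g), 0.0
        else:
            probs = brute_force_variants(g, table,
                                         prune_threshold=prune_threshold)
            mean = sum(p * view.peptide_fitness(pep)
                       for pep, p in probs.items())
            second = sum(p * view.peptide_fitness(pep) ** 2
                         for pep, p in probs.items())
            var = max(0.0, second - mean * mean) / params.n
        moments[g] = (mean, var)

    def neutral(a, b):
        ma, va = moments[a]
        mb, _ = moments[b]
        if ma <= 0 or mb <= 0:
            return False
        ne_a = params.N / (1 + va / ma**2)
        return abs(mb / ma - 1) < 1 / (4 * ne_a)

    parent = {g: g for g in sense}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    moment_set = set(sense)
    for g in sense:
        for nbr in single_nucleotide_neighbors(g):
            if nbr in moment_set and g < nbr:
                if neutral(g, nbr) and neutral(nbr, g):
                    parent[find(g)] = find(nbr)

    components = {}
    for g in sense:
        components.setdefault(find(g), set()).add(g)

    peaks = 0
    for comp in components.values():
        is_peak = True
        for g in comp:
            mg, vg = moments[g]
            if mg <= 0:
                is_peak = False
                break
            ne_g = params.N / (1 + vg / mg**2)
            for nbr in single_nucleotide_neighbors(g):
                if nbr in comp or nbr not in moment_set:
                    continue  # stop-containing neighbors are strictly lower
                s = moments[nbr][0] / mg - 1
                if not (s < -1 / (4 * ne_g)):
                    is_peak = False
                    break
            if not is_peak:
                break
        peaks += is_peak
    return peaks
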