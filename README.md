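# translerr

Quantitative modelling of how **mistranslation** — the erroneous
incorporation of amino acids during protein synthesis — reshapes protein
adaptive landscapes and the evolutionary dynamics that play out on them.

Translation errors occur at rates of 10⁻⁵–10⁻² per codon, orders of
magnitude above DNA mutation rates. A gene therefore encodes not one protein
but a *cloud* of protein variants, and the fitness of a genotype is a
property of that cloud. `translerr` is aimed at molecular evolutionists who
work with combinatorially complete protein fitness landscapes (deep
mutational scanning data and the like) and want to ask: what does the
landscape look like, and how do populations evolve on it, once translation
is error-prone?

## Model

For a nucleotide genotype of length 3L with codons c₁…c_L and a per-codon
error-rate table, each codon translates independently into its cognate amino
acid or one of the 19 others, so protein variant *v* is produced with
probability q_v = ∏ᵢ P(vᵢ | cᵢ). Variants with q_v below a prune threshold
(default 10⁻⁹) are dropped and the distribution renormalized. A cell
producing *n* protein copies draws them i.i.d. from this distribution
(multinomially); each copy contributes the landscape fitness f_v of its
variant, and cell fitness is the mean contribution:

- expected fitness  E(f) = Σ_v q_v f_v  (independent of n)
- between-cell variance  Var(f) = (Σ_v q_v f_v² − E(f)²) / n

A single-nucleotide mutation wt → mt is then scored by

- selection coefficient  s = E(f_mt)/E(f_wt) − 1
- effective population size  Ne = N / (1 + Var(f_wt)/E(f_wt)²)
  (nongenetic fitness variance amplifies drift)
- Kimura fixation probability
  u_fix = (1 − e^(−2·Ne·s·p)) / (1 − e^(−2·Ne·s)) with p = 1/N,
- near-neutrality when |s| < 1/(4·Ne).

On top of this sit origin-fixation adaptive walks (uniform proposals over
the 9L single-nucleotide neighbours, one Bernoulli fixation trial per
proposal), landscape-flattening regression, mutation-effect censuses with
and without mistranslation, nearly-neutral-network fitness-peak counting,
and epistasis-square classification (additive / magnitude / simple sign /
reciprocal sign). A synthetic-data module generates Rough-Mount-Fuji
landscapes and heterogeneous per-codon rate tables with realistic scales.

## Worked example

```python
import translerr as t

landscape, table, code = t.make_fixture("enumerable-L2")
view = t.GenotypeFitnessView(landscape)
params = t.PopulationParams(N=10**6, n=1)

dist = t.variant_distribution("GCTGAT", table)   # encodes peptide "AD"
m = t.fitness_moments(dist, view, n=1)
Ne = t.effective_population_size(params.N, m.mean, m.variance)
effect = t.mutation_effect(view, table, "GCTGAT", "GCCGAT", params)
```

prints, with the seeded fixture:

```
encoded peptide: AD
variants retained: 400
  AD  q=9.769e-01  f=0.1024
  ND  q=4.618e-03  f=0.2569
  AH  q=2.184e-03  f=0.1115
E(f)=0.10300  Var(f)=2.738e-04
Ne = 974844  (N = 1000000)
synonymous mutation GCT->GCC: s=-4.874e-03, class=deleterious, u_fix=0.000e+00
same mutation without mistranslation: s=0.0, u_fix=1.0e-06
```

Reading: error-prone translation of `GCTGAT` yields 400 protein variants
above the prune threshold; the encoded peptide keeps ~97.7% of the mass.
Because neighbouring variants here are on average fitter than "AD", the
expected fitness (0.103) sits slightly above the encoded fitness (0.102),
and the between-cell variance shrinks Ne by ~2.5%. Most strikingly, the
*synonymous* change GCT→GCC — exactly neutral under error-free translation
(u_fix = 1/N) — becomes deleterious, because GCC misreads into harmful
variants more often than GCT. This loss of synonymous neutrality is the
mechanism behind most of the package's landscape-level results.

The same pipelines are available from a shell:

```
translerr generate --L 2 --epistatic-sd 0.6 --seed 1 --out run/
translerr analyze --landscape run/landscape.tsv --rates run/rates.tsv \
    --N 1000000 --top-k 400 --out run/analysis/
translerr walk --landscape run/landscape.tsv --rates run/rates.tsv \
    --paired --N 100000000 --attempts 2000 --replicates 60 --out run/walks/
```

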