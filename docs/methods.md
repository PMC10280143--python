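# Methods

## The translation-error model

A genotype is a stop-free DNA sequence of length 3L whose codons are
translated independently. Independence across codons reflects the
observation that most translation errors arise from codon–anticodon
mispairing in the ribosome, a local event. The per-codon error model is a
categorical distribution over 20 amino acids: the cognate residue with
probability 1 − Σ(errors), and each of the 19 noncognate residues with its
measured (or generated) rate. Misreading into stop codons, processivity
errors, position-dependent rates, and misfolding/degradation effects are
out of scope.

**Variant enumeration.** The probability of producing protein variant *v*
is q_v = ∏ᵢ P(vᵢ|cᵢ). Enumerating all 20^L variants is unnecessary: the
enumerator does a depth-first branch-and-bound over per-codon substitutions,
abandoning any prefix whose probability, multiplied by the best achievable
suffix product, falls below the prune threshold (default 10⁻⁹ per variant).
The encoded peptide is always retained. After pruning, the retained mass is
renormalized to 1. Renormalization (rather than folding lost mass into the
encoded variant) keeps the distribution proper; at realistic rates the lost
mass is ≲10⁻⁵ and the choice is immaterial, as the brute-force oracle tests
confirm.

**Cell fitness moments.** A cell expresses *n* protein copies drawn i.i.d.
from the variant distribution; each copy contributes the landscape fitness
of its variant and cell fitness is the mean contribution. Hence
E(f) = Σ q_v f_v independent of n, and Var(f) = (Σ q_v f_v² − E(f)²)/n —
the variance of a mean of n i.i.d. draws. The multinomial count vector is
never materialized; only these two moments are consumed downstream. Both are
validated against direct multinomial Monte Carlo (10⁶ draws, 3-SE
agreement).

**Genotype mistranslation rate.** The probability that a produced protein
differs anywhere from the encoded peptide, 1 − ∏ᵢ cognate(cᵢ). This is an
exact identity with 1 minus the unpruned probability of the encoded
variant, and is the quantity tracked along adaptive walks (including "post
hoc" rates: the rates genotypes visited by error-free walks *would* have
had).

## Population genetics

For a single-nucleotide mutation wt → mt under a condition (a rate table or
none, an expression level n, a census size N):

- s = E(f_mt)/E(f_wt) − 1. Both means enter s; only the resident's moments
  enter Ne = N/(1 + Var(f_wt)/E(f_wt)²), because drift amplification is a
  property of the resident population.
- u_fix follows Kimura's diffusion formula with initial frequency p = 1/N
  (one copy among the N actual individuals — not 1/Ne).
- A mutation is (nearly) neutral when |s| < 1/(4Ne). The threshold uses the
  resident's Ne *under the active condition*, so the same |s| can be
  neutral without mistranslation and selected with it; this asymmetry is
  what depletes near-neutrality when errors are switched on.

Numerical care in u_fix: for |2·Ne·s| < 10⁻⁸ the formula is replaced by its
second-order series p·(1 + Ne·s·(1−p)), exact at s = 0 and avoiding 0/0
cancellation; for |2·Ne·s| > 700 asymptotic branches prevent overflow; the
result is clamped to [0, 1]. A dead resident with a viable mutant (never
reachable from viable walk starts) is scored as guaranteed rescue,
u_fix = 1.

The formula is validated against a vectorized haploid Wright–Fisher
simulator. The comparison tolerance is the Monte Carlo confidence interval
*plus* the diffusion approximation's own O(s²) bias — the diffusion's
selection parameter is ln(1+s), and at s = 0.05 the resulting offset is
detectable at 10⁵ replicates. This term is a property of the formula, not a
loosened test.

## Adaptive walks

Walks run in the origin-fixation (weak mutation–strong selection) regime:
each attempt draws one of the 9L single-nucleotide neighbours uniformly —
including stop-creating neighbours, which have fitness 0, s = −1 and
effectively never fix — and fixes it with a single Bernoulli draw at its
u_fix. The attempt index is the time proxy. Starts are sampled among viable
peptides in the bottom decile of the viable fitness distribution, with a
uniformly chosen synonymous encoding. Replicate r of a run seeded S uses
the stream `SeedSequence([S, r])`, so runs are reproducible per replicate
and the two conditions can be paired on identical proposal streams.

Per-genotype moments are memoized per condition; the cache is a performance
contract only. The full-scale profile is 10⁵ attempts × 10⁴ replicates; the
desk-scale default (10⁴ × 10²) is what tests and the acceptance script use,
with sizes stated inline where smaller.

One consequence of proposing stop-creating neighbours: on a perfectly flat
landscape the per-attempt fixation probability is not 1/N but
(1 − 23/549)/N, since 23 of the 549 directed mutations of a uniformly
drifting sense codon hit a stop. The neutral-calibration test asserts
binomial mean and variance against this exact closed form.

## Topography analyses

- **Flattening**: least-squares regression of E(f) with errors on encoded
  fitness over a genotype sample; slope m < 1 is the flattening signature
  (tops pulled down by deleterious variants, lethal/low genotypes pulled up
  by functional variants).
- **Censuses**: each sampled mutation is classified under both conditions;
  the 3×3 transition table exposes neutrality loss and
  beneficial↔deleterious sign flips, and the per-pair u_fix deltas the
  fixation-probability shifts.
- **Peaks**: the nearly-neutral graph joins neighbours that are mutually
  nearly neutral (both directions — this makes the networks well-defined
  undirected components despite the asymmetry of the ratio-form s). A
  connected component is a peak iff every outside neighbour of every member
  is deleterious relative to that member; stop-containing neighbours count
  as strictly lower. Ranking for top-K peak counting uses expected fitness
  under the active condition with lexicographic tie-breaks. Exhaustive
  enumeration over all 4^(3L) genotypes is only feasible at small L and is
  used as the test oracle; top-K subsetting is the supported path at scale.
- **Epistasis squares**: a wild type, two single-nucleotide mutations at
  distinct positions, and the double mutant. ε = f11 − f10 − f01 + f00 on
  raw (not log) fitness — the landscapes contain exact zeros, and the
  additive-scale definition matches the squares framework. |ε| below the
  wild-type drift scale E(f00)/(4·Ne00) is additive (configurable);
  otherwise the effect class of each mutation is compared across
  backgrounds (scored against the resident corner's Ne): zero, one or two
  class changes give magnitude, simple-sign and reciprocal-sign epistasis.
  Squares with an inviable corner are redrawn, since ratio-based classes
  are undefined there.

## Synthetic data

The landscape generator is Rough-Mount-Fuji: i.i.d. normal site/amino-acid
effects (weight `additive_weight`) plus i.i.d. normal epistatic noise per
peptide (`epistatic_sd`); the ratio of the two is the single ruggedness
knob. Values are min-max normalized, the lowest `lethal_fraction` quantile
is set to exact 0 (thresholding rather than a point mass, which preserves
neighbour-fitness correlation near the viability boundary), and viable
values are power-transformed (v → v^γ, rank- and endpoint-preserving) so
the viable mean hits `target_mean` (default 0.08, the scale of empirical
binding landscapes, with max fitness 1). Defaults: L = 2 over all 20 amino
acids — large enough for full 4⁶ genotype-space enumeration in oracles,
small enough for the test suite.

The rate generator draws log₁₀ rates normally around a per-codon random
effect (defaults: mean −3.5, sd 0.5, codon heterogeneity 0.5), clamped to
[10⁻⁵, 10⁻²] — the measured range of per-codon error rates in unstressed
*E. coli*. Per-codon error sums are validated < 1. All generators use
numpy's PCG64 with explicit `SeedSequence` integers, recorded in output
metadata.

What the synthetic data does **not** emulate: the empirical landscapes'
specific fitness distributions and correlation structure, codon-usage bias,
mRNA-level effects of synonymous changes, and any coupling between a
codon's error rate and its cognate residue's biochemistry. Passing tests
therefore establish the model's internal correctness and the *direction* of
mistranslation's effects on rugged landscapes — flattening (m < 1),
neutrality loss, extra peaks, extra epistasis, extra synonymous fixations —
not the magnitudes reported from any particular empirical dataset.

## Degenerate inputs and tie-breaking

Stop-containing genotypes stay in genotype space (walks must be able to
propose and reject them) with fitness 0; they are invalid inputs to the
variant model itself. s is 0 when both means are 0 and +∞ for rescue. Ne is
undefined (error) for a dead resident. Peptides absent from a
reduced-alphabet landscape follow an explicit missing policy (error or
fill-zero). Top-K ranking and all file writers order lexicographically;
floats are serialized at 17 significant digits and re-read with round-trip
parsing, so write→read is bit-exact.

## A note on codon-graph peaks

Even a purely additive peptide landscape generally has more than one
nucleotide-level peak: the codon graph does not allow every beneficial
amino-acid exchange in a single nucleotide step, so genotype-space local
optima exist that are not peptide-space optima. The generator tests
therefore assert single-peakedness of additive landscapes at the peptide
level, and monotonicity of the nucleotide-level peak count in the
ruggedness knob.

## Known limitations

Haploid, asexual, one-locus dynamics only; no clonal interference,
recombination or dominance. Time is measured in attempted mutations, not
generations. Exhaustive peak enumeration is limited to small L. The
variance model treats per-copy fitness contributions as independent, which
ignores any shared cellular state between copies.
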