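# Methods

## Pairwise dN/dS by counting

The estimator is the Nei–Gojobori (1986) counting scheme with Jukes–Cantor
correction, chosen over maximum-likelihood codon models because it is
deterministic, cheap, and checkable against exhaustive enumeration — every
site count and pathway average in the package is oracled in the test suite
by independent brute force. The pieces:

- **Sites.** For a sense codon, each of its nine single-nucleotide
  neighbours contributes ⅓ of a synonymous site if it encodes the same
  amino acid, otherwise ⅓ of a nonsynonymous site. Changes creating a stop
  codon count as nonsynonymous opportunities. S + N = 3 exactly per codon.
  For a pair of sequences, per-codon sites are summed and averaged between
  the two sequences.
- **Differences.** For codons differing at k positions, all k! orderings
  of single steps are enumerated; each step is classified synonymous or
  nonsynonymous; orderings passing through a stop codon are dropped and
  the average renormalised. Under the standard code every sense–sense pair
  retains at least one stop-free ordering (verified exhaustively in the
  tests); the fallback that classifies stop-passing steps as nonsynonymous
  is therefore unreachable in practice but kept and flagged. Orderings are
  weighted equally — no transition/transversion weighting in counting.
- **Correction.** pS = Sd/S and pN = Nd/N are corrected with
  d = −¾ ln(1 − 4p/3). p ≥ ¾ is saturation: the pair carries no usable
  signal and is excluded from downstream medians, with exclusion counts
  reported. One degenerate case gets a defined answer: a pair whose
  *synonymous* proportion saturates while Nd = 0 has ω = 0 (no
  nonsynonymous divergence at all), rather than being discarded.
- **ω is undefined when dS = 0** (including identical sequences); such
  pairs are excluded from medians, not capped.

### Known bias under transition-biased mutation

Because sites are counted with equal weight on all nine neighbours, the
estimator systematically underestimates ω when mutation favours
transitions. The expected low-divergence ratio of estimate to truth equals
(R_N/N)/(R_S/S), where R_S, R_N are the accepted synonymous/nonsynonymous
proposal fluxes over the uniform sense-codon distribution; at κ = 2 this
evaluates to 0.837 (0.945 at κ = 1, where the residual comes from
stop-codon rejection asymmetry). Monte-Carlo recovery under the package's
own simulator reproduces this: roughly −14 to −17% mean relative error at
κ = 2 across ω ∈ {0.1, 0.5, 1.0}, monotone in ω. This is the documented
price of a transparent counting method; it is immaterial for the median
*rank* statistic the pipeline is built around (the bias is nearly uniform
across ω), but absolute ω values should be read with it in mind.

## Codon substitution simulator

A sequence of n codons drawn uniformly over the 61 sense codons evolves by
Poisson(t·n) proposal events. Each event picks a codon and position
uniformly and proposes an alternative base with relative rate κ for the
transition and 1 for each transversion; the proposal is accepted with
probability 1 if synonymous, ω if nonsynonymous, 0 if it would create a
stop. `t` is therefore the expected number of proposals per codon, not the
realised substitution distance. All randomness flows through one
`numpy.random.Generator`, so outputs are byte-identical across runs for a
fixed seed.

## The median characteristic

For a gene and focal species, ω is estimated against every *other*
functional ortholog of the taxon (a star around the focal species, giving
one value per species as in a per-species scatter plot — not all pairs
within the taxon), and the median (mean of the two middle order statistics
for even counts) is taken over the defined, unsaturated pairs.
Pseudogene/lost species contribute no characteristic, never affect other
species' characteristics, and are excluded from regressions; per-species
exclusion counts keep the sample-size bookkeeping auditable. The
per-gene "median variation interval" is the (min, max) over species.

## Trait association

Ordinary least squares of trait on characteristic; the weight relationship
is fitted on lg(weight in grams), which linearises an exponential
weight–rate dependence. Significance is the standard two-sided t test of
Pearson's r with n − 2 df (`scipy.stats.linregress`). Species missing a
trait are dropped per trait, not listwise, so n can differ between the
MRLS and weight rows of one gene. No phylogenetic correction is applied —
species are treated as independent points, which overstates significance
when the trait and the characteristic are both phylogenetically
autocorrelated; p-values are raw (no multiple-testing correction across
genes or amino acids). The α threshold separating "associated" from
"not associated" defaults to 10⁻³ and is inclusive at the boundary.

## Composition and domain analyses

Occurrence is the percentage of each standard amino acid among counted
residues of a species' full (unaligned) protein; gaps and X are excluded
from the denominator, so profiles sum to 100% exactly. Correlation with a
trait is per amino acid across species; a constant occurrence yields an
undefined correlation for that amino acid only.

The domain consensus is per-column plurality over all species (gaps
ignored; ties broken alphabetically and flagged). Deviation tables count,
per taxon and position, species differing from the consensus — all
substitutions, or only radical ones, i.e. those crossing the six-group
partition {C} / {S,T,A,G,P} / {D,E,N,Q} / {H,R,K} / {M,I,L,V} / {W,Y,F}.
Gaps are never deviations and a radical count can never exceed the
all-substitutions count. The LQ comparison splits species at a 1-based
domain position — by exact residue or by radical-vs-consensus status — and
reports 100·(median_in − median_out)/median_out over species with an LQ.

## Synthetic studies

The generators define the study conditions and default to the magnitudes
of the motivating analysis: a 49-species panel, characteristic medians
spanning [0.074, 0.178], a planted lifespan regression y = 439x − 36
(noise calibrated so the population correlation is 0.76; lg-weight
y = 25x − 1 at r = 0.67), leucine/proline composition correlations
+0.62/−0.7, a 54-position domain, and a +17% carrier LQ shift. All are
configuration. Emulated features: star-shaped divergence from a common
ancestor with species-specific ω, pseudogenization (planted internal
stops), gene loss, Gaussian trait noise on the modelled scale, log-normal
LQ spread. Not emulated: realistic tree shape (no shared internal
branches), indels, codon-usage bias, and phylogenetic autocorrelation of
traits — so passing recovery tests demonstrates correctness of the
machinery, not robustness to those real-data features.

Two generator details are deliberate:

- Lifespans must be positive, so the trait generator redraws non-positive
  MRLS values (bounded retries, then a small positive floor). This
  truncation flattens the low end of a planted line whose intercept is
  negative; validation experiments that target the *planted* r therefore
  add a constant offset to the generated lifespans instead — slope,
  correlation and p-value are invariant under translation of y, so the
  recovered quantities are identical while every stored lifespan stays
  positive.
- Composition profiles keep unplanted amino acids at a fixed base
  occurrence and absorb the planted perturbations into one slack amino
  acid (glycine by default), so each profile sums to exactly 100%; the
  slack residue consequently carries an induced anti-correlation and
  should not itself be read as a planted signal.

## Numerical and format conventions

Alignment filtering is codon-granular: a gap or N at any of a codon's
three positions removes that codon column for all retained sequences,
preserving frame; sequences shorter than a configurable threshold
(default: half the alignment length in codons, gap-free) are dropped
first, and columns are re-evaluated on the remainder. Filtering is
idempotent and order-preserving. Reports are TSV with 1-based coordinates
and literal `NA` for undefined values; floats are written with a fixed
`%.10g` format and the manifest with sorted JSON keys, which is what makes
whole-pipeline reruns byte-identical. Species identifiers are exact-match
strings. Problem sizes in the validation suite (e.g. 2000-codon pairs for
estimator recovery, 49-point regressions, 200–1000 replicates, 14–30
species pipelines) were chosen as the smallest sizes at which Monte-Carlo
error is comfortably below the effect being measured.
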