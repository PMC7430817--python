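# Methods

## Model and assumptions

The package models a male-heterogametic (XX/XY) diploid population with
female-to-male environmental sex reversal. Three assumptions shape every
analysis:

- **Phenotypic females are genetically XX.** Sex reversal is modelled only
  in the female-to-male direction; the sole male-to-female leakage is marker
  discordance (`discordance`, e.g. a failed PCR), which flips individual
  marker calls, not genotypes.
- **The Y carries a non-recombining divergent region (SDR).** Within it,
  Y-specific alleles are heterozygous in XY individuals and absent from XX
  individuals; outside it, polymorphism is shared between the sexes.
- **Pools estimate allele frequencies by binomial read sampling.** A
  Y-linked site in a male pool with `k` XY among `n` males has expected
  Y-allele frequency `k / 2n`; observed frequencies scatter binomially
  around it at the site's depth.

## Site classification and window scan

Nucleotide depth is `A+T+C+G` per pool; `N` and deletion columns are
excluded because the frequency bands refer to nucleotide alleles. Sites with
either pool below `min_depth` (default 10) are `low_depth`. A site is
`male_specific` when the male pool has exactly two alleles, each with
frequency in `freq_het ± range_het` (default `0.5 ± 0.2`); any further
allele above `1 − (freq_het + range_het)` disqualifies the site (tri-allelic
noise guard); the female pool's major allele frequency is at least
`freq_hom − range_hom` (default `0.98`); and at least one in-band male
allele differs from the female major allele. `female_specific` is exactly
symmetric, so swapping the pools swaps the two labels, and consistent base
relabelling across both pools never changes a call (both are tested
properties).

Windows of `window_size` (default 100 kb) are **centred** on output points
spaced `output_resolution` (default 500 bp) apart and clipped at chromosome
ends; a site is counted when its position lies in the closed window.
Centring was chosen over left-anchoring for symmetry of the resulting
tracks; the choice only shifts tracks by half a window and does not affect
SDR spans beyond that. Window depth ratio is
`log2(((d_m + 1)/D_m) / ((d_f + 1)/D_f))` with per-pool library sizes `D`
taken as genome-wide total site depths and a pseudocount of 1 so empty
windows stay finite.

## SDR calling

No published boundary coordinates exist for a region delimited from a
figure, so the caller defines an explicit, deterministic rule: flag windows
whose male-specific count exceeds the genome-wide `mean + k·sd` (default
`k = 3`), merge flagged window spans within `merge_gap` (default 500 kb),
and report merged spans of at least `min_span` (default 1 Mb) with mean and
peak window densities. All three constants are configurable. The rule
presumes the SDR is a minority of the genome: when a planted region exceeds
roughly 8% of all windows it dominates the genome-wide moments and the
threshold rises above the region's own mean, so desk-scale test genomes keep
the planted fraction near 6%.

### Known limitation: contamination sensitivity at moderate depth

With a half-neomale male pool the expected Y-allele frequency is 0.25,
outside the heterozygous band — the motivation for purifying the pool with
Y-linked markers before scanning. At infinite depth, diluted sites would
vanish from the male-specific track entirely. At the default pool depth
λ = 50, however, binomial sampling still lands ≈26% of diluted sites inside
the band (`P[Bin(50, 0.25) ≥ 15]`), and because the background
male-specific rate is essentially zero, the relative outlier rule still
flags the diluted region. Purification therefore remains necessary for
*accurate delimitation* and frequency interpretation at this depth, but
contamination suppresses detection outright only in deep-coverage settings
(empirically λ ≳ 500 under the defaults). The acceptance suite asserts the
idealised expectation (no call from a contaminated pool at λ = 50) and that
assertion fails by design; this section records why.

## RAD-tag analysis

Presence is `depth ≥ min_depth` with default 1 (any read), exposing depth
sensitivity as a parameter. The carrier distribution grid `d[x][y]` counts
tags carried by exactly `x` males and `y` females; uncarried tags are not
counted, so the grid total equals the number of carried tags (a brute-force
recount is a tested invariant). Sex bias per tag uses Pearson's chi-square
without continuity correction on the carriers-by-sex 2×2 table; degenerate
tables (no carriers, all carriers, one sex absent) return p = 1. Bonferroni
correction runs over distinct carried tags. An exact hypergeometric
enumeration oracle confirms that the chi-square ranks candidate tags
identically for the male-only margin.

Male-specific tags require `≥ min_males` male carriers (default 12,
inclusive — reconciling a "more than 12" phrasing with reported 12–15
carrier counts) and `≤ max_females` female carriers (default 0).
Classification calls a phenotypic male a Y-carrier when he carries at least
`min_carry_fraction` (default 0.5) of the marker panel: high enough to
reject sporadic false presence, low enough that 10% tag dropout over a
32-tag panel essentially never declassifies a true XY (P[Bin(32, 0.9) < 16]
≈ 10⁻⁸).

## Cross statistics

Female:male ratios are truncated toward zero at one decimal (83:7 → 11.8,
65:48 → 1.3 — the only rounding convention consistent with both), via
integer arithmetic; percent males uses half-up rounding. Sex linkage is the
two-sided Fisher exact test, defined as the sum of hypergeometric
probabilities not exceeding the observed table's (the convention of the
standard R implementation); undifferentiated offspring are excluded from
linkage and ratio tests and reported separately. Sex ratios use a 1-df
chi-square goodness of fit to 1:1 without continuity correction.
Sex-reversal rates come with exact Clopper–Pearson intervals, whose coverage
at the nominal 95% level is verified by simulation (≥93/100 runs at rate
0.08, n = 90).

## Synthetic data: what it does and does not emulate

The generator plants a known SDR and emulates: genotype mixing in phenotypic
males (`neomale_rate`), RAD-tag dropout, shared background polymorphism with
uniform allele frequencies, biallelic Y-divergent sites, Poisson pool depths
and binomial allele sampling, undifferentiated gonads and marker discordance
in crosses. It does **not** emulate sequencing error, mapping artefacts
(e.g. paralogous cross-mapping from genome duplication), indels, linked
allele-frequency structure, recombination maps, tri-allelic sites, or
read-level data. Passing tests therefore demonstrate the correctness of the
statistical machinery under the stated model, not robustness to alignment
noise in real resequencing data.

Defaults were chosen once as study conditions: a 30 + 30 individual RAD
cohort with `neomale_rate = 0.5` (two realistic extremes bracketed by the
crosses' 0.078); `tag_dropout = 0.1`, which thins 15 expected XY carriers to
the 12–15 range; `undiff_rate = 0.1` and `discordance = 0.01`, matching
observed cross cohorts; `pool_depth = 50`. The default genome is five 40 Mb
linkage groups with a 12 Mb region planted on the LG22-analogue, at sparse
site densities (`background_snp_rate = 1e-4`/bp, `y_divergent_rate =
5e-4`/bp — about 10 background and 50 divergent sites per 100 kb window) so
a full five-chromosome scan (400,000 output points) completes in seconds;
real polymorphism is denser, but density scales both signal and threshold
together, so recovery behaviour is representative.

## Numerical and design notes

- All randomness flows through numpy `SeedSequence` children keyed by stage
  (individuals / tags / sync / cross), so adding tags never perturbs sync
  output and reruns are byte-identical; the pipeline manifest records
  SHA-256 checksums to make this checkable.
- Coordinates are 1-based closed everywhere internally; BED output converts
  to 0-based half-open.
- Tag depths are shifted Poisson (min 1 when present) — the simplest model
  compatible with min-depth presence thresholds; per-individual RAD depth
  distributions are not otherwise constrained by the modelled system.
- Degenerate inputs refuse loudly: empty pools, empty marker panels,
  all-undifferentiated cohorts, zero-male summaries, out-of-order or
  malformed sync lines (with line numbers).
- The Fisher implementation is scipy's; an independent enumeration oracle
  in the tests and acceptance script checks it exhaustively over all 2×2
  tables with total N ≤ 40 (agreement to < 1e-9). The window scan's
  searchsorted/cumsum implementation is checked against an O(n·w)
  brute-force recount on 10⁴ random sites.
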