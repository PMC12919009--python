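# Methods

This note records the models, conventions and numerical choices behind
`endoclock`, and what the synthetic-data tests do and do not demonstrate.

## Codivergence calibration

When an endosymbiont is obligately vertically inherited, host speciation
dates its symbiont's divergence. Given a fossil-calibrated host MRCA age
`T` (years, with an HPD interval) and the Jukes–Cantor-corrected sequence
divergence `d` (substitutions per third-position site, tip to tip) between
the symbionts of the two descendant host lineages, the substitution rate
is

    r = d / (2 T)

The factor 2 reflects the tip-to-tip convention: `d` accumulates along
two branches of length `T`. Only host-age uncertainty is propagated into
the rate interval — `r_slow = d / (2 T_upper)`, `r_fast = d / (2 T_lower)`
— matching the practice of treating the sequence divergence of
genome-scale concatenations as effectively noise-free relative to the
fossil uncertainty. When a trio (congener pair plus outgroup) provides two
sister-to-outgroup divergences, they are averaged before dividing.

Third-position distances use pairwise deletion (a site is compared only
when both taxa carry A/C/G/T) and the Jukes–Cantor correction
`d = −(3/4)·ln(1 − (4/3)p)`, which assumes equal base frequencies and
exchange rates; it saturates at `p = 3/4`, and the implementation refuses
p at or beyond that boundary rather than extrapolating. Printed divergence
percentages consumed from published-style tables are treated as already
corrected; raw counts are corrected exactly once.

## Rate uncertainty: lognormal multiplier and the CPR

Empirical support ranges for the calibrations run roughly from half to
double the point estimate. Rate uncertainty is therefore modeled as a
multiplicative lognormal `X = exp(Normal(0, σ))` with σ fixed by
`P[X < 1/fold] = P[X > fold] = tail_prob` (defaults fold = 2,
tail_prob = 0.025), i.e. `σ = ln(fold)/z_{tail}` = 0.353653 at the
defaults, giving `median(X) = 1` and `E[X] = exp(σ²/2) ≈ 1.06`. Node-age
intervals under a rate prior are equal-tailed 2.5/97.5 Monte Carlo
percentiles of `age/X` (linear interpolation); since `age ∝ 1/rate` these
match the analytic lognormal quantiles, which the tests verify to 1%.

Between-calibration spread dominates within-calibration statistics, so
point summaries average the fastest and slowest calibration and the
"conservative plausible range" (CPR) spans the fastest calibration's
statistical lower bound to the slowest calibration's upper bound. The CPR
always contains the plausible point by construction.

## Chronogram handling

Relative chronograms are rooted ultrametric trees with root age fixed
to 1. Ultrametricity is checked to a relative tolerance of 1e−6 of the
root depth (sampler output is never exact); the offending tip is named on
failure. Polytomies are accepted — collapsed low-support nodes are normal
input — and the MRCA of tips inside a polytomy is the polytomy node.
Scaling is linear: by a crown age in years, or by `depth_subs / rate`
with the lognormal multiplier supplying intervals as above.

## Horizontal-transfer screen

At a single-copy locus shared by a set of closely related genomes, a
horizontally acquired allele shows far more differences from every other
allele than the remaining alleles show among themselves. The screen
counts raw nucleotide differences over all sites (pairwise deletion) and
flags an allele as a two-fold outlier when its *minimum* pairwise
difference to all others is at least twice the *maximum* background
pairwise difference ("differed from all other alleles" — the weakest link
must satisfy the criterion). A zero-variation background makes the ratio
meaningless; the verdict is then `indeterminate` and the raw counts are
reported so callers can apply absolute thresholds. Exact ties between
candidate alleles also yield `indeterminate`. Locus filters retain
single-copy, in-frame loci (all gap runs multiples of 3, at most one
gapped genome by default, optional 300-bp minimum length for
recombination-style screens) and log one reason per rejected locus.

## mtDNA dating and acquisition modes

Because mitochondria and maternally inherited symbionts cotransmit,
introgression predicts concordant mtDNA and symbiont divergence times,
both more recent than host (nuclear) divergence. The mtDNA clock is a
conservative envelope built from recently diverged host pairs: the point
rate averages the per-pair point rates and the envelope spans the extreme
interval bounds. The classifier is pure interval algebra ("entirely
below" strict): symbiont CPR below the mtDNA interval ⇒ `horizontal`;
mtDNA not below host divergence (introgression excluded) with a young
symbiont ⇒ `horizontal` with its own rationale; symbiont/mtDNA overlap
with both below host ⇒ `introgression_possible`; everything overlapping
host ⇒ `cladogenic_consistent`; otherwise `indeterminate`. Judgments the
interval logic cannot encode (e.g. saturation-driven mtDNA rate slowdown
in deeply diverged pairs) are deliberately out of scope; the rationale
string names the governing comparison so such cases can be audited.

## Selection statistics

Paired ω contrasts use the one-sided Wilcoxon signed-rank test (exact
null by the generating-function recursion for n ≤ 25 without ties; zeros
dropped, ties fall back to a mid-rank normal approximation with tie and
continuity corrections, with a warning) and the Hodges–Lehmann estimator
(median of Walsh averages) with the exact CI from signed-rank inversion:
the CI endpoints are Walsh-average order statistics at the largest k with
`P(V ≤ k) ≤ α/2`. Unpaired contrasts use the exact Mann–Whitney analogue
with rank-sum inversion over the pairwise differences.

The Bayesian bootstrap draws flat-Dirichlet observation weights
(normalized Exp(1) samples) and computes the linearly interpolated
weighted median: CDF positions are the mid-cumulative weights
`c_i − w_i/2`, so a single observation returns itself and equal weights
reduce to the ordinary interpolated median; this convention keeps
`P(Δ < 0)` exactly symmetric on sign-symmetric data. Default B = 20,000.

Domain-vs-background contrasts of per-site posterior ω use the difference
of group means, a within-group percentile bootstrap (default 10,000) for
the CI, and a site-label permutation test (default 10,000,
p = (r+1)/(B+1)). The tested direction is fixed a priori
(`alternative="less"`, the domain-under-stronger-constraint hypothesis).
Taking the direction from the observed sign is available as
`alternative="observed"` for exploratory scans, but it is anti-conservative
under the null (about twice the nominal rate below any threshold) and is
therefore not the default. Masked sites (e.g. positions whose
positive-selection signal is a multi-nucleotide-mutation artifact) are
excluded from every summary.

## Spatial-window Ka/Ks and block resampling

For each residue of a reference structure, all residues within 10 Å
(Euclidean, inclusive, self included) are pooled and Nei–Gojobori-style
counting Ka/Ks is computed on the pooled codons: per-codon site fractions
averaged over the two sequences, multi-step codon differences averaged
over all minimal mutational pathways that avoid intermediate stop codons
(all pathways if every one is blocked), mutations creating stops counted
as nonsynonymous in site totals so each codon contributes exactly 3
sites, and Jukes–Cantor applied separately to pN and pS. Windows with no
synonymous signal at all receive a Ks = 99 sentinel; the filter then
keeps `0.1 ≤ Ks ≤ 2.0` (the regime where ω is neither unstable nor
saturated) and pLDDT ≥ 70 (confident structure prediction). Codons that
are stops in either sequence are skipped with a warning, not fatally —
disrupted alleles occur.

Window series inherit spatial autocorrelation from the shared-sphere
construction, so contrasts of `median log(ω + 10⁻⁶)` between two series
(Δ per pair; Δp averaging pairs; exp(Δp) the geometric-mean ω ratio) are
resampled at block level. The offset 10⁻⁶ is fixed, never silently
configurable. The integrated autocorrelation time is
`1 + 2·Σ ρ̂(k)`, summed until the first non-positive autocorrelation
(that terminating term included, so anti-correlated series give IAT < 1),
floored at 0.5; block length is `clamp(round(2·IAT), 6, 30)` per series
and the pairwise maximum is used. The non-circular non-overlapping
moving-block bootstrap (default B = 5,000) resamples blocks with
replacement to the original length (last partial block kept, excess
truncated) and reports BCa intervals: z₀ from the fraction of replicates
strictly below the observed Δp (ties counted half, clamped away from
0/1), acceleration from a leave-one-pair-out jackknife; a single pair
degrades to a percentile interval with a warning.

The block-label permutation test deals one shuffled pool of blocks to the
first label until its length is matched and the remainder to the second
(wrapping only to cover the at-most-L−1 shortfall truncation can leave),
with p = (r+1)/(B+1), default B = 10,000. An alternative scheme that
rebuilds each label independently from the pool (so one block can appear
under both labels) was evaluated and rejected: the shared blocks
correlate the two permuted series, shrink the null variance, and inflate
the false-positive rate to roughly twice nominal; the without-replacement
split is calibrated (5–8% of null simulations below p = 0.05) while
retaining power on planted effects.

## Synthetic data

The generators replace genome-scale inputs with desk-scale emulations
carrying planted, recoverable truth:

* **Codiverging triplets.** Sequences evolve site-independently under the
  exact Jukes–Cantor transition kernel along a shared ultrametric host
  tree, with compartment-specific rates. Defaults emulate the observed
  relative-rate structure — symbiont 1.82×10⁻⁹ and host-nuclear
  1.75×10⁻⁹ substitutions/third-site/year (ratio ≈ 1.04), mtDNA
  2.51×10⁻⁸ (≈ 13.8× the symbiont) — on a trio whose congeners split at
  3.1% of a 64.73 MY crown age. By default only third positions evolve
  (first/second positions are a shared constant backbone), sufficient and
  fast when only third-position divergence is consumed; a uniform mode
  evolves all positions.
* **HGT implants** replace one taxon's allele with the same allele
  evolved onward by a stated divergence over all positions, emulating
  replacement by a distant donor.
* **ω series** are stationary AR(1) Gaussians on the log scale
  (marginal sd 0.35 around log ω ≈ −1, i.e. ω ≈ 0.37, the purifying
  regime) with a planted location gap (−0.23 by default) and analytic
  IAT `(1+φ)/(1−φ)`.
* **Residue clouds** are ideal α-helices (2.3 Å radius, 1.5 Å rise,
  100° twist; ≈3.8 Å consecutive spacing) with a configurable
  low-confidence fraction.

What these emulations do **not** capture: among-site rate heterogeneity,
base-composition bias, indels and alignment error, recombination,
codon-model ω estimation error, and real protein geometry. Passing tests
therefore demonstrate the correctness and calibration of the arithmetic
and inference machinery under its stated assumptions, not robustness to
those real-data complications.

## Problem sizes

The test suite runs the recovery and calibration checks at deliberately
modest sizes chosen to keep Monte Carlo error well inside the asserted
tolerances: divergence recovery on 10⁴–10⁵ third positions, rate-ratio
recovery over 50 replicate loci of 4,000 codons, IAT on 2×10⁴-point
series, bootstrap coverage over 100 runs of three 400-point pairs at
B = 1,000, and null-calibration sweeps of 100–200 simulations at
B = 99–199. Production-scale defaults (B = 5,000/10,000/20,000) remain
the package defaults.

## Known limitations

* Rate intervals ignore divergence-estimation error by design; for short
  alignments that error is not negligible.
* The classifier encodes interval algebra only; biological judgment
  (hybridization feasibility, mtDNA saturation) must be applied by the
  user.
* Exact rank tests require tie-free data; posterior-ω tables rounded to
  few decimals will silently engage the normal approximation (a warning
  is emitted).
* The NG86 counting core is not a maximum-likelihood codon model; it is
  the deliberate, reproducible counting convention used for window
  statistics, not a substitute for model-based ω estimation.
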