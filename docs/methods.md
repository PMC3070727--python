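# Methods

This note documents the statistical models behind `orthocorr`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions a user relying on the
results should know.

## Differential expression

Expression values are assumed already normalized and log2-transformed;
the package performs no normalization (platform preprocessing such as RMA
is upstream of its scope).  The per-transcript effect is the difference
of group means on the log2 scale, Δg = mean(case) − mean(control), tested
with a pooled-variance two-sample t.  Because the mouse arm of the
emulated design has only 2–3 samples per group, per-transcript variances
are individually unreliable; the optional empirical-Bayes moderation
shrinks them toward a common prior.  Under the scaled-F working model
s²g ~ s²0·F(dg, d0), the first two moments of log s²g give closed-form
estimates of (d0, s²0) via digamma/trigamma inversion (a Newton iteration
solves trigamma(y) = x); the moderated variance is the precision-weighted
blend s̃²g = (d0·s²0 + dg·s²g)/(d0+dg) on d0+dg degrees of freedom.  When
the observed spread of log s²g does not exceed what sampling alone
implies, d0 = ∞ and every transcript uses s²0.  Moderation never changes
the sign of a statistic (the variance is shared between numerator-free
quantities), which the tests assert.  Transcripts with zero residual
variance get |t| = ∞ (p = 0) unless the fold change is also zero; a run
in which *every* transcript has zero variance without moderation is an
error rather than a silent answer.

Multiple testing uses Benjamini–Hochberg adjustment (statsmodels'
implementation behind the package's own surface, verified against a
definitional oracle over all small permutations).

Selection rules are centralized in `AnalysisConfig`: the broad human
selection (q < 0.05, |log2fc| > 0.5) feeds term-level analyses and model
clustering; the strict selection (q < 0.05, |log2fc| > 1.0) feeds the
concordance and contingency tests; the mouse selection is comparison-wise
p < 0.05 with no fold-change cutoff, reflecting the low power of an
n = 3 vs 3 design.  Exact zero fold changes count as "up" in two-way
splits; on continuous data this is a measure-zero convention, logged when
it fires.

## Ortholog pairing

The ortholog map is many-to-many at the transcript level; each
(human transcript, mouse transcript) pair contributes one row to the pair
table, so a human transcript with two mouse partners appears twice.
Pairs missing a fold change on either side are dropped with a logged
count.  Gene-level operations (enrichment-score analysis, trademark
lists) collapse transcripts to gene symbols by the per-sample maximum;
transcripts without a symbol are kept for transcript-level analyses and
dropped only by the collapse.

## The five significance methods

**Concordance proportions.** Every mapped mouse transcript of a human DE
set is classed increased (log2fc ≥ 0) or decreased — there is no
"unchanged" class, so n1 + n2 = n.  The null treats the n mapped
transcripts as a uniform draw from the mapped mouse population (M
transcripts, K increased); the band is the central 95% of
Hypergeom(M, K, n) on n1 and the p-value its upper tail.  Bands are
equal-tail with inner rounding: lo is the smallest x with CDF(x) > α/2,
hi the smallest with CDF(x) ≥ 1 − α/2, so coverage is ≥ 95% and, for the
set sizes this analysis meets (n in the hundreds), within about a point
of nominal.  The band is reported on n1; the decreased-count band is its
mirror n − (hi, lo).

**Ranked-list overlap.** Both species are ranked by signed fold change
within the ortholog-mapped universes.  At rank N, A(N) is the set of
mouse transcripts orthologous to the human top-N (each mouse transcript
counted once, entering at the smallest rank among its partners; size
a(N)), and the overlap is |A(N) ∩ mouse top-N|.  Ranking the mouse side
within the mapped universe (M_m transcripts) makes the null of the
overlap exactly Hypergeom(M_m, a(N), N), which is the band drawn; this
is the construction under which the band's coverage calibrates.  The
whole curve is computed in O(M log M) via entry-rank sorting.

**Contingency / adjusted residuals.** Ortholog pairs are cross-classified
by the strict human and comparison-wise mouse labels into a 3×3 table.
Adjusted residuals rᵢⱼ = (Oᵢⱼ − Eᵢⱼ)/√(Eᵢⱼ(1 − Rᵢ/T)(1 − Cⱼ/T)) are
approximately standard normal per cell under independence; cells with
|r| > 3 are flagged.  Calibration (mean ≈ 0, sd ≈ 1 over independent
label draws at the study's pair count) is asserted by test.

**Detection-rate curves.** The foreground is the human orthologs of the
200 mouse transcripts most strongly altered at p < 0.05; the background
is the human orthologs of mouse transcripts with p > 0.20.  Scanning the
human ranking, each curve is the cumulative fraction of its set
encountered; the area is the mean of (foreground − background) over all
ranks — 0 when the foreground is exchangeable with background, positive
when it concentrates at the top.  The area is reported descriptively; no
analytic null is attached to it.

**Running enrichment score.** The unweighted form: along a gene-level
ranking of M genes, the running sum gains 1/|S| at each member of the
set S and loses 1/(M−|S|) otherwise; it starts and ends at zero, and the
ES is the extremum of largest magnitude (exact ties resolve positive,
with a 1e-12 tolerance so floating-point noise cannot flip the sign).
The null draws random same-size gene sets from the ranking — the
hypothesis is about the placement of S, not about phenotype labels, and
with 2–3 mouse samples a phenotype permutation null would be degenerate.
The p-value is two-sided on the magnitude,
p = (1 + #{|ES*| ≥ |ES|})/(n_perm + 1), which is exactly uniform under
the null (asserted by a KS calibration test); a one-sided same-signed
count cannot exceed ≈ 0.5 and would not calibrate.  The reported band is
the edge of the lower 95% of the null on the observed sign.  ES values
are computed from hit positions in closed form (identical to the running
sum, verified exhaustively over all C(12,3) placements), which lets the
null be vectorized.

**Consensus genes.** The observed count of genes significant in the same
direction in all K models and carrying an ortholog is compared with a
null in which each model's significant set is an independent uniform
subset of its observed size, intersected across models and thinned by the
ortholog-mappable proportion φ.  The intersection chain is simulated
exactly by nested hypergeometric draws (the overlap of a fresh uniform
subset with any fixed set is hypergeometric, and the running intersection
remains conditionally uniform); a test checks this against literal subset
simulation.  p = (1 + #{null ≥ observed})/(n_sim + 1).

## Term-level analysis

Over-representation is the one-sided hypergeometric tail of a term's DE
members against the analysis background.  The conditional variant tests
leaves first given a parent→child relation and removes the members of
already-significant (p < α) descendants from each ancestor before testing
it, so parents are only credited with signal their children do not
explain; without a relation it degrades to the unconditional test with a
warning.  Terms need ≥ 10 DE members for headline tables and ≥ 3 for
supplementary-style tables.

Per-term cross-species correspondence is a one-sample two-tailed t of the
mouse ortholog log2 fold changes against zero (mouse transcripts reached
via several human members count once).  The underlying design question —
two-sample t versus a one-sample t of the mean log2 difference — is
genuinely ambiguous in this analysis family; the one-sample form is used
because the quantity of interest is the set's mean shift, and the choice
is surfaced here rather than hidden.  Significance marks: p < 0.05
("filled"), 0.05 ≤ p < 0.10 ("marginal"), matching the usual triangle
convention of such tables.

## Immunophenotyping

Signatures are the transcripts whose reference expression exceeds the
normal-skin baseline by θ = 2 log2 units (4-fold), ranked by that excess
and capped at 250; populations yielding fewer than 5 members are
excluded.  For a lesion DE table, n1/n2 counts signature transcripts with
log2fc ≥ 0 / < 0.  Significance is a one-sided binomial test of n1 in n
against p0 = the genome-wide fraction of increased transcripts — the
reference rule for this score lives in prior work not reproduced here, so
the package defines its own: testing against p0 rather than ½ controls
for global expression shifts in small-n designs.  BH correction runs
across populations; q < 0.05 flags a population.  Projection to the other
species maps each signature to the union of its ortholog transcripts
(size may grow under 1:n fanout) and reruns the same profile against the
human table.

## Synthetic data generator

The generator emulates the study design the pipeline targets: 58 case /
64 control human samples, 3/3 mouse samples, and an ortholog map covering
61% of human transcripts with a 0.8/0.1/0.1 mix of 1:1/1:2/2:1 families.
Default universes are 6,000 human and 5,500 mouse transcripts — large
enough that every statistic operates in its asymptotic regime while a
full pipeline run takes well under a second; full-platform sizes
(54,675/45,101) are reachable through the same config.

Expression is additive Gaussian on the log2 scale: baseline N(7, 1.5²)
per transcript, plus the planted effect in case samples, plus N(0, σ)
noise with σ = 1.0 (human, reflecting a heterogeneous outbred cohort) and
σ = 0.5 (mouse, inbred lines under controlled conditions).  No count
model is implied: the pipeline consumes only log2 values, and microarray
noise on that scale is well approximated as Gaussian.  Probe-level
artifacts, batch effects and normalization residuals are *not* simulated,
so passing tests demonstrate correctness of the statistics under their
own assumptions, not robustness to preprocessing failures in real data.

Differential expression is planted per ortholog family: each family (and
each unmapped transcript) is DE with probability π = 0.15; its human
transcripts share one signed effect with magnitude |N(1.0, 0.5²)| and
P(up) = 0.45 (disease signatures of this kind skew toward decreased
transcripts).  Each mouse member of a DE family is *concordant* with
probability ρ; a concordant transcript's effect is
ρ·e_h + √(1−ρ²)·sign(e_h)·|N(1.0, 0.5²)|, so direction is inherited, the
magnitude law is preserved, and ρ is a single dial running from
independence (ρ = 0) to exact effect sharing (ρ = 1).  Family-level
planting is what makes the ρ = 1 limit exact: without it, 2:1 families
mixing a DE and a null human transcript would cap the attainable
correlation.  A further 5% of mouse transcripts carry independent
mouse-only effects.  Annotation terms (40 by default, 30% of them
enriched) sample members with 8:1 odds in favor of DE transcripts.  The
cell reference plants disjoint 100-transcript signatures at +3 log2 over
baseline for eight leukocyte-style populations; chosen populations are
spiked into the mouse lesion samples (default: macrophage, +1.0 log2),
and optionally coupled into the human cases through the ortholog map to
emulate a shared infiltrate.  Spiking is mouse-only by default so that
ρ = 0 remains a true cross-species null.

Everything the generator plants is recorded in a `TruthBundle` written
beside the data, and a fixed seed reproduces every output byte for byte.

## Numerical conventions and limitations

* All randomized procedures take explicit seeds; Monte-Carlo results are
  bitwise reproducible given the seed.
* Hierarchical clustering of model profiles uses average linkage by
  default with complete linkage as an option; the choice is exposed
  because nothing in the analysis pins it down.
* Mahalanobis core sets use the plain sample covariance; membership is
  affine-invariant but not robust to gross outliers beyond what the 75%
  trimming itself provides.
* Trademark ties at rank k break by smaller q, then gene symbol; the
  representative transcript of a multi-transcript gene is the lowest-p
  one by default (largest |log2fc| as an option).
* Printed tail probabilities of the concordance test are hypergeometric;
  analyses of this kind sometimes print p-values from other (unstated)
  nulls, and no attempt is made to reproduce such values.
* The detection-rate area has no attached null; an optional label
  permutation could supply one but is intentionally out of the default
  path.
* Degenerate inputs fail loudly: empty intersections, singular
  covariances, zero margins, all-zero variances and infeasible generator
  configs raise errors naming the offending quantity.
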