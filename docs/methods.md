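# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices and the known limitations of switchgrain, in the package's
own terms.

## Study design and data model

The default design has five samples — UT (untreated), 6Fe, 6Zn, 24Fe, 24Zn
(6 h and 24 h after foliar iron/zinc application) — with three biological
replicates each, and four preferred contrasts: 24Fe/UT, 24Zn/UT, 6Zn/6Fe and
24Zn/24Fe (the 6-h samples are compared only with each other because they
were collected at a different time of day, confounding diurnal and treatment
effects). All components are generic over a user-supplied design with ≥ 2
replicates per compared sample.

A count matrix lives at one level (gene or transcript) and carries a unit
flag (`raw`, `RPM`, `corrected`) plus per-column *mapped totals* — the number
of exonic mapped reads used as the reads-per-million denominator. Totals are
taken as given input: they equal the column sums only when the matrix spans
the whole transcriptome, and only then do RPM columns sum to exactly 10⁶.
Event ids are opaque strings; no genomic-coordinate arithmetic occurs
anywhere. Structural invariants (unique ids, non-negative values, positive
totals, design/column agreement) are enforced at construction, never
deferred.

Gene models map gene → transcripts → protein ids → amino-acid sequences.
Identical protein sequences are merged to one id, so identity of sequence is
identity of id; transcripts without a coding sequence carry the sentinel
`non-coding`. Annotation is read either from GTF/GFF (via gffutils, with
sequences supplied separately) or from a flat four-column TSV dialect that
round-trips losslessly — the format the generator writes.

## Normalization and bias diagnostics

Two corrections are implemented and compared:

* **RPM** — value × 10⁶ / mapped_total(column); the genome-wide correction.
* **Reference-gene** — each column is divided by the geometric mean of a
  reference-gene panel in that column, anchored to the grand geometric mean
  over columns so the correction has no net scale effect. With one reference
  gene this is classic single-gene correction; the panel form is robust to
  one aberrant reference. The anchor makes the operation idempotent and
  invariant to rescaling the whole panel by a constant.

Schemes compose sequentially. Mapped totals are deliberately not recomputed
after reference correction; the unit becomes `corrected`.

Reproducibility is quantified by (i) the mean slope of
through-the-origin least squares of one replicate on another over events
expressed (> 0) in both — the origin is forced because the metric is a pure
proportionality check whose ideal is exactly 1; (ii) the mean percent
deviation of replicate ratios from 1, oriented max/min so it is
non-negative, pooled over events and replicate pairs, with no pseudo-counts
and a configurable expression floor (default: both values > 0); and (iii)
the inter-treatment bias, the mean |log₂| ratio of reference-gene means
between two samples, ≈ 0 for bias-free data. With three replicates all
three unordered pairs enter with equal weight.

## Reference-gene stability

Candidate normalizers are screened by the coefficient of variation,
CV% = 100·sd/mean, across all columns, using the sample (n−1) standard
deviation (the population/sample choice is not determined by any external
constraint; n−1 is the conventional default). Genes with zero mean are
excluded rather than given CV 0. Selection is strictly below the threshold
(default 10%); ties are broken by descending mean, then lexical id, making
the "most stable gene" pick order-invariant. When heterogeneous datasets
are pooled, an optional per-dataset rescaling to unit mean is available;
plain concatenation is the default since no harmonization scheme is
canonical.

## Differential expression

**Filter.** Weakly expressed events produce outlier-driven averages, so an
event is tested only if, in at least one of the two compared samples, the
full-replicate RPM mean *and* every leave-one-out (r−1)-replicate mean are
≥ θ (default 5 RPM). With 3 replicates the (r−1)-subsets are exactly the
three two-replicate combinations; for r ≠ 3 the leave-one-out subsets are
the natural generalization. The rule's scoping is ambiguous in prose — the
default applies both clauses within a single qualifying sample; a variant
requiring the plain mean in both samples is available as
`DEConfig(filter_scope="mean_both")`.

**Dispersion.** One φ for all events (variance μ + φμ²), estimated by
maximizing the summed conditional log-likelihood of within-sample replicate
counts given their totals,

    log P(y₁..y_r | Σy = z) = Σᵢ log C(yᵢ + r⋆ − 1, yᵢ) − log C(z + r·r⋆ − 1, z),

with r⋆ = 1/φ, after equalizing library sizes to their geometric mean
(scale + round — a linear stand-in for a quantile adjustment). The
conditional form is free of the per-event means, so between-sample effects
cannot leak into φ̂. The optimizer is bounded Brent on log φ over
[10⁻⁸, 50]; an optimum at the lower bound is reported as φ = 0. A
method-of-moments fallback averages the per-event solutions of
var = μ + φμ² over events with mean ≥ 1 (low-mean events are excluded
because their ratio is shot-noise dominated; a squared-mean-weighted
regression was rejected as badly biased at r = 3).

**Exact test.** Group sums of equalized counts are compared through the
conditional law above. The two-sided p-value is the minimum-likelihood form
— the sum over all outcomes whose conditional probability does not exceed
the observed one — which is well defined for asymmetric conditionals;
classical tail-doubling is available (`two_sided="doubling"`). The log-pmf
is evaluated in a symmetric grouping so that for equal group sizes the
array is exactly palindromic in floating point, making the p-value exactly
invariant under swapping numerator and denominator; probability ties are
accepted within a 10⁻¹² relative log tolerance. At φ = 0 the test reduces
to the binomial-conditioned Poisson exact test.

**Calling.** Benjamini–Hochberg runs per comparison per level over tested
events only. Fold changes come from filtered-RPM sample means with no
pseudo-count; a zero denominator yields an infinite |log₂FC| and the event
is classified by p-value and direction. Induced/Repressed require adjusted
p ≤ α (default 0.01) and |log₂FC| ≥ log₂(min fold change) (default 2). By
construction DE = Induced + Repressed in every summary.

The surface is a statsmodels-style pair: `NBExactTestModel(counts)` holds
the matrix and caches the dispersion fit; `fit(comparison)` returns a
`DEResults` with the per-event frame, counts, and a `summary()` table.

## Isoform switching

A gene switches in a comparison iff it has ≥ 1 transcript classified
Induced and ≥ 1 classified Repressed there (the strict significance-based
reading; proportion-level tests are out of scope). Classification examines
all (up, down) transcript pairs: any pair of distinct coding proteins ⇒
IS1; otherwise any coding pair (necessarily identical-sequence) ⇒ IS2 with
the `identical_protein` flag; only non-coding pairs ⇒ unclassified. Each
gene gets exactly one class, so IS1 + IS2 + unclassified partitions the
switch set — summaries never double-count. Genes whose switch involves
identical proteins are additionally emitted as a separate list, since that
phenomenon (one protein product routed through antagonistic regulatory
paths) merits its own reporting. After sequence merging, a shared-CDS
(UTR-only) pair and a convergent-CDS pair are indistinguishable by
construction, which is why both truth kinds map to IS2.

Gene-level IS counts switching genes that are themselves gene-level DE —
the only reading under which IS ≤ DE at gene level; transcript-level IS
counts DE transcripts belonging to switching genes. Cross-level discordance
is reported both ways: the fraction of DE genes with no DE member
transcript (a gene filtered out at transcript level counts as discordant),
and the fraction of DE transcripts whose parent gene is not DE.

## The synthetic-data generator

The generator emulates the study's *structure*, desk-scaled. Per gene: an
expected expression level in RPM (log-uniform, default 5–5000), a number of
isoforms (default mix ≈ 55% single-isoform, mean ≈ 1.8), and symmetric
Dirichlet (concentration 1) isoform proportions. Transcript counts are NB
with variance μ + φμ² (default φ = 0.1, a typical biological-replicate
value); gene counts are exact sums of their transcripts. Default depth is
17.2 million exonic reads per column, the study's scale.

Embedded signals, each tied to one randomly chosen treated sample:

* induced/repressed genes multiply (divide) their mean by `fold_change_de`
  (default 4) in the affected sample;
* switching genes move `switch_shift` proportion-mass points (default 0.8)
  from the dominant to the second isoform, leaving the gene total unchanged
  in expectation. A switch is only meaningful when the dominant isoform
  carries the mass being moved, so switch genes are conditioned on a major
  isoform holding ≥ shift + 0.02 of the gene (remaining isoforms rescaled).
  An earlier design that moved a *fraction of the donor's own* mass was
  rejected: whenever the top two proportions are near-equal the recipient
  isoform changes < 2-fold, so no threshold-based detector can see the
  switch — an artifact of the semantics, not of the method;
* reference genes (default 18) are single-isoform, highly expressed
  (200–2000 RPM), constant-mean across samples, with their own small
  dispersion (default 0.005, i.e. CV ≈ 7% — comfortably inside a 10%
  selection threshold, as genuine reference genes must be);
* a low-expression tail (default 20% of genes at 0.5–5 RPM) exercises the
  filter boundary; per-column bias factors multiply means and mapped totals.

Annotation: every transcript gets its own random protein sequence except
for designated pairs among a gene's top two isoforms — shared-CDS pairs
(same protein id) and convergent-CDS pairs (distinct ids, identical
sequence, merged on load) — plus a fraction of non-coding transcripts that
never participate in same-protein pairs. Ground truth records every event's
class per comparison, every switch gene's class and pair kind, the
reference ids and the bias factors.

**RPM bookkeeping.** Independently drawn per-gene RPM levels cannot both
span 5–5000 and sum to 10⁶ at study-like gene counts. The generator
therefore defaults to *subset semantics*: mapped totals equal the external
depth, the matrix models a highly expressed subset of a larger
transcriptome, nominal RPM values are exact (so the 5-RPM filter boundary
is meaningful), and configurations whose expected RPM budget exceeds 10⁶
are rejected (hence the default of 1200 genes). With
`full_transcriptome=True` the totals are instead the realized column sums,
the matrix is the whole transcriptome, and RPM columns sum to exactly 10⁶.

**What passing tests do and do not show.** The generator reproduces the
count-level statistical structure — NB noise, isoform mixing, library
biases, filter-boundary mass — but not positional/sequence biases,
correlated biological replicate structure, annotation errors, or
multi-mapping artifacts. Recovery results on it validate the statistical
machinery, not quantifier accuracy on real reads.

## Problem sizes and test calibrations

Test and acceptance runs use desk-scale sizes chosen once: null calibration
on 10,000 single-isoform events at depth 10⁶ (type-I error within three
binomial standard errors of α); dispersion recovery at φ = 0.2 on 5000
events (tolerance ±30%); switch recovery over 20 seeds at 300 genes,
gene RPM ≥ 50, φ = 0.1, the default shift 0.8 (sensitivity ≥ 0.8,
false-call rate ≤ 0.1, class labels matching truth exactly). At the shift
lower bound of 0.6 measured sensitivity is ≈ 0.78: the residual misses are
true 2.5–3-fold changes that a 3 v 3 exact test at φ = 0.1 correctly deems
non-significant at adjusted p ≤ 0.01 — a power limit, not a detection
defect. Bias-diagnostic checks inject log-normal column factors (σ = 0.3)
at φ = 0.001 so that slope restoration to 1 ± 0.02 is not masked by
regression attenuation (through-origin slopes shrink by ≈ 1/(1+φ) under NB
noise — visible already at φ = 0.05).

## Amino-acid composition

Enrichment of a protein set against a background follows the "X% higher"
convention, 100·(observed/background − 1), with residues pooled over
sequences by default (per-protein averaging behind a flag) and X/ambiguous
symbols excluded from numerator and denominator alike. The shipped
background is an approximate average amino-acid composition of plant
proteins (normalized dicot-proteome frequencies); it is a package constant,
clearly exposed and overridable, since no single canonical table exists.

## Known limitations

* Only common dispersion — no tagwise/trended shrinkage, no GLMs, no paired
  designs.
* Library-size equalization by scale-and-round is a first-order stand-in
  for a full quantile adjustment; at very small counts the rounding can
  perturb p-values slightly.
* Switch detection is threshold-based; subtle proportion shifts below the
  fold-change/significance thresholds are invisible by design.
* The reference-gene screen assumes expression columns are comparable as
  given; cross-platform harmonization beyond per-dataset rescaling is the
  user's responsibility.
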