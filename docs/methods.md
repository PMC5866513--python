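# Methods notes

This note records the statistical model, the numerical conventions, and
the genuinely open design choices behind `spliceflow`, in the spirit of a
package vignette. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Event model

Transcripts are exon chains with 1-based inclusive coordinates (GTF
convention); exons within a transcript are merged and sorted at parse
time. Events are *binary, local* splicing choices; complex nested
variation and alternative first/last exons are out of scope. Geometry per
type:

- **SE** — an internal exon whose flanking junctions `(e1_end, exon_start)`
  and `(exon_end, e3_start)` coexist in the inclusion transcripts while
  some transcript carries the direct junction `(e1_end, e3_start)`.
  Cassette exons < 28 nt are flagged as microexons.
- **A5/A3** — two introns sharing one boundary and differing at the other,
  with the additional requirement that the two alternative flanking exons
  *overlap*. The overlap condition is essential: without it every SE event
  also presents two junctions sharing a boundary and would be double-
  reported as a splice-site event. Labels are strand-aware (variation at
  an intron's genomic start is A5 on `+`, A3 on `−`).
- **MX** — two non-overlapping internal exons between identical flanking
  junctions, each supported by transcripts that never carry the other.
- **RI** — an exon spanning another transcript's exon–intron–exon block
  with identical outer boundaries; the retaining transcripts are the
  inclusion form.

The *inclusion* form is always the variant with more exonic sequence in
the variable region (the cassette-containing, longer-exon,
lower-coordinate-exon, or intron-retaining form respectively); this makes
PSI directly interpretable as "fraction spliced in". The *total* set pools
the transcripts carrying either form's defining junction structure
("pooled-junction" convention) rather than all transcripts of the gene, so
PSI is a proportion over event-informative transcripts only. Transcripts
that skip the entire event region without carrying either junction do not
enter the denominator; this is a deliberate choice the annotation format
cannot express either way.

Events are keyed and sorted by their identifier
`<gene>;<type>:<chrom>:<coords>:<strand>`, which makes enumeration
invariant to transcript input order and collapses duplicates arising from
more than two transcripts.

## PSI and the expression covariate

PSI = inclusion TPM / total TPM per sample, NaN when the total is ≤
`min_total_tpm` (default 0, i.e. defined whenever the denominator is
positive; raising the threshold can only turn defined values into NaN,
never the reverse). Expression terms use log10(pseudocount + Σ TPM) with
pseudocount 0.01, applied inside each replicate's logarithm before
averaging. Applying it on the mean instead changes nothing away from zero
expression; inside-the-log was chosen so single silent replicates cannot
produce −inf. PSI serialization writes shortest-exact decimal reprs, so
write/read cycles are bit-exact.

## The significance test

Null points are built only from replicate pairs *within* conditions
(cross-condition pairs would contain true signal), pooled across the two
compared conditions into a single background — the natural reading of "one
distribution of between-replicate ΔPSI". Each point's covariate E_rep uses
the replicates of that point's condition. The observed statistic is
ΔPSI = mean PSI(condition 2) − mean PSI(condition 1) ("later minus
earlier"); means run over the replicates with defined PSI, and an event
with no defined replicate in one condition is reported as NaN and excluded
from testing and correction.

Window mechanics: the background is sorted by E_rep once; a query locates
the nearest E_rep by binary search (ties to the lowest index), and the
window of 1000 values centered there shifts inward at the edges so its
size never shrinks, clamping to the whole background when it is smaller
than the window. With duplicated E_rep values different centers inside a
tie block can select different windows when the window is very small, so
determinism is guaranteed by the fixed lowest-index tie-break rather than
by window-content invariance.

The ECDF is right-continuous (counts ≤ the observation), giving
p = (1 − ECDF(|ΔPSI|))/2 under the symmetric-null assumption, with floor
1/(2n): empirical p-values cannot resolve below the background's
granularity, and exact zeros would destabilize BH ranking. Consequences
asserted by the property suite: p is symmetric in the sign of ΔPSI,
non-increasing in |ΔPSI|, and confined to [1/(2n), 1/2].

The test is conservative by construction: a between-condition difference
of means of m replicates has null variance 2σ²/m, while the background
pairs have variance 2σ², so null events concentrate well inside the
background ECDF. BH correction (via `statsmodels`) is applied within each
gene, because events sharing transcripts are not independent; correction
is optional to allow nominal-p workflows.

## Clustering

Profiles are per-condition mean PSI vectors of events significant
(nominal p by default, adjusted on request) in ≥ 1 adjacent-pair
comparison. DBSCAN and OPTICS come from scikit-learn; metrics are
Euclidean, Manhattan, and cosine (1 − cosine similarity; all-zero profiles
are dropped with a warning since the distance is undefined). Both
algorithms are deterministic given input order; profiles are indexed by
sorted event id.

OPTICS flat extraction was an open choice: the reachability profile bounds
clusters by S, but the cut distance D must be picked. A plain
silhouette-maximizing cut over-trims — excluding noise from the score
means a tiny D that strips every border point leaves ultra-tight cores
with a *higher* silhouette than the correct full partition. The objective
is therefore the coverage-weighted silhouette (silhouette over clustered
events × fraction of events clustered), evaluated on a 20-point grid in
(0, S] with ties resolved toward the larger D — matching the intuition of
choosing the largest D before quality drops. At any fixed D the extraction
coincides with DBSCAN(D), which the tests verify.

RMSSTD is the pooled within-cluster standard deviation,
sqrt(Σ_c Σ_{x∈c} ‖x − μ_c‖² / (d · Σ_c (n_c − 1))) with d the number of
conditions; it is NaN when every cluster is a singleton. Noise events are
excluded from both quality scores.

## Synthetic data generator

The generator emulates the simplest informative study design: two-isoform
genes carrying exactly one SE, A5 or A3 event (default mix 50/25/25,
apportioned by largest remainder so counts are deterministic), two or more
conditions with three replicates each, and isoform abundances drawn
log-uniformly from 1–100 TPM. Differential splicing is planted by
*exchanging* the two isoform abundances in all conditions after the first,
restricted to genes with relative abundance change > 0.2 (strict
inequality), so planted |ΔPSI| is always > 0.2 and analytic:
planted ΔPSI = (TPM₂ − TPM₁)/(TPM₁ + TPM₂). Negatives keep their
abundances, so their expected ΔPSI is exactly 0 and their total-expression
distribution matches the positives (eligibility constrains only the
ratio). Replicate noise is multiplicative log-normal per transcript and
sample with σ as the single depth-like knob (σ 0.05 ≈ deep, 0.2 ≈
shallow); defaults use σ = 0.1. Everything derives from one integer seed;
identical seeds give byte-identical GTF text and expression values.

What the generator does **not** emulate: read-level sampling and mapping
noise, length-dependent quantification bias, correlated errors between
isoforms sharing sequence, multi-isoform genes, and annotation
incompleteness. Passing tests therefore demonstrate correctness of the
statistical machinery under a clean abundance-level noise model, not
end-to-end performance on real libraries.

## Problem sizes in the test and acceptance runs

Unit and property tests use 50–500 simulated genes; the benchmark script
uses 1000 genes per noise level (500 negatives) with window 1000, 2
conditions × 3 replicates, at σ ∈ {0.05, 0.1, 0.2} — sizes chosen so the
background comfortably exceeds the window while the whole suite runs in
well under a minute on one core. The clustering fixtures use 3 planted
profile clusters (centers 0.3 apart per coordinate, σ = 0.01, 20 events
each), separation at which density methods must recover the partition
exactly.

## Known limitations

- Events are binary; genes with complex local variation produce several
  overlapping binary events rather than one multi-way event.
- The empirical test needs ≥ 2 replicates in at least one compared
  condition, and its resolution is bounded by the window (p ≥ 1/2000 at
  the default window).
- A5/A3 detection requires the alternative exons to overlap; alternative
  splice sites combined with a completely different exon are reported as
  separate events or not at all.
- PSI from TPM inherits any quantifier bias; the tool deliberately does
  not model read-level uncertainty.
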