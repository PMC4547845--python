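# Methods

This note documents the statistical model behind `splicedissect`, the
assumptions of its synthetic-data generator, the numerical choices, and the
places where the design was genuinely open.

## 1. Quantification model

Each alternative-splicing event is treated as a two-isoform mixture. A read
informative for the event supports the inclusion or the exclusion isoform;
with PSI = ψ the probability that an informative read is an inclusion read
is

    q(ψ) = ψ·c_inc / (ψ·c_inc + (1−ψ)·c_exc),

where the informativeness constants c_inc, c_exc (> 0, unitless) are the
effective numbers of read positions that distinguish each isoform. They
capture the first-order effect of an isoform-length correction: a longer
inclusion isoform offers more distinguishing positions, inflating the raw
inclusion-read fraction relative to ψ. Both default to 1, which reduces
q to the identity — the plain read-ratio model. A full per-read-position
generative model is deliberately out of scope.

With a Uniform(0,1) prior and a Binomial(n, q(ψ)) likelihood, the posterior
is Beta(n_inc+1, n_exc+1) whenever c_inc = c_exc; we report the posterior
mean, variance and the equal-tailed 95% credible interval. For unequal
constants the posterior is evaluated on a fixed 2,001-point grid with
Simpson integration; a 201- vs 2,001-point comparison in the tests bounds
the grid error near 1e-6 on the posterior mean at moderate depth.

## 2. Bayes-factor divergence test

The evidence for "two PSI values differ" is the Bayes factor

    BF = m(x₁) · m(x₂) / m_shared(x₁+x₂),

with m the marginal likelihood under an independent Uniform(0,1) PSI and
m_shared under one shared PSI. For equal informativeness constants this is
closed-form in Beta functions, BF = B(a₁,b₁)B(a₂,b₂)/B(a₁+a₂−1, b₁+b₂−1)
with a = n_inc+1, b = n_exc+1, computed in log space. The independent
numeric oracle is Gauss–Legendre quadrature (501 nodes), which is *exact*
for the polynomial integrand whenever total counts ≤ 1,000; the closed
form and the quadrature agree to ~1e-12 relative log-BF over a grid of
totals up to 200 (tested).

An event is divergent between two samples when BF > 5 in **every**
replicate pair (replicates paired by index) and |mean ΔPSI| > 0.1, both
strict, after a coverage filter of ≥ 20 reads (spliced-in + spliced-out)
in every replicate of both samples. Per-replicate ΔPSI uses posterior
means, first sample minus second (the reference strain/allele first).
Whether "average |ΔPSI|" means the absolute mean or the mean absolute
value was an open choice; the default is |mean of signed ΔPSI|, which
penalises sign-inconsistent replicates in the same spirit as the all-
replicates BF rule, and `delta_agg="abs-mean"` provides the alternative.

## 3. Permutation FDR

The FDR of the joint threshold is estimated per |ΔPSI| cutoff x ∈
{0.01, …, 0.20}: real positives are counted once; each of 100
pseudo-datasets bootstraps events with replacement and swaps the sample
labels of replicates 2..k between the two samples, forming a null
comparison whose positives are false by construction; FDR(x) is the mean
of FP/N_real, with a 2.5–97.5 percentile band. "Bootstrapped label
permutation" admitted two readings (bootstrap over events vs over
replicates); bootstrapping events while applying the fixed replicate-label
swap matches the replicate-2-and-3 phrasing of the procedure and yields
100 distinct pseudo-datasets. Note the label swap is the only
exchangeability transformation for k = 3 replicates, so the band reflects
bootstrap variation around a single null dataset.

With 3 replicates the joint criterion is extremely conservative under the
null: in a 5,000-event pure-null simulation at depth 200, no event passes
(< 0.02%), and the permutation estimate concurs.

## 4. Mock-hybrid filter

Allelic quantification uses only reads assignable to one allele, so events
with few nearby variants lose coverage, and events where assignability
correlates with isoform are biased. Both are screened with a *mock F1*:
equal amounts of the two parental read sets (count level: both parents
hypergeometrically downsampled to the smaller total), processed exactly
like a real hybrid. Two screens per allele:

1. **Coverage**: < 20 assignable mock reads in any replicate → drop.
2. **Consistency**: Z = (ψ_parental − ψ_mock)/σ_local(coverage), two-sided
   normal p, Benjamini–Hochberg at FDR 0.05 across all (event, allele)
   pairs; significant on either allele → drop.

σ_local is learned from the *downsampling comparison* — full parental
counts vs parental counts subsampled (hypergeometric, without replacement)
to the mock allelic coverage — which isolates pure sampling noise. Events
are sorted by coverage; each event's raw σ is the sample SD of the
downsampling deltas in a centered window holding 1% of events (minimum
20, truncated at the edges); the raw curve is smoothed against coverage
rank by loess and floored at 1e-4 to keep Z finite. The window was
specified only as "1% of events", so the minimum width, centering and
edge handling are this package's choices. Loess uses tricube weights with
local quadratic fits and span 0.75 (configurable); degree-2 local fits are
implemented directly because the available lowess routine is degree-1
only. σ is mapped onto mock events by interpolation over coverage. The
filter is a pure function of the parental/mock/downsampled data — real
hybrid counts never influence the drop set.

On unbiased synthetic data at depth 500 the filter drops ≤ 0.2% of events
and the kept-set parental-vs-mock PSI R² is ≈ 0.998; halving the mock
inclusion counts of 5% of events (a 2× assignability bias against the
inclusion isoform) is detected for ≈ 98–100% of them.

## 5. Cis/trans dissection

Inside an F1 hybrid both alleles share one trans environment, so the
allelic comparison isolates cis effects. Trans effects are inferred with
the Altman–Bland interaction test on log PSI ratios:

    z = (log R_parental − log R_allelic) / sqrt(SE_p² + SE_a²),

where R = ψ_B/ψ_S from counts pooled across replicates and SE² =
var₁/ψ₁² + var₂/ψ₂² by the delta method with Beta-posterior variances
(cross-checked against Monte-Carlo propagation in the tests). Ratios are
taken on the log scale so that globally swapping the two strains flips
signs but leaves |z|, q-values and all category assignments unchanged
(tested). How the original procedure obtained ratio SEs is not fully
specified; pooling replicates and using posterior variances is this
package's choice, matching the one-ratio-per-event framing of the
interaction test.

P-values become q-values via Storey's procedure: π₀(λ) = #{p>λ}/(m(1−λ))
on λ = 0.05…0.95, cubic-spline smoothed and read off at λ = 0.95 (capped
at 1; for m < 100 the λ = 0.5 value is used directly); q is the step-up
minimum of π₀·m·p/rank. Storey q-values are implemented here because no
maintained Python implementation ships with the scientific stack.

The trans significance cutoff defaults to "the same FDR as the cis
criterion": the permutation-FDR estimate of the parental threshold at the
configured Δ cutoff (a fixed absolute q cutoff is available). Categories:

| category | parental div. | allelic div. | trans sig. |
| --- | --- | --- | --- |
| cis_only | ✓ | ✓ | – |
| cis_and_trans | ✓ | ✓ | ✓ |
| trans_only | ✓ | – | ✓ |
| unexplained | ✓ | – | – |
| conserved | – | any | any |

Control events (for the genomic-feature comparisons) require BF < 1 and
0.05 < PSI < 0.95 in every replicate of both samples plus |mean ΔPSI| <
0.05, all strict.

## 6. Allele assignment

A hybrid read is compared against the local sequence of both haplotypes
and assigned to the strictly closer one by full Levenshtein distance
(edlib, infix mode, so an exact substring scores 0 regardless of flanking
slop); ties are discarded. Indel-aware distance matters because the strain
pairs this models differ by millions of indels and the exemplar causal
variant class includes short insertions. 'N' matches nothing — including
another 'N' — implemented by mapping 'N' to distinct sentinels on the two
sides. Locus retrieval is by the read's origin interval ± 20 nt of slop
(alignment itself is out of scope; synthetic reads carry origin
coordinates, and the 20 nt slop exceeds the maximum simulated indel of
9 nt, so interval mapping across indels is safe). With zero sequencing
error, misassignment is exactly zero and unassigned reads are exactly the
reads overlapping no variant (tested; stated over point variants, where
"overlapping a variant position" is unambiguous).

## 7. Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the analysis is validated under.

* **Catalog**: events of the five types with non-overlapping coordinates
  on toy chromosomes (200 events per chromosome); exon lengths uniform on
  [100, 300) nt, introns [200, 1500) nt, alternative-splice-site shifts
  [30, 150) nt; type mix proportional to a realistic 11,818-event
  transcriptome catalog (47.5% SE, 15.0% RI, 5.9% MXE, 18.9% A3SS,
  12.7% A5SS); 71.2% of events are placed in coding context. The intron
  minimum of 200 nt keeps the 100 nt flanking regions of distinct
  alternative regions disjoint.
* **Truth**: architectures conserved/cis/trans/cis+trans with
  configurable fractions (defaults 60/30/10/0%); base PSI uniform on
  [0.05, 0.95]; effect sizes |δ| fixed at 0.3 PSI units by default
  (uniform and Beta alternatives available) with random sign; effects are
  additive on the PSI scale and split symmetrically around the base
  (±δ/2), clipped to [0.01, 0.99] so every event stays informative.
  Allelic ΔPSI equals δ_cis and parental ΔPSI equals δ_cis + δ_trans
  (pre-clipping). Effect-size distributions in real data are essentially
  unknown; the fixed-0.3 default makes power interpretable.
* **Counts**: per-event per-replicate totals are negative-binomial
  (mean 200, dispersion 10) — overdispersion makes the ≥ 20-read filter
  non-trivial. The hybrid's total depth is 388.0/169.4 ≈ 2.29× the
  parental mean, reflecting the deeper F1 sequencing that makes allelic
  coverage comparable to parental coverage once only ~61% of hybrid reads
  are assignable (default assignability 0.6; a 'cast' preset of 0.3
  models a lower-divergence strain pair). Assignable reads split
  Binomial(½) between alleles; inclusion reads are Binomial(n, q(ψ)).
* **Variants**: SNVs and 1–9 nt indels (10% indels); background density
  0.015/nt (roughly the 35.4M SNVs + 4.5M indels of a highly diverged
  mouse strain pair over a 2.7 Gb genome), elevated to 0.030/nt in the
  flanking regions of cis events; 35% of cis events additionally receive
  one SNV inside a splice-site window. Variants are spaced ≥ ~10 nt apart
  and indel reference spans never cross exon/intron boundaries, keeping
  isoform sequences well defined on both haplotypes.
* **Reads**: drawn from the isoform sequences of the generating allele at
  its true PSI, error-free by default (optional uniform substitution
  rate); each read lies within a single isoform segment so its genomic
  footprint is contiguous and the edit-distance rule needs no spliced
  alignment. Each read carries its true allele/isoform/origin for oracle
  checks.

What the generator does **not** emulate: realistic sequence composition,
splicing-motif-aware regulation, position-specific coverage bias, quality
scores, mappability/GC effects, >2-isoform events. Passing tests therefore
demonstrate the correctness and calibration of the *procedure* under its
own statistical assumptions, not performance on real libraries.

## 8. Genomic-feature statistics

Flanking regions are the alternative region(s) plus 100 nt on each side
(SE: alt exon + intronic flanks; RI: retained intron + exonic flanks;
A3SS/A5SS: alternative exon region + exon/intron flanks; MXE: both
exons + intronic flanks), clipped at 0. Variant density is anchor-counted
per nt on half-open intervals. Splice-site windows default to donor
[−3, +6] and acceptor [−20, +3] relative to the boundary
(negative = exonic), strand-aware; a stricter window can be configured
down to the GT/AG dinucleotides. Coding/frame classes: an event is coding
iff its alternative region overlaps CDS; coding events are frame-neutral
iff the isoform length difference (for MXE, the difference of the two
exon lengths) is divisible by 3.

Comparison tests: two-sided Fisher exact (scipy; equals full
hypergeometric enumeration on all small tables — tested exhaustively to
total 30) and Mann–Whitney U (exact for a smaller group ≤ 8 without ties,
normal approximation with tie correction otherwise; equals rank
enumeration where exact). Splice-site strength is a PWM log-odds score in
bits against a uniform background with pseudo-frequency 1e-4; the bundled
donor/acceptor matrices are consensus-concentrated stand-ins suitable for
detecting disruption of the invariant GT/AG dinucleotides, not calibrated
biological models.

## 9. Problem sizes and determinism

The default validation studies use 2,000–5,000 events, depth 200–500 and
3 replicates; parameter recovery aggregates 10 seeded runs of 2,000
events. All randomness flows from explicit integer seeds: the generator
derives one independent stream per stage from its config seed, and the
model's `fit(seed=…)` derives per-stage sub-seeds, so any run is exactly
reproducible. Degenerate inputs have defined behaviour: empty count
records return the prior, all-zero 2×2 margins return p = 1 with a
warning, zero-variance SD windows hit the 1e-4 floor, zero-coverage
downsampling targets yield (0, 0) records that the coverage filter
removes.

## 10. Known limitations

* The permutation FDR uses the only exchangeability transformation
  available at 2–3 replicates; its uncertainty band understates
  permutation variability and, when many events carry large true effects,
  the null is contaminated and the estimate is conservative (too high).
  This matches the estimator it reproduces.
* The trans test inherits the delta-method normal approximation; for PSI
  near 0 the log-ratio SE is large and power is low.
* Classification treats the trans-cutoff choice as global, not per-event.
* The informativeness constants model isoform-length effects only to
  first order.
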