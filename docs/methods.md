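# Methods

This package analyses two-condition exon-junction microarray experiments:
arrays whose probes cover exon bodies and exon–exon junctions so that
alternative splicing can be read out as opposing intensity shifts between
the probesets supporting the inclusion isoform and those supporting the
exclusion isoform of an event. It also ships a seeded generator of such
experiments with known ground truth, and a small ChIP-qPCR
relative-quantification module. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Array model and coordinate system

The design hierarchy is gene → event → probeset → probe. Events are
cassette exons, alternative 5′/3′ splice sites, or mutually exclusive exon
pairs. Probesets carry a `group` label:

- **inclusion** — exon-body probes and flank–exon junction probes, whose
  signal scales with the fraction of transcripts containing the
  alternative exon (PSI);
- **exclusion** — the flank–flank (skipping) junction, scaling with 1 − PSI;
- **constitutive** — probes in exons present in every isoform, scaling
  with total transcript abundance; these alone define gene expression.

A cassette event has exactly one exclusion junction and up to three
inclusion probesets (one exon body, two inclusion junctions). Mutually
exclusive exon pairs are mapped onto the same dichotomy (exon A group =
inclusion, exon B group = exclusion) because the calling rule is stated in
those terms; for an alternative splice site the distal junction is the
inclusion side and the proximal one the exclusion side. Design coordinates
are 1-based inclusive; the BED export converts to 0-based half-open.

## Normalization and the gene expression index

1. **Array scaling.** Each sample column is multiplied by one scalar so
   its 2%-trimmed mean equals 500 fluorescence units. The target is chosen
   so that the absolute "expressed" cutoff of 500 coincides with the
   array-wide trimmed mean. Scaling makes the whole pipeline invariant to
   per-array gain differences.
2. **Probe-affinity correction.** Each probe's multiplicative affinity is
   estimated as the median over samples of its log2 residual against the
   per-sample median of its gene's **constitutive** probes, and divided
   out. Referencing constitutive probes (rather than all probes of the
   gene) keeps the corrected scale at transcript abundance: junction
   probes run at an isoform fraction of it and a whole-gene median would
   sit roughly two-fold low, which would defeat an absolute expressed
   threshold. The correction is a per-probe constant, so it changes no
   between-condition statistic — it serves interpretability of the
   absolute scale.
3. **Probe selection.** Per gene, constitutive probes whose cross-sample
   log2 profile has Pearson r ≥ 0.7 against the gene's median constitutive
   profile are retained; zero-variance profiles count as r = 0; if fewer
   than 3 survive, all constitutive probes are kept. This is a
   cross-hybridization guard. Event probesets are never filtered — they
   carry the signal of interest. Note that with few samples the profile
   correlations are noisy: with no true profile structure the filter drops
   probes essentially at random, and the `min_keep` fallback bounds the
   damage.
4. **Gene expression index.** The arithmetic mean of the selected
   constitutive probes on the linear scale, per gene and sample.

All four thresholds (trim 0.02, target 500, r_min 0.7, min_keep 3) are
config keys.

## Regulated-gene rule

A gene is *expressed* in a condition when its mean index there is ≥ 500
(inclusive). It is *regulated* when (i) it is expressed in at least one
condition, (ii) the symmetric fold change of the linear condition means,
max(m_t/m_c, m_c/m_t), is ≥ 1.5, and (iii) a two-sided unpaired
pooled-variance (Student) t-test on the log2 indices gives p ≤ 0.05.
Welch's form is available by config. No multiple-testing correction is
applied; the thresholds are raw cutoffs, and the null false-positive rate
is therefore the nominal α among genes passing the other two clauses.
Degenerate t-tests are resolved explicitly: zero pooled variance with
equal means gives t = 0, p = 1; with unequal means p = 0 plus a warning.

## Splicing statistics

For probe p and sample s the splicing index is
si(p, s) = log2(intensity(p, s) / index(gene(p), s)); a transcription
change moves numerator and denominator together and cancels, so si
isolates isoform redistribution. The condition contrast is
Δsi(p) = mean_treated si − mean_control si. Per probe, an unpaired
two-sided t-test compares si between conditions (the same routine as the
gene-level test; by config the test can instead run on raw log2 probe
signals, in which case expression changes also register). Probe p-values
within a probeset are combined with Fisher's method,
X = −2 Σ ln p_i ~ χ²(2k); p-values are clipped to [1e-300, 1] so the log
is finite, and for k = 1 the transform inverts exactly. A probeset is
significant when its combined p ≤ 0.01.

**Event calling.** An event is called when

- at least ⌈n_excl/3⌉ exclusion probesets are significant,
- at least ⌈n_incl/3⌉ inclusion probesets are significant, and
- every significant inclusion probeset's Δsi sign is opposite to the
  consensus sign (the sign of the summed Δsi of the significant exclusion
  probesets).

The ceiling makes "at least one-third" of a single probeset mean one. For
a cassette exon this reduces to: the exclusion junction and at least one
of the three inclusion probesets significant, with opposite regulation.
A zero consensus (exactly cancelling exclusion shifts) leaves the event
uncalled and is logged as indeterminate. The all-must-oppose reading of
the direction condition is the strictest one consistent with the cassette
special case; it is what makes the empirical false-positive rate far
below the per-probeset α (the null calibration below measures ~0 called
events per thousand at α = 0.01). Event direction is reported from the
inclusion side: +1 means inclusion up in treated.

Called-event counts are summarized as cassette / mutually exclusive /
alternative 5′+3′ (pooled) / total, next to the regulated-gene count.

## Synthetic experiment generator

The generator emulates the statistical structure this caller assumes, at
reduced scale, from a two-isoform mixture:

    constitutive probe mean = a_p · E_g
    inclusion probe mean    = a_p · PSI_e · E_g
    exclusion probe mean    = a_p · (1 − PSI_e) · E_g

with log2 E_g ~ Normal(10, 1.5) (a `fraction_unexpressed` of genes is
instead drawn near optical background, log2 E ≈ 7 ≈ 128 units, below the
500 cutoff), probe affinity log2 a_p ~ Normal(0, 0.5), baseline PSI ~
Uniform(0.2, 0.8), and multiplicative replicate noise 2^Normal(0, 0.25)
per probe and sample. Intensities are floored at 1.0 fluorescence unit
after noise so logs stay finite (scanner data are positive). Event types
are drawn in the ratio 13150 : 6517 : 1145 (≈63% cassette, 31%
alternative 5′/3′ split evenly, 6% mutually exclusive), matching the
composition of a human junction array; events per gene are Poisson with
mean 1.0 by default, a desk-scale stand-in for an array interrogating
~21k events over ~33k genes. Each gene gets two constitutive probesets
and each probeset 3–4 probes. Default replication is n = 3 arrays per
condition, a typical microarray design choice.

Injected effects: a fraction of events gets PSI shifted by ±0.3 (clipped
to [0, 1]) in the treated condition; a fraction of genes gets a 2-fold
expression change. The truth tables record, per gene, linear expression
per condition and the regulated flag, and per event the control/treated
PSI and true direction. One global seed drives three deterministically
derived substreams (design, truth, noise), so the full triple is
reproducible bit-for-bit and stages can be regenerated independently.

**What the generator does not model:** probe-sequence (GC) affinity
structure, cross-hybridization, spatial array artifacts, correlated
probe noise, partial isoform mixtures beyond two isoforms, or
condition-dependent background. Passing recovery tests therefore show
that the statistics behave as designed under the assumed signal model,
not that the pipeline is robust to the artifacts of real hybridizations.

## Calibration results the test-suite thresholds rest on

Null calibration (1000 genes, ~1200 events, n = 3, no injected effects):
the called-event fraction is ≈ 0 (well below 0.01) and the gene-level
p ≤ 0.05 fraction lies within binomial 99% bounds of 0.05 — the t-test is
calibrated and the event rule's conjunction suppresses the per-probeset α.

Power calibration (ΔPSI = 0.3 on 10% of events, noise sd 0.25, n = 3):
across several seeds the caller recovers 72–88% of injected events
(similar for cassettes), with direction accuracy 1.0 among true
positives and zero false positives in every run. The misses are events
whose weaker side has a small log2 isoform ratio — e.g. PSI 0.73 → 1.0
leaves the inclusion side at log2(1/0.73) ≈ 0.45, below what a 3-vs-3
per-probe t-test can reliably push through Fisher's method at α = 0.01.
A direct Monte-Carlo of the calling statistics alone puts the intrinsic
ceiling near 0.89 at these conditions; shared gene-index noise (which
correlates the probe p-values within a gene) and the noisy probe-selection
filter account for the rest. The recovery tests therefore assert
sensitivity ≥ 0.7 and exact direction accuracy, thresholds fixed from
this calibration; the acceptance script reports the measured sensitivity
itself.

## ChIP-qPCR quantification

Relative enrichment of immunoprecipitated chromatin over input DNA is
2^(Ct_reference − Ct_sample); only ΔCt matters, and no
amplification-efficiency correction is applied (the pure 2^ΔCt form).
Replicates — independent immunoprecipitations, at least three expected
per experiment, fewer triggering a warning — are aggregated as mean and
sample standard deviation of per-replicate ratios; a single replicate
reports sd 0 with a warning. Treated/control comparisons are ratios of
mean enrichments with first-order error propagation. Whether such bar
plots should show means of per-replicate ratios or ratios of means is a
genuinely open convention; per-replicate means are used here.

## Numerical and degenerate-input choices

- Intensities are floored at 1.0 before any log2, everywhere.
- An all-zero array column is a hard error (no scaling factor exists).
- A probeset with zero probes, an event without both sides, or a gene
  without constitutive probesets is rejected at design validation.
- Fisher combination of an empty p-value list is an error; a single
  p-value passes through unchanged.
- Sign conventions: direction = sign(treated − control) throughout;
  swapping condition labels flips every direction and no significance.
- Problem sizes in the shipped analyses and checks (1000 genes, ~1200
  events, n = 3) are desk-scale choices that keep every property measured
  at comfortable Monte-Carlo resolution.

## Known limitations

- The per-probeset α (0.01) is applied without multiple-testing
  correction, faithfully to the original filtering style; genome-scale
  error control is the conjunction rule, not an FDR guarantee.
- Sensitivity is intrinsically limited for events whose baseline PSI is
  near the end of its range in the shifted direction (small log-ratio on
  one side); see the power calibration above.
- The expressed cutoff is an absolute intensity threshold; with the
  generator's wide expression distribution (sd 1.5 log2 units) roughly
  half the simulated genes fall below it, so gene-level recovery numbers
  mostly reflect the brighter half of the transcriptome — as with real
  intensity cutoffs.
- Real-array ingestion starts from a plain probe × sample intensity
  table; scanner-native formats and vendor annotation files are out of
  scope.
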