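# Methods

## Retention model and filters

A retention *event* is one intron of one transcript together with its two
flanking exons, taken in transcription order (on the minus strand "upstream"
is the genomically-rightmost exon and all sequence is reverse-complemented).
Events are defined per transcript because reading frame and flanking exons
are transcript-specific; reporting deduplicates by genomic interval
(chrom:start-end:strand), so an intron shared by transcripts counts once.

Read support is region-level: a uniquely-mapped read (MAPQ ≥ 255 by STAR's
convention, or NH:i:1 when the tag is present — the tag wins) supports a
region when any aligned M/=/X block overlaps it by ≥ 1 bp. A spliced read
whose N gap spans the intron therefore supports excision, never retention.
Region abundances are TPMs computed over the universe of all intron and
flanking-exon regions of the annotation: rate_r = count_r/length_r,
TPM_r = 10⁶·rate_r/Σrates. The denominator choice (region universe rather
than the whole transcriptome) keeps the pipeline self-contained and robust
to library composition outside the regions of interest; note the intron/
flank TPM *ratio* is independent of this denominator. `flank_tpm` is the
arithmetic mean of the two flanking-exon TPMs (a `min` option exists for a
stricter comparison). RPKM = count/(length_kb · library_size/10⁶), with
library_size the number of unique reads counted in the region universe (a
config-level alternative is all aligned reads; the counts-TSV input carries
library_size explicitly).

A sample retains an intron when all three region counts are **strictly**
greater than 10 and the TPM ratio lies **strictly** in (0.05, 0.5); both
bounds are read literally and are config-overridable
(`FilterConfig(min_region_count, ratio_low, ratio_high)`). The upper ratio
bound guards against unannotated exons or intronless paralogs masquerading
as retention; the lower bound against noise. The normal panel is the union
of passing events over healthy controls — presence in a single control
suffices for removal, with no frequency threshold — and tumor-specific
events are the set difference.

## Translation and peptide model

Translation anchors at the exon/intron junction: the cumulative CDS length
5′ of the junction mod 3 gives the number of leftover coding nucleotides
(`frame_at_intron_start`); those join the first intronic nucleotides, so a
junction-spanning codon counts as intron-encoded. The exonic flank keeps at
most 10 complete codons (k_max − 1 = 10 residues: every junction-spanning
8–11-mer with ≥ 1 intronic residue is reachable and nothing fully exonic
beyond that is enumerated). Translation stops at the first in-frame stop
codon, or at the last complete codon inside the intron — it never reads into
the downstream exon, since retention transcripts are expected to terminate
(and be degraded) within the intron. Events whose upstream exon is
non-coding, or whose CDS ends before the junction, are skipped: no frame
anchors the extension. Codons containing ambiguous bases truncate the
translation at that point.

Candidate peptides are all 8–11-residue windows of flank+extension with at
least one intron-encoded residue, deduplicated per (peptide, event). The
closed form for the window count with flank f and intronic length m,
Σ_k [(f+m−k+1)₊ − (f−k+1)₊], is enforced as a test oracle. Self filtering
is exact substring membership against an 8–11-mer index of the reference
proteome — no I/L equivalence or near-match tolerance, matching the removal
of peptides "derivable from normal proteins" as an exact criterion; windows
containing non-standard residues are never indexed.

Binder calls use percentile rank < 2.0 (strict, configurable). The bundled
surrogate predictor maps (seed, peptide, allele) through SHA-256 to a
uniform rank in [0, 100): deterministic, allele-normalised
("A02:01" ≡ "HLA-A*02:01"), and calibrated to a 2% binder rate by
construction. It models no binding biology; real analyses should feed
NetMHCpan-4.1 output through the file adapter.

Per-sample load counts **unique binder peptides** (deduplicated across
alleles and events); a `peptide-allele` unit is available where per-pair
counting is wanted. The expression-weighted load is Σ over
neoantigen-producing events of RPKM(event) × (unique binders from that
event); an alternative sums RPKM once per event. A peptide produced by
several events contributes to each event's term — its presentation is
supported by each source transcript's abundance.

## Survival analysis

Cohorts are dichotomised at the median load; values exactly at the median go
to "low" (high means strictly above). Kaplan–Meier uses the product-limit
estimator with deaths-before-censorings at tied times. The log-rank test is
the standard (O−E)²/V statistic with the hypergeometric variance, 1 df. Cox
fits maximise the partial likelihood by Newton–Raphson with step-halving,
Breslow tie handling by default (Efron by flag), convergence at max|score| <
1e-8 within 50 iterations, Wald SEs from the observed information, and 95%
CIs as exp(β ± 1.96·se). Runaway coefficients (|β| > 50) or a singular
information matrix mark the fit unconverged — the usual presentation of
complete separation. Categorical covariates are one-hot encoded against a
declared reference level; the score test at β = 0 for a binary covariate
reproduces the log-rank statistic exactly (asserted to 1e-6 in tests).
Spearman correlation uses average ranks for ties and a t-approximation
p-value. All estimators are implemented from the formulas; lifelines and
scipy serve as independent cross-checks in the test suite, not as the
implementation. p-values are two-sided with no multiplicity correction.

## Synthetic study

The generator emulates the statistical structure of a retention cohort at
desk scale — by default 20 genes × 3 exons (CDS over the full exon, exon
lengths 90–150 nt forced to multiples of 3 so every junction has phase 0;
non-zero phases are exercised by hand-built fixtures in the unit tests),
intron lengths 90–180 nt with controlled stop placement (20% immediate stop,
60% short ORF of 6–12 codons then stop, 20% stop-free), 50 tumor and 5
normal samples. The proteome is the translated annotated CDS, so intronic
peptides are non-self by construction except for planted self-decoy 9-mers
appended deliberately to the proteome to exercise the filter.

Counts: flanking exons draw negative-binomial reads (mean 200, dispersion
0.05, clipped below at 12 so noise alone never fails the exon-count clause
of a planted event); intron counts are then set deterministically from the
realised flank rates — planted events target a TPM ratio uniform in
(0.1, 0.4), background introns sit at ratio ≈ 0.01, and three designated
decoys in one sample each violate exactly one filter clause (count = 10
with ratio in range; ratio ≈ 0.04 with counts > 10; ratio ≈ 0.7). This
makes planted/background classification exact, which is what the
planted-recovery tests assert. Each tumor sample's retention propensity is
drawn uniformly so event counts (and loads) spread widely across the
cohort; panel events (20% of introns) are each planted in ≥ 1 normal and may
also appear in tumors, exercising the subtraction.

Survival times are exponential with hazard h₀·exp(β·I(load > median)),
h₀ = 1/60 per month, planted β = log 2, independent exponential censoring
calibrated to ≈ 30% at baseline; age and sex are independent nuisance
covariates. Problem sizes throughout (50-sample cohorts, 200-replicate
recovery and calibration studies at n = 300) were chosen to give the
estimators realistic but quick workloads; the whole suite runs in well under
a minute.

What passing these tests shows — and does not. The synthetic data validates
coordinate arithmetic, filter logic, translation, enumeration, set algebra
and estimator correctness end to end. It does not emulate mapping artefacts,
coverage non-uniformity, overlapping genes, alternative isoform structure
within a gene, real HLA binding specificity, or NMD efficiency; conclusions
about real cohorts still depend on aligner settings, annotation quality and
the external binding predictor.

## Known limitations

- GTF (Ensembl/Gencode dialect) only; no GFF3, alternative codon tables, or
  selenocysteine recoding.
- Region counting loads each read once per region universe; no multi-mapper
  rescue, junction-read splice index, or per-base coverage uniformity test —
  the two retention filters above are the whole decision rule.
- The surrogate binding scorer is uniform by design; per-allele presentation
  summaries under it reflect sampling noise, not biology.
- Cox fits assume proportional hazards and support neither stratification
  nor time-varying covariates.
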