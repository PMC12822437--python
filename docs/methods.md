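# Methods

## Problem setting

Grafting two polymorphic accessions produces a chimeric plant in which every
transcript's tissue of origin can be read from accession-diagnostic SNPs: a
read carrying the graft partner's allele in a tissue that does not encode it
implies long-distance transport across the graft junction. `graftmobile`
implements this inference chain — diagnostic SNP reference construction,
error-aware foreign-read filtering, mobile calling and classification — plus
the companion analyses used to characterize mobile transcripts: translation
status from ribosome-affinity (TRAP) sequencing, a simplified
differential-expression rule, RNA secondary-structure statistics, targeted DMS
mutational profiling, and in-silico CAPS/dCAPS genotype verification.

All stages consume per-site allele-observation tables (counts of local-allele,
foreign-allele and other reads at each diagnostic SNP per sample), the
sufficient statistic for every decision rule in the pipeline. Read alignment
itself is upstream of the package.

## Reference SNP construction (`variants`)

Candidate variants carry GATK-style site annotations and depth evidence.  The
filter ladder is applied in a fixed order with first-failure attribution so
audit counts are reproducible:

1. **Hard filter** — fail if QD < 2.0, MQ < 40.0, FS > 60.0, SOR > 3.0 or
   DP < 10 (any clause removes the record; thresholds configurable).
2. **Support** — at least 10 reads in both DNA- and RNA-level data of both
   accessions.
3. **Genotype consistency** — every dataset of an accession must report the
   same single homozygous allele, and the two accessions' alleles must
   differ.  Heterozygous, ambiguous or multi-allelic calls fail.
4. **Organelle exclusion** — SNPs on mitochondrial/plastid contigs are
   removed (organellar RNA editing would mimic foreign alleles).

The ladder is monotone: relaxing any threshold can only grow the output set.
On clean synthetic evidence the recovered set equals the simulated diagnostic
set exactly (precision = recall = 1), which the tests assert.

## Foreign-read gating: beta-binomial Bayes factor (`mobility`)

Sequencing error produces spurious foreign-allele reads.  At each site the
heterograft count k_het/n_het is contrasted with the matched homograft count
k_homo/n_homo (homografts can only contain error reads):

- **M0 (error only)**: one rate θ ~ Beta(a0, b0) generates both counts.
- **M1 (mobility)**: the homograft has its own error rate θ_err ~ Beta(a0, b0)
  and the heterograft an independent rate θ_mob ~ Beta(a1, b1).

Both marginal likelihoods are exact beta-binomial integrals (log-beta
functions; binomial coefficients cancel), and the site is **informative** when
log10(m1/m0) > 1 (strict).  Priors default to Beta(1, 1) and are
configurable; with uniform priors the extra free rate under M1 carries a
substantial Occam penalty, so matched heterograft/homograft rates yield a
clearly negative log10 BF rather than ≈ 0 — conservative and desirable for a
gate.  The factor is monotone non-decreasing in k_het at fixed totals
(property-tested), and a heterograft site with zero coverage is flagged
non-informative.

Informative sites are selected **per tissue, pooling heterograft counts
across all conditions and replicates**.  Site selection is a dataset-level
reference-quality step, so pooling maximizes the depth behind each decision;
selecting sites per condition at shallow depth preferentially retains
upward-fluctuating sites and inflates downstream abundance estimates at low
transfer rates (a winner's-curse bias of ~15–25% in our simulations).

## Mobile calling, abundance, index, classification

- **Detection**: per transcript, condition and replicate, foreign reads are
  summed over the tissue's informative sites; the transcript is mobile when
  strictly more than 3 foreign SNP-covering reads are seen in at least 2
  biological replicates.  The >3-read rule is applied per replicate (the
  aggregate reading is available via configuration).
- **Mobile abundance**: foreign reads per million SNP-covering library reads,
  averaged over replicates.  The per-million normalization is this package's
  convention; numerator and denominator of the index below use it
  consistently, so the index is normalization-invariant up to library-size
  ratios.
- **Mobile index (MI)**: mean mobile abundance in the recipient tissue over
  mean local abundance in the donor tissue, both over the same informative
  sites (site count cancels).  Under the generator's model MI estimates the
  per-read transfer rate; simulations recover rates of 0.02–0.5 within a few
  percent once ≥ 50 foreign reads support the estimate.  MI is undefined
  (flagged) when donor abundance is zero.
- **Condition specificity** over the four Pi regimes {FP7D, NP3D, NP7D,
  NP7DRP2D}: *PSI-specific* = detected only under Pi deficiency
  (NP3D/NP7D); *PSD-specific* = only under effective sufficiency
  (FP7D/NP7DRP2D); *common* = at least one of each; *other* = none.  The
  four categories are disjoint and exhaustive (tested over all 16 patterns).
- **PHR dependence**: mobile transcripts of the wild-type graft absent from
  the PSR-mutant graft, with the retained fraction; set overlaps are scored
  with the upper-tail hypergeometric test.

## Translation status (`translatome`)

TRAP IP observations pass through the *same* informative-site and detection
thresholds as the RNA screen.  A mobile transcript detected in the recipient
tissue's IP is *translated*; otherwise *untranslated*.  Operationalizing
"absent from TRAP" as failing the detection rule (not literal zero) keeps the
two screens symmetric; a strict-zero mode can be had by setting
`min_reads=0, min_replicates=1` on the IP screen.  Translational efficiency
TE = TRAP abundance / RNA abundance on identically normalized scales, with
log2 TE contrasts between conditions; a 1.5× fold-change convention is
suggested for calling TE shifts, as the underlying decision rule in the
source workflow is unstated.

## Differential expression (`expression`)

A deliberately simple, self-contained stand-in (the package makes no claims
about DE beyond the cutoff rule): median-of-ratios size factors (factor =
median over all-positive genes of count / geometric row mean), log2 fold
change of pseudocounted (ε = 1) group means, and a two-sided Welch t-test on
log2(count + 1).  Status is Up iff log2FC > 1 and P < 0.05, Down for the
mirrored rule, NS otherwise.  On 2000 simulated null genes (n = 3 vs 3
Poisson replicates) the realized type-I rate is ≈ 0.03–0.04 — slightly
conservative, as expected for a t-test on discretized counts at n = 3.  No
multiple-testing correction is applied by default, matching the cutoff
semantics; dispersion shrinkage and GLM fitting are out of scope.

## RNA secondary structure (`structure`)

Regions (5'UTR/CDS/3'UTR) are extracted in transcript orientation from
1-based closed genomic intervals (reverse-complemented on minus strands).
Statistics per region: minimum free energy ΔG (≤ 0), the per-nucleotide
folding strength −ΔG/nt (lower = less structured), GC fraction and length.

Two interchangeable folding backends:

- **`nn`** — nearest-neighbor thermodynamic model at 37 °C via the ViennaRNA
  bindings; required only to reproduce published kcal/mol values.  Printed
  ΔG values can shift slightly across thermodynamic parameter-set versions.
- **`test`** — a built-in dynamic program maximizing weighted base pairs
  (GC = 3, AU = 2, GU = 1) plus a stacking bonus (1) per directly nested
  pair, minimum hairpin loop of 3.  Its recursion tracks interval-optimal and
  pair-constrained scores so stacking is exact; it is verified against
  exhaustive structure enumeration on hundreds of short random sequences.
  This makes the whole analysis testable to machine precision without a
  thermodynamics dependency.

Group contrasts: two-sample Kolmogorov–Smirnov D (max ECDF separation, checked
against a brute-force scan) with its p-value (exact for small samples,
verified against exhaustive label permutation), and the two-sided rank-sum
test; ECDF tables are returned for cumulative plots.  The quartile partition
labels ids bottom 25% / middle 50% / top 25% by value with boundaries at rank
⌈n/4⌉ from each end and ties broken by stable id order, and scores query-set
enrichment per stratum hypergeometrically.

## DMS mutational profiling (`dms`)

Raw reactivity = mismatch/depth at A and C positions only (DMS methylates
unpaired A/C); positions under the depth floor (default 500 reads — a
targeted-amplicon scale) are no-data.  Mismatches within 3 nt of an indel in
the same read are discarded as alignment artifacts (depth still counts;
widening the mask can only decrease mismatch counts — property-tested).
Replicate QC fails profiles showing the PCR-jackpot pathology — more than 90%
of A/C positions below 0.5% while some position spikes to ≥ 5% — and the
degenerate all-zero profile; these thresholds are this package's concrete
defaults for a qualitative exclusion rule and are configurable and logged.
Passing replicates are averaged position-wise **before** normalization (the
order is enforced and order-sensitivity is asserted on a crafted example);
the averaged profile is divided by the median of its top ⌈0.05·n⌉ rates
(midpoint median for even slices) and winsorized at 1.0.  Constraint export
is SHAPE-style two-column with −999 at non-A/C/no-data positions.  Agreement
with a reference structure is summarized as the AUC of normalized reactivity
separating unpaired from paired A/C; simulated profiles at depth 2000
(5% vs 0.5% rates) reach AUC ≈ 1.

## In-silico CAPS/dCAPS (`markers`)

Virtual PCR finds the unique best product: forward primer on the plus strand,
reverse primer as its reverse complement downstream, each tolerating a
configurable mismatch count except at the 3' terminus (a 3'-terminal mismatch
abolishes priming — the standard dCAPS assumption).  Zero or tied products
raise with the candidate list.  Digestion cuts after a fixed offset within
each recognition-site occurrence on both strands (RsaI = GTAC cut after 2 and
BamHI = GGATCC cut after 1 ship as built-ins); fragment lengths always sum to
the input length.  Genotype calling matches the observed fragment multiset to
expected patterns within ±2 bp (gel resolution), returning "ambiguous" for
zero or multiple matches.

## Synthetic data: what it does and does not emulate (`synthetic`)

The generator draws two accessions differing at biallelic SNPs
(Binomial(length, density) per transcript, density 0.01/nt default, mean
transcript length 1000 nt, one transcript per contig, ~4% organellar
contigs), a reciprocal graft design (heterograft plus two homograft controls,
shoot and root, four Pi regimes × 3 replicates), and per-site allele counts
at Poisson depth (default 50/site).  Sequencing error substitutes a read's
base uniformly over the three alternatives, so a fraction error/3 of local
reads mimics the foreign allele.  Mobile transcripts (~15% of transcripts;
PSI : PSD : constitutive ≈ 35 : 35 : 30) draw genuinely foreign reads at a
per-read transfer rate (default 0.05 → ~25 expected foreign reads per
replicate over ~10 SNPs) only in their conditions and direction.  TRAP IP
tables binomially thin the RNA observations, with foreign reads of
untranslated mobile transcripts absent entirely; DMS counts draw mismatches
at pairing-state-dependent rates at A/C and background elsewhere.  All
generators are deterministic given their seed, and counts conserve
(local + foreign + other = depth).

What this does *not* model: alignment and mappability artifacts, positional
coverage bias along transcripts, overdispersed biological replicate noise in
allele counts, RNA editing, partial transcript transport, or expression
differences between conditions (expression shifts are generated separately
for the DE module).  Passing tests therefore demonstrate the correctness of
the decision rules and estimators under the stated sampling model, not
robustness to alignment pathologies in real data.

## Problem sizes and numerical choices

Validation simulations use 200 transcripts (~2000 SNP sites, 72 samples) for
recovery and false-positive control, 60 transcripts for mobile-index
calibration, 200 random sequences of 5–18 nt for the folding oracle, 2000
genes for null DE calibration, and 120-nt amplicons at depth 2000 for DMS —
sizes at which every check runs in seconds while keeping binomial standard
errors far below the decision margins.  Ties in quartile ranking break by id
order; KS p-values use the exact small-sample distribution; Bayes factors are
computed in log space throughout; the MFE dynamic program and its
enumeration oracle treat T as U and are case-insensitive.

## Known limitations

- The Bayes-factor model is a re-derivation of the published gating idea
  (threshold log10 BF > 1), not a reimplementation of the cited tool; with
  informative priors the numeric values of the factor (not the gate's
  qualitative behavior) change.
- MI compares per-million abundances across tissues with different library
  compositions; strong global shifts in SNP-covering read totals between
  tissues would bias it.
- The DE stand-in is not a shrinkage estimator and should not be used for
  genome-wide inference beyond the cutoff rule it documents.
- Reproducing published kcal/mol ΔG values requires the `nn` backend and the
  original reference sequences; the built-in backend's energies are exact
  under its own model but not thermodynamic.
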