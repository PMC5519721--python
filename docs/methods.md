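# Methods

This note records the models implemented, the choices made where the design
was genuinely open, and what the synthetic data do and do not emulate.

## Coordinates and formats

Internally every coordinate is 0-based half-open; VCF/GFF3 (1-based) and BED
(0-based) adapters convert at the boundary, so a 1-based position p maps to
internal p−1 and an interval-track query for 1-based q tests containment of
q−1.  Only phased biallelic SNPs enter the pipeline; multi-allelic, indel and
unphased records are dropped and counted.  A missing ancestral allele keeps a
variant in F_ST and enrichment analyses but excludes it from DAF-dependent
statistics (iHS, DAF bins), with a reason code rather than a silent zero.

## SRE annotation

The 11-base reference context (5 bases each side) is extracted per SNP; for
each allele the six hexamer windows containing the SNP (last position →
first position) are exact-matched against the ESE/ESS/ISE motif lists.
Matching is done on the **transcribed strand** of the host gene (minus-strand
contexts and alleles are reverse-complemented before windowing), because the
motifs are pre-mRNA elements; the reverse-complement consistency of all calls
is property-tested.  An SRE call requires, per element type, the exon-skip
geometry: ESE/ESS inside an exon that is skipped (present in one isoform,
absent in another that retains both flanking exons), ISE anywhere within an
intron directly flanking such an exon ("immediately adjacent" is uncapped by
default; `max_intron_distance` tightens it).  A SNP whose two alleles both
match motifs is recorded with all matched types but flagged *ambiguous* and
excluded from disrupt/induce contrasts.  LOF is restricted to stop-gain and
canonical GT/AG splice-dinucleotide disruption (only SNPs are modelled, so
frameshift cannot occur); codon classification assumes the annotated CDS
chain starts in frame 0 at its 5′ end and refuses to classify (class
"other") when the CDS disagrees with the reference base.

## Selection statistics

**F_ST.** Weir–Cockerham (1984) two-population per-locus estimator computed
from haplotype (haploid) counts, with the within-individual heterozygosity
component zero under the haploid convention: θ̂ = a/(a+b).  Negative
estimates are retained in output and clipped to 0 only for bin assignment.
For *recovery* checks against the Balding–Nichols parameter c we use the
standard multi-locus ratio of sums Σa/Σ(a+b): the mean of per-locus ratios
is Jensen-biased downward (≈0.114 at c = 0.15 with 100 haplotypes per
population) and is not a consistent estimate of c.

**EHH / iHS / XP-EHH.** EHH at distance d is the probability that two
distinct random carrier haplotypes are identical at every site between the
core and d; curves are walked site by site until EHH < 0.05 or the
chromosome end (boundary truncation is flagged).  Integrals use the
trapezoid rule on genetic distance (cM) and sum both directions.  iHS puts
the ancestral integral in the numerator, so extended homozygosity on the
derived background gives negative raw scores; outlier calls use |score| ≥ 2
and are unaffected by the sign convention.  iHS is standardized within
derived-allele-frequency bins of width 0.05 (bins with < 20 defined scores
merge leftward); XP-EHH uses a single genome-wide bin.  XP-EHH anchors on
the derived allele where known, otherwise ALT (configurable).

**XP-CLR.** The neutral model for the P2 frequency at a SNP is a truncated
normal about the P1 sample frequency.  Two numerical choices matter and are
deliberate deviations from the simplest reading of the drift model:

* the variance is evaluated at the *pooled* sample frequency and includes
  binomial sampling noise, (ω + 1/n₁ + 1/n₂)·p̄(1−p̄).  Using p₀(1−p₀) with
  p₀ = p̂₁ degenerates when P1 is near fixation — single neutral SNPs then
  contribute ~100 log-likelihood units and null windows out-score real
  sweeps;
* the sweep alternative is a per-SNP *hitchhiking mixture*: with strength
  s = s_g·e^(−d/δ), the allele rides the sweeping haplotype with
  probability p₀ (mean shifted toward 1) and is otherwise pushed toward 0.
  A window-wide single shift direction cannot represent a sweep's
  per-site-signed frequency changes and loses essentially all power at
  moderate divergence.

This distance-decayed approximation (grid s_g ∈ {0, 0.05, …, 0.5},
δ ∈ {0.01, 0.1, 1} cM, windows of k = 50 SNPs sliding every 10, per-variant
score = max over covering windows) deliberately replaces the full
hitchhiking transition density of the original XP-CLR method; it preserves
the tested contract (null windows stochastically below planted-sweep
windows).  ω is calibrated by method of moments on putatively neutral SNPs —
mean[(p̂₁−p̂₂)² − sampling terms] / mean[p̄(1−p̄)] — floored at 1e−6; on
Balding–Nichols panels ω̂ tracks 2c/(1−c) within 20%.

**Composite likelihood.** log L(x) = α·log f_FST + β·log f_XPEHH +
γ·log f_XPCLR with histogram densities (50 bins, add-one smoothing).  The
exponents default to 1 and are config-only: no estimation procedure for them
is defined here.

## Enrichment

2×2 p-values use Fisher's exact test; a Haldane–Anscombe 0.5 correction is
applied (and flagged) to zero cells.  Extreme-F_ST flags are > 0.70 and
< 0.05; bins have width 0.1.  LD extent L = Σ r² uses a ±200 kb neighbour
window on haplotype 0/1 vectors (the window is a documented default — no
canonical value exists).  The CMH common odds ratio is the Mantel–Haenszel
estimator with a continuity-corrected chi-square test (statsmodels
`StratifiedTable` behind the module surface, cross-checked against the
direct formula in tests); degenerate strata are dropped with a log entry and
the crude pooled OR is reported alongside so confounding inflation is
visible.  Matched-null empirical p-values draw n random sets with exactly
the target's per-bin composition (B width 100, DAF width 0.05, LD intervals
[0,50), [50,85), [85,110), [110,140), ≥140; optional MAF width 0.05,
gene-size quintiles, junction-distance quartiles) and use the
(#{null ≥ obs}+1)/(n+1) convention; under-populated cells sample with
replacement and are logged, empty cells are errors.

## Models

The logistic overlap model is fitted by IRLS on internally z-scored features
with coefficients and SEs back-transformed to the original scale; Wald tests
per coefficient; perfect univariate separation and constant columns are
errors naming the feature.  The GREML partition uses AI-REML with EM-REML
fallback steps, an active-set treatment of the zero boundary (a component
pinned at the floor stays there unless its gradient points inward),
starting values of one third of the phenotypic variance each, and
convergence at |Δ logL| < 1e−6.  h²_SRE = σ̂²_SRE/(σ̂²_SRE+σ̂²_nonSRE+σ̂²_e)
with a delta-method SE from the inverse AI matrix.  Identical relatedness
matrices raise a non-identifiability error.  Case-control traits would be
analysed on the observed scale (no liability transformation) — a recorded
limitation; fixed effects default to an intercept.

## Synthetic data: what it emulates, what it does not

Population divergence follows the Balding–Nichols model (p₀ ~ U(0.05,0.95),
population frequencies Beta-distributed around p₀ with parameter c equal to
the expected F_ST), chosen precisely because c gives a closed-form recovery
target.  Haplotypes within a panel are **mutually independent** with local
LD induced by a Gaussian-copula AR(1) latent process (adjacent-site latent
correlation 0.9): this preserves exact Bernoulli(freq) marginals — so
per-site counts are exact binomial draws and frequency-based estimators see
the sampling model they assume — while giving realistic r² decay over tens
of sites.  A copy-one-haplotype-from-another scheme was rejected because any
cross-haplotype copying inflates realized-frequency variance far beyond
binomial (measured ω̂ ≈ 1.5 versus a target of 0.105), breaking F_ST and
drift-scale recovery.  Sweeps are planted by copying one template carrier
haplotype over a fraction f of the carriers of a favoured core allele within
±L sites (defaults f = 0.8, L = 100) — sufficient to create the EHH and
frequency-differentiation contrasts the statistics detect, with none of the
demographic realism of coalescent or forward simulation (no recombination
map heterogeneity, no drift trajectories, no mutation-age structure).
Passing tests therefore demonstrate correctness of the statistics under
their own sampling assumptions, not robustness to real human demography.

Gene models are plus-strand, codon-aligned exons with canonical GT/AG
introns; exactly round(skip_probability × n_genes) genes carry one skipped
internal exon so fixture capacity for exonic plants does not fluctuate
across seeds.  SRE SNPs are planted so that exactly one allele's context
matches a motif of exactly the intended element type and the other allele
matches nothing; decoy SNPs (real motif match, failing exon-skip geometry)
exercise the geometry gate; non-SRE SNPs match nothing with either allele
(rejection sampling, with an explicit generation error if constraints cannot
be met).  The ancestral allele is always REF in fixtures.  B-values are
drawn independently of genotypes; the CMH study instead uses directly
constructed stratum tables in which SRE membership and the high-F_ST rate
both rise across B strata while the within-stratum OR is constant — a
Simpson-type confounding fixture with a known common OR.

## Problem sizes and reproducibility

Study sizes used by the tests and the acceptance script: F_ST recovery at
20 000 SNPs and 100 haplotypes per population; sweep detection over 20
replicate panels of 1500 SNPs; matched-null calibration over 200 replicates
at 200 null sets; logistic recovery at n = 50 000; GREML coverage over 50
replicates at n = 2000 individuals and 5000 SNPs (2500 per component);
annotation truth over 10 fixture seeds of 1000 SNPs.  Every stochastic step
takes a single integer seed; identical seeds give identical outputs.

## Known limitations

* The XP-CLR alternative is a calibrated approximation, not the original
  hitchhiking transition density; scores are comparable within a run, not
  across tools.
* Composite-likelihood weights α, β, γ are not estimated.
* The EHH stopping rule (0.05) and the LD-extent window (±200 kb) are
  conventional defaults; results near chromosome edges carry a truncation
  flag rather than a correction.
* GREML SEs come from the inverse average-information matrix and are
  slightly optimistic near the zero boundary.
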