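# sre-selscan

Population-genetic selection analysis of **splicing-regulatory-element (SRE)
variants** — SNPs that create or destroy the hexameric motifs (exonic
splicing enhancers/silencers ESE/ESS, intronic splicing enhancers ISE) that
steer exon-skipping decisions.  The package asks whether such variants show
unusual population differentiation and haplotype signatures of selection,
and how much trait heritability they carry, and ships a synthetic-data
generator with planted truth so every statistical step is testable end to
end.

## Who it is for

Statistical/population geneticists who want a tested, seed-reproducible
implementation of the full chain:

1. **Annotation** — for each SNP, slide a 6-bp window across the 11-base
   context (SNP in last position, shifting to first position) per allele and
   exact-match against motif lists; an SRE call additionally requires
   exon-skip geometry (ESE/ESS inside a skipped exon, ISE in a directly
   flanking intron).  The motif-creating allele is *inducing*, the other
   *disrupting*.  Functional classes: intronic / synonymous / non-synonymous
   / LOF (stop-gain or GT/AG splice-dinucleotide disruption).
2. **Selection statistics** — per-SNP Weir–Cockerham F_ST
   (θ̂ = a/(a+b) from haploid counts), derived allele frequency, EHH with
   integrated scores

   - iHS = log(∫EHH_ancestral dη / ∫EHH_derived dη), standardized within
     DAF bins of width 0.05,
   - XP-EHH = log(∫EHH_P1 / ∫EHH_P2), standardized genome-wide,
   - XP-CLR: composite likelihood ratio of a distance-decayed hitchhiking
     mixture against the neutral drift model
     p₂ ~ N(p₀, (ω + 1/n₁ + 1/n₂)·p̄(1−p̄)) truncated to [0,1], with
     ω = t/2Nₑ calibrated by method of moments,
   - a composite likelihood L(x) = f_FST^α · f_XPEHH^β · f_XPCLR^γ over
     empirical densities.
3. **Enrichment** — odds ratios per F_ST bin (width 0.1, extreme flags
   F_ST > 0.70 and < 0.05), conditional ORs, the Cochran–Mantel–Haenszel
   common odds ratio across background-selection (B-value) strata, and
   empirical p-values from random SNP sets matched on B, DAF and LD-extent
   bins (p = (#{null ≥ obs}+1)/(n+1)).
4. **Models** — logistic regression of SRE overlap on per-SNP features,
   p = 1/(1+e^−(β₀+β·Δ)), and a two-variance-component GREML
   partition var(Y) = A_SRE σ²_SRE + A_nonSRE σ²_nonSRE + I σ²_e fitted by
   AI-REML, reporting h²_SRE = σ̂²_SRE/σ̂²_Y.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on a
synthetic study (two populations diverged at c = 0.15, 50 diploids each,
1000 SNPs of which 200 are planted in SRE motifs, one planted sweep):

```bash
python analysis/01_simulate_fixture.py --seed 42
python analysis/02_annotate_sre.py
python analysis/03_selection_scan.py
python analysis/04_enrichment.py
python analysis/05_models.py
```

Output excerpts (seed 42):

```
SNPs: 1000 total, 200 SRE ({'ISE': 100, 'ESS': 50, 'ESE': 50})
vs planted truth: sensitivity 1.000, false positives 0
calibrated drift scale omega = 0.3784
planted sweep 1:34778:C:A: xpehh_std = 3.03 (outlier threshold 2), xpclr = 7.5 (panel 99th percentile 9.0)
GREML h2_SRE estimates (truth 0.3):
 rep  h2_sre    se  converged
   0   0.278 0.045       True
```

Reading: annotation recovers every planted SRE SNP with no false positives;
the planted sweep is a clear standardized XP-EHH outlier (> 2) while its
XP-CLR sits just below the panel-wide 99th percentile at this divergence
(haplotype statistics are the more sensitive detector here); GREML returns
the construction value h²_SRE = 0.3 within one standard error.  Tables land
in `results/` as commented TSV.

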