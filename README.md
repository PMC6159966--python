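# dmmrkit

Tools for characterizing mismatch-repair-deficient (dMMR) tumors from
sequencing data, built around the analyses used to study dMMR in advanced
prostate cancer: microsatellite-instability (MSI) scoring from NGS allele
histograms, mutational-signature deconvolution, tumor-only somatic variant
filtering with mutation load, association of immune transcripts with dMMR
signature activity, and the biomarker/survival metrics used to compare dMMR
assays. A synthetic cohort generator with full ground truth makes every stage
testable end to end without access to patient data.

Intended users: computational oncology / cancer immunogenomics analysts who
need a reproducible, scriptable version of this analysis stack.

## Methods at a glance

**MSI by NGS.** For each microsatellite locus, the number of supported allele
lengths `a(s, l) = #{L : reads(L) ≥ f · max_L reads}` (default peak fraction
`f = 0.05`) is compared with a baseline built from MMR-intact specimens; a
locus is unstable when `a > μ_l + m·σ_l` (default multiplier `m = 2`). The
per-sample score is `unstable / evaluated`; exome-derived scores are scaled
by 0.209 onto the targeted-panel scale. A Promega-style classifier over the
five mononucleotide markers (BAT-25, BAT-26, NR-21, NR-24, MONO-27) calls
MSI-high at ≥ 2 unstable markers.

**Mutational signatures.** SNVs are classified into 96 pyrimidine-strand
trinucleotide channels, giving a catalog `V` (samples × 96). `V ≈ W·H` is
factorized by non-negative matrix factorization with multiplicative updates
minimizing the generalized Kullback–Leibler divergence
`D(V‖WH) = Σ (v log(v/ŵh) − v + ŵh)`, restarted from many random seeds with
the minimum-residual run retained. Discovered signatures are matched
one-to-one to references by cosine similarity; per-sample activity is the
row-normalized exposure, and a tumor is *MMR-dominant* when its summed
MMR-type activity strictly exceeds 0.5.

**Variant filter and mutation load.** Quality removal (haplotype score > 200,
mapping quality < 40, depth < 60, alt allele < 5 % of reads, multiallelic,
indels, blacklisted sites), germline removal (cohort allele frequency > 5 %,
≥ 2 population databases, or > 99.9 % alt reads), then COSMIC rescue of point
mutations reported somatic ≥ 10 times. Load is the surviving count per sample
(per Mb of panel, default 0.6 Mb), dichotomized at 5.5.

**Immune association.** Per-gene Pearson correlation of expression (TPM) with
dMMR signature activity, Benjamini–Hochberg FDR 0.1 over the gene set, and a
*consistent* call requiring nominal P < 0.05 within every biopsy-site stratum.
Includes the 32-gene immune-checkpoint panel geometric-mean score, pooled
LD-TIL density, and crude 2×2 odds ratios.

**Cohort metrics.** ROC AUC (Mann–Whitney identity), Youden-J optimal cutoffs
under a uniform "score ≥ cutoff is positive" rule, and Kaplan–Meier medians
with the log-rank test.

## Worked example

Simulate a 40-sample cohort, build an MSI baseline from the MMR-proficient
samples, filter variants, fit signatures, and evaluate the MSI score as a
dMMR biomarker:

```sh
dmmrkit simulate --out sim --seed 4
dmmrkit msings baseline --hist sim/histograms.tsv --normals normals.txt --out base.tsv
dmmrkit msings score --baseline base.tsv --hist sim/histograms.tsv --out scores.tsv
dmmrkit filter-variants --in sim/mutations.tsv --out filt
dmmrkit sigfit --maf filt/mutations_filtered.tsv --fasta sim/reference.fa --runs 5 --out sig
dmmrkit roc --in roc_in.tsv --score score --truth dmmr
dmmrkit survival --in sim/clinical.tsv --group dmmr
```

Output of the last three stages (seed 4):

```
20727 in, 16194 somatic (627 rescued) -> filt
rank 4, best residual 1776 -> sig
     auc  optimal_cutoff  sensitivity  specificity  youden_j
0.950893           0.045     0.916667     0.892857  0.809524
median[False] = 7.87
median[True] = 1
log-rank statistic 15.95, p = 6.52e-05
```

Reading: of 20,727 simulated variant calls, 16,194 survive the quality and
germline filters (627 re-admitted by COSMIC rescue). Ranking samples by MSI
score separates true dMMR from pMMR samples with AUC 0.95; the Youden-optimal
score cutoff of 0.045 gives 92 % sensitivity and 89 % specificity. Simulated
dMMR patients (hazard ratio 4) have a much shorter Kaplan–Meier median
survival (1.0 vs 7.9 years, log-rank P ≈ 7 × 10⁻⁵).

`dmmrkit run --out pipe --seed 7` executes the whole synthetic pipeline
(simulate → MSI → filter → signatures → immune association → metrics) and is
byte-identical across repeat runs with the same seed.

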