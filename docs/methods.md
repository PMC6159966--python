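# Methods

This note documents the models implemented in `dmmrkit`, the parameters that
matter, the design choices made where several readings were defensible, and
what the synthetic cohorts can and cannot show.

## MSI scoring from allele-length histograms (`dmmrkit.msi`)

The scoring unit is a per-locus histogram of read support over repeat
lengths. A length counts as a *supported allele* when its read count is at
least `peak_fraction` (default 0.05) of the locus's modal count, inclusive at
the threshold. The baseline (`MsingsBaseline`) records, per locus, the mean
and SD of the supported-allele count across MMR-intact specimens; scoring
flags a locus unstable when its allele count **strictly** exceeds
`mean + sd_multiplier × sd` (default multiplier 2.0). Consequences of the
strict inequality: at a locus with SD 0, any extra allele is unstable — the
intended behavior for clean mononucleotide runs.

Parameters (all config-exposed):

| parameter | default | meaning |
|---|---|---|
| `peak_fraction` | 0.05 | allele support threshold, fraction of modal reads |
| `sd_multiplier` | 2.0 | baseline exceedance multiplier |
| `min_reads` | 30 | minimum total reads for a locus to be evaluated |
| `min_evaluated` | 20 | minimum evaluated loci per scored sample |
| `min_baseline` | 2 | minimum covered baseline samples per locus |
| `ddof` | 0 | population SD — baselines are reference populations |

Loci absent from the baseline or below coverage are *not evaluated* and are
excluded from the score's denominator, so missing loci never deflate a
score. The per-sample score is `n_unstable / n_evaluated ∈ [0, 1]`.
Exome-derived scores are mapped onto the targeted-panel scale by a fixed
multiplicative factor (default 0.209); the factor is a configuration
constant, not re-derived, since no derivation is available for it.

Enriched-locus selection retains loci that are (a) coverage-callable in at
least `min_fraction` (default 0.9) of normals, (b) unstable in ≥ 1 known-dMMR
tumor, and (c) stable in every normal, ordered by locus id. This is one
defensible reading of "enriched reference set" selection; the exact original
rule is not published, so the implementation keeps every ingredient
configurable.

The PCR classifier takes instability flags for exactly the five
mononucleotide markers (BAT-25, BAT-26, NR-21, NR-24, MONO-27): ≥ 2 unstable
→ MSI-high, exactly 1 → MSI-low, 0 → MSS. Dichotomization groups MSI-low
with MSS; only MSI-high is positive.

## Mutational signatures (`dmmrkit.signatures`)

Channels are the 96 single-base substitutions in trinucleotide context on
the pyrimidine strand, ordered substitution-major (C>A, C>G, C>T, T>A, T>C,
T>G), then 5′ base, then 3′ base, each alphabetical. Purine-reference SNVs
are reverse-complemented (flanks swapped and complemented) before labeling.

Factorization minimizes the generalized KL divergence with multiplicative
updates (the Brunet scheme). Numerical choices:

- A floor of `eps = 1e-9` is applied inside update denominators and to the
  reconstruction before evaluating the objective; this is standard practice
  to avoid division by zero and does not measurably perturb the solution.
- Initialization is uniform random in [0.1, 1] scaled by `sqrt(mean(V))`,
  from a seeded generator; restart *r* of `n_runs` uses seed
  `random_state + r`, so a 20- or 200-restart fit is exactly reproducible.
  The best (minimum-divergence) run is kept; ties break toward the lowest
  restart seed.
- Stopping: relative divergence change below `tol = 1e-9` or
  `max_iter = 10000` sweeps. The tight default matters: flat signatures
  (HRD-like) converge slowly, and at a looser 1e-6 the factorization stops
  before the flat component has fully separated from the structured ones
  (matched cosine ~0.86 instead of ~0.96 in the recovery simulation). The
  divergence sequence is non-increasing by construction and asserted in
  tests.
- On output, columns of W are normalized to sum 1 with the compensating
  scale folded into H, so exposures stay on the mutation-count scale and
  `Σ_k H[s,k]` ≈ the sample's mutation count up to reconstruction error.

Matching to reference signatures maximizes total cosine similarity over
one-to-one assignments (Hungarian algorithm — exact for the K ≤ 8 ranks used
here); pairs below `report_threshold` (default 0.8) are flagged unmatched.
Activity is reported as row-normalized exposure *proportions* (all-zero rows
are undefined and excluded from dominance calls), and *MMR-dominant* means
the summed proportions of **both** MMR-type signatures strictly exceed 0.5.
Summing both is the natural reading of "dMMR-related" activity when two
MMR-like signatures are extracted; the signature set is an argument, so a
single-signature rule is a one-line change.

Rank selection is reported, not automated: `rank_diagnostics` emits, per
candidate rank, the cophenetic coefficient of the consensus matrix (mean
over runs of argmax-exposure co-assignment indicators, average-linkage
clustering), the best run's divergence, and its residual sum of squares. The
rank itself is an input (default 4).

The Bayesian NMF variant sometimes used as a concordance check is out of
scope; only the multiplicative-update path is implemented.

## Variant filtering and mutation load (`dmmrkit.variants`)

A record is removed by the quality stage when **any** condition holds:
haplotype score > 200, mapping quality < 40, depth < 60, alternate allele
< 5 % of reads, multiallelic, indel, or a known poorly-sequenced site (an
input flag / blacklist BED — no list is computed). Germline status is cohort
allele frequency > 0.05, presence in ≥ 2 population databases, or alternate
fraction > 0.999; COSMIC rescue re-admits germline-removed **SNVs** with ≥ 10
somatic reports. All inequalities are exactly as stated (strict "more than",
inclusive "at least") and each boundary is pinned by a paired test.

Missing-field policy: quality fields fail **closed** (record removed, reason
`missing-field`); germline evidence fails **open** (absent evidence is not
germline). This is the conservative direction for mutation load. Each record
receives exactly one disposition label, independent of table order, and the
stage counts balance (`input = final + removals − rescues`).

Indels: the default path excludes them from the SNV mutation count. With
`indels="separate"` they pass through the same quality (minus the indel
criterion) and germline rules on a side path and are labeled
`indel-somatic`/`indel-germline`, still outside the SNV load. Rescued COSMIC
variants count toward load identically to never-filtered variants.

Load is the surviving record count per sample and per megabase of panel
(default 0.6 Mb), dichotomized at ≥ 5.5. MMR-gene event status uses the
precedence biallelic-LOF (homozygous deletion, ≥ 1 nonsynonymous + LOH, or
≥ 2 nonsynonymous) > germline > single-allele-nonsynonymous > none, for
MSH2/MSH6/MLH1/PMS2; event annotation itself is upstream of this package.

## Immune association (`dmmrkit.immune`)

Per gene: Pearson r and two-sided p of expression (TPM) against dMMR
activity, BH-adjusted across the analyzed gene set; `passes_overall` is
q < 0.1. Per biopsy-site strata with ≥ `min_n` (default 10) samples, nominal
per-site p-values are computed; `passes_consistent` additionally requires
p < 0.05 in **every** tested stratum. Strata below `min_n` are excluded from
the consistency requirement and reported. BH within each site is also
emitted (`q_<site>`) as a secondary readout, but the consistency flag uses
nominal p.

Manual scatterplot review of outliers is automated as an optional
`robust-z` policy: residuals from the least-squares line beyond 3.5
MAD-scaled units are dropped and the removal count is always reported; the
default `none` policy is plain Pearson.

The geometric-mean panel score is `exp(mean(log(TPM + offset)))` with
offset 1 by default (TPM matrices are zero-inflated); offset 0 gives the
exact geometric mean and errors on zeros. The bundled 32-gene checkpoint
panel ships as an editable text file; discovery panels are user-supplied
files (the published 762-gene immune list is an external resource and not
bundled). LD-TIL density is the pooled ratio Σcells / Σarea (never the mean
of per-image ratios). The 2×2 odds ratio is ad/bc with optional
Haldane–Anscombe +0.5 correction applied only when a cell is zero and a
Woolf log-scale CI. Deconvolution (e.g. CIBERSORT-style inference) is not
reimplemented; when an inferred-infiltrate column exists it is treated as
data.

## Biomarker and survival metrics (`dmmrkit.metrics`)

Positivity is uniformly "score ≥ cutoff". The Youden scan evaluates
J = sens + spec − 1 at every distinct observed score plus an
everything-negative cutoff (so J ≥ 0 always); ties break toward the lowest
cutoff, favoring sensitivity (a flag flips this toward specificity). AUC is
the Mann–Whitney identity with ties counted half. Kaplan–Meier medians are
the first time survival drops to ≤ 0.5 (undefined if never reached); the
log-rank test is the standard one-degree-of-freedom statistic and requires
at least one event per group — an all-censored group is a flagged error
rather than a silent median. Multivariate survival modeling (Cox with
imputation) is deliberately out of scope; the cohort table is
analysis-ready for external tools.

## Synthetic cohorts (`dmmrkit.simulate`)

What the generator emulates, per layer:

- **Histograms.** Stutter noise is a symmetric geometric decay
  (`stutter_decay`, default 0.3) truncated at ±5 repeat units around the
  modal (reference) length — the simplest model consistent with PCR stutter.
  In dMMR samples each locus independently becomes unstable with
  `p_unstable_locus` (default 0.2), gaining a novel allele ≥ 2 units from
  the mode with ≥ 10 % of the modal support, so instability is separable
  from stutter **by construction**.
- **Catalogs.** Four bundled synthetic signatures (spiky aging-like C>T at
  CpG; flat HRD-like; two MMR-like C>T / T>C-rich profiles with distinct
  flank preferences; pairwise cosine ≤ 0.6 so recovery is well posed).
  Exposures are Dirichlet draws; the default concentration
  (2.0, 1.5, 0.25, 0.25) makes pMMR tumors aging/HRD-dominated with low
  background MMR activity, and dMMR samples multiply the MMR-type entries
  by `dmmr_exposure_boost` (default 16), so MMR-type activity typically
  exceeds 0.5 exactly in dMMR tumors — the structure the MMR-dominance
  readout presumes. Mutation counts are negative binomial (dispersion 5)
  around `mutations_per_sample`, Poisson optionally. Each mutation is
  realized as a concrete SNV at a position of the emitted 1-Mb synthetic
  chromosome whose flanks realize the drawn context (drawn jointly per
  context group so positions are unique within a sample); REF bases
  round-trip against the emitted FASTA.
- **Annotations.** Germline spike-ins (rate 0.15) get cohort AF ∈
  [0.08, 0.5], 2–3 database hits, or alt fraction 1.0; artifacts (rate 0.10)
  get MQ ≤ 35, depth ≤ 50, or alt fraction ≤ 0.03 — every spike-in clears
  its filter boundary by a margin, so recovery tests measure the filter, not
  boundary luck. A fraction (0.2) of germline spikes carries COSMIC ≥ 10.
- **Expression.** A latent infiltrate factor equals
  `effect · z(activity) + √(1−effect²) · noise` (default effect 0.24,
  matching the magnitude of infiltrate–activity correlation reported in
  this setting); the 32 panel genes load on the factor with gene-specific
  loadings near `panel_loading` (default 0.4) on the log scale, background
  genes are independent log-normal noise, and all values are positive
  TPM-scale.
- **Clinical.** Exponential survival (pMMR median 7 y), dMMR hazard ×
  `hazard_ratio` (default 4), independent exponential censoring, biopsy
  sites drawn from {bone, lymph_node, other}.

Determinism: every stage uses `numpy.random.default_rng` with a per-stage
seed derived from the master seed by CRC-32 of `"{seed}:{stage}"`, so a
fixed seed reproduces every file byte-for-byte and stages are insensitive to
each other's draw counts.

**What passing tests do and do not show.** The generator realizes exactly
the statistical structure the pipeline assumes: geometric stutter, clean
mixture catalogs on a uniform-composition chromosome, spike-ins clear of
filter boundaries, linear-Gaussian expression effects. Real data violate all
of these (locus-specific stutter, trinucleotide composition bias, boundary-
straddling artifacts, batch effects, heavy-tailed expression), so recovery
results here demonstrate correctness of the implementations under their own
model, not expected performance on patient cohorts. Read-level simulation
(FASTQ/BAM), indel realism beyond repeat-length shifts, and count-level
RNA-seq are out of scope.

## Problem sizes used by the test suite and acceptance script

Chosen to exercise each property at the smallest scale where it is
well-resolved: signature recovery at 150 samples × ~500 mutations with 20
restarts (and 100 × 500 with 10 restarts in the unit suite); MSI label
recovery at 200 loci with 10 dMMR + 30 pMMR samples; association error
control and sensitivity at n = 168 with a 200-gene matrix; filter oracle
equivalence on 10,000 random records; metric oracles on 100+ random
instances each; the end-to-end determinism check on the default 40-sample
configuration.

## Known limitations

- The MSI statistic is allele-count exceedance only; it does not model
  allele-length distribution shifts (e.g. Kolmogorov–Smirnov-style
  comparisons) that some scorers use.
- KL-NMF restarts are embarrassingly parallel but run serially here.
- The exome-to-panel harmonization factor is a constant; deriving it would
  require paired panel/exome data.
- `run_pipeline` wires only the synthetic entry point end to end; on
  external data the per-stage commands are composed manually (their file
  formats are the integration surface).
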