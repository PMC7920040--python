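# Methods

This note records the models implemented, the defaults chosen where the
design was genuinely open, and what the synthetic-data validation does
and does not demonstrate about real data.

## SNP calling from two-pool sync data

A site's two alleles are the two of {A, C, G, T} with the highest read
count summed across pools; N and deletion columns are never alleles.
Counts of a third-ranked allele are dropped from coverage rather than
redistributed — the simplest defensible biallelic projection, and the
dropped reads are counted in the log.  The *minor* allele is the
lower-summed of the two, with exact ties broken alphabetically so calls
are deterministic.  Default filters (per-pool coverage over the two
called alleles in [10, 500], total minor count ≥ 2, at least one minor
read) mirror common pool-seq practice; no thresholds are inherited from
any particular dataset and all are arguments.  Rejection is a tagged
outcome with a per-reason count, not an error.

## The F_ST estimator

The default estimator is the classical Nei-style
(H_total − H_within)/H_total computed from pool allele frequencies with
the pools weighted equally, regardless of their coverages (the design
is a symmetric two-population comparison; coverage weighting is an
option).  H_total = 0 cannot occur for a filter-passing SNP — a site
monomorphic in both pools never reaches the estimator — and is guarded
by an assertion rather than a silent zero.

A finite-sample correction (each H_i scaled by n_i/(n_i − 1),
n_i = min(coverage, 2·pool size)) is available behind a flag and off by
default, because the number of individuals per pool is often not known
downstream of public sync files.  Corrected values can be negative; they
are retained unclamped because clamping at zero would bias genome-wide
means upward and distort the permutation null.

Uncorrected per-SNP F_ST is biased relative to the generating
divergence parameter: read sampling at finite depth inflates
heterozygosity estimates on both layers.  The validation therefore
never compares the estimate to the Balding–Nichols F directly; it
compares it to a Monte-Carlo expectation computed from the generator's
recorded truth frequencies under the same sampling model (agreement
within ±0.02 at depth 100, pools of 50, 10⁵ SNPs, for F in
{0.01, 0.05, 0.2}).

Region-level F_ST aggregates per-SNP H components by ratio of sums
(the pooled-window convention), with mean-of-per-SNP-values available
as an alternative because either reading is compatible with published
per-gene estimates.  Empty regions yield NaN, never zero: a gene
without surviving exonic SNPs has no divergence estimate and is
excluded from gene-level summaries and from permutation backgrounds,
since an imputed zero would drag every null mean down.

## Gene and flanking aggregation

Coordinates are 0-based half-open internally; GFF3 and sync positions
are converted only at the file boundary.  Gene-level F_ST uses exonic
SNPs only (a flag widens the view to whole gene spans — published
descriptions of gene-wise masking do not always say which was used).
The flanking estimate covers exons plus 5 kb on each side, clipped at
scaffold edges, matching the symmetric slop convention; flanks are
disjoint from exons by construction so interval sums add exactly.
Strand is recorded but does not affect the combined estimate, which is
symmetric.  Indel masking removes a w-bp window centred on each indel
position (default w = 5: an indel at 1-based 100 masks 98–102);
overlapping windows merge, and masking is idempotent.

## Permutation tests

Null sets are drawn uniformly without replacement from the full
background *including* the candidates, the literal reading of
"randomly sampled genome-wide"; exclusion of candidates is a flag.  The
plus-one convention p = (1 + b)/(1 + n) keeps Monte-Carlo p-values off
zero, and ties count in both tails, so p_greater + p_less ≥ 1 + 1/(n+1).
Both tails plus the two-sided value are always reported; the analysis
never silently picks one.  Calibration is verified end to end: 200
uniformly drawn candidate sets of 73 genes give one-sided p-values
indistinguishable from U(0,1) (KS test, 1% level), and candidate genes
planted at twice the background divergence are rejected at p < 0.05 in
well over 80% of 100 datasets with 5,000-gene backgrounds.

All resampling uses one numpy Generator seeded explicitly; identical
(background, candidates, n_perm, seed) reproduce results bitwise.  The
pipeline derives stage seeds from a single master seed via
SeedSequence spawning.

## Outliers and enrichment

The outlier threshold is the linear-interpolation empirical percentile
(numpy's default definition; the definition is recorded in the output),
and outliers are *strictly above* it — ties at the threshold are
excluded and counted.  Enrichment is the one-sided hypergeometric
(classic Fisher) test per term with BH adjustment across retained
terms.  Terms are first restricted to the background of genes with
defined F_ST (genes without data cannot be outliers) and dropped below
five background members.  Graph-aware decorrelation methods that climb
the GO hierarchy are intentionally out of scope: no ontology DAG is
parsed, and a custom term containing the user's candidate genes can be
injected to make the candidate set itself testable.

## Immune-assay indices

The hemocytometer formula (cells × 10)/(squares × dilution) is
implemented with dilution as the hemolymph *fraction* (1/20 for an
8 µl : 152 µl protocol); this is the only reading that yields
concentrations of the observed ~14,000 cells/µl magnitude, and the
parameter is validated to (0, 1].  Replicate slides are pooled by
summing counts per larva before computing indices — the pooled ratio is
the individual-level point estimate and differs from the mean of
per-replicate ratios on unbalanced counts; per-replicate rows are kept
for mixed-model work downstream.  Records lacking a cell type entirely
are excluded from that type's analysis rather than zero-filled.  The
module stops at tidy per-individual and per-group tables: GLM fitting
and model selection belong to general statistics packages.

## Synthetic-data generator

The generator emulates the study design the pipeline targets: two
allopatric populations at low genome-wide divergence.  Divergence is
Balding–Nichols — per SNP, ancestral frequency p ~ U(0.05, 0.95) and
population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) — chosen over
coalescent simulation because it gives direct, seedable control of the
divergence parameter, which is exactly what parameter-recovery tests
need.  Observation adds the two layers that make pool-seq estimators
depth-sensitive: binomial sampling of 2N chromosomes per pool, then
binomial read sampling at Poisson depth.  Defaults are desk-scale
(2 scaffolds × 2 Mb, 500 genes with 1–10 exons, ~2×10⁴ SNPs, pools of
50 at depth 100, F = 0.05, 20 candidate genes); every size scales
through the config.  Monomorphic filler sites and indel positions are
emitted at configurable densities so the masking and rejection paths
see realistic input.

The cohort generator draws each larva's cell-type composition from a
Dirichlet with granulocytes dominant, per-slide cell totals from a
Poisson (default two slides of ~100 cells, i.e. ~200 cells per larva),
per-type phagocytosis as binomial at a propensity set by population,
sex and cell type (north above south, males slightly above females,
echoing the ~80% vs ~67% contrast such assays report), and hemocytometer
counts from a gamma-Poisson matched to mean ≈ 14,037 and SD ≈ 7,125
cells/µl.

What the generator does *not* model — and therefore what passing tests
cannot certify on real data: linkage and recombination (SNPs are
independent), selection and demography beyond a single divergence
parameter, sequencing error beyond binomial read sampling, mapping
artefacts, individual-level overdispersion in phagocytosis propensity,
and any correlation between gene function and divergence (term maps are
random apart from the planted candidate term).

## Validation experiment sizes and numerical choices

Validation runs are sized to finish in minutes on one core: parameter
recovery uses 10⁵ SNPs per F value; permutation calibration uses 200
candidate draws at n_perm = 2,000 over a ~490-gene background; power
uses 100 datasets of 5,000 genes at n_perm = 1,000; outlier detection
uses 100 seeds of 200-gene genomes.  The planted-outlier experiment
runs at ~26 exonic SNPs per gene, the density a deeply covered scan
produces; at that density a planted F = 0.4 gene exceeds the 97.5th
percentile in ≈96% of cases.  The residual misses are genes that by
chance receive only a handful of SNPs, whose region estimate then
carries the full Balding–Nichols sampling variance — a real property of
region estimators, not an implementation artefact, and the reason
per-gene SNP counts are reported alongside every gene-level estimate.

Degenerate inputs are handled explicitly: empty regions and absent cell
types are NaN (never zero) and excluded with a count; a constant value
vector yields zero outliers with a warning; an empty candidate
intersection or empty outlier set is an error.  CSV output uses a fixed
12-significant-digit float format so reruns under one seed are
byte-identical.
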