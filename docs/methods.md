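# Methods

This note documents the models implemented in `mosaicenrich`, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
cohorts do and do not emulate. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Mosaic de novo filtering

A candidate trio call passes the de novo hard filters iff

* father and mother alternate reads ≤ `max_parent_alt_reads` (default 1),
* proband depth ≥ `min_depth` (default 100) and alternate reads ≥
  `min_alt_reads` (default 3),
* VAF ≥ `vaf_min` (default 0.01),
* population allele frequency ≤ `max_pop_af` (default 0, i.e. absent), and
* the site is in neither the panel of normals nor the blacklist.

Every rejected call carries the full sorted tuple of reason codes, which
makes the partition order-independent by construction and lets attrition
tables be emitted. Passing calls are split **mosaic vs germline** by an
exact one-sided binomial test of the allele-fraction deficit under the
germline hypothesis `alt ~ Binomial(depth, 0.5)`: mosaic iff
`P(X ≤ alt_reads) < mosaic_binomial_alpha` (default 10⁻³) *and*
VAF < `vaf_max_mosaic` (default 0.35). This is the caller-free equivalent of
running separate somatic and germline callers; at depth ≥ 100 it separates a
5–12% mosaic from a 50% heterozygote with essentially no overlap. The
thresholds are deliberately configuration, not claims: the defaults describe
a ~300× deep-exome operating point.

INDELs flow through the filters for validation bookkeeping and are treated
as deleterious (the frameshift assumption) but are excluded from enrichment,
which is an SNV-only comparison.

Per-individual mosaic-count outliers (e.g. clonal haematopoiesis or sample
quality) are excluded by a Poisson rule: with λ estimated as the cohort mean
count, sample *i* is removed iff `P(X ≥ count_i | λ) < α / n_samples`
(Bonferroni, default α = 0.05). On i.i.d. Poisson cohorts this excludes
nobody in ≥ 95% of seeded replicates (tested).

## Trinucleotide categories and consequence classes

SNVs are binned into the standard 96 substitution categories: the 3-mer
context with the central base made a pyrimidine by reverse-complement
normalisation, × 3 alternates, ordered C>A, C>G, C>T, T>A, T>C, T>G × 16
contexts. The first and last base of a sequence have no full context and are
excluded from spectra and from the site index, with counts logged.

Consequences are codon-based calls on single-transcript gene models
(0-based half-open CDS intervals, BED convention; variants 1-based, VCF
convention; the conversions live in `variantio`): synonymous / missense /
nonsense, plus `canonical_splice` for the 2-bp intronic dinucleotides
flanking internal CDS boundaries of multi-interval models, and `noncoding`
elsewhere. Stop-loss is folded into missense (it is non-synonymous and not
stop-gain; the class system has no separate bin for it). Overlapping models
resolve by severity: nonsense > canonical_splice > missense > synonymous.
A CDS length not divisible by 3 is tolerated by truncating the tail codon
(excluded from classification, counted). Translation tables come from
Biopython (standard code, table 1).

The **site index** enumerates every (CDS ∪ splice) position × alternate,
keyed by (category, class). It is a partition — overlapping gene models are
deduplicated severity-first — and is the exact sampling space of the
permutation null.

## Permutation gene-set enrichment

Given observed SNVs (each carrying its gene, category, class and a
deleterious flag), a gene set, and a class filter (`deleterious` = nonsense ∪
canonical splice ∪ damaging missense; also `synonymous`, `non_synonymous`,
`lof`, `all`), each permutation independently re-places every filtered
variant uniformly at random among the index sites sharing its (category,
class) key and counts the placements landing in the set. Choices made where
the design was genuinely open:

* **Uniform within stratum.** Mutability differences act *between* strata
  through the conditioning on observed categories; no extra weighting is
  applied within a stratum. This keeps the null exactly defined and
  reproducible; the mutation-rate table is used only by the generator.
* **Variant-level counting.** A gene hit twice counts twice, matching an
  expected-hit-count statistic rather than a hit-gene count.
* **Ties are exceedances.** `p = max(r, 1)/n_perm` with
  `r = #{N_perm ≥ N_obs}`; the `1/n_perm` floor matches the resolution a
  permutation run can honestly claim. The `(r+1)/(n+1)` pseudocount
  convention is available by flag.
* **Stream splitting.** Per-stratum (and per-(set, filter) pair) RNG streams
  are spawned from the master seed via `numpy.random.SeedSequence`, so a
  result table is a pure function of (inputs, seed, n_perm) regardless of
  execution order. Within a stratum the in-set hit count of its m variants
  is drawn as `Binomial(m, f)` with `f` the in-set site fraction — exactly
  the distribution of m independent uniform placements.
* An empty stratum (an observed variant whose (category, class) key has no
  eligible site) is an error naming the key, never a silent drop.

Defaults: `n_perm = 10,000` for routine runs and tests; one million by flag
to match the resolution of published permutation frameworks.

Multiple-testing columns: Bonferroni `min(1, p·n_tests)` (n_tests may exceed
the number of reported tests, for families where only some p-values are of
interest) and Benjamini–Hochberg over the reported tests
(`scipy.stats.false_discovery_control`).

**Calibration diagnostics.** At the study operating point (~1 expected
in-set hit) the empirical p is a coarse lattice (achievable values ≈ 1,
0.65, 0.27, 0.08, 0.02, …), so its rejection rate at α = 0.05 is
conservative (~0.02) and a raw Kolmogorov–Smirnov test against Uniform(0,1)
fails mechanically for *any* correct implementation. Calibration is
therefore assessed on the uniformised (randomised) p-value
`p* = (r_> + U·(r_= + 1)) / (n_perm + 1)`, the standard exact construction
that is Uniform(0,1) precisely when the null distribution is correct; the
raw p must additionally stay on the conservative side. Both checks run over
200 seeded null cohorts in the acceptance suite.

**Power.** The post hoc power helper is a one-sided exact Poisson test:
smallest critical value k* with `P(Poisson(λ₀) ≥ k*) ≤ α`, power
`P(Poisson(λ₀·fold) ≥ k*)`. At λ₀ = 6/5.73, fold 5.73, α 0.05 it gives
0.849. The published figure for this configuration (0.89) came from an
unstated procedure; the two are reported side by side and not forced to
agree.

## Mitochondrial heteroplasmy

Variants on the circular genome are classified into exactly four genic
classes — synonymous, non-synonymous, tRNA, rRNA — with priority
tRNA > rRNA > protein at overlapping sites, and non-synonymous if the amino
acid (or stop status) changes in *any* overlapping protein record. Protein
records use the vertebrate mitochondrial code (Biopython table 2: AGA/AGG
stop, ATA Met, TGA Trp). Records crossing the replication origin are split
into two records whose listed order defines the coding concatenation. An
incomplete terminal codon is completed with adenines, mirroring the
post-transcriptional polyadenylation that completes mitochondrial stop
codons; the count of padded genes is logged. Intergenic positions are not a
class — they are excluded upstream, as are user-supplied low-mappability
BED regions.

The **theoretical null** is the exhaustive enumeration: every genic,
non-excluded position × 3 alternates, classified. Class totals are conserved
(Σ = 3 × positions) and the tRNA/rRNA class proportions equal those regions'
length shares exactly, because every alternate at such sites keeps the
class. Class-proportion comparisons (observed heteroplasmies vs the
exhaustive set, or vs homoplasmies of the same cohort) are two-sided Fisher
exact tests on the literal 2×2 table — the enumeration is treated as a
finite comparison group, not a binomial approximation.

Heteroplasmic/homoplasmic partitioning: heteroplasmic iff
`het_min_vaf ≤ VAF < hom_min_vaf`, defaults 0.01 (the 1% detection floor of
~700× mitochondrial coverage) and 0.95 (the homoplasmy threshold is not a
published constant; it is configurable).

**Carrier-frequency comparisons.** Two table conventions are exposed.
`carriers_vs_total` (default) tests `[[k₁, n₁], [k₂, n₂]]` — the convention
of population-database carrier screens, where carriers are quoted against
cohort size; `carriers_vs_noncarriers` tests the textbook
`[[k₁, n₁−k₁], [k₂, n₂−k₂]]`. With carrier counts this small the two differ
only in the third significant digit; the default reproduces the reported
population-screen comparisons exactly.

**NUMT flag.** A heteroplasmy present in the proband and *both* parents at a
comparable fraction (each parent within a factor of two) is the signature of
a transmitted nuclear-mitochondrial segment misalignment rather than de novo
heteroplasmy → `suspect`. A single carrier mother at or above the
heteroplasmy floor is flagged `maternally_inherited` instead. Missing
parental VAFs → `not_evaluable`.

## Synthetic cohorts

The generators are pure functions of (config, seed); identical inputs give
byte-identical outputs, and truth manifests list every planted variant.

**Nuclear.** Per proband, mosaic count ~ Poisson(λ_m = 0.85) — the
deep-exome detection rate of ~0.85 exonic mosaics per sample — and germline
de novo count ~ Poisson(1.2), a typical exonic de novo load. Placement
follows a per-site weight: a flat rate table with a ×10 CpG-transition
multiplier (a documented stand-in that exercises the context stratification;
the real context spectrum is not claimed), times `deleterious_fold` on sites
inside the planted gene set where the variant would be deleterious. Each
variant first draws its damaging-missense designation
(`p_damaging_missense = 0.2`, making ~18% of placements deleterious — about
the deleterious fraction seen in deep-exome mosaic sets) so that, at
fold = 1, placement is exactly uniform within every stratum and the
permutation test is exactly calibrated. Mosaic VAFs ~ Beta(1.3, 20) —
median ≈ 5%, right tail to ~35%, mimicking the reported 1–36% (median 4.1%)
range — read depths ~ Poisson(300) (the deep-exome operating point), alt
reads binomial. Germline variants sit at VAF 0.5. Artifact rows (rate 0.3
per proband) carry one of four signatures — panel-of-normals, blacklist,
population allele frequency, parental reads — for the filters to remove.

The **study-scale universe** is 8,000 equal-length 50-codon genes with a
285-gene planted set: at λ_m = 0.85 × 190 trios this puts the *expected null
in-set deleterious hit count at ≈ 1.05*, the operating point at which a
5.73-fold enrichment corresponds to roughly six observed in-set hits — the
configuration the replicate experiments (`run_enrichment_replicates`)
reproduce. Problem sizes (200 null cohorts, 100 power cohorts, 10,000
permutations) keep a full acceptance run under a minute on one CPU while
leaving Monte-Carlo error well inside the asserted margins.

**Mitochondrial.** The `toy` fixture is a 1-kb circle with one 70-bp tRNA
and one 300-bp protein gene (known length shares); `rcrs_like` is a 16,569-bp
synthetic genome carrying 13 protein / 22 tRNA / 2 rRNA records with the
gene order, names and coordinate scale of the standard human mitochondrial
annotation (sequence synthetic; a few real overlaps trimmed so records are
disjoint). Heteroplasmies are drawn class-first from the exhaustive-null
class proportions with the tRNA proportion multiplied by `trna_multiplier`
(default 2.82, the enrichment magnitude the pipeline is designed to detect)
and renormalised; VAFs uniform on 1–36%; homoplasmies (~2 per sample,
matching a 382/190 load) from the unmodified proportions. Optional planted
rows exercise the trio logic: maternal transmission (low-level carrier
mother) and NUMT mimics (both parents share the fraction).

**What the generators do not emulate** — and hence what passing tests do not
show about real data: read-level errors and alignment (artifacts are flag
rows, not mis-mapped reads); realistic gene length/GC/mutability
heterogeneity (genes are i.i.d. equal-length ORFs; the rate table is flat
plus CpG); transcript isoforms and UTRs; clonal haematopoiesis age
structure; mitochondrial haplogroups and position-specific hypermutability.
Recovery and calibration results on these cohorts validate the statistical
machinery, not the upstream calling.

## Degenerate inputs and numerics

* Fisher exact test: minimum-likelihood two-sided rule with a 1e-7 relative
  tie band (the same band R's `fisher.test` uses). Tables with N ≤ 2000 are
  summed in exact integer arithmetic (`math.comb` / `Fraction`), so the
  enumeration-oracle equivalence is exact by construction; larger tables use
  a log-space enumeration bounded by the smallest margin (≤ 60 terms for
  every table this pipeline meets), agreeing with scipy/R to 1e-9. All-zero
  tables, zero depths, zero-length comparison groups and zero vectors raise
  typed degenerate-input errors rather than returning NaN.
* Empirical p-values are never 0: the floor is `1/n_perm`.
* `fold = observed/expected` is reported as missing when the expectation is
  zero; class-proportion folds against an empty reference class are ∞.
* Cosine similarity is clipped into [0, 1] against rounding.
* Seeds derived from a master seed are reduced into [0, 2³¹) before use.

## Known limitations

* Single-transcript gene models; no isoform-aware annotation.
* No INDEL consequence calling (INDELs are validation bookkeeping only).
* Deleterious-missense status is consumed as input flags (MPC ≥ 2 /
  seven-predictor consensus are external resources, not recomputed).
* The uniform-within-stratum permutation null is a declared choice; a
  mutability-weighted within-stratum variant would need empirical
  context-resolved rates as input.
* The Poisson power procedure is an analogue, not a reconstruction, of the
  unpublished original.
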