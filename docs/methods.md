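# Methods

## Data model

Two marker matrices are analysed jointly. The SNP matrix holds
codominant genotype calls per locus and sample: homozygous reference
(`0`), homozygous alternate (`1`), heterozygous (`2`) and null (`-`, the
fragment carrying the SNP was not confidently observed in that sample's
genomic representation). The presence/absence (PA) matrix holds dominant
SilicoDArT calls: fragment present (`1`), absent (`0`) or null (`-`,
non-zero counts too low to call — at a hemizygous locus this often marks
a heterozygote). Each locus carries upstream metadata: call rate (the
fraction of samples with a non-null score) and reproducibility (the
fraction of consistent technical-replicate pairs). Both are treated as
given; nothing in the pipeline recomputes them, because the filtering
they feed is defined on the platform's own quality metrics.

The sex registry maps each sample to its field phenotype: `M`, `F` or
`U` (unknown — morphology inconclusive). Only `M`/`F` samples enter the
discovery scans.

## Quality filtering

SNP loci are retained at call rate ≥ 1 and reproducibility ≥ 1, i.e.
only loci scored in every sample with perfect replicate consistency.
PA loci use call rate ≥ 0.90 and reproducibility ≥ 1; the PA assay is
noisier, and hemizygous (Y-borne) fragments legitimately produce nulls,
so demanding a perfect call rate would discard exactly the loci of
interest. The 0.90 boundary is inclusive by default
(`pa_call_rate_strict` switches to a strict `>`); real retained loci sit
well above it either way, so both readings select the same markers.

## Discovery scan

For every locus and both heterogametic hypotheses the concordance score
is

S = prop(heterogametic sex heterozygous) + prop(homogametic sex homozygous reference),

each proportion over *all* confidently sexed individuals of that sex.
Nulls and discordant genotypes count against the numerator but stay in
the denominator — the score asks "what fraction of males/females shows
the expected genotype", not "of those called". With the call-rate-1 SNP
filter the distinction is moot for SNPs; a `denominator='called'`
variant exists for unfiltered reuse. Perfection (`S = 2`) is decided on
integer counts (both proportions exactly 1), never with a float
tolerance.

PA loci are sex-linked under a hypothesis when presence in the
heterogametic sex and absence in the homogametic sex both reach
`min_prop` (default 0.90) **and** the locus is contradiction-free: no
heterogametic-sex individual absent, no homogametic-sex individual
present. Shortfalls from 100 % may only be nulls.

The system call is deliberately conservative: XY requires at least one
XY-linked marker (SNP or PA) and zero ZW-linked markers, symmetrically
for ZW; anything else — no evidence, or conflicting evidence — is
UNDETERMINED rather than a majority vote.

### Spurious-linkage budget

Each individual is assumed to match a sex-specific genotype by chance
with probability one half, so a locus is spuriously sex-linked with
probability `P_i = 0.5^n` over `n` sexed individuals, and `m` tested
loci contribute `m · 0.5^n` expected false discoveries. This ignores
allele frequencies — the true per-locus probability is
`∫ (2pq)^n_het · (p²)^n_hom dF(p)`, always below `0.5^n` — so the model
is a deliberately simple upper-scale bound. The test suite checks the
implementation against a sex-label permutation oracle at small `n` and
asserts only order-of-magnitude agreement with the closed form.

`min_sample_size(m)` returns the smallest `n` with `m · 0.5^n < 1`
(strict). At `m = 20,111` this is 15: `20111 · 0.5^14 = 1.23` still
exceeds one expected false marker, `0.5^15` gives 0.61. Published
sample-size recommendations derived from the same formula sometimes
quote 14; the function implements the inequality literally.

## Genotypic sexing

Under XY each discovered marker votes male when the SNP call is
heterozygous (PA: present) and female when homozygous reference (PA:
absent); ZW mirrors the votes. Nulls are uninformative. A
homozygous-alternate call at a perfectly sex-linked locus is impossible
under the clean model; it is kept as an informative vote *for neither
sex*, so it lowers concordance instead of being silently dropped. SNP
and PA votes pool with equal weight. A sample is called M or F when at
least `unanimity` (default 1.0 — every informative marker) of its votes
agree; otherwise AMBIGUOUS. Discordance is flagged when a confident
phenotype and a confident genotype disagree; unknown phenotypes are
never discordant. The reported sex ratio is
(phenotypic males + genotypic males among unknowns) / all samples.

## Moderate loci and Y-lineage groups

After the unknowns are genotypically sexed, the registry is augmented
with their assignments and rescanned for moderately sex-linked loci:
every homogametic-sex call homozygous reference (nulls disqualify by
default; `allow_null_homogametic` relaxes this) and heterogametic-sex
heterozygosity in `[min_het_prop, 1)`. The default floor of 0.25 sits
safely below the ~0.38 minimum that a fully heterozygous core lineage
imposes whenever it makes up a quarter of the males, while still
excluding noise loci.

Per-male heterozygous fractions across the moderate loci use non-null
calls as the denominator (grouping is per individual; a null carries no
genotype). The threshold rule — exactly 1 → Males 1; `[0.85, 1)` →
Males 2; `≤ 0.20` → Males 3; otherwise unassigned — follows the
published grouping convention for recombining-Y lineages. Males 2 and
Males 3 percent-heterozygosity values are compared with a Welch
unequal-variance t-test; the degrees of freedom are reported both as
the real Welch–Satterthwaite value and floored, as conventionally
printed `t(df)`. p-values are never clamped.

## Population structure

* **F_ST** between sampling sites is Nei-style G_ST on expected
  heterozygosities, `(H_T − H_S)/H_T`, with `H_T` from the unweighted
  mean of site allele frequencies and the statistic accumulated as a
  ratio of averages (Σ numerators / Σ `H_T`) across loci; loci
  monomorphic in the pooled pair are skipped. No small-sample
  correction is applied, which inflates the absolute level slightly at
  small `n` — the statistic is used here as a relative substructure
  screen, not an estimator to be compared across studies.
* **Nei distance** between individuals treats each individual as a
  two-allele "population" with reference-allele frequency in
  {0, ½, 1}. Identity sums `J_xy`, `J_x`, `J_y` run over loci *before*
  the log, so a single opposite-homozygote locus cannot produce an
  infinity; loci null in either individual are dropped pairwise. A pair
  with zero total identity (or no shared called locus) is reported at a
  finite sentinel (50.0) with a warning rather than ∞, keeping the
  matrix usable for PCoA and heat maps.
* **PCoA** is classical metric scaling: double-centre `−D²/2`,
  eigendecompose, scale eigenvectors by √eigenvalue. Negative
  eigenvalues (non-Euclidean input) are dropped and excluded from the
  variance proportions; requesting more axes than there are positive
  eigenvalues truncates with a warning. Axis signs are fixed by making
  the largest-magnitude loading positive, so coordinate files are
  reproducible.

## The synthetic-data generator

The generator emulates the structure of a two-platform
genotyping-by-sequencing study of a wild population with a young XY
system. Study-preset defaults: 52 samples — 18 true females and 34 true
males in lineages of 13 (fully heterozygous Y), 12 (high-heterozygosity
recombining Y, per-locus heterozygosity 0.92) and 9 ("feminised" Y,
0.16) — with 8 randomly chosen phenotypes masked unknown; 11 perfect +
47 moderate sex-linked SNPs among 20,111 total and 6 Y-specific
fragments among 19,121 PA loci (the post-filter scale of the
motivating data set); three sampling sites assigned near-uniformly;
zero null-call and call-rate noise; fixed seed 2019. These defaults
*are* the tested study conditions; noise knobs (`null_rate`,
`callrate_noise`, `n_sex_reversed`) default to zero and are switched on
explicitly by tests that study degradation.

Design choices worth knowing:

* **Truth labels are guaranteed consistent with the matrices at zero
  noise.** Autosomal loci are Hardy–Weinberg draws (reference-allele
  frequency uniform on [0.05, 0.95]) *conditioned on not matching* a
  perfect/moderate/PA sex-linked pattern under either system with
  respect to the true sexes — without this, a 20,000-locus matrix would
  contain a handful of chance "moderate" patterns (per-locus
  probability ≈ 2×10⁻⁴) and the planted truth would be wrong. The
  unconditioned generator remains available as `hardy_weinberg_snp` and
  is what the Monte-Carlo null tests use.
* **Lineage heterozygosity is banded Bernoulli.** Each male's
  moderate-locus vector is Bernoulli(p_lineage) per locus, redrawn
  until his realised fraction lies in his lineage's band (exactly 1;
  [0.85, 1); (0, 0.20]). Pure Bernoulli would scatter males across the
  group boundaries in most realisations (e.g. a 0.92-lineage male has a
  ~2 % chance of being heterozygous at all 47 loci), making the planted
  lineage structure unrecoverable from a single draw; the banding keeps
  group means at p_lineage while matching the tight within-lineage
  structure such data sets show. A block-level redraw additionally
  prevents a moderate locus from being heterozygous in every male
  (which would silently promote it to perfect) except in the
  legitimate degenerate case where every lineage probability is 1.
* Unknown-sex masking and sex reversal act on phenotype only; genotypes
  always follow the true sex. Sequences are not simulated (allele
  sequences are reported metadata, never computed on), and there is no
  linkage disequilibrium among autosomal loci, no read-level error
  model and no shared haplotypic breakpoints within lineages — so
  passing tests demonstrate the pipeline's logic and numerics, not
  robustness to every artefact of real sequencing data.

What the zero-noise tests show: the scans recover exactly the planted
perfect/moderate/PA loci, the system call is XY, the unknowns are sexed
to their true sexes, planted sex-reversed individuals are exactly the
discordance-flagged set, and the lineage groups equal the planted
13/12/9. With nulls injected, the expected score of a planted perfect
locus degrades as `2(1 − null_rate)` under the all-individuals
denominator, which the Monte-Carlo test confirms.

## Numerical and reporting choices

Perfection and group-boundary decisions are integer/exact-float
comparisons, never tolerances. All scans are deterministic and
invariant to locus and sample permutation (output order follows input
order). Reports are plain TSV plus a `summary.md`/`summary.json` pair;
every number in the summary is re-derivable from the stage tables, and
repeated runs on the same inputs produce byte-identical files. The
simulation and analysis at full study scale (≈ 40,000 loci × 52
samples) complete in well under a second each; the acceptance script
re-runs the whole pipeline at that scale.

## Known limitations

* The spurious-linkage model is the field's conventional `0.5^n`
  heuristic, not an allele-frequency-aware null; use the permutation
  machinery for calibrated inference.
* The F_ST estimator is uncorrected G_ST; absolute values are not
  comparable to bias-corrected estimators (Weir–Cockerham, Nei's
  corrected G_ST) on small samples.
* Real DArT multi-header exports must be converted to the single-header
  CSV dialect first; no import shim is provided.
* Moderate-locus discovery assumes the homogametic sex is *exactly*
  homozygous reference; populations with X-linked polymorphism will
  need the thresholds relaxed.
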