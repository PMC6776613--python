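# Methods

## The measurement problem

A tumor is a mixture of cell populations: a founder clone carried by every
cancer cell and subclones carried by fractions of them, all diluted by normal
tissue. Whole-exome variant calls expose this structure only through each
mutation's mutant allele frequency (MAF). Two consequences drive everything
in this package: (i) the *spread* of the MAF distribution reflects how
subclonal the tumor is, and (ii) a *shift* in an individual variant's MAF
between two samplings of the same tumor reflects a change in its clone's
abundance — for paired pre-/post-treatment samples, a readout of selection.

## MATH score

For MAFs x₁…xₙ, MATH = 100 · MAD / median(x), with
MAD = 1.4826 · median |xᵢ − median(x)|. The 1.4826 factor is the usual
normal-consistency constant (the default of R's `mad`), kept so that scores
are comparable with the published MATH literature. The median is the standard
sample median (midpoint of central order statistics for even n).

Properties relied on, and tested: permutation invariance; exact invariance
under joint rescaling of all MAFs — the operational form of MATH's
first-order purity correction, since contamination multiplies every MAF by
the same factor; monotone response to mean-preserving widening of the
deviations. MAFs are **not** purity-corrected before scoring; purity is
checked separately as a cohort covariate.

Defaults: a variant enters the distribution at total depth ≥ 10
(`min_depth`), and a score is reported only from ≥ 5 qualifying variants
(`min_variants`); below that, or at median 0, the sample is flagged rather
than scored. Both knobs are exposed; the defaults stabilize the median on
low-mutation exomes without discarding samples silently.

## Exact binomial MAF-shift test

For a variant shared by reference sample A and comparison sample B, the null
is alt_B ~ Binomial(depth_B, p₀), p₀ = observed MAF in A. The two-sided
p-value uses the minimum-likelihood construction: sum the probabilities of
all outcomes whose point probability is at most the observed outcome's. A
central (doubled-tail) variant is available via `test_method="central"`
because the two constructions differ on asymmetric nulls. Implementation
notes: point probabilities are compared with 10⁻¹² relative slack so that
mathematically tied outcomes (the mirror pairs at p₀ = 0.5) are never split
by float rounding, and the selected probabilities are accumulated with an
exactly-rounded sum (`math.fsum`), making the result independent of
summation order. When every outcome qualifies the p-value is exactly 1.

Correction across the tested set is Bonferroni by default, with
Benjamini–Hochberg (`method="bh"`) available. A variant is *enriched* in B if
its adjusted p < α and MAF_B > MAF_A (enriched in A for the opposite sign).
Variants whose reference MAF is exactly 0 or 1 admit no two-sided binomial
null and are excluded with a logged count. For tumor pairs the tested set is
restricted by default to coding and splice-site mutations — the set where a
deleterious-load signal (the N/S ratio contrast) is interpretable; for
germline comparisons the restriction is off.

The direction convention — condition on A, test B — is a documented choice:
an exact test conditioning on both samples' counts (a two-proportion test)
would be equally defensible, and the output metadata records the convention
used.

### Known limitation: anti-conservativeness at moderate depth

Treating p₀ as known ignores that it is itself a binomial estimate. The null
variance of MAF_B − MAF_A is therefore ~2× what the one-sample test assumes
(a √2 z-inflation when both depths are comparable). At 100× coverage and
Bonferroni α = 0.05 over ~200 tests this yields roughly a 1% false-flag
probability per truly clonal variant — small, but not the nominal family-wise
level, so occasional single false flags on founder mutations are expected in
the selection experiments. The effect shrinks with depth (it is negligible
for the overall flagged fraction, which stays well under 5% in the null
calibration experiment) and would vanish under a two-proportion exact test;
the one-sample convention is retained as the documented default.

## Fisher N/S contrast

`summarize_enrichment` builds the 2×2 table of (nonsynonymous, synonymous)
counts for B-enriched vs A-enriched variants and reports Fisher's exact test.
The default is two-sided; a one-sided alternative (`"greater"`: does the
post-treatment side carry a larger N/S ratio?) is exposed, and is the variant
that matches the directional question usually asked of this table.

## Cohort statistics

Group contrasts use Wilcoxon rank tests: exact enumeration when both groups
have ≤ 25 values and no ties, otherwise the normal approximation with
continuity correction. Stage is grouped I+II vs III+IV and nodal status N0 vs
N1+N2 (labels like "Stage IIIA"/"N1mi" are normalized). Between-patient
groupings use the *unpaired* rank-sum test — cohort samples come from
independent patients, so a paired test is not applicable there even though
paired terminology sometimes appears in published figure legends; the
signed-rank test is reserved for within-patient PRE/POST contrasts (zero
differences dropped; all-zero → degenerate p = 1). Continuous covariates (CNV
count, purity) use Pearson correlation with the two-sided t-based p. No
correction is applied across the handful of cohort tests.

## Substitution spectra and signature refitting

Substitutions are collapsed to pyrimidine-reference classes (G>T ≡ C>A on the
opposite strand); 96-channel spectra reverse-complement the trinucleotide
context jointly with the substitution. Contexts are caller-supplied (the
simulator emits them; real data needs a reference genome, which is out of
scope), validated against the variant's reference base. Exposure refitting
solves non-negative least squares of the normalized spectrum against a
user-supplied signature matrix (COSMIC-format TSV, columns summing to 1) and
reports exposures normalized to sum 1 plus the residual norm; de novo
signature extraction is deliberately not provided.

## Simulator

The generator encodes the observational design it is meant to test: matched
PRE/POST tumor samples plus a germline pair (blood vs treatment-exposed
mucosa).

*Tumor model.* One founder clone (CCF 1 at both timepoints) plus mutually
exclusive subclones (no nesting — keeps CCF arithmetic unambiguous). Every
mutation is heterozygous in a diploid, CNV-free genome, so
E[MAF] = purity · CCF / 2; purity is the sole dilution factor. Per variant
and timepoint, depth ~ Poisson(mean_depth) truncated ≥ 1 and
alt ~ Binomial(depth, E[MAF]); a variant is detected when alt ≥
`min_alt_reads` (default 1), which is what creates PRE-only and POST-only
calls. POST additionally receives `post_private_mutations` on a clone absent
from PRE at CCF `post_private_ccf` (default 0.2) — mutations arising or
expanding from below detection. Effect classes are drawn per mutation
(coding with probability `coding_fraction` = 0.85; coding mutations are
splice with probability 0.05, otherwise nonsynonymous with probability
`ns_fraction` = 0.75); trinucleotide contexts are drawn uniformly around the
reference base.

*Defaults as study conditions.* Purity 0.8 (macrodissected samples with
≥ 80% tumor nuclei), mean depth 100× (exome scale), ~110–130 mutations per
sample, and a three-clone architecture — founder (25 mutations), a regressing
subclone (CCF 0.60 → 0.02, 55 mutations) and a treatment-selected subclone
(0.08 → 0.55, 35 mutations) — so that a default run displays both directions
of clonal turnover and a post-treatment rise in MATH.

*Germline model.* Inherited sites are read-sampled independently in the two
samples. A `hom_fraction` (default 1/3) of sites is homozygous-alternate
(E[MAF] 1.0) and the rest heterozygous (0.5): the het/hom mixture provides
the between-site variance that makes real matched germline call sets
correlate tightly (r² ≈ 0.9 at these settings); with het-only sites the
cross-sample MAF correlation would be ≈ 0 by construction. A small
`low_coverage_rate` (default 0.002) of site/sample draws is read at
Poisson(2) depth, emulating the poorly-covered exome tail that produces the
occasional detection dropout — a handful of single-sample-only calls per
~2,000 sites, as observed in matched normal pairs. `n_private_b` injects
het sites private to the second sample for iatrogenic-mutation power
experiments.

*Reproducibility.* Random streams are seeded per (clone, purpose) via
`numpy` `SeedSequence` spawn keys, so enlarging one clone never perturbs
another clone's draws, and identical configs are byte-identical on re-run.
Each clone draws positions without replacement inside its own coordinate
block (abstract coordinates on a single contig; the simulator does not model
a real genome).

*What the simulator does not emulate* — and hence what passing tests do not
establish about real data: sequencing error and mapping artifacts, caller
thresholds beyond a minimum-alt-read rule, copy-number change and LOH
(MAF shifts in real tumors can also reflect local CNV), purity differences
between timepoints beyond the configured values, topographic heterogeneity
from sampling different tumor regions, and nested clone phylogenies. In
particular, real paired samples share far fewer mutations (~20% in treated
rectal tumors) than the simulator's detection model alone produces at 100×,
because real private calls are driven by regional heterogeneity and caller
behavior, not only by read sampling.

## Validation experiments (`itgh.experiments`)

All are seeded, run in seconds, and are what `scripts/acceptance.py` reports:

- **Null calibration** — clone fractions identical PRE and POST (500 variants
  × 20 replicates): flagged fraction at Bonferroni α = 0.05 stays well below
  5% (typically < 1%).
- **Selection recovery** — subclone CCF 0.10 → 0.60, purity 0.8, 100×, 100
  founder + 100 subclone mutations: ≥ 80% (typically ~95%) of the selected
  clone's mutations flagged POST-enriched; founder mutations are expected to
  show ~1 false flag per run, per the anti-conservativeness analysis above.
- **MATH monotonicity** — a four-subclone tumor (CCFs 0.1/0.2/0.3/0.4) scores
  a far higher median MATH than a one-clone tumor at matched purity and
  depth, over 20 replicates.
- **Read-fraction calibration** — per-clone mean observed MAF within 3
  standard errors of purity · CCF / 2 (≥ 50 mutations per clone).
- **Germline experiment** — ≥ 99.9% call-set overlap and MAF r² ≈ 0.94
  between matched normals at the default 2,000 sites.

Problem sizes (500 variants, 20 replicates, 2,000 germline sites) are chosen
so each experiment gives stable estimates while the whole battery completes
in a few seconds.

## Numerical and degenerate-input conventions

Duplicate variant keys within one input keep the deeper record (logged).
Chromosome names are verbatim; `strip_chr_prefix` normalizes `chr1` → `1`
when matching across call sets with mixed conventions. Indels, MNVs and
symbolic alleles are dropped at ingest — the analyses are defined on point
mutations. Empty comparisons (no shared variants) return empty results, not
errors; statistics that need a minimum input (correlation n ≥ 3, MATH
n ≥ `min_variants`, N/S with zero synonymous count) return flagged
"unavailable" results with a reason. The multi-allelic MAF denominator is
the site's total depth (sum of all allele depths), so the per-allele MAFs of
a split record sum to at most 1.
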