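# Methods

This note documents the models, conventions, and numerical choices behind
`txdesign`, in the order a design-and-validation run encounters them.

## Coordinates, coding, and identity

All genomic positions are 1-based; interval predicates (region filters,
the extended-MHC preset chr6:25,500,000–34,000,000 on hg19) are closed on
both ends. Genotypes are alt-allele counts 0/1/2 with −1 as the
missingness sentinel — never 0, so MAF/MAC arithmetic is unambiguous.
Marker identity is (id, chrom, pos, ref, alt); no strand flipping or
allele harmonization is attempted, and mismatches are errors rather than
silent reconciliations, because silent flipping corrupts concordance
statistics in ways that are hard to detect downstream. Inputs must be
pre-harmonized.

## Synthetic panels

The generator reproduces the statistical structure the pipeline needs,
not demography.

**LD model (founder copying).** Each block of `markers_per_block`
adjacent markers carries a two-founder backbone: every haplotype draws an
indicator z ~ Bernoulli(p_pop) once per block, each site copies z or 1−z
(orientation fixed per site), and each allele is then flipped
independently with probability (1 − c)/2 where c =
`within_block_correlation`. Consequences: at c = 1 all intra-block
polymorphic pairs have r² exactly 1; at c = 0 sites are independent;
between blocks r² ≈ 0 because backbones are independent. Two founders
(rather than a larger founder set) are used so that c = 1 really yields
r² = 1 for *every* intra-block pair — with ≥3 founders two sites can
partition the founders differently and perfect copying would not imply
perfect LD. The mutation flip both titrates r² and diversifies per-site
allele frequencies within a block.

**Population divergence.** The alternate-founder frequency drifts per
population under the Balding–Nichols beta model with parameter `fst`
(default 0.05–0.08 in the shipped configurations, a typical
between-continental-population value); the ancestral frequency is drawn
uniformly from [`maf_low`, `maf_high`]. Markers can drift to realized
monomorphism in one population while remaining common in another, which
is exactly the situation the per-population tagging and coverage rules
must handle.

**Trios.** Parents are drawn without replacement within one population;
the child inherits one untouched parental haplotype per chromosome
(recombination only at chromosome boundaries — blocks never straddle
chromosomes, so the no-recombination-within-blocks contract holds).
Mendelian errors are injected by replacing the child genotype, with
probability `mendelian_error_rate` per site, by a uniformly chosen
genotype *incompatible* with the parents. Because injected errors are
incompatible by construction, every one is detectable, and the returned
ledger is an exact oracle for the downstream error count. Het × het
parent pairs admit every child genotype; such draws are skipped and
logged. Default validation runs use eight trios, matching the reference
validation experiment.

**Duplicates.** A duplicated sample suffers an independent single-allele
change per site with probability `duplicate_error_rate` (0→1, 1→0 or 2,
2→1) and missingness with `genotype_missing_rate`; trio founders are
excluded from pairing via the `exclude` argument so QC fixtures are not
confounded. The expected non-full-concordance rate equals the error rate,
which the tests verify to binomial precision.

**Imputation posteriors.** `posterior = (1 − noise)·onehot(truth) +
noise·Dirichlet(1,1,1)`. At noise 0 the posterior is degenerate on the
truth (INFO = 1); at noise 1 it is uniformly distributed over the
probability simplex, i.e. maximally uninformative. A Dirichlet draw
rather than the fixed point (⅓,⅓,⅓) is used so that best-guess accuracy
degrades *smoothly* with noise — with a deterministic blend the argmax
never moves until the blend weight crosses ½, which would make the noise
dial useless for calibration tests. Missing truth receives the pure
Dirichlet draw.

All randomness flows from a single integer seed through one
`numpy.random.Generator` per operation.

## LD engine

r² between two biallelic sites is D²/(p₁(1−p₁)p₂(1−p₂)) with
D = p₁₂ − p₁p₂, computed from phased haplotypes — algebraically the
squared Pearson correlation of the two 0/1 vectors, which is how the
windowed builder computes it (centered dot products). Composite
genotype-based r² (EM estimation) is out of scope; the panels here are
phased. Monomorphic sites have undefined r² and are excluded from stores,
tagging candidacy, and coverage denominators in that population.

Numerical choices: values are clamped to [0, 1]; values within 1e−12 of 1
are snapped to exactly 1.0 so that perfect-copy pairs survive an exact
r² ≥ 1.0 threshold. The window default is 250 kb — a conventional
pairwise-tagging horizon; it is configurable and recorded in every store
and report.

## Tag selection

Tagging is pairwise: candidate c tags target t in population p iff
r²(c,t) ≥ threshold in p (default 0.8, the community convention), or
c = t where t is polymorphic in p (direct genotyping counts as r² = 1).
A target owes coverage only in populations where it is polymorphic.

The greedy maximizes, at each step, the summed count of newly covered
targets across **all populations simultaneously** — selecting the marker
that tags the most markers from all populations first, rather than
optimizing populations one at a time. Coverage-so-far is a monotone
submodular function, so the implementation uses exact lazy evaluation
(a priority queue of stale marginal gains; a popped candidate is
re-scored and re-inserted unless it still dominates), which reproduces
the eager greedy's trace exactly while scaling to thousands of
candidates. Ties break by smaller genomic position, then lexicographic
marker id, making selection order a pure function of its inputs. The
classic (1 − 1/e) approximation bound applies and is asserted against
exhaustive enumeration on small instances in the tests.

The booster run seeds the greedy with the coverage an existing array
already provides and restricts targets to common variants (defaults
MAF > 0.02 in CEU and > 0.05 in AFR, strict inequalities); its gain log
is therefore the *incremental* coverage per added marker and is
non-increasing by submodularity.

## Array assembly

Modules are stacked highest-priority first; a marker whose identity key —
(chrom, pos, ref, alt) by default, marker id optionally — is already on
the array is skipped, and contribution stops at the budget (default
782,000 markers, the reference design's capacity). The audit satisfies
contributed + skipped + truncated = input size per module, and with an
unlimited budget the final set is order-invariant (only attribution
changes). Mandatory tiers that would be truncated raise an error naming
the module. The MAC content filter keeps markers observed strictly more
than 5 times in a reference count table (MAC 6 kept, MAC 5 dropped);
markers absent from the reference are dropped and counted separately.
Only biallelic markers are handled throughout.

## Coverage evaluation

For each eligible target (polymorphic, MAF strictly above the cutoff,
optionally inside a region), the maximum r² to any array marker within
the window is computed; targets directly on the array score 1.0 and are
included in the denominator (the self-inclusion choice is recorded in the
report). Coverage at threshold t is the fraction of eligible targets with
max r² ≥ t over the grid {0, 0.05, …, 1.0}; the mean of the max-r² values
gives the mean-r² figure used for regional comparisons. Reporting grids
follow the 0.01 and 0.05 MAF-cutoff conventions. Curves are non-increasing
in t and pointwise non-decreasing under array augmentation; both
invariants are asserted in the tests.

## QC metrics

**Mendelian errors.** A child genotype errs iff it cannot be composed of
one transmitted allele from each parent (classification by a precomputed
3×3×3 table; e.g. both parents hom-ref with a het child is an error).
Sites with any missing member are skipped and counted separately. All
markers are treated as autosomal-diploid; hemizygosity is out of scope.

**P-P-C heritability** is 100·(total − errors)/total with the *fixed
post-QC SNP total* as denominator — the reporting convention of the
reference validation tables — while the stricter per-trio non-missing
denominator is exposed alongside (`ppc_heritability_nonmissing`). The
identity error_rate + heritability/100 = 1 holds exactly on unrounded
values.

**Concordance** compares unordered allele multisets: 2/1/0 shared alleles
(IBS) → fully/half/fully-discordant, equivalently |g_a − g_b| on the
alt-count coding. Pairs with missingness in either call set are excluded
from the denominator; counts conserve (full + half + discordant = tested)
in every stratum. The displayed "Concordance (%)" is fully-concordant /
tested × 100, rounded half-up to 2 decimals (table convention; raw
fractions are retained in the report objects).

**INFO score.** With per-sample expected dosage eᵢ = p1ᵢ + 2p2ᵢ and
dosage variance vᵢ = p1ᵢ + 4p2ᵢ − eᵢ², and θ = Σeᵢ/2N, INFO =
1 − (Σvᵢ/N)/(2θ(1−θ)) — the standard ratio-of-variances definition
(observed dosage uncertainty against Hardy–Weinberg variance at the
estimated frequency). Degenerate posteriors give exactly 1; uniform
posteriors give −1/3 raw (clipped to 0); θ ∈ {0,1} is flagged
undefined-monomorphic rather than scored.

**Masked-imputation evaluation** hides a uniform random fraction of
markers (default 0.2 %, seeded; a 0.1 % variant is reachable by
argument), takes the best-guess genotype as the posterior argmax (ties to
the smaller dosage), and scores concordance against the hidden truth at
masked sites only, stratified by MAF bins of width 0.01 partitioning
(0, 0.5]. The headline accuracy additionally restricts to markers with
INFO above the threshold (default 0.8).

## Problem sizes and what the tests show

The shipped end-to-end configuration is a 3-population (CEU/ASN/AFR,
100 samples each), 500-block × 10-marker (5,000-marker) panel across 10
chromosomes with c = 0.95 and Fst = 0.08 — large enough that tagging,
windowing, stratification, and the QC battery are all exercised
non-trivially, and small enough to run in seconds on one CPU. Oracle
tests run on smaller instances where exhaustive enumeration (double-loop
LD, all b-subsets of candidates) is feasible.

Passing tests demonstrate internal correctness — formula-level agreement
with hand evaluations and brute-force oracles, exact recovery of injected
errors, reproduction of published summary statistics from their printed
counts — on synthetic data whose LD is blockwise and whose errors are
independent across sites. They do not demonstrate robustness to features
of real genotyping data the generator does not emulate: genotype-calling
artifacts correlated across samples, strand/build mismatches (rejected,
not repaired), realistic recombination and demography, structural
variation, or sex-chromosome inheritance.

## Known limitations

* Haplotype-based r² only; unphased input cannot be used for LD or
  tagging (it is accepted for the QC battery).
* Pairwise tagging only — no multi-marker haplotype tagging or
  imputation-aware (HMM) selection.
* Desk-scale text formats: VCF 4.x (GT only) and whitespace .ped/.map;
  no BCF/PLINK-binary/CRAM.
* The assembler audits and bounds content but does not model probe-level
  assay feasibility.
* Imputation itself (phasing/HMM engines) is out of scope; the evaluator
  consumes posteriors from any source.
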