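# Methods

This note records the models, defaults and numerical choices behind
`bsaqtl`, and what the simulation-based tests do and do not demonstrate.

## Genetic-map arithmetic (`bsaqtl.genmap`)

Map distances use the Kosambi function, d(cM) = 25·ln((1+2r)/(1−2r)), with
the closed-form inverse r = ½·tanh(d/50). Distances are stored in
centimorgans everywhere; Morgans appear only inside the formulas. The
round-trip is exact to better than 1e-12 across r ∈ [0, 0.49].

Genotype data from inbred lines observe a *cumulative* recombinant fraction:
every selfing generation gives an interval another chance to recombine, so
the recombinant fraction among lines exceeds the per-meiosis fraction. At
complete inbreeding the Haldane–Waddington result R = 2r/(1+2r) applies
(inverse r = R/(2(1−R))); for a finite filial generation g the package
iterates the exact 16-state two-locus diplotype recursion under selfing and
scores recombinants among lines homozygous at both loci, matching how R is
estimated from genotype matrices (heterozygotes excluded). The generation is
a parameter because advanced RIL populations are rarely at exact fixation;
map construction defaults to the infinite-selfing correction, which at F6
overstates r by only a few percent for loosely linked markers.

## The simulator (`bsaqtl.simulate`)

The generator emulates the experiment the analysis is designed for: a
biparental cross between near-isogenic parents differing at a small number
of large-effect flowering loci, advanced by single-seed descent, selectively
bulked and pool-sequenced.

* **Meiosis.** Gametes follow a Markov chain along each chromosome with
  inter-marker recombination probability kosambi_r(Δ cM) and no crossover
  interference. The Kosambi function is retained for distance↔fraction
  conversion so that simulation and map estimation share one convention,
  even though a Markov (no-interference) crossover process is, strictly,
  the Haldane regime; at the marker densities used the discrepancy is far
  below sampling error.
* **Defaults** (the "study" preset): n = 213 lines at F6; two 100-cM
  chromosomes with 200 evenly spaced parent-informative sites each at
  500 kb/cM (a realistic soybean-scale rate, 50-Mb chromosomes); one planted
  QTL per chromosome at 50 cM with additive effects +5 and +4 days per
  late-parent allele; baseline μ = 35 days to first flower, residual σ = 2
  days; bulks of 30 early and 21 late lines; pooled depth Poisson with
  mean λ = 50 per site and per-read allele error e = 0.005. The "null"
  preset is identical without QTLs. Both QTL effects default to the
  same sign (late parent delays), but signs are configurable — in real
  crosses either parent can contribute the delaying allele, which is why
  regions are called on |Δ| with the sign reported.
* **Phenotype.** y = μ + Σ a_q·(dose_q − 1) + ε, ε ~ N(0, σ²); purely
  additive, no dominance (RILs are nearly homozygous) and no epistasis.
  QTLs are snapped to the nearest marker of their chromosome (≤ 0.25 cM at
  default density); positions off the chromosome's map raise an error.
* **Bulking.** The n_early smallest and n_late largest phenotypes, ties
  resolved by line order; bulks are disjoint by construction. Depth can be
  made negative-binomial via an optional overdispersion parameter.
* **Reads.** At each site the pool's true late-allele frequency is
  f = Σdose/(2·bulk size); the late-allele read count is
  Binomial(depth, f(1−e) + (1−f)e).

What the generator does *not* emulate: segregation distortion, genotyping
error in the marker matrix, linkage drag structure beyond the two-parent
mosaic, reference bias in read mapping, variable site density (sites are
evenly spaced), and multi-allelic or clustered variants. Tests that pass on
these simulations therefore certify the statistical machinery under the
stated model, not robustness to those artefacts of real data.

## Site filtering (`bsaqtl.sites`)

Retention rules before index computation: both parents homozygous
(operationalised at read level as parental depth ≥ 10 with minor-allele
share ≤ 0.1) for different alleles; total depth ≥ 10 in *each* pool; site
quality ≥ 100; indels longer than 20 bp dropped; SNPs below 1% minor-allele
frequency dropped only when a cohort frequency is supplied (two pooled
bulks cannot estimate a cohort MAF, so requesting that filter without
frequencies is an error). All boundaries are inclusive. Filters are
row-wise predicates, hence idempotent and order-commutative; every removed
site is logged under exactly one reason code, first applicable reason wins.
VCF positions are 1-based; exported BED intervals 0-based half-open.

## The scan (`bsaqtl.scan`)

Per-site indices are oriented so the counted allele is the one carried by
parent B, decided per site from the parental read majorities. Sites with
zero depth in either pool are excluded (index is missing, never 0 — an
uncovered site carries no information).

**Windowing.** Sliding arithmetic mean of Δ, default 1 Mb window / 10 kb
step, windows with fewer than 3 contributing sites masked. The window mean
never exceeds the most extreme contributing site.

**Genome-wide threshold.** The threshold is the empirical (1−α) quantile
(α = 0.05, `higher` interpolation) of the genome-wide maximum of the
windowed |Δ| track over replicate null datasets generated at the *observed*
per-site depths. Two null models are implemented:

* `genedrop` (default): each replicate drops n_EF + n_LF fresh inbred-line
  genomes along the genetic map (two-state Markov chain with inter-site
  transition 2r/(1+2r)), splits them into bulks and resequences them
  binomially at the observed depths. Under the no-QTL model with random
  bulk membership this *is* the generating process, so the procedure is
  calibrated by construction; the type-I check over 200 simulated null
  genomes lands inside the 95% binomial band around α. Genetic positions
  come from the marker map when available, otherwise from a constant
  cM/Mb rate (default 2.0, matching the preset's 500 kb/cM).
* `reads`: read counts redrawn Binomial(depth, 0.5) in each pool. This
  textbook resampling ignores bulk-composition sampling variance — with
  bulks of 30/21 lines the composition term (SD ≈ 0.14 on Δ, correlated
  along chromosomes) dominates read noise at 50× — so its thresholds are
  roughly half the gene-drop values and its genome-wide false-positive rate
  on full null simulations approaches 1. It is kept for comparison, for
  data without any genetic-map information, and because it is the natural
  reading of a bare "permutation test" on pooled counts.

The number of replicates defaults to 1000 and is configurable.

**Region calls.** Maximal runs of unmasked, same-sign windows with
|mean Δ| ≥ threshold; runs separated by at most `merge_gap` grid steps
(default 1) are bridged. A second, coarser rule then coalesces same-sign
regions on a chromosome whose spans fall within `merge_span_bp` (default
10 Mb ≈ 20 cM at the preset rate): selective bulking elevates |Δ| across
whole linked chromosome arms, and with composition noise correlated over
tens of centimorgans the track can cross the threshold several times around
one locus; excursions closer than the method's mapping resolution are one
candidate region, not several. Set `merge_span_bp=0` to keep raw runs.
Each region reports its span, sign, peak |Δ| and peak position; BED output
is 0-based half-open.

## Linkage mapping and the LOD scan (`bsaqtl.linkage`)

Pairwise linkage uses only lines homozygous at both markers; R_obs is the
recombinant-class fraction and the p-value a Yates-corrected 1-d.f.
chi-square on the 2×2 homozygote table. Grouping is single-linkage with an
edge iff p < 0.001; when R is supplied an edge additionally requires
R_obs < 0.5, because linkage is one-sided — a significant repulsion-side
association is noise. Within a group, markers are ordered by greedy chain
extension from the tightest pair plus 2-opt reversals, minimising the sum
of adjacent R_obs; adjacent fractions then pass through r = R/(2(1−R)) and
the Kosambi function (fractions above 0.5 clipped to 0.4999 with a
warning), and cumulative positions are the running sum.

The scan is deliberately a **single-marker** one-way ANOVA (heterozygotes
form a third class where present), with LOD = (n/2)·log₁₀(RSS₀/RSS₁) from
the equivalent class-mean regression, base-10 logs. Multiple-QTL/composite
interval mapping is out of scope by design; single-marker ANOVA is the
standard confirmation analysis for a sparse PCR-marker map. Exact fits
(RSS₁ → 0) cap the log-ratio at 12 decades and flag the marker; constant
phenotypes and monomorphic markers are flagged with missing statistics.

The genome-wide threshold permutes phenotypes across lines (1000 replicates,
α = 0.05) and takes max(empirical quantile, 2.5): the 2.5 floor is a
conventional minimum evidence level and can only make the test more
conservative. On the default sparse map (11 markers per 100-cM chromosome,
n = 213) the permutation quantile sits near 2.5–2.6, so the floor binds only
occasionally and the realised genome-wide type-I rate stays at or below the
nominal 5% (checked over 200 null simulations).

## Fine mapping (`bsaqtl.finemap`)

Recombinants are lines whose calls at two flanking markers differ (any of
A/B, A/H, H/B). A line's progeny classify it by splitting at the parental
midpoint: `segregating` needs at least 3 progeny on each side (configurable),
fewer than 10 progeny is `untested`, otherwise the line is fixed toward the
majority side. Each informative line contributes a boolean constraint over
the elementary intervals between consecutive markers — a segregating line
allows intervals compatible with heterozygosity (touching an H call or a
breakpoint between opposite homozygotes), a fixed line allows intervals
touching a call of the matching allele — under a single-crossover-per-
interval assumption. The delimited interval is the intersection, reported
by flanking markers with the locus treated as strictly between them; an
empty intersection raises an error naming the conflicting lines. The
intersection is order-independent and monotone: adding a line whose allowed
segment contains the current interval never changes the result.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is bit-reproducible
given it. The bundled checks run at desk scale by choice: 50 replicate
scans for the two-locus recovery rate, 200 null genomes each for the Δ and
LOD calibration estimates (binomial SE ≈ 0.015 at α = 0.05), 100,000
lineages for the meiosis-simulation oracle, 1000 permutation replicates
throughout. The reported thresholds (e.g. |Δ| ≈ 0.50 under the gene-drop
null at 50×, 400 sites) are properties of these simulation conditions;
real experiments with different depths, bulk sizes and site densities will
produce different thresholds, which is why both are always recomputed from
the data at hand.

## Known limitations

Single-marker LOD scans cannot separate linked QTLs on one chromosome; the
region caller's coalescing scale is a resolution statement, not an
inference; the gene-drop null assumes random bulk membership under the
null and inherits the no-interference meiosis model; pooled data cannot
estimate within-bulk allele-frequency variance site by site, so no
per-region confidence intervals are attempted; and the VCF reader expects
exactly four named samples with AD fields and skips multiallelic records.
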