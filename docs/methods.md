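# Methods

## The inference problem

Two parapatric species meet along a biome boundary and interbreed.  Each
sampled individual carries four kinds of evidence about its ancestry:
a diploid genotype at ~10 unlinked microsatellite loci, uniparental and
sex-linked haplotypes (mtDNA, X, Y) whose species of origin is diagnostic,
a phenotype-based species label, and (for a subset) a vector of body
measurements.  The package infers, per individual, (i) the admixture
coefficient *q* — the fraction of the nuclear genome attributable to each
of K clusters, (ii) the posterior *Q* over six pedigree classes, and
(iii) an integrated pure/hybrid call, then asks how hybrids are arranged
in space and whether morphology tracks ancestry.

## Admixture model

The sampler targets the classic admixture posterior: each allele copy has
a latent cluster of origin z; individual memberships q have a symmetric
Dirichlet(α) prior; cluster-specific allele frequencies have flat
Dirichlet(1) priors, independent across clusters (the original
uncorrelated-frequencies model — the correlated-frequency variant is out
of scope here).  One Gibbs sweep updates frequencies | z, memberships | z
and origins | (q, p); all three conditionals are conjugate and fully
vectorised over individuals and loci.  Missing calls are excluded from
every count and contribute nothing to the likelihood.

α is sampled by a seeded Metropolis step (uniform prior on (0, 10],
log-normal random-walk proposal), as the standard admixture samplers do.
A fixed α is available (`infer_alpha=False`) but note the structural
consequence: with α fixed at 1 the posterior-mean membership of even a
perfectly diagnostic individual cannot exceed (α + 2L)/(2α + 2L) ≈ 0.95
at L = 10 loci, which would defeat the ≥ 0.95 parental-panel filter.
With α sampled, runs on pure two-population data concentrate α near
0.01–0.05 and pure individuals reach q ≈ 0.999, while mixed
parental-plus-hybrid runs settle near α ≈ 0.4.

The per-K model log-probability is the usual mean − variance/2 estimate
computed from the post-burn-in trace of the data log-likelihood; the ΔK
table is its absolute second difference across K divided by the
between-run SD.  Runs are aligned across label permutations (exhaustive
for K ≤ 6) before averaging.

Default chain lengths are 2,000 sweeps with 500 burn-in.  These are
desk-scale choices: at K = 2 with 10 loci the Monte-Carlo error of the
posterior-mean q under these lengths is well below 0.01 (checked against
exhaustive enumeration over all 2^16 origin configurations of a
4-individual × 2-locus instance via the label-invariant co-assignment
statistic E[q_i·q_j], which agrees within 0.02).  Longer,
literature-scale runs are a constructor argument away.

## Genotype-class posterior

Each pedigree class c is characterised by φ(c) = (φ0, φ1, φ2), the
probabilities that a locus carries both genes from species A, one from
each, or both from B: pure A (1,0,0), pure B (0,0,1), F1 (0,1,0),
F2 (¼,½,¼), backcrosses (½,½,0)/(0,½,½).  The genotype likelihood under c
mixes the three source-state genotype probabilities with these weights;
loci multiply.  Classes beyond the second generation are deliberately
absent — with ~10 loci they are not identifiable, and deeper backcrosses
masquerade as parentals (which is exactly why the sequence-based markers
enter the final call).

Two modes:

* **plug-in** (default test surface): parental allele frequencies fixed at
  their reference-panel estimates; the six-class posterior is then exact,
  computed in log space with equal class priors.  Reference frequencies
  receive a 0.5 pseudocount over the union support so an allele private to
  one panel cannot zero out whole classes; the raw likelihood primitive
  (`genotype_class_likelihood`) keeps the strict behaviour (zero with a
  warning).
* **joint**: a Gibbs sampler over class memberships, per-locus source
  states, the A-vs-B attribution of heterozygous one-each loci, and the
  two frequency vectors; reference individuals stay pinned to their pure
  class.  With large reference panels (~500) it agrees with plug-in
  within 0.03; with smaller panels the joint mode's integration over
  frequency uncertainty moves borderline backcrosses by up to ~0.05,
  which is a real feature of the model, not sampler error.

A structural note on ceilings: under equal priors over the six classes,
an all-heterozygous individual at 10 diagnostic loci has Q(F1) =
1/(1 + 3·2⁻¹⁰) ≈ 0.9971, because F2 and both backcrosses each retain
per-locus likelihood ½.  Thresholds above that are unreachable.

## Threshold calibration

The power experiment regenerates the study design: parental allele
frequencies → 200 simulated parentals per species → 100 genotypes of each
hybrid category by gametic crossing (parents drawn with replacement; the
pairing scheme of the original simulation tool is unstated, so
with-replacement is an explicit assumption) → one unsupervised K = 2
admixture run on the combined 800.  Correctness rules, made explicit and
configurable: a parental is correct when its own-cluster membership
reaches the threshold; a hybrid is correctly flagged when *both*
memberships fall below it (assignment to neither cluster); under the
class-posterior engine, parental correct means own-pure Q > 0.6 and
hybrid correct means pooled hybrid Q > 0.6.  Parental rates are
non-increasing and hybrid rates non-decreasing in the threshold by
construction, and backcrosses lose 20–30 points of detection when the
threshold drops from 0.9 to 0.8 — the permissive threshold protects
parentals at the cost of backcross sensitivity.

## Integrated decision rule

Per individual, three flags: STR (own-cluster q below 0.8, the
conservative default; 0.9 exposed), NH (pooled hybrid-class posterior
above 0.6, or own-pure Q below 0.6 when only that marginal exists), and
SEQ (any non-missing mtDNA/X/Y origin label differing from the phenotype,
a heterozygous X with one foreign allele included).  The call is hybrid
iff (STR ∧ NH) ∨ SEQ.  Requiring both microsatellite analyses to agree
suppresses false positives from either engine alone; the sequence
override is kept unilateral because a foreign fixed haplotype cannot
arise in a pure lineage, whereas a later-generation backcross can easily
look pure at 10 microsatellites.  Individuals pure by both nuclear
analyses but sequence-incongruent are therefore called hybrid.  At
q = threshold exactly, the individual is *not* flagged (the flag requires
strictly below); the parental-panel filter keeps q ≥ 0.95 inclusively.
No hard F1/F2/backcross call is emitted — only raw class posteriors —
since those calls are unreliable at this locus count.

## Differentiation statistics

F<sub>ST</sub>, R<sub>ST</sub> and Φ<sub>ST</sub> share one two-level
AMOVA variance-component engine on gene copies, differing only in the
squared distance: 0/1 allele identity (the Reynolds-style coancestry
analog for co-dominant markers), squared repeat-size difference
(Slatkin), or supplied p-distances for sequence haplotypes.  Multi-locus
values are ratios of summed components (ratio-of-sums, not
average-of-ratios).  Negative estimates are reported as computed.
Significance is by permutation of individuals between populations,
p = (1 + #{perm ≥ obs})/(n_perm + 1).  The Hardy–Weinberg test is the
probability-ordering exact test (complete enumeration of genotype tables
with the observed allele counts, summing probabilities ≤ the observed
table's) with a seeded Monte-Carlo fallback above a configurable
enumeration bound; linkage equilibrium is a permutation G-test on the
two-locus genotype table.  Per-locus p-values are reported raw — the
analysis counts significant tests at nominal 0.05, so no multiplicity
correction is applied.

## Synthetic data: what it emulates, what it does not

Locus models draw both parental frequency vectors from a Dirichlet
centred on a shared ancestral vector with concentration (1 − F)/F, so the
single drift parameter maps monotonically onto expected F<sub>ST</sub>;
`calibrate_divergence` bisects it against realized Reynolds F<sub>ST</sub>
on large samples (common random numbers across evaluations keep the
response monotone).  Repeat sizes step by 2 bp.  Crosses are gametic with
explicit parents, so Mendelian ratios, F1 heterozygosity at diagnostic
loci, and mtDNA/X/Y inheritance (mtDNA from the dam, Y from the sire, X
per sex) hold exactly; the F1 dam defaults to species B and is
configurable, as is which side of a backcross is the dam.

The default study emulates a 94-individual contact-zone sample dominated
by post-F1 hybrids (30 + 26 pure, 2 F1, 22 F2, 7 + 7 backcrosses), 10
loci × 8 alleles at drift 0.18 (realized F<sub>ST</sub> ≈ 0.15), hybrids
placed within the central longitude range with 30 km perpendicular
scatter and pure individuals offset 120 ± 45 km onto their own side of
the contact polyline (which bends north at its western end), morphometric
vectors driven by one latent size factor with male-biased dimorphism in
species B and hybrids drawn from the cluster of their assigned phenotype
— deliberately *not* intermediate, emulating the observed
genotype–phenotype discordance.  Missing data is off by default
(per-call dropout configurable).

Not emulated: coalescent history, mutation, linkage, allele-frequency
clines within species, uneven sampling effort, genotyping error, or any
correlation between morphology and individual admixture proportion.
Passing recovery tests therefore show that the inference machinery is
correct under its own assumptions, not that real contact-zone data meet
those assumptions.

## Spatial and morphometric conventions

Distances use an equirectangular projection (1° lat = 111.32 km,
longitude scaled by cos of the mean line latitude; < 0.5% error at these
latitudes, and it keeps the module free of geodesy dependencies).  The
contact polyline is ordered west→east; its left (north/east) side is
positive.  The log transform of signed distances is the odd extension
sign(d)·log10(1 + |d|) — the source analysis leaves the handling of
negative distances unstated, so an explicit sign-preserving choice is
made.  Min–max scaling to [−2, 2] is linear and affine-invariant.  The
central band defaults to ±80 km of the line between 54°W and 50°W.  The
hybrid-concentration test is a 2×2 Pearson χ² without continuity
correction (df = 1); whether the original used a correction is unstated.

Morphometrics: paired t-tests drop a measurement only when both species
show a significant inter-observer difference; measurements are z-scored
(ddof = 1) so covariance-PCA of the standardised matrix equals
correlation-PCA of the raw data; PCI is sign-oriented so larger animals
score higher; group comparisons use the equal-variance t-test (df =
n1 + n2 − 2, matching the reported df convention); the discriminant is a
two-group LDA scored by resubstitution — optimistic by design, matching
the style of the reported accuracies, and PCA-reduced first when features
exceed n − 2.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen as the package's own
defaults: 2,000-sweep admixture chains, 200 + 200 + 4×100 calibration
samples, 500-individual panels for frequency calibration, 30 bisection
replicates.  Ties and degenerate inputs: monomorphic loci contribute
nothing to differentiation sums; a monomorphic HWE test returns p = 1
exactly; constant columns abort standardisation with the column named;
an individual with no typed loci receives the prior class posterior and
is flagged.  All samplers take integer seeds and are bit-reproducible
given (data, parameters, seed).

## Known limitations

* The admixture model ignores allele-frequency correlation between
  clusters; at the differentiation levels studied here this mainly
  widens parental membership slightly.
* Class posteriors are meaningful only to the second generation; deeper
  ancestry aliases onto the six classes.
* The plug-in class posterior treats reference frequencies as known;
  with small panels prefer the joint mode.
* The brute-force exhaustive checks scale exponentially and are bound to
  toy sizes (4 individuals × 2 loci) by construction.
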