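# Methods

This note documents the models, conventions and numerical choices behind
ssrkit, and what its synthetic data do and do not establish about real
germplasm collections.

## Data model

Genotypes are diploid codominant calls: two allele sizes in base pairs per
accession × locus, unordered, stored ascending so that downstream outputs
(fingerprint strings, distance computations) are deterministic. Missing is an
explicit in-memory sentinel (`None`); in files it is the `0 0` cell pair, the
same convention fingerprints use (`00`). Zero is never a valid allele size.
Tables follow the GenAlEx-style two-columns-per-locus layout (tab-delimited
by default, UTF-8), which is what most SSR genotyping workflows export; the
reader counts every cell it turns into a missing call and surfaces the count.

## SSR mining

Perfect repeats of primitive 1–6 bp motifs are detected with per-length
minimum repeat counts, default mono 12, di 7, tri 5, tetra 4, penta 4,
hexa 4 — the screening thresholds common in genome-wide SSR surveys. The
scan is leftmost-maximal and non-overlapping: at each position the longest
qualifying tract wins, ties go to the shortest primitive unit (a 12-bp
poly-A is one mononucleotide run, never six AAs), and the scan resumes past
the reported tract. Tracts never span an N. Coordinates are 1-based
inclusive (GFF convention); a GFF3 writer emits `SSR` features.

Motif classes are written `canonical/revcomp(canonical)`. By default the
canonical representative is the smallest string over all cyclic rotations of
the motif and of its reverse complement, so e.g. TTA, TAT, ATT, TAA all
tabulate as AAT/ATT. Some screening tools do not normalise rotations and
list e.g. AG/CT and TC/GA separately; `rotate=False` reproduces that
grouping. Compound and imperfect repeats are out of scope: downstream marker
panels are designed on perfect tracts.

## Diversity statistics

Frequencies are allele-copy proportions over non-missing calls. Per locus:
Na (observed alleles), Ne = 1/Σp², Shannon I = −Σ p ln p (natural log),
Ho = heterozygous / genotyped individuals (missing excluded from the
denominator), He = 1 − Σp², and Botstein's PIC. He uses the plain Gini form
because that is what the GenAlEx-style reports this package mirrors print;
the unbiased 2n/(2n−1) variant sits behind `unbiased_he=True`. Monomorphic
loci are legitimate data (Na=1, Ne=1, I=He=PIC=0), not errors. A private
allele is counted for a population when its frequency is positive there and
exactly zero everywhere else. Reports round to 3 decimals (PIC to 4).

## AMOVA

Individual distances are the Smouse–Peakall codominant squared distance,
d² = ½Σ(y_a − y_b)² on per-locus dosage vectors, summed over loci genotyped
in both individuals; the per-locus values are the familiar 0/1/2/3/4 table.
Sums of squares come from the pairwise matrix (SS_total = Σ_{i<j}d²/N and
group analogues; SS_among by subtraction), with variance components
σ²_within = MS_within and σ²_among = (MS_among − MS_within)/n0,
n0 = (N − Σn_g²/N)/(G−1), floored at zero. ΦPT = σ²_among/σ²_total; on
complete data the SS decomposition equals the classical
squared-deviation-from-centroid form (tested against that oracle).
Nm = 0.25(1−Φ)/Φ is reported only for Φ > 0. Pairs sharing no genotyped
locus are excluded with a warning — genotype tables rarely say how their
tools handled this, so the conservative exclusion is made explicit. The
permutation test relabels accessions and uses the add-one rule
p = (1 + #{Φ_perm ≥ Φ_obs})/(n_perm + 1), default 999 permutations, seeded.
`amova_from_summary` rebuilds components from a printed df/SS table plus
group sizes, for auditing published AMOVA tables; components recomputed from
rounded printed values can differ from printed Nm in the third decimal,
which is rounding, not a different estimator.

## Distances, UPGMA, PCA

Nei's (1972) standard distance D = −ln(Jxy/√(Jx·Jy)) is used between
populations, with the identity coefficients averaged arithmetically across
loci; which Nei variant a given legacy analysis used is often unstated, so
the choice is documented rather than asserted universal. Disjoint support
makes D infinite; it is capped at 10.0 with a warning. Between individuals
the shared-allele distance 1 − shared/(2 × loci compared) is the default for
accession-level trees — an interpretation, selectable, since collection
studies often say only "Nei's distance" while clustering individuals.

UPGMA is implemented directly (not delegated) because the package pins a
deterministic tie-break: among equally close cluster pairs, the pair whose
smallest member labels sort first merges. Heights are half the average
linkage distance, so the tree is ultrametric; tests verify equality with
SciPy's average linkage on random matrices and exact recovery of ultrametric
inputs. Newick output carries branch lengths.

PCA encodes genotypes as 0/1/2 allele-dosage columns (one per locus-allele),
imputes missing cells with the column mean, centers, and takes the SVD; axis
signs are fixed by making the largest-magnitude loading positive so runs are
reproducible. Explained-variance fractions are over all dosage columns.

## Admixture model

The model is the standard admixture model with independent allele
frequencies: Q_i ~ Dirichlet(α·1_K), each allele copy picks a pool from Q_i
and an allele from that pool's locus frequencies P_kl ~ Dirichlet(λ·1).
Gibbs sweeps alternate (copy assignments | Q, P), (P | assignments),
(Q | assignments); missing copies are skipped. Priors are fixed at
α = λ = 1 — the customary flat defaults; the correlated-frequencies variant
is not implemented. The evidence estimate is LnP(D) ≈ mean(logL) − ½var(logL)
over post-burn-in sweeps. Desk-scale defaults are 2000 sweeps after 500
burn-in; production-scale runs (e.g. 100,000/100,000) are configuration, not
code changes. Evanno's ΔK pairs replicates by index, needs ≥3 consecutive K
and ≥2 replicates, is undefined at boundary K and wherever sd(LnP(D)) = 0,
and the argmax of the defined values is reported as the suggested K. Pool
labels are exchangeable; tests align against simulation truth with Hungarian
matching at evaluation time only. Hard assignment is argmax Q with ties to
the smaller pool index, plus counts of accessions whose max Q strictly
exceeds the 0.6 / 0.9 conventions.

A practical note on thresholded Q counts: posterior-mean Q under flat priors
shrinks toward the simplex center, so on small panels (~20 loci) a near-pure
individual's max Q can sit just below 0.9 even when the truth is 0.99; at
study-scale panels (~30 markers) the counts match the truth closely. This is
a property of the estimator, not a convergence failure.

## Fingerprints

Per locus, the observed distinct alleles are sorted ascending and coded
1–9 then A…Z (35 alleles max per locus; more is a hard error), 0 reserved
for missing. A fingerprint is two characters per locus — ascending within
the locus — concatenated in fixed panel order, so decode∘encode is the
identity wherever the codebook covers the data. Core markers are selected
greedily: repeatedly take the locus resolving the most currently-unresolved
accession pairs, ties broken toward higher PIC then lexicographic name. A
missing call never resolves a pair (conservative: absence of data is not
evidence of difference). Greedy set cover always reaches the full panel's
resolution but may use more loci than the optimum; tests compare its
resolution count against an all-subsets oracle on small instances. Synonym
candidates are pairs differing at ≤1 locus (threshold adjustable). Barcode
output is the text payload `name|origin|code` with backslash escaping; image
rendering belongs to whatever QR tool consumes the payload.

## Synthetic data

The generator emulates a germplasm collection drawn from K ancestral gene
pools: per pool and locus, allele frequencies ~ symmetric
Dirichlet(freq_concentration) over a ladder of `alleles_per_locus` sizes at
base 100 bp spaced by the motif length (capillary-style alleles);
accession i in labeled population g draws admixture from Dirichlet with
weight 1 + admixture_alpha on pool g and admixture_alpha elsewhere, so
admixture_alpha → 0 gives near-pure members of the labeled pool and large
values heavy admixture; each allele copy draws its pool then its allele;
missingness is i.i.d. Bernoulli per call. Draw order is fixed (pool
frequencies, admixture rows, copy pools, copy alleles, missingness) so one
seed reproduces a matrix exactly. Defaults — 6-allele ladders,
freq_concentration 0.3 (clearly divergent pools), 2 × 40 accessions,
20–25 locus panels — are sized like published SSR collection studies.

What the simulations do not emulate: stepwise mutation dynamics, linkage,
genotyping artefacts (stutter, null alleles, allele drop-out), uneven
population sizes with hierarchical substructure, or clonal pedigree
structure. Passing recovery tests therefore shows the estimators are correct
under the stated model, not that real collections will show structure this
clean; real panels with weak divergence will yield flatter ΔK profiles and
noisier Q than the synthetic anchors.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale by design: AMOVA
permutation calibration uses 500 simulations × 199 permutations on 20×8
matrices; admixture model selection uses 2 × 40 accessions × 25 loci with
5 replicates × (500 + 2000) sweeps over K = 1–5, which one core completes in
about half a minute per scan. All stochastic components (generator, Gibbs
sampler, permutation test, K-scan replicate seeds) run off explicit integer
seeds; replicate seeds derive from one root seed via `SeedSequence.spawn`,
so an entire K scan is reproducible from a single integer.
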