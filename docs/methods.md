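# Methods

`wolfpop` re-implements, as a tested pipeline, the standard population-genomic
characterization applied to hybrid wolfdog breeds (Czechoslovakian-Wolfdog-like
and Saarloos-Wolfdog-like) against their parental proxies (a dog breed and
wolves): panel harmonization, diversity statistics, pairwise F_ST, runs of
homozygosity, and LD-based effective-population-size trajectories. Because the
real genotype panels of such studies are typically only partly public, every
stage is validated against a forward Wright-Fisher simulator with recorded
ground truth rather than against archived data.

## Genotype container and panel harmonization

Genotypes are diploid, biallelic, autosomal SNP dosages in {0, 1, 2} counting
the `allele_b` copy, `-1` for missing; positions are 1-based (PLINK
convention). Chromosome labels that do not parse as positive integers (X, Y,
MT, XY, 0) are excluded on load with a count; numeric labels are assumed
autosomal, so species with numeric sex-chromosome codes must be recoded first.

Harmonization against a reference panel: allele pairs equal up to
reverse-complement are strand-flipped; pairs equal up to order are
dosage-reversed; strand-ambiguous SNPs (A/T, C/G) cannot be oriented from
allele labels alone and are removed; irreconcilable pairs are removed and
counted. Merging intersects SNP sets, unions samples, drops duplicate-position
SNPs (keeping the lexicographically first id), and re-orients dosage to the
global minor allele, giving a deterministic reference for frequency and r^2
computations. The missingness filter removes SNPs missing in strictly more
than `max_missing_samples` samples (default 6). The order of operations is
harmonize -> merge -> filter; the missingness filter is applied once, after
the final merge.

LiftOver between genome builds and VCF ingestion are out of scope. SNP
renaming across sources is supported only through an explicit user-supplied
id-mapping table, not inferred.

## Diversity statistics and F_ST

Per population: H_O is the fraction of heterozygous calls per SNP, H_E is
2p(1-p) from the within-population counted-allele frequency, both averaged
over all panel SNPs with at least one call in the population (including SNPs
monomorphic within it — restricting to polymorphic SNPs would inflate H).
No small-sample correction is applied by default; the 2n/(2n-1) correction is
available as an option. Polymorphic-site counts are SNPs with 0 < p < 1 among
non-missing calls.

Pairwise F_ST uses the Weir & Cockerham (1984) two-population estimator with
per-SNP variance components combined as a ratio of sums (sum of
among-population components over sum of total components); SNPs monomorphic
across both populations are excluded. Which estimator the original study's R
package used is not documented, so exact numeric comparability with published
tables is not claimed; a Hudson-type estimator (Bhatia et al. ratio of
averages) is available behind a flag for sensitivity. Raw estimates may be
negative for undifferentiated pairs; the reported matrix clamps at 0 and the
raw values are written to a side table.

## Runs of homozygosity

Sliding-window scan, per individual and chromosome: windows of 50 consecutive
SNPs (study setting) are called homozygous when they contain at most 1
heterozygous and at most 1 missing call; each SNP's support is the fraction
of its overlapping windows called homozygous, with the actual overlap count
as denominator near chromosome ends (no edge suppression); SNPs with support
>= 0.05 are in-run; maximal in-run stretches are reported when they contain
at least 20 SNPs (study setting), span at least 1 kb, and contain no
adjacent-SNP gap over 1 Mb (larger gaps split a stretch). The non-printed
knobs (het/missing allowances, inclusion threshold, length and gap limits)
follow the documented defaults of the standard sliding-window ROH packages
and are fully configurable; they are explicit assumptions, not
reconstructions. Segment coordinates are SNP-bounded (first to last in-run
SNP), so results are reproducible from the map alone.

Segments are classified into 0-2, 2-4, 4-8, 8-16 and >16 Mbp, half-open
[lo, hi): a segment of exactly 2.0 Mbp falls in 2-4. Per-population class
percentages are individual-wise means of each individual's per-class share of
its total ROH coverage; individuals without any ROH do not contribute to the
percentage mean. F_ROH is the summed segment length over the SNP-covered
genome length (per chromosome, max minus min mapped position plus one).

The whole-suite equivalence check compares detected segments against an
independent brute-force window-enumeration oracle on hundreds of random
structured chromosomes across random parameter draws.

## LD-decay effective population size

The Sved relation E(r^2) = 1/(1 + 4 N_E c) + 1/n links mean squared
genotypic correlation at genetic distance c (Morgans) to effective size, with
1/n the small-sample correction; n is the number of genotyped individuals,
exactly as the symbol is conventionally printed (a 1/(2n) chromosome-count
variant is available behind a flag, off by default). Distances come from
physical positions at 100 Mb = 1 Morgan. r^2 is the squared Pearson
correlation of unphased dosage vectors (composite LD) over individuals
non-missing at both SNPs, computed exactly with missing-aware matrix algebra
(pairwise counts and sums via products of the value and mask matrices), so no
pair subsampling is needed at supported panel scales.

Distance is mapped to time with the standard Sved/Hayes correspondence
t = 1/(2c): bins for t = 1..30 generations are centered at c = 1/(2t) with
edges at harmonic midpoints 1/(2(t±0.5)); the t = 1 edge is capped at 0.5
Morgans so the bins exactly partition (0, 0.5]. Pairs require
within-population MAF >= 0.05 (configurable; the threshold is an assumption,
not a published setting). Each bin is inverted to N_E; bins whose mean r^2
falls at or below the 1/n floor are flagged invalid and reported, never
clamped, interpolated or smoothed. Calendar years attach as
sampling_year - 3t (3-year dog generation interval); per-sample
collection-year heterogeneity is not modeled. The deepest default bin
(t = 30) therefore sits 90 years before sampling.

The worked closed-form quantity mu x generations x N_E (e.g.
1e-8 x 20 x 20000 = 0.004) is exposed as `expected_new_variation`; it shows
why new mutation is negligible on breed timescales, which in turn justifies
the simulator's no-mutation assumption.

## Wright-Fisher simulator

The generator emulates the features the analyses rely on:

- **Array-like frequency spectrum**: ancestral allele frequencies are drawn
  from Beta(0.8, 0.8) truncated to [MAF, 1-MAF] (default MAF 0.05),
  emulating common-variant ascertainment. No dog-vs-wolf ascertainment
  asymmetry is modeled.
- **Parental divergence**: dog and wolf pools descend from the shared
  spectrum and drift independently under Wright-Fisher reproduction with
  recombination; the closed-form drift expectation 1-(1-1/(2N))^t at the
  harmonic-mean size is recorded as truth for F_ST recovery checks.
- **Recombination**: per meiosis and chromosome, a Poisson(map length)
  crossover count with uniform positions and no interference — consistent
  with the fixed 1 cM/Mb assumption of the N_E module. No new mutations
  during breed history.
- **Breed founding and propagation**: dog founders are male and wolf
  founders female, so the first generation is truly hybrid; each later
  generation mates uniform dams to sires drawn with symmetric-Dirichlet
  popularity weights (concentration `popular_sire_weight`: values well below
  1 give a strong popular-sire effect), with wolves injected at scheduled
  generations. The full pedigree is recorded; F_ped comes from the standard
  recursive kinship (tabular) method, and per-generation realized Ne is
  reported both as the sex-ratio formula 4·Nm·Nf/(Nm+Nf) over actual breeders
  and as a Crow-Denniston offspring-variance-adjusted version.
- **Genotyping**: the final generation is sampled and masked with a uniform
  missingness rate; outputs round-trip exactly through the PLINK text codec.

Simulations are deterministic given a config (seed included), byte for byte.

### Shipped two-breed scenario

The default scenario builds four populations at the study's sample sizes
(46 + 20 + 12 + 20): a wolf pool; a GSH-like dog sample drawn from two lines
drifted apart for 12 generations at size 40 (closed stud books produce
line substructure, hence a Wahlund-type heterozygote deficit); a CSW-like
breed (4+4 founders, 21 generations at census 50, four single-wolf infusions
early in the history, neutral sire weights); and a SAW-like breed (a single
founder pair, 29 generations at census 30, three infusions, strong sire
concentration 0.25) — the qualitative histories of the two real breeds.
Panel scale is 10 chromosomes x 1,000 SNPs (100 kb spacing), chosen as a
desk-scale panel that still yields hundreds of ROH per population; the
parental split is 60 generations at size 120, giving a dog-wolf F_ST near
0.2. With 100 kb marker spacing the minimum 20-SNP run is ~2 Mb, so the
shortest ROH class is nearly empty in scenario output — a marker-density
artifact to keep in mind when comparing with dense-array results.

What passing scenario tests show — and what they do not: the contrasts
(higher F_ROH and more >16 Mbp ROH in the SAW-like breed; H_O >= H_E in
hybrids; H_O <= H_E in the line-structured dog pool) are directional
consequences of founder counts, sire reuse and infusions, robust across
seeds. They do not calibrate absolute magnitudes to any real breed: the
SAW-like breed here is more extreme than real Saarloos dogs because census
sizes and founder numbers are stylized, and real array data add
ascertainment asymmetries, uneven marker spacing, and collection-year
heterogeneity that the generator does not emulate.

## Numerical and scale choices

- N_E recovery runs at N = 100 with 50 sampled diploids, 10 x 2,000 SNPs and
  100 burn-in generations — long enough for LD at all probed distances
  (t <= 30, relaxation time ~1/(2c + 1/2N)) to equilibrate; the median over
  t in [5, 30] and 10 seeds is compared to truth within a factor of 1.5.
- Monomorphic SNPs and zero-variance pairs are excluded from r^2; bins with
  no qualifying pairs are reported empty rather than dropped.
- F_ST components are skipped per SNP when either population has no calls or
  the mean sample size is <= 1.
- Ties in minor-allele orientation (p = 0.5) keep the incoming orientation.
- All degenerate inputs (empty matrices, one-sample populations, unsorted
  maps, overlapping populations) raise typed errors rather than returning
  silent NaNs.

## Known limitations

- F_ST values are estimator-dependent at the third decimal; published tables
  computed with unspecified estimators may differ accordingly.
- The t = 1/(2c) time mapping is a heuristic correspondence; adjacent bins
  share drift history, so trajectory points are not independent.
- Admixture-generated LD contaminates drift LD in recently infused breeds;
  no correction is applied, so recent-generation N_E peaks after infusions
  are qualitative signals, not unbiased estimates.
- The simulator's even marker spacing and constant recombination rate remove
  map heterogeneity that affects real ROH length distributions.
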