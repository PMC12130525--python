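# Methods

`founder-tbd` implements the desk-scale analysis chain used to establish
that a rare disease allele is a population founder variant and that it
damages telomerase function: shared-haplotype delimitation among phased
carriers, rare in-cis marker distillation, control-panel screening,
pedigree co-segregation, direct-assay quantification, and age-adjusted
telomere-length percentiles.  Because the genotype panels such a study
runs on are access-controlled biobank data, every input is produced by a
simulator with known ground truth, and the package's guarantees are
phrased as parameter-recovery and containment properties against that
truth.

## Founder-population model

A diploid Wright–Fisher-style population of N individuals (2N
haplotypes) is seeded at generation 0 with exactly one copy of a founder
haplotype: the target variant plus a configurable number of rare marker
SNVs in cis (default 6, placed within a 500 kb span around the target —
the length scale of the shared block such studies report).  Each
offspring haplotype is a recombinant gamete of one random parent:
crossover count ~ Poisson(genetic length of the region), positions
i.i.d. uniform, no interference.  Under this model the one-sided genetic
length of founder material retained around the target after g meioses is
the minimum of g i.i.d. exponential crossover distances — exponential
with rate g, censored at the region edge — so the expected one-sided
length is (1 − e^(−gD))/g Morgans for edge distance D.  This closed form
is the oracle for the erosion tests.

Defaults: region 10 Mb, 400 evenly spaced biallelic sites, N = 200
diploids, g = 10 generations, recombination 10⁻⁸ Morgans/bp (≈1 cM/Mb),
at least 3 surviving target-allele copies.  The founder allele's true
age and the bottleneck demography are unknown for the population that
motivated the package, so g and N are free parameters, not fitted
quantities.

Design choices worth calling out:

* **Background linkage disequilibrium.** Background haplotypes are
  mosaics of a 20-haplotype founder panel with switch rate equal to the
  recombination rate.  This produces realistic incidental sharing so the
  identity-by-state vs identity-by-descent distinction is actually
  exercised; independent-site backgrounds would make the screening tests
  trivially easy.
* **Rare vs common annotation.** A 20-haplotype panel cannot represent
  sample frequencies below 5%, so background polymorphic sites carry
  common (≥1%) global-AF annotations while only the planted markers (and
  the target) carry rare ones.  The planted markers are therefore
  exactly the sites a rare-marker filter should recover, giving marker
  recovery a sharp truth.
* **Conditioning on allele survival** is by whole-run rejection (cap
  1,000 attempts, explicit failure beyond it), never by biased
  transmission, which would distort the neutral erosion law.
* **Descent tracking** is exact: each haplotype carries the list of bp
  intervals it inherited from the founder chromosome, spliced through
  every recombination, so the per-carrier descent interval around the
  target is available without approximation.
* **Determinism.** All randomness flows from one seeded
  `numpy.random.Generator`; identical seeds reproduce panels exactly.

What the simulator does not emulate: coalescent history, selection,
variable recombination maps, gene conversion, genotyping or sequencing
error, and population structure beyond the single founder event.
Passing tests therefore demonstrate correctness of the analysis
machinery under a clean neutral model, not robustness to real-data
artifacts such as phasing switch errors.

## Shared block and markers

Carrier haplotypes are the alt-bearing haplotypes at the target
(homozygotes contribute both; carriers whose target genotype is
unphased are dropped with a warning).  The block walks outward from the
target site: a site agrees when all carrier haplotypes with non-missing
calls match; the block runs to the outermost agreeing site before the
first disagreement on each side, and boundaries are reported as the
positions of those outermost agreeing sites (the convention that matches
reporting block ends at SNV coordinates).  Missing calls are
non-informative — conservative for block width.  This identity-by-state
block always contains the intersection of the carriers' true
identity-by-descent intervals, a containment asserted against simulator
truth on every run.

Markers are the block SNVs whose shared (founder) allele is the alt
allele with global MAF below the threshold (default 1%); sites without
an AF annotation are treated as common, failing safe against false rare
markers.  Indels never enter the marker set.  The pair of markers
nearest the target on each side are the flanks; a side without a marker
leaves the flank pair flagged undefined.

## Screens

The phased screen counts haplotypes carrying alt at every marker *and*
ref at the target — the founder marker string on a wild-type
chromosome.  The unphased screen classifies individuals lacking the
target alt: *full* (≥1 alt at every marker site), *partial* (both
flanks but not all markers), *none*.  Unphased "carrying all markers"
is genotype-level presence because cis cannot be verified without
phase.  Missing genotypes count as alt-absent, so missingness can only
undercount founder haplotypes.  Fold enrichment is the subpopulation AF
over the global AF, optionally rounded to significant figures.

## Segregation

Parental origin of a carrier child's variant is deduced by Mendelian
enumeration at the target; when both parents are heterozygous, all
pairings of target alleles with linked-microsatellite alleles and all
transmissions are enumerated (no recombination assumed between the
target and the linked locus), optionally constrained by the candidate
founder repeat count (a parent carrying both the variant and the founder
repeat is assumed to carry them in cis).  An origin is reported only
when every consistent configuration agrees; a child allele absent from
both parents is a named Mendelian error.

Co-segregation examines every informative meiosis (heterozygous parent,
genotyped child): the variant's transmission is compared with the
child's founder-marker content.  Microsatellite alleles match by exact
repeat count; a one-step mismatch is reported as a possible stepwise
mutation — the dominant STR error mode — rather than a failure.
Individuals of unknown carrier status are skipped, never imputed.  Zero
informative meioses yields an undefined (flagged) result, not a false.
Simulated families use four STR loci (a D5S1981 stand-in adjacent to the
target inside the block, three others across the region) mutating
stepwise at 10⁻³ per meiosis.

## Direct-assay quantification

Band intensities follow I(n) = A·c(n)·d(1−d)^(n−1): a geometric law in
the repeat number n with per-repeat dissociation probability d, under a
label-incorporation correction c(n) (default c(n) = n, labels
proportional to product length; configurable).  Fitting ln(I(n)/c(n))
against n gives slope ln(1−d); the default fit window excludes n = 1
(initiation artifacts) and requires ≥5 positive bands, and a
non-negative slope is rejected as not a dissociation signal.
Processivity is reported as 1/d̂ — the mean of the geometric law, i.e.
the average number of repeats added before dissociation; the decay
constant and the median product length (the other conventions in use)
are exposed on the same fit result.

Activity is total lane signal over the loading control, normalized to
recovered hTR, as a percent of the WT lane; assembly is
((IP hTR/WT)/(IP hTERT/WT))/(lysate hTR/WT) so plasmid-expression
differences cancel.  Replicate groups are compared as percent of the WT
mean with SEM and a two-sided Welch t-test (the robust default when no
test is named for n = 3 groups); two zero-variance groups get p = 1
(equal) or 0 (different) explicitly, since Welch is indeterminate
there.  The pipeline's default assay conditions put the simulated
variant at 0.67× WT processivity and 0.76× WT activity with 5%
multiplicative noise and n = 3 replicates, and the quantification
machinery recovers those reductions (≈33% and ≈24%) from the lanes.
Because total lane signal under c(n) = n scales as A/d, the simulated
variant's amplitude is compensated so its *measured* activity ratio is
the configured one.

## Telomere-length percentiles

The reference retains non-carrier controls (rare-variant carriers are
excluded so they cannot drag the reference down; exclusion only removes
records).  A case's percentile is the mid-rank of its measure among the
m controls within ±5 years of its age (minimum 20), clipped to
[100/(m+1), 100·m/(m+1)] so out-of-range cases are reported at the
resolution the window supports.  The windowed nonparametric convention
was chosen over regression residuals because it makes no distributional
assumption and has a testable calibration property: controls scored
against their own reference are uniform, checked by Kolmogorov–Smirnov.
The simulated reference declines linearly with age (default −0.02
units/yr, noise SD 0.5, ages 40–70); simulated carrier cases are shifted
−2 noise-SDs, for which the normal-tail oracle predicts ≈76% below the
10th percentile.

## Pipeline

`run_pipeline` composes the stages in dependency order with one seed
fanned out through `numpy.random.SeedSequence`; identical config and
seed give byte-identical report JSON (no timestamps are written).  Every
threshold that shapes a conclusion — MAF cutoff, fit window, age window,
percentile threshold — is logged into the report provenance together
with the seed, package version and a config hash.  A stage failure
aborts the run with the stage named; outputs of completed stages remain
on disk.

## Problem sizes

Default test and acceptance problem sizes — 100–300 sites, N = 60–200
diploids, g ≤ 20, 2,000-haplotype control panels, 600 erosion lineages,
200 noisy lanes, 10,000-control percentile references — were chosen so
the full suite completes in well under a minute while keeping
Monte-Carlo error comfortably inside the asserted tolerances (e.g. the
erosion mean's sampling error at 600 lineages is ≈4%, against a 10%
band).

## Known limitations

* The unphased "full" classification cannot distinguish in-cis from
  in-trans marker co-occurrence; with realistic rare-marker frequencies
  the in-trans probability is negligible, but it is a genotype-level
  statement.
* Marker-content scoring in co-segregation attributes marker presence in
  a child to the carrier parent; with a marker-carrying non-carrier
  spouse (not generated by the simulator, rare in practice) a meiosis
  could be mis-scored.
* The percentile reference assumes an age-stationary measurement scale;
  batch effects between cases and controls are not modeled.
* The erosion law is exact only for the no-interference Poisson
  crossover model; crossover interference would lengthen retained
  segments slightly.
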