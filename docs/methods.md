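# Methods

## The model

A closed breeding program produces `offspring_per_round` candidates per
round; the top `n_sires_selected` males by phenotype become the sires of
the next round and receive sequential registration (KPN) numbers, so KPN
orders animals by selection time. Because ancestry funnels through few
sires, the pedigree inbreeding coefficient F rises over rounds, recent
common ancestors leave long identical-by-descent (IBD) tracts, and those
tracts surface in genotype data as runs of homozygosity (ROH). The package
measures this process at three scales: genome-wide (F_roh, F_snp),
per 10 Mb bin (association with selection time and with body weight), and
per locus (EHH/iHS haplotype scans and shared-ROH overlap regions).

## Simulator

Haplotypes are breakpoint mosaics of founder-haplotype labels. Meiosis
draws a Poisson number of crossovers with mean equal to the chromosome map
length in Morgans (Haldane: no interference) at uniform physical positions;
the genetic map is linear per chromosome. There is no mutation: all
variation is standing founder variation, so an individual is autozygous at
a site exactly where its two haplotypes carry the same founder label, and
truth bookkeeping is exact. Founder allele frequencies are uniform on
[0.05, 0.5] per SNP; founder haplotype alleles are independent Bernoulli
draws, so founders carry no linkage disequilibrium — LD in descendants is
generated entirely by pedigree and drift.

Phenotype (12-month weight, kg) follows the infinitesimal model: a
founder's breeding value is N(0, h²σ²_P); an offspring receives the
parental mean plus Mendelian-sampling noise with variance
½σ²_A(1 − (F_s + F_d)/2); the residual is N(0, (1−h²)σ²_P) and a rearing
facility adds a N(0, σ_fac) shift shared by its animals. Defaults:
σ_P = 30 kg, h² = 0.3, mean 340 kg, σ_fac = 5 kg, three facilities —
values typical of yearling-weight evaluations in beef cattle. Body weight
has no built-in dependence on realized autozygosity, matching the weak
genome-wide F_roh–weight relationship the design emulates; bin-local
inbreeding depression is added explicitly in tests when an effect is
needed.

Two closed-form calibrations pin the machinery down: offspring of full-sib
matings have pedigree F = kinship(sire, dam) = 1/4 and mean realized IBD
fraction 1/4 (each replicate draws a fresh sib pair, since the expectation
conditional on one realized pair differs); and an autozygous tract tracing
to an ancestor g generations back ends at the crossovers of the 2g
separating meioses, so its length is exponential with mean 100/(2g) cM up
to truncation at chromosome ends (the calibration uses a 1000 cM
chromosome to keep truncation ≪ 10%).

The default cohort mirrors the emulated study: 21 rounds × 6 sires = 126
selected bulls plus 10 unselected animals bred by random founder mating;
the desk-scale genome is 3 chromosomes × 50 Mb / 50 cM. `impose_sweep`
converts a neutral panel into a hard-sweep panel by copying one donor
haplotype over a random subset of haplotypes inside a region until it
reaches the requested local frequency — an endpoint caricature of a sweep
(no partial recombination onto the swept background), which makes the
expected iHS signal conservative at the region edges.

What the simulator does **not** emulate: genotyping error and missingness
(exports are complete calls; the caller's missing-call allowance is
exercised with synthetic missingness in tests), founder LD, mutation,
overlapping generations, sex chromosomes and multi-trait selection
indices. Passing tests therefore demonstrate correctness of the inference
machinery under a clean pedigree process, not robustness to assay
artefacts.

## ROH calling

The caller is a transparent run-based detector rather than a hidden-Markov
smoother: within stretches where consecutive-SNP gaps stay ≤ `max_gap`
(500 kb), it finds maximal index windows containing at most `max_het` (0)
heterozygous and at most `max_missing` (2) missing calls, trims each
window to its first/last homozygous SNP, discards runs with fewer than
`min_snps` (20) homozygous SNPs and merges any overlap (possible only when
allowances are positive). A run-based caller has an exact brute-force
oracle — every call is checked segment-for-segment against an O(n²)
maximal-window enumerator — at the cost of diverging from HMM-smoothed
callers on borderline runs; results at the 500 kb autozygosity threshold
are insensitive to this on dense data, because true IBD tracts are long
and nearly uninterrupted. Segment coordinates are 1-based inclusive;
length = end − start + 1; F_roh divides by the summed autosome lengths
only. The threshold-profile grid is 0–2000 kb in 100 kb steps.

## SNP statistics

QC removes SNPs with missing rate > 0.05 or MAF < 0.01 (strict
inequalities, as are all filter boundaries in the package). LD pruning
slides 50-SNP windows in 5-SNP steps per chromosome; within a window,
offending pairs (r² > 0.5) are scanned left to right and the later SNP is
dropped — the tie rule is unspecified among common tools, and dropping the
higher index is deterministic and order-stable. F_snp uses cohort allele
frequencies with the n/(n−1) small-sample correction on expected
heterozygosity. The GRM is VanRaden method 1 with per-SNP mean imputation
of missing dosages and monomorphic SNPs excluded.

## REML mixed model

For y = Xβ + g + e with g ~ N(0, σ²_g G), e ~ N(0, σ²_e I), write
V = σ²_e(λG + I), λ = σ²_g/σ²_e. After eigendecomposition G = UDU′ the
restricted log-likelihood is a smooth scalar function of λ with σ²_e
profiled out in closed form; it is maximized by a coarse 49-point log-grid
followed by bounded Brent refinement (xatol 1e-10), with the λ = 0
boundary checked explicitly so iid phenotypes collapse exactly to ordinary
least squares. Wald tests use the GLS covariance at the optimum. Variance
components are well identified only when G has eigenvalue spread; the
recovery tests therefore use a full-sib-family GRM (300 animals, 60
families), where the median relative error at σ²_g = σ²_e is below 25%.

Analysis 1 (ROH status ~ KPN) uses a maximum-likelihood logit fit with
Wald p-values and McFadden pseudo-R² (the conventional fit statistic for
logistic models; reported explicitly as such). Constant-status bins and
bins with (effective) complete separation — detected by unbounded standard
errors — are flagged unconverged and excluded from summaries. Raw p < 0.01
defines significance with no multiple-testing correction, matching the
emulated workflow; a Benjamini–Hochberg adjustment can be applied to the
returned p-value columns by the caller. Unselected animals (no KPN) are
excluded from both analyses; facility enters Analysis 2 as an unordered
factor with first-level reference coding, and the dummy block is dropped
when only one level is present.

## EHH and iHS

EHH at offset x is the probability that two random carrier haplotypes of
the core allele are identical from the core to x (pair counting over
identity groups). iHH integrates EHH trapezoidally over physical distance
(no genetic map is assumed) outward until EHH < 0.05; the final trapezoid
down to the first sub-cutoff point is included. A core is undefined when a
gap > 200 kb is crossed or a chromosome edge is reached before the cutoff,
since a truncated integral would bias the score; cores with MAF < 0.01 or
fewer than two carriers of either allele are skipped. The score is
ln(iHH_derived/iHH_ancestral), antisymmetric under label swap. The
ancestral allele defaults to REF with a per-SNP override (the simulator
records truth). Standardization is z-scoring within 100 equal-width
derived-allele-frequency bins; bins with < 2 scores or zero spread are
flagged and passed through unstandardized. Window flagging uses
non-overlapping 100 kb windows, drops windows with < 10 scored SNPs, and
flags proportions ≥ the empirical 99th percentile — ties at the threshold
are included, so the flagged fraction can slightly exceed 1% (in a fully
null track every window ties at proportion 0 and the flag degenerates; the
proportion column disambiguates). A per-SNP mode (`top_snp_threshold`)
flags extreme individual |iHS| at the genome-wide top 1% instead.

## Overlap regions

"Complete overlap" is formalized as the maximal interval(s) attaining the
maximum distinct-sample coverage depth, computed by an endpoint sweep over
per-sample merged segments; each sample counts once per position, and ties
return every maximal interval. Regional curves are computed in 50 kb
windows per sample group: mean pairwise r² among window SNPs and
F = 1 − mean(observed het)/mean(expected het) with group allele
frequencies and the n/(n−1) correction; windows monomorphic within a group
are undefined rather than zero. The window size and the F definition are
deliberate design choices where the emulated figures leave the computation
unspecified.

## Pipeline and determinism

`run_pipeline` executes all stages from one config; every stage is a pure
function of (inputs, config, seed), and stage seeds are derived from the
run seed by hashing the stage name, so reproducibility does not depend on
stage order. The manifest records the seed and a SHA-256 parameter hash.
The demo configuration and the test suite use desk-scale problem sizes
(toy genomes of 1–3 chromosomes × 10–50 Mb, 20–136 samples, 10–100
SNPs/Mb, 200-track oracle comparisons, 1000-bin null calibrations,
10-seed sweep replicates), chosen so each stage's statistical check is
well powered while a full run stays in the minutes range on one core.

## Known limitations

- The run-based caller is not an HMM; with sparse SNPs or high genotyping
  error it will fragment runs that a smoothing caller would join.
- iHS integrates over physical distance; in regions where the local
  recombination rate departs strongly from the genome average, scores are
  comparable only through the frequency-bin standardization.
- The REML engine fits a single kinship; multiple variance components or
  leave-one-chromosome-out GRMs are out of scope.
- Logistic separation handling flags and drops bins rather than applying
  a penalized (Firth-type) fit.
- The per-bin ROH matrix attributes a boundary-spanning segment to both
  bins, so neighbouring bins are not independent tests.
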