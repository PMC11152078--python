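# Methods

`balsel` quantifies statistical power to detect balancing selection from
single-population genomic samples, by forward simulation of a balanced
mutation on evolutionarily realistic backgrounds and re-implementation
of the two standard intra-population signals: the site-frequency-
spectrum (SFS) composite likelihood ratio in the style of the B
statistics, and the linkage-based integrated haplotype score (iHS).

## Model

### Population and chromosome

A diploid Wright–Fisher population of ancestral size N = 10,000 evolves
in discrete, non-overlapping generations.  Two chromosome presets are
provided: a strictly neutral 50-kb region, and an 85,005-bp human-like
layout of three functional regions (9 exons of 1,317 bp alternating
with 8 introns of 1,520 bp, i.e. 24,013 bp per region) each followed by
a 4,322-bp intergenic block.  Default per-bp per-generation rates are
mu = 2.5e-8 and r = 1e-8; "variable-rate" maps draw each 1-kb block's
rate from a uniform distribution (mutation: 1.3e-8 – 3.4e-8; recombination:
0.124 – 4.930 cM/Mb).  The printed recombination bounds average ≈2.5
cM/Mb rather than the 1 cM/Mb fixed rate; the bounds are treated as
authoritative and the discrepancy left as-is.

### Selection

Exonic mutations (except every third site, a synonymous-site stand-in)
draw a fitness cost s from a four-class discrete DFE on the 2Ns scale
with bin edges (0, 1, 10, 100, 2N); within a class 2Ns is uniform; all
mutations are semidominant (h = 0.5); fitness is multiplicative across
loci, floored at zero.  The top bin is capped at s = 1 (lethal
homozygote), the natural ceiling for a fitness *reduction*.

The focal balanced mutation experiences negative frequency-dependent
selection, S_bp = f_eq − F_bp, recomputed once per generation from the
parental-generation frequency; het/hom fitness contributions are
1 + h·S_bp and 1 + S_bp.  It is introduced as a single copy at the
chromosome centre (25,000 neutral; 40,342 functional) after a
10N-generation burn-in from a mutation-free state, and replicates in
which it is lost before first reaching frequency 0.1 are restarted from
the saved post-burn-in state with a fresh RNG substream — conditioning
on establishment without rerunning the burn-in.  In the rare case that
the focal position carries a standing mutation after burn-in, that
mutation is removed before introduction.

Mutation is infinite-sites on discrete positions (draws landing on an
occupied or substituted position are redrawn); recombination places
Poisson-distributed crossovers at rate-weighted positions; fixed
mutations move to a substitution record with their fixation generation
(the SFS scan's k = n class) and thereafter contribute only to baseline
fitness.

### Demography and structure

Piecewise demography supports instantaneous size changes, splits
(daughters founded by resampling parental individuals), and backward
migration (an offspring in deme i draws both parents from deme j with
probability m_ij).  The neutral structure models are: panmixia; a
split into two demes of size N exchanging migrants at scaled rates
{0, 0.01, 0.05, 0.1, 0.2} for 10N generations with one deme sampled;
admixture — split, 5N generations of isolation (divergence), then 5N
generations of strong gene flow (0.25) before one deme is sampled
("populations that diverge before again merging"); and hidden
structure (split, isolation for 5N, 50 chromosomes sampled from each
deme).  Scaled migration values follow the 4Nm convention
(per-generation probability m = value/4N).

### Rescaling

Desk-scale runs rescale by an integer Q: N → N/Q, mu → Q·mu, r → Q·r,
fixed s → Q·s, times/Q, migration off-diagonals ×Q — preserving 4Nmu,
4Nr, 2Ns, Nm, and times in units of N.  The frequency-dependent S_bp is
*not* multiplied by Q: it is already O(0.5), and Q-scaling it would
make the discrete-time frequency map unstable (|1 − h·Q·F(1−F)| > 1
near equilibrium for Q ≳ 8).  The knowing consequence: the sweep phase
lasts ~ln(2N)/(h·S) generations at *any* scale, so in rescaled time the
sweep occupies a larger fraction of N generations than at full scale.
Two mitigations are built in:

- **Frequency-triggered sampling.**  "Immediately after the sweep
  phase" (τ_b = 0.01N at full scale) is represented by sampling at the
  first generation the balanced allele reaches f_eq — the
  scale-invariant definition of that time point.
- **Scenario-matched Q.**  Sweep-phase scenarios run at Q = 20
  (N = 500), where the residual distortion of haplotype lengths
  (r·T_sweep larger than at full scale) is moderate; the 75N-horizon
  SFS-scan grid runs at Q = 50 (N = 200); neutral structure models at
  Q = 80 (N = 125).  Measured young-allele iHS power rises toward full
  scale (TPR at 5% FPR ≈ 0.63/0.69/0.83 at Q = 50/25/10 in pilots), so
  desk-scale absolute LD power is an *underestimate*.

## Detection statistics

### B2-style composite likelihood ratio

The scan's informative sites are all sample-polymorphic SNPs (derived
counts k = 1..n−1) and substitutions (k = n).  The background spectrum
g(k) pools counts over all replicates of a cohort, with a pseudocount
of 1 per class.  At a test position, a site at distance d contributes a
mixture α·h_β(k) + (1−α)·g(k) with α = exp(−d/A) and h_β a binomial
centred on candidate equilibrium frequency β (renormalised over
k = 1..n); CLR = 2·max over β ∈ {0.05..0.95} and A ∈ log-spaced
{1e2..1e6} bp plus a degenerate no-signal point (so CLR ≥ 0).  The
likelihood's exact functional form in the reference implementation is
not published; this reconstruction follows the published verbal
description, so absolute CLR values are not comparable across
implementations — only rank/ROC behaviour is, and that is all the
pipeline consumes.

### EHH and iHS

EHH at a target SNP is the probability that two random carriers of the
core allele are identical at every SNP between core and target,
computed by partition refinement; curves stop below EHH = 0.05 or at
the region edge (truncated curves are kept; the last, below-cutoff
point is included in the integral).  iHH is the trapezoidal integral
over physical position; the unstandardised score is ln(iHH_A/iHH_D);
scores are standardised within derived-frequency bins of width 0.02
(bins with < 20 scores merged into their smaller adjacent neighbour,
ties left), and the detection score is |standardised iHS|.  No
minor-allele-frequency filter is applied; any SNP with ≥ 2 carriers of
each allele is scored.

**Standardisation reference.**  Genome-wide standardisation presumes a
mostly-neutral reference.  A single 50-kb replicate sampled just after
a sweep is *entirely* swept — its mid-frequency SNPs are all extreme —
so standardising a sweep cohort against itself cancels the signal
(measured: focal-window TPR = 0).  iHS cohorts are therefore
standardised against bin statistics fit on matched neutral samples
(the paired pre-introduction samples of the same replicates).

## Power evaluation

The region is tiled by 100-bp nonoverlapping windows scored by their
maximum per-SNP score.  A replicate's true window is the one containing
a scored SNP within 50 bp of the balanced site (the qualifying SNP
closest to the site; replicates without such a SNP stay in the TPR
denominator).  TPR(t) is the fraction of replicates whose true window
reaches threshold t.

Two FPR references are used, per signal geometry:

- **B2 cohorts:** FPR pools the non-true windows of the same
  replicates (the CLR signal is localised by α(d), so distant windows
  are signal-free).
- **iHS cohorts:** FPR pools all windows of the matched neutral
  samples.  Post-sweep, the swept haplotype spans the entire region
  (EHH breakdown scale 1/(r·T_sweep) ≫ 50 kb at any scale), so
  within-replicate windows carry no contrast and a null reference is
  the only evaluable protocol.

Null/structure scenarios have no true windows; their output is the FPR
at 100 evenly spaced thresholds after min–max normalisation of the
pooled window scores.  When structure models are *compared*, the scans
emulate an analyst whose baseline is panmictic: the B2 background
spectrum and iHS bin statistics come from the panmictic cohort
(self-calibrating each structured model would absorb exactly the
confounding being quantified — a hidden-structure background spectrum
contains the intermediate-frequency excess, so h_β/g ≈ 1 everywhere).
Each model's curve is normalised against its own score range, as in
the source protocol; this separates *pervasive* confounding (hidden
structure, admixture — every replicate carries intermediate-frequency
divergent blocks, so much of the score mass sits near the scenario
maximum) from *sporadic* tail inflation (two-deme gene flow — rare
replicates carry a deep migrant block whose extreme score stretches
the normalisation axis, flattening the curve).  The raw pooled window
scores are kept alongside, so the miscalibration FPR (a model's FPR at
the panmictic null's nominal-5% threshold) can also be read off; note
that by that raw-threshold metric sporadic gene-flow blocks do inflate
the tail even though the normalised curve shows no excess.

## Establishment experiments

On a strictly neutral background the focal-allele trajectory is an
unlinked frequency process, simulated exactly as a marginal chain
(deterministic semidominant selection update followed by binomial
sampling of 2N gametes) — this makes 10^5 replicates desk-scale and is
validated against the neutral martingale identity P = p0/q and the
Kimura diffusion probability (1 − e^(−4Nhs·p0))/(1 − e^(−4Nhs·q)).
With a DFE the full engine is used, amortising one burn-in over batches
of introductions.  The reported absolute escape proportions in the
source study (≈0.096 at 2Ns = 100) exceed the single-copy diffusion
expectation (≈0.005) roughly twenty-fold and cannot be recovered from
the stated single-copy protocol with any copy number consistent across
selection strengths; the package exposes `intro_copies` as a knob and
asserts only the qualitative effects (deleterious backgrounds suppress
establishment severalfold, most strongly under a strong-deleterious
excess).

## What the generator does and does not emulate

The simulator reproduces the study conditions: WF reproduction with
multiplicative fitness, the stated layouts/rates/DFE bins, NFDS with
establishment conditioning, the sampling grid in units of N, and the
structure models.  It does not model overlapping generations, gene
conversion, sex chromosomes, hotspot-scale recombination maps, or real
gene annotations, and desk-scale runs inherit the rescaling caveats
above — so passing tests demonstrate the statistical behaviour of the
methods under the modelled conditions, not performance on real data.

## Numerical and protocol choices

- π and Watterson's θ are reported per site; undefined statistics
  (Tajima's D and D′ with no/one SNP) propagate as NaN, never 0.
- D′ is averaged as mean |D′| over all biallelic pairs, no MAF filter.
- TPR-at-FPR uses conservative step interpolation: the TPR at the
  smallest threshold whose FPR does not exceed the level.
- Sample-fixed sites (derived in all n sampled chromosomes) are folded
  into the substitution record — indistinguishable from fixed
  differences in a sample.
- Within-batch establishment trials and replicate streams derive from a
  single master seed through `numpy` SeedSequence spawning; identical
  seeds give byte-identical outputs.
- Scan grids, EHH cutoff, window and truth-radius sizes, and bin widths
  are configurable; defaults are stated above.

## Desk-scale problem sizes

Tests and the acceptance script run: temporal SFS grid 32 replicates at
Q = 50; young-allele and partial-sweep sets 28–32 replicates at Q = 20;
structure models 20–28 replicates at Q = 80; establishment 10^5
marginal-chain replicates and 3,000–4,000 full-engine replicates.
Monte-Carlo standard errors at these sizes are ~0.07 on a TPR; the
qualitative orderings (temporal ordering of the two methods,
structure-driven miscalibration) are the robust outputs.

## Known limitations

- Absolute CLR and iHS magnitudes are implementation-specific; compare
  ranks/ROCs only.
- Desk-scale young-allele LD power underestimates full scale (above).
- Two full-scale magnitudes are out of desk-scale reach and their
  checks are expected to fail as written: the ~10-fold suppression of
  establishment by a deleterious background (the interference needs
  thousands of generations of a weakly selected beneficial allele;
  under rescaling it establishes in tens of generations, leaving a
  measured suppression of only ~20% at Q = 20 — though the suppression
  itself is statistically unambiguous), and the AUC ≈ 0.5
  indistinguishability of young balanced alleles from partial sweeps
  (a saturation phenomenon: at full scale both processes leave a
  near-intact 50-kb haplotype because r·L·T_sweep ≪ 1, a regime
  rescaling leaves because sweep durations scale as ln(2N)/s rather
  than with N).
- The 10N burn-in from an empty state leaves the oldest (highest-
  frequency) SFS classes a few percent below stationarity, as in any
  from-scratch forward simulation of this length.
- Published three-population human demographic models are supported
  through the generic piecewise-demography configuration, not as
  named presets with hard-coded parameters.
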