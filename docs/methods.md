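# Methods

## The pooled-dilution model

Pooling N diploid DNAs into one sequencing library dilutes each chromosome
to a 1/(2N) share of the reads. A site carrying `c` mutant alleles in the
pool therefore has expected alt fraction `f(c, N) = c/(2N)`; with symmetric
per-base substitution error `ε`, the probability a read shows the alt
allele is `q(c) = f(1−ε) + (1−f)ε`, and the alt count at depth D is
`Binomial(D, q)`. Everything in the toolkit — the caller's test, the
carrier-count estimator, the power calculations, the simulator — is built
on this one model.

The simulator adds two realism terms:

* **Equimolarity bias.** Each pooled sample contributes a lognormal DNA
  weight (sigma `equimolar_bias_sigma`, default 0.20) renormalized to sum
  to 1, shared by all sites of that pool. This emulates samples being over-
  or under-represented despite equimolar pooling, and is the mechanism that
  spreads observed het relative coverages across the empirical band
  [0.56, 1.54]/32 rather than exactly 1/32. The default sigma was chosen so
  simulated single-carrier sites fall in that band with comfortably more
  than 90% probability, matching how validated hets behaved in practice.
* **Depth dispersion.** Per-amplicon depth is lognormal (sigma 0.35) around
  the pool mean. Under the default `per_sample_times_N` rule the pool mean
  is 196·N: the reported per-sample depth of 196X is read as the
  per-individual-equivalent contribution, because a 196X *total* pool depth
  would put a 1/32 allele at ~6 expected reads against a 30X callable
  floor, which is irreconcilable with full control redetection. A
  `fixed_pool_depth` rule is provided for the alternative reading.

The error rate default (0.002 to a specific alt base) is a stand-in for an
uncharacterized platform error profile; it is exposed in `NoiseModel` and
`CallerParams` and should be recalibrated per chemistry. Indels are treated
identically to SNVs on alt-supporting counts; no realignment, strand-bias,
homopolymer or GC effects are modeled. Consequently, passing tests
demonstrate correctness of the statistical machinery under this model, not
robustness to alignment artifacts in real amplicon data.

## Calling and carrier-count estimation

`test_site` is the one-sided exact binomial tail `P(X ≥ alt | D, ε)`. When
the tail underflows double precision (~1e−300) it is recomputed as a
log-space sum of pmf terms (2000 terms past the observation, far beyond
convergence at the error rates involved), so p-values remain ordered at any
depth. A PASS call requires depth ≥ 30 (the per-pool callable floor),
alt reads ≥ 3 (singleton-error guard at extreme depth) and
p ≤ α (default 1e−5 per site; with ~10⁶ targeted bases that bounds expected
panel-wide false positives below ten per pool; optional Bonferroni over
targeted bases is available). The defaults are the analogous knobs of a
"somatic-mode" caller tuned for 1-in-32 alleles.

`estimate_carrier_count` maximizes the binomial likelihood over the integer
lattice c = 0..2N rather than rounding `2N·alt/D` to the nearest integer:
the observed practice places the 1-vs-2-allele boundary asymmetrically
(hets were accepted up to 1.54/32, two-allele calls down from 1.5/32, with
1.75–2.0/32 treated as suspicious for a second allele), which a naive 1.5
cut cannot express. Ties break toward smaller c — fewer carriers is the
conservative claim. The empirical concordance bands remain a separate QC
layer (`ConcordanceBands`); an out-of-band call carries the
`sequence_whole_pool` follow-up action rather than a changed estimate,
because over-representation bias, not extra carriers, is the common cause.

`detection_power` is exact at fixed depth (critical value from the null
tail, power from the alternative tail) and seeded Monte Carlo over the
depth distribution otherwise. `design_pool_size` sweeps N up to
min(max_pool, HRM batch limit) and recommends the largest N meeting the
target single-allele power; at the default depth rule this returns N = 16,
the reference design, where the binding constraint is the 16-sample melt
plate rather than power.

The cost model follows the spec'd decomposition: one library serves N
patients in the pooled arm (`sequencing_fold = N` by construction) and the
overall fold adds per-patient genotyping assays and fixed costs to the
pooled arm. Published fold-reductions depend on unpublished prices; the
defaults are placeholders and `poolrare cost` reads real prices from YAML.

## Deconvolution

HRM physics is not modeled. The melt assay is a Bernoulli flag channel per
pool member (sensitivity/specificity, both defaulting to 1.0 as observed in
practice), with zygosity taken from the Sanger-confirmation stand-in (the
simulation truth) for flagged samples — mirroring the real workflow where
every melt-positive sample is Sanger sequenced, so a false flag resolves
back to reference. Assay windows are 250–330 bp, centered on the variant
and shifted (never shrunk) at gene boundaries; batches carry at most 7
variants per run and 16 samples × 3 replicates per plate. How a melt curve
would distinguish a hom-alt from wild-type homoduplexes is deliberately not
modeled; the channel abstracts over it.

`resolve_and_check` accepts an assignment when its allele total matches the
ML carrier count or the relative coverage is consistent with the assigned
total; otherwise the whole pool is "re-sequenced" (truth re-read), which
both corrects the assignment and conserves the pool's true allele sum.

## Prioritization

Retention requires a criterion tier (previously reported pathogenic; novel
LOF; novel splice; reported missense with in-silico support; novel missense
with ≥ k damaging verdicts, k = 5 since exactly five predictors are
consumed) *and* the population filters: dominant genes need gnomAD
MAF < 0.001 and absence from the national variant server; recessive genes
need MAF < 0.003 and no homozygous observation there. Missing MAF means
absent from the database and is treated as 0.

Case resolution applies the allele quota per gene: recessive ≥ 2 alleles
(hom or compound het), dominant ≥ 1 with segregation confirmed, X-linked
male ≥ 1 hemizygous. Segregation "no" caps at VUS; compound hets with
unavailable segregation are provisionally SOLVED with rationale
`phase_unconfirmed` (families with untestable relatives are still counted
as characterized); a dominant allele without confirmed segregation is VUS.
Cross-gene (digenic) pairs are disabled by default and, when whitelisted,
yield at most VUS. Verdicts are invariant to variant order: all genes are
evaluated and the best verdict is returned deterministically.

The encoded reference cohort (`table1.py`) resolves to exactly 36 SOLVED of
115 (31.3%) with RP148/RP181/RP92 as VUS. Two encoding decisions are worth
restating: the family styled uncertain in the variant table but listed
among characterized patients (RP200) is counted SOLVED, and the published
49-causative/14-novel headline counts are stored verbatim because the
row-level recount (47 distinct causative, 16 novel) shows the published
figures follow a different counting convention; `novel_fraction` supports
both routes.

## MLPA

Dosage quotient: test heights are normalized to the mean of the test
sample's control probes, then divided by the median of the same ratio
across reference samples — median for robustness to one aberrant
reference. DQ thresholds 0.65/1.35 follow common MLPA practice (the
original analysis software's cutoffs are not published) and are
configurable. Isolated single-probe aberrations are reported but flagged
low-confidence; contiguous equal-status exons merge into inclusive spans,
so a heterozygous deletion of five consecutive probes reports as one
"exons 9–13" span. Synthetic tables with 5% CV multiplicative noise are
recovered as exactly one correct span in ≥ 99% of 1000 trials.

## Problem sizes, determinism, degenerate inputs

The test suite and acceptance script use scaled-down panels (24 genes × 6
amplicons rather than 316 × ~23) — the dilution statistics depend on depth,
N and ε, not on panel size, so scale only affects runtime. Simulation-based
checks use 50–10,000 replicates as noted per test. All randomness flows
through one integer seed; sub-streams are derived by hashing pool/site/
sample identifiers into the seed sequence, so evaluation order can never
change results and any child seed stays below 2³¹. Degenerate inputs are
explicit errors: zero depth for relative coverage, empty coverage lists,
inverted thresholds, mixed-pool count lists, windows that cannot fit a
gene span. Raw per-pool variant yields (thousands per pool) and sub-3.4%
low-coverage fractions from the real panel depend on human polymorphism
rates and the actual 316-gene design; the synthetic cohort does not attempt
to match them, and the coverage QC comparison in the tests is a calibration
note, not a claim.
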