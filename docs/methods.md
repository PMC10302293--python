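# Methods

`cherrypop` implements the statistical core of a haplotype-based
phylogeography study: from aligned sequences and population metadata to
haplotype networks, diversity and neutrality statistics, hierarchical AMOVA,
mismatch-distribution expansion tests, and ABC-based comparison of
demographic scenarios. This note records the models, the defaults and why,
the numerical choices, and what the synthetic data generator does and does
not emulate.

## Data model and indel handling

The root object is an aligned character matrix over `{A,C,G,T,-,N}` with one
row per sample and a deme → subgroup → group hierarchy attached. Gaps are
recoded before analysis, in one of two modes:

* **simple indel coding** — every distinct maximal gap run `(start, end)`
  becomes one binary presence/absence character. A row scores `1` if it
  carries exactly that run, `0` if it has no gap over the span, and missing
  if its own longer gap subsumes the span (the shorter event is then
  unobservable). This is the standard conservative treatment of indels as
  single mutation events; the binary characters participate in haplotype
  collapsing, raw-difference distances and the polymorphic-site counts
  ("indels as substitutions"), but not in the TN93 correction, which is
  defined on nucleotides.
* **drop gapped columns** — delete every column containing `-`.

Haplotypes are distinct rows after recoding; under the `match_ignoring_N`
policy a row with missing data merges into an existing haplotype only when
exactly one is compatible, otherwise it stays distinct (merging an ambiguous
row would be arbitrary). Default is `strict`, appropriate for data where
low-quality sequences were already removed. Coordinates are 0-based
half-open internally and 1-based in reports.

## Distances

Raw pairwise differences count all recoded characters, skipping missing
states pairwise. The Tamura–Nei (1993) distance uses the closed form with
empirical base frequencies pooled over the whole haplotype set (count
weighted), the two transition proportions P1 (A↔G) and P2 (C↔T), and the
transversion proportion Q. Pooling is the default because per-pair
frequencies are unstable on short fragments; a per-pair option exists.
Saturated pairs (any log argument ≤ 0) are flagged and assigned the largest
finite distance in the matrix, so downstream variance decompositions stay
finite; a zero base-class frequency (e.g. no pyrimidines at all) makes the
correction undefined and triggers a per-site p-distance fallback with a
warning.

## Diversity and neutrality statistics

Gene diversity `h = n(1 − Σp_i²)/(n−1)` with Nei's (1987) sampling variance;
nucleotide diversity is the mean pairwise difference per character, with the
usual total (sampling + evolutionary) variance, matching the ± values
population-genetics packages print. Tajima's D uses the standard constants;
Fu's Fs is the log-odds `ln(S′/(1−S′))` with `S′ = Pr(K ≥ k_obs)` under the
Ewens sampling distribution at θ equal to the mean pairwise difference.
Unsigned Stirling numbers of the first kind are built by the exact integer
recurrence and converted to logs (with a bit-shift guard above the float
range), and both tails are computed by log-sum-exp, so Fs is stable at any
sample size used here.

P-values for D and Fs come from simulating neutral constant-size coalescent
genealogies at the observed n, conditioned on the observed number of
segregating sites: S mutations are placed multinomially on branches in
proportion to branch length. The default report is one-sided (lower tail),
since the hypothesis of interest is expansion (negative statistics); a
two-sided option exists. Defaults: 1000 simulations, explicit seed.

## Mismatch distributions

The observed mismatch distribution is the frequency vector of pairwise raw
differences over all individual pairs (expanded from haplotype counts). The
sudden-expansion expectation (Rogers & Harpending 1992) for a population
jumping from θ0 to θ1 at mutational time τ before present is

    F_j = F_j(θ1) + e^{−τ(θ1+1)/θ1} Σ_{i≤j} τ^{j−i}/(j−i)! [F_i(θ0) − F_i(θ1)],

with `F_j(θ) = θ^j/(θ+1)^{j+1}`; the implementation was checked against an
independent two-lineage coalescent simulation of the same model.
Parameters are fitted by least squares (the SSD objective) over the observed
classes extended five classes past the observed maximum, with Nelder–Mead
from a moments-informed start and four further deterministic starts on
failure; θ1 is capped at 9999 (the conventional "infinite" post-expansion
size) and θ0 ≤ θ1 is enforced by parameterizing θ1 = θ0 + Δ, Δ ≥ 0.
Harpending's raggedness is computed with zero padding at both ends of the
observed vector, so a point mass at class 0 scores r = 2.

Significance is by parametric bootstrap: coalescent samples of the same size
are simulated under the fitted (τ, θ0, θ1) — time measured in mutational
units, in which a lineage pair coalesces at rate 1/θ(t) and each lineage
mutates at rate 1/2 — each replicate is refitted over its own support
exactly as the observed data was, and `p = Pr(statistic* ≥ statistic_obs)`.
The package default is 5000 replicates; the test suite and the acceptance
script use 25–200 replicates per analysis, which is ample for the
calibration and power properties they assert. Bootstrap-at-fitted-parameters
is only approximately calibrated (a well-known second-order effect); the
test suite verifies approximate uniformity of P_SSD by KS test.

## AMOVA and Φ-statistics

Three-level AMOVA (among groups / among demes within groups / within demes)
in the squared-distance framework, with unequal-sample-size coefficients,
yielding Φ-type fixation indices F_CT, F_SC, F_ST. Distance-based Φ is used
throughout (rather than allele-frequency F-statistics) because the distances
fed in may be model-corrected (TN93). Negative variance components are
reported as computed (truncation is an option; percentages always use the
untruncated values). Permutation schemes: individuals among all demes
(F_ST), individuals among demes within groups (F_SC), whole demes among
groups (F_CT); p = (b+1)/(n_perm+1), default 1000 permutations. Pairwise
Φ_ST is the two-level special case with individuals permuted between the
pair; an identity-based (frequency) variant is available. Note the exact
behavior at the no-differentiation boundary: for two demes with literally
identical compositions the estimator sits at −1/(n_c−1), a small negative
value, not zero — this is the standard unbiased-estimator floor.

## Median-joining networks

The network construction follows Bandelt, Forster & Röhl (1999): build the
ε-relaxed minimum spanning network over the current node set (a pair is
linked when its distance does not exceed its MST bottleneck distance plus
ε), collect quasi-medians of triplets that share feasible links (majority
state per character; three-way ties spawn every resolution, capped at 64
combinations per triplet), and admit the cheapest batch (connection cost ≤
λ_min + ε) only when it strictly shortens the pruned network. Unsampled
nodes of degree ≤ 2 are pruned (by the triangle inequality of Hamming
distance a degree-2 intermediate cannot shorten a path). The procedure is a
monotone length descent, hence terminates, and all tie-breaking is
lexicographic, hence the output is deterministic without any seed. ε
defaults to 0.

Adding medians can only shorten the network relative to the MSN over
observed haplotypes; on recombination-free infinite-sites data the result is
a tree whose total length also stays within the MST length (verified on
simulations). For general homoplastic data the MSN itself may exceed the
MST length (reticulations), so no MST bound is claimed there.

Lineage delimitation in the source workflow used model-based clustering; the
package offers only a clearly-labelled utility (connected components after
cutting edges above a weight threshold), which is not a substitute for such
clustering.

## The structured-coalescent generator

Backward-time structured coalescent: within a deme of size N carrying k
lineages, coalescence at rate k(k−1)/2 / (2N) per generation; events (in
years, converted via the generation time, default 4 years — a conservative
field estimate for these perennials) are population merges, size changes and
admixture pulses (each lineage of the recipient moves to the donor with the
pulse probability); optional continuous migration at per-lineage rates.
Scenario validation requires every sampled deme to reach a single root
through merges or migration. Mutations are Poisson on branches; infinite
sites (fresh column per mutation, random ancestral and derived bases) is the
default, with a finite-sites Jukes–Cantor alternative. All randomness flows
from one seed; truth records (scenario, drawn parameters, seed) allow exact
replay.

The generator emulates: multi-deme haplotype sequence data with divergence
events at two epochs, optional admixture/gene flow, a uniform mutation-rate
prior on [1e-4, 1e-3] per locus per generation for ABC, and group sample
sizes in the tens-to-hundreds. It does **not** emulate: recombination,
selection, sequencing error, double peaks/ambiguous base calls, missing
data, or the geographic sampling structure of real collections — so passing
tests demonstrate correctness of the statistical machinery under the stated
models, not robustness to those real-data complications.

A paired two-marker simulation (`simulate_two_locus_dataset`) emulates the
usual nuclear + chloroplast design: both loci share one demographic history
and drawn parameters but have independent genealogies, with the organellar
locus uniparental, non-recombining and at half the nuclear effective size in
every deme. The default everywhere else is a single locus.

Fixture presets: `five_group` (CC/WC/RC/EC/MC with three deep lineages;
deepest split 3.52 Ma, European split set at half that depth to keep the
epochs strictly ordered; per-locus mutation rate 1e-5 per generation, the
magnitude appropriate for ribosomal spacer sequence at Ma scales — the
microsatellite-scale ABC prior would saturate a 710-bp locus at these
depths), `three_group` (domestication-style: WC out of RC at 34,200 years
with a later gene-flow pulse, CC out of WC at 2,660 years ≡ 665 generations;
rate 3e-4, within the ABC prior), and `toy` (two demes, small n, for fast
tests). Default 60 samples per group, present sizes following the magnitudes
reported for such systems (cultivated bottleneck ~1.5k; wild pools 37–38k).

## ABC model choice

Reference tables draw parameters from each scenario's priors and record a
fixed summary vector: per deme the haplotype count, gene diversity,
per-site diversity, segregating sites and mean pairwise differences; per
deme pair Φ_ST and mean between-deme differences. Zero-variance statistics
and statistics that exactly duplicate an earlier one (per-site diversity is
a fixed rescaling of mean pairwise differences at one locus length) are
dropped and recorded. Statistics are z-normalized; the closest `retain`
fraction (default 1%) by Euclidean distance is kept; a multinomial logistic
regression of the scenario label on the statistics centered at the observed
point gives posterior probabilities at that point, with delta-method 95%
CIs from the intercept block of the asymptotic covariance. Singular or
non-convergent fits fall back to rejection proportions with binomial CIs
(flagged in the result). Parameter posteriors use local-linear regression
adjustment of the retained draws (skipped below 50 retained rows), reported
as median and 2.5/97.5 percentiles. Confusion error rates classify
pseudo-observed datasets simulated from each scenario's prior: type I for a
scenario is the fraction of its own pods not assigned to it; type II is the
mean rate at which other scenarios' pods are assigned to it.

Reference-table size is a knob: the package's analysis scripts and tests use
4,000–10,000 rows per scenario and 15–20 pods per scenario, sizes at which
the three-scenario system's recovery and error rates are stable; the
procedure is unchanged at any scale.

## Pipeline

`cherrypop run --config cfg.toml` executes ingestion → recoding →
haplotypes → distances → diversity/neutrality/mismatch tables → AMOVA →
pairwise Φ_ST → network export → optional ABC, writing a manifest with the
package version and every stage seed. A single master seed is fanned out to
stages through named `SeedSequence` children, so stages can be rerun in
isolation and the whole bundle is byte-reproducible; timings go to a
separate log so numeric outputs stay identical across reruns. Table numbers
are printed at 4 decimals.

## Known limitations

* Φ_ST p-values permute haplotype labels of individuals, which is exact for
  haploid data but not a genotypic permutation scheme (diploid AMOVA is out
  of scope).
* The sudden-expansion model is demographic only; the spatial-expansion
  variant is not implemented.
* The ABC CIs are asymptotic (logistic regression); bootstrap CIs are not
  offered.
* Median-joining on highly homoplastic data can produce dense quasi-median
  sets; the per-triplet resolution cap (64) bounds the blow-up but very
  messy inputs are better pre-partitioned.
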