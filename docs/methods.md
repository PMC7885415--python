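# Methods

This note documents the statistical models implemented in `haplopop`,
the numerical choices behind them, what the synthetic-data generator
does and does not emulate, and known limitations.

## Haplotype calling

Haplotype identity is exact string equality over the full marker window
(COI 657 bp, COII 518 bp), with no mismatch tolerance and no
reverse-complement search: a window-length, gap-free, unambiguous
sequence either equals a reference haplotype byte for byte or is novel.
This strictness is deliberate — equating sequences of different lengths
or with ambiguous calls can silently merge distinct haplotypes, so QC
rejects any sequence that is short for the window or contains a
character outside A/C/G/T (IUPAC codes and gaps count as ambiguous), and
reference entries violating those rules are excluded from the catalog
with a logged warning rather than matched approximately.

Novel names (`N<i>` for COI, `n<i>` for COII) are minted in
first-encounter order of the input file. The numbering therefore depends
on input order; what is order-invariant — and what the tests pin — is
the induced partition of individuals into shared-haplotype groups. The
novel counter starts past the largest novel index present among the
reference names so a published series can be continued, and can be set
explicitly. Combined haplotypes are the concatenation of the two
per-locus names and exist only for individuals called at both loci;
individuals with a single locus are recorded, not errors.

## Diversity and neutrality

* **Haplotype diversity** uses the unbiased estimator
  `Hd = n(1 − Σ p̂ᵢ²)/(n − 1)`, equivalently the probability that two
  individuals drawn without replacement carry different haplotypes.
  `n = 1` is undefined and reported NA.
* **Nucleotide diversity** is the mean pairwise difference count over
  all C(n, 2) individual pairs divided by the window length `L`
  (1175 bp for combined haplotypes), with no multiple-hit correction —
  appropriate at the within-species divergences involved (π ≲ 0.01).
* **Fu's Fs** uses `θ̂π = π·L` (the mean number of pairwise
  differences) as its θ plug-in and evaluates
  `S′ = Pr(K ≥ k_obs | θ)` under the Ewens sampling formula. Unsigned
  Stirling numbers of the first kind are computed exactly as arbitrary-
  precision integers by the standard recurrence (rows cached; supported
  up to n = 2000, far beyond any realistic sample); the Ewens terms are
  combined in log space. Rather than forming `1 − S′` by subtraction —
  which destroys precision exactly in the interesting regime where S′
  approaches 1 — Fs is computed as the difference of the two
  log-partial-sums (k ≥ k_obs vs k < k_obs), so values like Fs ≈ 10³
  remain finite and accurate. Conventions: monomorphic samples
  (k_obs ≤ 1 or θ = 0) report Fs = 0, matching how such rows are
  conventionally printed; a `+inf` sentinel is reserved for the
  (numerically unreachable with the log-space route) case of a zero
  complement with k_obs > 1. No p-values are attached to Fs: the
  coalescent simulation conventionally used for its significance is out
  of scope here.
* Report precision: Hd and Fs to 3 decimals, π to 5.

The test-suite oracle for `S′` is a Chinese-restaurant-process
simulation: the number of occupied tables after n seats is the sum of
independent Bernoulli(θ/(θ+i)) indicators, i = 0..n−1, which is the
exact CRP marginal for K and is simulated directly (≥10⁵ replicates per
grid point, 3-standard-error agreement), independent of the Stirling
route it checks.

## AMOVA and Φ_ST

The one-level AMOVA follows Excoffier's variance decomposition with
squared inter-individual distance taken as the pairwise nucleotide
difference count between haplotypes (the usual convention for haplotype
data, where the difference count *is* the squared Euclidean distance);
a 0/1 haplotype-identity metric is available as an option since the
frequency-based and distance-based variants answer slightly different
questions. Negative variance components are reported as computed;
Φ_ST is 0 by convention when total variance is zero, and negative
pairwise estimates are retained in the Φ_ST matrix (they are clamped to
zero only when the matrix is handed to the PCoA embedding). Permutation
p-values shuffle individuals among populations with sizes held fixed
and use the (hits + 1)/(B + 1) estimator; the seed is mandatory, and
B = 0 reports NA.

## PCoA

Classical Gower double-centering of −½ D∘D followed by a symmetric
eigendecomposition; coordinates are eigenvectors scaled by √λ over
positive eigenvalues only, and percent variance per axis is relative to
the sum of positive eigenvalues (the non-Euclidean negative part is
excluded from the denominator). Eigenvector sign is pinned by making
each axis's largest-magnitude loading positive. A Slatkin-transform
option (`d/(1−d)`) is provided because analyses differ on raw vs
linearized differentiation; raw is the default. The implementation is
cross-checked in tests against scikit-bio's PCoA but does not depend on
it.

## Statistical-parsimony network

Published formulations of the probability-of-parsimony calculation
behind the TCS connection limit differ in detail, and no reference
implementation is available in this environment to pin against; the
variant implemented here is therefore a documented sequential
distinct-sites model: assuming mutations strike sites of the L-bp
window uniformly and independently, a j-step connection is accepted as
parsimonious when all j mutations hit distinct sites, giving the closed
form `P(j) = Π_{i=1}^{j−1} (1 − i/L)`. P(1) = 1, P is strictly
decreasing in j and non-decreasing in L; the 95% limit is j_max = 11
for the 1175 bp combined window (8 for COI, 7 for COII), values pinned
as regression fixtures. A `fixed_limit` escape hatch reproduces any
externally chosen limit.

Construction processes candidate pairs in increasing Hamming distance
(ties: higher summed frequency first, then lexicographic), connects a
pair only when its endpoints are in different components, and inserts
d − 1 anonymous zero-frequency median nodes along each d-step
connection. The result is a deterministic forest: alternative equally
parsimonious connections (true reticulations) are dropped, which is the
right trade-off for qualitative network figures but means loop
structure is not represented. Pairs beyond the connection limit remain
in separate subnetworks.

## Synthetic worlds

The generator builds combined haplotypes on an explicit mutation tree,
with every mutation at a globally distinct site, so designed pairwise
distances are additive along tree paths and every downstream statistic
has a closed-form expectation; base composition is uniform with no
substitution model, which is irrelevant under exact-identity calling.
Populations receive fixed haplotype spectra (no multinomial sampling),
so calling plus tabulation must recover the configured spectra exactly
— this makes the pipeline's correctness sharply testable, at the cost
of not exercising sampling noise.

The preset world represents the study conditions of a 12-country
invasion survey: 428 individuals; three ancestral lineages (the
dominant haplotype, a second ancestor 4 steps away carried by the
invaded multi-haplotype countries, and a third 6 further steps away
confined to the Japan-like native country); two native countries
sampled in two provinces each with star-like derived haplotypes,
country-level Hd of 0.884 and 0.943 (26 and 33 haplotypes) and no
sharing between them; seven invaded "group A" countries (near-)fixed
for the dominant haplotype with any minor haplotypes one step off it
(star-like, so Fs ≤ 0, the expansion signature); and three invaded
"group B" countries segregating 2–3 haplotypes at intermediate
frequencies with Hd ≥ 0.5 and π ≥ 0.001 (so Fs > 0, the bottleneck
signature, and so the group classification rule recovers the
generating types exactly). Group membership thresholds (Hd ≥ 0.5 and
π ≥ 0.001, boundaries inclusive) follow the published definition of the
two invaded-range genetic groups.

What the generator does **not** emulate: sequencing error and
chromatogram quality, alignment uncertainty, per-individual locus
dropout (single-locus individuals are supported and unit-tested, but
the preset keeps all individuals two-locus so spectrum recovery stays
exact), within-population multinomial sampling noise, recombination
(absent in mtDNA anyway) and homoplasy (all designed distances are
additive). Passing tests therefore demonstrate correctness of the
estimators and plumbing under clean inputs, not robustness to
real-world data pathology — QC behaviour under dirty inputs is tested
separately with hand-built records.

## Pipeline conventions

Stage orchestration is deterministic given config and seed: all
artefacts are byte-identical across reruns except the wall-clock
timings block inside `summary.json` (every other field of the summary
is identical). Any stage failure removes partial artefacts and raises a
stage-tagged error. AMOVA defaults to 1000 permutations and pairwise
Φ_ST to 100 (66 population pairs make the full 1000 needlessly slow for
a matrix whose point estimates don't depend on permutation count);
the diversity table is always produced at region, country and
genetic-group level, while AMOVA/Φ_ST/PCoA/network composition use the
configured grouping level (country by default). Problem sizes
throughout the tests and the acceptance script are the preset world's
(428 individuals, 65 haplotypes) and smaller one-population worlds of
2–24 individuals, which keep the complete run under a few seconds.
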