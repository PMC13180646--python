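# Methods

## Scope and data model

The package analyzes two coupled data streams from multi-population studies
of courtship in the dancing dune fly:

1. **Behavior event logs** — one row per behavior *bout* (a maximal
   continuous expression of one of 18 ethogram behaviors) per actor (male
   or female) per courting pair, with start/end times in seconds.  Bouts of
   one actor may overlap: flies orient and wing-vibrate at once.
2. **Biallelic SNP panels** — alternate-allele dosages (0/1/2, missing) for
   individuals assigned to georeferenced populations, with per-locus assay
   metadata (reproducibility of technical replicates, call rate) typical of
   reduced-representation genotyping.

## Composite behavioral states

An actor's timeline is partitioned at every bout boundary; each segment is
labelled by the *set* of concurrently active behaviors plus an actor tag,
sorted alphabetically and joined by "-" (`Face-off-Wing-sweep-(M)`), giving
deterministic canonical labels.  Consecutive identical segments are merged
— including across inactive gaps, so a chain never contains a
self-transition — and `Bout-start` / `Bout-end` sentinels frame each
actor's sequence.  Bout merging uses a gap tolerance of 0 s (configurable);
timestamps are kept as exact decimals (a 60 fps source implies 1/60 s
resolution; no rounding is applied).  Behaviors scored for the wrong sex
are rejected at load time, which catches transcription errors early.

The packaged 41-state vocabulary of observed composite states includes two
behaviors beyond the core 18-behavior ethogram (`Copulation`, `Wing-swing`,
both female); the full-state preset therefore carries an extended
20-behavior vocabulary, while the default ethogram remains the 18 scored
behaviors.  A reduced 12-state preset keeps tests and examples fast.

## Courtship metrics

Per pair and behavior: mean bout duration, bout count divided by all bouts
of the pair, and mean inter-bout gap — the first and last expressed as
proportions of the pair's total interaction span, which absorbs the large
natural variation in interaction length.  Behaviors with a single bout have
no inter-bout interval and report NaN.  Occurrence tables give the fraction
of pairs per population expressing each (actor, behavior); the prevalence
filter retains rows above a threshold (default 50%) in *every* population,
with a configurable exclusion list for states that are not active courtship
signals.

## Transition structure and divergence

Transition counts are tallied within each actor's own chain by default; an
interleaved mode merges a pair's male and female states by onset time first
(both conventions are defensible readings of how display networks combine
the sexes, so both are provided and reported).  The permutation screen
shuffles the order of states independently within each sequence, preserving
per-sequence state multisets, recounts B = 1,000 times, and keeps cells with
one-sided `p = (1 + #{≥ observed}) / (B + 1) ≤ 0.05`.  No multiple-testing
correction is applied at this stage — the screen is descriptive, isolating
the display's nonrandom backbone, not a family of confirmatory tests.  The
+1 correction keeps p-values off zero; on heavily tied small counts the
estimator is mildly conservative, which the calibration test acknowledges
(observed type-I fraction ≈ 0.038 at α = 0.05).

Courtship distance between two individuals is the KL divergence (natural
log) between their row-major-vectorized S×S transition-count matrices after
Dirichlet smoothing with pseudocount a = 1.  Note the absolute scale of
this distance depends strongly on S and on chain length: with S² = 1,681
smoothed cells and chains of ~10² transitions, the smoothing pulls both
distributions toward uniform and typical divergences are of order 10⁻².
Comparisons are therefore meaningful within an analysis, not across state
spaces.  Population summaries symmetrize (mean of both KL directions) per
unordered individual pair before averaging; within-population means exclude
self-comparisons and populations of one individual report NaN.

## Population genetics

* **Filtering** is sequential — reproducibility, then call rate, then
  minor-allele frequency, keeping loci at or above each threshold.  The
  minor-allele threshold of 0.02 is interpreted as a *frequency* (a
  fractional count is not meaningful), and the report flags this.
* **Heterozygosity**: per locus and population, H_O is the heterozygote
  fraction among genotyped individuals and H_E the sample-size-corrected
  gene diversity `Hs = n/(n−1)(1 − Σp² − H_O/2n)`; summaries average both
  over loci and report `F_IS = 1 − mean(H_O)/mean(H_E)` (ratio of means,
  so the identity holds exactly at the summary level).
* **Pairwise F_ST**: Weir–Cockerham variance components per locus,
  combined as the ratio of summed components; negative multilocus
  estimates are reported as computed.  The bootstrap p is the one-sided
  probability (over locus resamples, +1-corrected) that θ ≤ 0.
* **Population-specific F_ST**: Weir–Goudet allele-matching betas,
  `β_i = 1 − Σ_l(1 − M_i,l) / Σ_l(1 − M_B,l)` with unbiased within-
  population matching and the between-population matching averaged over
  all population pairs.
* **AMOVA** operates on allele-copy squared distances derived from dosages
  without phase: between individuals the expected per-locus copy mismatch
  is `p_i(1−p_j) + p_j(1−p_i)` with `p = g/2`; within an individual it is
  its heterozygosity.  All group sums of squares involve either all copy
  pairs of a group or the fixed within-individual pair, so the phase-free
  expectation is exact, and the three strata (among populations, among
  individuals within, within individuals) follow the standard
  nested-design coefficients.  Missing loci are pairwise-deleted (per-pair
  means over shared loci).  Significance shuffles individuals among
  populations (B = 999 default) and compares the among-population
  component.
* **Distances**: Nei (1972) `D = −ln(J_xy/√(J_x J_y))` with J terms summed
  over loci before the ratio (infinite D flagged); Kosman distance
  `|g_1 − g_2|/2` per locus averaged over jointly genotyped loci (a metric
  on complete data, property-tested).
* **Mantel**: Pearson correlation between condensed distance matrices;
  genetic distance linearized as `F_ST/(1−F_ST)`; geographic distance
  great-circle (haversine) km despite coordinates sometimes being treated
  planar elsewhere — a planar option exists for strict replication.
  Permutations relabel populations; B = 10,000 default, one-sided.
* **PCA**: mean-imputed, column-centered dosages, plain SVD.

## Synthetic data generator

Behavior is simulated as a semi-Markov chain over composite states —
explicit gamma dwell times (default shape 2, scale 1 s, i.e. mean 2 s
bouts) because the metrics need durations and intervals, and a geometric
event count (mean 64, clipped to [5, 400]) so interaction lengths are
right-skewed like field recordings (medians ≈ 90–110 s, means larger).
Composite states are simulated directly as atoms and decomposed into
overlapping per-behavior bout records for the event log; a behavior active
in consecutive states emits one continuous bout.  The base transition
matrix is a fixed-seed Dirichlet draw with zero diagonal and cross-actor
transitions upweighted ×2 (courtship is turn-taking).  Divergence between
populations mixes in perturbation matrices: `P_pop = (1−ε)P_base +
εP_perturb(pop)`; a coupled mode drives every population toward one shared
perturbation with magnitude rising linearly along the population list, so
courtship divergence can be made to track a geographic/genetic gradient.

Genotypes follow the Balding–Nichols model: ancestral frequencies uniform
on a configurable range, deme frequencies `Beta(p(1−F)/F, (1−p)(1−F)/F)`,
genotypes Binomial(2, deme frequency).  `spatial="island"` drifts every
deme independently from the ancestor (exchangeable structure, E[F_ST] ≈ F);
`spatial="serial"` re-drifts each deme from its predecessor, accumulating
differentiation along the habitat and generating isolation by distance.
Per-locus missingness is Beta-distributed around the configured mean and
masked binomially; metadata reproducibility mixes a high component
(U(0.98, 1)) with a degraded fraction (U(0.7, 0.98)) so the standard
filters have realistic bite, and call rate is the realized per-locus
non-missing fraction (hence always consistent with the matrix).

What the generator does *not* emulate: linkage disequilibrium between
loci, within-individual allele-frequency error, observer effects or
kinematic detail of the display, and any dependence of display structure
on partner identity beyond the first-order chain.  Passing tests therefore
demonstrate correctness of the estimators and the pipeline under the
stated models, not robustness to those real-data features.

## Study-scale run and problem sizes

`scripts/acceptance.py` uses the field-study shape: seven populations with
the sampled sizes (9–23 genotyped flies, 94 total) and coordinates of the
studied beaches, 38,905 loci before filtering; three populations × 15
filmed pairs over the 41-state repertoire with mild display divergence
(ε = 0.1 — displays in this system are largely stable).  The serial drift
step (F = 0.12 per step), missingness (mean 6%) and degraded-assay
fraction (35%) were chosen once to emulate the strong population structure
and heavy reduced-representation attrition characteristic of such panels.
Bootstrap/permutation depths: 1,000 locus bootstraps per population pair,
999 AMOVA permutations, 10,000 Mantel permutations, 1,000 edge-screen
shuffles.  The unit/property suite runs at smaller sizes (12-state preset,
hundreds-to-thousands of loci) chosen so each check's statistical
resolution comfortably exceeds its tolerance.

## Numerical and design notes

* All randomness flows from one seed via `numpy` SeedSequence spawning;
  identical configurations give byte-identical outputs.
* Permutation/bootstrap p-values always use the +1 correction and lie in
  `[1/(B+1), 1]`.
* Negative variance components, negative F estimates and negative betas
  are reported as computed; nothing is clipped.
* Degenerate inputs: actors with no events yield sentinel-only sequences;
  sequences of fewer than two states yield all-zero count matrices with a
  warning; populations of one individual are excluded from pairwise F_ST
  (warned) and report NaN within-population divergence; monomorphic
  populations have H_E = 0 and undefined F_IS.
* The OLS R² of courtship on genetic distance is reported with an explicit
  small-sample flag below 10 population pairs; with the typical 3 pairs it
  is descriptive only.

## Known limitations

Chain-order first-order Markov structure is assumed throughout; bout
durations enter the metrics but not the sequence model.  The permutation
edge screen tests marginal cells, not the joint network.  AMOVA's
phase-free copy distances are exact in expectation but ignore gametic
phase; with strong LD the within-individual stratum would be misstated.
KL courtship distances are not comparable across different state universes
or strongly different chain lengths.
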