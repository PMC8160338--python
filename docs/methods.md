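# Methods

## Presence matrices and mutation classes

The unit of analysis is one patient with N sequenced lesions.  Starting
from per-lesion high-confidence calls, a mutation called anywhere is
*rescued* in any other lesion where it is supported by at least
`min_rescue_reads = 3` reads with median base quality ≥ 30 and median
mapping quality ≥ 60.  Rescue is monotone (it only adds presence) and
idempotent.  Lesions whose pileup lacks the locus are marked
`unpowered` rather than absent.

The *power filter* then retains only loci detectable everywhere: for
each lesion, detection power is P(Binomial(d, f) ≥ 3) where d is the
local depth and f the expected VAF of a clonal (CCF 1, multiplicity 1)
variant at the lesion's purity.  A mutation is *powered* only when this
probability reaches `power_target = 0.90` in **every** lesion; a
mutation present in all lesions but unpowered in one is left
unclassifiable, not called truncal.  Power is evaluated at CCF 1 and
multiplicity 1 because the filter asks whether a clonal variant would
have been seen, matching the intent of the rescue.

Classes over the powered set: truncal = present (called or rescued) in
all N lesions, private = exactly one, branch = 2..N−1.  Patients with a
single lesion cannot separate truncal from private and yield only
unclassifiable mutations.

Pairwise lesion similarity is the Jaccard index over powered
called-or-rescued mutation sets (rescued mutations are included, since
excluding them would re-inflate apparent heterogeneity, which the
rescue exists to prevent).  A seeded lesion-downsampling routine makes
medians comparable across patients with different N.  Tumor mutation
burden counts coding mutations at depth ≥ 30 with VAF strictly > 0.01
per megabase of adequately covered coding territory; the VAF threshold
is configurable because published analyses have used both 1% and 0.5%.
Dispersion summaries use the raw (unscaled) median absolute deviation.

## CCF model

The expected VAF of a mutation at cancer cell fraction c is

    f(c) = α·c·m / (α·q_t + (1 − α)·2)

with purity α, local tumor total copy number q_t, multiplicity m and
diploid normal tissue.  The posterior over a grid of 100 CCF values
(0.01 to 1.00 inclusive; c = 0 is not a somatic state) is the
normalized binomial likelihood Binom(a | d, f(c)) under a uniform
prior.  The point estimate is the posterior mode; the interval is the
central 95% credible interval read off the cumulative posterior (the
highest-density alternative was not adopted; for the unimodal binomial
likelihoods involved the two agree closely, and the central interval is
monotone in the cumulative sum and therefore cheap and deterministic).
Estimates at depth < 30 are flagged unreported.  Clonal means point
CCF ≥ 0.9, boundary inclusive.

When multiplicity is unknown it is estimated by inverting the VAF
model, m = round(f·(αq_t + (1−α)·2)/α) clipped to [1, major].  In
regions with major copy number ≥ 2, multiplicity > 1 dates a mutation
before the copy gain.  Whole-genome duplication is called when segments
with even major copy number cover strictly more than half the genome.

## Copy-number events

With sample ploidy ψ: high-level amplification total ≥ 3ψ; gain
2ψ ≤ total < 3ψ; partial deletion 0 < total < ψ/2; homozygous deletion
total = 0; LOH is a separate flag (minor = 0, total > 0, including
copy-neutral LOH).  Totals falling between ψ/2 and 2ψ are neutral for
driver purposes but count as altered for copy-number instability
whenever total ≠ round(ψ) or LOH holds; CIN is the altered fraction of
the genome, and LOH-only segments are included (a modelling choice —
excluding them would change CIN only for near-ploidy LOH).  The SCNA
similarity between two samples is a base-level Jaccard requiring the
same event class on both sides, which is robust to breakpoint jitter
where segment-identity matching is not.

A mutation-loss event requires (i) ≥ 1 lesion with the mutation and no
LOH, (ii) ≥ 1 lesion without the mutation and with LOH, and (iii) no
lesion lacking both (such loci are dropped as ambiguous, since the
wild-type copy may have been the one lost).

## Driver rules

A point mutation is functional when it lies in a panel gene and is an
inactivating mutation (nonsense/frameshift/splice) in a listed tumor
suppressor, a recurrent-site mutation in a listed oncogene (exact
amino-acid position match; no window, as recurrent hotspots are
position-specific), or any non-silent mutation in a census gene
observed in the matching cancer type.  A configurable blacklist drops
genes prone to alignment artifacts.  Copy-number drivers are oncogene
high-level amplifications and tumor-suppressor homozygous deletions;
an oncogene gain is promoted per lesion when another lesion of the
same patient carries a high-level amplification of the gene.  The
shipped rules fixture is a small illustrative list (PIK3CA, AKT1, ESR1,
FGFR2, ARID1B, SPEN, NSD1, MYC); real analyses supply their own TSVs —
the engine, not the list, is the deliverable.

The driver-clonality association reports the plain 2×2 sample odds
ratio with a two-sided Fisher exact p-value; no covariate-adjusted
model is implied.

## cfDNA detection and power

Tissue mutations are rescued in plasma at ≥ 3 supporting reads;
plasma-only variants below VAF 0.005 are filtered.  Loci not covered in
the plasma pileup are excluded from detection denominators.  The power
model first finds k*, the smallest read count whose error-only binomial
tail P(Binomial(d, e) ≥ k) stays at or below the false-positive
probability 5 × 10⁻⁷ with per-base error e = 10⁻³ (at 1000–1600×,
k* = 10–13).  The stated error rate is interpreted as a per-base
substitution error probability; it is not divided by three per
alternative base (configurable).  Power at ctDNA CCF c is the binomial
tail above k* at the expected plasma VAF, computed from the CCF model
with the plasma tumor fraction standing in for purity; the minimum CCF
with ≥ 90% power is found by bisection on the monotone power curve.
ctDNA CCFs are estimated with the same grid posterior, again with
tumor fraction as purity.

Detection is modelled jointly on the harboring-lesion count k and the
maximum tissue CCF by maximum-likelihood logistic regression with Wald
intervals (perfect separation falls back to an L2-penalized fit with a
warning); the ctDNA-CCF-per-lesion trend among detected sSNVs is
ordinary least squares.  No patient random effect is included — the
pooled two-covariate model is what the cross-patient records support
at this cohort size.

## Subset sampling and ROC thresholds

For subset size s, all C(N, s) lesion subsets are enumerated exactly; a
driver is detected when present in ≥ 1 sampled lesion and misclassified
as truncal when present in all s sampled lesions while not truly
truncal.  Summary statistics use the sample (n−1) standard deviation —
with one private driver among t truncal drivers, the subset counts are
Bernoulli and the closed forms mean = t + s/N and completeness = s/N
hold, which the tests verify for all N ≤ 20, s ≤ 5.  Above a
configurable cap (10⁶ subsets) a seeded Monte-Carlo sample replaces
enumeration; study-scale N ≤ 17, s ≤ 5 never triggers it.

ROC analysis scores mutations by ctDNA CCF against tissue-truth truncal
labels.  Candidate thresholds are midpoints between consecutive
distinct scores plus sentinels outside the observed range; calling is
score ≥ threshold.  AUC is the trapezoid rule over the (FPR, TPR)
staircase (equal to Mann–Whitney pairwise concordance with ties counted
one half, which the tests assert).  The operating point minimizes the
unweighted Euclidean distance to (FPR 0, TPR 1); ties break toward the
higher threshold, the conservative direction for truncal calling.

## Synthetic cohort

The generator reproduces the data structure the pipeline assumes, with
defaults fixed at the study conditions: 9 patients, lesions per patient
uniform on 4..17, tissue depth Poisson around 117×, plasma depth
Poisson around 1200× (within the assay's 1007–1643× range), plasma
tumor fraction 0.3, per-base error 10⁻³, purity Beta(6, 4) floored at
0.2 (breast-cancer-like cellularity), and expected per-patient class
counts of 40 truncal / 30 branch / 30 private mutations (Poisson
unless `fixed_class_counts`), of which 30% fall on the targeted panel
(drivers always do).

Branch mutations take the lesion set of a random internal edge of a
recursively bipartitioned clone tree, producing nested presence
patterns; the size distribution of those sets is a modelling choice,
and an alternative `uniform_k_nontruncal` mode draws the harboring
count k uniformly on 1..N−1 for designs that must sweep k evenly.
Within a harboring lesion mutations are clonal (CCF 1) unless a
subclonal fraction is configured.  Copy number is diploid throughout —
CNA analyses are tested on injected segments — so CCF-model copy
corrections are exercised by unit tests rather than by the cohort.
Read counts are Binomial(depth, expected VAF) with Poisson depths;
non-harboring lesions draw alt reads at the error rate.  The plasma
VAF of a mutation uses the shed-weighted ctDNA CCF
Σ_{i∈harboring} w_i·c_i (equal weights by default) with the tumor
fraction as purity, plus the error background.

What the generator does **not** emulate: overdispersed read counts,
mapping artifacts, subclonal copy-number states, unequal shedding
biology, germline contamination and real genome coordinates.  Passing
tests therefore demonstrate correctness of the algorithms under the
stated generative model, not robustness to those real-data effects.

## Problem sizes and determinism

Simulation-backed tests use cohorts of 2–12 patients and ~100–400
mutations per patient, sizes at which every statistical check (3–4
standard-error bands, exact enumeration oracles) is already sharp.
The acceptance script simulates ≥ 2000 non-truncal mutations across
eleven 12-lesion patients.  All randomness flows from a single integer
seed through one `numpy` generator per run; identical config + seed
give byte-identical outputs, and the pipeline manifest records the
seed and a config hash.
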