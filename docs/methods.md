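# Methods

This note documents the models, defaults and design choices behind
`wtitgh`, in the order the pipeline runs.

## Data model

A *case* is one tumor: ≥1 tumor SNP arrays plus (usually) one germline
normal array, all sharing a probe set after intersection
(`wtitgh.io.align_case`). Each array carries per-probe Log R Ratio
(LRR, log₂ observed/reference intensity; ~0 diploid) and B-allele
frequency (BAF; ~0/0.5/1 for germline AA/AB/BB). Chromosomes are ordered
1..22, X; Y is excluded. All intervals are 0-based half-open internally;
input TSV positions are 1-based and BED output is 0-based, per each
format's convention.

## Synthetic cases (what the simulator emulates, and what it does not)

The simulator generates a rooted clone tree whose edges carry segmental
events — single-allele gain (+1), loss (−1), and copy-neutral LOH
((1,1) → (0,2)) — and assigns each tumor sample one dominant clone. The
probe-level signal is the purity mixture

    total = p·(c_A + c_B) + (1−p)·2
    LRR   = log2(total/2) + s·wave(pos) + N(0, σ_LRR)
    BAF   = B-copies/total + N(0, σ_BAF), truncated to [0,1]

with germline genotypes drawn at `het_fraction` (default 0.33, the
approximate heterozygous fraction of genotyping arrays), the wave a fixed
case-level sum of two low-frequency sinusoids (periods 30 and 11 Mb)
scaled per sample by s ∈ [0.8, 1.2], and noise Gaussian. Homozygous
probes sit at BAF 0/1 regardless of copy state, as on real arrays.
Default desk scale is 4–6 chromosomes × 300–600 probes (the package's own
choice of test scale; real CytoSNP arrays have ~300k probes and the same
statistical structure per chromosome). A pure double loss has mixture
total 0; the simulator clips the total at 0.05 before the log so the LRR
is deep but finite, and sets BAF to 0.5 (no signal).

Not emulated: raw intensity channels, probe-specific GC effects (the wave
stands in for all smooth positional bias), subclonal mixtures within one
sample beyond purity dilution, and sequencing-style point mutations.
Passing synthetic tests therefore demonstrates correct recovery of the
model the pipeline assumes — not robustness to every artifact of real
arrays.

## Wave correction

Real arrays share smooth positional LRR bias. We estimate it model-free:
median LRR across normal arrays, smoothed by a running median (window 51
probes, odd, per chromosome), centered to mean zero. Each array is then
corrected by `LRR − β·wave` with β fit per array by least squares — wave
amplitude varies between hybridizations, so a per-sample scale is fitted
rather than subtracting the profile unscaled. Least-squares orthogonality
makes the corrected LRR exactly uncorrelated with the wave profile, and
the correction is idempotent. BAF is never touched. With no normal
arrays the profile is zero and correction is a logged no-op.

## Segmentation and calling

Per chromosome, changepoints minimize the sum of squared residuals around
segment means plus λσ²·log n per breakpoint (λ = 3 by default), solved
exactly by optimal partitioning (O(n²) dynamic program) with a minimum
segment length of 10 probes — deterministic, exact, and fast at desk
scale. σ is the robust noise estimate `1.4826·MAD(diff(LRR))/√2`.

States are called from segment mean LRR with absolute thresholds:
double_loss < −1.0 ≤ loss < −t ≤ neutral ≤ +t < gain ≤ 0.87 <
amplification, where `t = max(0.1, 3·σ/√n_probes)` adapts to segment size
and sample noise. The noiseless expectations anchor the defaults: a
single-copy gain at purity 1 sits at log₂(3/2) ≈ 0.585, a single loss at
−1, a balanced two-copy gain at 1 (hence 0.87 as the amplification
boundary, 1.5× the single-gain level). Calls use absolute LRR, so a
global median shift of an un-normalized array shifts calls; arrays are
assumed centered, as GenomeStudio-style LRR is.

## Region harmonization and filters

Per-sample breakpoints are pooled per chromosome, single-linkage-merged
when closer than 5 probes, and replaced by their (lower) median; the
resulting boundaries tile each chromosome identically for all samples of
the case. Each region's per-sample call is the state of the segment
covering the region midpoint. Because copy-neutral LOH produces no LRR
step, the pooled breakpoints also include changepoints of the
mirrored-BAF series over heterozygous probes (same penalized search),
mapped back to probe indices — without these, a 2+0 region inside a long
diploid stretch would never be isolated.

Regions with fewer than `filter_min_probes` probes are removed (default
100, the cohort-scale value for ~300k-probe arrays; desk-scale synthetic
runs set it to ~10 via config, scaling with probe counts), as are regions
whose log probe density falls outside the case median ± 3 robust MADs —
with the degenerate convention that when the MAD is exactly zero, any
deviation is an outlier.

## Allelic validation and CNNLOH

For each region and tumor sample, heterozygous probes are taken from the
matched normal (BAF within 0.15 of 0.5); without a normal, a less
specific tumor-only window [0.25, 0.75] is used and logged. The mirrored
BAF `mBAF = mean(0.5 + |BAF − 0.5|)` ranges over [0.5, 1]: 0.5 balanced,
2/3 single gain (2+1) at purity 1, 1.0 loss or uniparental disomy at
purity 1; at purity p a 2+0 region sits at 0.5 + p/2. The acceptance
threshold 0.56 sits between the balanced value plus folded-noise bias
(≈0.52 at σ_BAF = 0.03) and the purity-0.5 gain expectation (0.58…); the
LOH threshold 0.68 sits between the gain level (2/3) and the purity-0.5
CNNLOH level (0.75). Both are config keys.

Non-neutral calls with defined mBAF below 0.56 are reset to neutral and
flagged `rejected_no_imbalance`; with fewer than 10 informative probes
the call is retained but flagged `low_information`. CNNLOH detection runs
*after* validation and only sets a flag on neutral regions with mBAF ≥
0.68 — a rejected CNA is never rescued as LOH, and no state is ever
changed. Balanced two-copy gains (2+2) show no imbalance and are
rejected by this rule, as the validation rule demands; such rejections
are logged. Adjacent flagged regions are merged for reporting.

## Allele profiles and the minimum-event distance

Calls map per region to integer (major, minor) copies: neutral (1,1),
neutral+LOH (2,0), gain (2,1), amplification (3,1), loss (1,0),
double_loss (0,0) — the lowest-copy states consistent with each call and
its mBAF. Major/minor assignment is per-region (arrays carry no germline
phase), which can undercount events relative to a fully phased analysis;
this is a documented limitation.

The distance between two profiles is the minimum number of segmental
events — ±1 on one allele over a run of contiguous regions — transforming
one into the other. Copy number 0 is absorbing: a fully deleted region
can never regain copies (transforming 0 → >0 is infeasible) and blocks
later events from spanning it, exactly like a chromosome boundary. For
the per-allele difference vector d (target − source), with d⁺ = max(d,0),
d⁻ = max(−d,0) and the running values reset at chromosome starts:

    events = Σᵢ max(0, d⁺ᵢ − d⁺ᵢ₋₁) + Σᵢ max(0, d⁻ᵢ − d⁻ᵢ₋₁)

summed over both alleles. The test suite proves this closed form equal to
breadth-first search over the full move graph for *every* pair of
5-region profiles with copies ≤ 3, in both the single-chromosome and
split-chromosome layouts, including infeasibility.

## Tree building, refinement, classification

Pairwise distances are symmetrized (minimum over the two feasible
directions; a large finite guard if neither is feasible) and neighbor
joining (scikit-bio) gives the unrooted topology. The tree is rooted at
the normal sample, whose profile is all-(1,1) by construction. Internal
ancestor profiles are initialized to the child-wise elementwise minimum
and refined by integer local search: per node, region and allele,
candidate values between the incident nodes' values are tried and kept
when the summed incident-edge event count strictly decreases. Edges whose
direction violates zero-absorption are charged a large per-violating-
region penalty, graded so the search can repair one region at a time; the
total is integer-valued and bounded below, so refinement terminates. For
small cases an exhaustive search over all unrooted topologies is
available and used in tests as a lower-bound check.

Edge labels are produced by peeling maximal same-sign runs off the
per-allele difference and naming each run by the chromosome arm with
majority bp overlap (packaged hg19 arm table), e.g. `1q+(major)`.

Classification: *flat* if all tumor-leaf profiles are identical (all
events truncal or none), *branched* if any node has ≥2 children whose
subtrees each contain ≥1 event, *linear* otherwise. X is included with a
diploid baseline and no male dosage correction — a documented limitation
for male cases.

## Cohort statistics

A sample is positive for an arm biomarker (1q+, 16q−, 11p15 LOH) when
accepted calls of the right direction (or LOH flags) cover ≥ 50% of the
arm span in bp. Heterogeneity needs ≥ 2 samples; single-sampled tumors
are "not assessable". Over positive tumors with positive-sample fractions
fⱼ: the single-sampling full-detection probability is Π fⱼ; the mean miss
probability q̄ = mean(1 − fⱼ) carries a normal-approximation 95% CI
(q̄ ± 1.96·sd/√m, sample sd, clipped to [0,1]; a t-quantile variant is a
config option); and the design bound is the smallest n with 1 − q̄ⁿ >
0.95, from the cumulative binomial with per-sample detection probability
1 − q̄. The Welch one-tailed t-test (direct formula, Welch–Satterthwaite
df, p = P(T ≤ t)) compares ages between heterogeneity groups; it is
cross-checked against an independent implementation in the tests.
Independent tumor origins are reported when the "shares ≥1 accepted
somatic event (same region, same direction/LOH flag)" relation leaves
more than one connected component; samples with no events are reported as
"no evidence" singletons, never asserted independent.

The packaged cohort table assigns the four homogeneous unilateral cases
to one group and twelve heterogeneous unilateral cases to the other; the
case whose contralateral tumor was removed before the study is counted
among the unilateral heterogeneous patients (its remaining tumor is the
only one sampled), which is the grouping under which the published ages
reproduce t = −1.52 — the four fully bilateral cases stay outside both
groups.

## Numerical conventions and degenerate inputs

- Breakpoint-merge ties take the lower median (floor).
- Chromosomes shorter than twice the minimum segment length form a single
  segment.
- A region's mBAF is undefined (NaN) below 10 informative probes.
- detection_stats rejects fractions outside (0,1]; min_samples_needed
  rejects q = 1 (undetectable).
- Same seed ⇒ bit-identical simulator output; everything downstream of
  the simulator is deterministic.

## Known limitations

- Calling thresholds are fixed log₂ levels, not a mixture-model
  posterior; heavily aneuploid genomes with shifted baselines would need
  recentering upstream.
- The (major, minor) state vocabulary tops out at (3,1); higher
  amplifications are compressed into it.
- Purity is a simulator input, not estimated from data.
- Unphased per-region major/minor assignment can undercount events
  relative to phased analysis.
- Balanced gains (2+2) are rejected by the allelic-imbalance rule.
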