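# wtitgh

Multi-region SNP-array analysis of **intra-tumor genetic heterogeneity**
(ITGH): allele-specific copy-number and LOH calling across multiple samples
per tumor, minimum-event clonal phylogenetics rooted at normal tissue, and
the sampling-design statistics that tell you how many biopsies a
heterogeneous biomarker actually needs.

The package is aimed at tumor-genomics analysts working with Illumina-style
SNP arrays (Log R Ratio + B-allele frequency per probe) from several
spatially separated samples of the same tumor — the setting of multi-region
profiling studies in Wilms tumor, where arm-level biomarkers such as 1q
gain (1q+) are used for risk stratification but may be present in only a
subset of samples.

## What it computes

**Per case** (one tumor, ≥1 sample + matched normal):

1. *Wave correction* — smooth positional LRR bias ("genomic waves") is
   estimated from the normal array (centered running median) and regressed
   out of every array with a per-sample scale.
2. *Segmentation & calling* — per chromosome, exact penalized
   least-squares changepoints (penalty λσ²·log n per breakpoint, σ from the
   MAD of adjacent-probe differences); segment means are mapped to
   {double_loss, loss, neutral, gain, amplification} with an adaptive
   neutral band `t = max(0.1, 3·MAD/√n)`.
3. *Region harmonization* — sample breakpoints (LRR- and BAF-derived) are
   merged into one shared region set; regions with too few probes or
   outlying probe density are dropped.
4. *Allelic validation* — the mirrored BAF over germline-heterozygous
   probes, `mBAF = mean(0.5 + |BAF − 0.5|)`, must exceed 0.56 for a CNA
   call to survive; neutral regions with mBAF ≥ 0.68 are flagged as
   **copy-number-neutral LOH** (2+0), which is invisible in LRR.
5. *Phylogeny* — calls map to integer (major, minor) allele profiles;
   the distance between profiles is the **minimum-event distance**: the
   smallest number of segmental ±1 single-allele events transforming one
   profile into the other, with copy number 0 absorbing. For a difference
   vector d with positive/negative parts d⁺, d⁻ (reset at chromosome
   boundaries):

   `events = Σᵢ max(0, d⁺ᵢ − d⁺ᵢ₋₁) + Σᵢ max(0, d⁻ᵢ − d⁻ᵢ₋₁)`

   Neighbor joining gives the topology, the tree is rooted at the normal
   sample (all-diploid), internal ancestor profiles are refined by integer
   local search, and each tree is classified **flat / linear / branched**.

**Per cohort**: biomarker presence per sample (arm-coverage rule),
heterogeneity per tumor, and single-sampling design statistics — the
probability `Π fⱼ` that one sample per tumor detects the biomarker
everywhere it is present, the mean per-tumor miss probability
`q̄ = mean(1 − fⱼ)` with a normal-approximation CI, and the smallest n with
`1 − q̄ⁿ > 0.95`.

A seeded simulator (`wtitgh.simulate`) generates CytoSNP-like cases at desk
scale with known clone trees, events, purity, waves and noise, so every
stage is scored against ground truth.

## Worked example

```bash
python examples/sampling_design.py
```

```
positive-sample fractions: [1.0, 1.0, 1.0, 0.333, 0.333, 0.5, 0.667]
heterogeneous tumors: 4/7 (57%)
P(single sampling detects 1q+ in all 7 tumors) = 0.037
mean single-sample miss probability q = 0.31 (95% CI 0.08-0.54)
samples per tumor for >95% detection (1 - q^n > 0.95): n = 3
```

Seven multi-sampled 1q+ tumors: three are positive in every sample, four
in only a subset. One biopsy per tumor detects the biomarker in all seven
with probability 0.037; a positive tumor is missed about 31% of the time;
three samples per tumor push that below 5%.

```bash
python examples/simulate_and_run.py
```

```
true clone tree:     ((A:1,B:2)founder:1)root:0;
inferred event tree: (((R1:0,R2:0):1,(R3:0,R4:0):3):2)NK;
classification:      branched
total events:        6
  edge NK -> _anc1: 2 events  ['4q+(major)', '4q-(minor)']
  edge _anc1 -> _anc0: 1 events  ['1q+(major)']
  edge _anc1 -> _anc2: 3 events  ['3p+(major)', '2p-(minor)', '3p-(minor)']
```

A noisy purity-0.8 case simulated on a two-branch clone tree: the pipeline
recovers both branches, the truncal copy-neutral LOH (two events in allele
space), and classifies the tree as branched. `examples/cnnloh_detection.py`
and `examples/wave_correction.py` demonstrate the BAF-only LOH caller and
the wave model. The same pipeline is available from the shell:
`wtitgh simulate | run | cohort | stats`.

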