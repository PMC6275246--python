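# Methods

This note records the models implemented in `rnabc`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Pseudoalignment and abundance estimation

**Reference.** The quantification reference is the set of probe-set *target
sequences* — one nucleotide sequence per probe set, the region from which the
array's probes were selected. AFFX spike-in/control probe sets (ID prefix
`AFFX`) are removed before any indexing. Entry order in the FASTA defines the
row order of every downstream matrix.

**Index.** Every A/C/G/T window of length k contributes its canonical k-mer
(lexicographic minimum of the window and its reverse complement) to a
k-mer → targets map; windows containing N are skipped, and targets shorter
than k keep a matrix row but are unindexable (warned). k defaults to 31, the
conventional pseudoalignment default; it must be odd (a k-mer can then never
equal its own reverse complement) and within [11, 63] (two-bit packing in a
64-bit word). Canonical k-mers make the aligner strand-agnostic; a stranded
mode restricts the index to sense-strand k-mers for stranded protocols.

**Equivalence classes.** Per mate, the target sets of index-present k-mers
are intersected; k-mers absent from the index are *skipped*, not treated as
contradictions — this is what makes exact matching robust to sequencing
error (an erroneous k-mer almost surely occurs nowhere in the reference and
simply drops out). A mate with no index-present k-mer contributes no
constraint; paired mates are combined by intersection, a lone informative
mate decides alone, and an empty intersection leaves the read unassigned.

**EM.** Class counts feed the standard mixture model: a read from class C
arose from target t ∈ C with probability ∝ α_t/ℓ_t. The EM update
(fractional assignment by current weights, then α_t ← expected count / n)
maximizes the concave log-likelihood Σ_C n_C log Σ_{t∈C} α_t/ℓ_t subject to
Σα = 1. Effective length is the plain target length: probe-set targets are a
few hundred nt and no fragment-length model is fitted — a documented
simplification relative to full transcript quantifiers. Initialization is
uniform; convergence when the largest relative change of any α above 1e-12
falls below 1e-8 (default), capped at 1000 iterations; the log-likelihood
trace is retained and is asserted non-decreasing in the tests.
TPM_t = 1e6·(α_t/ℓ_t)/Σ_u(α_u/ℓ_u); expected counts are α_t·n_assigned.
Reads never seen in any class get TPM 0; a sample with no assigned reads
yields an all-zero table with a warning.

## Target quantile normalization

The target distribution is the sorted vector of per-probe *mean* training
intensities. Each test column is normalized independently: the value of rank
r (of R) maps to the target's empirical quantile at probability (r−0.5)/R,
linearly interpolated over the sorted target values and clamped at the
extremes; ties receive the mean of the values their ordinal ranks would have
mapped to. The (r−0.5)/R convention makes the mapping exact when R equals the
target length — a no-tie column then reproduces the sorted target values
bitwise — and rank preservation makes a prior log transform a no-op, so raw
TPM is fed to the normalizer directly (the log2(x+1) utility exists for
workflows that want FPKM′-style values). Because the mean-intensity target
is narrower than any individual sample, extreme values are compressed toward
the target range; the batch-correction step's scale model subsequently
re-expands per-probe spread toward the pooled scale, which is one reason the
two steps are only effective together. Single-sample normalization is
permitted but warned against: distribution matching against a full training
cohort is unreliable for lone samples, and batch correction is skipped
entirely for a single test sample (it requires ≥2 per batch).

## Empirical-Bayes batch correction

The parametric location/scale model: Y_ijg = α_g + X_j β_g + γ_ig + δ_ig
ε_ijg, with γ_ig ~ N(γ̄_i, τ²_i) and δ²_ig ~ InverseGamma(λ_i, θ_i) shared
across probes within batch i. Steps: least-squares fit of batch means and
covariate effects with a sample-size-weighted zero-sum constraint on γ
(identifiability); standardization by the pooled residual SD; method-of-
moments priors (γ̄, τ² from the mean/variance of γ̂; λ, θ from
E[δ²] = θ/(λ−1), Var[δ²] = θ²/((λ−1)²(λ−2))); coupled posterior updates of
γ*, δ²* iterated to relative change < 1e-4 (max 500); adjustment of *all*
batches — training included — onto the pooled scale, matching the use case
where both cohorts enter the correction together.

Numerical decisions: the pooled variance divides by the residual degrees of
freedom (N − rank of design), not N, so that it shares ddof with the
per-batch δ̂² estimates; a batch-free equal-variance dataset then
standardizes to δ̂² ≡ 1 and the correction is exactly idempotent in that
case. Zero within-batch variance of δ̂² across probes triggers a degenerate
prior (λ = 1e6, total shrinkage); a zero-variance probe within a batch is
excluded from EB estimation and receives additive-only correction (logged).
Because EB shrinkage pulls each probe's effect toward the batch mean effect,
correction is only *approximately* idempotent in general — the residual is
the shrinkage gap, which vanishes exactly when the per-probe effects are
homogeneous (τ² = 0). Covariates (categorical dummy-expanded, numeric as-is)
are optional and off by default; a covariate confounded with batch is a hard
error.

## Centroid classifier

Centroids are per-subtype means over the signature probe sets; DLDA mode
divides squared deviations by the pooled within-class variance per feature
(floored at 1e-8), which is the diagonal-covariance LDA discriminant with
uniform priors; 1−Pearson is available for gene-level signatures. The mixed
threshold t is the linearly interpolated 10th percentile of the C(K,2)
pairwise centroid distances. A sample is **mixed** when ≥2 subtypes lie
within t of the minimum distance (checked first), otherwise **outlier** when
its best distance exceeds `med_k + n·mad_k`, else **core**. MAD is raw (no
1.4826 constant); the threshold is invariant to that choice because the
constant would cancel between n = max_k (max−med)/mad and n·mad. Under the
`med_plus_n_mad` reading the most extreme training sample sits exactly on
its subtype's threshold, so no training sample is an outlier; the literal
`n_mad` reading (d > n·mad) is selectable. Exact argmin ties break by
subtype order (alphabetical, which reproduces the canonical basL…normL
ordering) and are logged.

A geometric consequence worth stating: with linear interpolation, t always
lies at or above the second-smallest pairwise centroid distance, so members
of the closest centroid pair(s) are mixed *by construction*, at any
separation-to-noise ratio. "Everything core" is not an achievable state of
this rule; the realistic state — and the one the synthetic world reproduces
— is stable core calls away from the close pair(s) and stable mixed calls
within them.

## Frozen-PCA projection

PCA is fit once on the (adjusted) training cohort: features centered and,
by default, scaled by the training SD (zero-variance features dropped with a
warning when scaling); rotation from SVD; each component's sign fixed so its
largest-magnitude loading is positive, making scores bit-reproducible across
runs. New samples are projected with the stored center/scale/rotation — no
refitting — so training scores are invariant to the test set. Two components
are retained by default for plotting.

## Synthetic world

The generator emulates the paired-platform regime end to end. Defaults and
reasons (all log2 units unless noted):

| parameter | default | why |
|---|---|---|
| probe sets / signature | 500 / 60 | desk-scale stand-ins for 54,613 / 375 |
| target lengths | U(400, 800) nt | typical probe-set target span |
| training cohort | 6 × 59 = 354 | emulates the 355-sample training set; ≥~50 per subtype is needed for stable med/MAD/max outlier statistics |
| test cohort | 6 × 5 paired | small-batch clinical scenario |
| baseline means | U(4, 12) | RMA-scale dynamic range |
| signature baselines | [7.8, 9.2] | real signatures use mid-range, reliably detected probes; regulated values stay inside the global range so the quantile map is locally linear on both platforms |
| centroid shift | +3.0 on own slice | marker genes are overexpressed in their subtype; separation/noise ≈ 6.7 |
| slice sizes | 15:1:7:7:15:15 | close luminal trio (lumA near lumB and lumC), every other pair far; all pairwise distances sit well away from t so confidence labels are stable |
| noise_sd | 0.45 (total) | within-subtype spread *as observed on the training platform*; test samples carry the biological share √(0.45²−0.15²) and each platform adds its own technical noise back |
| platform effect | shift_g ~ N(0, 1²), array noise 0.15 | per-probe location/scale structure, the regime ComBat models |
| reads | 50,000 × 75 nt single-end, error 0.005 | desk-scale depth; paired mode (fragment 200 nt) implemented and tested |

Read sampling inverts the log2(x+1) convention — probability ∝ (2^e − 1)·
length, so zero log-expression yields zero reads — with uniform fragment
starts, truncation of fragments longer than their target, substitution
errors, and strand flips for half the reads. Everything is deterministic
under the configuration seed (separate child streams for targets, world
parameters, training noise, and each test sample).

What the generator does **not** emulate: real probe sequence content and
cross-hybridization, empirical tumor covariance (genes are independent given
the subtype), non-Gaussian platform distortions, library-preparation biases,
and intra-tumor heterogeneity. Green tests therefore establish that the
machinery is correct and self-consistent in the regime its models assume —
not clinical performance. One realistic behavior does carry over: samples
near the mixed-threshold or outlier boundary can flip confidence (never
subtype, in our runs) between platforms, the same borderline phenomenon real
paired cohorts show; at the default seed 29/30 paired calls agree exactly.

## Pipeline and interface

`run_rnabc(PipelineConfig(...))` executes load → control removal → index →
pseudoalign/EM → quantile normalize → ComBat (training + test pooled) →
train classifier on adjusted training → classify → frozen-PCA projection,
writing TSV/JSON artifacts plus a manifest (package version, parameters,
SHA-256 of file inputs) when an output directory is given; reruns with
identical inputs are byte-identical. A microarray matrix can replace the
sequencing input and flows through the identical normalize/correct/classify
path — the property the cross-platform comparison rests on. Ablation flags
(`skip_normalize`, `skip_combat`) drop a step on whichever input a run
consumes, so paired ablation studies stay same-treatment on both platforms;
`skip_normalize` feeds raw TPM to the later stages (the normalizer is the
only scale bridge, which the ablation tests confirm by the collapse in
concordance). The package is deliberately library-shaped: `PipelineConfig`
plus `run_rnabc` and the `examples/` scripts are the interface; there is no
shell entry point to keep the dependency surface and the configuration story
minimal.

## Known limitations

- No fragment-length model in the EM; short targets make this benign but
  abundances are not comparable to genome-based quantifiers.
- Parametric EB only (no non-parametric ComBat variant); no missing-value
  handling anywhere (hard errors instead).
- The outlier rule's `n` is a max statistic of the training cohort; with few
  training samples per subtype it is noisy and the core/outlier boundary
  becomes unstable (why the synthetic default is 59 per subtype).
- Quantile normalization to a mean-intensity target compresses distribution
  tails; values regulated beyond the training range are clipped to it.
- Single-sample batches skip batch correction by necessity; run samples in
  batches.
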