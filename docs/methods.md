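# Methods

This note documents the models behind `oncoclock`, the numerical and
design choices made where the problem left room, what the synthetic
data generator does and does not emulate, and the known limitations.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The mutational clock

Clonal SNVs — present in every tumour cell — were acquired on the
lineage from the fertilised egg to the tumour's most recent common
ancestor (MRCA). Because calls are made against a matched blood
control, mutations private to the pre-gastrulation embryo cancel, and
the clonal density per haploid bp, m̃, is proportional to time since
gastrulation (~2 weeks post conception): m̃(t) = (μλ/day)·(t − 14 d)/3.3×10⁹,
where μλ is the SNV yield per haploid genome per day. A copy-number
gain duplicates the mutations already on the gained allele; mutations
observed on ≥2 copies therefore pre-date the gain, and a significantly
sub-MRCA density of such amplified mutations identifies an earlier
common ancestor (ECA).

## Per-tumour density estimation

**Clonal VAF peaks.** On a segment with total copy number CN and minor
allele copies b, in a sample of purity ρ, clonal mutations on m copies
peak at VAF mρ/ζ with ζ = ρ·CN + 2(1 − ρ). Multiplicities {1, b, CN−b}
that coincide (b = 1) collapse; zero-copy peaks are dropped.

**Classification.** A mutation is subclonal when the binomial
lower-tail probability of its variant read count at the one-copy peak
is < 0.05 ("smaller than 5%" read strictly); on trisomic segments a
clonal mutation is early clonal when its count is compatible
(lower tail ≥ 0.05) with the two-copy peak, else late clonal. Early/late
refinement is defined only for k = 3; clonal mutations on k = 4
segments keep the plain clonal label. Variants on CN = 0 segments are
labelled clonal by convention and excluded from densities.

**Counting.** Timing uses autosomal segments ≥ 10 Mb with
1 ≤ CN ≤ 4. Within a segment, clonal SNVs (indels are classified but
excluded from densities) are assigned to multiplicity classes by
maximum posterior under a binomial mixture whose success probabilities
are fixed at the peak VAFs; only the weights are free (EM, ≤ 200
iterations, relative log-likelihood tolerance 1e-8; posterior ties
break toward the lower multiplicity, which is conservative toward the
MRCA). Because the subclonal filter is a 5%-level test, it discards
~5% of truly clonal one-copy mutations; each retained mutation is
therefore weighted by the inverse of its exact retention probability
(computed from its depth and assigned peak; weights capped at 2), which
removes the otherwise systematic ~5% downward bias of every density.

**MRCA density and CI.** m̃_MRCA sums, over retained segments l,
(n₁ + n_{CN−b}(CN−b) + n_b·b) / (g·CN_l) with g the total retained
length (the retained-segment total; whether excluded segments should
enter g is ambiguous, and this is the stricter reading). The 95% CI
resamples segments with replacement (1,000 replicates by default,
percentile method).

**ECA detection.** Only gained segments (CN ≥ 3 with both parental
alleles present) are tested; LOH segments contribute to m̃_MRCA but
never define an ECA. Each gained segment's amplified count is compared
with m̃_MRCA × (amplified length) by a one-sided negative-binomial
test. The NB size is estimated by method of moments from the
inter-segment variability of clonal counts around their MRCA
expectation, using non-gained segments only — so genuine early gains
cannot inflate the null dispersion — with a Poisson floor when
under-dispersed. Benjamini–Hochberg adjusted P ≤ 0.01 marks a segment
candidate-early; the pooled ECA density is the amplified count over
the amplified length across candidates (minor allele included only
when b ≥ 2), with its own segment bootstrap; each candidate is then
re-tested two-sidedly for conformity with the pooled density (same NB,
FDR 0.01): conforming segments are assigned to the ECA, the rest to
"neither". An absent ECA is a valid outcome. Detection power scales
with burden × segment length: at 0.2 SNVs/Mb and whole-chromosome
gains a half-density ECA is detected in >90% of synthetic tumours,
while at very low burdens (a few amplified mutations expected) the
test correctly refuses to call.

## Initiation model

A transient progenitor population (for group 3/4 medulloblastoma,
unipolar brush cell progenitors) grows exponentially at λ₁ − δ₁
(division λ₁, differentiation δ₁, per day) until time T, then declines
at λ₂ − δ₂ < 0. Drivers arise at divisions with probabilities μ₁ (on
wild-type) and μ₂ (on first-driver cells) and act by reducing
differentiation by factors r and s. The ECA is the birth of the first
driver's clone, the MRCA the birth of the first *surviving* malignant
clone.

**Default parameters.** T = 266 d (expansion described from ~week 9
p.c. to birth), λ₁ = 0.13/day, δ₁ = 0.10/day, λ₂ = 0.10/day,
δ₂ = 0.12/day, μ₁ = μ₂ = 3×10⁻⁶ per division, r = 3, s = 10, neutral
yield μ = 3.3 SNVs per haploid genome per division, N₀ = 1 (exposed as
a parameter; not externally specified). These are order-of-magnitude
plausible for a human cerebellar progenitor pool and give cohort MRCA
densities in the 0.03–0.08 SNVs/Mb range.

**Evaluating P_MRCA(t).** The default (`method="branching"`) is a
semi-analytic evaluation validated against exact Gillespie simulation:

1. First-driver clones are founded as a Poisson process with rate
   μ₁λ(u)N(u).
2. The probability w(u, t) that a clone founded at u produces at least
   one malignant clone by the cutoff t that survives to the population
   horizon follows the backward equation of the type-1 branching
   process, −dh/dv = λ(1−μ₂)h² + λμ₂(1−ν₂(v))h + δ/r − (λ+δ/r)h with
   h(t) = 1 and w = 1 − h, where ν₂(v) is the finite-horizon survival
   probability of a malignant cell born at v (two-phase birth–death
   extinction composition). Solved by RK4 on a fixed grid (1,200 steps
   by default) with the phase switch as a grid point; a multi-target
   vectorised sweep (`p_mrca_curve`) evaluates whole CDF grids in one
   backward pass.
3. Founder-population fluctuations are integrated out with the
   large-population mixture N(u) ≈ W·e^{(λ₁−δ₁)u}, where W has an atom
   at 0 of mass q = δ₁/λ₁ (early extinction) and is otherwise
   exponential with mean 1/(1−q), giving
   P = 1 − [q + (1−q)/(1 + Λ̄(t)/(1−q))] for the accumulated hazard Λ̄.

A factorised closed form in the product structure
1 − (1−P_I)(1−P_II)(1−P_III), with the phase-I integral factor F
pluggable, is retained as `method="closed_form"` for comparison. Its
printed phase-I integrand reduces to z^(−α), which diverges for
α = (δ₁−sλ₁)/(δ₁−λ₁) ≥ 1 — the generic regime when s > 1 — so the
default F is the birth–death finite-time survival form
∫₀¹ ν₂,E/(1 − (1−ν₂,E)z^α) dz (correct limits at z → 0 and z → 1).
Even so, the factorised expression tracks the exact process only in
order of magnitude; the branching method is the one that matches
Gillespie frequencies within Monte-Carlo error and is used everywhere
downstream.

**Conditional ECA time.** P(t₁ | t₂) = t₁/t₂ for t₂ ≤ T; for t₂ > T
the decline-phase expression (continuous at t₁ = T, normalised at
t₁ → t₂) applies. Event-time sampling inverts both CDFs on grids
(96-point time grid, 240 RK4 steps for the sampler; the accuracy knob
is exposed).

**Exact simulator.** `simulate_lineage` is an event-driven Gillespie
realisation of the full model with per-clone bookkeeping. Malignant
clones are strongly supercritical, so a clone reaching 256 cells is
frozen as immortal (extinction probability (δ/(sλ))^256 ≈ 0), and a
run ends as soon as the earliest surviving malignant clone is decided;
this keeps exact simulation tractable without touching the law of the
recorded MRCA/ECA times.

## Growth model

Tumour growth from the MRCA is a linear birth–death process
(division λ_T, loss δ_T < λ_T). A mutation arising at time t is
carried by i cells at t_end with the classical geometric law
P(0) = α_τ, P(i ≥ 1) = (1−α_τ)(1−β_τ)β_τ^{i−1},
α_τ = δ(e^{γτ}−1)/(λe^{γτ}−δ), β_τ = λ(e^{γτ}−1)/(λe^{γτ}−δ),
γ = λ−δ, τ = t_end − t. With neutral yield μ per haploid genome per
division, the expected spectrum is
S_k(i, μ) = ∫₀^{t_end} P_{1,i}(τ)·μkλ_T·N_T(t) dt (adaptive
quadrature, relative tolerance 1e-6), and the cumulative histogram
M_k(a, μ) evaluates the geometric tail in closed form inside one time
integral. The continuous-i approximation is midpoint-corrected
(bounds a−½ to b−½, approximating the discrete sum over [a, b)),
which brings it within a fraction of a percent of direct summation
for a ≥ 5. The loss/division ratio δ_T/λ_T is the identifiable shape
parameter; μ_eff = μ/(1 − δ_T/λ_T) summarises the subclonal yield.

Pseudo-heterozygous VAFs, ζ/(2k)·VAF, put subclonal tails from
different copy-number states on the common diploid-heterozygous scale.
The default fit window is pseudo-VAF 0.05 (typical WGS sensitivity) to
0.45 (clonal boundary), both configurable; screening for subclonal
selection is out of scope — callers supply an include list.

## ABC-SMC

Generation 0 samples the prior and keeps all particles; later
generations resample, perturb with a Gaussian kernel at twice the
weighted covariance (in transformed coordinates: log scale for
log-uniform priors), and accept at the adaptive tolerance
ε_next = median accepted distance. Termination: generation cap or
ε ≤ target; defaults are population 1,000 and 25 generations or
ε ≤ 0.05, with a scaled profile (population 200, 8 generations) used
by the validation studies. Stalled generations (acceptance collapse at
the stochastic noise floor) return the last complete population.
Credible bounds cut 2.5% from each tail of the weighted sample.

**Initiation fit.** Distance: mean of the two ECDF sup-norm distances
(model-simulated vs observed) of MRCA densities and of ECA densities,
after converting sampled event times to densities via μ and the
divisions-by-t curve; with no observed ECA densities, the MRCA term
alone is used and flagged. Default free parameters are (μ₁, μ₂) with
log-uniform priors over four decades; every prior is configurable.
The driver probabilities are only weakly identified by timing
distributions alone — posteriors are honest but broad.

**Growth fit.** Distance: RMS between observed and simulated
cumulative histograms, both divided by the observed value at the lower
cutoff. Dividing each curve by its *own* lower-cutoff value would
cancel μ exactly (M_k is linear in μ) and make the rate
unidentifiable, so the shared observed normaliser is used. Two
simulators are available. The deterministic expectation M_k(a) is the
default and is fast, but its posterior width is set by the final
tolerance alone; on stochastic tumours, whose subclonal tails carry
heavy genealogical fluctuations from the few earliest clones, such
intervals undercover. `simulator="tree"` grows a scaled Gillespie
tumour per proposal (window counts are nearly independent of tumour
size, so a 300-cell tree reproduces the fluctuation law of a 10⁹-cell
tumour) and yields calibrated credible intervals; it is what the
recovery studies use. Near-critical proposals are bounded by an event
cap and bounded retries; proposals that cannot grow a tumour receive
infinite distance. Priors: μ log-uniform over [0.1, 1000],
δ_T/λ_T uniform on [0, 0.999]. The quality floor refuses fits with
fewer than 30 subclonal variants in the window.

## Real-time calibration

The division rate of the tumour's founding lineage is
λ = (m̃_MRCA/μ + log(10⁹)·μ_eff/μ)/t_D, with t_D = age at diagnosis +
250 d of embryogenesis after gastrulation and 10⁹ cells taken as the
diagnostic size (all of m̃_MRCA, μ, μ_eff per haploid genome).
Interpretation: m̃_MRCA/μ counts progenitor generations to the MRCA and
log(10⁹)·μ_eff/μ = λ_T·t_growth counts tumour generations, so the
quantity estimated is the time-averaged division rate of the lineage,
(λ·t_MRCA + sλ·t_growth)/t_D; it equals the progenitor rate when the
growth phase is short relative to t_D or s = 1. Uncertainty is
first-order propagation with each input's true sensitivity — in
particular σ(μ_eff) enters multiplied by log(10⁹), matching its weight
in the mean. Per-tumour μλ values (uncertainty μ·Δλ + λ·σ(μ)) average
to the cohort SNV rate per day, which anchors the weeks-p.c.
conversion. Era labels: first trimester ≤ 13 weeks p.c., birth at 40
weeks p.c., infancy ≤ 92 weeks p.c. (configurable; the reported eras
use per-tumour point estimates, not posterior-weighted draws).

## CNV drivers

Large-scale CNVs: ≥ 1 Mb with coverage ratio outside [0.9, 1.1].
Events at least 25% of the chromosome's p-arm length (the p arm is the
reference arm as printed; switchable) get an arm label — "both" when
spanning the centromere — and enter the enrichment test: one-sided
exact binomial per chromosome at success probability exactly 1/24
(22 autosomes + X + Y, kept as stated even though timing is
autosome-only), Holm-corrected across the 24 chromosomes, significance
at adjusted P < 0.05, gains and losses separately. The hg19
arm/centromere table ships as a plain TSV; other assemblies can be
supplied. Focal calls use fixed thresholds: amplification at copy
number ≥ 10, homozygous deletion < 0.9 copies, translocation at event
score ≥ 5, TERT promoter hotspots at hg19 chr5:1295228/1295250, and
SNCAIP duplication as the PRDM6 enhancer-hijacking class; the driver
gene catalogue is supplied by the caller, not bundled.

## Synthetic data: what it emulates, what it does not

`simulate_tumor_reads` places clonal mutations as Poisson counts at
the chosen densities — on amplified alleles at the gain-time density,
on single copies at the MRCA density — draws read depths Poisson
around the target coverage and variant reads binomially at the
expected VAF, over a 22-autosome genome of whole-chromosome segments
with hg19-like lengths (gains are single-step events, so pre/post-gain
placement is exact). The canonical study conditions are purity 0.8,
100× coverage, 0.2 SNVs/Mb per copy (within the observed group 3/4
range and enough for ≥ 500 clonal SNVs), three trisomic chromosomes.
The generator records the realised (placed) density next to the
generative one: estimator-error checks compare against the realised
value, since the Poisson fluctuation of placement (~4% at 600 SNVs) is
not estimator error; CI-coverage checks use the generative value.
Subclonal tails are drawn either from the expected birth–death
spectrum (`sample_subclonal_tail`, model-faithful by construction) or
from exact Gillespie trees (genealogically realistic, heavier
fluctuations). Not emulated: sequencing error beyond binomial
sampling, germline contamination, mapping artefacts, subclonal copy
number, multi-step gains, kataegis/clustered mutations. Passing tests
therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to upstream calling artefacts.

`simulate_cohort` draws ECA/MRCA times from the initiation model
(inverse-CDF), converts them to densities via μ, and induces ages from
the growth model as the time for the malignant clone to reach 10⁹
cells.

## Problem sizes of the validation studies

Chosen so the full suite runs in minutes on one CPU: 200 read-level
tumours for estimator error/CI coverage and for each arm of the ECA
operating characteristics; exhaustive classification oracle to depth
50 plus 5,000 simulated clonal variants for the test size; 10⁴
Gillespie replicates at five parameter sets for the MRCA-time law and
10⁴ for the clone-size law; 20 Gillespie tumours (3,000 cells, varied
δ_T/λ_T) for ABC recovery at the scaled profile; 20 round-trip tumours
for the division-rate recovery; 500 null cohorts for enrichment size.
The acceptance script re-runs the same studies at comparable or
slightly reduced sizes from a caller-supplied seed.

## Known limitations

- The factorised closed form of the MRCA-time law is kept only for
  comparison; quantitative work should use the default branching
  evaluation.
- Per-tumour growth fits against single stochastic tumours inherit the
  genealogical variance of the subclonal tail; only the tree simulator
  propagates it into the posterior, at ~10× the cost.
- The pooled ECA density conditions on segments passing the
  candidate-early test, so it carries a winner's-curse downward bias of
  a few percent when amplified counts are small; the detection calls
  themselves are unaffected.
- The NB dispersion estimate needs several non-gained segments; highly
  aneuploid genomes with few diploid segments fall back toward Poisson
  and may overcall early segments in the presence of unmodelled
  overdispersion.
- Real-time conversion assumes a constant μλ per day from gastrulation
  to diagnosis; developmental rate changes bias early timestamps
  accordingly.
- The pipeline assumes single-tumour calls with matched-normal
  subtraction already done; multi-sample VCFs and tumour-in-normal
  contamination are out of scope.
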