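# Methods

## Scope and data model

The pipeline operates on biallelic genotype likelihoods
(`GenotypeLikelihoodMatrix`): per site × sample triplets
P(reads | hom-ref), P(reads | het), P(reads | hom-alt), max-normalized,
with read depths and optional allelic depths. Hard calls
(`GenotypeMatrix`, alt-allele dosage 0/1/2/missing) are derived views.
Coordinates are 0-based half-open internally; VCF import/export converts
to 1-based. Windows are `[k·W, (k+1)·W)`.

## Synthetic data generator

`simdata` simulates what the estimators assume, nothing more:

- **Genealogies.** Each RAD locus is an independent Kingman coalescent
  genealogy (no intra-locus recombination — RAD loci are ~100–150 bp and
  far apart). Piecewise-constant demography enters by time rescaling:
  waiting times are exponential with rate C(k,2) on the rescaled axis
  τ = ∫dt/ν(t) and mapped back through the piecewise-linear inverse.
- **Mutations.** Poisson with rate θ/2 per site per unit of
  2N-generations time, placed on branches proportionally to length at
  distinct uniform positions (infinite sites within the finite locus;
  the mutation count is capped at the locus length). Site tables include
  every base of every locus, so invariant sites are first-class and the
  zero SFS class is meaningful.
- **Reads.** Depth ~ Poisson(mean_depth) per site × sample; each read
  reports the alternate allele with probability e, ½, 1−e for dosage
  0, 1, 2. Likelihood triplets follow the standard independent-reads
  biallelic model. The default error rate 0.002 is a generator fixture
  choice (the upstream variant-calling error model is not part of this
  package's scope), and the default mean depth 2.8 matches typical
  low-coverage RAD data.
- **Neo-sex panel.** Three region kinds: `autosomal` (both sexes diploid
  at a background θ, default 0.001 — the diversity scale of a severely
  contracted island population); `neo_suppressed` (background variation
  plus obligate-heterozygote sites in females at a fraction
  `gametologue_divergence` of positions, default 0.0115 = 1.15 fixed W/Z
  differences per 100 bp); `ancestral_Z` (female dosage is twice one
  haplotype's allele — all reads from a single chromosome copy, true
  heterozygosity zero; males diploid). Ground-truth intervals are
  returned for recovery tests.
- **Pedigrees.** Founders in Hardy–Weinberg equilibrium at per-SNP
  frequencies uniform on [0.05, 0.5] plus one offspring per founder
  pair, for relatedness validation.

What the generator does **not** emulate: allele dropout at restriction
sites, mapping/alignment artifacts, base-quality variation, linked
selection, or population structure. Passing recovery tests therefore
demonstrates correctness of the estimators under their own model, not
robustness to those real-data pathologies.

## Genotype calling and its error floor

Calls are the likelihood argmax, missing below 5 reads (the windowed
heterozygosity analysis considers only ≥5× sites) or on an exact
likelihood tie (ties are never broken arbitrarily — a biased tie-break
would leak into the sex scan). A consequence worth knowing: with a
symmetric per-read error rate e, a single miscalled read among d ≤ 8
reads makes the het likelihood exceed hom, so prior-free argmax calling
has a heterozygous false-call floor of roughly 10⁻⁴–10⁻³ depending on
the depth distribution (~3×10⁻⁴ at mean depth 20, e = 0.002). The scan
thresholds below are interpreted against that floor; analyses at mean
depth ≲ 8 should not rely on small absolute heterozygosity contrasts.

## Heterozygosity scan and region calling

Per individual, the proportion of heterozygous calls is computed in
250 kb windows (windows with <100 genotyped sites emit nothing) and
smoothed by tricube-weighted local *linear* regression over a fixed
10 Mb genomic span (half-width 5 Mb; local linear fits reproduce linear
trends exactly and are evaluated only at observed windows — excluded
windows are neither used nor imputed).

Sex inference: r = median Z-scaffold window heterozygosity / median
autosomal window heterozygosity; females (single Z) have r near zero.
Thresholds F < 0.25, M > 0.6, unknown otherwise, requiring ≥10 valued Z
windows. These defaults were validated on simulated panels.

Region calling uses the female/male contrast at two aggregation scales,
because the two region classes carry very different signals:

- **neo_suppressed** (strong absolute signal — obligate-het gametologue
  sites put females at ~0.012 against a ~0.001 background): windows are
  flagged on the *raw* rates pooled within sex (Σ het calls / Σ called
  sites — per-individual medians are too sparse at low diversity) where
  female ≥ 3× male and female ≥ 0.002; maximal runs of ≥8 flagged
  windows (gaps ≤2 bridged) are candidate regions; a candidate is
  reported only if it overlaps ≥1 window flagged on the 10 Mb-smoothed
  medians, so isolated raw noise (e.g. collapsed repeats) cannot seed a
  call. Raw-scale flagging keeps boundaries at window resolution: on
  synthetic 5 Mb truth regions at depth 20, both boundaries land within
  one window in 20/20 replicates.
- **ancestral_Z** (weak signal — a *reduction* of the small female rate
  toward the error floor, female < 0.25× male): per-window raw tests sit
  at the floor's noise level, so runs are taken from the smoothed
  medians instead. Detection is reliable when the Z is its own
  scaffold/chromosome (as in a real karyotype), but boundaries are only
  accurate to the smoothing scale, and a Z segment embedded mid-scaffold
  at sizes below the span is beyond this detector. This asymmetry is an
  information limit of the 0.25 ratio against the heterozygous-call
  floor, not a tuning artifact.

Gametologue divergence of a called region is the mean per-site
heterozygous-call density across females (denominator: genotyped sites,
variant and invariant), reported per 100 bp. Background heterozygosity
is included in the estimate (~+0.1/100 bp at θ = 0.001).

All four caller knobs (fold threshold 3, absolute floor 0.002, run
length 8, gap 2) and the ancestral ratio 0.25 are exposed.

## SFS estimation

Per site, the likelihood of each total alt-allele count j among n = 2D
chromosomes is the exchangeable-sampling sum

    L_s(j) = C(n,j)⁻¹ Σ_{Σg=j} Π_d C(2, g_d)·GL_d(g_d),

computed by convolving individuals one at a time (O(D²) per site,
vectorized across sites). Zero-depth samples contribute flat triplets,
keeping n fixed. The spectrum maximizes Σ_s log Σ_j p_j L_s(j) by EM;
this log-likelihood is concave in p, so EM converges to the global
optimum. Stopping: relative log-likelihood change < 10⁻⁸ or 100
iterations (the cap used in the motivating analysis); hitting the cap
sets a flag rather than raising. Folded mode sums the j and n−j
likelihood columns before the EM. Folded spectra are the default
(no outgroup polarization is assumed); unfolded mode is retained for
simulation work. Bootstrap resamples sites (or whole RAD loci, since
sites within a locus are linked); drop-one-out re-runs the EM without
each individual in turn.

## Diversity statistics

π = [Σ_i η_i · 2i(n−i)/(n(n−1))] / L with the invariant class in the
denominator only; identical on folded and unfolded spectra (the class
weight is symmetric in i ↔ n−i). θ_W = S/(a_n L). Tajima's D uses the
original 1989 constants, and is an error (not 0) at S = 0. The scalar
calculators are direct formula implementations; significant-figure
rounding helpers are public because downstream reporting uses one- and
two-significant-figure values.

## Demographic inference

**Expected SFS.** The lineage count of the rescaled coalescent is a pure
death chain with rates c_k = k(k−1)/2. Its state distribution is pushed
through each epoch with `expm` of the bidiagonal generator; the expected
rescaled occupancy of an epoch is A⁻¹(p_end − p_start) (triangular
solve), and real-time occupancy multiplies by the epoch's ν. Combined
with the branch-subtending probabilities p(i|n,k) this gives E[η_i]
exactly — machine precision against θL/i at constant size for n ≤ 60,
and within Monte-Carlo error of an independent coalescent simulator for
randomized piecewise histories. This route avoids both diffusion PDE
solvers (a grid-size knob therefore has no analogue here) and the
alternating-sum instability of explicit spectral formulas at large n.

**Nested fits.** The 0/1/2-change ladder maximizes the multinomial
composite likelihood of the polymorphic *shape* (matching the
convention that θ is not a free parameter); Nelder–Mead on
log-parameters from random multi-starts (default 10, up to 50). θ̂ is
then set so the expected segregating-site count matches the
observation. Composite likelihoods are comparable for point estimation
only — linked sites violate the independence assumption, so no
significance test is attached.

**Fixed-contraction scan.** Grid of 10 log-spaced relative sizes in
[0.001, 0.01]; the most recent epoch's ν is pinned at each grid value.
With the epoch's *duration free* the scan is intentionally faithful to
its weak-signal reality: a recent severe contraction affects the
spectrum almost solely through its scaled severity τ = duration/ν, so
the free duration compensates any grid size and the per-grid composite
likelihoods are near-flat — the quantitative face of "a recent collapse
leaves little mutational trace". Passing `duration=` (in 2N_anc
generations, e.g. from an independently dated event such as a known
settlement) pins the epoch length, and the grid becomes sharply
informative: a true ν = 0.003 collapse is then localized within one
grid step in ≥9/10 synthetic replicates.

**Stairway-style trajectories.** Per-lineage-count interval k the
scaled size s_k = 4N_k μ enters E[η_i] linearly
(E[η_i] = L Σ_k s_k p(i|n,k)/(k−1)), so the fit is a Poisson composite
likelihood over a non-negative linear model (L-BFGS-B on log s with
analytic gradients). Breakpoints at equally spaced quantiles of
expected coalescent time under a constant null group adjacent k
intervals to share one parameter; the breakpoint count (options 12, 25,
37, 50) is chosen by held-out composite likelihood on a random 67%
multinomial split of polymorphic sites, the full data are refit, and
percentile CIs come from multinomial site bootstraps (default 200; desk
tests use 20 via the flag). Output steps are converted to individuals
and years via μ and generation time. This construction is this
package's own; it shares the flexible-epoch idea with Stairway Plot but
is not claimed to be equivalent to that tool's internal "two-epoch"
mode.

## Relatedness screening

Reads sample a genotype's two alleles binomially, so the
error-corrected read-ratio dosage x = 2(n_alt/d − e)/(1 − 2e) is
conditionally *unbiased* for the true dosage at any depth — unlike hard
calls or posterior-mean dosages, whose shrinkage attenuates pairwise
products at low coverage (measured ~0.76× at depth 5, which would pull
parent–offspring pairs from 0.5 to ~0.38). Off-diagonal relatedness is
the ratio-of-sums GRM over SNPs covered in both samples. Allele
frequencies are estimated from posterior-mean dosages (iterated once;
shrinkage is harmless for frequencies). Because frequencies estimated
from the panel itself remove the mean component (the absolute level of
the GRM is unidentifiable), the off-diagonals are anchored by
subtracting the median entry — correct for screening panels in which
unrelated pairs are the norm, and documented as wrong for mostly-related
panels. The diagonal splits each SNP's reads into two halves and
multiplies their centered dosages: read noise is independent between
halves, so self-relatedness is estimated without the noise inflation of
a squared noisy dosage; values near 1 indicate a calibrated SNP set.
The per-SNP Hardy–Weinberg disequilibrium filter
(D = freq(hom-ref) − p², keep 0 ≤ D ≤ 0.1) strips loci with structural
excess heterozygosity — collapsed gametologue loci are obligate-het
with D = −0.25 — at the price of a mild selection effect on the
diagonal (a few percent, visible at high depth). On depth-5 pedigree
panels of 26 samples × 5×10⁴ SNPs the estimator recovers
parent–offspring pairs at 0.50 ± 0.03 and self-relatedness within
[0.97, 1.10].

## Pipeline

`run_pipeline` executes load → filter → call → sex scan → scaffold-level
masking (any scaffold overlapped by a neo_suppressed or ancestral_Z call
is excluded entirely, mirroring scaffold-wise exclusion practice) → SFS
→ diversity → optional demography → relatedness, logging every filter
count and echoing the config into the output directory. The report is
deterministic given (inputs, config, seed).

## Problem sizes and numerical choices

Synthetic validation uses panels of 10–26 diploids, 10⁵–10⁶ sites and
10–50 replicate seeds; spectra for model-fit recovery use θ = 0.005 per
site so the shape likelihood carries ~2×10⁴ segregating sites (at
θ = 0.001 the one-change model's ν̂ has sampling scatter wider than the
recovery band even at the likelihood optimum). Scan restarts default to
10; stairway bootstrap defaults to 200 with 20 used in desk tests.
Optimizer tolerances: Nelder–Mead xatol 10⁻⁶ / fatol 10⁻⁸; EM tol 10⁻⁸;
nesting assertions allow 10⁻⁴ slack for optimizer noise. Degenerate
inputs: zero-duration epochs collapse silently; θL exceeding the site
budget (negative expected invariant class) raises; spectra with no
polymorphic sites are rejected by the fitters.

## Known limitations

- The ancestral-Z boundary resolution and the mid-scaffold-Z blind spot
  described above.
- Argmax genotype calling is prior-free; its het false-call floor makes
  heterozygosity contrasts below ~10⁻³ unreliable at depths ≲ 8.
- The contraction scan's severity is unidentifiable without an external
  date anchor (by design of the data, not the code).
- Relatedness off-diagonals are anchored to a zero-median background and
  shade by O(1/N) for pairs involving duplicated/highly related samples.
- No migration, two-population models, linkage-aware likelihoods, or
  intra-locus recombination.
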