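# Methods

This note records the models behind each track, the parameters that matter,
the numerical choices made where the design was genuinely open, and the
limits of what the synthetic-data tests demonstrate.

## Imaging: the DNA Damage Index

**Model.** A nucleus injected into an oocyte carries chromatin-bound H2B
(proportional to chromatin amount and probe dose) and γH2A.X-bound Fab
(proportional to double-strand-break burden). Both are integrated over the
segmented 3D nucleus after background subtraction; their ratio cancels
probe dose and nucleus size, and dividing by the reference (fresh sperm)
cohort's median ratio puts all groups on a common unitless scale with the
reference median at 1.

**Segmentation** runs on the H2B channel — the probe common to every
injected nucleus — with Otsu's threshold and 26-connected 3D components;
components below `min_volume` (default 20 voxels) are discarded.
**Background** is the per-channel median of a 2-voxel dilated shell around
each mask, with other segmented nuclei excluded from the shell; a shell
median is robust to a bright neighbour (an oocyte's own metaphase
chromosomes sit near injected nuclei) where a whole-image statistic is not.
If the shell is empty the whole-frame histogram mode is used and a warning
raised. The integrated signal is `Σ(voxel − background)` over the mask,
clipped at zero as a sum (per-voxel clipping would bias noisy signals
upward).

**Normalization exactness.** DDI divides each raw ratio by the reference
median (interpolated: mean of the central pair at even n). For even-sized
reference groups the recomputed median of the normalized values can land
one ulp off 1.0 in floating point, so `compute_ddi` renormalizes to the
fixed point (empirically at most two passes) and the reference median is
exactly 1.0 in float. Scale invariance (multiplying both channels by any
c > 0) holds by construction.

**Competence** uses a strict inequality: DDI > 2 ⇒ incompetent, so a
nucleus at exactly 2 is competent. The threshold is exposed (CLI
`--threshold`).

**Time courses** re-segment every frame and link detections by nearest
centroid in physical (µm) coordinates with a 5 µm/frame gate — adequate for
nuclei that drift slowly relative to their spacing; no motion model is
attempted. A series is "repair-consistent" when its final value is below
its initial one.

**Open choice.** Whether γH2A.X should be integrated over the whole nucleus
or peripherally weighted (damage concentrates at the nuclear periphery in
heavily damaged material) is left at whole-nucleus integration; peripheral
enrichment is visible in the measurements (mask erosion would expose it)
but plays no role in the DDI as computed here.

## Statistics

**Steel many-one test.** Each treatment is compared with the single control
by the Mann–Whitney U (mid-ranks for ties); each U is standardized by its
permutation mean `n_c·n_t/2` and the tie-corrected variance
`n_c·n_t(n_c+n_t+1)/12·(1 − Σ(t³−t)/(N³−N))` (tie factor from the pooled
sample — any fixed monotone standardization yields a valid max-T
statistic). Family-wise adjusted p-values come from the joint permutation
distribution of the maximum standardized statistic: all observations are
relabelled together, preserving the dependence induced by the shared
control. When the multinomial count of distinct label assignments is at
most `n_permutations`, the null is enumerated exactly — in particular the
single-treatment small-sample case reduces, exactly, to the enumerated
rank-sum permutation test. Otherwise `n_permutations` (default 10,000)
random relabellings are drawn with the usual `(b+1)/(B+1)` estimate; a seed
is then required, and fewer than 100 permutations is refused. Sidedness
defaults to two-sided. Like any permutation test on a discrete statistic,
attained size is at or slightly below nominal at small n (measured ≈ 0.04
at α = 0.05 with three groups of 10).

**Assumption checks** are Shapiro–Wilk (3 ≤ n ≤ 5000) and Bartlett (≥ 2
non-constant groups), via scipy. **Fisher exact** on 2×2 outcome tables is
the standard two-sided hypergeometric sum (tables with probability ≤ the
observed); a zero margin returns p = 1 with a warning. The test suite
verifies it against an independent exact-rational enumeration for every
table with N ≤ 12.

## Proteomics: deamidation

**Counting score.** PSMs below 95% identification confidence are rejected
(boundary inclusive: exactly 95 is kept). The denominator is the number of
distinct peptide sequences containing at least one N or Q; the numerator
counts those with at least one retained PSM bearing a deamidation
modification on an N/Q residue — one deamidated observation flags the
sequence permanently. The score is therefore invariant to PSM row order and
duplication, and adding evidence to an already-flagged sequence cannot
change it. Sequence-level (not spectrum-level) counting is used for the
denominator; per-protein grouping is available.

**Mass constants** are computed from NIST monoisotopic atomic masses:
deamidation replaces NH₂ by OH, Δm = m(O) − m(N) − m(H) = +0.98402 Da; one
¹³C substitution adds 1.00336 Da. Their 19.3 mDa difference is below
routine LC-MS resolving power at peptide m/z, which is why the deamidated
form must be separated chromatographically, not by mass.

**XIC decomposition.** The non-deamidated channel is fit with one Gaussian
(area-parameterized). The +0.984 Da channel is modelled as (i) an
interference Gaussian *constrained* to the parent peak's fitted RT and
width with free amplitude — the M+1 isotopologue co-elutes exactly with its
parent — plus (ii) a free Gaussian for the deamidated peptide. The
deamidated area is component (ii)'s; the reported fraction is
`A_deam/(A_deam + A_nondeam)`. An averagine/exact-composition M+1/M ratio
is computed as a consistency check on the interference amplitude but never
subtracted blindly: the separation argument is chromatographic. If the
fitted RTs are closer than one fitted width the case is flagged unresolved
and only bounds on the fraction are reported (lower bound 0 — everything
could be interference — upper bound from the total shifted-channel area).
An exponentially modified Gaussian is available (`model="emg"`) for tailing
peaks. Fits use `scipy.optimize.curve_fit` with non-negative area bounds;
initialization takes the interference amplitude from the shifted channel's
height at the parent RT and the deamidated RT from the largest residual
more than one width away.

## Ancient DNA

**QC.** Reads with mean Phred quality strictly below 20 are removed ("mean
per read" is the chosen reading of a per-read QV threshold; per-base
trimming is deliberately not performed), as are reads containing 'N';
duplicates (same reference, start, strand, length) collapse to one. The
filter is idempotent and logs per-class counts.

**Pileup and consensus.** Per covered site, base counts (A/C/G/T/other),
plurality consensus, and `n_common`/`n_different` with
`n_common + n_different = depth` everywhere. Ties resolve to the reference
base when it is among the tied (else alphabetically) and the site is
flagged ambiguous — deterministic and auditable; IUPAC codes are not used.

**Terminal damage profile.** For each read, read and reference segment are
oriented to the template strand (reverse-complemented for '−' reads) so
position 0 is the molecule's own 5′ terminus; the 5′ statistic is the
frequency of T where the oriented reference has C, the 3′ statistic G→A
symmetrically. Denominators count reference-C (resp. G) opportunities, so
undamaged data gives exact zeros.

**Decay fit.** The profile is summarized by `p(i) = δ0·λ^i`, the simplest
two-parameter curve consistent with end-elevated deamination (a full
Bayesian damage model is out of scope). The fit is linear least squares on
log-frequencies with two numerical choices: positions are weighted by their
*observed substitution count* (the delta-method variance of log(num/den) is
≈ 1/num under binomial sampling, so this is inverse-variance weighting —
opportunity-count weights would let deep, nearly-empty tail positions
dominate), and the fit is restricted to the contiguous leading run of
positions with at least one observed substitution, since beyond it the
expected counts are sub-unit and a single stray mismatch would swing the
log scale. Noiseless geometric profiles invert exactly; at 10,000 reads the
parameters are recovered within a few percent across
δ0 ∈ {0.1, 0.3} × λ ∈ {0.3, 0.5, 0.7}. An all-zero profile returns δ0 = 0
with the decay undefined and the fit flagged.

**Fragment lengths.** Histogram at 5 bp bins, 3-bin moving average, mode =
center of the maximal smoothed bin; the nucleosome flag tests the mode
against the 140–180 bp window (the 146 bp histone-octamer footprint plus
linker breathing room).

**SNV calls.** A site is emitted iff depth ≥ 3 and the most frequent
non-reference base has ≥ 2 supporting reads (both inclusive; "minimum SNP"
is read as minimum alternate-supporting reads). Multi-allelic sites report
the top alternate, ties alphabetical. Calls are monotone in both
thresholds. Output is minimal VCF 4.2 (1-based positions, DP/AD INFO).

**Coordinates** are 0-based half-open throughout; SAM input converts on
read, and records with indels or clipping are skipped with a logged count
(gapless proxy for "aligned uniquely and properly"). A TSV dialect
(documented in `paleovia/io.py`) carries the same six fields in plain text.

## Synthetic generators

All generators are deterministic given their seed and return exact ground
truth with the data.

* **Image stacks**: nuclei are spheres rendered on a (z, y, x) grid (default
  24×96×96 voxels at 2×0.5×0.5 µm — a confocal-like anisotropic stack),
  blurred by an isotropic Gaussian PSF (σ = 1 voxel), with the γ channel
  scaled by `gamma_per_damage × damage_level`. Noise is additive Gaussian
  only — no Poisson term — so truth integrals are exact; for a ratio of
  large integrated signals the noise model is second order. An optional
  linear per-frame `repair_rate` emulates damage resolution during
  live imaging. Nuclei overlapping the boundary (including a 3σ blur
  margin) are rejected. Not emulated: peripheral damage enrichment,
  photobleaching, drift, metaphase chromosomes in the field — so passing
  tests demonstrate correctness of segmentation/measurement/normalization
  arithmetic, not robustness to real microscopy artefacts.
* **DDI cohorts**: per-group true damage from a configurable distribution;
  the raw γ/H2B ratio is proportional to damage with 5% lognormal noise;
  development outcome is Bernoulli with success probability logistic in
  damage, midpoint at damage = 2 (matching the DDI > 2 failure rule) and
  slope 2 by default.
* **PSM tables**: random 8–16-mer peptides over the 20 amino acids; each
  spectrum deamidates every N/Q residue independently with the configured
  probability; confidences uniform on [80, 100] (so the 95% filter removes
  ~75% — a deliberately harsh regime exercising the filter).
* **XIC traces**: sums of area-parameterized Gaussians on a time axis
  extending 6 widths beyond the outermost peaks, conserving requested areas
  to ≪ 0.5% under trapezoidal integration.
* **Ancient reads**: fragment lengths from a Gaussian mixture (default a
  single 158 ± 8 bp mononucleosome component; analyses also use
  0.8·N(158, 8) + 0.2·N(320, 30) for a dinucleosome shoulder), uniform
  placement, equiprobable strands; C→T applied on the template strand at 5′
  position i with probability δ0·λ^i and G→A symmetrically from the 3′ end;
  qualities N(35, 3) clipped to [2, 41], Phred+33 on disk. Not emulated:
  sequencing error, mapping error, overhang-length-dependent damage — the
  recovery tests validate the estimator against its own generative model,
  which is the point of a parameter-recovery check, not evidence about any
  particular specimen.

## Problem sizes

Defaults used by the tests, analysis scripts and the acceptance script:
cohorts of 30 embryos per group; stacks of 24×96×96 voxels with 2–3 nuclei;
10,000 reads on a 5 kb reference for damage-profile recovery; 500
null replicates × 10,000 permutations for Steel calibration; 50 peptides ×
5 spectra for PSM scoring. These sizes give sub-percent Monte-Carlo noise
on every reported quantity while keeping any single check in seconds.

## Known limitations

* The Steel implementation is permutation-based; it does not reproduce
  tabulated asymptotic critical values (by design), and at very small n its
  attained size is below nominal, as for any discrete exact test.
* The XIC decomposition assumes one deamidated species per trace; multiple
  deamidation sites with distinct RTs would need more components.
* The damage fit is a summary curve, not a likelihood model; it does not
  separate single- from double-stranded overhang contributions.
* Tracking is nearest-centroid with a hard gate; crossing nuclei can swap
  identities.
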