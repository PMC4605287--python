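# Methods

This note documents the models behind `ambarcode`: what is computed, which
assumptions and defaults it rests on, and what the synthetic experiments
do and do not demonstrate.

## Theoretical AM barcodes

A labelling methyltransferase deposits one fluorophore per motif
occurrence. The expected image of a fully labelled, uniformly stretched
molecule is a sum of point spread functions:

```
I(x) = Σ_j  G(x − c_j; σ),      c_j = site start + motif length / 2
```

with `G` a unit-integral Gaussian. "The PSF spans 1500 bp" is interpreted
as the **full width at half maximum** of that Gaussian (FWHM is the
standard width convention for a diffraction-limited spot), giving
σ = FWHM / (2 √(2 ln 2)) ≈ 637 bp at the default `fwhm_bp = 1500`. The
profile is sampled at pixel centres on a grid extending 3σ beyond both
genome ends (zero signal outside; molecules are treated as linear — both
model phages are imaged as linear DNA). Because each label carries unit
integral, `sum(profile) · bp_per_pixel` equals the number of labelled
sites; this mass conservation is exact up to Riemann-sum discretisation
(σ ≫ pixel, error ≪ 0.1 %) and is asserted in the tests.

Defaults and their reasoning:

| parameter | default | why |
|---|---|---|
| `fwhm_bp` | 1500 bp | diffraction-limited spot over nanochannel-stretched DNA |
| `bp_per_pixel` | 225 bp | 65 nm camera pixel at 100×, DNA at ≈ 0.29 nm/bp |
| motif | `TCGA` | M.TaqI recognition site |
| coordinates | 0-based, half-open | label placed at motif centre; sub-motif placement (≤ 4 bp) is far below pixel scale |

Motif scanning matches exactly, reports overlapping occurrences, never
matches N, and with `both_strands` also reports reverse-complement hits at
their forward-strand window start; palindromic motifs (TCGA, ATCGAT)
therefore yield identical site trains with either setting.

The **intercalation barcode** models GC-highlighting staining: the
per-base indicator (G/C → 1, A/T → 0, N → 0.5, an unbiased value for
unknown bases) is convolved with the same unit-sum Gaussian kernel at 1 bp
resolution and sampled on the same grid, so interior values are a smoothed
local GC fraction.

## The molecule simulator

The simulator stands in for experimental nanochannel snapshots. It
decomposes the experimental variability of this assay type — labelling
efficiency, degree of stretching, dye photophysics — into four
independent, separately testable components, applied in a fixed order:

1. **labelling**: each site kept with probability `label_efficiency`
   (default 0.8 — high but imperfect single-step chemistry);
2. **stretch**: one global factor `s ~ N(stretch_mean, stretch_sd)`
   (defaults 1.0, 0.02) scales label coordinates before convolution; the
   PSF stays fixed on the pixel grid because its width is optical, not
   molecular, in origin. Local (piecewise) stretch inhomogeneity is a
   documented limitation;
3. **brightness**: per-label lognormal with mean 1 and CV
   `brightness_cv` (default 0.3), so efficiency and brightness are
   separately identifiable from count and intensity moments;
4. **camera**: additive background (default 0.05) plus zero-mean Gaussian
   noise (sd 0.05), both in units of a single label's peak height, then a
   clip at zero — photon counts are non-negative. The clip is this
   package's choice; it only bites where background + signal is within
   ~2 noise sd of zero.

Finally the trace is reversed with probability `flip_prob = 0.5`
(molecules enter the channel in either orientation). With every noise term
switched off the output equals the theoretical barcode bit-for-bit, which
pins the simulator and the barcode builder to the same conventions. The
defaults were chosen once to resemble published single-frame snapshots of
M.TaqI-labelled phage genomes (visible molecule-to-molecule variation,
true-reference CC ≈ 0.9); they are not calibrated to any measured
data set.

Determinism: a `numpy` `Generator` seeded from `SimulationParams.seed`
drives all draws; `simulate_library` derives one child stream per molecule
from `(seed, genome index, replicate index)`, so libraries are reproducible
and any single molecule can be regenerated in isolation.

## Cross-correlation matching

The match statistic is the maximum Pearson correlation over integer pixel
shifts, both orientations, and a stretch grid (default ±6 % in 0.5 %
steps — generous cover for the simulator's 2 % stretch sd; the grid is
configurable). The reference, already padded by 3σ of zeros from the grid
convention, is resampled by linear interpolation for each trial stretch;
correlation is computed on the overlapping pixels only, subject to a
minimum overlap of 80 % of the query. Pearson on the overlap makes the
score invariant to affine intensity transforms of either profile, which is
what lets a fixed CC threshold act as a scale-free quality bar.

Implementation: all shifts are evaluated at once from cumulative sums and
one full cross-correlation (the classic normalised-cross-correlation
identity); a brute-force loop with `scipy.stats.pearsonr` serves as the
oracle in the tests. Windows with zero variance are invalid. Ties are
broken deterministically: smallest |shift|, then '+' orientation, then
stretch nearest 1.0, then reference list order.

Classification assigns each molecule to the arg-max reference if the
winning CC **exceeds** 0.85, else it is reported unclassified; the
threshold is applied as an acceptance condition on the winning CC (a
pre-filter mode can be emulated by filtering on the per-reference CC
vector, which is always reported). Detection of a strain in a sample
follows the screening design: the assignment histogram of the sample's
molecules over all references is summarised by its mean and sample SD, and
a reference counts as detected when its count exceeds mean + 1 SD. In a
deliberately balanced multi-strain experiment this rule is evaluated per
truth strain (each strain's own molecules against the library), since a
pooled balanced histogram always has at least one count at or below its
mean.

`paired_cc_test` is the paired t-test on per-molecule CC against the true
versus a false reference (`scipy.stats.ttest_rel`); zero-variance
differences are reported explicitly (±∞ with p = 0 when the mean differs
from zero, a degenerate flag when identically zero) instead of propagating
NaN.

## Information scores

A profile's identifying power is quantified relative to the typical
experimental noise `noise_sd`:

* **feature extraction**: all strict local extrema (run-compressed; profile
  ends included as run boundaries) form an alternating max/min sequence;
  the adjacent pair with the globally smallest depth is removed repeatedly
  while that depth ≤ `prominence_factor · noise_sd` (default factor 2).
  This is classical persistence pruning; removing the smallest pair first
  preserves alternation and ordering.
* **space score**: the number of surviving maxima.
* **contrast score**: Σ min(depth / noise_sd, `contrast_cap`) over adjacent
  surviving pairs (default cap 5) — beyond the cap, extra modulation depth
  no longer helps to separate neighbouring features, so its contribution
  saturates. An isolated peak is scored on both flanks, making its score
  symmetric (2 × cap when saturated).
* **information score**: `is_value = space + contrast` with equal default
  weights (configurable); the text this procedure reconstructs ranks
  profiles by feature count *and* depth without stating a combination
  rule, and equal additive weights are the least-informative choice. The
  score is a concrete reconstruction realising the stated properties
  (feature count, noise-relative contrast, saturation), not a reproduction
  of any legacy implementation's exact values.

Molecule filtering keeps profiles with `is_value ≥ is_threshold`. No
universal threshold is shipped: the appropriate value depends on the noise
level and pixel scale of the data at hand, so it is a required
configuration input where filtering is enabled.

**Cross-scheme comparison.** To compare chemistries with different native
intensity units, each theoretical profile is rescaled to **unit mean
intensity** before scoring, and `noise_sd` (default 0.1) is a fraction of
that mean — the scale on which shot noise and background live. This
choice, rather than equalising a quantile range of the modulations
themselves, preserves the physical difference the comparison is about:
sparse enzymatic labelling produces deep relative modulations, while
dense/frequent labelling produces shallow ones. Scores are reported per
genome and per kbp (the score itself is length-independent, so both
normalisations are given). A paired t-test across genomes accompanies the
mean enzymatic/intercalation ratios.

## Synthetic experiments: what they show

`ambarcode.experiments` builds reference panels of i.i.d. random genomes
(default 50 % GC) and runs typing and information-comparison experiments
against them. Two caveats define what passing results mean:

* i.i.d. genomes have no large-scale GC landscape, so their intercalation
  barcodes carry almost no information beyond the molecule envelope —
  the enzymatic/intercalation ratios measured on random panels (≈ 7–8×)
  are far larger than on real phage genomes, where GC varies on long
  scales (on λ: space 9 vs 2, contrast 87.6 vs 18.7 at the default
  scoring parameters, a ≈ 4–5× ratio). The direction of the comparison,
  not the ratio, is the transferable result.
* random genomes of equal length are maximally dissimilar references;
  real phage libraries contain related strains, so classification
  accuracy on random panels is an upper bound on what equally noisy real
  data would give.

Problem sizes used by the tests and the acceptance script: the headline
typing experiment uses 20 random 40 kbp genomes × 50 molecules; the
noise-degradation sweep (camera noise sd 0 → 0.5) uses 10 molecules per
genome per level; the single-strain discrimination test uses 27 simulated
λ molecules; moment-recovery tests use 1000–2000 replicates.

## Numerical choices and degenerate inputs

* Gaussian mixtures are evaluated exactly (no kernel truncation); the
  intercalation kernel is truncated at 5σ and renormalised, keeping a
  homopolymer interior flat to < 1e-6.
* Profile TSVs store floats with 17 significant digits (exact for IEEE
  doubles); round-trips are lossless.
* Constant profiles: z-normalisation raises a degenerate-input error;
  feature detection returns an empty list (score 0) — a flat molecule is
  uninformative, not an error.
* A query longer than the stretched reference (under the overlap
  constraint) raises a no-valid-alignment error rather than returning a
  meaningless score.
* FASTA input: IUPAC ambiguity codes are accepted and mapped to N with a
  warning (the downstream alphabet is {A,C,G,T,N}); U maps to T with a
  warning; anything else is a format error naming the line.
* Stretch factors must keep `stretch_mean − 3·stretch_sd > 0` so that
  resampled lengths stay positive across effectively all draws.

## Known limitations

* Global linear stretch only; no local stretch inhomogeneity or
  dynamic-programming alignment.
* No 2-D image rendering, kymograph synthesis or molecule segmentation —
  the simulator starts where image processing ends, at the 1-D trace.
* Two-fluorophore duplex labelling stoichiometry is not modelled (one
  label per duplex site).
* Circular genomes are treated as linear molecules.
* The information score is a declared reconstruction; absolute score
  values are not comparable to other software, only rankings and ratios
  computed within this package.
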