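# Methods

This note documents the models implemented in `hetquant`, the defaults they
ship with, what the synthetic-data generators do and do not emulate, and the
numerical choices that matter when reproducing results.

## Spread-image quantification (`imagequant`)

**Model.** Centromeres appear as bright, roughly diffraction-limited spots in
a marker channel (kinetochore stains such as HEC1 or CREST). Detection
thresholds the marker channel, takes connected components (8-connectivity by
default; 4-connectivity is available and is what the flood-fill oracle tests
use), and keeps components with `min_size <= area <= max_size`. Components
are reported with intensity-weighted centroids, which is what makes
sub-pixel localization of Gaussian-profile spots possible. Default
parameters mirror common practice for this assay: `min_size = 4` and a
sister-pairing distance of 17 px for pericentric quantification;
`min_size = 5`, `max_size = 60` for spot-only (centromere-finder)
quantification.

Sister centromeres are matched greedily by ascending centroid separation
subject to the maximum pairing distance; the result is a matching (no spot
in two pairs). Greedy-by-distance is deterministic and reproduced exactly by
an exhaustive enumeration oracle in the tests.

A pericentric region is the set of DNA-positive pixels within a fixed radius
(default 10 px) of either centroid of the owning pair (or of an unpaired
spot; regions fall back to single anchors so that asymmetric marker loss
does not silently drop chromosomes). DNA positivity comes from thresholding
the DNA channel. When candidate regions from different anchors overlap,
pixels go to the nearest anchor, ties to the lower anchor index — this makes
region masks invariant under anchor processing order.

**Thresholding.** The threshold strategy is Otsu's method per channel per
image by default, with a fixed-quantile alternative (`threshold=0.98` means
"pixels above the 98th percentile"). Otsu is parameter-free and reproducible;
quantile thresholds make detection exactly invariant under positive
intensity rescaling.

**Condition summaries.** Per-image values (integrated measurement-channel
intensity over regions, by default) are reduced per experiment to condition
means, then normalized as

    (mean(condition) − mean(background)) / (mean(reference) − mean(background)),

so the background condition (e.g. uninduced, no-GFP cells) maps to 0 and the
reference condition to 1. The final value is the mean across experiments
with its standard error. Normalization is refused when the reference mean
does not exceed the background mean. Integrated-per-region then
mean-per-image is the default reduction; per-region means are also reported.

## FRAP (`frapkit`)

**Normalization.** The ROI trace is double-normalized: divided by its
pre-bleach level, corrected by the whole-nucleus ratio total(t)/total(0)
(which removes whole-cell acquisition photobleaching — verified in tests by
generating traces with per-frame decay 0.995 and recovering the generating
parameters), and then mapped affinely so that the pre-bleach level is 1 and
the first post-bleach frame is 0. I(0) defaults to the mean over all
pre-bleach frames for robustness; a single-frame option exists.

**Fit.** Post-bleach points are fit with

    Y(x) = Ymax · (1 − exp(−(ln 2 / t½)(x − x0))),

so the model passes through Ymax/2 exactly at x0 + t½, Ymax estimates the
mobile fraction and t½ the recovery half-time in seconds. Initial guesses
are data-derived (Ymax from the last-quartile mean; t½ from the first
half-maximum crossing; x0 = 0 at the recorded bleach). Bounds: Ymax ∈ [0,
1.5] (values above 1 indicate normalization problems but should fail
loudly in summaries, not in the optimizer), t½ ∈ (0, 10 × duration], x0
within ±1 frame of the recorded bleach. A fit is flagged non-converged when
the optimizer fails or the plateau is indistinguishable from zero — with no
recovery, the half-time is unidentifiable. Summaries average converged fits
only and report the mobile fraction as a percentage.

## Equilibrium binding (`bindfit`)

Fraction bound is `bound / (bound + free)` from band or filter intensities;
values above 1 (quantification noise) are clipped to 1 with a warning.
Titrations are fit to the Hill isotherm

    f([P]) = Bmax · [P]^n / (Kd^n + [P]^n)

by nonlinear least squares with Kd parameterized as log Kd (positivity and
stability from nM to µM; the Kd standard error is propagated back with the
delta method). The default fits n and fixes Bmax = 1, matching how such
curves are usually reported; both toggles exist. Fits whose Kd lands outside
[min conc/100, max conc×100] are flagged: such a Kd is not constrained by
the sampled range. Protein is assumed in vast excess of probe (probe
concentrations of a few nM against Kd ≥ tens of nM); when a probe
concentration is supplied and the lowest protein concentration comes within
10× of it, a depletion warning is emitted. Mutants are classified by Kd
ratio against wild type with a 10-fold default threshold (strictly greater
than threshold → decreased binding; strictly less than its reciprocal →
increased; ratios of exactly the threshold count as unchanged).

Like any nonlinear least-squares estimator, the fitted Kd carries a small
positive bias of second order in the noise (about 1–2% relative at a
fraction-bound noise sd of 0.02–0.03 on a 9-point series); with enough
replicates this bias becomes resolvable against the shrinking standard
error even though it is negligible against experimental uncertainty.

Competition series are summarized by a monotonicity check: competition means
percent bound never increases with competitor and shows a net decrease.

## Repeat-family enrichment (`repeatstats`)

Counts per repeat type are normalized to the total repeat-masked reads of
each sample (frequency of detection); fold change is KO frequency over
control frequency. Inclusion requires strictly more than `min_reads`
(default 300) reads — in both samples by default, which keeps sparse
denominators from producing unstable folds; either-sample and summed-count
modes are provided. Frequencies are always computed over the full table, so
filtering does not change the denominators. Included types with zero control
frequency are reported with an infinite fold but excluded from the outlier
statistics. The outlier rule flags folds above mean + k·SD (default k = 2)
of the finite included folds, computed on raw folds by default with a
log-scale option. Rows are ranked by descending fold.

## qPCR and RIP (`qpcr`)

A dilution standard curve (Ct against natural-log relative input) gives the
per-cycle amplification `expAmp = exp(−1/slope)`; perfect doubling shows a
Ct step of log₂10 ≈ 3.32 per 10-fold dilution. Abundance is
`signal = expAmp^(−Ct)`; no-amplification wells are encoded as missing Ct
(never as "Ct 40") and propagate as signal 0. For repetitive targets the
−RT signal is subtracted from the +RT signal (floored at 0 and flagged when
background dominates), the result is divided by a reference-gene signal
(the reference is a required argument — different experiments legitimately
use different references, so there is no default), and RIP enrichment is
the normalized IP signal over the normalized input signal, optionally
renormalized to a control sample so the control maps to 1. Replicates are
averaged on the signal scale, where the arithmetic of ratios is defined;
Ct-scale averaging is deliberately not the default.

Note the direction of the efficiency correction: for a fixed positive Ct a
more efficient amplicon implies *less* starting template, so signal is
strictly decreasing in expAmp.

## Synthetic data (`synthdata`)

**What is emulated.** Spread images: Gaussian centromere spots
(σ = radius/2, so thresholding is actually exercised) in sister pairs
(separation 8 ± 1 px by default, safely below the 17-px pairing distance),
pericentric discs of radius 12 px carrying DNA signal and the
condition-dependent measurement amplitude, a dim elongated chromosome arm in
the DNA channel (so DNA segmentation has structure beyond the discs), and
additive Gaussian noise clipped at zero. Default amplitudes (marker 1000,
DNA 500, measurement 800, arm 150, noise sd 20 a.u.) give the strong
signal-to-background typical of fixed-cell imaging of induced constructs.
FRAP traces: exact single-exponential recovery over a bleach-depth floor,
constant whole-nucleus signal, per-frame multiplicative acquisition
bleaching applied to both series — precisely the artifact the double
normalization removes. Titrations: Hill isotherms on geometric dilution
series with additive noise clipped to [0, 1]. Repeat tables: shared
log-normal baseline proportions with enriched types carrying exact expected
fold changes (remaining mass rescaled uniformly), multinomial counts or
exact expectations. Ct tables: Ct = offset − log(abundance)/log(expAmp)
plus Gaussian Ct noise, optional −RT background fraction, and matching
standard-curve series.

**What is not emulated** — and therefore what passing tests do not show
about real data: optical blur beyond the Gaussian spot profile, z-stack
acquisition (generators produce projected images directly), spatially
structured background, chromatic misregistration, touching or overlapping
chromosomes, reaction–diffusion FRAP kinetics, probe depletion at high
probe:Kd ratios, PCR inhibitors or primer-dimer artifacts, and overdispersed
(non-multinomial) sequencing counts.

Every generator is seed-deterministic (NumPy `default_rng(seed)`); identical
spec and seed give bit-identical output.

## Problem sizes and reproduction

`scripts/acceptance.py` regenerates each experiment from scratch at the
sizes the analyses are designed around: 19 FRAP cells sampled at 1 s for
120 s with noise sd 0.02; a 10-point, 2-fold titration from 2.5 µM fit
noiselessly; 15 spread images (256×256 px, 10 pairs) per condition in 3
pseudo-experiments of 5 for the standard error; and a 2-sample × 2-fraction
× 2-primer RIP table. These sizes keep a full run under a minute on one
CPU while leaving the stochastic estimates well inside their sampling
tolerances.

## Known limitations

- Otsu thresholding assumes a reasonably bimodal histogram; images whose
  foreground occupies a very small pixel fraction may need the quantile
  strategy instead.
- The greedy pairing is not a minimum-weight matching; for pathological
  spot layouts (chains of nearly equidistant spots) a global matcher could
  pair differently. Real sister pairs are far closer to each other than to
  neighbors, where greedy and optimal agree.
- The FRAP model is a single exponential; binding-dominant recovery with
  two timescales will show structured residuals rather than a warning.
- The 2-SD outlier rule on raw folds is sensitive to a single dominant
  enrichment inflating the SD; the log-scale option mitigates this.
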