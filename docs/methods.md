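# Methods

`fgrs` analyses single-cell Raman spectra acquired under fluorescence
guidance to decide whether a cell carries a high or low amount of the
gap-junction protein connexin 43 (Cx43). The package implements the
full analysis chain — preprocessing, band statistics, channel
selection, classification — together with a synthetic spectrum
generator whose statistical structure is calibrated so that every stage
can be validated end to end without access to measured spectra.

## Preprocessing

Each spectrum is processed in a fixed order: crop, baseline removal,
cosmic-ray removal, normalization.

**Fingerprint crop.** Channels outside 400–1800 cm⁻¹ are discarded.
The wavenumber axis is treated as data (stored per file, never assumed
uniform), since CCD-based spectrometers deliver slightly non-uniform
axes of roughly 2.5–3 cm⁻¹ per pixel.

**Asymmetric least squares (AsLS) baseline.** The broad fluorescence
background under the Raman bands is estimated as the minimizer of

    Σᵢ wᵢ (yᵢ − zᵢ)²  +  λ Σⱼ (Δ²z)ⱼ² ,

iterating the asymmetric weights wᵢ = p if yᵢ > zᵢ else 1 − p. With
p ≪ ½ the smooth curve z hugs the signal from below, ignoring peaks.
Defaults λ = 10⁵, p = 0.01, ≤ 20 iterations, weight-change tolerance
10⁻⁶ — standard values for fingerprint-region Raman baselines. The
banded normal equations are solved by Cholesky factorization
(`scipy.linalg.solveh_banded`); a test verifies agreement with a dense
direct solve to < 10⁻⁶ relative, plus the two analytic limits
(constant signal → zero correction; λ → 0 → baseline equals signal).
The estimator is translation-equivariant, which the suite asserts.

**Cosmic-ray removal.** A cosmic ray is a spike confined to one or two
detector channels that towers above everything biological. The rule
implemented: a local maximum is removed when its *topographic
prominence* exceeds the amide I reference intensity — the maximum of
the baseline-corrected signal in 1640–1680 cm⁻¹, taken after a 3-point
median filter so a spike inside the window cannot inflate the reference
and mask itself — and its width at half prominence spans at most 3
channels. Prominence rather than raw height is used deliberately:
bands taller than amide I (the CH₂/CH₃ deformation region around
1449 cm⁻¹ often is) would otherwise let ordinary noise maxima riding on
their apex satisfy a height criterion, producing false removals.
Spikes are repaired by linear interpolation across their
half-prominence feet, i.e. only the channels the spike actually
occupies; interpolating between the more distant prominence bases would
take the apex of any underlying band with it. The pass repeats until
no spike remains, making the operation idempotent. Despiking runs on
the baseline-corrected, pre-normalization scale, so the whole pipeline
is invariant under a global rescale of the raw counts (regression
tested).

**Normalization.** Each spectrum is divided by its greatest intensity
(max = 1 exactly). The protocol phrase "vector normalized to the
greatest spectral intensity" conflates two conventions; this package
makes max-normalization the default and exposes unit-L2 normalization
as an option without asserting which a given laboratory used.

## Peak analysis and band extraction

Peaks are strict local maxima ranked by topographic prominence (the
height above the higher of the two lowest saddles separating the peak
from higher terrain or the signal ends), matching the semantics of the
common `findpeaks`/`find_peaks` implementations. Plateau maxima report
their leftmost channel (deterministic tie-break). The implementation
delegates to `scipy.signal.find_peaks` and is checked against an
exhaustive prominence oracle on thousands of random signals. Presence
comparison between two mean spectra flags peaks as shared or unique,
matching centers greedily within 5 cm⁻¹ (corresponding bands in
published tables differ by a few cm⁻¹, e.g. 746/750).

Band intensities are the maximum normalized intensity inside a band
window: printed ranges are used as-is; point shifts are expanded by a
half-window of 4 cm⁻¹ (no extraction window is stated in the protocol;
±4 cm⁻¹ spans ±1–2 channels on the default grid). A range narrower
than the channel spacing (amide I is tabulated as 1654–1655 on a
2.456 cm⁻¹ grid) snaps to the nearest channel; a window entirely
outside the axis is an error.

## Band statistics and channel selection

Per band, the two groups' window-max intensities are compared with the
two-sided Mann–Whitney U test (exact permutation null when both n ≤ 8
without ties, otherwise the normal approximation with continuity and
tie corrections) and the pooled-SD Cohen's d

    d = (x̄ − ȳ) / s_p ,   s_p² = ((n_x−1)s_x² + (n_y−1)s_y²) / (n_x+n_y−2).

Tables report |d|; the sign is retained internally. Stars: * p < 0.05,
** p ≤ 10⁻², *** p ≤ 10⁻³. No multiple-testing correction is applied,
matching the source protocol.

Channel selection uses the double-SD rule: a channel is kept when the
absolute between-group mean difference exceeds 2× a standard-deviation
threshold. The default threshold is **scalar** — the across-channel
sample SD of the absolute-difference spectrum — because the rule is
depicted as a single horizontal cut-off line; a per-channel pooled-SD
variant is available behind an option. Which convention the original
analysis used is not decidable from the text; the printed count of 82
selected channels cannot adjudicate without the raw data.

## Classification

Binary soft-margin SVM with Gaussian kernel K(u,v) = exp(−‖u−v‖²/s²),
box constraint C = 1, features standardized on the training data. The
kernel scale follows the "medium"/"coarse" presets: s = √P and s = 4√P
for P predictors (P = 571 channels for the full fingerprint, or the
selected-channel count for the double-SD mask). Classes are balanced
by seeded subsampling to the smaller class; 80% of the balanced data
train the model and training performance is reported as stratified
five-fold cross-validation on that portion. (The source protocol's
"20% were held out for a five-fold cross validation" cannot literally
mean CV on the holdout; this package interprets training accuracy as
CV on the 80% and uses the 20% only to complete test scenarios that
lack one class.) High Cx43 is the positive class; a decision score of
exactly zero predicts the negative class. Confusion-matrix metrics,
full-threshold-sweep ROC curves and trapezoid AUC are computed per
scenario. The experiment grid mirrors the published layout: 2 kernels
× 2 feature modes × {training, testing-1 (wildtype low class),
testing-2 (one high-like line pooled against three low-like lines)}.

## Synthetic data generator

The generator emulates the study conditions: 571 uniform channels over
400–1800 cm⁻¹, 95 spectra per class, pseudo-Voigt bands (η = 0.5,
FWHM 12 cm⁻¹ — typical fingerprint linewidths) at the 19 panel shifts,
a flat background (scale 0.2 a.u.) for the BFP-like tag in both
classes, i.i.d. Gaussian channel noise (SD 0.02 a.u. against band
amplitudes of 0.1–1.25 a.u.), and Poisson cosmic rays (0.05 per
spectrum, amplitude 2.5× the current amide-window maximum, drawn on
interior channels since an endpoint spike is not a local maximum and no
prominence-based despiker can see it).

Base amplitudes are chosen so the spectrum reads like a fixed-cell
fingerprint, with one deliberate constraint: the CH₂/CH₃ deformation
band (1449–1452 cm⁻¹, programmed contrast zero) is the tallest band and
therefore the max-normalization anchor. If the anchor carried a class
contrast, normalization would cancel that contrast exactly at the
anchor channel and no effect size could be realized there. Band
centers may sit a few cm⁻¹ from the printed extraction shift, as in
measured spectra; in particular the amide II peak is centered at
1576 cm⁻¹ (inside its 1550–1580 envelope), which is what keeps the
heavily overlapping 1580 and 1582 extraction windows statistically
distinguishable on a 2.456 cm⁻¹ grid.

**Effect-size calibration.** Class contrast is an additive amplitude
shift on the high-Cx43 class. Because baseline removal, normalization
and window-max extraction attenuate and mix raw amplitude shifts, the
per-band deltas are resolved numerically: a damped Newton iteration
drives the mean recovered |d| (measured through the *full* pipeline
over batches of seeded replicates, with common random numbers across
sweeps) to the programmed target. The Jacobian is analytic — the unit
profile of each band evaluated at every band's extraction channel,
scaled by the normalization anchor — and the per-band d-to-intensity
scale is the extracted-intensity SD measured at zero contrast. The
joint solve matters: the amide I (1654–1655) and lipid C–C (1660)
windows overlap so strongly that independent per-band root finding
cannot decouple them, while the linear system has a well-defined
positive solution (most of the apparent 1660 contrast is amide I
leakage, consistent with the observation that protein signal likely
contributes to that shift). Convergence is only accepted when
confirmed on a 320-replicate pool within 0.015 in d units; smaller
pools leave finite-sample calibration bias comparable to the ±0.05
validation band. Calibration plus the 200-replicate recovery takes a
few minutes on one CPU.

Programmed targets are the reported per-band magnitudes (amide I 1.98;
amide II/1580 1.30; tryptophan 752–760 1.29; amide III β-sheet
1235–1240 1.05; phenylalanine 1003 1.05; amide III 1337 0.91;
carbohydrate/lipid 877 0.72; cytochrome c 750 1.44 and 1582 1.39;
lipids 1297 0.27 and 1660 1.78) and zero for the bands reported
non-significant (480, 720, 811, 1081, 1090–1095, 1180, 1449–1452,
1605).

**Cell-line scenarios.** `make_cell_line_profiles` emits seven named
sets: transfected/control (training pair), wildtype (low, brighter
perturbed background), and four line-like sets (one high, three low)
with lognormal per-band amplitude multipliers and distinct background
shapes. With perturbation 0 each line collapses onto its training
class. The default spread is 0.01 (1% line-to-line amplitude
variability): because the generator's only within-class scatter is
channel noise, between-line shifts must stay comparable to that
scatter or transfer scenarios degenerate into pure domain shift; real
cells have far larger within-class variability that buffers transfer,
which is one more reason synthetic transfer accuracies are sanity
bounds rather than predictions.

## What the synthetic data do and do not show

The generator reproduces the *statistical* structure the analysis
rests on — band positions, class contrasts of programmed magnitude,
background shapes, spike artifacts — but not several properties of
measured spectra: correlated baseline residuals, multiplicative
intensity scatter between cells, shot-noise scaling with signal, band
shape and position variability, or genuine biochemical covariance
between bands (each band's contrast is programmed independently).
Classification accuracies on synthetic data are therefore *sanity
bounds* (chance on zero contrast, large lift under programmed
contrast), not predictions of the published accuracy table, which was
computed on unreleased measured spectra. The published training and
testing accuracies are used only as a structural template for the
experiment grid.

## Numerical choices and degenerate inputs

- AsLS asserts a positive penalty, so the banded system is positive
  definite; non-finite inputs are rejected with the sample named.
- Despiking caps at 10 passes (one pass suffices in practice; the cap
  guards pathological inputs).
- Normalization refuses non-positive maxima; standardization inside
  the SVM applies sklearn's unit-scale floor to zero-variance features.
- All randomness (generation, balancing, splitting, folds, spikes)
  derives from one recorded integer seed through
  `numpy.random.SeedSequence`; reruns are byte-identical, which the
  suite asserts on the full pipeline's file outputs.
- Score ties at exactly 0 predict low-Cx43.
- Exact rank-sum enumeration is used up to n = 8 per group; beyond
  that the normal approximation differs from the exact null by well
  under 0.02 in two-sided p (property tested).

## Problem sizes used in the validation suite

Effect-size recovery runs the study-sized generator (95 spectra per
class) with 200 evaluation replicates; classifier sanity checks use 20
seeds at study size; plumbing and determinism tests use 24–40 spectra
per class, which exercise identical code paths on smaller matrices.
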