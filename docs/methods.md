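# Methods

`hepafat` implements magnetic-resonance quantification of liver fat against a
histologic reference, end to end: a synthetic phantom/cohort generator, two
gradient-echo imaging estimators and one spectroscopy estimator of the proton
density fat fraction (PDFF), the NASH-CRN grading of biopsy steatosis, and the
diagnostic-accuracy statistics used to compare methods. This note records the
models, their assumptions, the free parameters, and the design choices made
where the design was genuinely open.

## Signal models

### Fat spectrum

Both branches share a six-peak liver triglyceride spectrum: chemical shifts
5.3, 4.2, 2.75, 2.1, 1.3, 0.9 ppm with relative amplitudes 0.047, 0.039,
0.006, 0.120, 0.700, 0.088 (water at 4.7 ppm). The 5.3 and 4.2 ppm resonances
lie under or beside the water line ("hidden", 8.6% of fat protons); the
remaining 91.4% are directly measurable between 0.5 and 3 ppm. Frequency
offsets use Δf = (δ − 4.7) · 42.576 MHz/T · B0 with B0 = 3 T. Alternate
spectra can be supplied as a small JSON document of shift/amplitude pairs.

### Gradient echo

The magnitude spoiled gradient-echo signal of an ROI is

    S(TE) = |W + F·c(TE)| · exp(−TE / T2*),   c(TE) = Σ_p a_p e^{i 2π Δf_p TE}

with W, F the water and fat proton densities and T2* the effective transverse
relaxation. T1 weighting is omitted: at TR 180 ms with 30°/15° flip angles
the signal is approximately proton-density weighted, and any residual T1
factor is common to W and F at this level of modelling, so it cancels in the
PDFF. (An optional global steady-state T1 factor exists for sensitivity
studies; it defaults off.) The model is magnitude-only; no complex-phase or
field-map reconstruction is attempted.

Two protocols are built in: triple-echo (TE 2.3/3.45/4.6 ms, flip 30°) and
multi-echo (TE 1.15–8.05 ms step 1.15, flip 15°), both TR 180 ms at 3 T.

### Spectroscopy

Single-voxel PRESS without water suppression: eight 2-average spectra at
TE 40–110 ms step 10 (TR 2000 ms) for T2 estimation, plus one 40-average
single-echo spectrum at TE 40 ms (TR 4000 ms) for the density estimate. Each
FID is a sum of Lorentzian-damped complex sinusoids

    y(t) = Σ_p ρ_p e^{−TE/T2_p} e^{(i 2π Δf_p − π·lw) t}

sampled at 1024 points over a 2000 Hz window, with the linewidth lw (FWHM)
set by the shim and shared across resonances. T1 effects are neglected given
the long TRs.

## Estimation

### Gradient-echo PDFF (`gre_pdff`)

1. *Noise-floor correction.* ROI magnitudes are Rician; using the
   second-moment relation E[m²] = s² + 2σ², each magnitude becomes
   √max(m² − 2σ², 0). σ comes from the simulation (known) or a background
   ROI (Rayleigh mean / √(π/2)); the correction is the identity at σ = 0.
2. *Multipeak fit.* Bounded nonlinear least squares of (W, F, T2*) with
   W, F ≥ 0 and T2* ∈ [1, 100] ms, from a 6-point multi-start grid spanning
   water-dominant, balanced and fat-dominant initializations at two T2*
   scales. Magnitude fitting has a fat/water-dominance ambiguity; the basin
   with the lower residual wins and exact ties break toward PDFF < 0.5,
   since liver PDFF above 50% is physiologically exceptional. At realistic
   noise (SNR ≈ 10) a minority of fits still land in the mirror basin — an
   intrinsic limitation of magnitude-only fitting, flagged but not hidden.
3. PDFF = F / (F + W). Both protocols share this code path; with three
   echoes the triple-echo fit is exactly determined.

Noiseless recovery is exact (PDFF error ≤ 1e-6 over a grid of PDFF and T2*
values, both protocols), verified in the test suite.

### Spectroscopy PDFF (`mrs_pdff`)

1. *Peak fitting.* Time-domain variable projection: water plus three grouped
   measurable fat resonances (0.9, 1.3, 2.1 ppm; the minor 2.75 ppm peak is
   unresolvable at 40–50 Hz linewidths and is absorbed by the 2.1 ppm
   window). Frequencies are bounded to ±0.1 ppm prior windows; all
   resonances share one linewidth parameter bounded in [5, 200] Hz — the
   linewidth is shim-dominated in vivo, and freeing per-peak dampings lets
   broad overlapping components cancel on noisy records. The hidden 5.3/4.2
   ppm fat peaks are included as satellites whose complex amplitudes are
   tied to the measurable-fat amplitude sum through the spectrum's relative
   amplitudes; this prior-knowledge constraint keeps hidden fat out of the
   water estimate without pretending to measure it. Peak area is the
   component amplitude at t = 0; alongside the magnitude area, each peak
   carries a *signed* area (projection onto the strongest component's
   phase), which is unbiased near zero where the magnitude has a
   Rician-type positive bias.
2. *T2 correction.* Water T2 is fitted on its eight signed areas
   (bounds [5, 500] ms). Fat T2 is fitted by default on the per-TE *sum* of
   the measurable fat areas ("pooled" mode) and applied to every fat peak:
   the measurable fat resonances have near-identical T2 in liver at 3 T,
   and weak individual peaks cannot pin their own T2 at realistic SNR — a
   misfitted T2 enters the density through exp(TE/T2) and can dominate the
   estimate. A strict per-peak mode is available (`fat_t2_mode="per_peak"`).
   In the pipeline the fat T2 search is restricted to a physiological
   window of [30, 120] ms; a fit pinned at a bound (fat signal too weak to
   carry T2 information) falls back to the typical value of 60 ms and the
   estimate is flagged.
3. *Densities.* The 40-average single-echo areas are back-extrapolated to
   TE = 0 with those T2s; measurable fat densities are summed and divided
   by 0.914 (the measurable amplitude fraction) to restore hidden fat;
   PDFF = fat / (fat + water). A record with no detectable water is an
   error, not a fat fraction of 1.

Noiseless end-to-end recovery is within 0.02 percentage points over
PDFF 2–30%; at the study noise level the RMSE is ≈ 1 percentage point
(both verified in the suite).

## Synthetic cohort (`phantom`)

The generator emulates the study population the analysis is designed for:
n = 73, steatosis grade probabilities (6, 35, 11, 21)/73, grade-conditional
true-PDFF medians (0.12, 4.98, 10.84, 18.26)%, steatohepatitis probability
rising with grade as (0, 0.25, 0.5, 0.6) (≈37% overall), fibrosis stage
probabilities (52, 12, 6, 2, 1)/73, and ~3% siderosis. Free parameters not
fixed by the emulated design, chosen once on physiological grounds:

| parameter | default | rationale |
|---|---|---|
| PDFF dispersion (log-σ) | 0.45 | right-skewed, widening IQRs across grades |
| PDFF truncation | 60% | upper physiologic bound |
| T2* | N(20, 3) ms clipped [12, 32] | liver at 3 T |
| water T2 | 25 ms | liver at 3 T |
| fat peak T2 | 60 ms (all peaks) | liver at 3 T |
| water linewidth | U(40, 50) Hz | shim performance window |
| GRE ROI SNR | 60 | ROI-mean of a ~900 mm² region |
| MRS SNR parameter | 90 | see below |

True PDFF is drawn from a log-normal (median per grade, σ = 0.45) truncated
to [0, 60]%; the histology percentage is drawn from the same latent uniform
inside the grade's band and rounded to 5% increments, making histology and
PDFF comonotone within grade — the coupling real cohorts show, in idealized
form. Grade bands for histology are none {0}, mild {5..30}, moderate
{35..65}, severe {70..100} (multiples of 5), consistent with the grading
convention below.

Gradient-echo noise is complex Gaussian added to the noise-free complex
signal before the magnitude (Rician magnitudes), with σ = (W+F)·e^(−TE₁/T2*)/SNR.
Spectral noise is complex Gaussian with σ = (W+F)/(SNR·√n_averages); the
SNR parameter is therefore a time-domain single-average quantity, and the
default of 90 corresponds to a conventional frequency-domain water-peak SNR
of ≈50 on the 40-average single-echo record at a 45 Hz linewidth (peak
height ≈ amplitude·sweep/(π·lw), spectral noise ≈ σ·√n_points).

What the phantom deliberately does not model — and hence what passing tests
do not demonstrate about real data: anatomy and partial-volume structure,
motion/respiration, B0 inhomogeneity beyond a global linewidth, J-coupling
(a known source of fat-T2 underestimation in PRESS), eddy currents and
baseline distortions, T1 effects, and siderosis-induced T2* shortening
(siderosis is carried as a flag only). The histology process is idealized:
real biopsy sampling error and inter-observer variation are absent, so
cohort-level correlations here are optimistic upper envelopes, not predicted
clinical performance.

## Histology (`histology`)

NASH-CRN steatosis bands: none <5%, mild 5–33%, moderate 33–66%, severe
>66%. The printed bands share endpoints, so a convention is declared:
5 → mild, 33 → moderate, 66 → moderate, >66 → severe (half-open,
exhaustive, monotone). Steatohepatitis and fibrosis stage are supplied
flags; no sub-scores are computed.

## Evaluation (`evaluation`)

* **Spearman correlation** with average-rank ties (constant input is an
  error, not NaN).
* **Empirical ROC/AUC** over all unique thresholds; the trapezoidal area
  equals the Mann–Whitney pairwise concordance with ties counting ½
  (verified against exhaustive enumeration).
* **Smoothed robust ROC**: scores are rank-transformed (robustness), each
  class is smoothed with a Gaussian kernel (Silverman's rule per class), and
  the continuous ROC is traced on a fine grid; thresholds are mapped back to
  the score scale by inverting the rank transform. As bandwidth → 0 the
  curve converges to the empirical ROC.
* **Youden threshold**: maximizes sensitivity + specificity − 1 on a given
  ROC; exact ties break toward the lower threshold (favoring sensitivity at
  the margin).
* **Paired AUC comparison**: DeLong's correlated-AUC test, two-sided, via
  per-class structural components with midranks. Identical inputs return
  p = 1. Type-I error calibration (~5%) and power are checked by simulation.
* **Obuchowski AUC** for the 4-level ordinal grade: pairwise between-level
  AUCs weighted by subject-pair counts — equivalently the mean concordance
  over all discordant-level subject pairs. Its standard error is the
  leave-one-subject-out jackknife of that U-statistic, the nonparametric
  route consistent with the structural-components approach; with two levels
  the estimate reduces exactly to the empirical AUC.
* **Linear models**: OLS of histology steatosis % on a method's fat
  fraction (as a proportion in [0, 1]), optionally with a steatohepatitis
  indicator and fibrosis indicators (F1, F2, merged F3-or-4; reference F0;
  empty levels dropped with a warning). Reported per model: estimates,
  standard errors, 0.95 intervals, R², and the Obuchowski AUC of fitted
  values against the grade. The orientation (histology as response) is a
  declared choice; the slope scale then depends on the predictor being a
  proportion.
* **Group summaries**: per-grade median and IQR with linear-interpolation
  (type-7) quantiles; pairwise two-sided Wilcoxon rank-sum tests. No
  multiple-testing correction is applied (raw p-values are reported).

## Pipeline (`cli`)

`hepafat simulate | quantify-gre | quantify-mrs | evaluate | run-all`. One
cohort CSV is the spine; each stage appends columns (per-method PDFF %, T2*,
water T2, convergence flags). Spectra are stored as per-record CSV (t, real,
imag) with a JSON sidecar; echo series as a long-form CSV; NIfTI per-echo
volumes are supported on the input side through ROI extraction. Every
artifact records the seed in the run manifest; reruns are byte-identical.
Per-subject failures (missing or corrupt inputs, degenerate fits) are
flagged in the table and logged, never fatal to the run.

## Numerical choices

* All nonlinear fits use bounded trust-region least squares with tight
  tolerances (1e-14/1e-15) so that noiseless recovery is limited by model
  identifiability, not optimizer slack.
* Multi-start grids are deterministic; ties in the GRE basin choice break
  toward the physiological basin.
* The exponential T2 fit is initialized from a log-linear regression of the
  positive areas; non-positive signed areas stay in the least-squares
  objective.
* Random draws derive from `numpy` `SeedSequence` spawning, so per-subject
  streams are independent and the whole pipeline is a pure function of the
  seed.

## Problem sizes

Default analyses run the full 73-subject cohort. The test suite uses the
same cohort size for the 100-replica sanity envelope (triple-echo branch,
the fastest estimator), 100–200 Monte-Carlo repetitions for bias/RMSE
properties, and n = 5000 per repetition for OLS coverage; these sizes give
stable pass/fail behavior at interactive runtimes.

## Known limitations

* Magnitude-only GRE fitting cannot fully resolve the fat/water ambiguity
  near PDFF 50% or at low SNR; complex-data methods are out of scope.
* The spectroscopy fat T2 is pooled across peaks by default; genuinely
  heterogeneous per-peak T2s would bias the correction (the per-peak mode
  exists but is noise-fragile).
* The smoothed-ROC threshold depends on the kernel bandwidth at small n;
  no confidence intervals are attached to thresholds.
* The phantom's grade-conditional dispersion is a free calibration knob;
  only the medians are anchored to the emulated design.
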