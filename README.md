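# hepafat

MR-based quantification of liver fat, evaluated against histology.

Hepatic steatosis — fat accumulation in the liver — is graded on biopsy by
the percentage of steatotic hepatocytes, but biopsy is invasive and poorly
suited to follow-up. Magnetic resonance offers a noninvasive surrogate: the
**proton density fat fraction** (PDFF), the fat proton density as a fraction
of total mobile protons,

```
PDFF = F / (F + W)
```

`hepafat` implements the three MR routes to PDFF that a liver imaging study
would compare, plus the statistics needed to judge them against the biopsy
reference:

* **Triple- and multi-echo gradient-echo imaging** — the ROI magnitude
  signal is modeled as `S(TE) = |W + F·c(TE)|·exp(−TE/T2*)`, where
  `c(TE) = Σ_p a_p exp(i2πΔf_p TE)` is the dephasing of a six-peak fat
  spectrum. Estimation includes Rician noise-floor correction
  (`m → √(m²−2σ²)`), a bounded multi-start fit of (W, F, T2*), and
  resolution of the magnitude fat/water ambiguity.
* **Multi-TE PRESS spectroscopy** — water and fat peaks are fitted in the
  time domain as damped complex sinusoids with prior-knowledge constraints,
  each peak is corrected for T2 decay using eight echo times (40–110 ms),
  and the fat resonances hidden under the water line (4.2/5.3 ppm) are
  restored from their published relative amplitudes.
* **Evaluation** — Spearman correlation with histology, empirical
  (trapezoidal) and smoothed robust ROC curves with Youden-index
  thresholds per steatosis grade cutpoint, DeLong tests between methods,
  the Obuchowski AUC for the 4-level ordinal grade, per-grade medians/IQRs
  with rank-sum tests, and linear models probing whether steatohepatitis or
  fibrosis distort fat quantification.

Because real patient data of this kind are not publicly deposited, the
package ships a first-class synthetic phantom (`hepafat.phantom`): a
73-subject cohort generator calibrated to the grade structure and
grade-conditional PDFF medians of a diabetic NAFLD population, plus forward
simulators for both acquisition types with realistic noise. Every estimator
is validated against this generator, from exact noiseless inversion to
Monte-Carlo bias and cohort-level diagnostic accuracy. See
`docs/methods.md` for models, parameters and limitations.

Intended users: researchers in quantitative body MRI and anyone needing a
tested, scriptable reference implementation of PDFF estimation and
diagnostic-accuracy analysis.

## Worked example

```python
from hepafat import triple_echo_protocol, estimate_pdff_triple, estimate_pdff_mrs
from hepafat.phantom import (CohortSpec, simulate_cohort,
                             simulate_gre_series, simulate_mrs_series)

spec = CohortSpec(seed=42)                     # default 73-subject study design
subject = simulate_cohort(spec)[7]
print(f"subject {subject.subject_id}: grade {subject.grade}, "
      f"histology {subject.histology_steatosis_percent:.0f}%, "
      f"true PDFF {subject.true_pdff_percent:.2f}%")

series = simulate_gre_series(subject, triple_echo_protocol(),
                             snr=spec.noise_snr, seed=1)
est = estimate_pdff_triple(series)
print(f"triple-echo PDFF {est.pdff_percent:.2f}%  (T2* {est.t2star_ms:.1f} ms)")

mrs = simulate_mrs_series(subject, seed=2)
est = estimate_pdff_mrs(mrs)
print(f"MRS PDFF         {est.pdff_percent:.2f}%  (water T2 {est.water_t2_ms:.1f} ms)")
```

Output:

```
subject subj_008: grade severe, histology 95%, true PDFF 29.29%
triple-echo PDFF 28.55%  (T2* 19.8 ms)
MRS PDFF         27.75%  (water T2 22.6 ms)
```

The subject's ground-truth PDFF is 29.29%; both estimators recover it to
within about 1.5 percentage points at the default noise levels, while also
returning their nuisance parameters (the gradient-echo T2*, here ~20 ms, and
the spectroscopic water T2). Histology (95% of hepatocytes steatotic) sits
far above the PDFF, as expected: the two scales measure different things and
are compared by rank correlation and ROC analysis, not identity.

The same pipeline runs from the shell:

```bash
hepafat run-all --out run1 --seed 7        # simulate -> quantify -> evaluate
cat run1/report.json                       # correlations, ROC/thresholds, models
```

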