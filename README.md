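# nmrfp — serum NMR fingerprinting for colorectal-cancer relapse risk

`nmrfp` implements a serum ¹H-NMR metabolomic fingerprinting analysis for
elderly colorectal-cancer (CRC) patients: it discriminates relapse-free early
CRC (eCRC) from metastatic CRC (mCRC) using a PCA–CA–kNN classifier on binned
spectra, projects relapsed early-stage patients onto that decision space, and
shows that the resulting high/low *metabolomic risk* label is prognostic for
relapse independently of tumor stage.  Because no patient-level data are
deposited for studies of this kind, the package ships a first-class synthetic
cohort generator that emulates the statistical structure of such a study
(three patient groups, 32 quantifiable serum signals with calibrated group
effect sizes, pulse-sequence-dependent spectra, survival endpoints driven by a
latent metastatic-likeness score), so every stage of the pipeline is testable
end to end.

It is intended for researchers in NMR metabolomics and clinical biostatistics
who want a reproducible, fully tested reference implementation of this
fingerprinting workflow.

## The method

1. **Spectra → features.** Each sample yields three 1-D frequency-domain
   spectra (NOESY 1D: all signals; CPMG: small molecules; diffusion-edited:
   macromolecules).  The ppm axis is calibrated to the anomeric glucose
   doublet at 5.24 ppm; 0.2–10.0 ppm is segmented into 0.05 ppm bins (196),
   and bins overlapping the residual-water/ethanol/edge exclusion windows are
   dropped, retaining 156 integrated bins.
2. **Normalization.** Probabilistic Quotient Normalization (PQN): rows are
   area-normalized, a median reference spectrum is formed, and each sample is
   divided by the median of its bin-wise quotients against the reference.
3. **Classification.** Covariance PCA retains the components explaining
   99.9 % of the variance; canonical analysis (the Fisher discriminant in
   PCA-score space, axis `a ∝ W⁻¹(μ_mCRC − μ_eCRC)`) gives a single canonical
   score; k-nearest neighbours (k = 9) in that space assigns the class.
   Performance is estimated by leave-one-out cross-validation with the whole
   chain (PQN reference, centering, PCA, CA) refit on every fold — the
   held-out sample never influences the model that classifies it.
4. **Univariate screen.** 32 metabolite/macromolecule signals are quantified
   by window integration; groups are compared with Wilcoxon rank-sum tests,
   Benjamini–Hochberg FDR control, signed Cliff's delta (positive = lower in
   mCRC), and median-threshold discrimination accuracies.
5. **Risk stratification and survival.** Every eCRC patient receives a
   high/low metabolomic risk label (LOOCV prediction for training members,
   projection for relapsed patients).  Relapse-free interval is compared
   between risk groups by Kaplan–Meier/log-rank, follow-up by reverse
   Kaplan–Meier, and the independence from stage by Cox models with
   bidirectional stepwise selection (p < 0.05 to enter and stay).

## Worked example

```python
import nmrfp

report = nmrfp.run_demo(seed=1)           # simulate 65/29/75 cohort + full analysis
m = report["loocv"]["NOESY"]
print(f"NOESY LOOCV: accuracy {m['accuracy']:.3f}, "
      f"sensitivity {m['sensitivity']:.3f}, specificity {m['specificity']:.3f}")
p = report["projection"]
print(f"relapsed predicted metastatic: {p['n_predicted_metastatic']}/{p['n_relapsed']}")
s = report["survival"]
print(f"log-rank p = {s['logrank_p']:.2e}, "
      f"univariate HR = {s['cox_univariate_risk']['hr']:.2f}, "
      f"multivariate: {s['cox_multivariate']['selected']}")
```

prints

```
NOESY LOOCV: accuracy 0.750, sensitivity 0.760, specificity 0.738
relapsed predicted metastatic: 24/29
log-rank p = 1.46e-07, univariate HR = 8.67, multivariate: ['risk_high', 'stage_iii', 'grade_3']
```

Read: the fingerprint separates relapse-free early from metastatic disease at
~75 % cross-validated accuracy on this cohort draw; most relapsed early-stage
patients resemble the metastatic profile; and the resulting risk label splits
relapse-free interval strongly, with the metabolomic risk retained alongside
stage in the stepwise Cox model (i.e. prognostic independently of stage).

The same demo is available from the shell:

```bash
nmrfp demo --seed 1 --out results/demo
nmrfp simulate --seed 1 --out results/cohort      # spectra TSVs + clinical.csv
nmrfp bin --spectra-dir results/cohort/spectra --out results/binned.csv
```

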