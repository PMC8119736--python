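# nirsnet

Resting-state fNIRS brain-network analysis for two-group infant studies.

`nirsnet` implements the full analysis chain used to compare resting-state
cortical networks between a patient group and healthy controls from
functional near-infrared spectroscopy (fNIRS) recordings:

1. **Preprocessing** — raw dual-wavelength (760/850 nm) light intensities →
   change in optical density ΔOD = −log₁₀(I/I_ref) → spline correction of
   motion artifacts (impulse and cliff-type jumps) → zero-phase 0.01–0.1 Hz
   band-pass → the modified Beer–Lambert law

   ΔOD_λ = (ε_HbO,λ·ΔC_HbO + ε_HbR,λ·ΔC_HbR) · r · DPF_λ

   solved per channel as a 2×2 system across the two wavelengths (DPF = 4),
   yielding ΔHbO/ΔHbR concentration changes in µM.
2. **Connectivity** — full-recording Pearson correlation between all 45
   channels (and between the mean series of six regions of interest),
   Fisher r-to-z transformed.
3. **Binary networks** — sparsity thresholding over the sweep
   s = 0.05…0.40 (36 thresholds): keep the top s·N(N−1)/2 node pairs.
4. **Graph metrics** — clustering coefficient Cp, characteristic path
   length Lp, modularity Q (best seeded Louvain partition, exact Q
   evaluation), global/local efficiency; each normalized by the mean over
   degree-preserving Maslov–Sneppen random surrogates:
   Cp_γ = Cp/Cp_rand, Lp_λ = Lp/Lp_rand, small-worldness σ = Cp_γ/Lp_λ,
   Eloc_γ, Eglob_γ; nodal degree and group hub (central-node) maps.
5. **Group statistics** — connection-wise and ROI-wise pooled two-sample
   t-tests with Benjamini–Hochberg FDR, normal-approximation power
   analysis, and the 20-column feature grid ({σ, Eloc_γ, Q, Cp_γ} × five
   thresholds 0.30–0.34).
6. **Classification** — linear SVM on the feature grid with repeated
   stratified 10:3 train/test splits per group, fivefold cross-validated
   grid search over C, and rank-based ROC/AUC per feature family.

Because clinical neonatal recordings cannot be redistributed, the package
ships a first-class **synthetic cohort generator**: latent band-limited ROI
hemodynamics with a controllable coupling structure are mixed down to
channel ΔHbO/ΔHbR, forwarded through the Beer–Lambert model to raw
intensities, and contaminated with cardiac/respiratory oscillations and
Poisson-timed motion artifacts. The patient-like group attenuates
contralateral parietal-involving couplings and boosts within-ROI coupling,
reproducing the direction of the group effects the pipeline is designed to
detect. Every stage is therefore testable end to end, with known ground
truth, at desk scale.

## Worked example

```python
from nirsnet import (CohortSpec, default_montage, simulate_cohort,
                     preprocess_recording, pearson_matrix, fisher_z,
                     threshold_by_sparsity, compute_metrics, power_two_sample)

montage = default_montage()                     # the packaged 45-channel layout
spec = CohortSpec(n_per_group=2, duration_s=600.0,
                  artifact_rate_per_min=0.0, seed=42)
cohort = simulate_cohort(spec, montage)

rec = cohort.recordings[-1]                     # raw intensities, 90 x 6000
hemo = preprocess_recording(rec, montage)       # ΔHbO/ΔHbR in µM
r = pearson_matrix(hemo, "HbR")                 # 45 x 45 Pearson matrix
z = fisher_z(r)
net = threshold_by_sparsity(z, 0.30)            # binary network, top 30% of pairs
m = compute_metrics(net, ensemble_count=100, seed=1)

print(f"subject {rec.subject_id} ({rec.group}): "
      f"mean r = {r.upper_triangle().mean():.3f}, edges = {net.n_edges}")
print(f"Cp = {m.cp:.3f}  Lp = {m.lp:.3f}  Q = {m.q:.3f}  "
      f"Eglob = {m.eglob:.3f}  Eloc = {m.eloc:.3f}")
print(f"Cp_gamma = {m.cp_gamma:.3f}  Lp_lambda = {m.lp_lambda:.3f}  "
      f"sigma = {m.sigma:.3f}")
print(f"power(0.57 vs 0.41, sd 0.14, n=13) = "
      f"{100 * power_two_sample(0.57, 0.41, 0.14, 13, 0.05):.2f}%")
```

prints

```
subject C02 (control): mean r = 0.548, edges = 297
Cp = 0.695  Lp = 1.893  Q = 0.395  Eglob = 0.618  Eloc = 0.839
Cp_gamma = 2.066  Lp_lambda = 1.099  sigma = 1.881
power(0.57 vs 0.41, sd 0.14, n=13) = 82.99%
```

The subject's 10-minute recording yields a mean between-channel HbR
correlation of 0.55; thresholding at 30% sparsity keeps 297 of the 990
channel pairs; σ ≈ 1.9 > 1 says the network is small-world relative to its
degree-matched random surrogates. The last line is the power of a
two-sided two-sample comparison of group mean connectivities 0.57 vs 0.41
(SD 0.14, 13 subjects per group) at α = 0.05.

## Command line

`nirsnet` exposes each stage and a full orchestrated run:

```bash
nirsnet simulate   --config cfg.json --seed 1 --out-dir cohort/
nirsnet preprocess --in-dir cohort/ --out-dir hemo/
nirsnet connect    --in-dir hemo/ --out-dir matrices/
nirsnet network    --in-dir matrices/ --out metrics.tsv --seed 1
nirsnet stats      --metrics metrics.tsv --matrices-dir matrices/ --out-dir stats/
nirsnet classify   --features features.tsv --seed 1 --out clf.json
nirsnet run-all    --config cfg.json --seed 1 --out-dir run/
```

`run-all` writes per-subject connectivity matrices, the long-format metric
table, connection/ROI/feature-grid test tables, the feature table,
classification results, and a `run_manifest.json` with a SHA-256 checksum
per artifact; reruns with the same config and seed reproduce identical
checksums.

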