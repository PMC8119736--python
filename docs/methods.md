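# Methods

## Signal model and preprocessing

The measured quantity at each of the 45 source–detector channels is light
intensity at 760 and 850 nm, sampled at 10 Hz. The pipeline works on the
change in optical density, ΔOD(t) = −log₁₀(I(t)/I_ref). Resting-state
recordings have no task baseline, so I_ref is the per-channel,
per-wavelength mean intensity over the whole recording; any constant offset
this choice introduces is removed by the band-pass.

**Motion artifacts.** Neonatal recordings contain impulse spikes and
cliff-type baseline jumps from probe–scalp sliding. The detector flags
samples where a centred 1-s moving-window SD, or the absolute first
difference, exceeds 5 robust (MAD-based) SDs of the row; flagged runs are
padded by half a window and merged. Correction is interval-local: within
each flagged interval the series is replaced by its residual from a
least-squares spline (degree 3, knots every 5 samples), re-anchored onto
the straight line joining the samples that bracket the interval. Samples
outside flagged intervals are never modified. Consequences worth knowing:

- a spike is removed essentially completely;
- a finite-duration step is removed completely only when the flagged
  interval covers the shifted plateau. The automatic detector sees only
  the two jump edges, so in fully automatic operation part of the plateau
  survives (and partially passes the band-pass), which dilutes
  between-channel correlations. When artifact windows are known — as with
  the synthetic generator's event log, or an operator's pre-localization —
  they should be passed to `preprocess_recording(..., artifact_intervals=…)`;
  the end-to-end acceptance run does exactly that.

**Band-pass.** 0.01–0.1 Hz, order-3 Butterworth, zero phase. The
forward–backward (squared-magnitude) response is applied spectrally rather
than by time-domain `filtfilt`: the 0.01 Hz edge gives the filter ~100-s
time constants, and time-domain forward–backward filtering rings its
startup transient into the first and last minute of a 10-minute record,
which measurably corrupts full-record correlations. The spectral
realization has the identical magnitude response (measured: 2 Hz sinusoids
attenuated to 3×10⁻⁹ of input power, 0.05 Hz passed at 99.9%) and exactly
zero phase, with no transient.

**Beer–Lambert conversion.** Per channel, the two-wavelength ΔOD pair is
inverted through ΔOD_λ = (ε_HbO,λ ΔC_HbO + ε_HbR,λ ΔC_HbR)·r·DPF with the
source–detector distance r from the montage (20/25/30 mm, converted to cm)
and DPF = 4 at both wavelengths. Extinction coefficients default to the
standard compiled molar values (0.586/1.058 for HbO and 1.549/0.691 for
HbR at 760/850 nm, per mM·cm); compilations differ by up to ~10%, so the
table is an explicit configuration object. Concentrations are reported in
µM. The stage order (ΔOD → artifact correction → band-pass → Beer–Lambert)
is enforced by stage tags on the recording container; since both the
filter and the conversion are linear, swapping the last two steps would
change nothing beyond round-off, but only the stated order is allowed.

## Connectivity and networks

Connectivity is the Pearson correlation between channel time series over
the full recording (one matrix per subject; no windowing), Fisher
r-to-z-transformed for group statistics; |r| is clipped at 1−10⁻⁷ before
atanh with a logged warning. HbR is the default chromophore — generally
the more reliable signal for resting-state network metrics — with HbO
available through the same interfaces. ROI-level matrices average the
member-channel time series of each of the six lateral ROIs before
correlating; the single medial prefrontal channel (AFz–Fz, index 23)
belongs to no lateral ROI and is excluded from ROI analyses. (Its ROI
column in the channel table reads only "prefrontal cortex", without a
hemisphere; treating it as a seventh midline pseudo-ROI and excluding it is
the one reading consistent with a six-ROI scheme.)

Binary networks keep the top round(s·N(N−1)/2) node pairs by signed
correlation value (group-level correlations here are strongly positive, so
negative-edge handling is immaterial); ties at the cutoff break
lexicographically by (row, column) for cross-platform determinism, and
rounding is half-up. The sweep covers s = 0.05–0.40 in steps of 0.01, i.e.
36 network models per subject.

Metrics on the binary graph: mean nodal clustering Cp (nodes with degree
< 2 contribute 0); characteristic path length Lp as the mean shortest path
over *connected* pairs (disconnected pairs are excluded with a logged
warning — thresholds are meant to keep the network intact, but the
implementation must stay defined when they do not); modularity Q as the
best value over 10 seeded Louvain restarts, with Q of any partition
evaluated exactly as Σ_m [l_m/L − (d_m/2L)²]; global efficiency as the
mean inverse shortest-path length (1/∞ = 0); local efficiency as the mean
over nodes of the global efficiency of each neighborhood subgraph (0 below
2 neighbors). All-pairs distances use a vectorized frontier-expansion BFS,
exact for unweighted graphs.

**Random-network normalization.** Each network is compared against
degree-preserving surrogates generated by Maslov–Sneppen double-edge
swaps: 10×n_edges swap attempts, rejecting self-loops and multi-edges, so
every surrogate has exactly the original degree sequence. Cp_γ, Lp_λ,
Eloc_γ, Eglob_γ are ratios of the real metric to the ensemble mean, and
σ = Cp_γ/Lp_λ. The ensemble size is configurable: 1000 for full-fidelity
runs, 100 for the calibration checks in the test suite, smaller for smoke
tests. On reference graphs the normalization behaves as the small-world
literature predicts: σ ≈ 3.5–4 for Watts–Strogatz lattices (N=45, k=6,
p=0.1) and σ ≈ 0.9–1.1 for density-matched Erdős–Rényi graphs.

**Central nodes.** The group hub map flags nodes whose group-mean degree
exceeds the across-node mean by more than one SD. No quantitative hub
definition is standard for this design; mean+1 SD is this package's
choice, deliberately simple and scale-free.

## Group statistics

Two-sample comparisons use the pooled-variance (Student) t-test,
two-sided, df = n₁+n₂−2 — the form consistent with df = 24 for 13+13
subjects. Multiple testing uses Benjamini–Hochberg FDR; connection-wise
results report significance counts both before and after correction.
Power analysis defaults to the normal approximation
Φ(|δ|/(sd√(2/n)) − z₁₋α/₂) + Φ(−|δ|/(sd√(2/n)) − z₁₋α/₂), which gives
82.99% for group means 0.57/0.41, SD 0.14, n = 13, α = 0.05; the
noncentral-t variant (79.83%) is available via `method="nct"`. The
classification feature grid is {σ, Eloc_γ, Q, Cp_γ} × {0.30…0.34},
metric-major, 20 columns per subject.

## Classification

Linear-kernel SVM with repeated stratified splits: 10 training and 3 test
subjects per group per repeat (24 repeats by default, so accuracies are
multiples of 1/24). Within each repeat, features are z-scored with
statistics from the training split only, the penalty C is chosen by
fivefold cross-validated grid search on the training split, and the
refitted model is scored on the held-out 6 subjects. A `g` grid is
accepted in configuration for compatibility but is inert under the linear
kernel. Per-family ROC/AUC scores each subject by the mean of the family's
five standardized threshold columns; AUC uses the rank (Mann–Whitney)
formulation with ties counting ½. The permutation baseline shuffles group
labels once (seeded) and reruns the identical procedure.

## Synthetic cohort generator

The generator is the package's substitute for clinical recordings and
defines the study conditions: two groups of 13 subjects, 600 s at 10 Hz,
the packaged 45-channel montage.

- **Latents.** Six ROI signals are white noise band-passed to
  0.02–0.07 Hz (order-4 Butterworth) and mixed by the Cholesky factor of
  the target ROI coupling matrix. The band sits strictly inside the flat
  region of the 0.01–0.1 Hz analysis passband so that preprocessing can in
  principle recover the latents exactly; with latent power extending to
  the 0.01 Hz corner, the analysis filter itself would destroy ~10% of
  latent variance and no recovery bound would be meaningful.
- **Channels.** ΔHbO of a channel is √w·(its ROI latent) + √(1−w)·private
  noise, so within-ROI channel correlations target w = `coupling_within`
  (default 0.80) and between-ROI correlations target w·C_RS with baseline
  C_RS = `coupling_between` (default 0.72). ΔHbR = −0.3·ΔHbO + independent
  noise (SD 0.06 vs HbO SD 1.0 µM) — a typical anticorrelation with
  configurable magnitude. The midline channel loads on the mean of the two
  prefrontal latents.
- **Group effects.** The patient-like group multiplies the five
  contralateral parietal-involving couplings (LPL–RPL, LPL–RTL, LPL–RPFC,
  LTL–RPL, LPFC–RPL) by `patient_longrange_attenuation` (default 0.6) and
  the within-ROI coupling by `patient_local_boost` (default 1.15). The
  boost raises the channel loading w; to keep between-ROI correlations
  governed by the attenuation alone, the latent couplings are divided by
  the boost. A marginally indefinite target pattern is replaced by the
  nearest correlation matrix (eigenvalue clipping; perturbation of order
  |min eigenvalue|, ≲0.03 at the strongest settings). `ground_truth()`
  returns the unmodified targets.
- **Optics and nuisance.** Clean concentrations are forwarded through the
  Beer–Lambert model to ΔOD, plus cardiac (≈2 Hz) and respiratory
  (≈0.4 Hz) sinusoids (amplitudes 0.004/0.006 OD, per-channel random
  phase, per-subject 5% frequency jitter), and Poisson-timed motion events
  (default 0.5/min): impulse spikes (1–3 samples, 5–20× the row SD) or
  finite cliff-type steps (5–20 s, 2–5× the row SD), identical windows
  across rows with row-specific amplitude and sign. Intensities are
  1.0·10^(−ΔOD), hence strictly positive. Event windows are recorded as
  ground truth.

Defaults were chosen once to land the control group's mean HbR
connectivity near the reported clinical scale (≈0.55 measured vs 0.57
reported) while keeping every coupling a valid correlation; the clinical
group means, significant-connection counts, feature-grid t/p values and
classifier accuracies of the original cohort are *not* reproduction
targets — with no access to the recordings they cannot be — and the test
suite instead verifies directional and calibration properties with known
ground truth.

**What the generator does not emulate:** optical head models or photon
transport, neonatal anatomy, heterogeneous channel SNR, slow drifts,
superficial (scalp) hemodynamics, or non-Gaussian hemodynamic waveforms.
Passing tests therefore certify the analysis chain's correctness and
statistical calibration under a plausible signal model, not clinical
performance on real recordings.

## Verification strategy and problem sizes

Graph metrics are checked exactly against independent brute-force oracles
(triangle enumeration, Floyd–Warshall, pair enumeration) on 200 random
graphs with ≤10 nodes, and modularity evaluation against networkx on
random partitions. Statistical calibration uses 200 null cohorts (13+13,
120-s hemoglobin-stage recordings) for the ~5% type-I rate of the
connection-wise test; effect recovery uses 25 replicate cohorts (300 s)
with halved contralateral-parietal coupling, and a strong-effect cohort
(attenuation 0.5, boost 1.3, within-coupling 0.75 so the boosted target
stays below 1) for metric directions and classifier performance with a
30-surrogate ensemble. These sizes are the package's chosen desk-scale
conditions; raising durations toward 600 s and ensembles toward 1000
changes precision, not conclusions.

## Known limitations

- The automatic artifact detector localizes step edges, not plateaus;
  fully automatic correction of long cliff-type steps is partial by
  design (the correction contract forbids touching unflagged samples).
- Lp over connected pairs only makes between-network comparisons subtle
  when fragmentation differs; the warning reports the disconnected-pair
  count for exactly this reason.
- The Louvain heuristic under-estimates the true maximal Q in principle;
  10 seeded restarts make this negligible at N = 45.
- With 13 subjects per group, the classifier's test sets have 6 subjects;
  accuracy estimates are correspondingly coarse (multiples of 1/6 per
  repeat).
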