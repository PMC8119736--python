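"""Two-group synthetic resting-state fNIRS cohorts.

The generator emulates 10-minute, 10 Hz, 45-channel neonatal recordings for
a patient-like and a control group, from latent ROI hemodynamics down to
raw dual-wavelength intensities:

1. six latent ROI signals — white noise band-passed to 0.02–0.07 Hz, the
   flat core of the resting-state analysis band — mixed by the Cholesky
   factor of a target ROI coupling matrix;
2. per-channel ΔHbO = √w·(own-ROI latent) + √(1−w)·channel noise, so the
   within-ROI channel correlation targets ``w = coupling_within`` and the
   between-ROI correlation targets ``w · coupling`` of the ROI pair;
3. ΔHbR = −0.3·ΔHbO + independent noise (typical anticorrelation);
4. forward modified Beer–Lambert to ΔOD at 760/850 nm, plus cardiac
   (≈2 Hz) and respiratory (≈0.4 Hz) sinusoids, motion spikes and
   cliff-type steps at Poisson-distributed times;
5. exponentiation around a unit baseline to strictly positive intensities.

The patient-like group multiplies the contralateral parietal-involving ROI
couplings (LPL–RPL, LPL–RTL, LPL–RPFC, LTL–RPL, LPFC–RPL) by
``patient_longrange_attenuation`` and the within-ROI channel coupling by
``patient_local_boost``, mirroring the reduced long-range connectivity and
elevated local coupling reported for hypoxic-ischemic brain damage.
Identical seeds reproduce identical cohorts bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from statsmodels.stats.correlation_tools import corr_clipped

from .montage import MIDLINE, ROI_TOKENS, Montage, default_montage, roi_members
from .preprocess import ExtinctionTable, forward_delta_od
from .recording import Recording

GROUPS = ("patient", "control")

#: contralateral, parietal-involving ROI pairs weakened in the patient group
PATIENT_ATTENUATED_PAIRS = frozenset(
    frozenset(p)
    for p in [("LPL", "RPL"), ("LPL", "RTL"), ("LPL", "RPFC"), ("LTL", "RPL"), ("LPFC", "RPL")]
)

# latent power sits inside the flat region of the 0.01-0.1 Hz analysis
# passband, so band-pass preprocessing preserves the latent waveforms
_LATENT_BAND_HZ = (0.02, 0.07)
_LATENT_FILTER_ORDER = 4


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class CohortSpec:
    n_per_group: int = 13
    duration_s: float = 600.0
    fs_hz: float = 10.0
    coupling_within: float = 0.80
    coupling_between: float = 0.72
    patient_longrange_attenuation: float = 0.6
    patient_local_boost: float = 1.15
    artifact_rate_per_min: float = 0.5
    hbo_sd_um: float = 1.0
    hbr_scale: float = -0.3
    hbr_noise_sd_um: float = 0.06
    cardiac_hz: float = 2.0
    cardiac_amp_od: float = 0.004
    respiratory_hz: float = 0.4
    respiratory_amp_od: float = 0.006
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise SpecError("n_per_group must be >= 1")
        if not (0 <= self.coupling_within < 1 and 0 <= self.coupling_between < 1):
            raise SpecError("coupling targets must lie in [0, 1)")
        if not 0 < self.patient_longrange_attenuation <= 1:
            raise SpecError("patient_longrange_attenuation must lie in (0, 1]")
        if self.patient_local_boost < 1:
            raise SpecError("patient_local_boost must be >= 1")
        if self.coupling_within * self.patient_local_boost >= 1:
            raise SpecError(
                "coupling_within * patient_local_boost must stay below 1 "
                "(a correlation target)"
            )
        if self.artifact_rate_per_min < 0:
            raise SpecError("artifact_rate_per_min must be >= 0")
        n = self.duration_s * self.fs_hz
        if abs(n - round(n)) > 1e-9 or n < 2:
            raise SpecError("duration_s * fs_hz must be a positive integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_hz))


@dataclass
class SyntheticCohort:
    """Generated cohort plus the ground truth needed by recovery tests."""

    spec: CohortSpec
    recordings: list[Recording]  # stage=intensity
    hemoglobin_truth: list[Recording]  # clean latent hemodynamics, stage=hemoglobin
    coupling_targets: dict[str, pd.DataFrame]
    artifact_log: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def by_group(self, group: str, stage: str = "intensity") -> list[Recording]:
        recs = self.recordings if stage == "intensity" else self.hemoglobin_truth
        return [r for r in recs if r.group == group]


def ground_truth(spec: CohortSpec) -> dict[str, pd.DataFrame]:
    """Per-group 6×6 target ROI coupling matrices (unit diagonal, symmetric)."""
    mats = {}
    for group in GROUPS:
        m = np.full((6, 6), spec.coupling_between)
        np.fill_diagonal(m, 1.0)
        if group == "patient":
            for i, a in enumerate(ROI_TOKENS):
                for j, b in enumerate(ROI_TOKENS):
                    if i != j and frozenset((a, b)) in PATIENT_ATTENUATED_PAIRS:
                        m[i, j] *= spec.patient_longrange_attenuation
        mats[group] = pd.DataFrame(m, index=ROI_TOKENS, columns=ROI_TOKENS)
    return mats


def _band_limited_noise(rng: np.random.Generator, n_rows: int, n_samples: int, fs: float) -> np.ndarray:
    """Standardized rows of white noise band-passed to the resting-state band."""
    white = rng.standard_normal((n_rows, n_samples))
    sos = signal.butter(
        _LATENT_FILTER_ORDER, _LATENT_BAND_HZ, btype="bandpass", fs=fs, output="sos"
    )
    x = signal.sosfiltfilt(sos, white, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _subject_hemoglobin(
    rng: np.random.Generator, spec: CohortSpec, montage: Montage, group: str
) -> tuple[np.ndarray, np.ndarray]:
    """Clean (ΔHbO, ΔHbR) arrays, 45 channels × samples, in µM."""
    n = spec.n_samples
    coupling = ground_truth(spec)[group].to_numpy()
    w = spec.coupling_within
    if group == "patient":
        # the local boost raises the within-ROI channel correlation to
        # w*boost; dividing the latent couplings by the boost keeps the
        # between-ROI channel correlations governed by attenuation alone
        w_eff = min(w * spec.patient_local_boost, 0.999)
        off = ~np.eye(6, dtype=bool)
        coupling[off] *= w / w_eff
        w = w_eff
    # the attenuated target pattern can be marginally indefinite; mix with
    # the nearest correlation matrix instead (perturbation O(|min eig|))
    if np.linalg.eigvalsh(coupling)[0] < 1e-6:
        coupling = corr_clipped(coupling, threshold=1e-6)
    latents = _band_limited_noise(rng, 6, n, spec.fs_hz)
    chol = np.linalg.cholesky(coupling + 1e-12 * np.eye(6))
    roi_sig = chol @ latents
    roi_sig -= roi_sig.mean(axis=1, keepdims=True)
    roi_sig /= roi_sig.std(axis=1, keepdims=True)
    roi_index = {roi: i for i, roi in enumerate(ROI_TOKENS)}
    ch_noise = _band_limited_noise(rng, montage.n_channels, n, spec.fs_hz)
    midline = roi_sig[roi_index["LPFC"]] + roi_sig[roi_index["RPFC"]]
    midline = (midline - midline.mean()) / midline.std()

    hbo = np.empty((montage.n_channels, n))
    for c in montage.channels:
        base = midline if c.roi == MIDLINE else roi_sig[roi_index[c.roi]]
        hbo[c.index - 1] = np.sqrt(w) * base + np.sqrt(1 - w) * ch_noise[c.index - 1]
    hbo *= spec.hbo_sd_um

    hbr_noise = _band_limited_noise(rng, montage.n_channels, n, spec.fs_hz)
    hbr = spec.hbr_scale * hbo + spec.hbr_noise_sd_um * hbr_noise
    return hbo, hbr


def _inject_artifacts(
    rng: np.random.Generator, od: np.ndarray, spec: CohortSpec
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Add Poisson-timed spikes and cliff-type steps to every ΔOD row."""
    n_rows, n = od.shape
    duration_min = spec.duration_s / 60.0
    n_events = rng.poisson(spec.artifact_rate_per_min * duration_min)
    row_sd = od.std(axis=1)
    row_sd[row_sd == 0] = od.std() or 1.0
    events: list[tuple[int, int]] = []
    out = od.copy()
    for _ in range(n_events):
        start = int(rng.integers(0, n))
        if rng.random() < 0.5:  # impulse
            length = int(rng.integers(1, 4))
            amp_mult = rng.uniform(5.0, 20.0, size=n_rows)
        else:  # cliff-type step, finite duration
            length = int(rng.uniform(5.0, 20.0) * spec.fs_hz)
            amp_mult = rng.uniform(2.0, 5.0, size=n_rows)
        end = min(start + max(length, 1), n)
        sign = rng.choice([-1.0, 1.0], size=n_rows)
        out[:, start:end] += (sign * amp_mult * row_sd)[:, None]
        events.append((start, end))
    events.sort()
    return out, events


def simulate_hemoglobin_cohort(
    spec: CohortSpec, montage: Montage | None = None
) -> list[Recording]:
    """Clean hemoglobin-stage cohort (no optics, artifacts or nuisance).

    Fast path for statistical calibration studies; the recordings are
    bit-identical to the ``hemoglobin_truth`` of :func:`simulate_cohort`
    under the same spec.
    """
    montage = montage or default_montage()
    cohort = []
    children = np.random.SeedSequence(spec.seed).spawn(2 * spec.n_per_group)
    for k, (group, prefix) in enumerate([("patient", "P"), ("control", "C")]):
        for i in range(spec.n_per_group):
            rng = np.random.default_rng(children[k * spec.n_per_group + i])
            hbo, hbr = _subject_hemoglobin(rng, spec, montage, group)
            cohort.append(
                Recording.from_blocks(
                    {"HbO": hbo, "HbR": hbr},
                    subject_id=f"{prefix}{i + 1:02d}",
                    group=group,
                    stage="hemoglobin",
                    fs_hz=spec.fs_hz,
                    meta={"units": "uM", "synthetic": True},
                )
            )
    return cohort


def simulate_cohort(spec: CohortSpec, montage: Montage | None = None) -> SyntheticCohort:
    """Full synthetic cohort down to raw dual-wavelength intensities."""
    montage = montage or default_montage()
    ext = ExtinctionTable()
    lengths = np.array(montage.distances_mm, dtype=float)
    n = spec.n_samples
    t = np.arange(n) / spec.fs_hz

    recordings: list[Recording] = []
    truth: list[Recording] = []
    artifact_log: dict[str, list[tuple[int, int]]] = {}
    children = np.random.SeedSequence(spec.seed).spawn(2 * spec.n_per_group)
    for k, (group, prefix) in enumerate([("patient", "P"), ("control", "C")]):
        for i in range(spec.n_per_group):
            rng = np.random.default_rng(children[k * spec.n_per_group + i])
            subject = f"{prefix}{i + 1:02d}"
            hbo, hbr = _subject_hemoglobin(rng, spec, montage, group)
            truth.append(
                Recording.from_blocks(
                    {"HbO": hbo, "HbR": hbr},
                    subject_id=subject,
                    group=group,
                    stage="hemoglobin",
                    fs_hz=spec.fs_hz,
                    meta={"units": "uM", "synthetic": True},
                )
            )
            od760, od850 = forward_delta_od(hbo, hbr, lengths, ext, dpf=4.0)
            od = np.vstack([od760, od850])
            # physiological nuisance: per-channel random phase, per-subject freq jitter
            f_card = spec.cardiac_hz * rng.uniform(0.95, 1.05)
            f_resp = spec.respiratory_hz * rng.uniform(0.95, 1.05)
            phase = rng.uniform(0, 2 * np.pi, size=(2, od.shape[0]))
            od = od + spec.cardiac_amp_od * np.sin(2 * np.pi * f_card * t[None, :] + phase[0][:, None])
            od = od + spec.respiratory_amp_od * np.sin(2 * np.pi * f_resp * t[None, :] + phase[1][:, None])
            od, events = _inject_artifacts(rng, od, spec)
            artifact_log[subject] = events
            intensity = 1.0 * np.power(10.0, -od)
            recordings.append(
                Recording(
                    subject_id=subject,
                    group=group,
                    stage="intensity",
                    data=intensity,
                    fs_hz=spec.fs_hz,
                    n_channels=montage.n_channels,
                    meta={
                        "synthetic": True,
                        "artifact_events": [list(e) for e in events],
                    },
                )
            )
    return SyntheticCohort(
        spec=spec,
        recordings=recordings,
        hemoglobin_truth=truth,
        coupling_targets=ground_truth(spec),
        artifact_log=artifact_log,
    )


def artifact_intervals_for(rec: Recording, events: list[tuple[int, int]]) -> dict:
    """Ground-truth events expanded to the per-row interval map the
    preprocessing stage consumes (every event hits every row)."""
    return {label: [tuple(e) for e in events] for label in rec.row_labels}
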