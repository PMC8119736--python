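"""Raw intensity → ΔHbO/ΔHbR preprocessing chain.

The chain runs in a fixed order: intensity to change in optical density
(ΔOD), spline correction of motion artifacts, zero-phase band-pass
(0.01–0.1 Hz), then the modified Beer–Lambert law

    ΔOD_λ = (ε_HbO,λ · ΔC_HbO + ε_HbR,λ · ΔC_HbR) · r · DPF_λ

solved per channel as a 2×2 linear system across the two wavelengths, with
``r`` the source–detector distance and a differential path-length factor
DPF = 4 at both wavelengths. Concentrations are reported in µM (distances
converted to cm). Each operation checks the stage of its input so the chain
cannot be applied out of order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import LSQUnivariateSpline
from scipy.ndimage import uniform_filter1d

from .montage import Montage
from .recording import Recording, RecordingError, require_stage

logger = logging.getLogger(__name__)

Interval = tuple[int, int]  # half-open [start, end) in samples
IntervalMap = dict[str, list[Interval]]  # keyed by recording row label


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients, 1/(mM·cm), at 760 and 850 nm.

    Defaults are the widely used compiled values (Prahl's tabulation of
    hemoglobin molar extinction, scaled from 1/(M·cm)). Compilations differ
    by up to ~10%, so the table is an explicit, overridable configuration
    object rather than a buried constant.
    """

    hbo_760: float = 0.586
    hbr_760: float = 1.54852
    hbo_850: float = 1.058
    hbr_850: float = 0.69132
    source_citation: str = "Prahl compilation, Oregon Medical Laser Center"

    def __post_init__(self) -> None:
        m = self.as_matrix()
        if np.any(m <= 0):
            raise ConfigurationError("extinction coefficients must be positive")
        cond = np.linalg.cond(m)
        if not np.isfinite(cond) or cond >= 100:
            raise ConfigurationError(
                f"extinction matrix ill-conditioned (cond={cond:.3g} >= 100); "
                "the two-wavelength system is not reliably invertible"
            )

    def as_matrix(self) -> np.ndarray:
        """Rows = wavelengths (760, 850), columns = chromophores (HbO, HbR)."""
        return np.array(
            [[self.hbo_760, self.hbr_760], [self.hbo_850, self.hbr_850]], dtype=float
        )


@dataclass(frozen=True)
class PreprocessConfig:
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    dpf: float = 4.0
    artifact_window_s: float = 1.0
    artifact_sd_threshold: float = 5.0
    spline_degree: int = 3
    filter_order: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ConfigurationError("require 0 < band_low_hz < band_high_hz")
        if self.dpf <= 0:
            raise ConfigurationError("dpf must be positive")
        if self.artifact_window_s <= 0 or self.artifact_sd_threshold <= 0:
            raise ConfigurationError("artifact detection parameters must be positive")
        if self.spline_degree < 1:
            raise ConfigurationError("spline_degree must be >= 1")


def intensity_to_delta_od(rec: Recording) -> Recording:
    """ΔOD(t) = −log10(I(t)/I_ref), I_ref the per-row whole-recording mean.

    Resting-state recordings have no task baseline, so the reference is the
    mean intensity of each channel/wavelength over the recording.
    """
    require_stage(rec, "intensity", "intensity_to_delta_od")
    if not np.all(rec.data > 0):
        r, s = np.argwhere(~(rec.data > 0))[0]
        raise RecordingError(
            f"nonpositive intensity at row {rec.row_labels[r]!r}, sample {s}"
        )
    ref = rec.data.mean(axis=1, keepdims=True)
    od = -np.log10(rec.data / ref)
    return rec.with_data(od, stage="delta_od")


def _robust_sd(x: np.ndarray) -> float:
    mad = np.median(np.abs(x - np.median(x)))
    sd = 1.4826 * mad
    return sd if sd > 0 else float(np.std(x))


def _mask_to_intervals(mask: np.ndarray, pad: int) -> list[Interval]:
    """Runs of True, padded by ``pad`` samples, merged when overlapping."""
    n = mask.size
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    raw = [(max(int(idx[a]) - pad, 0), min(int(idx[b]) + pad + 1, n)) for a, b in zip(starts, ends)]
    merged = [raw[0]]
    for s, e in raw[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def detect_motion_artifacts(rec: Recording, cfg: PreprocessConfig) -> IntervalMap:
    """Flag impulse- and cliff-type excursions on each ΔOD row.

    A sample is flagged when the centred moving-window SD exceeds
    ``artifact_sd_threshold`` × the row's robust (MAD-based) SD, or when the
    absolute first difference exceeds the same multiple of the robust SD of
    the differenced row. Flagged runs are padded by half a window and merged
    into half-open ``[start, end)`` intervals.
    """
    require_stage(rec, "delta_od", "detect_motion_artifacts")
    window = max(int(round(cfg.artifact_window_s * rec.fs_hz)), 3)
    out: IntervalMap = {}
    for label, x in zip(rec.row_labels, rec.data):
        mean = uniform_filter1d(x, size=window, mode="nearest")
        sq = uniform_filter1d(x * x, size=window, mode="nearest")
        mov_sd = np.sqrt(np.maximum(sq - mean * mean, 0.0))
        d = np.diff(x)
        jump = np.zeros_like(x, dtype=bool)
        d_sd = _robust_sd(d)
        if d_sd > 0:
            hit = np.abs(d) > cfg.artifact_sd_threshold * d_sd
            jump[:-1] |= hit
            jump[1:] |= hit
        sd = _robust_sd(x)
        mask = jump
        if sd > 0:
            mask = mask | (mov_sd > cfg.artifact_sd_threshold * sd)
        out[label] = _mask_to_intervals(mask, pad=window // 2)
    return out


def _anchor_ramp(x: np.ndarray, start: int, end: int) -> np.ndarray:
    """Linear ramp joining the samples just outside [start, end)."""
    n = x.size
    left = x[start - 1] if start > 0 else None
    right = x[end] if end < n else None
    if left is None and right is None:
        level = float(np.median(x[start:end]))
        left = right = level
    elif left is None:
        left = right
    elif right is None:
        right = left
    return np.linspace(left, right, end - start)


def _fit_artifact_shape(seg: np.ndarray, degree: int) -> np.ndarray:
    """Least-squares spline capture of the artifact trajectory in a segment."""
    n = seg.size
    k = min(degree, 5)
    t = np.arange(n, dtype=float)
    spacing = max(5, k + 1)
    knots = t[spacing:-spacing:spacing] if n > 2 * spacing else np.array([])
    if knots.size:
        spl = LSQUnivariateSpline(t, seg, knots, k=k)
        return spl(t)
    deg = min(k, n - 1)
    coef = np.polynomial.polynomial.polyfit(t, seg, deg)
    return np.polynomial.polynomial.polyval(t, coef)


def spline_correct(
    rec: Recording, intervals: IntervalMap, cfg: PreprocessConfig | None = None
) -> Recording:
    """Remove flagged motion artifacts by spline detrending within intervals.

    Inside each flagged interval the series is replaced by its residual from
    a fitted spline, re-anchored onto the straight line joining the samples
    that bracket the interval, so segment endpoints stay continuous with the
    surrounding signal. Samples outside every interval are bit-identical to
    the input. Intervals shorter than the spline support fall back to the
    linear anchor alone; intervals touching a recording edge anchor
    one-sided.
    """
    require_stage(rec, "delta_od", "spline_correct")
    cfg = cfg or PreprocessConfig()
    data = rec.data.copy()
    labels = rec.row_labels
    n = rec.n_samples
    for label, ivals in intervals.items():
        if label not in labels:
            raise RecordingError(f"unknown row label {label!r} in interval map")
        r = labels.index(label)
        x = data[r]
        for start, end in ivals:
            if not (0 <= start < end <= n):
                raise RecordingError(
                    f"interval ({start}, {end}) out of bounds for {n} samples"
                )
            seg = x[start:end]
            ramp = _anchor_ramp(x, start, end)
            if seg.size < cfg.spline_degree + 2:
                x[start:end] = ramp
                continue
            fit = _fit_artifact_shape(seg, cfg.spline_degree)
            x[start:end] = (seg - fit) + ramp
    return rec.with_data(data)


def bandpass(rec: Recording, cfg: PreprocessConfig) -> Recording:
    """Zero-phase Butterworth band-pass of every row; removes DC.

    The forward–backward (squared-magnitude) Butterworth response is applied
    spectrally, which has exactly zero phase and no startup transient, so
    between-channel correlations are not distorted by filter edge effects.
    """
    require_stage(rec, "delta_od", "bandpass")
    nyq = rec.fs_hz / 2.0
    if cfg.band_high_hz >= nyq:
        raise ConfigurationError(
            f"band_high_hz={cfg.band_high_hz} must be below Nyquist ({nyq} Hz)"
        )
    min_samples = int(np.ceil(3.0 / cfg.band_low_hz * rec.fs_hz))
    if rec.n_samples < min_samples:
        raise RecordingError(
            f"recording too short for the {cfg.band_low_hz} Hz high-pass edge: "
            f"{rec.n_samples} samples < {min_samples} "
            f"(≈3 periods of the low cutoff, {3.0 / cfg.band_low_hz:.0f} s)"
        )
    sos = signal.butter(
        cfg.filter_order,
        [cfg.band_low_hz, cfg.band_high_hz],
        btype="bandpass",
        fs=rec.fs_hz,
        output="sos",
    )
    # forward-backward response |H|^2 applied spectrally: time-domain
    # filtfilt rings its ~1/band_low startup transient (~100 s here) into
    # the record edges, which distorts full-record correlations
    n = rec.n_samples
    freqs = np.fft.rfftfreq(n, 1.0 / rec.fs_hz)
    _, h = signal.sosfreqz(sos, worN=freqs, fs=rec.fs_hz)
    gain = np.abs(h) ** 2
    filtered = np.fft.irfft(np.fft.rfft(rec.data, axis=1) * gain, n, axis=1)
    return rec.with_data(filtered)


def forward_delta_od(
    hbo_um: np.ndarray,
    hbr_um: np.ndarray,
    lengths_mm: np.ndarray,
    ext: ExtinctionTable,
    dpf: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward Beer–Lambert: concentrations (µM, channels×samples) → ΔOD pair."""
    hbo_mm = np.asarray(hbo_um, dtype=float) / 1000.0
    hbr_mm = np.asarray(hbr_um, dtype=float) / 1000.0
    path_cm = (np.asarray(lengths_mm, dtype=float) / 10.0 * dpf)[:, None]
    m = ext.as_matrix()
    od760 = (m[0, 0] * hbo_mm + m[0, 1] * hbr_mm) * path_cm
    od850 = (m[1, 0] * hbo_mm + m[1, 1] * hbr_mm) * path_cm
    return od760, od850


def delta_od_to_hemoglobin(
    rec: Recording,
    montage: Montage,
    ext: ExtinctionTable | None = None,
    cfg: PreprocessConfig | None = None,
) -> Recording:
    """Invert the modified Beer–Lambert law channel-wise; output in µM."""
    require_stage(rec, "delta_od", "delta_od_to_hemoglobin")
    ext = ext or ExtinctionTable()
    cfg = cfg or PreprocessConfig()
    if rec.n_channels != montage.n_channels:
        raise RecordingError(
            f"recording has {rec.n_channels} channels, montage {montage.n_channels}"
        )
    minv = np.linalg.inv(ext.as_matrix())
    od = np.stack([rec.block("760nm"), rec.block("850nm")])  # 2 x ch x T
    conc_mm = np.einsum("ij,jct->ict", minv, od)  # HbO, HbR in mM·(r·DPF)
    path_cm = np.array(montage.distances_mm, dtype=float) / 10.0 * cfg.dpf
    conc_um = conc_mm / path_cm[None, :, None] * 1000.0
    return Recording.from_blocks(
        {"HbO": conc_um[0], "HbR": conc_um[1]},
        subject_id=rec.subject_id,
        group=rec.group,
        stage="hemoglobin",
        fs_hz=rec.fs_hz,
        meta={**rec.meta, "units": "uM", "dpf": cfg.dpf},
    )


def preprocess_recording(
    rec: Recording,
    montage: Montage,
    cfg: PreprocessConfig | None = None,
    ext: ExtinctionTable | None = None,
    artifact_intervals: IntervalMap | None = None,
) -> Recording:
    """Full chain: ΔOD → motion correction → band-pass → Beer–Lambert.

    ``artifact_intervals`` overrides the automatic detector (e.g. with
    ground-truth intervals from the synthetic generator).
    """
    cfg = cfg or PreprocessConfig()
    od = intensity_to_delta_od(rec)
    ivals = artifact_intervals if artifact_intervals is not None else detect_motion_artifacts(od, cfg)
    od = spline_correct(od, ivals, cfg)
    od = bandpass(od, cfg)
    return delta_od_to_hemoglobin(od, montage, ext, cfg)
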