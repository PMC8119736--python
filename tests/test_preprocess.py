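"""Preprocessing chain: ΔOD, artifact detection/correction, band-pass, MBLL."""

import numpy as np
import pytest

from nirsnet.preprocess import (
    ConfigurationError,
    ExtinctionTable,
    PreprocessConfig,
    bandpass,
    delta_od_to_hemoglobin,
    detect_motion_artifacts,
    forward_delta_od,
    intensity_to_delta_od,
    preprocess_recording,
    spline_correct,
)
from nirsnet.connectivity import pearson_matrix
from nirsnet.recording import Recording, RecordingError

FS = 10.0


def _rec(data, stage="delta_od", n_channels=1, fs=FS):
    return Recording(
        subject_id="t", group="control", stage=stage, data=np.asarray(data, float),
        fs_hz=fs, n_channels=n_channels,
    )


def _smooth(n, rng, f=0.05):
    t = np.arange(n) / FS
    return np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)) + 0.2 * rng.standard_normal(n).cumsum() / np.sqrt(n)


# --- ΔOD ---------------------------------------------------------------


def test_constant_intensity_gives_zero_od():
    rec = _rec(np.full((2, 100), 3.7), stage="intensity")
    od = intensity_to_delta_od(rec)
    assert od.stage == "delta_od"
    assert np.allclose(od.data, 0.0)


def test_decade_drop_gives_od_one():
    # one sample at a tenth of the reference; others chosen so the mean is 1
    n = 100
    x = np.full(n, (n - 0.1) / (n - 1))
    x[40] = 0.1
    rec = _rec(np.vstack([x, x]), stage="intensity")
    od = intensity_to_delta_od(rec)
    assert od.data[0, 40] == pytest.approx(1.0, abs=1e-12)


def test_sinusoidal_modulation_matches_closed_form():
    n, m = 2000, 0.05
    t = np.arange(n) / FS
    s = 1.0 + m * np.sin(2 * np.pi * 0.03 * t)
    rec = _rec(np.vstack([s, s]), stage="intensity")
    od = intensity_to_delta_od(rec)
    expected = -np.log10(1.0 + m * np.sin(2 * np.pi * 0.03 * t)) + np.log10(s.mean())
    assert np.allclose(od.data[0], expected, atol=1e-12)


def test_nonpositive_intensity_names_location():
    x = np.ones((2, 50))
    x[1, 7] = 0.0
    with pytest.raises(RecordingError, match=r"ch01_850nm.*sample 7"):
        _rec(x, stage="intensity")


def test_stage_order_enforced(hemo_rec, montage):
    od = _rec(np.ones((2, 50)))
    with pytest.raises(RecordingError, match="intensity"):
        intensity_to_delta_od(od)
    with pytest.raises(RecordingError, match="delta_od"):
        delta_od_to_hemoglobin(
            Recording(
                subject_id="t", group="control", stage="intensity",
                data=np.ones((90, 50)), fs_hz=FS, n_channels=45,
            ),
            montage,
        )


# --- motion artifacts ---------------------------------------------------


def test_clean_channel_yields_no_intervals(rng):
    x = _smooth(6000, rng)
    rec = _rec(np.vstack([x, x]))
    intervals = detect_motion_artifacts(rec, PreprocessConfig())
    assert all(v == [] for v in intervals.values())


def test_single_spike_detected_in_one_interval(rng):
    x = _smooth(6000, rng)
    spike_at = 2500
    x2 = x.copy()
    x2[spike_at : spike_at + 2] += 10 * np.std(x)
    rec = _rec(np.vstack([x2, x]))
    intervals = detect_motion_artifacts(rec, PreprocessConfig())
    hits = intervals["ch01_760nm"]
    assert len(hits) == 1
    start, end = hits[0]
    assert start <= spike_at and end >= spike_at + 2
    assert intervals["ch01_850nm"] == []


def test_abutting_spikes_merge(rng):
    x = _smooth(6000, rng)
    x[3000:3002] += 12 * np.std(x)
    x[3004:3006] -= 12 * np.std(x)
    rec = _rec(np.vstack([x, x]))
    intervals = detect_motion_artifacts(rec, PreprocessConfig())
    assert len(intervals["ch01_760nm"]) == 1


# --- spline correction --------------------------------------------------


def test_empty_intervals_noop(rng):
    x = np.vstack([_smooth(1000, rng), _smooth(1000, rng)])
    rec = _rec(x)
    out = spline_correct(rec, {})
    assert np.array_equal(out.data, x)


def test_step_artifact_removed_on_constant_signal():
    amp = 5.0
    x = np.zeros(2000)
    x[800:950] += amp  # cliff-type step, flagged interval covers the plateau
    rec = _rec(np.vstack([x, np.zeros(2000)]))
    out = spline_correct(rec, {"ch01_760nm": [(800, 950)]})
    assert np.ptp(out.data[0]) < 0.1 * amp


def test_samples_outside_intervals_bit_identical(rng):
    x = np.vstack([_smooth(2000, rng), _smooth(2000, rng)])
    x[0, 1000:1010] += 8.0
    rec = _rec(x)
    out = spline_correct(rec, {"ch01_760nm": [(1000, 1010)]})
    mask = np.ones(2000, bool)
    mask[1000:1010] = False
    assert np.array_equal(out.data[0, mask], x[0, mask])
    assert np.array_equal(out.data[1], x[1])
    assert not np.array_equal(out.data[0, ~mask], x[0, ~mask])


def test_interval_at_edge_uses_one_sided_anchor(rng):
    x = _smooth(1000, rng)
    x2 = x.copy()
    x2[:30] += 20.0
    rec = _rec(np.vstack([x2, x]))
    out = spline_correct(rec, {"ch01_760nm": [(0, 30)]})
    assert np.abs(out.data[0, :30] - x[30]).max() < 1.0  # pulled back to signal level


def test_out_of_bounds_interval_rejected(rng):
    rec = _rec(np.vstack([_smooth(100, rng), _smooth(100, rng)]))
    with pytest.raises(RecordingError, match="out of bounds"):
        spline_correct(rec, {"ch01_760nm": [(50, 200)]})


# --- band-pass ----------------------------------------------------------


@pytest.mark.parametrize(
    "freq,check",
    [
        (2.0, lambda ratio: ratio < 0.01),  # cardiac: strong attenuation
        (0.05, lambda ratio: abs(ratio - 1.0) < 0.05),  # passband
    ],
)
def test_bandpass_frequency_response(freq, check):
    t = np.arange(6000) / FS
    x = np.sin(2 * np.pi * freq * t)
    rec = _rec(np.vstack([x, x]))
    out = bandpass(rec, PreprocessConfig())
    ratio = np.std(out.data[0]) / np.std(x)
    assert check(ratio)


def test_bandpass_removes_dc():
    rec = _rec(np.full((2, 6000), 4.2))
    out = bandpass(rec, PreprocessConfig())
    assert np.abs(out.data).max() < 1e-10


def test_bandpass_rejects_short_recording():
    rec = _rec(np.zeros((2, 500)))
    with pytest.raises(RecordingError, match="too short"):
        bandpass(rec, PreprocessConfig())


# --- Beer–Lambert -------------------------------------------------------


def test_zero_od_gives_zero_concentration(montage):
    rec = _rec(np.zeros((90, 50)), n_channels=45)
    hemo = delta_od_to_hemoglobin(rec, montage)
    assert hemo.stage == "hemoglobin"
    assert np.allclose(hemo.data, 0.0)


def test_forward_then_invert_recovers_concentrations(montage, rng):
    hbo = rng.standard_normal((45, 200))
    hbr = rng.standard_normal((45, 200))
    lengths = np.array(montage.distances_mm, float)
    od760, od850 = forward_delta_od(hbo, hbr, lengths, ExtinctionTable(), dpf=4.0)
    rec = _rec(np.vstack([od760, od850]), n_channels=45)
    hemo = delta_od_to_hemoglobin(rec, montage)
    assert np.allclose(hemo.block("HbO"), hbo, atol=1e-10)
    assert np.allclose(hemo.block("HbR"), hbr, atol=1e-10)


def test_identical_od_scales_inversely_with_distance(montage, rng):
    # channel 1 is 20 mm, channel 7 is 30 mm; same ΔOD → conc ratio 30/20
    od = np.tile(rng.standard_normal(100), (90, 1))
    rec = _rec(od, n_channels=45)
    hemo = delta_od_to_hemoglobin(rec, montage)
    ratio = hemo.block("HbO")[0] / hemo.block("HbO")[6]
    assert np.allclose(ratio, 30.0 / 20.0)


def test_ill_conditioned_extinction_rejected():
    with pytest.raises(ConfigurationError, match="conditioned"):
        ExtinctionTable(hbo_760=1.0, hbr_760=1.0, hbo_850=1.0, hbr_850=1.0001)


# --- full chain ---------------------------------------------------------


def test_chain_preserves_correlation_structure(clean_cohort, montage):
    rec = clean_cohort.recordings[0]
    truth = clean_cohort.hemoglobin_truth[0]
    hemo = preprocess_recording(rec, montage)
    before = pearson_matrix(truth, "HbR").upper_triangle()
    after = pearson_matrix(hemo, "HbR").upper_triangle()
    assert np.abs(before - after).max() < 0.05


def test_chain_recovers_latent_hemodynamics(clean_cohort, montage):
    rec = clean_cohort.recordings[0]
    truth = clean_cohort.hemoglobin_truth[0]
    hemo = preprocess_recording(rec, montage)
    for chrom in ("HbO", "HbR"):
        r = [
            np.corrcoef(hemo.block(chrom)[i], truth.block(chrom)[i])[0, 1]
            for i in range(45)
        ]
        assert min(r) >= 0.95
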