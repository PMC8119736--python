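"""Multichannel recording container shared by every pipeline stage.

A :class:`Recording` holds one subject's multichannel time series at a named
processing stage:

``intensity``
    raw detected light intensity, one row per (channel, wavelength),
    strictly positive, arbitrary units;
``delta_od``
    change in optical density, −log10(I / I_ref), same row layout;
``hemoglobin``
    chromophore concentration changes, one row per (channel, chromophore),
    in µM.

Rows are labelled ``ch<index>_<band>`` where band is ``760nm``/``850nm`` for
the optical stages and ``HbO``/``HbR`` for the hemoglobin stage, channels
ordered 1..N and the first band's block stacked above the second's.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

STAGES = ("intensity", "delta_od", "hemoglobin")
WAVELENGTHS_NM = (760, 850)
CHROMOPHORES = ("HbO", "HbR")


class RecordingError(ValueError):
    """Invalid recording content or an operation applied at the wrong stage."""


def row_labels(n_channels: int, bands: tuple) -> list[str]:
    """Row labels for ``bands`` blocks stacked over ``n_channels`` channels."""
    return [f"ch{c:02d}_{b}" for b in bands for c in range(1, n_channels + 1)]


def _bands_for_stage(stage: str) -> tuple:
    return CHROMOPHORES if stage == "hemoglobin" else ("760nm", "850nm")


@dataclass
class Recording:
    subject_id: str
    group: str  # "patient" | "control"
    stage: str
    data: np.ndarray  # rows (channel x band) x samples
    fs_hz: float
    n_channels: int
    wavelengths_nm: tuple = WAVELENGTHS_NM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise RecordingError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise RecordingError("data must be 2-D (rows x samples)")
        expected = 2 * self.n_channels
        if self.data.shape[0] != expected:
            raise RecordingError(
                f"stage {self.stage!r} expects {expected} rows "
                f"({self.n_channels} channels x 2 bands), got {self.data.shape[0]}"
            )
        if self.fs_hz <= 0:
            raise RecordingError("fs_hz must be positive")
        if self.stage == "intensity":
            if not np.all(self.data > 0):
                r, s = np.argwhere(~(self.data > 0))[0]
                raise RecordingError(
                    f"intensity must be strictly positive; first violation at "
                    f"row {self.row_labels[r]!r}, sample {s}"
                )

    @property
    def bands(self) -> tuple:
        return _bands_for_stage(self.stage)

    @property
    def row_labels(self) -> list[str]:
        return row_labels(self.n_channels, self.bands)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def block(self, band: str) -> np.ndarray:
        """The ``n_channels x n_samples`` block for one wavelength/chromophore."""
        bands = self.bands
        if band not in bands:
            raise RecordingError(f"band {band!r} not in {bands} for stage {self.stage!r}")
        i = bands.index(band)
        return self.data[i * self.n_channels : (i + 1) * self.n_channels]

    def with_data(self, data: np.ndarray, stage: str | None = None) -> "Recording":
        return replace(self, data=data, stage=self.stage if stage is None else stage)

    @classmethod
    def from_blocks(
        cls,
        blocks: Mapping[str, np.ndarray],
        *,
        subject_id: str,
        group: str,
        stage: str,
        fs_hz: float,
        meta: dict | None = None,
    ) -> "Recording":
        bands = _bands_for_stage(stage)
        if set(blocks) != set(bands):
            raise RecordingError(f"stage {stage!r} needs blocks {bands}, got {tuple(blocks)}")
        arrs = [np.atleast_2d(np.asarray(blocks[b], dtype=float)) for b in bands]
        n_channels = arrs[0].shape[0]
        if any(a.shape != arrs[0].shape for a in arrs):
            raise RecordingError("all band blocks must share one shape")
        return cls(
            subject_id=subject_id,
            group=group,
            stage=stage,
            data=np.vstack(arrs),
            fs_hz=fs_hz,
            n_channels=n_channels,
            meta=dict(meta or {}),
        )


def require_stage(rec: Recording, stage: str, op: str) -> None:
    """Enforce the fixed stage order of the preprocessing chain."""
    if rec.stage != stage:
        raise RecordingError(
            f"{op} requires a {stage!r}-stage recording, got {rec.stage!r} "
            f"(stage order: intensity -> delta_od -> hemoglobin)"
        )
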