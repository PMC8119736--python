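"""Functional-connectivity matrices from hemoglobin time series.

Channel-level (45×45) and ROI-level (6×6) Pearson correlation over the full
recording, Fisher r-to-z transformation, and group averaging. HbR is the
default chromophore throughout (generally the more reliable signal for
resting-state network metrics); HbO is available through the same calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .montage import ROI_TOKENS, Montage, roi_members
from .recording import Recording, require_stage

logger = logging.getLogger(__name__)

_CLIP = 1.0 - 1e-7


class ConnectivityError(ValueError):
    pass


@dataclass
class ConnectivityMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal
    kind: str  # "pearson_r" | "fisher_z"
    chromophore: str  # "HbO" | "HbR"
    subject_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ConnectivityError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ConnectivityError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ConnectivityError("diagonal must be zero")
        if self.kind == "pearson_r" and np.any(np.abs(self.values) > 1 + 1e-12):
            raise ConnectivityError("pearson r entries must lie in [-1, 1]")
        if not np.all(np.isfinite(self.values)):
            raise ConnectivityError("entries must be finite")

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def _corr_with_zero_diag(series: np.ndarray, labels: list[str]) -> np.ndarray:
    sd = series.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ConnectivityError(
            f"zero-variance series: {[labels[i] for i in dead]} (correlation undefined)"
        )
    r = np.corrcoef(series)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return r


def pearson_matrix(rec: Recording, chromophore: str = "HbR") -> ConnectivityMatrix:
    """Pairwise Pearson r between all channels over the full time series."""
    require_stage(rec, "hemoglobin", "pearson_matrix")
    series = rec.block(chromophore)
    if series.shape[0] < 2 or series.shape[1] < 3:
        raise ConnectivityError("need >= 2 channels and >= 3 samples")
    labels = [f"ch{i:02d}" for i in range(1, rec.n_channels + 1)]
    return ConnectivityMatrix(
        labels=labels,
        values=_corr_with_zero_diag(series, labels),
        kind="pearson_r",
        chromophore=chromophore,
        subject_id=rec.subject_id,
        group=rec.group,
    )


def fisher_z(mat: ConnectivityMatrix) -> ConnectivityMatrix:
    """Elementwise r-to-z (atanh) for improved normality; diagonal stays 0."""
    if mat.kind != "pearson_r":
        raise ConnectivityError(f"fisher_z expects pearson_r, got {mat.kind!r}")
    r = mat.values
    if np.any(np.abs(r) > _CLIP):
        logger.warning(
            "fisher_z: clipping %d |r| values above %.7f", int(np.sum(np.abs(r) > _CLIP)), _CLIP
        )
        r = np.clip(r, -_CLIP, _CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return replace(mat, values=z, kind="fisher_z")


def fisher_z_inverse(mat: ConnectivityMatrix) -> ConnectivityMatrix:
    """tanh back-transform of a fisher_z matrix; diagonal stays 0."""
    if mat.kind != "fisher_z":
        raise ConnectivityError(f"fisher_z_inverse expects fisher_z, got {mat.kind!r}")
    r = np.tanh(mat.values)
    np.fill_diagonal(r, 0.0)
    return replace(mat, values=r, kind="pearson_r")


def roi_matrix(
    rec: Recording, montage: Montage, chromophore: str = "HbR"
) -> ConnectivityMatrix:
    """6×6 between-ROI Pearson r from ROI-mean time series.

    Member-channel time series are averaged per ROI before correlation; the
    midline channel belongs to no lateral ROI and is excluded.
    """
    require_stage(rec, "hemoglobin", "roi_matrix")
    series = rec.block(chromophore)
    means = np.vstack(
        [series[[i - 1 for i in roi_members(montage, roi)]].mean(axis=0) for roi in ROI_TOKENS]
    )
    return ConnectivityMatrix(
        labels=list(ROI_TOKENS),
        values=_corr_with_zero_diag(means, list(ROI_TOKENS)),
        kind="pearson_r",
        chromophore=chromophore,
        subject_id=rec.subject_id,
        group=rec.group,
    )


@dataclass
class GroupAverage:
    matrix: ConnectivityMatrix
    mean_offdiag: float  # grand mean of the unique off-diagonal entries
    sd_offdiag: float


def group_average(mats: list[ConnectivityMatrix]) -> GroupAverage:
    """Elementwise mean matrix plus the grand mean±SD of unique pairs."""
    if not mats:
        raise ConnectivityError("no matrices to average")
    first = mats[0]
    for m in mats[1:]:
        if m.labels != first.labels or m.kind != first.kind:
            raise ConnectivityError("matrices must share labels and kind")
    mean_vals = np.mean([m.values for m in mats], axis=0)
    avg = ConnectivityMatrix(
        labels=list(first.labels),
        values=mean_vals,
        kind=first.kind,
        chromophore=first.chromophore,
        subject_id=None,
        group=first.group if len({m.group for m in mats}) == 1 else None,
    )
    ut = avg.upper_triangle()
    return GroupAverage(matrix=avg, mean_offdiag=float(ut.mean()), sd_offdiag=float(ut.std(ddof=1)))
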