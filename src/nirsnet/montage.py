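"""The 45-channel neonatal probe montage: channel table, ROIs, accessors.

The montage covers the prefrontal, temporal and parietal lobes with 45
source–detector channels grouped into six lateral regions of interest
(LPFC, LTL, LPL and their right-hemisphere counterparts). One medial
prefrontal channel (index 23, AFz–Fz) belongs to no lateral ROI and is
tagged ``MIDLINE``; ROI-level analyses exclude it. Inter-probe distances
(20/25/30 mm) enter the Beer–Lambert conversion; MNI coordinates and
anatomical labels are carried as metadata only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

ROI_TOKENS = ("LPFC", "LTL", "LPL", "RPFC", "RTL", "RPL")
MIDLINE = "MIDLINE"
VALID_LENGTHS_MM = (20, 25, 30)
N_CHANNELS = 45
MIDLINE_CHANNEL = 23

_COLUMNS = ("channel", "source", "detector", "length_mm", "x", "y", "z", "roi", "label")


class MontageError(ValueError):
    """Malformed or inconsistent montage table."""


@dataclass(frozen=True)
class Channel:
    index: int
    source: str
    detector: str
    length_mm: int
    mni: tuple[int, int, int]
    roi: str
    label: str


@dataclass(frozen=True)
class Montage:
    """Validated, ordered collection of the 45 measurement channels.

    ``n_sources``/``n_detectors`` are the probe counts declared for the cap
    (20 sources, 16 detectors); the 10–20 optode names in the channel table
    do not map one-to-one onto physical probes, so these are metadata, not
    derived from the table.
    """

    channels: tuple[Channel, ...]
    n_sources: int = 20
    n_detectors: int = 16

    def __post_init__(self) -> None:
        _validate(self.channels)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel(self, index: int) -> Channel:
        return self.channels[index - 1]

    @property
    def distances_mm(self) -> list[int]:
        return [c.length_mm for c in self.channels]

    def roi_of(self, index: int) -> str:
        return self.channels[index - 1].roi

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(_COLUMNS)
            for c in self.channels:
                writer.writerow(
                    [c.index, c.source, c.detector, c.length_mm, *c.mni, c.roi, c.label]
                )


def _validate(channels: tuple[Channel, ...]) -> None:
    n = len(channels)
    if n != N_CHANNELS:
        raise MontageError(f"expected {N_CHANNELS} channels, got {n}")
    indices = [c.index for c in channels]
    if indices != list(range(1, N_CHANNELS + 1)):
        seen: set[int] = set()
        for c in channels:
            if c.index in seen:
                raise MontageError(f"duplicate channel index {c.index}")
            seen.add(c.index)
        raise MontageError("channel indices must cover 1..45 in order")
    for c in channels:
        if c.length_mm not in VALID_LENGTHS_MM:
            raise MontageError(
                f"channel {c.index}: length {c.length_mm} mm not in {VALID_LENGTHS_MM}"
            )
        if c.roi not in ROI_TOKENS and c.roi != MIDLINE:
            raise MontageError(f"channel {c.index}: unknown ROI token {c.roi!r}")
    midline = [c.index for c in channels if c.roi == MIDLINE]
    if midline != [MIDLINE_CHANNEL]:
        raise MontageError(
            f"exactly channel {MIDLINE_CHANNEL} must be MIDLINE, got {midline}"
        )


def load_montage(path: str | Path | None = None) -> Montage:
    """Load and validate a montage table (TSV); default is the packaged table.

    The table has one header row and columns
    ``channel source detector length_mm x y z roi label``, tab-delimited.
    """
    if path is None:
        ref = resources.files("nirsnet").joinpath("data/montage_45ch.tsv")
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    rows = list(csv.reader(text.splitlines(), delimiter="\t"))
    if not rows or tuple(rows[0]) != _COLUMNS:
        raise MontageError(f"header must be {_COLUMNS}, got {rows[0] if rows else None}")
    channels = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not f for f in row):
            continue
        if len(row) != len(_COLUMNS):
            raise MontageError(f"row {lineno}: expected {len(_COLUMNS)} fields, got {len(row)}")
        try:
            channels.append(
                Channel(
                    index=int(row[0]),
                    source=row[1],
                    detector=row[2],
                    length_mm=int(row[3]),
                    mni=(int(row[4]), int(row[5]), int(row[6])),
                    roi=row[7],
                    label=row[8],
                )
            )
        except ValueError as exc:
            raise MontageError(f"row {lineno}: {exc}") from exc
    channels.sort(key=lambda c: c.index)
    seen: set[int] = set()
    for c in channels:
        if c.index in seen:
            raise MontageError(f"duplicate channel index {c.index}")
        seen.add(c.index)
    return Montage(channels=tuple(channels))


@lru_cache(maxsize=1)
def default_montage() -> Montage:
    """The packaged 45-channel montage, loaded once."""
    return load_montage()


def roi_members(montage: Montage, roi: str) -> list[int]:
    """Ascending 1-based channel indices of one of the six lateral ROIs.

    The MIDLINE channel is outside the six-ROI scheme and cannot be queried
    through it.
    """
    if roi not in ROI_TOKENS:
        raise MontageError(
            f"unknown ROI token {roi!r}; the six lateral ROIs are {ROI_TOKENS}"
        )
    return [c.index for c in montage.channels if c.roi == roi]
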