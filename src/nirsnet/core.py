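"""Core containers shared across the pipeline.

The pipeline's in-memory currency is small and explicit: a raw two-wavelength
intensity recording with its optode montage, a set of labelled time intervals
(artifacts, exclusions, stimulus blocks), the HbO/HbR concentration series
produced by preprocessing, and symmetric channel-by-channel functional
connectivity (FC) matrices at the three analysis stages:

* stage ``A`` — window-averaged Pearson correlations,
* stage ``B`` — Fisher-z values with the age effect regressed out,
* stage ``R`` — task minus rest residual.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

HEMISPHERES = ("L", "R")
REGIONS = ("frontal", "temporal", "temporoparietal", "temporooccipital")

__all__ = [
    "Montage",
    "Interval",
    "AnnotationSet",
    "RawRecording",
    "HemoSeries",
    "FCMatrix",
    "default_montage",
]


@dataclass(frozen=True)
class Montage:
    """Channel layout: source/detector ids, hemisphere, region, distance.

    ``table`` has one row per measurement channel with columns
    ``channel, source, detector, hemisphere, region, distance_mm``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"channel", "source", "detector", "hemisphere", "region", "distance_mm"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"montage missing columns: {sorted(missing)}")
        if not self.table["hemisphere"].isin(HEMISPHERES).all():
            raise ValueError("montage hemisphere must be 'L' or 'R'")
        if (self.table["distance_mm"] <= 0).any():
            raise ValueError("source-detector distance must be positive")
        if self.table["channel"].duplicated().any():
            raise ValueError("duplicate channel names in montage")

    @property
    def n_channels(self) -> int:
        return len(self.table)

    @property
    def channels(self) -> list[str]:
        return list(self.table["channel"])

    @property
    def hemisphere(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy()

    @property
    def distance_mm(self) -> np.ndarray:
        return self.table["distance_mm"].to_numpy(dtype=float)

    def hemisphere_index(self, hemi: str) -> np.ndarray:
        """Indices of channels on hemisphere ``hemi`` ('L' or 'R')."""
        return np.flatnonzero(self.hemisphere == hemi)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Montage":
        return cls(pd.read_csv(path, sep="\t"))


def default_montage(n_channels: int = 50, distance_mm: float = 30.0) -> Montage:
    """Bilateral fronto-temporal montage emulating a 10-20 style layout.

    Channels are split evenly between hemispheres and cycled through the
    four covered regions. Distances default to 30 mm, the usual adult/child
    source-detector separation.
    """
    rows = []
    per_hemi = (n_channels + 1) // 2
    for idx in range(n_channels):
        hemi = "L" if idx < per_hemi else "R"
        local = idx if hemi == "L" else idx - per_hemi
        rows.append(
            {
                "channel": f"CH{idx + 1:02d}",
                "source": f"S{local // 3 + (0 if hemi == 'L' else 8) + 1}",
                "detector": f"D{local // 3 + (0 if hemi == 'L' else 8) + 1}",
                "hemisphere": hemi,
                "region": REGIONS[local % len(REGIONS)],
                "distance_mm": distance_mm,
            }
        )
    return Montage(pd.DataFrame(rows))


@dataclass(frozen=True)
class Interval:
    """Half-open labelled interval [onset, onset+duration) in seconds.

    ``channels`` is None when the interval applies to all channels, else a
    tuple of channel indices.
    """

    onset_s: float
    duration_s: float
    label: str
    channels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("interval onset must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("interval duration must be > 0")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    def sample_slice(self, fs: float) -> slice:
        """Sample-index slice using floor(start)/ceil(end) convention."""
        start = int(np.floor(self.onset_s * fs))
        stop = int(np.ceil(self.end_s * fs))
        return slice(start, stop)


class AnnotationSet:
    """Ordered collection of labelled intervals with mask conversion."""

    def __init__(self, intervals: Iterable[Interval] = ()):  # noqa: D107
        self.intervals: list[Interval] = sorted(intervals, key=lambda iv: iv.onset_s)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def with_label(self, *labels: str) -> "AnnotationSet":
        return AnnotationSet(iv for iv in self.intervals if iv.label in labels)

    def add(self, interval: Interval) -> None:
        self.intervals.append(interval)
        self.intervals.sort(key=lambda iv: iv.onset_s)

    def extend(self, intervals: Iterable[Interval]) -> None:
        for iv in intervals:
            self.add(iv)

    def mask(self, n_samples: int, fs: float, labels: Sequence[str] | None = None) -> np.ndarray:
        """Boolean mask, True where any (selected) interval covers the sample."""
        out = np.zeros(n_samples, dtype=bool)
        for iv in self.intervals:
            if labels is not None and iv.label not in labels:
                continue
            sl = iv.sample_slice(fs)
            out[max(sl.start, 0) : min(sl.stop, n_samples)] = True
        return out

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "onset_s": [iv.onset_s for iv in self.intervals],
                "duration_s": [iv.duration_s for iv in self.intervals],
                "label": [iv.label for iv in self.intervals],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationSet":
        df = pd.read_csv(path, sep="\t")
        return cls(
            Interval(float(r.onset_s), float(r.duration_s), str(r.label))
            for r in df.itertuples()
        )


@dataclass
class RawRecording:
    """Raw continuous-wave intensity: channels x wavelengths x time."""

    intensity: np.ndarray
    fs: float
    wavelengths: tuple[float, float]
    montage: Montage
    subject: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[1] != 2:
            raise ValueError("intensity must be (n_channels, 2, n_times)")
        if self.intensity.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"intensity has {self.intensity.shape[0]} channels but montage "
                f"describes {self.montage.n_channels}"
            )
        if not np.all(self.intensity > 0):
            raise ValueError("raw intensity must be strictly positive")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_times(self) -> int:
        return self.intensity.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs


@dataclass
class HemoSeries:
    """HbO/HbR concentration-change series (µM) with validity bookkeeping."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    valid_mask: np.ndarray
    retained_channels: np.ndarray
    dpf: tuple[float, float] | None = None
    montage: Montage | None = None
    subject: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        self.retained_channels = np.asarray(self.retained_channels, dtype=bool)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr shapes differ")
        if self.valid_mask.shape[0] != self.hbo.shape[1]:
            raise ValueError("valid_mask length must equal the time axis")
        if self.retained_channels.shape[0] != self.hbo.shape[0]:
            raise ValueError("retained_channels length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_times(self) -> int:
        return self.hbo.shape[1]


def _check_symmetric_zero_diag(values: np.ndarray) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("FC matrix must be square")
    if not np.allclose(values, values.T, equal_nan=True):
        raise ValueError("FC matrix must be symmetric")
    if not np.allclose(np.diag(values), 0.0):
        raise ValueError("FC matrix diagonal must be zero")


@dataclass
class FCMatrix:
    """Symmetric channel x channel FC matrix at stage A, B or R."""

    values: np.ndarray
    stage: str
    condition: str
    subject: str = ""
    n_samples_used: int = 0
    channels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.stage not in ("A", "B", "R"):
            raise ValueError("stage must be 'A', 'B' or 'R'")
        _check_symmetric_zero_diag(self.values)
        off = self.values[~np.eye(self.values.shape[0], dtype=bool)]
        finite = off[np.isfinite(off)]
        if self.stage == "A" and finite.size and np.any(np.abs(finite) >= 1.0):
            raise ValueError("stage-A off-diagonal correlations must lie in (-1, 1)")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def copy_with(self, **kwargs) -> "FCMatrix":
        return replace(self, **kwargs)
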