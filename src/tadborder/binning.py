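"""Binned data matrix construction.

The genome is tiled into fixed-size bins (50 bp for *Drosophila*-scale
analyses, 1 kb for human-scale — both plain parameters, never hard-coded).
Each bin receives a border label ``Y`` (1 if it overlaps a window centered
on a TAD junction) and one column per genomic feature, encoded either as
the fraction of the bin covered by the feature's intervals (coordinate
mode, values in [0, 1]) or as the length-weighted mean of a quantitative
signal over the bin (quantitative mode).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import GenomeLayout, GenomicInterval, SignalTrack

__all__ = [
    "BinIndex",
    "FeatureMatrix",
    "make_bins",
    "label_borders",
    "encode_coordinate_feature",
    "encode_quantitative_feature",
    "assemble_matrix",
]


@dataclass(frozen=True)
class BinIndex:
    """A genome-wide tiling into fixed-size bins.

    Bins tile each chromosome without gaps or overlaps; every bin has
    length ``bin_size`` except possibly the last bin of a chromosome.
    """

    layout: GenomeLayout
    bin_size: int

    @property
    def bins_per_chrom(self) -> tuple[int, ...]:
        return tuple(
            math.ceil(length / self.bin_size) for length in self.layout.lengths
        )

    @property
    def n_bins(self) -> int:
        return sum(self.bins_per_chrom)

    def chrom_offset(self, chrom: str) -> tuple[int, int]:
        """Return (global offset, bin count) for one chromosome."""
        offset = 0
        for name, count in zip(self.layout.chroms, self.bins_per_chrom):
            if name == chrom:
                return offset, count
            offset += count
        raise KeyError(f"unknown chromosome {chrom!r}")

    @property
    def bins(self) -> list[GenomicInterval]:
        """Materialize the ordered genome-wide bin list."""
        out: list[GenomicInterval] = []
        for chrom, length in self.layout.items():
            for start in range(0, length, self.bin_size):
                out.append(GenomicInterval(chrom, start, min(start + self.bin_size, length)))
        return out

    def bin_frame(self) -> pd.DataFrame:
        """Bin coordinates as a (chrom, start, end) DataFrame."""
        chroms, starts, ends = [], [], []
        for chrom, length in self.layout.items():
            s = np.arange(0, length, self.bin_size)
            chroms.extend([chrom] * len(s))
            starts.append(s)
            ends.append(np.minimum(s + self.bin_size, length))
        return pd.DataFrame(
            {
                "chrom": chroms,
                "start": np.concatenate(starts) if starts else [],
                "end": np.concatenate(ends) if ends else [],
            }
        )


def make_bins(layout: GenomeLayout, bin_size: int) -> BinIndex:
    """Tile the genome into ``bin_size`` bins."""
    if bin_size <= 0:
        raise ValueError(f"bin_size must be > 0, got {bin_size}")
    return BinIndex(layout, int(bin_size))


def _group_by_chrom(
    intervals: Iterable[GenomicInterval],
) -> dict[str, list[GenomicInterval]]:
    grouped: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        grouped.setdefault(iv.chrom, []).append(iv)
    return grouped


def _validate_tads(tads_by_chrom: dict[str, list[GenomicInterval]]) -> None:
    for chrom, tads in tads_by_chrom.items():
        tads.sort(key=lambda t: t.start)
        for a, b in zip(tads, tads[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping TADs on {chrom}: [{a.start},{a.end}) and "
                    f"[{b.start},{b.end})"
                )


def border_points(
    tads: Sequence[GenomicInterval], include_chrom_ends: bool = False
) -> dict[str, list[int]]:
    """TAD junction positions per chromosome.

    A border point is any position where one TAD ends and the next begins.
    When two TADs are separated by a gap, both gap edges are border points
    (the conservative reading).  Chromosome-terminal edges (the start of
    the first TAD and the end of the last) are excluded unless
    ``include_chrom_ends`` is set.
    """
    grouped = _group_by_chrom(tads)
    _validate_tads(grouped)
    points: dict[str, list[int]] = {}
    for chrom, chrom_tads in grouped.items():
        pts: set[int] = set()
        for a, b in zip(chrom_tads, chrom_tads[1:]):
            pts.add(a.end)
            if b.start != a.end:
                pts.add(b.start)
        if include_chrom_ends:
            pts.add(chrom_tads[0].start)
            pts.add(chrom_tads[-1].end)
        points[chrom] = sorted(pts)
    return points


def label_borders(
    bins: BinIndex,
    tads: Sequence[GenomicInterval],
    window: int,
    include_chrom_ends: bool = False,
) -> np.ndarray:
    """Border indicator per bin.

    ``Y = 1`` for every bin overlapping ``[point - window//2,
    point + window - window//2)`` around any border point; overlapping
    windows are unioned, so no bin is counted twice.
    """
    if window <= 0:
        raise ValueError(f"window must be > 0, got {window}")
    y = np.zeros(bins.n_bins, dtype=np.int8)
    half = window // 2
    for chrom, points in border_points(tads, include_chrom_ends).items():
        offset, count = bins.chrom_offset(chrom)
        chrom_len = bins.layout.length_of(chrom)
        for point in points:
            lo = max(point - half, 0)
            hi = min(point + (window - half), chrom_len)
            if lo >= hi:
                continue
            first = lo // bins.bin_size
            last = (hi - 1) // bins.bin_size
            y[offset + first : offset + last + 1] = 1
    return y


def _merge_intervals(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    pairs.sort()
    merged: list[tuple[int, int]] = []
    for s, e in pairs:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def _accumulate_coverage(
    n_bins: int,
    bin_size: int,
    chrom_len: int,
    entries: Iterable[tuple[int, int, float]],
) -> np.ndarray:
    """Sum of value x covered-bp per bin, via point + range-difference adds."""
    point = np.zeros(n_bins)
    rng = np.zeros(n_bins + 1)
    for s, e, v in entries:
        s, e = max(s, 0), min(e, chrom_len)
        if s >= e:
            continue
        first, last = s // bin_size, (e - 1) // bin_size
        if first == last:
            point[first] += v * (e - s)
            continue
        point[first] += v * ((first + 1) * bin_size - s)
        point[last] += v * (e - last * bin_size)
        if last > first + 1:
            rng[first + 1] += v * bin_size
            rng[last] -= v * bin_size
    return point + np.cumsum(rng[:-1])


def _bin_lengths(n_bins: int, bin_size: int, chrom_len: int) -> np.ndarray:
    lengths = np.full(n_bins, float(bin_size))
    if n_bins:
        lengths[-1] = chrom_len - (n_bins - 1) * bin_size
    return lengths


def encode_coordinate_feature(
    bins: BinIndex,
    intervals: Sequence[GenomicInterval],
    on_unknown_chrom: str = "warn",
) -> np.ndarray:
    """Fraction of each bin covered by the union of the intervals.

    A peak covering x% of a bin yields a value of x/100; overlapping peaks
    are unioned, never summed.  Intervals on chromosomes absent from the
    layout are skipped with a warning by default (``on_unknown_chrom`` one
    of ``"warn"``, ``"skip"``, ``"error"``).
    """
    if on_unknown_chrom not in ("warn", "skip", "error"):
        raise ValueError(f"invalid on_unknown_chrom {on_unknown_chrom!r}")
    values = np.zeros(bins.n_bins)
    grouped = _group_by_chrom(intervals)
    for chrom, chrom_ivs in grouped.items():
        if chrom not in bins.layout:
            if on_unknown_chrom == "error":
                raise KeyError(f"interval on unknown chromosome {chrom!r}")
            if on_unknown_chrom == "warn":
                warnings.warn(
                    f"skipping {len(chrom_ivs)} interval(s) on unknown chromosome {chrom!r}"
                )
            continue
        offset, count = bins.chrom_offset(chrom)
        chrom_len = bins.layout.length_of(chrom)
        merged = _merge_intervals([(iv.start, iv.end) for iv in chrom_ivs])
        covered = _accumulate_coverage(
            count, bins.bin_size, chrom_len, ((s, e, 1.0) for s, e in merged)
        )
        values[offset : offset + count] = covered / _bin_lengths(
            count, bins.bin_size, chrom_len
        )
    return np.clip(values, 0.0, 1.0)


def encode_quantitative_feature(bins: BinIndex, track: SignalTrack) -> np.ndarray:
    """Length-weighted mean signal per bin; uncovered bases contribute 0."""
    track.validate()
    values = np.zeros(bins.n_bins)
    for chrom, entries in track.data.items():
        if chrom not in bins.layout:
            warnings.warn(f"skipping signal on unknown chromosome {chrom!r}")
            continue
        offset, count = bins.chrom_offset(chrom)
        chrom_len = bins.layout.length_of(chrom)
        weighted = _accumulate_coverage(count, bins.bin_size, chrom_len, entries)
        values[offset : offset + count] = weighted / _bin_lengths(
            count, bins.bin_size, chrom_len
        )
    return values


@dataclass
class FeatureMatrix:
    """The central bin-by-feature design matrix with border labels.

    ``X`` is ``n_bins x p``; ``Y`` holds the 0/1 border indicator.  In
    coordinate mode every entry of ``X`` lies in [0, 1].
    """

    Y: np.ndarray
    X: np.ndarray
    feature_names: list[str]
    mode: str = "coordinate"
    bin_index: BinIndex | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X.reshape(-1, 1)
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but Y has {self.Y.shape[0]}"
            )
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match X columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        if not np.isin(self.Y, (0, 1)).all():
            raise ValueError("Y must be binary 0/1")
        if self.mode not in ("coordinate", "quantitative"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if self.mode == "coordinate" and self.X.size:
            if self.X.min() < -1e-12 or self.X.max() > 1 + 1e-12:
                raise ValueError("coordinate-mode values must lie in [0, 1]")

    @property
    def n_bins(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = (
            self.bin_index.bin_frame()
            if self.bin_index is not None
            else pd.DataFrame(index=range(self.n_bins))
        )
        df["Y"] = self.Y.astype(int)
        for j, name in enumerate(self.feature_names):
            df[name] = self.X[:, j]
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, mode: str = "coordinate") -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        meta = [c for c in ("chrom", "start", "end") if c in df.columns]
        names = [c for c in df.columns if c not in meta + ["Y"]]
        return cls(
            Y=df["Y"].to_numpy(),
            X=df[names].to_numpy(dtype=float),
            feature_names=names,
            mode=mode,
        )


def assemble_matrix(
    bins: BinIndex | None,
    Y: np.ndarray,
    features: Mapping[str, np.ndarray] | Sequence[tuple[str, np.ndarray]],
    mode: str = "coordinate",
) -> FeatureMatrix:
    """Stack named feature vectors into a :class:`FeatureMatrix`."""
    if isinstance(features, Mapping):
        items = list(features.items())
    else:
        items = list(features)
    names = [name for name, _ in items]
    n = len(Y)
    for name, vec in items:
        if len(vec) != n:
            raise ValueError(
                f"feature {name!r} has length {len(vec)}, expected {n}"
            )
    X = (
        np.column_stack([np.asarray(vec, dtype=float) for _, vec in items])
        if items
        else np.empty((n, 0))
    )
    return FeatureMatrix(Y=np.asarray(Y), X=X, feature_names=names, mode=mode, bin_index=bins)
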