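"""Reading and writing the genomic file formats the framework consumes.

All coordinates are 0-based, half-open (BED convention) throughout the
package.  Chromosome names are matched exactly: no ``chr`` prefix
normalization is ever applied, because silent renaming corrupts mixed
*Drosophila*/human analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "GenomeLayout",
    "SignalTrack",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "read_signal",
    "read_fasta",
]


class BedParseError(ValueError):
    """A malformed line in a BED-like file; the message names the line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in 0-based half-open coordinates.

    Holds TADs, ChIP-seq peaks, functional elements or motif hits alike.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp)."""

    chroms: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chroms) != len(self.lengths):
            raise ValueError("chroms and lengths differ in length")
        if len(set(self.chroms)) != len(self.chroms):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "GenomeLayout":
        names, lengths = zip(*pairs) if pairs else ((), ())
        return cls(tuple(names), tuple(int(l) for l in lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[self.chroms.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def items(self) -> Iterable[tuple[str, int]]:
        return zip(self.chroms, self.lengths)


@dataclass
class SignalTrack:
    """Per-chromosome sorted, non-overlapping (interval, value) pairs.

    Houses quantitative data such as log(ChIP/Input) signal.
    """

    data: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)

    def add(self, chrom: str, start: int, end: int, value: float) -> None:
        self.data.setdefault(chrom, []).append((int(start), int(end), float(value)))

    def validate(self) -> None:
        for chrom, entries in self.data.items():
            entries.sort(key=lambda t: t[0])
            prev_end = -1
            for start, end, _ in entries:
                if start >= end or start < 0:
                    raise ValueError(
                        f"invalid interval [{start}, {end}) on {chrom}"
                    )
                if start < prev_end:
                    raise ValueError(
                        f"overlapping intervals on {chrom} at {start}"
                    )
                prev_end = end

    def chroms(self) -> list[str]:
        return list(self.data)


def _parse_bed_line(line: str, lineno: int) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise BedParseError(f"line {lineno}: expected >=3 tab-separated fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise BedParseError(
            f"line {lineno}: non-integer coordinate in {fields[1]!r}/{fields[2]!r}"
        ) from None
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    score: float | None = None
    if len(fields) > 4 and fields[4] not in (".", ""):
        try:
            score = float(fields[4])
        except ValueError:
            raise BedParseError(f"line {lineno}: non-numeric score {fields[4]!r}") from None
    try:
        return GenomicInterval(chrom, start, end, name, score)
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: {exc}") from None


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into intervals, preserving file order.

    Columns beyond the third are optional; column 4 maps to ``name`` and
    column 5 to ``score`` (the minimal dialect covering MACS peak output).
    Lines starting with ``track``, ``browser`` or ``#`` are skipped.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            intervals.append(_parse_bed_line(line, lineno))
    return intervals


def write_bed(path: str | Path, intervals: Sequence[GenomicInterval]) -> None:
    """Write intervals as BED; emits name/score columns only when present."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                fields.append(repr(iv.score))
            fh.write("\t".join(fields) + "\n")


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Read a two-column ``name<TAB>length`` chrom.sizes file."""
    pairs: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(f"line {lineno}: expected name and length")
            try:
                pairs.append((fields[0], int(fields[1])))
            except ValueError:
                raise BedParseError(
                    f"line {lineno}: non-integer length {fields[1]!r}"
                ) from None
    return GenomeLayout.from_pairs(pairs)


def read_signal(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Intervals on one chromosome must not overlap; abutting intervals are
    retained as separate entries.
    """
    track = SignalTrack()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise BedParseError(f"line {lineno}: expected 4 bedGraph fields")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise BedParseError(f"line {lineno}: malformed bedGraph fields") from None
            if start >= end or start < 0:
                raise BedParseError(f"line {lineno}: invalid interval [{start}, {end})")
            track.add(fields[0], start, end, value)
    track.validate()
    return track


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{name: uppercase sequence}``, order preserved.

    Duplicate record names raise a ``ValueError``.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA record name {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    return sequences
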