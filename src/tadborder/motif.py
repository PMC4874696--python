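"""IUPAC consensus-motif scanning and SNP-effect analysis.

A consensus motif (e.g., the CTCF-like 13-mer CCANNAGNNGGCA or the
BEAF-32 pentamer CGATA) is mapped genome-wide by exact IUPAC matching on
both strands.  Single-base variants of a concrete motif position are
enumerated and their border influence is estimated jointly with the
wild-type motif in one multiple logistic regression, so a variant's
beta below the wild-type beta reads directly as the SNP diminishing the
motif's influence on domain borders.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .binning import BinIndex, assemble_matrix, encode_coordinate_feature
from .genomic_io import GenomicInterval
from .mlr import BorderLogitResults, fit_logistic_irls

__all__ = [
    "MotifPattern",
    "VariantSet",
    "scan_motif",
    "enumerate_snp_variants",
    "snp_effect_analysis",
]

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class MotifPattern:
    """A consensus motif over the IUPAC nucleotide alphabet."""

    iupac: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("motif must be non-empty")
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC codes {sorted(bad)} in {self.iupac!r}")
        object.__setattr__(self, "iupac", self.iupac.upper())
        if not self.name:
            object.__setattr__(self, "name", self.iupac)

    def __len__(self) -> int:
        return len(self.iupac)

    def to_regex(self) -> str:
        return "".join(
            base if len(IUPAC[base]) == 1 else f"[{IUPAC[base]}]"
            for base in self.iupac
        )

    def reverse_complement(self) -> "MotifPattern":
        return MotifPattern(
            str(Seq(self.iupac).reverse_complement()), name=f"{self.name}(rc)"
        )


@dataclass(frozen=True)
class VariantSet:
    """The three single-base variants of one concrete motif position."""

    position: int  # 1-based index into the motif
    wild_type: MotifPattern
    variants: tuple[MotifPattern, ...]

    def __post_init__(self) -> None:
        if len(self.variants) != 3:
            raise ValueError("expected exactly 3 variants for a concrete position")


def _forward_matches(sequence: str, pattern: MotifPattern) -> set[tuple[int, int]]:
    # lookahead keeps overlapping matches
    regex = re.compile(f"(?=({pattern.to_regex()}))")
    return {
        (m.start(), m.start() + len(pattern)) for m in regex.finditer(sequence)
    }


def scan_motif(
    sequences: dict[str, str], pattern: MotifPattern
) -> list[GenomicInterval]:
    """All exact IUPAC matches on both strands, in forward coordinates.

    Reverse-strand hits are found by scanning the reverse-complement
    pattern on the forward sequence, so coordinates need no flipping;
    palindromic double hits are deduplicated.  A pattern longer than a
    sequence simply yields no matches there.
    """
    rc = pattern.reverse_complement()
    out: list[GenomicInterval] = []
    for chrom, seq in sequences.items():
        seq = seq.upper()
        hits = _forward_matches(seq, pattern) | _forward_matches(seq, rc)
        out.extend(
            GenomicInterval(chrom, start, end, name=pattern.name)
            for start, end in sorted(hits)
        )
    return out


def enumerate_snp_variants(pattern: MotifPattern, position: int) -> VariantSet:
    """The three alternative-allele motifs at a concrete position.

    ``position`` is 1-based.  Ambiguity codes (including N) have no
    defined alternative alleles and raise an error.
    """
    if not (1 <= position <= len(pattern)):
        raise ValueError(
            f"position {position} outside motif of length {len(pattern)}"
        )
    base = pattern.iupac[position - 1]
    if base not in "ACGT":
        raise ValueError(
            f"position {position} holds ambiguity code {base!r}; "
            "SNP variants are defined only for concrete bases"
        )
    variants = tuple(
        MotifPattern(
            pattern.iupac[: position - 1] + alt + pattern.iupac[position:],
            name=f"{pattern.name}:{position}{base}>{alt}",
        )
        for alt in "ACGT"
        if alt != base
    )
    return VariantSet(position=position, wild_type=pattern, variants=variants)


def snp_effect_analysis(
    bins: BinIndex,
    Y: np.ndarray,
    sequences: dict[str, str],
    pattern: MotifPattern,
    position: int,
) -> BorderLogitResults:
    """Joint MLR of the wild-type motif and its three variants.

    Each of the four motifs is scanned genome-wide and encoded as a
    coordinate-mode feature; a single multiple logistic regression then
    estimates all four betas together.  An allele diminishes the motif's
    influence when its beta falls below the wild-type beta.  Variants
    with zero genomic matches are dropped with a warning.
    """
    vset = enumerate_snp_variants(pattern, position)
    features: dict[str, np.ndarray] = {}
    for motif in (vset.wild_type, *vset.variants):
        hits = scan_motif(sequences, motif)
        if not hits:
            warnings.warn(f"motif {motif.name!r} has no genomic matches; dropped")
            continue
        column = encode_coordinate_feature(bins, hits, on_unknown_chrom="skip")
        if column.max() == 0:
            warnings.warn(f"motif {motif.name!r} covers no bins; dropped")
            continue
        features[motif.name] = column
    if not features:
        raise ValueError("no motif produced any genomic coverage")
    matrix = assemble_matrix(bins, Y, features, mode="coordinate")
    return fit_logistic_irls(matrix)
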