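"""Shared in-memory containers.

Coordinate convention: all internal coordinates are 1-based inclusive (the
VCF convention). BED output converts to 0-based half-open at the writer
boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError

#: Valid single-character genotype codes in marker tables.
#: A = green-parent homozygote, B = yellow-parent homozygote,
#: H = heterozygote, "-" = missing.
GENOTYPE_CODES = ("A", "B", "H", "-")

PHENOTYPES = ("green", "yellow")


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome span, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) < start ({self.start}) on {self.chrom}"
            )

    @property
    def width_bp(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class GenotypeMatrix:
    """Individuals x ordered markers, with phenotypes.

    Parameters
    ----------
    ids : list of str
        Individual identifiers (unique).
    markers : list of str
        Marker labels, in map order.
    codes : ndarray of shape (n_individuals, n_markers), dtype '<U1'
        Genotype codes from :data:`GENOTYPE_CODES`.
    phenotypes : dict mapping id -> "green" | "yellow", optional
        May be empty when phenotypes are unknown.
    positions : ndarray of int, optional
        Physical marker positions (bp), strictly increasing when given.
    chrom : str, optional
        Chromosome the markers lie on.
    """

    ids: list
    markers: list
    codes: np.ndarray
    phenotypes: dict = field(default_factory=dict)
    positions: np.ndarray | None = None
    chrom: str | None = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype="<U1")
        if self.codes.shape != (len(self.ids), len(self.markers)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.markers)} markers"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ParseError("duplicate individual id in genotype matrix")
        bad = set(np.unique(self.codes)) - set(GENOTYPE_CODES)
        if bad:
            raise ParseError(f"unknown genotype code(s): {sorted(bad)}")
        for ph in self.phenotypes.values():
            if ph not in PHENOTYPES:
                raise ParseError(f"unknown phenotype {ph!r}")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if len(self.positions) != len(self.markers):
                raise ValueError("positions length does not match markers")
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("marker positions must be strictly increasing")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not in matrix") from None

    def column(self, marker: str) -> np.ndarray:
        return self.codes[:, self.marker_index(marker)]

    def row(self, individual: str) -> np.ndarray:
        try:
            i = self.ids.index(individual)
        except ValueError:
            raise KeyError(f"individual {individual!r} not in matrix") from None
        return self.codes[i]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codes, index=pd.Index(self.ids, name="id"),
                          columns=self.markers)
        return df
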