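"""Core domain types shared across the pipeline.

All genomic intervals use 0-based half-open coordinates internally; the GTF
writer converts to the 1-based inclusive on-disk dialect.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

SIMPLE_CLASSES = ("known", "chimeric", "non_chimeric")
CLASS_CODES = ("=", "j", "m", "e", "o", "i", "y", "s", "x", "p", "u")


@dataclass
class TranscriptModel:
    """An exon-structured transcript on a genome.

    ``exons`` is an ordered list of (start, end) pairs in genome coordinates;
    exons must be sorted, non-overlapping, and separated by introns of
    length >= 1.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple
    class_code: Optional[str] = None
    simple_class: Optional[str] = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not exons:
            raise ValueError(f"{self.transcript_id}: transcript has zero exons")
        for s, e in exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: exon end must exceed start ({s},{e})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"{self.transcript_id}: exons must be sorted with intron length >= 1"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple:
        return tuple((e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]))

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def tss(self) -> int:
        """Transcription start site: first base in transcript orientation."""
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1] - 1


@dataclass(frozen=True)
class TEInterval:
    """A transposable-element interval with its class/family/subfamily labels."""

    chrom: str
    start: int
    end: int
    strand: str
    te_class: str
    te_family: str
    te_subfamily: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("TE interval end must exceed start")
        if not (self.te_class and self.te_family and self.te_subfamily):
            raise ValueError("TE hierarchy fields must be non-empty")

    @property
    def name(self) -> str:
        return f"{self.te_class}/{self.te_family}/{self.te_subfamily}"


@dataclass
class TssAnnotation:
    transcript_id: str
    tss_position: int
    chrom: str
    te_subfamily: Optional[str]
    te_class: Optional[str] = None
    te_family: Optional[str] = None
    distance: Optional[int] = None


@dataclass
class EnrichmentResult:
    """One 2x2 Fisher enrichment row for a TE group."""

    te_group: str
    level: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float


@dataclass
class OrfRecord:
    """An open reading frame in transcript-relative coordinates.

    ``nt_start``/``nt_end`` are 0-based half-open on the spliced transcript;
    the stop codon, when present, is included in the interval but never
    translated.
    """

    orf_id: str
    transcript_id: str
    frame: int
    nt_start: int
    nt_end: int
    completeness: str
    aa_sequence: str

    @property
    def aa_length(self) -> int:
        return len(self.aa_sequence)

    @property
    def has_stop(self) -> bool:
        return (self.nt_end - self.nt_start) == 3 * self.aa_length + 3


@dataclass(frozen=True)
class PeptideHit:
    peptide: str
    orf_id: str
    aa_offset: int
    mismatches: int = 0
    transcript_id: Optional[str] = None


@dataclass(frozen=True)
class GenomicBlocks:
    """Genomic footprint of a peptide occurrence, split at splice junctions."""

    chrom: str
    strand: str
    blocks: tuple

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass
class Spectrum:
    """A peak list; ``role`` distinguishes eluted vs synthetic-peptide spectra."""

    peaks: np.ndarray
    peptide: str
    role: str
    precursor_charge: Optional[int] = None

    def __post_init__(self):
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if peaks.size:
            if np.any(peaks[:, 0] <= 0):
                raise ValueError("m/z values must be positive")
            if np.any(peaks[:, 1] < 0):
                raise ValueError("intensities must be non-negative")
            peaks = peaks[np.argsort(peaks[:, 0], kind="stable")]
        object.__setattr__(self, "peaks", peaks)

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]


@dataclass(frozen=True)
class FragmentIon:
    series: str
    index: int
    charge: int
    mz: float


@dataclass
class ValidationResult:
    peptide: str
    r_squared: float
    n_matched: int
    validated: bool
    insufficient_evidence: bool = False
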