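"""Peptide-to-ORF scanning, splice-aware genomic projection, and
sequence-polymorphism rates.

Peptides identified by MS are located in the predicted ORF database with an
ungapped (Hamming) mismatch-tolerant scan, projected through the encoding
transcript's exon structure to genomic blocks (BED12-style), and classified
as uniquely or multiply mapped at 0/1/2 mismatches, where uniqueness is
decided at the level of genomic loci after projection so that redundant
isoforms of one locus do not break uniqueness.
"""
from __future__ import annotations

from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .models import GenomicBlocks, OrfRecord, PeptideHit, TranscriptModel
from .orfs import translate_codon
from .spectra import RESIDUE_MASS

_AA = set(RESIDUE_MASS)


def scan_peptide(
    peptide: str,
    orf_db: Mapping[str, str],
    max_mismatch: int = 0,
) -> List[PeptideHit]:
    """All ungapped occurrences of ``peptide`` in the ORF translations with
    Hamming distance <= ``max_mismatch``."""
    if set(peptide) - _AA:
        raise ValueError(f"non-standard residue in peptide {peptide!r}")
    if max_mismatch not in (0, 1, 2, 3):
        raise ValueError("max_mismatch must be in {0,1,2,3}")
    pep = np.frombuffer(peptide.encode(), dtype=np.uint8)
    L = len(pep)
    hits: List[PeptideHit] = []
    for orf_id in sorted(orf_db):
        seq = orf_db[orf_id]
        n = len(seq)
        if n < L:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        mm = (windows != pep).sum(axis=1)
        for off in np.nonzero(mm <= max_mismatch)[0]:
            hits.append(PeptideHit(peptide, orf_id, int(off), int(mm[off])))
    return hits


def project_to_genome(
    hit: PeptideHit,
    orf: OrfRecord,
    t: TranscriptModel,
) -> GenomicBlocks:
    """Map a peptide occurrence to genomic blocks through the splice structure.

    The nt interval [orf.nt_start + 3*aa_offset, +3*len) on the spliced
    transcript is mapped base-by-base through the exons; contiguous runs are
    merged into blocks reported in ascending genome order.
    """
    L = len(hit.peptide)
    if hit.aa_offset < 0 or hit.aa_offset + L > orf.aa_length:
        raise ValueError(
            f"peptide window [{hit.aa_offset},{hit.aa_offset + L}) outside ORF "
            f"of length {orf.aa_length}"
        )
    nt_lo = orf.nt_start + 3 * hit.aa_offset
    nt_hi = nt_lo + 3 * L
    tx_len = t.spliced_length
    if nt_hi > tx_len:
        raise ValueError(
            f"peptide interval [{nt_lo},{nt_hi}) exceeds transcript length {tx_len}"
        )
    # genomic position of each spliced-transcript base, in transcript order
    positions = np.empty(tx_len, dtype=np.int64)
    k = 0
    for s, e in t.exons:
        positions[k : k + (e - s)] = np.arange(s, e)
        k += e - s
    if t.strand == "-":
        positions = positions[::-1]
    span = np.sort(positions[nt_lo:nt_hi])
    blocks: List[Tuple[int, int]] = []
    start = prev = int(span[0])
    for pos in span[1:]:
        pos = int(pos)
        if pos == prev + 1:
            prev = pos
        else:
            blocks.append((start, prev + 1))
            start = prev = pos
    blocks.append((start, prev + 1))
    return GenomicBlocks(chrom=t.chrom, strand=t.strand, blocks=tuple(blocks))


def classify_uniqueness(
    peptide: str,
    orf_db: Mapping[str, str],
    canonical_db: Mapping[str, str],
    orf_index: Mapping[str, OrfRecord],
    transcripts: Mapping[str, TranscriptModel],
) -> Dict[int, dict]:
    """Uniqueness of a peptide's genomic origin at 0/1/2 mismatches.

    For each k the peptide is scanned against the combined ORF + canonical
    databases; ORF hits are projected to genomic loci and the peptide is
    unique iff all hits collapse to a single locus.  Canonical-protein hits
    count as distinct loci (identified by protein).  A peptide claimed to be
    database-derived must have at least one exact hit.
    """
    out: Dict[int, dict] = {}
    for k in (0, 1, 2):
        loci = set()
        for hit in scan_peptide(peptide, orf_db, max_mismatch=k):
            orf = orf_index[hit.orf_id]
            tx = transcripts[orf.transcript_id]
            gb = project_to_genome(hit, orf, tx)
            loci.add((gb.chrom, gb.strand, gb.blocks))
        for hit in scan_peptide(peptide, canonical_db, max_mismatch=k):
            loci.add(("canonical", hit.orf_id, hit.aa_offset))
        if k == 0 and not loci:
            raise ValueError(f"peptide {peptide!r} has no exact hit in either database")
        out[k] = {"unique": len(loci) == 1, "n_loci": len(loci), "loci": sorted(loci, key=repr)}
    return out


def translate_nt(seq: str) -> str:
    return "".join(translate_codon(seq[i : i + 3]) for i in range(0, len(seq) - 2, 3))


def polymorphism_rate(
    haplotypes: Sequence[str],
    reference: str,
    per_position: bool = False,
) -> Dict[str, float]:
    """Percent polymorphism of a haplotype panel against the reference coding
    sequence, at DNA and amino-acid level.

    Default (haplotype-level): the percentage of haplotypes differing from
    the reference at >= 1 nucleotide (resp. >= 1 residue after translation).
    ``per_position`` instead reports the percentage of positions polymorphic
    in >= 1 haplotype.
    """
    if len(reference) % 3 != 0:
        raise ValueError("reference length must be divisible by 3")
    for h in haplotypes:
        if len(h) != len(reference):
            raise ValueError("haplotype length differs from reference")
    n = len(haplotypes)
    ref_aa = translate_nt(reference)
    if per_position:
        dna_poly = set()
        aa_poly = set()
        for h in haplotypes:
            dna_poly |= {i for i, (a, b) in enumerate(zip(h, reference)) if a != b}
            aa_poly |= {i for i, (a, b) in enumerate(zip(translate_nt(h), ref_aa)) if a != b}
        return {
            "n_haplotypes": n,
            "pct_dna_polymorphic": 100.0 * len(dna_poly) / len(reference),
            "pct_aa_polymorphic": 100.0 * len(aa_poly) / len(ref_aa),
        }
    dna = sum(1 for h in haplotypes if h != reference)
    aa = sum(1 for h in haplotypes if translate_nt(h) != ref_aa)
    return {
        "n_haplotypes": n,
        "pct_dna_polymorphic": 100.0 * dna / n if n else 0.0,
        "pct_aa_polymorphic": 100.0 * aa / n if n else 0.0,
    }
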