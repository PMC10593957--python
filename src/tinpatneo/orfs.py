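"""Spliced transcript sequence extraction and ORF prediction.

ORFs are enumerated on the forward strand of the spliced transcript only
(the transcript orientation already encodes the genomic strand), in all
three frames, from stop-to-stop segments:

* complete           — first ATG of a segment through its stop codon,
* five_prime_partial — frame open at the transcript 5' end (no upstream
                       stop), running to the first stop,
* three_prime_partial— ATG-started but running off the 3' end without stop,
* internal           — open at both ends.

Selection keeps complete and 5'-partial ORFs only; within a 5'-open segment
containing internal methionines, the longest reading (the full open
segment) is kept rather than any M-started sub-ORF duplicating its suffix.
Retained ORFs are numbered .p1, .p2, ... in descending amino-acid length.
The minimum length is 8 residues by default.
"""
from __future__ import annotations

from typing import Dict, List, Mapping, Sequence

from Bio.Data import CodonTable

from .models import OrfRecord, TranscriptModel

MIN_AA = 8

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: Dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)  # TAA, TAG, TGA
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon; any codon containing N yields X and is never a
    start or stop."""
    if "N" in codon:
        return "X"
    if codon in STOP_CODONS:
        return "*"
    return CODON_TO_AA.get(codon, "X")


def spliced_sequence(genome: Mapping[str, str], t: TranscriptModel) -> str:
    """Exon sequences concatenated 5'->3'; reverse-complemented for strand -."""
    chrom = genome[t.chrom]
    n = len(chrom)
    parts = []
    for s, e in t.exons:
        if s < 0 or e > n:
            raise ValueError(
                f"{t.transcript_id}: exon ({s},{e}) outside chromosome {t.chrom} (len {n})"
            )
        parts.append(chrom[s:e])
    seq = "".join(parts).upper()
    return reverse_complement(seq) if t.strand == "-" else seq


def enumerate_orfs(mrna: str, min_aa: int = MIN_AA, transcript_id: str = "tx") -> List[OrfRecord]:
    """All candidate ORFs of the forward frames of ``mrna``.

    Candidates shorter than ``min_aa`` residues are discarded.  A 5'-open
    segment yields both the full open reading (five_prime_partial or, with no
    stop at all, internal) and its first-ATG complete/3'-partial sub-ORF;
    selection later removes duplicated suffixes.
    """
    mrna = mrna.upper()
    if set(mrna) - set("ACGTN"):
        raise ValueError("mRNA must be over the alphabet {A,C,G,T,N}")
    out: List[OrfRecord] = []
    n = len(mrna)
    for frame in range(3):
        codon_starts = range(frame, n - 2, 3)
        codons = [mrna[i : i + 3] for i in codon_starts]
        aas = [translate_codon(c) for c in codons]
        # segment boundaries: indices of stop codons
        seg_start = 0  # codon index where the current stop-free run begins
        i = 0
        while seg_start < len(codons):
            # find next stop at or after seg_start
            stop_idx = None
            for i in range(seg_start, len(codons)):
                if aas[i] == "*":
                    stop_idx = i
                    break
            seg_end = stop_idx if stop_idx is not None else len(codons)
            five_open = seg_start == 0
            has_stop = stop_idx is not None
            # first ATG within the segment
            atg = next((k for k in range(seg_start, seg_end) if codons[k] == START_CODON), None)

            def _emit(start_codon_idx: int, completeness: str) -> None:
                aa_seq = "".join(aas[start_codon_idx:seg_end])
                if len(aa_seq) < min_aa:
                    return
                nt_start = frame + 3 * start_codon_idx
                nt_end = frame + 3 * seg_end + (3 if has_stop else 0)
                out.append(
                    OrfRecord(
                        orf_id="",
                        transcript_id=transcript_id,
                        frame=frame,
                        nt_start=nt_start,
                        nt_end=nt_end,
                        completeness=completeness,
                        aa_sequence=aa_seq,
                    )
                )

            if five_open and seg_start < seg_end:
                starts_with_atg = codons[seg_start] == START_CODON
                if starts_with_atg:
                    label = "complete" if has_stop else "three_prime_partial"
                else:
                    label = "five_prime_partial" if has_stop else "internal"
                _emit(seg_start, label)
            if atg is not None and not (five_open and atg == seg_start):
                _emit(atg, "complete" if has_stop else "three_prime_partial")
            seg_start = seg_end + 1 if stop_idx is not None else len(codons)
    return out


def select_orfs(candidates: Sequence[OrfRecord]) -> List[OrfRecord]:
    """Retain complete and 5'-partial ORFs, dropping M-started sub-ORFs that
    duplicate the suffix of a retained 5'-open reading; assign .p ids in
    descending amino-acid length."""
    partials = [c for c in candidates if c.completeness == "five_prime_partial"]
    partial_keys = {(c.frame, c.nt_end) for c in partials}
    kept = list(partials)
    for c in candidates:
        if c.completeness == "complete" and (c.frame, c.nt_end) not in partial_keys:
            kept.append(c)
    kept.sort(key=lambda c: (-c.aa_length, c.frame, c.nt_start))
    out = []
    for i, c in enumerate(kept, start=1):
        out.append(
            OrfRecord(
                orf_id=f"ORF_{c.transcript_id}.p{i}",
                transcript_id=c.transcript_id,
                frame=c.frame,
                nt_start=c.nt_start,
                nt_end=c.nt_end,
                completeness=c.completeness,
                aa_sequence=c.aa_sequence,
            )
        )
    return out


def predict_orfs(
    genome: Mapping[str, str],
    transcripts: Sequence[TranscriptModel],
    min_aa: int = MIN_AA,
) -> List[OrfRecord]:
    """Predict and select ORFs for a set of transcripts."""
    out: List[OrfRecord] = []
    for t in transcripts:
        mrna = spliced_sequence(genome, t)
        out.extend(select_orfs(enumerate_orfs(mrna, min_aa=min_aa, transcript_id=t.transcript_id)))
    return out
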