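"""Independent brute-force oracles used to check the implementation.

Everything here is written against the documented contracts using naive
primitives (per-base sets, pure-python loops, exact rational arithmetic) and
deliberately shares no code with the package's own implementations.
"""
from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import List, Optional


# --------------------------------------------------------------- class codes

def _bases(exons) -> set:
    out = set()
    for s, e in exons:
        out |= set(range(s, e))
    return out


def class_code_oracle(q, refs, run_on: int = 2000) -> str:
    """Naive per-base evaluation of every class-code category, then the
    priority ladder =, j, m, e, o, i, y, s, x, p, u."""
    priority = "=jmeoiysxpu"
    best = "u"
    for r in refs:
        if r.chrom != q.chrom:
            continue
        code = _oracle_category(q, r, run_on)
        if code is not None and priority.index(code) < priority.index(best):
            best = code
    return best


def _oracle_category(q, r, run_on) -> Optional[str]:
    same = q.strand == r.strand
    qb, rb = _bases(q.exons), _bases(r.exons)
    q_introns = [(e1, s2) for (_, e1), (s2, _) in zip(q.exons, q.exons[1:])]
    r_introns = [(e1, s2) for (_, e1), (s2, _) in zip(r.exons, r.exons[1:])]
    exonic = bool(qb & rb)
    if same:
        if len(q.exons) > 1 and len(r.exons) > 1 and q_introns == r_introns:
            return "="
        if len(q.exons) == 1 and len(r.exons) == 1 and exonic:
            return "="
        if len(q.exons) > 1 and set(q_introns) & set(r_introns):
            return "j"
        if exonic:
            for qs, qe in q.exons:
                exon_bases = set(range(qs, qe))
                if any(set(range(a, b)) <= exon_bases for a, b in r_introns):
                    return "m"
            if len(q.exons) == 1 and any(qb & set(range(a, b)) for a, b in r_introns):
                return "e"
            return "o"
        if any(qb <= set(range(a, b)) for a, b in r_introns):
            return "i"
        if any(rb <= set(range(a, b)) for a, b in q_introns):
            return "y"
        q_lo, q_hi = min(qb), max(qb) + 1
        r_lo, r_hi = min(rb), max(rb) + 1
        if q_hi <= r_lo or r_hi <= q_lo:
            gap = max(r_lo - q_hi, q_lo - r_hi)
            if gap <= run_on:
                return "p"
        return None
    if set(q_introns) & set(r_introns):
        return "s"
    if exonic:
        return "x"
    return None


# ----------------------------------------------------------------------- ORFs

_STOPS = ("TAA", "TAG", "TGA")

_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "GAA": "E", "GAG": "E", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G", "TGT": "C", "TGC": "C",
    "TGG": "W",
}


def _aa(codon: str) -> str:
    if "N" in codon:
        return "X"
    if codon in _STOPS:
        return "*"
    return _CODE[codon]


def orf_scan_oracle(mrna: str, min_aa: int) -> List[tuple]:
    """Brute-force frame scan returning (frame, nt_start, nt_end, completeness,
    aa) tuples for every candidate ORF per the documented contract."""
    out = []
    for frame in range(3):
        codons = [mrna[i : i + 3] for i in range(frame, len(mrna) - 2, 3)]
        aas = [_aa(c) for c in codons]
        runs = []
        start = 0
        for i, a in enumerate(aas):
            if a == "*":
                runs.append((start, i, True))
                start = i + 1
        if start < len(aas):
            runs.append((start, len(aas), False))

        def emit(ci, run_end, stopped, label):
            aa = "".join(aas[ci:run_end])
            if len(aa) < min_aa:
                return
            out.append(
                (frame, frame + 3 * ci, frame + 3 * run_end + (3 if stopped else 0), label, aa)
            )

        for a0, b0, stopped in runs:
            if b0 <= a0:
                continue
            if a0 == 0:
                if codons[a0] == "ATG":
                    emit(a0, b0, stopped, "complete" if stopped else "three_prime_partial")
                else:
                    emit(a0, b0, stopped, "five_prime_partial" if stopped else "internal")
            atgs = [k for k in range(a0, b0) if codons[k] == "ATG"]
            if atgs and not (a0 == 0 and atgs[0] == a0):
                emit(atgs[0], b0, stopped, "complete" if stopped else "three_prime_partial")
    return out


# ----------------------------------------------------------- peptide scanning

def hamming_scan_oracle(peptide: str, db: dict, max_mm: int) -> set:
    """Sliding-window Hamming scan, pure python."""
    hits = set()
    for orf_id, seq in db.items():
        for off in range(len(seq) - len(peptide) + 1):
            mm = sum(1 for a, b in zip(peptide, seq[off : off + len(peptide)]) if a != b)
            if mm <= max_mm:
                hits.add((orf_id, off, mm))
    return hits


# ------------------------------------------------------------- Fisher / hyper

def hypergeom_tail(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for X ~ Hypergeometric(N=a+b+c+d, K=a+c, n=a+b), by direct
    enumeration with exact rational arithmetic."""
    N, K, n = a + b + c + d, a + c, a + b
    total = Fraction(0)
    for x in range(a, min(K, n) + 1):
        if n - x > N - K:
            continue
        total += Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
    return float(total)


# ------------------------------------------------------- genomic projection

def per_base_projection_oracle(t, nt_lo: int, nt_hi: int) -> List[tuple]:
    """Genomic blocks of a spliced interval by mapping every base separately."""
    positions = []
    for s, e in t.exons:
        positions.extend(range(s, e))
    if t.strand == "-":
        positions = positions[::-1]
    genomic = sorted(positions[nt_lo:nt_hi])
    blocks = []
    run = [genomic[0], genomic[0] + 1]
    for g in genomic[1:]:
        if g == run[1]:
            run[1] += 1
        else:
            blocks.append(tuple(run))
            run = [g, g + 1]
    blocks.append(tuple(run))
    return blocks
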