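"""Class-code assignment of de novo transcripts against a reference annotation.

Each assembled transcript is compared with the reference transcripts on its
chromosome and receives a single-character class code describing its
structural relationship to the closest reference transcript (the convention
of assembly comparators): "=" exact intron-chain match, "j" at least one
shared junction, "m" intron retention, "e"/"o" other same-strand exonic
overlap, "i" contained in a reference intron, "y" contains a reference in an
intron, "s"/"x" antisense overlap, "p" possible run-on, "u" intergenic.

Codes are then simplified into the three classes used throughout the
pipeline: "=" -> known; {m, j, e, o} -> chimeric (novel transcripts splicing
into known structures); {s, x, i, y, p, u} -> non_chimeric (novel
transcripts not associated with known transcription).

The code is decided by a fixed ladder: the categories below are tested in
priority order against every same-chromosome reference transcript and the
highest-priority category achieved anywhere wins.  Intron retention ("m") is
tested before the generic overlap codes so that it remains reachable.
"""
from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from scipy import stats

from .models import EnrichmentResult, TEInterval, TranscriptModel, TssAnnotation

RUN_ON_DISTANCE = 2000

_PRIORITY = ("=", "j", "m", "e", "o", "i", "y", "s", "x", "p", "u")
_RANK = {c: i for i, c in enumerate(_PRIORITY)}

SIMPLIFY = {
    "=": "known",
    "m": "chimeric",
    "j": "chimeric",
    "e": "chimeric",
    "o": "chimeric",
    "s": "non_chimeric",
    "x": "non_chimeric",
    "i": "non_chimeric",
    "y": "non_chimeric",
    "p": "non_chimeric",
    "u": "non_chimeric",
}


def simplify_class(code: str) -> str:
    """Collapse a class code into known / chimeric / non_chimeric."""
    try:
        return SIMPLIFY[code]
    except KeyError:
        raise ValueError(f"unknown class code {code!r}") from None


def _exon_overlap(q: TranscriptModel, r: TranscriptModel) -> int:
    total = 0
    for qs, qe in q.exons:
        for rs, re_ in r.exons:
            total += max(0, min(qe, re_) - max(qs, rs))
    return total


def _span_overlap(q: TranscriptModel, r: TranscriptModel) -> bool:
    return q.start < r.end and r.start < q.end


def _category(
    q: TranscriptModel, r: TranscriptModel, run_on_distance: int = RUN_ON_DISTANCE
) -> Optional[str]:
    """Most specific class code of query ``q`` against one reference ``r``."""
    if q.chrom != r.chrom:
        return None
    same = q.strand == r.strand
    q_introns, r_introns = set(q.introns), set(r.introns)
    exonic = _exon_overlap(q, r) > 0

    if same:
        if len(q.exons) > 1 and len(r.exons) > 1 and q.introns == r.introns:
            return "="
        if len(q.exons) == 1 and len(r.exons) == 1 and exonic:
            return "="
        if len(q.exons) > 1 and q_introns & r_introns:
            return "j"
        if exonic:
            # intron retention: a query exon spans >= 1 full reference intron
            for qs, qe in q.exons:
                if any(qs <= is_ and ie <= qe for is_, ie in r.introns):
                    return "m"
            if len(q.exons) == 1:
                qs, qe = q.exons[0]
                # mono-exonic fragment covering an exon/intron boundary
                for is_, ie in r.introns:
                    if max(qs, is_) < min(qe, ie):
                        return "e"
            return "o"
        # fully contained within a single reference intron
        for is_, ie in r.introns:
            if is_ <= q.start and q.end <= ie:
                return "i"
        # contains a reference within one of its introns
        for is_, ie in q.introns:
            if is_ <= r.start and r.end <= ie:
                return "y"
        if not _span_overlap(q, r):
            gap = max(r.start - q.end, q.start - r.end)
            if 0 <= gap <= run_on_distance:
                return "p"
        return None
    # opposite strand
    if q_introns & r_introns:
        return "s"
    if exonic:
        return "x"
    return None


def assign_class_code(
    query: TranscriptModel,
    reference: Iterable[TranscriptModel],
    run_on_distance: int = RUN_ON_DISTANCE,
) -> str:
    """Assign the class code of ``query`` versus a reference transcript set."""
    best = "u"
    for r in reference:
        code = _category(query, r, run_on_distance)
        if code is not None and _RANK[code] < _RANK[best]:
            best = code
            if best == "=":
                break
    return best


def classify_transcripts(
    queries: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel],
    run_on_distance: int = RUN_ON_DISTANCE,
) -> List[TranscriptModel]:
    """Assign class_code and simple_class to every query transcript (in place)."""
    by_chrom: Dict[str, List[TranscriptModel]] = defaultdict(list)
    for r in reference:
        by_chrom[r.chrom].append(r)
    for q in queries:
        q.class_code = assign_class_code(q, by_chrom.get(q.chrom, ()), run_on_distance)
        q.simple_class = simplify_class(q.class_code)
    return list(queries)


def transcript_tss(t: TranscriptModel) -> int:
    """TSS position: first base of the first exon in transcript orientation."""
    return t.tss()


def annotate_tss_te(
    transcripts: Sequence[TranscriptModel],
    te_intervals: Sequence[TEInterval],
) -> List[TssAnnotation]:
    """Annotate each transcript TSS with its overlapping or closest TE.

    Overlap requires the TSS base inside the TE interval (strand ignored; TE
    promoters act bidirectionally).  Otherwise the nearest TE is reported,
    with distance counted as the number of bases strictly between the TSS
    base and the interval; ties break toward the smaller TE start.  If the
    chromosome has no TEs the annotation carries te=None and no distance.
    """
    by_chrom: Dict[str, List[TEInterval]] = defaultdict(list)
    for te in te_intervals:
        by_chrom[te.chrom].append(te)
    for tes in by_chrom.values():
        tes.sort(key=lambda t: (t.start, t.end))

    out = []
    for t in transcripts:
        pos = t.tss()
        tes = by_chrom.get(t.chrom)
        if not tes:
            out.append(TssAnnotation(t.transcript_id, pos, t.chrom, None))
            continue
        best = None  # (distance, start) ordering
        for te in tes:
            if te.start <= pos < te.end:
                d = 0
            elif pos < te.start:
                d = te.start - pos - 1
            else:
                d = pos - te.end
            key = (d, te.start)
            if best is None or key < best[0]:
                best = (key, te)
        _, te = best
        out.append(
            TssAnnotation(
                t.transcript_id, pos, t.chrom,
                te_subfamily=te.te_subfamily, te_class=te.te_class,
                te_family=te.te_family, distance=best[0][0],
            )
        )
    return out


def _overlapping_group(ann: TssAnnotation, level: str) -> Optional[str]:
    if ann.distance != 0:
        return None
    return {"class": ann.te_class, "family": ann.te_family, "subfamily": ann.te_subfamily}[level]


def enrich_te(
    foreground: Sequence[TranscriptModel],
    background: Sequence[TranscriptModel],
    te_intervals: Sequence[TEInterval],
    level: str = "subfamily",
) -> List[EnrichmentResult]:
    """One-sided Fisher enrichment of TE groups in foreground TSSs.

    The 2x2 table per group is [foreground overlapping / not, background-only
    overlapping / not], where "background-only" is the background minus the
    foreground.  Results are ordered by ascending p-value; groups with no
    overlap anywhere are retained with p = 1.
    """
    if level not in ("class", "family", "subfamily"):
        raise ValueError(f"level must be class/family/subfamily, got {level!r}")
    if not foreground:
        raise ValueError("empty foreground")
    fg_ids = {t.transcript_id for t in foreground}
    bg_ids = {t.transcript_id for t in background}
    if not fg_ids <= bg_ids:
        raise ValueError("foreground must be a subset of background")

    anns = {a.transcript_id: a for a in annotate_tss_te(background, te_intervals)}
    groups = sorted(
        {getattr(te, {"class": "te_class", "family": "te_family", "subfamily": "te_subfamily"}[level])
         for te in te_intervals}
    )
    n_fg = len(fg_ids)
    rest_ids = bg_ids - fg_ids
    results = []
    for g in groups:
        a = sum(1 for i in fg_ids if _overlapping_group(anns[i], level) == g)
        c = sum(1 for i in rest_ids if _overlapping_group(anns[i], level) == g)
        b = n_fg - a
        d = len(rest_ids) - c
        odds = np.inf if b * c == 0 and a * d > 0 else (
            (a * d) / (b * c) if b * c else np.nan
        )
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        results.append(EnrichmentResult(g, level, a, b, c, d, float(odds), float(p)))
    results.sort(key=lambda r: (r.p_value, -r.a, r.te_group))
    return results
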