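"""Immunopeptidome comparative profiling and t-neopeptide selection.

Peptide-spectrum identifications (long table, one row per peptide x
replicate) are filtered at the search-engine thresholds (FDR 5% for HLA
class I, 1% for class II; XCorr >= 1), assigned to the novel-ORF repertoire
when they occur in a predicted novel ORF but not in the canonical proteome,
profiled by per-condition presentation frequency, and selected as
t-neopeptides:

* relaxed — novel-ORF-exclusive, absent from every control replicate,
  identified in >= 2 treated replicates;
* strict  — additionally identified in 100% of treated replicates.

Peptide identity is the stripped (unmodified) sequence; I and L are kept
distinct as emitted by the search engine.
"""
from __future__ import annotations

import warnings
from typing import List, Mapping, Sequence

import numpy as np
import pandas as pd

Q_CUTOFF = {"I": 0.05, "II": 0.01}
XCORR_MIN = 1.0


def filter_psms(table: pd.DataFrame, hla_class: str = "I") -> pd.DataFrame:
    """Apply FDR and XCorr filters: q <= 0.05 (class I) / 0.01 (class II)
    and XCorr >= 1.  Rows with missing q-values are rejected (counted)."""
    if hla_class not in Q_CUTOFF:
        raise ValueError("hla_class must be 'I' or 'II'")
    required = {"peptide", "q_value", "xcorr"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"missing required columns: {sorted(missing_cols)}")
    na_q = table["q_value"].isna()
    if na_q.any():
        warnings.warn(f"{int(na_q.sum())} rows rejected (missing q_value)")
    keep = (~na_q) & (table["q_value"] <= Q_CUTOFF[hla_class]) & (table["xcorr"] >= XCORR_MIN)
    return table[keep].copy()


def assign_novel_exclusive(
    peptides: Sequence[str],
    canonical_db: Mapping[str, str],
    orf_db: Mapping[str, str],
) -> pd.DataFrame:
    """Flag peptides exclusively assignable to the novel ORF repertoire.

    novel_exclusive <=> exact substring of >= 1 novel ORF translation and not
    an exact substring of any canonical protein.  All source ORF ids are
    enumerated; peptides matching neither database are flagged unassigned.
    """
    rows = []
    for pep in peptides:
        sources = sorted(orf_id for orf_id, seq in orf_db.items() if pep in seq)
        in_canonical = any(pep in seq for seq in canonical_db.values())
        rows.append(
            {
                "peptide": pep,
                "novel_exclusive": bool(sources) and not in_canonical,
                "in_canonical": in_canonical,
                "unassigned": not sources and not in_canonical,
                "source_orf_ids": sources,
                "n_sources": len(sources),
            }
        )
    return pd.DataFrame(rows).set_index("peptide")


def presentation_frequency(
    identifications: pd.DataFrame,
    replicates: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-peptide fraction of replicates with >= 1 identification, per
    condition.

    ``replicates`` maps condition -> full list of replicate ids, so that
    replicates without any identification still count as negative.
    """
    for cond, reps in replicates.items():
        seen = set(identifications.loc[identifications["condition"] == cond, "replicate_id"])
        silent = set(reps) - seen
        if silent:
            warnings.warn(f"{len(silent)} {cond} replicates without identifications")
    peptides = sorted(identifications["peptide"].unique())
    out = pd.DataFrame(index=pd.Index(peptides, name="peptide"))
    for cond, reps in replicates.items():
        sub = identifications[identifications["condition"] == cond]
        counts = sub.groupby("peptide")["replicate_id"].nunique()
        out[f"n_reps_{cond}"] = counts.reindex(peptides).fillna(0).astype(int)
        out[f"freq_{cond}"] = out[f"n_reps_{cond}"] / len(reps)
    return out


def select_t_neopeptides(
    profile: pd.DataFrame,
    treated: str = "treated",
    control: str = "control",
) -> pd.DataFrame:
    """Strict and relaxed t-neopeptide flags.

    relaxed: novel-ORF-exclusive, zero control identifications, >= 2 treated
    replicates; strict: the same with presentation in 100% of treated
    replicates.
    """
    out = profile.copy()
    exclusive = out["novel_exclusive"].fillna(False)
    no_control = out[f"freq_{control}"] == 0
    out["t_neopeptide_relaxed"] = exclusive & no_control & (out[f"n_reps_{treated}"] >= 2)
    out["t_neopeptide_strict"] = (
        exclusive & no_control & (out[f"freq_{treated}"] == 1.0)
    )
    return out


def profile_immunopeptidome(
    identifications: pd.DataFrame,
    canonical_db: Mapping[str, str],
    orf_db: Mapping[str, str],
    replicates: Mapping[str, Sequence[str]],
    hla_class: str = "I",
    treated: str = "treated",
    control: str = "control",
) -> pd.DataFrame:
    """Filter -> assign -> frequency -> selection, returning the full profile."""
    filtered = filter_psms(identifications, hla_class=hla_class)
    profile = presentation_frequency(filtered, replicates)
    flags = assign_novel_exclusive(list(profile.index), canonical_db, orf_db)
    profile = profile.join(flags)
    return select_t_neopeptides(profile, treated=treated, control=control)


def length_distribution(peptides: Sequence[str]) -> pd.Series:
    """Fraction of peptides per length; fractions sum to 1."""
    if len(peptides) == 0:
        raise ValueError("empty peptide set")
    lengths = pd.Series([len(p) for p in peptides])
    return (lengths.value_counts(normalize=True)).sort_index()


def intensity_ranks(all_intensities: Sequence[float], subset: Sequence[float]) -> List[int]:
    """Descending dense ranks of ``subset`` members within the pooled
    intensity distribution (rank 1 = most intense)."""
    pool = np.asarray(all_intensities, dtype=float)
    if np.any(pool <= 0):
        raise ValueError("intensities must be > 0")
    uniq = np.unique(pool)[::-1]  # descending
    rank_of = {v: i + 1 for i, v in enumerate(uniq)}
    ranks = []
    for v in subset:
        if v not in rank_of:
            raise ValueError(f"subset intensity {v} absent from pool")
        ranks.append(rank_of[v])
    return ranks
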