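"""Synthetic data with the statistical structure the pipeline assumes.

The generator lays each chromosome out as a series of isolated gene slots
separated by wide spacers, so that every planted transcript class is
recoverable by construction:

* reference transcripts (multi-exon) occupy slots, optionally with a TE
  placed on their 5' side;
* "known" de novo transcripts are exact copies of reference transcripts;
* chimeric novels start inside the slot's TE and splice into the reference
  exon chain (sharing all but the first junction);
* non-chimeric novels occupy their own slots with no reference overlap, a
  configurable fraction initiating inside a TE.

Treatment-induced transcripts are drawn from the novels, preferring
LTR12C-initiated ones (the dominant source of treatment-induced transcripts
in the system this emulates); their counts carry the planted log2 fold
change under a negative-binomial model (variance mu + alpha*mu^2).
Planted t-neopeptides are written into the genome as complete ORFs inside
the first exon of induced novel transcripts.  All generators are
deterministic under (seed, config).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .config import TE_HIERARCHY, SimulationConfig
from .models import Spectrum, TEInterval, TranscriptModel
from .orfs import predict_orfs, reverse_complement
from .spectra import RESIDUE_MASS, theoretical_ions

SLOT = 5000
SPACER = 3000
TE_LEN = 500

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# one fixed codon per residue (no stop codons)
CODON_OF = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}
_AA_LIST = sorted(RESIDUE_MASS)


@dataclass
class GroundTruth:
    """Planted labels for parameter-recovery tests."""

    induced_transcript_ids: Set[str] = field(default_factory=set)
    planted_te_initiated: Dict[str, str] = field(default_factory=dict)
    true_lfc: Dict[str, float] = field(default_factory=dict)
    planted_t_neopeptides: Set[str] = field(default_factory=set)
    planted_spectrum_concordance: Dict[str, str] = field(default_factory=dict)
    transcript_classes: Dict[str, str] = field(default_factory=dict)
    peptide_sources: Dict[str, str] = field(default_factory=dict)


@dataclass
class AnnotationSet:
    genome: Dict[str, str]
    te_intervals: List[TEInterval]
    reference: List[TranscriptModel]
    denovo: List[TranscriptModel]
    truth: GroundTruth


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _chrom_names(config: SimulationConfig) -> List[str]:
    return [f"chr{i + 1}" for i in range(config.n_chromosomes)]


def _slot_positions(config: SimulationConfig) -> List[Tuple[str, int]]:
    per_chrom = (config.chrom_length - SPACER) // (SLOT + SPACER)
    if per_chrom < 1:
        raise ValueError(
            f"chromosome length {config.chrom_length} too short for one gene slot "
            f"({SLOT + 2 * SPACER} bp required)"
        )
    return [
        (chrom, SPACER + k * (SLOT + SPACER))
        for chrom in _chrom_names(config)
        for k in range(per_chrom)
    ]


def make_genome(config: SimulationConfig) -> Tuple[Dict[str, str], List[TEInterval]]:
    """Random chromosomes plus TE intervals.

    TEs fill the 5' zones of gene slots first (left zone for a future
    plus-strand gene, right zone for minus), then spacer regions; slot
    strands are decided here through the TE position.
    """
    rng = _rng(config, 0)
    genome = {}
    for chrom in _chrom_names(config):
        arr = _BASES[rng.integers(0, 4, size=config.chrom_length)]
        genome[chrom] = arr.tobytes().decode()

    slots = _slot_positions(config)
    strands = rng.choice(np.array(["+", "-"]), size=len(slots))
    spacer_anchors = [(chrom, s + SLOT) for chrom, s in slots]
    if config.n_te > len(slots) + len(spacer_anchors):
        raise ValueError(
            f"cannot place {config.n_te} TEs: only "
            f"{len(slots) + len(spacer_anchors)} positions available at this genome size"
        )
    subfams = list(config.te_subfamily_weights)
    probs = np.array([config.te_subfamily_weights[s] for s in subfams])
    tes: List[TEInterval] = []
    for i in range(config.n_te):
        sub = subfams[int(rng.choice(len(subfams), p=probs))]
        te_class, te_family = TE_HIERARCHY[sub]
        if i < len(slots):
            chrom, s = slots[i]
            start = s + 300 if strands[i] == "+" else s + SLOT - 300 - TE_LEN
        else:
            chrom, anchor = spacer_anchors[i - len(slots)]
            start = anchor + (SPACER - TE_LEN) // 2
        tes.append(
            TEInterval(chrom, start, start + TE_LEN, "+", te_class, te_family, sub)
        )
    return genome, tes


def _class_counts(config: SimulationConfig) -> Dict[str, int]:
    """Largest-remainder rounding of class_mix * n_novel_transcripts."""
    n = config.n_novel_transcripts
    raw = {k: config.class_mix.get(k, 0.0) * n for k in ("known", "chimeric", "non_chimeric")}
    counts = {k: int(v) for k, v in raw.items()}
    rem = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:rem]:
        counts[k] += 1
    return counts


def _make_ref_exons(rng: np.random.Generator, lo: int, hi: int) -> Tuple[Tuple[int, int], ...]:
    """3-5 exons of 100-250 bp separated by 100-300 bp introns inside [lo, hi)."""
    k = int(rng.integers(3, 6))
    exon_lens = rng.integers(100, 251, size=k)
    intron_lens = rng.integers(100, 301, size=k - 1)
    total = int(exon_lens.sum() + intron_lens.sum())
    start = lo + int(rng.integers(0, max(1, hi - lo - total)))
    exons = []
    pos = start
    for i in range(k):
        exons.append((pos, pos + int(exon_lens[i])))
        pos += int(exon_lens[i])
        if i < k - 1:
            pos += int(intron_lens[i])
    return tuple(exons)


def _write_spliced(
    genome: Dict[str, bytearray], t: TranscriptModel, offset: int, seq: str
) -> None:
    """Write ``seq`` (transcript orientation) at spliced offset ``offset``."""
    positions: List[int] = []
    for s, e in t.exons:
        positions.extend(range(s, e))
    if t.strand == "-":
        positions = positions[::-1]
        seq = reverse_complement(seq)[::-1]  # complemented, transcript order
    chrom = genome[t.chrom]
    for i, base in enumerate(seq):
        chrom[positions[offset + i]] = ord(base)


def _orf_cassette(peptide: str) -> str:
    """ATG | pad | peptide | pad | TAA as a nucleotide cassette."""
    return "ATG" + "GCT" + "".join(CODON_OF[aa] for aa in peptide) + "GCA" + "TAA"


def make_annotations(
    genome: Mapping[str, str],
    te_intervals: Sequence[TEInterval],
    config: SimulationConfig,
) -> AnnotationSet:
    """Reference and de novo transcript sets with planted classes, induction
    labels, and t-neopeptide-encoding ORFs written into the genome."""
    rng = _rng(config, 1)
    counts = _class_counts(config)
    slots = _slot_positions(config)
    te_by_slot: Dict[int, TEInterval] = {}
    for te in te_intervals:
        for i, (chrom, s) in enumerate(slots):
            if te.chrom == chrom and s <= te.start < s + SLOT:
                te_by_slot[i] = te
                break
    n_ref = config.n_ref_transcripts
    n_nonchim = counts["non_chimeric"]
    if n_ref + n_nonchim > len(slots):
        raise ValueError(
            f"genome too small: {n_ref + n_nonchim} gene slots requested, "
            f"{len(slots)} available"
        )
    if counts["chimeric"] > 0 and n_ref == 0:
        raise ValueError("chimeric transcripts requested but n_ref_transcripts is 0")
    chim_hosts = [i for i in range(n_ref) if i in te_by_slot]
    if counts["chimeric"] > len(chim_hosts):
        raise ValueError(
            f"{counts['chimeric']} chimeric transcripts requested but only "
            f"{len(chim_hosts)} reference slots carry a TE"
        )

    def slot_strand(i: int) -> str:
        te = te_by_slot.get(i)
        if te is not None:
            chrom, s = slots[i]
            return "+" if te.start - s < SLOT // 2 else "-"
        return str(rng.choice(np.array(["+", "-"])))

    truth = GroundTruth()
    reference: List[TranscriptModel] = []
    for i in range(n_ref):
        chrom, s = slots[i]
        strand = slot_strand(i)
        lo, hi = (s + 1500, s + 4700) if strand == "+" else (s + 300, s + 3500)
        exons = _make_ref_exons(rng, lo, hi)
        reference.append(
            TranscriptModel(f"REF.{i + 1}", f"GENE.{i + 1}", chrom, strand, exons)
        )

    denovo: List[TranscriptModel] = []
    # exact copies of reference transcripts
    for j in range(counts["known"]):
        ref = reference[j % n_ref]
        t = TranscriptModel(
            f"NOVEL.K{j + 1}", ref.gene_id, ref.chrom, ref.strand, ref.exons
        )
        denovo.append(t)
        truth.transcript_classes[t.transcript_id] = "known"

    # chimeric: new TE-internal first exon spliced onto the reference chain
    for j in range(counts["chimeric"]):
        i = chim_hosts[j]
        ref = reference[i]
        te = te_by_slot[i]
        if ref.strand == "+":
            tss = int(rng.integers(te.start + 50, te.start + 300))
            first = (tss, tss + 150)
            exons = (first,) + ref.exons[1:]
        else:
            tss = int(rng.integers(te.end - 300, te.end - 50))
            first = (tss - 149, tss + 1)
            exons = ref.exons[:-1] + (first,)
        t = TranscriptModel(f"NOVEL.C{j + 1}", f"GENE.NC{j + 1}", ref.chrom, ref.strand, exons)
        denovo.append(t)
        truth.transcript_classes[t.transcript_id] = "chimeric"
        truth.planted_te_initiated[t.transcript_id] = te.te_subfamily

    # non-chimeric: isolated slots, optionally TE-initiated
    for j in range(n_nonchim):
        i = n_ref + j
        chrom, s = slots[i]
        te = te_by_slot.get(i)
        strand = slot_strand(i)
        te_init = te is not None and rng.random() < config.te_init_prob
        if te_init:
            if strand == "+":
                tss = int(rng.integers(te.start + 50, te.end - 250))
                exons = ((tss, tss + 200), (tss + 400, tss + 700))
            else:
                tss = int(rng.integers(te.start + 250, te.end - 50))
                exons = ((tss - 699, tss - 399), (tss - 199, tss + 1))
        else:
            lo = s + 1500
            start = lo + int(rng.integers(0, 300))
            exons = ((start, start + 200), (start + 400, start + 700))
        t = TranscriptModel(f"NOVEL.N{j + 1}", f"GENE.NN{j + 1}", chrom, strand, exons)
        denovo.append(t)
        truth.transcript_classes[t.transcript_id] = "non_chimeric"
        if te_init:
            truth.planted_te_initiated[t.transcript_id] = te.te_subfamily

    # induction labels: prefer LTR12C-initiated, then other TE-initiated novels
    novels = [t for t in denovo if truth.transcript_classes[t.transcript_id] != "known"]
    groups = {"ltr12c": [], "te": [], "rest": []}
    for t in novels:
        sub = truth.planted_te_initiated.get(t.transcript_id)
        key = "ltr12c" if sub == "LTR12C" else ("te" if sub else "rest")
        groups[key].append(t.transcript_id)
    ordered = []
    for key in ("ltr12c", "te", "rest"):
        ids = groups[key]
        rng.shuffle(ids)
        ordered.extend(ids)
    if config.n_induced > len(ordered):
        raise ValueError(
            f"n_induced={config.n_induced} exceeds {len(ordered)} novel transcripts"
        )
    for tid in ordered[: config.n_induced]:
        truth.induced_transcript_ids.add(tid)
        # clamp below so planted "induced" labels stay consistent with the
        # strong induction they represent (de-repressed LTR promoters go from
        # silent to highly expressed, well above the lfc > 2 call threshold)
        truth.true_lfc[tid] = float(
            max(rng.normal(config.lfc_mean, config.lfc_sd), config.lfc_min)
        )
    for t in denovo:
        truth.true_lfc.setdefault(t.transcript_id, 0.0)

    # plant t-neopeptide ORFs in induced novel first exons
    editable = {c: bytearray(seq.encode()) for c, seq in genome.items()}
    by_id = {t.transcript_id: t for t in denovo}
    hosts = [tid for tid in ordered[: config.n_induced]
             if truth.transcript_classes[tid] == "non_chimeric"]
    hosts += [tid for tid in ordered[: config.n_induced]
              if truth.transcript_classes[tid] == "chimeric"]
    if config.n_planted_peptides and not hosts:
        raise ValueError("planted peptides requested but no induced novel transcripts")
    next_offset: Dict[str, int] = {}
    for k in range(config.n_planted_peptides):
        while True:
            pep = "".join(rng.choice(_AA_LIST, size=config.peptide_length))
            if pep not in truth.planted_t_neopeptides:
                break
        tid = hosts[k % len(hosts)]
        t = by_id[tid]
        cassette = _orf_cassette(pep)
        first_len = (t.exons[0][1] - t.exons[0][0]) if t.strand == "+" else (
            t.exons[-1][1] - t.exons[-1][0]
        )
        offset = next_offset.get(tid, 9)
        if offset + len(cassette) > first_len:
            raise ValueError(
                f"first exon of {tid} too short for another planted ORF"
            )
        _write_spliced(editable, t, offset, cassette)
        next_offset[tid] = offset + len(cassette) + 6
        truth.planted_t_neopeptides.add(pep)
        truth.peptide_sources[pep] = tid
        truth.planted_spectrum_concordance[pep] = (
            "discordant" if rng.random() < config.spectrum_discordant_fraction else "concordant"
        )
    edited = {c: arr.decode() for c, arr in ((c, bytes(a)) for c, a in editable.items())}

    # planting integrity: every planted peptide must survive ORF prediction
    host_models = [by_id[tid] for tid in dict.fromkeys(truth.peptide_sources.values())]
    if host_models:
        translations = [o.aa_sequence for o in predict_orfs(edited, host_models)]
        for pep in truth.planted_t_neopeptides:
            if not any(pep in aa for aa in translations):
                raise RuntimeError(f"planted peptide {pep} not recoverable from any ORF")

    return AnnotationSet(edited, list(te_intervals), reference, denovo, truth)


def simulate_counts(
    transcripts: Sequence[TranscriptModel],
    truth: GroundTruth,
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """NB count matrix over the de novo transcripts plus design metadata.

    Planted induced transcripts carry their true log2 fold change in the
    treated samples; everything else is flat.  Variance is mu + alpha*mu^2
    with the configured common dispersion.
    """
    rng = _rng(config, 2)
    n = config.n_replicates_per_condition
    ids = [t.transcript_id for t in transcripts]
    mu = config.count_mean * rng.lognormal(0.0, config.count_mean_sigma, size=len(ids))
    mu = np.maximum(mu, config.count_mean_floor)
    lfc = np.array([truth.true_lfc.get(t, 0.0) for t in ids])
    samples = [f"control_{i + 1}" for i in range(n)] + [f"treated_{i + 1}" for i in range(n)]
    cond = ["control"] * n + ["treated"] * n
    mat = np.empty((len(ids), 2 * n), dtype=np.int64)
    alpha = config.nb_dispersion
    for j, c in enumerate(cond):
        m = mu * (2.0 ** lfc if c == "treated" else 1.0)
        if alpha < 1e-12:
            mat[:, j] = rng.poisson(m)
        else:
            r = 1.0 / alpha
            p = r / (r + m)
            mat[:, j] = rng.negative_binomial(r, p)
    counts = pd.DataFrame(mat, index=pd.Index(ids, name="transcript_id"), columns=samples)
    design = pd.DataFrame({"sample": samples, "condition": cond}).set_index("sample")
    return counts, design


def make_canonical_db(config: SimulationConfig) -> Dict[str, str]:
    """A synthetic canonical proteome (random sequences)."""
    rng = _rng(config, 3)
    return {
        f"CANON.{i + 1}": "".join(rng.choice(_AA_LIST, size=config.canonical_protein_length))
        for i in range(config.n_canonical_proteins)
    }


def simulate_immunopeptidome(
    orf_db: Mapping[str, str],
    canonical_db: Mapping[str, str],
    truth: GroundTruth,
    config: SimulationConfig,
    planted_treated_reps: Optional[int] = None,
    planted_control_reps: int = 0,
) -> Tuple[pd.DataFrame, Dict[str, List[str]]]:
    """Per-replicate HLA class I identification tables for both conditions.

    Planted t-neopeptides appear in ``planted_treated_reps`` treated
    replicates (all of them by default) and ``planted_control_reps`` control
    replicates; background peptides are canonical-proteome substrings with
    the configured treated-exclusive / shared / control-only emission mix.
    """
    if not orf_db:
        raise ValueError("empty ORF database")
    rng = _rng(config, 4)
    n = config.n_replicates_per_condition
    reps = {
        "treated": [f"treated_{i + 1}" for i in range(n)],
        "control": [f"control_{i + 1}" for i in range(n)],
    }
    if planted_treated_reps is None:
        planted_treated_reps = n
    alleles = ["A*32:01", "A*24:02", "B*40:01", "C*02:02"]
    rows: List[dict] = []

    def emit(pep: str, condition: str, rep_ids: Sequence[str]) -> None:
        for rid in rep_ids:
            rows.append(
                {
                    "peptide": pep,
                    "replicate_id": rid,
                    "condition": condition,
                    "hla_class": "I",
                    "q_value": float(rng.uniform(0.0, 0.04)),
                    "xcorr": float(rng.uniform(1.2, 4.0)),
                    "intensity": float(rng.lognormal(13.0, 1.0)),
                    "hla_allele": alleles[int(rng.integers(len(alleles)))],
                }
            )

    for pep in sorted(truth.planted_t_neopeptides):
        if not any(pep in seq for seq in orf_db.values()):
            raise ValueError(f"planted peptide {pep} is not a substring of any ORF translation")
        if any(pep in seq for seq in canonical_db.values()):
            raise ValueError(f"planted peptide {pep} collides with the canonical proteome")
        chosen = rng.choice(n, size=planted_treated_reps, replace=False)
        emit(pep, "treated", [reps["treated"][i] for i in sorted(chosen)])
        if planted_control_reps:
            chosen = rng.choice(n, size=planted_control_reps, replace=False)
            emit(pep, "control", [reps["control"][i] for i in sorted(chosen)])

    cats = list(config.peptide_emission)
    probs = np.array([config.peptide_emission[c] for c in cats])
    canon_ids = sorted(canonical_db)
    seen = set(truth.planted_t_neopeptides)
    for _ in range(config.n_background_peptides):
        for _try in range(100):
            src = canonical_db[canon_ids[int(rng.integers(len(canon_ids)))]]
            start = int(rng.integers(0, len(src) - config.peptide_length + 1))
            pep = src[start : start + config.peptide_length]
            if pep not in seen:
                break
        seen.add(pep)
        cat = cats[int(rng.choice(len(cats), p=probs))]
        k_t = int(rng.integers(1, n + 1))
        k_c = int(rng.integers(1, n + 1))
        if cat in ("treated_exclusive", "shared"):
            chosen = sorted(rng.choice(n, size=k_t, replace=False))
            emit(pep, "treated", [reps["treated"][i] for i in chosen])
        if cat in ("control_only", "shared"):
            chosen = sorted(rng.choice(n, size=k_c, replace=False))
            emit(pep, "control", [reps["control"][i] for i in chosen])
    table = pd.DataFrame(rows)
    return table, reps


def simulate_spectrum_pair(
    peptide: str,
    concordance: str,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    low_mass_cutoff: float = 100.0,
) -> Tuple[Spectrum, Spectrum]:
    """An (experimental, synthetic) spectrum pair for one peptide.

    The synthetic spectrum holds the theoretical b/y peaks (charges 1-2,
    full series) with a smooth intensity profile; the experimental spectrum
    carries multiplicative log-normal noise (concordant) or has its
    intensities permuted across the matched ions (discordant), which
    preserves the peak count while destroying the correlation.
    """
    if concordance not in ("concordant", "discordant"):
        raise ValueError("concordance must be 'concordant' or 'discordant'")
    if rng is None:
        rng = _rng(config, 5)
    ions = theoretical_ions(
        peptide, max_charge=2, include_full_length=True, low_mass_cutoff=low_mass_cutoff
    )
    n = len(peptide)
    mz = np.array([ion.mz for ion in ions])
    base = np.array(
        [
            (1.0 if ion.series == "y" else 0.7)
            * (1.0 if ion.charge == 1 else 0.35)
            * (0.25 + 0.75 * np.exp(-(((ion.index / n) - 0.5) ** 2) / (2 * 0.3**2)))
            for ion in ions
        ]
    )
    synthetic = Spectrum(np.column_stack([mz, base]), peptide, "synthetic", precursor_charge=2)
    if concordance == "concordant":
        exp_int = base * np.exp(rng.normal(0.0, config.spectrum_noise_sd, size=base.size))
    else:
        exp_int = rng.permutation(base)
    experimental = Spectrum(
        np.column_stack([mz, exp_int]), peptide, "experimental", precursor_charge=2
    )
    return experimental, synthetic


def simulate_haplotypes(
    coding_sequence: str,
    n_samples: int,
    mutation_spec: Sequence[Tuple[int, str, float]],
    seed: int = 0,
) -> List[str]:
    """A phased haplotype panel: 2 x n_samples sequences.

    ``mutation_spec`` is a list of (position, alt_base, haplotype_fraction);
    the number of carriers is round(fraction * 2n) (round half to even),
    chosen at random among the haplotypes.
    """
    if len(coding_sequence) % 3 != 0:
        raise ValueError("coding sequence length must be divisible by 3")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_samples
    panel = [list(coding_sequence) for _ in range(n_hap)]
    for pos, alt, frac in mutation_spec:
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"haplotype fraction {frac} outside [0, 1]")
        if not (0 <= pos < len(coding_sequence)):
            raise ValueError(f"variant position {pos} outside the sequence")
        k = int(round(frac * n_hap))
        for i in rng.choice(n_hap, size=k, replace=False):
            panel[i][pos] = alt
    return ["".join(h) for h in panel]


def simulate_silac(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Heavy/medium intensity matrix over 7 replicates plus truth labels.

    Rows are planted one-channel ("strongly translated": >= 4 heavy values,
    no medium), differential (nonzero mean log2 H/M), or null.  Missingness
    is left-censored: low intensities are preferentially dropped.
    """
    rng = _rng(config, 6)
    n_reps = 7
    G = config.n_silac_proteins
    ids = [f"PROT.{i + 1}" for i in range(G)]
    is_one = np.zeros(G, dtype=bool)
    is_diff = np.zeros(G, dtype=bool)
    is_one[: config.n_silac_onechannel] = True
    is_diff[config.n_silac_onechannel : config.n_silac_onechannel + config.n_silac_differential] = True
    base = rng.normal(20.0, 2.0, size=G)
    delta = np.where(is_diff, config.silac_effect, 0.0)
    noise_sd = config.silac_effect_sd / np.sqrt(2.0)
    log_h = base[:, None] + delta[:, None] / 2 + rng.normal(0, noise_sd, size=(G, n_reps))
    log_m = base[:, None] - delta[:, None] / 2 + rng.normal(0, noise_sd, size=(G, n_reps))
    H = 2.0 ** log_h
    M = 2.0 ** log_m

    def censor(mat: np.ndarray, protect: np.ndarray) -> np.ndarray:
        out = mat.copy()
        if config.silac_missing_rate <= 0:
            return out
        for j in range(n_reps):
            col = out[:, j]
            ranks = np.argsort(np.argsort(col)) / max(1, G - 1)
            p_miss = np.clip(config.silac_missing_rate * 2.0 * (1.0 - ranks), 0, 1)
            drop = (rng.random(G) < p_miss) & ~protect
            col[drop] = np.nan
        return out

    H = censor(H, protect=is_one)
    M = censor(M, protect=np.zeros(G, dtype=bool))
    M[is_one] = np.nan  # silent channel of the one-channel candidates
    cols_h = [f"H_{i + 1}" for i in range(n_reps)]
    cols_m = [f"M_{i + 1}" for i in range(n_reps)]
    matrix = pd.DataFrame(
        np.column_stack([H, M]), index=pd.Index(ids, name="protein_id"),
        columns=cols_h + cols_m,
    )
    truth = pd.DataFrame(
        {
            "one_channel": is_one,
            "differential": is_diff,
            "true_log2_ratio": delta,
        },
        index=matrix.index,
    )
    return matrix, truth


def generate_dataset(config: SimulationConfig) -> AnnotationSet:
    """Genome, TEs, transcript sets and truth in one call."""
    genome, tes = make_genome(config)
    return make_annotations(genome, tes, config)
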