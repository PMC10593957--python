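"""End-to-end discovery runs: simulate -> classify -> DE/TINPAT -> TE
enrichment -> ORFs -> immunopeptidome profile -> peptide mapping -> spectral
validation -> report.

The run writes every stage product under the output directory and returns a
machine-readable report plus a manifest (config hash, seed, per-stage record
counts).  Reruns with the same seed and config are byte-identical.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__, io
from .classify import classify_transcripts, enrich_te
from .config import SimulationConfig
from .de import bh_adjust, call_tinpats, wald_test
from .orfs import predict_orfs
from .pepmap import project_to_genome, scan_peptide
from .profiling import length_distribution, profile_immunopeptidome
from .simulate import (
    generate_dataset,
    make_canonical_db,
    simulate_counts,
    simulate_immunopeptidome,
    simulate_spectrum_pair,
)
from .spectra import spectral_r2


def _config_hash(config: SimulationConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_discovery(
    config: SimulationConfig,
    outdir,
    seed: Optional[int] = None,
) -> Tuple[dict, dict]:
    """Execute the full discovery chain on a simulated dataset.

    Returns (manifest, report); both are also written as JSON files.
    """
    if seed is not None:
        config = SimulationConfig(**{**asdict(config), "seed": int(seed)})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_counts: Dict[str, int] = {}

    # --- simulate -------------------------------------------------------
    ds = generate_dataset(config)
    truth = ds.truth
    io.write_fasta(ds.genome, outdir / "genome.fa")
    io.write_bed6(ds.te_intervals, outdir / "te.bed")
    io.write_gtf(ds.reference, outdir / "reference.gtf")
    io.write_gtf(ds.denovo, outdir / "denovo.gtf")
    truth_df = pd.DataFrame(
        {
            "simple_class": pd.Series(truth.transcript_classes),
            "induced": pd.Series(
                {t: t in truth.induced_transcript_ids for t in truth.transcript_classes}
            ),
            "true_lfc": pd.Series(truth.true_lfc),
            "te_subfamily": pd.Series(truth.planted_te_initiated),
        }
    )
    truth_df.index.name = "transcript_id"
    io.write_tsv(truth_df, outdir / "truth_transcripts.tsv")
    stage_counts["simulate"] = len(ds.denovo)

    # --- classification -------------------------------------------------
    classify_transcripts(ds.denovo, ds.reference)
    cls = pd.DataFrame(
        {
            "class_code": {t.transcript_id: t.class_code for t in ds.denovo},
            "simple_class": {t.transcript_id: t.simple_class for t in ds.denovo},
        }
    )
    cls.index.name = "transcript_id"
    io.write_tsv(cls, outdir / "classification.tsv")
    class_confusion = (
        pd.crosstab(
            cls["simple_class"],
            pd.Series(truth.transcript_classes).reindex(cls.index),
        )
        .to_dict()
    )
    class_agreement = float(
        (cls["simple_class"] == pd.Series(truth.transcript_classes).reindex(cls.index)).mean()
    )
    stage_counts["classify"] = len(cls)

    # --- differential induction ----------------------------------------
    counts, design = simulate_counts(ds.denovo, truth, config)
    io.write_tsv(counts, outdir / "counts.tsv")
    io.write_tsv(design, outdir / "design.tsv")
    de = wald_test(counts, design["condition"].to_dict(), ("treated", "control"))
    de["p_adj"] = bh_adjust(de["p_value"].to_numpy())
    de = call_tinpats(de, {t.transcript_id: t.simple_class for t in ds.denovo})
    io.write_tsv(de, outdir / "de_results.tsv")
    called_tinpats = set(de.index[de["tinpat"]])
    called_induced = set(de.index[de["induced"]])
    true_set = truth.induced_transcript_ids
    recall = len(called_tinpats & true_set) / len(true_set) if true_set else float("nan")
    fdp = (
        len(called_tinpats - true_set) / len(called_tinpats) if called_tinpats else 0.0
    )
    stage_counts["de"] = len(de)

    # --- TE enrichment ---------------------------------------------------
    by_id = {t.transcript_id: t for t in ds.denovo}
    enrichment_top = None
    if called_tinpats and ds.te_intervals:
        fg = [by_id[t] for t in sorted(called_tinpats)]
        enr = enrich_te(fg, ds.denovo, ds.te_intervals, level="subfamily")
        enr_df = pd.DataFrame([vars(r) for r in enr]).set_index("te_group")
        io.write_tsv(enr_df, outdir / "te_enrichment.tsv")
        enrichment_top = enr[0].te_group
        stage_counts["enrich_te"] = len(enr)

    # --- ORF prediction --------------------------------------------------
    analysis_tx = [by_id[t] for t in sorted(called_induced)]
    orf_records = predict_orfs(ds.genome, analysis_tx)
    orf_db = {o.orf_id: o.aa_sequence for o in orf_records}
    orf_index = {o.orf_id: o for o in orf_records}
    orf_table = pd.DataFrame(
        [
            {
                "orf_id": o.orf_id,
                "transcript_id": o.transcript_id,
                "frame": o.frame,
                "nt_start": o.nt_start,
                "nt_end": o.nt_end,
                "completeness": o.completeness,
                "aa_length": o.aa_length,
            }
            for o in orf_records
        ]
    )
    if len(orf_table):
        orf_table = orf_table.set_index("orf_id")
    io.write_tsv(orf_table, outdir / "orfs.tsv")
    io.write_fasta(orf_db, outdir / "orfs.fa")
    stage_counts["orfs"] = len(orf_records)

    # --- immunopeptidome -------------------------------------------------
    # the measured tables reflect the truly induced repertoire; the analysis
    # below sees only the pipeline's own ORF database
    truth_tx = [by_id[t] for t in sorted(true_set)]
    orf_db_true = {o.orf_id: o.aa_sequence for o in predict_orfs(ds.genome, truth_tx)}
    canonical = make_canonical_db(config)
    io.write_fasta(canonical, outdir / "canonical.fa")
    if orf_db_true:
        idents, reps = simulate_immunopeptidome(orf_db_true, canonical, truth, config)
        io.write_tsv(idents, outdir / "identifications.tsv", index=False)
        profile = profile_immunopeptidome(idents, canonical, orf_db, reps)
        io.write_tsv(profile.drop(columns=["source_orf_ids"]), outdir / "profile.tsv")
        strict = set(profile.index[profile["t_neopeptide_strict"]])
        relaxed = set(profile.index[profile["t_neopeptide_relaxed"]])
        lengths = length_distribution(list(profile.index))
    else:  # nothing induced, nothing presented
        profile = pd.DataFrame()
        strict, relaxed = set(), set()
        lengths = pd.Series(dtype=float)
    stage_counts["profile"] = len(profile)

    # --- peptide-to-genome mapping --------------------------------------
    bed_records = []
    for pep in sorted(strict):
        for hit in scan_peptide(pep, orf_db, max_mismatch=0):
            orf = orf_index[hit.orf_id]
            gb = project_to_genome(hit, orf, by_id[orf.transcript_id])
            bed_records.append((f"{pep}|{hit.orf_id}", gb))
    io.write_bed12(bed_records, outdir / "strict_peptides.bed12")
    stage_counts["map_peptides"] = len(bed_records)

    # --- spectral validation ---------------------------------------------
    rng = np.random.default_rng([config.seed, 7])
    validation = {}
    for pep in sorted(truth.planted_t_neopeptides):
        concord = truth.planted_spectrum_concordance[pep]
        exp, syn = simulate_spectrum_pair(pep, concord, config, rng=rng)
        res = spectral_r2(exp, syn)
        validation[pep] = {
            "r_squared": round(res.r_squared, 6),
            "validated": bool(res.validated),
            "planted_concordance": concord,
        }
    val_df = pd.DataFrame(validation).T
    val_df.index.name = "peptide"
    io.write_tsv(val_df, outdir / "spectral_validation.tsv")
    stage_counts["validate_spectra"] = len(validation)

    report = {
        "n_reference_transcripts": len(ds.reference),
        "n_denovo_transcripts": len(ds.denovo),
        "class_composition": cls["simple_class"].value_counts().to_dict(),
        "class_agreement_with_truth": class_agreement,
        "class_confusion": {str(k): v for k, v in class_confusion.items()},
        "n_induced_called": len(called_induced),
        "n_tinpats": len(called_tinpats),
        "tinpat_recall": recall,
        "tinpat_false_discovery_proportion": fdp,
        "te_enrichment_top": enrichment_top,
        "n_orfs": len(orf_records),
        "strict_t_neopeptides": sorted(strict),
        "relaxed_t_neopeptides": sorted(relaxed),
        "planted_t_neopeptides": sorted(truth.planted_t_neopeptides),
        "strict_equals_planted": strict == truth.planted_t_neopeptides,
        "peptide_length_fractions": {int(k): float(v) for k, v in lengths.items()},
        "spectral_validation": validation,
    }
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stage_counts": stage_counts,
        "outputs": sorted(
            p.name
            for p in outdir.iterdir()
            if p.is_file() and p.name not in ("report.json", "manifest.json")
        ),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest, report
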