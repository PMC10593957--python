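"""On-disk formats: FASTA, GTF2.2, BED6, MGF, TSV.

Internal coordinates are 0-based half-open; the GTF writer emits the 1-based
inclusive dialect and the reader converts back.  FASTA goes through
Biopython, MGF through pyteomics; tables are plain TSV via pandas.
"""
from __future__ import annotations

import re
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .models import Spectrum, TEInterval, TranscriptModel

# --------------------------------------------------------------------- FASTA

def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ----------------------------------------------------------------------- GTF

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def write_gtf(transcripts: Sequence[TranscriptModel], path, source: str = "tinpatneo") -> None:
    """Emit transcript + exon features (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            if t.class_code is not None:
                attrs += f' class_code "{t.class_code}";'
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def read_gtf(path) -> List[TranscriptModel]:
    """Read transcripts from exon features, grouped by transcript_id."""
    exons: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Tuple[str, str, str, str]] = {}
    order: List[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, _, feature, start, end, _, strand, _, attr_str = fields[:9]
            if feature != "exon":
                continue
            attrs = dict(_ATTR_RE.findall(attr_str))
            tid = attrs["transcript_id"]
            if tid not in exons:
                exons[tid] = []
                meta[tid] = (attrs.get("gene_id", tid), chrom, strand, attrs.get("class_code"))
                order.append(tid)
            exons[tid].append((int(start) - 1, int(end)))
    out = []
    for tid in order:
        gene_id, chrom, strand, class_code = meta[tid]
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=tuple(sorted(exons[tid])),
            class_code=class_code,
        )
        out.append(t)
    return out


# ----------------------------------------------------------------------- BED

def write_bed6(tes: Sequence[TEInterval], path) -> None:
    """BED6 with name = class/family/subfamily."""
    with open(path, "w") as fh:
        for te in tes:
            fh.write(f"{te.chrom}\t{te.start}\t{te.end}\t{te.name}\t0\t{te.strand}\n")


def read_bed6(path) -> List[TEInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, _, strand = line.rstrip("\n").split("\t")[:6]
            te_class, te_family, te_subfamily = name.split("/")
            out.append(
                TEInterval(chrom, int(start), int(end), strand, te_class, te_family, te_subfamily)
            )
    return out


def write_bed12(
    records: Sequence[Tuple[str, object]],
    path,
) -> None:
    """One BED12 line per (name, GenomicBlocks) peptide occurrence."""
    with open(path, "w") as fh:
        for name, gb in records:
            starts = [s for s, _ in gb.blocks]
            sizes = [e - s for s, e in gb.blocks]
            chrom_start, chrom_end = starts[0], gb.blocks[-1][1]
            rel = [s - chrom_start for s in starts]
            fh.write(
                "\t".join(
                    [
                        gb.chrom,
                        str(chrom_start),
                        str(chrom_end),
                        name,
                        "0",
                        gb.strand,
                        str(chrom_start),
                        str(chrom_end),
                        "0",
                        str(len(gb.blocks)),
                        ",".join(map(str, sizes)) + ",",
                        ",".join(map(str, rel)) + ",",
                    ]
                )
                + "\n"
            )


# ----------------------------------------------------------------------- MGF

def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    """TITLE carries 'peptide|role'."""
    entries = []
    for sp in spectra:
        params = {"title": f"{sp.peptide}|{sp.role}"}
        if sp.precursor_charge:
            params["charge"] = sp.precursor_charge
        entries.append(
            {"params": params, "m/z array": sp.mz.copy(), "intensity array": sp.intensity.copy()}
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_mgf(path) -> List[Spectrum]:
    out = []
    with _mgf.read(str(path)) as reader:
        for entry in reader:
            title = entry["params"]["title"]
            peptide, role = title.split("|", 1)
            peaks = np.column_stack([entry["m/z array"], entry["intensity array"]])
            charge = entry["params"].get("charge")
            charge = int(charge[0]) if charge else None
            out.append(Spectrum(peaks=peaks, peptide=peptide, role=role, precursor_charge=charge))
    return out


# ----------------------------------------------------------------------- TSV

def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
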