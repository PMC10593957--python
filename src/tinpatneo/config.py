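"""Simulation configuration.

The defaults encode the study design the pipeline targets: two treatment
arms (vehicle control vs combined DNMTi+HDACi analog) with three biological
replicates each, a de novo transcript set mixing known, chimeric and
non-chimeric classes, treatment-induced novel transcripts initiating
preferentially in LTR12C elements with strong (~16-fold) induction, and
HLA ligand tables in which planted t-neopeptides are treated-exclusive.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict


def _default_te_weights() -> Dict[str, float]:
    return {"LTR12C": 0.40, "LTR12D": 0.15, "MLT1B": 0.15, "L1M5": 0.15, "AluY": 0.15}


def _default_class_mix() -> Dict[str, float]:
    return {"known": 0.30, "chimeric": 0.35, "non_chimeric": 0.35}


def _default_emission() -> Dict[str, float]:
    return {"treated_exclusive": 0.20, "shared": 0.60, "control_only": 0.20}


# TE hierarchy used for BED name fields (class/family/subfamily)
TE_HIERARCHY: Dict[str, tuple] = {
    "LTR12C": ("LTR", "ERV1"),
    "LTR12D": ("LTR", "ERV1"),
    "LTR7": ("LTR", "ERV1"),
    "MLT1B": ("LTR", "ERVL-MaLR"),
    "L1M5": ("LINE", "L1"),
    "AluY": ("SINE", "Alu"),
}


@dataclass
class SimulationConfig:
    seed: int = 0

    # genome layout
    n_chromosomes: int = 2
    chrom_length: int = 250_000
    n_te: int = 80
    te_subfamily_weights: Dict[str, float] = field(default_factory=_default_te_weights)

    # transcript sets
    n_ref_transcripts: int = 30
    n_novel_transcripts: int = 60
    class_mix: Dict[str, float] = field(default_factory=_default_class_mix)
    te_init_prob: float = 0.7  # non-chimeric novels initiating inside a TE

    # induction / counts
    n_induced: int = 20
    lfc_mean: float = 4.0
    lfc_sd: float = 0.5
    lfc_min: float = 3.0  # planted induction stays clearly above the 2.0 call threshold
    nb_dispersion: float = 0.05
    n_replicates_per_condition: int = 3
    count_mean: float = 100.0       # median of the log-normal baseline mean
    count_mean_sigma: float = 1.0
    count_mean_floor: float = 50.0  # assembler detection floor

    # immunopeptidome
    n_planted_peptides: int = 8
    peptide_length: int = 9
    n_background_peptides: int = 60
    n_canonical_proteins: int = 40
    canonical_protein_length: int = 250
    peptide_emission: Dict[str, float] = field(default_factory=_default_emission)

    # spectra
    spectrum_noise_sd: float = 0.10
    spectrum_discordant_fraction: float = 0.25

    # SILAC
    silac_missing_rate: float = 0.2
    n_silac_proteins: int = 200
    n_silac_onechannel: int = 10
    n_silac_differential: int = 20
    silac_effect: float = 2.0
    silac_effect_sd: float = 0.3

    def __post_init__(self):
        for name in ("n_chromosomes", "chrom_length", "n_ref_transcripts",
                     "n_novel_transcripts", "n_replicates_per_condition",
                     "peptide_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_te", "n_induced", "n_planted_peptides", "n_background_peptides"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name, probs in (
            ("te_subfamily_weights", self.te_subfamily_weights),
            ("class_mix", self.class_mix),
            ("peptide_emission", self.peptide_emission),
        ):
            vals = list(probs.values())
            if any(not (0.0 <= v <= 1.0) for v in vals):
                raise ValueError(f"{name} probabilities must lie in [0, 1]")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for name in ("te_init_prob", "silac_missing_rate", "spectrum_discordant_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.nb_dispersion < 0 or self.spectrum_noise_sd < 0:
            raise ValueError("dispersion and noise sd must be >= 0")
        unknown = set(self.te_subfamily_weights) - set(TE_HIERARCHY)
        if unknown:
            raise ValueError(f"unknown TE subfamilies: {sorted(unknown)}")
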