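"""Theoretical b/y fragment ions and spectral correlation (R²) validation.

HLA-ligand identifications are validated by comparing the fragment spectrum
of the experimentally eluted peptide against the spectrum of the matching
synthetic peptide: both spectra are annotated with the theoretical b/y ion
series, matched intensities are assembled into a pair of aligned vectors, and
the squared Pearson correlation of those vectors is the spectral correlation
coefficient.  Peptides with R² >= 0.70 count as spectrum-validated.

The aligned vector spans the union of theoretical b/y ions at charges 1..2,
excluding the precursor-like b_n and y_n ions; unmatched ions contribute 0,
and each spectrum is base-peak normalized before correlating.
"""
from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .models import FragmentIon, Spectrum, ValidationResult

PROTON = 1.007276
WATER = 18.010565

# Monoisotopic residue masses (Da), unit-tested against independent sources.
RESIDUE_MASS = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

R2_THRESHOLD = 0.70
DEFAULT_TOLERANCE = 0.02  # Da; high-resolution MS2


def _check_peptide(peptide: str) -> None:
    if len(peptide) < 2:
        raise ValueError("peptide must have length >= 2")
    bad = set(peptide) - set(RESIDUE_MASS)
    if bad:
        raise ValueError(f"unknown residue(s) in peptide: {sorted(bad)}")


def peptide_mass(peptide: str) -> float:
    """Monoisotopic neutral mass of the peptide."""
    _check_peptide(peptide)
    return sum(RESIDUE_MASS[aa] for aa in peptide) + WATER


def theoretical_ions(
    peptide: str,
    max_charge: int = 2,
    include_full_length: bool = False,
    low_mass_cutoff: float = 0.0,
) -> List[FragmentIon]:
    """Theoretical b/y series for ``peptide``.

    b_i = sum of the first i residue masses + proton;
    y_i = sum of the last i residue masses + water + proton;
    multiply-charged m/z = (M + z*proton)/z.

    The full-length b_n/y_n ions are excluded by default (they are
    precursor-like, not backbone fragments); generators of synthetic spectra
    may include them via ``include_full_length``.
    """
    _check_peptide(peptide)
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    n = len(peptide)
    top = n if include_full_length else n - 1
    prefix = np.cumsum([RESIDUE_MASS[aa] for aa in peptide])
    ions: List[FragmentIon] = []
    for i in range(1, top + 1):
        b_neutral = prefix[i - 1]          # singly protonated neutral fragment mass
        y_neutral = prefix[-1] - prefix[n - i - 1] + WATER if i < n else prefix[-1] + WATER
        for z in range(1, max_charge + 1):
            for series, neutral in (("b", b_neutral), ("y", y_neutral)):
                mz = (neutral + z * PROTON) / z
                if mz >= low_mass_cutoff:
                    ions.append(FragmentIon(series=series, index=i, charge=z, mz=mz))
    return ions


def annotate_spectrum(
    spectrum: Spectrum,
    ions: Sequence[FragmentIon],
    tolerance: float = DEFAULT_TOLERANCE,
    ppm: bool = False,
) -> List[Tuple[FragmentIon, int]]:
    """Match theoretical ions to peaks.

    Greedy assignment by ascending |Δm/z|: each ion is matched to at most one
    peak, each peak is used at most once, and only pairs within the tolerance
    are considered.  Returns (ion, peak index) pairs.
    """
    mz = spectrum.mz
    if mz.size == 0 or not ions:
        return []
    candidates = []
    for ion in ions:
        tol = tolerance * ion.mz * 1e-6 if ppm else tolerance
        lo = np.searchsorted(mz, ion.mz - tol, side="left")
        hi = np.searchsorted(mz, ion.mz + tol, side="right")
        for j in range(lo, hi):
            candidates.append((abs(mz[j] - ion.mz), ion, j))
    candidates.sort(key=lambda t: (t[0], t[1].series, t[1].index, t[1].charge, t[2]))
    used_peaks: set = set()
    used_ions: set = set()
    matches = []
    for delta, ion, j in candidates:
        if j in used_peaks or ion in used_ions:
            continue
        used_peaks.add(j)
        used_ions.add(ion)
        matches.append((ion, j))
    return matches


def _aligned_vectors(
    experimental: Spectrum,
    synthetic: Spectrum,
    peptide: str,
    tolerance: float,
    max_charge: int,
    ppm: bool,
) -> Tuple[np.ndarray, np.ndarray, int]:
    ions = theoretical_ions(peptide, max_charge=max_charge)
    v_exp = np.zeros(len(ions))
    v_syn = np.zeros(len(ions))
    index = {ion: k for k, ion in enumerate(ions)}
    both = [0, 0]
    for vec, spec in ((v_exp, experimental), (v_syn, synthetic)):
        base = spec.intensity.max() if spec.peaks.size else 1.0
        base = base if base > 0 else 1.0
        for ion, j in annotate_spectrum(spec, ions, tolerance=tolerance, ppm=ppm):
            vec[index[ion]] = spec.intensity[j] / base
    n_matched = int(np.sum((v_exp > 0) & (v_syn > 0)))
    return v_exp, v_syn, n_matched


def spectral_r2(
    experimental: Spectrum,
    synthetic: Spectrum,
    peptide: str | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
    max_charge: int = 2,
    threshold: float = R2_THRESHOLD,
    ppm: bool = False,
    sqrt_transform: bool = False,
) -> ValidationResult:
    """Spectral correlation coefficient between an eluted and a synthetic spectrum.

    Fewer than 3 ions matched in both spectra is reported as R² = 0 with the
    ``insufficient_evidence`` flag.  Validation uses R² >= ``threshold``
    (inclusive).
    """
    if peptide is None:
        peptide = experimental.peptide
    if experimental.peptide != synthetic.peptide:
        raise ValueError("both spectra must be attributed to the same peptide")
    v_exp, v_syn, n_matched = _aligned_vectors(
        experimental, synthetic, peptide, tolerance, max_charge, ppm
    )
    if sqrt_transform:
        v_exp, v_syn = np.sqrt(v_exp), np.sqrt(v_syn)
    if n_matched < 3:
        return ValidationResult(peptide, 0.0, n_matched, False, insufficient_evidence=True)
    sd_e, sd_s = v_exp.std(), v_syn.std()
    if sd_e == 0 or sd_s == 0:
        r2 = 1.0 if np.allclose(v_exp, v_syn) else 0.0
    else:
        r = float(np.corrcoef(v_exp, v_syn)[0, 1])
        r2 = r * r
    r2 = min(max(r2, 0.0), 1.0)
    return ValidationResult(peptide, r2, n_matched, bool(r2 >= threshold))


def validate_pairs(
    pairs: Iterable[Tuple[Spectrum, Spectrum]],
    tolerance: float = DEFAULT_TOLERANCE,
    threshold: float = R2_THRESHOLD,
    max_charge: int = 2,
) -> List[ValidationResult]:
    """Validate a collection of (experimental, synthetic) spectrum pairs."""
    return [
        spectral_r2(exp, syn, tolerance=tolerance, threshold=threshold, max_charge=max_charge)
        for exp, syn in pairs
    ]
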