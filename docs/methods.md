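# Methods

This note records the models, the committed conventions where the design was
genuinely open, the defaults and why, and what the synthetic data does and
does not emulate.

## Coordinates and formats

All intervals are 0-based half-open internally. The GTF writer emits
1-based inclusive coordinates and the reader converts back; TE intervals are
BED6 with the name field `class/family/subfamily`; peptide occurrences
project to BED12. Spectra are MGF with `TITLE = peptide|role`.

## Transcript classification

A query transcript is compared with every reference transcript on its
chromosome and receives the highest-priority category achieved:

| order | code | definition (committed) |
|---|---|---|
| 1 | `=` | identical intron chain, same strand (mono-exonic: ≥1 bp exon overlap with a mono-exonic reference) |
| 2 | `j` | multi-exon, same strand, ≥1 complete shared intron |
| 3 | `m` | same-strand exonic overlap and a query exon fully spanning ≥1 reference intron (intron retention) |
| 4 | `e` | mono-exonic, same-strand exonic overlap covering an exon–intron boundary |
| 5 | `o` | any other same-strand exonic overlap |
| 6 | `i` | fully inside a single same-strand reference intron |
| 7 | `y` | contains a same-strand reference within one of its introns |
| 8 | `s` | ≥1 intron exactly matching a reference intron on the opposite strand |
| 9 | `x` | exonic overlap on the opposite strand |
| 10 | `p` | same strand, no overlap, within 2000 bp (possible run-on; configurable) |
| 11 | `u` | intergenic |

Intron retention (`m`) is tested *before* the generic overlap codes `e`/`o`;
tested after them it could never fire, because every `m` case also has
same-strand exonic overlap. Simplification: `=` → known; {m, j, e, o} →
chimeric; {s, x, i, y, p, u} → non-chimeric.

TSS–TE annotation ignores strand (LTR promoters act bidirectionally);
distance is the number of bases strictly between the TSS base and the
interval (0 when overlapping), ties breaking toward the smaller TE start.
TE enrichment is a one-sided (over-representation) Fisher's exact test on
[foreground overlapping / not; background-minus-foreground overlapping /
not], reported per group ordered by p, without multiple-testing correction
(the ranking is the product; BH is available).

## Differential induction

The caller is a deliberately small NB Wald test, not a reimplementation of
a full DE package: median-of-ratios size factors; NB log-link regression per
transcript with the log size factors as offsets, fitted by batched Fisher
scoring (all transcripts share the design matrix, so the IRLS sweeps are
vectorized); Wald z = β̂/se(β̂) on the treatment coefficient with two-sided
normal p; BH adjustment within each contrast. An optional covariate (e.g.
cell line) enters as fixed-effect dummies. Degenerate fits (an all-zero
group, |β| diverging, non-convergence) are reported as p = NA, never
silently dropped.

**Dispersion.** The model assumes a dispersion α shared across transcripts
(variance μ + αμ²). The default estimator is a ratio-of-sums method of
moments pooled over all transcripts, α̂ = Σᵢ(s²ᵢ − μ̄ᵢ)/Σᵢμ̄ᵢ², floored at
10⁻⁸ for likelihood stability. A per-transcript moment estimator is also
provided and can be passed explicitly, but at 3–10 replicates its noise
makes the plug-in Wald test anti-conservative (measured type-I error
0.07–0.12 at nominal 0.05, versus nominal with the true α), while the pooled
estimator recovers α within a few percent and calibrates the test at all
replicate numbers. No shrinkage, fold-change moderation, outlier
replacement or independent filtering is performed.

**Thresholds.** Induced: adjusted p < 0.01 and log2 fc > 2, both strict;
TINPAT additionally requires a novel (chimeric/non-chimeric) class; known
transcripts passing the thresholds are induced but never TINPATs.

TPM divides counts by transcript length and scales each sample to 10⁶.
ΔΔCt normalizes the target Ct to the housekeeping gene and the mean ΔCt of
the reference (vehicle) condition; relative expression is 2^(−ΔΔCt).

## ORF prediction

Forward frames of the spliced transcript only (strand is already encoded by
the extraction step). Stop-to-stop segments yield complete (first ATG to
stop), 5'-partial (frame open at the transcript 5' end, no upstream stop,
to the first stop), 3'-partial (ATG to transcript end without stop) and
internal (open both ends) candidates; minimum 8 residues. Codons containing
N translate to X and never act as start or stop. Selection keeps complete
and 5'-partial ORFs; in a 5'-open segment the full open reading wins over
any M-started sub-ORF sharing its stop (a complete ORF is dropped exactly
when a retained 5'-partial has the same frame and nt end). ORFs at the 3'
edge without a stop codon are discarded. Retained ORFs are numbered
`ORF_<transcript>.p1…` in descending amino-acid length. The standard
nuclear codon table is used; alternative starts are not.

## Peptide genomics

Mismatch scanning is ungapped Hamming matching (no indels) over all ORF
translations, exhaustive by construction. Projection maps the peptide's nt
interval on the spliced transcript through the exon chain to genomic
blocks; block lengths always sum to 3× the peptide length and blocks are
reported in ascending genome order for both strands. "Uniquely mapped" is
decided at the genomic-locus level after projection — ORF hits from
redundant isoforms that produce identical blocks collapse to one locus;
canonical-proteome hits count as separate loci. Polymorphism rates are
reported per haplotype (share of the 2n haplotypes differing from the
reference at ≥1 nt, and ≥1 residue after translation); a per-position mode
exists behind a flag because the percentage's denominator is a judgment
call.

## Immunopeptidome profiling

Filters are exactly as printed: q ≤ 0.05 (HLA class I) or q ≤ 0.01 (class
II), XCorr ≥ 1; rows without a q-value are rejected and counted. Peptide
identity is the stripped sequence (I/L distinct). Novel-ORF-exclusive means
an exact substring of ≥1 novel ORF translation and of no canonical protein,
with all source ORFs enumerated. Presentation frequency is the fraction of
replicates per condition with ≥1 passing identification, replicates with no
identifications counting as negative. Selection: *relaxed* =
novel-exclusive, zero control identifications, ≥2 treated replicates;
*strict* = the same at 100% treated-replicate frequency. Binding-prediction
columns are ingested annotations, never computed.

## Spectral validation

b/y ions from an embedded monoisotopic residue table (unit-tested against
pyteomics and Biopython); proton 1.007276 Da, water 18.010565 Da;
bᵢ = Σ(residues 1..i) + H⁺, yᵢ = Σ(last i residues) + H₂O + H⁺, multiply
charged m/z = (M + z·H⁺)/z. The aligned vector spans charges 1–2 and
excludes the precursor-like b_n/y_n ions and neutral losses. Peak matching
is greedy by ascending |Δm/z| within a 0.02 Da default tolerance (ppm
available), each peak used at most once. Each spectrum is base-peak
normalized, unmatched ions contribute 0, and R² is the squared Pearson
correlation; fewer than 3 co-matched ions reports R² = 0 with an
insufficient-evidence flag. Validation is inclusive at R² ≥ 0.70. An
optional square-root intensity transform is off by default.

## SILAC analysis

Wide matrices with columns `H_1..H_7`, `M_1..M_7`; ratios are log2 H/M where
both channels are present. Valid-value filter: ≥4 of 7 ratios. One-channel
candidates: ≥4 intensities in exactly one channel and none in the other.
Imputation draws missing values per replicate column from
Normal(0.75 × min(observed), sd(observed)), truncated at 0, on the intensity
scale as given; columns with <2 observed values refuse imputation. The
differential test is an ordinary one-sample two-sided t-test of the mean
log2 ratio against 0 with BH adjustment — a deliberate simplification of a
moderated-test + multivariate-imputation workflow; its acceptance basis is
calibration and power on synthetic data, not numeric identity with any
specific package. Zero-variance rows yield p = NA.

## Assay calls

Priming is positive at ≥0.1% peptide-specific CD8⁺ T cells and ≥3× the
negative control (a zero control is treated as an infinite fold change);
ELISpot at >10 spots/500,000 cells and ≥3× the negative-control mean.
"Three-fold higher" is read inclusively (≥3×, with a 10⁻⁹ slack against
float rounding), configurable. Cytotoxicity curves divide by the t = 0
measurement.

## Synthetic data

The generator lays each chromosome out as isolated 5 kb gene slots separated
by 3 kb spacers (wider than the 2 kb run-on distance), so planted classes
are recoverable by construction: known = exact reference copies; chimeric =
a new first exon inside the slot's TE spliced onto the reference chain
(sharing all but the first junction, hence `j`); non-chimeric = transcripts
in their own slots with no reference overlap (hence `u`), a configurable
fraction (default 0.7) initiating inside a TE. TEs are 500 bp, labelled by
subfamily from configurable weights (default 40% LTR12C).

Defaults encode the emulated study design: two conditions (vehicle control
vs combined treatment) × 3 biological replicates; counts are NB with shared
dispersion 0.05, log-normal baseline means (median 100, floored at 50 — an
assembler only reports transcripts with appreciable coverage); 20 induced
transcripts drawn preferentially from LTR12C-initiated novels with planted
log2 fold changes from N(4, 0.5) clamped below at 3, because the induced
label represents promoters switching from silent to active and must sit
clearly above the call threshold of 2 to be a recoverable truth.
t-neopeptides (default eight 9-mers) are written into the genome as
complete ORF cassettes (ATG · pad · peptide · pad · stop) in the first exon
of induced novel transcripts and are verified at generation time to survive
ORF prediction; identification tables emit them in all treated and no
control replicates, on top of background peptides drawn from a synthetic
canonical proteome with a treated-exclusive/shared/control-only emission
mix. Synthetic spectra carry the full b/y series (charges 1–2, 100 Th
low-mass cutoff) with a smooth intensity profile; concordant experimental
spectra add multiplicative log-normal noise (sd 0.10), discordant ones
permute intensities across ions, which preserves the peak count while
destroying the correlation. SILAC matrices are log-normal with planted
one-channel and differential (mean log2 ratio 2, per-replicate sd 0.3)
rows; missingness is left-censored via a rank-based drop probability.
Haplotype panels are 2 × n samples with variants at specified haplotype
fractions, carriers = round(fraction × 2n) (round half to even).

Every generator is byte-deterministic under (seed, config); sub-streams are
derived from the seed per stage.

**What the generator does not emulate** — and hence what green tests do not
show about real data: read-level sequencing (no alignment or assembly
ambiguity, no mis-assembled intron chains), overlapping gene structures and
isoform complexity beyond the planted classes, retention time, charge-state
and modification structure in MS (no chimeric spectra, no FDR estimation —
q-values are emitted, not computed), batch effects or per-replicate library
composition bias beyond global size factors, and linkage structure in the
haplotype panel. Recovery rates here are upper bounds for real pipelines,
which inherit upstream assembly and search-engine errors.

## Problem sizes

The shipped checks run at desk scale by design: oracle equivalence on 500
small random genomes (3 references × 6 queries each), TINPAT recovery over
20 seeds of 200-transcript simulations (30 induced, 5+5 replicates), a
2000-transcript null for Wald calibration, 300 random 2 kb sequences for
the ORF oracle, 200 spectrum pairs for concordance classification, and
10⁴-draw imputation moment checks. The headline counts of the emulated
study (tens of thousands of novel transcripts, thousands of TINPATs) derive
from deposited raw sequencing data and are not reproduced here; the package
checks properties, calibrations and planted-truth recovery instead.
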