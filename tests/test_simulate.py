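"""Synthetic-data generator: determinism, planting, statistical structure."""
import dataclasses

import numpy as np
import pytest

from tinpatneo.config import SimulationConfig
from tinpatneo.simulate import (
    generate_dataset,
    make_genome,
    simulate_counts,
    simulate_haplotypes,
    simulate_immunopeptidome,
    simulate_spectrum_pair,
)
from tinpatneo.spectra import theoretical_ions


class TestMakeGenome:
    def test_deterministic_under_seed(self, small_config):
        g1, t1 = make_genome(small_config)
        g2, t2 = make_genome(small_config)
        assert g1 == g2 and t1 == t2

    def test_no_te_request_yields_empty_set(self, small_config):
        cfg = dataclasses.replace(
            small_config, n_te=0, n_planted_peptides=0,
            class_mix={"known": 0.5, "chimeric": 0.0, "non_chimeric": 0.5},
            te_init_prob=0.0, n_induced=5,
        )
        genome, tes = make_genome(cfg)
        assert tes == []

    def test_pure_ltr12c_weights_label_every_interval(self, small_config):
        cfg = dataclasses.replace(
            small_config, n_te=50, te_subfamily_weights={"LTR12C": 1.0}
        )
        _, tes = make_genome(cfg)
        assert len(tes) == 50
        assert all(te.te_subfamily == "LTR12C" for te in tes)
        assert all(te.name == "LTR/ERV1/LTR12C" for te in tes)

    def test_intervals_within_chromosome_bounds(self, small_config):
        genome, tes = make_genome(small_config)
        for te in tes:
            assert 0 <= te.start < te.end <= len(genome[te.chrom])

    def test_too_small_chromosome_is_sizing_error(self):
        with pytest.raises(ValueError):
            make_genome(SimulationConfig(chrom_length=5000))


class TestAnnotations:
    def test_ground_truth_verifiable_by_independent_interval_checks(self, dataset):
        tes = dataset.te_intervals
        by_id = {t.transcript_id: t for t in dataset.denovo}
        # TE-initiated plantings: TSS base inside the named TE subfamily
        for tid, sub in dataset.truth.planted_te_initiated.items():
            t = by_id[tid]
            pos = t.tss()
            assert any(
                te.chrom == t.chrom and te.start <= pos < te.end and te.te_subfamily == sub
                for te in tes
            )
        # non-chimeric plantings: no same-strand exon overlap with any reference
        for tid, cls in dataset.truth.transcript_classes.items():
            if cls != "non_chimeric":
                continue
            t = by_id[tid]
            for r in dataset.reference:
                if r.chrom != t.chrom or r.strand != t.strand:
                    continue
                for qs, qe in t.exons:
                    for rs, re_ in r.exons:
                        assert min(qe, re_) <= max(qs, rs), (
                            f"{tid} overlaps reference {r.transcript_id}"
                        )

    def test_known_only_mix_copies_reference_structure(self, small_config):
        cfg = dataclasses.replace(
            small_config, class_mix={"known": 1.0, "chimeric": 0.0, "non_chimeric": 0.0},
            n_induced=0, n_planted_peptides=0,
        )
        ds = generate_dataset(cfg)
        ref_chains = {(r.chrom, r.strand, r.exons) for r in ds.reference}
        for t in ds.denovo:
            assert (t.chrom, t.strand, t.exons) in ref_chains

    def test_chimeric_without_references_is_config_error(self, small_config):
        cfg = dataclasses.replace(
            small_config, n_ref_transcripts=1,
            class_mix={"known": 0.0, "chimeric": 1.0, "non_chimeric": 0.0},
        )
        # 30 chimerics requested but only one reference slot
        with pytest.raises(ValueError):
            generate_dataset(cfg)


class TestCounts:
    def test_null_lfc_gives_flat_mean_ratio(self, small_config):
        cfg = dataclasses.replace(small_config, n_induced=0, n_planted_peptides=0,
                                  n_replicates_per_condition=10)
        ds = generate_dataset(cfg)
        counts, design = simulate_counts(ds.denovo, ds.truth, cfg)
        treated = counts.loc[:, design["condition"] == "treated"].mean(axis=1)
        control = counts.loc[:, design["condition"] == "control"].mean(axis=1)
        log_ratio = np.log2(treated + 0.5) - np.log2(control + 0.5)
        assert abs(log_ratio.mean()) < 0.1

    def test_poisson_limit_as_dispersion_vanishes(self, small_config):
        cfg = dataclasses.replace(small_config, nb_dispersion=0.0, n_induced=0,
                                  n_planted_peptides=0, n_replicates_per_condition=200,
                                  count_mean_sigma=0.0)
        ds = generate_dataset(cfg)
        counts, _ = simulate_counts(ds.denovo, ds.truth, cfg)
        mat = counts.to_numpy(float)
        mean, var = mat.mean(axis=1), mat.var(axis=1, ddof=1)
        assert np.allclose(var / mean, 1.0, atol=0.35)

    def test_nb_moment_oracle_for_planted_fold_change(self):
        cfg = SimulationConfig(seed=5, n_replicates_per_condition=50, lfc_mean=4.0,
                               lfc_sd=0.0, n_planted_peptides=2)
        ds = generate_dataset(cfg)
        counts, design = simulate_counts(ds.denovo, ds.truth, cfg)
        induced = sorted(ds.truth.induced_transcript_ids)
        treated = counts.loc[induced, design["condition"] == "treated"].to_numpy(float)
        control = counts.loc[induced, design["condition"] == "control"].to_numpy(float)
        ratio = treated.mean(axis=1) / control.mean(axis=1)
        # NB moments: mean ratio 2^4 = 16; 3 SE band per transcript
        mu_c = control.mean(axis=1)
        alpha, n = cfg.nb_dispersion, 50
        se = ratio * np.sqrt(
            (1 / (16 * mu_c) + alpha) / n + (1 / mu_c + alpha) / n
        )
        assert (np.abs(ratio - 16.0) < 3 * np.maximum(se, 1e-9) + 16 * 0.1).all()

    def test_counts_deterministic_under_seed(self, small_config, dataset):
        c1, _ = simulate_counts(dataset.denovo, dataset.truth, small_config)
        c2, _ = simulate_counts(dataset.denovo, dataset.truth, small_config)
        assert c1.equals(c2)


class TestImmunopeptidome:
    def _orf_dbs(self, dataset):
        from tinpatneo.orfs import predict_orfs
        from tinpatneo.simulate import make_canonical_db

        hosts = sorted(dataset.truth.induced_transcript_ids)
        by_id = {t.transcript_id: t for t in dataset.denovo}
        orfs = predict_orfs(dataset.genome, [by_id[t] for t in hosts])
        return {o.orf_id: o.aa_sequence for o in orfs}, make_canonical_db

    def test_planted_peptides_only_in_requested_replicates(self, dataset, small_config):
        from tinpatneo.simulate import make_canonical_db

        orf_db, _ = self._orf_dbs(dataset)
        canon = make_canonical_db(small_config)
        table, reps = simulate_immunopeptidome(orf_db, canon, dataset.truth, small_config)
        for pep in dataset.truth.planted_t_neopeptides:
            sub = table[table["peptide"] == pep]
            assert set(sub["condition"]) == {"treated"}
            assert set(sub["replicate_id"]) == set(reps["treated"])

    def test_zero_exclusive_emission_gives_shared_sets(self, dataset, small_config):
        from tinpatneo.simulate import GroundTruth, make_canonical_db

        cfg = dataclasses.replace(
            small_config,
            peptide_emission={"treated_exclusive": 0.0, "shared": 1.0, "control_only": 0.0},
        )
        orf_db, _ = self._orf_dbs(dataset)
        canon = make_canonical_db(cfg)
        table, _ = simulate_immunopeptidome(orf_db, canon, GroundTruth(), cfg)
        treated = set(table.loc[table["condition"] == "treated", "peptide"])
        control = set(table.loc[table["condition"] == "control", "peptide"])
        assert treated == control

    def test_unplantable_peptide_is_generation_error(self, dataset, small_config):
        from tinpatneo.simulate import GroundTruth, make_canonical_db

        truth = GroundTruth(planted_t_neopeptides={"WWWWWWWWW"})
        orf_db = {"ORF_x.p1": "AAAAAAAAAAAA"}
        with pytest.raises(ValueError):
            simulate_immunopeptidome(orf_db, make_canonical_db(small_config), truth, small_config)

    def test_replicate_frequency_follows_binomial_expectation(self, dataset, small_config):
        from tinpatneo.simulate import make_canonical_db

        orf_db, _ = self._orf_dbs(dataset)
        canon = make_canonical_db(small_config)
        table, reps = simulate_immunopeptidome(
            orf_db, canon, dataset.truth, small_config, planted_treated_reps=2
        )
        for pep in dataset.truth.planted_t_neopeptides:
            sub = table[table["peptide"] == pep]
            assert len(sub) == 2 and set(sub["condition"]) == {"treated"}


class TestSpectraAndHaplotypes:
    def test_ga_synthetic_spectrum_ion_content(self, small_config):
        exp, syn = simulate_spectrum_pair("GA", "concordant", small_config)
        expected = {
            round(i.mz, 4)
            for i in theoretical_ions("GA", max_charge=2, include_full_length=True,
                                      low_mass_cutoff=100.0)
        }
        assert {round(m, 4) for m in syn.mz} == expected
        # b2 and y2 survive the 100 Th cutoff; b1 and y1 fall below it
        series = {(i.series, i.index, i.charge)
                  for i in theoretical_ions("GA", max_charge=2, include_full_length=True,
                                            low_mass_cutoff=100.0)}
        assert ("b", 2, 1) in series and ("y", 2, 1) in series
        assert ("b", 1, 1) not in series and ("y", 1, 1) not in series

    def test_haplotype_panel_size_and_carrier_count(self):
        panel = simulate_haplotypes("ATGGCTGCT", 2504, [(3, "A", 0.1)], seed=1)
        assert len(panel) == 5008
        carriers = sum(1 for h in panel if h[3] == "A")
        assert carriers == 501  # round(0.1 * 5008)

    def test_empty_mutation_spec_copies_input(self):
        ref = "ATGGCTGCTAAA"
        assert set(simulate_haplotypes(ref, 10, [], seed=0)) == {ref}

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            simulate_haplotypes("ATG", 5, [(0, "A", 1.5)], seed=0)


class TestEndToEndDeterminism:
    def test_dataset_regeneration_is_identical(self, small_config, dataset):
        ds2 = generate_dataset(small_config)
        assert ds2.genome == dataset.genome
        assert ds2.truth.planted_t_neopeptides == dataset.truth.planted_t_neopeptides
        assert [t.exons for t in ds2.denovo] == [t.exons for t in dataset.denovo]
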