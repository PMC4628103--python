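"""Generator tests: planted sequence structure, sampling model, determinism."""

import numpy as np
import pytest

from cenrepeat.simulate import (RepeatFamilySpec, assemble_genome,
                                build_line_master, generate_dispersed_family,
                                generate_tandem_array, revcomp,
                                simulate_fractions, simulate_qpcr)
from cenrepeat.characterize import compute_at_content, find_orfs

from conftest import small_specs


class TestTandemArray:
    def test_array_length_and_composition(self):
        cons, arr = generate_tandem_array(187, 200, 0.583, 0.02, seed=1)
        assert len(arr) == 37_400
        assert len(cons) == 187
        assert abs(compute_at_content(cons) - 0.583) <= 0.02

    def test_single_undiverged_copy_is_consensus(self):
        cons, arr = generate_tandem_array(50, 1, 0.5, 0.0, seed=2)
        assert arr == cons

    def test_explicit_consensus_tiling(self):
        cons, arr = generate_tandem_array(4, 3, consensus="ACGT", seed=0)
        assert arr == "ACGTACGTACGT"

    @pytest.mark.parametrize("bad_at", [-0.1, 1.5])
    def test_at_fraction_out_of_range(self, bad_at):
        with pytest.raises(ValueError):
            generate_tandem_array(100, 10, bad_at, 0.0, seed=0)

    def test_divergence_scatters_copies(self):
        cons, arr = generate_tandem_array(100, 20, 0.5, 0.05, seed=3)
        diffs = [sum(1 for a, b in zip(cons, arr[i * 100:(i + 1) * 100]) if a != b)
                 for i in range(20)]
        assert 1 <= np.mean(diffs) <= 10  # ~5 per copy expected


class TestDispersedFamily:
    def line_spec(self):
        return RepeatFamilySpec("L", "line_like", 2100, 5, divergence=0.4,
                                orf_length_nt=429, enrichment_factor=1.0)

    def test_master_contains_requested_orf(self):
        master = build_line_master(self.line_spec(), np.random.default_rng(1))
        orfs = find_orfs(master, min_aa=140)
        assert any(o.aa_length == 143 and o.end - o.start == 429 for o in orfs)

    def test_zero_subcopies(self):
        assert generate_dispersed_family(self.line_spec(), 0, 0.4, seed=1) == []

    def test_ltr_terminal_repeats_identical(self):
        spec = RepeatFamilySpec("T", "ltr", 1200, 3, ltr_length_bp=150)
        for div in (0.0, 0.05):
            for copy in generate_dispersed_family(spec, 3, div, seed=2):
                assert copy[:150] == copy[-150:]

    @pytest.mark.parametrize("target", [0.1, 0.4])
    def test_mean_pairwise_identity(self, target):
        spec = RepeatFamilySpec("L", "line_like", 1500, 8, divergence=target,
                                orf_length_nt=429)
        copies = generate_dispersed_family(spec, 8, target, seed=5)
        idents = []
        for i in range(len(copies)):
            for j in range(i + 1, len(copies)):
                same = sum(1 for a, b in zip(copies[i], copies[j]) if a == b)
                idents.append(same / len(copies[i]))
        assert abs(np.mean(idents) - (1 - target)) <= 0.05

    def test_orf_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            RepeatFamilySpec("L", "line_like", 2100, 5, orf_length_nt=428)


class TestAssembleGenome:
    def test_empty_specs_pure_background(self):
        fx = assemble_genome([], 10_000, seed=1)
        assert fx.total_length == 10_000
        assert fx.features == []

    def test_single_tandem_single_feature(self):
        spec = RepeatFamilySpec("S", "tandem", 100, 30, divergence=0.01)
        fx = assemble_genome([spec], 20_000, seed=2)
        assert len(fx.features) == 1
        f = fx.features[0]
        assert f.end - f.start == 3000

    def test_default_fixture_feature_recount(self, small_fixture):
        # independent recount: one feature per array family, one per dispersed copy
        expected = {}
        for spec in small_fixture.specs:
            expected[spec.family_id] = 1 if spec.arrangement == "array" else spec.copy_number
        observed = {}
        for f in small_fixture.features:
            observed[f.family_id] = observed.get(f.family_id, 0) + 1
        assert observed == expected

    def test_features_within_bounds_and_disjoint(self, small_fixture):
        feats = sorted(small_fixture.features, key=lambda f: f.start)
        for f in feats:
            assert 0 <= f.start < f.end <= small_fixture.total_length
        for a, b in zip(feats, feats[1:]):
            assert a.end <= b.start

    def test_ltr_feature_roundtrip(self):
        spec = RepeatFamilySpec("T", "ltr", 1200, 4, divergence=0.02, ltr_length_bp=150)
        fx = assemble_genome([spec], 40_000, seed=3)
        genome = fx.sequences["chr1"]
        for f in fx.features:
            seq = genome[f.start:f.end]
            if f.strand == "-":
                seq = revcomp(seq)
            # within a copy the two terminal repeats are identical by construction
            assert seq[:150] == seq[-150:]

    def test_regeneration_is_byte_identical(self):
        specs = small_specs()
        a = assemble_genome(specs, 60_000, seed=7)
        b = assemble_genome(small_specs(), 60_000, seed=7)
        assert a.sequences == b.sequences
        assert [(f.start, f.end, f.family_id) for f in a.features] == \
               [(f.start, f.end, f.family_id) for f in b.features]

    def test_overflow_raises(self):
        spec = RepeatFamilySpec("S", "tandem", 1000, 50)
        with pytest.raises(ValueError):
            assemble_genome([spec], 20_000, seed=1)


class TestSimulateFractions:
    def test_read_length_and_determinism(self, small_fixture):
        inp, chip = simulate_fractions(small_fixture, 0.5, 0.5, seed=9)
        for pr in inp.reads[:50] + chip.reads[:50]:
            assert len(pr.seq1) == 300 and len(pr.seq2) == 300
        inp2, chip2 = simulate_fractions(small_fixture, 0.5, 0.5, seed=9)
        assert [r.seq1 for r in inp.reads] == [r.seq1 for r in inp2.reads]
        assert [r.seq2 for r in chip.reads] == [r.seq2 for r in chip2.reads]

    def test_reads_derive_from_genome(self, small_fixture):
        inp, _ = simulate_fractions(small_fixture, 0.2, 0.2, seed=10, error_rate=0.0)
        genome = small_fixture.sequences["chr1"]
        for pr in inp.reads[:25]:
            assert pr.seq1 in genome or revcomp(pr.seq1) in genome
            assert pr.seq2 in genome or revcomp(pr.seq2) in genome

    def test_null_model_equal_proportions(self):
        specs = [RepeatFamilySpec("S", "tandem", 187, 60, divergence=0.02,
                                  enrichment_factor=1.0)]
        fx = assemble_genome(specs, 50_000, seed=4)
        inp, chip = simulate_fractions(fx, 2.0, 2.0, seed=5)
        phi = 187 * 60 / 50_000
        for lib in (inp, chip):
            k = sum(1 for r in lib.reads if r.true_family_id == "S")
            n = len(lib.reads)
            sd = (n * phi * (1 - phi)) ** 0.5
            assert abs(k - n * phi) <= 3 * sd

    def test_enrichment_binomial_oracle(self):
        factor = 8.0
        specs = [RepeatFamilySpec("S", "tandem", 187, 60, divergence=0.02,
                                  enrichment_factor=factor)]
        fx = assemble_genome(specs, 50_000, seed=4)
        inp, chip = simulate_fractions(fx, 2.0, 2.0, seed=6)
        k_in = sum(1 for r in inp.reads if r.true_family_id == "S")
        k_ch = sum(1 for r in chip.reads if r.true_family_id == "S")
        ratio = k_ch / k_in
        # binomial error propagation on the count ratio
        sd = ratio * (1 / k_in + 1 / k_ch) ** 0.5
        assert abs(ratio - factor) <= 3 * sd

    def test_enrichment_calibration_over_seeds(self):
        factor = 8.0
        specs = [RepeatFamilySpec("S", "tandem", 187, 60, divergence=0.02,
                                  enrichment_factor=factor)]
        fx = assemble_genome(specs, 50_000, seed=4)
        ratios = []
        for seed in range(10):
            inp, chip = simulate_fractions(fx, 2.0, 2.0, seed=100 + seed)
            k_in = sum(1 for r in inp.reads if r.true_family_id == "S")
            k_ch = sum(1 for r in chip.reads if r.true_family_id == "S")
            ratios.append(k_ch / k_in)
        assert abs(np.mean(ratios) - factor) / factor <= 0.05

    def test_bad_parameters(self, small_fixture):
        with pytest.raises(ValueError):
            simulate_fractions(small_fixture, 0.0, 1.0, seed=1)
        with pytest.raises(ValueError):
            simulate_fractions(small_fixture, 1.0, 1.0, read_length_bp=900,
                               insert_mean=700, seed=1)


class TestSimulateQPCR:
    def test_equal_amounts_no_noise(self):
        plate = simulate_qpcr(5.0, 5.0, efficiency=1.0, ct_noise_sd=0.0,
                              n_replicates=4, seed=1)
        t = plate.table
        ab = t[t.fraction == "antibody"].ct.to_numpy()
        mock = t[t.fraction == "mock"].ct.to_numpy()
        assert np.allclose(ab, mock)

    def test_ratio_32_gives_ct_gap_5(self):
        plate = simulate_qpcr(32.0, 1.0, efficiency=1.0, ct_noise_sd=0.0,
                              n_replicates=3, seed=1)
        t = plate.table
        gap = t[t.fraction == "mock"].ct.mean() - t[t.fraction == "antibody"].ct.mean()
        assert gap == pytest.approx(5.0)

    def test_four_replicates_eight_rows(self):
        plate = simulate_qpcr(10.0, 1.0, n_replicates=4, seed=1)
        assert len(plate.table) == 8

    def test_bad_amounts(self):
        with pytest.raises(ValueError):
            simulate_qpcr(0.0, 1.0, seed=1)
        with pytest.raises(ValueError):
            simulate_qpcr(1.0, 1.0, efficiency=1.5, seed=1)
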