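"""Generator: reference building, library design, selection, and reads."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from tlscan.synthetic_data import (
    GOF_SPIKE_IDS,
    LOF_SPIKE_IDS,
    WT_ID,
    ClassProfileConfig,
    assign_true_effects,
    design_library,
    make_library,
    make_reference,
    simulate_reads,
    simulate_screen,
    simulate_selection,
    write_fastq,
)


class TestMakeReference:
    def test_default_is_31_codons_spanning_1076_1106(self):
        ref = make_reference()
        assert ref.n_codons == 31
        assert ref.residue_numbers[0] == 1076
        assert ref.residue_numbers[-1] == 1106

    def test_single_codon_reference(self):
        ref = make_reference(amino_acids="M", first_residue_number=1)
        assert ref.n_codons == 1
        assert ref.protein == "M"

    def test_translation_matches_independent_codon_table(self):
        ref = make_reference(amino_acids="MKVLHGA", first_residue_number=7)
        assert ref.protein == str(Seq(ref.coding_sequence).translate()) == "MKVLHGA"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"coding_sequence": "ATGXAA"},
            {"coding_sequence": "ATGA"},
            {"coding_sequence": "ATGTAAGGG"},  # internal stop
            {"coding_sequence": "ATG", "upstream_flank": ""},
        ],
    )
    def test_invalid_references_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_reference(**kwargs)

    def test_residue_codon_index_round_trip(self, ref):
        for ci in (1, 10, 31):
            assert ref.codon_index_of(ref.residue_of(ci)) == ci


class TestLibraryDesign:
    def test_programmed_codons_differ_from_wt(self, ref, evs):
        for ci, codon in evs.programmed:
            assert codon != ref.wt_codon(ci)

    def test_excluded_variants_not_programmed(self, ref, evs):
        programmed_aa = {
            (ref.residue_of(ci), evs.variant_id(ci, c)[-1])
            for ci, c in evs.programmed
        }
        assert not programmed_aa & set(evs.excluded)

    def test_five_spike_ins(self, evs):
        assert set(evs.spike_ids) == set(LOF_SPIKE_IDS) | set(GOF_SPIKE_IDS)

    def test_uniform_library_partitions_mass_evenly(self, evs):
        lib = make_library(evs, wt_fraction=0.2)
        spike = [v for v in lib.index if v in evs.spike_ids]
        prog = lib.drop(spike)
        expected = (1 - 0.2 - 5 * 0.005) / len(prog)
        assert np.allclose(prog, expected)
        assert np.isclose(lib.sum(), 0.8)

    def test_excluded_unspiked_variant_has_no_pool_fraction(self, evs):
        lib = make_library(evs)
        # H1085Y is excluded from synthesis; it appears only as spike-in
        assert lib["H1085Y"] == pytest.approx(0.005)
        # an excluded variant never programmed nor spiked is simply absent
        evs2 = design_library(evs.reference, spike_ins=())
        lib2 = make_library(evs2)
        assert "H1085Y" not in lib2.index

    def test_dirichlet_fractions_sum_to_mass(self, evs):
        lib = make_library(evs, wt_fraction=0.15, mode="dirichlet", seed=7)
        assert abs(lib.sum() - 0.85) < 1e-12

    def test_unknown_mode_and_bad_wt_fraction_raise(self, evs):
        with pytest.raises(ValueError):
            make_library(evs, mode="zipf")
        with pytest.raises(ValueError):
            make_library(evs, wt_fraction=1.5)


class TestSimulateSelection:
    @pytest.fixture()
    def fractions(self, evs):
        return make_library(evs, wt_fraction=0.5)

    def test_neutral_selection_preserves_frequencies(self, fractions, rng):
        effects = pd.Series(0.0, index=fractions.index)
        depth = 2_000_000
        counts = simulate_selection(fractions, effects, depth, rng)
        sub = fractions.iloc[:50]
        obs = counts[sub.index] / depth
        se = np.sqrt(sub * (1 - sub) / depth)
        assert (np.abs(obs - sub) < 4 * se).mean() > 0.95

    def test_plus_one_effect_doubles_ratio_to_wt(self, fractions, rng):
        effects = pd.Series(0.0, index=fractions.index)
        v = fractions.index[0]
        effects[v] = 1.0
        depth = 10_000_000
        counts = simulate_selection(fractions, effects, depth, rng)
        unsel = simulate_selection(fractions, None, depth, rng)
        ratio = (counts[v] / counts[WT_ID]) / (unsel[v] / unsel[WT_ID])
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_counts_conserve_depth(self, fractions, rng):
        counts = simulate_selection(fractions, None, 12345, rng)
        assert counts.sum() == 12345
        assert (counts >= 0).all()

    def test_effect_monotonicity_in_expectation(self, fractions):
        # closed-form expected frequency is monotone in the effect
        v = fractions.index[3]
        freqs = []
        for e in (-2.0, 0.0, 2.0):
            eff = pd.Series(0.0, index=fractions.index)
            eff[v] = e
            w = fractions * np.exp2(eff)
            wt = 1 - fractions.sum()
            freqs.append(w[v] / (w.sum() + wt))
        assert freqs[0] < freqs[1] < freqs[2]

    def test_nonpositive_depth_rejected(self, fractions):
        with pytest.raises(ValueError):
            simulate_selection(fractions, None, 0)


class TestSimulateReads:
    def test_noiseless_reads_reconstruct_sources(self, ref, evs):
        lib = make_library(evs)
        counts = simulate_selection(lib, None, 2000, 5)
        reads = simulate_reads(counts, ref, evs, error_rate=0.0,
                               template_switch_rate=0.0)
        molecules = evs.molecules()
        expected = {}
        for vid, k in counts.items():
            if k == 0:
                continue
            codons = list(ref.codons)
            if vid != WT_ID:
                ci, codon = molecules[vid]
                codons[ci - 1] = codon
            amp = ref.upstream_flank + "".join(codons) + ref.downstream_flank
            expected[amp] = expected.get(amp, 0) + int(k)
        assert dict(reads) == expected

    def test_read_counts_conserved_under_noise(self, ref, evs):
        lib = make_library(evs)
        counts = simulate_selection(lib, None, 5000, 5)
        reads = simulate_reads(counts, ref, evs, error_rate=0.01,
                               template_switch_rate=0.05, seed=5)
        assert sum(reads.values()) == 5000

    def test_identical_seeds_give_byte_identical_fastq(self, ref, evs, tmp_path):
        lib = make_library(evs)
        counts = simulate_selection(lib, None, 3000, 11)
        files = []
        for run in ("a", "b"):
            rs = simulate_reads(counts, ref, evs, error_rate=0.005,
                                template_switch_rate=0.02, seed=99)
            f1, f2 = tmp_path / f"{run}_1.fq", tmp_path / f"{run}_2.fq"
            write_fastq(rs, f1, f2)
            files.append((f1.read_bytes(), f2.read_bytes()))
        assert files[0] == files[1]

    def test_switch_rate_zero_produces_no_doubles(self, ref, evs):
        lib = make_library(evs)
        counts = simulate_selection(lib, None, 20000, 3)
        reads = simulate_reads(counts, ref, evs, error_rate=0.0,
                               template_switch_rate=0.0, seed=3)
        wt_core = ref.coding_sequence
        for amp in reads:
            core = amp[len(ref.upstream_flank):-len(ref.downstream_flank)]
            diff = sum(
                core[3 * i : 3 * i + 3] != wt_core[3 * i : 3 * i + 3]
                for i in range(ref.n_codons)
            )
            assert diff <= 1

    def test_double_fraction_matches_closed_form(self, ref):
        # two spike-ins at distinct positions dominate a tiny pool
        evs2 = design_library(ref, spike_fraction=0.1)
        counts = pd.Series([600_000, 200_000, 200_000],
                           index=[WT_ID, "H1085Y", "G1097D"])
        p = 0.05
        reads = simulate_reads(counts, ref, evs2, error_rate=0.0,
                               template_switch_rate=p, pcr_mode="regular",
                               seed=17)
        core_y = ref.coding_sequence
        mol = evs2.molecules()
        def core_of(*vids):
            codons = list(ref.codons)
            for v in vids:
                ci, c = mol[v]
                codons[ci - 1] = c
            return ref.upstream_flank + "".join(codons) + ref.downstream_flank
        n_double = reads.get(core_of("H1085Y", "G1097D"), 0)
        total = sum(reads.values())
        # expected double fraction = p * 2 * f1 * f2 with f = 0.2 each
        expect = p * 2 * 0.2 * 0.2
        assert n_double / total == pytest.approx(expect, rel=0.15)

    def test_emulsion_suppresses_switching(self, ref, evs):
        lib = make_library(evs, wt_fraction=0.3)
        counts = (lib * 1_000_000).round().astype(int)
        counts[WT_ID] = 1_000_000 - counts.sum()
        kw = dict(error_rate=0.0, template_switch_rate=0.1, seed=4)
        def n_doubles(mode):
            reads = simulate_reads(counts, ref, evs, pcr_mode=mode, **kw)
            up = len(ref.upstream_flank)
            n = 0
            for amp, k in reads.items():
                core = amp[up : up + len(ref.coding_sequence)]
                diffs = sum(
                    core[3 * i : 3 * i + 3] != ref.coding_sequence[3 * i : 3 * i + 3]
                    for i in range(ref.n_codons)
                )
                if diffs == 2:
                    n += k
            return n
        ratio = n_doubles("regular") / n_doubles("emulsion")
        assert ratio == pytest.approx(2.5, rel=0.2)

    def test_invalid_rates_rejected(self, ref, evs):
        counts = pd.Series([10], index=[WT_ID])
        with pytest.raises(ValueError):
            simulate_reads(counts, ref, evs, error_rate=1.5)
        with pytest.raises(ValueError):
            simulate_reads(counts, ref, evs, template_switch_rate=-0.1)


class TestClassProfiles:
    def test_default_config_is_14_conditions_summing_proportions(self):
        cfg = ClassProfileConfig()
        assert len(cfg.conditions) == 14
        assert sum(cfg.class_proportions.values()) == pytest.approx(1.0)

    def test_spike_ins_anchor_their_classes(self, rng):
        cfg = ClassProfileConfig(seed=3)
        ids = list(LOF_SPIKE_IDS + GOF_SPIKE_IDS) + [f"A{i}G" for i in range(50)]
        effects, labels = assign_true_effects(ids, cfg)
        assert set(labels[list(LOF_SPIKE_IDS)]) == {"Class 1"}
        assert set(labels[list(GOF_SPIKE_IDS)]) == {"Class 3"}
        assert effects.shape == (len(ids), 14)

    def test_class_means_recovered_at_low_noise(self):
        cfg = ClassProfileConfig(noise_sd=0.01, seed=0)
        ids = [f"A{i}G" for i in range(300)]
        effects, labels = assign_true_effects(ids, cfg)
        for cls in ("Class 1", "Class 3"):
            got = effects[labels == cls].mean()
            want = cfg.class_effects.loc[cls, list(cfg.conditions)]
            assert np.allclose(got, want, atol=0.05)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            ClassProfileConfig(class_proportions={"Class 1": 0.4, "neutral": 0.4})


class TestSimulateScreen:
    def test_screen_shapes_and_determinism(self):
        a = simulate_screen(n_variants=30, depth=2000, n_replicates=2, seed=8)
        b = simulate_screen(n_variants=30, depth=2000, n_replicates=2, seed=8)
        assert len(a.pool_fractions) == 35  # 30 + 5 spike-ins
        assert a.counts.shape[1] == 2 * (1 + 14)
        assert a.counts.equals(b.counts)
        assert a.readsets == b.readsets
        assert (a.counts.sum(axis=0) == 2000).all()

    def test_frequency_recovery_at_depth(self, rng):
        sim = simulate_screen(n_variants=100, depth=1_000_000, n_replicates=1,
                              make_reads=False, seed=2)
        pool = sim.counts["SC-Leu_rep1"]
        obs = pool / pool.sum()
        f = sim.pool_fractions
        se = np.sqrt(f * (1 - f) / pool.sum())
        ok = (np.abs(obs[f.index] - f) <= 3 * se)
        assert ok.mean() >= 0.99
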