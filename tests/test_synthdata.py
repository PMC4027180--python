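"""Synthetic-data generators: determinism, validation, noise behavior."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest

from wingbind import motifs, synthdata
from wingbind.synthdata import SynthSpec


class TestSpecValidation:
    def test_defaults_are_valid(self):
        SynthSpec()

    def test_overlapping_topology_rejected(self):
        with pytest.raises(ValueError, match="topology"):
            SynthSpec(topology=(("H", 5, 15), ("E", 10, 20)))

    def test_topology_outside_chain_rejected(self):
        with pytest.raises(ValueError, match="topology"):
            SynthSpec(n_residues=30, topology=(("H", 25, 40),))

    def test_bad_topology_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            SynthSpec(topology=(("X", 5, 10),))

    def test_interface_outside_chain_rejected(self):
        with pytest.raises(ValueError, match="interface"):
            SynthSpec(n_residues=30, topology=(("H", 5, 20),),
                      interface_residues=frozenset({40}))

    @pytest.mark.parametrize("field_name", ["tau_c_ns", "kd1_m", "hill_n",
                                            "stoichiometry_break"])
    def test_nonpositive_parameters_rejected(self, field_name):
        with pytest.raises(ValueError, match="positive"):
            SynthSpec(**{field_name: 0.0})

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise"):
            SynthSpec(noise={**synthdata.DEFAULT_NOISE, "itc": -0.1})

    def test_noiseless_zeroes_every_level(self, spec):
        assert all(v == 0.0 for v in spec.noiseless().noise.values())


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a, b = SynthSpec(seed=11), SynthSpec(seed=11)
        pd.testing.assert_frame_equal(synthdata.gen_shift_table(a),
                                      synthdata.gen_shift_table(b))
        assert np.array_equal(synthdata.gen_itc_thermogram(a).heats_cal,
                              synthdata.gen_itc_thermogram(b).heats_cal)
        assert synthdata.gen_sequence(a) == synthdata.gen_sequence(b)

    def test_different_seeds_differ(self):
        a = synthdata.gen_shift_table(SynthSpec(seed=1))
        b = synthdata.gen_shift_table(SynthSpec(seed=2))
        assert not np.allclose(a["ca"], b["ca"])

    def test_streams_independent_of_call_order(self):
        spec = SynthSpec(seed=5)
        first = synthdata.gen_titration_curve(spec)
        synthdata.gen_emsa_curve(spec)          # interleaved call
        second = synthdata.gen_titration_curve(spec)
        pd.testing.assert_frame_equal(first, second)


class TestSequence:
    def test_length_and_alphabet(self, spec):
        seq = synthdata.gen_sequence(spec)
        assert len(seq) == spec.n_residues
        assert "P" not in seq       # every residue must carry an amide peak

    def test_labels_match_topology(self, spec):
        labels = synthdata.residue_labels(spec)
        assert labels[7] == "H" and labels[20] == "E" and labels[5] == "C"
        assert len(labels) == spec.n_residues


class TestNoiseMonotonicity:
    @pytest.mark.parametrize("gen,key,col", [
        (synthdata.gen_titration_curve, "titration", "signal"),
        (synthdata.gen_emsa_curve, "emsa", "fraction_bound"),
    ])
    def test_rms_deviation_grows_with_noise(self, gen, key, col):
        levels = (0.005, 0.02, 0.08)
        means = []
        for level in levels:
            devs = []
            for seed in range(20):
                clean = gen(SynthSpec(seed=seed).noiseless())[col]
                noisy = gen(SynthSpec(
                    seed=seed,
                    noise={**synthdata.DEFAULT_NOISE, key: level}))[col]
                devs.append(float(np.sqrt(np.mean((noisy - clean) ** 2))))
            means.append(np.mean(devs))
        assert means[0] < means[1] < means[2]

    def test_zero_noise_is_exactly_clean(self, spec0):
        df = synthdata.gen_titration_curve(spec0)
        x0 = spec0.stoichiometry_break
        expect = df["ratio"] - 0.9 * np.maximum(df["ratio"] - x0, 0.0)
        assert df["signal"].to_numpy() == pytest.approx(expect.to_numpy(),
                                                        abs=1e-12)


class TestRelaxationGenerator:
    def test_degenerate_delays_rejected(self, spec):
        with pytest.raises(ValueError, match="degenerate"):
            synthdata.gen_relaxation_series(spec, r1_delays=(0.1,) * 8)

    def test_flexible_residues_decay_slower_in_r2(self, spec0):
        _, r2 = synthdata.gen_relaxation_series(spec0)
        data = r2.data
        last = data["delay_s"].max()

        def endpoint(res):
            sub = data[(data["residue"] == res) & (data["delay_s"] == last)]
            return float(sub["intensity"].iloc[0])

        # flexible tail residues keep far more signal at the last delay
        assert endpoint(1) > 2 * endpoint(40)


class TestItcGenerator:
    def test_too_few_injections_rejected(self, spec):
        with pytest.raises(ValueError, match="10 injections"):
            synthdata.gen_itc_thermogram(spec, n_injections=8)

    def test_biphasic_profile(self, spec0):
        tg = synthdata.gen_itc_thermogram(spec0)
        assert tg.heats_cal[0] > 0 and tg.heats_cal[-1] < 0


class TestPromoter:
    def test_planted_operators_are_the_only_paired_sites(self, spec):
        seq, planted = synthdata.gen_promoter(spec)
        pairs = motifs.find_paired_sites(seq)
        assert len(pairs) == 2
        spans = sorted((p.first.start, p.second.end) for p in pairs)
        expect = sorted(tuple(v["index_span"]) for v in planted.values())
        assert spans == expect

    def test_tss_spans_match_coordinates(self, spec):
        seq, planted = synthdata.gen_promoter(spec)
        for site in planted.values():
            lo, hi = site["tss_span"]
            assert motifs.tss_span_length(lo, hi) == 15
            start, end = site["index_span"]
            assert seq.tss_position(start) == lo
            assert seq.tss_position(end) == hi

    def test_site_free_background_has_no_boxes(self, spec):
        seq, planted = synthdata.gen_promoter(spec, with_sites=False)
        assert planted == {}
        assert motifs.scan_motif(seq) == []

    def test_site_a_retains_direct_repeat_context(self, spec):
        seq, planted = synthdata.gen_promoter(spec)
        start, end = planted["site_a"]["index_span"]
        window = seq.bases[start - 1 - 4:end + 1]   # AGTA flank + core + T
        res = motifs.direct_repeat_check(
            motifs.DnaSequence("siteA", window))
        assert res.is_repeat and res.mismatches <= 2


class TestBundle:
    def test_bundle_files_and_truth_sidecar(self, tmp_path, spec):
        truth = synthdata.write_bundle(spec, tmp_path)
        expected = [
            "shifts.csv", "shifts.str", "hsqc_free.csv", "hsqc_bound.csv",
            "relax_r1.csv", "relax_r2.csv", "itc.csv", "itc_design.json",
            "titration.csv", "melt_free.csv", "melt_bound.csv", "emsa.csv",
            "emission_free.csv", "emission_bound.csv", "promoter.fasta",
            "ground_truth.json",
        ]
        for name in expected:
            assert (tmp_path / name).exists(), name
        reread = json.loads((tmp_path / "ground_truth.json").read_text())
        assert reread["tau_c_ns"] == truth["tau_c_ns"] == spec.tau_c_ns
        assert reread["hill_n"] == spec.hill_n
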