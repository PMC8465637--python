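"""Generators: construction identities, determinism, forward-model fidelity."""

import numpy as np
import pytest

from parabind import binding, motifs, synthetic, thermal
from parabind.synthetic import (
    PromoterArchitecture,
    PromoterElement,
    build_promoter_sequence,
    simulate_isotherm,
    simulate_melt_curve,
    simulate_sensorgrams,
    simulate_trajectory,
)


class TestPromoterBuilder:
    def test_f_truth_table_composition(self, f_promoter):
        _, seq, truth = f_promoter
        assert len(seq) == 136
        exact_plus = truth[(truth.mismatches == 0) & (truth.strand == "+")]
        exact_minus = truth[(truth.mismatches == 0) & (truth.strand == "-")]
        two_mm_minus = truth[(truth.mismatches == 2) & (truth.strand == "-")]
        assert len(exact_plus) == 3
        assert len(exact_minus) == 1
        assert len(two_mm_minus) == 1

    def test_truth_table_self_consistent(self, f_promoter):
        """Rescanning the built sequence finds every truth motif in place."""
        arch, seq, truth = f_promoter
        hits = {
            (h.start, h.strand, h.observed)
            for h in motifs.scan_motifs(seq, arch.consensus, 2)
        }
        for row in truth.itertuples():
            assert (row.start, row.strand, row.sequence) in hits

    def test_exact_hits_match_truth_for_many_seeds(self):
        arch = synthetic.default_f_architecture()
        for seed in range(8):
            seq, truth = build_promoter_sequence(arch, seed)
            exact = {
                (h.start, h.strand)
                for h in motifs.scan_motifs(seq, arch.consensus, 0)
            }
            expected = {
                (int(r.start), r.strand)
                for r in truth.itertuples()
                if r.mismatches == 0
            }
            assert exact == expected

    def test_single_element_no_background(self):
        arch = PromoterArchitecture(
            elements=(PromoterElement("CTTTGC", "+", 0),),
            flank_left=0,
            flank_right=0,
            background_at_fraction=1.0,
        )
        seq, truth = build_promoter_sequence(arch, seed=0)
        assert seq == "CTTTGC"
        assert truth.iloc[0].start == 0

    def test_gap_construction_identity(self):
        arch = PromoterArchitecture(
            elements=(
                PromoterElement("CTTTGC", "+", 0),
                PromoterElement("CTTTGC", "+", 13),
            ),
            flank_left=5,
            flank_right=5,
        )
        _, truth = build_promoter_sequence(arch, seed=0)
        s1, s2 = truth.start.tolist()
        assert s2 - (s1 + 6) == 13

    def test_minus_strand_embedded_as_revcomp(self):
        arch = PromoterArchitecture(
            elements=(PromoterElement("CTTTGC", "-", 0),),
            flank_left=0,
            flank_right=0,
        )
        seq, _ = build_promoter_sequence(arch, seed=0)
        assert seq == "GCAAAG"

    def test_overlapping_elements_error_names_pair(self):
        arch = PromoterArchitecture(
            elements=(
                PromoterElement("CTTTGC", "+", 0, name="a"),
                PromoterElement("CTTTGC", "+", 0, name="b"),
            )
        )
        # zero gap is allowed (adjacent); force a collision via the layout
        bad = PromoterArchitecture(
            elements=(
                PromoterElement("CTTTGC", "+", 0, name="a"),
                PromoterElement("CTTTGC", "-", 0, name="b"),
            ),
            flank_left=0,
            flank_right=0,
        )
        assert build_promoter_sequence(bad, 0)[0]  # adjacency is legal
        with pytest.raises(ValueError, match="gaps must be >= 0"):
            PromoterArchitecture(
                elements=(
                    PromoterElement("CTTTGC", "+", 0, name="a"),
                    PromoterElement("CTTTGC", "+", -3, name="b"),
                )
            )

    def test_validation(self):
        with pytest.raises(ValueError):
            PromoterArchitecture(
                elements=(PromoterElement("CTTTG", "+", 0),)
            )
        with pytest.raises(ValueError):
            PromoterArchitecture(elements=(), background_at_fraction=1.2)

    def test_determinism(self):
        arch = synthetic.default_f_architecture()
        s1, _ = build_promoter_sequence(arch, seed=5)
        s2, _ = build_promoter_sequence(arch, seed=5)
        assert s1 == s2

    def test_at_fraction_realized(self):
        arch = synthetic.default_f_architecture()
        seq, truth = build_promoter_sequence(arch, seed=9)
        embedded = set()
        for r in truth.itertuples():
            embedded.update(range(r.start, r.start + 6))
        bg = [seq[i] for i in range(len(seq)) if i not in embedded]
        at = sum(1 for b in bg if b in "AT") / len(bg)
        assert at == pytest.approx(0.73, abs=0.12)


class TestSprGenerator:
    def test_rmax_truth_value(self):
        scen = synthetic.default_spr_scenario()
        assert synthetic.spr_rmax_true(scen) == pytest.approx(882.35, abs=0.01)

    def test_noiseless_plateau_at_high_conc(self):
        scen = synthetic.default_spr_scenario(noise_sd=0.0)
        curves = simulate_sensorgrams(scen)
        top = curves[-1]  # highest concentration
        req = 882.3529 * scen.ka_true * top.conc / (scen.ka_true * top.conc + scen.kd_true)
        end_assoc = top.response[top.times <= scen.t_assoc][-1]
        assert end_assoc == pytest.approx(req, rel=1e-3)
        assert req / 882.3529 > 0.97  # saturation regime

    def test_zero_dimers_flat(self):
        scen = synthetic.default_spr_scenario(true_dimers_bound=0, noise_sd=0.0)
        assert all(np.all(sg.response == 0) for sg in simulate_sensorgrams(scen))

    def test_determinism(self):
        scen = synthetic.default_spr_scenario(seed=3)
        a = simulate_sensorgrams(scen)
        b = simulate_sensorgrams(scen)
        assert all(np.array_equal(x.response, y.response) for x, y in zip(a, b))

    def test_invalid_scenarios(self):
        with pytest.raises(ValueError):
            synthetic.default_spr_scenario(t_assoc=-1.0)
        with pytest.raises(ValueError):
            synthetic.default_spr_scenario(concentrations=(1e-6, 1e-7))


class TestIsothermGenerator:
    def test_hill_midpoint(self):
        scen = synthetic.default_emsa_scenario(
            noise_sd=0.0, protein_concs=(85.0,), kd_true=85.0
        )
        iso = simulate_isotherm(scen)
        assert iso.fraction_bound[0] == pytest.approx(0.5)

    def test_depletion_value(self):
        scen = synthetic.default_parb_emsa_scenario(
            noise_sd=0.0, protein_concs=(25.0,), kd_true=10.0, probe_conc=15.0
        )
        iso = simulate_isotherm(scen)
        assert iso.fraction_bound[0] == pytest.approx(0.61257, abs=1e-4)

    def test_noiseless_matches_forward_model(self):
        scen = synthetic.default_emsa_scenario(noise_sd=0.0)
        iso = simulate_isotherm(scen)
        expected = binding.hill_model(iso.conc_nM, scen.kd_true, scen.hill_h_true)
        assert np.allclose(iso.fraction_bound, expected)

    def test_noise_clipped_and_deterministic(self):
        scen = synthetic.default_emsa_scenario(seed=7, noise_sd=0.3)
        a = simulate_isotherm(scen)
        b = simulate_isotherm(scen)
        assert np.array_equal(a.fraction_bound, b.fraction_bound)
        assert np.all((a.fraction_bound >= 0) & (a.fraction_bound <= 1))

    def test_unknown_model_kind(self):
        with pytest.raises(ValueError):
            synthetic.TitrationScenario(model_kind="linear")


class TestMeltGenerator:
    def test_midpoint_ratio(self):
        scen = synthetic.default_melt_scenario("apo", noise_sd=0.0)
        curve = simulate_melt_curve(scen)
        i = np.argmin(np.abs(curve.temperatures - scen.tm_true))
        b = scen.baselines
        expected = 0.5 * (b.folded(44.5) + b.unfolded(44.5))
        assert curve.ratio()[i] == pytest.approx(expected, rel=1e-4)

    def test_large_enthalpy_approaches_step(self):
        scen = synthetic.default_melt_scenario("apo", dH_vant_hoff=5000.0)
        f = thermal.two_state_fraction_unfolded(
            simulate_melt_curve(scen).temperatures, 44.5, 5000.0
        )
        assert f[0] < 1e-6 and f[-1] > 1 - 1e-6
        # transition confined to ~2 degC of the 40 degC range (0.1 degC grid)
        assert np.sum((f > 0.01) & (f < 0.99)) < 20

    def test_conditions_differ_only_by_transition(self):
        apo = simulate_melt_curve(synthetic.default_melt_scenario("apo"))
        adp = simulate_melt_curve(synthetic.default_melt_scenario("adp"))
        # identical baselines far from both transitions
        assert apo.ratio()[0] == pytest.approx(adp.ratio()[0], abs=1e-3)
        assert apo.ratio()[-1] == pytest.approx(adp.ratio()[-1], abs=1e-3)
        mid = np.argmin(np.abs(apo.temperatures - 45.3))
        assert abs(apo.ratio()[mid] - adp.ratio()[mid]) > 0.02

    def test_tm_outside_range_rejected(self):
        with pytest.raises(ValueError):
            synthetic.MeltScenario(tm_true=80.0, t_range=(25.0, 65.0))


class TestTrajectoryGenerator:
    def test_zero_sigma_static(self):
        scen = synthetic.default_trajectory_scenario(
            core_sigma=0.0, loop_sigma=0.0, n_frames=5, n_residues=20,
            loop_interval=(5, 10),
        )
        traj = simulate_trajectory(scen)
        assert np.allclose(traj.coords, traj.coords[0])

    def test_marker_displacement_construction(self):
        scen = synthetic.wing_marker_trajectory_scenario(
            seed=2, core_sigma=0.0, loop_sigma=0.0, n_frames=50
        )
        traj = simulate_trajectory(scen)
        d = np.linalg.norm(traj.coords[-1, 74] - traj.coords[0, 74])
        assert d == pytest.approx(30.0, abs=1e-9)

    def test_marker_out_of_range(self):
        with pytest.raises(ValueError):
            synthetic.TrajectoryScenario(marker_residue=500)

    def test_determinism(self):
        scen = synthetic.default_trajectory_scenario(seed=8, n_frames=4, n_residues=10,
                                                     loop_interval=(3, 6))
        a = simulate_trajectory(scen)
        b = simulate_trajectory(scen)
        assert np.array_equal(a.coords, b.coords)


class TestWriters:
    def test_fasta_roundtrip(self, tmp_path, f_promoter):
        _, seq, _ = f_promoter
        path = tmp_path / "p.fasta"
        synthetic.write_promoter_fasta(seq, path, "test_id")
        back = motifs.read_fasta(path)
        assert back == {"test_id": seq}
        # 60-column wrap
        body = path.read_text().strip().split("\n")[1:]
        assert all(len(line) <= 60 for line in body)

    def test_sensorgram_csv_roundtrip(self, tmp_path):
        curves = simulate_sensorgrams(synthetic.default_spr_scenario(seed=1))
        path = tmp_path / "spr.csv"
        synthetic.write_sensorgrams_csv(curves, path)
        back = binding.read_sensorgrams_csv(path)
        assert len(back) == len(curves)
        orig = {sg.conc: sg for sg in curves}
        for sg in back:
            assert np.allclose(sg.response, orig[sg.conc].response)
            assert sg.t_stop == orig[sg.conc].t_stop

    def test_isotherm_csv_roundtrip(self, tmp_path):
        iso = simulate_isotherm(synthetic.default_emsa_scenario(seed=2))
        path = tmp_path / "iso.csv"
        synthetic.write_isotherm_csv(iso, path)
        back = binding.read_isotherm_csv(path, probe_conc_nM=15.0)
        assert np.allclose(back.fraction_bound, iso.fraction_bound)

    def test_melt_csv_roundtrip(self, tmp_path):
        curve = simulate_melt_curve(synthetic.default_melt_scenario("adp", seed=1))
        path = tmp_path / "melt.csv"
        thermal.write_melt_csv(curve, path)
        back = thermal.read_melt_csv(path, label="adp")
        assert np.allclose(back.f350, curve.f350)

    def test_scenario_json(self, tmp_path):
        import json

        path = tmp_path / "scen.json"
        synthetic.scenario_to_json(synthetic.default_spr_scenario(seed=3), path)
        payload = json.loads(path.read_text())
        assert payload["kind"] == "SprScenario"
        assert payload["seed"] == 3
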